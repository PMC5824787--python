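"""Run the whole pipeline end-to-end on a self-generated fixture.

Equivalent to `ancestlib demo`: family simulation -> filtering -> NJ tree
-> ancestral reconstruction -> node ranking -> structural shell ->
candidate substitutions -> oligo design -> library simulation -> screen
simulation and hit calling -> kinetic round trips.  Writes a report under
./pipeline_demo/.
"""

import json

from ancestlib.pipeline import run_demo

results = run_demo("pipeline_demo", seed=0)
print(json.dumps(results, indent=2, default=str))
print("\nSee pipeline_demo/report.md for the narrative summary; each stage "
      "also writes its machine-readable output (TSV/FASTA/Newick/JSON).")
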