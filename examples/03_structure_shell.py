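"""Select diversification positions within 15 A of the catalytic residue.

Creates an ideal-helix toy structure for a 60-residue target with a
catalytic histidine at position 30, maps structure residues onto the
target by alignment, and lists every position within the distance shell.
"""

from ancestlib import (SelectionConfig, SequenceRecord,
                       map_structure_to_target, parse_structure,
                       residues_within)
from ancestlib.simulate import ToyStructureSpec, make_toy_structure

seq = "MKTAYIAKQRQISFVKSHFSRQLEERLGLHEVQAPILSRVGDGTQDNLSGAEKAVQVHHH"
spec = ToyStructureSpec(seq, geometry="helix", catalytic_position=30)
pdb_text, _ = make_toy_structure(spec)

structure = parse_structure(pdb_text, spec.chain)
target = SequenceRecord("target", seq)
mapping = map_structure_to_target(structure, target)
cfg = SelectionConfig(catalytic_position=30, catalytic_aa="H",
                      distance_cutoff_A=15.0, distance_mode="CA")
shell = residues_within(structure, mapping, 30, cfg)
print(f"{len(shell)} of 60 positions lie within {cfg.distance_cutoff_A} A "
      "of the catalytic His30:")
for pos, dist in shell[:10]:
    print(f"  position {pos:2d} ({seq[pos - 1]})  {dist:5.2f} A")
print("  ...")
print("Only these spatially proximal positions are considered for "
      "ancestral substitutions; distant positions are left wild type.")
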