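"""Filter a protein family against an engineering target.

Builds a small synthetic family, measures global-alignment identity of
every member to the target, and applies the inclusion band (keep 45-95%
identity, drop truncated sequences).
"""

from ancestlib import FilterConfig, SequenceRecord, filter_family
from ancestlib.simulate import FamilySimSpec, simulate_family

family, _, _ = simulate_family(FamilySimSpec(seed=42))
records = [family.ungapped(i) for i in family.ids]
# add a verbatim copy and a truncated fragment to show the filters firing
records.append(SequenceRecord("copy", records[0].sequence))
records.append(SequenceRecord("fragment", records[0].sequence[:20]))

kept, report = filter_family(records, family.reference_id, FilterConfig())
print(report.to_string(index=False))
print(f"\nkept {len(kept)} of {len(records)} sequences")
print("Members inside the 45-95% identity band survive; the verbatim copy "
      "(identity 1.0) and the 33%-length fragment are removed.")
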