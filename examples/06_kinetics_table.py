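"""Michaelis-Menten round trip reproducing a comparative kinetic table.

Generates noiseless initial-rate data for a wild-type enzyme and two
improved variants at E0 = 0.3 uM, fits each dataset, and prints the
percent-of-WT comparison (kcat, KM, kcat/KM).
"""

from ancestlib import comparative_table, fit_mm
from ancestlib.simulate import DEFAULT_S_GRID, simulate_mm

CONSTANTS = {  # (kcat s^-1, KM uM) per (variant, peptide)
    ("WT", "TNFa-myr"): (0.0033, 8.1),
    ("D1", "TNFa-myr"): (0.0062, 8.1),
    ("6A4", "TNFa-myr"): (0.0057, 23.7),
}

fits = {}
for key, (kcat, km) in CONSTANTS.items():
    data = simulate_mm(kcat, km, 0.3, DEFAULT_S_GRID, noise_cv=0.0, seed=0)
    fits[key] = fit_mm(data["substrate_conc_uM"], data["v_uM_per_s"],
                       e0_uM=0.3)

table = comparative_table(fits, "WT")
cols = ["variant", "kcat_fmt", "kcat_pct_wt_fmt", "km_fmt", "km_pct_wt_fmt",
        "efficiency_fmt", "efficiency_pct_wt_fmt"]
print(table[cols].to_string(index=False))
print("\nD1 improves turnover (kcat ~188% of WT) at unchanged KM, so its "
      "efficiency rises in step; 6A4's turnover gain (~172%) is offset by "
      "a ~3-fold KM increase, leaving it below WT efficiency.")
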