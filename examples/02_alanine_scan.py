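"""Alanine scan analysis: curve fits, fold changes, hotspots, restraints.

Simulates a serial-dilution ELISA panel with known Kd values (one knockout,
one strong and one mild knockdown), fits four-parameter logistic curves,
computes fold decreases vs wild type with censoring, bins them, and builds
the epitope-restraint scenarios that would guide data-driven docking.
"""

from epidock.alascan import (
    Bin,
    HotspotTable,
    build_scenarios,
    export_restraints,
    fit_4pl,
    fold_change,
)
from epidock.synthetic import make_elisa_panel

true_kds = {"WT": 0.5, "H52A": 3.5, "Y124A": 25.0, "H117A": 1e6}
curves = make_elisa_panel(true_kds, noise_sigma=0.02, seed=0)
fits = {c.mutant_id: fit_4pl(c) for c in curves}

records = {}
print("mutant   fold-decrease  bin")
for mutant in ("H52A", "Y124A", "H117A"):
    rec = fold_change(fits[mutant], fits["WT"], censor_bound=100.0)
    records[mutant] = rec
    print(f"{mutant:8s} {rec.fold_label:>12s}  {rec.bin.label}")
# expected: H52A ~7-fold (*), Y124A ~50-fold (**), H117A censored >100 (***)

table = HotspotTable(records, hotspot_threshold_bin=Bin.STAR)
print("hotspots:", [r.mutant_id for r in table.hotspots()])

scenarios = build_scenarios(
    {"D2": [("A", 52, ""), ("A", 124, "")],
     "D3": [("A", 76, ""), ("A", 117, ""), ("A", 108, "")]},
    paratope_hotspots=[("H", 33, ""), ("H", 95, ""), ("H", 98, ""),
                       ("L", 50, ""), ("L", 96, "")],
)
print(f"\n{len(scenarios)} restraint scenarios:")
for s in scenarios:
    epi = ",".join(f"{c}:{n}" for c, n, _ in s.epitope_active)
    print(f"  {s.name:10s} epitope {{{epi}}}")
    export_restraints(s, f"restraints_{s.name}.txt")
# one scenario per epitope group plus the combined set; the paratope
# restraints are held constant across scenarios
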