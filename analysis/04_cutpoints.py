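"""Cut-point selection from the relative-risk curves.

Reads the SHAP curves written by 03_rsf_shap.py, runs the two-segment
change-point detector for the repopulation-aware BED variants, and places
the no-repopulation cut-point at the matching percentile of its dose
distribution.  Compares against the manual defaults (61.8 / 57.6 / 70 Gy).
"""

import json
from pathlib import Path

import pandas as pd

from fracsurv.cohort import CohortSpec, sample_cohort
from fracsurv.cutpoints import DEFAULT_CUTPOINTS, suggest_cutpoint, transfer_cutpoint_by_percentile

ROOT = Path(__file__).resolve().parents[1] / "results"
curves = pd.read_csv(ROOT / "rsf" / "shap_curves.csv")
cohort = sample_cohort(CohortSpec(n_patients=3346, seed=0))

suggested = {}
for v in ("bed_dd", "bed_di"):
    c = curves[curves.variant == v]
    suggested[v] = suggest_cutpoint(c["value"], c["smoothed"], dose_values=cohort[v])
suggested["bed_simp"] = transfer_cutpoint_by_percentile(
    suggested["bed_dd"], cohort["bed_dd"], cohort["bed_simp"]
)

print(f"{'variant':10s} {'suggested':>10s} {'manual default':>15s}")
for v, cut in suggested.items():
    print(f"{v:10s} {cut:10.2f} {DEFAULT_CUTPOINTS[v]:15.1f}")
(ROOT / "cutpoints.json").write_text(json.dumps(suggested, indent=2) + "\n")
print(f"\nwrote {ROOT / 'cutpoints.json'}")
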