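"""Audit treatment plans against model predictions; conformity index.

A planned lung V5/V10 exceeding the model prediction by more than a margin
(default 5 percentage points) signals optimization headroom: the plan can
likely be tightened without sacrificing target coverage.  The worked case
uses the published-style values: planned V5 57.65% vs predicted 48.58%.
The conformity index CI = (V_D_PTV/V_D)·(V_D_PTV/V_PTV) summarizes how
tightly the prescribed-dose volume wraps the target (1 = perfect).
"""

from dvhpredict import PlanDoseSummary, audit, conformity_index
from dvhpredict.audit import audit_frame

plans = [
    PlanDoseSummary(case_id="case-2", v5=57.65, v10=39.87),
    PlanDoseSummary(case_id="case-9", v5=42.79, v10=31.62),
]
predictions = {
    "case-2": {"v5": 48.58, "v10": 30.81},
    "case-9": {"v5": 40.00, "v10": 30.00},
}
flags = audit(plans, predictions, margin=5.0)
print(audit_frame(flags).round(2).to_string(index=False))
print("\ncase-2 exceeds its prediction by > 5 pp on both outputs -> flagged for")
print("re-optimization; case-9 is close to its prediction -> left alone.")

ci = conformity_index(v_ptv=100.0, v_d_ptv=90.0, v_d=120.0)
print(f"\nconformity index for (V_PTV=100, V_D_PTV=90, V_D=120): {ci:.3f}")
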