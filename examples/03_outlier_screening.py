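"""Multivariate outlier screening with the Mahalanobis distance.

Screens the default 103-case synthetic cohort on its (P, L, S) features
against the 0.95 chi-square cutoff with 3 degrees of freedom (7.81).  The
seven planted outliers are removed and 96 cases remain for modeling —
mirroring the cohort reduction of the emulated study.
"""

from dvhpredict import CohortSpec, generate_cohort, mahalanobis_filter

cohort = generate_cohort(CohortSpec(seed=1))
retained, report = mahalanobis_filter(cohort, alpha=0.05)

print(f"squared-distance threshold: {report.threshold:.2f} (alpha={report.alpha})")
print(f"retained {report.retained_count} of {len(cohort)} cases")
print("removed:", ", ".join(report.removed_ids))
planted = {r.case_id for r in cohort if r.planted_outlier}
print("planted-truth recovery:", "exact" if set(report.removed_ids) == planted else "partial")
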