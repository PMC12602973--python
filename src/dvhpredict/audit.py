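"""Plan audit: flag dose-volume values with optimization headroom; conformity index.

During planning, a calculated lung dose-volume value that exceeds the
model-predicted value by more than a margin suggests the plan can still be
tightened: the audit compares planned V5/V10 (by default) against model
predictions and flags such cases.  The conformity index

    CI = (V_D_PTV / V_D) x (V_D_PTV / V_PTV)

combines target coverage and dose spill; 1 means the prescribed-dose volume
coincides exactly with the planning target volume.  Heart mean dose and
spinal-cord PRV maximum dose are carried through as report columns only.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

DEFAULT_MARGIN = 5.0  # percentage points
DEFAULT_AUDITED_OUTPUTS = ("v5", "v10")

PLAN_COLUMNS = ("case_id", "V5", "V10", "heart_dmean", "scprv_dmax", "v_ptv", "v_d_ptv", "v_d")


@dataclass(frozen=True)
class PlanDoseSummary:
    """Planned dose summary of one case (volumes in cm³, doses in Gy, Vx in %)."""

    case_id: str
    v5: float
    v10: float
    heart_dmean: float | None = None
    sc_prv_dmax: float | None = None
    v_ptv: float | None = None
    v_d_ptv: float | None = None
    v_d: float | None = None


@dataclass(frozen=True)
class AuditFlag:
    case_id: str
    output: str
    planned: float
    predicted: float
    excess: float  # planned - predicted, percentage points
    flagged: bool


def conformity_index(v_ptv: float, v_d_ptv: float, v_d: float) -> float:
    """CI = (V_D_PTV / V_D) x (V_D_PTV / V_PTV), in (0, 1]."""
    if not (v_ptv > 0 and v_d > 0):
        raise ValueError("V_PTV and V_D must be positive")
    if v_d_ptv < 0 or v_d_ptv > min(v_ptv, v_d):
        raise ValueError("V_D_PTV must lie in [0, min(V_PTV, V_D)]")
    return (v_d_ptv / v_d) * (v_d_ptv / v_ptv)


def audit(
    plans: Sequence[PlanDoseSummary],
    predictions: Mapping[str, Mapping[str, float]],
    margin: float = DEFAULT_MARGIN,
    outputs: Sequence[str] = DEFAULT_AUDITED_OUTPUTS,
) -> list[AuditFlag]:
    """Compare planned values against predictions; flag excess above ``margin``.

    ``predictions`` maps case_id to a mapping of output name ("v5", "v10", ...)
    to the model-predicted percent value.
    """
    flags: list[AuditFlag] = []
    for plan in plans:
        if plan.case_id not in predictions:
            raise KeyError(f"no model prediction available for case {plan.case_id!r}")
        pred = predictions[plan.case_id]
        for name in outputs:
            planned = getattr(plan, name)
            if name not in pred:
                raise KeyError(f"prediction for case {plan.case_id!r} lacks output {name!r}")
            excess = planned - float(pred[name])
            flags.append(
                AuditFlag(
                    case_id=plan.case_id,
                    output=name,
                    planned=float(planned),
                    predicted=float(pred[name]),
                    excess=float(excess),
                    flagged=bool(excess > margin),
                )
            )
    return flags


def read_plan_summaries(path: str | Path) -> list[PlanDoseSummary]:
    """Read plan summaries from CSV (case_id,V5,V10,heart_dmean,scprv_dmax,v_ptv,v_d_ptv,v_d)."""
    frame = pd.read_csv(path)
    missing = [c for c in ("case_id", "V5", "V10") if c not in frame.columns]
    if missing:
        raise ValueError(f"plan table is missing columns: {missing}")

    def _opt(row, col):
        return float(getattr(row, col)) if col in frame.columns else None

    return [
        PlanDoseSummary(
            case_id=str(row.case_id),
            v5=float(row.V5),
            v10=float(row.V10),
            heart_dmean=_opt(row, "heart_dmean"),
            sc_prv_dmax=_opt(row, "scprv_dmax"),
            v_ptv=_opt(row, "v_ptv"),
            v_d_ptv=_opt(row, "v_d_ptv"),
            v_d=_opt(row, "v_d"),
        )
        for row in frame.itertuples(index=False)
    ]


def audit_frame(flags: Sequence[AuditFlag]) -> pd.DataFrame:
    """Comparison table (original vs predicted vs margin status), one row per check."""
    return pd.DataFrame(
        [
            {
                "case_id": f.case_id,
                "output": f.output.upper(),
                "planned": f.planned,
                "predicted": f.predicted,
                "excess": f.excess,
                "flagged": f.flagged,
            }
            for f in flags
        ]
    )
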