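"""Curve-regression association analysis of dose-volume outputs on tumor position.

Four candidate families are fitted by ordinary least squares for each output
regressed on P — linear, quadratic, cubic and logarithmic
(y = b0 + b1·ln x) — and the best is selected on adjusted R² with a parsimony
tie-break: if a simpler family comes within 0.01 adjusted R² of the best, the
simpler family wins.  Fits are delegated to statsmodels OLS, which supplies
the coefficient t-test p-values and the overall F-test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from dvhpredict.synthetic import OUTPUT_NAMES, CaseRecord

FAMILIES = ("linear", "quadratic", "cubic", "logarithmic")

#: Total coefficient count (including intercept) per family.
_N_COEF = {"linear": 2, "quadratic": 3, "cubic": 4, "logarithmic": 2}


@dataclass
class RegressionFit:
    family: str
    coefficients: np.ndarray  # intercept first
    r2: float
    adj_r2: float
    coef_pvalues: np.ndarray
    overall_pvalue: float
    n: int

    @property
    def n_coefficients(self) -> int:
        return len(self.coefficients)

    def predict(self, x: np.ndarray) -> np.ndarray:
        return _design(np.asarray(x, dtype=float), self.family) @ self.coefficients

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "coefficients": [float(c) for c in self.coefficients],
            "r2": self.r2,
            "adj_r2": self.adj_r2,
            "coef_pvalues": [float(p) for p in self.coef_pvalues],
            "overall_pvalue": self.overall_pvalue,
            "n": self.n,
        }


def _design(x: np.ndarray, family: str) -> np.ndarray:
    if family == "linear":
        cols = [x]
    elif family == "quadratic":
        cols = [x, x**2]
    elif family == "cubic":
        cols = [x, x**2, x**3]
    elif family == "logarithmic":
        if np.any(x <= 0):
            raise ValueError("logarithmic family requires all x > 0")
        cols = [np.log(x)]
    else:
        raise ValueError(f"unknown family {family!r}; choose one of {FAMILIES}")
    return sm.add_constant(np.column_stack(cols), has_constant="add")


def fit_curve(x: Sequence[float], y: Sequence[float], family: str) -> RegressionFit:
    """OLS fit of one candidate family of y on x."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d vectors of equal length")
    design = _design(x, family)
    if len(x) <= design.shape[1]:
        raise ValueError(f"need more than {design.shape[1]} observations for {family}")
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("rank-deficient design (degenerate x values)")
    if np.ptp(y) == 0.0:
        # constant response: the intercept-only fit is exact; no variance to
        # explain, so R² is 0 and the slope terms are maximally insignificant
        coefs = np.zeros(design.shape[1])
        coefs[0] = y[0]
        pvals = np.ones(design.shape[1])
        pvals[0] = 0.0
        return RegressionFit(
            family=family,
            coefficients=coefs,
            r2=0.0,
            adj_r2=0.0,
            coef_pvalues=pvals,
            overall_pvalue=1.0,
            n=len(x),
        )
    res = sm.OLS(y, design).fit()
    return RegressionFit(
        family=family,
        coefficients=np.asarray(res.params, dtype=float),
        r2=float(res.rsquared),
        adj_r2=float(res.rsquared_adj),
        coef_pvalues=np.asarray(res.pvalues, dtype=float),
        overall_pvalue=float(res.f_pvalue) if np.isfinite(res.f_pvalue) else 1.0,
        n=int(res.nobs),
    )


#: Canonical preference order for equal-complexity ties (linear before
#: logarithmic: no transform of the regressor).
_FAMILY_ORDER = {fam: i for i, fam in enumerate(FAMILIES)}

PARSIMONY_MARGIN = 0.01


def select_model(fits: Sequence[RegressionFit]) -> RegressionFit:
    """Best adjusted R² with a parsimony tie-break.

    Among fits within 0.01 adjusted R² of the maximum, the family with the
    fewest coefficients wins; equal-complexity ties follow the canonical
    family order (linear, quadratic, cubic, logarithmic).
    """
    if len(fits) == 0:
        raise ValueError("select_model needs at least one candidate fit")
    best_adj = max(f.adj_r2 for f in fits)
    contenders = [f for f in fits if f.adj_r2 >= best_adj - PARSIMONY_MARGIN]
    return min(contenders, key=lambda f: (f.n_coefficients, _FAMILY_ORDER[f.family]))


def association_table(
    cohort: Sequence[CaseRecord], families: Sequence[str] = FAMILIES
) -> dict[str, RegressionFit]:
    """Selected curve fit of each output (V5..V30) on P over the cohort."""
    p = np.array([r.p for r in cohort], dtype=float)
    selected: dict[str, RegressionFit] = {}
    for name in OUTPUT_NAMES:
        y = np.array([getattr(r, name) for r in cohort], dtype=float)
        fits = [fit_curve(p, y, fam) for fam in families]
        selected[name] = select_model(fits)
    return selected


def association_frame(table: Mapping[str, RegressionFit]) -> pd.DataFrame:
    """Serializable summary (one row per output) of an association table."""
    rows = []
    for name, fit in table.items():
        rows.append(
            {
                "output": name.upper(),
                "family": fit.family,
                "adj_r2": fit.adj_r2,
                "r2": fit.r2,
                "overall_pvalue": fit.overall_pvalue,
                "coefficients": " ".join(f"{c:.6g}" for c in fit.coefficients),
                "coef_pvalues": " ".join(f"{p:.3g}" for p in fit.coef_pvalues),
                "n": fit.n,
            }
        )
    return pd.DataFrame(rows)
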