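"""Tumor geometry features P, L, S from raw tumor/lung measurements.

Coordinates follow the cranio-caudal "increasing downward" convention: the
superior (upper) lung edge has the smaller coordinate.  Only the part of the
PTV-C lying between the superior and inferior boundaries of the combined
both-lung structure is measured, so all lengths/volumes here are understood
as restricted to the lung bounds.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import pandas as pd

GEOMETRY_COLUMNS = ("case_id", "lung_sup", "lung_inf", "ptv_length", "ptv_volume", "ptv_center")


@dataclass(frozen=True)
class TumorLungGeometry:
    """Raw scalar measurements for one case.

    ``ptv_center`` may be either the geometric centroid or the mid-point of the
    cranio-caudal extent; both readings are accepted, the caller decides.
    """

    lung_sup: float
    lung_inf: float
    ptv_length_in_lung: float
    ptv_volume_in_lung: float
    ptv_center: float

    def lung_length(self) -> float:
        return self.lung_inf - self.lung_sup

    def validate(self) -> None:
        if not self.lung_inf > self.lung_sup:
            raise ValueError("lung_inf must exceed lung_sup (increasing-downward axis)")
        if not 0.0 < self.ptv_length_in_lung <= self.lung_length():
            raise ValueError("ptv_length_in_lung must lie in (0, lung length]")
        if not self.ptv_volume_in_lung > 0.0:
            raise ValueError("ptv_volume_in_lung must be positive")
        if not self.lung_sup <= self.ptv_center <= self.lung_inf:
            raise ValueError("ptv_center must lie within the lung bounds")


def relative_position(g: TumorLungGeometry) -> float:
    """P = (distance from PTV-C center to superior lung edge) / lung length."""
    g.validate()
    return (g.ptv_center - g.lung_sup) / g.lung_length()


def relative_length(g: TumorLungGeometry) -> float:
    """L = (PTV-C length) / (lung length), in (0, 1]."""
    g.validate()
    return g.ptv_length_in_lung / g.lung_length()


def cross_sectional_area(g: TumorLungGeometry) -> float:
    """S = (PTV-C volume) / (PTV-C length): mean axial cross-section in cm²."""
    if not g.ptv_length_in_lung > 0.0:
        raise ValueError("ptv_length_in_lung must be positive")
    return g.ptv_volume_in_lung / g.ptv_length_in_lung


def extract_features(g: TumorLungGeometry) -> tuple[float, float, float]:
    """(P, L, S) for one geometry record."""
    return (relative_position(g), relative_length(g), cross_sectional_area(g))


def geometry_from_features(
    p: float, l: float, s: float, lung_length: float = 30.0, lung_sup: float = 0.0
) -> TumorLungGeometry:
    """Construct a geometry whose features reproduce (p, l, s) exactly."""
    length = l * lung_length
    return TumorLungGeometry(
        lung_sup=lung_sup,
        lung_inf=lung_sup + lung_length,
        ptv_length_in_lung=length,
        ptv_volume_in_lung=s * length,
        ptv_center=lung_sup + p * lung_length,
    )


def features_from_csv(path: str | Path) -> pd.DataFrame:
    """Read a raw-geometry CSV and emit the features table used downstream.

    Input columns: case_id, lung_sup, lung_inf, ptv_length, ptv_volume,
    ptv_center.  Output columns: case_id, P, L, S.
    """
    frame = pd.read_csv(path)
    missing = [c for c in GEOMETRY_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"geometry table is missing columns: {missing}")
    rows = []
    for row in frame.itertuples(index=False):
        g = TumorLungGeometry(
            lung_sup=float(row.lung_sup),
            lung_inf=float(row.lung_inf),
            ptv_length_in_lung=float(row.ptv_length),
            ptv_volume_in_lung=float(row.ptv_volume),
            ptv_center=float(row.ptv_center),
        )
        rows.append((str(row.case_id), *extract_features(g)))
    return pd.DataFrame(rows, columns=["case_id", "P", "L", "S"])
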