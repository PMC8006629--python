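"""Quantitative-CT lung aeration compartments from Hounsfield-unit arrays.

Each lung region of interest (ROI) is a flat array of per-pixel X-ray
attenuation values in Hounsfield units (HU).  Pixels are binned into the four
standard aeration compartments:

=================  =================
compartment        HU bin
=================  =================
hyperinflated      [-1000, -900)
normally aerated   [-900, -500)
poorly aerated     [-500, -100)
non-aerated        [-100, 100]
=================  =================

Bins are half-open, closed on the left, with the last bin closed on both
ends; this makes boundary assignment deterministic (the conventional verbal
ranges overlap at the shared edges).  Pixels outside [-1000, 100] HU (bone,
contrast, artifact) are tracked as ``excluded`` rather than dropped, so the
five fractions always sum to one.

ROI geometry (drawing regions on axial slices) and DICOM handling are out of
scope; the module consumes flat HU arrays per (patient, field).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "HU_EDGES",
    "COMPARTMENTS",
    "CtRoi",
    "AerationFractions",
    "classify_hu",
    "quantify_roi",
    "read_rois_json",
    "quantify_rois",
]

#: Interior bin edges; full support is [-1000, 100].
HU_EDGES = (-1000.0, -900.0, -500.0, -100.0, 100.0)

COMPARTMENTS = ("hyperinflated", "normal", "poor", "non_aerated")


@dataclass(frozen=True)
class CtRoi:
    """HU sample array for one lung field of one patient."""

    patient_id: str
    field_index: int
    hu_values: np.ndarray

    def __post_init__(self) -> None:
        if not 1 <= self.field_index <= 12:
            raise ValueError(f"field_index {self.field_index} outside 1..12")
        hu = np.asarray(self.hu_values, dtype=float)
        if hu.ndim != 1:
            hu = hu.ravel()
        if hu.size == 0:
            raise ValueError(
                f"ROI ({self.patient_id!r}, field {self.field_index}) is empty"
            )
        if not np.all(np.isfinite(hu)):
            raise ValueError(
                f"ROI ({self.patient_id!r}, field {self.field_index}) "
                "contains non-finite HU values"
            )
        object.__setattr__(self, "hu_values", hu)


@dataclass(frozen=True)
class AerationFractions:
    """Pixel fractions of the four aeration compartments plus excluded pixels."""

    hyperinflated: float
    normally_aerated: float
    poorly_aerated: float
    non_aerated: float
    excluded_fraction: float

    def __post_init__(self) -> None:
        total = (
            self.hyperinflated
            + self.normally_aerated
            + self.poorly_aerated
            + self.non_aerated
            + self.excluded_fraction
        )
        if not np.isclose(total, 1.0, atol=1e-9):
            raise ValueError(f"fractions sum to {total}, expected 1")

    def as_array(self) -> np.ndarray:
        """Compartment fractions in bin order, excluded last."""
        return np.array(
            [
                self.hyperinflated,
                self.normally_aerated,
                self.poorly_aerated,
                self.non_aerated,
                self.excluded_fraction,
            ]
        )


def classify_hu(hu: float) -> str:
    """Assign one HU value to its aeration compartment (or ``excluded``)."""
    if not np.isfinite(hu):
        raise ValueError(f"non-finite HU value: {hu!r}")
    if hu < -1000.0 or hu > 100.0:
        return "excluded"
    if hu < -900.0:
        return "hyperinflated"
    if hu < -500.0:
        return "normal"
    if hu < -100.0:
        return "poor"
    return "non_aerated"


def quantify_roi(roi: CtRoi) -> AerationFractions:
    """Decompose an ROI into per-compartment pixel fractions."""
    hu = roi.hu_values
    n = hu.size
    inside = (hu >= -1000.0) & (hu <= 100.0)
    # interior edges only, so the top edge (100 HU) stays in the last bin
    idx = np.searchsorted(HU_EDGES[1:-1], hu[inside], side="right")
    counts = np.bincount(idx, minlength=4)
    return AerationFractions(
        hyperinflated=counts[0] / n,
        normally_aerated=counts[1] / n,
        poorly_aerated=counts[2] / n,
        non_aerated=counts[3] / n,
        excluded_fraction=(n - inside.sum()) / n,
    )


# ---------------------------------------------------------------------------
# tabular I/O


def read_rois_json(path) -> list[CtRoi]:
    """Read ROIs from JSON: a list of ``{patient_id, field_index, hu_values}``."""
    with open(path) as fh:
        records = json.load(fh)
    return [
        CtRoi(str(r["patient_id"]), int(r["field_index"]), np.asarray(r["hu_values"]))
        for r in records
    ]


def quantify_rois(rois: Iterable[CtRoi]) -> pd.DataFrame:
    """Quantify many ROIs into a frame, one row per (patient, field)."""
    rows = []
    for roi in rois:
        f = quantify_roi(roi)
        rows.append(
            {
                "patient_id": roi.patient_id,
                "field_index": roi.field_index,
                "f_hyper": f.hyperinflated,
                "f_normal": f.normally_aerated,
                "f_poor": f.poorly_aerated,
                "f_non": f.non_aerated,
                "f_excluded": f.excluded_fraction,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "patient_id",
            "field_index",
            "f_hyper",
            "f_normal",
            "f_poor",
            "f_non",
            "f_excluded",
        ],
    )
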