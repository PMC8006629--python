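"""Reconstruction of patient-level score multisets from printed ROC tables.

An empirical ROC table over an integer score, together with the two class
sizes, uniquely determines the per-class score multisets: between consecutive
cutoffs the drop in sensitivity (rise in specificity) times the class size is
the number of positives (negatives) holding the lower cutoff's value, and a
value absent from the cutoff column is held by no patient.  This module
inverts such tables and ships the two deterministic study fixtures:

* the 25-patient training cohort (20 non-focal / 5 focal ventral scores),
  recovered from the published training-set ROC operating points; and
* the 22-patient validation cohort (16 non-focal / 6 focal), recovered from
  the published validation confusion matrix (uniquely determined by the
  whole-percent sensitivity 94% of 16 and specificity 100% of 6), with
  within-stratum values fixed to deterministic constants close to the
  published stratum medians/IQRs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .diagnostics import NEGATIVE_LABEL, POSITIVE_LABEL

__all__ = [
    "PrintedRocRow",
    "FixtureCohort",
    "TRAINING_ROC_ROWS",
    "TRAINING_N_POS",
    "TRAINING_N_NEG",
    "invert_roc_table",
    "build_training_fixture",
    "build_validation_fixture",
]


@dataclass(frozen=True)
class PrintedRocRow:
    """One printed operating point (percent scale, as published)."""

    cutoff: int  # for the sentinel row: any value > the last regular cutoff
    sensitivity_pct: float
    specificity_pct: float
    sentinel: bool = False


#: Published training-set ventral-score operating points (sens%, spec%).
TRAINING_ROC_ROWS: tuple[PrintedRocRow, ...] = (
    PrintedRocRow(0, 100.00, 0.00),
    PrintedRocRow(1, 95.00, 40.00),
    PrintedRocRow(3, 95.00, 100.00),
    PrintedRocRow(4, 85.00, 100.00),
    PrintedRocRow(6, 75.00, 100.00),
    PrintedRocRow(7, 40.00, 100.00),
    PrintedRocRow(8, 35.00, 100.00),
    PrintedRocRow(9, 15.00, 100.00),
    PrintedRocRow(10, 0.00, 100.00, sentinel=True),
)
TRAINING_N_POS = 20  # non-focal
TRAINING_N_NEG = 5  # focal


@dataclass(frozen=True)
class FixtureCohort:
    """Per-class integer score multisets with provenance."""

    scores_nonfocal: tuple[int, ...]
    scores_focal: tuple[int, ...]
    provenance: str  # training_table, validation_results, or synthetic

    def scores_labels(self) -> tuple[np.ndarray, np.ndarray]:
        """Parallel (scores, morphology labels) arrays, non-focal first."""
        scores = np.array([*self.scores_nonfocal, *self.scores_focal], dtype=int)
        labels = np.array(
            [POSITIVE_LABEL] * len(self.scores_nonfocal)
            + [NEGATIVE_LABEL] * len(self.scores_focal),
            dtype=object,
        )
        return scores, labels

    def to_dataframe(self, score_column: str = "lus_v") -> pd.DataFrame:
        scores, labels = self.scores_labels()
        return pd.DataFrame(
            {
                "patient_id": [f"{self.provenance}_{i + 1:03d}" for i in range(scores.size)],
                score_column: scores,
                "morphology": labels,
            }
        )


def _integral(count: float, tol: float, context: str) -> int:
    rounded = round(count)
    if abs(count - rounded) > tol:
        raise ValueError(
            f"{context}: implied patient count {count:.4f} is not an integer "
            f"(tolerance {tol})"
        )
    return int(rounded)


def invert_roc_table(
    rows: Sequence[PrintedRocRow],
    n_pos: int,
    n_neg: int,
    tol: float = 0.05,
    provenance: str = "training_table",
) -> FixtureCohort:
    """Invert printed (cutoff, sens%, spec%) rows into per-class multisets.

    ``rows`` must be sorted by cutoff, start at cutoff 0 with sensitivity 100
    and specificity 0, and end with the sentinel row (sensitivity 0,
    specificity 100).  For consecutive cutoffs c_k < c_{k+1}, patients whose
    score lies in [c_k, c_{k+1}) are all placed at value c_k: a cutoff absent
    from the table means no patient held that value.  Implied non-integral
    counts are rejected, naming the offending row.
    """
    if len(rows) < 2:
        raise ValueError("need at least the cutoff-0 row and the sentinel row")
    first, last = rows[0], rows[-1]
    if first.cutoff != 0 or first.sensitivity_pct != 100.0 or first.specificity_pct != 0.0:
        raise ValueError("first row must be cutoff 0 with sensitivity 100, specificity 0")
    if not last.sentinel or last.sensitivity_pct != 0.0 or last.specificity_pct != 100.0:
        raise ValueError("last row must be the sentinel with sensitivity 0, specificity 100")
    cutoffs = [r.cutoff for r in rows]
    if cutoffs != sorted(cutoffs) or len(set(cutoffs)) != len(cutoffs):
        raise ValueError("rows must be sorted by strictly increasing cutoff")
    sens = [r.sensitivity_pct for r in rows]
    if any(a < b - 1e-9 for a, b in zip(sens, sens[1:])):
        raise ValueError("sensitivity must be non-increasing in the cutoff")

    positives: list[int] = []
    negatives: list[int] = []
    for lower, upper in zip(rows[:-1], rows[1:]):
        ctx = f"rows '>= {lower.cutoff}' -> '{'>' if upper.sentinel else '>='} {upper.cutoff}'"
        n_p = _integral(
            n_pos * (lower.sensitivity_pct - upper.sensitivity_pct) / 100.0, tol, ctx
        )
        n_n = _integral(
            n_neg * (upper.specificity_pct - lower.specificity_pct) / 100.0, tol, ctx
        )
        if n_p < 0 or n_n < 0:
            raise ValueError(f"{ctx}: negative implied count")
        positives.extend([lower.cutoff] * n_p)
        negatives.extend([lower.cutoff] * n_n)

    if len(positives) != n_pos or len(negatives) != n_neg:
        raise ValueError(
            f"reconstructed class sizes {len(positives)}/{len(negatives)} "
            f"do not match the stated {n_pos}/{n_neg}"
        )
    return FixtureCohort(
        scores_nonfocal=tuple(positives),
        scores_focal=tuple(negatives),
        provenance=provenance,
    )


def build_training_fixture() -> FixtureCohort:
    """The 25-patient training ventral-score cohort recovered from the
    published operating-point table (20 non-focal, 5 focal)."""
    return invert_roc_table(
        TRAINING_ROC_ROWS, TRAINING_N_POS, TRAINING_N_NEG, provenance="training_table"
    )


#: Deterministic validation ventral scores.  Non-focal: 15 of 16 at >= 3
#: (whole-percent sensitivity 94%), one below; stratum median 6, quartiles
#: (4, 7) under linear interpolation, matching the published 6 (4-7).
#: Focal: all 6 below 3 (specificity 100%); median 2 as published (the
#: published upper quartile of 3 is unattainable without a false positive).
_VALIDATION_NONFOCAL = (2, 3, 4, 4, 4, 5, 5, 6, 6, 6, 7, 7, 7, 8, 8, 9)
_VALIDATION_FOCAL = (1, 1, 2, 2, 2, 2)


def build_validation_fixture() -> FixtureCohort:
    """The 22-patient validation ventral-score cohort (16 non-focal, 6 focal).

    At cutoff 3 the confusion matrix is TP 15, FN 1, TN 6, FP 0 — the unique
    integer solution to the published whole-percent sensitivity (94% of 16)
    and specificity (100% of 6).
    """
    return FixtureCohort(
        scores_nonfocal=_VALIDATION_NONFOCAL,
        scores_focal=_VALIDATION_FOCAL,
        provenance="validation_results",
    )
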