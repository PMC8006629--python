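"""Semi-quantitative lung ultrasound (LUS) aeration scoring.

Twelve thoracic fields, six per hemithorax, are each assigned one of four
aeration patterns: ``N`` (normal aeration: lung sliding with A-lines or fewer
than two isolated B-lines per intercostal space), ``B1`` (moderate loss:
multiple spaced B-lines), ``B2`` (severe loss: coalescent B-lines) and ``C``
(consolidation: tissue pattern with or without air bronchograms).  Patterns
map to integer scores 0..3; the total score ranges 0..36 and regional scores
(ventral, intermediate, dorsal) each sum four fields, ranging 0..12.

Field numbering convention (fixed for file I/O; regional sums are invariant
to within-region order): fields 1-6 right hemithorax, 7-12 left, with 1-2 /
7-8 ventral, 3-4 / 9-10 intermediate and 5-6 / 11-12 dorsal.

Pattern adjudication from raw ultrasound images is upstream of this package;
inputs are pattern labels.  Missing or unscorable fields are rejected, not
imputed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "PATTERN_SCORES",
    "REGION_FIELDS",
    "LusExam",
    "LusScores",
    "score_field",
    "regional_scores",
    "classify_morphology",
    "read_exams_csv",
    "score_exams",
    "write_scores_csv",
]

#: Pattern label -> integer aeration score.
PATTERN_SCORES: dict[str, int] = {"N": 0, "B1": 1, "B2": 2, "C": 3}

#: Region -> 1-based field indices summed into the regional score.
REGION_FIELDS: dict[str, tuple[int, int, int, int]] = {
    "ventral": (1, 2, 7, 8),
    "intermediate": (3, 4, 9, 10),
    "dorsal": (5, 6, 11, 12),
}

N_FIELDS = 12

#: Smallest cutoff exceeding any attainable ventral score ("greater than max").
CUTOFF_SENTINEL_MAX = 13


def score_field(pattern: str) -> int:
    """Return the aeration score for one field pattern (N=0, B1=1, B2=2, C=3)."""
    try:
        return PATTERN_SCORES[pattern]
    except (KeyError, TypeError):
        raise ValueError(
            f"unknown aeration pattern {pattern!r}; expected one of "
            f"{sorted(PATTERN_SCORES)}"
        ) from None


@dataclass(frozen=True)
class LusExam:
    """One patient's 12-field LUS exam (pattern labels, fields 1..12)."""

    patient_id: str
    patterns: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.patterns) != N_FIELDS:
            raise ValueError(
                f"exam {self.patient_id!r}: expected {N_FIELDS} fields, "
                f"got {len(self.patterns)}"
            )
        for i, p in enumerate(self.patterns, start=1):
            if p not in PATTERN_SCORES:
                raise ValueError(
                    f"exam {self.patient_id!r}, field {i}: unknown pattern {p!r}"
                )

    def field_score(self, index: int) -> int:
        """Score of field ``index`` (1-based)."""
        if not 1 <= index <= N_FIELDS:
            raise ValueError(f"field index {index} outside 1..{N_FIELDS}")
        return PATTERN_SCORES[self.patterns[index - 1]]


@dataclass(frozen=True)
class LusScores:
    """Total and regional LUS scores for one exam."""

    total: int
    ventral: int
    intermediate: int
    dorsal: int

    def __post_init__(self) -> None:
        if self.total != self.ventral + self.intermediate + self.dorsal:
            raise ValueError("total must equal ventral + intermediate + dorsal")
        for name in ("ventral", "intermediate", "dorsal"):
            v = getattr(self, name)
            if not 0 <= v <= 12:
                raise ValueError(f"{name} score {v} outside 0..12")


def regional_scores(exam: LusExam) -> LusScores:
    """Aggregate a 12-field exam into total and regional scores.

    Ventral = fields 1, 2, 7, 8; intermediate = 3, 4, 9, 10;
    dorsal = 5, 6, 11, 12; total = all twelve.
    """
    sums = {
        region: sum(exam.field_score(i) for i in idx)
        for region, idx in REGION_FIELDS.items()
    }
    return LusScores(
        total=sum(sums.values()),
        ventral=sums["ventral"],
        intermediate=sums["intermediate"],
        dorsal=sums["dorsal"],
    )


def classify_morphology(scores: LusScores, cutoff: int) -> str:
    """Predict ARDS morphology from the ventral score at a given cutoff.

    The test is positive for non-focal morphology when ``ventral >= cutoff``.
    ``cutoff`` may range 0..13; 13 encodes "greater than any attainable
    score" (every patient predicted focal).
    """
    if not 0 <= cutoff <= CUTOFF_SENTINEL_MAX:
        raise ValueError(f"cutoff {cutoff} outside 0..{CUTOFF_SENTINEL_MAX}")
    return "non-focal" if scores.ventral >= cutoff else "focal"


# ---------------------------------------------------------------------------
# tabular I/O

FIELD_COLUMNS = [f"field_{i:02d}" for i in range(1, N_FIELDS + 1)]


def read_exams_csv(path) -> list[LusExam]:
    """Read exams from CSV with columns ``patient_id, field_01..field_12``."""
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in ["patient_id", *FIELD_COLUMNS] if c not in df.columns]
    if missing:
        raise ValueError(f"exam CSV missing columns: {missing}")
    return [
        LusExam(row["patient_id"], tuple(row[c] for c in FIELD_COLUMNS))
        for _, row in df.iterrows()
    ]


def score_exams(exams: Iterable[LusExam]) -> pd.DataFrame:
    """Score exams into a frame ``patient_id, lus_total, lus_v, lus_i, lus_d``."""
    rows = []
    for exam in exams:
        s = regional_scores(exam)
        rows.append(
            {
                "patient_id": exam.patient_id,
                "lus_total": s.total,
                "lus_v": s.ventral,
                "lus_i": s.intermediate,
                "lus_d": s.dorsal,
            }
        )
    return pd.DataFrame(
        rows, columns=["patient_id", "lus_total", "lus_v", "lus_i", "lus_d"]
    )


def write_scores_csv(exams: Sequence[LusExam], path) -> pd.DataFrame:
    """Score ``exams`` and write the scores CSV; returns the frame written."""
    df = score_exams(exams)
    df.to_csv(path, index=False)
    return df
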