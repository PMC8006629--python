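"""Two-phase study orchestration: cut-point estimation on a training cohort,
frozen-cutoff assessment on a validation cohort, and report emission.

Phase 1 computes empirical ROC tables of the total and regional LUS scores
for non-focal morphology on the training cohort and selects the Youden
cut-point of the ventral score.  Phase 2 applies that cutoff, unchanged, to
the validation cohort.  The chosen cutoff is a function of the training
cohort only (leakage guard: validation labels never influence it).

Cohorts are data frames carrying a ``morphology`` column plus either the
twelve pattern columns ``field_01..field_12`` (scored on the fly) or any
subset of the score columns ``lus_total, lus_v, lus_i, lus_d`` (the
reconstructed fixtures carry only ``lus_v``).

Quantile convention for descriptive tables: linear interpolation between
order statistics.  Group-comparison hypothesis tests are deliberately not
part of this surface; standard library routines apply directly to the
emitted tables.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .diagnostics import (
    NEGATIVE_LABEL,
    POSITIVE_LABEL,
    DiagnosticSummary,
    RocTable,
    diagnostic_summary,
    empirical_roc,
    youden_cutoff,
)
from .lus_scoring import FIELD_COLUMNS, LusExam, score_exams

__all__ = ["StudyReport", "run_study", "summarize_cohort", "write_report"]

SCORE_COLUMNS = {
    "total": "lus_total",
    "ventral": "lus_v",
    "intermediate": "lus_i",
    "dorsal": "lus_d",
}

CONVENTIONS = (
    "positive class: non-focal morphology; test positive iff score >= cutoff",
    "quantiles: linear interpolation between order statistics",
    "confidence intervals: Clopper-Pearson exact, 95%",
    "table percents: 2 decimals; likelihood ratios: 4 decimals; "
    "narrative percents: whole, round half-up",
)


def _ensure_scores(cohort: pd.DataFrame) -> pd.DataFrame:
    """Normalize a cohort frame to score columns plus morphology."""
    if "morphology" not in cohort.columns:
        raise ValueError("cohort must carry a 'morphology' column")
    bad = set(cohort["morphology"]) - {POSITIVE_LABEL, NEGATIVE_LABEL}
    if bad:
        raise ValueError(f"unknown morphology labels: {sorted(bad)}")
    if set(FIELD_COLUMNS) <= set(cohort.columns):
        exams = [
            LusExam(str(row.get("patient_id", i)), tuple(row[c] for c in FIELD_COLUMNS))
            for i, row in cohort.iterrows()
        ]
        scored = score_exams(exams)
        scored["morphology"] = cohort["morphology"].to_numpy()
        return scored
    present = [c for c in SCORE_COLUMNS.values() if c in cohort.columns]
    if not present:
        raise ValueError(
            "cohort must carry field_01..field_12 or at least one of "
            f"{sorted(SCORE_COLUMNS.values())}"
        )
    keep = ["patient_id"] if "patient_id" in cohort.columns else []
    return cohort[keep + present + ["morphology"]].copy()


def summarize_cohort(cohort: pd.DataFrame) -> pd.DataFrame:
    """Median and IQR of each available score by morphology stratum.

    Returns one row per (morphology, score) with columns ``n, median, q1,
    q3``; an empty stratum is simply absent from the table.
    """
    scores = _ensure_scores(cohort)
    rows = []
    for morph, grp in scores.groupby("morphology", sort=True):
        for region, col in SCORE_COLUMNS.items():
            if col not in grp.columns or len(grp) == 0:
                continue
            vals = grp[col].to_numpy(dtype=float)
            q1, med, q3 = np.percentile(vals, [25, 50, 75])
            rows.append(
                {
                    "morphology": morph,
                    "score": region,
                    "n": len(grp),
                    "median": med,
                    "q1": q1,
                    "q3": q3,
                }
            )
    return pd.DataFrame(rows, columns=["morphology", "score", "n", "median", "q1", "q3"])


@dataclass(frozen=True)
class StudyReport:
    """Everything the two-phase analysis produces."""

    training_summary: pd.DataFrame
    validation_summary_table: pd.DataFrame
    roc_tables: Mapping[str, RocTable]  # training-set ROC per available score
    chosen_cutoff: int
    cutoff_region: str
    validation_summary: DiagnosticSummary

    @property
    def training_aucs(self) -> dict[str, float]:
        return {region: t.auc for region, t in self.roc_tables.items()}

    @property
    def best_region_by_auc(self) -> str:
        return max(self.roc_tables, key=lambda r: self.roc_tables[r].auc)


def run_study(
    training: pd.DataFrame,
    validation: pd.DataFrame,
    cutoff_region: str = "ventral",
) -> StudyReport:
    """Run both phases and return the assembled report.

    The Youden cutoff is estimated on the training cohort's
    ``cutoff_region`` score and applied unchanged to the validation cohort.
    """
    train = _ensure_scores(training)
    valid = _ensure_scores(validation)
    cutoff_col = SCORE_COLUMNS[cutoff_region]
    for name, frame in (("training", train), ("validation", valid)):
        if cutoff_col not in frame.columns:
            raise ValueError(f"{name} cohort lacks the {cutoff_region} score")
        if len(set(frame["morphology"])) < 2:
            raise ValueError(f"{name} cohort must contain both morphology classes")

    roc_tables = {
        region: empirical_roc(train[col].to_numpy(int), train["morphology"].to_numpy())
        for region, col in SCORE_COLUMNS.items()
        if col in train.columns
    }
    cutoff = youden_cutoff(roc_tables[cutoff_region])
    summary = diagnostic_summary(
        valid[cutoff_col].to_numpy(int), valid["morphology"].to_numpy(), cutoff
    )
    return StudyReport(
        training_summary=summarize_cohort(train),
        validation_summary_table=summarize_cohort(valid),
        roc_tables=roc_tables,
        chosen_cutoff=cutoff,
        cutoff_region=cutoff_region,
        validation_summary=summary,
    )


def write_report(report: StudyReport, outdir) -> None:
    """Write table2.csv, table3_<score>.csv, summary.json and conventions.txt.

    Output is deterministic: identical reports produce byte-identical files.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    summary_tbl = pd.concat(
        [
            report.training_summary.assign(cohort="training"),
            report.validation_summary_table.assign(cohort="validation"),
        ],
        ignore_index=True,
    )
    summary_tbl.to_csv(out / "table2.csv", index=False, float_format="%.2f")
    for region, table in sorted(report.roc_tables.items()):
        table.to_dataframe(printed=True).to_csv(out / f"table3_{region}.csv", index=False)
    payload = {
        "chosen_cutoff": report.chosen_cutoff,
        "cutoff_region": report.cutoff_region,
        "training_aucs": {k: round(v, 6) for k, v in sorted(report.training_aucs.items())},
        "best_region_by_auc": report.best_region_by_auc,
        "validation": report.validation_summary.to_dict(),
    }
    (out / "summary.json").write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    (out / "conventions.txt").write_text("\n".join(CONVENTIONS) + "\n")
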