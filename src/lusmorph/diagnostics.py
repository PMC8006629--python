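"""Diagnostic-accuracy statistics: empirical ROC, Youden cut-point,
confusion-matrix summaries with exact confidence intervals, and Cohen's kappa.

Conventions, fixed throughout the package:

* The positive class is **non-focal** morphology; the test is positive when
  the score is greater than or equal to the cutoff.
* The ROC table enumerates one row per element of {0} plus every observed
  score value, plus a final "greater than max" sentinel row (sensitivity 0,
  specificity 100), the standard layout of empirical ROC tables over an
  integer-valued marker.
* AUC is the trapezoidal area over the (1 - specificity, sensitivity)
  polyline anchored at (0, 0) and (1, 1); with ties this equals the
  tie-corrected Mann-Whitney statistic.
* Binomial 95% confidence intervals use the exact Clopper-Pearson method.
* Table percentages are rendered to two decimals and likelihood ratios to
  four; narrative percentages round half-up to whole percent.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.inter_rater import cohens_kappa as _sm_cohens_kappa
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "POSITIVE_LABEL",
    "NEGATIVE_LABEL",
    "RocRow",
    "RocTable",
    "Proportion",
    "DiagnosticSummary",
    "empirical_roc",
    "youden_cutoff",
    "diagnostic_summary",
    "cohens_kappa",
    "clopper_pearson",
    "round_half_up_pct",
]

POSITIVE_LABEL = "non-focal"
NEGATIVE_LABEL = "focal"


def clopper_pearson(successes: int, trials: int, alpha: float = 0.05):
    """Exact (Clopper-Pearson) binomial confidence interval as fractions."""
    if trials <= 0:
        raise ValueError("trials must be positive")
    lo, hi = proportion_confint(successes, trials, alpha=alpha, method="beta")
    # statsmodels returns nan for the degenerate edges 0/n and n/n
    lo = 0.0 if np.isnan(lo) else float(lo)
    hi = 1.0 if np.isnan(hi) else float(hi)
    return lo, hi


def round_half_up_pct(fraction: float) -> int:
    """Render a fraction as a whole percent, rounding half away from zero."""
    return int(
        Decimal(repr(fraction * 100.0)).quantize(Decimal("1"), rounding=ROUND_HALF_UP)
    )


@dataclass(frozen=True)
class Proportion:
    """A binomial point estimate with its exact 95% CI (all fractions)."""

    successes: int
    trials: int
    estimate: float
    ci_low: float
    ci_high: float

    @classmethod
    def from_counts(cls, successes: int, trials: int) -> "Proportion":
        lo, hi = clopper_pearson(successes, trials)
        return cls(successes, trials, successes / trials, lo, hi)


@dataclass(frozen=True)
class RocRow:
    """One operating point: test positive iff score >= cutoff."""

    cutoff: int
    sentinel: bool  # True for the "greater than max score" row
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def label(self) -> str:
        return f"> {self.cutoff - 1}" if self.sentinel else f">= {self.cutoff}"

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn)

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp)

    @property
    def correctly_classified(self) -> float:
        return (self.tp + self.tn) / (self.tp + self.fp + self.tn + self.fn)

    @property
    def lr_plus(self) -> Optional[float]:
        """sens / (1 - spec); undefined (None) at specificity 1."""
        if self.specificity == 1.0:
            return None
        return self.sensitivity / (1.0 - self.specificity)

    @property
    def lr_minus(self) -> Optional[float]:
        """(1 - sens) / spec; undefined (None) at specificity 0."""
        if self.specificity == 0.0:
            return None
        return (1.0 - self.sensitivity) / self.specificity


@dataclass(frozen=True)
class RocTable:
    """Ordered empirical ROC operating points plus the trapezoidal AUC."""

    rows: tuple[RocRow, ...]
    auc: float

    def to_dataframe(self, printed: bool = False) -> pd.DataFrame:
        """Tabulate the operating points.

        With ``printed=True``, percentages are formatted to two decimals and
        likelihood ratios to four, with undefined ratios left blank.
        """
        recs = []
        for r in self.rows:
            rec = {
                "cutoff": r.label,
                "sensitivity_pct": 100.0 * r.sensitivity,
                "specificity_pct": 100.0 * r.specificity,
                "correctly_classified_pct": 100.0 * r.correctly_classified,
                "lr_plus": r.lr_plus,
                "lr_minus": r.lr_minus,
            }
            if printed:
                for k in ("sensitivity_pct", "specificity_pct", "correctly_classified_pct"):
                    rec[k] = f"{rec[k]:.2f}"
                for k in ("lr_plus", "lr_minus"):
                    rec[k] = "" if rec[k] is None else f"{rec[k]:.4f}"
            recs.append(rec)
        return pd.DataFrame(recs)


def _validate_cohort(scores, truths):
    scores = np.asarray(scores, dtype=int)
    truths = np.asarray(truths, dtype=object)
    if scores.shape != truths.shape or scores.ndim != 1:
        raise ValueError("scores and truths must be equal-length 1-d sequences")
    bad = set(truths) - {POSITIVE_LABEL, NEGATIVE_LABEL}
    if bad:
        raise ValueError(f"unknown morphology labels: {sorted(bad)}")
    if np.any(scores < 0):
        raise ValueError("scores must be non-negative integers")
    pos = scores[truths == POSITIVE_LABEL]
    neg = scores[truths == NEGATIVE_LABEL]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("cohort must contain both focal and non-focal patients")
    return pos, neg


def empirical_roc(scores: Sequence[int], truths: Sequence[str]) -> RocTable:
    """Build the empirical ROC table of an integer score for non-focal disease.

    ``truths`` holds per-patient morphology labels; the positive class is
    non-focal.  One row is produced for cutoff 0, for each observed score
    value, and for the trailing "greater than max" sentinel.
    """
    pos, neg = _validate_cohort(scores, truths)
    n_pos, n_neg = pos.size, neg.size
    observed = np.unique(np.concatenate([pos, neg]))
    cutoffs = sorted(set([0, *observed.tolist()]))
    sentinel_cutoff = int(observed.max()) + 1

    rows = []
    for c, is_sent in [*((c, False) for c in cutoffs), (sentinel_cutoff, True)]:
        tp = int((pos >= c).sum())
        fp = int((neg >= c).sum())
        rows.append(
            RocRow(cutoff=c, sentinel=is_sent, tp=tp, fp=fp, tn=n_neg - fp, fn=n_pos - tp)
        )

    fpr = np.array([1.0 - r.specificity for r in rows])
    tpr = np.array([r.sensitivity for r in rows])
    # anchor at (0,0) and (1,1); rows already include both via cutoff 0 and
    # the sentinel, sort by increasing false-positive rate for integration
    order = np.lexsort((tpr, fpr))
    auc = float(np.trapezoid(tpr[order], fpr[order]))
    return RocTable(rows=tuple(rows), auc=auc)


def youden_cutoff(roc: RocTable) -> int:
    """Cutoff maximizing Youden's J = sensitivity + specificity - 1.

    Ties are broken toward the smallest cutoff (the sentinel row, ordered
    last, can win only if it is the strict maximizer).
    """
    best_row = None
    best_j = -np.inf
    for row in roc.rows:
        j = row.sensitivity + row.specificity - 1.0
        if j > best_j + 1e-12:
            best_j = j
            best_row = row
    return best_row.cutoff


@dataclass(frozen=True)
class DiagnosticSummary:
    """Confusion counts and accuracy metrics at one frozen cutoff."""

    cutoff: int
    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: Proportion
    specificity: Proportion
    ppv: Optional[Proportion]  # None when no patient tests positive
    npv: Optional[Proportion]  # None when no patient tests negative

    def to_dict(self) -> dict:
        """JSON-friendly summary; narrative percents round half-up."""

        def prop(p: Optional[Proportion]):
            if p is None:
                return None
            return {
                "successes": p.successes,
                "trials": p.trials,
                "estimate": p.estimate,
                "ci95": [p.ci_low, p.ci_high],
                "percent": round_half_up_pct(p.estimate),
                "ci95_percent": [
                    round_half_up_pct(p.ci_low),
                    round_half_up_pct(p.ci_high),
                ],
            }

        return {
            "cutoff": self.cutoff,
            "confusion": {"tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn},
            "sensitivity": prop(self.sensitivity),
            "specificity": prop(self.specificity),
            "ppv": prop(self.ppv),
            "npv": prop(self.npv),
            "ci_method": "clopper-pearson-exact-95",
            "rounding": "percent-half-up-v1",
        }


def diagnostic_summary(
    scores: Sequence[int], truths: Sequence[str], cutoff: int
) -> DiagnosticSummary:
    """Confusion matrix and sens/spec/PPV/NPV with exact 95% CIs at ``cutoff``.

    Predictive values are computed from the cohort's own confusion matrix
    (no external prevalence adjustment); when a predicted class is empty the
    corresponding predictive value is reported as absent (None), not zero.
    """
    pos, neg = _validate_cohort(scores, truths)
    tp = int((pos >= cutoff).sum())
    fp = int((neg >= cutoff).sum())
    fn = pos.size - tp
    tn = neg.size - fp
    return DiagnosticSummary(
        cutoff=cutoff,
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
        sensitivity=Proportion.from_counts(tp, tp + fn),
        specificity=Proportion.from_counts(tn, tn + fp),
        ppv=Proportion.from_counts(tp, tp + fp) if tp + fp > 0 else None,
        npv=Proportion.from_counts(tn, tn + fn) if tn + fn > 0 else None,
    )


def cohens_kappa(ratings_a: Sequence, ratings_b: Sequence, alpha: float = 0.05):
    """Cohen's kappa between two raters with a large-sample 95% CI.

    kappa = (p_o - p_e) / (1 - p_e), with chance agreement p_e from the
    product of the marginal category frequencies.  The CI uses the
    Fleiss-Cohen-Everitt large-sample standard error.

    Returns ``(kappa, (ci_low, ci_high))``.
    """
    a = np.asarray(ratings_a, dtype=object)
    b = np.asarray(ratings_b, dtype=object)
    if a.shape != b.shape or a.ndim != 1 or a.size == 0:
        raise ValueError("ratings must be equal-length non-empty 1-d sequences")
    categories = sorted(set(a) | set(b), key=str)
    if len(categories) < 2:
        raise ValueError("need at least two observed rating categories")
    table = pd.crosstab(
        pd.Categorical(a, categories=categories),
        pd.Categorical(b, categories=categories),
        dropna=False,
    ).to_numpy()

    n = table.sum()
    p_o = np.trace(table) / n
    marg_a = table.sum(axis=1) / n
    marg_b = table.sum(axis=0) / n
    p_e = float(marg_a @ marg_b)
    if p_e == 1.0:  # all mass in one cell despite >=2 categories declared
        raise ValueError("chance agreement is 1; kappa undefined")
    kappa = (p_o - p_e) / (1.0 - p_e)

    if p_o == 1.0:
        return 1.0, (1.0, 1.0)  # degenerate: zero variance
    res = _sm_cohens_kappa(table, return_results=True)
    z = stats.norm.ppf(1.0 - alpha / 2.0)
    half = z * float(np.sqrt(res.var_kappa))
    return float(kappa), (max(kappa - half, -1.0), min(kappa + half, 1.0))
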