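"""Unit, oracle and property tests for ROC, Youden, exact CIs and kappa."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from sklearn.metrics import cohen_kappa_score, roc_auc_score

from lusmorph.diagnostics import (
    NEGATIVE_LABEL,
    POSITIVE_LABEL,
    clopper_pearson,
    cohens_kappa,
    diagnostic_summary,
    empirical_roc,
    round_half_up_pct,
    youden_cutoff,
)


def make_cohort(pos_scores, neg_scores):
    scores = np.array([*pos_scores, *neg_scores], dtype=int)
    labels = np.array(
        [POSITIVE_LABEL] * len(pos_scores) + [NEGATIVE_LABEL] * len(neg_scores),
        dtype=object,
    )
    return scores, labels


def brute_force_auc(pos_scores, neg_scores):
    """Tie-corrected Mann-Whitney pair statistic: the AUC oracle."""
    wins = 0.0
    for p in pos_scores:
        for n in neg_scores:
            if p > n:
                wins += 1.0
            elif p == n:
                wins += 0.5
    return wins / (len(pos_scores) * len(neg_scores))


# ---------------------------------------------------------------------------
# empirical ROC


def test_roc_perfect_separation_auc_one():
    scores, labels = make_cohort([1, 1, 1], [0, 0])
    assert empirical_roc(scores, labels).auc == pytest.approx(1.0)


def test_roc_uninformative_tied_scores_auc_half():
    scores, labels = make_cohort([4, 4, 4], [4, 4])
    assert empirical_roc(scores, labels).auc == pytest.approx(0.5)


def test_roc_rejects_single_class():
    scores = np.array([1, 2, 3])
    labels = np.array([POSITIVE_LABEL] * 3, dtype=object)
    with pytest.raises(ValueError, match="both"):
        empirical_roc(scores, labels)


def test_roc_anchor_rows():
    scores, labels = make_cohort([2, 5], [0, 1])
    table = empirical_roc(scores, labels)
    first, last = table.rows[0], table.rows[-1]
    assert first.cutoff == 0 and first.sensitivity == 1.0 and first.specificity == 0.0
    assert last.sentinel and last.sensitivity == 0.0 and last.specificity == 1.0


cohorts = st.tuples(
    st.lists(st.integers(0, 12), min_size=1, max_size=25),
    st.lists(st.integers(0, 12), min_size=1, max_size=25),
)


@given(cohorts)
@settings(max_examples=300, deadline=None, derandomize=True)
def test_auc_equals_mann_whitney_oracle_and_sklearn(cohort):
    pos, neg = cohort
    scores, labels = make_cohort(pos, neg)
    auc = empirical_roc(scores, labels).auc
    assert auc == pytest.approx(brute_force_auc(pos, neg), abs=1e-12)
    assert auc == pytest.approx(
        roc_auc_score((labels == POSITIVE_LABEL).astype(int), scores), abs=1e-12
    )


@given(cohorts)
@settings(max_examples=300, deadline=None, derandomize=True)
def test_roc_monotonicity_invariants(cohort):
    """Sensitivity falls and specificity rises as the cutoff increases."""
    pos, neg = cohort
    scores, labels = make_cohort(pos, neg)
    rows = empirical_roc(scores, labels).rows
    sens = [r.sensitivity for r in rows]
    spec = [r.specificity for r in rows]
    assert all(a >= b for a, b in zip(sens, sens[1:]))
    assert all(a <= b for a, b in zip(spec, spec[1:]))


def test_lr_undefined_cells():
    scores, labels = make_cohort([3, 3], [0, 0])
    rows = empirical_roc(scores, labels).rows
    assert rows[0].specificity == 0.0 and rows[0].lr_minus is None
    assert rows[-1].specificity == 1.0 and rows[-1].lr_plus is None
    printed = empirical_roc(scores, labels).to_dataframe(printed=True)
    assert printed.loc[0, "lr_minus"] == ""


# ---------------------------------------------------------------------------
# Youden cut-point


def test_youden_on_training_fixture(training_fixture):
    scores, labels = training_fixture.scores_labels()
    assert youden_cutoff(empirical_roc(scores, labels)) == 3


def test_youden_perfect_separation_smallest_winning_cutoff():
    scores, labels = make_cohort([5, 7], [1, 2])
    # smallest tabulated cutoff achieving J = 1 (cutoffs enumerate observed values)
    assert youden_cutoff(empirical_roc(scores, labels)) == 5


def test_youden_all_tied_breaks_to_zero():
    scores, labels = make_cohort([4, 4], [4, 4])
    assert youden_cutoff(empirical_roc(scores, labels)) == 0


# ---------------------------------------------------------------------------
# diagnostic summaries and exact intervals


def test_validation_summary_reproduces_published_metrics(validation_fixture):
    scores, labels = validation_fixture.scores_labels()
    d = diagnostic_summary(scores, labels, 3)
    assert (d.tp, d.fp, d.tn, d.fn) == (15, 0, 6, 1)
    assert d.npv.estimate == pytest.approx(6 / 7)
    assert round_half_up_pct(d.npv.estimate) == 86
    assert round_half_up_pct(d.sensitivity.estimate) == 94
    assert d.ppv.estimate == 1.0


def test_clopper_pearson_15_of_16_lower_bound():
    """Numerical inversion of the binomial tail reproduces the lower bound."""
    lo, hi = clopper_pearson(15, 16)
    # independent oracle: p with P[X >= 15 | n=16, p] = 0.025
    from scipy.optimize import brentq

    oracle = brentq(lambda p: stats.binom.sf(14, 16, p) - 0.025, 1e-9, 1 - 1e-9)
    assert lo == pytest.approx(oracle, abs=1e-9)
    assert lo == pytest.approx(0.6977, abs=5e-4)
    assert round_half_up_pct(lo) == 70


def test_clopper_pearson_all_successes_closed_form():
    lo, hi = clopper_pearson(6, 6)
    assert lo == pytest.approx(0.025 ** (1 / 6), abs=1e-12)
    assert round_half_up_pct(lo) == 54
    assert hi == 1.0


def test_ci_contains_point_estimate():
    for k, n in [(0, 10), (3, 10), (10, 10), (15, 16)]:
        lo, hi = clopper_pearson(k, n)
        assert lo <= k / n <= hi


def test_summary_extreme_cutoffs(validation_fixture):
    scores, labels = validation_fixture.scores_labels()
    at0 = diagnostic_summary(scores, labels, 0)
    assert at0.sensitivity.estimate == 1.0 and at0.specificity.estimate == 0.0
    assert at0.npv is None  # nobody tests negative at cutoff 0
    sentinel = int(scores.max()) + 1
    athi = diagnostic_summary(scores, labels, sentinel)
    assert athi.sensitivity.estimate == 0.0 and athi.specificity.estimate == 1.0
    assert athi.ppv is None


def test_clopper_pearson_coverage_is_conservative():
    """Coverage of the exact 95% CI stays at or above nominal in simulation."""
    rng = np.random.default_rng(20260101)
    for p in (0.1, 0.5, 0.9):
        for n in (10, 25):
            draws = rng.binomial(n, p, size=2000)
            lo = np.where(draws > 0, stats.beta.ppf(0.025, draws, n - draws + 1), 0.0)
            hi = np.where(
                draws < n, stats.beta.ppf(0.975, draws + 1, n - draws), 1.0
            )
            coverage = np.mean((lo <= p) & (p <= hi))
            assert coverage >= 0.95, (p, n, coverage)
            # the package interval matches the vectorized formula above
            k = int(draws[0])
            assert clopper_pearson(k, n) == pytest.approx((lo[0], hi[0]), abs=1e-12)


# ---------------------------------------------------------------------------
# Cohen's kappa


def test_kappa_identical_ratings_is_one():
    k, (lo, hi) = cohens_kappa(["N", "B1", "C", "N"], ["N", "B1", "C", "N"])
    assert k == 1.0 and (lo, hi) == (1.0, 1.0)


def test_kappa_independent_ratings_near_zero():
    rng = np.random.default_rng(7)
    a = rng.integers(0, 3, size=4000)
    b = rng.integers(0, 3, size=4000)
    k, (lo, hi) = cohens_kappa(a, b)
    assert abs(k) < 0.05
    assert lo < k < hi


def test_kappa_constructed_two_by_two():
    """Observed agreement 0.9 against chance 0.5 gives kappa 0.8."""
    a = ["x"] * 45 + ["y"] * 5 + ["x"] * 5 + ["y"] * 45
    b = ["x"] * 45 + ["x"] * 5 + ["y"] * 5 + ["y"] * 45
    k, (lo, hi) = cohens_kappa(a, b)
    assert k == pytest.approx(0.8)
    assert lo < 0.8 < hi
    assert k == pytest.approx(cohen_kappa_score(a, b))


def test_kappa_rejects_bad_input():
    with pytest.raises(ValueError):
        cohens_kappa(["x", "y"], ["x"])
    with pytest.raises(ValueError, match="two"):
        cohens_kappa(["x", "x"], ["x", "x"])
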