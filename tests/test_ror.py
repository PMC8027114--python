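"""ROR estimators against closed-form, grid-search and exact-tail oracles."""

from __future__ import annotations

import math
import random
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import minimize_scalar
from scipy.special import gammaln
from scipy.stats.contingency import odds_ratio as scipy_odds_ratio

from pvror import (
    AnalysisSettings,
    ContingencyTable,
    ExposureDef,
    RorEstimate,
    analyze,
    classify_signal,
    compute_ror,
    conditional_mle_or,
    continuity_correct,
    estimate_table,
    exact_ci,
    woolf_ci,
)
from pvror.ror import DegenerateTableError, UndefinedEstimateError
from tests.test_contingency import TOY

Z95 = 1.959963984540054


# --- independent oracles ----------------------------------------------------


def cond_loglik(t: ContingencyTable, log_psi: float) -> float:
    """Conditional log-likelihood of the a cell, written from scratch."""
    n, n1, m1 = int(t.n), int(t.n_exposed), int(t.n_events)
    xs = np.arange(max(0, m1 + n1 - n), min(m1, n1) + 1)
    logw = (
        gammaln(n1 + 1) - gammaln(xs + 1) - gammaln(n1 - xs + 1)
        + gammaln(n - n1 + 1) - gammaln(m1 - xs + 1) - gammaln(n - n1 - m1 + xs + 1)
        + xs * log_psi
    )
    shift = logw.max()
    a = int(t.a)
    return float(logw[xs == a][0] - shift - np.log(np.sum(np.exp(logw - shift))))


def grid_search_mle(t: ContingencyTable) -> float:
    """Maximize the conditional likelihood by dense grid plus Brent refine."""
    grid = np.linspace(np.log(1e-4), np.log(1e4), 2001)
    best = grid[np.argmax([cond_loglik(t, lp) for lp in grid])]
    res = minimize_scalar(
        lambda lp: -cond_loglik(t, lp),
        bounds=(best - 0.02, best + 0.02),
        method="bounded",
        options={"xatol": 1e-12},
    )
    return math.exp(res.x)


def tail_probs(t: ContingencyTable, psi: float) -> tuple[float, float]:
    """(P(X >= a), P(X <= a)) under psi, computed directly."""
    n, n1, m1 = int(t.n), int(t.n_exposed), int(t.n_events)
    xs = np.arange(max(0, m1 + n1 - n), min(m1, n1) + 1)
    logw = (
        gammaln(n1 + 1) - gammaln(xs + 1) - gammaln(n1 - xs + 1)
        + gammaln(n - n1 + 1) - gammaln(m1 - xs + 1) - gammaln(n - n1 - m1 + xs + 1)
        + xs * math.log(psi)
    )
    w = np.exp(logw - logw.max())
    w /= w.sum()
    a = int(t.a)
    return float(w[xs >= a].sum()), float(w[xs <= a].sum())


def random_table(rng: random.Random, max_margin: int = 40) -> ContingencyTable:
    while True:
        n1 = rng.randint(1, max_margin)
        n2 = rng.randint(1, max_margin)
        a = rng.randint(0, n1)
        c = rng.randint(0, n2)
        t = ContingencyTable(a, n1 - a, c, n2 - c)
        lo = max(0, int(t.n_events + t.n_exposed - t.n))
        hi = min(int(t.n_events), int(t.n_exposed))
        if hi > lo:
            return t


# --- point estimate ---------------------------------------------------------


class TestComputeRor:
    @pytest.mark.parametrize(
        "cells, expected",
        [((1, 1, 1, 1), 1.0), ((20, 80, 10, 90), 2.25), ((0, 10, 5, 85), 0.0)],
    )
    def test_known_values(self, cells, expected):
        assert compute_ror(ContingencyTable(*cells)) == pytest.approx(expected)

    def test_large_table_matches_rational_arithmetic(self):
        t = ContingencyTable(224, 1500, 99027, 9272485)
        exact = Fraction(224 * 9272485, 1500 * 99027)
        assert compute_ror(t) == pytest.approx(float(exact), rel=1e-14)

    @pytest.mark.parametrize("cells, cell", [((5, 0, 3, 2), "b"), ((5, 3, 0, 2), "c")])
    def test_zero_cell_error_names_cell(self, cells, cell):
        with pytest.raises(UndefinedEstimateError, match=f"cell {cell}"):
            compute_ror(ContingencyTable(*cells))

    @given(
        a=st.integers(1, 10**6), b=st.integers(1, 10**6),
        c=st.integers(1, 10**6), d=st.integers(1, 10**6),
    )
    @settings(max_examples=200, derandomize=True)
    def test_transposition_symmetry(self, a, b, c, d):
        # swapping exposure and event roles leaves the odds ratio unchanged
        t = ContingencyTable(a, b, c, d)
        swapped = ContingencyTable(a, c, b, d)
        assert compute_ror(t) == pytest.approx(compute_ror(swapped), rel=1e-12)


class TestWoolfCi:
    def test_symmetric_table(self):
        lo, hi = woolf_ci(ContingencyTable(1, 1, 1, 1), level=0.95)
        assert lo == pytest.approx(math.exp(-2 * Z95), rel=1e-9)
        assert hi == pytest.approx(math.exp(2 * Z95), rel=1e-9)

    def test_worked_example(self):
        # SE = sqrt(1/20 + 1/80 + 1/10 + 1/90) = 5/12
        lo, hi = woolf_ci(ContingencyTable(20, 80, 10, 90))
        assert lo == pytest.approx(2.25 * math.exp(-Z95 * 5 / 12), rel=1e-9)
        assert (lo, hi) == pytest.approx((0.99429, 5.09155), rel=1e-4)

    def test_zero_cell_rejected(self):
        with pytest.raises(UndefinedEstimateError):
            woolf_ci(ContingencyTable(0, 10, 5, 85))

    @given(
        a=st.integers(1, 10**5), b=st.integers(1, 10**5),
        c=st.integers(1, 10**5), d=st.integers(1, 10**5),
    )
    @settings(max_examples=200, derandomize=True)
    def test_containment_and_log_symmetry(self, a, b, c, d):
        t = ContingencyTable(a, b, c, d)
        ror = compute_ror(t)
        lo, hi = woolf_ci(t)
        assert lo <= ror <= hi
        assert lo * hi == pytest.approx(ror**2, rel=1e-9)

    def test_monotone_in_level(self):
        t = ContingencyTable(20, 80, 10, 90)
        lo90, hi90 = woolf_ci(t, 0.90)
        lo95, hi95 = woolf_ci(t, 0.95)
        assert lo95 < lo90 and hi95 > hi90


class TestContinuityCorrect:
    def test_half_added_to_all_cells(self):
        t = continuity_correct(ContingencyTable(0, 10, 5, 85))
        assert t.cells() == (0.5, 10.5, 5.5, 85.5)

    def test_identity_without_zero_cell(self):
        t = ContingencyTable(1, 2, 3, 4)
        assert continuity_correct(t) is t

    def test_corrected_table_has_finite_ror(self):
        t = continuity_correct(ContingencyTable(0, 10, 5, 85))
        assert math.isfinite(compute_ror(t))
        assert compute_ror(t) > 0


# --- exact conditional estimator --------------------------------------------


class TestConditionalMle:
    def test_symmetric_table(self):
        assert conditional_mle_or(ContingencyTable(1, 1, 1, 1)) == pytest.approx(1.0)

    def test_support_boundaries(self):
        assert conditional_mle_or(ContingencyTable(2, 0, 0, 2)) == math.inf
        assert conditional_mle_or(ContingencyTable(0, 2, 2, 0)) == 0.0

    def test_against_grid_search(self):
        t = ContingencyTable(5, 3, 2, 8)
        assert conditional_mle_or(t) == pytest.approx(grid_search_mle(t), rel=1e-6)

    def test_frozen_exact_test_values(self):
        # values from a reference exact-conditional 2x2 implementation
        assert conditional_mle_or(ContingencyTable(5, 3, 2, 8)) == pytest.approx(
            5.89913171951, rel=1e-5
        )
        assert conditional_mle_or(ContingencyTable(20, 80, 10, 90)) == pytest.approx(
            2.24103521918, rel=1e-5
        )

    def test_matches_scipy_conditional(self):
        rng = random.Random(5)
        for _ in range(25):
            t = random_table(rng)
            if t.a in (0, min(t.n_exposed, t.n_events)):
                continue
            ref = scipy_odds_ratio(
                [[int(t.a), int(t.b)], [int(t.c), int(t.d)]], kind="conditional"
            )
            assert conditional_mle_or(t) == pytest.approx(ref.statistic, rel=1e-6)

    def test_degenerate_margins_flagged(self):
        with pytest.raises(DegenerateTableError):
            conditional_mle_or(ContingencyTable(0, 0, 5, 5))

    def test_non_integer_cells_rejected(self):
        with pytest.raises(ValueError):
            conditional_mle_or(ContingencyTable(0.5, 1.5, 1.5, 1.5))


class TestExactCi:
    def test_symmetric_table_log_symmetric_about_one(self):
        lo, hi = exact_ci(ContingencyTable(1, 1, 1, 1))
        assert lo * hi == pytest.approx(1.0, rel=1e-9)

    def test_level_monotonicity(self):
        t = ContingencyTable(5, 3, 2, 8)
        intervals = [exact_ci(t, lvl) for lvl in (0.90, 0.95, 0.99)]
        for (lo1, hi1), (lo2, hi2) in zip(intervals, intervals[1:]):
            assert lo2 <= lo1 and hi2 >= hi1

    def test_bounds_invert_tail_probabilities(self):
        t = ContingencyTable(5, 3, 2, 8)
        lo, hi = exact_ci(t, 0.95)
        sf_at_lo, _ = tail_probs(t, lo)
        _, cdf_at_hi = tail_probs(t, hi)
        assert sf_at_lo == pytest.approx(0.025, abs=1e-10)
        assert cdf_at_hi == pytest.approx(0.025, abs=1e-10)

    def test_frozen_exact_test_values(self):
        # reference implementation's interval solver is looser (~0.2%)
        assert exact_ci(ContingencyTable(5, 3, 2, 8)) == pytest.approx(
            (0.57481781205, 96.8257449645), rel=5e-3
        )
        assert exact_ci(ContingencyTable(1, 1, 1, 1)) == pytest.approx(
            (0.00641299089985, 155.933481837), rel=5e-3
        )
        assert exact_ci(ContingencyTable(20, 80, 10, 90)) == pytest.approx(
            (0.93528062691, 5.69879551852), rel=5e-3
        )

    def test_contains_conditional_mle(self):
        rng = random.Random(17)
        for _ in range(25):
            t = random_table(rng)
            lo, hi = exact_ci(t)
            assert lo <= conditional_mle_or(t) <= hi

    def test_boundary_gives_one_sided_interval(self):
        lo, hi = exact_ci(ContingencyTable(2, 0, 0, 2))
        assert hi == math.inf and 0 < lo < math.inf
        lo0, hi0 = exact_ci(ContingencyTable(0, 2, 2, 0))
        assert lo0 == 0.0 and math.isfinite(hi0)


# --- classification and whole-store analysis --------------------------------


def _estimate(ror, lo, hi):
    return RorEstimate(ror=ror, ci_low=lo, ci_high=hi)


class TestClassifySignal:
    def test_lower_bound_above_one_flags(self):
        # e.g. ROR 13.3 (11.6-15.3): flagged
        assert classify_signal(_estimate(13.3, 11.6, 15.3), case_count=224)

    def test_lower_bound_below_one_does_not_flag(self):
        # e.g. ROR 1.7 (0.8-3.8): not flagged
        assert not classify_signal(_estimate(1.7, 0.8, 3.8), case_count=6)

    def test_boundary_is_strict(self):
        assert not classify_signal(_estimate(1.5, 1.0, 2.2), case_count=100)

    def test_min_cases_gate(self):
        assert not classify_signal(_estimate(5.0, 2.0, 12.0), case_count=2, min_cases=3)


class TestAnalyze:
    def test_empty_exposures_empty_result(self):
        result = analyze(TOY, [])
        assert result.results == [] and result.n == 4 and result.e == 2

    def test_symmetric_toy_store(self):
        result = analyze(TOY, [ExposureDef.single("drugX")])
        (r,) = result.results
        assert r.estimate.ror == pytest.approx(1.0)
        assert not r.signal

    def test_error_names_failing_exposure(self):
        store = [t for t in TOY if "drugY" not in t.compounds]  # drugX only
        with pytest.raises(UndefinedEstimateError, match="drugX"):
            analyze(store, [ExposureDef.single("drugX")])

    def test_exact_estimator_labels_results(self):
        result = analyze(
            TOY, [ExposureDef.single("drugX")], AnalysisSettings(estimator="exact")
        )
        assert result.results[0].estimate.estimator == "exact"

    def test_fingerprint_tracks_settings(self):
        a = AnalysisSettings(estimator="woolf").fingerprint()
        b = AnalysisSettings(estimator="exact").fingerprint()
        assert a != b
        assert a == AnalysisSettings(estimator="woolf").fingerprint()


class TestEstimateTable:
    def test_zero_cell_needs_opt_in_correction(self):
        t = ContingencyTable(0, 50, 100, 1000)
        with pytest.raises(UndefinedEstimateError):
            estimate_table(t, AnalysisSettings())
        est = estimate_table(t, AnalysisSettings(correct_zero_cells=True))
        assert est.corrected and est.ror > 0

    def test_exact_handles_boundary_without_correction(self):
        est = estimate_table(
            ContingencyTable(5, 0, 10, 100), AnalysisSettings(estimator="exact")
        )
        assert est.ror == math.inf and est.ci_high == math.inf
        assert math.isfinite(est.ci_low)

    def test_estimate_validation_rejects_inverted_interval(self):
        with pytest.raises(ValueError):
            RorEstimate(ror=2.0, ci_low=3.0, ci_high=4.0)
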