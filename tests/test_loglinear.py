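"""Log-linear estimation: design matrices, closed-form oracles, comparison."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.special import expit, gammaln

from multicrc.loglinear import (
    EstimateUnboundedError,
    ModelSpec,
    build_design_matrix,
    chao_lower_bound,
    fit_model,
    model_comparison,
    pairwise_analysis,
    profile_ci,
)
from multicrc.tables import (
    CaptureHistoryTable,
    IndividualRecords,
    ValidationError,
    aggregate_individuals,
    observable_patterns,
)


def simulate_logitnormal(rng, N, k, mu, sigma):
    eps = rng.normal(0, sigma, N) if sigma > 0 else np.zeros(N)
    p = expit(np.asarray(mu)[None, :] + eps[:, None])
    caught = rng.random((N, k)) < p
    rows = caught[caught.any(axis=1)].astype(int)
    return aggregate_individuals(IndividualRecords(k=k, rows=rows))


class TestDesignMatrix:
    def test_m0_capture_count_column(self):
        d = build_design_matrix(ModelSpec("M0"), 3)
        assert d.X.shape == (7, 2)
        assert d.X[:, 1].tolist() == [1, 1, 1, 2, 2, 2, 3]

    def test_mt_event_indicators(self):
        d = build_design_matrix(ModelSpec("Mt"), 2)
        assert d.X.shape == (3, 3)
        assert d.X[:, 1:].tolist() == [[1, 0], [0, 1], [1, 1]]

    def test_darroch_column_is_half_square(self):
        d = build_design_matrix(ModelSpec("Mth", "darroch"), 3)
        assert sorted(set(d.X[:, -1])) == [0.5, 2.0, 4.5]

    def test_heterogeneity_columns_vanish_at_zero_captures(self):
        for variant in ("poisson2", "darroch", "gamma3.5"):
            d = build_design_matrix(ModelSpec("Mh", variant), 4)
            # evaluating the fitted surface at c=0 must reduce to the intercept
            from multicrc.loglinear import _g
            assert _g(variant, np.array([0.0]))[0] == pytest.approx(0.0)

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValidationError):
            ModelSpec("Mh", "cauchy")
        with pytest.raises(ValidationError):
            ModelSpec("M0", "darroch")


class TestPetersenEquivalence:
    @given(st.integers(1, 100), st.integers(1, 100), st.integers(1, 100))
    def test_mt_two_lists_equals_petersen(self, x10, x01, x11):
        t = CaptureHistoryTable.from_counts(
            {"10": x10, "01": x01, "11": x11}, k=2)
        n1, n2, m = x10 + x11, x01 + x11, x11
        petersen = n1 * n2 / m
        fit = fit_model(t, ModelSpec("Mt"))
        assert fit.N_hat == pytest.approx(petersen, rel=1e-6)

    def test_worked_petersen(self):
        t = CaptureHistoryTable.from_counts({"11": 20, "10": 80, "01": 30}, k=2)
        fit = fit_model(t, ModelSpec("Mt"))
        assert fit.N_hat == pytest.approx(250.0, abs=1e-6)
        assert fit.ci[0] <= fit.N_hat <= fit.ci[1]

    def test_m0_symmetric_table(self):
        t = CaptureHistoryTable.from_counts({"11": 25, "10": 25, "01": 25}, k=2)
        assert fit_model(t, ModelSpec("M0")).N_hat == pytest.approx(100.0, abs=1e-6)

    def test_no_recaptures_is_unbounded(self):
        t = CaptureHistoryTable.from_counts({"10": 50, "01": 50, "11": 0}, k=2)
        with pytest.raises(EstimateUnboundedError):
            fit_model(t, ModelSpec("Mt"))


def brute_force_m0_grid(t: CaptureHistoryTable) -> tuple[float, float]:
    """Plain 2-D grid search over (N, p) for the uniform-capture model.

    Returns (argmax of the estimator's own likelihood surface, argmax of the
    exact multinomial likelihood).  The two targets differ by design: the
    log-linear fit maximises the observed-cell likelihood and extrapolates
    the empty cell, which is the conditional MLE; the full multinomial MLE
    over integer-like N sits O(1) below it, so agreement is exact-to-the-grid
    for the former and within a couple of individuals for the latter.
    """
    n, k = t.n, t.k
    caps = np.array([sum(p) for p in observable_patterns(k)])
    S = int(t.counts @ caps)
    grid_N = np.arange(n + 0.05, 4 * n, 0.05)
    grid_p = np.linspace(S / (k * 4 * n), 0.95, 4000)
    logpi_coef = caps  # captures per history

    best_cond, best_cond_val = n, -np.inf
    best_mult, best_mult_val = n, -np.inf
    for N in grid_N:
        # profile p in closed form where available, else inner grid
        # conditional/extrapolation surface: sum_h x_h log pi_h + n log N - N(1 - pi0)
        vals_cond = (S * np.log(grid_p) + (k * n - S) * np.log1p(-grid_p)
                     + n * math.log(N) - N * (1 - (1 - grid_p) ** k))
        i = int(np.argmax(vals_cond))
        if vals_cond[i] > best_cond_val:
            best_cond_val, best_cond = vals_cond[i], N
        # exact multinomial: the p-profile is closed form (p = S / (kN))
        p = S / (k * N)
        if p < 1:
            v = (gammaln(N + 1) - gammaln(N - n + 1)
                 + S * math.log(p) + (k * n - S) * math.log1p(-p)
                 + (N - n) * k * math.log1p(-p))
            if v > best_mult_val:
                best_mult_val, best_mult = v, N
    return float(best_cond), float(best_mult)


class TestBruteForceMLE:
    @pytest.mark.parametrize("counts", [
        {"100": 12, "010": 9, "001": 14, "110": 6, "101": 4, "011": 5, "111": 2},
        {"100": 30, "010": 25, "001": 20, "110": 10, "101": 8, "011": 6, "111": 3},
        {"100": 10, "010": 10, "001": 10, "110": 10, "101": 10, "011": 10,
         "111": 10},
    ])
    def test_m0_matches_grid_search(self, counts):
        t = CaptureHistoryTable.from_counts(counts, k=3)
        glm = fit_model(t, ModelSpec("M0")).N_hat
        bf_own, bf_multinomial = brute_force_m0_grid(t)
        assert glm == pytest.approx(bf_own, abs=0.5)
        assert glm == pytest.approx(bf_multinomial, abs=2.0)

    def test_mt_close_to_multinomial_grid(self):
        t = CaptureHistoryTable.from_counts(
            {"100": 15, "010": 10, "001": 8, "110": 7, "101": 5, "011": 4,
             "111": 3}, k=3)
        n = t.n
        pats = np.array(observable_patterns(3))
        n_j = pats.T @ t.counts

        def ll(N):
            p = n_j / N
            logpi = pats @ np.log(p) + (1 - pats) @ np.log1p(-p)
            return (gammaln(N + 1) - gammaln(N - n + 1)
                    + float(t.counts @ logpi) + (N - n) * float(np.log1p(-p).sum()))

        grid = np.arange(n + 0.1, 4 * n, 0.05)
        bf = grid[np.argmax([ll(N) for N in grid])]
        assert fit_model(t, ModelSpec("Mt")).N_hat == pytest.approx(bf, abs=2.5)


class TestChao:
    def test_no_doubletons_uses_bias_corrected_form(self, worked_history):
        fit = chao_lower_bound(worked_history)
        assert fit.N_hat == 120 + 110 * 109 / 2  # 6115
        assert fit.is_lower_bound

    def test_closed_form_with_doubletons(self):
        # n=100, f1=10, f2=5 -> 100 + 100/10 = 110
        counts = {"100": 4, "010": 3, "001": 3, "110": 2, "101": 2, "011": 1,
                  "111": 85}
        t = CaptureHistoryTable.from_counts(counts, k=3)
        fit = chao_lower_bound(t)
        assert fit.N_hat == pytest.approx(110.0)
        assert fit.se > 0

    def test_all_recaptured_bound_equals_n(self):
        t = CaptureHistoryTable.from_counts({"110": 5, "011": 3, "111": 2}, k=3)
        fit = chao_lower_bound(t)
        assert fit.N_hat == t.n
        assert fit.warnings

    def test_loglinear_chao_variant_agrees_with_moment_bound(self, rng):
        for _ in range(5):
            t = simulate_logitnormal(rng, 1500, 4, [-1.5, -1.2, -1.0, -1.4], 0.7)
            moment = chao_lower_bound(t).N_hat
            glm = fit_model(t, ModelSpec("Mh", "chao")).N_hat
            assert glm == pytest.approx(moment, abs=0.5)


class TestNormalVariant:
    def test_recovers_heterogeneous_population(self, rng):
        t = simulate_logitnormal(rng, 5000, 3, [-1.0, -1.3, -1.1], 0.5)
        fit = fit_model(t, ModelSpec("Mth", "normal"))
        assert abs(fit.N_hat - 5000) / 5000 < 0.15
        assert fit.ci[0] <= fit.N_hat <= fit.ci[1]
        assert fit.se > 0

    def test_collapses_to_mt_on_homogeneous_data(self, rng):
        t = simulate_logitnormal(rng, 3000, 3, [-1.0, -1.0, -1.0], 0.0)
        mt = fit_model(t, ModelSpec("Mt"))
        mthn = fit_model(t, ModelSpec("Mth", "normal"))
        assert mthn.N_hat == pytest.approx(mt.N_hat, rel=0.05)


class TestModelComparison:
    def test_two_events_exclude_heterogeneous_models(self):
        t = CaptureHistoryTable.from_counts({"11": 20, "10": 80, "01": 30}, k=2)
        labels = [r.spec.model_class for r in model_comparison(t)]
        assert sorted(labels) == ["M0", "Mt"]

    def test_every_estimate_at_least_n(self, rng):
        t = simulate_logitnormal(rng, 800, 3, [-1.0, -0.8, -1.2], 0.4)
        for row in model_comparison(t):
            if row.fit is not None:
                assert row.fit.N_hat >= t.n

    def test_mt_data_prefers_mt_by_mean_aic(self, rng):
        wins = 0
        reps = 150
        for _ in range(reps):
            t = simulate_logitnormal(rng, 2000, 3,
                                     [math.log(0.2 / 0.8), math.log(0.3 / 0.7),
                                      math.log(0.25 / 0.75)], 0.0)
            aic = {s: fit_model(t, ModelSpec(s)).aic for s in ("M0", "Mt")}
            wins += aic["Mt"] < aic["M0"]
        assert wins / reps > 0.9

    def test_darroch_and_gamma_correct_upward_of_poisson2(self, rng):
        # on heterogeneous data the Darroch and especially Gamma columns
        # produce larger corrections than Poisson2, as a statistical tendency
        darroch_ge, gamma_ge, reps = 0, 0, 40
        for _ in range(reps):
            t = simulate_logitnormal(rng, 1500, 4, [-1.6, -1.3, -1.5, -1.4], 0.8)
            est = {v: fit_model(t, ModelSpec("Mh", v)).N_hat
                   for v in ("poisson2", "darroch", "gamma3.5")}
            darroch_ge += est["darroch"] >= est["poisson2"]
            gamma_ge += est["gamma3.5"] >= est["poisson2"]
        assert darroch_ge / reps >= 0.9
        assert gamma_ge / reps >= 0.9

    def test_failed_fits_are_flagged_rows(self):
        t = CaptureHistoryTable.from_counts({"10": 50, "01": 50}, k=2)
        rows = model_comparison(t)
        assert all(r.fit is None and r.error for r in rows)


class TestM0Recovery:
    def test_median_relative_bias_small(self, rng):
        errs = []
        for _ in range(500):
            t = simulate_logitnormal(rng, 1000, 3, [math.log(0.3 / 0.7)] * 3, 0.0)
            errs.append(fit_model(t, ModelSpec("M0")).N_hat / 1000 - 1)
        assert abs(np.median(errs)) < 0.02


class TestPairwise:
    def test_chapman_worked_values(self):
        t = CaptureHistoryTable.from_counts({"10": 80, "01": 30, "11": 20}, k=2)
        row = pairwise_analysis(t)[0]
        assert (row.n_a, row.n_b, row.m) == (100, 50, 20)
        assert row.N_hat == pytest.approx(101 * 51 / 21 - 1)  # ~244.29

    def test_perfect_overlap(self):
        t = CaptureHistoryTable.from_counts({"11": 50}, k=2)
        row = pairwise_analysis(t)[0]
        assert row.N_hat == pytest.approx(50.0)
        assert row.se == 0

    def test_three_events_give_three_labelled_pairs(self, worked_history):
        rows = pairwise_analysis(worked_history)
        assert [r.label for r in rows] == ["pa12", "pa13", "pa23"]

    def test_no_overlap_flagged_and_floored(self):
        t = CaptureHistoryTable.from_counts({"100": 10, "010": 10, "001": 5}, k=3)
        for row in pairwise_analysis(t):
            assert row.flag
            assert row.ci[0] >= row.n_a + row.n_b - row.m

    @given(st.integers(0, 2 ** 31 - 1))
    def test_overlap_and_floor_invariants(self, seed):
        from conftest import random_table
        t = random_table(np.random.default_rng(seed), 3)
        for row in pairwise_analysis(t):
            assert row.m <= min(row.n_a, row.n_b)
            assert row.N_hat >= row.n_a + row.n_b - row.m - 1e-9


class TestProfileCI:
    def test_contains_estimate_and_brackets_wald(self, rng):
        t = simulate_logitnormal(rng, 1200, 3, [-1.2, -1.0, -1.1], 0.0)
        fit = fit_model(t, ModelSpec("Mt"))
        lo, hi = profile_ci(t, ModelSpec("Mt"))
        assert lo < fit.N_hat < hi
        # roughly comparable to the Wald interval on well-behaved data
        assert lo == pytest.approx(fit.ci[0], rel=0.1)
        assert hi == pytest.approx(fit.ci[1], rel=0.1)
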