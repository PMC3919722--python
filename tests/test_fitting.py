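"""Hill-model count-likelihood fitting, bootstrap, LOOCV, individual fits."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import evacdyn as e
from evacdyn.fitting import _hill


def cells_from_model(rate_fn, qs, n_per_cell, extra_cols=None):
    """Noiseless cells: event counts are expectations rounded to integers."""
    rows = []
    for q in qs:
        r = rate_fn(q)
        row = {"q": q, "n": n_per_cell, "m": int(round(r * n_per_cell))}
        row.update(extra_cols or {})
        rows.append(row)
    return pd.DataFrame(rows)


class TestHillRate:
    def test_half_maximum_at_threshold(self):
        p = e.HillParams(r_max=0.4, theta=0.65, h=7.0)
        assert e.hill_rate(0.65, p) == pytest.approx(0.2, rel=1e-12)

    def test_zero_likelihood_gives_zero_rate(self):
        p = e.HillParams(r_max=0.4, theta=0.65, h=7.0)
        assert e.hill_rate(0.0, p) == 0.0

    def test_saturation_value(self):
        p = e.HillParams(r_max=0.37, theta=0.70, h=9.3)
        assert e.hill_rate(1.0, p) == pytest.approx(0.357, abs=5e-4)

    def test_rejects_out_of_range_likelihood(self):
        p = e.HillParams(r_max=0.4, theta=0.65, h=7.0)
        with pytest.raises(ValueError):
            e.hill_rate(1.2, p)

    @given(
        st.floats(0.01, 1.0),
        st.floats(0.05, 0.95),
        st.floats(0.5, 30.0),
    )
    @settings(derandomize=True, max_examples=100)
    def test_monotone_nondecreasing_in_q(self, r_max, theta, h):
        p = e.HillParams(r_max=r_max, theta=theta, h=h)
        qs = np.linspace(0, 1, 50)
        rates = e.hill_rate(qs, p)
        assert np.all(np.diff(rates) >= -1e-12)
        assert e.hill_rate(theta, p) == pytest.approx(r_max / 2, rel=1e-9)


class TestCountLogLikelihood:
    def test_scalar_rate_maximized_at_event_fraction(self):
        m, n = 13.0, 40.0
        grid = np.linspace(0.01, 0.99, 981)
        ll = [e.count_log_likelihood([r], [m], [n]) for r in grid]
        assert grid[int(np.argmax(ll))] == pytest.approx(m / n, abs=2e-3)

    def test_additive_over_duplicated_cells(self):
        single = e.count_log_likelihood([0.2], [5], [30])
        double = e.count_log_likelihood([0.2, 0.2], [5, 5], [30, 30])
        assert double == pytest.approx(2 * single, rel=1e-12)

    def test_zero_exposure_cells_rejected(self):
        with pytest.raises(ValueError):
            e.count_log_likelihood([0.2, 0.3], [0, 1], [0, 4])


class TestFitHill:
    def test_recovers_noiseless_counts(self):
        truth = e.HillParams(r_max=0.35, theta=0.6, h=6.0)
        cells = cells_from_model(lambda q: e.hill_rate(q, truth), e.DISPLAY_LEVELS, 10**7)
        fit = e.fit_hill(cells)
        assert fit.params.r_max == pytest.approx(truth.r_max, abs=1e-3)
        assert fit.params.theta == pytest.approx(truth.theta, abs=1e-3)
        assert fit.params.h == pytest.approx(truth.h, rel=5e-3)

    def test_all_zero_events_flagged_degenerate(self):
        cells = pd.DataFrame({"q": list(e.DISPLAY_LEVELS), "m": 0, "n": 500})
        fit = e.fit_hill(cells)
        assert fit.degenerate

    def test_pooled_threshold_between_capacity_extremes(self):
        """A by-q fit on single-regime data mixing capacity levels lands
        between the B=10 and B=50 thresholds of the generating model
        (pooling over time windows would additionally confound r_max)."""
        pool = e.default_trajectory_pool(seed=81)
        design = e.make_design(
            n_runs=40,
            regimes=(e.Regime.CERTAIN_TIME,),
            trajectory_pool=pool,
            seed=81,
        )
        logs, _ = e.generate_experiment(design, e.DEFAULT_POPULATION_MODEL, rng_seed=81)
        cells = e.aggregate_counts(e.build_indicators(logs), "by_q")
        fit = e.fit_hill(cells)
        model = e.DEFAULT_POPULATION_MODEL
        assert model.theta(10) - 0.03 < fit.params.theta < model.theta(50) + 0.03

    def test_too_few_cells_rejected(self):
        cells = pd.DataFrame({"q": [0.1, 0.2], "m": [1, 2], "n": [10, 10]})
        with pytest.raises(ValueError):
            e.fit_hill(cells)


class TestFitCapacityModel:
    @staticmethod
    def _capacity_cells(theta0, c, r_max=0.3, h=6.0, n_per_cell=10**7):
        frames = []
        for B in (10, 20, 30, 40, 50):
            rate_fn = lambda q: _hill(q, r_max, theta0 + c * B, h)
            frames.append(cells_from_model(rate_fn, e.DISPLAY_LEVELS, n_per_cell, {"B": B}))
        return pd.concat(frames, ignore_index=True)

    def test_recovers_noiseless_counts(self):
        cells = self._capacity_cells(theta0=0.6, c=0.002)
        fit = e.fit_capacity_model(cells)
        assert fit.params["theta0"] == pytest.approx(0.6, abs=1e-3)
        assert fit.params["c"] == pytest.approx(0.002, abs=1e-4)
        assert fit.params["r_max"] == pytest.approx(0.3, abs=1e-3)

    def test_positive_slope_orders_thresholds(self, small_panel):
        cells = e.aggregate_counts(small_panel, "by_q_B")
        fit = e.fit_capacity_model(cells)
        theta = lambda B: fit.params["theta0"] + fit.params["c"] * B
        assert theta(10) < theta(50)

    def test_single_capacity_level_redirects_to_hill(self):
        cells = self._capacity_cells(theta0=0.6, c=0.0).query("B == 30")
        with pytest.raises(ValueError, match="fit_hill"):
            e.fit_capacity_model(cells)


class TestFitSixParam:
    def test_recovers_window_rate_ordering(self, small_panel):
        cells = e.aggregate_counts(small_panel, "by_q_B_T")
        fit = e.fit_six_param(cells)
        p = fit.params
        assert p.r_t2 > p.r_t3 > p.r_t1

    def test_missing_window_rejected(self, small_panel):
        cells = e.aggregate_counts(small_panel, "by_q_B_T")
        with pytest.raises(ValueError):
            e.fit_six_param(cells[cells["T"] != 2])

    def test_nesting_inequalities(self, small_panel):
        """More flexible models attain no worse a maximum likelihood,
        evaluated on the finest partition."""
        fine = e.aggregate_counts(small_panel, "by_q_B_T")
        obs = fine[~fine["unobserved"]]
        q, B, T = obs["q"].to_numpy(), obs["B"].to_numpy(), obs["T"].to_numpy()
        m, n = obs["m"].to_numpy(), obs["n"].to_numpy()

        hill = e.fit_hill(e.aggregate_counts(small_panel, "by_q")).params
        cap = e.fit_capacity_model(e.aggregate_counts(small_panel, "by_q_B")).params
        six = e.fit_six_param(fine).params

        ll_hill = e.count_log_likelihood(e.hill_rate(q, hill), m, n)
        ll_cap = e.count_log_likelihood(
            _hill(q, cap["r_max"], cap["theta0"] + cap["c"] * B, cap["h"]), m, n
        )
        ll_six = e.count_log_likelihood(
            np.array([six.rate(qi, Bi, Ti) for qi, Bi, Ti in zip(q, B, T)]), m, n
        )
        assert ll_six >= ll_cap - 1e-6
        assert ll_cap >= ll_hill - 1e-6

    def test_argmax_invariant_under_cell_duplication(self, small_panel):
        cells = e.aggregate_counts(small_panel, "by_q_B_T")
        doubled = pd.concat([cells, cells], ignore_index=True)
        a = e.fit_six_param(cells).params
        b = e.fit_six_param(doubled).params
        for name in ("h", "r_t1", "r_t2", "r_t3", "theta0", "c"):
            assert getattr(a, name) == pytest.approx(getattr(b, name), rel=1e-4, abs=1e-6)


class TestBootstrap:
    def test_identical_logs_give_zero_sd(self, small_experiment):
        _, logs, _ = small_experiment
        sds, reps = e.bootstrap_params([logs[0]], e.fit_hill, n_boot=4, rng_seed=0)
        assert len(reps) == 4
        assert sds["r_max"] == pytest.approx(0.0, abs=1e-9)

    def test_seeded_twice_identical(self, small_experiment):
        _, logs, _ = small_experiment
        a, _ = e.bootstrap_params(logs[:10], e.fit_hill, n_boot=5, rng_seed=3)
        b, _ = e.bootstrap_params(logs[:10], e.fit_hill, n_boot=5, rng_seed=3)
        assert a == b

    def test_sd_shrinks_with_more_runs(self):
        """Bootstrap SDs scale roughly like 1/sqrt(number of runs) on
        well-specified (single-regime) data: quadrupling the run count
        should halve the SDs, within a factor of two."""
        pool = e.default_trajectory_pool(seed=31)
        kw = dict(regimes=(e.Regime.CERTAIN_TIME,), trajectory_pool=pool, seed=31)
        small = e.make_design(n_runs=20, **kw)
        big = e.make_design(n_runs=80, **kw)
        logs_small, _ = e.generate_experiment(small, e.DEFAULT_POPULATION_MODEL, rng_seed=31)
        logs_big, _ = e.generate_experiment(big, e.DEFAULT_POPULATION_MODEL, rng_seed=31)
        sd_small, _ = e.bootstrap_params(logs_small, e.fit_hill, n_boot=16, rng_seed=5)
        sd_big, _ = e.bootstrap_params(logs_big, e.fit_hill, n_boot=16, rng_seed=5)
        for name in ("r_max", "theta", "h"):
            assert 1.0 <= sd_small[name] / sd_big[name] <= 4.0, name

    def test_rejects_tiny_bootstrap(self, small_experiment):
        _, logs, _ = small_experiment
        with pytest.raises(ValueError):
            e.bootstrap_params(logs, n_boot=1)


class TestLoocv:
    def test_two_run_folds_train_on_single_run(self, small_experiment):
        _, logs, _ = small_experiment
        curves = e.loocv(logs[:2], e.fit_hill, scheme="by_q")
        assert set(curves["run_id"]) == {logs[0].run_id, logs[1].run_id}
        assert {"observed", "full_model", "heldout"} <= set(curves.columns)

    def test_single_run_rejected(self, small_experiment):
        _, logs, _ = small_experiment
        with pytest.raises(ValueError):
            e.loocv(logs[:1])


class _HeterogeneousModel:
    """Per-agent Hill laws sharing theta and h (testing aid)."""

    def __init__(self, r_max_values, theta=0.6, h=6.0):
        self.r_max = np.asarray(r_max_values)
        self.theta, self.h = theta, h

    def rate(self, q, capacity=None, window=None):
        return _hill(q, self.r_max, self.theta, self.h)


@pytest.fixture(scope="module")
def hetero_logs():
    truth = np.linspace(0.05, 0.6, 50)
    pool = e.default_trajectory_pool(seed=41)
    design = e.make_design(n_runs=60, trajectory_pool=pool, seed=41)
    logs, _ = e.generate_experiment(design, _HeterogeneousModel(truth), rng_seed=41)
    return truth, logs


class TestIndividualFits:
    def test_recovers_rate_heterogeneity_rank(self, hetero_logs):
        truth, logs = hetero_logs
        fits = e.fit_individuals(logs)
        ok = ~fits["degenerate"]
        rho, _ = stats.spearmanr(truth[fits.index[ok]], fits.loc[ok, "r_max"])
        assert ok.sum() >= 30
        assert rho > 0.5

    def test_never_evacuating_agent_flagged(self, small_experiment):
        _, logs, _ = small_experiment
        frozen = []
        for log in logs[:10]:
            log2 = e.RunLog(**{**log.__dict__})
            log2.evac_time = log.evac_time.copy()
            log2.bed_index = log.bed_index.copy()
            log2.evac_time[0] = -1
            log2.bed_index[0] = -1
            # renumber remaining beds to stay contiguous
            beds = log2.bed_index[log2.bed_index >= 0]
            order = np.argsort(beds)
            idx = np.nonzero(log2.bed_index >= 0)[0][order]
            log2.bed_index[idx] = np.arange(len(idx))
            frozen.append(log2)
        fits = e.fit_individuals(frozen)
        assert bool(fits.loc[0, "degenerate"])

    def test_score_correlations_report_shape(self, hetero_logs):
        truth, logs = hetero_logs
        fits = e.fit_individuals(logs)
        scores = np.sum([e.score_run(log) for log in logs], axis=0)
        corr = e.score_parameter_correlations(fits, scores)
        assert list(corr.index) == ["r_max", "theta", "h"]
        assert np.isfinite(corr.loc["r_max", "pearson_r"])
        assert 0 <= corr.loc["r_max", "p_value"] <= 1
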