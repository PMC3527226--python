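"""Profile-likelihood machinery: chi-square thresholds, closed-form CI
agreement, nonidentifiability classification, profile correlations, bands."""

import numpy as np
import pytest

from stat1ple import TimeSeriesDataset
from stat1ple.fitting import FitProblem, FitSettings, ParameterSpec, fit
from stat1ple.profiles import (
    LikelihoodProfile,
    ProfileOptions,
    ThresholdSpec,
    ci_threshold,
    classify,
    profile,
    profile_correlation,
    trajectory_band,
)

from conftest import line_problem, make_records

TH95 = ThresholdSpec(0.95, 1)


def fitted_line(seed=3, n=5, sigma=0.5, a_true=2.0):
    t = np.arange(1.0, n + 1)
    rng = np.random.default_rng(seed)
    y = a_true * t + rng.normal(0, sigma, n)
    problem = line_problem(t, y, sigma)
    res = fit(problem, FitSettings(restarts=2, seed=0, anneal_steps=40))
    se = sigma / np.sqrt((t**2).sum())
    return problem, res, se


def product_problem():
    records = make_records(np.arange(1.0, 7.0), 4.0, 0.5)
    data = TimeSeriesDataset(records)

    def predict(params, d):
        return params["p1"] * params["p2"] * np.ones(len(d.records))

    specs = [
        ParameterSpec("p1", 3.0, 1e-2, 1e2),
        ParameterSpec("p2", 1.0, 1e-6, 1e6),
    ]
    problem = FitProblem(predict, data, specs)
    res = fit(problem, FitSettings(restarts=3, seed=0, anneal_steps=50))
    return problem, res


class TestThreshold:
    @pytest.mark.parametrize(
        "alpha,df,expected,tol",
        [
            (0.6827, 1, 1.000, 0.001),
            (0.95, 1, 3.841, 0.001),
            (0.95, 20, 31.410, 0.01),
        ],
    )
    def test_quantiles(self, alpha, df, expected, tol):
        assert ci_threshold(ThresholdSpec(alpha, df)) == pytest.approx(
            expected, abs=tol
        )

    def test_rejects_bad_alpha_and_df(self):
        with pytest.raises(ValueError):
            ThresholdSpec(1.2, 1)
        with pytest.raises(ValueError):
            ThresholdSpec(0.5, 0)


class TestLinearGaussianProfile:
    def test_ci_matches_closed_form(self):
        problem, res, se = fitted_line()
        prof = profile("a", res, problem, [TH95], FitSettings(seed=1))
        a_hat = res.theta_hat["a"]
        half = np.sqrt(ci_threshold(TH95)) * se
        ci = prof.ci[TH95.key]
        assert prof.status == "identifiable"
        assert ci["lower"] == pytest.approx(a_hat - half, abs=0.01 * se)
        assert ci["upper"] == pytest.approx(a_hat + half, abs=0.01 * se)
        assert ci["lower"] < prof.optimum_value < ci["upper"]

    def test_delta_chi2_zero_at_optimum(self):
        problem, res, _ = fitted_line()
        prof = profile("a", res, problem, [TH95], FitSettings(seed=1))
        assert prof.delta_chi2[prof.optimum_index] == pytest.approx(0.0, abs=1e-9)
        assert prof.delta_chi2.min() >= -1e-3  # never below re-anchor tolerance

    def test_repeat_runs_identical(self):
        problem, res, _ = fitted_line()
        p1 = profile("a", res, problem, [TH95], FitSettings(seed=1))
        p2 = profile("a", res, problem, [TH95], FitSettings(seed=2))
        np.testing.assert_allclose(p1.grid, p2.grid)
        np.testing.assert_allclose(p1.delta_chi2, p2.delta_chi2, atol=1e-9)

    def test_pointwise_nested_in_simultaneous(self):
        # same data, two free parameters: slope and intercept-like coefficient
        t = np.arange(1.0, 9.0)
        rng = np.random.default_rng(6)
        y = 1.0 + 2.0 * t + rng.normal(0, 0.4, t.size)
        records = make_records(t, y, 0.4)
        data = TimeSeriesDataset(records)

        def predict(params, d):
            tt = d.records["time_min"].to_numpy()
            return params["c0"] + params["c1"] * tt

        specs = [
            ParameterSpec("c0", 0.5, -20.0, 20.0, log10=False),
            ParameterSpec("c1", 0.5, -20.0, 20.0, log10=False),
        ]
        problem = FitProblem(predict, data, specs)
        res = fit(problem, FitSettings(restarts=3, seed=2, anneal_steps=40))
        point, simult = ThresholdSpec(0.95, 1), ThresholdSpec(0.95, 2)
        for name in ("c0", "c1"):
            prof = profile(name, res, problem, [point, simult], FitSettings(seed=1))
            ci_p, ci_s = prof.ci[point.key], prof.ci[simult.key]
            assert ci_s["lower"] <= ci_p["lower"]
            assert ci_p["upper"] <= ci_s["upper"]

    def test_profiling_fixed_parameter_rejected(self):
        problem, res, _ = fitted_line()
        with pytest.raises(ValueError, match="fixed or unknown"):
            profile("sigma", res, problem, [TH95])


class TestNonidentifiability:
    def test_product_model_is_structural_with_inverse_correlation(self):
        problem, res = product_problem()
        prof = profile("p1", res, problem, [TH95], FitSettings(seed=1))
        assert prof.status == "structurally_nonidentifiable"
        # flat over the parameter's entire 4-decade box
        assert np.all(prof.delta_chi2 <= 0.01 * ci_threshold(TH95))
        assert np.log10(prof.grid[-1] / prof.grid[0]) == pytest.approx(4.0, abs=0.1)
        corr = profile_correlation(prof, "p2", ci_threshold(TH95))
        assert corr["slope"] == pytest.approx(-1.0, abs=0.02)
        products = np.array([c["p1"] * c["p2"] for c in prof.cofits])
        assert np.ptp(products) / products.mean() < 0.02

    def test_one_sided_rise_is_practical(self):
        # synthetic profile: rises through the threshold on the left,
        # flat to the right (range exhausted)
        grid = np.logspace(-2, 2, 41)
        delta = np.where(grid < 0.1, 10 * (np.log10(0.1 / grid)) ** 2, 0.0)
        prof = LikelihoodProfile(
            parameter_id="k",
            grid=grid,
            delta_chi2=delta,
            cofits=[{"k": g} for g in grid],
            optimum_value=1.0,
            optimum_index=30,
            chi2_hat=5.0,
            theta_hat={"k": 1.0},
            log10=True,
            termination={"lower": "threshold", "upper": "bound"},
        )
        status = classify(prof, ci_threshold(TH95))
        assert status == "practically_nonidentifiable"
        ci = prof.ci  # bounds extracted separately
        from stat1ple.profiles import _extract_ci

        bounds = _extract_ci(prof, ci_threshold(TH95))
        assert not bounds["lower_unbounded"]
        assert bounds["upper_unbounded"]

    def test_numeric_failure_is_indeterminate(self):
        grid = np.logspace(-1, 1, 11)
        prof = LikelihoodProfile(
            parameter_id="k",
            grid=grid,
            delta_chi2=np.zeros(11),
            cofits=[{"k": g} for g in grid],
            optimum_value=1.0,
            optimum_index=5,
            chi2_hat=1.0,
            theta_hat={"k": 1.0},
            log10=True,
            termination={"lower": "failure", "upper": "bound"},
        )
        assert classify(prof, ci_threshold(TH95)) == "indeterminate"

    def test_correlation_of_decoupled_parameters_is_flat(self):
        # two parameters fitting disjoint observables: profiling one leaves
        # the co-fitted other at its own optimum
        t = np.arange(1.0, 7.0)
        rng = np.random.default_rng(1)
        rec_a = make_records(t, 2.0 * t + rng.normal(0, 0.3, 6), 0.3, "pSTAT1_wb")
        rec_b = make_records(t, 5.0 + rng.normal(0, 0.3, 6), 0.3, "SOCS1_mrna")
        import pandas as pd

        data = TimeSeriesDataset(pd.concat([rec_a, rec_b], ignore_index=True))

        def predict(params, d):
            r = d.records
            out = np.where(
                r["observable"] == "pSTAT1_wb",
                params["a"] * r["time_min"],
                params["b"],
            )
            return out.astype(float)

        problem = FitProblem(
            predict,
            data,
            [ParameterSpec("a", 1.0, 1e-2, 1e2), ParameterSpec("b", 1.0, 1e-2, 1e2)],
        )
        res = fit(problem, FitSettings(restarts=3, seed=0, anneal_steps=40))
        prof = profile("a", res, problem, [TH95], FitSettings(seed=1))
        corr = profile_correlation(prof, "b", ci_threshold(TH95))
        assert corr["slope"] == pytest.approx(0.0, abs=0.05)

    def test_correlation_needs_enough_in_ci_points(self):
        grid = np.logspace(-1, 1, 6)
        prof = LikelihoodProfile(
            parameter_id="k",
            grid=grid,
            delta_chi2=np.array([50.0, 40, 0, 40, 50, 60]),
            cofits=[{"k": g, "r": 1.0} for g in grid],
            optimum_value=grid[2],
            optimum_index=2,
            chi2_hat=0.0,
            theta_hat={"k": grid[2], "r": 1.0},
            log10=True,
            termination={"lower": "threshold", "upper": "threshold"},
        )
        with pytest.raises(ValueError, match="at least 5"):
            profile_correlation(prof, "r", ci_threshold(TH95))


class TestTrajectoryBand:
    def synthetic_profile(self):
        grid = np.logspace(-0.5, 0.5, 21)
        delta = 8.0 * np.log10(grid) ** 2
        return LikelihoodProfile(
            parameter_id="k",
            grid=grid,
            delta_chi2=delta,
            cofits=[{"k": g} for g in grid],
            optimum_value=1.0,
            optimum_index=10,
            chi2_hat=0.0,
            theta_hat={"k": 1.0},
            log10=True,
            termination={"lower": "threshold", "upper": "threshold"},
        )

    def test_singleton_band_has_zero_width(self):
        prof = self.synthetic_profile()
        time_grid = np.linspace(0, 10, 11)
        fn = lambda m: m["k"] * time_grid
        band = trajectory_band(prof, fn, time_grid, ci_threshold(TH95), n_sets=1)
        np.testing.assert_array_equal(band.lower, band.upper)

    def test_envelope_contains_best_fit_everywhere(self):
        prof = self.synthetic_profile()
        time_grid = np.linspace(0, 10, 11)
        fn = lambda m: m["k"] * time_grid
        band = trajectory_band(prof, fn, time_grid, ci_threshold(TH95), n_sets=11)
        assert np.all(band.lower <= band.best + 1e-12)
        assert np.all(band.best <= band.upper + 1e-12)
        assert band.members.shape[1] == time_grid.size

    def test_empty_ci_rejected(self):
        prof = self.synthetic_profile()
        prof.delta_chi2 = prof.delta_chi2 + 100.0
        with pytest.raises(ValueError, match="no grid points"):
            trajectory_band(
                prof, lambda m: np.zeros(3), np.arange(3.0), ci_threshold(TH95)
            )


class TestCoverage:
    def test_simultaneous_ci_covers_truth(self):
        # 50 noisy replicates of the line model; the alpha=0.95 CI of the
        # (identifiable) slope should contain the truth in >= 85% of runs
        alpha_hits = 0
        n_rep = 50
        for seed in range(n_rep):
            problem, res, _ = fitted_line(seed=seed)
            prof = profile(
                "a", res, problem, [TH95], FitSettings(seed=seed, anneal_steps=0)
            )
            ci = prof.ci[TH95.key]
            alpha_hits += ci["lower"] <= 2.0 <= ci["upper"]
        assert alpha_hits / n_rep >= 0.95 - 0.10


class TestSerialization:
    def test_profile_json_roundtrip(self, tmp_path):
        problem, res, _ = fitted_line()
        prof = profile("a", res, problem, [TH95], FitSettings(seed=1))
        path = tmp_path / "profile.json"
        prof.to_json(path)
        again = LikelihoodProfile.from_json(path)
        np.testing.assert_allclose(again.grid, prof.grid)
        np.testing.assert_allclose(again.delta_chi2, prof.delta_chi2)
        assert again.status == prof.status
        assert again.ci == prof.ci
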