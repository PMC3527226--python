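"""Chi-square cost and hybrid multistart estimation."""

import numpy as np
import pandas as pd
import pytest

from stat1ple import (
    TimeSeriesDataset,
    chi_squared,
    default_design,
    generate_dataset,
    make_preset,
)
from stat1ple.data import SamplingDesign, _noise_free_records
from stat1ple.fitting import (
    FitProblem,
    FitSettings,
    ParameterSpec,
    PathwayProblem,
    fit,
)

from conftest import make_records


def noise_free_dataset(params, design=None):
    design = design or default_design()
    records = _noise_free_records(params, design)
    records["sigma"] = records["value"].abs().groupby(records["observable"]).transform(
        "max"
    ) * 0.1
    return TimeSeriesDataset(records)


class TestChiSquared:
    def test_perfect_fit_is_zero(self, psc):
        data = noise_free_dataset(psc)
        assert chi_squared(psc, data) == pytest.approx(0.0, abs=1e-10)

    def test_two_sigma_residual_gives_four(self, psc):
        design = SamplingDesign(times={"pSTAT1_wb": [60.0, 120.0]})
        records = _noise_free_records(psc, design).iloc[:1].copy()
        records["sigma"] = 0.5
        records["value"] += 2 * 0.5
        assert chi_squared(psc, TimeSeriesDataset(records)) == pytest.approx(4.0)

    def test_hand_summed_three_record_fixture(self, psc):
        design = SamplingDesign(times={"pSTAT1_wb": [30.0, 60.0, 120.0]})
        records = _noise_free_records(psc, design)
        records["sigma"] = [0.2, 0.4, 0.1]
        records["value"] += np.array([1.0, -0.5, 2.0]) * records["sigma"]
        # residuals of 1, -0.5 and 2 sigma: 1 + 0.25 + 4
        assert chi_squared(psc, TimeSeriesDataset(records)) == pytest.approx(5.25)

    def test_undefined_ratio_record_raises(self, psc):
        records = make_records([0.0, 60.0], [1.0, 1.0], 0.1, "ratio_STAT1D_nc")
        data = TimeSeriesDataset(records)
        with pytest.raises(ValueError, match="undefined"):
            chi_squared(psc, data)  # no phospho pools at t=0


class TestFit:
    def test_separable_quadratic_recovers_known_minimum(self):
        targets = {"p0": 0.3, "p1": -1.2, "p2": 4.0}
        records = make_records([1.0, 2.0, 3.0], list(targets.values()), 1.0)
        data = TimeSeriesDataset(records)

        def predict(params, d):
            return np.array([params[k] for k in targets])

        specs = [ParameterSpec(k, 0.0, -10.0, 10.0, log10=False) for k in targets]
        res = fit(FitProblem(predict, data, specs), FitSettings(restarts=3, seed=1))
        assert res.success
        for k, v in targets.items():
            assert res.theta_hat[k] == pytest.approx(v, abs=1e-6)

    def test_start_at_optimum_is_fixed_point(self, psc):
        data = noise_free_dataset(psc)
        specs = [
            ParameterSpec(name, value, max(value / 100, 1e-12), max(value * 100, 1.0),
                          fixed=name not in ("k_act", "k_deph"))
            for name, value in psc.items()
        ]
        problem = PathwayProblem(data, specs)
        settings = FitSettings(restarts=1, seed=0, anneal_steps=0)
        res = fit(problem, settings, start=psc.as_dict())
        assert res.chi2_hat <= 1e-8

    def test_recovers_transport_rates_from_noise_free_data(self, psc):
        data = noise_free_dataset(psc)
        free = ("k_act", "k_impD", "k_deph")
        specs = [
            ParameterSpec(name, value * (3 if name in free else 1),
                          max(value / 100, 1e-12), max(value * 100, 1.0),
                          fixed=name not in free)
            for name, value in psc.items()
        ]
        problem = PathwayProblem(data, specs)
        res = fit(problem, FitSettings(restarts=3, seed=7, anneal_steps=60))
        assert res.success
        truth_cost = chi_squared(psc, data, rtol=1e-7, atol=1e-9)
        assert res.chi2_hat <= truth_cost + 1e-6

    def test_returned_cost_never_exceeds_any_start_cost(self):
        rng = np.random.default_rng(5)
        y = 2.0 * np.arange(1.0, 9.0) + rng.normal(0, 0.5, 8)
        records = make_records(np.arange(1.0, 9.0), y, 0.5)

        def predict(params, d):
            return params["a"] * d.records["time_min"].to_numpy()

        problem = FitProblem(
            predict, TimeSeriesDataset(records), [ParameterSpec("a", 1.0, 1e-2, 1e2)]
        )
        res = fit(problem, FitSettings(restarts=6, seed=3))
        for record in res.restarts:
            assert record["cost"] <= record["cost_start"] + 1e-12
        assert res.chi2_hat == pytest.approx(min(r["cost"] for r in res.restarts))

    def test_scaling_factor_equivariance(self, psc):
        # rescaling a blot scaling factor together with its observable's data
        # leaves the optimum cost unchanged
        design = SamplingDesign(
            times={"pSTAT1_wb": [10.0, 30, 60, 120, 240, 540]}
        )
        data = noise_free_dataset(psc, design)
        free = ("k_act", "s_pstat")

        def build(scale):
            d = data.copy()
            d.records[["value", "sigma"]] *= scale
            specs = [
                ParameterSpec(name, value, max(value / 100, 1e-12),
                              max(value * 100, 10.0), fixed=name not in free)
                for name, value in psc.items()
            ]
            return PathwayProblem(d, specs)

        settings = FitSettings(restarts=1, seed=11, anneal_steps=0)
        start = psc.as_dict() | {"k_act": psc.k_act * 2}
        res1 = fit(build(1.0), settings, start=start)
        res5 = fit(build(5.0), settings, start=start | {"s_pstat": 5.0})
        assert res1.chi2_hat == pytest.approx(0.0, abs=1e-6)
        assert res5.chi2_hat == pytest.approx(0.0, abs=1e-6)
        assert res5.theta_hat["s_pstat"] == pytest.approx(
            5.0 * res1.theta_hat["s_pstat"], rel=1e-3
        )
        assert res5.theta_hat["k_act"] == pytest.approx(
            res1.theta_hat["k_act"], rel=1e-3
        )

    def test_noisy_fits_reach_record_count_band(self, psc):
        # with 2 free parameters the optimum chi2 should fall at or below the
        # record count in at least half the replicates
        free = ("k_act", "k_deph")
        specs = [
            ParameterSpec(name, value, max(value / 30, 1e-12), max(value * 30, 1.0),
                          fixed=name not in free)
            for name, value in psc.items()
        ]
        design = SamplingDesign(
            times={"pSTAT1_wb": [10.0, 30, 60, 120, 240, 540],
                   "ratio_STAT1D_nc": [10.0, 30, 60, 120, 240, 540]}
        )
        hits = 0
        n_seeds = 20
        for seed in range(n_seeds):
            data = generate_dataset(psc, design, seed=seed)
            problem = PathwayProblem(data, specs)
            res = fit(
                problem, FitSettings(restarts=1, seed=seed, anneal_steps=0),
                start=psc.as_dict(),
            )
            hits += res.chi2_hat <= len(data)
        assert hits >= n_seeds // 2

    def test_all_failures_reported_explicitly(self):
        records = make_records([1.0, 2.0], [1.0, 2.0], 0.1)

        def predict(params, d):
            raise ValueError("model always undefined")

        problem = FitProblem(
            predict, TimeSeriesDataset(records), [ParameterSpec("a", 1.0, 1e-2, 1e2)]
        )
        res = fit(problem, FitSettings(restarts=3, seed=0, anneal_steps=5))
        assert not res.success
        assert np.isinf(res.chi2_hat)
        assert len(res.restarts) == 3

    def test_fixed_seed_reproducible(self):
        rng = np.random.default_rng(0)
        y = 1.5 * np.arange(1.0, 6.0) + rng.normal(0, 0.3, 5)
        records = make_records(np.arange(1.0, 6.0), y, 0.3)

        def predict(params, d):
            return params["a"] * d.records["time_min"].to_numpy()

        problem = FitProblem(
            predict, TimeSeriesDataset(records), [ParameterSpec("a", 1.0, 1e-2, 1e2)]
        )
        r1 = fit(problem, FitSettings(restarts=4, seed=21))
        r2 = fit(problem, FitSettings(restarts=4, seed=21))
        assert r1.theta_hat == r2.theta_hat
        assert [r["cost"] for r in r1.restarts] == [r["cost"] for r in r2.restarts]


class TestFitResultSerialization:
    def test_json_roundtrip(self, tmp_path):
        records = make_records([1.0, 2.0], [2.0, 4.0], 0.5)

        def predict(params, d):
            return params["a"] * d.records["time_min"].to_numpy()

        problem = FitProblem(
            predict, TimeSeriesDataset(records), [ParameterSpec("a", 1.0, 1e-2, 1e2)]
        )
        res = fit(problem, FitSettings(restarts=2, seed=1))
        path = tmp_path / "fit.json"
        res.to_json(path)
        from stat1ple.fitting import FitResult

        again = FitResult.from_json(path)
        assert again.theta_hat == res.theta_hat
        assert again.chi2_hat == res.chi2_hat
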