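"""Synthetic-data generator: preset contrasts, noise statistics, randomized
datasets, and the CSV dialect."""

import numpy as np
import pandas as pd
import pytest

from stat1ple import (
    TimeSeriesDataset,
    SamplingDesign,
    chi_squared,
    default_design,
    generate_dataset,
    load_dataset,
    make_preset,
    randomize_like,
    save_dataset,
    simulate_observables,
)
from stat1ple.data import _noise_free_records


class TestPresets:
    def test_receptor_activation_contrast(self, psc, pc):
        assert psc.k_act / pc.k_act >= 10.0

    def test_nuclear_import_contrast(self, psc, pc):
        assert psc.k_impD / pc.k_impD >= 10.0

    def test_psc_dephosphorylation_balances_import(self, psc):
        assert 0.8 <= psc.k_deph / psc.k_impD <= 1.25

    def test_presets_are_valid_parameter_sets(self, psc, pc):
        # construction already enforces the invariants; re-assert key ones
        for p in (psc, pc):
            assert all(v >= 0 for _, v in p.items())
            assert p.R_tot > 0

    def test_nuclear_accumulation_contrast(self, psc, pc):
        grid = np.linspace(0, 540, 55)
        psc_ratio = simulate_observables(psc, 100.0, grid)["ratio_STAT1_nc"]
        pc_ratio = simulate_observables(pc, 100.0, grid)["ratio_STAT1_nc"]
        assert np.nanmax(psc_ratio) > 2.0
        assert np.nanmax(pc_ratio) < 1.5

    def test_unknown_cell_type_rejected(self):
        with pytest.raises(ValueError, match="unknown cell type"):
            make_preset("fibroblast")


class TestGenerate:
    def test_zero_noise_limit_returns_model_exactly(self, psc):
        design = default_design()
        design = SamplingDesign(
            times=design.times,
            sigmas={obs: np.zeros(len(ts)) for obs, ts in design.times.items()},
        )
        data = generate_dataset(psc, design, seed=5)
        clean = _noise_free_records(psc, design)
        np.testing.assert_array_equal(
            data.records["value"].to_numpy(), clean["value"].to_numpy()
        )

    def test_seed_determinism(self, psc):
        a = generate_dataset(psc, default_design(), seed=9)
        b = generate_dataset(psc, default_design(), seed=9)
        pd.testing.assert_frame_equal(a.records, b.records)
        c = generate_dataset(psc, default_design(), seed=10)
        assert not a.records["value"].equals(c.records["value"])

    def test_noise_moments_across_replicates(self, psc):
        design = SamplingDesign(
            times={"pSTAT1_wb": [60.0, 120.0]}, replicates=10_000
        )
        data = generate_dataset(psc, design, seed=13)
        block = data.records[data.records["time_min"] == 60.0]
        sigma = block["sigma"].iloc[0]
        truth = _noise_free_records(psc, design)
        true_value = truth[truth["time_min"] == 60.0]["value"].iloc[0]
        assert block["value"].mean() == pytest.approx(
            true_value, abs=3 * sigma / 100.0
        )
        assert block["value"].std(ddof=1) == pytest.approx(sigma, rel=0.03)

    def test_sigma_rule_is_fraction_of_series_max(self, psc):
        data = generate_dataset(psc, default_design(), seed=3)
        clean = _noise_free_records(psc, default_design())
        for obs, block in clean.groupby("observable"):
            expected = 0.10 * block["value"].abs().max()
            got = data.records.loc[
                data.records["observable"] == obs, "sigma"
            ].unique()
            assert got == pytest.approx(expected)

    def test_chi2_of_generating_parameters_matches_record_count(self, psc):
        # E[chi2] = number of records under the generating model
        design = default_design()
        chi2s = [
            chi_squared(psc, generate_dataset(psc, design, seed=s))
            for s in range(200)
        ]
        n = len(generate_dataset(psc, design, seed=0))
        assert np.mean(chi2s) == pytest.approx(n, rel=0.10)


class TestRandomize:
    def test_zero_sigma_limit_is_identity(self, psc_dataset):
        data = psc_dataset.copy()
        data.records["sigma"] = np.finfo(float).tiny
        out = randomize_like(data, seed=4)
        np.testing.assert_allclose(
            out.records["value"], data.records["value"], rtol=0, atol=1e-290
        )

    def test_seed_determinism(self, psc_dataset):
        a = randomize_like(psc_dataset, seed=8)
        b = randomize_like(psc_dataset, seed=8)
        pd.testing.assert_frame_equal(a.records, b.records)

    def test_design_is_preserved(self, psc_dataset):
        out = randomize_like(psc_dataset, seed=8)
        for col in ("time_min", "observable", "sigma", "dose_ng_ml", "replicate"):
            assert out.records[col].equals(psc_dataset.records[col])

    def test_moments_match_original_value_and_sigma(self, psc_dataset):
        row = psc_dataset.records.iloc[7]
        draws = np.array(
            [
                randomize_like(psc_dataset, seed=s).records["value"].iloc[7]
                for s in range(5000)
            ]
        )
        se_mean = row["sigma"] / np.sqrt(draws.size)
        assert draws.mean() == pytest.approx(row["value"], abs=3 * se_mean)
        se_sd = row["sigma"] / np.sqrt(2 * (draws.size - 1))
        assert draws.std(ddof=1) == pytest.approx(row["sigma"], abs=3 * se_sd)

    def test_series_moments_mode(self, psc_dataset):
        out = randomize_like(psc_dataset, seed=1, mode="series_moments")
        assert out.metadata["randomized"]["mode"] == "series_moments"
        assert len(out) == len(psc_dataset)

    def test_empty_dataset_rejected(self):
        empty = TimeSeriesDataset(
            pd.DataFrame(
                columns=[
                    "time_min",
                    "observable",
                    "value",
                    "sigma",
                    "dose_ng_ml",
                    "replicate",
                ]
            )
        )
        with pytest.raises(ValueError, match="empty"):
            randomize_like(empty, seed=0)


class TestDesignValidation:
    def test_unknown_observable_rejected(self):
        with pytest.raises(ValueError, match="unknown observable"):
            SamplingDesign(times={"phospho_JAK": [0.0, 60.0]})

    def test_single_time_point_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            SamplingDesign(times={"pSTAT1_wb": [60.0]})


class TestCsvDialect:
    def test_roundtrip_field_by_field(self, psc_dataset, tmp_path):
        path = tmp_path / "data.csv"
        save_dataset(psc_dataset, path)
        again = load_dataset(path)
        for col in psc_dataset.records.columns:
            if psc_dataset.records[col].dtype == object:
                assert again.records[col].equals(psc_dataset.records[col])
            else:
                np.testing.assert_array_equal(
                    again.records[col].to_numpy(),
                    psc_dataset.records[col].to_numpy(),
                )

    def test_zero_sigma_row_rejected_with_location(self, psc_dataset, tmp_path):
        bad = psc_dataset.records.copy()
        bad.loc[3, "sigma"] = 0.0
        path = tmp_path / "bad.csv"
        bad.to_csv(path, index=False)
        with pytest.raises(ValueError, match="line 5"):  # header + 0-based row 3
            load_dataset(path)

    def test_unknown_observable_rejected_on_load(self, psc_dataset, tmp_path):
        bad = psc_dataset.records.copy()
        bad.loc[0, "observable"] = "mystery_blot"
        path = tmp_path / "bad.csv"
        bad.to_csv(path, index=False)
        with pytest.raises(ValueError, match="mystery_blot"):
            load_dataset(path)

    def test_extra_column_preserved_in_metadata(self, psc_dataset, tmp_path):
        extra = psc_dataset.records.copy()
        extra["batch"] = "gel_A"
        path = tmp_path / "extra.csv"
        extra.to_csv(path, index=False)
        loaded = load_dataset(path)
        assert loaded.metadata["extra_columns"] == ["batch"]
        assert (loaded.records["batch"] == "gel_A").all()

    def test_non_numeric_value_reported_with_line(self, psc_dataset, tmp_path):
        bad = psc_dataset.records.copy().astype({"value": object})
        bad.loc[2, "value"] = "smudge"
        path = tmp_path / "bad.csv"
        bad.to_csv(path, index=False)
        with pytest.raises(ValueError, match="line 4"):
            load_dataset(path)
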