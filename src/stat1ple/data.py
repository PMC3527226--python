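"""Synthetic time-series data with the statistical structure of sparse
immunoblot / immunofluorescence experiments.

Records carry an independent Gaussian measurement error per point (the noise
model under which the chi-square cost is the maximum-likelihood objective),
irregular sampling over 0–540 min, and one stimulation dose per record.  Two
calibrated parameter presets emulate the two cell-type regimes: ``PSC_like``
(pancreatic stellate cells — fast receptor activation, strong nuclear
accumulation of phospho-STAT1) and ``PC_like`` (pancreatic carcinoma cells —
slow activation, no nuclear accumulation).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .model import OBSERVABLE_NAMES, simulate_observables
from .params import PathwayParameters, consistent_initial_stat1

__all__ = [
    "TimeSeriesDataset",
    "SamplingDesign",
    "make_preset",
    "default_design",
    "generate_dataset",
    "randomize_like",
    "load_dataset",
    "save_dataset",
]

DATASET_COLUMNS = ("time_min", "observable", "value", "sigma", "dose_ng_ml", "replicate")


@dataclass
class TimeSeriesDataset:
    """Tidy collection of measured points with per-point errors.

    ``records`` columns: time_min, observable, value, sigma, dose_ng_ml,
    replicate.  ``metadata`` may carry the cell-type label, the generator seed
    and the generating parameters.
    """

    records: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = set(DATASET_COLUMNS) - set(self.records.columns)
        if missing:
            raise ValueError(f"dataset missing columns: {sorted(missing)}")
        self.validate()

    def validate(self) -> None:
        r = self.records
        if len(r) == 0:
            return
        if (r["sigma"] <= 0).any():
            bad = r.index[r["sigma"] <= 0][0]
            raise ValueError(f"sigma must be > 0 (row {bad})")
        if (r["time_min"] < 0).any():
            raise ValueError("times must be >= 0")
        unknown = set(r["observable"]) - set(OBSERVABLE_NAMES)
        if unknown:
            raise ValueError(f"unknown observable ids: {sorted(unknown)}")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def n_observables(self) -> int:
        """M of the double-sum cost: number of distinct observables."""
        return self.records["observable"].nunique()

    @property
    def n_time_points(self) -> dict[str, int]:
        """N per observable: number of sampled time points."""
        return self.records.groupby("observable").size().to_dict()

    def copy(self) -> "TimeSeriesDataset":
        return TimeSeriesDataset(self.records.copy(), dict(self.metadata))


@dataclass
class SamplingDesign:
    """Which observables are sampled when, at which doses, with what error.

    ``sigmas`` may map an observable to a per-point array (aligned with its
    time list); observables not listed fall back to the fraction-of-maximum
    rule: ``sigma = max(sigma_fraction, sigma_floor_fraction) · max_t |y(t)|``
    evaluated on the noise-free series.
    """

    times: Mapping[str, Sequence[float]]
    doses: Sequence[float] = (100.0,)
    sigmas: Mapping[str, Sequence[float]] = field(default_factory=dict)
    sigma_fraction: float = 0.10
    sigma_floor_fraction: float = 0.05
    replicates: int = 1

    def __post_init__(self) -> None:
        if not self.times:
            raise ValueError("design must include at least one observable")
        for obs, ts in self.times.items():
            if obs not in OBSERVABLE_NAMES:
                raise ValueError(f"design references unknown observable {obs!r}")
            if len(ts) < 2:
                raise ValueError(f"observable {obs!r} needs at least 2 time points")
        for obs, sg in self.sigmas.items():
            if len(sg) != len(self.times[obs]):
                raise ValueError(f"sigmas for {obs!r} must align with its times")
            if np.any(np.asarray(sg, dtype=float) < 0):
                raise ValueError("explicit sigmas must be >= 0")


def default_design() -> SamplingDesign:
    """Sparse irregular sampling typical of immunoblot time courses: 11–12 points
    per observable over 0–540 min, denser before 120 min, one 100 ng/ml dose.
    Ratio observables skip t = 0 where the phospho pools are empty."""
    dense = [0.0, 10.0, 20.0, 30.0, 45.0, 60.0, 90.0, 120.0, 180.0, 240.0, 360.0, 540.0]
    no_zero = dense[1:]
    return SamplingDesign(
        times={
            "pSTAT1_wb": dense,
            "STAT1_wb": dense,
            "SOCS1_mrna": dense,
            "ratio_STAT1_nc": no_zero,
            "ratio_STAT1D_nc": no_zero,
        }
    )


# ---------------------------------------------------------------------------
# cell-type presets


def make_preset(cell_type: str) -> PathwayParameters:
    """Calibrated parameter set for one of the two cell-type regimes.

    ``PSC_like``: fast receptor activation and fast nuclear import of
    phospho-STAT1 (both ≥ 10× the PC values), nuclear dephosphorylation
    roughly balancing nuclear import (k_deph/k_impD ≈ 1), slow nuclear export
    — the regime with strong, sustained nuclear accumulation where the
    nuclear:cytoplasmic phospho-STAT1 ratio settles near 3.5.

    ``PC_like``: slow receptor activation, slow nuclear import, fast
    dephosphorylation and export — phosphorylation happens but STAT1 stays
    cytoplasmic.
    """
    common = dict(
        R_tot=1.0,
        k_phos=0.002,
        k_inh=20.0,
        k_impU=1e-4,
        k_tc_socs=0.050,
        d_m_socs=0.020,
        k_tl_socs=0.10,
        d_socs=0.010,
        b_m_stat=2.2e-4,
        k_tc_stat=0.10,
        d_m_stat=0.010,
        k_tl_stat=2e-3,
        d_stat=1e-4,
        tau_socs=20.0,
        tau_stat=60.0,
        s_pstat=1.0,
        s_stat=1.0,
        s_socs=1.0,
        v_nc=3.5,
    )
    if cell_type == "PSC_like":
        spec = dict(
            common,
            k_act=5e-3,
            k_inact=0.010,
            k_impD=2.0,
            k_deph=2.0,
            k_exp=1e-3,
        )
    elif cell_type == "PC_like":
        spec = dict(
            common,
            k_act=2e-4,
            k_inact=0.010,
            k_impD=0.20,
            k_deph=1.0,
            k_exp=0.020,
        )
    else:
        raise ValueError(f"unknown cell type {cell_type!r}; use PSC_like or PC_like")
    params = PathwayParameters(**spec, stat1_uc0=0.0, stat1_un0=0.0)
    uc0, un0 = consistent_initial_stat1(params)
    return params.replace(stat1_uc0=uc0, stat1_un0=un0)


# ---------------------------------------------------------------------------
# dataset generation


def _noise_free_records(
    params: PathwayParameters, design: SamplingDesign
) -> pd.DataFrame:
    rows = []
    for dose in design.doses:
        all_times = sorted({t for ts in design.times.values() for t in ts} | {0.0})
        obs_set = simulate_observables(params, dose, np.asarray(all_times))
        index = {t: i for i, t in enumerate(all_times)}
        for obs, ts in design.times.items():
            series = obs_set[obs]
            values = np.array([series[index[t]] for t in ts], dtype=float)
            if np.isnan(values).any():
                t_bad = np.asarray(ts)[np.isnan(values)][0]
                raise ValueError(
                    f"observable {obs!r} undefined at t={t_bad} min (dose {dose})"
                )
            if obs in design.sigmas:
                sigma = np.asarray(design.sigmas[obs], dtype=float)
            else:
                frac = max(design.sigma_fraction, design.sigma_floor_fraction)
                sigma = np.full(len(ts), frac * np.abs(values).max())
            rows.append(
                pd.DataFrame(
                    {
                        "time_min": np.asarray(ts, dtype=float),
                        "observable": obs,
                        "value": values,
                        "sigma": sigma,
                        "dose_ng_ml": float(dose),
                        "replicate": 0,
                    }
                )
            )
    return pd.concat(rows, ignore_index=True)


def generate_dataset(
    params: PathwayParameters,
    design: SamplingDesign,
    seed: int,
    cell_type: str | None = None,
) -> TimeSeriesDataset:
    """Simulate the model and add independent Gaussian noise per record.

    Values are left untruncated (negative draws are kept — measurement noise
    can undershoot zero).  Identical seeds give identical datasets.  Records
    with an explicit sigma of 0 are returned noise-free but re-assigned a
    small positive sigma floor is NOT applied: a zero sigma would make the
    dataset invalid, so explicit zeros are only allowed via ``sigmas`` for
    noise-free reference sets and are stored as the smallest positive float.
    """
    base = _noise_free_records(params, design)
    rng = np.random.default_rng(seed)
    frames = []
    for rep in range(design.replicates):
        block = base.copy()
        block["replicate"] = rep
        noise = rng.standard_normal(len(block)) * block["sigma"].to_numpy()
        block["value"] = block["value"].to_numpy() + noise
        frames.append(block)
    records = pd.concat(frames, ignore_index=True)
    records.loc[records["sigma"] == 0.0, "sigma"] = np.finfo(float).tiny
    metadata = {
        "seed": int(seed),
        "cell_type": cell_type,
        "params": params.as_dict(),
    }
    return TimeSeriesDataset(records, metadata)


def randomize_like(
    data: TimeSeriesDataset, seed: int, mode: str = "parametric"
) -> TimeSeriesDataset:
    """Randomized dataset with the same design, errors and statistics.

    ``mode='parametric'`` (default): each value is redrawn from a Gaussian
    centred on the original value with that record's measurement sigma — the
    parametric-bootstrap construction under which the overfitting statistic of
    a linear model follows its theoretical chi-square law.

    ``mode='series_moments'`` (experimental): values within each
    (observable, dose, replicate) series are drawn i.i.d. from a Gaussian with
    that series' empirical mean and standard deviation, a literal per-series
    reading of "same mean and same standard deviation".
    """
    if len(data) == 0:
        raise ValueError("dataset is empty")
    rng = np.random.default_rng(seed)
    records = data.records.copy()
    if mode == "parametric":
        records["value"] = records["value"].to_numpy() + rng.standard_normal(
            len(records)
        ) * records["sigma"].to_numpy()
    elif mode == "series_moments":
        for _, idx in records.groupby(
            ["observable", "dose_ng_ml", "replicate"]
        ).groups.items():
            vals = records.loc[idx, "value"].to_numpy()
            records.loc[idx, "value"] = rng.normal(
                vals.mean(), vals.std(ddof=0), size=len(idx)
            )
    else:
        raise ValueError(f"unknown randomization mode {mode!r}")
    metadata = dict(data.metadata)
    metadata["randomized"] = {"seed": int(seed), "mode": mode}
    return TimeSeriesDataset(records, metadata)


# ---------------------------------------------------------------------------
# CSV dialect: header time_min, observable, value, sigma, dose_ng_ml,
# replicate; UTF-8; "." decimal separator


def save_dataset(data: TimeSeriesDataset, path) -> None:
    """Write a dataset as tidy CSV at full float precision (lossless round
    trip via :func:`load_dataset`)."""
    cols = list(DATASET_COLUMNS) + [
        c for c in data.records.columns if c not in DATASET_COLUMNS
    ]
    data.records[cols].to_csv(path, index=False, float_format="%.17g")


def load_dataset(path) -> TimeSeriesDataset:
    """Read a tidy-CSV dataset, validating rows and reporting offending line
    numbers.  Unknown extra columns are preserved (and noted in metadata)."""
    import pandas.errors

    try:
        records = pd.read_csv(path, float_precision="round_trip")
    except (pandas.errors.ParserError, UnicodeDecodeError) as exc:
        raise ValueError(f"{path}: malformed CSV: {exc}") from exc
    missing = set(DATASET_COLUMNS) - set(records.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    for col in ("time_min", "value", "sigma", "dose_ng_ml"):
        coerced = pd.to_numeric(records[col], errors="coerce")
        bad = records.index[coerced.isna() & records[col].notna()]
        if len(bad):
            raise ValueError(
                f"{path}: non-numeric {col!r} at line {int(bad[0]) + 2}"
            )
        records[col] = coerced
    for col, pred, msg in (
        ("sigma", lambda s: s <= 0, "sigma must be > 0"),
        ("time_min", lambda s: s < 0, "time must be >= 0"),
    ):
        bad = records.index[pred(records[col]) | records[col].isna()]
        if len(bad):
            raise ValueError(f"{path}: {msg} at line {int(bad[0]) + 2}")
    unknown_obs = set(records["observable"]) - set(OBSERVABLE_NAMES)
    if unknown_obs:
        line = int(
            records.index[records["observable"].isin(unknown_obs)][0]
        ) + 2
        raise ValueError(
            f"{path}: unknown observable ids {sorted(unknown_obs)} (line {line})"
        )
    extra = [c for c in records.columns if c not in DATASET_COLUMNS]
    metadata = {"source": str(path)}
    if extra:
        metadata["extra_columns"] = extra
    return TimeSeriesDataset(records, metadata)
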