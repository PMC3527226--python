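import numpy as np
import pandas as pd
import pytest

from stat1ple import (
    PathwayParameters,
    TimeSeriesDataset,
    default_design,
    generate_dataset,
    make_preset,
)
from stat1ple.fitting import FitProblem, ParameterSpec


@pytest.fixture(scope="session")
def psc():
    return make_preset("PSC_like")


@pytest.fixture(scope="session")
def pc():
    return make_preset("PC_like")


@pytest.fixture(scope="session")
def psc_dataset(psc):
    return generate_dataset(psc, default_design(), seed=42, cell_type="PSC_like")


@pytest.fixture(scope="session")
def default_grid():
    return np.array(
        [0.0, 10, 20, 30, 45, 60, 90, 120, 180, 240, 360, 540], dtype=float
    )


def make_records(times, values, sigmas, observable="pSTAT1_wb", dose=100.0):
    """Small tidy record table for constructed test models."""
    return pd.DataFrame(
        {
            "time_min": np.asarray(times, dtype=float),
            "observable": observable,
            "value": np.asarray(values, dtype=float),
            "sigma": np.asarray(sigmas, dtype=float),
            "dose_ng_ml": dose,
            "replicate": 0,
        }
    )


def line_problem(times, y, sigma, bounds=(1e-2, 1e2), start=1.0):
    """One-parameter straight line through the origin: y = a*t."""
    data = TimeSeriesDataset(make_records(times, y, sigma))

    def predict(params, d):
        return params["a"] * d.records["time_min"].to_numpy()

    return FitProblem(predict, data, [ParameterSpec("a", start, *bounds)])


def polynomial_problem(times, y, sigma, degree):
    """Linear-in-parameters polynomial model with coefficients c0..c(d-1),
    optimized on linear scale so the model stays exactly linear-Gaussian."""
    data = TimeSeriesDataset(make_records(times, y, sigma))
    t = np.asarray(times, dtype=float)
    tmax = t.max()

    def predict(params, d):
        tt = d.records["time_min"].to_numpy() / tmax
        return sum(params[f"c{k}"] * tt**k for k in range(degree))

    specs = [
        ParameterSpec(f"c{k}", 0.5, -50.0, 50.0, log10=False) for k in range(degree)
    ]
    return FitProblem(predict, data, specs)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
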