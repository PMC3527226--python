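"""Chi-square cost and hybrid global/local multistart parameter estimation.

The cost is the double sum over observables and time points of squared,
sigma-normalized residuals between data and model observables — the
maximum-likelihood objective under independent Gaussian measurement noise.
Each restart draws a start uniformly in (log-transformed) bounds, runs a
simulated-annealing global stage (Metropolis acceptance, geometric cooling)
and polishes with a derivative-based trust-region stage.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.optimize import least_squares

from .data import TimeSeriesDataset
from .model import IntegrationError, simulate_observables
from .params import PathwayParameters

__all__ = [
    "ParameterSpec",
    "FitSettings",
    "FitResult",
    "FitProblem",
    "PathwayProblem",
    "chi_squared",
    "fit",
]

#: residual magnitude standing in for a failed model evaluation during search
_FAIL_RESIDUAL = 1e8

#: two restart costs within this of each other count as a tie (earliest wins)
_TIE_TOL = 1e-9


def json_default(obj):
    """Serializer for numpy scalars/arrays in result payloads."""
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


@dataclass(frozen=True)
class ParameterSpec:
    """One estimable parameter: reference value, box bounds, scale.

    ``log10=True`` (the default for rates and concentrations, which span
    orders of magnitude) optimizes the base-10 logarithm; delays and other
    linear-scale parameters set it to False.  ``fixed=True`` pins the
    parameter at ``value``.
    """

    name: str
    value: float
    lower: float
    upper: float
    log10: bool = True
    fixed: bool = False

    def __post_init__(self) -> None:
        if not self.fixed:
            if not (np.isfinite(self.lower) and np.isfinite(self.upper)):
                raise ValueError(f"{self.name}: bounds must be finite")
            if not self.lower < self.upper:
                raise ValueError(f"{self.name}: lower must be < upper")
            if self.log10 and self.lower <= 0:
                raise ValueError(f"{self.name}: log10 scale requires lower > 0")

    def to_internal(self, v: float) -> float:
        return float(np.log10(v)) if self.log10 else float(v)

    def from_internal(self, x: float) -> float:
        return float(10.0**x) if self.log10 else float(x)


@dataclass
class FitSettings:
    """Multistart settings: restarts, annealing schedule, local tolerances."""

    restarts: int = 50
    seed: int | None = None
    anneal_steps: int = 200
    anneal_t0: float | None = None  # default: the start cost (at least 1)
    anneal_cooling: float = 0.96
    anneal_step_fraction: float = 0.1  # proposal SD as fraction of box width
    local_ftol: float = 1e-10
    local_xtol: float = 1e-8
    local_max_nfev: int | None = None
    # finite-difference step for the trust-region jacobian, in internal
    # coordinates; must sit well above the integrator's relative noise floor
    local_diff_step: float = 1e-5

    def __post_init__(self) -> None:
        if self.restarts < 1:
            raise ValueError("restarts must be >= 1")
        if not 0 < self.anneal_cooling <= 1:
            raise ValueError("anneal_cooling must be in (0, 1]")


@dataclass
class FitResult:
    """Best fit over all restarts, with full multistart provenance."""

    theta_hat: dict[str, float]  # full parameter mapping, fixed values included
    chi2_hat: float
    free_names: list[str]
    restarts: list[dict]  # per restart: start, cost_start, cost_anneal, cost, converged
    success: bool
    seed: int | None
    settings: dict = field(default_factory=dict)

    @property
    def n_free(self) -> int:
        return len(self.free_names)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, default=json_default))

    @classmethod
    def from_json(cls, path: str | Path) -> "FitResult":
        return cls(**json.loads(Path(path).read_text()))


class FitProblem:
    """Couples a prediction function, a dataset and parameter specs.

    ``predict(params, data)`` maps a full parameter dict to model values
    aligned with ``data.records``; it may raise ``IntegrationError`` (or
    ``ValueError`` for undefined observables), which the search treats as an
    infinite-cost point.  Optimization happens in internal coordinates
    (log10 where flagged).
    """

    def __init__(
        self,
        predict: Callable[[Mapping[str, float], TimeSeriesDataset], np.ndarray],
        data: TimeSeriesDataset,
        specs: Sequence[ParameterSpec],
    ):
        names = [s.name for s in specs]
        if len(set(names)) != len(names):
            raise ValueError("duplicate parameter names")
        self.predict = predict
        self.data = data
        self.specs = list(specs)
        self.free_specs = [s for s in self.specs if not s.fixed]
        self.free_names = [s.name for s in self.free_specs]
        self._values = data.records["value"].to_numpy(dtype=float)
        self._sigmas = data.records["sigma"].to_numpy(dtype=float)

    # -- coordinate transforms ----------------------------------------------

    @property
    def internal_bounds(self) -> tuple[np.ndarray, np.ndarray]:
        lo = np.array([s.to_internal(s.lower) for s in self.free_specs])
        hi = np.array([s.to_internal(s.upper) for s in self.free_specs])
        return lo, hi

    def internal_start(self) -> np.ndarray:
        return np.array([s.to_internal(s.value) for s in self.free_specs])

    def to_params(self, x: np.ndarray) -> dict[str, float]:
        params = {s.name: s.value for s in self.specs}
        for s, xi in zip(self.free_specs, x):
            params[s.name] = s.from_internal(xi)
        return params

    def with_data(self, data: TimeSeriesDataset) -> "FitProblem":
        return FitProblem(self.predict, data, self.specs)

    def with_fixed(self, name: str, value: float) -> "FitProblem":
        """Pin one free parameter (used by profile-likelihood walks)."""
        specs = []
        for s in self.specs:
            if s.name == name:
                specs.append(
                    ParameterSpec(s.name, value, s.lower, s.upper, s.log10, fixed=True)
                )
            else:
                specs.append(s)
        return FitProblem(self.predict, self.data, specs)

    # -- objective -----------------------------------------------------------

    def residuals(self, x: np.ndarray, *, strict: bool = False) -> np.ndarray:
        try:
            pred = np.asarray(self.predict(self.to_params(x), self.data), dtype=float)
        except (IntegrationError, ValueError, FloatingPointError):
            if strict:
                raise
            return np.full(len(self._values), _FAIL_RESIDUAL)
        if pred.shape != self._values.shape:
            raise ValueError("predict returned wrong number of values")
        if strict and not np.all(np.isfinite(pred)):
            raise ValueError("model observable undefined at a data time point")
        res = (pred - self._values) / self._sigmas
        res[~np.isfinite(res)] = _FAIL_RESIDUAL
        return res

    def chi2(self, x: np.ndarray) -> float:
        res = self.residuals(x)
        if np.any(res >= _FAIL_RESIDUAL):
            return float("inf")
        return float(res @ res)


def chi_squared(
    params: "PathwayParameters | Mapping[str, float]",
    data: TimeSeriesDataset,
    model: Callable[[Mapping[str, float], TimeSeriesDataset], np.ndarray] | None = None,
    **sim_kwargs,
) -> float:
    """Chi-square of a parameter set against a dataset.

    With the default pathway model, every record is predicted by simulating at
    the record's dose and evaluating the record's observable at its time; an
    undefined ratio observable at a data time point raises (a record never
    silently drops out of the sum).
    """
    mapping = params.as_dict() if isinstance(params, PathwayParameters) else dict(params)
    predict = model if model is not None else pathway_predictor(**sim_kwargs)
    pred = np.asarray(predict(mapping, data), dtype=float)
    if not np.all(np.isfinite(pred)):
        bad = data.records.iloc[int(np.flatnonzero(~np.isfinite(pred))[0])]
        raise ValueError(
            "model observable undefined at data point "
            f"({bad['observable']}, t={bad['time_min']} min)"
        )
    res = (pred - data.records["value"].to_numpy()) / data.records["sigma"].to_numpy()
    return float(res @ res)


def pathway_predictor(**sim_kwargs) -> Callable:
    """Prediction function for the STAT1 pathway model: one simulation per
    dose over the union of that dose's record times."""

    def predict(mapping: Mapping[str, float], data: TimeSeriesDataset) -> np.ndarray:
        params = PathwayParameters.from_dict(mapping)
        records = data.records.reset_index(drop=True)
        out = np.empty(len(records))
        for dose, idx in records.groupby("dose_ng_ml").groups.items():
            block = records.loc[idx]
            times = np.unique(block["time_min"].to_numpy(dtype=float))
            grid = times if times[0] == 0.0 else np.concatenate(([0.0], times))
            obs = simulate_observables(params, float(dose), grid, **sim_kwargs)
            pos = {t: i for i, t in enumerate(grid)}
            rows = np.fromiter((pos[t] for t in block["time_min"]), dtype=int)
            for name in block["observable"].unique():
                sel = block["observable"] == name
                out[block.index[sel].to_numpy()] = obs[name][rows[sel.to_numpy()]]
        return out

    return predict


class PathwayProblem(FitProblem):
    """FitProblem bound to the STAT1 pathway model."""

    def __init__(
        self,
        data: TimeSeriesDataset,
        specs: Sequence[ParameterSpec],
        **sim_kwargs,
    ):
        sim_kwargs.setdefault("rtol", 1e-7)
        sim_kwargs.setdefault("atol", 1e-9)
        super().__init__(pathway_predictor(**sim_kwargs), data, specs)


# ---------------------------------------------------------------------------
# hybrid multistart search


def _anneal(
    problem: FitProblem,
    x0: np.ndarray,
    settings: FitSettings,
    rng: np.random.Generator,
) -> tuple[np.ndarray, float]:
    """Metropolis annealing on the chi-square with geometric cooling."""
    lo, hi = problem.internal_bounds
    width = hi - lo
    x = x0.copy()
    cost = problem.chi2(x)
    best_x, best_cost = x.copy(), cost
    temp = settings.anneal_t0
    if temp is None:
        temp = max(1.0, cost if np.isfinite(cost) else 1.0)
    for _ in range(settings.anneal_steps):
        prop = x + rng.standard_normal(x.size) * settings.anneal_step_fraction * width
        np.clip(prop, lo, hi, out=prop)
        c = problem.chi2(prop)
        delta = c - cost
        if delta <= 0 or (
            np.isfinite(c) and rng.random() < np.exp(-delta / max(temp, 1e-300))
        ):
            x, cost = prop, c
            if cost < best_cost:
                best_x, best_cost = x.copy(), cost
        temp *= settings.anneal_cooling
    return best_x, best_cost


def _local(
    problem: FitProblem, x0: np.ndarray, settings: FitSettings
) -> tuple[np.ndarray, float, bool]:
    """Trust-region least-squares refinement within bounds."""
    lo, hi = problem.internal_bounds
    x0 = np.clip(x0, lo, hi)
    try:
        sol = least_squares(
            problem.residuals,
            x0,
            bounds=(lo, hi),
            method="trf",
            ftol=settings.local_ftol,
            xtol=settings.local_xtol,
            gtol=1e-12,
            diff_step=settings.local_diff_step,
            max_nfev=settings.local_max_nfev,
        )
    except Exception:
        return x0, problem.chi2(x0), False
    cost = problem.chi2(sol.x)
    start_cost = problem.chi2(x0)
    # monotone improvement: never return a point worse than the stage start
    if not np.isfinite(cost) or cost > start_cost:
        return x0, start_cost, False
    return sol.x, cost, bool(sol.success)


def fit(
    problem: FitProblem,
    settings: FitSettings | None = None,
    *,
    start: np.ndarray | Mapping[str, float] | None = None,
) -> FitResult:
    """Hybrid multistart estimation.

    Each restart draws a uniform start in the internal (log-bounded) box, runs
    the annealing stage, then the trust-region stage.  ``start`` pins the
    first restart's start point (internal vector or parameter mapping).
    Restarts tying within 1e-9 resolve to the earliest.  If no restart
    produces a finite cost the result carries ``success=False`` and diagnostic
    records — never a silent partial answer.
    """
    settings = settings or FitSettings()
    if not problem.free_specs:
        theta = problem.to_params(np.empty(0))
        cost = problem.chi2(np.empty(0))
        return FitResult(theta, cost, [], [], np.isfinite(cost), settings.seed)
    rng = np.random.default_rng(settings.seed)
    lo, hi = problem.internal_bounds

    pinned = None
    if start is not None:
        if isinstance(start, Mapping):
            pinned = np.array(
                [s.to_internal(start[s.name]) for s in problem.free_specs]
            )
        else:
            pinned = np.asarray(start, dtype=float)

    records: list[dict] = []
    best: tuple[float, int, np.ndarray] | None = None
    for k in range(settings.restarts):
        if k == 0 and pinned is not None:
            x0 = pinned.copy()
        else:
            x0 = rng.uniform(lo, hi)
        c0 = problem.chi2(x0)
        if settings.anneal_steps > 0:
            xa, ca = _anneal(problem, x0, settings, rng)
        else:
            xa, ca = x0, c0
        xl, cl, converged = _local(problem, xa, settings)
        if cl > c0:  # never report worse than the start point
            xl, cl = x0, c0
        records.append(
            {
                "start": problem.to_params(x0),
                "cost_start": c0,
                "cost_anneal": ca,
                "cost": cl,
                "converged": converged and np.isfinite(cl),
            }
        )
        if np.isfinite(cl) and (best is None or cl < best[0] - _TIE_TOL):
            best = (cl, k, xl.copy())

    if best is None:
        return FitResult(
            theta_hat=problem.to_params(problem.internal_start()),
            chi2_hat=float("inf"),
            free_names=problem.free_names,
            restarts=records,
            success=False,
            seed=settings.seed,
            settings=asdict(settings),
        )
    cost, _, x_best = best
    return FitResult(
        theta_hat=problem.to_params(x_best),
        chi2_hat=cost,
        free_names=problem.free_names,
        restarts=records,
        success=True,
        seed=settings.seed,
        settings=asdict(settings),
    )
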