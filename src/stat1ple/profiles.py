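"""Profile-likelihood identifiability analysis.

For each free parameter the profile likelihood is the chi-square re-minimized
over all other parameters while the target is stepped away from its optimum.
A confidence interval at level alpha is the region where the profile stays
below the chi-square quantile with df = 1 (pointwise) or df = number of free
parameters (simultaneous).  A parameter is identifiable when both CI bounds
are finite; a profile that rises on one side only is practically
nonidentifiable; a profile flat over the whole explored range (redundant
parameterization) is structurally nonidentifiable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from scipy import stats

from .fitting import FitProblem, FitResult, FitSettings, fit, _local

__all__ = [
    "ThresholdSpec",
    "ProfileOptions",
    "LikelihoodProfile",
    "TrajectoryBand",
    "ci_threshold",
    "profile",
    "classify",
    "profile_correlation",
    "trajectory_band",
]

#: fraction of the threshold below which a profile counts as flat
FLATNESS_FRACTION = 0.01


@dataclass(frozen=True)
class ThresholdSpec:
    """Confidence level and degrees of freedom defining a likelihood threshold.

    df = 1 gives the pointwise CI; df = number of free parameters the
    simultaneous CI; an externally estimated effective dof may be supplied
    instead.
    """

    alpha: float
    df: int

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.df < 1:
            raise ValueError("df must be >= 1")

    @property
    def key(self) -> str:
        return f"alpha={self.alpha:g},df={self.df}"


def ci_threshold(spec: ThresholdSpec) -> float:
    """Chi-square quantile at probability alpha with df degrees of freedom."""
    return float(stats.chi2.ppf(spec.alpha, spec.df))


@dataclass
class ProfileOptions:
    """Step control for the profile walk (per direction)."""

    target_fraction: float = 0.1  # aim for delta-chi2 increments of this x threshold
    min_step: float = 1e-3  # in internal (log10 or linear) units
    max_step: float = 0.3
    initial_step: float = 0.05
    max_steps: int = 100
    reanchor_tol: float = 1e-3
    max_reanchors: int = 3
    cold_restarts: int = 5  # multistart fallback when a warm refit fails


@dataclass
class LikelihoodProfile:
    """One parameter's profile: grid, delta-chi2, co-fitted vectors, CIs."""

    parameter_id: str
    grid: np.ndarray  # profiled values, external units, increasing
    delta_chi2: np.ndarray
    cofits: list[dict]  # full parameter mapping per grid point
    optimum_value: float
    optimum_index: int
    chi2_hat: float
    theta_hat: dict[str, float]
    log10: bool
    ci: dict[str, dict] = field(default_factory=dict)  # ThresholdSpec.key -> bounds
    status: str | None = None
    termination: dict[str, str] = field(default_factory=dict)  # 'lower'/'upper'
    n_reanchors: int = 0

    def in_ci_mask(self, threshold: float) -> np.ndarray:
        return self.delta_chi2 <= threshold

    def to_json(self, path: str | Path) -> None:
        payload = asdict(self)
        payload["grid"] = [float(v) for v in self.grid]
        payload["delta_chi2"] = [float(v) for v in self.delta_chi2]
        from .fitting import json_default
        Path(path).write_text(json.dumps(payload, indent=2, default=json_default))

    @classmethod
    def from_json(cls, path: str | Path) -> "LikelihoodProfile":
        payload = json.loads(Path(path).read_text())
        payload["grid"] = np.asarray(payload["grid"], dtype=float)
        payload["delta_chi2"] = np.asarray(payload["delta_chi2"], dtype=float)
        return cls(**payload)


def _reminimize(
    problem: FitProblem,
    name: str,
    value: float,
    warm: dict[str, float],
    options: ProfileOptions,
    settings: FitSettings,
    rng: np.random.Generator,
) -> tuple[float, dict[str, float]] | None:
    """Cost minimized over all parameters except ``name`` pinned at ``value``.

    Warm-started from ``warm``; falls back to a small cold multistart.
    Returns (cost, full parameter dict) or None on persistent failure.
    """
    pinned = problem.with_fixed(name, value)
    if not pinned.free_specs:
        x = np.empty(0)
        cost = pinned.chi2(x)
        return (cost, pinned.to_params(x)) if np.isfinite(cost) else None
    lo, hi = pinned.internal_bounds
    x_warm = np.clip(
        np.array([s.to_internal(warm[s.name]) for s in pinned.free_specs]), lo, hi
    )
    x, cost, _ = _local(pinned, x_warm, settings)
    if np.isfinite(cost):
        return cost, pinned.to_params(x)
    if options.cold_restarts > 0:
        cold = fit(
            pinned,
            FitSettings(
                restarts=options.cold_restarts,
                seed=int(rng.integers(2**31 - 1)),
                anneal_steps=50,
                local_ftol=settings.local_ftol,
                local_xtol=settings.local_xtol,
            ),
        )
        if cold.success:
            return cold.chi2_hat, cold.theta_hat
    return None


def profile(
    parameter_id: str,
    fit_result: FitResult,
    problem: FitProblem,
    thresholds: Sequence[ThresholdSpec],
    settings: FitSettings | None = None,
    options: ProfileOptions | None = None,
) -> LikelihoodProfile:
    """Walk ``parameter_id`` away from the optimum in both directions,
    re-minimizing all other parameters at each grid point.

    Steps adapt to target delta-chi2 increments of ~0.1 x the largest
    threshold (clamped to [min_step, max_step] internal units, at most
    ``max_steps`` per direction); each direction stops after one point beyond
    the threshold crossing, at the step limit / parameter bound, or on
    numeric failure.  If re-minimization beats the anchor by more than the
    re-anchor tolerance the optimum is replaced and the profile restarts.
    CI bounds come from linear interpolation of delta-chi2 across crossings.
    """
    if not fit_result.success:
        raise ValueError("cannot profile an unconverged fit")
    if parameter_id not in problem.free_names:
        raise ValueError(f"parameter {parameter_id!r} is fixed or unknown in this fit")
    settings = settings or FitSettings()
    options = options or ProfileOptions()
    spec = next(s for s in problem.free_specs if s.name == parameter_id)
    threshold_max = max(ci_threshold(t) for t in thresholds)
    target = options.target_fraction * threshold_max
    rng = np.random.default_rng(settings.seed)

    theta_hat = dict(fit_result.theta_hat)
    anchor = _reminimize(
        problem, parameter_id, theta_hat[parameter_id], theta_hat, options, settings, rng
    )
    if anchor is None:
        raise ValueError("re-minimization failed at the optimum itself")
    chi2_hat, theta_hat = anchor

    for _ in range(options.max_reanchors + 1):
        out = _walk_both(
            problem,
            spec,
            theta_hat,
            chi2_hat,
            threshold_max,
            target,
            options,
            settings,
            rng,
        )
        if isinstance(out, tuple):  # re-anchor: better optimum found
            chi2_hat, theta_hat = out
            continue
        prof = out
        break
    else:  # pragma: no cover - excessive re-anchoring
        out = _walk_both(
            problem, spec, theta_hat, chi2_hat, np.inf, target, options, settings, rng
        )
        if isinstance(out, tuple):
            raise RuntimeError("profile re-anchoring failed to converge")
        prof = out

    prof.parameter_id = parameter_id
    for t in thresholds:
        prof.ci[t.key] = _extract_ci(prof, ci_threshold(t))
    prof.status = classify(prof, threshold_max)
    return prof


def _walk_both(problem, spec, theta_hat, chi2_hat, threshold_max, target,
               options, settings, rng):
    """One full two-direction walk; returns a profile, or (cost, theta) when a
    better optimum forces re-anchoring."""
    x_opt = spec.to_internal(theta_hat[spec.name])
    lo, hi = spec.to_internal(spec.lower), spec.to_internal(spec.upper)
    sides: dict[str, tuple[list, str]] = {}
    n_reanchors = 0
    for label, direction, limit in (("upper", +1.0, hi), ("lower", -1.0, lo)):
        points = []  # (internal value, cost, theta)
        step = options.initial_step
        x = x_opt
        warm = dict(theta_hat)
        prev_delta = 0.0
        reason = "step_limit"
        retries = 0
        while len(points) < options.max_steps:
            if (x - limit) * direction >= -1e-12:
                reason = "bound"
                break
            x_next = x + direction * step
            if (x_next - limit) * direction > 0:
                x_next = limit
            value = spec.from_internal(x_next)
            res = _reminimize(
                problem, spec.name, value, warm, options, settings, rng
            )
            if res is None:
                reason = "failure"
                break
            cost, theta = res
            delta = cost - chi2_hat
            if delta < -options.reanchor_tol:
                return cost, theta  # re-anchor
            inc = delta - prev_delta
            # retract an overshooting step so crossings are finely resolved
            if (
                inc > 2.0 * target
                and step > options.min_step * 1.0001
                and retries < 20
            ):
                step = max(step * 0.5, options.min_step)
                retries += 1
                continue
            retries = 0
            points.append((x_next, cost, theta))
            warm = theta
            x = x_next
            if delta > threshold_max:
                reason = "threshold"
                break
            if inc < 0.25 * target:
                step = min(step * 1.6, options.max_step)
            prev_delta = delta
        sides[label] = (points, reason)

    lower_pts, lower_reason = sides["lower"]
    upper_pts, upper_reason = sides["upper"]
    internal = (
        [x for x, _, _ in reversed(lower_pts)] + [x_opt] + [x for x, _, _ in upper_pts]
    )
    costs = (
        [c for _, c, _ in reversed(lower_pts)] + [chi2_hat] + [c for _, c, _ in upper_pts]
    )
    cofits = (
        [t for _, _, t in reversed(lower_pts)]
        + [dict(theta_hat)]
        + [t for _, _, t in upper_pts]
    )
    grid = np.array([spec.from_internal(v) for v in internal])
    delta = np.array(costs) - chi2_hat
    return LikelihoodProfile(
        parameter_id=spec.name,
        grid=grid,
        delta_chi2=delta,
        cofits=cofits,
        optimum_value=spec.from_internal(x_opt),
        optimum_index=len(lower_pts),
        chi2_hat=chi2_hat,
        theta_hat=dict(theta_hat),
        log10=spec.log10,
        termination={"lower": lower_reason, "upper": upper_reason},
        n_reanchors=n_reanchors,
    )


def _extract_ci(prof: LikelihoodProfile, threshold: float) -> dict:
    """Interpolated crossing points of delta-chi2 with the threshold."""
    grid, delta, k = prof.grid, prof.delta_chi2, prof.optimum_index

    def crossing(indices) -> float | None:
        for i, j in zip(indices[:-1], indices[1:]):
            lo_d, hi_d = delta[i], delta[j]
            if lo_d <= threshold < hi_d:
                w = (threshold - lo_d) / (hi_d - lo_d)
                if prof.log10:
                    return float(
                        10 ** (np.log10(grid[i]) * (1 - w) + np.log10(grid[j]) * w)
                    )
                return float(grid[i] * (1 - w) + grid[j] * w)
        return None

    upper = crossing(list(range(k, len(grid))))
    lower = crossing(list(range(k, -1, -1)))
    return {
        "threshold": threshold,
        "lower": lower if lower is not None else float(grid[0]),
        "upper": upper if upper is not None else float(grid[-1]),
        "lower_unbounded": lower is None,
        "upper_unbounded": upper is None,
    }


def classify(prof: LikelihoodProfile, threshold: float) -> str:
    """identifiable / practically_nonidentifiable / structurally_nonidentifiable.

    A side terminated by numeric failure makes the overall status
    ``indeterminate`` — never a guess.
    """
    if any(r == "failure" for r in prof.termination.values()):
        return "indeterminate"
    ci = _extract_ci(prof, threshold)
    if not ci["lower_unbounded"] and not ci["upper_unbounded"]:
        return "identifiable"
    if np.all(prof.delta_chi2 <= FLATNESS_FRACTION * threshold):
        return "structurally_nonidentifiable"
    return "practically_nonidentifiable"


def profile_correlation(
    prof: LikelihoodProfile,
    cofit_parameter_id: str,
    threshold: float,
    bounds: tuple[float, float] | None = None,
) -> dict:
    """Log-log relation between the profiled parameter and one co-fitted
    parameter over the in-CI portion of the profile.

    Slope -1 with low residual indicates inverse proportionality (their
    product is fixed by the data); slope +1, a fixed ratio.  The relation is
    flagged unreliable when the co-fitted parameter sits at a bound on more
    than half the points.
    """
    mask = prof.in_ci_mask(threshold)
    if mask.sum() < 5:
        raise ValueError("need at least 5 in-CI grid points for a correlation")
    xs = np.log10(prof.grid[mask])
    ys = np.log10([c[cofit_parameter_id] for c, m in zip(prof.cofits, mask) if m])
    slope, intercept = np.polyfit(xs, ys, 1)
    resid = float(np.sqrt(np.mean((ys - (slope * xs + intercept)) ** 2)))
    unreliable = False
    if bounds is not None:
        lo, hi = bounds
        span = np.log10(hi) - np.log10(lo)
        at_bound = np.mean(
            (np.abs(ys - np.log10(lo)) < 0.01 * span)
            | (np.abs(ys - np.log10(hi)) < 0.01 * span)
        )
        unreliable = at_bound > 0.5
    return {
        "parameter_id": prof.parameter_id,
        "cofit_parameter_id": cofit_parameter_id,
        "slope": float(slope),
        "intercept": float(intercept),
        "residual": resid,
        "n_points": int(mask.sum()),
        "unreliable": unreliable,
    }


@dataclass
class TrajectoryBand:
    """Envelope of trajectories for parameter sets along an in-CI profile."""

    parameter_id: str
    time_grid: np.ndarray
    members: np.ndarray  # (n_sets, n_times)
    member_values: list[float]  # profiled parameter value per member
    best: np.ndarray
    lower: np.ndarray
    upper: np.ndarray


def trajectory_band(
    prof: LikelihoodProfile,
    simulate_fn: Callable[[dict], np.ndarray],
    time_grid: np.ndarray,
    threshold: float,
    n_sets: int = 11,
) -> TrajectoryBand:
    """Simulate ``n_sets`` parameter vectors evenly spaced along the in-CI
    portion of the profile (the best fit always included) and return the
    per-time envelope.  ``simulate_fn`` maps a full parameter dict to values
    on ``time_grid``."""
    if n_sets < 1:
        raise ValueError("n_sets must be >= 1")
    mask = prof.in_ci_mask(threshold)
    if not mask.any():
        raise ValueError("profile has no grid points inside the CI")
    idx = np.flatnonzero(mask)
    internal = np.log10(prof.grid[idx]) if prof.log10 else prof.grid[idx]
    if n_sets == 1:
        chosen = [prof.optimum_index]
    else:
        targets = np.linspace(internal[0], internal[-1], n_sets)
        chosen = sorted(
            {int(idx[np.argmin(np.abs(internal - t))]) for t in targets}
            | {prof.optimum_index}
        )
    members, values = [], []
    for i in chosen:
        members.append(np.asarray(simulate_fn(prof.cofits[i]), dtype=float))
        values.append(float(prof.grid[i]))
    members_arr = np.stack(members)
    best = np.asarray(simulate_fn(prof.theta_hat), dtype=float)
    return TrajectoryBand(
        parameter_id=prof.parameter_id,
        time_grid=np.asarray(time_grid, dtype=float),
        members=members_arr,
        member_values=values,
        best=best,
        lower=np.minimum(members_arr.min(axis=0), best),
        upper=np.maximum(members_arr.max(axis=0), best),
    )
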