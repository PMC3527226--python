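"""Time-dependent metabolic control coefficients (MCCs).

The MCC of parameter p on state variable x at time t is the relative response
(p/x(t)) · (dx(t)/dp), realized as a one-sided finite difference with a
−1% perturbation.  A forward-sensitivity integration
of the augmented system (exact derivatives via complex-step differentiation
of the right-hand side) serves as an independent oracle, and finite-fraction
inhibition runs connect the local coefficients to therapeutically sized
perturbations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .model import (
    OBSERVABLE_NAMES,
    STATE_NAMES,
    _DN_INDEX,
    _History,
    _integrate,
    basal_steady_state,
    observe,
    rhs,
    simulate,
    StateTrajectory,
)
from .params import PathwayParameters
from .profiles import LikelihoodProfile

__all__ = [
    "ControlCoefficientSeries",
    "mcc",
    "mcc_band",
    "inhibition_sim",
    "forward_sensitivity_mcc",
]

#: unperturbed variable values below this are reported as undefined
DENOM_EPS = 1e-9

# parameters appearing directly in each state's equation (initial conditions
# included); used to decide, by reachability, whether a parameter can
# influence a variable at all
_DIRECT_PARAMS: dict[str, set[str]] = {
    "IIr": {"k_act", "k_inact", "R_tot"},
    "STAT1Uc": {"k_phos", "k_inh", "k_impU", "k_exp", "k_tl_stat", "d_stat", "stat1_uc0"},
    "STAT1Dc": {"k_phos", "k_inh", "k_impD"},
    "STAT1Dn": {"k_impD", "k_deph"},
    "STAT1Un": {"k_deph", "k_impU", "k_exp", "d_stat", "stat1_un0"},
    "mSTAT1": {"b_m_stat", "k_tc_stat", "d_m_stat", "tau_stat"},
    "mSOCS1": {"k_tc_socs", "d_m_socs", "tau_socs"},
    "SOCS1": {"k_tl_socs", "d_socs"},
}

# state -> states feeding its equation
_STATE_INPUTS: dict[str, set[str]] = {
    "IIr": set(),
    "STAT1Uc": {"IIr", "SOCS1", "STAT1Un", "mSTAT1"},
    "STAT1Dc": {"IIr", "STAT1Uc", "SOCS1"},
    "STAT1Dn": {"STAT1Dc"},
    "STAT1Un": {"STAT1Dn", "STAT1Uc"},
    "mSTAT1": {"STAT1Dn"},
    "mSOCS1": {"STAT1Dn"},
    "SOCS1": {"mSOCS1"},
}

_OBS_INPUTS: dict[str, tuple[set[str], set[str]]] = {
    # observable -> (states entering it, parameters entering the map itself)
    "pSTAT1_wb": ({"STAT1Dc", "STAT1Dn"}, {"s_pstat"}),
    "STAT1_wb": ({"STAT1Uc", "STAT1Un", "STAT1Dc", "STAT1Dn"}, {"s_stat"}),
    "SOCS1_mrna": ({"mSOCS1"}, {"s_socs"}),
    "ratio_STAT1_nc": ({"STAT1Uc", "STAT1Un", "STAT1Dc", "STAT1Dn"}, set()),
    "ratio_STAT1D_nc": ({"STAT1Dc", "STAT1Dn"}, set()),
}


def parameter_influences(parameter_id: str, variable_id: str) -> bool:
    """True unless the parameter provably cannot influence the variable
    (static reachability through the reaction network)."""
    if variable_id in OBSERVABLE_NAMES:
        states, direct = _OBS_INPUTS[variable_id]
        if parameter_id in direct:
            return True
        return any(parameter_influences(parameter_id, s) for s in states)
    if variable_id not in STATE_NAMES:
        raise ValueError(f"unknown variable {variable_id!r}")
    seen: set[str] = set()
    stack = [variable_id]
    while stack:
        s = stack.pop()
        if s in seen:
            continue
        seen.add(s)
        if parameter_id in _DIRECT_PARAMS[s]:
            return True
        stack.extend(_STATE_INPUTS[s] - seen)
    return False


@dataclass
class ControlCoefficientSeries:
    """Time-resolved MCC of one parameter on one variable, optionally with a
    CI band over profile-derived parameter sets.  Undefined points (variable
    below the denominator epsilon) are NaN."""

    parameter_id: str
    variable_id: str
    time_grid: np.ndarray
    coefficient: np.ndarray
    delta: float
    band_lower: np.ndarray | None = None
    band_upper: np.ndarray | None = None
    members: np.ndarray | None = None  # (n_sets, n_times)
    member_values: list[float] = field(default_factory=list)


def _variable_series(
    traj: StateTrajectory, params: PathwayParameters, variable_id: str
) -> np.ndarray:
    if variable_id in STATE_NAMES:
        return traj.state(variable_id)
    if variable_id in OBSERVABLE_NAMES:
        return observe(traj, params)[variable_id]
    raise ValueError(f"unknown variable {variable_id!r}")


def _simulate_variable(
    params: PathwayParameters,
    variable_id: str,
    dose: float,
    grid: np.ndarray,
    **sim_kwargs,
) -> np.ndarray:
    """Variable values on ``grid``; a grid not starting at 0 is simulated from
    the stimulation time and sliced."""
    if grid.size and grid[0] == 0.0:
        traj = simulate(params, dose, grid, **sim_kwargs)
        return _variable_series(traj, params, variable_id)
    full = np.concatenate(([0.0], grid))
    traj = simulate(params, dose, full, **sim_kwargs)
    return _variable_series(traj, params, variable_id)[1:]


def mcc(
    params: PathwayParameters,
    parameter_id: str,
    variable_id: str = "STAT1Dn",
    dose: float = 100.0,
    time_grid: Sequence[float] | np.ndarray | None = None,
    delta: float = -0.01,
    **sim_kwargs,
) -> ControlCoefficientSeries:
    """One-sided finite-difference MCC: perturb p -> p·(1+delta), simulate
    both systems on the same grid, return (relative response)/(delta).

    Points where the unperturbed variable is below the denominator epsilon
    are masked (NaN); parameters that provably cannot influence the variable
    return an exact zero series.
    """
    if delta == 0 or abs(delta) >= 1:
        raise ValueError("delta must be nonzero with |delta| < 1")
    value = params[parameter_id]
    if value <= 0:
        raise ValueError(f"parameter {parameter_id} must be > 0 to perturb relatively")
    grid = np.asarray(
        time_grid if time_grid is not None else default_mcc_grid(), dtype=float
    )
    base = _simulate_variable(params, variable_id, dose, grid, **sim_kwargs)
    defined = np.abs(base) > DENOM_EPS

    if not parameter_influences(parameter_id, variable_id):
        coeff = np.zeros_like(base)
        coeff[~defined] = np.nan
        return ControlCoefficientSeries(
            parameter_id, variable_id, grid, coeff, delta
        )

    perturbed = params.replace(**{parameter_id: value * (1.0 + delta)})
    pert = _simulate_variable(perturbed, variable_id, dose, grid, **sim_kwargs)
    coeff = np.full_like(base, np.nan)
    coeff[defined] = (pert[defined] - base[defined]) / base[defined] / delta
    return ControlCoefficientSeries(parameter_id, variable_id, grid, coeff, delta)


def default_mcc_grid() -> np.ndarray:
    """Observation grid of the sensitivity analysis: every 30 min from 30 to
    540 (t = 0, where the phospho pools are empty, is excluded up front)."""
    return np.arange(30.0, 541.0, 30.0)


def mcc_band(
    prof: LikelihoodProfile,
    parameter_id: str,
    variable_id: str = "STAT1Dn",
    dose: float = 100.0,
    time_grid: Sequence[float] | np.ndarray | None = None,
    threshold: float | None = None,
    n_sets: int = 20,
    delta: float = -0.01,
    **sim_kwargs,
) -> ControlCoefficientSeries:
    """MCC envelope over ``n_sets`` parameter vectors evenly spaced along the
    in-CI portion of a likelihood profile (co-fitted partners included).

    The returned series' ``coefficient`` is the best-fit set's MCC; the band
    is the per-time min/max over all members, which always contains it.
    """
    if threshold is None:
        if not prof.ci:
            raise ValueError("profile carries no CI; pass threshold explicitly")
        threshold = list(prof.ci.values())[-1]["threshold"]
    mask = prof.in_ci_mask(threshold)
    if not mask.any():
        raise ValueError("profile has no grid points inside the CI")
    grid = np.asarray(
        time_grid if time_grid is not None else default_mcc_grid(), dtype=float
    )
    idx = np.flatnonzero(mask)
    internal = np.log10(prof.grid[idx]) if prof.log10 else prof.grid[idx]
    targets = np.linspace(internal[0], internal[-1], n_sets)
    chosen = sorted(
        {int(idx[np.argmin(np.abs(internal - t))]) for t in targets}
        | {prof.optimum_index}
    )
    members, values = [], []
    for i in chosen:
        p_i = PathwayParameters.from_dict(prof.cofits[i])
        series = mcc(
            p_i, parameter_id, variable_id, dose, grid, delta, **sim_kwargs
        )
        members.append(series.coefficient)
        values.append(float(prof.grid[i]))
    members_arr = np.stack(members)
    best = mcc(
        PathwayParameters.from_dict(prof.theta_hat),
        parameter_id,
        variable_id,
        dose,
        grid,
        delta,
        **sim_kwargs,
    ).coefficient
    with np.errstate(invalid="ignore"):
        lower = np.fmin(np.nanmin(members_arr, axis=0), best)
        upper = np.fmax(np.nanmax(members_arr, axis=0), best)
    return ControlCoefficientSeries(
        parameter_id=parameter_id,
        variable_id=variable_id,
        time_grid=grid,
        coefficient=best,
        delta=delta,
        band_lower=lower,
        band_upper=upper,
        members=members_arr,
        member_values=values,
    )


def inhibition_sim(
    params: PathwayParameters,
    parameter_id: str,
    fraction: float,
    dose: float = 100.0,
    time_grid: Sequence[float] | np.ndarray | None = None,
    variable_id: str = "STAT1Dn",
    **sim_kwargs,
) -> dict:
    """Simulate a finite inhibition: parameter scaled by (1 − fraction).

    Returns both trajectories and the per-time relative change of the target
    variable (NaN where the default run is below the denominator epsilon).
    """
    if not 0.0 <= fraction < 1.0:
        raise ValueError("fraction must be in [0, 1)")
    grid = np.asarray(
        time_grid if time_grid is not None else default_mcc_grid(), dtype=float
    )
    if grid.size == 0 or grid[0] != 0.0:
        grid = np.concatenate(([0.0], grid))
    base = simulate(params, dose, grid, **sim_kwargs)
    inhibited_params = params.replace(
        **{parameter_id: params[parameter_id] * (1.0 - fraction)}
    )
    inhibited = simulate(inhibited_params, dose, grid, **sim_kwargs)
    x0 = _variable_series(base, params, variable_id)
    x1 = _variable_series(inhibited, inhibited_params, variable_id)
    rel = np.full_like(x0, np.nan)
    ok = np.abs(x0) > DENOM_EPS
    rel[ok] = (x1[ok] - x0[ok]) / x0[ok]
    return {
        "parameter_id": parameter_id,
        "fraction": fraction,
        "variable_id": variable_id,
        "time_grid": grid,
        "default": base,
        "inhibited": inhibited,
        "relative_change": rel,
    }


# ---------------------------------------------------------------------------
# forward-sensitivity oracle (complex-step through the right-hand side)

_CS_H = 1e-100  # complex-step size; exact to machine precision

_IC_PARAMS = {"stat1_uc0": "STAT1Uc", "stat1_un0": "STAT1Un"}


def forward_sensitivity_mcc(
    params: PathwayParameters,
    parameter_id: str,
    variable_id: str = "STAT1Dn",
    dose: float = 100.0,
    time_grid: Sequence[float] | np.ndarray | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    method: str = "LSODA",
) -> ControlCoefficientSeries:
    """MCC from the forward-sensitivity augmented system.

    The state is extended with s = dx/dp and both blocks are integrated
    together; the sensitivity right-hand side (including delayed sensitivity
    terms) is obtained exactly by a complex-step directional derivative of the
    model right-hand side.  Delay parameters are not supported (the derivative
    with respect to a lag involves the delayed time derivative, outside this
    construction's scope).
    """
    if parameter_id in ("tau_socs", "tau_stat"):
        raise NotImplementedError("forward sensitivities for delay parameters")
    if parameter_id not in PathwayParameters.field_names():
        raise ValueError(f"unknown parameter {parameter_id!r}")
    grid = np.asarray(
        time_grid if time_grid is not None else default_mcc_grid(), dtype=float
    )
    if grid[0] != 0.0:
        grid_full = np.concatenate(([0.0], grid))
    else:
        grid_full = grid
    p = params.as_dict()
    p_value = p[parameter_id]
    n = len(STATE_NAMES)

    p_cs = dict(p)
    p_cs[parameter_id] = p[parameter_id] + 1j * _CS_H

    def aug_rhs(t, Y, dns, dnt):
        x = Y[:n]
        s = Y[n:]
        dns_x, dns_s = dns
        dnt_x, dnt_s = dnt
        base = rhs(t, x, dns_x, dnt_x, p, dose)
        z = rhs(
            t,
            x + 1j * _CS_H * s,
            dns_x + 1j * _CS_H * dns_s,
            dnt_x + 1j * _CS_H * dnt_s,
            p_cs,
            dose,
        )
        return np.concatenate([np.asarray(base, dtype=float), np.imag(z) / _CS_H])

    y0 = basal_steady_state(params)
    s0 = np.zeros(n)
    if parameter_id in _IC_PARAMS:
        s0[STATE_NAMES.index(_IC_PARAMS[parameter_id])] = 1.0
    elif parameter_id == "b_m_stat" and params.d_m_stat > 0:
        s0[STATE_NAMES.index("mSTAT1")] = 1.0 / params.d_m_stat
    elif parameter_id == "d_m_stat" and params.d_m_stat > 0:
        s0[STATE_NAMES.index("mSTAT1")] = -params.b_m_stat / params.d_m_stat**2
    Y0 = np.concatenate([y0, s0])

    def rhs_with_delays(t, Y, dns_pair, dnt_pair):
        return aug_rhs(t, Y, dns_pair, dnt_pair)

    # the delayed quantities are (state, sensitivity) pairs of STAT1Dn
    tau_socs, tau_stat = params.tau_socs, params.tau_stat

    class _PairHistory:
        def __init__(self, hist):
            self.hist = hist

        def fetch(self, t, Y, lag):
            if lag <= 0.0:
                return Y[_DN_INDEX], Y[n + _DN_INDEX]
            vec = self.hist(t - lag)
            return vec[_DN_INDEX], vec[n + _DN_INDEX]

    from scipy.integrate._ivp.ivp import METHODS

    history = _History(Y0)
    pair = _PairHistory(history)

    def wrapped(t, Y):
        return rhs_with_delays(
            t, Y, pair.fetch(t, Y, tau_socs), pair.fetch(t, Y, tau_stat)
        )

    t_end = float(grid_full[-1])
    positive = [lag for lag in (tau_socs, tau_stat) if lag > 0.0]
    max_step = min(positive) if positive else np.inf
    if t_end > 0:
        solver = METHODS[method](
            wrapped, 0.0, Y0, t_end, max_step=max_step, rtol=rtol, atol=atol
        )
        while solver.status == "running":
            message = solver.step()
            if solver.status == "failed":
                raise RuntimeError(f"sensitivity integration failed: {message}")
            history.append(solver.dense_output())
    Y = np.stack([history(t) for t in grid])

    x = Y[:, : n]
    s = Y[:, n :]
    traj = StateTrajectory(grid, np.clip(x, 0.0, None), float(dose))
    if variable_id in STATE_NAMES:
        xv = x[:, STATE_NAMES.index(variable_id)]
        sv = s[:, STATE_NAMES.index(variable_id)]
    else:
        xv, sv = _observable_sensitivity(traj, x, s, params, parameter_id, variable_id)
    coeff = np.full(len(grid), np.nan)
    ok = np.isfinite(xv) & (np.abs(xv) > DENOM_EPS)
    coeff[ok] = p_value * sv[ok] / xv[ok]
    return ControlCoefficientSeries(
        parameter_id, variable_id, grid, coeff, delta=0.0
    )


def _observable_sensitivity(traj, x, s, params, parameter_id, variable_id):
    """Chain rule through the observation map, complex-step on its inputs."""
    idx = {name: j for j, name in enumerate(STATE_NAMES)}
    p = params.as_dict()
    dp = {k: (1.0 if k == parameter_id else 0.0) for k in p}

    def obs_fn(states_row, pmap):
        Uc, Dc = states_row[idx["STAT1Uc"]], states_row[idx["STAT1Dc"]]
        Dn, Un = states_row[idx["STAT1Dn"]], states_row[idx["STAT1Un"]]
        mC = states_row[idx["mSOCS1"]]
        if variable_id == "pSTAT1_wb":
            return pmap["s_pstat"] * (Dc + Dn)
        if variable_id == "STAT1_wb":
            return pmap["s_stat"] * (Uc + Un + Dc + Dn)
        if variable_id == "SOCS1_mrna":
            return pmap["s_socs"] * mC
        if variable_id == "ratio_STAT1_nc":
            return pmap["v_nc"] * (Dn + Un) / (Dc + Uc)
        if variable_id == "ratio_STAT1D_nc":
            return pmap["v_nc"] * Dn / Dc
        raise ValueError(f"unknown variable {variable_id!r}")

    p_cs = {k: v + 1j * _CS_H * dp[k] for k, v in p.items()}
    xv = np.empty(x.shape[0])
    sv = np.empty(x.shape[0])
    with np.errstate(divide="ignore", invalid="ignore"):
        for i in range(x.shape[0]):
            xv[i] = float(np.real(obs_fn(x[i], p)))
            sv[i] = float(np.imag(obs_fn(x[i] + 1j * _CS_H * s[i], p_cs)) / _CS_H)
    return xv, sv
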