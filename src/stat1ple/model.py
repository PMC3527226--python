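"""Delay-ODE model of IFNγ-induced STAT1 signalling.

The network: IFNγ activates the type II interferon receptor (JAKs lumped into
the active complex ``IIr``); active receptor phosphorylates cytoplasmic STAT1
(``STAT1Uc`` → ``STAT1Dc``, homodimerization collapsed into this step and all
phospho pools counted in monomer equivalents); phospho-STAT1 translocates to
the nucleus (``STAT1Dn``), is dephosphorylated there (``STAT1Un``) and exported
back; nuclear phospho-STAT1 drives delayed transcription of the feedback
inhibitor SOCS1 and of STAT1 itself.  SOCS1 protein inhibits the
phosphorylation step through the saturating factor ``1/(1 + k_inh·SOCS1)``.

Transcriptional delays are constant lags handled by the method of steps with
dense-output history interpolation; the pre-stimulus history equals the basal
state.  A linear-chain (gamma-stage) approximation of the delays is available
as an independent integration route.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .params import PathwayParameters

__all__ = [
    "STATE_NAMES",
    "OBSERVABLE_NAMES",
    "StateTrajectory",
    "ObservableSet",
    "IntegrationError",
    "basal_steady_state",
    "rhs",
    "simulate",
    "observe",
    "simulate_observables",
]

STATE_NAMES: tuple[str, ...] = (
    "IIr",
    "STAT1Uc",
    "STAT1Dc",
    "STAT1Dn",
    "STAT1Un",
    "mSTAT1",
    "mSOCS1",
    "SOCS1",
)

OBSERVABLE_NAMES: tuple[str, ...] = (
    "pSTAT1_wb",
    "STAT1_wb",
    "SOCS1_mrna",
    "ratio_STAT1_nc",
    "ratio_STAT1D_nc",
)

#: denominator below which a ratio observable is reported as undefined (NaN)
RATIO_EPS = 1e-9

#: states reported more negative than this raise IntegrationError
NEGATIVE_TOL = 1e-8


class IntegrationError(RuntimeError):
    """Raised when the delay-ODE integration fails or produces invalid states."""


@dataclass(frozen=True)
class StateTrajectory:
    """Model states on a time grid, in arbitrary units."""

    time_grid: np.ndarray  # minutes, strictly increasing, starts at 0
    states: np.ndarray  # shape (n_times, 8), columns follow STATE_NAMES
    dose: float  # IFNγ, ng/ml

    def __post_init__(self) -> None:
        if self.states.shape != (self.time_grid.size, len(STATE_NAMES)):
            raise ValueError("states must have one row per time point")

    def state(self, name: str) -> np.ndarray:
        return self.states[:, STATE_NAMES.index(name)]

    def to_frame(self) -> pd.DataFrame:
        """Tidy representation: time_min, variable, value, dose_ng_ml."""
        frames = []
        for j, name in enumerate(STATE_NAMES):
            frames.append(
                pd.DataFrame(
                    {
                        "time_min": self.time_grid,
                        "variable": name,
                        "value": self.states[:, j],
                        "dose_ng_ml": self.dose,
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)


@dataclass(frozen=True)
class ObservableSet:
    """The five measured quantities evaluated on a trajectory's grid.

    Undefined ratio points (denominator below ``RATIO_EPS``) are NaN.
    """

    time_grid: np.ndarray
    values: dict[str, np.ndarray]
    dose: float

    def __getitem__(self, name: str) -> np.ndarray:
        return self.values[name]

    def to_frame(self) -> pd.DataFrame:
        frames = []
        for name in OBSERVABLE_NAMES:
            frames.append(
                pd.DataFrame(
                    {
                        "time_min": self.time_grid,
                        "variable": name,
                        "value": self.values[name],
                        "dose_ng_ml": self.dose,
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# right-hand side


def rhs(t, y, delayed_dn_socs, delayed_dn_stat, p, dose):
    """Time derivative of the eight model states.

    ``delayed_dn_socs`` / ``delayed_dn_stat`` are STAT1Dn evaluated at
    ``t - tau_socs`` and ``t - tau_stat``.  Written to be dtype-generic so the
    same code propagates complex-step sensitivities.
    """
    IIr, Uc, Dc, Dn, Un, mS, mC, S = y
    flux = p["k_phos"] * IIr * Uc / (1.0 + p["k_inh"] * S)
    dIIr = p["k_act"] * dose * (p["R_tot"] - IIr) - p["k_inact"] * IIr
    dUc = (
        -flux
        - p["k_impU"] * Uc
        + p["k_exp"] * Un
        + p["k_tl_stat"] * mS
        - p["d_stat"] * Uc
    )
    dDc = flux - p["k_impD"] * Dc
    dDn = p["k_impD"] * Dc - p["k_deph"] * Dn
    dUn = p["k_deph"] * Dn + p["k_impU"] * Uc - p["k_exp"] * Un - p["d_stat"] * Un
    dmS = p["b_m_stat"] + p["k_tc_stat"] * delayed_dn_stat - p["d_m_stat"] * mS
    dmC = p["k_tc_socs"] * delayed_dn_socs - p["d_m_socs"] * mC
    dS = p["k_tl_socs"] * mC - p["d_socs"] * S
    if isinstance(y, np.ndarray):
        return np.array([dIIr, dUc, dDc, dDn, dUn, dmS, dmC, dS], dtype=y.dtype)
    return [dIIr, dUc, dDc, dDn, dUn, dmS, dmC, dS]


def _make_fast_rhs(p: dict, dose: float) -> Callable:
    """Closure over plain floats; avoids per-call dict lookups in the solver
    inner loop.  Semantically identical to :func:`rhs`."""
    k_act, k_inact, R_tot = p["k_act"], p["k_inact"], p["R_tot"]
    k_phos, k_inh = p["k_phos"], p["k_inh"]
    k_impD, k_impU, k_exp, k_deph = p["k_impD"], p["k_impU"], p["k_exp"], p["k_deph"]
    k_tc_socs, d_m_socs = p["k_tc_socs"], p["d_m_socs"]
    k_tl_socs, d_socs = p["k_tl_socs"], p["d_socs"]
    b_m_stat, k_tc_stat, d_m_stat = p["b_m_stat"], p["k_tc_stat"], p["d_m_stat"]
    k_tl_stat, d_stat = p["k_tl_stat"], p["d_stat"]
    act_in = k_act * dose * R_tot
    act_out = k_act * dose + k_inact

    def fast_rhs(t, y, dns, dnt):
        IIr, Uc, Dc, Dn, Un, mS, mC, S = y
        flux = k_phos * IIr * Uc / (1.0 + k_inh * S)
        return np.array(
            [
                act_in - act_out * IIr,
                -flux - k_impU * Uc + k_exp * Un + k_tl_stat * mS - d_stat * Uc,
                flux - k_impD * Dc,
                k_impD * Dc - k_deph * Dn,
                k_deph * Dn + k_impU * Uc - k_exp * Un - d_stat * Un,
                b_m_stat + k_tc_stat * dnt - d_m_stat * mS,
                k_tc_socs * dns - d_m_socs * mC,
                k_tl_socs * mC - d_socs * S,
            ]
        )

    return fast_rhs


def basal_steady_state(
    params: PathwayParameters, return_residual: bool = False
) -> np.ndarray | tuple[np.ndarray, float]:
    """Unstimulated (dose = 0) state used as pre-stimulus history.

    Receptor and all phospho/SOCS1 pools are zero; STAT1 mRNA sits at its
    synthesis/degradation balance ``b_m_stat/d_m_stat``; the unphosphorylated
    STAT1 pools take the (estimable) initial conditions from ``params``.  If
    the initial conditions are not chosen consistently with synthesis and
    turnover the state is not an exact equilibrium; the right-hand-side
    residual norm is returned alongside when ``return_residual`` is set.
    """
    if params.d_m_stat <= 0 and params.b_m_stat > 0:
        raise ValueError("no finite basal state: b_m_stat > 0 with d_m_stat = 0")
    m_stat = params.b_m_stat / params.d_m_stat if params.d_m_stat > 0 else 0.0
    y0 = np.zeros(len(STATE_NAMES))
    y0[STATE_NAMES.index("STAT1Uc")] = params.stat1_uc0
    y0[STATE_NAMES.index("STAT1Un")] = params.stat1_un0
    y0[STATE_NAMES.index("mSTAT1")] = m_stat
    if return_residual:
        p = params.as_dict()
        dn = y0[STATE_NAMES.index("STAT1Dn")]
        residual = float(np.linalg.norm(rhs(0.0, y0, dn, dn, p, 0.0)))
        return y0, residual
    return y0


# ---------------------------------------------------------------------------
# method-of-steps integration with dense-output history


class _History:
    """Piecewise trajectory: constant basal state for t <= 0, then the dense
    interpolant of every accepted solver step."""

    def __init__(self, y0: np.ndarray):
        self.y0 = y0
        self.t_grid: list[float] = [0.0]  # step boundaries
        self.interpolants: list = []

    def append(self, interp) -> None:
        self.interpolants.append(interp)
        self.t_grid.append(interp.t_max if interp.t_max > interp.t_min else interp.t_min)

    def __call__(self, t: float):
        if t <= 0.0:
            return self.y0
        hi = self.t_grid[-1]
        if t > hi + 1e-9:
            raise IntegrationError(f"history requested beyond integrated range: t={t}")
        import bisect

        k = bisect.bisect_left(self.t_grid, t) - 1
        k = min(max(k, 0), len(self.interpolants) - 1)
        return self.interpolants[k](min(t, hi))


_DN_INDEX = STATE_NAMES.index("STAT1Dn")

_SOLVERS = {
    "RK45": "RK45",
    "DOP853": "DOP853",
    "LSODA": "LSODA",
    "BDF": "BDF",
    "Radau": "Radau",
}


def _integrate(
    rhs_fn: Callable,
    y0: np.ndarray,
    t_end: float,
    lags: tuple[float, float],
    dn_index: int,
    method: str,
    rtol: float,
    atol: float,
    max_steps: int = 100_000,
) -> _History:
    """Integrate ``y' = rhs_fn(t, y, dn(t-tau_socs), dn(t-tau_stat))`` by the
    method of steps.

    A single solver instance steps with ``max_step`` equal to the smallest
    positive lag, so every delayed lookup falls into already-completed dense
    output; zero lags are evaluated from the current state.
    """
    from scipy.integrate._ivp.ivp import METHODS

    history = _History(y0)
    tau_socs, tau_stat = lags
    # lags far below the horizon are numerically indistinguishable from the
    # plain-ODE limit and would force pathologically small max_step
    small_lag = max(1e-9, 1e-4 * t_end)
    positive = [lag for lag in lags if lag > small_lag]
    max_step = min(positive) if positive else np.inf

    def wrapped(t, y):
        dns = y[dn_index] if tau_socs <= small_lag else history(t - tau_socs)[dn_index]
        dnt = y[dn_index] if tau_stat <= small_lag else history(t - tau_stat)[dn_index]
        return rhs_fn(t, y, dns, dnt)

    try:
        solver_cls = METHODS[_SOLVERS[method]]
    except KeyError as exc:
        raise ValueError(f"unknown integration method {method!r}") from exc
    solver = solver_cls(
        wrapped, 0.0, y0, t_end, max_step=max_step, rtol=rtol, atol=atol
    )
    n = 0
    while solver.status == "running":
        message = solver.step()
        if solver.status == "failed":
            raise IntegrationError(f"integration failed at t={solver.t}: {message}")
        history.append(solver.dense_output())
        n += 1
        if n > max_steps:
            raise IntegrationError("integration failed: step limit exceeded")
    return history


def _validate_grid(time_grid: np.ndarray) -> np.ndarray:
    grid = np.asarray(time_grid, dtype=float)
    if grid.ndim != 1 or grid.size < 1:
        raise ValueError("time_grid must be a 1-D array with at least one point")
    if grid[0] != 0.0:
        raise ValueError("time_grid must start at 0 (stimulation time)")
    if grid.size > 1 and not np.all(np.diff(grid) > 0):
        raise ValueError("time_grid must be strictly increasing")
    return grid


def simulate(
    params: PathwayParameters,
    dose: float,
    time_grid: Sequence[float] | np.ndarray,
    *,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    method: str = "LSODA",
    delay_method: str = "steps",
    chain_order: int = 20,
    y0: np.ndarray | None = None,
) -> StateTrajectory:
    """Integrate the stimulated pathway on ``time_grid`` (minutes, from 0).

    ``delay_method='steps'`` (default) integrates the true constant-lag system
    by the method of steps; ``'chain'`` replaces each lag by a linear chain of
    ``chain_order`` first-order stages, which converges to the constant lag as
    the order grows and serves as an independent cross-check.
    ``method`` is any scipy ``solve_ivp`` method name.
    """
    grid = _validate_grid(time_grid)
    if dose < 0:
        raise ValueError("dose must be >= 0")
    if y0 is None:
        y0 = basal_steady_state(params)
    p = params.as_dict()
    t_end = float(grid[-1])

    if delay_method == "steps":
        rhs_fn = _make_fast_rhs(p, dose)
        if t_end > 0:
            history = _integrate(
                rhs_fn,
                y0,
                t_end,
                (params.tau_socs, params.tau_stat),
                _DN_INDEX,
                method,
                rtol,
                atol,
            )
            states = np.stack([history(t) for t in grid])
        else:
            states = y0[None, :].copy()
    elif delay_method == "chain":
        states = _simulate_chain(p, dose, grid, y0, chain_order, method, rtol, atol)
    else:
        raise ValueError(f"unknown delay_method {delay_method!r}")

    low = states.min(initial=0.0)
    neg_tol = max(NEGATIVE_TOL, 10.0 * atol, rtol)
    if low < -neg_tol * max(1.0, float(np.abs(states).max())):
        raise IntegrationError(
            f"integration failed: negative state beyond tolerance (min={low:.3e})"
        )
    states = np.clip(states, 0.0, None) if low < 0 else states
    return StateTrajectory(time_grid=grid, states=states, dose=float(dose))


def _simulate_chain(
    p: dict,
    dose: float,
    grid: np.ndarray,
    y0: np.ndarray,
    order: int,
    method: str,
    rtol: float,
    atol: float,
) -> np.ndarray:
    """Linear-chain (Erlang-stage) approximation of the two delay terms."""
    if order < 1:
        raise ValueError("chain_order must be >= 1")
    n = len(STATE_NAMES)
    use_socs = p["tau_socs"] > 0
    use_stat = p["tau_stat"] > 0
    n_socs = order if use_socs else 0
    n_stat = order if use_stat else 0
    dn0 = y0[_DN_INDEX]

    def full_rhs(t, z):
        y = z[:n]
        dn = y[_DN_INDEX]
        if use_socs:
            chain_s = z[n : n + n_socs]
            dns = chain_s[-1]
        else:
            chain_s = np.empty(0)
            dns = dn
        if use_stat:
            chain_t = z[n + n_socs :]
            dnt = chain_t[-1]
        else:
            chain_t = np.empty(0)
            dnt = dn
        dy = rhs(t, y, dns, dnt, p, dose)
        parts = [dy]
        if use_socs:
            rate = order / p["tau_socs"]
            inputs = np.concatenate(([dn], chain_s[:-1]))
            parts.append(rate * (inputs - chain_s))
        if use_stat:
            rate = order / p["tau_stat"]
            inputs = np.concatenate(([dn], chain_t[:-1]))
            parts.append(rate * (inputs - chain_t))
        return np.concatenate(parts)

    z0 = np.concatenate([y0, np.full(n_socs + n_stat, dn0)])
    t_end = float(grid[-1])
    if t_end == 0:
        return y0[None, :].copy()
    sol = solve_ivp(
        full_rhs,
        (0.0, t_end),
        z0,
        method=method,
        t_eval=grid,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise IntegrationError(f"integration failed: {sol.message}")
    return sol.y[:n].T


# ---------------------------------------------------------------------------
# observation map


def observe(traj: StateTrajectory, params: PathwayParameters) -> ObservableSet:
    """Map model states to the five measured quantities.

    Immunoblot channels are model pools times their arbitrary-unit scaling
    factor.  Immunofluorescence channels are nuclear:cytoplasmic
    *concentration* ratios: model states are amounts (so that total STAT1 is
    conserved in monomer equivalents), and the measured pixel-intensity ratio
    equals the amount ratio times the cytoplasm:nucleus volume ratio ``v_nc``.
    Both ratios remain invariant under rescaling of all STAT1 species.  Ratio
    points whose denominator falls below ``RATIO_EPS`` are undefined (NaN),
    not an error.
    """
    s = traj.states
    idx = {name: j for j, name in enumerate(STATE_NAMES)}
    Uc, Dc = s[:, idx["STAT1Uc"]], s[:, idx["STAT1Dc"]]
    Dn, Un = s[:, idx["STAT1Dn"]], s[:, idx["STAT1Un"]]
    mC = s[:, idx["mSOCS1"]]
    values = {
        "pSTAT1_wb": params.s_pstat * (Dc + Dn),
        "STAT1_wb": params.s_stat * (Uc + Un + Dc + Dn),
        "SOCS1_mrna": params.s_socs * mC,
        "ratio_STAT1_nc": params.v_nc * _safe_ratio(Dn + Un, Dc + Uc),
        "ratio_STAT1D_nc": params.v_nc * _safe_ratio(Dn, Dc),
    }
    return ObservableSet(time_grid=traj.time_grid, values=values, dose=traj.dose)


def _safe_ratio(num: np.ndarray, den: np.ndarray) -> np.ndarray:
    out = np.full_like(num, np.nan, dtype=float)
    ok = den > RATIO_EPS
    out[ok] = num[ok] / den[ok]
    return out


def simulate_observables(
    params: PathwayParameters,
    dose: float,
    time_grid: Sequence[float] | np.ndarray,
    **kwargs,
) -> ObservableSet:
    """Convenience: :func:`simulate` followed by :func:`observe`."""
    return observe(simulate(params, dose, time_grid, **kwargs), params)
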