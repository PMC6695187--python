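"""Vector fields and trajectory integration for the APL model.

The untreated system is

    dN/dt = r_N − μ_N·N − β1·N·A
    dA/dt = r_A·A·(1 − A/K_A) − β2·N·A − μ_A·A

and induction therapy adds an ATRA maturation flux β3·A from the leukemic
to the normal pool while the ATRA window is active, a proportional chemo
kill −γ·D on both populations, and a drug amount D driven by instantaneous
doses ρ·bsa (mg) at the scheduled days with first-order clearance τ.

Doses are genuine impulses: the integrator restarts at every dose day with
D incremented, and also breaks at the ATRA window edges so no discontinuity
ever sits inside an adaptive step.  Because D is autonomous, its exact
solution is the superposition of decaying exponentials implemented in
:func:`chemo_concentration`; every simulation can be checked against it.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .params import ModelParameters, ModelState, Trajectory, TreatmentProtocol

__all__ = [
    "SimulationError",
    "untreated_rhs",
    "treated_rhs",
    "chemo_concentration",
    "simulate",
    "simulate_at",
]

#: default integrator tolerances (cells/mm³ scale)
RTOL = 1e-8
ATOL = 1e-8
#: negative undershoot beyond -100·atol is treated as an integration failure
CLIP_FACTOR = 100.0


class SimulationError(RuntimeError):
    """Integration failed; carries the time at which it failed."""

    def __init__(self, message: str, t: float | None = None):
        super().__init__(message)
        self.t = t


def _check_state(state) -> None:
    arr = np.asarray(state, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"non-finite state {state!r}")


def untreated_rhs(params: ModelParameters, state) -> tuple[float, float]:
    """Right-hand side of the untreated competition system at (N, A)."""
    _check_state(state)
    N, A = float(state[0]), float(state[1])
    p = params
    dN = p.r_N - p.mu_N * N - p.beta1 * N * A
    dA = p.r_A * A * (1.0 - A / p.K_A) - p.beta2 * N * A - p.mu_A * A
    return dN, dA


def treated_rhs(
    params: ModelParameters, protocol: TreatmentProtocol, state: ModelState
) -> tuple[float, float, float]:
    """Continuous part of the treated system at a state (t, N, A, D).

    Dose impulses are *not* part of this field; they are applied by the
    integrator.  The ATRA switch is evaluated at ``state.t`` with the
    half-open convention [atra_start, atra_end).
    """
    _check_state((state.t, state.N, state.A, state.D))
    dN, dA = untreated_rhs(params, (state.N, state.A))
    if protocol.atra_active(state.t):
        dN += protocol.beta3 * state.A
        dA -= protocol.beta3 * state.A
    dN -= protocol.gamma * state.D * state.N
    dA -= protocol.gamma * state.D * state.A
    dD = -protocol.tau * state.D
    return dN, dA, dD


def chemo_concentration(protocol: TreatmentProtocol, t) -> np.ndarray | float:
    """Closed-form drug amount D(t) = Σ_{t_i ≤ t} ρ·bsa·exp(−τ·(t−t_i)), mg.

    The post-dose convention D(t_i) = D(t_i⁺) is used.  This is the exact
    solution of the impulsive decay equation and serves as the analytic
    oracle for the integrator's D component.
    """
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    D = np.zeros_like(t_arr)
    for ti in protocol.dose_days:
        mask = t_arr >= ti
        D[mask] += protocol.dose_mg * np.exp(-protocol.tau * (t_arr[mask] - ti))
    return D if np.ndim(t) else float(D[0])


def chemo_oracle_error(traj: Trajectory) -> float:
    """Max |D(t) − closed form| over a trajectory, honouring impulses.

    The closed form uses the post-dose convention D(t_i) = D(t_i⁺); the
    trajectory stores both the pre- and post-dose value at each dose day,
    so the pre-dose sample is compared against the closed form minus the
    impulse just delivered.
    """
    proto = traj.protocol
    expected = np.asarray(chemo_concentration(proto, traj.t))
    dose_set = set(proto.dose_days)
    for i in range(len(traj.t) - 1):
        if traj.t[i] == traj.t[i + 1] and traj.t[i] in dose_set:
            expected[i] -= proto.dose_mg
    return float(np.max(np.abs(traj.D - expected)))


def chemo_exposure(protocol: TreatmentProtocol, t_end: float) -> float:
    """Closed-form cumulative exposure ∫₀^t_end D(s) ds, mg·day."""
    total = 0.0
    for ti in protocol.dose_days:
        if ti < t_end:
            total += protocol.dose_mg * (1.0 - math.exp(-protocol.tau * (t_end - ti))) / protocol.tau
    return total


def _breakpoints(protocol: TreatmentProtocol, t_end: float) -> list[float]:
    pts = {0.0, float(t_end)}
    for edge in (protocol.atra_start, protocol.atra_end):
        if 0.0 < edge < t_end:
            pts.add(float(edge))
    for ti in protocol.dose_days:
        if ti <= t_end:
            pts.add(float(ti))
    return sorted(pts)


def _segment_rhs(params: ModelParameters, protocol: TreatmentProtocol,
                 atra_on: bool, D0: float, t0: float):
    """(N, A) field on one smooth segment.

    The drug subsystem is linear and autonomous, so within a segment it
    is propagated exactly as D(t) = D0·exp(−τ·(t−t0)) instead of being
    integrated numerically; only the nonlinear (N, A) pair goes through
    the ODE solver.
    """
    p, g, tau, b3 = params, protocol.gamma, protocol.tau, protocol.beta3

    def rhs(t, y):
        N, A = y
        D = D0 * math.exp(-tau * (t - t0))
        dN = p.r_N - p.mu_N * N - p.beta1 * N * A - g * D * N
        dA = p.r_A * A * (1.0 - A / p.K_A) - p.beta2 * N * A - p.mu_A * A - g * D * A
        if atra_on:
            dN += b3 * A
            dA -= b3 * A
        return (dN, dA)

    return rhs


def _clip(y: np.ndarray, atol: float, t: float) -> np.ndarray:
    low = y.min()
    if low < -CLIP_FACTOR * atol:
        raise SimulationError(
            f"state went negative ({low:.3g}) beyond clipping tolerance", t=t
        )
    return np.maximum(y, 0.0)

def _integrate(params, protocol, init, t_end, *, rtol, atol, method,
               grid_times, extra_times):
    """Piecewise integration shared by :func:`simulate` and :func:`simulate_at`.

    ``grid_times``: sorted array of output times in (0, t_end]; dose days
    are additionally emitted pre- and post-impulse when ``grid_times is
    not None`` (dense mode).  ``extra_times`` is used in sparse mode.
    """
    N0, A0 = float(init[0]), float(init[1])
    if N0 < 0 or A0 < 0:
        raise ValueError("initial cell counts must be non-negative")
    dose_days = [ti for ti in protocol.dose_days if ti <= t_end]
    breaks = _breakpoints(protocol, t_end)
    out_t = np.asarray(grid_times if grid_times is not None else extra_times,
                       dtype=float)

    freeze_A = A0 == 0.0
    y = np.array([N0, A0])
    D = 0.0
    ts: list[float] = [0.0]
    ys: list[np.ndarray] = []
    Ds: list[float] = []
    # dose at t=0, if any, applies before anything else
    if 0.0 in dose_days:
        ys.append(y.copy())
        Ds.append(D)
        ts.append(0.0)
        D += protocol.dose_mg
    ys.append(y.copy())
    Ds.append(D)

    for a, b in zip(breaks[:-1], breaks[1:]):
        atra_on = protocol.atra_active(0.5 * (a + b))
        t_eval = out_t[(out_t > a) & (out_t < b)]
        t_eval = np.concatenate([t_eval, [b]])
        sol = solve_ivp(
            _segment_rhs(params, protocol, atra_on, D, a),
            (a, b),
            y,
            method=method,
            rtol=rtol,
            atol=atol,
            t_eval=t_eval,
        )
        if not sol.success:
            raise SimulationError(f"integrator failed: {sol.message}", t=float(sol.t[-1]) if len(sol.t) else a)
        seg_y = sol.y.T
        seg_y = np.vstack([_clip(row, atol, t) for t, row in zip(sol.t, seg_y)])
        if freeze_A:
            seg_y[:, 1] = 0.0
        ts.extend(sol.t.tolist())
        ys.extend(list(seg_y))
        Ds.extend((D * np.exp(-protocol.tau * (sol.t - a))).tolist())
        y = seg_y[-1].copy()
        D = Ds[-1]
        if b in dose_days:
            # pre-dose state is the last sample; record the post-dose one
            D += protocol.dose_mg
            ts.append(b)
            ys.append(y.copy())
            Ds.append(D)

    t_arr = np.asarray(ts)
    y_arr = np.column_stack([np.asarray(ys), np.asarray(Ds)])
    return t_arr, y_arr


def simulate(
    params: ModelParameters,
    protocol: TreatmentProtocol,
    init: Sequence[float],
    t_end: float,
    *,
    rtol: float = RTOL,
    atol: float = ATOL,
    points_per_day: int = 20,
    method: str = "LSODA",
) -> Trajectory:
    """Integrate the treated model from (N0, A0) with D(0⁻) = 0.

    Returns a :class:`Trajectory` on a uniform grid of ``points_per_day``
    samples per day plus the pre- and post-dose states at every dose day.
    """
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    grid = np.linspace(0.0, t_end, int(round(points_per_day * t_end)) + 1)
    t_arr, y_arr = _integrate(
        params, protocol, init, float(t_end),
        rtol=rtol, atol=atol, method=method,
        grid_times=grid, extra_times=None,
    )
    return Trajectory(
        t=t_arr, N=y_arr[:, 0], A=y_arr[:, 1], D=y_arr[:, 2],
        params=params, protocol=protocol,
    )


def simulate_at(
    params: ModelParameters,
    protocol: TreatmentProtocol,
    init: Sequence[float],
    times,
    *,
    rtol: float = 1e-6,
    atol: float = 1e-3,
    method: str = "LSODA",
) -> tuple[np.ndarray, np.ndarray]:
    """Fast path: (N, A) at the requested observation days only.

    Used by the fitting objective, where only a handful of observation
    days matter and looser tolerances suffice (the objective is summed
    over counts of order 10³ cells/mm³).
    """
    times = np.sort(np.asarray(times, dtype=float))
    t_end = float(max(times[-1], 1e-6))
    t_arr, y_arr = _integrate(
        params, protocol, init, t_end,
        rtol=rtol, atol=atol, method=method,
        grid_times=None, extra_times=times,
    )
    N = np.interp(times, t_arr, y_arr[:, 0])
    A = np.interp(times, t_arr, y_arr[:, 1])
    return N, A
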