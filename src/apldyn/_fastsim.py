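"""Compiled fast path for the fitting objective.

The multistart estimator evaluates the model at a handful of observation
days tens of thousands of times; the generic scipy integrator's per-call
overhead dominates there.  This module provides a numba-compiled
adaptive Dormand–Prince (RK45) integrator for the (N, A) pair with the
drug amount propagated analytically, mirroring
:func:`apldyn.dynamics.simulate_at`.  It is an optimisation only: the
scipy path remains the reference, the two are cross-checked in the test
suite, and everything works (slower) if numba is unavailable.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is an optional accelerator
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f

        return wrap if not (args and callable(args[0])) else args[0]


# Dormand–Prince 5(4) coefficients
_C = np.array([0.0, 1 / 5, 3 / 10, 4 / 5, 8 / 9, 1.0, 1.0])
_A2 = np.array([1 / 5])
_A3 = np.array([3 / 40, 9 / 40])
_A4 = np.array([44 / 45, -56 / 15, 32 / 9])
_A5 = np.array([19372 / 6561, -25360 / 2187, 64448 / 6561, -212 / 729])
_A6 = np.array([9017 / 3168, -355 / 33, 46732 / 5247, 49 / 176, -5103 / 18656])
_B = np.array([35 / 384, 0.0, 500 / 1113, 125 / 192, -2187 / 6784, 11 / 84, 0.0])
_E = np.array(
    [71 / 57600, 0.0, -71 / 16695, 71 / 1920, -17253 / 339200, 22 / 525, -1 / 40]
)


@njit(cache=True)
def _rhs(t, N, A, r_N, mu_N, r_A, K_A, mu_A, b1, b2, b3, gam, tau, atra, D0, t0):
    D = D0 * np.exp(-tau * (t - t0))
    dN = r_N - mu_N * N - b1 * N * A - gam * D * N
    dA = r_A * A * (1.0 - A / K_A) - b2 * N * A - mu_A * A - gam * D * A
    if atra:
        dN += b3 * A
        dA -= b3 * A
    return dN, dA


@njit(cache=True)
def _step_to(t, tb, N, A, r_N, mu_N, r_A, K_A, mu_A, b1, b2, b3, gam, tau,
             atra, D0, t0, rtol, atol):
    """Adaptive DP45 from t to tb; returns (N, A, ok)."""
    h = min(0.05, tb - t)
    kN = np.empty(7)
    kA = np.empty(7)
    n_reject = 0
    while t < tb - 1e-12:
        if h > tb - t:
            h = tb - t
        kN[0], kA[0] = _rhs(t, N, A, r_N, mu_N, r_A, K_A, mu_A, b1, b2, b3,
                            gam, tau, atra, D0, t0)
        # stage 2
        yN = N + h * _A2[0] * kN[0]
        yA = A + h * _A2[0] * kA[0]
        kN[1], kA[1] = _rhs(t + _C[1] * h, yN, yA, r_N, mu_N, r_A, K_A, mu_A,
                            b1, b2, b3, gam, tau, atra, D0, t0)
        yN = N + h * (_A3[0] * kN[0] + _A3[1] * kN[1])
        yA = A + h * (_A3[0] * kA[0] + _A3[1] * kA[1])
        kN[2], kA[2] = _rhs(t + _C[2] * h, yN, yA, r_N, mu_N, r_A, K_A, mu_A,
                            b1, b2, b3, gam, tau, atra, D0, t0)
        yN = N + h * (_A4[0] * kN[0] + _A4[1] * kN[1] + _A4[2] * kN[2])
        yA = A + h * (_A4[0] * kA[0] + _A4[1] * kA[1] + _A4[2] * kA[2])
        kN[3], kA[3] = _rhs(t + _C[3] * h, yN, yA, r_N, mu_N, r_A, K_A, mu_A,
                            b1, b2, b3, gam, tau, atra, D0, t0)
        yN = N + h * (_A5[0] * kN[0] + _A5[1] * kN[1] + _A5[2] * kN[2]
                      + _A5[3] * kN[3])
        yA = A + h * (_A5[0] * kA[0] + _A5[1] * kA[1] + _A5[2] * kA[2]
                      + _A5[3] * kA[3])
        kN[4], kA[4] = _rhs(t + _C[4] * h, yN, yA, r_N, mu_N, r_A, K_A, mu_A,
                            b1, b2, b3, gam, tau, atra, D0, t0)
        yN = N + h * (_A6[0] * kN[0] + _A6[1] * kN[1] + _A6[2] * kN[2]
                      + _A6[3] * kN[3] + _A6[4] * kN[4])
        yA = A + h * (_A6[0] * kA[0] + _A6[1] * kA[1] + _A6[2] * kA[2]
                      + _A6[3] * kA[3] + _A6[4] * kA[4])
        kN[5], kA[5] = _rhs(t + h, yN, yA, r_N, mu_N, r_A, K_A, mu_A,
                            b1, b2, b3, gam, tau, atra, D0, t0)
        N5 = N + h * (_B[0] * kN[0] + _B[2] * kN[2] + _B[3] * kN[3]
                      + _B[4] * kN[4] + _B[5] * kN[5])
        A5 = A + h * (_B[0] * kA[0] + _B[2] * kA[2] + _B[3] * kA[3]
                      + _B[4] * kA[4] + _B[5] * kA[5])
        kN[6], kA[6] = _rhs(t + h, N5, A5, r_N, mu_N, r_A, K_A, mu_A,
                            b1, b2, b3, gam, tau, atra, D0, t0)
        errN = h * (_E[0] * kN[0] + _E[2] * kN[2] + _E[3] * kN[3]
                    + _E[4] * kN[4] + _E[5] * kN[5] + _E[6] * kN[6])
        errA = h * (_E[0] * kA[0] + _E[2] * kA[2] + _E[3] * kA[3]
                    + _E[4] * kA[4] + _E[5] * kA[5] + _E[6] * kA[6])
        sN = atol + rtol * max(abs(N), abs(N5))
        sA = atol + rtol * max(abs(A), abs(A5))
        err = np.sqrt(0.5 * ((errN / sN) ** 2 + (errA / sA) ** 2))
        if err <= 1.0:
            t += h
            N, A = N5, A5
            if not (np.isfinite(N) and np.isfinite(A)):
                return N, A, False
            if N < -1e-3 or A < -1e-3:
                return N, A, False
            if N < 0.0:
                N = 0.0
            if A < 0.0:
                A = 0.0
            n_reject = 0
        else:
            n_reject += 1
            if n_reject > 60:
                return N, A, False
        factor = 0.9 * err ** (-0.2) if err > 1e-10 else 5.0
        h *= min(5.0, max(0.2, factor))
        if h < 1e-10:
            return N, A, False
    return N, A, True


@njit(cache=True)
def integrate_obs(times, breaks, atra_on, dose_at, theta, rtol, atol):
    """(N, A) at observation ``times``.

    ``breaks``: segment boundaries (first = 0, last = horizon);
    ``atra_on``: per-segment ATRA flag; ``dose_at``: drug mass added at
    each boundary (index aligned with ``breaks``); ``theta``: the 10
    rates (r_N, mu_N, r_A, K_A, mu_A, β1, β2, β3, γ, τ) followed by
    (N0, A0).  Returns (N, A, ok).
    """
    r_N, mu_N, r_A, K_A, mu_A, b1, b2, b3, gam, tau, N, A = theta
    outN = np.empty(times.size)
    outA = np.empty(times.size)
    j = 0
    D0 = dose_at[0]
    for s in range(breaks.size - 1):
        a = breaks[s]
        b = breaks[s + 1]
        flag = atra_on[s]
        t = a
        while j < times.size and times[j] <= b + 1e-12:
            tt = min(times[j], b)
            if tt > t:
                N, A, ok = _step_to(t, tt, N, A, r_N, mu_N, r_A, K_A, mu_A,
                                    b1, b2, b3, gam, tau, flag, D0, a,
                                    rtol, atol)
                if not ok:
                    return outN, outA, False
                t = tt
            if times[j] <= b - 1e-12 or s == breaks.size - 2:
                outN[j] = N
                outA[j] = A
                j += 1
            else:
                break
        if t < b:
            N, A, ok = _step_to(t, b, N, A, r_N, mu_N, r_A, K_A, mu_A,
                                b1, b2, b3, gam, tau, flag, D0, a,
                                rtol, atol)
            if not ok:
                return outN, outA, False
        D0 = D0 * np.exp(-tau * (b - a)) + dose_at[s + 1]
    while j < times.size:  # times at the final boundary
        outN[j] = N
        outA[j] = A
        j += 1
    return outN, outA, True


def fast_observe(params, protocol, init, times, rtol=1e-6, atol=1e-3):
    """Python-facing wrapper matching :func:`apldyn.dynamics.simulate_at`."""
    times = np.sort(np.asarray(times, dtype=float))
    t_end = float(max(times[-1], 1e-6))
    pts = {0.0, t_end}
    for edge in (protocol.atra_start, protocol.atra_end):
        if 0.0 < edge < t_end:
            pts.add(float(edge))
    dose_days = [ti for ti in protocol.dose_days if ti <= t_end]
    pts.update(float(ti) for ti in dose_days if ti < t_end or ti == t_end)
    breaks = np.array(sorted(pts))
    atra_on = np.array(
        [protocol.atra_active(0.5 * (a + b))
         for a, b in zip(breaks[:-1], breaks[1:])]
    )
    dose_at = np.array(
        [protocol.dose_mg if b in dose_days else 0.0 for b in breaks]
    )
    theta = np.array(
        [params.r_N, params.mu_N, params.r_A, params.K_A, params.mu_A,
         params.beta1, params.beta2, protocol.beta3, protocol.gamma,
         protocol.tau, float(init[0]), float(init[1])]
    )
    N, A, ok = integrate_obs(times, breaks, atra_on, dose_at, theta,
                             float(rtol), float(atol))
    if not ok:
        raise ArithmeticError("fast integration failed")
    return N, A
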