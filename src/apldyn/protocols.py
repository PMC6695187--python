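"""Induction-protocol library and outcome metrics.

Two scalar summaries grade a simulated 30-day induction course:

* ``Nmin`` — the nadir of the normal-leukocyte count over the window, a
  proxy for hematological toxicity (lower is more cytotoxic);
* ``t_REM`` — the first time the leukemic count falls below
  10 cells/mm³ *and stays below it through the horizon*; infinity means
  no sustained remission (including transient responses that relapse
  within the induction window).

The built-in library holds the standard induction schedule P0 (chemo
60 mg/m² on days 2, 4, 6, 8 plus ATRA days 0–30), its lower/sparser-dose
chemo variants P1–P8, and the ATRA-window variants Q1–Q4.  ATRA dose
changes map multiplicatively onto the maturation rate β3 under a linear
dose–response assumption.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline
from scipy.optimize import brentq

from . import dynamics
from .dynamics import SimulationError, simulate
from .params import ModelParameters, Trajectory, TreatmentProtocol, load_fixture

__all__ = [
    "ProtocolOutcome",
    "builtin_protocols",
    "n_min",
    "t_rem",
    "compare_protocols",
    "atra_threshold",
]

REMISSION_THRESHOLD = 10.0  # cells/mm³
HORIZON = 30.0  # days of induction


@dataclass
class ProtocolOutcome:
    """Outcome of one protocol on one virtual patient."""

    label: str
    n_min: float
    t_rem: float  # math.inf when no sustained remission
    remission: bool
    trajectory: Trajectory | None = None
    error: str | None = None


def builtin_protocols(
    beta3: float,
    gamma: float,
    *,
    tau: float | None = None,
    bsa: float | None = None,
) -> list[TreatmentProtocol]:
    """The 13 library protocols with a patient's drug-effect rates substituted.

    ``beta3``/``gamma`` are the patient's fitted ATRA and chemo effect
    rates for the *standard* daily doses; the Q variants scale β3 by
    their relative ATRA intensity (Q2 half dose → β3/2, Q3 double dose
    → 2β3, Q4 no ATRA → 0).
    """
    fx = load_fixture("table2_fixed.json")
    tau = fx["tau"] if tau is None else tau
    bsa = fx["bsa"] if bsa is None else bsa
    lib = load_fixture("protocols_table4.json")
    out = []
    for entry in lib["chemo_variants"] + lib["atra_variants"]:
        out.append(
            TreatmentProtocol(
                beta3=beta3 * entry["atra_scale"],
                gamma=gamma,
                tau=tau,
                dose_days=tuple(entry["dose_days"]),
                dose_per_bsa=entry["dose_per_bsa"],
                bsa=bsa,
                atra_start=entry["atra_start"],
                atra_end=entry["atra_end"],
                label=entry["label"],
            )
        )
    return out


def _window(traj: Trajectory, horizon: float):
    if traj.t[-1] < horizon - 1e-9:
        raise ValueError(
            f"trajectory ends at day {traj.t[-1]:.3g}, before the "
            f"{horizon:.3g}-day window"
        )
    mask = traj.t <= horizon + 1e-12
    return traj.t[mask], traj.N[mask], traj.A[mask]


def n_min(traj: Trajectory, *, horizon: float = HORIZON) -> float:
    """Nadir of the normal-leukocyte count over [0, horizon] days."""
    _, N, _ = _window(traj, horizon)
    return float(N.min())


def _refine_crossing(t: np.ndarray, A: np.ndarray, i: int, threshold: float) -> float:
    """Locate A(t*) = threshold within grid cell [t[i], t[i+1]] to 1e-6 days."""
    lo, hi = t[i], t[i + 1]
    if hi <= lo:  # duplicated dose-day point
        return float(hi)
    a = max(0, i - 3)
    b = min(len(t), i + 4)
    tt, aa = t[a:b], A[a:b]
    keep = np.concatenate([[True], np.diff(tt) > 0])
    tt, aa = tt[keep], aa[keep]
    try:
        f = CubicSpline(tt, aa)
        g = lambda x: f(x) - threshold
        if g(lo) * g(hi) <= 0:
            return float(brentq(g, lo, hi, xtol=1e-6))
    except ValueError:
        pass
    # fall back to inverse linear interpolation
    return float(lo + (hi - lo) * (threshold - A[i]) / (A[i + 1] - A[i]))


def t_rem(
    traj: Trajectory,
    *,
    threshold: float = REMISSION_THRESHOLD,
    horizon: float = HORIZON,
) -> float:
    """Time of sustained remission, or ``inf``.

    The earliest t* with A(t*) = threshold such that A stays below the
    threshold on (t*, horizon].  A dip below the threshold followed by
    regrowth within the window (relapse during induction) returns inf.
    Already-in-remission trajectories (A < threshold throughout) return 0.
    """
    t, _, A = _window(traj, horizon)
    below = A < threshold
    if not below[-1]:
        return math.inf
    if bool(below.all()):
        return 0.0
    j = int(np.where(~below)[0][-1])  # last sample at/above threshold
    return _refine_crossing(t, A, j, threshold)


def compare_protocols(
    params: ModelParameters,
    base_protocol: TreatmentProtocol,
    init,
    *,
    horizon: float = HORIZON,
    threshold: float = REMISSION_THRESHOLD,
    keep_trajectories: bool = False,
) -> pd.DataFrame:
    """Simulate every built-in protocol for one patient.

    The patient's fitted β3/γ (and τ, bsa) are taken from
    ``base_protocol``; one row per protocol with columns
    ``protocol, Nmin, t_REM, remission``.  Failures of individual rows
    are reported in an ``error`` column without aborting the table.
    """
    rows = []
    for proto in builtin_protocols(
        base_protocol.beta3, base_protocol.gamma,
        tau=base_protocol.tau, bsa=base_protocol.bsa,
    ):
        try:
            traj = simulate(params, proto, init, horizon)
            nm = n_min(traj, horizon=horizon)
            tr = t_rem(traj, threshold=threshold, horizon=horizon)
            rows.append(
                ProtocolOutcome(proto.label, nm, tr, math.isfinite(tr),
                                traj if keep_trajectories else None)
            )
        except (SimulationError, ValueError) as exc:
            rows.append(ProtocolOutcome(proto.label, math.nan, math.inf, False,
                                        None, error=str(exc)))
    df = pd.DataFrame(
        {
            "protocol": [r.label for r in rows],
            "Nmin": [r.n_min for r in rows],
            "t_REM": [r.t_rem for r in rows],
            "remission": [r.remission for r in rows],
            "error": [r.error for r in rows],
        }
    )
    if keep_trajectories:
        df.attrs["outcomes"] = rows
    return df


def write_outcomes_csv(df: pd.DataFrame, path) -> None:
    """Table-4-shaped CSV; infinity is written as the literal ``inf``."""
    out = df[["protocol", "Nmin", "t_REM", "remission"]].copy()
    out["t_REM"] = out["t_REM"].map(lambda v: "inf" if math.isinf(v) else v)
    out.to_csv(path, index=False)


def atra_threshold(
    params: ModelParameters,
    protocol_template: TreatmentProtocol,
    init,
    *,
    horizon: float = HORIZON,
    threshold: float = REMISSION_THRESHOLD,
    bracket: tuple[float, float] = (0.0, 1.0),
    tol: float = 1e-4,
) -> float:
    """Smallest maturation rate β3 achieving sustained remission by bisection.

    ``protocol_template`` is typically the ATRA-only schedule (no chemo
    doses); its β3 is overridden during the search.  Raises if remission
    status does not change sign across the bracket.
    """

    def in_remission(b3: float) -> bool:
        proto = protocol_template.with_patient_effects(b3, protocol_template.gamma)
        traj = simulate(params, proto, init, horizon)
        return math.isfinite(t_rem(traj, threshold=threshold, horizon=horizon))

    lo, hi = bracket
    if in_remission(lo):
        return lo
    if not in_remission(hi):
        raise ValueError("no threshold in range: remission not achieved at "
                         f"beta3 = {hi}")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if in_remission(mid):
            hi = mid
        else:
            lo = mid
    return hi


# re-export the closed-form exposure integral used by the dose-invariance check
chemo_exposure = dynamics.chemo_exposure
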