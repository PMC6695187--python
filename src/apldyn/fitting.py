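"""Multistart least-squares estimation of per-patient parameters.

Five parameters X = (r_N, β1, β2, β3, γ) vary between patients, the
remaining rates being fixed cohort-wide.  The objective is the plain
quadratic error between the simulated course and the laboratory series,

    E(X) = Σ_j (N(t_j) + A(t_j) − L_j)² + Σ_k (A(t_k) − I_k)²,

on raw (linear) counts: L_j are total-leukocyte measurements and I_k the
immature (promyelocyte) counts, which are available for far fewer days.

The estimation procedure samples K tuples uniformly from the search box,
keeps the ``n_keep`` with smallest E, polishes each by projected steepest
descent (central finite differences in box-scaled coordinates with a
backtracking line search; a Nelder–Mead polish is available via
``method="nm"``), classifies every local minimum into Scenario I/II/III,
and selects the smallest-E minimum outside Scenario I — a disease-free
phase portrait cannot describe a diagnosed patient, however well it
interpolates a short time series.  The scenario census over all local
minima is retained: its split between Scenarios II and III is a
relapse-risk indicator in its own right.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dynamics import SimulationError, simulate_at
from .equilibria import classify_scenario
from .params import (
    FREE_PARAMETER_NAMES,
    ModelParameters,
    TreatmentProtocol,
    fixed_parameters,
    parameter_box,
)

__all__ = [
    "LabSeries",
    "FitResult",
    "error_E",
    "multistart_fit",
    "scenario_census",
    "default_init",
]


@dataclass
class LabSeries:
    """Observed blood counts over the induction window.

    ``t_wbc``/``wbc``: days and values of total leukocytes (n1 ≥ 1);
    ``t_imm``/``imm``: days and values of immature leukocytes (may be
    empty — most patients have at most one differential count).
    """

    patient_id: str
    t_wbc: np.ndarray
    wbc: np.ndarray
    t_imm: np.ndarray = field(default_factory=lambda: np.empty(0))
    imm: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        self.t_wbc = np.asarray(self.t_wbc, dtype=float)
        self.wbc = np.asarray(self.wbc, dtype=float)
        self.t_imm = np.asarray(self.t_imm, dtype=float)
        self.imm = np.asarray(self.imm, dtype=float)
        if self.t_wbc.size < 1:
            raise ValueError("at least one total-leukocyte observation required")
        if self.t_wbc.shape != self.wbc.shape or self.t_imm.shape != self.imm.shape:
            raise ValueError("day and count arrays must have matching shapes")
        if (self.wbc < 0).any() or (self.imm < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def n1(self) -> int:
        return int(self.t_wbc.size)

    @property
    def n2(self) -> int:
        return int(self.t_imm.size)

    def to_frame(self) -> pd.DataFrame:
        rows = {float(t): [w, np.nan] for t, w in zip(self.t_wbc, self.wbc)}
        for t, v in zip(self.t_imm, self.imm):
            rows.setdefault(float(t), [np.nan, np.nan])[1] = v
        days = sorted(rows)
        return pd.DataFrame(
            {
                "patient_id": self.patient_id,
                "day": days,
                "wbc_total": [rows[d][0] for d in days],
                "immature": [rows[d][1] for d in days],
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, patient_id: str | None = None) -> "LabSeries":
        if patient_id is None:
            patient_id = str(df["patient_id"].iloc[0])
        else:
            df = df[df["patient_id"].astype(str) == str(patient_id)]
        w = df[df["wbc_total"].notna()]
        i = df[df["immature"].notna()]
        return cls(
            patient_id=str(patient_id),
            t_wbc=w["day"].to_numpy(float),
            wbc=w["wbc_total"].to_numpy(float),
            t_imm=i["day"].to_numpy(float),
            imm=i["immature"].to_numpy(float),
        )

    @classmethod
    def from_csv(cls, path, patient_id: str | None = None) -> "LabSeries":
        return cls.from_frame(pd.read_csv(path), patient_id)


def default_init(lab: LabSeries) -> tuple[float, float]:
    """Initial state from the day-0 laboratory values.

    A(0) is the day-0 immature count when present (0 otherwise) and
    N(0) the day-0 total minus that; the convention is configurable by
    passing an explicit ``init`` to the fitting routines.
    """
    j = int(np.argmin(lab.t_wbc))
    if lab.t_wbc[j] > 1e-9:
        raise ValueError("lab series has no day-0 total-leukocyte value")
    L0 = float(lab.wbc[j])
    A0 = 0.0
    if lab.n2:
        k = int(np.argmin(lab.t_imm))
        if lab.t_imm[k] <= 1e-9:
            A0 = float(lab.imm[k])
    return max(L0 - A0, 0.0), A0


def _tuple_box(box: dict[str, tuple[float, float]] | None) -> np.ndarray:
    box = parameter_box() if box is None else box
    return np.array([box[name] for name in FREE_PARAMETER_NAMES], dtype=float)


def _split(x, fixed: dict) -> tuple[ModelParameters, float, float]:
    params = ModelParameters(
        r_N=float(x[0]),
        mu_N=fixed["mu_N"],
        r_A=fixed["r_A"],
        K_A=fixed["K_A"],
        mu_A=fixed["mu_A"],
        beta1=float(x[1]),
        beta2=float(x[2]),
    )
    return params, float(x[3]), float(x[4])


def error_E(
    x,
    lab: LabSeries,
    init,
    protocol: TreatmentProtocol,
    *,
    fixed: dict | None = None,
    rtol: float = 1e-6,
    atol: float = 1e-3,
    fast: bool = True,
) -> float:
    """Quadratic error E(X) of a free-parameter tuple against a lab series.

    Simulation failures return ``inf`` so the tuple is discarded by the
    sampler rather than aborting the whole run.  ``fast`` routes the
    inner integration through the compiled evaluator (same model, same
    tolerances; cross-checked against the scipy path in the test suite).
    """
    fixed = fixed_parameters() if fixed is None else fixed
    try:
        params, beta3, gamma = _split(x, fixed)
    except ValueError:
        return math.inf
    proto = protocol.with_patient_effects(beta3, gamma)
    days = np.union1d(lab.t_wbc, lab.t_imm)
    try:
        if fast:
            from ._fastsim import fast_observe

            N, A = fast_observe(params, proto, init, days, rtol=rtol, atol=atol)
        else:
            N, A = simulate_at(params, proto, init, days, rtol=rtol, atol=atol)
    except (SimulationError, ValueError, ArithmeticError):
        return math.inf
    total = np.interp(lab.t_wbc, days, N + A)
    err = float(np.sum((total - lab.wbc) ** 2))
    if lab.n2:
        imm = np.interp(lab.t_imm, days, A)
        err += float(np.sum((imm - lab.imm) ** 2))
    return err


@dataclass
class FitResult:
    """Everything the multistart procedure produced."""

    samples: np.ndarray          # (K, 5) sampled tuples
    sample_errors: np.ndarray    # (K,)
    starts: np.ndarray           # (n_keep, 5) selected starts
    start_errors: np.ndarray
    minima: np.ndarray           # (n_keep, 5) polished local minima
    minima_errors: np.ndarray
    scenarios: list[str]         # per-minimum scenario label
    census: dict[str, float]     # percentage of minima per scenario
    best_index: int              # argmin E among non-Scenario-I minima
    seed: int | None

    @property
    def best(self) -> np.ndarray:
        return self.minima[self.best_index]

    @property
    def best_error(self) -> float:
        return float(self.minima_errors[self.best_index])

    @property
    def best_scenario(self) -> str:
        return self.scenarios[self.best_index]

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "best": dict(zip(FREE_PARAMETER_NAMES, self.best.tolist())),
            "best_error": self.best_error,
            "best_scenario": self.best_scenario,
            "census": self.census,
            "minima": self.minima.tolist(),
            "minima_errors": self.minima_errors.tolist(),
            "scenarios": self.scenarios,
        }


def scenario_census(minima, *, fixed: dict | None = None) -> dict[str, float]:
    """Percentage of tuples falling in each scenario (I/II/III/boundary)."""
    fixed = fixed_parameters() if fixed is None else fixed
    minima = np.asarray(minima, dtype=float)
    if minima.size == 0:
        raise ValueError("empty list of minima")
    minima = np.atleast_2d(minima)
    labels = [_classify_tuple(x, fixed) for x in minima]
    out: dict[str, float] = {}
    for lab in labels:
        out[lab] = out.get(lab, 0.0) + 100.0 / len(labels)
    return out


def _classify_tuple(x, fixed: dict) -> str:
    params, _, _ = _split(x, fixed)
    return classify_scenario(params, attach_equilibria=False).scenario


def _project(x: np.ndarray, box: np.ndarray) -> np.ndarray:
    return np.clip(x, box[:, 0], box[:, 1])


def _descend(f, x0, box, *, max_iter=200, fd_rel=1e-4, tol=1e-8):
    """Projected steepest descent in box-scaled coordinates.

    Gradients by central finite differences with steps proportional to
    each interval's width; backtracking line search; stops when the
    relative improvement of E falls below ``tol`` or the projected
    gradient vanishes.
    """
    width = box[:, 1] - box[:, 0]
    x = _project(np.asarray(x0, dtype=float), box)
    fx = f(x)
    step = 0.1  # in units of box width
    for _ in range(max_iter):
        g = np.zeros_like(x)
        for i in range(x.size):
            h = fd_rel * width[i]
            xp = x.copy(); xp[i] = min(x[i] + h, box[i, 1])
            xm = x.copy(); xm[i] = max(x[i] - h, box[i, 0])
            denom = xp[i] - xm[i]
            g[i] = (f(xp) - f(xm)) / denom if denom > 0 else 0.0
        gs = g * width  # gradient in scaled coordinates
        if not np.any(gs):
            break
        direction = -gs / np.linalg.norm(gs)
        improved = False
        s = step
        for _ in range(30):
            x_new = _project(x + s * direction * width, box)
            f_new = f(x_new)
            if f_new < fx:
                improved = True
                break
            s *= 0.5
        if not improved:
            break
        gain = fx - f_new
        x, fx = x_new, f_new
        step = min(max(s * 2.0, 1e-6), 0.5)
        if gain < tol * (1.0 + fx):
            break
    return x, fx


def _nm_polish(f, x0, box, *, max_iter=400):
    """Nelder–Mead in box-scaled coordinates with out-of-box penalty."""
    from scipy.optimize import minimize

    width = box[:, 1] - box[:, 0]

    def g(z):
        x = box[:, 0] + np.clip(z, 0.0, 1.0) * width
        penalty = float(np.sum(np.maximum(np.abs(z - 0.5) - 0.5, 0.0) ** 2))
        return f(x) + penalty * 1e6

    z0 = (np.asarray(x0, dtype=float) - box[:, 0]) / width
    res = minimize(g, z0, method="Nelder-Mead",
                   options={"maxiter": max_iter, "xatol": 1e-6, "fatol": 1e-10})
    z = np.clip(res.x, 0.0, 1.0)
    x = box[:, 0] + z * width
    return x, f(x)


def multistart_fit(
    lab: LabSeries,
    init,
    protocol: TreatmentProtocol,
    *,
    K: int = 10000,
    n_keep: int = 100,
    seed: int | None = None,
    box: dict[str, tuple[float, float]] | None = None,
    fixed: dict | None = None,
    method: str = "descent",
    latin_hypercube: bool = False,
    max_iter: int = 200,
) -> FitResult:
    """Uniform sampling, top-``n_keep`` selection, local descent, census.

    ``method`` is ``"descent"`` (projected steepest descent),
    ``"nm"`` (Nelder–Mead polish) or ``"descent+nm"``.  Sampling is
    independent uniform per coordinate by default; set
    ``latin_hypercube`` for stratified sampling.
    """
    fixed = fixed_parameters() if fixed is None else fixed
    b = _tuple_box(box)
    rng = np.random.default_rng(seed)
    if latin_hypercube:
        u = (rng.permuted(np.tile(np.arange(K), (b.shape[0], 1)), axis=1).T
             + rng.random((K, b.shape[0]))) / K
    else:
        u = rng.random((K, b.shape[0]))
    samples = b[:, 0] + u * (b[:, 1] - b[:, 0])

    f = lambda x: error_E(x, lab, init, protocol, fixed=fixed)
    sample_errors = np.array([f(x) for x in samples])
    order = np.argsort(sample_errors, kind="stable")[:n_keep]
    starts = samples[order]
    start_errors = sample_errors[order]

    minima = np.empty_like(starts)
    minima_errors = np.empty(len(starts))
    for i, x0 in enumerate(starts):
        if not math.isfinite(start_errors[i]):
            minima[i], minima_errors[i] = x0, start_errors[i]
            continue
        x, fx = x0, float(start_errors[i])
        if "descent" in method:
            x, fx = _descend(f, x, b, max_iter=max_iter)
        if "nm" in method:
            x_nm, f_nm = _nm_polish(f, x, b)
            if f_nm <= fx:
                x, fx = x_nm, f_nm
        minima[i], minima_errors[i] = x, fx

    scenarios = [_classify_tuple(x, fixed) for x in minima]
    census = scenario_census(minima, fixed=fixed)
    eligible = [
        i for i, s in enumerate(scenarios)
        if s != "I" and math.isfinite(minima_errors[i])
    ]
    if not eligible:
        raise RuntimeError(
            "no clinically relevant minimum: every local minimum falls in "
            "Scenario I (leukemia-free phase portrait)"
        )
    best_index = min(eligible, key=lambda i: minima_errors[i])
    return FitResult(
        samples=samples,
        sample_errors=sample_errors,
        starts=starts,
        start_errors=start_errors,
        minima=minima,
        minima_errors=minima_errors,
        scenarios=scenarios,
        census=census,
        best_index=best_index,
        seed=seed,
    )
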