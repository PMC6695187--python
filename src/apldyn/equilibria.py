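"""Steady states and qualitative scenarios of the untreated model.

The untreated system always has the leukemia-free equilibrium
P0 = (r_N/μ_N, 0).  Coexistence equilibria satisfy N = r_N/(μ_N + β1·A)
with A a positive root of the quadratic

    −(r_A/K_A)·β1·A² + (l_A·β1 − (r_A/K_A)·μ_N)·A + (l_A·μ_N − r_N·β2) = 0,

where l_A = r_A − μ_A.  Three phase portraits arise:

* Scenario I   — only P0, globally stable: leukemia dies out regardless
  of the initial state.
* Scenario II  — P0 and P2 both locally stable, separated by the stable
  manifold of the saddle P1: the outcome depends on the initial state.
* Scenario III — P0 unstable; the disease equilibrium P2 attracts every
  initial state with A(0) > 0.

The classification is governed by two thresholds:

    β2th   = (μ_N/r_N)·l_A          (transcritical: stability of P0)
    β1,Δth = β1th + 2η + 2·sqrt(η·(β1th + η))   (saddle-node), with
    η      = r_A·r_N·(β2 − β2th)/(K_A·l_A²)

β2 < β2th gives Scenario III; β2 > β2th gives Scenario II when
β1 > β1,Δth and Scenario I otherwise.  The auxiliary β1th is the
saddle-node threshold at η = 0; it is not printed in the source
literature and is derived here from the discriminant-zero condition of
the coexistence quadratic, which yields

    β1th = r_A·μ_N/(K_A·l_A).

(Setting β2 = β2th kills the constant coefficient, and the discriminant
(l_A·β1 − (r_A/K_A)·μ_N)² then vanishes exactly at that β1.  The general
formula follows from the product/sum of the roots of the discriminant,
viewed as a quadratic in β1; the numeric cross-check against a
discriminant-zero bisection ships in the test suite.)
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .dynamics import untreated_rhs
from .params import ModelParameters

__all__ = [
    "EquilibriumSet",
    "ScenarioReport",
    "coexistence_quadratic",
    "coexistence_equilibria",
    "equilibrium_set",
    "jacobian",
    "jacobian_stability",
    "thresholds",
    "classify_scenario",
    "basin_membership",
]

#: relative tolerance within which a parameter set is called "boundary"
BOUNDARY_RTOL = 1e-9


@dataclass
class EquilibriumSet:
    """Steady states of the untreated system with stability labels."""

    P0: tuple[float, float]
    P1: tuple[float, float] | None
    P2: tuple[float, float] | None
    stability: dict[str, str] = field(default_factory=dict)

    def __iter__(self):
        for name in ("P0", "P1", "P2"):
            pt = getattr(self, name)
            if pt is not None:
                yield name, pt


@dataclass
class ScenarioReport:
    """Threshold values and the resulting qualitative scenario."""

    beta2_th: float
    eta: float | None
    beta1_th: float
    beta1_delta_th: float | None
    scenario: str | None = None  # "I" | "II" | "III" | "boundary"
    equilibria: EquilibriumSet | None = None

    def to_dict(self) -> dict:
        d = {
            "beta2_th": self.beta2_th,
            "eta": self.eta,
            "beta1_th": self.beta1_th,
            "beta1_delta_th": self.beta1_delta_th,
            "scenario": self.scenario,
        }
        if self.equilibria is not None:
            d["equilibria"] = {
                name: {"N": pt[0], "A": pt[1],
                       "stability": self.equilibria.stability.get(name)}
                for name, pt in self.equilibria
            }
        return d


def coexistence_quadratic(params: ModelParameters) -> tuple[float, float, float]:
    """Coefficients (a2, a1, a0) of the coexistence quadratic in A.

    Obtained by substituting N = r_N/(μ_N + β1·A) into dA/dt = 0, A > 0.
    With β1 = 0 the equation degenerates to a linear one (a2 = 0).
    """
    p = params
    c = p.r_A / p.K_A
    a2 = -c * p.beta1
    a1 = p.l_A * p.beta1 - c * p.mu_N
    a0 = p.l_A * p.mu_N - p.r_N * p.beta2
    return a2, a1, a0


def coexistence_equilibria(params: ModelParameters) -> list[tuple[float, float]]:
    """Positive coexistence equilibria (N_i, A_i), ordered by increasing A."""
    a2, a1, a0 = coexistence_quadratic(params)
    if a2 == 0.0:
        roots = [] if a1 == 0.0 else [-a0 / a1]
    else:
        disc = a1 * a1 - 4.0 * a2 * a0
        if disc < 0.0:
            roots = []
        else:
            s = math.sqrt(disc)
            roots = [(-a1 - s) / (2.0 * a2), (-a1 + s) / (2.0 * a2)]
    out = []
    for A in sorted(roots):
        if A > 0.0:
            N = params.r_N / (params.mu_N + params.beta1 * A)
            if N > 0.0:
                out.append((N, A))
    return out


def jacobian(params: ModelParameters, point) -> np.ndarray:
    """Analytic 2×2 Jacobian of the untreated vector field at (N, A)."""
    N, A = float(point[0]), float(point[1])
    p = params
    return np.array(
        [
            [-p.mu_N - p.beta1 * A, -p.beta1 * N],
            [-p.beta2 * A, p.r_A * (1.0 - 2.0 * A / p.K_A) - p.beta2 * N - p.mu_A],
        ]
    )


def _residual(params: ModelParameters, point) -> float:
    dN, dA = untreated_rhs(params, point)
    scale = max(params.r_N, params.r_A * params.K_A / 4.0)
    return max(abs(dN), abs(dA)) / scale


def jacobian_stability(
    params: ModelParameters, point, *, check_residual: bool = True
) -> str:
    """Stability label at an equilibrium from the eigenvalues of the Jacobian.

    Returns ``"stable"``, ``"saddle"``, ``"unstable"`` or ``"degenerate"``
    (an eigenvalue real part within 1e-9 of zero).
    """
    if check_residual and _residual(params, point) > 1e-6:
        raise ValueError(f"point {point!r} is not an equilibrium")
    eig = np.linalg.eigvals(jacobian(params, point))
    re = np.real(eig)
    scale = max(1.0, np.max(np.abs(re)))
    if np.any(np.abs(re) <= 1e-9 * scale):
        return "degenerate"
    neg = int(np.sum(re < 0))
    return {2: "stable", 1: "saddle", 0: "unstable"}[neg]


def equilibrium_set(params: ModelParameters) -> EquilibriumSet:
    """All equilibria with stability labels from the Jacobian oracle."""
    P0 = (params.homeostatic_N, 0.0)
    coex = coexistence_equilibria(params)
    P1 = coex[0] if len(coex) == 2 else None
    P2 = coex[-1] if coex else None
    es = EquilibriumSet(P0=P0, P1=P1, P2=P2)
    for name, pt in es:
        es.stability[name] = jacobian_stability(params, pt, check_residual=False)
    return es


def thresholds(params: ModelParameters) -> ScenarioReport:
    """Scenario thresholds β2th, η, β1th and (when defined) β1,Δth."""
    p = params
    beta2_th = (p.mu_N / p.r_N) * p.l_A
    beta1_th = p.r_A * p.mu_N / (p.K_A * p.l_A)
    if p.beta2 >= beta2_th:
        eta = p.r_A * p.r_N * (p.beta2 - beta2_th) / (p.K_A * p.l_A**2)
        beta1_delta_th = beta1_th + 2.0 * eta + 2.0 * math.sqrt(eta * (beta1_th + eta))
    else:
        eta = None
        beta1_delta_th = None
    return ScenarioReport(
        beta2_th=beta2_th, eta=eta, beta1_th=beta1_th,
        beta1_delta_th=beta1_delta_th,
    )


def _near(x: float, ref: float) -> bool:
    return abs(x - ref) <= BOUNDARY_RTOL * max(abs(x), abs(ref), 1e-300)


def classify_scenario(
    params: ModelParameters, *, attach_equilibria: bool = True, warn: bool = True
) -> ScenarioReport:
    """Classify a parameter set into Scenario I, II or III.

    Parameter sets within relative 1e-9 of a threshold are labelled
    ``"boundary"`` instead of being forced into a scenario.  When
    ``attach_equilibria`` is set, the report carries the equilibria with
    Jacobian stability labels, and a warning is emitted if the
    formula-based scenario disagrees with the picture those imply.
    """
    rep = thresholds(params)
    if _near(params.beta2, rep.beta2_th) or (
        rep.beta1_delta_th is not None and _near(params.beta1, rep.beta1_delta_th)
    ):
        rep.scenario = "boundary"
    elif params.beta2 < rep.beta2_th:
        rep.scenario = "III"
    elif params.beta1 > rep.beta1_delta_th:
        rep.scenario = "II"
    else:
        rep.scenario = "I"
    if attach_equilibria:
        rep.equilibria = equilibrium_set(params)
        if warn and rep.scenario in ("I", "II", "III"):
            implied = _implied_scenario(rep.equilibria)
            if implied is not None and implied != rep.scenario:
                import warnings

                warnings.warn(
                    f"formula-based scenario {rep.scenario} disagrees with "
                    f"equilibrium/stability-based scenario {implied}",
                    stacklevel=2,
                )
    return rep


def _implied_scenario(es: EquilibriumSet) -> str | None:
    """Scenario implied by equilibrium existence + stability (the oracle)."""
    p0 = es.stability.get("P0")
    n_coex = int(es.P1 is not None) + int(es.P2 is not None)
    if "degenerate" in es.stability.values():
        return None
    if p0 == "stable" and n_coex == 0:
        return "I"
    if p0 == "stable" and n_coex == 2:
        if es.stability.get("P1") == "saddle" and es.stability.get("P2") == "stable":
            return "II"
        return None
    if p0 in ("saddle", "unstable") and n_coex == 1 and es.stability.get("P2") == "stable":
        return "III"
    return None


def basin_membership(
    params: ModelParameters,
    init,
    *,
    t_max: float = 2000.0,
    rel_tol: float = 1e-3,
) -> str:
    """Which attractor (``"P0"`` or ``"P2"``) the untreated flow reaches.

    Integrates from ``init`` until the state is within 0.1% (relative,
    per component) of a stable equilibrium, or ``"undetermined"`` if
    neither is approached by ``t_max`` days.
    """
    from scipy.integrate import solve_ivp

    es = equilibrium_set(params)
    targets = {
        name: np.asarray(pt)
        for name, pt in (("P0", es.P0), ("P2", es.P2))
        if pt is not None and es.stability.get(name) == "stable"
    }
    if not targets:
        return "undetermined"

    def rhs(t, y):
        return untreated_rhs(params, np.maximum(y, 0.0))

    y = np.asarray(init, dtype=float)
    t = 0.0
    chunk = 50.0
    while t < t_max:
        sol = solve_ivp(rhs, (t, min(t + chunk, t_max)), y, method="LSODA",
                        rtol=1e-8, atol=1e-8)
        if not sol.success:
            return "undetermined"
        for name, pt in targets.items():
            scale = np.maximum(np.abs(pt), 1.0)
            if np.all(np.abs(sol.y[:, -1] - pt) <= rel_tol * scale):
                return name
        y = sol.y[:, -1]
        t = sol.t[-1]
    return "undetermined"
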