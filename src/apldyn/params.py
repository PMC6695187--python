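"""Domain types for the APL leukocyte-competition model.

Two cell populations circulate in peripheral blood: normal leukocytes
``N`` (replenished at a constant tissue-driven flux, dying at a
first-order rate) and leukemic promyelocyte-like cells ``A`` (logistic
growth up to a carrying capacity).  Each population inhibits the other
through mass-action competition terms.  Induction therapy adds an
ATRA-driven maturation flux from ``A`` into ``N`` (active on a fixed
time window) and an anthracycline amount ``D`` delivered as instantaneous
intravenous doses that decay exponentially and kill both populations
proportionally.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict, replace
from importlib import resources
from typing import Sequence

import numpy as np

__all__ = [
    "ModelParameters",
    "TreatmentProtocol",
    "ModelState",
    "Trajectory",
    "fixed_parameters",
    "parameter_box",
    "patient_parameters",
    "ical_protocol",
    "load_fixture",
]

#: Names and order of the per-patient free parameters, (r_N, β1, β2, β3, γ).
FREE_PARAMETER_NAMES = ("r_N", "beta1", "beta2", "beta3", "gamma")


def load_fixture(name: str) -> dict:
    """Load one of the packaged JSON fixtures by file name."""
    with resources.files("apldyn.data").joinpath(name).open() as fh:
        return json.load(fh)


@dataclass(frozen=True)
class ModelParameters:
    """Rates of the untreated two-population competition model.

    Parameters
    ----------
    r_N : float
        Constant production flux of normal leukocytes, cells/(mm³·day).
    mu_N : float
        Normal-cell death rate, day⁻¹.
    r_A : float
        Leukemic per-capita proliferation rate, day⁻¹.
    K_A : float
        Leukemic carrying capacity, cells/mm³.
    mu_A : float
        Leukemic death rate, day⁻¹.
    beta1 : float
        Inhibition of normal cells by leukemic cells, (cells/mm³)⁻¹·day⁻¹.
    beta2 : float
        Inhibition of leukemic cells by normal cells, (cells/mm³)⁻¹·day⁻¹.

    The net leukemic growth rate ``l_A = r_A - mu_A`` must be positive:
    the scenario thresholds divide by it, and a leukemia that cannot
    outgrow its own death rate never presents clinically.
    """

    r_N: float
    mu_N: float
    r_A: float
    K_A: float
    mu_A: float
    beta1: float
    beta2: float

    def __post_init__(self) -> None:
        for name in ("r_N", "mu_N", "r_A", "K_A", "mu_A"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be strictly positive, got {v!r}")
        for name in ("beta1", "beta2"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v >= 0):
                raise ValueError(f"{name} must be non-negative, got {v!r}")
        if self.r_A <= self.mu_A:
            raise ValueError(
                f"net leukemic growth l_A = r_A - mu_A must be positive "
                f"(r_A={self.r_A}, mu_A={self.mu_A})"
            )

    @property
    def l_A(self) -> float:
        """Net leukemic growth rate r_A − mu_A, day⁻¹."""
        return self.r_A - self.mu_A

    @property
    def homeostatic_N(self) -> float:
        """Leukemia-free steady level of normal leukocytes, r_N/mu_N."""
        return self.r_N / self.mu_N

    def with_free(self, x: Sequence[float]) -> "ModelParameters":
        """Return a copy with (r_N, beta1, beta2) replaced from a free tuple.

        ``x`` is the 5-tuple (r_N, β1, β2, β3, γ); the treatment entries
        are ignored here (they belong to :class:`TreatmentProtocol`).
        """
        return replace(self, r_N=float(x[0]), beta1=float(x[1]), beta2=float(x[2]))

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParameters":
        keys = ("r_N", "mu_N", "r_A", "K_A", "mu_A", "beta1", "beta2")
        return cls(**{k: float(d[k]) for k in keys})

    @classmethod
    def from_json(cls, path) -> "ModelParameters":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


@dataclass(frozen=True)
class TreatmentProtocol:
    """An induction-therapy schedule: impulsive chemo plus an ATRA window.

    Chemotherapy doses of ``dose_per_bsa`` mg/m² are given at ``dose_days``;
    each impulse adds ``dose_per_bsa * bsa`` mg to the circulating amount
    ``D``, which decays at rate ``tau`` (day⁻¹) and kills both populations
    at per-mg rate ``gamma``.  ATRA drives leukemic maturation at rate
    ``beta3`` while ``atra_start <= t < atra_end`` (half-open window).
    """

    beta3: float
    gamma: float
    tau: float
    dose_days: tuple[float, ...]
    dose_per_bsa: float
    bsa: float
    atra_start: float = 0.0
    atra_end: float = 30.0
    label: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "dose_days", tuple(float(t) for t in self.dose_days))
        for name in ("beta3", "gamma", "tau", "dose_per_bsa", "bsa"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v >= 0):
                raise ValueError(f"{name} must be non-negative, got {v!r}")
        if self.atra_start > self.atra_end:
            raise ValueError("atra_start must not exceed atra_end")
        days = self.dose_days
        if any(t < 0 for t in days):
            raise ValueError("dose days must be non-negative")
        if any(b <= a for a, b in zip(days, days[1:])):
            raise ValueError("dose days must be strictly increasing")

    @property
    def dose_mg(self) -> float:
        """Mass of one dose in mg (dose_per_bsa × body surface area)."""
        return self.dose_per_bsa * self.bsa

    def atra_active(self, t: float) -> bool:
        """ATRA switch u: active on [atra_start, atra_end)."""
        return self.atra_start <= t < self.atra_end

    def with_patient_effects(self, beta3: float, gamma: float) -> "TreatmentProtocol":
        """Substitute a patient's fitted drug-effect rates into this schedule."""
        return replace(self, beta3=float(beta3), gamma=float(gamma))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["dose_days"] = list(self.dose_days)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TreatmentProtocol":
        d = dict(d)
        d["dose_days"] = tuple(float(t) for t in d.get("dose_days", ()))
        return cls(**d)

    @classmethod
    def from_json(cls, path) -> "TreatmentProtocol":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


@dataclass(frozen=True)
class ModelState:
    """State (t, N, A, D): day, cell densities (cells/mm³), drug amount (mg)."""

    t: float
    N: float
    A: float
    D: float = 0.0

    def __post_init__(self) -> None:
        if not all(math.isfinite(v) for v in (self.t, self.N, self.A, self.D)):
            raise ValueError("state components must be finite")
        if self.N < 0 or self.A < 0 or self.D < 0:
            raise ValueError("N, A, D must be non-negative")


@dataclass
class Trajectory:
    """A solved (N, A, D) time course on a dense grid.

    Dose days appear twice in ``t`` (pre- and post-impulse value of D).
    """

    t: np.ndarray
    N: np.ndarray
    A: np.ndarray
    D: np.ndarray
    params: ModelParameters | None = None
    protocol: TreatmentProtocol | None = None

    @property
    def wbc(self) -> np.ndarray:
        """Total white-cell count N + A, the laboratory observable."""
        return self.N + self.A

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"day": self.t, "N": self.N, "A": self.A, "D": self.D,
             "WBC_total": self.wbc}
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def at(self, times) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Linear interpolation of (N, A, D) at the requested days."""
        times = np.asarray(times, dtype=float)
        return (
            np.interp(times, self.t, self.N),
            np.interp(times, self.t, self.A),
            np.interp(times, self.t, self.D),
        )


# --- packaged defaults -----------------------------------------------------

def fixed_parameters() -> dict:
    """The cohort-wide fixed rates (death/proliferation/capacity, τ, schedule)."""
    return load_fixture("table2_fixed.json")


def parameter_box() -> dict[str, tuple[float, float]]:
    """Search intervals for the five per-patient free parameters."""
    raw = fixed_parameters()["intervals"]
    return {k: (float(lo), float(hi)) for k, (lo, hi) in raw.items()}


def patient_parameters(patient: str) -> tuple[ModelParameters, float, float]:
    """Packaged fitted parameters for reference patients ``"18"`` / ``"22"``.

    Returns (ModelParameters, beta3, gamma).
    """
    d = load_fixture(f"patient{patient}.json")
    return ModelParameters.from_dict(d), float(d["beta3"]), float(d["gamma"])


def ical_protocol(beta3: float = 0.0, gamma: float = 0.0) -> TreatmentProtocol:
    """The standard induction schedule: 60 mg/m² chemo on days 2, 4, 6, 8
    and ATRA on days 0–30, with the given patient drug-effect rates."""
    fx = fixed_parameters()
    return TreatmentProtocol(
        beta3=beta3,
        gamma=gamma,
        tau=fx["tau"],
        dose_days=tuple(fx["dose_days"]),
        dose_per_bsa=fx["dose_per_bsa"],
        bsa=fx["bsa"],
        atra_start=fx["atra_start"],
        atra_end=fx["atra_end"],
        label="P0",
    )
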