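"""Virtual APL patients with cohort-realistic observation sparsity.

No per-patient laboratory time courses are publicly deposited for this
kind of cohort, so testing the estimation and protocol machinery needs
simulated patients whose *data density* matches what induction-phase
records actually look like: every patient has total-WBC values in the
first 30 days (median 11 of them), but only about 68% have any immature
(promyelocyte) count at all, typically a single value.

A virtual patient is a ground-truth free-parameter tuple drawn uniformly
from the search box (Scenario-I draws rejected by default — such
patients would never be diagnosed), an invented initial state, a
simulated course under the standard induction schedule, and sparse
observations contaminated with multiplicative lognormal noise and
rounded to integer counts.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .dynamics import SimulationError, simulate_at
from .equilibria import classify_scenario
from .fitting import LabSeries, _split
from .params import FREE_PARAMETER_NAMES, fixed_parameters, ical_protocol, parameter_box

__all__ = ["PatientConfig", "VirtualPatient", "sample_patient",
           "generate_cohort", "write_cohort", "read_cohort"]

#: WBC observation-count draw: 4 + Binomial(14, 1/2) has support
#: {4, ..., 18} with median and mode 11, matching the cohort's reported
#: median of 11 values over the first 30 days.
WBC_COUNT_OFFSET = 4
WBC_COUNT_TRIALS = 14
#: distribution of the number of immature counts, given any exist;
#: median 1, as in the cohort.
IMM_COUNT_VALUES = (1, 2, 3, 4)
IMM_COUNT_PROBS = (0.6, 0.25, 0.1, 0.05)


@dataclass
class PatientConfig:
    """Knobs of the virtual-patient generator.

    The defaults emulate the study conditions: search box for the true
    tuple, 10% multiplicative noise (σ of log counts), invented initial
    states N0 ~ U[200, 3000] and A0 ~ U[500, 20000] cells/mm³ chosen so
    the standard protocol produces both remission and relapse across a
    cohort, observation-day counts with median 11 (WBC) and availability
    0.68 / median 1 (immature).
    """

    box: dict[str, tuple[float, float]] | None = None
    noise_sigma: float = 0.1
    n0_range: tuple[float, float] = (200.0, 3000.0)
    a0_range: tuple[float, float] = (500.0, 20000.0)
    immature_prob: float = 0.68
    horizon: int = 30
    reject_scenario_I: bool = True
    dense_daily: bool = False      # daily observations of both series
    immature_day0: bool = False    # force an immature count at day 0
    max_resample: int = 50


@dataclass
class VirtualPatient:
    """Ground truth plus the observed lab series for one simulated patient."""

    patient_id: str
    x_true: np.ndarray                 # (r_N, β1, β2, β3, γ)
    init: tuple[float, float]
    scenario: str
    lab: LabSeries
    trajectory_days: np.ndarray        # integer days 0..horizon
    trajectory_N: np.ndarray
    trajectory_A: np.ndarray
    seed: int

    def truth_dict(self) -> dict:
        return {
            "patient_id": self.patient_id,
            "params": dict(zip(FREE_PARAMETER_NAMES, self.x_true.tolist())),
            "init": {"N0": self.init[0], "A0": self.init[1]},
            "scenario": self.scenario,
            "seed": self.seed,
        }


def _draw_days(rng: np.random.Generator, n: int, horizon: int) -> np.ndarray:
    """Day 0 plus a sorted draw without replacement from days 1..horizon."""
    n_extra = min(max(n - 1, 0), horizon)
    extra = rng.choice(np.arange(1, horizon + 1), size=n_extra, replace=False)
    return np.concatenate([[0], np.sort(extra)]).astype(float)


def sample_patient(seed: int, config: PatientConfig | None = None,
                   patient_id: str | None = None) -> VirtualPatient:
    """Draw one virtual patient; deterministic in ``seed``.

    Simulation failures (or Scenario-I draws when rejected) advance to
    the next RNG substream and redraw.
    """
    config = config or PatientConfig()
    box = parameter_box() if config.box is None else config.box
    fixed = fixed_parameters()
    lo = np.array([box[k][0] for k in FREE_PARAMETER_NAMES])
    hi = np.array([box[k][1] for k in FREE_PARAMETER_NAMES])
    horizon = config.horizon

    for attempt in range(config.max_resample):
        rng = np.random.default_rng((seed, attempt))
        x = lo + rng.random(lo.size) * (hi - lo)
        params, beta3, gamma = _split(x, fixed)
        scenario = classify_scenario(params, attach_equilibria=False).scenario
        if config.reject_scenario_I and scenario not in ("II", "III"):
            continue
        N0 = rng.uniform(*config.n0_range)
        A0 = rng.uniform(*config.a0_range)
        proto = ical_protocol(beta3, gamma)
        days = np.arange(0, horizon + 1, dtype=float)
        try:
            N, A = simulate_at(params, proto, (N0, A0), days)
        except (SimulationError, ValueError):
            continue

        if config.dense_daily:
            t_wbc = days
            t_imm = days
        else:
            n_wbc = WBC_COUNT_OFFSET + int(rng.binomial(WBC_COUNT_TRIALS, 0.5))
            t_wbc = _draw_days(rng, n_wbc, horizon)
            if rng.random() < config.immature_prob:
                n_imm = int(rng.choice(IMM_COUNT_VALUES, p=IMM_COUNT_PROBS))
                t_imm = rng.choice(t_wbc, size=min(n_imm, t_wbc.size),
                                   replace=False)
                t_imm = np.sort(t_imm)
            else:
                t_imm = np.empty(0)
            if config.immature_day0 and (t_imm.size == 0 or t_imm[0] > 0):
                t_imm = np.concatenate([[0.0], t_imm[t_imm > 0]])

        def observe(values):
            noisy = values * np.exp(
                rng.normal(0.0, config.noise_sigma, size=values.shape)
            ) if config.noise_sigma > 0 else values.copy()
            return np.maximum(np.rint(noisy), 0.0)

        idx_w = t_wbc.astype(int)
        idx_i = t_imm.astype(int)
        obs_wbc = observe(N[idx_w] + A[idx_w])
        obs_imm = observe(A[idx_i]) if idx_i.size else np.empty(0)

        pid = patient_id if patient_id is not None else f"synthetic-{seed}"
        lab = LabSeries(patient_id=pid, t_wbc=t_wbc, wbc=obs_wbc,
                        t_imm=t_imm, imm=obs_imm)
        return VirtualPatient(
            patient_id=pid,
            x_true=x,
            init=(float(N0), float(A0)),
            scenario=scenario,
            lab=lab,
            trajectory_days=days,
            trajectory_N=N,
            trajectory_A=A,
            seed=seed,
        )
    raise RuntimeError(f"could not generate a patient from seed {seed} "
                       f"after {config.max_resample} attempts")


def generate_cohort(n: int, seed: int,
                    config: PatientConfig | None = None) -> list[VirtualPatient]:
    """A reproducible cohort: patient k is drawn from sub-seed (seed, k)."""
    ss = np.random.SeedSequence(seed).spawn(n)
    return [
        sample_patient(int(s.generate_state(1)[0] % (2**31)), config,
                       patient_id=f"synthetic-{k:03d}")
        for k, s in enumerate(ss)
    ]


def write_cohort(patients: list[VirtualPatient], directory) -> list[Path]:
    """One lab-series CSV per patient plus a ground-truth JSON."""
    if not patients:
        raise ValueError("empty cohort")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for p in patients:
        path = directory / f"{p.patient_id}.csv"
        p.lab.to_csv(path)
        paths.append(path)
    truth = directory / "ground_truth.json"
    with open(truth, "w") as fh:
        json.dump([p.truth_dict() for p in patients], fh, indent=2)
    paths.append(truth)
    return paths


def read_cohort(directory) -> tuple[list[LabSeries], list[dict]]:
    """Read back a written cohort: (lab series, ground-truth records)."""
    directory = Path(directory)
    with open(directory / "ground_truth.json") as fh:
        truth = json.load(fh)
    labs = [
        LabSeries.from_csv(directory / f"{rec['patient_id']}.csv")
        for rec in truth
    ]
    return labs, truth
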