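"""Model/Results interface over the estimation machinery.

``APLInductionModel`` is constructed from one patient's laboratory series
(and an induction schedule); ``fit()`` runs the multistart least-squares
procedure and returns an ``APLInductionResults`` carrying the selected
parameter tuple, the spread of the local minima (the only uncertainty
the procedure itself supports), the scenario census, and helpers for
simulation, protocol comparison and plotting.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .dynamics import simulate
from .equilibria import classify_scenario
from .fitting import (
    FitResult,
    LabSeries,
    default_init,
    error_E,
    multistart_fit,
    _split,
)
from .params import (
    FREE_PARAMETER_NAMES,
    TreatmentProtocol,
    fixed_parameters,
    ical_protocol,
    parameter_box,
)
from .protocols import compare_protocols as _compare_protocols

__all__ = ["APLInductionModel", "APLInductionResults"]


class APLInductionModel:
    """Two-population leukocyte competition model for one induction course.

    Parameters
    ----------
    lab : LabSeries
        Observed total and immature leukocyte counts over days 0–30.
    protocol : TreatmentProtocol, optional
        The schedule the patient received; defaults to the standard
        induction protocol (chemo 60 mg/m² days 2/4/6/8, ATRA days 0–30).
        Its β3/γ entries are placeholders — they are estimated.
    init : (N0, A0), optional
        Initial cell counts; defaults to the day-0 laboratory convention
        (A0 = day-0 immature count or 0, N0 = day-0 total minus A0).
    box, fixed : optional
        Search intervals for the free parameters and the cohort-wide
        fixed rates.
    """

    def __init__(self, lab: LabSeries, protocol: TreatmentProtocol | None = None,
                 init=None, box=None, fixed=None):
        self.lab = lab
        self.protocol = protocol if protocol is not None else ical_protocol()
        self.init = tuple(init) if init is not None else default_init(lab)
        self.box = parameter_box() if box is None else box
        self.fixed = fixed_parameters() if fixed is None else fixed

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, patient_id: str | None = None,
                       **kwargs) -> "APLInductionModel":
        """Build from a tidy frame with columns patient_id, day, wbc_total, immature."""
        return cls(LabSeries.from_frame(df, patient_id), **kwargs)

    @classmethod
    def from_csv(cls, path, patient_id: str | None = None,
                 **kwargs) -> "APLInductionModel":
        return cls(LabSeries.from_csv(path, patient_id), **kwargs)

    def loglike_error(self, x) -> float:
        """The quadratic objective E(X) at a free-parameter tuple."""
        return error_E(x, self.lab, self.init, self.protocol, fixed=self.fixed)

    def fit(self, K: int = 10000, n_keep: int = 100, seed: int | None = None,
            method: str = "descent", **kwargs) -> "APLInductionResults":
        res = multistart_fit(
            self.lab, self.init, self.protocol,
            K=K, n_keep=n_keep, seed=seed, box=self.box, fixed=self.fixed,
            method=method, **kwargs,
        )
        return APLInductionResults(self, res)


class APLInductionResults:
    """Estimates, local-minima spread, scenario census and diagnostics."""

    def __init__(self, model: APLInductionModel, fitres: FitResult):
        self.model = model
        self.fitres = fitres
        self.params = pd.Series(fitres.best, index=list(FREE_PARAMETER_NAMES))
        self.error = fitres.best_error
        self.scenario = fitres.best_scenario
        self.census = fitres.census

    # -- uncertainty proxy ---------------------------------------------------
    def minima_spread(self, q: tuple[float, float] = (25.0, 75.0)) -> pd.DataFrame:
        """Per-parameter percentile spread across the polished local minima.

        The multistart procedure yields a cloud of local minima rather
        than a sampling distribution; the spread of that cloud is
        reported as the (only) available dispersion measure.
        """
        ok = np.isfinite(self.fitres.minima_errors)
        m = self.fitres.minima[ok]
        lo = np.percentile(m, q[0], axis=0)
        hi = np.percentile(m, q[1], axis=0)
        return pd.DataFrame(
            {"estimate": self.params.values, f"p{q[0]:g}": lo, f"p{q[1]:g}": hi},
            index=list(FREE_PARAMETER_NAMES),
        )

    def model_parameters(self):
        """(ModelParameters, beta3, gamma) at the selected tuple."""
        return _split(self.params.values, self.model.fixed)

    def scenario_report(self):
        params, _, _ = self.model_parameters()
        return classify_scenario(params)

    def simulate(self, t_end: float = 30.0, **kwargs):
        """Trajectory of the fitted model under the fitted protocol."""
        params, beta3, gamma = self.model_parameters()
        proto = self.model.protocol.with_patient_effects(beta3, gamma)
        return simulate(params, proto, self.model.init, t_end, **kwargs)

    def compare_protocols(self, **kwargs) -> pd.DataFrame:
        """Outcome table (Nmin, t_REM) of the built-in protocol library."""
        params, beta3, gamma = self.model_parameters()
        proto = self.model.protocol.with_patient_effects(beta3, gamma)
        return _compare_protocols(params, proto, self.model.init, **kwargs)

    def summary(self) -> str:
        spread = self.minima_spread()
        lines = [
            "APL induction model — multistart least-squares fit",
            "=" * 58,
            f"patient id:        {self.model.lab.patient_id}",
            f"observations:      {self.model.lab.n1} total WBC, "
            f"{self.model.lab.n2} immature",
            f"initial state:     N0={self.model.init[0]:.6g}, "
            f"A0={self.model.init[1]:.6g} cells/mm3",
            f"samples / starts:  {len(self.fitres.samples)} / "
            f"{len(self.fitres.minima)}",
            f"quadratic error E: {self.error:.6g}",
            f"scenario:          {self.scenario}",
            "scenario census:   "
            + ", ".join(f"{k}: {v:.0f}%" for k, v in sorted(self.census.items())),
            "-" * 58,
            f"{'parameter':<10}{'estimate':>14}{'minima p25':>14}{'minima p75':>14}",
        ]
        for name in FREE_PARAMETER_NAMES:
            row = spread.loc[name]
            lines.append(
                f"{name:<10}{row['estimate']:>14.6g}{row['p25']:>14.6g}"
                f"{row['p75']:>14.6g}"
            )
        lines.append("=" * 58)
        return "\n".join(lines)

    def plot_fit(self, ax=None, t_end: float = 30.0):
        """Fitted trajectory with the lab observations overlaid."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        traj = self.simulate(t_end)
        ax.plot(traj.t, traj.wbc, label="model N+A", color="C0")
        ax.plot(traj.t, traj.A, label="model A", color="C1")
        lab = self.model.lab
        ax.plot(lab.t_wbc, lab.wbc, "o", color="C0", label="observed WBC")
        if lab.n2:
            ax.plot(lab.t_imm, lab.imm, "s", color="C1", label="observed immature")
        ax.set_xlabel("day of induction")
        ax.set_ylabel("cells/mm³")
        ax.legend()
        return ax
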