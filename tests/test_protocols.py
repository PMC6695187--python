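"""Protocol library, cytotoxicity nadir and sustained-remission time."""

import dataclasses
import json
import math

import numpy as np
import pytest

import apldyn as a
from apldyn.dynamics import chemo_exposure
from apldyn.params import Trajectory, TreatmentProtocol


def _flat_traj(t, A, N=1000.0):
    t = np.asarray(t, dtype=float)
    return Trajectory(t=t, N=np.full_like(t, N), A=np.asarray(A, dtype=float),
                      D=np.zeros_like(t))


class TestNmin:
    def test_constant_solution_without_chemo(self, p18):
        params, beta3, _ = p18
        proto = dataclasses.replace(a.ical_protocol(beta3, 0.0), dose_days=())
        N0 = params.r_N / params.mu_N
        traj = a.simulate(params, proto, (N0, 0.0), 30)
        assert a.n_min(traj) == pytest.approx(N0, rel=1e-9)

    def test_monotone_recovery_has_nadir_at_start(self, p18):
        params, beta3, _ = p18
        proto = dataclasses.replace(a.ical_protocol(beta3, 0.0), dose_days=())
        traj = a.simulate(params, proto, (100.0, 0.0), 30)
        assert a.n_min(traj) == pytest.approx(100.0)

    def test_more_chemo_cannot_raise_the_nadir(self, p18):
        params, beta3, gamma = p18
        weak = a.ical_protocol(beta3, gamma * 0.5)
        strong = a.ical_protocol(beta3, gamma)
        init = (1500.0, 5000.0)
        nm_weak = a.n_min(a.simulate(params, weak, init, 30))
        nm_strong = a.n_min(a.simulate(params, strong, init, 30))
        assert nm_strong <= nm_weak

    def test_requires_full_window(self, p18):
        params, beta3, gamma = p18
        traj = a.simulate(params, a.ical_protocol(beta3, gamma), (1500, 5000), 10)
        with pytest.raises(ValueError):
            a.n_min(traj)


class TestTRem:
    def test_already_in_remission_returns_zero(self):
        t = np.linspace(0, 30, 301)
        traj = _flat_traj(t, 5.0 * np.exp(-0.1 * t))
        assert a.t_rem(traj) == 0.0

    def test_never_below_threshold_returns_inf(self):
        t = np.linspace(0, 30, 301)
        traj = _flat_traj(t, np.full_like(t, 5000.0))
        assert a.t_rem(traj) == math.inf

    def test_dip_and_relapse_within_window_returns_inf(self):
        # below 10 cells/mm3 around day 12, regrows past it by day 25
        t = np.linspace(0, 30, 601)
        A = 2000.0 * np.exp(-0.8 * t) + 0.02 * np.exp(0.45 * t)
        traj = _flat_traj(t, A)
        assert A.min() < 10.0 < A[-1]
        assert a.t_rem(traj) == math.inf

    def test_simulated_weak_protocol_relapses(self, scenario3_params):
        # leukemia always develops untreated; a short ATRA pulse only dents it
        proto = TreatmentProtocol(beta3=4.0, gamma=0.0, tau=0.623054,
                                  dose_days=(), dose_per_bsa=0.0, bsa=1.82,
                                  atra_start=0.0, atra_end=6.0, label="pulse")
        traj = a.simulate(scenario3_params, proto, (1000.0, 2000.0), 30)
        assert traj.A.min() < 10.0
        assert a.t_rem(traj) == math.inf

    def test_crossing_time_located_between_grid_points(self, p18):
        params, beta3, gamma = p18
        traj = a.simulate(params, a.ical_protocol(beta3, gamma), (1500, 5000), 30)
        t_star = a.t_rem(traj)
        assert math.isfinite(t_star)
        A_at = np.interp(t_star, traj.t, traj.A)
        assert A_at == pytest.approx(10.0, rel=1e-2)
        after = traj.A[traj.t > t_star + 1e-6]
        assert np.all(after < 10.0 + 1e-6)


class TestBuiltinProtocols:
    def test_library_contents_and_schedules(self):
        protos = {p.label: p for p in a.builtin_protocols(0.29, 0.09)}
        assert len(protos) == 13
        assert protos["P0"].dose_days == (2.0, 4.0, 6.0, 8.0)
        assert protos["P0"].dose_per_bsa == 60.0
        assert protos["P1"].dose_days == tuple(range(2, 10))
        assert protos["P1"].dose_per_bsa == 30.0
        # equal cumulative dose for P0 and P1
        assert sum(protos["P0"].dose_mg for _ in protos["P0"].dose_days) == \
            pytest.approx(sum(protos["P1"].dose_mg for _ in protos["P1"].dose_days))
        assert protos["P8"].dose_days == ()
        assert (protos["P8"].atra_start, protos["P8"].atra_end) == (0.0, 30.0)

    def test_atra_intensity_scales_beta3_linearly(self):
        protos = {p.label: p for p in a.builtin_protocols(0.29, 0.09)}
        assert protos["Q1"].beta3 == pytest.approx(0.29)
        assert protos["Q1"].atra_end == 15.0
        assert protos["Q2"].beta3 == pytest.approx(0.145)
        assert protos["Q3"].beta3 == pytest.approx(0.58)
        assert protos["Q3"].atra_end == 15.0
        assert protos["Q4"].beta3 == 0.0

    def test_json_round_trip_is_bit_identical(self, tmp_path):
        for proto in a.builtin_protocols(0.289005, 0.093906):
            path = tmp_path / f"{proto.label}.json"
            proto.to_json(path)
            back = TreatmentProtocol.from_json(path)
            assert back == proto
            assert json.dumps(back.to_dict()) == json.dumps(proto.to_dict())

    def test_cumulative_exposure_p0_equals_p1_up_to_timing(self):
        protos = {p.label: p for p in a.builtin_protocols(0.0, 0.0)}
        # closed-form integral of the decay superposition; equal cumulative
        # mass implies equal exposure up to the tail of the last doses
        e0 = chemo_exposure(protos["P0"], 1000.0)
        e1 = chemo_exposure(protos["P1"], 1000.0)
        assert e0 == pytest.approx(e1, rel=1e-9)
        # over the finite induction window, later doses leave more tail
        assert chemo_exposure(protos["P0"], 30.0) == pytest.approx(
            chemo_exposure(protos["P1"], 30.0), rel=0.01
        )


class TestCompareProtocols:
    def test_leukemia_free_patient_all_protocols_trivially_remit(self, p18):
        params, beta3, gamma = p18
        df = a.compare_protocols(params, a.ical_protocol(beta3, gamma),
                                 (1500.0, 0.0))
        assert len(df) == 13
        assert (df["t_REM"] == 0.0).all()
        assert df["remission"].all()
        # Nmin differences across chemo variants are chemo-driven
        nmin = df.set_index("protocol")["Nmin"]
        assert nmin["P8"] >= nmin["P0"] - 1e-6

    def test_progressive_patient_fails_atra_only(self, scenario3_params):
        base = a.ical_protocol(0.05, 0.03)  # ATRA too weak vs invasion rate
        df = a.compare_protocols(scenario3_params, base, (1000.0, 5000.0))
        row = df.set_index("protocol").loc["P8"]
        assert row["t_REM"] == math.inf and not row["remission"]

    def test_split_doses_are_gentler_on_normal_cells(self, p18):
        params, beta3, gamma = p18
        df = a.compare_protocols(params, a.ical_protocol(beta3, gamma),
                                 (1500.0, 5000.0)).set_index("protocol")
        assert df.loc["P1", "Nmin"] >= df.loc["P0", "Nmin"]

    def test_outcomes_csv_serializes_infinity(self, tmp_path, scenario3_params):
        from apldyn.protocols import write_outcomes_csv

        base = a.ical_protocol(0.05, 0.03)
        df = a.compare_protocols(scenario3_params, base, (1000.0, 5000.0))
        path = tmp_path / "outcomes.csv"
        write_outcomes_csv(df, path)
        text = path.read_text()
        assert "inf" in text


class TestAtraThreshold:
    def test_already_below_remission_level_gives_zero(self, scenario2_params,
                                                      atra_only):
        # a bistable patient whose tiny leukemic load sits in the
        # remission basin needs no ATRA at all
        assert a.atra_threshold(scenario2_params, atra_only, (1500.0, 5.0)) == 0.0

    def test_threshold_separates_remission_outcomes(self, p18, atra_only):
        params, _, _ = p18
        init = (1500.0, 5000.0)
        th = a.atra_threshold(params, atra_only, init)
        assert 0.0 < th < 1.0
        lo = a.simulate(params, atra_only.with_patient_effects(th * 0.9, 0.0),
                        init, 30)
        hi = a.simulate(params, atra_only.with_patient_effects(th * 1.1, 0.0),
                        init, 30)
        assert a.t_rem(lo) == math.inf
        assert math.isfinite(a.t_rem(hi))

    def test_remission_time_decreases_with_atra_strength(self, p18, atra_only):
        params, _, _ = p18
        init = (1500.0, 5000.0)
        th = a.atra_threshold(params, atra_only, init)
        times = [
            a.t_rem(a.simulate(params,
                               atra_only.with_patient_effects(b3, 0.0),
                               init, 30))
            for b3 in (th * 1.02, th * 1.1, th * 1.25)
        ]
        assert times[0] >= times[1] >= times[2]

    def test_no_threshold_in_range_raises(self, scenario3_params, atra_only):
        weak = dataclasses.replace(atra_only, atra_end=2.0)
        with pytest.raises(ValueError, match="no threshold"):
            a.atra_threshold(scenario3_params, weak, (1000.0, 20000.0))

    def test_percentage_of_standard_dose_arithmetic(self):
        # linear dose-response reading: a remission threshold of 0.1658
        # against a fitted 0.289005 corresponds to 57% of the standard dose
        assert 100 * 0.1658 / 0.289005 == pytest.approx(57.0, abs=0.5)
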