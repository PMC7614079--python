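"""Kinetic network, running unfolded fraction, isomer detection, force fits."""

import numpy as np
import pandas as pd
import pytest

from foldscape.idealize import Thresholds, estimate_levels, label_and_excise
from foldscape.io import Trajectory
from foldscape.kinetics import (
    build_transition_table,
    detect_isomer_switches,
    fit_isomerization_rate,
    folded_fraction_vs_force,
    rescue_probability,
    running_unfolded_fraction,
)
from foldscape.simulate import ObservationSpec, simulate_trajectory, two_state_network
from tests.conftest import square_wave_trajectory

THR2 = Thresholds(np.array([0.0, 18.2]), ["N", "U"])


def _duty_cycle_trajectory(folded_fraction, period_s=2.0, n_cycles=40, rate=500.0):
    """Square wave whose folded dwell is a fixed fraction of each period."""
    n_f = max(int(round(folded_fraction * period_s * rate)), 4)
    n_u = max(int(round((1 - folded_fraction) * period_s * rate)), 4)
    block = np.concatenate([np.zeros(n_f), np.full(n_u, 18.2)])
    z = np.tile(block, n_cycles)
    return Trajectory(np.arange(z.size) / rate, z, 8.5, rate)


class TestTransitionTable:
    def test_alternating_unit_dwells(self):
        traj = square_wave_trajectory(noise_sd=0.0, dwell_s=1.0, n_cycles=100)
        table = build_transition_table(label_and_excise(traj, THR2))
        assert len(table) == 2
        assert table["mean_time_s"].to_numpy() == pytest.approx([1.0, 1.0], abs=1e-9)
        assert table["n_events"].sum() == 198  # 199 transitions, first censored

    def test_empty_idealization_gives_empty_table(self):
        z = np.zeros(100)
        traj = Trajectory(np.arange(z.size) / 100.0, z, 8.5, 100.0)
        with pytest.warns(UserWarning):
            ide = label_and_excise(traj, THR2)
        assert build_transition_table(ide).empty

    def test_pooling_over_recordings(self):
        traj = square_wave_trajectory(noise_sd=0.0, dwell_s=1.0, n_cycles=10)
        ide = label_and_excise(traj, THR2)
        single = build_transition_table(ide)
        pooled = build_transition_table([ide, ide])
        assert (pooled["n_events"].to_numpy() == 2 * single["n_events"].to_numpy()).all()

    def test_catalogue_rates_recovered_within_three_sem(self, short_two_state):
        traj, _ = short_two_state
        thr = estimate_levels(traj, 2, labels=["F", "U"])
        table = build_transition_table(label_and_excise(traj, thr))
        fu = table[(table["from_label"] == "F")].iloc[0]
        assert abs(fu["mean_time_s"] - 1.4) < 3 * fu["sem_s"]

    def test_detailed_balance_event_counts(self, short_two_state):
        traj, _ = short_two_state
        thr = estimate_levels(traj, 2, labels=["F", "U"])
        events = label_and_excise(traj, thr).transition_events()
        n_fu = len(events[events["from_label"] == "F"])
        n_uf = len(events[events["from_label"] == "U"])
        assert abs(n_fu - n_uf) <= 1


class TestRunningUnfoldedFraction:
    def test_equal_dwells_give_half(self):
        traj = square_wave_trajectory(noise_sd=0.0, dwell_s=1.0, n_cycles=30)
        ide = label_and_excise(traj, THR2)
        pu = running_unfolded_fraction(ide, n=10)
        assert np.allclose(pu["P_U"], 0.5, atol=1e-9)
        # stride one transition
        events = ide.transition_events()
        assert len(pu) == len(events) - 10 + 1

    def test_three_to_one_dwell_ratio(self):
        traj = _duty_cycle_trajectory(folded_fraction=0.25, n_cycles=30)
        pu = running_unfolded_fraction(label_and_excise(traj, THR2), n=10)
        assert np.allclose(pu["P_U"], 0.75, atol=1e-6)

    def test_window_equal_to_total_matches_whole_trace(self):
        traj = _duty_cycle_trajectory(folded_fraction=0.4, n_cycles=12)
        ide = label_and_excise(traj, THR2)
        n_total = len(ide.transition_events())
        pu = running_unfolded_fraction(ide, n=n_total)
        assert len(pu) == 1
        assert pu["P_U"].iloc[0] == pytest.approx(0.6, abs=1e-6)

    def test_bounds_always_respected(self, short_two_state):
        traj, _ = short_two_state
        thr = estimate_levels(traj, 2, labels=["N", "U"])
        pu = running_unfolded_fraction(label_and_excise(traj, thr), n=10)
        assert ((pu["P_U"] >= 0) & (pu["P_U"] <= 1)).all()

    def test_too_few_transitions_warns_empty(self):
        traj = square_wave_trajectory(noise_sd=0.0, dwell_s=1.0, n_cycles=2)
        ide = label_and_excise(traj, THR2)
        with pytest.warns(UserWarning, match="fewer"):
            pu = running_unfolded_fraction(ide, n=10)
        assert pu.empty


class TestIsomerSwitches:
    @staticmethod
    def _series(pu_values, dt=1.0):
        return pd.DataFrame(
            {"window": np.arange(len(pu_values)),
             "time_s": np.arange(len(pu_values)) * dt,
             "P_U": pu_values}
        )

    def test_constant_occupancy_yields_no_events(self):
        events = detect_isomer_switches(self._series(np.full(200, 0.5)))
        assert events.empty

    def test_single_switch_duration(self):
        pu = np.concatenate([np.full(50, 0.5), np.full(63, 0.95), np.full(50, 0.5)])
        events = detect_isomer_switches(self._series(pu))
        assert len(events) == 1
        assert events["duration_s"].iloc[0] == pytest.approx(63.0, rel=0.2)

    def test_two_separated_switches(self):
        pu = np.concatenate(
            [np.full(30, 0.5), np.full(40, 0.95), np.full(30, 0.5),
             np.full(40, 0.95), np.full(30, 0.5)]
        )
        events = detect_isomer_switches(self._series(pu))
        assert len(events) == 2

    def test_open_event_reported_with_nan_offset(self):
        pu = np.concatenate([np.full(30, 0.5), np.full(40, 0.95)])
        events = detect_isomer_switches(self._series(pu))
        assert len(events) == 1 and np.isnan(events["offset_s"].iloc[0])

    def test_hysteresis_ignores_brief_excursions(self):
        pu = np.full(100, 0.5)
        pu[40:42] = 0.95  # shorter than min_windows
        assert detect_isomer_switches(self._series(pu)).empty

    def test_switch_detected_in_idealized_recording(self):
        # folding equilibrium flips from 50 % to 90 % unfolded mid-recording
        native = _duty_cycle_trajectory(folded_fraction=0.5, period_s=2.0, n_cycles=40)
        trans = _duty_cycle_trajectory(folded_fraction=0.1, period_s=2.0, n_cycles=40)
        z = np.concatenate([native.extension, trans.extension, native.extension])
        traj = Trajectory(np.arange(z.size) / 500.0, z, 8.5, 500.0)
        pu = running_unfolded_fraction(label_and_excise(traj, THR2), n=10)
        events = detect_isomer_switches(pu)
        assert len(events) == 1
        switch_on = 40 * 2.0  # ground-truth onset time
        assert abs(events["onset_s"].iloc[0] - switch_on) < 2 * 2.0  # within 2 windows


class TestIsomerizationRate:
    def test_noiseless_identity(self):
        forces = [7.5, 8.0, 8.5, 9.0, 9.5]
        pu = {f: 1.0 / (1.0 + np.exp(-(f - 8.5) / 0.35)) for f in forces}
        k_true = 0.0017
        time = {f: 1e5 for f in forces}
        counts = {f: k_true * pu[f] * time[f] for f in forces}
        fit = fit_isomerization_rate(counts, time, pu)
        assert fit.k_per_s == pytest.approx(k_true, rel=1e-12)
        assert fit.timescale_s == pytest.approx(588.2, abs=0.1)

    def test_poisson_counting_recovery(self):
        rng = np.random.default_rng(17)
        forces = [7.5, 8.0, 8.5, 9.0, 9.5]
        pu = {f: 1.0 / (1.0 + np.exp(-(f - 8.5) / 0.35)) for f in forces}
        k_true = 0.0017
        time = {f: 2e5 for f in forces}
        counts = {f: int(rng.poisson(k_true * pu[f] * time[f])) for f in forces}
        fit = fit_isomerization_rate(counts, time, pu)
        assert fit.k_per_s == pytest.approx(k_true, rel=0.15)

    def test_unidentifiable_when_never_unfolded(self):
        forces = [7.5, 8.5, 9.5]
        with pytest.warns(UserWarning, match="unidentifiable"):
            fit = fit_isomerization_rate(
                {f: 0 for f in forces}, {f: 1e4 for f in forces}, {f: 0.0 for f in forces}
            )
        assert not fit.identifiable and np.isnan(fit.k_per_s)

    def test_input_validation(self):
        with pytest.raises(ValueError, match="3 force"):
            fit_isomerization_rate({8.5: 1}, {8.5: 10.0}, {8.5: 0.5})
        with pytest.raises(ValueError, match="observation time"):
            fit_isomerization_rate(
                {7.5: 1, 8.5: 1, 9.5: 1}, {7.5: 0.0, 8.5: 1.0, 9.5: 1.0},
                {7.5: 0.5, 8.5: 0.5, 9.5: 0.5}
            )


class TestFoldedFractionVsForce:
    def test_symmetric_occupancies_give_exact_midpoint(self):
        fractions = {7.5: 0.9, 8.0: 0.75, 9.0: 0.25, 9.5: 0.1}
        ides = {
            f: label_and_excise(_duty_cycle_trajectory(p, n_cycles=25), THR2)
            for f, p in fractions.items()
        }
        resp = folded_fraction_vs_force(ides, folded_label="N")
        assert resp.midpoint_pN == pytest.approx(8.5, abs=0.05)
        got = dict(zip(resp.per_force["force_pN"], resp.per_force["folded_fraction"]))
        for f, p in fractions.items():
            assert got[f] == pytest.approx(p, abs=0.01)

    def test_bell_simulation_recovers_response_width(self):
        conf, net = two_state_network(delta_x_total=12.0)
        ides = {}
        for i, force in enumerate([7.5, 8.0, 8.5, 9.0, 9.5]):
            traj, _ = simulate_trajectory(
                net, conf, duration=300.0, force=force,
                observation=ObservationSpec(sampling_rate=1000.0), seed=50 + i,
                initial_label="F",
            )
            thr = estimate_levels(traj, 2, labels=["N", "U"])
            ides[force] = label_and_excise(traj, thr)
        resp = folded_fraction_vs_force(ides, folded_label="N")
        assert resp.midpoint_pN == pytest.approx(8.5, abs=0.2)
        assert resp.width_10_90_pN == pytest.approx(4.11 * np.log(81.0) / 12.0, rel=0.2)

    def test_degenerate_occupancies_rejected(self):
        z = np.zeros(2_000)
        traj = Trajectory(np.arange(z.size) / 500.0, z, 8.5, 500.0)
        with pytest.warns(UserWarning):
            ide = label_and_excise(traj, THR2)
        ides = {f: ide for f in [7.5, 8.0, 9.0, 9.5]}
        with pytest.raises(ValueError, match="degenerate"):
            folded_fraction_vs_force(ides, folded_label="N")

    def test_requires_four_forces(self):
        ides = {8.5: label_and_excise(_duty_cycle_trajectory(0.5), THR2)}
        with pytest.raises(ValueError, match="4 force"):
            folded_fraction_vs_force(ides)


class TestRescueProbability:
    def test_all_rescued(self):
        table = rescue_probability({15.0: [True] * 10})
        assert table["p_rescue"].iloc[0] == 1.0 and table["sem"].iloc[0] == 0.0

    def test_seven_of_ten(self):
        table = rescue_probability({10.0: [True] * 7 + [False] * 3})
        assert table["p_rescue"].iloc[0] == pytest.approx(0.7)
        assert table["sem"].iloc[0] == pytest.approx(0.145, abs=0.001)

    def test_escape_rate_model_closed_form(self):
        # 15 s pulses with Bell-type escape rate: P = 1 - exp(-k(F) * 15)
        rng = np.random.default_rng(23)
        outcomes = {}
        expected = {}
        for force in [6.0, 10.0, 14.0, 18.0]:
            k = 0.02 * np.exp((force - 6.0) * 1.0 / 4.11)
            p = 1.0 - np.exp(-k * 15.0)
            expected[force] = p
            outcomes[force] = list(rng.random(60) < p)
        table = rescue_probability(outcomes)
        for row in table.itertuples(index=False):
            p = expected[row.force_pN]
            se = np.sqrt(p * (1 - p) / 60)
            assert abs(row.p_rescue - p) <= 3 * max(se, 1e-9)

    def test_empty_trials_rejected(self):
        with pytest.raises(ValueError, match="no trials"):
            rescue_probability({10.0: []})
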