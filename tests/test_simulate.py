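"""Synthetic trajectory generator: network construction, Gillespie, rendering."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from foldscape import reference
from foldscape.polymer import fjc_variance_factor
from foldscape.simulate import (
    ConformationSpec,
    ForceProtocol,
    KineticNetworkSpec,
    ObservationSpec,
    RateEdge,
    StatePath,
    bell_rate,
    network_from_tables,
    r3_scenario,
    region_scenario,
    render_trajectory,
    simulate_state_path,
    simulate_trajectory,
    two_state_network,
)


class TestNetworkFromTables:
    def test_edge_rate_is_reciprocal_mean_time(self):
        conf, net = r3_scenario()
        rate_fu = next(e.rate for e in net.edges if (e.from_label, e.to_label) == ("F", "U"))
        assert rate_fu == pytest.approx(1.0 / 1.4, rel=1e-12)
        assert rate_fu == pytest.approx(0.714, abs=5e-4)

    def test_single_conformation_table_has_no_edges(self):
        conf = pd.DataFrame([{"state": "i", "label": "F", "delta_z_nm": 0.0, "delta_var_nm2": 0.0}])
        trans = pd.DataFrame(columns=["from_label", "to_label", "mean_time_s"])
        specs, net = network_from_tables(conf, trans)
        assert list(specs) == ["F"] and net.edges == []

    def test_unknown_endpoint_rejected(self):
        conf = pd.DataFrame([{"state": "i", "label": "F", "delta_z_nm": 0.0, "delta_var_nm2": 0.0}])
        trans = pd.DataFrame([{"from_label": "F", "to_label": "U", "mean_time_s": 1.4}])
        with pytest.raises(ValueError, match="unknown conformation"):
            network_from_tables(conf, trans)

    def test_non_positive_time_rejected(self):
        conf = pd.DataFrame(
            [
                {"state": "i", "label": "F", "delta_z_nm": 0.0, "delta_var_nm2": 0.0},
                {"state": "i", "label": "U", "delta_z_nm": 18.2, "delta_var_nm2": 5.8},
            ]
        )
        trans = pd.DataFrame([{"from_label": "F", "to_label": "U", "mean_time_s": 0.0}])
        with pytest.raises(ValueError, match="must be > 0"):
            network_from_tables(conf, trans)

    def test_unfolded_exit_rate_reproduces_short_dwell(self):
        # competing clocks: the expected U dwell is 1/(sum of exit rates),
        # dominated by refolding; the catalogued rates give ~1.3 s
        _, net = r3_scenario()
        total = sum(e.rate for e in net.edges if e.from_label == "U")
        expected = 1.0 / sum(
            1.0 / t
            for _st, a, _b, t, _n in reference.TRANSITION_TABLE
            if a == "U"
        )
        assert 1.0 / total == pytest.approx(expected, rel=1e-12)
        assert 1.0 / total == pytest.approx(1.3, abs=0.01)


class TestGillespie:
    def test_symmetric_two_state_occupancy_is_half(self):
        net = KineticNetworkSpec([RateEdge("A", "B", 1.0), RateEdge("B", "A", 1.0)])
        path = simulate_state_path(net, duration=20_000.0, force_protocol=8.5, seed=1)
        assert len(path.labels) >= 10_000
        times = np.append(path.entry_times, path.duration)
        dur = np.diff(times)
        occ_a = dur[np.array(path.labels) == "A"].sum() / path.duration
        n = len(path.labels)
        se = 0.5 * np.sqrt(2.0 / n)  # occupancy s.e. for alternating exponential dwells
        assert abs(occ_a - 0.5) < 3 * se

    def test_single_conformation_is_constant_with_warning(self):
        net = KineticNetworkSpec([RateEdge("A", "B", 1.0)])
        with pytest.warns(UserWarning, match="absorbing"):
            path = simulate_state_path(net, duration=10.0, force_protocol=8.5, seed=0,
                                       initial_label="B")
        assert path.labels == ["B"]

    def test_exit_fractions_match_rate_ratio(self):
        # star network with the catalogued U->F and U->H clocks: the fraction
        # of U exits entering H is the multinomial rate ratio
        net = KineticNetworkSpec(
            [
                RateEdge("U", "F", 1.0 / 1.3),
                RateEdge("U", "H", 1.0 / 1251.8),
                RateEdge("F", "U", 1.0 / 1.4),
                RateEdge("H", "U", 1.0 / 96.3),
            ]
        )
        path = simulate_state_path(net, duration=100_000.0, force_protocol=8.5, seed=3,
                                   initial_label="U")
        labels = np.array(path.labels)
        exits_from_u = labels[1:][labels[:-1] == "U"]
        p = (1.0 / 1251.8) / (1.0 / 1.3 + 1.0 / 1251.8)
        n = exits_from_u.size
        observed = int((exits_from_u == "H").sum())
        assert abs(observed - n * p) <= 3 * np.sqrt(n * p * (1 - p))

    def test_dwell_times_are_exponential(self):
        net = KineticNetworkSpec([RateEdge("A", "B", 2.0), RateEdge("B", "A", 0.5)])
        path = simulate_state_path(net, duration=3_500.0, force_protocol=8.5, seed=7,
                                   initial_label="A")
        times = np.append(path.entry_times, path.duration)
        dur = np.diff(times)[:-1]  # last dwell censored
        labels = np.array(path.labels)[:-1]
        a_dwells = dur[labels == "A"]
        assert a_dwells.size >= 1_000
        ks = stats.kstest(a_dwells, "expon", args=(0, 0.5))
        assert ks.pvalue > 0.01

    def test_force_protocol_segments_respected(self):
        # strong Bell factor: at high force the unfolded state dominates
        conf, net = two_state_network(delta_x_total=12.0)
        protocol = ForceProtocol(((50.0, 6.5), (50.0, 10.5)))
        path = simulate_state_path(net, force_protocol=protocol, seed=5, initial_label="F")
        times = np.append(path.entry_times, path.duration)
        dur = np.diff(times)
        labels = np.array(path.labels)
        mid = np.searchsorted(path.entry_times, 50.0)
        occ_f_low = dur[: mid][labels[: mid] == "F"].sum() / 50.0
        occ_f_high = dur[mid:][labels[mid:] == "F"].sum() / 50.0
        assert occ_f_low > 0.9 and occ_f_high < 0.1


class TestBellRate:
    def test_identity_at_reference_force(self):
        assert bell_rate(0.7, 8.5, 8.5, 6.0) == pytest.approx(0.7, rel=1e-15)

    def test_response_width_closed_form(self):
        # folded fraction k_f/(k_f+k_u) is logistic in force with
        # 10-90 % width kT ln(81) / delta_x_total
        kT, dx_total = 4.11, 12.0

        def folded_fraction(force):
            ku = bell_rate(1.0, force, 8.5, +dx_total / 2, kT)
            kf = bell_rate(1.0, force, 8.5, -dx_total / 2, kT)
            return kf / (kf + ku)

        width = kT * np.log(81.0) / dx_total
        f_lo = 8.5 - width / 2
        f_hi = 8.5 + width / 2
        assert folded_fraction(f_lo) == pytest.approx(0.9, abs=1e-12)
        assert folded_fraction(f_hi) == pytest.approx(0.1, abs=1e-12)
        assert width == pytest.approx(1.505, abs=0.01)

    def test_doubling_distance_halves_width(self):
        kT = 4.11
        width = lambda dx: kT * np.log(81.0) / dx
        assert width(24.0) == pytest.approx(width(12.0) / 2)

    def test_non_positive_kT_rejected(self):
        with pytest.raises(ValueError):
            bell_rate(1.0, 8.5, 8.5, 6.0, kT=0.0)


class TestRender:
    def test_zero_noise_renders_exact_levels(self):
        conf = {
            "F": ConformationSpec("F", 0.0, 0.0),
            "U": ConformationSpec("U", 18.2, 0.0),
        }
        path = StatePath(["F", "U", "F"], np.array([0.0, 1.0, 2.0]), 3.0)
        traj = render_trajectory(path, ObservationSpec(sampling_rate=100.0, baseline_noise_sd=0.0),
                                 conf, seed=0)
        assert len(traj) == 300
        assert np.all(traj.extension[:100] == 0.0)
        assert np.all(traj.extension[100:200] == 18.2)
        assert np.all(traj.extension[200:] == 0.0)

    def test_baseline_noise_variance(self):
        conf = {"F": ConformationSpec("F", 0.0, 0.0)}
        path = StatePath(["F"], np.array([0.0]), 100.0)
        traj = render_trajectory(path, ObservationSpec(sampling_rate=1000.0, baseline_noise_sd=0.85),
                                 conf, seed=1)
        n = len(traj)
        var = traj.extension.var(ddof=1)
        se = 0.85**2 * np.sqrt(2.0 / (n - 1))
        assert abs(var - 0.7225) < 3 * se

    def test_fjc_forward_variance_recovered(self):
        # U-state excess variance set by the forward model for the unfolded
        # contour-length increment at 8.5 pN
        v = fjc_variance_factor(8.5)
        excess = 42.5 * v
        conf = {"U": ConformationSpec("U", 18.2, excess)}
        path = StatePath(["U"], np.array([0.0]), 100.0)
        traj = render_trajectory(path, ObservationSpec(sampling_rate=1000.0, baseline_noise_sd=0.85),
                                 conf, seed=2)
        n = len(traj)
        total_var = 0.85**2 + excess
        se = total_var * np.sqrt(2.0 / (n - 1))
        assert abs(traj.extension.var(ddof=1) - total_var) < 3 * se

    def test_sample_count_conservation(self):
        conf, net = two_state_network()
        traj, path = simulate_trajectory(net, conf, duration=12.34, force=8.5,
                                         observation=ObservationSpec(sampling_rate=1500.0), seed=3)
        assert len(traj) == int(round(12.34 * 1500.0))

    def test_seed_reproducibility(self):
        conf, net = two_state_network()
        t1, p1 = simulate_trajectory(net, conf, duration=30.0, force=8.5, seed=99)
        t2, p2 = simulate_trajectory(net, conf, duration=30.0, force=8.5, seed=99)
        assert np.array_equal(t1.extension, t2.extension)
        assert p1.labels == p2.labels
        assert np.array_equal(p1.entry_times, p2.entry_times)

    def test_finite_transition_paths_ramp_between_levels(self):
        conf = {
            "F": ConformationSpec("F", 0.0, 0.0),
            "U": ConformationSpec("U", 18.2, 0.0),
        }
        path = StatePath(["F", "U"], np.array([0.0, 1.0]), 2.0)
        obs = ObservationSpec(sampling_rate=1000.0, baseline_noise_sd=0.0,
                              transition_path_duration=0.01)
        traj = render_trajectory(path, obs, conf, seed=0)
        ramp = traj.extension[1000:1010]
        assert np.all(np.diff(ramp) > 0)
        assert np.all((ramp >= 0) & (ramp <= 18.2))
        assert traj.extension[1010] == 18.2


class TestSpecs:
    def test_negative_excess_variance_rejected(self):
        with pytest.raises(ValueError):
            ConformationSpec("X", 0.0, -1.0)

    def test_protocol_validation(self):
        with pytest.raises(ValueError):
            ForceProtocol(((0.0, 8.5),))
        with pytest.raises(ValueError):
            ForceProtocol(((10.0, -1.0),))

    def test_conformation_from_contour_length_matches_forward_model(self):
        spec = ConformationSpec.from_contour_length("U", 18.2, 42.5, 8.5)
        assert spec.excess_var_nm2 == pytest.approx(42.5 * fjc_variance_factor(8.5), rel=1e-12)

    def test_region_scenario_shapes(self):
        conf, net, start = region_scenario("v")
        assert set(conf) == {"L1", "L2", "L3"}
        assert net is not None and len(net.edges) == 4
        conf_iv, net_iv, start_iv = region_scenario("iv")
        assert net_iv is None and start_iv == "H"
        with pytest.raises(ValueError):
            region_scenario("vii")
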