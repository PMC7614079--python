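"""Synthetic magnetic-tweezers trajectories from a continuous-time Markov chain.

The generator emulates a single protein tether hopping between conformations:
a Gillespie realisation of a kinetic network (exponential dwells, competing
clocks) rendered through a Gaussian observation model. Each conformation
contributes its mean extension offset Δz and an excess extension variance Δσ²
on top of the bead-tracking point-spread function, so that only unstructured
sequence adds to the measured fluctuations, as in the freely-jointed-chain
picture. Force protocols (constant force, quenches, pulses) rescale the edge
rates through the Bell model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import Trajectory
from .polymer import FJCParams, fjc_variance_factor
from . import reference

__all__ = [
    "ConformationSpec",
    "RateEdge",
    "KineticNetworkSpec",
    "ForceProtocol",
    "ObservationSpec",
    "StatePath",
    "bell_rate",
    "network_from_tables",
    "r3_scenario",
    "region_scenario",
    "two_state_network",
    "simulate_state_path",
    "render_trajectory",
    "simulate_trajectory",
    "write_ground_truth",
]


@dataclass(frozen=True)
class ConformationSpec:
    """One conformation of the tethered protein.

    ``offset_nm`` is the mean extension relative to the natively folded form;
    ``excess_var_nm2`` the extra extension variance contributed by its
    unstructured sequence. ``state`` is the region (i–vi) it belongs to.
    """

    label: str
    offset_nm: float
    excess_var_nm2: float
    state: str = ""

    def __post_init__(self) -> None:
        if self.excess_var_nm2 < 0:
            raise ValueError(f"{self.label}: excess variance must be >= 0")

    @staticmethod
    def from_contour_length(
        label: str,
        offset_nm: float,
        unstructured_Lc_nm: float,
        force: float,
        params: FJCParams = FJCParams(),
        state: str = "",
    ) -> "ConformationSpec":
        """Derive the excess variance from an unstructured contour length via
        the FJC forward model: Δσ² = ΔL_c · v(F)."""
        return ConformationSpec(
            label, offset_nm, unstructured_Lc_nm * fjc_variance_factor(force, params), state
        )


@dataclass(frozen=True)
class RateEdge:
    """Directed transition with an exponential clock.

    ``delta_x_nm`` is the signed Bell distance: positive for unfolding-like
    edges (rate grows with force), negative for folding-like edges. Zero means
    force-independent.
    """

    from_label: str
    to_label: str
    rate: float
    delta_x_nm: float = 0.0

    def __post_init__(self) -> None:
        if self.rate <= 0:
            raise ValueError(f"{self.from_label}->{self.to_label}: rate must be > 0")


@dataclass
class KineticNetworkSpec:
    """Directed kinetic network with Bell force sensitivity around a reference force."""

    edges: list[RateEdge]
    ref_force: float = reference.COEXISTENCE_FORCE_PN
    thermal_energy: float = 4.11

    def labels(self) -> list[str]:
        seen: dict[str, None] = {}
        for e in self.edges:
            seen.setdefault(e.from_label)
            seen.setdefault(e.to_label)
        return list(seen)

    def exits(self, label: str) -> list[RateEdge]:
        return [e for e in self.edges if e.from_label == label]

    def rates_at(self, label: str, force: float) -> tuple[list[str], np.ndarray]:
        """Exit targets and Bell-rescaled rates from ``label`` at ``force``."""
        exits = self.exits(label)
        targets = [e.to_label for e in exits]
        rates = np.array(
            [
                bell_rate(e.rate, force, self.ref_force, e.delta_x_nm, self.thermal_energy)
                for e in exits
            ]
        )
        return targets, rates


@dataclass(frozen=True)
class ForceProtocol:
    """Ordered (duration s, force pN) segments."""

    segments: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        for dur, force in self.segments:
            if dur <= 0:
                raise ValueError("segment durations must be > 0")
            if force < 0:
                raise ValueError("forces must be >= 0")

    @staticmethod
    def constant(duration: float, force: float) -> "ForceProtocol":
        return ForceProtocol(((duration, force),))

    @property
    def duration(self) -> float:
        return sum(d for d, _ in self.segments)

    def boundaries(self) -> np.ndarray:
        return np.concatenate([[0.0], np.cumsum([d for d, _ in self.segments])])

    def force_at(self, t: float) -> float:
        edges = self.boundaries()
        idx = min(np.searchsorted(edges, t, side="right") - 1, len(self.segments) - 1)
        return self.segments[max(idx, 0)][1]

    def force_series(self, time: np.ndarray) -> np.ndarray:
        edges = self.boundaries()
        idx = np.clip(np.searchsorted(edges, time, side="right") - 1, 0, len(self.segments) - 1)
        return np.array([f for _, f in self.segments])[idx]


@dataclass(frozen=True)
class ObservationSpec:
    """Observation model of the instrument.

    ``baseline_noise_sd`` is the bead/point-spread-function noise applied to
    every conformation; per-conformation observed sd is
    ``sqrt(baseline² + Δσ²)``. ``transition_path_duration`` > 0 renders a
    finite linear ramp between levels instead of an instantaneous jump.
    ``ar1_corr_time`` > 0 switches the noise to an AR(1) process with that
    correlation time (white Gaussian otherwise).
    """

    sampling_rate: float = 1500.0
    baseline_noise_sd: float = reference.PSF_SD_NM
    drift_rate: float = 0.0
    transition_path_duration: float = 0.0
    ar1_corr_time: float | None = None

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be > 0")
        if self.baseline_noise_sd < 0:
            raise ValueError("baseline_noise_sd must be >= 0")


@dataclass
class StatePath:
    """Gillespie realisation: conformation labels and their entry times."""

    labels: list[str]
    entry_times: np.ndarray
    duration: float

    def __post_init__(self) -> None:
        self.entry_times = np.asarray(self.entry_times, dtype=float)

    def label_at(self, time: np.ndarray) -> np.ndarray:
        """Index into ``labels`` for each query time."""
        return np.clip(
            np.searchsorted(self.entry_times, time, side="right") - 1,
            0,
            len(self.labels) - 1,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"label": self.labels, "t_entry_s": self.entry_times})


def bell_rate(
    base_rate: float,
    force: float,
    ref_force: float,
    delta_x: float,
    kT: float = 4.11,
) -> float:
    """Bell-model rate ``k(F) = k0 · exp((F − F_ref) · Δx / kT)``.

    ``delta_x`` is signed: positive for unfolding-like transitions whose rate
    increases with force, negative for folding-like transitions.
    """
    if kT <= 0:
        raise ValueError("kT must be > 0")
    return base_rate * float(np.exp((force - ref_force) * delta_x / kT))


def network_from_tables(
    conformations: pd.DataFrame,
    transitions: pd.DataFrame,
    ref_force: float = reference.COEXISTENCE_FORCE_PN,
) -> tuple[dict[str, ConformationSpec], KineticNetworkSpec]:
    """Build the generator inputs from printed summary tables.

    ``conformations`` needs columns label, delta_z_nm, delta_var_nm2 (and
    optionally state); ``transitions`` needs from_label, to_label,
    mean_time_s. Each edge rate is the reciprocal of its printed mean
    transition time, read as a competing exponential clock.
    """
    specs: dict[str, ConformationSpec] = {}
    for row in conformations.itertuples(index=False):
        specs[row.label] = ConformationSpec(
            label=row.label,
            offset_nm=float(row.delta_z_nm),
            excess_var_nm2=float(row.delta_var_nm2),
            state=str(getattr(row, "state", "")),
        )
    edges = []
    for row in transitions.itertuples(index=False):
        for endpoint in (row.from_label, row.to_label):
            if endpoint not in specs:
                raise ValueError(f"transition references unknown conformation {endpoint!r}")
        if row.mean_time_s <= 0:
            raise ValueError(
                f"{row.from_label}->{row.to_label}: mean transition time must be > 0"
            )
        edges.append(RateEdge(row.from_label, row.to_label, 1.0 / float(row.mean_time_s)))
    return specs, KineticNetworkSpec(edges=edges, ref_force=ref_force)


def r3_scenario() -> tuple[dict[str, ConformationSpec], KineticNetworkSpec]:
    """Default scenario: the full talin R3(IVVI) conformational catalog.

    The trans-proline isomer conformations U2/F2 (state ii) share the U/F
    extension levels and variances but their own folding equilibrium.
    """
    conf = reference.conformation_table()
    trans_rows = pd.DataFrame(
        [
            {"state": "ii", "label": "U2", "delta_z_nm": 18.2, "delta_var_nm2": 5.8},
            {"state": "ii", "label": "F2", "delta_z_nm": 0.0, "delta_var_nm2": 0.0},
        ]
    )
    conf = pd.concat([conf, trans_rows], ignore_index=True)
    return network_from_tables(conf, reference.transition_table())


def region_scenario(
    region: str,
) -> tuple[dict[str, ConformationSpec], KineticNetworkSpec | None, str]:
    """Conformations and *internal* kinetics of one catalogued state region.

    Returns (conformations, network, initial_label); the network holds only
    the edges internal to the region (entry/exit edges to the unfolded
    conformation are dropped), so a realisation renders a representative
    stretch of that region's dynamics. Single-conformation regions (iii, iv)
    return ``network=None``. Region ii is the trans-proline isomer: the F/U
    extension levels with the trans-state folding equilibrium.
    """
    table = reference.conformation_table()
    lookup = {
        row.label: (float(row.delta_z_nm), float(row.delta_var_nm2))
        for row in table.itertuples(index=False)
    }
    if region == "ii":
        conf = {
            "F2": ConformationSpec("F2", 0.0, 0.0, "ii"),
            "U2": ConformationSpec("U2", 18.2, 5.8, "ii"),
        }
        net = KineticNetworkSpec(
            edges=[RateEdge("F2", "U2", 1.0 / 0.07), RateEdge("U2", "F2", 1.0 / 3.2)]
        )
        return conf, net, "U2"
    labels = {row.label for row in table.itertuples(index=False) if row.state == region}
    if not labels:
        raise ValueError(f"unknown state region {region!r}")
    conf = {lab: ConformationSpec(lab, *lookup[lab], state=region) for lab in labels}
    edges = [
        RateEdge(a, b, 1.0 / t)
        for st, a, b, t, _n in reference.TRANSITION_TABLE
        if st == region and a in labels and b in labels
    ]
    start = sorted(labels)[0]
    if not edges:
        return conf, None, start
    return conf, KineticNetworkSpec(edges=edges), start


def two_state_network(
    unfold_rate: float = 1.0 / 1.4,
    fold_rate: float = 1.0 / 1.3,
    ref_force: float = reference.COEXISTENCE_FORCE_PN,
    delta_x_total: float = 0.0,
    delta_z: float = 18.2,
    excess_var_U: float = 5.8,
    kT: float = 4.11,
) -> tuple[dict[str, ConformationSpec], KineticNetworkSpec]:
    """Native two-state (region i) scenario with optional Bell force response.

    ``delta_x_total`` is the total distance to the transition state (sum of the
    unfolding and folding Bell distances, split evenly); it sets the width of
    the folded-fraction force response, 10–90 % width ≈ kT·ln(81)/Δx_total.
    """
    specs = {
        "F": ConformationSpec("F", 0.0, 0.0, "i"),
        "U": ConformationSpec("U", delta_z, excess_var_U, "i"),
    }
    half = delta_x_total / 2.0
    net = KineticNetworkSpec(
        edges=[
            RateEdge("F", "U", unfold_rate, delta_x_nm=+half),
            RateEdge("U", "F", fold_rate, delta_x_nm=-half),
        ],
        ref_force=ref_force,
        thermal_energy=kT,
    )
    return specs, net


def simulate_state_path(
    network: KineticNetworkSpec,
    duration: float | None = None,
    force_protocol: ForceProtocol | float = reference.COEXISTENCE_FORCE_PN,
    seed: int | np.random.Generator = 0,
    initial_label: str | None = None,
) -> StatePath:
    """Gillespie realisation of the network under a (piecewise-constant) force protocol.

    Dwells are exponential with the conformation's total exit rate at the
    current force; the successor is drawn proportionally to the edge rates.
    Piecewise-constant force is handled by the memoryless property: the clock
    is simply redrawn at each protocol boundary.
    """
    if isinstance(force_protocol, (int, float)):
        if duration is None:
            raise ValueError("duration required when force_protocol is a constant force")
        force_protocol = ForceProtocol.constant(duration, float(force_protocol))
    total = force_protocol.duration if duration is None else float(duration)
    if total <= 0:
        raise ValueError("duration must be > 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    boundaries = force_protocol.boundaries()
    current = initial_label or network.labels()[0]
    labels = [current]
    entry_times = [0.0]
    t = 0.0
    while t < total:
        force = force_protocol.force_at(t)
        seg_idx = min(
            np.searchsorted(boundaries, t, side="right") - 1, len(force_protocol.segments) - 1
        )
        seg_end = min(boundaries[seg_idx + 1], total)
        targets, rates = network.rates_at(current, force)
        if len(targets) == 0:
            warnings.warn(f"conformation {current!r} is absorbing; dwelling to the end")
            t = total
            break
        r_tot = float(rates.sum())
        dt = rng.exponential(1.0 / r_tot)
        if t + dt >= seg_end:
            t = seg_end  # clock is memoryless: redraw at the new force
            continue
        t += dt
        current = targets[int(rng.choice(len(targets), p=rates / r_tot))]
        labels.append(current)
        entry_times.append(t)
    return StatePath(labels=labels, entry_times=np.array(entry_times), duration=total)


def render_trajectory(
    path: StatePath,
    observation: ObservationSpec,
    conformations: dict[str, ConformationSpec],
    seed: int | np.random.Generator = 0,
    force: ForceProtocol | float = reference.COEXISTENCE_FORCE_PN,
    molecule_id: str = "sim0",
) -> Trajectory:
    """Render a state path into a noisy extension–time recording.

    Per-sample extension = conformation offset + Gaussian noise with
    sd = sqrt(baseline² + Δσ²) (+ optional linear drift). With a finite
    ``transition_path_duration`` the level and sd ramp linearly after each
    switch instead of jumping.
    """
    if len(path.labels) == 0:
        raise ValueError("empty state path")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = int(round(path.duration * observation.sampling_rate))
    time = np.arange(n) / observation.sampling_rate

    label_list = list(conformations)
    index = {lab: i for i, lab in enumerate(label_list)}
    offsets = np.array([conformations[lab].offset_nm for lab in label_list])
    sds = np.array(
        [
            np.sqrt(observation.baseline_noise_sd**2 + conformations[lab].excess_var_nm2)
            for lab in label_list
        ]
    )
    try:
        path_idx = np.array([index[lab] for lab in path.labels])
    except KeyError as err:
        raise ValueError(f"state path visits unknown conformation {err}") from None
    per_sample = path_idx[path.label_at(time)]
    mean = offsets[per_sample]
    sd = sds[per_sample]

    if observation.transition_path_duration > 0 and len(path.labels) > 1:
        tp = observation.transition_path_duration
        for k in range(1, len(path.labels)):
            t0 = path.entry_times[k]
            i0 = int(np.ceil(t0 * observation.sampling_rate))
            i1 = min(int(np.ceil((t0 + tp) * observation.sampling_rate)), n)
            if i1 <= i0:
                continue
            frac = (time[i0:i1] - t0) / tp
            prev_i, new_i = path_idx[k - 1], path_idx[k]
            mean[i0:i1] = offsets[prev_i] + frac * (offsets[new_i] - offsets[prev_i])
            sd[i0:i1] = sds[prev_i] + frac * (sds[new_i] - sds[prev_i])

    noise = rng.standard_normal(n)
    if observation.ar1_corr_time and observation.ar1_corr_time > 0:
        # AR(1) with unit stationary variance; scaled per-sample afterwards
        rho = float(np.exp(-1.0 / (observation.ar1_corr_time * observation.sampling_rate)))
        innov_sd = np.sqrt(1.0 - rho**2)
        ar = np.empty(n)
        acc = noise[0]
        ar[0] = acc
        for i in range(1, n):  # short traces only; AR(1) is an optional robustness mode
            acc = rho * acc + innov_sd * noise[i]
            ar[i] = acc
        noise = ar
    extension = mean + sd * noise
    if observation.drift_rate:
        extension = extension + observation.drift_rate * time

    if isinstance(force, ForceProtocol):
        force_arr: np.ndarray | float = force.force_series(time)
        if np.ndim(force_arr) and np.allclose(force_arr, force_arr[0]):
            force_arr = float(force_arr[0])
    else:
        force_arr = float(force)
    return Trajectory(
        time=time,
        extension=extension,
        force=force_arr,
        sampling_rate=observation.sampling_rate,
        molecule_id=molecule_id,
        meta={"generator": "foldscape.simulate"},
    )


def simulate_trajectory(
    network: KineticNetworkSpec,
    conformations: dict[str, ConformationSpec],
    duration: float,
    force: ForceProtocol | float = reference.COEXISTENCE_FORCE_PN,
    observation: ObservationSpec = ObservationSpec(),
    seed: int = 0,
    initial_label: str | None = None,
    molecule_id: str = "sim0",
) -> tuple[Trajectory, StatePath]:
    """Simulate a state path and render it; one seed drives both stages."""
    rng = np.random.default_rng(seed)
    path = simulate_state_path(network, duration, force, rng, initial_label)
    traj = render_trajectory(path, observation, conformations, rng, force, molecule_id)
    traj.meta["seed"] = seed
    return traj, path


def write_ground_truth(path: StatePath, file) -> None:
    """Sidecar ground-truth state path as TSV (label, t_entry_s)."""
    path.to_frame().to_csv(file, sep="\t", index=False)
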