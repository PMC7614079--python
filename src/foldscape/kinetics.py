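"""Kinetic-network reconstruction and force-dependence analysis.

From idealized recordings: pooled mean transition times per directed edge (the
kinetic-network table), a running unfolded fraction P_U for detecting
cis–trans proline-isomer switches, the force-independent isomerization rate
from per-force switch counts via r(F) = P_U(F)·k, the folded-fraction force
response with its coexistence force F_0.5, and rescue-probability estimation
for force-pulse protocols.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .idealize import Idealization

__all__ = [
    "build_transition_table",
    "running_unfolded_fraction",
    "detect_isomer_switches",
    "fit_isomerization_rate",
    "folded_fraction_vs_force",
    "rescue_probability",
    "ForceResponse",
    "IsomerFit",
]


def build_transition_table(idealizations: list[Idealization] | Idealization) -> pd.DataFrame:
    """Pool directed transitions over recordings into a kinetic-network table.

    Returns one row per directed pair with the mean dwell time preceding that
    transition, its s.e.m. and the event count. Censored (recording-edge)
    dwells are excluded.
    """
    if isinstance(idealizations, Idealization):
        idealizations = [idealizations]
    events = [
        ide.transition_events().assign(recording=i) for i, ide in enumerate(idealizations)
    ]
    if not events:
        return pd.DataFrame(
            columns=["from_label", "to_label", "mean_time_s", "sem_s", "n_events"]
        )
    pooled = pd.concat(events, ignore_index=True)
    pooled = pooled[~pooled["censored"]]
    if pooled.empty:
        return pd.DataFrame(
            columns=["from_label", "to_label", "mean_time_s", "sem_s", "n_events"]
        )
    rows = []
    for (a, b), grp in pooled.groupby(["from_label", "to_label"], sort=False):
        t = grp["preceding_dwell_s"].to_numpy()
        rows.append(
            {
                "from_label": a,
                "to_label": b,
                "mean_time_s": t.mean(),
                "sem_s": t.std(ddof=1) / np.sqrt(t.size) if t.size > 1 else np.nan,
                "n_events": t.size,
            }
        )
    return pd.DataFrame(rows)


def running_unfolded_fraction(
    idealization: Idealization,
    n: int = 10,
    folded_label: str = "N",
    unfolded_label: str = "U",
) -> pd.DataFrame:
    """Unfolded fraction P_U = ⟨t_U⟩/(⟨t_U⟩+⟨t_F⟩) over a running window.

    The window covers ``n`` consecutive transitions (stride one transition);
    ⟨t_U⟩ and ⟨t_F⟩ are the mean dwell times of the two conformations within
    the window. Returns a DataFrame with window index, central time, P_U and
    the constituent means; empty (with a warning) when the recording holds
    fewer than ``n`` transitions.
    """
    if n < 2:
        raise ValueError("window must span at least 2 transitions")
    events = idealization.transition_events()
    events = events[
        events["from_label"].isin([folded_label, unfolded_label])
        & events["to_label"].isin([folded_label, unfolded_label])
    ].reset_index(drop=True)
    if len(events) < n:
        warnings.warn(f"fewer than n={n} transitions; empty P_U series")
        return pd.DataFrame(columns=["window", "time_s", "P_U", "mean_t_U_s", "mean_t_F_s"])
    rows = []
    for w in range(len(events) - n + 1):
        win = events.iloc[w : w + n]
        t_u = win.loc[win["from_label"] == unfolded_label, "preceding_dwell_s"]
        t_f = win.loc[win["from_label"] == folded_label, "preceding_dwell_s"]
        if t_u.empty or t_f.empty:
            # a window with only one conformation's exits pins P_U to 0 or 1
            pu = 1.0 if t_f.empty else 0.0
            mu_u = t_u.mean() if not t_u.empty else 0.0
            mu_f = t_f.mean() if not t_f.empty else 0.0
        else:
            mu_u, mu_f = t_u.mean(), t_f.mean()
            pu = mu_u / (mu_u + mu_f)
        rows.append(
            {
                "window": w,
                "time_s": win["time_s"].iloc[n // 2],
                "P_U": pu,
                "mean_t_U_s": mu_u,
                "mean_t_F_s": mu_f,
            }
        )
    return pd.DataFrame(rows)


def detect_isomer_switches(
    pu_series: pd.DataFrame,
    high_cut: float = 0.8,
    low_cut: float = 0.6,
    min_windows: int = 3,
) -> pd.DataFrame:
    """Hysteresis detection of abrupt shifts of the folding equilibrium.

    An event (e.g. a cis→trans proline switch) starts when P_U stays at or
    above ``high_cut`` for at least ``min_windows`` consecutive windows and
    ends when P_U stays at or below ``low_cut`` likewise. Returns onset/offset
    times and durations; an event still open at the end of the series is
    reported with ``offset_s = NaN``.
    """
    if pu_series.empty:
        return pd.DataFrame(columns=["onset_s", "offset_s", "duration_s"])
    if not (0 <= low_cut <= high_cut <= 1):
        raise ValueError("need 0 <= low_cut <= high_cut <= 1")
    pu = pu_series["P_U"].to_numpy()
    times = pu_series["time_s"].to_numpy()
    events = []
    inside = False
    onset = np.nan
    run = 0
    for i in range(pu.size):
        if not inside:
            run = run + 1 if pu[i] >= high_cut else 0
            if run >= min_windows:
                inside = True
                onset = times[i - min_windows + 1]
                run = 0
        else:
            run = run + 1 if pu[i] <= low_cut else 0
            if run >= min_windows:
                inside = False
                offset = times[i - min_windows + 1]
                events.append({"onset_s": onset, "offset_s": offset})
                run = 0
    if inside:
        events.append({"onset_s": onset, "offset_s": np.nan})
    out = pd.DataFrame(events, columns=["onset_s", "offset_s"])
    out["duration_s"] = out["offset_s"] - out["onset_s"]
    return out


@dataclass(frozen=True)
class IsomerFit:
    """Per-force isomerization rates and the fitted force-independent rate k.

    The model is r(F) = P_U(F) · k: isomerization proceeds only from the
    unfolded conformation, at a force-independent intrinsic rate.
    """

    per_force: pd.DataFrame  # force_pN, rate_per_s, P_U
    k_per_s: float
    identifiable: bool

    @property
    def timescale_s(self) -> float:
        return 1.0 / self.k_per_s if self.k_per_s > 0 else np.inf


def fit_isomerization_rate(
    switch_counts: dict[float, int],
    observation_time: dict[float, float],
    unfolded_fraction_curve: dict[float, float],
) -> IsomerFit:
    """Least-squares fit of k in r(F) = P_U(F)·k from per-force switch counts.

    ``switch_counts[F]`` events observed over ``observation_time[F]`` seconds
    give the empirical rate r̂(F); ``unfolded_fraction_curve[F]`` is the
    independently measured P_U(F). Requires at least 3 force points.
    """
    forces = sorted(switch_counts)
    if len(forces) < 3:
        raise ValueError("need at least 3 force points")
    rows = []
    for f in forces:
        t = observation_time[f]
        if t <= 0:
            raise ValueError(f"zero observation time at {f} pN")
        pu = unfolded_fraction_curve[f]
        if not 0 <= pu <= 1:
            raise ValueError(f"P_U({f}) = {pu} outside [0, 1]")
        rows.append({"force_pN": f, "rate_per_s": switch_counts[f] / t, "P_U": pu})
    per_force = pd.DataFrame(rows)
    pu = per_force["P_U"].to_numpy()
    r = per_force["rate_per_s"].to_numpy()
    denom = float(np.sum(pu**2))
    if denom == 0:
        warnings.warn("P_U is zero at every force: k is unidentifiable")
        return IsomerFit(per_force=per_force, k_per_s=np.nan, identifiable=False)
    k = float(np.sum(pu * r) / denom)
    return IsomerFit(per_force=per_force, k_per_s=k, identifiable=True)


@dataclass(frozen=True)
class ForceResponse:
    """Folded fraction versus force with its fitted logistic response.

    ``midpoint_pN`` is the coexistence force F_0.5 (occupancy 1/2);
    ``width_pN`` the logistic scale kT/Δx, so the 10–90 % width is
    width·ln(81).
    """

    per_force: pd.DataFrame  # force_pN, folded_fraction, sem
    midpoint_pN: float
    width_pN: float

    @property
    def width_10_90_pN(self) -> float:
        return self.width_pN * np.log(81.0)


def _logistic(force, midpoint, width):
    return 1.0 / (1.0 + np.exp((force - midpoint) / width))


def folded_fraction_vs_force(
    idealizations: dict[float, Idealization | list[Idealization]],
    folded_label: str = "N",
) -> ForceResponse:
    """Occupancy-based folded fraction at each force, with a logistic fit.

    The folded fraction at each force is the time fraction spent in
    ``folded_label`` (dwell samples only, matching the time-based definition
    of P_U). Requires ≥ 4 forces spanning the transition.
    """
    if len(idealizations) < 4:
        raise ValueError("need idealizations at >= 4 forces")
    rows = []
    for force in sorted(idealizations):
        ides = idealizations[force]
        if isinstance(ides, Idealization):
            ides = [ides]
        folded = sum(
            int(
                (ide.segments.loc[ide.segments["label"] == folded_label, "end"]
                 - ide.segments.loc[ide.segments["label"] == folded_label, "start"]).sum()
            )
            for ide in ides
        )
        total = sum(ide.dwell_sample_count() for ide in ides)
        n_events = sum(len(ide.transition_events()) for ide in ides)
        frac = folded / total
        # binomial-style uncertainty with the transition count as the
        # effective number of independent occupancy observations
        sem = np.sqrt(frac * (1 - frac) / max(n_events, 1))
        rows.append({"force_pN": force, "folded_fraction": frac, "sem": sem})
    per_force = pd.DataFrame(rows)
    y = per_force["folded_fraction"].to_numpy()
    if np.all(y <= 0.0) or np.all(y >= 1.0):
        raise ValueError("degenerate occupancies (all folded or all unfolded): no midpoint")
    x = per_force["force_pN"].to_numpy()
    p0 = (float(np.interp(0.5, y[::-1], x[::-1])), 0.35)
    popt, _ = curve_fit(_logistic, x, y, p0=p0, maxfev=10_000)
    return ForceResponse(per_force=per_force, midpoint_pN=float(popt[0]), width_pN=float(popt[1]))


def rescue_probability(pulse_outcomes: dict[float, list[bool]]) -> pd.DataFrame:
    """Binomial rescue probability ± s.e.m. per pulse force.

    A trial counts as rescued when native two-state dynamics is observed after
    the force pulse. Returns force_pN, n_trials, p_rescue, sem.
    """
    rows = []
    for force in sorted(pulse_outcomes):
        outcomes = np.asarray(pulse_outcomes[force], dtype=bool)
        if outcomes.size == 0:
            raise ValueError(f"no trials at {force} pN")
        p = outcomes.mean()
        rows.append(
            {
                "force_pN": force,
                "n_trials": outcomes.size,
                "p_rescue": p,
                "sem": np.sqrt(p * (1 - p) / outcomes.size),
            }
        )
    return pd.DataFrame(rows)
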