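"""Threshold idealization of extension–time recordings.

A recording of a protein hopping between K conformational levels is converted
into an ordered list of labelled dwell segments plus excised transition paths.
The thresholds are the mean extensions of the levels themselves: a transition
from level a to level b is the stretch of trajectory that leaves a's mean (in
the direction of b) and directly reaches b's mean without returning. Those
transition-path samples represent a diffusive excursion over the barrier and
are excluded from every downstream statistic (dwell times, variances).

Levels are estimated by a Gaussian-mixture fit to the extension histogram;
alternatively midpoint thresholds between adjacent level means can be used.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.mixture import GaussianMixture

from .io import Trajectory

__all__ = [
    "Thresholds",
    "Idealization",
    "estimate_levels",
    "label_and_excise",
    "dwell_statistics",
]


@dataclass
class Thresholds:
    """Per-conformation extension levels, sorted ascending.

    ``levels`` are the mean extensions (nm) of each conformation; ``sds`` the
    fitted component standard deviations; ``labels`` the conformation names in
    level order.
    """

    levels: np.ndarray
    labels: list[str]
    sds: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.levels = np.asarray(self.levels, dtype=float)
        if self.levels.ndim != 1 or self.levels.size < 1:
            raise ValueError("need at least one level")
        if np.any(np.diff(self.levels) <= 0):
            raise ValueError("levels must be strictly increasing")
        if len(self.labels) != self.levels.size:
            raise ValueError("one label per level required")

    @property
    def k(self) -> int:
        return self.levels.size


def _default_labels(k: int) -> list[str]:
    if k == 1:
        return ["C1"]
    if k == 2:
        return ["N", "U"]
    return [f"C{i + 1}" for i in range(k)]


def estimate_levels(
    trajectory: Trajectory,
    k_levels: int | None = 2,
    labels: list[str] | None = None,
    max_components: int = 4,
    max_samples: int = 200_000,
    min_dip: float = 0.001,
    seed: int = 0,
) -> Thresholds:
    """Fit a Gaussian mixture to the extension histogram and return level means.

    Parameters
    ----------
    k_levels : int or None
        Number of conformational levels. ``None`` selects 1..``max_components``
        by BIC.
    labels : list of str, optional
        Conformation names in ascending level order.
    max_samples : int
        The mixture is fitted on at most this many samples (deterministically
        strided subsample) — ample for locating means on multi-million-sample
        recordings.
    min_dip : float
        Resolvability criterion: between each pair of adjacent component
        means the fitted mixture density must dip below both endpoint values
        by at least this relative depth; otherwise the components describe a
        single mode and an error is raised.

    Raises
    ------
    ValueError
        If the requested number of modes cannot be resolved in the histogram.
    """
    z = trajectory.extension
    if z.size > max_samples:
        z = z[:: int(np.ceil(z.size / max_samples))]
    x = z.reshape(-1, 1)

    def fit(k: int) -> GaussianMixture:
        return GaussianMixture(
            n_components=k,
            covariance_type="full",
            n_init=3,
            max_iter=1000,
            tol=1e-6,
            random_state=seed,
        ).fit(x)

    if k_levels is None:
        fits = [fit(k) for k in range(1, max_components + 1)]
        bics = [g.bic(x) for g in fits]
        gm = fits[int(np.argmin(bics))]
        k_levels = gm.n_components
    else:
        gm = fit(k_levels)

    order = np.argsort(gm.means_[:, 0])
    means = gm.means_[order, 0]
    sds = np.sqrt(gm.covariances_[order, 0, 0])
    weights = gm.weights_[order]

    def mixture_pdf(grid: np.ndarray) -> np.ndarray:
        out = np.zeros_like(grid)
        for w, mu, sd in zip(weights, means, sds):
            out += w * np.exp(-0.5 * ((grid - mu) / sd) ** 2) / (sd * np.sqrt(2 * np.pi))
        return out

    for i in range(means.size - 1):
        grid = np.linspace(means[i], means[i + 1], 101)
        pdf = mixture_pdf(grid)
        endpoint = min(pdf[0], pdf[-1])
        if pdf[1:-1].min() >= endpoint * (1.0 - min_dip):
            raise ValueError(
                f"extension histogram resolves fewer than {k_levels} modes: no density "
                f"dip between components at {means[i]:.2f} and {means[i + 1]:.2f} nm"
            )
    return Thresholds(levels=means, labels=labels or _default_labels(k_levels), sds=sds)


@dataclass
class Idealization:
    """Dwell segments and excised transition paths of one recording.

    ``segments`` has one row per dwell with half-open sample interval
    [start, end), label, fragment index j, start/end times and a censored flag
    (first and last dwells are censored by the recording edges).
    ``tp_intervals`` is an (m, 2) array of excised half-open sample intervals.
    """

    segments: pd.DataFrame
    tp_intervals: np.ndarray
    n_samples: int
    sampling_rate: float
    thresholds: Thresholds | None = None
    meta: dict = field(default_factory=dict)

    @property
    def n_dwells(self) -> int:
        return len(self.segments)

    def dwell_sample_count(self) -> int:
        return int((self.segments["end"] - self.segments["start"]).sum())

    def tp_sample_count(self) -> int:
        if self.tp_intervals.size == 0:
            return 0
        return int((self.tp_intervals[:, 1] - self.tp_intervals[:, 0]).sum())

    def occupancy(self) -> pd.Series:
        """Fraction of dwell samples per label (censored dwells included)."""
        counts = (
            self.segments.assign(length=self.segments["end"] - self.segments["start"])
            .groupby("label")["length"]
            .sum()
        )
        return counts / counts.sum()

    def sample_labels(self) -> np.ndarray:
        """Per-sample label array ('TP' on excised transition paths)."""
        out = np.full(self.n_samples, "TP", dtype=object)
        for row in self.segments.itertuples(index=False):
            out[row.start : row.end] = row.label
        return out

    def transition_events(self) -> pd.DataFrame:
        """Directed transitions between consecutive differently-labelled dwells.

        Columns: time_s (entry into the new dwell), from_label, to_label,
        preceding_dwell_s (time between the previous transition and this one),
        censored (True when the preceding dwell touches the recording start).
        """
        rows = []
        seg = self.segments
        prev_entry = None
        prev_label = None
        for row in seg.itertuples(index=False):
            if prev_label is None:
                prev_label, prev_entry = row.label, row.t_start
                first_censored = True
                continue
            if row.label == prev_label:
                continue  # debounced blip between same-label dwells
            rows.append(
                {
                    "time_s": row.t_start,
                    "from_label": prev_label,
                    "to_label": row.label,
                    "preceding_dwell_s": row.t_start - prev_entry,
                    "censored": first_censored,
                }
            )
            first_censored = False
            prev_label, prev_entry = row.label, row.t_start
        return pd.DataFrame(
            rows, columns=["time_s", "from_label", "to_label", "preceding_dwell_s", "censored"]
        )


def label_and_excise(
    trajectory: Trajectory,
    thresholds: Thresholds,
    debounce: int = 3,
    threshold_mode: str = "means",
) -> Idealization:
    """Label every sample as a dwell in one conformation or a transition path.

    The detector is a hysteresis state machine over the level thresholds: while
    dwelling at level a, a transition to level b is recorded at the first
    sample that reaches b's threshold; the samples after the last home-side
    crossing of a's threshold and before that arrival are excised as the
    transition path. Dwells shorter than ``debounce`` samples are reclassified
    as excised (instrument-resolution chatter).

    ``threshold_mode`` "means" places thresholds at the level means (the
    literal reading of the procedure); "midpoints" places the arrival
    thresholds halfway between adjacent level means.
    """
    z = trajectory.extension
    n = z.size
    mu = thresholds.levels
    k = thresholds.k
    if threshold_mode == "means":
        arrive = mu.copy()
        home = mu.copy()
    elif threshold_mode == "midpoints":
        # arrival threshold of level m seen from below/above is the midpoint
        # with its neighbour in the direction of travel; home stays the mean
        arrive = mu.copy()
        home = mu.copy()
        mid = (mu[:-1] + mu[1:]) / 2.0
        arrive_up = np.concatenate([[mu[0]], mid])  # threshold to reach level m from below
        arrive_dn = np.concatenate([mid, [mu[-1]]])  # ... from above
    else:
        raise ValueError("threshold_mode must be 'means' or 'midpoints'")

    if k == 1:
        segments = pd.DataFrame(
            [
                {
                    "label": thresholds.labels[0],
                    "start": 0,
                    "end": n,
                    "j": 0,
                    "t_start": trajectory.time[0],
                    "t_end": trajectory.time[0] + n / trajectory.sampling_rate,
                    "censored": True,
                }
            ]
        )
        return Idealization(
            segments, np.empty((0, 2), dtype=int), n, trajectory.sampling_rate, thresholds
        )

    def thr_arrive(m: int, going_up: bool) -> float:
        if threshold_mode == "midpoints":
            return arrive_up[m] if going_up else arrive_dn[m]
        return arrive[m]

    # Precomputed crossing indices per level; transitions are sparse, so the
    # state machine walks these via searchsorted instead of every sample.
    idx_ge = [np.flatnonzero(z >= thr_arrive(m, True)) for m in range(k)]
    idx_le = [np.flatnonzero(z <= thr_arrive(m, False)) for m in range(k)]
    if threshold_mode == "means":
        home_ge, home_le = idx_ge, idx_le
    else:
        home_ge = [np.flatnonzero(z >= home[m]) for m in range(k)]
        home_le = [np.flatnonzero(z <= home[m]) for m in range(k)]

    head = z[: min(50, n)]
    cur = int(np.argmin(np.abs(mu - np.median(head))))
    pos = 0
    dwells: list[tuple[int, int, int]] = []  # (level, start, end)
    tps: list[tuple[int, int]] = []

    while True:
        best_e = n
        best_m = -1
        for m in range(k):
            if m == cur:
                continue
            arr = idx_ge[m] if m > cur else idx_le[m]
            j = np.searchsorted(arr, pos, side="left")
            if j < arr.size:
                e = int(arr[j])
                if e < best_e or (
                    e == best_e and abs(mu[m] - mu[cur]) > abs(mu[best_m] - mu[cur])
                ):
                    best_e, best_m = e, m
        if best_m < 0 or best_e >= n:
            dwells.append((cur, pos, n))
            break
        going_up = best_m > cur
        home_arr = home_le[cur] if going_up else home_ge[cur]
        j = np.searchsorted(home_arr, best_e, side="left") - 1
        if j >= 0 and home_arr[j] >= pos:
            dwell_end = int(home_arr[j]) + 1
        else:
            dwell_end = pos  # never settled at home: the whole stretch is a TP
        dwells.append((cur, pos, dwell_end))
        if best_e > dwell_end:
            tps.append((dwell_end, best_e))
        pos = best_e
        cur = best_m

    if len(dwells) == 1:
        warnings.warn("trajectory never crosses a threshold: single-dwell idealization")

    # debounce: dwells shorter than the instrument resolution are excised
    kept: list[tuple[int, int, int]] = []
    for lev, start, end in dwells:
        if end - start < max(debounce, 1) and len(dwells) > 1:
            if end > start:
                tps.append((start, end))
            continue
        kept.append((lev, start, end))
    if not kept:  # everything debounced away: fall back to the raw segmentation
        kept = dwells
        tps = [t for t in tps if t[1] - t[0] > 0]

    t0 = float(trajectory.time[0])
    rate = trajectory.sampling_rate
    seg_rows = []
    for jfrag, (lev, start, end) in enumerate(kept):
        seg_rows.append(
            {
                "label": thresholds.labels[lev],
                "start": start,
                "end": end,
                "j": jfrag,
                "t_start": t0 + start / rate,
                "t_end": t0 + end / rate,
                "censored": jfrag == 0 or jfrag == len(kept) - 1,
            }
        )
    tp_arr = (
        np.array(sorted(tps), dtype=int) if tps else np.empty((0, 2), dtype=int)
    )
    return Idealization(
        segments=pd.DataFrame(seg_rows),
        tp_intervals=tp_arr,
        n_samples=n,
        sampling_rate=rate,
        thresholds=thresholds,
        meta={"debounce": debounce, "threshold_mode": threshold_mode},
    )


def dwell_statistics(idealization: Idealization) -> pd.DataFrame:
    """Mean dwell time preceding each directed transition type.

    The first and last dwells of a recording are censored by the observation
    window and excluded from the means. Returns one row per directed pair with
    mean_time_s, sem_s and n_events.
    """
    events = idealization.transition_events()
    if events.empty:
        return pd.DataFrame(columns=["from_label", "to_label", "mean_time_s", "sem_s", "n_events"])
    valid = events[~events["censored"]]
    rows = []
    for (a, b), grp in valid.groupby(["from_label", "to_label"], sort=False):
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
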