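"""Per-fragment fluctuation statistics and unstructured-contour-length summary.

Each dwell fragment j of conformation c contributes a relative extension
Δz_{c,j} = ⟨z_j⟩ − z_ref and relative fluctuations
Δσ²_{c,j} = var(z_j) − ⟨σ²_ref⟩, both taken against the natively folded
reference conformation. The mean excess variance per conformation is converted
to an unstructured contour-length increment through the FJC inversion
ΔL_c = ⟨Δσ²⟩ / v(F), and normalised by the increment of the fully unfolded
conformation to give a fraction of unstructured sequence. Transition-path
samples never enter these statistics.

A rule-based classifier assigns a contiguous recording stretch to one of the
six catalogued state regions (i–vi) from its level structure and occupancy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.mixture import GaussianMixture

from . import reference
from .idealize import Idealization
from .io import Trajectory
from .polymer import FJCParams, contour_length_from_variance, unstructured_fraction

__all__ = [
    "fragment_statistics",
    "summarize_state",
    "classify_region",
    "classify_stretch",
    "region_templates",
    "RegionCatalog",
]

#: fragments shorter than this many samples carry too noisy a variance estimate
MIN_FRAGMENT_SAMPLES = 8


def fragment_statistics(
    idealization: Idealization,
    trajectory: Trajectory,
    reference_label: str = "N",
    min_samples: int = MIN_FRAGMENT_SAMPLES,
) -> pd.DataFrame:
    """Relative extension and variance of every dwell fragment.

    The reference level z_ref and reference variance ⟨σ²_ref⟩ are the
    duration-weighted means over all fragments of ``reference_label``.
    Fragments shorter than ``min_samples`` are excluded (their count is
    reported in the ``n_excluded`` DataFrame attribute).

    Returns a DataFrame with one row per retained fragment: j, label,
    duration_s, mean_nm, var_nm2, delta_z_nm, delta_var_nm2.
    """
    seg = idealization.segments
    if reference_label not in set(seg["label"]):
        raise ValueError(f"reference conformation {reference_label!r} has no dwell")
    z = trajectory.extension
    rows = []
    n_excluded = 0
    for row in seg.itertuples(index=False):
        length = row.end - row.start
        if length < min_samples:
            n_excluded += 1
            continue
        frag = z[row.start : row.end]
        rows.append(
            {
                "j": row.j,
                "label": row.label,
                "duration_s": length / idealization.sampling_rate,
                "n_samples": length,
                "mean_nm": frag.mean(),
                "var_nm2": frag.var(ddof=1),
            }
        )
    frags = pd.DataFrame(rows)
    ref = frags[frags["label"] == reference_label] if not frags.empty else frags
    if ref.empty:
        raise ValueError(
            f"no fragment of reference conformation {reference_label!r} survives the "
            f"{min_samples}-sample cut"
        )
    w = ref["n_samples"].to_numpy(float)
    z_ref = float(np.average(ref["mean_nm"], weights=w))
    var_ref = float(np.average(ref["var_nm2"], weights=w))
    frags["delta_z_nm"] = frags["mean_nm"] - z_ref
    frags["delta_var_nm2"] = frags["var_nm2"] - var_ref
    frags.attrs["reference_label"] = reference_label
    frags.attrs["z_ref_nm"] = z_ref
    frags.attrs["var_ref_nm2"] = var_ref
    frags.attrs["n_excluded"] = n_excluded
    return frags


def summarize_state(
    fragments: pd.DataFrame,
    force: float,
    fjc_params: FJCParams = FJCParams(),
    reference_Lc: float = reference.REFERENCE_LC_NM,
    weighted: bool = True,
    min_fragments: int = 3,
) -> pd.DataFrame:
    """Per-conformation summary: Δz, Δσ², ΔL_c and unstructured fraction.

    The mean excess variance of each conformation is converted to a contour
    length (mean-then-convert); spreads are standard deviations over fragments,
    propagated linearly through the FJC inversion. ``weighted`` selects
    duration-weighted fragment means (matching sample-level statistics).
    Conformations with fewer than ``min_fragments`` fragments are flagged
    ``low_n``.
    """
    ref_label = fragments.attrs.get("reference_label")
    rows = []
    for label, grp in fragments.groupby("label", sort=False):
        w = grp["n_samples"].to_numpy(float) if weighted else np.ones(len(grp))
        dz = float(np.average(grp["delta_z_nm"], weights=w))
        dvar = float(np.average(grp["delta_var_nm2"], weights=w))
        dz_sd = float(grp["delta_z_nm"].std(ddof=1)) if len(grp) > 1 else np.nan
        dvar_sd = float(grp["delta_var_nm2"].std(ddof=1)) if len(grp) > 1 else np.nan
        if label == ref_label:
            dz, dvar = 0.0, 0.0
        dvar_pos = max(dvar, 0.0)
        dlc = contour_length_from_variance(dvar_pos, force, fjc_params)
        # linear error propagation through the (linear) inversion
        dlc_sd = (
            contour_length_from_variance(dvar_sd, force, fjc_params)
            if np.isfinite(dvar_sd)
            else np.nan
        )
        frac = unstructured_fraction(dlc, reference_Lc)
        frac_sd = unstructured_fraction(dlc_sd, reference_Lc) if np.isfinite(dlc_sd) else np.nan
        rows.append(
            {
                "label": label,
                "n_fragments": len(grp),
                "delta_z_nm": dz,
                "delta_z_sd_nm": dz_sd,
                "delta_var_nm2": dvar,
                "delta_var_sd_nm2": dvar_sd,
                "delta_Lc_nm": dlc,
                "delta_Lc_sd_nm": dlc_sd,
                "unstructured_pct": frac,
                "unstructured_pct_sd": frac_sd,
                "low_n": len(grp) < min_fragments,
            }
        )
        if len(grp) < min_fragments:
            warnings.warn(f"conformation {label!r} has only {len(grp)} fragments")
    out = pd.DataFrame(rows).sort_values("delta_z_nm", ignore_index=True)
    out.attrs["force_pN"] = force
    out.attrs["reference_Lc_nm"] = reference_Lc
    return out


@dataclass(frozen=True)
class RegionCatalog:
    """Signatures of the six catalogued state regions.

    Offsets are relative to the folded level; a stretch matches a region when
    its level count agrees and every level offset falls within ``tol_nm`` of
    the catalogued value. Regions i and ii share the two-state F/U levels and
    are separated by folded-state occupancy (region ii, the trans-proline
    isomer, dwells mostly unfolded).
    """

    tol_nm: float = 1.5
    folded_occupancy_cut: float = 0.25
    unfolded_offset: float = 18.2
    intermediate_offset: float = 5.4  # region iii, conformation I
    halfway_offset: float = 15.6  # region iv, conformation H
    three_level_offsets: tuple[float, float, float] = (3.3, 7.6, 14.9)  # region v
    two_mid_offsets: tuple[float, float] = (7.45, 14.3)  # region vi


def classify_region(
    level_offsets: np.ndarray,
    occupancy: np.ndarray | None = None,
    catalog: RegionCatalog = RegionCatalog(),
) -> str:
    """Assign a state region (i–vi) from level offsets relative to the folded level.

    ``level_offsets`` are sorted mean extensions minus the folded reference;
    ``occupancy`` (same order) is required only to split regions i and ii.
    Returns ``"unknown"`` when no catalogued signature matches.
    """
    off = np.sort(np.asarray(level_offsets, dtype=float))
    tol = catalog.tol_nm

    def close(a: float, b: float) -> bool:
        return abs(a - b) <= tol

    if off.size == 1:
        if close(off[0], catalog.intermediate_offset):
            return "iii"
        if close(off[0], catalog.halfway_offset):
            return "iv"
        return "unknown"
    if off.size == 2:
        if close(off[0], 0.0) and close(off[1], catalog.unfolded_offset):
            if occupancy is None:
                return "i"
            folded = float(np.asarray(occupancy)[int(np.argmin(off))])
            return "i" if folded >= catalog.folded_occupancy_cut else "ii"
        if close(off[0], catalog.two_mid_offsets[0]) and close(off[1], catalog.two_mid_offsets[1]):
            return "vi"
        return "unknown"
    if off.size == 3:
        if all(close(o, c) for o, c in zip(off, catalog.three_level_offsets)):
            return "v"
        return "unknown"
    return "unknown"


def region_templates() -> dict[str, list[tuple[float, float]]]:
    """Catalogued (Δz, Δσ²) components per region; regions i and ii share the
    two-state template and are split by folded-state occupancy."""
    by_region: dict[str, list[tuple[float, float]]] = {}
    for state, _label, dz, dvar, _lc in reference.CONFORMATION_TABLE:
        by_region.setdefault(state, []).append((dz, dvar))
    return by_region


def _template_loglik(
    z: np.ndarray, comps: list[tuple[float, float]], baseline_sd: float, iters: int = 60
) -> tuple[float, np.ndarray]:
    """Log-likelihood of a fixed-mean/fixed-variance Gaussian mixture with
    weights fitted by EM; returns (loglik, weights)."""
    mu = np.array([c[0] for c in comps])
    var = baseline_sd**2 + np.array([c[1] for c in comps])
    k = len(comps)
    w = np.full(k, 1.0 / k)
    log_norm = -0.5 * ((z[:, None] - mu[None, :]) ** 2 / var[None, :] + np.log(2 * np.pi * var[None, :]))
    for _ in range(iters):
        a = log_norm + np.log(np.clip(w, 1e-300, None))[None, :]
        m = a.max(axis=1, keepdims=True)
        resp = np.exp(a - m)
        resp /= resp.sum(axis=1, keepdims=True)
        w = resp.mean(axis=0)
    a = log_norm + np.log(np.clip(w, 1e-300, None))[None, :]
    m = a.max(axis=1)
    loglik = float((m + np.log(np.exp(a - m[:, None]).sum(axis=1))).sum())
    return loglik, w


def classify_stretch(
    trajectory: Trajectory,
    folded_level_nm: float,
    catalog: RegionCatalog = RegionCatalog(),
    baseline_sd: float = reference.PSF_SD_NM,
    max_samples: int = 8_000,
    margin_per_sample: float = 0.02,
    seed: int = 0,
) -> str:
    """Classify a contiguous recording stretch against the region catalog.

    Each region is scored by the BIC of a matched-template mixture: component
    means and variances fixed at the catalogued (Δz, Δσ²) values (shifted by
    ``folded_level_nm`` and broadened by the baseline noise), only the weights
    fitted by EM. The template approach remains sensitive to levels holding a
    few percent occupancy (e.g. the briefly visited top level of region v),
    where a free mixture fit drifts. A free BIC-selected Gaussian mixture is
    the alternative hypothesis: when it beats the best template by more than
    ``margin_per_sample`` per sample (in −2·loglik units), the stretch is
    declared ``"unknown"``. Regions i and ii share the two-state template and
    are separated by the fitted folded-state weight.
    """
    z = trajectory.extension - folded_level_nm
    if z.size > max_samples:
        z = z[:: z.size // max_samples + 1]
    n = z.size
    best_region, best_bic, best_w = "unknown", np.inf, None
    for region, comps in region_templates().items():
        if region == "ii":
            continue  # shares region i's template
        loglik, w = _template_loglik(z, comps, baseline_sd)
        bic = -2.0 * loglik + (len(comps) - 1) * np.log(n)
        if bic < best_bic:
            best_region, best_bic, best_w = region, bic, w
    x = z.reshape(-1, 1)
    free_bic = min(
        GaussianMixture(n_components=k, n_init=2, random_state=seed).fit(x).bic(x)
        for k in range(1, 5)
    )
    if free_bic < best_bic - margin_per_sample * n:
        return "unknown"
    if best_region == "i":
        comps = region_templates()["i"]
        folded_idx = int(np.argmin([abs(c[0]) for c in comps]))
        if best_w[folded_idx] < catalog.folded_occupancy_cut:
            return "ii"
    return best_region
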