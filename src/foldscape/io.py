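"""Trajectory container, tabular/HDF5 readers and writers, display smoothing.

The canonical interchange format is tab-separated text with a header line and
columns ``time_s``, ``extension_nm``, ``force_pN``. An HDF5 container with the
same datasets (plus metadata attributes) is supported for long recordings.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

__all__ = [
    "Trajectory",
    "read_trajectory",
    "write_trajectory",
    "smooth_for_display",
    "write_segments",
    "read_segments",
]

_REQUIRED_COLUMNS = ("time_s", "extension_nm", "force_pN")

#: relative tolerance on time-grid uniformity
_GRID_RTOL = 1e-6


@dataclass
class Trajectory:
    """A uniformly sampled extension–time recording.

    Attributes
    ----------
    time : ndarray
        Sample times in s, uniform grid.
    extension : ndarray
        End-to-end extension in nm.
    force : ndarray or float
        Applied force in pN, per-sample or constant.
    sampling_rate : float
        Samples per second (Hz).
    molecule_id : str
        Identifier of the tether/molecule.
    meta : dict
        Free-form provenance (seed, generator specs, ...).
    """

    time: np.ndarray
    extension: np.ndarray
    force: np.ndarray | float
    sampling_rate: float
    molecule_id: str = "mol0"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.extension = np.asarray(self.extension, dtype=float)
        if self.time.shape != self.extension.shape or self.time.ndim != 1:
            raise ValueError("time and extension must be 1-d arrays of equal length")
        if self.time.size < 2:
            raise ValueError("a trajectory needs at least 2 samples")
        if not (np.all(np.isfinite(self.time)) and np.all(np.isfinite(self.extension))):
            raise ValueError("trajectory contains non-finite values")
        if np.ndim(self.force) > 0:
            self.force = np.asarray(self.force, dtype=float)
            if self.force.shape != self.time.shape:
                raise ValueError("per-sample force must match the time grid")
        _check_uniform(self.time)

    def __len__(self) -> int:
        return self.time.size

    @property
    def duration(self) -> float:
        return float(self.time[-1] - self.time[0])

    def force_at(self, index: int) -> float:
        """Force at a sample index (constant or per-sample)."""
        if np.ndim(self.force) > 0:
            return float(self.force[index])
        return float(self.force)

    def to_frame(self) -> pd.DataFrame:
        force = self.force if np.ndim(self.force) > 0 else np.full(len(self), self.force)
        return pd.DataFrame(
            {"time_s": self.time, "extension_nm": self.extension, "force_pN": force}
        )


def _check_uniform(time: np.ndarray) -> None:
    dt = np.diff(time)
    dt0 = (time[-1] - time[0]) / (time.size - 1)
    if dt0 <= 0 or np.any(np.abs(dt - dt0) > _GRID_RTOL * abs(dt0) + 1e-12):
        raise ValueError("time grid is not uniform (tolerance 1 ppm)")


def read_trajectory(path, fmt: str | None = None, molecule_id: str | None = None) -> Trajectory:
    """Read a trajectory from tab-separated text or an HDF5 container.

    The format is inferred from the file suffix (``.h5``/``.hdf5`` → HDF5,
    anything else → delimited text) unless ``fmt`` is ``"table"`` or ``"hdf5"``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt is None:
        fmt = "hdf5" if path.suffix.lower() in (".h5", ".hdf5") else "table"
    if fmt == "hdf5":
        return _read_hdf5(path, molecule_id)
    df = pd.read_csv(path, sep=None, engine="python")
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    if df[list(_REQUIRED_COLUMNS)].isna().any().any():
        raise ValueError(f"{path}: NaN values in trajectory columns")
    time = df["time_s"].to_numpy(float)
    force = df["force_pN"].to_numpy(float)
    if np.allclose(force, force[0]):
        force = float(force[0])
    dt = (time[-1] - time[0]) / (time.size - 1)
    return Trajectory(
        time=time,
        extension=df["extension_nm"].to_numpy(float),
        force=force,
        sampling_rate=1.0 / dt,
        molecule_id=molecule_id or path.stem,
    )


def write_trajectory(trajectory: Trajectory, path, fmt: str | None = None) -> Path:
    """Write a trajectory as tab-separated text or HDF5."""
    path = Path(path)
    if fmt is None:
        fmt = "hdf5" if path.suffix.lower() in (".h5", ".hdf5") else "table"
    if fmt == "hdf5":
        _write_hdf5(trajectory, path)
    else:
        trajectory.to_frame().to_csv(path, sep="\t", index=False)
    return path


def _write_hdf5(trajectory: Trajectory, path: Path) -> None:
    import h5py

    with h5py.File(path, "w") as h5:
        h5.create_dataset("time_s", data=trajectory.time)
        h5.create_dataset("extension_nm", data=trajectory.extension)
        h5.create_dataset("force_pN", data=np.atleast_1d(trajectory.force))
        h5.attrs["sampling_rate"] = trajectory.sampling_rate
        h5.attrs["molecule_id"] = trajectory.molecule_id
        for key, value in trajectory.meta.items():
            if isinstance(value, (str, int, float)):
                h5.attrs[f"meta_{key}"] = value


def _read_hdf5(path: Path, molecule_id: str | None) -> Trajectory:
    import h5py

    with h5py.File(path, "r") as h5:
        time = h5["time_s"][:]
        ext = h5["extension_nm"][:]
        force = h5["force_pN"][:]
        rate = float(h5.attrs["sampling_rate"])
        mol = molecule_id or str(h5.attrs.get("molecule_id", path.stem))
        meta = {
            key[5:]: h5.attrs[key] for key in h5.attrs if key.startswith("meta_")
        }
    if force.size == 1:
        force = float(force[0])
    return Trajectory(time, ext, force, rate, mol, meta)


def smooth_for_display(trajectory: Trajectory, window: int = 101, order: int = 2) -> np.ndarray:
    """Savitzky–Golay smoothed copy of the extension signal, for plotting only.

    All analysis stages consume the raw recording; smoothing exists purely for
    display. ``window`` must be odd and at least ``order + 2``.
    """
    if window % 2 == 0:
        raise ValueError("Savitzky-Golay window must be odd")
    if window < order + 2:
        raise ValueError("window must be at least order + 2")
    return savgol_filter(trajectory.extension, window, order)


def write_segments(segments: pd.DataFrame, path) -> Path:
    """Write dwell segments (label, t_start_s, t_end_s, ...) as TSV."""
    path = Path(path)
    segments.to_csv(path, sep="\t", index=False)
    return path


def read_segments(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
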