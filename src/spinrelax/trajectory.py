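"""Distance-trajectory container and I/O.

The central object of the package is the time series of metal--proton
distances measured along an MD trajectory: at every frame, the distance
from the paramagnetic metal centre (here vanadium) to the nearest water
proton.  All downstream analysis (wavelet selection, autocorrelation,
relaxation rates) consumes this one series.

Coordinates and distances are in angstrom, times in picoseconds; SI
conversion happens only inside the dipolar-constant computation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DistanceTrajectory",
    "read_distance_series",
    "write_distance_series",
    "extract_min_vh_distances",
    "restrict_to_selection",
]

MIN_FRAMES = 8
_STRIDE_RTOL = 1e-6

DEFAULT_METAL_SELECTION = "name V*"
DEFAULT_PROTON_SELECTION = "name H* and resname WAT HOH SOL"


@dataclass(frozen=True)
class DistanceTrajectory:
    """Uniformly sampled metal--proton distance time series.

    Attributes
    ----------
    times : ndarray
        Frame times in ps, strictly increasing with a constant stride.
    distances : ndarray
        Metal--proton distances in angstrom, all strictly positive.
    frame_ids : ndarray
        Integer ids of the frames in the originating trajectory.
    """

    times: np.ndarray
    distances: np.ndarray
    frame_ids: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        distances = np.asarray(self.distances, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "distances", distances)
        if self.frame_ids is None:
            object.__setattr__(self, "frame_ids", np.arange(times.size))
        else:
            object.__setattr__(
                self, "frame_ids", np.asarray(self.frame_ids, dtype=int)
            )
        if not (times.size == distances.size == self.frame_ids.size):
            raise ValueError(
                "times, distances and frame_ids must have equal length"
            )
        if times.size < MIN_FRAMES:
            raise ValueError(
                f"need at least {MIN_FRAMES} frames, got {times.size}"
            )
        steps = np.diff(times)
        if np.any(steps <= 0):
            row = int(np.argmax(steps <= 0)) + 1
            raise ValueError(f"times must be strictly increasing (row {row + 1})")
        stride = steps[0]
        bad = np.abs(steps - stride) > _STRIDE_RTOL * abs(stride)
        if np.any(bad):
            row = int(np.argmax(bad)) + 2  # 1-based row of the offending time
            raise ValueError(
                f"non-uniform time stride at row {row}: "
                f"expected {stride:g} ps, got {steps[row - 2]:g} ps"
            )
        if np.any(distances <= 0):
            row = int(np.argmax(distances <= 0)) + 1
            raise ValueError(f"non-positive distance at row {row}")

    @property
    def n_frames(self) -> int:
        return self.times.size

    @property
    def dt(self) -> float:
        """Time stride in ps."""
        return float(self.times[1] - self.times[0])

    @property
    def total_time(self) -> float:
        """Span from first to last frame in ps."""
        return float(self.times[-1] - self.times[0])

    @property
    def phi(self) -> float:
        """Mean metal--proton distance in angstrom."""
        return float(np.mean(self.distances))


def read_distance_series(path, fmt: str | None = None) -> DistanceTrajectory:
    """Read a two-column time/distance series (CSV or TSV, with header).

    The first column is time in ps, the second distance in angstrom.
    The format is inferred from the extension unless ``fmt`` is given.
    """
    if fmt is None:
        fmt = "tsv" if str(path).endswith((".tsv", ".txt")) else "csv"
    if fmt not in ("csv", "tsv"):
        raise ValueError(f"unsupported format {fmt!r}; use 'csv' or 'tsv'")
    sep = "," if fmt == "csv" else "\t"
    df = pd.read_csv(path, sep=sep)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two numeric columns with header")
    times = pd.to_numeric(df.iloc[:, 0], errors="raise").to_numpy(float)
    dists = pd.to_numeric(df.iloc[:, 1], errors="raise").to_numpy(float)
    return DistanceTrajectory(times=times, distances=dists)


def write_distance_series(traj: DistanceTrajectory, path) -> None:
    """Write ``time_ps,distance_angstrom`` CSV (header included)."""
    df = pd.DataFrame(
        {"time_ps": traj.times, "distance_angstrom": traj.distances}
    )
    df.to_csv(path, index=False, float_format="%.6f")


def _load_universe(frames):
    import MDAnalysis as mda

    if isinstance(frames, mda.Universe):
        return frames
    return mda.Universe(str(frames))


def extract_min_vh_distances(
    frames,
    metal_selection: str = DEFAULT_METAL_SELECTION,
    proton_selection: str = DEFAULT_PROTON_SELECTION,
    dt_ps: float = 100.0,
) -> DistanceTrajectory:
    """Per-frame minimum metal--proton distance from a coordinate trajectory.

    ``frames`` is an MDAnalysis Universe or a path to a multi-model PDB /
    multi-frame XYZ file.  For each frame the Euclidean distance from the
    (single) metal site to the nearest selected proton is recorded; the
    identity of the closest proton may change from frame to frame.

    Frame times are assigned on a uniform ``dt_ps`` stride because neither
    format carries reliable time stamps.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # element-guessing chatter
        u = _load_universe(frames)
    metals = u.select_atoms(metal_selection)
    protons = u.select_atoms(proton_selection)
    if metals.n_atoms == 0:
        raise ValueError(f"no metal site matches selection {metal_selection!r}")
    if metals.n_atoms > 1:
        raise ValueError(
            f"expected exactly one metal site, found {metals.n_atoms}"
        )
    dists = np.empty(len(u.trajectory))
    for i, _ts in enumerate(u.trajectory):
        if protons.n_atoms == 0:
            raise ValueError(f"frame {i}: no protons match selection")
        delta = protons.positions - metals.positions[0]
        dists[i] = float(np.sqrt((delta**2).sum(axis=1)).min())
    times = dt_ps * np.arange(dists.size)
    return DistanceTrajectory(times=times, distances=dists)


def restrict_to_selection(
    traj: DistanceTrajectory, indices
) -> DistanceTrajectory:
    """Sub-trajectory at selected frames, re-gridded to a uniform stride.

    Wavelet-selected frames are non-uniformly spaced, but lag-based
    autocorrelation arithmetic needs uniform sampling.  The selection is
    therefore re-expressed on the endpoint-preserving effective stride
    ``dt_eff = (t_last - t_first) / (m - 1)``.  The true (non-uniform)
    times remain available to the lag-binned ACF path, which receives the
    original trajectory and the index list instead.
    """
    idx = np.asarray(indices, dtype=int)
    if idx.size == 0:
        raise ValueError("empty selection")
    if idx.size == 1:
        raise ValueError("selection of a single frame carries no dynamics")
    if np.any(np.diff(idx) <= 0):
        raise ValueError("indices must be sorted and unique")
    if idx[0] < 0 or idx[-1] >= traj.n_frames:
        raise ValueError("selection index out of range")
    t0, t1 = traj.times[idx[0]], traj.times[idx[-1]]
    dt_eff = (t1 - t0) / (idx.size - 1)
    times = t0 + dt_eff * np.arange(idx.size)
    return DistanceTrajectory(
        times=times,
        distances=traj.distances[idx],
        frame_ids=traj.frame_ids[idx],
    )
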