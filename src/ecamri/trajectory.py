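"""Time-tagged Cartesian k-space orderings and their temporal partitions.

The central object is a :class:`KTrajectory`: an ordered list of k-grid
indices with one acquisition timestamp per sample.  The UnWRAP ordering
(Undersampling With Repeated Advancing Phase) splits the phase-encode plane
into ``f`` contiguous sections, splits each section into ``f`` sheaves, and
acquires one sheaf from every section before any section gets its next
sheaf.  Partitioning the timestamps into short equal intervals then gives
each reconstruction time point a near-uniform spread of spatial frequencies.

k-grid indices are stored on the centered grid (DC component at
``n // 2`` along each axis, i.e. ``fftshift`` convention).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "KTrajectory",
    "Partition",
    "AccelSpec",
    "unwrap_trajectory",
    "raster_trajectory",
    "partition_trajectory",
    "acceleration_factor",
    "spectral_uniformity",
]


@dataclass
class KTrajectory:
    """Ordered k-space samples with acquisition timestamps.

    Attributes
    ----------
    indices : (N, 3) int array
        Centered k-grid index triples in acquisition order.
    times : (N,) float array
        Strictly increasing acquisition timestamps (s).
    grid_shape : tuple of int
        Shape of the k-space grid (equals the image grid).
    sweep_time : float
        Duration of one Nyquist-complete pass (s).
    """

    indices: np.ndarray
    times: np.ndarray
    grid_shape: tuple[int, int, int]
    sweep_time: float

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=np.int32)
        self.times = np.asarray(self.times, dtype=np.float64)
        if self.indices.shape != (self.times.size, 3):
            raise ValueError("indices must be (N, 3) matching timestamps")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("timestamps must be strictly increasing")

    @property
    def n_samples(self) -> int:
        return self.times.size

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.grid_shape))

    @property
    def n_sweeps(self) -> int:
        return self.n_samples // self.n_voxels

    @property
    def duration(self) -> float:
        """Total scan duration (s)."""
        return self.n_sweeps * self.sweep_time if self.n_sweeps else float(self.times[-1])

    def flat_indices(self) -> np.ndarray:
        """Row-major linearization of the centered index triples."""
        return np.ravel_multi_index(self.indices.T, self.grid_shape)


@dataclass
class Partition:
    """Assignment of trajectory samples to half-open time intervals.

    Interval ``i`` covers ``[i*dt, (i+1)*dt)``; a timestamp exactly on a
    boundary belongs to the later interval.
    """

    dt: float
    n_intervals: int
    interval_of_sample: np.ndarray

    @property
    def midpoints(self) -> np.ndarray:
        return (np.arange(self.n_intervals) + 0.5) * self.dt

    def counts(self) -> np.ndarray:
        """Number of samples in each interval."""
        return np.bincount(self.interval_of_sample, minlength=self.n_intervals)

    def samples_in(self, i: int) -> np.ndarray:
        """Positions (into the trajectory) of samples in interval ``i``."""
        return np.flatnonzero(self.interval_of_sample == i)


@dataclass
class AccelSpec:
    """Bookkeeping for the acceleration factor alpha = V*T/N."""

    V: int
    T: int
    N: int

    def __post_init__(self) -> None:
        if self.N <= 0:
            raise ValueError("N must be positive")


def acceleration_factor(spec: AccelSpec) -> float:
    """Acceleration factor alpha = V*T/N: reconstructed voxel-time points per
    acquired k-space sample."""
    return spec.V * spec.T / spec.N


def _split_contiguous(n: int, parts: int) -> list[np.ndarray]:
    """Split range(n) into ``parts`` contiguous blocks of size n // parts,
    with the last block absorbing any remainder."""
    size = n // parts
    bounds = [i * size for i in range(parts)] + [n]
    return [np.arange(bounds[i], bounds[i + 1]) for i in range(parts)]


def unwrap_trajectory(grid_shape, sweep_time: float, f: int, n_sweeps: int = 1,
                      readout_axis: int = 0) -> KTrajectory:
    """UnWRAP k-space ordering with ``f`` sections of ``f`` sheaves.

    Full readout lines are atomic: the phase-encode plane (the two non-readout
    axes, linearized row-major) is split into ``f`` contiguous sections, each
    split into ``f`` contiguous sheaves; acquisition interleaves one sheaf per
    section before any section's next sheaf.  Samples are spaced uniformly in
    time across each sweep; ``f = 1`` degenerates to a plain sequential
    raster.

    Parameters
    ----------
    grid_shape : tuple of int
        Image/k-grid shape.
    sweep_time : float
        Duration of one Nyquist-complete sweep (s).
    f : int
        Section (and sheaf) count.  When ``f`` does not divide the line
        count, the last section/sheaf absorbs the remainder.
    n_sweeps : int
        Number of repeated sweeps (total duration ``n_sweeps * sweep_time``).
    """
    grid_shape = tuple(int(n) for n in grid_shape)
    if len(grid_shape) != 3:
        raise ValueError("grid_shape must be 3-dimensional")
    phase_axes = [ax for ax in range(3) if ax != readout_axis]
    n_read = grid_shape[readout_axis]
    plane_shape = tuple(grid_shape[ax] for ax in phase_axes)
    n_lines = int(np.prod(plane_shape))
    if f > n_lines:
        raise ValueError(f"f={f} exceeds the number of phase-encode lines ({n_lines})")
    if f < 1:
        raise ValueError("f must be >= 1")

    sections = _split_contiguous(n_lines, f)
    sheaves = [_split_contiguous(len(sec), f) for sec in sections]
    line_order = np.concatenate([
        sections[s][sheaves[s][j]]
        for j in range(f)       # sheaf pass
        for s in range(f)       # one sheaf from every section per pass
    ])

    py, pz = np.unravel_index(line_order, plane_shape)
    idx_sweep = np.empty((n_lines * n_read, 3), dtype=np.int32)
    read = np.arange(n_read, dtype=np.int32)
    idx_sweep[:, readout_axis] = np.tile(read, n_lines)
    idx_sweep[:, phase_axes[0]] = np.repeat(py.astype(np.int32), n_read)
    idx_sweep[:, phase_axes[1]] = np.repeat(pz.astype(np.int32), n_read)

    V = n_lines * n_read
    indices = np.tile(idx_sweep, (n_sweeps, 1))
    times = np.arange(n_sweeps * V, dtype=np.float64) * (sweep_time / V)
    return KTrajectory(indices=indices, times=times, grid_shape=grid_shape,
                       sweep_time=float(sweep_time))


def raster_trajectory(grid_shape, sweep_time: float, n_sweeps: int = 1,
                      readout_axis: int = 0) -> KTrajectory:
    """Plain sequential raster ordering (UnWRAP with a single section)."""
    return unwrap_trajectory(grid_shape, sweep_time, f=1, n_sweeps=n_sweeps,
                             readout_axis=readout_axis)


def partition_trajectory(traj: KTrajectory, dt: float) -> Partition:
    """Partition trajectory samples into half-open intervals of length ``dt``.

    ``T = ceil(duration / dt)`` intervals jointly cover the scan; a sample at
    exactly ``i * dt`` falls in interval ``i``.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    duration = traj.duration
    if dt > duration:
        raise ValueError(f"dt={dt} exceeds the scan duration {duration}")
    n_intervals = int(np.ceil(duration / dt - 1e-12))
    which = np.floor(traj.times / dt + 1e-12).astype(np.int64)
    which = np.clip(which, 0, n_intervals - 1)
    return Partition(dt=float(dt), n_intervals=n_intervals, interval_of_sample=which)


def spectral_uniformity(traj: KTrajectory, partition: Partition,
                        n_bands: int = 4, axes: tuple[int, ...] | None = None) -> tuple[np.ndarray, float]:
    """Per-interval histogram of radial k-space frequency bands.

    Each sample's normalized radial frequency (0 at DC, 1 at the grid corner)
    is binned into ``n_bands`` equal-width bands.  ``axes`` selects which
    grid axes enter the radius — pass the phase-encode axes to ignore the
    readout direction, which every line spans anyway.  Returns the
    ``(T, n_bands)`` count matrix and a scalar uniformity score in (0, 1]:
    one minus the mean total-variation distance between each interval's band
    distribution and the whole-scan band distribution.  A well-interleaved
    ordering scores near 1; a sequential raster partitioned finely scores
    low.
    """
    axes = tuple(range(3)) if axes is None else tuple(axes)
    center = (np.asarray(traj.grid_shape) - 1) / 2.0
    half = np.maximum(np.asarray(traj.grid_shape) // 2, 1)
    rel = (traj.indices - center) / half
    radial = np.linalg.norm(rel[:, axes], axis=1)
    radial = radial / max(radial.max(), 1e-12)
    band = np.minimum((radial * n_bands).astype(int), n_bands - 1)
    counts = np.zeros((partition.n_intervals, n_bands), dtype=np.int64)
    np.add.at(counts, (partition.interval_of_sample, band), 1)

    overall = counts.sum(axis=0).astype(float)
    overall /= overall.sum()
    per = counts.astype(float)
    row_tot = per.sum(axis=1, keepdims=True)
    nonempty = row_tot[:, 0] > 0
    per[nonempty] /= row_tot[nonempty]
    tv = 0.5 * np.abs(per[nonempty] - overall).sum(axis=1)
    score = float(1.0 - tv.mean()) if nonempty.any() else 0.0
    return counts, score
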