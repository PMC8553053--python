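"""Virtual k-space scanner: time-resolved acquisition of a phantom.

Each sample of the trajectory measures one Fourier coefficient of the
phantom image at the sample's timestamp.  The phantom is fully re-evaluated
only every ``update_interval`` (50 ms by default) of scan time; between
updates the image — and, since the Fourier transform is linear, every
k-space coefficient — is linearly interpolated.  Measurement noise is
independent complex Gaussian in k-space; the default scalar scale is
calibrated so acquisitions reach a target image-domain PSNR.

All transforms use the unitary ("ortho") FFT normalization, so Parseval
identities hold exactly and k-space noise maps to image noise of the same
per-voxel variance.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .phantom import Phantom, evaluate_phantom
from .trajectory import KTrajectory

__all__ = [
    "KSampleSeries",
    "NoiseModel",
    "acquire",
    "add_noise",
    "psnr",
    "calibrate_noise_sigma",
    "sweep_grids",
    "PSNR_CAP_DB",
]

#: Reported PSNR for numerically identical clean/noisy inputs.
PSNR_CAP_DB = 300.0


@dataclass
class KSampleSeries:
    """Measured complex k-space samples with timestamps and provenance.

    ``indices`` are centered k-grid triples (same convention as
    :class:`~ecamri.trajectory.KTrajectory`).
    """

    indices: np.ndarray
    times: np.ndarray
    values: np.ndarray
    grid_shape: tuple[int, int, int]
    sweep_time: float
    noise_sigma: float | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=np.int32)
        self.times = np.asarray(self.times, dtype=np.float64)
        self.values = np.asarray(self.values, dtype=np.complex128)
        if not (len(self.indices) == len(self.times) == len(self.values)):
            raise ValueError("indices, times and values must have equal length")

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
        return self.n_sweeps * self.sweep_time

    def flat_indices(self) -> np.ndarray:
        return np.ravel_multi_index(self.indices.T, self.grid_shape)


@dataclass
class NoiseModel:
    """Independent complex Gaussian k-space noise.

    ``sigma`` is the standard deviation of each of the real and imaginary
    components, either a scalar or a per-k-point map on the centered grid.
    """

    sigma: float | np.ndarray
    seed: int | None = None

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.sigma) < 0):
            raise ValueError("noise SD must be nonnegative")

    def sigma_at(self, series: KSampleSeries) -> np.ndarray:
        sig = np.asarray(self.sigma, dtype=float)
        if sig.ndim == 0:
            return np.broadcast_to(sig, (series.n_samples,))
        if sig.shape != series.grid_shape:
            raise ValueError("per-k-point SD map must match the grid shape")
        return sig.reshape(-1)[series.flat_indices()]


def _fft_volume(vol: np.ndarray) -> np.ndarray:
    """Unitary FFT with the DC coefficient at the grid center."""
    return np.fft.fftshift(np.fft.fftn(np.fft.ifftshift(vol), norm="ortho"))


def _ifft_volume(grid: np.ndarray) -> np.ndarray:
    return np.fft.fftshift(np.fft.ifftn(np.fft.ifftshift(grid), norm="ortho"))


def acquire(ph: Phantom, traj: KTrajectory, update_interval: float = 0.05) -> KSampleSeries:
    """Noiselessly acquire the phantom along a trajectory.

    Each measured value is the centered unitary FFT coefficient, at the
    sample's k-index, of the phantom image linearly interpolated between the
    two bracketing full re-evaluations (every ``update_interval`` seconds).
    Because the FFT is linear, interpolating coefficients of the update-time
    volumes is identical to transforming the interpolated image.
    """
    if tuple(traj.grid_shape) != tuple(ph.grid_shape):
        raise ValueError("trajectory grid does not match phantom grid")
    if update_interval <= 0:
        raise ValueError("update interval must be positive")

    t_end = float(traj.times[-1])
    n_seg = max(int(np.ceil(t_end / update_interval - 1e-12)), 1)
    update_times = np.arange(n_seg + 1) * update_interval

    flat = traj.flat_indices()
    seg = np.minimum((traj.times / update_interval).astype(np.int64), n_seg - 1)
    u = (traj.times - update_times[seg]) / update_interval

    values = np.empty(traj.n_samples, dtype=np.complex128)
    f_curr = None  # FFT of the phantom at update_times[j], carried forward
    for j in range(n_seg):
        pick = np.flatnonzero(seg == j)
        if pick.size == 0:
            f_curr = None
            continue
        if f_curr is None:
            f_curr = _fft_volume(evaluate_phantom(ph, update_times[j])).reshape(-1)
        f_next = _fft_volume(evaluate_phantom(ph, update_times[j + 1])).reshape(-1)
        values[pick] = (1.0 - u[pick]) * f_curr[flat[pick]] + u[pick] * f_next[flat[pick]]
        f_curr = f_next

    return KSampleSeries(indices=traj.indices, times=traj.times, values=values,
                         grid_shape=traj.grid_shape, sweep_time=traj.sweep_time)


def add_noise(series: KSampleSeries, nm: NoiseModel, seed: int | None = None) -> KSampleSeries:
    """Add independent complex Gaussian noise to every sample.

    ``seed`` overrides the noise model's own seed; the realization is
    reproducible for a fixed seed.
    """
    use_seed = nm.seed if seed is None else seed
    rng = np.random.default_rng(use_seed)
    sd = nm.sigma_at(series)
    noise = rng.standard_normal(series.n_samples) + 1j * rng.standard_normal(series.n_samples)
    sigma_meta = float(np.asarray(nm.sigma).ravel()[0]) if np.asarray(nm.sigma).ndim == 0 else None
    return replace(series, values=series.values + sd * noise,
                   noise_sigma=sigma_meta, seed=use_seed)


def sweep_grids(series: KSampleSeries) -> np.ndarray:
    """Assemble samples into per-sweep centered k-space grids.

    Requires whole Nyquist-complete sweeps (every grid index exactly once per
    consecutive block of V samples).  Returns shape ``(n_sweeps, *grid)``.
    """
    V = series.n_voxels
    if series.n_samples == 0 or series.n_samples % V != 0:
        raise ValueError("sample series does not contain whole sweeps")
    n_sweeps = series.n_samples // V
    flat = series.flat_indices().reshape(n_sweeps, V)
    grids = np.empty((n_sweeps, V), dtype=np.complex128)
    vals = series.values.reshape(n_sweeps, V)
    for s in range(n_sweeps):
        counts = np.bincount(flat[s], minlength=V)
        if counts.max() != 1 or counts.min() != 1:
            raise ValueError(f"sweep {s} is not Nyquist-complete")
        grids[s, flat[s]] = vals[s]
    return grids.reshape((n_sweeps,) + tuple(series.grid_shape))


def psnr(clean: KSampleSeries, noisy: KSampleSeries) -> float:
    """Image-domain peak signal-to-noise ratio in dB, averaged over sweeps.

    Per sweep: ``20 log10(peak / rms)`` with ``peak`` the maximum magnitude
    of the clean sweep-IFFT volume and ``rms`` the root-mean-square magnitude
    of the image-domain noise (IFFT of the k-space perturbation).  Identical
    inputs report the cap :data:`PSNR_CAP_DB`.
    """
    if clean.n_samples != noisy.n_samples or not np.array_equal(clean.indices, noisy.indices):
        raise ValueError("clean and noisy series must sample the same points")
    g_clean = sweep_grids(clean)
    g_noisy = sweep_grids(noisy)
    vals = []
    for s in range(g_clean.shape[0]):
        img = _ifft_volume(g_clean[s])
        noise = _ifft_volume(g_noisy[s] - g_clean[s])
        peak = float(np.abs(img).max())
        rms = float(np.sqrt(np.mean(np.abs(noise) ** 2)))
        if rms == 0.0:
            vals.append(PSNR_CAP_DB)
        else:
            vals.append(min(20.0 * np.log10(peak / rms), PSNR_CAP_DB))
    return float(np.mean(vals))


def calibrate_noise_sigma(clean: KSampleSeries, target_psnr_db: float = 37.0) -> float:
    """Scalar k-space noise SD whose expected image-domain PSNR hits the target.

    With unitary transforms, per-component k-space SD ``sigma`` yields
    image-domain complex noise of RMS ``sigma * sqrt(2)``; setting the
    geometric mean of the clean sweep peaks over that RMS to the target ratio
    makes the sweep-averaged PSNR equal ``target_psnr_db`` in expectation.
    """
    grids = sweep_grids(clean)
    peaks = np.array([np.abs(_ifft_volume(g)).max() for g in grids])
    if np.any(peaks <= 0):
        raise ValueError("clean acquisition has a zero-signal sweep")
    geo_peak = float(np.exp(np.mean(np.log(peaks))))
    return geo_peak / (np.sqrt(2.0) * 10.0 ** (target_psnr_db / 20.0))
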