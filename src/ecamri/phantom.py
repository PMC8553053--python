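"""Continuous-time digital breast phantoms for DCE-MRI simulation.

A phantom is a *function of continuous time*: a static background volume plus
additive enhancement at vessel voxels (Parker population arterial input
function) and lesion voxels (truncated-exponential uptake model), rendered
through a steady-state spoiled gradient-echo (SPGR) signal model.  Because the
phantom is parametric it can be evaluated at any time point, which is what
lets the virtual scanner time-tag individual k-space samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

__all__ = [
    "EmmParams",
    "AifParams",
    "SignalModelParams",
    "PhantomConfig",
    "Phantom",
    "LESION_CASES",
    "lesion_concentration",
    "parker_aif",
    "spgr_signal",
    "build_phantom",
    "evaluate_phantom",
    "ground_truth_series",
    "voxel_timecourses",
]

#: Per-case lesion uptake parameter distributions (mean, SD) fitted from
#: ultrafast breast DCE-MRI series: upper concentration limit A (mM), uptake
#: rate alpha (1/s) and bolus arrival time t0 (s).  Case 1 (a grade-III
#: invasive ductal carcinoma) is the default study condition.
LESION_CASES = {
    1: {"A": (1.56, 0.45), "alpha": (0.14, 0.13), "t0": (15.0, 2.2)},
    2: {"A": (0.12, 0.25), "alpha": (0.019, 0.038), "t0": (17.0, 7.3)},
    3: {"A": (0.84, 0.70), "alpha": (0.041, 0.033), "t0": (20.0, 8.2)},
    4: {"A": (1.4, 0.38), "alpha": (0.075, 0.020), "t0": (21.0, 2.8)},
    5: {"A": (1.0, 0.70), "alpha": (0.020, 0.015), "t0": (32.0, 9.1)},
}


@dataclass
class EmmParams:
    """Truncated-exponential lesion uptake parameters.

    Attributes
    ----------
    A : float or ndarray
        Upper limit of tracer concentration (mM).
    alpha : float or ndarray
        Uptake rate (1/s).
    t0 : float or ndarray
        Bolus arrival time (s).
    """

    A: np.ndarray | float
    alpha: np.ndarray | float
    t0: np.ndarray | float

    def __post_init__(self) -> None:
        for name in ("A", "alpha", "t0"):
            v = np.asarray(getattr(self, name), dtype=float)
            if np.any(v < 0):
                raise ValueError(f"EmmParams.{name} must be nonnegative")
            setattr(self, name, v)


@dataclass
class AifParams:
    """Parker population arterial input function, plus an arrival offset.

    The functional form is a bi-Gaussian first/second pass plus a
    sigmoid-gated exponential washout.  Coefficient defaults are the published
    population values with time expressed in minutes; ``t0`` is a per-voxel
    bolus arrival offset in seconds, and concentration is identically zero
    before it.
    """

    a1: float = 0.809       # mM * min
    a2: float = 0.330       # mM * min
    tc1: float = 0.17046    # min
    tc2: float = 0.365      # min
    sigma1: float = 0.0563  # min
    sigma2: float = 0.132   # min
    alpha_exp: float = 1.050  # mM
    beta: float = 0.1685    # 1/min
    s: float = 38.078       # 1/min
    tau: float = 0.483      # min
    t0: np.ndarray | float = 0.0  # s

    def __post_init__(self) -> None:
        if self.sigma1 <= 0 or self.sigma2 <= 0:
            raise ValueError("AIF Gaussian widths must be positive")
        if self.beta <= 0:
            raise ValueError("AIF washout decay rate must be positive")
        self.t0 = np.asarray(self.t0, dtype=float)


@dataclass
class SignalModelParams:
    """Steady-state spoiled gradient-echo acquisition parameters.

    Baseline longitudinal relaxation times are per tissue class; contrast
    agent shortens T1 linearly via the relaxivity ``r1``:
    ``R1(t) = 1/T1_baseline + r1 * C(t)``.  Transverse (T2*) decay is not
    modeled, so TE is carried only as metadata.
    """

    flip_angle_deg: float = 10.0
    tr_ms: float = 3.2
    te_ms: float = 1.6
    t1_background_s: float = 0.5
    t1_vessel_s: float = 1.6
    t1_lesion_s: float = 1.4
    r1_relaxivity: float = 4.5  # 1/s/mM
    m0: float = 1.0             # equilibrium magnetization, a.u.

    def __post_init__(self) -> None:
        if not 0.0 < self.flip_angle_deg < 90.0:
            raise ValueError("flip angle must lie in (0, 90) degrees")
        if not self.tr_ms > self.te_ms > 0.0:
            raise ValueError("require TR > TE > 0")


def lesion_concentration(t, p: EmmParams) -> np.ndarray:
    """Lesion contrast concentration C(t) = A (1 - exp(-alpha (t - t0))) for
    t >= t0, zero before arrival.

    Broadcasts ``t`` against the (possibly per-voxel) parameter arrays.
    """
    t = np.asarray(t, dtype=float)
    if not np.all(np.isfinite(t)):
        raise ValueError("time must be finite")
    dt = t - p.t0
    return np.where(dt >= 0.0, p.A * -np.expm1(-p.alpha * np.maximum(dt, 0.0)), 0.0)


def parker_aif(t, p: AifParams) -> np.ndarray:
    """Arterial blood concentration of contrast agent (mM) at time t (s).

    Evaluates the population AIF shifted by the voxel arrival offset
    ``p.t0`` and clamped to zero before arrival.
    """
    t = np.asarray(t, dtype=float)
    if not np.all(np.isfinite(t)):
        raise ValueError("time must be finite")
    tm = (t - p.t0) / 60.0  # model coefficients are expressed in minutes
    g1 = p.a1 / (p.sigma1 * np.sqrt(2.0 * np.pi)) * np.exp(
        -((tm - p.tc1) ** 2) / (2.0 * p.sigma1**2)
    )
    g2 = p.a2 / (p.sigma2 * np.sqrt(2.0 * np.pi)) * np.exp(
        -((tm - p.tc2) ** 2) / (2.0 * p.sigma2**2)
    )
    washout = p.alpha_exp * np.exp(-p.beta * np.maximum(tm, 0.0))
    washout = washout / (1.0 + np.exp(-p.s * (tm - p.tau)))
    c = g1 + g2 + washout
    return np.where(tm >= 0.0, c, 0.0)


def spgr_signal(C, m: SignalModelParams, t1_baseline_s: float | np.ndarray | None = None,
                m0: float | np.ndarray | None = None) -> np.ndarray:
    """Steady-state SPGR signal for contrast concentration ``C`` (mM).

    S = M0 sin(FA) (1 - E1) / (1 - E1 cos(FA)),  E1 = exp(-TR * R1),
    with R1 = 1/T1_baseline + r1 * C.  ``t1_baseline_s`` defaults to the
    background class T1.
    """
    C = np.asarray(C, dtype=float)
    if np.any(C < 0):
        raise ValueError("concentration must be nonnegative")
    if t1_baseline_s is None:
        t1_baseline_s = m.t1_background_s
    if m0 is None:
        m0 = m.m0
    fa = np.deg2rad(m.flip_angle_deg)
    r1 = 1.0 / np.asarray(t1_baseline_s, dtype=float) + m.r1_relaxivity * C
    e1 = np.exp(-(m.tr_ms * 1e-3) * r1)
    return m0 * np.sin(fa) * (1.0 - e1) / (1.0 - e1 * np.cos(fa))


@dataclass
class PhantomConfig:
    """Procedural phantom geometry and parameter distributions.

    The default grid (32 x 28 x 7, 1 mm^3 voxels) keeps the phase-encode
    plane at 28 x 7 = 196 lines so an f = 14 interleaved ordering divides it
    evenly into 14 sections of 14 sheaves.  Lesion voxels draw (A, alpha, t0)
    independently from normal distributions truncated at zero (means/SDs from
    ``LESION_CASES``); vessel voxels get a smooth arrival-time gradient along
    the vessel axis, standing in for bolus propagation.
    """

    grid_shape: tuple[int, int, int] = (32, 28, 7)
    lesion_center: tuple[float, float, float] = (16.0, 13.0, 3.2)
    lesion_semiaxes: tuple[float, float, float] = (5.5, 4.5, 2.3)
    vessel_centers: tuple[tuple[float, float], ...] = ((4.0, 2.0), (24.0, 5.0))
    vessel_radius: float = 1.5
    lesion_case: int = 1
    lesion_A: tuple[float, float] | None = None       # (mean, sd) mM
    lesion_alpha: tuple[float, float] | None = None   # (mean, sd) 1/s
    lesion_t0: tuple[float, float] | None = None      # (mean, sd) s
    vessel_t0_range: tuple[float, float] = (12.0, 18.0)  # s, along vessel axis
    background_level: float = 1.0
    background_texture: float = 0.2
    signal: SignalModelParams = field(default_factory=SignalModelParams)
    aif: AifParams = field(default_factory=AifParams)
    # Optional user-supplied geometry; overrides the procedural shapes.
    vessel_mask: np.ndarray | None = None
    lesion_mask: np.ndarray | None = None

    def lesion_distributions(self) -> dict[str, tuple[float, float]]:
        case = LESION_CASES[self.lesion_case]
        return {
            "A": self.lesion_A or case["A"],
            "alpha": self.lesion_alpha or case["alpha"],
            "t0": self.lesion_t0 or case["t0"],
        }


@dataclass
class Phantom:
    """A continuous-time phantom: static background plus additive enhancement.

    ``lesion_params`` / ``vessel_aif`` hold one parameter entry per masked
    voxel, ordered as ``np.flatnonzero(mask)``.
    """

    grid_shape: tuple[int, int, int]
    background: np.ndarray
    vessel_mask: np.ndarray
    lesion_mask: np.ndarray
    lesion_params: EmmParams
    vessel_aif: AifParams
    signal: SignalModelParams

    def __post_init__(self) -> None:
        if np.any(self.vessel_mask & self.lesion_mask):
            raise ValueError("vessel and lesion masks must be disjoint")
        if self.lesion_params.A.shape != (int(self.lesion_mask.sum()),):
            raise ValueError("one lesion parameter set per lesion voxel required")
        if np.atleast_1d(self.vessel_aif.t0).shape != (int(self.vessel_mask.sum()),):
            raise ValueError("one arrival offset per vessel voxel required")

    @property
    def min_arrival_time(self) -> float:
        times = np.concatenate([
            np.atleast_1d(self.lesion_params.t0),
            np.atleast_1d(self.vessel_aif.t0),
        ])
        return float(times.min()) if times.size else np.inf


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float, n: int) -> np.ndarray:
    """Draw from N(mean, sd) truncated below at zero."""
    if sd == 0:
        return np.full(n, float(mean))
    a = (0.0 - mean) / sd
    return stats.truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=n, random_state=rng)


def _smooth_field(shape: tuple[int, int, int]) -> np.ndarray:
    """Deterministic smooth modulation in [-1, 1] used for background texture."""
    ax = [np.linspace(0.0, np.pi, n) for n in shape]
    gx, gy, gz = np.meshgrid(*ax, indexing="ij")
    return np.sin(gx) * np.sin(1.7 * gy + 0.3) * np.cos(0.9 * gz)


def build_phantom(config: PhantomConfig, seed: int | None = 0) -> Phantom:
    """Build a phantom from procedural geometry and parameter distributions.

    Deterministic for a fixed seed.  User-supplied masks must be disjoint.
    """
    shape = tuple(config.grid_shape)
    rng = np.random.default_rng(seed)
    ii, jj, kk = np.meshgrid(*[np.arange(n, dtype=float) for n in shape], indexing="ij")

    if config.lesion_mask is not None:
        lesion_mask = np.asarray(config.lesion_mask, dtype=bool)
    else:
        cx, cy, cz = config.lesion_center
        ax_, ay, az = config.lesion_semiaxes
        if min(ax_, ay, az) > 0:
            lesion_mask = ((ii - cx) / ax_) ** 2 + ((jj - cy) / ay) ** 2 + ((kk - cz) / az) ** 2 <= 1.0
        else:
            lesion_mask = np.zeros(shape, dtype=bool)

    if config.vessel_mask is not None:
        vessel_mask = np.asarray(config.vessel_mask, dtype=bool)
    else:
        vessel_mask = np.zeros(shape, dtype=bool)
        for cy, cz in config.vessel_centers:
            vessel_mask |= (jj - cy) ** 2 + (kk - cz) ** 2 <= config.vessel_radius**2

    if np.any(vessel_mask & lesion_mask):
        if config.vessel_mask is not None or config.lesion_mask is not None:
            raise ValueError("user-supplied vessel and lesion masks overlap")
        lesion_mask &= ~vessel_mask  # procedural geometry: vessel wins

    dists = config.lesion_distributions()
    n_lesion = int(lesion_mask.sum())
    lesion_params = EmmParams(
        A=_truncated_normal(rng, *dists["A"], n_lesion),
        alpha=_truncated_normal(rng, *dists["alpha"], n_lesion),
        t0=_truncated_normal(rng, *dists["t0"], n_lesion),
    )

    # Arrival offsets vary linearly along the vessel (readout) axis: the bolus
    # front advances smoothly through each vessel.
    vx = ii[vessel_mask]
    lo, hi = config.vessel_t0_range
    span = max(shape[0] - 1, 1)
    vessel_t0 = lo + (hi - lo) * vx / span
    vessel_aif = replace(config.aif, t0=vessel_t0)

    sig = config.signal
    t1_map = np.full(shape, sig.t1_background_s)
    t1_map[vessel_mask] = sig.t1_vessel_s
    t1_map[lesion_mask] = sig.t1_lesion_s
    m0_map = config.background_level * (1.0 + config.background_texture * _smooth_field(shape))
    background = spgr_signal(np.zeros(shape), sig, t1_baseline_s=t1_map, m0=m0_map * sig.m0)

    return Phantom(
        grid_shape=shape,
        background=background,
        vessel_mask=vessel_mask,
        lesion_mask=lesion_mask,
        lesion_params=lesion_params,
        vessel_aif=vessel_aif,
        signal=sig,
    )


def _enhancement(ph: Phantom, times: np.ndarray, mask: np.ndarray,
                 concentration) -> np.ndarray:
    """Signal enhancement (over the tissue baseline) for masked voxels.

    Returns an array of shape ``(len(times), mask.sum())``.
    """
    sig = ph.signal
    t1 = sig.t1_vessel_s if mask is ph.vessel_mask else sig.t1_lesion_s
    c = concentration(times[:, None])
    base = spgr_signal(0.0, sig, t1_baseline_s=t1)
    return spgr_signal(c, sig, t1_baseline_s=t1) - base


def evaluate_phantom(ph: Phantom, t) -> np.ndarray:
    """Evaluate the phantom signal volume at time(s) ``t`` (s).

    Scalar ``t`` returns one volume; an array of times returns a stacked
    ``(len(t), *grid_shape)`` array.  Before the earliest bolus arrival the
    result equals the background exactly.
    """
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    if np.any(t_arr < 0):
        raise ValueError("time must be nonnegative")
    out = np.broadcast_to(ph.background, (t_arr.size,) + ph.background.shape).copy()
    if ph.lesion_mask.any():
        les = _enhancement(ph, t_arr, ph.lesion_mask,
                           lambda ts: lesion_concentration(ts, ph.lesion_params))
        out[:, ph.lesion_mask] += les
    if ph.vessel_mask.any():
        ves = _enhancement(ph, t_arr, ph.vessel_mask,
                           lambda ts: parker_aif(ts, ph.vessel_aif))
        out[:, ph.vessel_mask] += ves
    return out[0] if np.isscalar(t) or np.ndim(t) == 0 else out


def voxel_timecourses(ph: Phantom, times, mask: np.ndarray) -> np.ndarray:
    """Exact signal time courses, shape ``(len(times), mask.sum())``.

    Dense evaluation of the continuous-time model at masked voxels only —
    used for ground-truth reference curves without rendering full volumes.
    """
    times = np.asarray(times, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    out = np.broadcast_to(ph.background[mask], (times.size, int(mask.sum()))).copy()
    for cls_mask, conc in (
        (ph.lesion_mask, lambda ts, sub: lesion_concentration(
            ts, EmmParams(ph.lesion_params.A[sub], ph.lesion_params.alpha[sub],
                          ph.lesion_params.t0[sub]))),
        (ph.vessel_mask, lambda ts, sub: parker_aif(
            ts, replace(ph.vessel_aif, t0=np.atleast_1d(ph.vessel_aif.t0)[sub]))),
    ):
        overlap = mask & cls_mask
        if not overlap.any():
            continue
        sub = overlap[cls_mask]          # selector within the class voxel list
        cols = overlap[mask]             # selector within the output columns
        sig = ph.signal
        t1 = sig.t1_vessel_s if cls_mask is ph.vessel_mask else sig.t1_lesion_s
        c = conc(times[:, None], sub)
        out[:, cols] += spgr_signal(c, sig, t1_baseline_s=t1) - spgr_signal(0.0, sig, t1_baseline_s=t1)
    return out


def ground_truth_series(ph: Phantom, partition):
    """Ground-truth image series at the midpoints of a reconstruction partition.

    The i-th volume is the phantom evaluated at the center of interval i.
    """
    from .recon import ImageSeries

    if partition.n_intervals == 0:
        raise ValueError("empty partition")
    mids = partition.midpoints
    data = evaluate_phantom(ph, mids)
    return ImageSeries(data=data, dt=partition.dt, t_mid=mids)
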