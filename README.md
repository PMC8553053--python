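# ecamri — enhancement-constrained acceleration for breast DCE-MRI

Dynamic contrast-enhanced MRI of the breast must trade spatial against
temporal resolution: a Nyquist-complete "ultrafast" sweep of k-space takes
about 3.5 s, too slow to resolve the bolus arrival time (BAT) and initial
enhancement slope that help separate malignant from benign enhancement.
**Enhancement-constrained acceleration (ECA)** re-partitions time-tagged
k-space data into much shorter intervals (0.25 s here, acceleration factor
α = V·T/N = 14) and reconstructs the image time series

&nbsp;&nbsp;&nbsp;&nbsp; X* = argmin<sub>X</sub> Σ<sub>v</sub> w<sub>v</sub> Σ<sub>t</sub> |Δ X<sub>v</sub>(t)|²  subject to  X̃<sub>t</sub>[k] = d<sub>t</sub>[k] for every k-entry measured in interval t,

i.e. the temporally smoothest series that *exactly* matches every measured
Fourier coefficient in its own acquisition interval (Δ is a first- or
second-order temporal difference; the default curvature penalty makes the
solution spline-like).  The package provides everything needed to study
this reconstruction *in silico*:

- **`ecamri.phantom`** — continuous-time digital breast phantoms: static
  background, vessel voxels enhancing via the Parker population arterial
  input function (with per-voxel arrival offsets), lesion voxels enhancing
  via the truncated-exponential uptake model C(t) = A(1 − e^(−α(t−t₀))),
  all rendered through a steady-state SPGR signal model (FA 10°,
  TR/TE 3.2/1.6 ms).
- **`ecamri.trajectory`** — time-tagged Cartesian orderings, principally
  **UnWRAP** (Undersampling With Repeated Advancing Phase): the phase-encode
  plane is split into *f* sections of *f* sheaves and acquisition interleaves
  one sheaf per section, so every short interval samples a uniform spread of
  spatial frequencies while each full sweep stays Nyquist-complete.
- **`ecamri.scanner`** — a virtual scanner that evaluates the phantom every
  50 ms, linearly interpolates k-space between updates, adds complex
  Gaussian k-space noise, and calibrates the noise scale to a target
  image-domain PSNR (37 dB by default).
- **`ecamri.recon`** — the ECA solver (conjugate gradients on the
  unmeasured Fourier entries, measured entries held bit-exactly) and the
  sweep-by-sweep IFFT baseline.
- **`ecamri.kinetics`** — BAT estimators (time of peak enhancement in
  vessels, earliest 20%-of-max crossing in lesions), modified-Akima initial
  slope, empirical uptake-model fitting, and paired per-voxel error-ratio
  statistics with 5σ confidence intervals.
- **`ecamri.pipeline` / the `eca` CLI** — the full experiment
  (phantom → scan → both reconstructions → analysis) with provenance
  manifests; NIfTI/HDF5/CSV/YAML I/O in `ecamri.io`.

## Worked example

```python
import numpy as np
from ecamri import (PhantomConfig, build_phantom, unwrap_trajectory,
                    partition_trajectory, acquire, calibrate_noise_sigma,
                    add_noise, NoiseModel, psnr, eca_reconstruct,
                    ifft_reconstruct, EcaConfig, ground_truth_series)

ph = build_phantom(PhantomConfig(), seed=0)
print(f"phantom {ph.grid_shape}: {int(ph.vessel_mask.sum())} vessel, "
      f"{int(ph.lesion_mask.sum())} lesion voxels")
traj = unwrap_trajectory(ph.grid_shape, sweep_time=3.5, f=14, n_sweeps=4)
clean = acquire(ph, traj)                    # 14 s scan, 50 ms updates
sigma = calibrate_noise_sigma(clean)         # 37 dB calibration
noisy = add_noise(clean, NoiseModel(sigma=sigma, seed=0))
print(f"noise sigma = {sigma:.2e}, PSNR = {psnr(clean, noisy):.2f} dB")
part = partition_trajectory(traj, dt=0.25)
eca = eca_reconstruct(noisy, part, EcaConfig())
ifft = ifft_reconstruct(noisy)
truth = ground_truth_series(ph, part)
print(f"ECA: {eca.n_times} volumes at 0.25 s "
      f"({eca.solver_info.iterations} CG iters), "
      f"IFFT: {ifft.n_times} volumes at 3.5 s")
rms = np.sqrt(np.mean(np.abs(eca.data - truth.data) ** 2))
print(f"ECA rms error vs ground truth: {rms:.2e}")
```

prints:

```
phantom (32, 28, 7): 576 vessel, 245 lesion voxels
noise sigma = 6.91e-04, PSNR = 36.99 dB
ECA: 56 volumes at 0.25 s (900 CG iters), IFFT: 4 volumes at 3.5 s
ECA rms error vs ground truth: 1.43e-03
```

The phantom has 576 vessel and 245 lesion voxels on a 32×28×7 grid of
1 mm³ voxels; the
calibrated k-space noise lands within 0.01 dB of the 37 dB target; ECA turns
the same 4-sweep acquisition into 56 volumes at 0.25 s with an rms intensity
error of ~1.4 × 10⁻³ (about 1% of the enhanced-vessel signal) against the
continuous-time ground truth evaluated at each interval midpoint.

The same experiment from a shell:

```sh
eca run-all --seed 1 --out results/demo
```

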