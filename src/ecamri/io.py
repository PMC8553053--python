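"""Readers and writers for the pipeline's standard formats.

Complex-valued objects (k-space sample series, trajectories, complex image
series) live in HDF5; magnitude image series and parameter maps are
exported as NIfTI-1 with time as the 4th dimension and the temporal spacing
in ``pixdim[4]``; statistics go to CSV/JSON and configurations to YAML.
Round-trips are bit-exact for HDF5 and float32-exact for NIfTI magnitudes.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import h5py
import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .recon import ImageSeries
from .scanner import KSampleSeries
from .trajectory import KTrajectory

__all__ = [
    "save_ksamples", "load_ksamples",
    "save_trajectory", "load_trajectory",
    "trajectory_to_csv", "trajectory_from_csv",
    "save_series_nifti", "load_series_nifti",
    "save_series_hdf5", "load_series_hdf5",
    "save_volume_nifti", "load_volume_nifti",
    "save_json", "load_json",
    "load_yaml_config", "dump_yaml_config",
]


def save_ksamples(path, series: KSampleSeries) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("indices", data=series.indices.astype(np.int32))
        f.create_dataset("times", data=series.times.astype(np.float64))
        f.create_dataset("values", data=series.values.astype(np.complex128))
        f.attrs["grid_shape"] = series.grid_shape
        f.attrs["sweep_time"] = series.sweep_time
        if series.noise_sigma is not None:
            f.attrs["noise_sigma"] = series.noise_sigma
        if series.seed is not None:
            f.attrs["seed"] = series.seed


def load_ksamples(path) -> KSampleSeries:
    with h5py.File(path, "r") as f:
        _require(f, ["indices", "times", "values"], path)
        return KSampleSeries(
            indices=f["indices"][()],
            times=f["times"][()],
            values=f["values"][()],
            grid_shape=tuple(int(n) for n in f.attrs["grid_shape"]),
            sweep_time=float(f.attrs["sweep_time"]),
            noise_sigma=float(f.attrs["noise_sigma"]) if "noise_sigma" in f.attrs else None,
            seed=int(f.attrs["seed"]) if "seed" in f.attrs else None,
        )


def save_trajectory(path, traj: KTrajectory) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("indices", data=traj.indices.astype(np.int32))
        f.create_dataset("times", data=traj.times.astype(np.float64))
        f.attrs["grid_shape"] = traj.grid_shape
        f.attrs["sweep_time"] = traj.sweep_time


def load_trajectory(path) -> KTrajectory:
    with h5py.File(path, "r") as f:
        _require(f, ["indices", "times"], path)
        return KTrajectory(
            indices=f["indices"][()], times=f["times"][()],
            grid_shape=tuple(int(n) for n in f.attrs["grid_shape"]),
            sweep_time=float(f.attrs["sweep_time"]),
        )


def trajectory_to_csv(path, traj: KTrajectory) -> None:
    df = pd.DataFrame({
        "kx": traj.indices[:, 0], "ky": traj.indices[:, 1], "kz": traj.indices[:, 2],
        "time_s": traj.times,
    })
    with open(path, "w") as fh:
        fh.write(f"# grid_shape={','.join(map(str, traj.grid_shape))}"
                 f" sweep_time={traj.sweep_time!r}\n")
        df.to_csv(fh, index=False, float_format="%.17g")


def trajectory_from_csv(path) -> KTrajectory:
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("# grid_shape="):
            raise ValueError(f"{path}: missing trajectory CSV header line")
        fields = dict(part.split("=") for part in header[2:].split())
        grid_shape = tuple(int(x) for x in fields["grid_shape"].split(","))
        sweep_time = float(fields["sweep_time"])
        df = pd.read_csv(fh, float_precision="round_trip")
    return KTrajectory(indices=df[["kx", "ky", "kz"]].to_numpy(),
                       times=df["time_s"].to_numpy(),
                       grid_shape=grid_shape, sweep_time=sweep_time)


def save_series_nifti(path, series: ImageSeries) -> None:
    """Magnitude image series as float32 NIfTI-1, time on the 4th axis."""
    data = np.moveaxis(np.abs(series.data), 0, -1).astype(np.float32)
    img = nib.Nifti1Image(data, affine=np.eye(4))
    img.header["pixdim"][4] = series.dt
    img.header.set_xyzt_units(xyz="mm", t="sec")
    nib.save(img, str(path))


def load_series_nifti(path) -> ImageSeries:
    img = nib.load(str(path))
    data = np.moveaxis(np.asarray(img.dataobj, dtype=np.float32), -1, 0)
    dt = float(img.header["pixdim"][4])
    mids = (np.arange(data.shape[0]) + 0.5) * dt
    return ImageSeries(data=data, dt=dt, t_mid=mids)


def save_series_hdf5(path, series: ImageSeries) -> None:
    """Complex image series, bit-exact."""
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=series.data.astype(np.complex128))
        f.create_dataset("t_mid", data=series.t_mid)
        f.attrs["dt"] = series.dt
        if series.solver_info is not None:
            f.attrs["solver"] = json.dumps(dataclasses.asdict(series.solver_info))


def load_series_hdf5(path) -> ImageSeries:
    from .recon import SolverInfo

    with h5py.File(path, "r") as f:
        _require(f, ["data", "t_mid"], path)
        info = None
        if "solver" in f.attrs:
            info = SolverInfo(**json.loads(f.attrs["solver"]))
        return ImageSeries(data=f["data"][()], dt=float(f.attrs["dt"]),
                           t_mid=f["t_mid"][()], solver_info=info)


def save_volume_nifti(path, vol: np.ndarray) -> None:
    nib.save(nib.Nifti1Image(np.asarray(vol, dtype=np.float32), affine=np.eye(4)), str(path))


def load_volume_nifti(path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).dataobj, dtype=np.float32)


def save_json(path, obj) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_jsonify) + "\n")


def load_json(path):
    return json.loads(Path(path).read_text())


def load_yaml_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: top-level YAML mapping expected")
    return cfg


def dump_yaml_config(path, cfg: dict) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def _require(f: h5py.File, keys: list[str], path) -> None:
    missing = [k for k in keys if k not in f]
    if missing:
        raise ValueError(f"{path}: malformed file, missing datasets {missing}")
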