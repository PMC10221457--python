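"""CSV/JSON readers and writers for the pipeline's on-disk formats.

* raw sEMG CSV: ``time_s,RF,VM,VL,GM,GL`` — one row per 1/2000 s sample;
* marker CSV: ``time_s,ax,ay,az,bx,by,bz,cx,cy,cz`` — one row per 1/100 s
  frame, coordinates in millimetres;
* dataset CSV: ``gc_id,phase,af_RF,...,angle_deg`` — one row per phase point;
* model JSON: kernel spec plus the fitted parameters of either model family;
* sweep CSV: ``train_gcs,method,seed,mae_deg,rmse_deg,r2,n_test``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .kernels import MultiKernelSpec
from .lssvr import LssvrModel
from .recordings import EmgRecording, GaitCycleDataset, MarkerTrajectory
from .rvr import RvrModel


def write_emg_csv(path, rec: EmgRecording) -> None:
    frame = pd.DataFrame(rec.samples, columns=list(rec.channel_names))
    frame.insert(0, "time_s", np.arange(rec.n_samples) / rec.rate_hz)
    frame.to_csv(path, index=False, float_format="%.6g")


def read_emg_csv(path) -> EmgRecording:
    frame = pd.read_csv(path)
    time = frame.pop("time_s").to_numpy()
    if len(time) < 2:
        raise ValueError("need at least two samples to infer the rate")
    rate = 1.0 / float(np.median(np.diff(time)))
    return EmgRecording(frame.to_numpy(), rate, tuple(frame.columns))


def write_markers_csv(path, traj: MarkerTrajectory) -> None:
    cols = {}
    for prefix, pts in (("a", traj.points_a), ("b", traj.points_b), ("c", traj.points_c)):
        for j, axis in enumerate("xyz"):
            cols[f"{prefix}{axis}"] = pts[:, j]
    frame = pd.DataFrame(cols)
    frame.insert(0, "time_s", np.arange(traj.n_frames) / traj.rate_hz)
    frame.to_csv(path, index=False, float_format="%.6g")


def read_markers_csv(path) -> MarkerTrajectory:
    frame = pd.read_csv(path)
    time = frame["time_s"].to_numpy()
    rate = 1.0 / float(np.median(np.diff(time)))
    points = [
        frame[[f"{p}x", f"{p}y", f"{p}z"]].to_numpy() for p in ("a", "b", "c")
    ]
    return MarkerTrajectory(*points, rate_hz=rate)


def write_dataset_csv(path, dataset: GaitCycleDataset) -> None:
    dataset.to_frame().to_csv(path, index=False, float_format="%.8g")


def read_dataset_csv(path) -> GaitCycleDataset:
    return GaitCycleDataset.from_frame(pd.read_csv(path))


def write_model_json(path, model) -> None:
    """Serialize a fitted RVR or LS-SVR model (row-major input matrices)."""
    if isinstance(model, RvrModel):
        payload = {
            "model_type": "rvr",
            "kernel_spec": json.loads(model.kernel_spec.to_json()),
            "relevance_inputs": model.relevance_inputs.tolist(),
            "weights": model.weights.tolist(),
            "alphas": model.alphas.tolist(),
            "beta": model.beta,
            "sigma": model.sigma.tolist(),
            "training_summary": model.training_summary,
        }
    elif isinstance(model, LssvrModel):
        payload = {
            "model_type": "lssvr",
            "kernel_spec": json.loads(model.kernel_spec.to_json()),
            "support_inputs": model.support_inputs.tolist(),
            "dual_coefficients": model.dual_coefficients.tolist(),
            "bias": model.bias,
            "reg_gamma": model.reg_gamma,
            "training_summary": model.training_summary,
        }
    else:
        raise TypeError(f"cannot serialize model of type {type(model).__name__}")
    Path(path).write_text(json.dumps(payload))


def read_model_json(path):
    payload = json.loads(Path(path).read_text())
    spec = MultiKernelSpec.from_json(json.dumps(payload["kernel_spec"]))
    if payload["model_type"] == "rvr":
        return RvrModel(
            relevance_inputs=np.asarray(payload["relevance_inputs"], dtype=float),
            weights=np.asarray(payload["weights"], dtype=float),
            alphas=np.asarray(payload["alphas"], dtype=float),
            beta=float(payload["beta"]),
            sigma=np.asarray(payload["sigma"], dtype=float),
            kernel_spec=spec,
            training_summary=payload["training_summary"],
        )
    if payload["model_type"] == "lssvr":
        return LssvrModel(
            support_inputs=np.asarray(payload["support_inputs"], dtype=float),
            dual_coefficients=np.asarray(payload["dual_coefficients"], dtype=float),
            bias=float(payload["bias"]),
            reg_gamma=float(payload["reg_gamma"]),
            kernel_spec=spec,
            training_summary=payload["training_summary"],
        )
    raise ValueError(f"unknown model_type {payload['model_type']!r}")


def write_truth_json(path, truth, downsample: int = 1) -> None:
    """Ground-truth JSON: boundaries, (optionally downsampled) activations, angle."""
    payload = {
        "cycle_boundaries": [list(b) for b in truth.cycle_boundaries],
        "activations": truth.activations[::downsample].tolist(),
        "clean_angle": truth.clean_angle[::downsample].tolist(),
        "downsample": downsample,
    }
    Path(path).write_text(json.dumps(payload))
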