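"""NIfTI and TSV input/output for simulated runs and analysis products."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .synthgen import Block, BlockSchedule, BlinkTrain, MultiEchoSeries, UrgeTrace

__all__ = [
    "save_nifti",
    "load_nifti",
    "write_run",
    "read_run",
    "write_events_tsv",
    "read_schedule_tsv",
    "read_blinks_tsv",
    "write_urge_tsv",
    "read_urge_tsv",
]


def save_nifti(data: np.ndarray, path, voxel_size_mm: float = 3.0, tr_ms: float | None = None):
    affine = np.diag([voxel_size_mm] * 3 + [1.0])
    img = nib.Nifti1Image(np.asarray(data, np.float64), affine)
    if tr_ms is not None and data.ndim == 4:
        img.header.set_zooms((voxel_size_mm,) * 3 + (tr_ms / 1000.0,))
    nib.save(img, str(path))


def load_nifti(path) -> np.ndarray:
    return np.asanyarray(nib.load(str(path)).dataobj)


def write_events_tsv(df: pd.DataFrame, path):
    df.to_csv(path, sep="\t", index=False)


def read_schedule_tsv(path) -> BlockSchedule:
    df = pd.read_csv(path, sep="\t")
    blocks = tuple(
        Block(str(r.trial_type), float(r.onset), float(r.duration))
        for r in df.itertuples()
    )
    return BlockSchedule(blocks=blocks, run_length_s=blocks[-1].end_s)


def read_blinks_tsv(path, run_length_s: float) -> BlinkTrain:
    df = pd.read_csv(path, sep="\t")
    return BlinkTrain(
        onsets_s=df["onset"].to_numpy(float),
        durations_s=df["duration"].to_numpy(float),
        run_length_s=run_length_s,
    )


def write_urge_tsv(urge: UrgeTrace, path):
    urge.to_dataframe().to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_urge_tsv(path) -> UrgeTrace:
    df = pd.read_csv(path, sep="\t")
    dt = np.diff(df["time_s"].to_numpy())
    rate = 1.0 / float(np.median(dt))
    return UrgeTrace(
        rate_hz=round(rate, 6),
        values=df["urge"].to_numpy(float),
        condition=df["condition"].to_numpy(str),
    )


def write_run(series: MultiEchoSeries, out_dir, prefix: str = "run") -> dict:
    """Write a simulated run: per-echo 4D NIfTI, mean image, masks, metadata."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    for k, echo in enumerate(series.echoes, start=1):
        p = out / f"{prefix}_echo-{k}.nii.gz"
        save_nifti(echo, p, tr_ms=series.tr_ms)
        paths[f"echo{k}"] = str(p)
    save_nifti(series.mean_image, out / f"{prefix}_mean.nii.gz")
    save_nifti(series.brain_mask.astype(np.int16), out / f"{prefix}_mask.nii.gz")
    paths["mean"] = str(out / f"{prefix}_mean.nii.gz")
    paths["mask"] = str(out / f"{prefix}_mask.nii.gz")
    if series.truth is not None:
        save_nifti(series.truth.roi_labels.astype(np.int16), out / f"{prefix}_roi-labels.nii.gz")
        paths["roi_labels"] = str(out / f"{prefix}_roi-labels.nii.gz")
    meta = dict(tes_ms=list(series.tes_ms), tr_ms=series.tr_ms)
    (out / f"{prefix}_meta.json").write_text(json.dumps(meta, indent=2))
    return paths


def read_run(echo_paths, mask_path=None, mean_path=None, tes_ms=None, tr_ms=None) -> MultiEchoSeries:
    echoes = tuple(load_nifti(p).astype(float) for p in echo_paths)
    grid = echoes[0].shape[:-1]
    mask = load_nifti(mask_path).astype(bool) if mask_path else np.ones(grid, bool)
    if mean_path:
        mean = load_nifti(mean_path).astype(float)
    else:
        mean = echoes[0].mean(axis=-1)
    return MultiEchoSeries(
        echoes=echoes,
        tes_ms=tuple(tes_ms),
        tr_ms=float(tr_ms),
        mean_image=mean,
        brain_mask=mask,
    )
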