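"""Standard-format I/O: NIfTI volumes and fields, CSV tables, JSON reports."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, Tuple

import nibabel as nib
import numpy as np
import pandas as pd

from .core import ImageVolume
from .phantom import CardiacTimeline, RespTrace
from .registration import DeformationField
from .resp_motion import BinAssignment, TranslationTrace


def _affine(spacing) -> np.ndarray:
    aff = np.eye(4)
    for i, s in enumerate(spacing[:3]):
        aff[i, i] = s
    return aff


def save_volume(vol: ImageVolume, path) -> None:
    """Write a (possibly complex) volume as NIfTI; complex data saves |.|."""
    data = np.abs(vol.data) if np.iscomplexobj(vol.data) else vol.data
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float64), _affine(vol.spacing)), str(path))


def load_volume(path) -> ImageVolume:
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata())
    spacing = tuple(float(z) for z in img.header.get_zooms()[: data.ndim])
    return ImageVolume(data, spacing)


def save_field(field: DeformationField, path) -> None:
    """Displacement field as a vector NIfTI (last axis = component, voxels)."""
    nib.save(nib.Nifti1Image(field.disp, _affine(field.spacing)), str(path))


def load_field(path, spacing=None) -> DeformationField:
    img = nib.load(str(path))
    disp = np.asarray(img.get_fdata())
    if spacing is None:
        spacing = tuple(float(z) for z in img.header.get_zooms()[: disp.ndim - 1])
    return DeformationField(disp, tuple(spacing))


def resp_trace_to_csv(trace: RespTrace, path) -> None:
    pd.DataFrame({"time_s": trace.times, "fh_mm": trace.fh, "rl_mm": trace.rl}).to_csv(
        path, index=False
    )


def resp_trace_from_csv(path) -> RespTrace:
    df = pd.read_csv(path)
    return RespTrace(df["time_s"].to_numpy(), df["fh_mm"].to_numpy(), df["rl_mm"].to_numpy())


def timeline_to_csv(timeline: CardiacTimeline, path) -> None:
    pd.DataFrame(
        {
            "trigger_s": timeline.triggers,
            "rr_s": timeline.rr,
            "max_contraction_s": timeline.max_contraction,
        }
    ).to_csv(path, index=False)


def translation_trace_to_csv(trace: TranslationTrace, path) -> None:
    pd.DataFrame(
        {
            "beat": trace.beat,
            "phase": trace.phase,
            "time_s": trace.time,
            "fh_mm": trace.fh_mm,
            "rl_mm": trace.rl_mm,
        }
    ).to_csv(path, index=False)


def translation_trace_from_csv(path) -> TranslationTrace:
    df = pd.read_csv(path)
    return TranslationTrace(
        beat=df["beat"].to_numpy(),
        phase=df["phase"].to_numpy(),
        time=df["time_s"].to_numpy(),
        fh_mm=df["fh_mm"].to_numpy(),
        rl_mm=df["rl_mm"].to_numpy(),
    )


def bins_to_csv(bins: BinAssignment, trace: TranslationTrace, path) -> None:
    df = pd.DataFrame(
        {
            "beat": trace.beat,
            "phase": trace.phase,
            "time_s": trace.time,
            "fh_mm": trace.fh_mm,
            "rl_mm": trace.rl_mm,
            "bin": bins.labels,
            "rejected": bins.rejected,
        }
    )
    for b in range(bins.n_bins):
        df[f"weight_bin{b}"] = bins.weights[:, b]
    df.to_csv(path, index=False)


def save_json(obj: Dict, path) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON-serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, default=default))
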