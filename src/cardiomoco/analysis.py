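"""Functional and regional image analysis.

Left-ventricular volumetry (EDV/ESV/SV/EF), Bland-Altman agreement
statistics, the AHA 17-segment partition of a 3D LV myocardium mask,
and per-segment relative signal increase between corrected and
uncorrected PET images.  A 2D angular-sector variant of the segment map
serves the planar phantom, where the through-plane dimension needed for
the basal/mid/apical split does not exist.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Tuple

import numpy as np

from .core import ImageVolume


@dataclass
class LVIndices:
    """End-diastolic/systolic volumes (mL), stroke volume, ejection fraction."""

    edv_ml: float
    esv_ml: float

    def __post_init__(self) -> None:
        if self.edv_ml <= 0:
            raise ValueError("EDV must be positive (EF undefined otherwise)")
        if self.esv_ml < 0 or self.esv_ml > self.edv_ml:
            raise ValueError("need EDV >= ESV >= 0")

    @property
    def sv_ml(self) -> float:
        return self.edv_ml - self.esv_ml

    @property
    def ef_percent(self) -> float:
        return 100.0 * self.sv_ml / self.edv_ml


def mask_volume_ml(mask: np.ndarray, spacing) -> float:
    """Mask volume in mL from voxel count x voxel volume (mm^3 -> mL).

    In 2D the voxel 'volume' is area x 1 mm nominal slice thickness.
    """
    vox = float(np.prod(spacing))
    if mask.ndim == 2:
        pass  # 1 mm nominal thickness
    return float(mask.sum()) * vox / 1000.0


def lv_indices(edv_ml: float, esv_ml: float) -> LVIndices:
    """LV function indices from end-diastolic and end-systolic volumes."""
    return LVIndices(edv_ml=edv_ml, esv_ml=esv_ml)


def lv_indices_from_masks(
    edv_mask: np.ndarray, esv_mask: np.ndarray, spacing
) -> LVIndices:
    return lv_indices(mask_volume_ml(edv_mask, spacing), mask_volume_ml(esv_mask, spacing))


@dataclass
class BlandAltman:
    """Agreement statistics between two paired measurement series."""

    bias: float
    sd: float
    loa_low: float
    loa_high: float
    n: int


def bland_altman(series_a, series_b) -> BlandAltman:
    """Bias and 95% limits of agreement of ``a - b`` (sample SD, n-1)."""
    a = np.asarray(series_a, dtype=float)
    b = np.asarray(series_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("need two equal-length 1D series")
    if len(a) < 2:
        raise ValueError("need at least 2 paired observations")
    d = a - b
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return BlandAltman(
        bias=bias, sd=sd, loa_low=bias - 1.96 * sd, loa_high=bias + 1.96 * sd, n=len(a)
    )


@dataclass
class SegmentMap:
    """Integer segment labels over a myocardium mask (0 = outside)."""

    labels: np.ndarray
    segment_ids: Tuple[int, ...]

    def segment_mask(self, s: int) -> np.ndarray:
        return self.labels == s

    def segment_means(self, img: np.ndarray) -> Dict[int, float]:
        return {s: float(img[self.labels == s].mean()) for s in self.segment_ids}


def _sector_index(theta: np.ndarray, ref_angle: float, n_sectors: int) -> np.ndarray:
    rel = np.mod(theta - ref_angle, 2.0 * np.pi)
    return np.minimum((rel / (2.0 * np.pi / n_sectors)).astype(int), n_sectors - 1)


def aha17_segments(
    lv_mask: np.ndarray,
    base_center: np.ndarray,
    apex_center: np.ndarray,
    ref_angle: float = 0.0,
    apex_frac: float = 0.85,
) -> SegmentMap:
    """AHA 17-segment partition of a 3D LV myocardium mask.

    Voxels are projected on the base-to-apex long axis; the portion up
    to ``apex_frac`` is cut into basal/mid/apical thirds with 6/6/4
    angular sectors (measured about the long axis from ``ref_angle``),
    the remainder is the apical cap (segment 17).  Labels: basal 1-6,
    mid 7-12, apical 13-16, apex 17.
    """
    if lv_mask.ndim != 3:
        raise ValueError("AHA segmentation needs a 3D mask (see angular_sectors for 2D)")
    base = np.asarray(base_center, dtype=float)
    apex = np.asarray(apex_center, dtype=float)
    axis = apex - base
    norm = np.linalg.norm(axis)
    if norm == 0:
        raise ValueError("degenerate long axis (base == apex)")
    axis = axis / norm

    vox = np.argwhere(lv_mask).astype(float)
    rel = vox - base
    lam = (rel @ axis) / norm  # 0 at base, 1 at apex
    lam = np.clip(lam, 0.0, 1.0)
    # angular position about the long axis, using the in-plane components
    perp = rel - np.outer(rel @ axis, axis)
    theta = np.arctan2(perp[:, 1], perp[:, 0])

    labels = np.zeros(lv_mask.shape, dtype=int)
    lab = np.empty(len(vox), dtype=int)
    cap = lam >= apex_frac
    lab[cap] = 17
    body = ~cap
    third = np.minimum((lam[body] / (apex_frac / 3.0)).astype(int), 2)
    sec6 = _sector_index(theta[body], ref_angle, 6)
    sec4 = _sector_index(theta[body], ref_angle, 4)
    out = np.empty(body.sum(), dtype=int)
    out[third == 0] = 1 + sec6[third == 0]
    out[third == 1] = 7 + sec6[third == 1]
    out[third == 2] = 13 + sec4[third == 2]
    lab[body] = out
    labels[tuple(vox.astype(int).T)] = lab
    return SegmentMap(labels=labels, segment_ids=tuple(range(1, 18)))


def angular_sectors(
    lv_mask: np.ndarray,
    center: np.ndarray,
    n_sectors: int = 6,
    ref_angle: float = 0.0,
) -> SegmentMap:
    """Angular sector partition of a 2D myocardium ring (planar analog of
    the basal short-axis segments)."""
    if lv_mask.ndim != 2:
        raise ValueError("angular_sectors expects a 2D mask")
    vox = np.argwhere(lv_mask).astype(float)
    rel = vox - np.asarray(center, dtype=float)
    theta = np.arctan2(rel[:, 1], rel[:, 0])
    sec = 1 + _sector_index(theta, ref_angle, n_sectors)
    labels = np.zeros(lv_mask.shape, dtype=int)
    labels[tuple(vox.astype(int).T)] = sec
    return SegmentMap(labels=labels, segment_ids=tuple(range(1, n_sectors + 1)))


def segment_relative_increase(
    img_corrected: ImageVolume | np.ndarray,
    img_uncorrected: ImageVolume | np.ndarray,
    segmap: SegmentMap,
) -> Dict[int, float]:
    """Percent increase of mean segment signal, corrected over uncorrected."""
    a = img_corrected.data if isinstance(img_corrected, ImageVolume) else img_corrected
    b = img_uncorrected.data if isinstance(img_uncorrected, ImageVolume) else img_uncorrected
    if a.shape != b.shape or a.shape != segmap.labels.shape:
        raise ValueError("images and segment map must share a grid")
    out = {}
    for s in segmap.segment_ids:
        m = segmap.labels == s
        mu_u = float(b[m].mean())
        if mu_u == 0:
            raise ValueError(f"zero uncorrected mean in segment {s}")
        out[s] = 100.0 * (float(a[m].mean()) - mu_u) / mu_u
    return out


def profile_sharpness(
    img: np.ndarray,
    center: Tuple[float, float],
    inner_radius_vox: float,
    outer_radius_vox: float,
    axis: int = 0,
    band: int = 1,
) -> float:
    """Peak-to-trough ratio of a line profile through the myocardial ring.

    The profile runs through ``center`` along ``axis`` (default the FH
    axis, where respiratory blur acts), averaged over ``2*band+1``
    parallel lines to suppress reconstruction noise.  The peak is the
    maximum over each wall crossing; the trough is the mean of the
    central blood-pool section.  Sharper (less motion-blurred)
    reconstructions give larger ratios.
    """
    c0, c1 = int(round(center[0])), int(round(center[1]))
    if axis == 0:
        prof = img[:, c1 - band : c1 + band + 1].mean(axis=1)
        c = c0
    else:
        prof = img[c0 - band : c0 + band + 1, :].mean(axis=0)
        c = c1
    ri, ro = int(np.floor(inner_radius_vox)), int(np.ceil(outer_radius_vox))
    low = prof[c - ro : c - ri + 1]
    high = prof[c + ri : c + ro + 1]
    pool = prof[c - (ri - 2) : c + (ri - 2) + 1]
    peak = 0.5 * (low.max() + high.max())
    trough = float(pool.mean())
    if trough <= 0:
        raise ValueError("non-positive trough; profile outside the object?")
    return float(peak / trough)
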