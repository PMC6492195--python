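"""Simulated dual-phase CMRA acquisition.

Each heartbeat acquires one interleaf of a golden-step Cartesian spiral
phase-encode order twice — once in the mid-systolic and once in the
mid-diastolic quiescent window — preceded by a low-resolution 2D image
navigator (iNAV) per phase.  The simulator applies the instantaneous
ground-truth deformation to the phantom, weights by the coil
sensitivities, takes the centered DFT and samples the interleaf's
phase-encode points, adding complex Gaussian noise.

The 2D grid plays the role of the two phase-encode axes of the 3D
sequence (the frequency-encode axis is not simulated); a "k-space line"
here is a single phase-encode point.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Optional, Tuple

import numpy as np

from .core import ImageVolume, cfft, icfft, pullback_warp, rng_from_seed
from .phantom import CardiacTimeline, DynamicPhantom, RespTrace

GOLDEN_ANGLE = 2.0 * np.pi * (1.0 - 2.0 / (1.0 + np.sqrt(5.0)))  # ~222.49 deg

PHASES = ("systole", "diastole")


def lines_per_heartbeat(window_ms: float, tr_ms: float) -> int:
    """Number of k-space lines that fit in one acquisition window per phase."""
    if window_ms <= 0 or tr_ms <= 0:
        raise ValueError("window and TR must be positive")
    return int(window_ms // tr_ms)


@dataclass
class SamplingPattern:
    """Ordered phase-encode samples tagged with acquisition metadata.

    ``coords`` are centered integer k-space indices (k in
    ``[-n//2, n//2)`` per axis).  Before scheduling, ``beat`` equals the
    interleaf index and times/phases are unset; after
    :func:`schedule_dual_phase` every entry carries its heartbeat,
    cardiac phase and acquisition time, and :func:`resp_motion.compute_bins`
    later adds the respiratory-bin tag.
    """

    grid_shape: Tuple[int, int]
    coords: np.ndarray  # (n, 2) int
    interleaf: np.ndarray  # (n,) int
    beat: Optional[np.ndarray] = None  # (n,) int
    phase: Optional[np.ndarray] = None  # (n,) int index into PHASES
    time: Optional[np.ndarray] = None  # (n,) s

    @property
    def n_interleaves(self) -> int:
        return int(self.interleaf.max()) + 1

    @property
    def n_samples(self) -> int:
        return len(self.coords)

    def flat_index(self) -> np.ndarray:
        """Row-major index of each coordinate into the fftshifted k-space grid."""
        n0, n1 = self.grid_shape
        i0 = self.coords[:, 0] + n0 // 2
        i1 = self.coords[:, 1] + n1 // 2
        return i0 * n1 + i1

    def interleaf_azimuths(self) -> np.ndarray:
        """Circular-mean azimuth of each interleaf's coordinates (rad)."""
        az = np.empty(self.n_interleaves)
        theta = np.arctan2(self.coords[:, 1], self.coords[:, 0])
        for k in range(self.n_interleaves):
            th = theta[self.interleaf == k]
            az[k] = np.angle(np.exp(1j * th).mean())
        return az


def golden_step_spiral_order(
    pe_grid_shape: Tuple[int, int], lines_per_interleaf: int, twist: float = 0.0
) -> SamplingPattern:
    """Partition the Cartesian phase-encode grid into golden-step spiral arms.

    Arm center azimuths follow the golden-angle sequence (successive
    interleaf azimuths advance by ~222.5 deg); each grid point joins the
    angularly nearest arm (optionally after a radius-proportional twist of
    ``twist`` radians from center to edge, curving the arms) and arms
    are read center-out.  The union of all interleaves covers
    the grid exactly once.  Interleaf sizes vary around
    ``lines_per_interleaf`` — the wedges around the non-uniformly spaced
    golden centers cut the discrete grid unevenly, much as the actual
    sequence acquires a variable number of lines per heartbeat.
    """
    n0, n1 = pe_grid_shape
    if n0 < 4 or n1 < 4:
        raise ValueError("phase-encode grid must be at least 4x4")
    n_pts = n0 * n1
    if lines_per_interleaf > n_pts:
        raise ValueError("lines_per_interleaf exceeds the phase-encode grid size")
    if lines_per_interleaf < 1:
        raise ValueError("lines_per_interleaf must be >= 1")
    n_arms = int(np.ceil(n_pts / lines_per_interleaf))

    k0, k1 = np.meshgrid(
        np.arange(n0) - n0 // 2, np.arange(n1) - n1 // 2, indexing="ij"
    )
    coords = np.stack([k0.ravel(), k1.ravel()], axis=-1)
    theta = np.arctan2(coords[:, 1], coords[:, 0])
    radius = np.hypot(coords[:, 0], coords[:, 1])
    r_max = radius.max()
    theta_tw = theta - twist * radius / max(r_max, 1.0)

    centers = np.mod(np.arange(n_arms) * GOLDEN_ANGLE, 2.0 * np.pi)
    # angular distance of every (twisted) point azimuth to every arm center
    diff = np.abs(np.angle(np.exp(1j * (theta_tw[:, None] - centers[None, :]))))
    arm = np.argmin(diff, axis=1)
    # a center squeezed between close golden neighbours can end up with no
    # grid point; steal the angularly nearest point from a richer arm
    counts = np.bincount(arm, minlength=n_arms)
    for k in np.flatnonzero(counts == 0):
        for i in np.argsort(diff[:, k]):
            if counts[arm[i]] >= 2:
                counts[arm[i]] -= 1
                arm[i] = k
                counts[k] += 1
                break

    order = []
    interleaf = []
    for k in range(n_arms):
        sel = np.flatnonzero(arm == k)
        sel = sel[np.lexsort((theta[sel], radius[sel]))]
        order.append(sel)
        interleaf.append(np.full(len(sel), k, dtype=int))
    order = np.concatenate(order)
    return SamplingPattern(
        grid_shape=(n0, n1),
        coords=coords[order],
        interleaf=np.concatenate(interleaf),
    )


def schedule_dual_phase(
    pattern: SamplingPattern, timeline: CardiacTimeline, tr: float = 0.0037
) -> SamplingPattern:
    """Assign each interleaf to a heartbeat, acquired once per cardiac phase.

    Interleaf ``j`` is acquired at beat ``j`` in both the mid-systolic
    and the mid-diastolic window; sample times step by ``tr`` (s) within
    the window.
    """
    if pattern.n_interleaves > timeline.n_beats:
        raise ValueError(
            f"pattern needs {pattern.n_interleaves} beats, timeline has {timeline.n_beats}"
        )
    coords, inter = [], []
    beat, phase, time = [], [], []
    for ph_idx, ph in enumerate(PHASES):
        for j in range(pattern.n_interleaves):
            sel = pattern.interleaf == j
            n = int(sel.sum())
            t0 = timeline.window_start(j, ph)
            coords.append(pattern.coords[sel])
            inter.append(np.full(n, j))
            beat.append(np.full(n, j))
            phase.append(np.full(n, ph_idx))
            time.append(t0 + tr * np.arange(n))
    return SamplingPattern(
        grid_shape=pattern.grid_shape,
        coords=np.concatenate(coords),
        interleaf=np.concatenate(inter),
        beat=np.concatenate(beat),
        phase=np.concatenate(phase),
        time=np.concatenate(time),
    )


@dataclass
class CoilMaps:
    """Smooth complex coil sensitivities on the phantom grid."""

    maps: np.ndarray  # (n_coils, *grid)
    spacing: Tuple[float, ...]

    @property
    def n_coils(self) -> int:
        return self.maps.shape[0]

    def rss(self) -> np.ndarray:
        return np.sqrt((np.abs(self.maps) ** 2).sum(axis=0))


def make_coil_maps(shape: Tuple[int, ...], spacing, n_coils: int = 6) -> CoilMaps:
    """Gaussian-profile sensitivities centered on a ring around the FOV.

    Deterministic layout; enough coils for SENSE conditioning at the
    per-bin undersampling the binning produces.
    """
    shape2 = shape[:2]
    c0, c1 = shape2[0] / 2.0, shape2[1] / 2.0
    rad = 0.55 * max(shape2)
    sigma = 0.55 * max(shape2)
    X0, X1 = np.meshgrid(np.arange(shape2[0]), np.arange(shape2[1]), indexing="ij")
    maps = []
    for c in range(n_coils):
        ang = 2.0 * np.pi * c / n_coils
        p0, p1 = c0 + rad * np.cos(ang), c1 + rad * np.sin(ang)
        mag = np.exp(-(((X0 - p0) ** 2 + (X1 - p1) ** 2) / (2.0 * sigma**2)))
        pha = 2.0 * np.pi * 0.05 * ((X0 - c0) * np.cos(ang) + (X1 - c1) * np.sin(ang)) / max(shape2)
        m = mag * np.exp(1j * pha)
        if len(shape) == 3:
            m = np.repeat(m[:, :, None], shape[2], axis=2)
        maps.append(m)
    return CoilMaps(maps=np.stack(maps), spacing=tuple(spacing))


@dataclass
class KSpaceData:
    """Complex samples aligned row-for-row with a scheduled pattern."""

    pattern: SamplingPattern
    data: np.ndarray  # (n_samples, n_coils)
    spacing: Tuple[float, ...]
    noise_sd: float

    @property
    def n_coils(self) -> int:
        return self.data.shape[1]


@dataclass
class INavSeries:
    """Per (heartbeat, cardiac phase) low-resolution 2D image navigators."""

    images: np.ndarray  # (n_beats, 2, n0, n1) magnitude
    times: np.ndarray  # (n_beats, 2) s
    spacing: Tuple[float, float]
    n_lines: int  # acquired phase-encode lines (resolution along axis 1)


def _inav_from(obj2d: np.ndarray, n_lines: int) -> np.ndarray:
    """Low-resolution navigator: k-space truncated to the central
    ``n_lines`` phase-encode (RL) lines, full resolution along FH."""
    k = cfft(obj2d)
    n1 = obj2d.shape[1]
    keep = np.zeros(n1, dtype=bool)
    lo = n1 // 2 - n_lines // 2
    keep[lo : lo + n_lines] = True
    k[:, ~keep] = 0.0
    return np.abs(icfft(k))


def simulate_acquisition(
    phantom: DynamicPhantom,
    trace: RespTrace,
    timeline: CardiacTimeline,
    pattern: SamplingPattern,
    coils: CoilMaps,
    noise_sd: float,
    seed,
    inav_lines: int = 14,
    inav_lead: float = 0.02,
) -> Tuple[KSpaceData, INavSeries]:
    """Acquire multi-coil dual-phase k-space plus per-beat iNAVs.

    The respiratory state is sampled once per interleaf (at its mean
    sample time); the cardiac state is the phase's quiescent reference
    volume.  iNAVs image the same deformed object ``inav_lead`` seconds
    before each window with a single uniform-sensitivity channel.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if pattern.time is None:
        raise ValueError("pattern must be scheduled (schedule_dual_phase)")
    if coils.maps.shape[1:] != phantom.config.shape:
        raise ValueError("coil maps and phantom grids differ")
    if len(phantom.config.shape) != 2:
        raise ValueError("the acquisition simulator runs on the 2D phantom")
    if pattern.grid_shape != phantom.config.shape:
        raise ValueError("sampling pattern grid and phantom grid differ")
    rng = rng_from_seed(seed)
    n_beats = pattern.n_interleaves
    data = np.empty((pattern.n_samples, coils.n_coils), dtype=complex)
    inavs = np.empty((n_beats, 2) + phantom.config.shape[:2])
    inav_times = np.empty((n_beats, 2))
    flat = pattern.flat_index()
    for ph_idx, ph in enumerate(PHASES):
        for j in range(n_beats):
            sel = (pattern.beat == j) & (pattern.phase == ph_idx)
            if not np.any(sel):
                continue
            t = float(pattern.time[sel].mean())
            fh, rl = trace.at(t)
            if fh == 0.0 and rl == 0.0:
                obj = phantom.mr[ph].data
            else:
                obj = pullback_warp(
                    phantom.mr[ph].data, phantom.resp_field(float(fh), float(rl))
                )
            for c in range(coils.n_coils):
                k = cfft(coils.maps[c] * obj)
                data[sel, c] = k.ravel()[flat[sel]]
            t_nav = timeline.window_start(j, ph) - inav_lead
            fh_n, rl_n = trace.at(t_nav)
            if fh_n == 0.0 and rl_n == 0.0:
                obj_n = phantom.mr[ph].data
            else:
                obj_n = pullback_warp(
                    phantom.mr[ph].data, phantom.resp_field(float(fh_n), float(rl_n))
                )
            obj2d = obj_n if obj_n.ndim == 2 else obj_n[:, :, obj_n.shape[2] // 2]
            inavs[j, ph_idx] = _inav_from(obj2d, inav_lines)
            inav_times[j, ph_idx] = t_nav
    if noise_sd > 0:
        data = data + noise_sd * (
            rng.standard_normal(data.shape) + 1j * rng.standard_normal(data.shape)
        )
    ksp = KSpaceData(
        pattern=pattern, data=data, spacing=phantom.mu_map.spacing, noise_sd=noise_sd
    )
    nav = INavSeries(
        images=inavs,
        times=inav_times,
        spacing=tuple(phantom.config.spacing[:2]),
        n_lines=inav_lines,
    )
    return ksp, nav
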