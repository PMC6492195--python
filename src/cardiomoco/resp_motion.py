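"""Pre-reconstruction respiratory processing.

Three steps run between the simulated acquisition and any image
reconstruction: (1) template tracking of the beat-to-beat 2D iNAVs to
estimate translational FH/RL heart motion, (2) equal-count respiratory
binning of the interleaves on the FH estimate with 2-SD outlier
rejection and exponential soft weights, (3) 2D translational k-space
pre-correction of every interleaf to the center of its respiratory bin
by a linear phase.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from .mr_sim import INavSeries, KSpaceData

REJECTED = -1


@dataclass
class TranslationTrace:
    """Per-interleaf (heartbeat x cardiac phase) translation estimates."""

    beat: np.ndarray  # (n,)
    phase: np.ndarray  # (n,) index into mr_sim.PHASES
    time: np.ndarray  # (n,) s
    fh_mm: np.ndarray
    rl_mm: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.beat)
        for name in ("phase", "time", "fh_mm", "rl_mm"):
            if len(getattr(self, name)) != n:
                raise ValueError("trace arrays must have equal length")
        if not (np.all(np.isfinite(self.fh_mm)) and np.all(np.isfinite(self.rl_mm))):
            raise ValueError("translation estimates must be finite")

    def __len__(self) -> int:
        return len(self.beat)

    def fh_at(self, t) -> np.ndarray:
        """Piecewise-linear interpolation of the FH estimate at time(s) t."""
        order = np.argsort(self.time)
        return np.interp(t, self.time[order], self.fh_mm[order])


@dataclass
class BinAssignment:
    """Respiratory bin labels, edges, and soft weights per interleaf."""

    n_bins: int
    edges: np.ndarray  # (n_bins + 1,) mm, end-expiration -> end-inspiration
    centers: np.ndarray  # (n_bins,) mm, median FH of members
    labels: np.ndarray  # (n,) bin index or REJECTED
    rejected: np.ndarray  # (n,) bool
    weights: np.ndarray  # (n, n_bins) in [0, 1]
    alpha: float
    accept_window: Tuple[float, float]  # mm

    def members(self, b: int) -> np.ndarray:
        return np.flatnonzero(self.labels == b)

    @property
    def reference_bin(self) -> int:
        """End-expiratory bin (smallest FH displacement)."""
        return 0


def _ncc(template: np.ndarray, patch: np.ndarray) -> float:
    t = template - template.mean()
    p = patch - patch.mean()
    denom = np.sqrt((t**2).sum() * (p**2).sum())
    if denom == 0:
        return -np.inf
    return float((t * p).sum() / denom)


def _parabolic_offset(fm1: float, f0: float, fp1: float) -> float:
    denom = fm1 - 2.0 * f0 + fp1
    if denom >= 0 or not np.isfinite(denom):  # not a proper maximum
        return 0.0
    return float(np.clip(0.5 * (fm1 - fp1) / denom, -0.5, 0.5))


def track_inav(
    inavs: INavSeries,
    template_roi: Optional[Tuple[slice, slice]] = None,
    search_frac: float = 0.15,
    subpixel: bool = True,
) -> TranslationTrace:
    """Estimate per-interleaf FH/RL translation by template matching.

    A rectangular template around the heart, taken per cardiac phase
    from the first beat's navigator of that phase (the two phases show
    different cardiac anatomy, so each is tracked against its own
    reference), is matched to every navigator by exhaustive normalized
    cross-correlation over integer shifts within ``search_frac`` of the
    navigator extent, then refined to sub-pixel precision by a parabolic
    fit of the correlation peak.  Ties in NCC are broken toward the
    smaller-magnitude shift.
    """
    imgs = inavs.images
    n_beats, n_phases, n0, n1 = imgs.shape
    if template_roi is None:
        h, w = n0 // 4, n1 // 4
        template_roi = (
            slice(n0 // 2 - h // 2, n0 // 2 + h // 2),
            slice(n1 // 2 - w // 2, n1 // 2 + w // 2),
        )
    templates = [imgs[0, p][template_roi] for p in range(n_phases)]
    for tpl in templates:
        if tpl.std() == 0:
            raise ValueError("flat (zero-variance) template: correlation undefined")
    r0, r1 = template_roi
    s0max, s1max = int(round(search_frac * n0)), int(round(search_frac * n1))
    # candidate shifts ordered by magnitude so ties resolve to the smaller
    cand = [
        (s0, s1)
        for s0 in range(-s0max, s0max + 1)
        for s1 in range(-s1max, s1max + 1)
    ]
    cand.sort(key=lambda s: (s[0] ** 2 + s[1] ** 2, abs(s[0]), abs(s[1])))

    beats, phases, times, fhs, rls = [], [], [], [], []
    for j in range(n_beats):
        for p in range(n_phases):
            img = imgs[j, p]
            template = templates[p]
            scores = {}
            best, best_s = -np.inf, (0, 0)
            for s0, s1 in cand:
                a0, b0 = r0.start + s0, r0.stop + s0
                a1, b1 = r1.start + s1, r1.stop + s1
                if a0 < 0 or a1 < 0 or b0 > n0 or b1 > n1:
                    continue
                sc = _ncc(template, img[a0:b0, a1:b1])
                scores[(s0, s1)] = sc
                if sc > best + 1e-12:
                    best, best_s = sc, (s0, s1)
            s0, s1 = best_s
            d0 = d1 = 0.0
            if subpixel:
                k0m, k0p = scores.get((s0 - 1, s1)), scores.get((s0 + 1, s1))
                if k0m is not None and k0p is not None:
                    d0 = _parabolic_offset(k0m, best, k0p)
                k1m, k1p = scores.get((s0, s1 - 1)), scores.get((s0, s1 + 1))
                if k1m is not None and k1p is not None:
                    d1 = _parabolic_offset(k1m, best, k1p)
            beats.append(j)
            phases.append(p)
            times.append(inavs.times[j, p])
            # the template was cut from the reference at its own (nonzero)
            # position; estimates are relative to the first navigator
            fhs.append((s0 + d0) * inavs.spacing[0])
            rls.append((s1 + d1) * inavs.spacing[1])
    return TranslationTrace(
        beat=np.array(beats),
        phase=np.array(phases),
        time=np.array(times),
        fh_mm=np.array(fhs),
        rl_mm=np.array(rls),
    )


def compute_bins(
    trace: TranslationTrace,
    n_bins: int,
    alpha: float = 1.0,
    reject_n_sd: float = 2.0,
) -> BinAssignment:
    """Equal-count respiratory binning with 2-SD rejection and soft weights.

    Interleaves whose FH estimate falls outside ``reject_n_sd`` standard
    deviations (population SD) of the mean are rejected outright (deep
    breaths).  Remaining interleaves are split into ``n_bins``
    equal-count quantile bins ordered end-expiration to end-inspiration;
    each bin's center is the median FH of its members.  Soft weights are
    1 inside the assigned bin and decay as ``exp(-alpha * d)`` with
    ``d`` the distance to the target bin's center in units of that
    bin's width (computed from post-rejection statistics).
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    fh = np.asarray(trace.fh_mm, dtype=float)
    n = len(fh)
    mean, sd = fh.mean(), fh.std()
    rejected = np.abs(fh - mean) > reject_n_sd * sd if sd > 0 else np.zeros(n, bool)
    accepted = np.flatnonzero(~rejected)
    if len(accepted) == 0:
        raise ValueError("all interleaves rejected")
    if len(accepted) < n_bins:
        raise ValueError("fewer accepted interleaves than bins")

    order = accepted[np.argsort(fh[accepted], kind="stable")]
    chunks = np.array_split(order, n_bins)
    labels = np.full(n, REJECTED, dtype=int)
    centers = np.empty(n_bins)
    inner_edges = np.empty(max(n_bins - 1, 0))
    for b, chunk in enumerate(chunks):
        labels[chunk] = b
        centers[b] = np.median(fh[chunk])
        if b > 0:
            inner_edges[b - 1] = 0.5 * (fh[chunks[b - 1]].max() + fh[chunk].min())
    # bin edges span the accepted data (bin widths used for the weight
    # decay); the wider 2-SD acceptance window is kept separately and is
    # what the PET gating reuses for its outer bounds
    edges = np.concatenate([[fh[accepted].min()], inner_edges, [fh[accepted].max()]])
    lo = min(mean - reject_n_sd * sd, fh[accepted].min()) if sd > 0 else fh.min()
    hi = max(mean + reject_n_sd * sd, fh[accepted].max()) if sd > 0 else fh.max()

    widths = np.maximum(np.diff(edges), 1e-9)
    dist = np.abs(fh[:, None] - centers[None, :]) / widths[None, :]
    weights = np.exp(-alpha * dist)
    own = labels >= 0
    weights[np.flatnonzero(own), labels[own]] = 1.0
    weights[rejected] = 0.0
    return BinAssignment(
        n_bins=n_bins,
        edges=edges,
        centers=centers,
        labels=labels,
        rejected=rejected,
        weights=weights,
        alpha=alpha,
        accept_window=(float(lo), float(hi)),
    )


def phase_correct(
    kspace: KSpaceData,
    trace: TranslationTrace,
    bins: BinAssignment,
    target_bin: Optional[int] = None,
) -> KSpaceData:
    """Translate every interleaf's k-space to a bin center (linear phase).

    With ``target_bin=None`` each interleaf moves to its *own* bin's
    center (the correction the motion-compensated reconstruction wants,
    where per-bin sampling operators carry the inter-bin motion).  With
    an explicit ``target_bin`` every interleaf moves to *that* bin's
    center — the correction the soft-gated reconstruction of that bin
    wants, so that all its (soft-weighted) data share one translational
    state.

    The residual shift ``delta = (fh - center, rl - 0)`` (in voxels) is
    removed by multiplying each sample by ``exp(+2i pi k . delta / N)``,
    the Fourier-shift factor that moves the image content back by
    ``-delta``; magnitudes are untouched.  Rejected interleaves are
    passed through unchanged (they carry zero weight downstream).
    """
    pat = kspace.pattern
    if pat.beat is None or pat.phase is None:
        raise ValueError("k-space pattern is not scheduled")
    key = {(int(b), int(p)): i for i, (b, p) in enumerate(zip(trace.beat, trace.phase))}
    n0, n1 = pat.grid_shape
    sp = kspace.spacing
    data = kspace.data.copy()
    # group samples by interleaf (beat, phase)
    pairs = np.stack([pat.beat, pat.phase], axis=1)
    uniq, inv = np.unique(pairs, axis=0, return_inverse=True)
    for u, (b, p) in enumerate(uniq):
        ti = key.get((int(b), int(p)))
        if ti is None:
            raise ValueError(f"no translation estimate for interleaf (beat={b}, phase={p})")
        lbl = bins.labels[ti] if target_bin is None else target_bin
        if lbl == REJECTED:
            continue
        d0 = (trace.fh_mm[ti] - bins.centers[lbl]) / sp[0]
        d1 = trace.rl_mm[ti] / sp[1]
        if d0 == 0.0 and d1 == 0.0:
            continue
        sel = inv == u
        k = pat.coords[sel]
        ph = np.exp(2j * np.pi * (k[:, 0] * d0 / n0 + k[:, 1] * d1 / n1))
        data[sel] *= ph[:, None]
    return KSpaceData(
        pattern=pat, data=data, spacing=kspace.spacing, noise_sd=kspace.noise_sd
    )
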