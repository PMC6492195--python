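"""List-mode PET simulation, dual gating, OSEM and motion-compensated
aggregation.

The scanner is modelled as a 2D parallel-beam geometry whose system
matrix ``P`` is built explicitly as a sparse matrix (rotate-and-sum
with bilinear interpolation), so the back-projector is exactly the
adjoint ``P^T``.  List-mode events are drawn from a Poisson process
whose instantaneous line-of-response intensities follow the deformed
emission volume through normalization and (motion-state-dependent)
attenuation, plus uniform randoms and scatter.

Events are dual-gated — a cardiac window of one third of each R-R
interval centered on maximum contraction goes to the systolic gate, the
rest to diastole, and the respiratory bin windows are reused from the
MR binning — then each gate is reconstructed with OSEM and the gate
images are warped back to the reference (diastole, end-expiration) and
summed (post-reconstruction registration).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import scipy.sparse as sp

from .core import ImageVolume, rng_from_seed
from .phantom import CardiacTimeline, DynamicPhantom, RespTrace, cardiac_phase_weight
from .registration import MotionOperator, _interp_matrix
from .resp_motion import BinAssignment, TranslationTrace

CARDIAC_GATES = ("systole", "diastole")


@dataclass
class PETGeometry:
    """2D parallel-beam geometry; defines the system forward projector."""

    n_angles: int = 84
    n_radial: int = 96
    pixel_size: float = 1.0  # mm
    image_shape: Tuple[int, int] = (96, 96)

    def __post_init__(self) -> None:
        if self.n_angles < 8:
            raise ValueError("need at least 8 projection angles")
        self._proj: Optional[sp.csr_matrix] = None

    @property
    def n_lor(self) -> int:
        return self.n_angles * self.n_radial

    @property
    def angles(self) -> np.ndarray:
        return np.pi * np.arange(self.n_angles) / self.n_angles

    def projector(self) -> sp.csr_matrix:
        """Sparse system matrix, shape ``(n_lor, n_voxels)``.

        Row (angle a, radial r) integrates the image along the line at
        angle ``a`` through radial bin ``r`` (units: voxel path length;
        multiply line integrals by ``pixel_size`` for mm).
        """
        if self._proj is None:
            self._proj = self._build()
        return self._proj

    def _build(self) -> sp.csr_matrix:
        n0, n1 = self.image_shape
        c0, c1 = (n0 - 1) / 2.0, (n1 - 1) / 2.0
        cr = (self.n_radial - 1) / 2.0
        blocks = []
        # rotate-and-sum: for each angle, bilinearly resample the image on
        # a grid rotated by -theta and sum along the integration axis
        t = np.arange(n0) - c0  # integration axis samples
        r = np.arange(self.n_radial) - cr
        T, R = np.meshgrid(t, r, indexing="ij")
        for theta in self.angles:
            ct, st = np.cos(theta), np.sin(theta)
            # LOR at angle theta, radial offset r: points (t*u + r*v)
            # with u = (cos, sin), v = (-sin, cos)
            p0 = c0 + T * ct - R * st
            p1 = c1 + T * st + R * ct
            disp = np.stack([p0, p1], axis=-1)
            inside = (
                (p0 >= -0.5) & (p0 <= n0 - 0.5) & (p1 >= -0.5) & (p1 <= n1 - 0.5)
            )
            samp = _sampling_matrix(disp, (n0, n1), inside)
            ones = sp.csr_matrix(
                (np.ones(n0 * self.n_radial), (np.tile(np.arange(self.n_radial), n0), np.arange(n0 * self.n_radial))),
                shape=(self.n_radial, n0 * self.n_radial),
            )
            # samp rows are ordered (t, r) row-major -> index t*n_radial + r
            blocks.append((ones @ samp).tocsr())
        return sp.vstack(blocks).tocsr()


def _sampling_matrix(pos: np.ndarray, shape: Tuple[int, int], valid: np.ndarray) -> sp.csr_matrix:
    """Bilinear sampling matrix at arbitrary positions (invalid rows zero)."""
    n0, n1 = shape
    npos = pos.reshape(-1, 2)
    nval = valid.ravel()
    m = len(npos)
    p = npos.copy()
    p[:, 0] = np.clip(p[:, 0], 0, n0 - 1)
    p[:, 1] = np.clip(p[:, 1], 0, n1 - 1)
    b0 = np.minimum(np.floor(p[:, 0]).astype(int), n0 - 2)
    b1 = np.minimum(np.floor(p[:, 1]).astype(int), n1 - 2)
    f0 = p[:, 0] - b0
    f1 = p[:, 1] - b1
    rows, cols, vals = [], [], []
    for o0 in (0, 1):
        for o1 in (0, 1):
            w = (f0 if o0 else 1 - f0) * (f1 if o1 else 1 - f1)
            w = np.where(nval, w, 0.0)
            keep = w > 0
            rows.append(np.flatnonzero(keep))
            cols.append((b0 + o0)[keep] * n1 + (b1 + o1)[keep])
            vals.append(w[keep])
    return sp.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(m, n0 * n1),
    ).tocsr()


def make_normalization(geom: PETGeometry) -> np.ndarray:
    """Smooth per-LOR detection efficiencies in [0.8, 1.0]."""
    a = np.arange(geom.n_angles)[:, None] / geom.n_angles
    r = np.arange(geom.n_radial)[None, :] / geom.n_radial
    s = 0.5 + 0.25 * np.sin(2 * np.pi * a) + 0.25 * np.cos(2 * np.pi * r)
    return (0.8 + 0.2 * s).ravel()


def attenuation_factors(mu_map: ImageVolume, geom: PETGeometry) -> np.ndarray:
    """Survival probabilities ``exp(-integral mu)`` per LOR, in (0, 1]."""
    mu = mu_map.data
    if np.any(mu < 0):
        raise ValueError("attenuation map must be non-negative")
    line = geom.projector() @ mu.ravel()
    return np.exp(-line * geom.pixel_size)


@dataclass
class ListModeEvents:
    """Timestamped coincidence events on LOR indices."""

    t: np.ndarray  # s
    lor: np.ndarray  # flat (angle * n_radial + radial) index
    geom: PETGeometry
    randoms_rate: float  # expected randoms per LOR per s
    scatter_rate: float  # expected scatter per LOR per s

    def __len__(self) -> int:
        return len(self.t)


def simulate_listmode(
    phantom: DynamicPhantom,
    trace: RespTrace,
    timeline: CardiacTimeline,
    geom: PETGeometry,
    mean_counts: float,
    randoms_fraction: float = 0.1,
    scatter_fraction: float = 0.1,
    seed=None,
    n_substeps: int = 8,
) -> ListModeEvents:
    """Poisson list-mode events over the MR scan interval.

    Each R-R interval is cut into ``n_substeps`` time steps; within a
    step the emission volume is deformed to the instantaneous cardiac
    and respiratory state, forward projected, attenuated by the equally
    deformed attenuation map and scaled so the expected total
    (trues + randoms + scatter) equals ``mean_counts``.
    """
    if mean_counts <= 0:
        raise ValueError("mean_counts must be positive")
    if len(phantom.config.shape) != 2:
        raise ValueError("the list-mode simulator runs on the 2D phantom")
    rng = rng_from_seed(seed)
    P = geom.projector()
    N = make_normalization(geom)
    t_start, t_end = float(timeline.triggers[0]), timeline.scan_end
    duration = t_end - t_start

    steps: List[Tuple[float, float]] = []
    for j in range(timeline.n_beats):
        edges = timeline.triggers[j] + timeline.rr[j] * np.linspace(0, 1, n_substeps + 1)
        steps.extend(zip(edges[:-1], edges[1:]))

    def step_intensity(t_mid: float) -> np.ndarray:
        w = float(cardiac_phase_weight(t_mid, timeline)[0])
        fh, rl = trace.at(t_mid)
        em = phantom.state_volume("emission", w, float(fh), float(rl))
        mu = phantom.state_volume("mu", w, float(fh), float(rl))
        att = np.exp(-(P @ mu.ravel()) * geom.pixel_size)
        return N * att * (P @ em.ravel())

    # first pass: unnormalized expected trues
    totals = np.empty(len(steps))
    for i, (a, b) in enumerate(steps):
        lam = step_intensity(0.5 * (a + b))
        totals[i] = lam.sum() * (b - a)
    trues_frac = 1.0 - randoms_fraction - scatter_fraction
    if trues_frac <= 0:
        raise ValueError("randoms and scatter fractions must sum to < 1")
    scale = mean_counts * trues_frac / totals.sum() if totals.sum() > 0 else 0.0
    r_rate = mean_counts * randoms_fraction / (geom.n_lor * duration)
    s_rate = mean_counts * scatter_fraction / (geom.n_lor * duration)

    # second pass: draw events
    ts, lors = [], []
    for a, b in steps:
        dt = b - a
        lam = step_intensity(0.5 * (a + b)) * scale * dt + (r_rate + s_rate) * dt
        counts = rng.poisson(lam)
        nz = np.flatnonzero(counts)
        for idx in nz:
            k = counts[idx]
            ts.append(a + dt * rng.random(k))
            lors.append(np.full(k, idx))
    if ts:
        t_all = np.concatenate(ts)
        lor_all = np.concatenate(lors)
        order = np.argsort(t_all)
        t_all, lor_all = t_all[order], lor_all[order]
    else:
        t_all = np.empty(0)
        lor_all = np.empty(0, dtype=int)
    return ListModeEvents(
        t=t_all, lor=lor_all, geom=geom, randoms_rate=r_rate, scatter_rate=s_rate
    )


@dataclass
class GatedPETData:
    """Dual-gated sinogram counts with per-gate correction factors."""

    y: np.ndarray  # (n_bins, 2, n_lor) counts
    durations: np.ndarray  # (n_bins, 2) s of exposure per gate
    n_discarded: int
    geom: PETGeometry
    normalization: np.ndarray  # (n_lor,)
    randoms: np.ndarray  # (n_lor,) expected counts per gate-second basis: rate
    scatter: np.ndarray
    attenuation: Optional[np.ndarray] = None  # (n_bins, 2, n_lor), filled later

    @property
    def n_bins(self) -> int:
        return self.y.shape[0]

    def gate_counts(self) -> np.ndarray:
        return self.y.sum(axis=2)


def assign_gates(
    t: np.ndarray,
    timeline: CardiacTimeline,
    bins: BinAssignment,
    trace: TranslationTrace,
) -> Tuple[np.ndarray, np.ndarray]:
    """Cardiac gate (0=systole, 1=diastole, -1=discard) and respiratory
    bin (-1=discard) for each timestamp.

    The systolic gate is the window of R-R/3 centered on each beat's
    maximum-contraction time; the respiratory bin is looked up from the
    interpolated iNAV FH value against the MR bin edges (values outside
    the 2-SD acceptance window are discarded).
    """
    t = np.asarray(t, dtype=float)
    inside = (t >= timeline.triggers[0]) & (t < timeline.scan_end)
    beat = np.clip(
        np.searchsorted(timeline.triggers, t, side="right") - 1, 0, timeline.n_beats - 1
    )
    t_mc = timeline.max_contraction[beat]
    half = timeline.rr[beat] / 6.0
    cardiac = np.where(np.abs(t - t_mc) <= half, 0, 1)
    cardiac = np.where(inside, cardiac, -1)

    fh = trace.fh_at(t)
    # inner bin edges partition the acceptance window (the same windows
    # the CMRA binning used); FH values beyond the 2-SD window discard
    lo, hi = bins.accept_window
    inner = bins.edges[1:-1]
    rbin = np.clip(np.searchsorted(inner, fh, side="right"), 0, bins.n_bins - 1)
    rbin = np.where((fh >= lo) & (fh <= hi), rbin, -1)
    rbin = np.where(inside, rbin, -1)
    return cardiac, rbin


def dual_gate(
    events: ListModeEvents,
    timeline: CardiacTimeline,
    bins: BinAssignment,
    trace: TranslationTrace,
    duration_dt: float = 0.01,
) -> GatedPETData:
    """Histogram accepted events into (respiratory bin, cardiac phase) gates."""
    if len(events) and (
        events.t.max() < timeline.triggers[0] or events.t.min() >= timeline.scan_end
    ):
        raise ValueError("event stream and cardiac timeline do not overlap in time")
    cardiac, rbin = assign_gates(events.t, timeline, bins, trace)
    ok = (cardiac >= 0) & (rbin >= 0)
    y = np.zeros((bins.n_bins, 2, events.geom.n_lor), dtype=np.int64)
    np.add.at(y, (rbin[ok], cardiac[ok], events.lor[ok]), 1)

    # per-gate exposure time by fine time sampling of the same rules
    tt = np.arange(timeline.triggers[0], timeline.scan_end, duration_dt)
    c2, r2 = assign_gates(tt, timeline, bins, trace)
    durations = np.zeros((bins.n_bins, 2))
    ok2 = (c2 >= 0) & (r2 >= 0)
    np.add.at(durations, (r2[ok2], c2[ok2]), duration_dt)

    return GatedPETData(
        y=y,
        durations=durations,
        n_discarded=int((~ok).sum()),
        geom=events.geom,
        normalization=make_normalization(events.geom),
        randoms=np.full(events.geom.n_lor, events.randoms_rate),
        scatter=np.full(events.geom.n_lor, events.scatter_rate),
    )


def warp_mumap(
    mu_map: ImageVolume,
    resp_op: Optional[MotionOperator],
    cardiac_op: Optional[MotionOperator],
    gate: Tuple[int, str],
) -> ImageVolume:
    """Deform the static reference attenuation map to a gate's motion state.

    The map (diastole, end-expiration) is warped by the cardiac
    diastole-to-systole operator for systolic gates, then by the
    respiratory reference-to-bin operator.  Non-negativity is preserved
    (convex interpolation weights).
    """
    b, c = gate
    out = mu_map
    if c == "systole":
        if cardiac_op is None:
            raise ValueError("systolic gate requested but no cardiac operator given")
        out = ImageVolume(cardiac_op.apply(out.data), out.spacing)
    if resp_op is not None:
        out = ImageVolume(resp_op.apply(out.data), out.spacing)
    return out


def poisson_loglik(y: np.ndarray, ybar: np.ndarray) -> float:
    """Poisson log-likelihood up to the y! constant (0 log 0 = 0)."""
    ybar = np.maximum(ybar, 1e-30)
    return float((y * np.log(ybar) - ybar).sum())


def osem(
    y: np.ndarray,
    geom: PETGeometry,
    normalization: np.ndarray,
    attenuation: np.ndarray,
    randoms: np.ndarray,
    scatter: np.ndarray,
    n_iter: int = 3,
    n_subsets: int = 21,
    init: Optional[np.ndarray] = None,
) -> ImageVolume:
    """Ordered-subsets EM with the standard multiplicative update.

    Per subset: ``rho <- rho / (P^T A^T N^T 1) * P^T A^T N^T
    [y / (N A P rho + r + s)]`` restricted to the subset's angles.
    Subsets are angle-interleaved (subset k takes angles k, k+n_subsets,
    ...).  Voxels with zero sensitivity are frozen (multiplier 1).
    """
    if np.any(y < 0) or np.any(randoms < 0) or np.any(scatter < 0):
        raise ValueError("counts and additive terms must be non-negative")
    if geom.n_angles % n_subsets != 0:
        raise ValueError("n_subsets must divide the number of angles")
    P = geom.projector()
    na = normalization * attenuation
    rho = (
        np.full(np.prod(geom.image_shape), 1.0)
        if init is None
        else np.asarray(init, dtype=float).ravel().copy()
    )
    if np.any(rho <= 0):
        raise ValueError("initial image must be positive")
    lor_angle = np.repeat(np.arange(geom.n_angles), geom.n_radial)
    for _ in range(n_iter):
        for k in range(n_subsets):
            sel = np.flatnonzero(lor_angle % n_subsets == k)
            Ps = P[sel]
            nas = na[sel]
            sens = Ps.T @ nas
            ybar = nas * (Ps @ rho) + randoms[sel] + scatter[sel]
            ratio = np.divide(
                y[sel], ybar, out=np.zeros_like(ybar), where=ybar > 0
            )
            back = Ps.T @ (nas * ratio)
            mult = np.divide(back, sens, out=np.ones_like(back), where=sens > 0)
            rho = rho * mult
    return ImageVolume(rho.reshape(geom.image_shape), (geom.pixel_size,) * 2)


def prr_aggregate(
    gate_images: Dict[Tuple[int, str], ImageVolume],
    resp_ops: Dict[str, Dict[int, MotionOperator]],
    cardiac_op: Optional[MotionOperator],
) -> ImageVolume:
    """Sum all gate images after warping back to diastole/end-expiration.

    ``resp_ops`` maps cardiac phase name -> bin -> operator; each gate
    is inverse-warped by its own phase's respiratory operator, and
    systolic gates are additionally inverse-warped by the cardiac
    operator (diastole is the cardiac reference).
    """
    out = None
    for (b, c), img in gate_images.items():
        data = img.data
        op = resp_ops.get(c, {}).get(b)
        if op is not None:
            data = op.apply_inverse(data)
        if c == "systole":
            if cardiac_op is None:
                raise ValueError("systolic gate image but no cardiac operator")
            data = cardiac_op.apply_inverse(data)
        out = data if out is None else out + data
    if out is None:
        raise ValueError("no gate images to aggregate")
    return ImageVolume(out, next(iter(gate_images.values())).spacing)
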