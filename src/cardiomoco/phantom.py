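"""Dynamic numerical heart/torso phantom with ground-truth motion.

The phantom supplies everything the simulated acquisition and the
reconstruction validation need: a dual-phase (mid-systole / mid-diastole)
MR contrast volume, an FDG-like emission map, an attenuation map at the
reference state (mid-diastole, end-expiration), analytic ground-truth
deformation fields for both motion families, a pseudo-periodic
respiratory trace with occasional deep breaths, and an ECG trigger
timeline.

Anatomy (2D default, optionally extruded to thin-3D): a left ventricle
modelled as a concentric ring (myocardium around a blood pool, with two
papillary-muscle inserts), an elliptical liver, and an elliptical body
outline.  Cardiac contraction is a radial map about the LV center that
shrinks the blood pool by the contraction fraction while conserving
myocardial cross-sectional area (so the systolic wall is thicker).
Respiratory motion is translation-dominant (FH >> RL) with a smooth
diaphragm-driven compression of the inferior wall superimposed, so
non-rigid registration is genuinely required to recover it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, Optional, Tuple

import numpy as np

from .core import ImageVolume, pullback_warp, rng_from_seed

# tissue label codes in the phantom label map
LBL_AIR = 0
LBL_BODY = 1
LBL_LIVER = 2
LBL_MYO = 3
LBL_BLOOD = 4

TISSUES = ("body", "liver", "myocardium", "blood")
_LABEL_OF = {"body": LBL_BODY, "liver": LBL_LIVER, "myocardium": LBL_MYO, "blood": LBL_BLOOD}


@dataclass
class PhantomConfig:
    """Geometry, contrast, activity and motion parameters of the phantom.

    Intensities are arbitrary units; emission activities are expected
    counts per voxel per unit of the simulator's rate scale; attenuation
    values are linear attenuation coefficients in 1/mm (soft tissue at
    511 keV is about 0.0096/mm).
    """

    shape: Tuple[int, ...] = (96, 96)
    spacing: Tuple[float, ...] = (1.0, 1.0)
    # T2-prepared, fat-saturated CMRA-like contrast: bright blood,
    # suppressed myocardium.
    mr_intensity: Dict[str, float] = field(
        default_factory=lambda: {"body": 0.25, "liver": 0.5, "myocardium": 0.35, "blood": 1.0}
    )
    # FDG-like uptake at late imaging: hot myocardium, blood pool cleared
    # to near-background, moderate liver.
    emission: Dict[str, float] = field(
        default_factory=lambda: {"body": 0.1, "liver": 0.7, "myocardium": 4.0, "blood": 0.1}
    )
    mu: Dict[str, float] = field(
        default_factory=lambda: {"body": 0.0096, "liver": 0.01, "myocardium": 0.0096, "blood": 0.0096}
    )
    resp_amp_fh: float = 8.0  # mm, end-expiration to end-inspiration
    resp_amp_rl: float = 2.0  # mm
    resp_nonrigid_frac: float = 0.0  # optional FH-gradient modulation across the FOV
    # respiratory-driven non-rigid deformation of the ventricular wall:
    # abdominal pressure from the descending diaphragm compresses the
    # inferior wall on inspiration.  Peak inward radial displacement of
    # the inferior wall, as a fraction of the instantaneous FH excursion.
    resp_squeeze: float = 0.7
    contraction_fraction: float = 0.35  # blood-pool radius shrink, in [0, 1); EF ~ 58%
    deep_breath_prob: float = 0.05  # per breath
    deep_breath_mag: float = 3.0  # amplitude multiplier of a deep breath
    seed: int = 0

    # geometry in mm, relative to the grid center
    lv_center_frac: Tuple[float, float] = (0.52, 0.45)  # fraction of FOV
    lv_blood_radius: float = 11.0
    lv_epi_radius: float = 19.0
    lv_taper_radius: float = 30.0  # cardiac motion decays to zero here
    papillary_radius: float = 2.2
    papillary_offset: float = 6.0
    papillary_angles: Tuple[float, float] = (0.9, 2.6)  # radians
    liver_center_mm: Tuple[float, float] = (36.0, -12.0)  # from grid center (FH, RL)
    liver_axes_mm: Tuple[float, float] = (14.0, 22.0)
    body_axes_frac: Tuple[float, float] = (0.42, 0.40)  # fraction of FOV

    def validate(self) -> None:
        if len(self.shape) not in (2, 3):
            raise ValueError("phantom grid must be 2D or thin-3D")
        if len(self.spacing) != len(self.shape):
            raise ValueError("spacing rank must match grid rank")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("voxel spacing must be positive")
        if not (0.0 <= self.contraction_fraction < 1.0):
            raise ValueError("contraction fraction must lie in [0, 1)")
        if self.resp_amp_fh < 0 or self.resp_amp_rl < 0:
            raise ValueError("respiratory amplitudes must be >= 0")
        for name in TISSUES:
            if self.mr_intensity[name] < 0 or self.emission[name] < 0 or self.mu[name] < 0:
                raise ValueError("intensities/activities/mu must be >= 0")
        if min(self.shape[:2]) < 32:
            raise ValueError("grid too small to contain the heart model (min 32 in-plane)")


@dataclass
class RespTrace:
    """Respiratory displacement trace sampled on a regular time grid."""

    times: np.ndarray  # s
    fh: np.ndarray  # mm
    rl: np.ndarray  # mm

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.fh = np.asarray(self.fh, dtype=float)
        self.rl = np.asarray(self.rl, dtype=float)
        if not np.all(np.diff(self.times) > 0):
            raise ValueError("trace times must be strictly increasing")
        if not (np.all(np.isfinite(self.fh)) and np.all(np.isfinite(self.rl))):
            raise ValueError("trace values must be finite")

    def at(self, t) -> Tuple[np.ndarray, np.ndarray]:
        """Piecewise-linear (FH, RL) displacement at time(s) ``t`` in mm."""
        return (
            np.interp(t, self.times, self.fh),
            np.interp(t, self.times, self.rl),
        )

    def outlier_fraction(self, n_sd: float = 2.0) -> float:
        """Fraction of FH samples outside mean +/- ``n_sd`` SD of the trace."""
        m, sd = self.fh.mean(), self.fh.std()
        if sd == 0:
            return 0.0
        return float(np.mean(np.abs(self.fh - m) > n_sd * sd))


@dataclass
class CardiacTimeline:
    """ECG trigger stream with per-beat acquisition timing."""

    triggers: np.ndarray  # R-wave times, s
    rr: np.ndarray  # per-beat R-R interval, s
    systole_delay: float  # s after trigger, start of systolic window
    diastole_delay: float  # s
    window: float  # acquisition window length, s
    max_contraction: np.ndarray  # per-beat time of maximum contraction, s

    def __post_init__(self) -> None:
        self.triggers = np.asarray(self.triggers, dtype=float)
        self.rr = np.asarray(self.rr, dtype=float)
        self.max_contraction = np.asarray(self.max_contraction, dtype=float)
        if not np.all(np.diff(self.triggers) > 0):
            raise ValueError("trigger times must be strictly increasing")
        if not self.systole_delay < self.diastole_delay:
            raise ValueError("systolic delay must precede diastolic delay")
        if self.diastole_delay + self.window > self.rr.min():
            raise ValueError("acquisition window does not fit in the shortest R-R")

    @property
    def n_beats(self) -> int:
        return len(self.triggers)

    @property
    def scan_end(self) -> float:
        return float(self.triggers[-1] + self.rr[-1])

    def window_start(self, beat: int, phase: str) -> float:
        delay = self.systole_delay if phase == "systole" else self.diastole_delay
        return float(self.triggers[beat] + delay)


def _ellipse_mask(coords_mm: np.ndarray, center_mm, axes_mm) -> np.ndarray:
    d = (coords_mm[..., 0] - center_mm[0]) / axes_mm[0], (
        coords_mm[..., 1] - center_mm[1]
    ) / axes_mm[1]
    return d[0] ** 2 + d[1] ** 2 <= 1.0


class _RadialContraction:
    """Monotone radial map r_systole -> r_diastole about the LV center.

    Inside the systolic blood pool the map is uniform scaling by
    1/(1-cf); across the wall it conserves annular area (wall
    thickening); beyond the epicardium it blends smoothly to the
    identity at the taper radius.
    """

    def __init__(self, rb_d: float, re_d: float, cf: float, r_taper: float):
        self.cf = cf
        self.rb_d = rb_d
        self.rb_s = rb_d * (1.0 - cf)
        self.re_d = re_d
        self.re_s = float(np.sqrt(re_d**2 - rb_d**2 + self.rb_s**2))
        self.r_taper = r_taper
        # Dense samples of the map, with the radial *scale* (displacement
        # over radius) lightly smoothed so the field is C1 — slope kinks
        # at the pool/wall edges would otherwise defeat the bilinear
        # interpolation used when composing fields.  Smoothing the scale
        # (not the displacement) preserves the linear behaviour at r=0.
        from scipy.ndimage import gaussian_filter1d

        r = np.linspace(0.0, r_taper, 4096)
        dr = r[1] - r[0]
        rd = self._forward_analytic(r)
        scale = np.empty_like(r)
        scale[1:] = rd[1:] / r[1:] - 1.0
        scale[0] = cf / (1.0 - cf) if cf > 0 else 0.0
        scale = gaussian_filter1d(scale, sigma=1.0 / dr, mode="nearest")
        self._r_s = r
        self._r_d = r * (1.0 + scale)

    def forward(self, r_s: np.ndarray) -> np.ndarray:
        """Diastolic radius as a function of systolic radius (smoothed map)."""
        r_s = np.asarray(r_s, dtype=float)
        return np.where(r_s >= self.r_taper, r_s, np.interp(r_s, self._r_s, self._r_d))

    def _forward_analytic(self, r_s: np.ndarray) -> np.ndarray:
        r_s = np.asarray(r_s, dtype=float)
        out = np.array(r_s, dtype=float)
        if self.cf == 0:
            return out
        blood = r_s <= self.rb_s
        out[blood] = r_s[blood] / (1.0 - self.cf)
        wall = (r_s > self.rb_s) & (r_s <= self.re_s)
        out[wall] = np.sqrt(r_s[wall] ** 2 - self.rb_s**2 + self.rb_d**2)
        taper = (r_s > self.re_s) & (r_s < self.r_taper)
        if np.any(taper):
            # smoothstep blend of the epicardial offset down to zero
            u = (self.r_taper - r_s[taper]) / (self.r_taper - self.re_s)
            s = u * u * (3.0 - 2.0 * u)
            out[taper] = r_s[taper] + (self.re_d - self.re_s) * s
        return out

    def inverse(self, r_d: np.ndarray) -> np.ndarray:
        """Systolic radius as a function of diastolic radius (numeric inside the
        taper radius, identity beyond it)."""
        r_d = np.asarray(r_d, dtype=float)
        return np.where(r_d >= self.r_taper, r_d, np.interp(r_d, self._r_d, self._r_s))


@dataclass
class DynamicPhantom:
    """The generated phantom with its analytic ground-truth motion."""

    config: PhantomConfig
    mr: Dict[str, ImageVolume]  # per cardiac phase ("systole", "diastole")
    emission: Dict[str, ImageVolume]
    labels: Dict[str, np.ndarray]
    mu_map: ImageVolume  # reference state: diastole, end-expiration
    lv_center_vox: np.ndarray  # in-plane LV center, voxels

    # ------------------------------------------------------------------
    # ground-truth motion
    # ------------------------------------------------------------------
    def resp_modulation(self) -> np.ndarray:
        """Smooth spatial modulation g(x) of the FH respiratory shift.

        Respiratory displacement of the heart is diaphragm-driven: it is
        largest caudally (toward the liver/diaphragm, +FH) and decreases
        cranially.  g is a smooth FH gradient, zero at the LV center (so
        iNAV tracking of the heart reads the nominal trace), positive
        below it and negative above.
        """
        shape = self.config.shape
        sp = self.config.spacing
        x0 = (np.arange(shape[0]) - self.lv_center_vox[0]) * sp[0]
        fov0 = shape[0] * sp[0]
        g0 = np.sin(np.pi * x0 / fov0)
        g = np.broadcast_to(g0[:, None], shape[:2])
        if len(shape) == 3:
            g = np.broadcast_to(g[..., None], shape)
        return np.array(g, dtype=float)

    def resp_field(self, fh_mm: float, rl_mm: float) -> np.ndarray:
        """Ground-truth respiratory displacement field (voxels, pull-back).

        ``out(x) = ref(x + u(x))`` moves the reference anatomy *to* the
        given respiratory state, i.e. the imaged object at displacement
        (fh, rl) is ``pullback_warp(ref, resp_field(fh, rl))``.
        """
        cfg = self.config
        u = np.zeros(cfg.shape + (len(cfg.shape),), dtype=float)
        # The non-rigid parts saturate at the nominal tidal amplitude:
        # beyond it a deep breath displaces the thorax globally without
        # further internal redistribution.  This also bounds the field's
        # strain, keeping it diffeomorphic for any excursion.
        sat = cfg.resp_amp_fh if cfg.resp_amp_fh > 0 else abs(fh_mm)
        diff = np.sign(fh_mm) * min(abs(fh_mm), sat)
        # pull-back: object displaced by +d means sampling at x - d
        g = self.resp_modulation()
        u[..., 0] = -(fh_mm + cfg.resp_nonrigid_frac * g * diff) / cfg.spacing[0]
        u[..., 1] = -rl_mm / cfg.spacing[1]
        if cfg.resp_squeeze > 0:
            sq = cfg.resp_squeeze * diff * self._squeeze_profile()
            u[..., 0] += sq[..., 0] / cfg.spacing[0]
            u[..., 1] += sq[..., 1] / cfg.spacing[1]
        return u

    def _squeeze_profile(self) -> np.ndarray:
        """Unit-amplitude inward radial squeeze pattern of the LV wall.

        Radially: zero inside the blood pool (so iNAV template tracking
        sees rigid motion), rising smoothly across the wall, decaying to
        zero by the taper radius.  Angularly: maximal toward the
        diaphragm (+FH), zero at the superior wall, as diaphragm-driven
        compression is.  Cached per phantom.
        """
        if getattr(self, "_sq_cache", None) is not None:
            return self._sq_cache
        cfg = self.config
        shape2 = cfg.shape[:2]
        sp = cfg.spacing
        ax = [(np.arange(n) - c) * s for n, c, s in zip(shape2, self.lv_center_vox, sp[:2])]
        X0, X1 = np.meshgrid(ax[0], ax[1], indexing="ij")
        r = np.hypot(X0, X1)
        theta = np.arctan2(X1, X0)  # 0 along +FH (inferior)

        def smoothstep(x):
            x = np.clip(x, 0.0, 1.0)
            return x * x * (3.0 - 2.0 * x)

        # confined to the myocardial band: decays to zero within 5 mm of
        # the epicardium so the neighbouring liver moves purely with the
        # global translation
        r_in, r_full = cfg.lv_blood_radius + 1.0, cfg.lv_epi_radius
        radial = smoothstep((r - r_in) / max(r_full - r_in, 1e-6)) * (
            1.0 - smoothstep((r - r_full) / 5.0)
        )
        # angular profile with a floor: the whole wall deforms with
        # breathing, the diaphragm-facing side about 3x more than the
        # superior side
        angular = 0.3 + 0.7 * 0.5 * (1.0 + np.cos(theta))
        mag = radial * angular
        with np.errstate(invalid="ignore"):
            n0 = np.where(r > 1e-9, X0 / np.maximum(r, 1e-9), 0.0)
            n1 = np.where(r > 1e-9, X1 / np.maximum(r, 1e-9), 0.0)
        # inward compression of the object; the caller's sign gives the
        # matching pull-back field
        sq = np.stack([mag * n0, mag * n1], axis=-1)
        if len(cfg.shape) == 3:
            sq = np.repeat(sq[:, :, None, :], cfg.shape[2], axis=2)
        self._sq_cache = sq
        return sq

    def _radial_map(self) -> _RadialContraction:
        cfg = self.config
        return _RadialContraction(
            cfg.lv_blood_radius, cfg.lv_epi_radius, cfg.contraction_fraction, cfg.lv_taper_radius
        )

    def _radial_field(self, map_fn: Callable[[np.ndarray], np.ndarray]) -> np.ndarray:
        cfg = self.config
        shape = cfg.shape
        sp = cfg.spacing
        ax = [(np.arange(n) - c) * s for n, c, s in zip(shape[:2], self.lv_center_vox, sp[:2])]
        X0, X1 = np.meshgrid(ax[0], ax[1], indexing="ij")
        r = np.hypot(X0, X1)
        with np.errstate(divide="ignore", invalid="ignore"):
            scale = np.where(r > 1e-9, map_fn(r) / np.maximum(r, 1e-9) - 1.0, 0.0)
        u = np.zeros(shape + (len(shape),), dtype=float)
        u2 = np.stack([scale * X0 / sp[0], scale * X1 / sp[1]], axis=-1)
        if len(shape) == 3:
            u[..., :2] = u2[:, :, None, :]
        else:
            u[..., :2] = u2
        return u

    def cardiac_field(self) -> np.ndarray:
        """Pull-back field turning the diastolic volume into the systolic one.

        ``pullback_warp(diastole, cardiac_field()) ~= systole``.
        """
        return self._radial_field(self._radial_map().forward)

    def cardiac_field_inverse(self) -> np.ndarray:
        """Pull-back field turning the systolic volume into the diastolic one."""
        return self._radial_field(self._radial_map().inverse)

    def total_field(self, phase_weight: float, fh_mm: float, rl_mm: float) -> np.ndarray:
        """Composite pull-back field for a partially contracted, displaced state.

        ``phase_weight`` is 0 at mid-diastole and 1 at maximum
        contraction; the cardiac field is scaled linearly in between.
        Composition order matches :meth:`state_volume`.
        """
        uc = phase_weight * self.cardiac_field()
        ur = self.resp_field(fh_mm, rl_mm)
        # compose pull-backs: x -> x + ur(x) -> + uc(x + ur(x))
        comp = ur.copy()
        for a in range(uc.shape[-1]):
            comp[..., a] += pullback_warp(uc[..., a], ur, mode="nearest")
        return comp

    def state_volume(
        self, which: str, phase_weight: float, fh_mm: float, rl_mm: float
    ) -> np.ndarray:
        """Instantaneous volume (``which`` in {mr, emission, mu}) at a motion state."""
        if which == "mu":
            base = self.mu_map.data
        elif which == "mr":
            base = self.mr["diastole"].data
        elif which == "emission":
            base = self.emission["diastole"].data
        else:
            raise ValueError(f"unknown volume kind {which!r}")
        if phase_weight != 0.0:
            base = pullback_warp(base, phase_weight * self.cardiac_field())
        if fh_mm != 0.0 or rl_mm != 0.0:
            base = pullback_warp(base, self.resp_field(fh_mm, rl_mm))
        return base

    def lv_blood_mask(self, phase: str) -> np.ndarray:
        return self.labels[phase] == LBL_BLOOD

    def lv_myo_mask(self, phase: str) -> np.ndarray:
        return self.labels[phase] == LBL_MYO


def _paint(cfg: PhantomConfig, contracted: bool) -> np.ndarray:
    """Rasterize the tissue label map for one cardiac phase (in-plane)."""
    shape2 = cfg.shape[:2]
    sp = cfg.spacing[:2]
    center = np.array([f * n for f, n in zip(cfg.lv_center_frac, shape2)])
    grid_c = np.array([n / 2.0 for n in shape2])
    ax = [np.arange(n) * s for n, s in zip(shape2, sp)]
    X0, X1 = np.meshgrid(ax[0], ax[1], indexing="ij")
    coords = np.stack([X0, X1], axis=-1)

    cf = cfg.contraction_fraction if contracted else 0.0
    rb = cfg.lv_blood_radius * (1.0 - cf)
    re = float(np.sqrt(cfg.lv_epi_radius**2 - cfg.lv_blood_radius**2 + rb**2))

    lbl = np.zeros(shape2, dtype=np.int8)
    body_c = grid_c * sp
    body_ax = (cfg.body_axes_frac[0] * shape2[0] * sp[0], cfg.body_axes_frac[1] * shape2[1] * sp[1])
    lbl[_ellipse_mask(coords, body_c, body_ax)] = LBL_BODY
    liver_c = (body_c[0] + cfg.liver_center_mm[0], body_c[1] + cfg.liver_center_mm[1])
    lbl[_ellipse_mask(coords, liver_c, cfg.liver_axes_mm)] = LBL_LIVER

    lv_c = center * sp
    r = np.hypot(coords[..., 0] - lv_c[0], coords[..., 1] - lv_c[1])
    lbl[r <= re] = LBL_MYO
    lbl[r <= rb] = LBL_BLOOD
    # papillary-muscle inserts ride with the blood-pool scaling
    for ang in cfg.papillary_angles:
        pc = (
            lv_c[0] + cfg.papillary_offset * (1.0 - cf) * np.cos(ang),
            lv_c[1] + cfg.papillary_offset * (1.0 - cf) * np.sin(ang),
        )
        pr = np.hypot(coords[..., 0] - pc[0], coords[..., 1] - pc[1])
        lbl[pr <= cfg.papillary_radius * (1.0 - cf)] = LBL_MYO
    return lbl


def _lift_3d(lbl2: np.ndarray, cfg: PhantomConfig) -> np.ndarray:
    """Extrude the in-plane label map along the long axis with an apical taper."""
    nz = cfg.shape[2]
    out = np.zeros(cfg.shape, dtype=np.int8)
    center = np.array([f * n for f, n in zip(cfg.lv_center_frac, cfg.shape[:2])])
    sp = cfg.spacing
    ax = [np.arange(n) * s for n, s in zip(cfg.shape[:2], sp[:2])]
    X0, X1 = np.meshgrid(ax[0], ax[1], indexing="ij")
    lv_c = center * sp[:2]
    r = np.hypot(X0 - lv_c[0], X1 - lv_c[1])
    for k in range(nz):
        z = k / max(nz - 1, 1)  # 0 = apex, 1 = base
        sl = lbl2.copy()
        # LV radius tapers toward the apex; outside the taper keep body tissue
        shrink = 0.35 + 0.65 * np.sqrt(max(z, 1e-3))
        heart = (sl == LBL_MYO) | (sl == LBL_BLOOD)
        rim = heart & (r > shrink * cfg.lv_epi_radius)
        sl[rim] = LBL_BODY
        blood_rim = (sl == LBL_BLOOD) & (r > shrink * cfg.lv_blood_radius)
        sl[blood_rim] = LBL_MYO
        if z < 0.12:  # apical cap is solid myocardium
            sl[sl == LBL_BLOOD] = LBL_MYO
        out[:, :, k] = sl
    return out


def _fill(lbl: np.ndarray, values: Dict[str, float]) -> np.ndarray:
    out = np.zeros(lbl.shape, dtype=float)
    for name, code in _LABEL_OF.items():
        out[lbl == code] = values[name]
    return out


def make_phantom(config: PhantomConfig) -> DynamicPhantom:
    """Build the dual-phase phantom and its ground-truth motion model."""
    config.validate()
    labels = {}
    for phase, contracted in (("diastole", False), ("systole", True)):
        lbl = _paint(config, contracted)
        if len(config.shape) == 3:
            lbl = _lift_3d(lbl, config)
        labels[phase] = lbl
    mr = {
        p: ImageVolume(_fill(labels[p], config.mr_intensity), config.spacing) for p in labels
    }
    emission = {
        p: ImageVolume(_fill(labels[p], config.emission), config.spacing) for p in labels
    }
    mu = ImageVolume(_fill(labels["diastole"], config.mu), config.spacing)
    center = np.array([f * n for f, n in zip(config.lv_center_frac, config.shape[:2])])
    return DynamicPhantom(
        config=config,
        mr=mr,
        emission=emission,
        labels=labels,
        mu_map=mu,
        lv_center_vox=center,
    )


def make_resp_trace(
    config: PhantomConfig, duration: float, seed, dt: float = 0.05, start_pause: float = 1.2
) -> RespTrace:
    """Pseudo-periodic respiratory trace with occasional deep breaths.

    Breaths have a 3-5 s period and ~15% beat-to-beat amplitude
    variability; with probability ``deep_breath_prob`` a breath is
    ``deep_breath_mag`` times deeper, producing the outliers the 2-SD
    rejection step exists for.  The trace starts with a short
    end-expiratory pause so the first heartbeat is acquired near the
    reference respiratory position.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    rng = rng_from_seed(seed)
    t = np.arange(0.0, duration + dt, dt)
    fh = np.zeros_like(t)
    t0 = start_pause
    while t0 < duration:
        period = rng.uniform(3.0, 5.0)
        amp = config.resp_amp_fh * max(0.0, 1.0 + 0.15 * rng.standard_normal())
        if rng.uniform() < config.deep_breath_prob:
            amp *= config.deep_breath_mag
        sel = (t >= t0) & (t < t0 + period)
        tau = (t[sel] - t0) / period
        fh[sel] = amp * np.sin(np.pi * tau) ** 3
        t0 += period
    rl = (config.resp_amp_rl / max(config.resp_amp_fh, 1e-12)) * fh if config.resp_amp_fh > 0 else np.zeros_like(fh)
    return RespTrace(times=t, fh=fh, rl=rl)


def make_cardiac_timeline(
    rr_mean: float,
    rr_jitter: float,
    n_beats: int,
    seed,
    systole_delay: float = 0.30,
    diastole_delay: float = 0.65,
    window: float = 0.104,
    max_contraction_frac: float = 0.35,
) -> CardiacTimeline:
    """ECG trigger stream with per-beat timing (all times in seconds).

    Maximum contraction is placed at ``max_contraction_frac`` of each
    R-R interval after the trigger (configurable; mid-systolic and
    mid-diastolic delays default to 300 and 650 ms).
    """
    rng = rng_from_seed(seed)
    rr = rr_mean + rr_jitter * rng.standard_normal(n_beats)
    rr = np.clip(rr, 0.5 * rr_mean, 1.5 * rr_mean)
    if diastole_delay + window > rr.min():
        raise ValueError("acquisition window does not fit in the shortest simulated R-R")
    triggers = np.concatenate([[0.0], np.cumsum(rr[:-1])])
    return CardiacTimeline(
        triggers=triggers,
        rr=rr,
        systole_delay=systole_delay,
        diastole_delay=diastole_delay,
        window=window,
        max_contraction=triggers + max_contraction_frac * rr,
    )


def cardiac_phase_weight(t, timeline: CardiacTimeline) -> np.ndarray:
    """Continuous contraction weight in [0, 1] at time(s) ``t``.

    A raised-cosine bump centered on each beat's maximum-contraction
    time with half-width R-R/4: 1 at maximum contraction, 0 through
    diastole.  Used by the PET list-mode simulator; the MR acquisition
    windows sit at the quiescent mid-systolic (weight ~ peak) and
    mid-diastolic (weight ~ 0) phases.
    """
    t = np.atleast_1d(np.asarray(t, dtype=float))
    idx = np.clip(np.searchsorted(timeline.triggers, t, side="right") - 1, 0, timeline.n_beats - 1)
    tm = timeline.max_contraction[idx]
    hw = timeline.rr[idx] / 4.0
    x = np.clip(np.abs(t - tm) / hw, 0.0, 1.0)
    return 0.5 * (1.0 + np.cos(np.pi * x))
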