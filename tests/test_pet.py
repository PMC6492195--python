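"""PET projector, list-mode simulation, dual gating, OSEM and PRR."""

import numpy as np
import pytest
from scipy import stats

from cardiomoco.core import ImageVolume
from cardiomoco.pet import (
    ListModeEvents,
    PETGeometry,
    assign_gates,
    attenuation_factors,
    dual_gate,
    make_normalization,
    osem,
    poisson_loglik,
    prr_aggregate,
    simulate_listmode,
    warp_mumap,
)
from cardiomoco.phantom import (
    PhantomConfig,
    make_cardiac_timeline,
    make_phantom,
    make_resp_trace,
)
from cardiomoco.registration import DeformationField, MotionOperator
from cardiomoco.resp_motion import TranslationTrace, compute_bins


@pytest.fixture(scope="module")
def geom():
    return PETGeometry()


@pytest.fixture(scope="module")
def disc_mu():
    X0, X1 = np.meshgrid(np.arange(96) - 47.5, np.arange(96) - 47.5, indexing="ij")
    return ImageVolume(0.01 * ((X0**2 + X1**2) <= 30**2), (1.0, 1.0))


class TestProjector:
    def test_adjoint_identity(self, geom, rng):
        P = geom.projector()
        x = rng.random(96 * 96)
        y = rng.random(geom.n_lor)
        lhs = np.dot(P @ x, y)
        rhs = np.dot(x, P.T @ y)
        assert abs(lhs - rhs) <= 1e-8 * abs(lhs)

    def test_uniform_disc_central_chord_length(self, geom, disc_mu):
        A = attenuation_factors(disc_mu, geom).reshape(geom.n_angles, geom.n_radial)
        # central LOR passes through the full 60 mm diameter
        expected = np.exp(-0.01 * 60.0)
        assert A[0, 47] == pytest.approx(expected, rel=0.01)

    def test_vacuum_gives_unity_factors(self, geom):
        A = attenuation_factors(ImageVolume(np.zeros((96, 96)), (1.0, 1.0)), geom)
        np.testing.assert_array_equal(A, 1.0)

    def test_factors_monotone_in_mu_scaling(self, geom, disc_mu):
        a1 = attenuation_factors(disc_mu, geom)
        a2 = attenuation_factors(ImageVolume(2 * disc_mu.data, (1.0, 1.0)), geom)
        assert np.all(a2 <= a1)
        assert a1.min() > 0 and a1.max() <= 1

    def test_negative_mu_rejected(self, geom):
        with pytest.raises(ValueError):
            attenuation_factors(ImageVolume(-np.ones((96, 96)), (1.0, 1.0)), geom)


@pytest.fixture(scope="module")
def short_scan():
    cfg = PhantomConfig()
    ph = make_phantom(cfg)
    tl = make_cardiac_timeline(1.0, 0.0, 40, seed=2)
    tr = make_resp_trace(cfg, tl.scan_end + 2.0, seed=3)
    return cfg, ph, tl, tr


class TestSimulateListmode:
    def test_zero_activity_gives_zero_events(self, geom, short_scan):
        cfg, ph, tl, tr = short_scan
        dark = make_phantom(cfg)
        for k in dark.emission:
            dark.emission[k] = ImageVolume(np.zeros(cfg.shape), cfg.spacing)
        ev = simulate_listmode(
            dark, tr, tl, geom, mean_counts=1e5, randoms_fraction=0.0, scatter_fraction=0.0, seed=1
        )
        assert len(ev) == 0

    def test_total_count_matches_configured_expectation(self, geom, short_scan):
        cfg, ph, tl, tr = short_scan
        mean_counts = 2e5
        ev = simulate_listmode(ph, tr, tl, geom, mean_counts=mean_counts, seed=4)
        assert abs(len(ev) - mean_counts) < 4 * np.sqrt(mean_counts)

    def test_static_histogram_matches_forward_model(self, geom):
        cfg = PhantomConfig(resp_amp_fh=0.0, resp_amp_rl=0.0, contraction_fraction=0.0)
        ph = make_phantom(cfg)
        tl = make_cardiac_timeline(1.0, 0.0, 40, seed=2)
        tr = make_resp_trace(cfg, tl.scan_end + 2.0, seed=3)
        ev = simulate_listmode(
            ph, tr, tl, geom, mean_counts=5e5, randoms_fraction=0.0, scatter_fraction=0.0, seed=5
        )
        P = geom.projector()
        lam = make_normalization(geom) * attenuation_factors(ph.mu_map, geom) * (
            P @ ph.emission["diastole"].data.ravel()
        )
        lam = lam / lam.sum() * 5e5
        counts = np.bincount(ev.lor, minlength=geom.n_lor)
        keep = lam > 5
        # chi-square goodness of fit against the projector-forward model
        chi2 = ((counts[keep] - lam[keep]) ** 2 / lam[keep]).sum()
        dof = keep.sum() - 1
        p = stats.chi2.sf(chi2, dof)
        assert p > 0.01

    def test_nonpositive_counts_rejected(self, geom, short_scan):
        cfg, ph, tl, tr = short_scan
        with pytest.raises(ValueError):
            simulate_listmode(ph, tr, tl, geom, mean_counts=0.0, seed=0)


def _uniform_events(geom, timeline, n, seed=0):
    rng = np.random.default_rng(seed)
    t = rng.uniform(timeline.triggers[0], timeline.scan_end, n)
    lor = rng.integers(0, geom.n_lor, n)
    return ListModeEvents(
        t=np.sort(t), lor=lor, geom=geom, randoms_rate=0.0, scatter_rate=0.0
    )


def _flat_trace(timeline, value=0.0):
    n = timeline.n_beats
    return TranslationTrace(
        beat=np.arange(n),
        phase=np.zeros(n, dtype=int),
        time=timeline.triggers + 0.3,
        fh_mm=np.full(n, value) + np.linspace(0, 1e-6, n),
        rl_mm=np.zeros(n),
    )


class TestDualGate:
    def test_systolic_gate_takes_one_third_of_uniform_events(self, geom):
        tl = make_cardiac_timeline(1.0, 0.0, 100, seed=0)
        ev = _uniform_events(geom, tl, 100_000, seed=1)
        trace = _flat_trace(tl)
        bins = compute_bins(trace, 1)
        gated = dual_gate(ev, tl, bins, trace)
        frac = gated.y[:, 0].sum() / gated.y.sum()
        assert abs(frac - 1.0 / 3.0) < 0.01
        # window duration is exactly R-R/3 per beat
        np.testing.assert_allclose(
            gated.durations[:, 0].sum() / tl.n_beats, 1.0 / 3.0, atol=0.02
        )

    def test_constant_trace_lands_in_single_bin(self, geom):
        tl = make_cardiac_timeline(1.0, 0.0, 50, seed=0)
        ev = _uniform_events(geom, tl, 5000, seed=2)
        n = tl.n_beats
        trace = TranslationTrace(
            beat=np.arange(n),
            phase=np.zeros(n, dtype=int),
            time=tl.triggers + 0.3,
            fh_mm=np.full(n, 3.0),
            rl_mm=np.zeros(n),
        )
        bins = compute_bins(trace, 4)
        gated = dual_gate(ev, tl, bins, trace)
        per_bin = gated.y.sum(axis=(1, 2))
        assert (per_bin > 0).sum() == 1

    def test_counts_match_per_event_brute_force_recount(self, geom, short_scan):
        cfg, ph, tl, tr = short_scan
        ev = simulate_listmode(ph, tr, tl, geom, mean_counts=5e4, seed=6)
        # realistic varying trace
        n = tl.n_beats
        trace = TranslationTrace(
            beat=np.arange(n),
            phase=np.zeros(n, dtype=int),
            time=tl.triggers + 0.3,
            fh_mm=tr.at(tl.triggers + 0.3)[0],
            rl_mm=tr.at(tl.triggers + 0.3)[1],
        )
        bins = compute_bins(trace, 3)
        gated = dual_gate(ev, tl, bins, trace)
        # brute force: loop over events, recompute gate per event
        y2 = np.zeros_like(gated.y)
        n_disc = 0
        lo, hi = bins.accept_window
        inner = bins.edges[1:-1]
        order = np.argsort(trace.time)
        for t, lor in zip(ev.t, ev.lor):
            if not (tl.triggers[0] <= t < tl.scan_end):
                n_disc += 1
                continue
            j = np.searchsorted(tl.triggers, t, side="right") - 1
            j = min(max(j, 0), tl.n_beats - 1)
            c = 0 if abs(t - tl.max_contraction[j]) <= tl.rr[j] / 6.0 else 1
            fh = np.interp(t, trace.time[order], trace.fh_mm[order])
            if not (lo <= fh <= hi):
                n_disc += 1
                continue
            b = min(int(np.searchsorted(inner, fh, side="right")), bins.n_bins - 1)
            y2[b, c, lor] += 1
        np.testing.assert_array_equal(gated.y, y2)
        assert gated.n_discarded == n_disc

    def test_every_event_in_exactly_one_gate(self, geom, short_scan):
        cfg, ph, tl, tr = short_scan
        ev = simulate_listmode(ph, tr, tl, geom, mean_counts=3e4, seed=7)
        trace = _flat_trace(tl)
        bins = compute_bins(trace, 2)
        gated = dual_gate(ev, tl, bins, trace)
        assert gated.y.sum() + gated.n_discarded == len(ev)

    def test_disjoint_event_stream_is_error(self, geom):
        tl = make_cardiac_timeline(1.0, 0.0, 10, seed=0)
        ev = ListModeEvents(
            t=np.array([100.0, 101.0]),
            lor=np.array([0, 1]),
            geom=geom,
            randoms_rate=0.0,
            scatter_rate=0.0,
        )
        trace = _flat_trace(tl)
        bins = compute_bins(trace, 1)
        with pytest.raises(ValueError):
            dual_gate(ev, tl, bins, trace)


class TestWarpMumap:
    def test_identity_fields_leave_map_bitwise(self, disc_mu):
        op = MotionOperator.identity((96, 96), (1.0, 1.0))
        out = warp_mumap(disc_mu, op, op, (0, "systole"))
        np.testing.assert_array_equal(out.data, disc_mu.data)

    def test_translation_preserves_total_attenuation(self, disc_mu):
        u = np.zeros((96, 96, 2))
        u[..., 0] = 3.0
        op = MotionOperator(DeformationField(u, (1.0, 1.0)))
        out = warp_mumap(disc_mu, op, None, (0, "diastole"))
        assert out.data.sum() == pytest.approx(disc_mu.data.sum(), rel=0.005)
        assert out.data.min() >= 0

    def test_systolic_gate_without_cardiac_operator_is_error(self, disc_mu):
        op = MotionOperator.identity((96, 96), (1.0, 1.0))
        with pytest.raises(ValueError):
            warp_mumap(disc_mu, op, None, (0, "systole"))


@pytest.fixture(scope="module")
def mlem_setup(geom):
    X0, X1 = np.meshgrid(np.arange(96) - 47.5, np.arange(96) - 47.5, indexing="ij")
    em = 2.0 * ((X0**2 + X1**2) <= 20**2) + 0.5
    mu = ImageVolume(0.0096 * ((X0**2 + X1**2) <= 40**2), (1.0, 1.0))
    N = make_normalization(geom)
    A = attenuation_factors(mu, geom)
    zero = np.zeros(geom.n_lor)
    ybar = N * A * (geom.projector() @ em.ravel())
    return geom, em, N, A, zero, ybar


class TestOSEM:
    def test_fixed_point_on_consistent_data(self, mlem_setup):
        geom, em, N, A, zero, ybar = mlem_setup
        out = osem(ybar, geom, N, A, zero, zero, n_iter=2, n_subsets=21, init=em.ravel())
        np.testing.assert_allclose(out.data, em, rtol=1e-10)

    def test_mlem_count_conservation_each_iteration(self, mlem_setup):
        geom, em, N, A, zero, ybar = mlem_setup
        y = np.random.default_rng(0).poisson(ybar).astype(float)
        rho = np.full(96 * 96, 1.0)
        P = geom.projector()
        for _ in range(3):
            rho = osem(y, geom, N, A, zero, zero, n_iter=1, n_subsets=1, init=rho).data.ravel()
            total = (N * A * (P @ rho)).sum()
            assert total == pytest.approx(y.sum(), rel=1e-6)

    @pytest.mark.parametrize("noisy", [False, True])
    def test_mlem_loglikelihood_nondecreasing(self, mlem_setup, noisy):
        geom, em, N, A, zero, ybar = mlem_setup
        y = (
            np.random.default_rng(1).poisson(ybar).astype(float)
            if noisy
            else ybar.copy()
        )
        P = geom.projector()
        rho = np.full(96 * 96, 1.0)
        lls = []
        for _ in range(20):
            rho = osem(y, geom, N, A, zero, zero, n_iter=1, n_subsets=1, init=rho).data.ravel()
            lls.append(poisson_loglik(y, N * A * (P @ rho)))
        assert all(b >= a - 1e-6 * abs(a) for a, b in zip(lls, lls[1:]))

    def test_default_configuration_is_three_iterations_21_subsets(self):
        import inspect

        sig = inspect.signature(osem)
        assert sig.parameters["n_iter"].default == 3
        assert sig.parameters["n_subsets"].default == 21

    def test_negative_counts_rejected(self, mlem_setup):
        geom, em, N, A, zero, ybar = mlem_setup
        with pytest.raises(ValueError):
            osem(-np.ones(geom.n_lor), geom, N, A, zero, zero)


class TestPRRAggregate:
    def test_identity_operators_give_plain_sum(self, rng):
        imgs = {
            (b, c): ImageVolume(rng.random((96, 96)), (1.0, 1.0))
            for b in range(2)
            for c in ("systole", "diastole")
        }
        ident = {b: MotionOperator.identity((96, 96), (1.0, 1.0)) for b in range(2)}
        ops = {"systole": ident, "diastole": ident}
        card = MotionOperator.identity((96, 96), (1.0, 1.0))
        out = prr_aggregate(imgs, ops, card)
        expected = sum(v.data for v in imgs.values())
        np.testing.assert_array_equal(out.data, expected)

    def test_point_source_realigned_and_peak_enhanced(self):
        # a point source imaged at two displaced states: aggregation with the
        # true inverse operators must beat the uncorrected sum
        img0 = np.zeros((96, 96))
        img0[48, 48] = 1.0
        u = np.zeros((96, 96, 2))
        u[..., 0] = -6.0  # gate 1 sees the source displaced by +6
        op1 = MotionOperator(DeformationField(u, (1.0, 1.0)))
        img1 = op1.apply(img0)
        imgs = {(0, "diastole"): ImageVolume(img0, (1.0, 1.0)), (1, "diastole"): ImageVolume(img1, (1.0, 1.0))}
        ops = {
            "diastole": {
                0: MotionOperator.identity((96, 96), (1.0, 1.0)),
                1: op1,
            }
        }
        mc = prr_aggregate(imgs, ops, None)
        nmc = img0 + img1
        assert mc.data.max() > nmc.max()
        peak = np.unravel_index(np.argmax(mc.data), mc.data.shape)
        assert abs(peak[0] - 48) <= 1 and abs(peak[1] - 48) <= 1

    def test_mass_preserved_within_interpolation_tolerance(self, rng):
        imgs = {}
        ops = {"diastole": {}}
        base = np.zeros((96, 96))
        base[30:60, 30:60] = rng.random((30, 30))
        for b in range(3):
            u = np.zeros((96, 96, 2))
            u[..., 0] = 2.0 * b
            op = MotionOperator(DeformationField(u, (1.0, 1.0)))
            imgs[(b, "diastole")] = ImageVolume(op.apply(base), (1.0, 1.0))
            ops["diastole"][b] = op
        out = prr_aggregate(imgs, ops, None)
        total_gates = sum(v.data.sum() for v in imgs.values())
        assert out.data.sum() == pytest.approx(total_gates, rel=0.01)
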