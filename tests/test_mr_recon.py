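"""Encoding operator, conjugate-direction solver, soft-gated SENSE and the
motion-compensated reconstruction against dense direct solves."""

import numpy as np
import pytest

from cardiomoco.core import cfft, icfft
from cardiomoco.mr_recon import (
    EncodingOperator,
    ReconConfig,
    conjugate_residual,
    motion_corrected_recon,
    pooled_sense,
    soft_gated_sense,
)
from cardiomoco.mr_sim import CoilMaps, KSpaceData, SamplingPattern
from cardiomoco.registration import DeformationField, MotionOperator
from cardiomoco.resp_motion import TranslationTrace, compute_bins


def _coils(n, n_coils, rng, smooth=True):
    maps = []
    for c in range(n_coils):
        if smooth:
            ang = 2 * np.pi * c / n_coils
            X0, X1 = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
            p0 = n / 2 + 0.6 * n * np.cos(ang)
            p1 = n / 2 + 0.6 * n * np.sin(ang)
            m = np.exp(-((X0 - p0) ** 2 + (X1 - p1) ** 2) / (2 * (0.6 * n) ** 2))
            m = m * np.exp(1j * 0.1 * (X0 * np.cos(ang) + X1 * np.sin(ang)))
        else:
            m = rng.uniform(0.5, 1, (n, n)) * np.exp(1j * rng.standard_normal((n, n)))
        maps.append(m)
    return CoilMaps(maps=np.stack(maps), spacing=(1.0, 1.0))


def _pattern(n, idx=None, phase=None, beat=None):
    k0, k1 = np.meshgrid(np.arange(n) - n // 2, np.arange(n) - n // 2, indexing="ij")
    coords = np.stack([k0.ravel(), k1.ravel()], axis=-1)
    if idx is not None:
        coords = coords[idx]
    m = len(coords)
    return SamplingPattern(
        grid_shape=(n, n),
        coords=coords,
        interleaf=np.zeros(m, dtype=int) if beat is None else beat,
        beat=np.zeros(m, dtype=int) if beat is None else beat,
        phase=np.zeros(m, dtype=int) if phase is None else phase,
        time=np.zeros(m),
    )


def _dense_encoding(enc, n):
    cols = []
    for j in range(n * n):
        e = np.zeros(n * n)
        e[j] = 1.0
        cols.append(enc.forward(e.reshape(n, n)).ravel())
    return np.stack(cols, axis=1)


class TestEncodingOperator:
    def test_adjoint_identity(self, rng):
        n = 16
        coils = _coils(n, 2, rng, smooth=False)
        idx = rng.choice(n * n, size=n * n // 2, replace=False)
        enc = EncodingOperator(coils, (n, n), idx)
        x = rng.standard_normal((n, n)) + 1j * rng.standard_normal((n, n))
        y = rng.standard_normal((len(idx), 2)) + 1j * rng.standard_normal((len(idx), 2))
        lhs = np.vdot(y, enc.forward(x))
        rhs = np.vdot(enc.adjoint(y), x)
        assert abs(lhs - rhs) <= 1e-10 * abs(lhs)


class TestConjugateResidual:
    def test_residual_history_monotone_nonincreasing(self, rng):
        n = 40
        m = rng.standard_normal((n, n))
        a = m @ m.T + 0.1 * np.eye(n)
        b = rng.standard_normal(n)
        _, hist = conjugate_residual(lambda x: a @ x, b, tol=1e-12, max_iter=60)
        assert all(x >= y - 1e-12 for x, y in zip(hist, hist[1:]))

    def test_solves_spd_system(self, rng):
        n = 30
        m = rng.standard_normal((n, n))
        a = m @ m.T + np.eye(n)
        x_true = rng.standard_normal(n)
        x, _ = conjugate_residual(lambda v: a @ v, a @ x_true, tol=1e-12, max_iter=200)
        np.testing.assert_allclose(x, x_true, atol=1e-8)


def _trace_for(pattern):
    pairs = sorted({(int(b), int(p)) for b, p in zip(pattern.beat, pattern.phase)})
    n = len(pairs)
    return TranslationTrace(
        beat=np.array([b for b, _ in pairs]),
        phase=np.array([p for _, p in pairs]),
        time=np.arange(n, dtype=float),
        fh_mm=np.zeros(n),
        rl_mm=np.zeros(n),
    )


class TestSoftGatedSense:
    def test_fully_sampled_unit_coil_equals_inverse_dft(self, rng):
        n = 16
        coils = CoilMaps(maps=np.ones((1, n, n), dtype=complex), spacing=(1.0, 1.0))
        pat = _pattern(n)
        img = rng.random((n, n))
        data = cfft(img).ravel()[pat.flat_index()][:, None]
        ksp = KSpaceData(pattern=pat, data=data, spacing=(1.0, 1.0), noise_sd=0.0)
        trace = _trace_for(pat)
        bins = compute_bins(trace, 1)
        out, hist = soft_gated_sense(ksp, bins, trace, coils, 0, 0, ReconConfig(tol=1e-12, max_iter=50))
        np.testing.assert_allclose(out.data, img, atol=1e-8)

    def test_matches_dense_pseudo_inverse_solve(self, rng):
        n = 16
        coils = _coils(n, 3, rng)
        idx = rng.choice(n * n, size=n * n // 2, replace=False)
        # two interleaves with different soft weights
        beat = (np.arange(len(idx)) % 2).astype(int)
        pat = _pattern(n, idx=idx, beat=beat)
        trace = TranslationTrace(
            beat=np.array([0, 1]),
            phase=np.array([0, 0]),
            time=np.array([0.0, 1.0]),
            fh_mm=np.array([0.0, 3.0]),
            rl_mm=np.zeros(2),
        )
        bins = compute_bins(trace, 1, alpha=1.0)
        enc = EncodingOperator(coils, (n, n), pat.flat_index())
        k = rng.standard_normal((len(idx), 3)) + 1j * rng.standard_normal((len(idx), 3))
        ksp = KSpaceData(pattern=pat, data=k, spacing=(1.0, 1.0), noise_sd=0.0)
        w = np.array([bins.weights[0, 0] if b == 0 else bins.weights[1, 0] for b in beat])
        E = _dense_encoding(enc, n)
        W2 = np.repeat(w**2, 3)
        A = E.conj().T @ (W2[:, None] * E)
        rhs = E.conj().T @ (W2 * k.ravel())
        x_dense = np.linalg.pinv(A, rcond=1e-10) @ rhs
        out, _ = soft_gated_sense(
            ksp, bins, trace, coils, 0, 0, ReconConfig(tol=1e-13, max_iter=600)
        )
        rel = np.linalg.norm(out.data.ravel() - x_dense) / np.linalg.norm(x_dense)
        assert rel < 1e-5

    def test_weight_decay_rate_matches_exponential(self, rng):
        trace = TranslationTrace(
            beat=np.arange(40),
            phase=np.zeros(40, dtype=int),
            time=np.arange(40.0),
            fh_mm=np.concatenate([rng.uniform(0, 1, 20), rng.uniform(4, 5, 20)]),
            rl_mm=np.zeros(40),
        )
        alpha = 1.3
        bins = compute_bins(trace, 2, alpha=alpha)
        i = bins.members(1)[0]
        d = abs(trace.fh_mm[i] - bins.centers[0]) / (bins.edges[1] - bins.edges[0])
        assert bins.weights[i, 0] == pytest.approx(np.exp(-alpha * d))


class TestMotionCorrectedRecon:
    def test_identity_operators_equal_pooled_sense(self, rng):
        n = 16
        coils = _coils(n, 3, rng)
        pat = _pattern(n, beat=(np.arange(n * n) % 4).astype(int))
        img = rng.random((n, n))
        data = np.stack(
            [cfft(coils.maps[c] * img).ravel()[pat.flat_index()] for c in range(3)], axis=1
        )
        ksp = KSpaceData(pattern=pat, data=data, spacing=(1.0, 1.0), noise_sd=0.0)
        trace = _trace_for(pat)
        bins = compute_bins(trace, 2)
        ops = {b: MotionOperator.identity((n, n), (1.0, 1.0)) for b in range(2)}
        cfg = ReconConfig(tol=1e-12, max_iter=80)
        mc, _ = motion_corrected_recon(ksp, bins, trace, ops, coils, 0, cfg)
        pooled, _ = pooled_sense(ksp, coils, 0, cfg)
        np.testing.assert_allclose(mc.data, pooled.data, atol=1e-6)

    def test_matches_dense_normal_equation_solve_with_translations(self, rng):
        n = 8
        coils = _coils(n, 3, rng)
        half = rng.permutation(n * n)
        idx_a, idx_b = np.sort(half[: n * n // 2]), np.sort(half[n * n // 2 :])
        pat = _pattern(
            n,
            idx=np.concatenate([idx_a, idx_b]),
            beat=np.concatenate([np.zeros(len(idx_a), int), np.ones(len(idx_b), int)]),
        )
        trace = TranslationTrace(
            beat=np.array([0, 1]),
            phase=np.array([0, 0]),
            time=np.array([0.0, 1.0]),
            fh_mm=np.array([0.0, 5.0]),
            rl_mm=np.zeros(2),
        )
        bins = compute_bins(trace, 2)
        u = np.zeros((n, n, 2))
        u[..., 0] = 1.0
        ops = {0: MotionOperator.identity((n, n), (1.0, 1.0)), 1: MotionOperator(DeformationField(u, (1.0, 1.0)))}
        k = rng.standard_normal((n * n, 3)) + 1j * rng.standard_normal((n * n, 3))
        ksp = KSpaceData(pattern=pat, data=k, spacing=(1.0, 1.0), noise_sd=0.0)

        # dense oracle: A = sum_b (S_b E U_b)^H (S_b E U_b)
        flat = pat.flat_index()
        rows_a, rows_b = np.arange(len(idx_a)), np.arange(len(idx_a), n * n)
        A_mats, y_vecs = [], []
        for rows, op in ((rows_a, ops[0]), (rows_b, ops[1])):
            enc = EncodingOperator(coils, (n, n), flat[rows])
            E = _dense_encoding(enc, n)
            U = op._w.toarray()
            A_mats.append(E @ U)
            y_vecs.append(k[rows].ravel())
        A = sum(M.conj().T @ M for M in A_mats)
        rhs = sum(M.conj().T @ y for M, y in zip(A_mats, y_vecs))
        x_dense = np.linalg.pinv(A, rcond=1e-12) @ rhs

        out, _ = motion_corrected_recon(
            ksp, bins, trace, ops, coils, 0, ReconConfig(tol=1e-14, max_iter=500)
        )
        rel = np.linalg.norm(out.data.ravel() - x_dense) / np.linalg.norm(x_dense)
        assert rel < 1e-5

    def test_linearity_in_the_data(self, rng):
        n = 16
        coils = _coils(n, 2, rng)
        pat = _pattern(n, beat=(np.arange(n * n) % 2).astype(int))
        trace = _trace_for(pat)
        bins = compute_bins(trace, 2)
        ops = {b: MotionOperator.identity((n, n), (1.0, 1.0)) for b in range(2)}
        cfg = ReconConfig(tol=1e-12, max_iter=100)
        k1 = rng.standard_normal((n * n, 2)) + 1j * rng.standard_normal((n * n, 2))
        k2 = rng.standard_normal((n * n, 2)) + 1j * rng.standard_normal((n * n, 2))

        def recon(k):
            ksp = KSpaceData(pattern=pat, data=k, spacing=(1.0, 1.0), noise_sd=0.0)
            return motion_corrected_recon(ksp, bins, trace, ops, coils, 0, cfg)[0].data

        combo = recon(2.0 * k1 - 0.5 * k2)
        np.testing.assert_allclose(
            combo, 2.0 * recon(k1) - 0.5 * recon(k2), atol=1e-6
        )

    def test_missing_operator_for_nonempty_bin_is_error(self, rng):
        n = 16
        coils = _coils(n, 2, rng)
        pat = _pattern(n, beat=(np.arange(n * n) % 2).astype(int))
        trace = _trace_for(pat)
        bins = compute_bins(trace, 2)
        ksp = KSpaceData(
            pattern=pat,
            data=np.zeros((n * n, 2), dtype=complex),
            spacing=(1.0, 1.0),
            noise_sd=0.0,
        )
        with pytest.raises(ValueError):
            motion_corrected_recon(
                ksp, bins, trace, {0: MotionOperator.identity((n, n), (1.0, 1.0))}, coils, 0
            )
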