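"""iNAV tracking, respiratory binning with outlier rejection, k-space
phase pre-correction."""

import numpy as np
import pytest

from cardiomoco.core import cfft, icfft
from cardiomoco.mr_sim import INavSeries, KSpaceData, SamplingPattern
from cardiomoco.phantom import PhantomConfig, make_phantom
from cardiomoco.resp_motion import (
    REJECTED,
    TranslationTrace,
    compute_bins,
    phase_correct,
    track_inav,
)


def _nav_series(images):
    images = np.asarray(images)
    n_beats = images.shape[0]
    return INavSeries(
        images=images,
        times=np.arange(n_beats * 2, dtype=float).reshape(n_beats, 2),
        spacing=(1.0, 1.0),
        n_lines=14,
    )


@pytest.fixture(scope="module")
def ref_nav():
    from cardiomoco.mr_sim import _inav_from

    ph = make_phantom(PhantomConfig())
    return _inav_from(ph.mr["diastole"].data, 14)


class TestTrackInav:
    def test_identical_navigators_give_zero_shift(self, ref_nav):
        nav = _nav_series([[ref_nav, ref_nav]] * 3)
        tr = track_inav(nav)
        assert np.abs(tr.fh_mm).max() < 0.05
        assert np.abs(tr.rl_mm).max() < 0.05

    def test_integer_circular_shift_recovered_exactly(self, ref_nav):
        shifted = np.roll(ref_nav, 3, axis=0)
        nav = _nav_series([[ref_nav, ref_nav], [shifted, shifted]])
        tr = track_inav(nav, subpixel=False)
        # brute-force NCC oracle: exhaustive integer-shift search
        from cardiomoco.resp_motion import _ncc

        r0, r1 = slice(36, 60), slice(36, 60)
        scores = {
            s: _ncc(ref_nav[r0, r1], shifted[r0.start + s : r0.stop + s, r1])
            for s in range(-10, 11)
        }
        assert max(scores, key=scores.get) == 3
        est = tr.fh_mm.reshape(2, 2)[1]
        np.testing.assert_array_equal(est, [3.0, 3.0])
        assert np.all(tr.rl_mm.reshape(2, 2)[1] == 0.0)

    def test_subvoxel_shift_recovered_within_quarter_voxel(self, ref_nav):
        k = cfft(ref_nav)
        kk = np.arange(96) - 48
        sub = np.abs(icfft(k * np.exp(-2j * np.pi * kk[:, None] * 0.5 / 96)))
        nav = _nav_series([[ref_nav, ref_nav], [sub, sub]])
        tr = track_inav(nav)
        assert abs(tr.fh_mm.reshape(2, 2)[1][0] - 0.5) < 0.25

    def test_flat_template_reported_as_error(self):
        flat = np.zeros((2, 2, 96, 96))
        with pytest.raises(ValueError):
            track_inav(_nav_series(flat))


def _trace(fh, rl=None):
    n = len(fh)
    return TranslationTrace(
        beat=np.arange(n),
        phase=np.zeros(n, dtype=int),
        time=np.arange(n, dtype=float),
        fh_mm=np.asarray(fh, dtype=float),
        rl_mm=np.zeros(n) if rl is None else np.asarray(rl, dtype=float),
    )


class TestComputeBins:
    def test_single_bin_collects_everything(self):
        bins = compute_bins(_trace([1.0, 2.0, 3.0]), 1)
        assert bins.n_bins == 1
        assert np.all(bins.labels == 0)

    def test_two_sd_rejection_worked_example(self):
        # mean 2, population SD 6, window [-10, 14]: only the 20 mm beat out
        bins = compute_bins(_trace([0.0] * 9 + [20.0]), 3)
        assert np.flatnonzero(bins.rejected).tolist() == [9]
        assert bins.labels[9] == REJECTED
        assert (bins.labels[:9] >= 0).all()
        assert np.all(bins.weights[9] == 0.0)

    def test_equal_count_quantile_bins(self, rng):
        bins = compute_bins(_trace(rng.uniform(0, 10, 1000)), 4)
        counts = [len(bins.members(b)) for b in range(4)]
        assert counts == [250, 250, 250, 250]

    def test_binning_permutation_invariant(self, rng):
        fh = rng.uniform(0, 10, 200)
        perm = rng.permutation(200)
        a = compute_bins(_trace(fh), 4)
        b = compute_bins(_trace(fh[perm]), 4)
        np.testing.assert_array_equal(a.labels[perm], b.labels)

    def test_weight_unity_inside_bin_and_decaying_outside(self, rng):
        bins = compute_bins(_trace(rng.uniform(0, 10, 400)), 4, alpha=1.0)
        own = bins.labels >= 0
        rows = np.flatnonzero(own)
        assert np.all(bins.weights[rows, bins.labels[rows]] == 1.0)
        # weights strictly decrease with distance from a bin's center
        order = np.argsort(np.abs(bins.centers[0] - bins.centers))
        mean_w = [bins.weights[bins.labels == b, 0].mean() for b in order]
        assert all(x >= y for x, y in zip(mean_w, mean_w[1:]))

    def test_all_rejected_is_error(self):
        tr = _trace([0.0, 0.0])
        with pytest.raises(ValueError):
            compute_bins(tr, 3)  # fewer accepted than bins


def _full_pattern(n):
    k0, k1 = np.meshgrid(np.arange(n) - n // 2, np.arange(n) - n // 2, indexing="ij")
    coords = np.stack([k0.ravel(), k1.ravel()], axis=-1)
    z = np.zeros(n * n, dtype=int)
    return SamplingPattern(
        grid_shape=(n, n), coords=coords, interleaf=z, beat=z, phase=z, time=z.astype(float)
    )


class TestPhaseCorrect:
    def _kspace(self, img):
        pat = _full_pattern(img.shape[0])
        data = cfft(img).ravel()[pat.flat_index()][:, None]
        return KSpaceData(pattern=pat, data=data, spacing=(1.0, 1.0), noise_sd=0.0)

    def test_zero_residual_shift_leaves_kspace_bitwise(self, rng):
        img = rng.random((16, 16))
        ksp = self._kspace(img)
        tr = _trace([2.0])
        bins = compute_bins(tr, 1)  # center = 2.0 -> zero residual
        out = phase_correct(ksp, tr, bins)
        np.testing.assert_array_equal(out.data, ksp.data)

    def test_shift_theorem_restores_unshifted_kspace(self, rng):
        img = rng.random((16, 16))
        shifted = np.roll(np.roll(img, 2, axis=0), -1, axis=1)
        ksp = self._kspace(shifted)
        tr = _trace([2.0], rl=[-1.0])
        bins = compute_bins(tr, 1)
        bins.centers[0] = 0.0  # correct all the way to the reference
        out = phase_correct(ksp, tr, bins)
        ref = cfft(img).ravel()[ksp.pattern.flat_index()][:, None]
        np.testing.assert_allclose(out.data, ref, atol=1e-10)

    def test_magnitudes_unchanged(self, rng):
        img = rng.random((16, 16))
        ksp = self._kspace(np.roll(img, 3, axis=0))
        tr = _trace([3.0])
        bins = compute_bins(tr, 1)
        bins.centers[0] = 0.7
        out = phase_correct(ksp, tr, bins)
        np.testing.assert_allclose(np.abs(out.data), np.abs(ksp.data), atol=1e-12)

    def test_missing_translation_estimate_is_error(self, rng):
        img = rng.random((16, 16))
        ksp = self._kspace(img)
        tr = _trace([0.0])
        bins = compute_bins(tr, 1)
        bad = TranslationTrace(
            beat=np.array([5]),
            phase=np.array([0]),
            time=np.array([0.0]),
            fh_mm=np.array([0.0]),
            rl_mm=np.array([0.0]),
        )
        with pytest.raises(ValueError):
            phase_correct(ksp, bad, bins)
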