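"""Fidelity metrics: NRMSE, SSIM, FWHM, counting, occupancy."""

import numpy as np
import pytest
from skimage.metrics import structural_similarity

from cacs.metrics import (
    count_objects,
    fwhm_profile,
    match_to_truth,
    nmj_occupancy,
    nrmse,
    otsu_mask,
    ssim3d,
)
from cacs.volume import ImageVolume


class TestNrmse:
    def test_identical_zero(self, rng):
        x = rng.random((8, 8, 8))
        assert nrmse(x, x) == 0.0

    def test_binary_ref_offset_closed_form(self, rng):
        ref = (rng.random((8, 8, 8)) > 0.5).astype(float)
        assert nrmse(ref + 0.1, ref) == pytest.approx(0.1, rel=1e-12)

    def test_elementwise_oracle(self, rng):
        x = rng.random((6, 6, 6))
        ref = rng.random((6, 6, 6))
        acc = 0.0
        for a, b in zip(x.ravel(), ref.ravel()):
            acc += (a - b) ** 2
        oracle = np.sqrt(acc / x.size) / (ref.max() - ref.min())
        assert nrmse(x, ref) == pytest.approx(oracle, abs=1e-12)

    def test_linear_in_error_amplitude(self, rng):
        ref = rng.random((8, 8, 8))
        err = rng.standard_normal((8, 8, 8))
        assert nrmse(ref + 2 * err, ref) == pytest.approx(2 * nrmse(ref + err, ref), rel=1e-9)

    def test_constant_ref_rejected(self):
        with pytest.raises(ValueError):
            nrmse(np.ones((4, 4, 4)), np.ones((4, 4, 4)))


class TestSsim3d:
    def test_identical_unity(self, rng):
        x = rng.random((16, 16, 16))
        assert ssim3d(x, x) == pytest.approx(1.0)

    def test_anticorrelated_negative(self, rng):
        ref = rng.standard_normal((16, 16, 16))
        ref -= ref.mean()
        assert ssim3d(-ref, ref, data_range=float(ref.max() - ref.min())) < 0

    def test_symmetric(self, rng):
        x = rng.random((14, 14, 14))
        y = rng.random((14, 14, 14))
        L = 1.0
        assert ssim3d(x, y, data_range=L) == pytest.approx(ssim3d(y, x, data_range=L), rel=1e-12)

    def test_common_rescaling_invariance(self, rng):
        # SSIM is invariant to a common intensity scaling when the dynamic
        # range is rescaled with it
        x = rng.random((14, 14, 14))
        y = rng.random((14, 14, 14))
        a = 3.0
        s1 = ssim3d(x, y, data_range=1.0)
        s2 = ssim3d(a * x, a * y, data_range=a)
        assert s2 == pytest.approx(s1, rel=1e-9)

    def test_agreement_with_independent_reference(self, rng):
        # skimage's Gaussian-weighted SSIM is an independent implementation
        # of the same statistic (sigma 1.5, 11-voxel window, crop pad)
        x = rng.random((32, 32, 32))
        y = np.clip(x + 0.1 * rng.standard_normal(x.shape), 0, 1)
        mine = ssim3d(x, y, data_range=1.0)
        ref = structural_similarity(
            x, y, data_range=1.0, gaussian_weights=True, sigma=1.5,
            use_sample_covariance=False,
        )
        assert mine == pytest.approx(ref, abs=1e-6)

    def test_window_too_large(self, rng):
        with pytest.raises(ValueError):
            ssim3d(rng.random((8, 8, 8)), rng.random((8, 8, 8)))


def gaussian_volume(sigma_vox, shape=(33, 33, 33), pitch=0.5):
    c = np.array(shape) // 2
    z, y, x = np.indices(shape)
    r2 = ((z - c[0]) ** 2 + (y - c[1]) ** 2 + (x - c[2]) ** 2).astype(float)
    return ImageVolume(np.exp(-r2 / (2 * sigma_vox**2)), (pitch,) * 3)


class TestFwhmProfile:
    def test_gaussian_closed_form(self):
        vol = gaussian_volume(2.0)
        center = ((np.array(vol.shape) // 2 + 0.5) * 0.5)
        for axis in range(3):
            assert fwhm_profile(vol, center, axis) == pytest.approx(2.355, abs=0.05)

    def test_single_voxel_sampling_floor(self):
        data = np.zeros((21, 21, 21))
        data[10, 10, 10] = 1.0
        vol = ImageVolume(data, (0.5,) * 3)
        center = (10.5 * 0.5, 10.5 * 0.5, 10.5 * 0.5)
        assert fwhm_profile(vol, center, 0) <= 2 * 0.5

    def test_asymmetric_profile_vs_fine_grid_oracle(self):
        # asymmetric peak: skewed double-gaussian along x
        shape = (15, 15, 41)
        z, y, x = np.indices(shape).astype(float)
        c = (7, 7, 20)
        prof = np.where(
            x >= c[2],
            np.exp(-((x - c[2]) ** 2) / (2 * 3.0**2)),
            np.exp(-((x - c[2]) ** 2) / (2 * 1.5**2)),
        )
        data = prof * np.exp(-((z - c[0]) ** 2 + (y - c[1]) ** 2) / (2 * 2.0**2))
        pitch = 0.4
        vol = ImageVolume(data, (pitch,) * 3)
        measured = fwhm_profile(vol, ((c[0] + 0.5) * pitch, (c[1] + 0.5) * pitch, (c[2] + 0.5) * pitch), 2)
        # dense-grid numeric oracle on the analytic 1D profile
        xf = np.linspace(0, shape[2] - 1, 40001)
        pf = np.where(xf >= c[2], np.exp(-((xf - c[2]) ** 2) / 18.0), np.exp(-((xf - c[2]) ** 2) / 4.5))
        above = xf[pf >= 0.5]
        oracle = (above.max() - above.min()) * pitch
        assert measured == pytest.approx(oracle, abs=pitch)

    def test_no_peak_errors(self):
        vol = ImageVolume(np.zeros((11, 11, 11)), (0.5,) * 3)
        with pytest.raises(ValueError):
            fwhm_profile(vol, (2.75, 2.75, 2.75), 0)


class TestCountObjects:
    def test_two_separated_beads(self):
        data = np.zeros((24, 24, 24))
        data[6, 6, 6] = 1.0
        data[18, 18, 18] = 0.9
        vol = ImageVolume(data, (0.5,) * 3)
        det = count_objects(vol, min_distance_um=2.0, rel_threshold=0.2)
        assert len(det) == 2

    def test_empty_volume(self):
        vol = ImageVolume(np.zeros((12, 12, 12)), (0.5,) * 3)
        det = count_objects(vol, 2.0)
        assert len(det) == 0

    def test_nuclei_ground_truth_self_consistency(self):
        # detection on the noiseless HR truth recovers the exact count
        from cacs.phantoms import PhantomSpec, generate_phantom

        spec = PhantomSpec(kind="nuclei", extent=100.0, pitch=0.5, seed=7,
                           nuclei_density=2.4e5, nuclei_min_sep=8.0)
        ph = generate_phantom(spec)
        det = count_objects(ph.volume, min_distance_um=6.0, rel_threshold=0.2)
        assert len(det) == 240
        n_match, _, _ = match_to_truth(det, ph.truth["positions_um"], 6.0)
        assert n_match == 240

    def test_min_distance_validated(self):
        vol = ImageVolume(np.zeros((8, 8, 8)), (0.5,) * 3)
        with pytest.raises(ValueError):
            count_objects(vol, 0.1)


class TestNmjOccupancy:
    def test_full_occupancy(self):
        mask = np.zeros((8, 8, 8), bool)
        mask[2:6, 2:6, 2:6] = True
        assert nmj_occupancy(mask, mask) == pytest.approx(100.0)

    def test_empty_pre(self):
        post = np.ones((4, 4, 4), bool)
        assert nmj_occupancy(np.zeros((4, 4, 4), bool), post) == 0.0

    def test_half_occupancy(self):
        post = np.zeros((8, 8, 8), bool)
        post[:4] = True
        pre = np.zeros((8, 8, 8), bool)
        pre[:2] = True
        assert nmj_occupancy(pre, post) == pytest.approx(50.0)

    def test_clip_to_post_option(self):
        post = np.zeros((8, 8, 8), bool)
        post[:4] = True
        pre = np.zeros((8, 8, 8), bool)
        pre[2:6] = True  # half inside, half outside
        assert nmj_occupancy(pre, post) == pytest.approx(100.0)
        assert nmj_occupancy(pre, post, clip_to_post=True) == pytest.approx(50.0)

    def test_empty_post_rejected(self):
        with pytest.raises(ValueError):
            nmj_occupancy(np.ones((4, 4, 4), bool), np.zeros((4, 4, 4), bool))

    def test_phantom_masks_reproduce_generation_occupancy(self):
        from cacs.phantoms import PhantomSpec, generate_phantom

        spec = PhantomSpec(kind="nmj", extent=40.0, pitch=0.5, occupancy=0.4, seed=1)
        ph = generate_phantom(spec)
        occ = nmj_occupancy(ph.truth["pre_mask"], ph.truth["post_mask"])
        assert occ == pytest.approx(40.0, abs=1.0)
        # Otsu masks on the smoothed channels land close to construction
        occ_otsu = nmj_occupancy(otsu_mask(ph.channels["pre"]), otsu_mask(ph.channels["post"]))
        assert occ_otsu == pytest.approx(40.0, abs=8.0)
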