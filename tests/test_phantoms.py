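"""Phantom generation and acquisition simulation."""

import numpy as np
import pytest

from cacs.operators import make_operator
from cacs.phantoms import (
    AcquisitionSpec,
    GenerationError,
    PhantomSpec,
    generate_phantom,
    simulate_acquisition,
)


class TestBeads:
    def test_deterministic_given_seed(self):
        spec = PhantomSpec(kind="beads", extent=32.0, pitch=0.5, n_beads=5,
                           bead_min_sep=8.0, seed=11)
        a = generate_phantom(spec)
        b = generate_phantom(spec)
        np.testing.assert_array_equal(a.volume.data, b.volume.data)
        np.testing.assert_array_equal(a.truth["positions_um"], b.truth["positions_um"])

    def test_min_separation_enforced(self):
        spec = PhantomSpec(kind="beads", extent=40.0, pitch=0.5, n_beads=6,
                           bead_min_sep=12.0, seed=3)
        pos = generate_phantom(spec).truth["positions_um"]
        d = np.linalg.norm(pos[:, None] - pos[None, :], axis=-1)
        np.fill_diagonal(d, np.inf)
        assert d.min() >= 12.0

    def test_splat_centroid_matches_truth(self):
        spec = PhantomSpec(kind="beads", extent=20.0, pitch=0.5, n_beads=1,
                           bead_min_sep=1.0, seed=5)
        ph = generate_phantom(spec)
        data = ph.volume.data
        idx = np.indices(data.shape)
        w = data / data.sum()
        centroid = np.array([(i * w).sum() for i in idx])
        centroid_um = (centroid + 0.5) * 0.5
        np.testing.assert_allclose(centroid_um, ph.truth["positions_um"][0], atol=1e-9)

    def test_infeasible_packing_raises(self):
        spec = PhantomSpec(kind="beads", extent=10.0, pitch=0.5, n_beads=50,
                           bead_min_sep=8.0, seed=0)
        with pytest.raises(GenerationError):
            generate_phantom(spec)


class TestNuclei:
    def test_exact_count_from_density(self):
        # 2.4e5 / mm^3 in a (100 um)^3 extent -> exactly 240 centers
        spec = PhantomSpec(kind="nuclei", extent=100.0, pitch=0.5, seed=7,
                           nuclei_density=2.4e5, nuclei_min_sep=8.0)
        ph = generate_phantom(spec)
        assert ph.truth["count"] == 240
        assert len(ph.truth["positions_um"]) == 240

    def test_small_volume_count(self):
        spec = PhantomSpec(kind="nuclei", extent=50.0, pitch=0.5, seed=1,
                           nuclei_density=2.4e5, nuclei_min_sep=8.0)
        ph = generate_phantom(spec)
        assert ph.truth["count"] == round(2.4e5 * 0.05**3)  # = 30


class TestFilaments:
    def test_tube_volume_nonempty_and_bounded(self):
        spec = PhantomSpec(kind="filaments", extent=32.0, pitch=0.5,
                           n_filaments=4, tube_radius=0.75, seed=2)
        ph = generate_phantom(spec)
        assert ph.volume.data.max() == pytest.approx(1.0)
        assert (ph.volume.data > 0.1).mean() > 0.001
        assert len(ph.truth["centerlines_um"]) == 4

    def test_spines_generated_at_rate(self):
        spec = PhantomSpec(kind="filaments", extent=32.0, pitch=0.5, n_filaments=2,
                           spine_rate=0.5, seed=2)
        ph = generate_phantom(spec)
        assert len(ph.truth["spines"]) > 0


class TestNmj:
    def test_occupancy_matches_request(self):
        spec = PhantomSpec(kind="nmj", extent=40.0, pitch=0.5, occupancy=0.5, seed=0)
        ph = generate_phantom(spec)
        pre = ph.truth["pre_mask"]
        post = ph.truth["post_mask"]
        ratio = 100.0 * pre.sum() / post.sum()
        assert ratio == pytest.approx(50.0, abs=1.0)

    def test_pre_mask_subset_of_shell(self):
        spec = PhantomSpec(kind="nmj", extent=40.0, pitch=0.5, occupancy=0.3, seed=0)
        ph = generate_phantom(spec)
        assert np.all(ph.truth["post_mask"][ph.truth["pre_mask"]])


class TestSimulateAcquisition:
    def test_noise_free_limit_matches_forward_model(self, small_psf, rng):
        gt_data = np.clip(rng.standard_normal((16, 16, 16)), 0, None)
        from cacs.volume import ImageVolume

        gt = ImageVolume(gt_data, (0.5, 0.5, 0.5))
        acq = AcquisitionSpec(psf=small_psf, factor=2, photon_scale=None, read_noise=0.0)
        raw = simulate_acquisition(gt, acq)
        op = make_operator(small_psf, (16, 16, 16), factor=2)
        expected = op.forward_spatial(gt_data) * raw.meta["gain"]
        assert np.abs(raw.data - expected).max() <= 0.5 + 1e-9  # quantization only

    def test_delta_ground_truth_gives_psf(self, small_psf):
        from cacs.volume import ImageVolume

        n = 16
        gt = np.zeros((n, n, n))
        gt[n // 2, n // 2, n // 2] = 1.0
        acq = AcquisitionSpec(psf=small_psf, factor=1, photon_scale=None, read_noise=0.0)
        raw = simulate_acquisition(ImageVolume(gt, (0.5,) * 3), acq)
        k = small_psf.kernel
        sl = tuple(slice(n // 2 - s // 2, n // 2 - s // 2 + s) for s in k.shape)
        expected = np.zeros((n, n, n))
        expected[sl] = k * raw.meta["gain"]
        assert np.abs(raw.data - expected).max() <= 0.5 + 1e-9

    def test_noise_model_unbiased_monte_carlo(self, small_psf):
        # mean over noisy realizations of a constant scene stays within
        # 3 standard errors of the noiseless value
        from cacs.volume import ImageVolume

        gt = ImageVolume(np.full((8, 8, 8), 1.0), (0.5,) * 3)
        noiseless = simulate_acquisition(
            gt, AcquisitionSpec(psf=small_psf, factor=2, photon_scale=None, read_noise=0.0)
        )
        n_rep = 100
        photon = 200.0
        means = []
        for seed in range(n_rep):
            raw = simulate_acquisition(
                gt,
                AcquisitionSpec(psf=small_psf, factor=2, photon_scale=photon,
                                read_noise=2.0, seed=seed),
            )
            means.append(raw.data.mean())
        grand = np.mean(means)
        # noiseless path uses a different gain; compare in photon units
        expected = photon  # constant scene: every LR voxel at the peak
        se = np.std(means, ddof=1) / np.sqrt(n_rep)
        assert abs(grand - expected) <= 3 * max(se, 1e-6) + 0.5  # 0.5 = quantization

    def test_pitch_mismatch_rejected(self, small_psf):
        from cacs.volume import ImageVolume

        gt = ImageVolume(np.zeros((8, 8, 8)), (1.0, 1.0, 1.0))
        with pytest.raises(ValueError):
            simulate_acquisition(gt, AcquisitionSpec(psf=small_psf, factor=2))

    def test_deterministic_under_seed(self, small_psf, rng):
        from cacs.volume import ImageVolume

        gt = ImageVolume(rng.random((16, 16, 16)), (0.5,) * 3)
        acq = AcquisitionSpec(psf=small_psf, factor=2, photon_scale=100.0, seed=42)
        a = simulate_acquisition(gt, acq)
        b = simulate_acquisition(gt, acq)
        np.testing.assert_array_equal(a.data, b.data)
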