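"""Spatial-frequency decomposition and Gaussian-aperture mask sampling."""

import numpy as np
import pytest

from sir import bubbles as bb


def _base_image(size=256, seed=0):
    return np.random.default_rng(seed).random((size, size))


class TestDecomposeSF:
    def test_flat_image_energy_only_in_last_band(self):
        d = bb.decompose_sf(np.full((256, 256), 0.37))
        for band in d.band_images[:-1]:
            assert np.abs(band).max() < 1e-10
        np.testing.assert_allclose(d.band_images[-1], 0.37, atol=1e-10)

    def test_sinusoid_energy_lands_in_its_octave(self):
        # 48 cycles/image belongs to the band with cutoffs (32, 64]
        size = 256
        x = np.arange(size)
        img = np.sin(2 * np.pi * 48 * x / size)[None, :] * np.ones((size, 1))
        d = bb.decompose_sf(img)
        energies = np.array([np.sum(b**2) for b in d.band_images])
        assert energies[1] / energies.sum() >= 0.90  # band 2 spans (32, 64]

    def test_reference_cutoffs_and_reconstruction(self):
        img = _base_image()
        d = bb.decompose_sf(img)
        assert d.n_bands == 6
        assert d.cutoffs_cpi == [128, 64, 32, 16, 8, 4]
        np.testing.assert_allclose(d.reconstruct(), img, atol=1e-10)

    def test_white_noise_bands_have_disjoint_frequency_support(self):
        img = _base_image(seed=3)
        d = bb.decompose_sf(img)
        f = np.fft.fftfreq(256) * 256
        radius = np.hypot(*np.meshgrid(f, f))
        # each interior band's spectral energy concentrates inside its octave;
        # the top band is a residual high-pass (corner frequencies included)
        spec0 = np.abs(np.fft.fft2(d.band_images[0])) ** 2
        assert spec0[radius > 64].sum() / spec0.sum() > 0.95
        for k, (hi, lo) in enumerate(zip(d.cutoffs_cpi[1:4], d.cutoffs_cpi[2:5]), 1):
            spec = np.abs(np.fft.fft2(d.band_images[k])) ** 2
            inside = spec[(radius > lo) & (radius <= hi)].sum()
            assert inside / spec.sum() > 0.85

    @pytest.mark.parametrize(
        "img, cutoffs, msg",
        [
            (np.zeros((256, 128)), None, "square"),
            (np.zeros((200, 200)), None, "power of two"),
            (np.zeros((256, 256)), [128], "at least 2"),
            (np.zeros((256, 256)), [64, 128], "descending"),
        ],
    )
    def test_rejects_bad_inputs(self, img, cutoffs, msg):
        with pytest.raises(ValueError, match=msg):
            bb.decompose_sf(img, cutoffs)


class TestBubbleMasks:
    def test_single_center_aperture_matches_gaussian_closed_form(self):
        class _Fixed:
            def uniform(self, lo, hi, size):
                return np.full(size, 128.0)

        ms = bb.generate_bubble_masks(
            _Fixed(), [1, 0, 0, 0, 0], [10.0, 20.0, 30.0, 40.0, 50.0], 256
        )
        m = ms.masks[0]
        assert m[128, 128] == pytest.approx(1.0)
        for r in (5, 13, 27):
            assert m[128, 128 + r] == pytest.approx(np.exp(-(r**2) / 200.0), rel=1e-6)

    def test_default_allocation_totals_sixty(self):
        assert sum(bb.default_aperture_allocation()) == 60
        ms = bb.generate_bubble_masks(np.random.default_rng(0))
        assert ms.total_apertures == 60

    def test_identical_seeds_give_bit_identical_masks(self):
        a = bb.generate_bubble_masks(np.random.default_rng(7))
        b = bb.generate_bubble_masks(np.random.default_rng(7))
        for ma, mb in zip(a.masks, b.masks):
            assert np.array_equal(ma, mb)

    def test_mask_values_bounded(self, rng):
        ms = bb.generate_bubble_masks(rng, combine="sum")
        for m in ms.masks:
            assert m.min() >= 0.0 and m.max() <= 1.0

    def test_rejects_degenerate_requests(self, rng):
        with pytest.raises(ValueError, match="at least one aperture"):
            bb.generate_bubble_masks(rng, [0, 0, 0, 0, 0])
        with pytest.raises(ValueError, match="positive"):
            bb.generate_bubble_masks(rng, sigmas_px=[-1, 2, 3, 4, 5])
        with pytest.raises(ValueError, match="increasing"):
            bb.generate_bubble_masks(rng, sigmas_px=[5, 4, 3, 2, 1])

    def test_coverage_stationary_across_trials(self):
        # expected revealed area per band stable for a fixed allocation
        covers = []
        for seed in range(300):
            ms = bb.generate_bubble_masks(np.random.default_rng(seed), image_size=64)
            covers.append([m.mean() for m in ms.masks])
        covers = np.array(covers)
        rel_sd = covers.std(axis=0) / covers.mean(axis=0) / np.sqrt(len(covers))
        assert (rel_sd < 0.05).all()


class TestComposeStimulus:
    @pytest.fixture(scope="class")
    def decomp(self):
        return bb.decompose_sf(_base_image(seed=1))

    def _unit_masks(self, value):
        sig = [bb.deg_to_px(s) for s in bb.DEFAULT_SIGMAS_DEG]
        return bb.BubbleMaskSet([np.full((256, 256), value)] * 5, [[]] * 5, sig)

    def test_full_visibility_reconstructs_base(self, decomp):
        stim = bb.compose_stimulus(decomp, self._unit_masks(1.0))
        np.testing.assert_allclose(stim.pixels, decomp.reconstruct(), atol=1e-10)

    def test_zero_visibility_leaves_constant_band(self, decomp):
        stim = bb.compose_stimulus(decomp, self._unit_masks(0.0))
        np.testing.assert_allclose(stim.pixels, decomp.band_images[-1], atol=1e-12)

    def test_matches_pixel_loop_reference(self, decomp, rng):
        ms = bb.generate_bubble_masks(rng)
        stim = bb.compose_stimulus(decomp, ms)
        ref = decomp.band_images[-1].copy()
        for k in range(5):
            ref = ref + ms.masks[k] * decomp.band_images[k]
        np.testing.assert_allclose(stim.pixels, ref, atol=1e-12)

    def test_composition_linear_in_mask_scale(self, decomp, rng):
        ms = bb.generate_bubble_masks(rng)
        for a in (0.25, 0.8):
            scaled = bb.BubbleMaskSet(
                [a * m for m in ms.masks], ms.aperture_centers, ms.sigmas_px
            )
            lhs = bb.compose_stimulus(decomp, scaled).pixels
            full = bb.compose_stimulus(decomp, ms).pixels
            rhs = a * (full - decomp.band_images[-1]) + decomp.band_images[-1]
            np.testing.assert_allclose(lhs, rhs, atol=1e-10)

    def test_grid_mismatch_rejected(self, decomp):
        small = bb.BubbleMaskSet([np.ones((64, 64))] * 5, [[]] * 5, [1, 2, 3, 4, 5])
        with pytest.raises(ValueError, match="grid"):
            bb.compose_stimulus(decomp, small)


class TestDownsampleMasks:
    def test_constant_mask_stays_constant(self):
        ms = bb.BubbleMaskSet([np.full((256, 256), 0.5)] * 5, [[]] * 5, [1, 2, 3, 4, 5])
        out = bb.downsample_masks(ms, 64)
        for m in out.masks:
            assert m.shape == (64, 64)
            np.testing.assert_allclose(m, 0.5, atol=1e-12)

    def test_single_aperture_peak_preserved(self, rng):
        ms = bb.generate_bubble_masks(rng, [0, 0, 0, 0, 1])
        out = bb.downsample_masks(ms, 64)
        src_peak = np.unravel_index(np.argmax(ms.masks[4]), (256, 256))
        dst_peak = np.unravel_index(np.argmax(out.masks[4]), (64, 64))
        assert abs(src_peak[0] / 4 - dst_peak[0]) <= 1
        assert abs(src_peak[1] / 4 - dst_peak[1]) <= 1

    def test_upsampling_rejected(self):
        ms = bb.BubbleMaskSet([np.ones((64, 64))] * 5, [[]] * 5, [1, 2, 3, 4, 5])
        with pytest.raises(ValueError, match="upsampling"):
            bb.downsample_masks(ms, 128)
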