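import numpy as np
import pytest

import plaquefir as pf
from plaquefir.spectra_core import channel_slice
from plaquefir.synthetic_scene import (
    ConfigError,
    GRAY_MATTER_BANDS,
    SamplingError,
    single_plaque_config,
)


def _noise_free(cfg):
    import dataclasses

    return dataclasses.replace(
        cfg,
        mie_enabled=False,
        noise_sigma=0.0,
        low_snr_fraction=0.0,
        protein_heterogeneity=0.0,
        lipid_heterogeneity=0.0,
    )


class TestSimulateScene:
    def test_degenerate_config_is_pure_gray_matter(self):
        cfg = _noise_free(pf.SceneConfig(rows=6, cols=6, seed=0))
        cube, truth = pf.simulate_scene(cfg)
        base = GRAY_MATTER_BANDS.evaluate(cube.axis) + np.array(
            [0.1 * np.exp(-0.5 * ((cube.axis.values - 1738.0) / 9.0) ** 2)]
        ).ravel()
        for r in range(cube.rows):
            for c in range(cube.cols):
                assert np.allclose(cube.data[r, c], base, atol=1e-6)
        assert truth.density.max() == 0.0

    def test_same_seed_bit_identical(self):
        cfg = single_plaque_config("classic_cored", seed=7)
        cube1, truth1 = pf.simulate_scene(cfg)
        cube2, truth2 = pf.simulate_scene(cfg)
        assert np.array_equal(cube1.data, cube2.data)
        assert np.array_equal(truth1.density, truth2.density)
        assert np.array_equal(truth1.qc_valid, truth2.qc_valid)

    def test_core_has_higher_fibril_fraction(self, cored_scene):
        _, _, truth = cored_scene
        core = truth.core_masks[0]
        inside = truth.fibril_fraction[core].mean()
        outside = truth.fibril_fraction[~core].mean()
        assert inside > outside

    def test_core_mask_subset_of_plaque_mask(self, cored_scene):
        _, _, truth = cored_scene
        assert not (truth.core_masks[0] & ~truth.plaque_masks[0]).any()

    def test_only_cored_plaques_have_cores(self):
        cfg = pf.cohort_scene_config(1, 1, 1, rows=100, cols=100, seed=3)
        _, truth = pf.simulate_scene(cfg)
        for label, cmask in zip(truth.labels, truth.core_masks):
            assert cmask.any() == (label == "classic_cored")

    def test_plaque_out_of_bounds_rejected(self):
        cfg = pf.SceneConfig(
            rows=20, cols=20,
            plaques=[pf.PlaqueSpec("diffuse", (2.0, 2.0), 20.0)],
        )
        with pytest.raises(ConfigError):
            pf.simulate_scene(cfg)

    def test_silent_region_has_no_band_absorbance(self):
        cfg = _noise_free(single_plaque_config("classic_cored", seed=0))
        cube, _ = pf.simulate_scene(cfg)
        sl = channel_slice(cube.axis, 1810.0, 2290.0)
        assert np.abs(cube.data[:, :, sl]).max() < 1e-6

    def test_amplitude_linearity_of_deposit(self):
        base = _noise_free(pf.SceneConfig(rows=40, cols=40, seed=0))
        import dataclasses

        def with_density(d):
            spec = pf.PlaqueSpec(
                "compact", (20.0, 20.0), 12.0, density_scale=d, fibril_fraction=0.5
            )
            return dataclasses.replace(base, plaques=[spec])

        cube0, _ = pf.simulate_scene(dataclasses.replace(base, plaques=[]))
        cube1, _ = pf.simulate_scene(with_density(0.5))
        cube2, _ = pf.simulate_scene(with_density(1.0))
        ab1 = cube1.data - cube0.data
        ab2 = cube2.data - cube0.data
        assert np.allclose(ab2, 2.0 * ab1, atol=1e-5)

    def test_fibril_fraction_lowers_beta_centroid(self):
        # intensity-weighted centroid of 1640-1615 decreases with f
        import dataclasses

        base = _noise_free(pf.SceneConfig(rows=30, cols=30, seed=0))
        centroids = []
        for f in (0.0, 0.3, 0.6, 0.9):
            spec = pf.PlaqueSpec(
                "compact", (15.0, 15.0), 10.0, density_scale=1.0, fibril_fraction=f
            )
            cube, truth = pf.simulate_scene(dataclasses.replace(base, plaques=[spec]))
            mean = cube.data[truth.plaque_masks[0]].mean(axis=0)
            sl = channel_slice(cube.axis, 1615.0, 1640.0)
            wn = cube.axis.values[sl]
            centroids.append(float((wn * mean[sl]).sum() / mean[sl].sum()))
        assert all(a > b for a, b in zip(centroids, centroids[1:]))


class TestRenderIHC:
    def test_zero_density_gives_uniform_background(self):
        cfg = pf.SceneConfig(rows=16, cols=16, seed=0)
        _, truth = pf.simulate_scene(cfg)
        img = pf.render_ihc(truth, cfg)
        assert np.allclose(img, cfg.ihc_background, atol=1e-9)

    def test_darkest_pixel_inside_densest_plaque(self, cored_scene):
        import dataclasses

        cfg, _, truth = cored_scene
        aligned = dataclasses.replace(
            cfg, ihc_magnification=1.0, ihc_rotation_deg=0.0, ihc_translation=(0.0, 0.0)
        )
        truth2 = dataclasses.replace(truth, affine=aligned.misalignment())
        img = pf.render_ihc(truth2, aligned)
        r, c = np.unravel_index(np.argmin(img[: truth.density.shape[0], : truth.density.shape[1]]), truth.density.shape)
        assert truth.plaque_masks[0][r, c]

    def test_hollow_core_brighter_at_centroid_than_rim(self):
        import dataclasses

        cfg = single_plaque_config("classic_cored", seed=5, ihc_hollow_cores=True)
        aligned = dataclasses.replace(
            cfg, ihc_magnification=1.0, ihc_rotation_deg=0.0, ihc_translation=(0.0, 0.0)
        )
        cube, truth = pf.simulate_scene(aligned)
        truth = dataclasses.replace(truth, affine=aligned.misalignment())
        img = pf.render_ihc(truth, aligned)[: truth.density.shape[0], : truth.density.shape[1]]
        core = truth.core_masks[0]
        rr, cc = np.nonzero(core)
        centroid = img[int(rr.mean()), int(cc.mean())]
        from scipy import ndimage

        rim = core & ~ndimage.binary_erosion(core, iterations=2)
        assert centroid > img[rim].mean()

    def test_intensity_monotone_decreasing_in_density(self, cored_scene):
        import dataclasses

        cfg, _, truth = cored_scene
        aligned = dataclasses.replace(
            cfg, ihc_magnification=1.0, ihc_rotation_deg=0.0, ihc_translation=(0.0, 0.0)
        )
        truth2 = dataclasses.replace(truth, affine=aligned.misalignment())
        img = pf.render_ihc(truth2, aligned)
        h, w = truth.density.shape
        d = truth.density.ravel()
        i = img[:h, :w].ravel()
        # stain saturates with density, so the association is monotone
        # rather than linear: rank correlation must be essentially 1
        from scipy.stats import spearmanr

        assert spearmanr(d, -i).statistic > 0.999


class TestControlPatches:
    def test_patches_on_empty_scene(self):
        cfg = pf.SceneConfig(rows=120, cols=120, seed=0)
        _, truth = pf.simulate_scene(cfg)
        patches = pf.sample_control_patches(truth, 1, patch_um=100.0, seed=1)
        side = round(100.0 / 1.1)
        assert patches[0].count == side * side

    def test_patches_avoid_plaques_and_each_other(self, cored_scene):
        _, _, truth = cored_scene
        patches = pf.sample_control_patches(truth, 3, patch_um=15.0, seed=2)
        occupancy = np.zeros_like(truth.density, dtype=int)
        for p in patches:
            assert not (p.mask & truth.plaque_masks[0]).any()
            assert (truth.density[p.mask] == 0).all()
            occupancy += p.mask
        assert occupancy.max() == 1

    def test_insufficient_area_raises(self, cored_scene):
        _, _, truth = cored_scene
        with pytest.raises(SamplingError):
            pf.sample_control_patches(truth, 50, patch_um=40.0, seed=3)
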