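"""Phantom simulator: geometry, determinism, ground truth, recovery behavior."""

import numpy as np
import pytest

import calscore as cs

CAL = cs.CTCalibration(pv_water=1000.0, pv_air=0.0)
NO_US = cs.USNoise.none()
NO_CT = cs.CTNoise.none()


class TestDefaultScene:
    def test_nine_specks_with_paper_masses(self):
        scene = cs.default_scene(0)
        assert [s.mass_mg for s in scene.specks] == [2, 4, 6, 8, 10, 20, 30, 40, 50]

    def test_same_seed_same_scene(self):
        a, b = cs.default_scene(7), cs.default_scene(7)
        assert a.specks == b.specks and a.rng_seed == b.rng_seed

    def test_mass_override(self):
        scene = cs.default_scene(0, masses_mg=[5])
        assert len(scene.specks) == 1 and scene.specks[0].mass_mg == 5

    def test_overlapping_specks_rejected(self):
        with pytest.raises(cs.ValidationError):
            cs.PhantomScene(
                specks=[
                    cs.Speck(mass_mg=5, center_xy_mm=(50, 50)),
                    cs.Speck(mass_mg=5, center_xy_mm=(50, 51)),
                ]
            )

    def test_speck_outside_block_rejected(self):
        with pytest.raises(cs.ValidationError):
            cs.PhantomScene(specks=[cs.Speck(mass_mg=5, center_xy_mm=(99, 50))])


class TestRenderUs:
    def test_pure_agar_stays_below_threshold(self):
        scene = cs.default_scene(0, masses_mg=[0.0])
        for noise in (NO_US, cs.USNoise()):
            stack, gt = cs.render_us(scene, "long", noise=noise)
            assert stack.pixels.max() < 130
            assert not gt.masks.any()

    def test_noiseless_threshold_mask_equals_ground_truth(self):
        scene = cs.default_scene(0)
        for axis in ("short", "long"):
            stack, gt = cs.render_us(scene, axis, speck_index=4, noise=NO_US)
            for i in range(stack.n_slices):
                mask = cs.select_calcium_mask(stack.pixels[i], 130)
                np.testing.assert_array_equal(mask, gt.masks[i])

    def test_agar_speckle_never_reaches_threshold(self):
        scene = cs.default_scene(3, masses_mg=[10.0])
        stack, gt = cs.render_us(scene, "short", noise=cs.USNoise())
        agar = stack.pixels[~gt.masks]
        assert agar.max() < 130

    def test_deterministic_given_seed(self):
        a, _ = cs.render_us(cs.default_scene(5), "long", speck_index=2)
        b, _ = cs.render_us(cs.default_scene(5), "long", speck_index=2)
        np.testing.assert_array_equal(a.pixels, b.pixels)

    def test_different_seeds_differ(self):
        a, _ = cs.render_us(cs.default_scene(5), "long", speck_index=2)
        b, _ = cs.render_us(cs.default_scene(6), "long", speck_index=2)
        assert (a.pixels != b.pixels).any()

    def test_shadowing_darkens_below_the_deposit(self):
        scene = cs.default_scene(0, masses_mg=[50.0])
        plain, gt = cs.render_us(scene, "long", noise=NO_US)
        shadowed, _ = cs.render_us(
            scene, "long",
            noise=cs.USNoise(speckle=False, agar_sigma_pv=0, calcium_sigma_pv=0,
                             shadow_db_per_mm=3.0),
        )
        mid = plain.n_slices // 2
        below = np.zeros(plain.pixels[mid].shape, dtype=bool)
        rows, cols = np.nonzero(gt.masks[mid])
        below[rows.max() + 1 :, cols.min() : cols.max() + 1] = True
        assert (shadowed.pixels[mid][below] < plain.pixels[mid][below]).all()
        np.testing.assert_array_equal(shadowed.pixels[mid][gt.masks[mid]],
                                      plain.pixels[mid][gt.masks[mid]])

    def test_mass_conserved_on_us_grid_with_nominal_density(self):
        scene = cs.default_scene(0)
        for idx in (0, 4, 8):
            stack, gt = cs.render_us(scene, "long", speck_index=idx, noise=NO_US)
            vol = gt.voxel_volume_mm3(stack.pixel_spacing_mm, stack.slice_spacing_mm)
            assert vol * cs.PACKING_DENSITY_MG_MM3 == pytest.approx(
                scene.specks[idx].mass_mg, rel=1e-9
            )
            assert gt.density_mg_per_mm3 == pytest.approx(cs.PACKING_DENSITY_MG_MM3)


class TestRenderCt:
    def test_pure_agar_scene_scores_zero(self):
        scene = cs.default_scene(0, masses_mg=[0.0])
        stack, gt = cs.render_ct(scene, CAL, noise=NO_CT)
        assert cs.hu_from_pv(float(stack.pixels.max()), CAL) < 700
        assert not gt.masks.any()

    def test_noiseless_threshold_mask_equals_ground_truth(self):
        scene = cs.default_scene(0)
        stack, gt = cs.render_ct(scene, CAL, speck_index=1, noise=NO_CT)
        pv_t = cs.pv_from_hu(700.0, CAL, as_threshold=True)
        for i in range(stack.n_slices):
            np.testing.assert_array_equal(stack.pixels[i] >= pv_t, gt.masks[i])

    def test_deterministic_given_seed(self):
        a, _ = cs.render_ct(cs.default_scene(9), CAL, speck_index=3)
        b, _ = cs.render_ct(cs.default_scene(9), CAL, speck_index=3)
        np.testing.assert_array_equal(a.pixels, b.pixels)

    def test_effective_density_recovers_mass_exactly(self):
        scene = cs.default_scene(0)
        for idx in (0, 8):
            stack, gt = cs.render_ct(scene, CAL, speck_index=idx, noise=NO_CT)
            vol = gt.voxel_volume_mm3(stack.pixel_spacing_mm, stack.slice_spacing_mm)
            assert vol * gt.density_mg_per_mm3 == pytest.approx(scene.specks[idx].mass_mg)
            # rasterized density stays close to the nominal packing density
            assert gt.density_mg_per_mm3 == pytest.approx(
                cs.PACKING_DENSITY_MG_MM3, rel=0.3
            )


class TestRenderIb:
    def test_zero_mass_gives_zero_contrast(self):
        scene = cs.default_scene(0, masses_mg=[0.0])
        for r in cs.render_ib(scene, "long"):
            assert r.ib_calcium_db == r.ib_agar_db

    def test_fixed_seed_reproducible(self):
        a = cs.render_ib(cs.default_scene(2), "short", speck_index=1, noise_sigma_db=0.5)
        b = cs.render_ib(cs.default_scene(2), "short", speck_index=1, noise_sigma_db=0.5)
        assert a == b

    def test_contrast_increases_with_mass(self):
        scene = cs.default_scene(0)
        contrasts = []
        for idx in range(9):
            readings = cs.render_ib(scene, "long", speck_index=idx)
            contrasts.append(np.mean([r.ib_calcium_db - r.ib_agar_db for r in readings]))
        assert all(b > a for a, b in zip(contrasts, contrasts[1:]))


class TestSceneScores:
    def test_us_and_ct_scores_strictly_increasing_in_mass(self, noiseless_table):
        for method in ("US", "CT"):
            sub = noiseless_table[noiseless_table.method == method].sort_values("mass_mg")
            vals = sub.value.to_numpy()
            assert (np.diff(vals) > 0).all(), f"{method} not strictly increasing: {vals}"

    def test_noiseless_score_vs_mass_linearity(self, noiseless_table):
        us = noiseless_table[noiseless_table.method == "US"].sort_values("mass_mg")
        sel = us.mass_mg <= 40
        _, r2_us, _ = cs.pearson_r2(us.mass_mg[sel], us.value[sel])
        assert r2_us >= 0.99
        ct = noiseless_table[noiseless_table.method == "CT"].sort_values("mass_mg")
        _, r2_ct, _ = cs.pearson_r2(ct.mass_mg, ct.value)
        assert r2_ct >= 0.99

    def test_us_brightness_saturates_towards_the_ceiling(self):
        # deposit brightness is concave in areal density and bounded by 250:
        # equal mass increments buy less brightness at the top of the range
        rho = np.array([2.0, 12.0, 40.0, 50.0]) / 45.0  # mg per mm2 footprint
        mu = np.array([cs.us_mean_intensity(r) for r in rho])
        assert mu[3] - mu[2] < mu[1] - mu[0]  # same 10 mg step, smaller gain
        assert mu.max() < 250.0
        assert (np.diff(mu) > 0).all()

    def test_us_and_cib_scores_concordant(self, noiseless_table):
        us = noiseless_table[noiseless_table.method == "US"].sort_values("speck_id").value
        cib = noiseless_table[noiseless_table.method == "cIB"].sort_values("speck_id").value
        _, r2, _ = cs.pearson_r2(us, cib)
        assert r2 > 0.9
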