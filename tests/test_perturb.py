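"""Perturbation modes: rigid transform, noise, contour randomization, sampling."""

import numpy as np
import pytest

from radrobust.perturb import (
    PerturbationGrid,
    PerturbationRealization,
    _raw_uniform_field,
    add_noise,
    apply_realization,
    estimate_noise,
    randomize_contour,
    rigid_transform,
    sample_realizations,
)
from radrobust.phantom import PhantomSpec, generate_phantom
from radrobust.volume import dice


class TestSampleRealizations:
    def test_default_grid_yields_sixty(self):
        assert len(sample_realizations(PerturbationGrid(), seed=0)) == 60

    def test_singleton_sets_give_constant_parameters(self):
        grid = PerturbationGrid(
            translations_px=(0.0,), rotations_deg=(0.0,), noise_multipliers=(0.0,),
            n_realizations=10,
        )
        reals = sample_realizations(grid, seed=1)
        assert {(r.tx_px, r.ty_px, r.angle_deg, r.noise_multiplier) for r in reals} == {
            (0.0, 0.0, 0.0, 0.0)
        }

    def test_fixed_seed_reproducible(self):
        a = sample_realizations(PerturbationGrid(), seed=5)
        b = sample_realizations(PerturbationGrid(), seed=5)
        assert a == b

    def test_parameters_come_from_grid_sets(self):
        grid = PerturbationGrid(n_realizations=200)
        for r in sample_realizations(grid, seed=2):
            assert r.tx_px in grid.translations_px
            assert r.ty_px in grid.translations_px
            assert r.angle_deg in grid.rotations_deg
            assert r.noise_multiplier in grid.noise_multipliers


class TestRigidTransform:
    def test_identity_is_bit_exact(self, textured_phantom):
        out = rigid_transform(textured_phantom, 0.0, 0.0, 0.0)
        assert np.array_equal(out.image, textured_phantom.image)
        assert np.array_equal(out.mask, textured_phantom.mask)

    def test_integer_shift_moves_values_exactly(self, quiet_phantom):
        out = rigid_transform(quiet_phantom, 3.0, 2.0, 0.0)
        rolled = np.roll(quiet_phantom.image, shift=(2, 3), axis=(1, 2))
        # away from the grid boundary the shift is exact
        assert np.allclose(out.image[:, 5:-5, 5:-5], rolled[:, 5:-5, 5:-5])
        rolled_mask = np.roll(quiet_phantom.mask, shift=(2, 3), axis=(1, 2))
        assert np.array_equal(out.mask[:, 5:-5, 5:-5], rolled_mask[:, 5:-5, 5:-5])

    def test_rotation_composed_with_inverse_is_near_identity(self, quiet_phantom):
        fwd = rigid_transform(quiet_phantom, 0.0, 0.0, 20.0)
        back = rigid_transform(fwd, 0.0, 0.0, -20.0)
        assert dice(back.mask, quiet_phantom.mask) > 0.98

    def test_empty_mask_rejected(self, textured_phantom):
        vm = textured_phantom.copy()
        vm.mask[:] = False
        with pytest.raises(ValueError, match="center"):
            rigid_transform(vm, 0.1, 0.0, 0.0)


class TestEstimateNoise:
    def test_noise_free_phantom_near_zero(self):
        vm = generate_phantom(
            PhantomSpec(noise_sigma_hu=0.0, texture_amplitude_hu=0.0)
        )
        assert estimate_noise(vm) < 0.5

    @pytest.mark.parametrize("sigma", [5.0, 10.0, 20.0])
    def test_injected_noise_recovered(self, sigma):
        vm = generate_phantom(PhantomSpec(noise_sigma_hu=sigma, seed=21))
        assert estimate_noise(vm) == pytest.approx(sigma, rel=0.15)

    def test_dc_offset_invariance(self, textured_phantom):
        shifted = textured_phantom.copy()
        shifted.image += 100.0
        a, b = estimate_noise(textured_phantom), estimate_noise(shifted)
        assert a == pytest.approx(b, rel=0.10)

    def test_too_few_body_voxels_rejected(self):
        vm = generate_phantom(PhantomSpec(seed=0))
        vm = vm.copy()
        vm.image[:] = -1000.0  # all air
        with pytest.raises(ValueError, match="body voxels"):
            estimate_noise(vm)


class TestAddNoise:
    def test_zero_multiplier_is_identity(self, textured_phantom):
        out = add_noise(textured_phantom, 0.0, 10.0, seed=1)
        assert np.array_equal(out.image, textured_phantom.image)

    def test_injected_std_matches_request(self, textured_phantom):
        out = add_noise(textured_phantom, 2.0, 10.0, seed=2)
        delta = out.image - textured_phantom.image
        assert delta.size >= 10**5
        assert 19.8 <= delta.std() <= 20.2

    def test_mask_untouched_and_seeds_differ(self, textured_phantom):
        a = add_noise(textured_phantom, 1.0, 10.0, seed=1)
        b = add_noise(textured_phantom, 1.0, 10.0, seed=2)
        assert np.array_equal(a.mask, textured_phantom.mask)
        assert not np.array_equal(a.image, b.image)

    def test_mean_shift_is_small(self, textured_phantom):
        out = add_noise(textured_phantom, 5.0, 10.0, seed=3)
        n = textured_phantom.image.size
        assert abs(out.image.mean() - textured_phantom.image.mean()) < 3 * 50 / np.sqrt(n)


class TestRandomizeContour:
    def test_zero_amplitude_is_identity(self, textured_phantom):
        out = randomize_contour(textured_phantom, 10.0, 0.0, seed=1)
        assert np.array_equal(out.mask, textured_phantom.mask)

    def test_sphere_dice_within_expected_band(self):
        vm = generate_phantom(
            PhantomSpec(
                grid_shape=(64, 64, 64), spacing_mm=(1, 1, 1),
                tumor_axes_mm=(20, 20, 20), noise_sigma_hu=0, texture_amplitude_hu=0,
            )
        )
        d = dice(randomize_contour(vm, 10.0, 1.0, seed=4).mask, vm.mask)
        assert 0.85 < d < 1.0

    def test_volume_preserved_within_20pct(self):
        vm = generate_phantom(
            PhantomSpec(
                grid_shape=(64, 64, 64), spacing_mm=(1, 1, 1),
                tumor_axes_mm=(15, 15, 15), noise_sigma_hu=0, texture_amplitude_hu=0,
            )
        )
        for seed in range(5):
            out = randomize_contour(vm, 10.0, 1.0, seed=seed)
            assert out.mask.sum() == pytest.approx(vm.mask.sum(), rel=0.2)

    def test_raw_field_z_component_constant_per_slice(self, rng):
        uz, uy, ux = _raw_uniform_field((6, 8, 8), rng)
        for z in range(6):
            assert np.unique(uz[z]).size == 1
        assert np.unique(uy).size > 1

    def test_image_untouched(self, textured_phantom):
        out = randomize_contour(textured_phantom, 10.0, 1.0, seed=7)
        assert np.array_equal(out.image, textured_phantom.image)


class TestApplyRealization:
    def test_identity_realization_is_noop(self, textured_phantom):
        r = PerturbationRealization(0, 0, 0, 0, contour_seed=1, contour_amplitude_vox=0)
        out = apply_realization(textured_phantom, r, sigma_hu=10.0)
        assert np.array_equal(out.image, textured_phantom.image)
        assert np.array_equal(out.mask, textured_phantom.mask)

    def test_sixty_realizations_vary_the_mask(self, quiet_phantom):
        reals = sample_realizations(PerturbationGrid(), seed=3)
        counts = {
            apply_realization(quiet_phantom, r, sigma_hu=5.0, mask_only=True).mask.sum()
            for r in reals[:20]
        }
        assert len(counts) > 1

    def test_reproducible_given_realization(self, quiet_phantom):
        r = sample_realizations(PerturbationGrid(), seed=8)[0]
        a = apply_realization(quiet_phantom, r, sigma_hu=5.0)
        b = apply_realization(quiet_phantom, r, sigma_hu=5.0)
        assert np.array_equal(a.image, b.image)
        assert np.array_equal(a.mask, b.mask)

    def test_mask_only_path_produces_identical_mask(self, quiet_phantom):
        for r in sample_realizations(PerturbationGrid(), seed=9)[:5]:
            full = apply_realization(quiet_phantom, r, sigma_hu=5.0)
            fast = apply_realization(quiet_phantom, r, sigma_hu=5.0, mask_only=True)
            assert np.array_equal(full.mask, fast.mask)

    def test_mask_stays_binary_through_chain(self, quiet_phantom):
        r = sample_realizations(PerturbationGrid(), seed=10)[1]
        out = apply_realization(quiet_phantom, r, sigma_hu=5.0)
        assert out.mask.dtype == bool and out.mask.any()
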