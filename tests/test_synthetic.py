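"""Phantom presets, dose maps, frame simulation and setup perturbation."""

import dataclasses

import numpy as np
import pytest

from cherenkovdsc import (
    CherenkovImage,
    DeliverySpec,
    FrameStack,
    accumulate_frames,
    apply_rigid_transform,
    cie_lightness,
    default_delivery,
    expected_accumulated_background,
    generate_dose_map,
    make_phantom_presets,
    noiseless,
    perturb_setup,
    simulate_family_images,
    simulate_frames,
)
from cherenkovdsc.synthetic import expected_frame_means


class TestPresets:
    def test_six_types_with_study_mi_endpoints(self, presets):
        assert [p.fitzpatrick_type for p in presets] == ["I", "II", "III", "IV", "V", "VI"]
        mi = [p.melanin_index for p in presets]
        assert mi == pytest.approx([37.0, 53.6, 70.2, 86.8, 103.4, 120.0], abs=1e-9)

    def test_reflectance_follows_mi_formula(self, presets):
        assert presets[5].rr_680 == pytest.approx(10**-1.2, rel=1e-12)
        assert presets[5].rr_680 == pytest.approx(0.0631, abs=1e-4)

    def test_lightness_decreases_with_mi(self, presets):
        l_stars = [p.l_star for p in presets]
        assert all(0.0 <= v <= 100.0 for v in l_stars)
        assert np.all(np.diff(l_stars) < 0)
        assert presets[0].l_star == pytest.approx(cie_lightness(presets[0].rr_680))


class TestDoseMaps:
    def test_shapes_and_positivity(self, dose_maps, config):
        for dm in dose_maps.values():
            assert dm.shape == config.shape
            assert np.all(dm.values >= 0.0)
            assert np.all(np.isfinite(dm.values))
            assert dm.values.max() > 0.0

    def test_hotspot_caps(self, dose_maps, config):
        p = config.prescription
        assert dose_maps["tangent"].values.max() == pytest.approx(1.10 * p)
        assert dose_maps["field_in_field"].values.max() == pytest.approx(1.05 * p)
        assert dose_maps["vmat"].values.max() == pytest.approx(1.00 * p)
        # sub-field hotspot reduction: FIF never exceeds the tangent plan
        assert dose_maps["field_in_field"].values.max() <= dose_maps["tangent"].values.max()

    def test_vmat_out_of_field_bath(self, dose_maps, config):
        corner = dose_maps["vmat"].values[:8, :8]
        assert corner == pytest.approx(0.02 * config.prescription)
        assert dose_maps["tangent"].values[:8, :8] == pytest.approx(0.0)

    def test_30pct_footprint_identical_across_plans(self, dose_maps):
        masks = [dm.footprint(0.30) for dm in dose_maps.values()]
        assert all(np.array_equal(masks[0], m) for m in masks[1:])
        assert masks[0].sum() > 0

    def test_mirror_symmetry(self, dose_maps):
        for dm in dose_maps.values():
            assert np.array_equal(dm.values, dm.values[:, ::-1])

    def test_unknown_plan_and_small_shape_rejected(self):
        with pytest.raises(ValueError):
            generate_dose_map("arc")
        with pytest.raises(ValueError):
            generate_dose_map("tangent", shape=(32, 32))


class TestDeliverySpec:
    def test_defaults_encode_vmat_monitor_unit_burden(self):
        tangent = default_delivery("tangent")
        vmat = default_delivery("vmat")
        assert vmat.n_frames > tangent.n_frames
        assert vmat.mu_factor > 1.0 >= tangent.mu_factor
        assert tangent.ambient_per_frame > 0.0

    def test_invalid_values_rejected(self):
        with pytest.raises(ValueError):
            DeliverySpec("tangent", n_frames=0, mu_factor=1.0,
                         ambient_per_frame=0, leakage_per_frame=0, read_noise_sigma=0)
        with pytest.raises(ValueError):
            DeliverySpec("tangent", n_frames=10, mu_factor=1.0,
                         ambient_per_frame=-0.1, leakage_per_frame=0, read_noise_sigma=0)

    def test_background_ratio_matches_closed_form(self):
        tangent = default_delivery("tangent")
        vmat = default_delivery("vmat")
        ratio = expected_accumulated_background(vmat) / expected_accumulated_background(tangent)
        expected = (
            vmat.n_frames * (vmat.ambient_per_frame + vmat.leakage_per_frame * vmat.mu_factor)
        ) / (
            tangent.n_frames
            * (tangent.ambient_per_frame + tangent.leakage_per_frame * tangent.mu_factor)
        )
        assert ratio == pytest.approx(expected, rel=1e-12)
        assert ratio > 1.0  # VMAT accumulates more background


class TestSimulation:
    def test_same_seed_bitwise_identical(self, dose_maps, presets, model):
        delivery = default_delivery("tangent")
        a = simulate_frames(dose_maps["tangent"], presets[0], model, delivery, seed=42)
        b = simulate_frames(dose_maps["tangent"], presets[0], model, delivery, seed=42)
        assert np.array_equal(a.frames, b.frames)
        c = simulate_frames(dose_maps["tangent"], presets[0], model, delivery, seed=43)
        assert not np.array_equal(a.frames, c.frames)

    def test_noiseless_accumulation_proportional_to_dose(self, dose_maps, presets, model):
        delivery = noiseless(default_delivery("tangent"))
        stack = simulate_frames(dose_maps["tangent"], presets[0], model, delivery, seed=0)
        image = accumulate_frames(stack)
        # reference tone: transmission 1, so the image is the dose map itself
        assert np.allclose(image.values, dose_maps["tangent"].values, rtol=1e-9)

    def test_accumulated_signal_conserved_across_delivery(self, dose_maps, presets, model):
        # same planned dose split over different frame counts accumulates the
        # same expected signal (fluence conservation under per-frame scaling)
        dose = dose_maps["tangent"]
        totals = []
        for plan in ("tangent", "field_in_field", "vmat"):
            d = noiseless(default_delivery(plan))
            totals.append(expected_frame_means(dose, presets[0], model, d).sum() * d.n_frames)
        assert totals[1] == pytest.approx(totals[0], rel=1e-12)
        assert totals[2] == pytest.approx(totals[0], rel=1e-12)

    def test_out_of_field_background_expectation(self, dose_maps, presets, model):
        # analytic accumulated background, verified within 3 Monte-Carlo SE
        # (read noise off: the zero-clip of read noise adds a small bias)
        delivery = dataclasses.replace(default_delivery("vmat"), read_noise_sigma=0.0)
        stack = simulate_frames(dose_maps["tangent"], presets[0], model, delivery, seed=7)
        image = accumulate_frames(stack)
        region = image.values[:20, :20]  # far out of field: dose exactly zero
        expected = expected_accumulated_background(delivery)
        mc_se = np.sqrt(expected / region.size)  # Poisson variance of the mean
        assert abs(region.mean() - expected) < 3.0 * mc_se

    def test_all_values_finite_nonnegative(self, dose_maps, presets, model):
        stack = simulate_frames(
            dose_maps["vmat"], presets[5], model, default_delivery("vmat"), seed=3
        )
        assert np.all(np.isfinite(stack.frames)) and np.all(stack.frames >= 0.0)

    def test_light_to_dark_intensity_ratio_is_ten(self, dose_maps, presets, model):
        # noiseless, background-free: preset I vs preset VI in-field means
        # differ by exactly the calibrated factor of 10
        delivery = noiseless(default_delivery("tangent"))
        mask = dose_maps["tangent"].footprint(0.30)
        means = {}
        for p in (presets[0], presets[5]):
            img = accumulate_frames(
                simulate_frames(dose_maps["tangent"], p, model, delivery, seed=0)
            )
            means[p.fitzpatrick_type] = img.values[mask].mean()
        assert means["I"] / means["VI"] == pytest.approx(10.0, rel=1e-12)


class TestFamilySimulation:
    def test_marginal_matches_single_tone_statistics(self, dose_maps, presets, model):
        # coupled draw is reproducible and marginally sane: noiseless family
        # images equal the single-tone noiseless accumulations exactly
        delivery = noiseless(default_delivery("tangent"), keep_background=True)
        family = simulate_family_images(
            dose_maps["tangent"], presets, model, delivery, seed=5
        )
        for p in (presets[0], presets[5]):
            single = accumulate_frames(
                simulate_frames(dose_maps["tangent"], p, model, delivery, seed=5)
            )
            assert np.allclose(family[p.fitzpatrick_type].values, single.values, rtol=1e-9)

    def test_coupled_images_pointwise_ordered_by_tone(self, dose_maps, presets, model):
        delivery = dataclasses.replace(default_delivery("tangent"), read_noise_sigma=0.0)
        family = simulate_family_images(
            dose_maps["tangent"], presets, model, delivery, seed=11
        )
        order = [p.fitzpatrick_type for p in presets]
        for light, dark in zip(order, order[1:]):
            assert np.all(family[light].values >= family[dark].values)

    def test_reproducible(self, dose_maps, presets, model):
        delivery = default_delivery("field_in_field")
        a = simulate_family_images(dose_maps["field_in_field"], presets, model, delivery, 9)
        b = simulate_family_images(dose_maps["field_in_field"], presets, model, delivery, 9)
        for k in a:
            assert np.array_equal(a[k].values, b[k].values)


class TestAccumulate:
    def test_single_frame_identity(self, rng):
        delivery = DeliverySpec("tangent", 1, 1.0, 0.0, 0.0, 0.0)
        frame = rng.random((8, 8))
        stack = FrameStack(frames=frame[None], delivery=delivery, seed=0)
        image = accumulate_frames(stack)
        assert np.array_equal(image.values, frame)
        assert image.n_frames_summed == 1

    def test_constant_frames_sum(self):
        delivery = DeliverySpec("tangent", 4, 1.0, 0.0, 0.0, 0.0)
        stack = FrameStack(frames=np.full((4, 6, 6), 2.5), delivery=delivery, seed=0)
        assert accumulate_frames(stack).values == pytest.approx(10.0)

    def test_empty_stack_rejected(self):
        delivery = DeliverySpec("tangent", 1, 1.0, 0.0, 0.0, 0.0)
        with pytest.raises(ValueError):
            FrameStack(frames=np.empty((0, 4, 4)), delivery=delivery, seed=0)
        good = FrameStack(frames=np.zeros((1, 4, 4)), delivery=delivery, seed=0)
        good.frames = np.empty((0, 4, 4))
        with pytest.raises(ValueError):
            accumulate_frames(good)


class TestPerturbSetup:
    def test_zero_magnitude_is_identity(self, rng):
        image = CherenkovImage(values=rng.random((32, 32)), n_frames_summed=1)
        out = perturb_setup(image, seed=0, max_shift_px=0.0, max_rotation_deg=0.0)
        assert np.array_equal(out.values, image.values)

    def test_integer_translation_moves_argmax_exactly(self):
        values = np.zeros((21, 21))
        values[10, 10] = 1.0
        moved = apply_rigid_transform(values, shift_px=(2.0, -1.0), angle_deg=0.0)
        assert np.unravel_index(np.argmax(moved), moved.shape) == (12, 9)
        assert moved[12, 9] == pytest.approx(1.0)

    def test_same_seed_same_transform(self, rng):
        image = CherenkovImage(values=rng.random((64, 64)), n_frames_summed=1)
        a = perturb_setup(image, seed=21)
        b = perturb_setup(image, seed=21)
        assert np.array_equal(a.values, b.values)
        c = perturb_setup(image, seed=22)
        assert not np.array_equal(a.values, c.values)
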