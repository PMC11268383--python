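"""Hyperspectral RandAugment: plan sampling and every transform's contract."""

import numpy as np
import pytest
from scipy.optimize import linear_sum_assignment

from hsipath.augment import (
    TRANSFORMS,
    AugmentPlan,
    NMFConfig,
    TransformRanges,
    add_spectral_noise,
    adjust_brightness,
    adjust_contrast,
    apply_geometric,
    apply_plan,
    apply_spectral_ramp,
    contrast_formula,
    nmf_stain_augment,
    od_nmf,
    rand_augment,
    sample_plan,
    sharpen_bands,
    spectral_ramp_factor,
    zero_bands,
)
from hsipath.cube import TRANSMITTANCE, Hypercube


class TestPlanSampling:
    def test_plan_length_and_bounds(self):
        ranges = TransformRanges()
        for seed in range(20):
            plan = sample_plan(ranges, np.random.default_rng(seed))
            assert len(plan.steps) == 3
            for name, strength, _ in plan.steps:
                lo, hi = ranges.bounds_for(name)
                assert lo <= strength <= hi

    def test_same_seed_same_plan(self):
        ranges = TransformRanges()
        p1 = sample_plan(ranges, np.random.default_rng(99))
        p2 = sample_plan(ranges, np.random.default_rng(99))
        assert p1.steps == p2.steps

    def test_uniform_over_13_transforms(self):
        # 10,000 plans = 30,000 slots; each transform count ~ Binomial(n, 1/13)
        ranges = TransformRanges()
        rng = np.random.default_rng(0)
        counts = {t: 0 for t in TRANSFORMS}
        n_plans = 10_000
        for _ in range(n_plans):
            for name, _, _ in sample_plan(ranges, rng).steps:
                counts[name] += 1
        n = 3 * n_plans
        p = 1.0 / len(TRANSFORMS)
        sigma = np.sqrt(n * p * (1 - p))
        for t, c in counts.items():
            assert abs(c - n * p) < 4 * sigma, f"{t}: {c}"

    def test_plan_must_hold_three_steps(self):
        with pytest.raises(ValueError, match="3"):
            AugmentPlan(steps=[("identity", 0.0, {})])

    def test_invalid_ranges(self):
        with pytest.raises(ValueError):
            TransformRanges(rotate=(1.0, 0.5))
        with pytest.raises(ValueError, match="integer"):
            TransformRanges(zeroing=(0, 2.5))


class TestGeometric:
    def test_quarter_turn_matches_index_permutation(self, small_cube):
        out = apply_geometric(small_cube, "rotate", np.pi / 2, fill=1.0)
        n = small_cube.shape[0]
        oracle = np.empty_like(small_cube.data)
        for r in range(n):
            for c in range(n):
                oracle[r, c] = small_cube.data[n - 1 - c, r]
        np.testing.assert_allclose(out.data, oracle, atol=1e-12)

    def test_zero_translation_is_identity(self, small_cube):
        out = apply_geometric(small_cube, "translateX", 0.0)
        np.testing.assert_allclose(out.data, small_cube.data, atol=1e-12)

    def test_half_frame_translation(self, wl8):
        rng = np.random.default_rng(3)
        cube = Hypercube(rng.random((100, 100, 8)), wl8, TRANSMITTANCE)
        out = apply_geometric(cube, "translateY", 0.5, fill=0.25)
        np.testing.assert_allclose(out.data[:50], 0.25)
        np.testing.assert_allclose(out.data[50:], cube.data[:50], atol=1e-12)

    def test_same_map_on_every_band(self, small_cube):
        out = apply_geometric(small_cube, "shearX", 0.3, fill=0.0)
        # shearing a band individually must equal the corresponding output band
        single = Hypercube(
            small_cube.data[:, :, :1], small_cube.wavelengths[:1], TRANSMITTANCE
        )
        np.testing.assert_allclose(
            apply_geometric(single, "shearX", 0.3, fill=0.0).data[:, :, 0],
            out.data[:, :, 0],
        )

    def test_unknown_kind(self, small_cube):
        with pytest.raises(ValueError, match="unknown"):
            apply_geometric(small_cube, "twist", 0.1)


class TestIntensityTransforms:
    def test_brightness_arithmetic(self, wl8):
        cube = Hypercube(np.full((4, 4, 8), 0.2), wl8, TRANSMITTANCE)
        cube.data[0, 0, 0] = 0.4  # max
        out = adjust_brightness(cube, 0.5)
        assert out.data[1, 1, 1] == pytest.approx(0.2 + 0.5 * 0.4, abs=1e-12)

    def test_brightness_saturates(self, small_cube):
        out = adjust_brightness(small_cube, 1.0)
        mx = small_cube.data.max()
        assert (out.data[small_cube.data + mx >= 1.0] == 1.0).all()

    def test_contrast_zero_is_identity(self, small_cube):
        out = adjust_contrast(small_cube, 0.0)
        np.testing.assert_allclose(out.data, small_cube.data, atol=1e-12)

    @pytest.mark.parametrize("C", [0.0, 0.3, 0.9, 1.5, 2.0])
    def test_contrast_midpoint_fixed(self, C):
        assert contrast_formula(0.5, C) == pytest.approx(0.5, abs=1e-12)

    def test_contrast_printed_example(self, wl8):
        # direct evaluation of the published equation, independent arithmetic
        expected = 1.0157 * (0.5 + 1.0) * (0.75 - 0.5) / (1.0157 - 0.5) + 0.5
        assert contrast_formula(0.75, 0.5) == pytest.approx(expected, abs=1e-12)
        assert round(float(contrast_formula(0.75, 0.5)), 4) == 1.2386
        cube = Hypercube(np.full((2, 2, 8), 0.75), wl8, TRANSMITTANCE)
        assert (adjust_contrast(cube, 0.5).data == 1.0).all()  # post-clip

    def test_sharpen_constant_band_unchanged(self, wl8):
        cube = Hypercube(np.full((10, 10, 8), 0.4), wl8, TRANSMITTANCE)
        out = sharpen_bands(cube, 4.0)
        np.testing.assert_allclose(out.data, 0.4, atol=1e-12)

    def test_sharpen_overshoots_step_edge(self, wl8):
        data = np.zeros((10, 10, 8))
        data[:, 5:] = 0.5
        cube = Hypercube(data, wl8, TRANSMITTANCE)
        out = sharpen_bands(cube, 1.0)
        # hand-convolved 3x3 mean on the edge columns: blur at col 4 is 0.5/3,
        # so I + (I - blur) undershoots to -0.5/3 -> clipped 0; col 5 overshoots
        assert (out.data[:, 4] == 0.0).all()
        assert out.data[0, 5, 0] == pytest.approx(0.5 + 0.5 / 3.0, abs=1e-12)


class TestSpectralTransforms:
    def test_noise_offsets_shift_band_means(self, wl8):
        cube = Hypercube(np.full((20, 20, 8), 0.2), wl8, TRANSMITTANCE)
        out, delta = add_spectral_noise(cube, 0.5, np.random.default_rng(5))
        pre = cube.data.mean(axis=(0, 1))
        post = out.data.mean(axis=(0, 1))
        np.testing.assert_allclose(post - pre, delta, atol=1e-12)

    def test_noise_seeded_determinism(self, small_cube):
        a, _ = add_spectral_noise(small_cube, 0.3, np.random.default_rng(11))
        b, _ = add_spectral_noise(small_cube, 0.3, np.random.default_rng(11))
        np.testing.assert_array_equal(a.data, b.data)

    def test_ramp_anchor_band_unchanged(self):
        wl = np.array([500.0, 550.0, 600.0, 650.0, 700.0])
        cube = Hypercube(np.full((4, 4, 5), 0.3), wl, TRANSMITTANCE)
        for A in (0.0, 0.7, 2.0):
            out = apply_spectral_ramp(cube, A)
            np.testing.assert_allclose(out.data[:, :, 2], 0.3, atol=1e-12)

    def test_ramp_factor_arithmetic(self):
        wl = np.linspace(467.0, 721.0, 84)
        f = spectral_ramp_factor(wl, 2.0)
        assert f[-1] == pytest.approx(1.0 + 2.0 * (721 - 600) / (721 - 467), abs=1e-12)

    def test_zeroing_band_integrity(self, wl84):
        rng_data = np.random.default_rng(0).random((8, 8, 84))
        cube = Hypercube(rng_data, wl84, TRANSMITTANCE)
        out = zero_bands(cube, 3, np.random.default_rng(21))
        zeroed = [b for b in range(84) if (out.data[:, :, b] == 0).all()]
        assert len(zeroed) == 3
        keep = [b for b in range(84) if b not in zeroed]
        np.testing.assert_array_equal(out.data[:, :, keep], cube.data[:, :, keep])

    def test_zeroing_seeded_band_choice(self, small_cube):
        a = zero_bands(small_cube, 2, np.random.default_rng(4))
        b = zero_bands(small_cube, 2, np.random.default_rng(4))
        np.testing.assert_array_equal(a.data, b.data)


class TestNMFStainTransform:
    def test_gamma_one_equals_plain_reconstruction(self, rendered_cancer):
        cube, _, _ = rendered_cancer
        out = nmf_stain_augment(cube, gamma=1.0, seed=0)
        w, s, _ = od_nmf(cube, NMFConfig(), 0)
        recon = np.clip(
            10.0 ** (-(w @ s).reshape(cube.shape)), 0.0, 1.0
        )
        np.testing.assert_allclose(out.data, recon, atol=1e-8)

    def test_objective_nonincreasing_along_iterations(self, rendered_cancer):
        cube, _, _ = rendered_cancer
        errs = []
        for it in (5, 20, 60, 150):
            w, s, od = od_nmf(cube, NMFConfig(max_iter=it, tol=0.0), 0)
            errs.append(np.linalg.norm(od - w @ s))
        assert all(a >= b - 1e-10 for a, b in zip(errs, errs[1:]))

    def test_accepts_transmittance_above_one(self, wl8):
        # calibrated cubes may exceed 1 where tissue outshines the blank
        # reference; the OD factorization must clamp rather than fail
        rng = np.random.default_rng(0)
        cube = Hypercube(1.2 * rng.random((16, 16, 8)), wl8, TRANSMITTANCE)
        out = nmf_stain_augment(cube, gamma=0.8, seed=1)
        assert out.data.min() >= 0.0 and out.data.max() <= 1.0

    def test_endmember_recovery_on_synthetic_scene(self, rendered_cancer):
        cube, _, basis = rendered_cancer
        _, s, _ = od_nmf(cube, NMFConfig(), 0)
        S = basis.spectra
        C = np.array(
            [
                [
                    S[i] @ s[j] / (np.linalg.norm(S[i]) * np.linalg.norm(s[j]))
                    for j in range(3)
                ]
                for i in range(3)
            ]
        )
        r, c = linear_sum_assignment(-C)
        assert C[r, c].mean() >= 0.95


class TestComposition:
    def test_identity_plan_is_noop(self, small_cube):
        plan = AugmentPlan([("identity", 0.0, {})] * 3)
        out = apply_plan(small_cube, plan)
        np.testing.assert_array_equal(out.data, small_cube.data)

    def test_seeded_reproducibility(self, small_cube):
        a = rand_augment(small_cube, rng=1234)
        b = rand_augment(small_cube, rng=1234)
        np.testing.assert_array_equal(a.data, b.data)

    @pytest.mark.parametrize("seed", range(15))
    def test_shape_wavelengths_and_range_preserved(self, small_cube, seed):
        out = rand_augment(small_cube, rng=seed)
        assert out.shape == small_cube.shape
        np.testing.assert_array_equal(out.wavelengths, small_cube.wavelengths)
        assert out.data.min() >= 0.0 and out.data.max() <= 1.0

    @pytest.mark.parametrize(
        "name",
        [t for t in TRANSFORMS if t != "nmf"],
    )
    def test_low_end_strength_is_identity(self, small_cube, name):
        ranges = TransformRanges()
        lo, _ = ranges.bounds_for(name)
        plan = AugmentPlan(
            [(name, float(lo), {"seed": 0, "direction": 1}), ("identity", 0.0, {}), ("identity", 0.0, {})]
        )
        out = apply_plan(small_cube, plan)
        np.testing.assert_allclose(out.data, small_cube.data, atol=1e-8)

    def test_batch_transformer_reproducible_per_sample(self, wl8):
        from hsipath.augment import HyperspectralRandAugment

        X = np.random.default_rng(0).random((4, 16, 16, 8))
        aug = HyperspectralRandAugment(wavelengths=wl8, random_state=5)
        full = aug.transform(X, sample_ids=np.arange(4))
        last = aug.transform(X[2:], sample_ids=np.arange(2, 4))
        np.testing.assert_array_equal(full[2:], last)
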