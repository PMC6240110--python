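"""Gradient quantification: ratio images, linescans, normalization, metrics."""

import math

import numpy as np
import pytest

from rhograd.errors import (
    DegenerateNormalizationError,
    FitError,
    GeometryError,
    InvalidParameterError,
)
from rhograd.quant import (
    ProfileEnsemble,
    average_ensemble,
    detect_peak,
    edge_enrichment_fraction,
    fit_bump_decay,
    fit_decay_length,
    linescan,
    measure_extent,
    normalize_profile,
    pointwise_compare,
    profiles_match,
    ratio_image,
    subtract_prestimulus,
)
from rhograd.synth import GeneratorConfig, render_cell_images, sample_fret_profiles


def disk_mask(h, w, radius, center=None):
    cy, cx = center or ((h - 1) / 2, (w - 1) / 2)
    yy, xx = np.mgrid[0:h, 0:w]
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2


class TestRatioImage:
    def test_uniform_ratio(self):
        mask = disk_mask(64, 64, 20)
        donor = np.where(mask, 100.0, 5.0)
        fret = 2.0 * donor
        out = ratio_image(fret, donor, mask)
        assert np.allclose(out[mask], 2.0)
        assert np.all(np.isnan(out[~mask]))

    def test_background_subtraction_invariance(self):
        mask = disk_mask(64, 64, 20)
        bg_region = ~disk_mask(64, 64, 28)
        donor = np.where(mask, 100.0, 0.0)
        fret = np.where(mask, 150.0, 0.0)
        plain = ratio_image(fret, donor, mask)
        shifted = ratio_image(fret + 30.0, donor + 30.0, mask, background_region=bg_region)
        np.testing.assert_allclose(shifted[mask], plain[mask], rtol=1e-9)

    def test_low_donor_signal_raises(self):
        mask = disk_mask(64, 64, 20)
        donor = np.where(mask, 1.0, 0.0)
        with pytest.raises(FitError):
            ratio_image(donor, donor, mask, background=(0.0, 5.0))


class TestSubtractPrestimulus:
    def test_noiseless_differential_is_exact_signal(self, gen_config, rac1_shape):
        x = gen_config.positions
        stack = render_cell_images(
            rac1_shape.evaluate(x), x, gen_config, noiseless=True, n_prestim=2,
            n_frames=3,
        )
        diff = subtract_prestimulus(stack)
        amp = stack.metadata["amplitude"]
        # reporter differential equals the rendered signal, no baseline left
        assert diff.metadata["clipped_fraction"] == pytest.approx(0.0, abs=1e-12)
        h, w = stack.mask.shape
        centre = (h // 2, w // 2)
        # distance of that pixel from the bright cell edge along the axis
        px = gen_config.pixel_size
        dist = (centre[1] - (w - 1) / 2) * px + stack.metadata["diameter_um"] / 2
        assert diff.frames[0, 0][centre] == pytest.approx(
            amp * np.interp(dist, x, rac1_shape.evaluate(x)), rel=1e-6
        )

    def test_unstimulated_stack_is_noise_level(self, gen_config, cdc42_shape):
        x = gen_config.positions
        stack = render_cell_images(
            np.zeros_like(x), x, gen_config, n_prestim=3, n_frames=3,
            rng=np.random.default_rng(0),
        )
        diff = subtract_prestimulus(stack)
        inside = diff.frames[:, 0][:, stack.mask]
        assert np.mean(inside) < 20.0  # half-normal residue of read+shot noise

    def test_clipped_fraction_small_at_default_noise(self, gen_config, rac1_shape):
        x = gen_config.positions
        stack = render_cell_images(
            rac1_shape.evaluate(x), x, gen_config, rng=np.random.default_rng(1)
        )
        diff = subtract_prestimulus(stack)
        # clipping only affects sub-noise pixels (outside mask and dim cell rear)
        assert diff.metadata["clipped_fraction"] < 0.5

    def test_requires_prestimulus_frames(self, gen_config, rac1_shape):
        x = gen_config.positions
        stack = render_cell_images(rac1_shape.evaluate(x), x, gen_config, n_prestim=0)
        with pytest.raises(InvalidParameterError):
            subtract_prestimulus(stack)


class TestLinescan:
    def make_gradient_image(self, gen_config, shape):
        x = gen_config.positions
        stack = render_cell_images(shape.evaluate(x), x, gen_config, noiseless=True)
        img = stack.frames[-1, 0] - stack.metadata["baseline"] * stack.mask
        return stack, img

    def test_roundtrip_recovers_profile(self, gen_config, cdc42_shape):
        stack, img = self.make_gradient_image(gen_config, cdc42_shape)
        px = gen_config.pixel_size
        h, w = img.shape
        radius_px = stack.metadata["diameter_um"] / 2 / px
        origin = ((h - 1) / 2, (w - 1) / 2 - radius_px + 1)
        ls = linescan(img, origin, 0.0, length=18.0, width=10, pixel_size=px)
        expected = stack.metadata["amplitude"] * cdc42_shape.evaluate(
            ls.positions + 1 * px
        )
        err = np.abs(ls.values - expected) / expected.max()
        assert err.max() < 0.01

    def test_width_irrelevant_on_laterally_uniform_image(self):
        img = np.tile(np.linspace(1, 2, 64), (64, 1))
        a = linescan(img, (32, 5), 0.0, length=10.0, width=1, pixel_size=0.25)
        b = linescan(img, (32, 5), 0.0, length=10.0, width=10, pixel_size=0.25)
        np.testing.assert_allclose(a.values, b.values, rtol=1e-9)

    def test_rotation_invariance(self):
        h = w = 201
        yy, xx = np.mgrid[0:h, 0:w]
        img = np.exp(-np.hypot(yy - 100, xx - 100) / 40.0)
        base = linescan(img, (100.0, 100.0), 0.0, length=20.0, width=5, pixel_size=0.25)
        rot = linescan(
            img, (100.0, 100.0), math.radians(37), length=20.0, width=5, pixel_size=0.25
        )
        assert np.max(np.abs(base.values - rot.values)) / base.values.max() < 0.02

    def test_line_leaving_image_raises(self):
        img = np.zeros((32, 32))
        with pytest.raises(GeometryError):
            linescan(img, (16, 28), 0.0, length=10.0, width=3, pixel_size=0.25)


class TestNormalizeProfile:
    def test_linear_ramp_extremes(self):
        v = np.linspace(0.0, 1.0, 100)
        out = normalize_profile(v)
        # mean of five extreme samples sits 2/99 inside each end
        assert out[0] == pytest.approx(-(2 / 99) / (1 - 4 / 99), rel=1e-6)
        assert out[-1] > 1.0

    def test_affine_invariance(self, rng):
        v = rng.random(50)
        np.testing.assert_allclose(
            normalize_profile(3.7 * v - 1.2), normalize_profile(v), rtol=1e-9
        )

    def test_none_mode_passthrough(self, rng):
        v = rng.random(20)
        np.testing.assert_array_equal(normalize_profile(v, mode="none"), v)

    def test_short_and_constant_profiles_raise(self):
        with pytest.raises(InvalidParameterError):
            normalize_profile(np.arange(9.0))
        with pytest.raises(DegenerateNormalizationError):
            normalize_profile(np.ones(20))


class TestAverageEnsemble:
    def test_identical_cells(self):
        p = np.linspace(1, 0, 30)
        mean, sd, n = average_ensemble([[p, p], [p], [p, p, p]])
        np.testing.assert_allclose(mean, p)
        np.testing.assert_allclose(sd, 0.0, atol=1e-12)
        assert n == 3

    def test_cell_first_averaging_downweights_replicate_outlier(self):
        p = np.ones(12)
        outlier = 7.0 * np.ones(12)
        # outlier is one of two lines in one of three cells
        mean, _, _ = average_ensemble([[p], [p], [p, outlier]])
        cell_first = 1.0 + (7.0 - 1.0) / 6.0
        pooled = np.mean([p, p, p, outlier], axis=0)[0]  # = 1 + 6/4
        assert mean[0] == pytest.approx(cell_first)
        assert mean[0] < pooled

    def test_ensemble_passthrough(self, rng):
        ens = ProfileEnsemble(np.arange(10.0), rng.random((4, 10)))
        mean, sd, n = average_ensemble(ens)
        np.testing.assert_allclose(mean, ens.profiles.mean(axis=0))
        assert n == 4


class TestDecayFits:
    def test_pure_exponential_recovered_to_four_digits(self):
        x = np.linspace(0, 20, 201)
        fit = fit_decay_length(x, np.exp(-x / 8.3))
        assert fit.decay == pytest.approx(8.3, abs=5e-4)

    def test_baseline_offset_absorbed(self):
        x = np.linspace(0, 20, 201)
        fit = fit_decay_length(x, 2.0 * np.exp(-x / 6.0) + 0.8)
        assert fit.decay == pytest.approx(6.0, rel=1e-4)
        assert fit.baseline == pytest.approx(0.8, abs=1e-3)

    def test_plateau_shape_fit_beyond_plateau(self, cdc42_shape, window_positions):
        x = window_positions
        v = cdc42_shape.evaluate(x)
        fit = fit_decay_length(x, v, fit_range=(cdc42_shape.w, x[-1]))
        assert fit.decay == pytest.approx(8.3, rel=0.02)

    def test_bump_model_fit_recovers_asymptotic_decay(
        self, rac1_shape, window_positions
    ):
        fit = fit_bump_decay(window_positions, rac1_shape.evaluate(window_positions))
        assert fit.decay == pytest.approx(9.6, rel=1e-3)


class TestPeakAndExtent:
    def test_peak_matches_bump_position_on_model_profile(self, default_grid):
        from rhograd.model import GTPaseParams, rac1_profile

        prof = rac1_profile(GTPaseParams(), default_grid)
        peak = detect_peak(default_grid.positions, prof.values)
        assert peak == pytest.approx(5.0 * math.log(2), abs=0.1)

    @pytest.mark.parametrize("r,expect_interior", [
        (2.0, False), (1.0, False), (0.6, True), (0.3, True), (0.2, True), (0.1, True),
    ])
    def test_peak_agrees_with_existence_sweep(self, r, expect_interior, default_grid):
        from rhograd.model import GTPaseParams, bump_position, rac1_profile

        prof = rac1_profile(GTPaseParams(beta_r=r, beta_b=1.0), default_grid)
        peak = detect_peak(default_grid.positions, prof.values)
        if not expect_interior:
            assert peak is None
        else:
            assert peak == pytest.approx(
                bump_position(10.0, 5.0, r), abs=2 * default_grid.spacing + 0.05
            )

    def test_monotone_profile_is_edge_peaked(self, cdc42_shape, window_positions):
        assert detect_peak(window_positions, cdc42_shape.evaluate(window_positions)) is None

    def test_extent_of_pure_exponential_zero_baseline(self):
        # with a true zero baseline (no five-extreme estimate involved) the
        # half-amplitude extent of e^(−x/λ) is exactly λ·ln 2
        x = np.linspace(0, 80, 1601)
        lam = 8.0
        assert measure_extent(x, np.exp(-x / lam)) == pytest.approx(
            lam * math.log(2), rel=1e-3
        )
        # the five-extreme estimate of the baseline shifts it only slightly
        out = normalize_profile(np.exp(-x / lam))
        assert measure_extent(x, out) == pytest.approx(lam * math.log(2), rel=0.02)

    def test_extent_beyond_window_is_inf(self):
        x = np.linspace(0, 10, 101)
        v = normalize_profile(np.linspace(1.0, 0.9, 101) + 0.001 * np.sin(x))
        # normalized values stay near the top half over most of the window
        assert measure_extent(x, np.clip(v, 0.6, None)) == math.inf


class TestPointwiseCompare:
    def test_identical_ensembles_not_significant(self, gen_config, cdc42_shape):
        ens = sample_fret_profiles(
            cdc42_shape, 10, gen_config, rng=np.random.default_rng(3)
        )
        res = pointwise_compare(ens, ens)
        assert res.significant.sum() == 0

    def test_distinct_shapes_differ_near_edge(
        self, gen_config, cdc42_shape, rac1_shape
    ):
        # per-cell [0, 1] normalization first (the convention for comparing
        # two different reporters), then pointwise rank-sum: the plateaued
        # Cdc42 shape and the tip-chopped Rac1 shape differ most at the edge
        a = sample_fret_profiles(cdc42_shape, 19, gen_config, rng=np.random.default_rng(4))
        b = sample_fret_profiles(rac1_shape, 31, gen_config, rng=np.random.default_rng(5))
        for ens in (a, b):
            ens.profiles = np.array([normalize_profile(row) for row in ens.profiles])
        res = pointwise_compare(a, b)
        near_edge = res.positions < 3.0
        assert res.significant[near_edge].mean() > 0.5

    def test_requires_five_cells(self, gen_config, cdc42_shape):
        small = sample_fret_profiles(cdc42_shape, 4, gen_config, rng=np.random.default_rng(6))
        with pytest.raises(InvalidParameterError):
            pointwise_compare(small, small)


class TestProfilesMatch:
    def test_identical_profiles_match_exactly(self, window_positions, rac1_shape):
        v = rac1_shape.evaluate(window_positions)
        ok, diff = profiles_match(window_positions, v, v)
        assert ok and diff == 0.0


class TestEdgeEnrichment:
    @staticmethod
    def rim_image(frac_rim, h=160, w=160, radius=60, rim_px=4, pixel_size=0.25):
        mask = disk_mask(h, w, radius)
        inner = disk_mask(h, w, radius - rim_px)
        yy, xx = np.mgrid[0:h, 0:w]
        angle = np.arctan2(yy - (h - 1) / 2, xx - (w - 1) / 2)
        rim = mask & ~inner & (np.abs(angle) <= frac_rim * math.pi)
        img = np.where(mask, 100.0, 0.0) + np.where(rim, 200.0, 0.0)
        return img, mask

    def test_uniform_cell_is_a_coin_flip(self, rng):
        img, mask = self.rim_image(0.0)
        noisy = img + rng.normal(0, 1.0, img.shape)
        frac = edge_enrichment_fraction(noisy, mask)
        assert 0.3 < frac < 0.7

    def test_partial_rim_fraction(self):
        img, mask = self.rim_image(0.6)
        frac = edge_enrichment_fraction(img, mask)
        assert frac == pytest.approx(0.6, abs=0.05)

    def test_full_rim(self):
        img, mask = self.rim_image(1.0)
        assert edge_enrichment_fraction(img, mask) > 0.95

    def test_mask_touching_border_raises(self):
        mask = np.ones((32, 32), dtype=bool)
        with pytest.raises(GeometryError):
            edge_enrichment_fraction(np.ones((32, 32)), mask)
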