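"""Averaging, arithmetic, matching, merging, regridding, calibration."""

import numpy as np
import pytest

from saskit.curve import ScatteringCurve
from saskit.curve_ops import (
    arith,
    average_curves,
    crop,
    extrapolate_zero_concentration,
    merge_ranges,
    regrid,
    scale_shift_match,
    to_absolute_scale,
)
from saskit.formfactors import Body, hard_sphere_sf
from saskit.synthetic import NoiseModel, dilution_series


def flat_curve(n=100, value=10.0, sigma=0.5, smax=0.5):
    s = np.linspace(0.01, smax, n)
    return ScatteringCurve(s=s, i=np.full(n, value), sigma=np.full(n, sigma))


def model_curve(n=200, seed=None, noise=0.0):
    s = np.linspace(0.01, 0.5, n)
    i = 100.0 * np.exp(-(s**2) * 180.0)
    sigma = np.maximum(0.01 * i, 1e-6)
    if seed is not None and noise > 0:
        rng = np.random.default_rng(seed)
        sigma = noise * i
        i = i + rng.normal(0, 1, n) * sigma
    return ScatteringCurve(s=s, i=i, sigma=sigma)


class TestAverage:
    def test_two_identical_curves_keep_mean_and_shrink_sigma(self):
        c = flat_curve()
        avg = average_curves([c, c])
        np.testing.assert_allclose(avg.i, c.i)
        np.testing.assert_allclose(avg.sigma, c.sigma / np.sqrt(2))

    def test_inverse_sqrt_n_law(self):
        c = flat_curve()
        avg = average_curves([c] * 4)
        np.testing.assert_allclose(avg.sigma, c.sigma / 2.0)

    def test_mean_converges_to_model(self):
        # stochastic: mean over many replicates within 3 standard errors
        rng = np.random.default_rng(11)
        base = model_curve()
        reps = []
        n_rep = 50
        for _ in range(n_rep):
            reps.append(
                ScatteringCurve(
                    s=base.s,
                    i=base.i + rng.normal(0, 1, len(base)) * base.sigma,
                    sigma=base.sigma,
                )
            )
        avg = average_curves(reps)
        z = (avg.i - base.i) / (base.sigma / np.sqrt(n_rep))
        assert abs(z.mean()) < 3.0 / np.sqrt(len(base))  # 3 SE on the grand mean

    def test_grid_mismatch_rejected(self):
        a = flat_curve()
        b = flat_curve()
        b.s = b.s.copy()
        b.s[10] *= 1.01
        with pytest.raises(ValueError, match="grid mismatch"):
            average_curves([a, b])

    def test_missing_sigma_rejected(self):
        a = flat_curve()
        b = ScatteringCurve(s=a.s.copy(), i=a.i.copy())
        with pytest.raises(ValueError, match="sigma"):
            average_curves([a, b])


class TestArith:
    def test_self_subtraction_zero_with_quadrature_sigma(self):
        c = flat_curve()
        d = arith(c, c, "sub")
        np.testing.assert_allclose(d.i, 0.0)
        np.testing.assert_allclose(d.sigma, c.sigma * np.sqrt(2))

    def test_scalar_multiplication_scales_i_and_sigma(self):
        c = flat_curve()
        d = arith(c, 2.0, "mul")
        np.testing.assert_allclose(d.i, 2 * c.i)
        np.testing.assert_allclose(d.sigma, 2 * c.sigma)

    def test_division_by_curve_with_zero_rejected(self):
        c = flat_curve()
        z = flat_curve()
        z.i = z.i.copy()
        z.i[5] = 0.0
        with pytest.raises(ZeroDivisionError):
            arith(c, z, "div")


class TestScaleShiftMatch:
    def test_exact_scale(self):
        c = model_curve()
        ref = ScatteringCurve(s=c.s, i=2 * c.i, sigma=c.sigma)
        res = scale_shift_match(c, ref)
        assert res.factor == pytest.approx(2.0, rel=1e-12)
        assert res.shift == pytest.approx(0.0, abs=1e-9)

    def test_exact_shift(self):
        c = model_curve()
        ref = ScatteringCurve(s=c.s, i=c.i + 5.0, sigma=c.sigma)
        res = scale_shift_match(c, ref)
        assert res.factor == pytest.approx(1.0, rel=1e-9)
        assert res.shift == pytest.approx(5.0, rel=1e-9)

    def test_noisy_factor_recovered_within_one_percent(self):
        # closed-form weighted-LSQ oracle cross-check at 1% noise
        rng = np.random.default_rng(1)
        c = model_curve()
        noise = rng.normal(0, 1, len(c)) * 0.01 * c.i
        ref = ScatteringCurve(s=c.s, i=3.0 * c.i + noise, sigma=0.01 * c.i)
        res = scale_shift_match(c, ref, allow_shift=False)
        assert res.factor == pytest.approx(3.0, rel=0.01)
        w = 1.0 / ref.sigma**2
        oracle = (w * c.i * ref.i).sum() / (w * c.i**2).sum()
        assert res.factor == pytest.approx(oracle, rel=1e-12)

    def test_insufficient_overlap_rejected(self):
        c = model_curve()
        with pytest.raises(ValueError, match="overlap"):
            scale_shift_match(c, c, fit_range=(0.496, 0.5))


class TestMerge:
    def test_pure_rescale_recovers_low_curve(self):
        low = model_curve()
        high = arith(low, 0.5, "mul")
        res = merge_ranges(low, high, (0.01, 0.3), (0.1, 0.5))
        on_low = np.interp(res.merged.s, low.s, low.i)
        np.testing.assert_allclose(res.merged.i, on_low, rtol=1e-9)
        assert res.scale_applied == pytest.approx(2.0, rel=1e-9)

    def test_idempotent_on_identical_curves(self):
        c = model_curve()
        res = merge_ranges(c, c, (0.01, 0.3), (0.1, 0.5))
        np.testing.assert_allclose(res.merged.i, np.interp(res.merged.s, c.s, c.i))
        assert set(res.source_map) == {"low", "high"}

    def test_structure_factor_dip_taken_from_dilute_curve(self):
        # concentrated sample suppressed at low angles: merged low-s
        # region must equal the dilute curve
        body = Body("sphere", {"radius": 30.0})
        s = np.linspace(0.005, 0.5, 300)
        low, high = dilution_series(
            body, [1.0, 8.0], interaction_eta_per_conc=0.02,
            noise=NoiseModel(relative_level=0.0), s_grid=s,
        )
        res = merge_ranges(low, high, (0.005, 0.2), (0.12, 0.5))
        low_region = res.merged.s < 0.05
        np.testing.assert_allclose(
            res.merged.i[low_region],
            np.interp(res.merged.s[low_region], low.s, low.i),
            rtol=1e-12,
        )

    def test_no_overlap_rejected(self):
        c = model_curve()
        with pytest.raises(ValueError, match="overlap"):
            merge_ranges(c, c, (0.01, 0.05), (0.3, 0.5))


class TestZeroConcentration:
    def test_proportional_series_is_exact(self):
        c = model_curve()
        series = [(arith(c, conc, "mul"), conc) for conc in (0.5, 1.0, 2.0)]
        res = extrapolate_zero_concentration(series)
        np.testing.assert_allclose(res.i, c.i, rtol=1e-12)

    def test_linear_interaction_model_recovered(self):
        # I(s, c) = c * I0(s) * (1 - k c) -> intercept of I/c is I0
        c = model_curve()
        k = 0.05
        series = [
            (ScatteringCurve(s=c.s, i=conc * c.i * (1 - k * conc), sigma=c.sigma), conc)
            for conc in (0.5, 1.0, 2.0, 4.0)
        ]
        res = extrapolate_zero_concentration(series)
        np.testing.assert_allclose(res.i, c.i, rtol=0.005)

    def test_single_concentration_rejected(self):
        c = model_curve()
        with pytest.raises(ValueError):
            extrapolate_zero_concentration([(c, 1.0)])
        with pytest.raises(ValueError, match="distinct"):
            extrapolate_zero_concentration([(c, 1.0), (c, 1.0)])

    def test_dilution_series_closes_the_loop(self):
        # generator with hard-sphere interaction; extrapolation recovers
        # the pure form factor within 1% at zero noise
        body = Body("sphere", {"radius": 30.0})
        curves = dilution_series(
            body, [0.5, 1.0, 2.0, 4.0], interaction_eta_per_conc=0.005,
            noise=NoiseModel(relative_level=0.0),
        )
        series = [(c, c.meta["concentration"]) for c in curves]
        res = extrapolate_zero_concentration(series)
        from saskit.formfactors import body_intensity

        truth = body_intensity(body, res.s, normalized=False).i
        np.testing.assert_allclose(res.i, truth, rtol=0.01)


class TestCropRegrid:
    def test_crop_closed_interval_count(self):
        s = np.round(np.arange(0.01, 0.501, 0.01), 10)
        c = ScatteringCurve(s=s, i=np.ones(len(s)))
        assert len(crop(c, 0.1, 0.3)) == 21

    def test_crop_full_support_is_identity(self):
        c = model_curve()
        out = crop(c, c.s[0], c.s[-1])
        np.testing.assert_array_equal(out.i, c.i)

    def test_crop_outside_support_rejected(self):
        c = model_curve()
        with pytest.raises(ValueError):
            crop(c, 0.9, 1.0)

    def test_bin_by_two_averages_pairs(self):
        c = flat_curve(n=100)
        out = regrid(c, "bin-by-k", 2)
        assert len(out) == 50
        np.testing.assert_allclose(out.sigma, c.sigma[0] / np.sqrt(2))
        np.testing.assert_allclose(out.s, c.s.reshape(-1, 2).mean(axis=1))

    def test_template_own_grid_is_identity(self):
        c = model_curve()
        out = regrid(c, "template-grid", c.s.copy())
        np.testing.assert_allclose(out.i, c.i, rtol=1e-12)

    def test_template_beyond_support_rejected(self):
        c = model_curve()
        with pytest.raises(ValueError, match="extrapolation"):
            regrid(c, "template-grid", np.linspace(0.1, 0.6, 10))


class TestAbsoluteScale:
    def test_plateau_equal_to_constant_is_identity(self):
        sample = model_curve()
        water = flat_curve(value=0.01632, sigma=1e-4)
        out = to_absolute_scale(sample, water, water_constant=0.01632)
        np.testing.assert_allclose(out.i, sample.i, rtol=1e-12)
        assert out.meta["intensity_unit"] == "cm^-1"

    def test_double_plateau_halves_intensities(self):
        sample = model_curve()
        water = flat_curve(value=2 * 0.01632, sigma=1e-4)
        out = to_absolute_scale(sample, water, water_constant=0.01632)
        np.testing.assert_allclose(out.i, sample.i / 2, rtol=1e-12)

    def test_negative_plateau_rejected(self):
        sample = model_curve()
        water = flat_curve(value=-1.0, sigma=1e-4)
        with pytest.raises(ValueError, match="plateau"):
            to_absolute_scale(sample, water)


class TestHardSphereSF:
    def test_zero_eta_is_unity(self):
        s = np.linspace(0.001, 0.5, 50)
        np.testing.assert_array_equal(hard_sphere_sf(s, 0.0, 30.0), 1.0)

    def test_low_angle_suppression_grows_with_eta(self):
        s = np.array([1e-4])
        s_low = [float(hard_sphere_sf(s, eta, 30.0)[0]) for eta in (0.01, 0.05, 0.2)]
        assert s_low[0] > s_low[1] > s_low[2]
        assert all(0 < v < 1 for v in s_low)
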