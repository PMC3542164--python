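"""Robust scale estimators, exact 1-D MCD, and the flagging rules."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate, stats

from robustqc import (
    DegenerateScatterError,
    DistributionSpec,
    IndicatorSample,
    MCDFit,
    consistency_factor,
    default_h,
    gamma_params_from_skewness,
    iqr_scale,
    mad_scale,
    mcd_univariate,
    robust_distances,
    screen,
    simulate_indicator,
)


def sample_of(*values):
    return IndicatorSample(values=np.asarray(values, dtype=float))


class TestIqrScale:
    def test_linear_interpolation_convention(self):
        fit = iqr_scale(sample_of(1, 2, 3, 4, 5))
        assert fit.scale_sigma_hat == pytest.approx(2.0 / 1.355)
        assert fit.status == "ok"

    def test_estimates_normal_sigma(self, normal_sample):
        """On 1e5 N(0,1)-shaped draws the IQR/1.355 scale is close to
        1.349/1.355 (population quartiles at +-0.6745)."""
        fit = iqr_scale(normal_sample(n=100_000, mean=0.0, sd=1.0))
        assert fit.scale_sigma_hat == pytest.approx(1.349 / 1.355, abs=0.02)

    def test_constant_sample_is_degenerate(self):
        fit = iqr_scale(sample_of(*([3.0] * 10)))
        assert fit.scale_sigma_hat == 0.0
        assert fit.status == "degenerate"

    def test_degenerate_when_quartiles_coincide_without_constancy(self):
        # 80% zeros: q25 == q75 == 0 although the sample is not constant.
        fit = iqr_scale(sample_of(*([0.0] * 8), 5.0, 9.0))
        assert fit.status == "degenerate"

    def test_median_center_option(self):
        fit = iqr_scale(sample_of(1, 2, 3, 4, 100), center="median")
        assert fit.location_T == 3.0

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            iqr_scale(IndicatorSample(values=np.array([])))


class TestMadScale:
    def test_hand_computed_example(self):
        fit = mad_scale(sample_of(1, 2, 3, 4, 5, 6, 7, 8, 9))
        assert fit.scale_sigma_hat == pytest.approx(2.0 / 0.666)

    def test_scale_is_sign_symmetric(self):
        x = np.array([0.3, 1.7, 2.2, 8.9, 4.4])
        a = mad_scale(IndicatorSample(values=x))
        b = mad_scale(IndicatorSample(values=-x))
        assert a.scale_sigma_hat == pytest.approx(b.scale_sigma_hat)

    def test_majority_zeros_degenerate(self):
        """More than half zeros => MAD = 0, the rare-event failure mode."""
        fit = mad_scale(sample_of(*([0.0] * 6), 1.0, 2.0, 3.0, 4.0))
        assert fit.status == "degenerate"


class TestConsistencyFactor:
    def test_full_sample_limit(self):
        assert consistency_factor(1.0) == 1.0

    def test_half_sample_matches_truncated_normal_variance(self):
        """Independent oracle: 1 / variance of the central 50% of N(0,1),
        by numeric integration."""
        q = stats.norm.ppf(0.75)
        second_moment, _ = integrate.quad(
            lambda t: t * t * stats.norm.pdf(t), -q, q
        )
        oracle = 1.0 / (second_moment / 0.5)
        assert consistency_factor(0.5) == pytest.approx(oracle, rel=1e-9)

    def test_monotone_decreasing(self):
        grid = np.linspace(0.5, 1.0, 26)
        factors = [consistency_factor(f) for f in grid]
        assert np.all(np.diff(factors) < 0)

    @pytest.mark.parametrize("bad", [0.0, -0.1, 1.2])
    def test_out_of_range_rejected(self, bad):
        with pytest.raises(ValueError):
            consistency_factor(bad)


class TestMcdUnivariate:
    def test_small_example_ties_break_low(self):
        """{1,2,3,4,100}, h=3: windows {1,2,3} and {2,3,4} tie at variance 1;
        the lower start wins."""
        fit = mcd_univariate(sample_of(1, 2, 3, 4, 100), h=3, reweight=False)
        assert fit.window_start == 0
        assert fit.raw_T == pytest.approx(2.0)
        assert fit.raw_C == pytest.approx(1.0)
        assert fit.corrected_C == pytest.approx(
            1.0 * consistency_factor(3 / 5)
        )

    def test_repeated_values_degenerate(self):
        fit = mcd_univariate(sample_of(5, 5, 5, 5, 5, 90, 91), h=4)
        assert fit.raw_C == 0.0
        assert fit.status == "degenerate"

    def test_breakdown_upper_contamination(self):
        """Observations above the optimal window can be made arbitrarily
        extreme without moving the fit: they carry zero weight."""
        rng = np.random.default_rng(8)
        x = np.sort(rng.normal(8, 1, 40))
        h = default_h(40)
        base = mcd_univariate(IndicatorSample(values=x), h=h, reweight=False)
        top = base.window_start + h
        assert top < 40  # the property is vacuous otherwise
        corrupted = x.copy()
        corrupted[top:] = 1e9 + np.arange(40 - top)
        worse = mcd_univariate(
            IndicatorSample(values=corrupted), h=h, reweight=False
        )
        assert worse.window_start == base.window_start
        assert worse.raw_T == pytest.approx(base.raw_T)
        assert worse.raw_C == pytest.approx(base.raw_C)

    @pytest.mark.parametrize("n", [5, 8, 11])
    def test_contiguous_window_is_global_optimum(self, n):
        """Spot-check the exhaustive C(n, h) oracle (full sweep lives in the
        acceptance suite)."""
        rng = np.random.default_rng(n)
        x = rng.gamma(1.0, 8.0, n)
        for h in range(default_h(n), n + 1):
            fit = mcd_univariate(IndicatorSample(values=x), h=h, reweight=False)
            brute = min(
                np.var(sub, ddof=1)
                for sub in itertools.combinations(x, h)
            )
            assert fit.raw_C == pytest.approx(brute)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            mcd_univariate(sample_of(1, 2))
        with pytest.raises(ValueError):
            mcd_univariate(sample_of(1, 2, 3, 4), h=2)
        with pytest.raises(ValueError):
            mcd_univariate(sample_of(1, 2, 3, 4), h=5)

    def test_reweighted_fit_tracks_clean_normal_variance(self, normal_sample):
        fit = mcd_univariate(normal_sample(n=20_000, mean=0.0, sd=2.0))
        assert fit.reweighted
        assert fit.final_T == pytest.approx(0.0, abs=0.1)
        assert fit.final_C == pytest.approx(4.0, rel=0.05)


class TestRobustDistances:
    def test_direct_substitution(self):
        fit = MCDFit(
            n=3, p=1, h=2, window_start=0, raw_T=0.0, raw_C=1.0,
            consistency_factor=1.0, corrected_C=1.0, reweighted=False,
            final_T=0.0, final_C=1.0, status="ok",
        )
        d = robust_distances(sample_of(2.0, 0.0, -2.0), fit)
        assert d == pytest.approx([4.0, 0.0, 4.0])

    def test_degenerate_fit_raises(self):
        fit = mcd_univariate(sample_of(5, 5, 5, 5, 5, 90, 91), h=4)
        with pytest.raises(DegenerateScatterError):
            robust_distances(sample_of(1, 2, 3), fit)


class TestScreen:
    @pytest.mark.parametrize("method", ["iqr", "mad", "mcd"])
    def test_gross_outlier_flagged_by_every_method(self, method, normal_sample):
        clean = normal_sample(n=999)
        values = np.append(clean.values, 60.0)
        result = screen(IndicatorSample(values=values), method)
        assert result.status == "ok"
        assert result.flags[-1]
        assert result.n_flagged == int(result.flags.sum())

    @pytest.mark.parametrize("method", ["iqr", "mad", "mcd"])
    def test_flags_equal_statistic_threshold(self, method, gamma_sample):
        result = screen(gamma_sample(2.0), method)
        assert np.array_equal(result.flags, result.statistics >= result.cutoff)

    @settings(deadline=None, derandomize=True, max_examples=20)
    @given(
        a=st.floats(min_value=0.01, max_value=100).flatmap(
            lambda v: st.sampled_from([v, -v])
        ),
        b=st.floats(min_value=-50, max_value=50),
        seed=st.integers(min_value=0, max_value=2**31 - 1),
        method=st.sampled_from(["iqr", "mad", "mcd"]),
    )
    def test_affine_equivariance_of_flags(self, a, b, seed, method):
        """screen(a*x + b) flags exactly the observations screen(x) flags,
        for every method and any a != 0."""
        sample = simulate_indicator(
            DistributionSpec.gamma(gamma_params_from_skewness(8.0, 2.0)),
            200,
            seed,
        )
        base = screen(sample, method)
        moved = screen(
            IndicatorSample(values=a * sample.values + b), method
        )
        assert np.array_equal(base.flags, moved.flags)

    def test_zero_inflated_failure_pattern(self):
        """55-60% zeros: MAD and MCD fail while IQR still screens; at >= 75%
        zeros all three fail (the dash pattern of degenerate indicators)."""
        gamma = gamma_params_from_skewness(8.0, 2.0)
        moderate = simulate_indicator(
            DistributionSpec.zero_inflated_gamma(0.6, gamma), 1000, seed=2
        )
        assert screen(moderate, "mad").status == "failed"
        assert screen(moderate, "mcd").status == "failed"
        assert screen(moderate, "iqr").status == "ok"
        heavy = simulate_indicator(
            DistributionSpec.zero_inflated_gamma(0.8, gamma), 1000, seed=2
        )
        for method in ("iqr", "mad", "mcd"):
            result = screen(heavy, method)
            assert result.status == "failed"
            assert result.n_flagged == 0
            assert not result.flags.any()

    def test_unknown_method_rejected(self, gamma_sample):
        with pytest.raises(ValueError):
            screen(gamma_sample(1.0), "zscore")

    def test_default_cutoffs(self, gamma_sample):
        assert screen(gamma_sample(1.0), "iqr").cutoff == 2.24
        assert screen(gamma_sample(1.0), "mcd").cutoff == 5.02
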