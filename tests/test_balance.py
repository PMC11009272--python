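import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import nitribalance as nb
from nitribalance.errors import ParameterError

from _oracles import ols_closed_form
from conftest import noise_free_dataset, run_balance


class TestTheoreticalBand:
    def test_published_band(self):
        band = nb.theoretical_band(mode="published")
        assert (band.low, band.central, band.high) == (2.6, 6.9, 15.8)

    def test_computed_band_from_rounded_traits(self):
        band = nb.theoretical_band(mode="computed")
        assert round(band.low, 3) == 2.540
        assert round(band.central, 3) == 7.667
        assert round(band.high, 3) == 15.500
        assert band.provenance == "computed_from_traits"

    def test_unit_traits_give_unit_band(self):
        traits = nb.TraitSet(yield_ratio=(1, 1, 1), quota_ratio=(1, 1, 1))
        band = nb.theoretical_band(traits, mode="computed")
        assert (band.low, band.central, band.high) == (1.0, 1.0, 1.0)

    def test_invalid_traits_rejected(self):
        with pytest.raises(ParameterError, match="quota_ratio"):
            nb.theoretical_band(
                nb.TraitSet(quota_ratio=(0.5, 0.3, 0.6)), mode="computed"
            )

    def test_unknown_mode_rejected(self):
        with pytest.raises(ParameterError, match="mode"):
            nb.theoretical_band(mode="guess")


class TestSampleRatios:
    def test_simple_ratio(self):
        ratios, excluded = nb.sample_ratios(
            pd.Series({"a": 1e7}), pd.Series({"a": 1e6})
        )
        assert ratios["a"] == pytest.approx(10.0)
        assert excluded == []

    def test_zero_nob_excluded_and_listed(self):
        ratios, excluded = nb.sample_ratios(
            pd.Series({"a": 1e7, "b": 2e7}), pd.Series({"a": 1e6, "b": 0.0})
        )
        assert list(ratios.index) == ["a"]
        assert excluded == ["b"]

    def test_all_zero_nob_rejected(self):
        with pytest.raises(ParameterError, match="zero NOB"):
            nb.sample_ratios(pd.Series({"a": 1.0}), pd.Series({"a": 0.0}))


class TestRegression:
    def test_exact_proportional_points(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        for with_intercept in (True, False):
            fit = nb.fit_abundance_regression(26 * x, x, with_intercept=with_intercept)
            assert fit.slope == pytest.approx(26.0)
            assert fit.r_squared == pytest.approx(1.0)

    def test_small_noise_converges_to_slope(self):
        rng = np.random.default_rng(5)
        x = rng.uniform(1, 10, size=200)
        y = 3 * x + rng.normal(0, 1e-6, size=200)
        fit = nb.fit_abundance_regression(y, x)
        assert fit.slope == pytest.approx(3.0, rel=1e-4)

    @given(seed=st.integers(min_value=0, max_value=10**6))
    def test_matches_closed_form_oracle(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.uniform(0, 10, size=20)
        y = 2.5 * x + rng.normal(0, 2, size=20)
        for with_intercept in (True, False):
            fit = nb.fit_abundance_regression(y, x, with_intercept=with_intercept)
            slope, r2 = ols_closed_form(x, y, with_intercept=with_intercept)
            assert fit.slope == pytest.approx(slope, rel=1e-9)
            assert fit.r_squared == pytest.approx(r2, rel=1e-9)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ParameterError, match="zero variance"):
            nb.fit_abundance_regression([1.0, 2.0, 3.0], [5.0, 5.0, 5.0])
        with pytest.raises(ParameterError, match="n >= 3"):
            nb.fit_abundance_regression([1.0, 2.0], [1.0, 2.0])


class TestSummarizeRatios:
    BAND = nb.PUBLISHED_BAND

    def test_median_of_three(self):
        s = nb.summarize_ratios([1.0, 2.0, 3.0], self.BAND, seed=0, n_boot=100)
        assert s.median == 2.0

    def test_degenerate_bootstrap_ci(self):
        s = nb.summarize_ratios([7.0] * 5, self.BAND, seed=0, n_boot=100)
        assert (s.ci_low, s.ci_high) == (7.0, 7.0)

    def test_band_exceedance_counting(self):
        s = nb.summarize_ratios([5.0, 20.0, 50.0], self.BAND, seed=0, n_boot=100)
        assert s.n_above_band == 2
        assert s.n_below_band == 0

    def test_seeded_determinism(self):
        ratios = np.random.default_rng(3).lognormal(2, 1, size=50)
        a = nb.summarize_ratios(ratios, self.BAND, seed=9)
        b = nb.summarize_ratios(ratios, self.BAND, seed=9)
        assert (a.ci_low, a.ci_high) == (b.ci_low, b.ci_high)

    @given(seed=st.integers(min_value=0, max_value=10**6))
    def test_counts_partition_the_samples(self, seed):
        ratios = np.random.default_rng(seed).lognormal(2, 1.5, size=30)
        s = nb.summarize_ratios(ratios, self.BAND, seed=0, n_boot=50)
        n_in = ((ratios >= self.BAND.low) & (ratios <= self.BAND.high)).sum()
        assert s.n_above_band + s.n_below_band + n_in == s.n
        assert s.ci_low <= s.median <= s.ci_high


class TestReattribution:
    def test_noise_free_medians_follow_inflation_law(self):
        # r_true = 8, f_candidate = 0.6: medians (20, 8). Exact on the truth
        # abundances; through the count path the only deviation is the <=1-read
        # quantization of the deterministic count model.
        ds = noise_free_dataset(r_true=8.0, f_candidate=0.6)
        truth_abs = nb.AbundanceMatrix(
            pd.DataFrame(
                {
                    "AOA": ds.truth["aoa"],
                    "NOB_Nitrospiraceae": ds.truth["nob_nitrospiraceae"],
                    "NOB_Nitrospinaceae": ds.truth["nob_nitrospinaceae"],
                    "NOB_candidate": ds.truth["nob_candidate"],
                }
            ),
            "absolute",
        )
        zones = nb.split_redox_zones(
            ds.samples, {c: ds.params.opd_for_core(0) for c in ds.geochem}
        )
        exact = nb.reattribution_analysis(
            truth_abs, zones, nb.PUBLISHED_BAND, n_boot=100, seed=1
        )
        assert exact.with_candidate.summary.median == pytest.approx(8.0, rel=1e-12)
        assert exact.without_candidate.summary.median == pytest.approx(20.0, rel=1e-12)

        counted = run_balance(ds, n_boot=100)
        assert counted.with_candidate.summary.median == pytest.approx(8.0, rel=2e-3)
        assert counted.without_candidate.summary.median == pytest.approx(20.0, rel=2e-3)

    def test_empty_candidate_guild_gives_identical_arms(self):
        with pytest.warns(UserWarning, match="candidate"):
            result = run_balance(noise_free_dataset(r_true=3.0, f_candidate=0.0), n_boot=100)
        assert result.median_ratio == pytest.approx(1.0)
        assert (
            result.without_candidate.summary.median
            == result.with_candidate.summary.median
        )

    def test_identical_sample_set_in_both_arms(self, default_analysis):
        _, _, _, absolute, zones = default_analysis
        result = nb.reattribution_analysis(
            absolute, zones, nb.PUBLISHED_BAND, n_boot=100, seed=1
        )
        assert list(result.without_candidate.summary.ratios.index) == list(
            result.with_candidate.summary.ratios.index
        )
        assert result.n_oxic == 100

    def test_regression_slopes_bracket_the_medians(self, default_analysis):
        _, _, _, absolute, zones = default_analysis
        result = nb.reattribution_analysis(
            absolute, zones, nb.PUBLISHED_BAND, n_boot=100, seed=1
        )
        assert result.with_candidate.fit.slope == pytest.approx(10.0, rel=0.15)
        assert result.without_candidate.fit.slope == pytest.approx(28.6, rel=0.15)
        assert result.with_candidate.fit.r_squared > 0.9
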