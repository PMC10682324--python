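"""Meta-pooling: quantile conversion, SE recovery, random-effects machinery."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from cad_breakeven import (
    EffectInput,
    ci_to_se,
    median_iqr_to_mean_sd,
    pool_random_effects,
    pool_reading_times,
    summarize_second_reader,
)
from cad_breakeven.pooling import Arm, MultiReaderPolicy, PoolingMethod, extract_effects
from cad_breakeven.simulate import SimulationSpec, simulate_corpus


class TestMedianIqrToMeanSd:
    def test_published_with_cad_quartiles(self):
        # median 86, IQR 51-141: mean (51+86+141)/3, SD (141-51)/1.35
        mean, sd = median_iqr_to_mean_sd(86, 51, 141)
        assert mean == pytest.approx(92.6667, abs=1e-3)
        assert sd == pytest.approx(66.6667, abs=1e-3)

    def test_n_dependent_denominator_matches_quantile_formula(self):
        # independent route: denominator 2*Phi^-1((0.75n-0.125)/(n+0.25))
        n = 40
        _, sd = median_iqr_to_mean_sd(100, 80, 130, n=n)
        denom = 2 * stats.norm.ppf((0.75 * n - 0.125) / (n + 0.25))
        assert sd == pytest.approx((130 - 80) / denom, rel=1e-12)

    @given(m=st.floats(10, 500), half=st.floats(0.1, 100))
    def test_symmetric_quartiles_return_median_as_mean(self, m, half):
        mean, _ = median_iqr_to_mean_sd(m, m - half, m + half)
        assert mean == pytest.approx(m, rel=1e-12)

    def test_degenerate_iqr_gives_zero_sd_with_warning(self):
        with pytest.warns(UserWarning, match="degenerate"):
            mean, sd = median_iqr_to_mean_sd(50, 50, 50)
        assert (mean, sd) == (50, 0.0)

    def test_inverted_quartiles_rejected(self):
        with pytest.raises(ValueError):
            median_iqr_to_mean_sd(100, 130, 80)


class TestCiToSe:
    def test_published_second_reader_ci(self):
        assert ci_to_se(39, 44) == pytest.approx(5 / (2 * 1.959964), rel=1e-6)

    def test_unit_z_interval(self):
        a = 1.959964
        assert ci_to_se(-a, a) == pytest.approx(1.0, rel=1e-4)

    def test_zero_width_warns(self):
        with pytest.warns(UserWarning, match="zero-width"):
            assert ci_to_se(5, 5) == 0.0

    def test_bad_level_rejected(self):
        with pytest.raises(ValueError):
            ci_to_se(0, 1, level=1.5)


def _effects(values, ses=None):
    ses = ses or [None] * len(values)
    return [
        EffectInput(study_label=f"s{i}", estimate=v, se=s)
        for i, (v, s) in enumerate(zip(values, ses))
    ]


class TestPoolRandomEffects:
    def test_zero_heterogeneity_closed_form(self):
        pooled = pool_random_effects(_effects([10, 10, 10], [1, 1, 1]), "dersimonian_laird")
        assert pooled.mean == pytest.approx(10)
        assert pooled.tau2 == 0
        assert pooled.ci_hi - pooled.mean == pytest.approx(1.959964 / math.sqrt(3), rel=1e-6)

    def test_single_effect(self):
        pooled = pool_random_effects(_effects([42], [2]), "dersimonian_laird")
        assert pooled.mean == 42
        assert pooled.ci_lo == pytest.approx(42 - 1.959964 * 2, rel=1e-6)

    def test_matches_independent_dl_implementation(self):
        # statsmodels' DerSimonian-Laird as the independent oracle
        from statsmodels.stats.meta_analysis import combine_effects

        y = [10.0, 12.0, 8.0, 15.0, 9.0]
        se = [1.0, 1.4, 1.2, 1.6, 1.1]
        pooled = pool_random_effects(_effects(y, se), "dersimonian_laird")
        res = combine_effects(np.array(y), np.array(se) ** 2, method_re="dl")
        frame = res.summary_frame().loc["random effect"]
        assert pooled.mean == pytest.approx(frame["eff"], rel=1e-10)
        assert pooled.ci_lo == pytest.approx(frame["ci_low"], rel=1e-6)
        assert pooled.ci_hi == pytest.approx(frame["ci_upp"], rel=1e-6)
        assert pooled.tau2 == pytest.approx(res.tau2, rel=1e-10)

    def test_dl_equals_fixed_effect_when_tau2_clamps(self):
        # homogeneous effects force tau2 = 0 => identical to inverse-variance pool
        y, se = [5.0, 5.2, 4.9, 5.1], [2.0, 2.5, 2.2, 2.1]
        dl = pool_random_effects(_effects(y, se), "dersimonian_laird")
        fe = pool_random_effects(_effects(y, se), "fixed_effect")
        assert dl.tau2 == 0.0
        assert dl.mean == pytest.approx(fe.mean, abs=1e-10)
        assert dl.ci_lo == pytest.approx(fe.ci_lo, abs=1e-10)

    def test_unweighted_t_interval(self):
        vals = [60.0, 70.0, 90.0, 88.0]
        pooled = pool_random_effects(_effects(vals), "unweighted")
        m, sd = np.mean(vals), np.std(vals, ddof=1)
        half = stats.t.ppf(0.975, 3) * sd / 2
        assert pooled.mean == pytest.approx(m)
        assert pooled.ci_hi == pytest.approx(m + half, rel=1e-10)

    def test_dl_with_missing_se_instructs_fallback(self):
        with pytest.raises(ValueError, match="unweighted"):
            pool_random_effects(_effects([1, 2], [1, None]), "dersimonian_laird")

    def test_empty_pool_rejected(self):
        with pytest.raises(ValueError):
            pool_random_effects([], "unweighted")

    @given(
        data=st.lists(
            st.tuples(st.floats(-100, 300), st.floats(0.5, 30)), min_size=2, max_size=8
        ),
        method=st.sampled_from(["unweighted", "dersimonian_laird", "fixed_effect"]),
    )
    def test_pooled_mean_within_study_range(self, data, method):
        effects = _effects([d[0] for d in data], [d[1] for d in data])
        pooled = pool_random_effects(effects, method)
        vals = [d[0] for d in data]
        assert min(vals) - 1e-9 <= pooled.mean <= max(vals) + 1e-9

    @given(scale=st.floats(0.1, 0.95))
    def test_ci_narrows_as_se_shrinks(self, scale):
        # homogeneous effects keep tau2 clamped at zero at both scales, so
        # the CI width shrinks exactly linearly with the common SE factor
        y, se = [10.0, 10.1, 9.9, 10.05], [2.0, 1.5, 2.5, 1.8]
        wide = pool_random_effects(_effects(y, se), "dersimonian_laird")
        narrow = pool_random_effects(
            _effects(y, [s * scale for s in se]), "dersimonian_laird"
        )
        assert wide.tau2 == narrow.tau2 == 0.0
        assert (narrow.ci_hi - narrow.ci_lo) == pytest.approx(
            scale * (wide.ci_hi - wide.ci_lo), rel=1e-9
        )


class TestPoolReadingTimes:
    def test_saved_time_within_published_ci(self, corpus):
        pooled = pool_reading_times(corpus, "saved_time_concurrent", "unweighted")
        assert pooled.k_studies == 5
        assert 47 <= pooled.mean <= 107

    def test_no_cad_within_published_ci(self, corpus):
        pooled = pool_reading_times(corpus, "no_cad", "unweighted")
        assert 111 <= pooled.mean <= 212

    def test_with_cad_within_published_ci(self, corpus):
        pooled = pool_reading_times(corpus, "with_cad_concurrent", "unweighted")
        assert 82 <= pooled.mean <= 154

    def test_multi_reader_rows_average_within_study(self, corpus):
        effects = extract_effects(corpus, Arm.SAVED_TIME_CONCURRENT)
        hempel = next(e for e in effects if e.study_label == "Hempel 2022")
        assert hempel.estimate == pytest.approx((75.6 + 136.6) / 2)

    def test_independent_policy_keeps_reader_rows(self, corpus):
        effects = extract_effects(
            corpus, Arm.SAVED_TIME_CONCURRENT, MultiReaderPolicy.TREAT_AS_INDEPENDENT
        )
        assert len(effects) == 6

    def test_single_study_pool_equals_study_estimate(self, corpus):
        one = [next(o for o in corpus if o.study_label == "Kozuka 2020")]
        with pytest.warns(UserWarning, match="single study"):
            pooled = pool_reading_times(one, "saved_time_concurrent", "unweighted")
        assert pooled.mean == 18

    def test_dl_on_real_corpus_requires_imputation(self, corpus):
        # several published arms carry no dispersion at all
        with pytest.raises(ValueError, match="unweighted"):
            pool_reading_times(corpus, "saved_time_concurrent", "dersimonian_laird")


class TestSecondReaderSummary:
    def test_published_range(self, corpus):
        assert summarize_second_reader(corpus) == (33, 41)

    def test_single_study(self, corpus):
        hsu = [o for o in corpus if o.reading_mode.value == "second_reader"][:1]
        assert summarize_second_reader(hsu) == (41, 41)

    def test_no_second_reader_rows_rejected(self, corpus):
        concurrent = [o for o in corpus if o.reading_mode.value == "concurrent_reader"]
        with pytest.raises(ValueError):
            summarize_second_reader(concurrent)


class TestParameterRecovery:
    def test_dl_recovers_truth_in_simulation(self):
        # 300 simulated corpora with known mu; bias within 2 Monte-Carlo SEs
        mu, n_rep = 77.0, 300
        means = []
        for rep in range(n_rep):
            spec = SimulationSpec(
                n_studies=6, scans_per_reader=100, mu_saving_s=mu,
                tau_between_study_s=25, sigma_within_s=40, seed=10_000 + rep,
            )
            pooled = pool_reading_times(
                simulate_corpus(spec), "saved_time_concurrent", "dersimonian_laird"
            )
            means.append(pooled.mean)
        means = np.array(means)
        mc_se = means.std(ddof=1) / math.sqrt(n_rep)
        assert abs(means.mean() - mu) < 2 * mc_se
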