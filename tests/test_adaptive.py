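import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from kernelscan.adaptive import test_window as adaptive_window_test
from kernelscan.adaptive import (
    BetaNull,
    adjust,
    bonferroni_threshold,
    fit_beta_observed,
    fit_beta_permutation,
    scan_windows,
    two_stage_scan,
)
from kernelscan.geno_io import make_fixed_windows, standardize
from kernelscan.preprocess import NuisanceModel, build_projection
from kernelscan.simulate import SimulationConfig, simulate_genotypes, simulate_linear_phenotype


@pytest.fixture(scope="module")
def window_instance():
    n, m = 300, 6
    g = simulate_genotypes(n=n, m=m, seed=31)
    z = standardize(g)
    proj = build_projection(NuisanceModel(np.ones((n, 1)), ["intercept"]))
    rng = np.random.default_rng(32)
    y_res = proj.apply(rng.standard_normal(n))
    return y_res, z, proj


class TestTestWindow:
    def test_single_gamma_p_min_is_the_p(self, window_instance):
        y_res, z, proj = window_instance
        res = adaptive_window_test(y_res, z, proj, gamma_grid=(0.1,), d_mult=10, seed=0)
        assert res.p_min == res.pvalues[0]
        assert res.d == 10 * z.shape[1]

    def test_reproducible_given_seed(self, window_instance):
        y_res, z, proj = window_instance
        a = adaptive_window_test(y_res, z, proj, d_mult=10, seed=5)
        b = adaptive_window_test(y_res, z, proj, d_mult=10, seed=5)
        assert a.pvalues == b.pvalues

    def test_different_seeds_differ(self, window_instance):
        y_res, z, proj = window_instance
        a = adaptive_window_test(y_res, z, proj, d_mult=10, seed=5)
        b = adaptive_window_test(y_res, z, proj, d_mult=10, seed=6)
        assert a.pvalues != b.pvalues

    def test_gamma_min_consistent(self, window_instance):
        y_res, z, proj = window_instance
        res = adaptive_window_test(y_res, z, proj, d_mult=10, seed=1)
        assert res.pvalues[res.gammas.index(res.gamma_min)] == res.p_min


class TestFitBetaObserved:
    def test_minimum_of_uniforms_recovers_theory(self, rng):
        # min of H iid uniforms ~ Beta(1, H)
        minima = rng.uniform(size=(100_000, 10)).min(axis=1)
        null = fit_beta_observed(minima)
        assert 0.97 <= null.alpha <= 1.03
        assert 9.7 <= null.beta <= 10.3

    def test_beta_sample_mle_consistency(self, rng):
        sample = rng.beta(1.0, 5.0, size=100_000)
        null = fit_beta_observed(sample)
        assert 0.98 <= null.alpha <= 1.02

    def test_too_few_values_error_mentions_permutation(self, rng):
        with pytest.raises(ValueError, match="permutation"):
            fit_beta_observed(rng.uniform(size=10))

    def test_degenerate_sample_rejected(self):
        with pytest.raises(ValueError, match="degenerate|identical"):
            fit_beta_observed(np.full(100, 0.5))

    def test_values_of_one_handled(self, rng):
        vals = np.concatenate([rng.uniform(size=99), [1.0]])
        null = fit_beta_observed(vals)
        assert null.alpha > 0 and null.beta > 0

    def test_invalid_values_rejected(self, rng):
        with pytest.raises(ValueError, match="0, 1"):
            fit_beta_observed(np.concatenate([rng.uniform(size=99), [0.0]]))


class TestAdjust:
    def test_endpoints(self):
        null = BetaNull(1.3, 4.2, "observed", 100)
        assert adjust(0.0, null) == 0.0
        assert adjust(1.0, null) == 1.0

    def test_closed_form_alpha_one(self):
        null = BetaNull(1.0, 5.0, "theoretical", 0)
        assert adjust(0.01, null) == pytest.approx(1 - (1 - 0.01) ** 5, rel=1e-10)
        assert adjust(0.01, null) == pytest.approx(0.049010, abs=1e-6)

    def test_identity_when_uniform(self):
        null = BetaNull(1.0, 1.0, "theoretical", 0)
        assert adjust(0.37, null) == pytest.approx(0.37)

    @given(st.lists(st.floats(0.0, 1.0), min_size=2, max_size=20))
    @settings(deadline=None, max_examples=50)
    def test_monotone_in_p_min(self, ps):
        null = BetaNull(0.9, 3.7, "observed", 100)
        adjusted = [adjust(p, null) for p in sorted(ps)]
        assert all(a <= b + 1e-15 for a, b in zip(adjusted, adjusted[1:]))


class TestMinimumPDistribution:
    def test_independent_uniform_minima_are_beta_1_h(self, rng):
        # the equality case: min of H=3 independent uniforms ~ Beta(1, 3)
        minima = rng.uniform(size=(20_000, 3)).min(axis=1)
        assert stats.kstest(minima, stats.beta(1, 3).cdf).pvalue > 0.01


class TestBonferroni:
    def test_genome_wide_scan_threshold(self):
        thresh = bonferroni_threshold(28_818, 53)
        assert thresh == pytest.approx(3.27e-8, rel=5e-3)

    def test_invalid_counts(self):
        with pytest.raises(ValueError):
            bonferroni_threshold(0, 5)


@pytest.fixture(scope="module")
def null_scan_setup():
    """Small genome plus a null phenotype for scan-level tests."""
    cfg = SimulationConfig(n=400, m=60 * 5, causal_ratio=1.0, h2=0.3, seed=41)
    g = simulate_genotypes(cfg.n, cfg.m, cfg.maf_range, seed=41, snps_per_window=5)
    windows = make_fixed_windows(g)
    y = simulate_linear_phenotype(g, cfg)
    return g, windows, y


class TestFitBetaPermutation:
    def test_zero_permutations_rejected(self, null_scan_setup):
        g, windows, y = null_scan_setup
        with pytest.raises(ValueError, match="n_perm"):
            fit_beta_permutation(g, y, windows, n_perm=0, d_mult=4, seed=0)

    def test_reproducible_given_seed(self, null_scan_setup):
        g, windows, y = null_scan_setup
        kw = dict(gamma_grid=(0.1,), d_mult=4, n_perm=1, seed=3, superwindow=1)
        a = fit_beta_permutation(g, y, windows, **kw)
        b = fit_beta_permutation(g, y, windows, **kw)
        assert (a.alpha, a.beta) == (b.alpha, b.beta)
        assert a.source == "permutation"

    def test_agrees_with_observed_null(self, null_scan_setup):
        # both approaches estimate the same null distribution of minima
        g, windows, y = null_scan_setup
        res = scan_windows(g, y, windows, gamma_grid=(0.1, 1.0), d_mult=4, seed=7)
        obs = fit_beta_observed(np.array([r.p_min for r in res]))
        perm = fit_beta_permutation(
            g, y, windows, gamma_grid=(0.1, 1.0), d_mult=4, n_perm=2, seed=7
        )
        # compare the implied rejection quantiles rather than raw parameters
        q_obs = stats.beta.ppf(0.05, obs.alpha, obs.beta)
        q_perm = stats.beta.ppf(0.05, perm.alpha, perm.beta)
        assert q_perm == pytest.approx(q_obs, rel=0.5)


class TestTwoStageScan:
    def test_null_scan_no_significant_hits(self, null_scan_setup):
        g, windows, y = null_scan_setup
        traits = pd.DataFrame({"trait": y})
        table = two_stage_scan(
            g, windows, traits, gamma_grid=(0.1,), d1_mult=4, d2_mult=8,
            n_seeds=2, seed=0, superwindow=3,
        )
        assert len(table) == len(windows)
        assert table["significant"].sum() == 0

    def test_deterministic_rerun(self, null_scan_setup):
        g, windows, y = null_scan_setup
        traits = pd.DataFrame({"trait": y})
        kw = dict(gamma_grid=(0.1,), d1_mult=4, d2_mult=8, n_seeds=2, seed=0,
                  superwindow=3)
        a = two_stage_scan(g, windows, traits, **kw)
        b = two_stage_scan(g, windows, traits, **kw)
        pd.testing.assert_frame_equal(a, b)

    def test_moderate_stage1_p_never_advances(self, null_scan_setup):
        # any pair with stage-1 adjusted p >= alpha1 stays in stage 1
        g, windows, y = null_scan_setup
        traits = pd.DataFrame({"trait": y})
        table = two_stage_scan(
            g, windows, traits, gamma_grid=(0.1,), d1_mult=4, d2_mult=8,
            n_seeds=2, seed=0, superwindow=3, alpha1=1e-5,
        )
        not_advanced = table[table["p_adjusted"] >= 1e-5]
        assert (not_advanced["stage"] == 1).all()
        assert not_advanced["p_stage2_max"].isna().all()

    def test_output_schema(self, null_scan_setup):
        g, windows, y = null_scan_setup
        traits = pd.DataFrame({"t1": y})
        table = two_stage_scan(
            g, windows, traits, gamma_grid=(0.1, 1.0), d1_mult=4, d2_mult=8,
            n_seeds=1, seed=0, superwindow=3,
        )
        for col in ("trait", "chrom", "start", "end", "label", "n_snps", "D",
                    "seed", "p_gamma_0.1", "p_gamma_1", "p_min", "p_adjusted",
                    "stage", "significant"):
            assert col in table.columns
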