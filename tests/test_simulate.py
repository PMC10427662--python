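import numpy as np
import pytest
from scipy import stats

from kernelscan.geno_io import standardize
from kernelscan.rff import exact_rbf_kernel
from kernelscan.simulate import (
    KernelAltConfig,
    SimulationConfig,
    calibration_run,
    power_concordance_run,
    qq_coordinates,
    simulate_genotypes,
    simulate_kernel_phenotype,
    simulate_linear_phenotype,
)


class TestSimulationConfig:
    @pytest.mark.parametrize(
        "bad",
        [
            dict(h2=1.2),
            dict(maf_range=(0.0, 0.5)),
            dict(maf_range=(0.01, 0.6)),
            dict(causal_ratio=0.0),
            dict(causal_maf_bin="WEIRD"),
        ],
    )
    def test_invalid_configs_rejected(self, bad):
        with pytest.raises(ValueError):
            SimulationConfig(n=100, m=10, **bad)


class TestSimulateGenotypes:
    def test_allele_frequency_matches_maf(self):
        g = simulate_genotypes(n=100_000, m=1, maf_range=(0.5, 0.5), seed=0)
        freq = g.dosages.mean() / 2
        se = np.sqrt(0.5 * 0.5 / (2 * 100_000))
        assert abs(freq - 0.5) < 3 * se

    def test_no_ld_uncorrelated_adjacent(self):
        g = simulate_genotypes(n=50_000, m=2, maf_range=(0.3, 0.3), seed=1, ld_r=0.0)
        r = np.corrcoef(g.dosages.T.astype(float))[0, 1]
        assert abs(r) < 0.02

    def test_copying_process_adjacent_correlation(self):
        # equal MAFs: adjacent dosage correlation equals the copying rate
        g = simulate_genotypes(
            n=100_000, m=2, maf_range=(0.3, 0.3), seed=2, ld_r=0.9, ld_model="copying"
        )
        r = np.corrcoef(g.dosages.T.astype(float))[0, 1]
        assert r == pytest.approx(0.9, abs=0.02)

    def test_founder_model_polymorphic_and_correlated(self):
        g = simulate_genotypes(
            n=5000, m=34, seed=3, ld_model="founder", snps_per_window=17,
            n_founders=20,
        )
        assert (g.variants["maf"] > 0).all()
        z = standardize(g)
        corr = np.corrcoef(z.T)
        off = np.abs(corr[np.triu_indices(34, k=1)])
        assert off.mean() > 0.05  # within-block dependence exists

    def test_bitwise_reproducible(self):
        a = simulate_genotypes(n=50, m=20, seed=7, ld_r=0.5, ld_model="copying")
        b = simulate_genotypes(n=50, m=20, seed=7, ld_r=0.5, ld_model="copying")
        np.testing.assert_array_equal(a.dosages, b.dosages)

    def test_unknown_ld_model_rejected(self):
        with pytest.raises(ValueError, match="ld_model"):
            simulate_genotypes(n=10, m=5, seed=0, ld_r=0.5, ld_model="nope")


class TestLinearPhenotype:
    def test_h2_zero_pure_noise(self):
        g = simulate_genotypes(n=2000, m=50, seed=5)
        cfg = SimulationConfig(n=2000, m=50, h2=0.0, seed=5)
        y, info = simulate_linear_phenotype(g, cfg, return_info=True)
        assert info["causal"].size == 0
        assert stats.kstest(y, "norm").pvalue > 1e-4

    def test_heritability_enforced(self):
        n = 10_000
        g = simulate_genotypes(n=n, m=200, seed=6)
        ratios = []
        rng = np.random.default_rng(6)
        for _ in range(10):
            cfg = SimulationConfig(n=n, m=200, h2=0.5, causal_ratio=1.0, seed=6)
            y, info = simulate_linear_phenotype(g, cfg, rng=rng, return_info=True)
            ratios.append(info["genetic"].var() / y.var())
        assert np.mean(ratios) == pytest.approx(0.5, abs=0.01)

    def test_unit_total_variance(self):
        n = 20_000
        g = simulate_genotypes(n=n, m=100, seed=8)
        cfg = SimulationConfig(n=n, m=100, h2=0.5, causal_ratio=1.0, seed=8)
        y = simulate_linear_phenotype(g, cfg)
        assert y.var() == pytest.approx(1.0, abs=0.02)

    def test_causal_count_is_rounded_ratio(self):
        g = simulate_genotypes(n=200, m=1000, seed=9)
        cfg = SimulationConfig(n=200, m=1000, causal_ratio=0.005, seed=9)
        _, info = simulate_linear_phenotype(g, cfg, return_info=True)
        assert info["causal"].size == 5

    def test_causal_variants_respect_maf_bin(self):
        g = simulate_genotypes(n=500, m=400, maf_range=(0.01, 0.5), seed=10)
        cfg = SimulationConfig(
            n=500, m=400, causal_ratio=0.05, causal_maf_bin="RARE", seed=10
        )
        _, info = simulate_linear_phenotype(g, cfg, return_info=True)
        mafs = g.variants["maf"].to_numpy()[info["causal"]]
        assert np.all((mafs >= 0.01) & (mafs <= 0.05))

    def test_empty_bin_raises(self):
        g = simulate_genotypes(n=100, m=20, maf_range=(0.2, 0.5), seed=11)
        cfg = SimulationConfig(
            n=100, m=20, causal_ratio=0.5, causal_maf_bin="RARE", seed=11
        )
        with pytest.raises(ValueError, match="bin"):
            simulate_linear_phenotype(g, cfg)


class TestKernelPhenotype:
    def test_no_signal_is_pure_noise(self):
        z = standardize(simulate_genotypes(n=2000, m=10, seed=12))
        alt = KernelAltConfig(sigma_g2=0.0, sigma_e2=0.8)
        y = simulate_kernel_phenotype(z, alt, seed=1)
        assert y.var() == pytest.approx(0.8, rel=0.1)

    def test_marginal_variance_is_total(self):
        z = standardize(simulate_genotypes(n=3000, m=10, seed=13))
        alt = KernelAltConfig(sigma_g2=0.3, sigma_e2=0.7)
        y = simulate_kernel_phenotype(z, alt, seed=2)
        # diag(K) = 1 so var(y_i) = sg2 + se2
        assert y.var() == pytest.approx(1.0, rel=0.1)

    def test_exact_path_covariance_matches(self):
        n, reps = 100, 3000
        z = standardize(simulate_genotypes(n=n, m=8, seed=14))
        alt = KernelAltConfig(gamma=0.1, sigma_g2=0.3, sigma_e2=0.7)
        draws = np.stack(
            [simulate_kernel_phenotype(z, alt, seed=s) for s in range(reps)]
        )
        sample_cov = np.cov(draws.T)
        truth = alt.sigma_g2 * exact_rbf_kernel(z, alt.gamma) + alt.sigma_e2 * np.eye(n)
        # SE of a sample covariance entry ~ sqrt((s_ii*s_jj + s_ij^2)/reps)
        var_entry = (
            np.outer(np.diag(truth), np.diag(truth)) + truth**2
        ) / reps
        zscores = (sample_cov - truth) / np.sqrt(var_entry)
        assert np.mean(np.abs(zscores) > 3) < 0.01

    def test_rff_path_variance(self):
        z = standardize(simulate_genotypes(n=3000, m=10, seed=15))
        alt = KernelAltConfig(gamma=0.1, sigma_g2=0.3, sigma_e2=0.7)
        y = simulate_kernel_phenotype(z, alt, seed=3, method="rff")
        assert y.var() == pytest.approx(1.0, rel=0.1)


class TestHarnesses:
    def test_calibration_run_schema_and_rates(self):
        cfg = SimulationConfig(n=300, m=60 * 5, causal_ratio=1.0, h2=0.3, seed=20)
        res = calibration_run(
            n_windows=60, cfg=cfg, snps_per_window=5, gamma_grid=(0.1,),
            d_mult=4, superwindow=1, seed=20,
        )
        assert set(res.rates.columns) == {"alpha", "n", "n_reject", "rate", "ci_lo", "ci_hi"}
        assert (res.rates["ci_lo"] <= res.rates["rate"]).all()
        assert (res.rates["rate"] <= res.rates["ci_hi"]).all()
        assert len(res.adjusted_p) == 60

    def test_qq_band_contains_uniform_quantiles(self, rng):
        qq = qq_coordinates(rng.uniform(size=500))
        inside = (qq["observed"] >= qq["band_lo"]) & (qq["observed"] <= qq["band_hi"])
        assert inside.mean() > 0.9

    def test_power_increases_with_signal(self):
        alts = (
            KernelAltConfig(gamma=0.1, sigma_g2=0.0, sigma_e2=1.0),
            KernelAltConfig(gamma=0.1, sigma_g2=0.3, sigma_e2=0.7),
        )
        table = power_concordance_run(
            n=400, n_windows=40, snps_per_window=10, alt_grid=alts,
            d_mults=(20,), seed=21, run_exact=False,
        )
        p_null = table.loc[table["sigma_g2"] == 0.0, "power_rff"].iloc[0]
        p_alt = table.loc[table["sigma_g2"] == 0.3, "power_rff"].iloc[0]
        assert p_null < 0.15  # near alpha
        assert p_alt > p_null + 0.2
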