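"""Synthetic genotypes and phenotypes for calibration and power studies.

Genotypes are biallelic hard calls with per-variant MAF drawn uniformly
from a configurable range. Two optional linkage-disequilibrium processes
are provided:

* ``copying`` — each haplotype allele copies its left neighbour with
  probability ``ld_r``, else is drawn fresh at the site's MAF. Adjacent
  haplotype correlation is approximately ``ld_r``; the induced cross-site
  dependence is linear in the conditional mean.
* ``gaussian`` — alleles are thresholded latent Gaussian AR(1) variables
  with autocorrelation ``ld_r``. Thresholding makes conditional means
  mildly nonlinear across sites with unequal MAFs.
* ``founder`` — haplotypes are drawn from a finite pool of founder
  haplotypes within blocks of consecutive sites (plus a small mutation
  rate). When the pool is larger than the SNP count of a tested window,
  flanking sites are additive functions of founder identity that the
  window's linear span cannot absorb but its quadratic span partially
  can — the feature of real haplotype structure that makes insufficient
  linear residualization visible as miscalibration of the nonlinear test.

Null phenotypes follow a linear additive architecture: a fraction of
variants (optionally restricted to a MAF bin) is causal, effects are iid
normal on standardized genotypes, and the genetic and noise components are
rescaled so the trait has heritability h2 and unit variance. Alternative
phenotypes are Gaussian-process draws y ~ N(0, sg2*K + se2*I) with K the
RBF kernel of the tested window.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .adaptive import (
    DEFAULT_GAMMA_GRID,
    adjust,
    fit_beta_observed,
    BetaNull,
    scan_windows,
)
from .geno_io import GenotypeDataset, compute_variant_stats, make_fixed_windows, standardize
from .preprocess import NuisanceModel, build_projection, estimate_sigma_eps
from .rff import exact_rbf_kernel, sample_feature_map, transform
from .score_test import exact_score_test, rff_score_test

logger = logging.getLogger(__name__)

MAF_BINS: dict[str, tuple[float, float]] = {
    "ALL": (0.01, 0.5),
    "COMMON": (0.05, 0.5),
    "RARE": (0.01, 0.05),
}


@dataclass(frozen=True)
class SimulationConfig:
    """Linear-architecture (null-for-the-nonlinear-test) trait design."""

    n: int
    m: int
    maf_range: tuple[float, float] = (0.01, 0.5)
    causal_ratio: float = 0.001
    causal_maf_bin: str = "ALL"
    h2: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.h2 <= 1.0:
            raise ValueError("h2 must lie in [0, 1]")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must be within (0, 0.5]")
        if not 0.0 < self.causal_ratio <= 1.0:
            raise ValueError("causal_ratio must lie in (0, 1]")
        if self.causal_maf_bin not in MAF_BINS:
            raise ValueError(f"causal_maf_bin must be one of {sorted(MAF_BINS)}")


@dataclass(frozen=True)
class KernelAltConfig:
    """Kernel-GP alternative: y ~ N(0, sg2*K_gamma + se2*I)."""

    gamma: float = 0.1
    sigma_g2: float = 0.05
    sigma_e2: float = 0.95
    window_size: int = 100_000

    def __post_init__(self) -> None:
        if self.sigma_g2 + self.sigma_e2 <= 0:
            raise ValueError("total variance must be positive")
        if self.sigma_g2 < 0 or self.sigma_e2 < 0:
            raise ValueError("variance components must be nonnegative")
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------


def simulate_genotypes(
    n: int,
    m: int,
    maf_range: tuple[float, float] = (0.01, 0.5),
    seed: int = 0,
    ld_r: float = 0.0,
    ld_model: str = "copying",
    window_size_bp: int = 100_000,
    snps_per_window: int = 17,
    chrom: str = "1",
    n_founders: int = 40,
    founder_block_snps: int | None = None,
    mutation_rate: float = 0.02,
) -> GenotypeDataset:
    """Simulate hard-call genotypes with optional first-order LD.

    Variants are laid out at regular spacing so that fixed windows of
    ``window_size_bp`` contain ``snps_per_window`` variants each. The
    ``founder`` model ignores ``ld_r`` and is parameterized by the pool
    size, the block length (default three windows of sites) and the
    per-allele mutation rate.
    """
    if n < 1 or m < 1:
        raise ValueError("N and M must be >= 1")
    if not 0.0 <= ld_r < 1.0:
        raise ValueError("ld_r must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    maf = rng.uniform(maf_range[0], maf_range[1], size=m)

    if ld_model == "founder":
        block = founder_block_snps or 3 * snps_per_window
        dosages = _founder_pool_haplotypes(n, maf, rng, n_founders, block, mutation_rate)
    elif ld_r == 0.0:
        dosages = rng.binomial(2, maf, size=(n, m)).astype(np.int8)
    elif ld_model == "copying":
        dosages = _copying_haplotypes(n, maf, ld_r, rng)
    elif ld_model == "gaussian":
        dosages = _gaussian_threshold_haplotypes(n, maf, ld_r, rng)
    else:
        raise ValueError("ld_model must be 'copying', 'gaussian' or 'founder'")

    spacing = max(window_size_bp // snps_per_window, 1)
    pos = 1 + spacing * np.arange(m)
    variants = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": pos,
            "id": [f"snp{j}" for j in range(m)],
            "allele_a": "A",
            "allele_b": "G",
        }
    )
    variants = compute_variant_stats(dosages, variants)
    samples = [f"ind{i}" for i in range(n)]
    return GenotypeDataset(dosages, variants, samples)


def _copying_haplotypes(n: int, maf: np.ndarray, r: float, rng: np.random.Generator) -> np.ndarray:
    """Markov copying process on two haplotypes per individual: allele j is a
    copy of allele j-1 with probability r, else fresh Bernoulli(maf_j)."""
    m = maf.size
    hap = np.empty((n, 2, m), dtype=np.int8)
    hap[:, :, 0] = rng.random((n, 2)) < maf[0]
    for j in range(1, m):
        copy = rng.random((n, 2)) < r
        fresh = rng.random((n, 2)) < maf[j]
        hap[:, :, j] = np.where(copy, hap[:, :, j - 1], fresh)
    return hap.sum(axis=1, dtype=np.int8)


def _gaussian_threshold_haplotypes(
    n: int, maf: np.ndarray, r: float, rng: np.random.Generator
) -> np.ndarray:
    """Latent Gaussian AR(1) per haplotype, thresholded at the MAF quantile."""
    m = maf.size
    thresholds = stats.norm.ppf(maf)
    x = np.empty((n, 2, m))
    x[:, :, 0] = rng.standard_normal((n, 2))
    scale = np.sqrt(1.0 - r * r)
    for j in range(1, m):
        x[:, :, j] = r * x[:, :, j - 1] + scale * rng.standard_normal((n, 2))
    hap = (x < thresholds).astype(np.int8)
    return hap.sum(axis=1, dtype=np.int8)


def _founder_pool_haplotypes(
    n: int,
    maf: np.ndarray,
    rng: np.random.Generator,
    n_founders: int,
    block_snps: int,
    mutation_rate: float,
) -> np.ndarray:
    """Blockwise founder-pool haplotypes: within each block of consecutive
    sites every haplotype copies one of ``n_founders`` founder haplotypes
    (chosen independently per block), then mutates each allele with
    probability ``mutation_rate``. Founder carrier counts are set to
    max(1, round(K * maf)) so no site is monomorphic in the pool."""
    m = maf.size
    hap = np.empty((n, 2, m), dtype=np.int8)
    for b0 in range(0, m, block_snps):
        b1 = min(b0 + block_snps, m)
        width = b1 - b0
        founders = np.zeros((n_founders, width), dtype=np.int8)
        for j in range(width):
            carriers = max(1, int(round(n_founders * maf[b0 + j])))
            founders[rng.choice(n_founders, size=carriers, replace=False), j] = 1
        idx = rng.integers(0, n_founders, size=(n, 2))
        h = founders[idx]  # (n, 2, width)
        mut = rng.random(h.shape) < mutation_rate
        hap[:, :, b0:b1] = np.where(mut, 1 - h, h)
    return hap.sum(axis=1, dtype=np.int8)


# ---------------------------------------------------------------------------
# Phenotypes
# ---------------------------------------------------------------------------


def simulate_linear_phenotype(
    g: GenotypeDataset,
    cfg: SimulationConfig,
    rng: np.random.Generator | None = None,
    return_info: bool = False,
) -> np.ndarray | tuple[np.ndarray, dict]:
    """Linear additive trait: round(causal_ratio * M) causal variants drawn
    uniformly from the configured MAF bin, iid normal effects on standardized
    genotypes, genetic variance rescaled to h2 and noise to 1 - h2.

    With ``return_info`` also returns the causal indices and effects.
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    n = g.n_samples
    noise = rng.standard_normal(n)
    if cfg.h2 == 0.0:
        return (noise, {"causal": np.empty(0, int), "beta": np.empty(0)}) if return_info else noise
    lo, hi = MAF_BINS[cfg.causal_maf_bin]
    maf = g.variants["maf"].to_numpy()
    in_bin = np.flatnonzero((maf >= lo) & (maf <= hi))
    if in_bin.size == 0:
        raise ValueError(f"no variants in causal MAF bin {cfg.causal_maf_bin} [{lo}, {hi}]")
    n_causal = max(int(round(cfg.causal_ratio * g.n_variants)), 1)
    if n_causal > in_bin.size:
        logger.info("bin holds %d < %d requested causal variants; using all", in_bin.size, n_causal)
        n_causal = in_bin.size
    causal = rng.choice(in_bin, size=n_causal, replace=False)
    z = standardize(g, causal)
    beta = rng.standard_normal(n_causal)
    genetic = z @ beta
    gsd = genetic.std()
    if gsd == 0:
        raise ValueError("degenerate genetic component")
    genetic *= np.sqrt(cfg.h2) / gsd
    noise *= np.sqrt(1.0 - cfg.h2) / noise.std()
    y = genetic + noise
    if return_info:
        return y, {"causal": causal, "beta": beta, "genetic": genetic}
    return y


def simulate_kernel_phenotype(
    z_window_std: np.ndarray,
    alt: KernelAltConfig,
    seed: int = 0,
    method: str = "exact",
    d: int | None = None,
) -> np.ndarray:
    """Draw y ~ N(0, sg2*K + se2*I) with K the RBF kernel of the window.

    ``exact`` factors the dense covariance (Cholesky, with a 1e-10 jitter
    retry on numerical non-PSD); ``rff`` draws y = sqrt(sg2)*Phi a +
    sqrt(se2)*e, which is exact for the approximate kernel Phi Phi'.
    """
    rng = np.random.default_rng(seed)
    z = np.asarray(z_window_std, dtype=np.float64)
    n = z.shape[0]
    e = rng.standard_normal(n)
    if alt.sigma_g2 == 0.0:
        return np.sqrt(alt.sigma_e2) * e
    if method == "exact":
        k = exact_rbf_kernel(z, alt.gamma)
        cov = alt.sigma_g2 * k + alt.sigma_e2 * np.eye(n)
        try:
            chol = np.linalg.cholesky(cov)
        except np.linalg.LinAlgError:
            logger.warning("covariance numerically non-PSD; adding 1e-10 jitter")
            chol = np.linalg.cholesky(cov + 1e-10 * np.eye(n))
        return chol @ rng.standard_normal(n)
    if method == "rff":
        d = d or 50 * z.shape[1]
        fmap = sample_feature_map(z.shape[1], d, alt.gamma, seed=int(rng.integers(2**31)))
        phi = transform(z, fmap)
        a = rng.standard_normal(d)
        return np.sqrt(alt.sigma_g2) * (phi @ a) + np.sqrt(alt.sigma_e2) * e
    raise ValueError("method must be 'exact' or 'rff'")


def simulate_covariates(n: int, seed: int = 0) -> pd.DataFrame:
    """Synthetic sample covariates: binary sex and a standardized age."""
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        {"sex": rng.integers(0, 2, size=n).astype(float), "age": rng.standard_normal(n)}
    )


# ---------------------------------------------------------------------------
# Harnesses
# ---------------------------------------------------------------------------


@dataclass
class CalibrationResult:
    """Rejection rates with exact binomial CIs plus QQ coordinates."""

    rates: pd.DataFrame
    qq: pd.DataFrame
    adjusted_p: np.ndarray
    p_min: np.ndarray
    beta_null: BetaNull


def _clopper_pearson(k: int, n: int, conf: float = 0.95) -> tuple[float, float]:
    a = (1 - conf) / 2
    lo = stats.beta.ppf(a, k, n - k + 1) if k > 0 else 0.0
    hi = stats.beta.ppf(1 - a, k + 1, n - k) if k < n else 1.0
    return float(lo), float(hi)


def qq_coordinates(pvals: np.ndarray, conf: float = 0.95) -> pd.DataFrame:
    """Sorted observed p-values against uniform expectation, with the
    pointwise Beta(i, n-i+1) confidence band for the i-th order statistic."""
    p = np.sort(np.asarray(pvals))
    n = p.size
    i = np.arange(1, n + 1)
    a = (1 - conf) / 2
    return pd.DataFrame(
        {
            "expected": (i - 0.5) / n,
            "observed": p,
            "band_lo": stats.beta.ppf(a, i, n - i + 1),
            "band_hi": stats.beta.ppf(1 - a, i, n - i + 1),
        }
    )


def calibration_run(
    n_windows: int = 2000,
    cfg: SimulationConfig | None = None,
    snps_per_window: int = 17,
    gamma_grid: tuple[float, ...] = DEFAULT_GAMMA_GRID,
    d_mult: int = 10,
    superwindow: int = 5,
    ld_r: float = 0.0,
    ld_model: str = "copying",
    alphas: tuple[float, ...] = (0.05, 0.01, 1e-3),
    seed: int = 0,
    n_phenotypes: int = 1,
) -> CalibrationResult:
    """Full-pipeline null calibration: simulate a genome of ``n_windows``
    fixed windows, draw linear-architecture phenotype(s), run the adaptive
    test on every window, adjust via the observed-minima Beta null, and
    report empirical rejection rates with Clopper-Pearson 95% CIs."""
    if cfg is None:
        cfg = SimulationConfig(n=5000, m=n_windows * snps_per_window, seed=seed)
    g = simulate_genotypes(
        cfg.n, cfg.m, cfg.maf_range, seed=cfg.seed, ld_r=ld_r, ld_model=ld_model,
        snps_per_window=snps_per_window,
    )
    windows = make_fixed_windows(g)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 7]))
    minima = []
    for rep in range(n_phenotypes):
        y = simulate_linear_phenotype(g, cfg, rng=rng)
        results = scan_windows(
            g, y, windows, gamma_grid=gamma_grid, d_mult=d_mult,
            seed=cfg.seed + rep, superwindow=superwindow,
        )
        minima.extend(r.p_min for r in results)
    p_min = np.asarray(minima)
    null = fit_beta_observed(p_min)
    adj = np.array([adjust(p, null) for p in p_min])
    rows = []
    for alpha in alphas:
        k = int((adj < alpha).sum())
        lo, hi = _clopper_pearson(k, adj.size)
        rows.append(
            {"alpha": alpha, "n": adj.size, "n_reject": k, "rate": k / adj.size,
             "ci_lo": lo, "ci_hi": hi}
        )
    return CalibrationResult(pd.DataFrame(rows), qq_coordinates(adj), adj, p_min, null)


def power_concordance_run(
    n: int = 2000,
    n_windows: int = 200,
    snps_per_window: int = 20,
    alt_grid: tuple[KernelAltConfig, ...] = (KernelAltConfig(),),
    d_mults: tuple[int, ...] = (50,),
    maf_range: tuple[float, float] = (0.05, 0.5),
    alpha: float = 0.05,
    seed: int = 0,
    run_exact: bool = True,
) -> pd.DataFrame:
    """Power and exact-vs-approximate concordance under kernel alternatives.

    For every (alternative, D-multiplier) setting, draws ``n_windows``
    independent windows, simulates y ~ N(0, sg2*K + se2*I) per window, and
    tests with both the dense-kernel path and the random-feature path. The
    nuisance (intercept plus window linear genotypes) mirrors the
    nonlinear-test protocol. Reports rejection rates at ``alpha``, the
    Pearson correlation of -log10 p pairs, and accept/reject concordance.
    """
    ss = np.random.SeedSequence([seed, 11])
    child = ss.spawn(n_windows)
    rows = []
    for alt in alt_grid:
        for d_mult in d_mults:
            rec = {"gamma": alt.gamma, "sigma_g2": alt.sigma_g2, "d_mult": d_mult}
            p_exact, p_rff = [], []
            for w in range(n_windows):
                wseed = int(child[w].generate_state(1)[0] % (2**31))
                g = simulate_genotypes(
                    n, snps_per_window, maf_range, seed=wseed,
                    snps_per_window=snps_per_window,
                )
                z = standardize(g)
                y = simulate_kernel_phenotype(z, alt, seed=wseed + 1)
                nuis = NuisanceModel(
                    np.hstack([np.ones((n, 1)), z]),
                    ["intercept"] + [f"snp{j}" for j in range(z.shape[1])],
                )
                proj = build_projection(nuis)
                y_res = proj.apply(y)
                sigma2 = estimate_sigma_eps(y_res, proj)
                fmap = sample_feature_map(
                    z.shape[1], d_mult * z.shape[1], alt.gamma, seed=wseed + 2
                )
                f_res = proj.apply(transform(z, fmap))
                p_rff.append(rff_score_test(y_res, f_res, sigma2).pvalue)
                if run_exact:
                    p_exact.append(exact_score_test(y, z, proj, alt.gamma).pvalue)
            p_rff = np.asarray(p_rff)
            rec["power_rff"] = float((p_rff < alpha).mean())
            rec["se_rff"] = float(np.sqrt(rec["power_rff"] * (1 - rec["power_rff"]) / n_windows))
            if run_exact:
                p_exact = np.asarray(p_exact)
                rec["power_exact"] = float((p_exact < alpha).mean())
                rec["se_exact"] = float(
                    np.sqrt(rec["power_exact"] * (1 - rec["power_exact"]) / n_windows)
                )
                lp_e = -np.log10(np.clip(p_exact, 1e-300, 1.0))
                lp_r = -np.log10(np.clip(p_rff, 1e-300, 1.0))
                rec["pearson_r_log10p"] = float(np.corrcoef(lp_e, lp_r)[0, 1])
                rec["pearson_r_p"] = float(np.corrcoef(p_exact, p_rff)[0, 1])
                rec["concordance"] = float(((p_exact < alpha) == (p_rff < alpha)).mean())
            rows.append(rec)
    return pd.DataFrame(rows)
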