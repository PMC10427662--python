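"""Hyperparameter-adaptive testing and the two-stage genome-wide scan.

The RBF scale gamma is unknown a priori, so each window is tested over a
grid {gamma_1, ..., gamma_H} and the minimum p-value taken as the statistic.
Were the H p-values independent uniforms, the minimum would be Beta(1, H);
in practice the tests share data and features, so a two-parameter Beta null
is fitted either to the observed genome-wide minima (valid when most windows
are null) or to minima recomputed on permuted phenotypes. The adjusted
p-value is the fitted Beta CDF evaluated at the observed minimum.

The genome-wide scan is two-stage: a cheap screen at a small approximation
dimension (default D = 10M) with a relaxed threshold, then confirmation of
the candidates at D = 50M across several independent feature-map seeds.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .geno_io import GenotypeDataset, WindowSet, standardize
from .preprocess import (
    Projection,
    assemble_nuisance,
    build_projection,
    estimate_sigma_eps,
)
from .rff import derive_map_seed, sample_feature_map, transform
from .score_test import rff_score_test

logger = logging.getLogger(__name__)

DEFAULT_GAMMA_GRID = (0.01, 0.1, 1.0)

_CLIP_HI = 1.0 - 1e-12


@dataclass
class WindowResult:
    """Adaptive test of one window: per-gamma p-values and the minimum."""

    label: str
    gammas: tuple[float, ...]
    pvalues: tuple[float, ...]
    d: int
    seed: int
    stage: int = 1
    adjusted_p: float | None = None
    degenerate: bool = False
    methods: tuple[str, ...] = ()

    @property
    def p_min(self) -> float:
        return min(self.pvalues)

    @property
    def gamma_min(self) -> float:
        return self.gammas[int(np.argmin(self.pvalues))]


@dataclass
class BetaNull:
    """Fitted Beta(alpha, beta) null for the minimum p-value."""

    alpha: float
    beta: float
    source: str  # "observed" | "permutation" | "theoretical"
    n_fitted: int
    fit_method: str = "mle"  # "mle" | "moments"

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("Beta shape parameters must be positive")


def test_window(
    y_res: np.ndarray,
    z_window_std: np.ndarray,
    proj: Projection,
    gamma_grid: tuple[float, ...] = DEFAULT_GAMMA_GRID,
    d_mult: int = 50,
    seed: int = 0,
    window_index: int = 0,
    replicate: int = 0,
    label: str = "",
    stage: int = 1,
) -> WindowResult:
    """Adaptive score test of one window over a gamma grid.

    Each gamma gets an independent feature map whose seed is derived
    deterministically from (seed, window_index, gamma_index, replicate).
    The noise variance is estimated once per window (the null model does
    not involve gamma). D = d_mult * M.
    """
    z_window_std = np.asarray(z_window_std, dtype=np.float64)
    m = z_window_std.shape[1]
    d = d_mult * m
    sigma_eps2 = estimate_sigma_eps(y_res, proj)
    if sigma_eps2 <= 0:
        logger.warning("window %s: zero residual variance; degenerate", label)
        ones = tuple(1.0 for _ in gamma_grid)
        return WindowResult(label, tuple(gamma_grid), ones, d, seed, stage,
                            degenerate=True, methods=("degenerate",) * len(gamma_grid))
    pvals, methods = [], []
    for h, gamma in enumerate(gamma_grid):
        map_seed = derive_map_seed(seed, window_index, h, replicate)
        fmap = sample_feature_map(m, d, gamma, map_seed)
        f_res = proj.apply(transform(z_window_std, fmap))
        res = rff_score_test(y_res, f_res, sigma_eps2)
        pvals.append(res.pvalue)
        methods.append(res.method)
    return WindowResult(
        label=label,
        gammas=tuple(gamma_grid),
        pvalues=tuple(pvals),
        d=d,
        seed=seed,
        stage=stage,
        methods=tuple(methods),
    )


# ---------------------------------------------------------------------------
# Beta null for the minimum p-value
# ---------------------------------------------------------------------------


def _beta_moments(vals: np.ndarray) -> tuple[float, float]:
    m, v = float(np.mean(vals)), float(np.var(vals))
    if v <= 0:
        raise ValueError("degenerate sample: zero variance")
    common = m * (1 - m) / v - 1.0
    if common <= 0:
        raise ValueError("sample inconsistent with a Beta distribution")
    return m * common, (1 - m) * common


def fit_beta_observed(p_min_values: np.ndarray, min_n: int = 50) -> BetaNull:
    """Two-parameter Beta MLE on observed minima (values exactly 1 are
    clipped just below 1 to avoid boundary degeneracy). Falls back to
    method-of-moments if the MLE fails, and flags it."""
    vals = np.asarray(p_min_values, dtype=np.float64)
    if vals.size < min_n:
        raise ValueError(
            f"only {vals.size} minima (< {min_n}); too few for a stable "
            "observed-data fit — use the permutation approach"
        )
    if np.any((vals <= 0) | (vals > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    if np.unique(vals).size < 2:
        raise ValueError("degenerate sample: all minima identical")
    vals = np.clip(vals, None, _CLIP_HI)
    try:
        a, b, _, _ = stats.beta.fit(vals, floc=0, fscale=1)
        if not (np.isfinite(a) and np.isfinite(b) and a > 0 and b > 0):
            raise ValueError("non-finite MLE")
        return BetaNull(float(a), float(b), "observed", vals.size, "mle")
    except Exception as e:
        logger.warning("Beta MLE failed (%s); method-of-moments fallback", e)
        a, b = _beta_moments(vals)
        return BetaNull(a, b, "observed", vals.size, "moments")


def adjust(p_min: float, null: BetaNull) -> float:
    """Adjusted p-value: Beta CDF of the observed minimum under the fitted
    null. Monotone nondecreasing in p_min; maps 0 -> 0 and 1 -> 1."""
    if not 0.0 <= p_min <= 1.0:
        raise ValueError("p_min must lie in [0, 1]")
    return float(stats.beta.cdf(p_min, null.alpha, null.beta))


# ---------------------------------------------------------------------------
# Whole-scan machinery
# ---------------------------------------------------------------------------


def bonferroni_threshold(n_windows: int, n_traits: int = 1, alpha: float = 0.05) -> float:
    """Family-wise threshold alpha / (n_windows * n_traits)."""
    if n_windows < 1 or n_traits < 1:
        raise ValueError("counts must be positive")
    return alpha / (n_windows * n_traits)


@dataclass
class _WindowContext:
    """Per-window projection cache shared across stages and permutations."""

    proj: Projection
    z_std: np.ndarray
    label: str
    index: int


def _window_contexts(
    g: GenotypeDataset,
    window_set: WindowSet,
    covariates: np.ndarray | pd.DataFrame | None,
    superwindow: int,
    include_quadratic: bool = False,
    include_pairwise: bool = False,
) -> list[_WindowContext]:
    out = []
    for i, w in enumerate(window_set):
        nuis = assemble_nuisance(
            g, i, window_set, covariates=covariates, superwindow=superwindow,
            include_quadratic=include_quadratic, include_pairwise=include_pairwise,
        )
        proj = build_projection(nuis)
        z = standardize(g, list(w.variant_indices))
        out.append(_WindowContext(proj=proj, z_std=z, label=w.label, index=i))
    return out


def scan_windows(
    g: GenotypeDataset,
    y: np.ndarray,
    window_set: WindowSet,
    covariates: np.ndarray | pd.DataFrame | None = None,
    gamma_grid: tuple[float, ...] = DEFAULT_GAMMA_GRID,
    d_mult: int = 50,
    seed: int = 0,
    superwindow: int = 5,
    replicate: int = 0,
    stage: int = 1,
    contexts: list[_WindowContext] | None = None,
    include_quadratic: bool = False,
    include_pairwise: bool = False,
) -> list[WindowResult]:
    """Adaptive test of every window against one phenotype."""
    if contexts is None:
        contexts = _window_contexts(
            g, window_set, covariates, superwindow, include_quadratic, include_pairwise
        )
    y = np.asarray(y, dtype=np.float64)
    results = []
    for ctx in contexts:
        t0 = time.perf_counter()
        y_res = ctx.proj.apply(y)
        res = test_window(
            y_res, ctx.z_std, ctx.proj, gamma_grid, d_mult, seed,
            window_index=ctx.index, replicate=replicate, label=ctx.label,
            stage=stage,
        )
        logger.debug(
            "window=%s stage=%d D=%d p_min=%.4g gamma_min=%g methods=%s time=%.3fs",
            res.label, stage, res.d, res.p_min, res.gamma_min,
            ",".join(res.methods), time.perf_counter() - t0,
        )
        results.append(res)
    return results


def fit_beta_permutation(
    g: GenotypeDataset,
    y: np.ndarray,
    window_set: WindowSet,
    covariates: np.ndarray | pd.DataFrame | None = None,
    gamma_grid: tuple[float, ...] = DEFAULT_GAMMA_GRID,
    d_mult: int = 50,
    n_perm: int = 10,
    seed: int = 0,
    superwindow: int = 5,
    min_n: int = 50,
    contexts: list[_WindowContext] | None = None,
) -> BetaNull:
    """Beta null from permuted phenotypes: permute individual labels of y
    ``n_perm`` times, recompute every window's minimum p-value under each
    permutation, and fit a single Beta to the pooled minima."""
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if contexts is None:
        contexts = _window_contexts(g, window_set, covariates, superwindow)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x5EED]))
    minima = []
    y = np.asarray(y, dtype=np.float64)
    for perm in range(n_perm):
        y_perm = y[rng.permutation(y.size)]
        res = scan_windows(
            g, y_perm, window_set, covariates, gamma_grid, d_mult, seed,
            superwindow, replicate=1000 + perm, contexts=contexts,
        )
        minima.extend(r.p_min for r in res)
    minima = np.asarray(minima)
    if minima.size < min_n:
        raise ValueError(
            f"only {minima.size} pooled minima (< {min_n}); increase n_perm "
            "or the number of windows"
        )
    null = fit_beta_observed(minima, min_n=min_n)
    return BetaNull(null.alpha, null.beta, "permutation", null.n_fitted, null.fit_method)


def two_stage_scan(
    g: GenotypeDataset,
    window_set: WindowSet,
    traits: pd.DataFrame,
    covariates: np.ndarray | pd.DataFrame | None = None,
    gamma_grid: tuple[float, ...] = DEFAULT_GAMMA_GRID,
    alpha1: float = 1e-5,
    d1_mult: int = 10,
    d2_mult: int = 50,
    n_seeds: int = 5,
    seed: int = 0,
    superwindow: int = 5,
    alpha_family: float = 0.05,
    beta_source: str = "observed",
    n_perm: int = 10,
    include_quadratic: bool = False,
    include_pairwise: bool = False,
) -> pd.DataFrame:
    """Two-stage scan over every (trait, window) pair.

    Stage 1 screens all pairs at D = d1_mult * M; pairs with adjusted
    p < alpha1 advance. Stage 2 retests candidates at D = d2_mult * M under
    ``n_seeds`` independent feature-map seeds; a pair is declared significant
    iff all n_seeds adjusted p-values fall below the Bonferroni threshold
    alpha_family / (n_windows * n_traits). The Beta null is fitted per trait
    from the stage-1 genome-wide minima (or from permutations) and reused to
    adjust stage-2 minima.
    """
    if len(window_set) == 0 or traits.shape[1] == 0:
        raise ValueError("need at least one window and one trait")
    contexts = _window_contexts(
        g, window_set, covariates, superwindow, include_quadratic, include_pairwise
    )
    thresh = bonferroni_threshold(len(window_set), traits.shape[1], alpha_family)
    rows = []
    for trait in traits.columns:
        y = traits[trait].to_numpy(dtype=np.float64)
        stage1 = scan_windows(
            g, y, window_set, covariates, gamma_grid, d1_mult, seed,
            superwindow, replicate=0, stage=1, contexts=contexts,
        )
        minima = np.array([r.p_min for r in stage1])
        if beta_source == "permutation":
            null = fit_beta_permutation(
                g, y, window_set, covariates, gamma_grid, d1_mult, n_perm=n_perm,
                seed=seed, superwindow=superwindow, contexts=contexts,
            )
        elif minima.size >= 50:
            null = fit_beta_observed(minima)
        else:
            # too few windows for a stable fit: independent-uniform null
            null = BetaNull(1.0, float(len(gamma_grid)), "theoretical", 0)
        logger.info("trait %s: Beta null alpha=%.3f beta=%.3f (%s/%s)",
                    trait, null.alpha, null.beta, null.source, null.fit_method)
        for r in stage1:
            r.adjusted_p = adjust(r.p_min, null)

        for ctx, r1 in zip(contexts, stage1):
            row = {
                "trait": trait,
                "chrom": window_set[ctx.index].chrom,
                "start": window_set[ctx.index].start,
                "end": window_set[ctx.index].end,
                "label": r1.label,
                "n_snps": window_set[ctx.index].n_snps,
                "D": r1.d,
                "seed": seed,
                **{f"p_gamma_{gam:g}": p for gam, p in zip(r1.gammas, r1.pvalues)},
                "p_min": r1.p_min,
                "p_adjusted": r1.adjusted_p,
                "stage": 1,
                "significant": 0,
            }
            if r1.adjusted_p is not None and r1.adjusted_p < alpha1:
                y_res = ctx.proj.apply(y)
                adj2 = []
                for rep in range(1, n_seeds + 1):
                    r2 = test_window(
                        y_res, ctx.z_std, ctx.proj, gamma_grid, d2_mult, seed,
                        window_index=ctx.index, replicate=rep, stage=2,
                    )
                    adj2.append(adjust(r2.p_min, null))
                row["stage"] = 2
                row["p_stage2_max"] = float(np.max(adj2))
                row["significant"] = int(all(a < thresh for a in adj2))
            rows.append(row)
    out = pd.DataFrame(rows)
    if "p_stage2_max" not in out.columns:
        out["p_stage2_max"] = np.nan
    return out
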