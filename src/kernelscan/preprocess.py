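"""Phenotype normalization and fixed-effect projection.

A nonlinear set test is only meaningful after linear signal correlated with
the tested SNPs has been removed. The nuisance space therefore contains an
intercept, sample covariates (sex, age, PCs, ...) and the standardized
genotypes of a *superwindow*: the target window plus flanking windows whose
linear effects could otherwise leak into the nonlinear statistic through
linkage disequilibrium. Projection is realized through an orthonormal basis
(pivoted QR) of the nuisance columns; the explicit N x N projector is never
formed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .geno_io import GenotypeDataset, Window, WindowSet, standardize

logger = logging.getLogger(__name__)


def inverse_rank_normalize(y: np.ndarray) -> np.ndarray:
    """Map values to normal quantiles by rank: rank k of n -> Phi^-1((k-0.5)/n).

    Ties receive the average rank. Constant input raises.
    """
    y = np.asarray(y, dtype=np.float64)
    if y.ndim != 1:
        raise ValueError("expected a 1-D phenotype vector")
    if np.unique(y).size < 2:
        raise ValueError("phenotype is constant; cannot rank-normalize")
    ranks = stats.rankdata(y, method="average")
    return stats.norm.ppf((ranks - 0.5) / y.size)


@dataclass
class NuisanceModel:
    """Fixed-effect design: columns to be projected out of phenotype and
    feature matrices. The intercept is always the first column."""

    columns: np.ndarray  # (N, P)
    labels: list[str]

    def __post_init__(self) -> None:
        self.columns = np.asarray(self.columns, dtype=np.float64)
        if self.columns.shape[1] != len(self.labels):
            raise ValueError("label count does not match column count")

    @property
    def n_columns(self) -> int:
        return self.columns.shape[1]


@dataclass
class Projection:
    """Orthonormal basis Q of the nuisance column space; rank r = Q.shape[1].

    ``apply`` computes (I - Q Q^T) v without materializing the projector.
    """

    basis: np.ndarray  # (N, r)
    dropped: list[str]

    @property
    def rank(self) -> int:
        return self.basis.shape[1]

    @property
    def n_samples(self) -> int:
        return self.basis.shape[0]

    @property
    def residual_dof(self) -> int:
        return self.n_samples - self.rank

    def apply(self, v: np.ndarray) -> np.ndarray:
        v = np.asarray(v, dtype=np.float64)
        if v.shape[0] != self.n_samples:
            raise ValueError(
                f"leading dimension {v.shape[0]} != N={self.n_samples}"
            )
        return v - self.basis @ (self.basis.T @ v)


def build_projection(nuisance: NuisanceModel, rank_tol: float = 1e-10) -> Projection:
    """Pivoted-QR orthonormal basis of the nuisance span. Numerically
    dependent columns are dropped (and logged by label)."""
    X = nuisance.columns
    q, r, piv = linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    if diag.size == 0:
        raise ValueError("empty nuisance model")
    keep = diag > rank_tol * diag[0]
    rank = int(keep.sum())
    dropped = [nuisance.labels[piv[i]] for i in range(rank, len(piv))]
    if dropped:
        logger.info("dropping %d collinear nuisance column(s): %s", len(dropped), dropped)
    return Projection(basis=np.ascontiguousarray(q[:, :rank]), dropped=dropped)


def project_out(v: np.ndarray, proj: Projection) -> np.ndarray:
    """Residualize a vector or matrix against the nuisance space."""
    return proj.apply(v)


def estimate_sigma_eps(y_res: np.ndarray, proj: Projection) -> float:
    """Null residual-variance estimate y'Py / (N - r), with r the achieved
    nuisance rank."""
    if proj.residual_dof <= 0:
        raise ValueError("no residual degrees of freedom (N <= rank)")
    y_res = np.asarray(y_res, dtype=np.float64)
    return float(y_res @ y_res) / proj.residual_dof


def assemble_nuisance(
    g: GenotypeDataset,
    window_index: int,
    window_set: WindowSet,
    covariates: np.ndarray | pd.DataFrame | None = None,
    superwindow: int = 5,
    include_quadratic: bool = False,
    include_pairwise: bool = False,
) -> NuisanceModel:
    """Build the fixed-effect design for one tested window.

    Columns: intercept; covariates; standardized genotypes of the
    superwindow (target window plus (superwindow-1)/2 same-chromosome
    neighbours on each side, clipped at chromosome ends); optionally the
    squared standardized genotypes of the target window; optionally all
    within-target-window pairwise products.
    """
    if superwindow < 1 or superwindow % 2 == 0:
        raise ValueError("superwindow must be odd and >= 1")
    n = g.n_samples
    cols = [np.ones((n, 1))]
    labels = ["intercept"]
    if covariates is not None:
        if isinstance(covariates, pd.DataFrame):
            labels += [str(c) for c in covariates.columns]
            cov = covariates.to_numpy(dtype=np.float64)
        else:
            cov = np.atleast_2d(np.asarray(covariates, dtype=np.float64))
            if cov.shape[0] != n:
                cov = cov.T
            labels += [f"cov{j}" for j in range(cov.shape[1])]
        cols.append(cov)

    flank = (superwindow - 1) // 2
    member_windows = window_set.neighbors(window_index, flank)
    snp_idx: list[int] = []
    for j in member_windows:
        snp_idx.extend(window_set[j].variant_indices)
    snp_idx = sorted(set(snp_idx))
    z_super = standardize(g, snp_idx)
    cols.append(z_super)
    labels += [f"snp:{g.variants['id'].iloc[i]}" for i in snp_idx]

    target = window_set[window_index]
    if include_quadratic or include_pairwise:
        z_t = standardize(g, list(target.variant_indices))
        if include_quadratic:
            cols.append(z_t**2)
            labels += [
                f"snp2:{g.variants['id'].iloc[i]}" for i in target.variant_indices
            ]
        if include_pairwise:
            m = z_t.shape[1]
            prods = [
                z_t[:, a] * z_t[:, b] for a in range(m) for b in range(a + 1, m)
            ]
            if prods:
                cols.append(np.column_stack(prods))
                ids = [str(g.variants["id"].iloc[i]) for i in target.variant_indices]
                labels += [
                    f"snpx:{ids[a]}*{ids[b]}"
                    for a in range(m)
                    for b in range(a + 1, m)
                ]
    return NuisanceModel(np.hstack(cols), labels)


def gene_superwindow_indices(g: GenotypeDataset, window: Window, mult: int = 2) -> list[int]:
    """For gene windows the flanks are taken as +/- mult * (window span) in
    base pairs around the gene."""
    span = window.end - window.start
    lo = window.start - mult * span
    hi = window.end + mult * span
    chroms = g.variants["chrom"].to_numpy()
    pos0 = g.variants["pos"].to_numpy() - 1
    return [int(i) for i in np.flatnonzero((chroms == window.chrom) & (pos0 >= lo) & (pos0 < hi))]


def load_phenotype_table(
    path: str | Path, sample_order: list[str]
) -> pd.DataFrame:
    """Read a whitespace/tab-delimited table with a header whose first column
    is the individual ID, reindexed to ``sample_order``. Rows with missing
    values propagate as NaN (callers drop and log per trait)."""
    tab = pd.read_csv(path, sep=r"\s+")
    tab = tab.set_index(tab.columns[0])
    tab.index = tab.index.astype(str)
    missing = [s for s in sample_order if s not in tab.index]
    if missing:
        logger.warning("%d sample(s) absent from %s", len(missing), path)
    return tab.reindex(sample_order)
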