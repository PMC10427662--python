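"""Variance-component score test with a weighted sum-of-chi-square null.

Under y ~ N(Xb, sg2*K + se2*I), the score statistic for H0: sg2 = 0 is

    Q = y' P K P y / se2,      P = I - X (X'X)^-1 X',

asymptotically distributed as sum_n rho_n * chi2_1 where rho_n are the
eigenvalues of P K P. With the random-feature factorization K = F F', the
statistic reduces to ||F_res' y_res||^2 / se2 and the weights to the squared
singular values of the projected feature matrix F_res = P F, so no N x N
matrix is ever formed on the approximate path.

Tail probabilities of the weighted chi-square are computed by numerical
inversion of the characteristic function (Imhof's integral, the quantity
Davies' algorithm computes), with a Liu-type moment-matched chi-square
fallback when the inversion is unreliable.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import integrate, stats
from scipy.linalg import svdvals

from .preprocess import Projection, estimate_sigma_eps
from .rff import DEFAULT_EXACT_N_GUARD, exact_rbf_kernel

logger = logging.getLogger(__name__)

WEIGHT_REL_TOL = 1e-8


@dataclass
class ScoreTestResult:
    """One score test: statistic, null spectrum, and p-value."""

    statistic: float
    weights: np.ndarray  # descending, positive, truncated
    sigma_eps2: float
    pvalue: float
    method: str  # "davies" (CF inversion) or "moment_matched"
    n_truncated: int = 0


def score_statistic(y_res: np.ndarray, f_res: np.ndarray, sigma_eps2: float) -> float:
    """Q = ||F_res' y_res||^2 / sigma_eps2 (= y'PKPy/se2 for K = FF')."""
    if sigma_eps2 <= 0:
        raise ValueError("sigma_eps2 must be positive")
    v = np.asarray(f_res).T @ np.asarray(y_res)
    return float(v @ v) / sigma_eps2


def null_weights(f_res: np.ndarray, rel_tol: float = WEIGHT_REL_TOL) -> np.ndarray:
    """Squared singular values of the projected feature matrix, descending,
    with values below rel_tol * max discarded (directions annihilated by the
    projection are numerically zero, not signal)."""
    s = svdvals(np.asarray(f_res, dtype=np.float64))
    w = s**2
    if w.size == 0 or w[0] <= 0:
        return np.empty(0)
    return w[w >= rel_tol * w[0]]


# ---------------------------------------------------------------------------
# Weighted chi-square tail probability
# ---------------------------------------------------------------------------


def _imhof_tail(q: float, weights: np.ndarray, epsabs: float = 1e-12) -> float:
    """P(sum_i w_i chi2_1 > q) by characteristic-function inversion:

    p = 1/2 + (1/pi) * int_0^inf sin(theta(u)) / (u * rho(u)) du,
    theta(u) = 1/2 sum arctan(w_i u) - q u / 2,
    rho(u)   = prod (1 + w_i^2 u^2)^(1/4).
    """
    w = weights

    def integrand(u: float) -> float:
        wu = w * u
        theta = 0.5 * np.sum(np.arctan(wu)) - 0.5 * q * u
        log_rho = 0.25 * np.sum(np.log1p(wu * wu))
        return float(np.sin(theta) * np.exp(-log_rho) / u)

    # the integrand -> (sum(w) - q)/2 as u -> 0; quad handles the endpoint
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", integrate.IntegrationWarning)
        val, _ = integrate.quad(
            integrand, 0.0, np.inf, epsabs=epsabs, epsrel=1e-10, limit=100_000
        )
    return 0.5 + val / np.pi


def _liu_tail(q: float, weights: np.ndarray) -> float:
    """Liu-Tang-Zhang moment-matched noncentral-chi-square approximation to
    the weighted chi-square survival function."""
    c1 = float(np.sum(weights))
    c2 = float(np.sum(weights**2))
    c3 = float(np.sum(weights**3))
    c4 = float(np.sum(weights**4))
    s1 = c3 / c2**1.5
    s2 = c4 / c2**2
    if s1**2 > s2:
        a = 1.0 / (s1 - np.sqrt(s1**2 - s2))
        delta = s1 * a**3 - a**2
        dof = a**2 - 2 * delta
    else:
        delta = 0.0
        dof = 1.0 / s2
    mu_q = c1
    sigma_q = np.sqrt(2 * c2)
    t_star = (q - mu_q) / sigma_q
    mu_x = dof + delta
    sigma_x = np.sqrt(2 * (dof + 2 * delta))
    return float(stats.ncx2.sf(t_star * sigma_x + mu_x, df=dof, nc=delta))


def pvalue_weighted_chisq(q: float, weights: np.ndarray) -> tuple[float, str]:
    """Tail probability P(sum w_i chi2_1 > q).

    Primary route is characteristic-function inversion ("davies"); if the
    quadrature fails or yields a value outside (0, 1], the moment-matched
    approximation is used and flagged. Empty weights mean the projected
    feature matrix was identically zero and the test is vacuous (p = 1).
    """
    weights = np.asarray(weights, dtype=np.float64)
    if weights.size == 0:
        return 1.0, "davies"
    if np.any(weights < 0):
        raise ValueError("weights must be nonnegative")
    if q < 0:
        raise ValueError("statistic must be nonnegative")
    if q == 0:
        return 1.0, "davies"
    if weights.size == 1:
        # single weight: exact scaled chi-square closed form
        return float(stats.chi2.sf(q / weights[0], df=1)), "davies"
    try:
        with np.errstate(over="ignore"):
            p = _imhof_tail(q, weights)
    except Exception:  # quadrature breakdown
        p = np.nan
    if np.isfinite(p) and 1e-13 < p <= 1.0:
        return float(min(p, 1.0)), "davies"
    p = _liu_tail(q, weights)
    logger.debug("CF inversion unreliable (p=%r); moment-matched fallback", p)
    return float(np.clip(p, np.nextafter(0, 1), 1.0)), "moment_matched"


# ---------------------------------------------------------------------------
# Full tests
# ---------------------------------------------------------------------------


def rff_score_test(
    y_res: np.ndarray,
    f_res: np.ndarray,
    sigma_eps2: float,
    rel_tol: float = WEIGHT_REL_TOL,
) -> ScoreTestResult:
    """Score test from an already-projected phenotype and feature matrix."""
    weights = null_weights(f_res, rel_tol=rel_tol)
    q = score_statistic(y_res, f_res, sigma_eps2)
    if weights.size == 0:
        return ScoreTestResult(q, weights, sigma_eps2, 1.0, "davies")
    p, method = pvalue_weighted_chisq(q, weights)
    n_trunc = min(f_res.shape) - weights.size
    return ScoreTestResult(q, weights, sigma_eps2, p, method, max(n_trunc, 0))


def exact_score_test(
    y: np.ndarray,
    z_std: np.ndarray,
    proj: Projection,
    gamma: float,
    n_guard: int = DEFAULT_EXACT_N_GUARD,
    rel_tol: float = WEIGHT_REL_TOL,
) -> ScoreTestResult:
    """Dense-kernel score test (validation path, O(N^2) memory / O(N^3) time).

    Builds the exact RBF kernel, computes Q = y'PKPy / se2 and the
    eigenvalues of PKP with the same truncation and p-value machinery as the
    approximate path. Deterministic: no random features are involved.
    """
    y = np.asarray(y, dtype=np.float64)
    k = exact_rbf_kernel(z_std, gamma, n_guard=n_guard)
    y_res = proj.apply(y)
    sigma_eps2 = estimate_sigma_eps(y_res, proj)
    ky = k @ y_res
    q = float(y_res @ proj.apply(ky)) / sigma_eps2

    # PKP via the orthonormal nuisance basis B: PKP = K - B(B'K) - (KB)B' + B(B'KB)B'
    b = proj.basis
    kb = k @ b
    btk = b.T @ k
    btkb = b.T @ kb
    pkp = k - b @ btk - kb @ b.T + b @ btkb @ b.T
    eig = np.linalg.eigvalsh(pkp)[::-1]
    eig = eig[eig > 0]
    weights = eig[eig >= rel_tol * eig[0]] if eig.size else np.empty(0)
    if weights.size == 0:
        return ScoreTestResult(q, weights, sigma_eps2, 1.0, "davies")
    p, method = pvalue_weighted_chisq(max(q, 0.0), weights)
    return ScoreTestResult(q, weights, sigma_eps2, p, method, int(eig.size - weights.size))
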