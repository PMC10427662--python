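"""Random Fourier features approximating the RBF kernel.

The RBF kernel is parameterized as k(z, z') = exp(-gamma * ||z - z'||^2 / 2).
Bochner's theorem gives k as the characteristic function of its spectral
density; for this parameterization the frequencies are omega ~ N(0, gamma*I).
With phases b ~ Uniform[0, 2*pi), the feature

    phi_d(z) = sqrt(2/D) * cos(omega_d' z + b_d)

satisfies E[phi(z)' phi(z')] = k(z, z'), so K_tilde = Phi Phi' is an unbiased
Monte Carlo estimate of K with D the approximation dimension.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

DEFAULT_EXACT_N_GUARD = 20_000


@dataclass(frozen=True)
class KernelModelSpec:
    """Variance-component model with an RBF kernel: y ~ N(Xb, sg2*K + se2*I)."""

    gamma: float
    sigma_g2: float = 0.0
    sigma_e2: float = 1.0

    def __post_init__(self) -> None:
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")
        if self.sigma_g2 < 0 or self.sigma_e2 < 0:
            raise ValueError("variance components must be nonnegative")


@dataclass(frozen=True)
class FeatureMap:
    """Sampled random Fourier parameters defining one approximate kernel."""

    gamma: float
    omega: np.ndarray  # (D, M) frequencies
    phases: np.ndarray  # (D,) in [0, 2*pi)
    seed: int

    @property
    def n_features(self) -> int:
        return self.omega.shape[0]

    @property
    def n_snps(self) -> int:
        return self.omega.shape[1]

    def save(self, path) -> None:
        """Archive the sampled parameters (npz) for audit/replay."""
        np.savez_compressed(
            path, gamma=self.gamma, omega=self.omega, phases=self.phases,
            seed=self.seed,
        )

    @classmethod
    def load(cls, path) -> "FeatureMap":
        with np.load(path) as arc:
            return cls(
                gamma=float(arc["gamma"]), omega=arc["omega"],
                phases=arc["phases"], seed=int(arc["seed"]),
            )


def sample_feature_map(m: int, d: int, gamma: float, seed: int) -> FeatureMap:
    """Draw a feature map: omega rows iid N(0, gamma*I_M), phases iid
    Uniform[0, 2*pi). Deterministic given ``seed``."""
    if m < 1 or d < 1:
        raise ValueError("M and D must be >= 1")
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    rng = np.random.default_rng(seed)
    omega = rng.normal(scale=np.sqrt(gamma), size=(d, m))
    phases = rng.uniform(0.0, 2.0 * np.pi, size=d)
    return FeatureMap(gamma=gamma, omega=omega, phases=phases, seed=seed)


def transform(z_std: np.ndarray, fmap: FeatureMap) -> np.ndarray:
    """Apply the feature map: entry (i, d) = sqrt(2/D) cos(omega_d' z_i + b_d)."""
    z_std = np.asarray(z_std, dtype=np.float64)
    if z_std.ndim != 2 or z_std.shape[1] != fmap.n_snps:
        raise ValueError(
            f"genotype matrix has {z_std.shape[-1]} columns, feature map "
            f"expects {fmap.n_snps}"
        )
    proj = z_std @ fmap.omega.T + fmap.phases
    np.cos(proj, out=proj)
    proj *= np.sqrt(2.0 / fmap.n_features)
    return proj


def exact_rbf_kernel(
    z_std: np.ndarray, gamma: float, n_guard: int = DEFAULT_EXACT_N_GUARD
) -> np.ndarray:
    """Dense RBF kernel K_ij = exp(-gamma*||z_i - z_j||^2 / 2).

    Intended as a validation oracle at small N; refuses above ``n_guard``
    since it is O(N^2) in memory and O(N^3) downstream.
    """
    z_std = np.asarray(z_std, dtype=np.float64)
    n = z_std.shape[0]
    if n > n_guard:
        raise ValueError(
            f"exact kernel refused for N={n} > guard {n_guard}; use the "
            "random-feature path or raise n_guard explicitly"
        )
    sq = squareform(pdist(z_std, metric="sqeuclidean"))
    return np.exp(-0.5 * gamma * sq)


def derive_map_seed(
    global_seed: int, window_index: int, gamma_index: int, replicate: int = 0
) -> int:
    """Deterministic per-(window, gamma, replicate) seed so that multi-seed
    retesting and reruns are reproducible."""
    ss = np.random.SeedSequence([global_seed, window_index, gamma_index, replicate])
    return int(ss.generate_state(1)[0] % (2**31))
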