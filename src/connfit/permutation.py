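"""Within-region permutation null for ridge model fits.

Activation values are shuffled across a region's vertices (each vertex keeps
its connectivity fingerprint, multiset of activations preserved) and the
ridge model is refit at the *true* model's penalty — no re-optimization —
once per permutation. The resulting R² distribution is the chance level
against which the true fit is compared.

The refits use an SVD identity: with Xc = U S Vᵀ (centered) and shrinkage
d_i = s_i²/(s_i²+λ), the in-sample R² of a permuted response y is
``Σ d_i(2−d_i) z_i² / ‖yc‖²`` with z = Uᵀ yc, so each permutation costs
O(n·k). Because d_i ∈ [0, 1), every permuted R² lies in [0, 1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from ._seeds import STREAM_PERMUTATION, substream
from .exceptions import DataError


@dataclass
class PermutationResult:
    """Permutation-null summary for one (region, domain) model."""

    region_id: int
    domain_id: int
    n_permutations: int
    perm_r2: np.ndarray = field(repr=False)
    p_value: float
    q99: float
    true_r2: float

    @property
    def perm_mean(self) -> float:
        return float(np.mean(self.perm_r2))

    @property
    def perm_sd(self) -> float:
        return float(np.std(self.perm_r2, ddof=1)) if self.perm_r2.size > 1 else 0.0


def permute_within_region(
    y: np.ndarray, seed: int | np.random.Generator
) -> np.ndarray:
    """Uniformly random permutation of a region's activation values (seeded)."""
    y = np.asarray(y)
    if y.shape[0] < 2:
        raise DataError("cannot permute fewer than 2 values")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return y[rng.permutation(y.shape[0])]


def empirical_p(perm_r2: np.ndarray, true_r2: float, smoothed: bool = False) -> float:
    """Fraction of permuted fits strictly exceeding the true fit.

    ``count(perm > true)/n`` by default; the smoothed ``(count+1)/(n+1)``
    estimator is available behind a flag.
    """
    perm_r2 = np.asarray(perm_r2, dtype=np.float64)
    if perm_r2.size == 0:
        raise DataError("empty permutation distribution")
    count = int(np.sum(perm_r2 > true_r2))
    if smoothed:
        return (count + 1) / (perm_r2.size + 1)
    return count / perm_r2.size


def percentile_99(perm_r2: np.ndarray) -> float:
    """Nearest-rank 99th percentile: the ⌈0.99·n⌉-th order statistic."""
    perm_r2 = np.asarray(perm_r2, dtype=np.float64)
    n = perm_r2.size
    if n == 0:
        raise DataError("empty permutation distribution")
    if n < 100:
        warnings.warn(
            f"99th percentile from only {n} permutations is coarse",
            RuntimeWarning,
            stacklevel=2,
        )
    rank = int(np.ceil(0.99 * n))  # 1-based
    return float(np.sort(perm_r2)[rank - 1])


def permutation_distribution(
    X_region: np.ndarray,
    y_region: np.ndarray,
    lambda_true: float,
    n_permutations: int = 1000,
    seed: int = 0,
    region_id: int = 0,
    domain_id: int = 0,
    standardize: bool = False,
) -> PermutationResult:
    """Null distribution of in-sample R² under within-region shuffling.

    Each permutation's seed derives from ``(seed, region_id, domain_id,
    perm_index)``, so the distribution is reproducible and independent of
    evaluation order or worker count. The true model's R² at ``lambda_true``
    is computed on the same SVD path.
    """
    if n_permutations < 1:
        raise DataError("n_permutations must be >= 1")
    X = np.asarray(X_region, dtype=np.float64)
    y = np.asarray(y_region, dtype=np.float64)
    if y.shape[0] != X.shape[0]:
        raise DataError("X and y disagree on the number of vertices")
    if np.ptp(y) == 0:
        raise DataError("constant activation: permutation null undefined")
    xc = X - X.mean(axis=0)
    if standardize:
        col = xc.std(axis=0, ddof=0)
        col[col == 0] = 1.0
        xc = xc / col
    u, s, _ = np.linalg.svd(xc, full_matrices=False)
    gain = None

    def insample_r2(yv: np.ndarray) -> float:
        yc = yv - yv.mean()
        z = u.T @ yc
        return float(gain @ (z**2) / (yc @ yc))

    d = s**2 / (s**2 + lambda_true)
    gain = d * (2.0 - d)
    true_r2 = insample_r2(y)

    perm_r2 = np.empty(n_permutations)
    for i in range(n_permutations):
        rng = substream(seed, STREAM_PERMUTATION, region_id, domain_id, i)
        perm_r2[i] = insample_r2(permute_within_region(y, rng))

    return PermutationResult(
        region_id=int(region_id),
        domain_id=int(domain_id),
        n_permutations=int(n_permutations),
        perm_r2=perm_r2,
        p_value=empirical_p(perm_r2, true_r2),
        q99=percentile_99(perm_r2),
        true_r2=true_r2,
    )
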