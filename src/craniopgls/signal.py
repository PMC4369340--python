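"""Phylogenetic signal: Blomberg's K and its multivariate extension K_mult.

K compares the observed ratio of among-species variance to
phylogenetically corrected variance against the ratio expected under
Brownian motion on the given tree:

    K = [ (x - a)'(x - a) / (x - a)' C^-1 (x - a) ] / E,
    E = [ tr(C) - N / (1' C^-1 1) ] / (N - 1),

with a = (1'C^-1 1)^-1 1'C^-1 x the phylogenetically weighted mean.
K = 1 matches Brownian motion exactly on a star phylogeny; K < 1 means
relatives resemble each other less than Brownian motion predicts.

K_mult replaces squared deviations by squared Euclidean distances across
all p traits (numerator sum ||Y_i - a||^2; denominator the same after
whitening Y - 1a' by C^(-1/2)), divided by the same trait-count-free
expectation E.  For p = 1 it reduces exactly to K.

Significance is assessed by shuffling the species means among the tips
of the phylogeny and recomputing the statistic; the observed value is
counted among the permutations, p = (1 + #{perm >= obs}) / (n_perm + 1).

Both statistics are computed through the eigendecomposition-based
C^(-1/2), so quadratic forms in C^-1 are squared norms of whitened
deviations; this makes the p = 1 reduction hold to machine precision and
handles singular C via the pseudo-inverse tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .phylo import PhyloCovariance


@dataclass
class SignalResult:
    statistic: float
    p_value: float | None
    n_perm: int
    permuted_stats: np.ndarray | None = None
    name: str = "K"

    def summary(self) -> str:
        p = "NA" if self.p_value is None else f"{self.p_value:.4g}"
        return (
            f"Phylogenetic signal {self.name} = {self.statistic:.4f}, "
            f"P = {p} ({self.n_perm} permutations)"
        )


def _as_matrix(data, C: PhyloCovariance) -> np.ndarray:
    """Align a SpeciesMeans table (or array) to the covariance taxon order."""
    if isinstance(data, pd.DataFrame):
        Y = data.reindex(C.taxa).to_numpy(dtype=float)
        if np.isnan(Y).any():
            missing = [t for t in C.taxa if t not in data.index]
            raise ValueError(f"taxa misaligned/missing in species means: {missing}")
    elif isinstance(data, pd.Series):
        return _as_matrix(data.to_frame(), C)
    else:
        Y = np.asarray(data, dtype=float)
        if Y.ndim == 1:
            Y = Y[:, None]
        if Y.shape[0] != C.n:
            raise ValueError("species means rows do not match covariance taxa")
    return Y


def _k_statistic(Y: np.ndarray, C: PhyloCovariance) -> float:
    N = C.n
    if N < 3:
        raise ValueError("need at least 3 taxa")
    P = C.inv_sqrt()
    one = np.ones(N)
    P1 = P @ one
    denom = float(P1 @ P1)  # 1' C^-1 1
    PY = P @ Y
    a = (P1 @ PY) / denom  # phylogenetically weighted mean, per trait
    D = Y - one[:, None] * a
    num = float(np.sum(D * D))
    if num <= 0:
        raise ValueError("constant trait: phylogenetic signal undefined")
    U = P @ D
    den = float(np.sum(U * U))
    E = (np.trace(C.matrix) - N / denom) / (N - 1)
    return (num / den) / E


def blomberg_k(x, C: PhyloCovariance) -> float:
    """Blomberg's K for a univariate trait of species means."""
    X = _as_matrix(x, C)
    if X.shape[1] != 1:
        raise ValueError("blomberg_k expects a single trait; use k_mult")
    return _k_statistic(X, C)


def k_mult(Y, C: PhyloCovariance) -> float:
    """Multivariate phylogenetic signal across all traits jointly."""
    return _k_statistic(_as_matrix(Y, C), C)


def signal_permutation_test(data, C: PhyloCovariance, n_perm: int = 1000,
                            seed: int | None = None,
                            keep_permutations: bool = False) -> SignalResult:
    """Tip-shuffling permutation test for K (p=1) or K_mult (p>1).

    Rows of the species-mean matrix are randomly reassigned to tips
    (C fixed) and the statistic recomputed; ties count as >= (conservative).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    Y = _as_matrix(data, C)
    obs = _k_statistic(Y, C)
    rng = np.random.default_rng(seed)
    N = C.n
    idx = np.stack([rng.permutation(N) for _ in range(n_perm)])
    M = Y[idx]  # (n_perm, N, p)
    P = C.inv_sqrt()
    P1 = P @ np.ones(N)
    denom = float(P1 @ P1)
    PM = np.einsum("ij,bjp->bip", P, M)
    a = np.einsum("j,bjp->bp", P1, PM) / denom
    D = M - a[:, None, :]
    num = np.sum(D * D, axis=(1, 2))
    den = np.sum(np.einsum("ij,bjp->bip", P, D) ** 2, axis=(1, 2))
    E = (np.trace(C.matrix) - N / denom) / (N - 1)
    perms = (num / den) / E
    p = (1 + int(np.sum(perms >= obs))) / (n_perm + 1)
    return SignalResult(
        statistic=obs,
        p_value=p,
        n_perm=n_perm,
        permuted_stats=perms if keep_permutations else None,
        name="K" if Y.shape[1] == 1 else "K_mult",
    )
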