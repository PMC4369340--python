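"""Principal components analysis on the covariance matrix of shape ratios.

Covariance (not correlation) PCA: the log-shape ratios share a common
log-mm scale, so axes are extracted from the sample covariance matrix of
the column-centred data.  Because every shape-ratio row sums to zero the
covariance matrix is rank-deficient by one; the null axis is retained
with eigenvalue 0 and simply carries no variance.

Eigenvector signs are basis-arbitrary; each loading column is flipped so
its largest-magnitude entry is positive, and comparisons to published
loadings should be made on magnitudes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class PcaResult:
    """Eigenstructure of a covariance PCA.

    loadings : p x k DataFrame, unit-norm orthonormal columns PC1..PCk
    scores : n x k DataFrame of centred data projected on the loadings
    eigenvalues : k-vector, non-increasing, >= 0 (clipped at tiny negatives)
    proportions : eigenvalues / total variance
    tied : True where the relative gap to the next eigenvalue < 1e-8
        (component ordering within a tied block is not meaningful)
    """

    loadings: pd.DataFrame
    scores: pd.DataFrame
    eigenvalues: np.ndarray
    proportions: np.ndarray
    tied: np.ndarray

    def summary(self, n_components: int = 4) -> pd.DataFrame:
        """Loadings table with a leading proportion-of-variance row (percent)."""
        k = min(n_components, self.loadings.shape[1])
        cols = self.loadings.columns[:k]
        table = self.loadings[cols].copy()
        prop = pd.DataFrame(
            [100 * self.proportions[:k]], columns=cols,
            index=["Proportion of variance (%)"],
        )
        return pd.concat([prop, table])


def pca_covariance(Y, var_names: list[str] | None = None) -> PcaResult:
    """PCA by eigendecomposition of the sample covariance (ddof=1) of Y.

    Y may be an ndarray or a DataFrame (column names become variable
    names, the index labels the scores).  Raises on constant input.
    """
    if isinstance(Y, pd.DataFrame):
        var_names = list(Y.columns) if var_names is None else var_names
        index = Y.index
        X = Y.to_numpy(dtype=float)
    else:
        X = np.asarray(Y, dtype=float)
        index = pd.RangeIndex(X.shape[0])
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need an n x p matrix with n >= 2")
    if np.isnan(X).any():
        raise ValueError("missing values are not allowed")
    n, p = X.shape
    if var_names is None:
        var_names = [f"v{j+1}" for j in range(p)]

    Xc = X - X.mean(axis=0)
    S = (Xc.T @ Xc) / (n - 1)
    w, V = np.linalg.eigh(S)
    order = np.argsort(w)[::-1]
    w, V = w[order], V[:, order]
    total = float(w.sum())
    if total <= 0:
        raise ValueError("zero total variance: constant input matrix")
    w = np.clip(w, 0.0, None)

    # sign convention: largest-magnitude loading positive per column
    flip = np.sign(V[np.argmax(np.abs(V), axis=0), np.arange(p)])
    flip[flip == 0] = 1.0
    V = V * flip

    gaps = np.abs(np.diff(w)) / max(w[0], np.finfo(float).tiny)
    tied = np.zeros(p, dtype=bool)
    tied[:-1] |= gaps < 1e-8
    tied[1:] |= gaps < 1e-8

    pcs = [f"PC{j+1}" for j in range(p)]
    loadings = pd.DataFrame(V, index=var_names, columns=pcs)
    scores = pd.DataFrame(Xc @ V, index=index, columns=pcs)
    return PcaResult(
        loadings=loadings,
        scores=scores,
        eigenvalues=w,
        proportions=w / total,
        tied=tied,
    )
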