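"""Distance-based phylogenetic generalized least squares (D-PGLS).

Linear models of (possibly multivariate) species means under Brownian
motion.  Data and design are premultiplied by P = C^(-1/2), the inverse
square root of the phylogenetic covariance matrix, and fitted by
ordinary least squares in the transformed space.  Sums of squares are
trace-based — summed squared transformed residuals across all traits —
so the same machinery covers ANOVA (factor predictors), MANOVA
(multivariate response) and multivariate regression:

    SS_total = ||P Y - P 1 b0||^2       (intercept-only transformed fit)
    SS_resid = ||P Y - P X b||^2        (full transformed fit)
    SS_model = SS_total - SS_resid
    F = (SS_model / df_model) / (SS_resid / df_resid),  R^2 = SS_model/SS_total

For univariate responses this is numerically identical to explicit GLS
with covariance C; the distance-based form keeps working when the number
of traits approaches the number of species.  Significance comes from a
permutation test that shuffles the raw species means among the tips of
the phylogeny (X and C fixed), recomputing F each time, with the observed
value counted among the permutations.

The model/results split follows the statsmodels convention:
``DPGLS(Y, predictor, C).fit(n_perm=1000, seed=0)`` returns a
:class:`DPGLSResults` with a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .phylo import PhyloCovariance
from .signal import _as_matrix


@dataclass
class DesignMatrix:
    """Intercept-first design matrix with dummy-coded factors.

    Factor levels are coded against the alphabetically first level;
    covariates enter as raw values alongside the intercept.
    """

    X: np.ndarray
    term_labels: list[str]
    df_model: int

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        if not np.allclose(self.X[:, 0], 1.0):
            raise ValueError("first design column must be the intercept")


def build_design(predictor, taxa_order: list[str]) -> DesignMatrix:
    """Design matrix for a single factor or covariate, rows in taxa_order.

    ``predictor`` is a Series indexed by species (categorical/bool/object
    values are dummy-coded; numeric values enter as a covariate) or a
    plain array already in taxa order.
    """
    if isinstance(predictor, pd.DataFrame):
        if predictor.shape[1] != 1:
            raise ValueError("single-term models only")
        predictor = predictor.iloc[:, 0]
    if isinstance(predictor, pd.Series):
        name = predictor.name or "x"
        aligned = predictor.reindex(taxa_order)
        if aligned.isna().any():
            missing = [t for t in taxa_order if t not in predictor.index]
            raise ValueError(f"taxa missing from predictor: {missing}")
        values = aligned
    else:
        name = "x"
        arr = np.asarray(predictor)
        if arr.shape[0] != len(taxa_order):
            raise ValueError("predictor length does not match taxa order")
        values = pd.Series(arr, index=taxa_order, name=name)

    n = len(taxa_order)
    if pd.api.types.is_numeric_dtype(values) and values.dtype != bool:
        X = np.column_stack([np.ones(n), values.to_numpy(dtype=float)])
        return DesignMatrix(X, ["Intercept", name], 1)

    levels = sorted(map(str, values.astype(str).unique()))
    if len(levels) < 2:
        raise ValueError(f"factor '{name}' has a single level")
    cols = [np.ones(n)]
    labels = ["Intercept"]
    for lev in levels[1:]:  # alphabetically first level is the reference
        cols.append((values.astype(str) == lev).to_numpy(dtype=float))
        labels.append(f"{name}[{lev}]")
    return DesignMatrix(np.column_stack(cols), labels, len(levels) - 1)


@dataclass
class DPGLSResults:
    """Fit statistics of a D-PGLS model, statsmodels-results style."""

    ss_model: float
    ss_resid: float
    ss_total: float
    df_model: int
    df_resid: int
    F: float
    R2: float
    p_value: float | None
    n_perm: int
    coefficients: pd.DataFrame
    term_labels: list[str] = field(default_factory=list)
    permuted_F: np.ndarray | None = None

    def anova_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "df": [self.df_model, self.df_resid, self.df_model + self.df_resid],
                "SS": [self.ss_model, self.ss_resid, self.ss_total],
                "MS": [self.ss_model / self.df_model,
                       self.ss_resid / self.df_resid, np.nan],
                "F": [self.F, np.nan, np.nan],
                "R2": [self.R2, np.nan, np.nan],
                "P(perm)": [self.p_value, np.nan, np.nan],
            },
            index=["model", "residual", "total"],
        )

    def summary(self) -> str:
        lines = ["D-PGLS fit (Brownian motion covariance)",
                 self.anova_table().to_string(float_format=lambda v: f"{v:.6g}")]
        if self.p_value is not None:
            lines.append(f"permutations: {self.n_perm} (tip-shuffling of species means)")
        return "\n".join(lines)


class DPGLS:
    """Phylogenetic linear model of species means under Brownian motion.

    Parameters
    ----------
    Y : DataFrame indexed by species (or aligned ndarray), N x p response.
    predictor : Series/array for a single factor or covariate, or a
        prebuilt :class:`DesignMatrix`.
    C : PhyloCovariance from the study tree; Y and the predictor are
        re-indexed to its taxon order.
    """

    def __init__(self, Y, predictor, C: PhyloCovariance):
        self.C = C
        self.Y = _as_matrix(Y, C)
        self.design = (predictor if isinstance(predictor, DesignMatrix)
                       else build_design(predictor, C.taxa))
        if self.design.X.shape[0] != C.n:
            raise ValueError("design rows do not match covariance taxa")
        n, q = self.design.X.shape
        self.df_model = self.design.df_model
        self.df_resid = n - q
        if self.df_resid < 1:
            raise ValueError("no residual degrees of freedom")
        P = C.inv_sqrt()
        self._Xt = P @ self.design.X
        self._X0t = P @ np.ones((n, 1))
        if np.linalg.matrix_rank(self._Xt) < q:
            raise ValueError("rank-deficient design after phylogenetic transform")
        self._P = P
        # hat/annihilator matrices reused across permutations
        self._Q_full = self._annihilator(self._Xt)
        self._Q_null = self._annihilator(self._X0t)

    @staticmethod
    def _annihilator(X: np.ndarray) -> np.ndarray:
        XtXinv = np.linalg.pinv(X.T @ X)
        return np.eye(X.shape[0]) - X @ XtXinv @ X.T

    def _ss(self, Y: np.ndarray) -> tuple[float, float, float]:
        Yt = self._P @ Y
        ss_resid = float(np.sum((self._Q_full @ Yt) ** 2))
        ss_total = float(np.sum((self._Q_null @ Yt) ** 2))
        return ss_total - ss_resid, ss_resid, ss_total

    def _f(self, Y: np.ndarray) -> float:
        ss_model, ss_resid, _ = self._ss(Y)
        return (ss_model / self.df_model) / (ss_resid / self.df_resid)

    def fit(self, n_perm: int = 0, seed: int | None = None,
            keep_permutations: bool = False,
            permutation: str = "tips") -> DPGLSResults:
        """Fit the model; with ``n_perm >= 1`` also run the permutation test.

        ``permutation='tips'`` (default) shuffles the raw species means
        among the tips of the phylogeny, the scheme classically printed
        for D-PGLS.  It is exact only when tip values are exchangeable
        under the null: for phylogenetically correlated responses it is
        anticonservative when the predictor aligns with clades and
        conservative when it does not.  ``permutation='rrpp'`` permutes
        the residuals of the intercept-only transformed model instead
        (residual randomization), which keeps the type-I error nominal
        on structured trees.
        """
        ss_model, ss_resid, ss_total = self._ss(self.Y)
        if ss_total <= 0:
            raise ValueError("constant response: no variation to model")
        F = (ss_model / self.df_model) / (ss_resid / self.df_resid)
        Yt = self._P @ self.Y
        beta, *_ = np.linalg.lstsq(self._Xt, Yt, rcond=None)
        coef = pd.DataFrame(beta, index=self.design.term_labels)

        p_value = None
        perms = None
        if n_perm >= 1:
            if permutation not in ("tips", "rrpp"):
                raise ValueError("permutation must be 'tips' or 'rrpp'")
            rng = np.random.default_rng(seed)
            n = self.C.n
            idx = np.stack([rng.permutation(n) for _ in range(n_perm)])
            if permutation == "tips":
                M = self.Y[idx]  # raw species means shuffled among tips
                A = self._Q_full @ self._P
                B = self._Q_null @ self._P
            else:
                # residual randomization: permute intercept-only transformed
                # residuals (the null fitted values lie in span(X) and drop
                # out of both quadratic forms)
                M = (self._Q_null @ Yt)[idx]
                A = self._Q_full
                B = self._Q_null
            ssr = np.sum(np.einsum("ij,bjp->bip", A, M) ** 2, axis=(1, 2))
            sst = np.sum(np.einsum("ij,bjp->bip", B, M) ** 2, axis=(1, 2))
            ssm = sst - ssr
            perms = (ssm / self.df_model) / (ssr / self.df_resid)
            p_value = (1 + int(np.sum(perms >= F))) / (n_perm + 1)

        return DPGLSResults(
            ss_model=ss_model, ss_resid=ss_resid, ss_total=ss_total,
            df_model=self.df_model, df_resid=self.df_resid,
            F=F, R2=ss_model / ss_total, p_value=p_value,
            n_perm=n_perm, coefficients=coef,
            term_labels=list(self.design.term_labels),
            permuted_F=perms if keep_permutations else None,
        )


def dpgls_fit(Y, predictor, C: PhyloCovariance) -> DPGLSResults:
    """One-shot fit without permutation inference."""
    return DPGLS(Y, predictor, C).fit()


def dpgls_permutation_test(Y, predictor, C: PhyloCovariance,
                           n_perm: int = 1000, seed: int | None = None,
                           **kw) -> DPGLSResults:
    """Fit plus tip-shuffling permutation test of F."""
    return DPGLS(Y, predictor, C).fit(n_perm=n_perm, seed=seed, **kw)


def dpgls_regression(Y, covariate, C: PhyloCovariance, n_perm: int = 1000,
                     seed: int | None = None, **kw) -> DPGLSResults:
    """Multivariate regression of species means on a single covariate."""
    cov = covariate
    if isinstance(cov, pd.DataFrame):
        if cov.shape[1] != 1:
            raise ValueError("a single covariate is required")
        cov = cov.iloc[:, 0]
    return DPGLS(Y, cov, C).fit(n_perm=n_perm, seed=seed, **kw)
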