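"""Correlation and principal-component analyses of the fitted parameters.

Pearson correlations (pairwise-complete, two-sided p from the t-transform
with n-2 degrees of freedom, unadjusted) relate the dielectric parameters
to milk-solids covariates; PCA on the standardised parameter block
(delta_eps, tau, alpha, sigma_dc — the units differ by orders of
magnitude, so the correlation-matrix form is used) projects samples onto
two components for biplots and cluster comparison between reproductive
stages.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import silhouette_score

from .model import ValidationError

__all__ = [
    "CorrelationMatrix",
    "PCAResult",
    "correlation_matrix",
    "pca_project",
    "biplot_export",
    "stage_separation_score",
]

DIELECTRIC_VARS = ("delta_eps", "tau", "alpha", "sigma_dc")


@dataclass
class CorrelationMatrix:
    """Symmetric Pearson r matrix with p-values and pairwise n."""

    variables: list[str]
    r: pd.DataFrame
    p: pd.DataFrame
    n: pd.DataFrame
    undefined_pairs: list[tuple[str, str]] = field(default_factory=list)

    def cross_table(self, rows: Sequence[str], cols: Sequence[str]) -> pd.DataFrame:
        """Rectangular r block, e.g. covariates x dielectric parameters."""
        return self.r.loc[list(rows), list(cols)]


def correlation_matrix(
    table: pd.DataFrame,
    dielectric_vars: Sequence[str] = DIELECTRIC_VARS,
    covariate_vars: Sequence[str] = (),
    min_n: int = 3,
) -> CorrelationMatrix:
    """Pearson correlation matrix over dielectric and covariate columns.

    Missing values are handled pairwise-complete.  A pair with fewer than
    ``min_n`` complete rows, or involving a zero-variance column, is flagged
    in ``undefined_pairs`` and carries ``r = NaN`` without poisoning other
    pairs.
    """
    variables = list(dict.fromkeys(list(dielectric_vars) + list(covariate_vars)))
    missing = [v for v in variables if v not in table.columns]
    if missing:
        raise ValidationError(f"columns absent from table: {missing}")
    k = len(variables)
    r = np.eye(k)
    p = np.zeros((k, k))
    n = np.full((k, k), len(table), dtype=int)
    undefined: list[tuple[str, str]] = []
    for i in range(k):
        for j in range(i + 1, k):
            xi = table[variables[i]].to_numpy(dtype=float)
            xj = table[variables[j]].to_numpy(dtype=float)
            ok = np.isfinite(xi) & np.isfinite(xj)
            n[i, j] = n[j, i] = int(ok.sum())
            if ok.sum() < min_n or np.std(xi[ok]) == 0 or np.std(xj[ok]) == 0:
                r[i, j] = r[j, i] = np.nan
                p[i, j] = p[j, i] = np.nan
                undefined.append((variables[i], variables[j]))
                continue
            res = stats.pearsonr(xi[ok], xj[ok])
            r[i, j] = r[j, i] = res.statistic
            p[i, j] = p[j, i] = res.pvalue
    idx = pd.Index(variables)
    return CorrelationMatrix(
        variables=variables,
        r=pd.DataFrame(r, index=idx, columns=idx),
        p=pd.DataFrame(p, index=idx, columns=idx),
        n=pd.DataFrame(n, index=idx, columns=idx),
        undefined_pairs=undefined,
    )


@dataclass
class PCAResult:
    """Scores, loadings and explained variance of a standardised PCA."""

    scores: pd.DataFrame           # samples x PCs
    loadings: pd.DataFrame         # variables x PCs, columns orthonormal
    explained_variance_ratio: np.ndarray
    center: pd.Series
    scale: pd.Series


def pca_project(
    table: pd.DataFrame,
    variables: Sequence[str] = DIELECTRIC_VARS,
    n_components: int = 2,
) -> PCAResult:
    """PCA of the standardised parameter block.

    Columns are centred and scaled to unit variance, so the decomposition
    is of the correlation matrix; constant columns are dropped with a
    warning.  Loading signs are fixed deterministically: the
    largest-magnitude entry of each component is made positive.
    """
    variables = list(variables)
    missing = [v for v in variables if v not in table.columns]
    if missing:
        raise ValidationError(f"columns absent from table: {missing}")
    X = table[variables].to_numpy(dtype=float)
    if X.shape[0] < n_components + 1:
        raise ValidationError(
            f"need >= {n_components + 1} rows for {n_components} components, "
            f"got {X.shape[0]}"
        )
    sd = X.std(axis=0, ddof=1)
    keep = sd > 0
    if not keep.all():
        dropped = [v for v, k in zip(variables, keep) if not k]
        warnings.warn(f"dropping constant columns before PCA: {dropped}")
        variables = [v for v, k in zip(variables, keep) if k]
        X = X[:, keep]
        sd = sd[keep]
    if X.shape[1] < n_components:
        raise ValidationError("fewer non-constant variables than components")
    mean = X.mean(axis=0)
    Z = (X - mean) / sd
    corr = (Z.T @ Z) / (Z.shape[0] - 1)
    evals, evecs = np.linalg.eigh(corr)
    order = np.argsort(evals)[::-1][:n_components]
    evals_sorted = np.clip(evals[order], 0.0, None)
    V = evecs[:, order]
    # deterministic sign: largest-|loading| entry positive per component
    for c in range(V.shape[1]):
        imax = np.argmax(np.abs(V[:, c]))
        if V[imax, c] < 0:
            V[:, c] = -V[:, c]
    pcs = [f"PC{c + 1}" for c in range(n_components)]
    scores = pd.DataFrame(Z @ V, index=table.index, columns=pcs)
    loadings = pd.DataFrame(V, index=variables, columns=pcs)
    evr = evals_sorted / np.trace(corr)
    return PCAResult(
        scores=scores, loadings=loadings,
        explained_variance_ratio=evr,
        center=pd.Series(mean, index=variables),
        scale=pd.Series(sd, index=variables),
    )


def biplot_export(pca: PCAResult, labels: Sequence[str]) -> pd.DataFrame:
    """Long-format, plot-ready table of PCA scores and loading arrows.

    One ``kind="score"`` row per sample (with its stage label) and one
    ``kind="loading"`` row per variable; no rendering is done here.
    """
    labels = list(labels)
    if len(labels) != len(pca.scores):
        raise ValidationError(
            f"{len(labels)} labels for {len(pca.scores)} score rows"
        )
    pcs = list(pca.scores.columns)
    score_rows = pca.scores.copy()
    score_rows.insert(0, "kind", "score")
    score_rows.insert(1, "name", [str(i) for i in pca.scores.index])
    score_rows.insert(2, "label", labels)
    loading_rows = pca.loadings.copy()
    loading_rows.insert(0, "kind", "loading")
    loading_rows.insert(1, "name", list(pca.loadings.index))
    loading_rows.insert(2, "label", "")
    out = pd.concat([score_rows, loading_rows], ignore_index=True)
    return out[["kind", "name", "label", *pcs]]


def stage_separation_score(pca: PCAResult, labels: Sequence[str]) -> float:
    """Mean silhouette of the label groups in PC-score space.

    Higher means more clearly separated clusters (e.g. stage1 vs stage3 in
    a pregnant cow's biplot); requires at least two distinct labels.
    """
    labels = np.asarray(list(labels))
    if len(labels) != len(pca.scores):
        raise ValidationError("labels must align with scores")
    if np.unique(labels).size < 2:
        raise ValidationError("need at least two distinct labels")
    return float(silhouette_score(pca.scores.to_numpy(), labels))
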