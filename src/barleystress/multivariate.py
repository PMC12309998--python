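"""Pearson correlation matrices, thresholded trait networks and PCA.

All three operate on genotype x trait matrices of treatment means (replicate
noise averaged out before the multivariate step).  PCA is run on the
correlation matrix by default (standardized traits); the sign of each
component is fixed so its largest-magnitude loading is positive, making
results reproducible across eigen-solvers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import PhenomicsWarning
from .tables import PhenotypeTable


def genotype_trait_means(table: PhenotypeTable, treatment: str) -> pd.DataFrame:
    """Genotype x trait matrix of cell means for one treatment."""
    d = table.data[table.data["treatment"] == treatment]
    if d.empty:
        raise ValueError(f"treatment {treatment!r} absent")
    return d.pivot_table(index="genotype", columns="trait", values="value",
                         aggfunc="mean")


@dataclass
class CorrelationResult:
    r: pd.DataFrame
    p: pd.DataFrame
    n: pd.DataFrame


def correlation_matrix(means: pd.DataFrame) -> CorrelationResult:
    """Pairwise-complete Pearson r with two-sided P from the t transform.

    Traits with zero variance are excluded with a warning; pairs with fewer
    than 3 complete observations are left missing.
    """
    if len(means) < 3:
        raise ValueError("need >= 3 genotypes for correlations")
    keep = []
    for c in means.columns:
        v = means[c].dropna()
        if len(v) and v.nunique() > 1:
            keep.append(c)
    dropped = [c for c in means.columns if c not in keep]
    if dropped:
        warnings.warn(f"zero-variance trait(s) excluded: {dropped}",
                      PhenomicsWarning, stacklevel=2)
    cols = keep
    k = len(cols)
    r = pd.DataFrame(np.eye(k), index=cols, columns=cols)
    p = pd.DataFrame(np.zeros((k, k)), index=cols, columns=cols)
    n = pd.DataFrame(0, index=cols, columns=cols)
    for i, a in enumerate(cols):
        n.loc[a, a] = means[a].notna().sum()
        for b in cols[i + 1:]:
            pair = means[[a, b]].dropna()
            n.loc[a, b] = n.loc[b, a] = len(pair)
            if len(pair) < 3:
                r.loc[a, b] = r.loc[b, a] = np.nan
                p.loc[a, b] = p.loc[b, a] = np.nan
                continue
            rr, pp = stats.pearsonr(pair[a], pair[b])
            r.loc[a, b] = r.loc[b, a] = rr
            p.loc[a, b] = p.loc[b, a] = pp
    return CorrelationResult(r=r, p=p, n=n)


def correlation_network(corr: CorrelationResult, threshold: float = 0.6) -> pd.DataFrame:
    """Weighted edge list (trait_a, trait_b, r) for |r| >= threshold.

    Sign is retained; edges are ordered deterministically by trait names.
    Raising the threshold never adds an edge.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must be in [0, 1]")
    cols = list(corr.r.columns)
    edges = []
    for i, a in enumerate(cols):
        for b in cols[i + 1:]:
            rr = corr.r.loc[a, b]
            if pd.notna(rr) and abs(rr) >= threshold:
                edges.append((a, b, float(rr)))
    out = pd.DataFrame(edges, columns=["trait_a", "trait_b", "r"])
    return out.sort_values(["trait_a", "trait_b"]).reset_index(drop=True)


@dataclass
class PcaResult:
    eigenvalues: np.ndarray
    variance_pct: np.ndarray
    cumulative_pct: np.ndarray
    scores: pd.DataFrame    # genotypes x components
    loadings: pd.DataFrame  # traits x components
    standardized: bool


def pca(means: pd.DataFrame, standardize: bool = True) -> PcaResult:
    """Eigen-decomposition PCA of a genotype x trait mean matrix.

    With ``standardize=True`` (default) the decomposition is of the
    correlation matrix, otherwise of the covariance matrix.  Variance
    explained sums to 100 over all components; eigenvalues are
    non-increasing.
    """
    X = means.to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("missing entries; complete the matrix before PCA")
    n, pdim = X.shape
    if pdim > n:
        warnings.warn(f"more traits ({pdim}) than genotypes ({n}); "
                      "trailing components are null", PhenomicsWarning,
                      stacklevel=2)
    center = X - X.mean(axis=0)
    if standardize:
        sd = X.std(axis=0, ddof=1)
        if (sd == 0).any():
            zero = [c for c, s in zip(means.columns, sd) if s == 0]
            raise ValueError(f"zero-variance trait(s) {zero}; cannot standardize")
        Z = center / sd
        S = np.corrcoef(X, rowvar=False)
    else:
        Z = center
        S = np.cov(X, rowvar=False)
    S = np.atleast_2d(S)
    eigval, eigvec = np.linalg.eigh(S)
    order = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[order], 0.0, None)
    eigvec = eigvec[:, order]
    # sign convention: largest-|loading| entry of each component positive
    for j in range(eigvec.shape[1]):
        imax = np.argmax(np.abs(eigvec[:, j]))
        if eigvec[imax, j] < 0:
            eigvec[:, j] = -eigvec[:, j]
    comp = [f"PC{j + 1}" for j in range(eigvec.shape[1])]
    scores = pd.DataFrame(Z @ eigvec, index=means.index, columns=comp)
    loadings = pd.DataFrame(eigvec, index=means.columns, columns=comp)
    total = eigval.sum()
    var_pct = 100.0 * eigval / total if total > 0 else np.zeros_like(eigval)
    return PcaResult(
        eigenvalues=eigval,
        variance_pct=var_pct,
        cumulative_pct=np.cumsum(var_pct),
        scores=scores,
        loadings=loadings,
        standardized=standardize,
    )
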