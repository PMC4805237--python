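"""Multivariate structure of the trait table.

PCA composite bill size, a Pillai's-trace MANOVA screen for sex differences
adjusted for subspecies, Mahalanobis-distance outlier screening against
chi-square quantiles, complete-linkage clustering with a small-ensemble
optimal-k vote, canonical linear discriminant analysis with resubstitution
classification matrices, and Spearman rank correlations among the ordinal
color scores.

All operations take a :class:`pandas.DataFrame` of complete cases (see
``specimen_data.complete_cases``) plus the trait columns to use; grouping is
a column name (``region`` or ``subspecies``).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.stats import chi2, f as f_dist
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.metrics import calinski_harabasz_score, silhouette_score

logger = logging.getLogger(__name__)


class DegenerateInputError(ValueError):
    """A trait column is constant or the covariance is singular."""


def _trait_array(table: pd.DataFrame, traits) -> np.ndarray:
    X = table[list(traits)].to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("trait matrix holds missing values; run complete_cases first")
    return X


# ---------------------------------------------------------------- PCA

@dataclass(frozen=True)
class PCAResult:
    """Principal components of the trait correlation matrix.

    ``loadings`` holds unit-norm eigenvectors (traits x components);
    ``variance_ratio`` the eigenvalue shares (sums to 1); ``scores`` the
    standardized-variable projections per specimen.  PC1 — the composite
    bill-size axis — is oriented so that it correlates positively with bill
    depth (falling back to the first trait).
    """

    traits: tuple[str, ...]
    loadings: pd.DataFrame
    variance_ratio: np.ndarray
    scores: pd.DataFrame
    loading_correlations: pd.Series  # corr(PC1 score, each trait)

    @property
    def pc1(self) -> pd.Series:
        return self.scores["PC1"]


def pca_composite(
    table: pd.DataFrame, traits, scale: str = "correlation"
) -> PCAResult:
    """Eigen-decomposition of the trait correlation (or covariance) matrix.

    The correlation matrix is the default: the traits are on different mm
    scales and the composite should weight them comparably.
    """
    X = _trait_array(table, traits)
    if X.shape[0] < 3:
        raise ValueError("need >= 3 specimens for PCA")
    sd = X.std(axis=0, ddof=1)
    if np.any(sd == 0):
        bad = [t for t, s in zip(traits, sd) if s == 0]
        raise DegenerateInputError(f"constant trait column(s): {bad}")
    centered = X - X.mean(axis=0)
    if scale == "correlation":
        work = centered / sd
    elif scale == "covariance":
        work = centered
    else:
        raise ValueError("scale must be 'correlation' or 'covariance'")
    C = np.cov(work, rowvar=False)
    eigval, eigvec = np.linalg.eigh(C)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]

    scores = work @ eigvec
    # orientation: PC1 correlates positively with bill depth
    anchor = list(traits).index("bill_depth_mm") if "bill_depth_mm" in traits else 0
    for j in range(eigvec.shape[1]):
        ref = np.corrcoef(scores[:, j], X[:, anchor])[0, 1] if j == 0 else eigvec[anchor, j]
        if ref < 0:
            eigvec[:, j] *= -1
            scores[:, j] *= -1

    comp_names = [f"PC{j + 1}" for j in range(len(traits))]
    loadings = pd.DataFrame(eigvec, index=list(traits), columns=comp_names)
    score_df = pd.DataFrame(scores, index=table.index, columns=comp_names)
    if "specimen_id" in table.columns:
        score_df.insert(0, "specimen_id", table["specimen_id"].to_numpy())
    corr = pd.Series(
        [np.corrcoef(scores[:, 0], X[:, i])[0, 1] for i in range(len(traits))],
        index=list(traits),
        name="r_with_pc1",
    )
    return PCAResult(
        traits=tuple(traits),
        loadings=loadings,
        variance_ratio=eigval / eigval.sum(),
        scores=score_df,
        loading_correlations=corr,
    )


# ---------------------------------------------------------------- MANOVA

def _design(labels: pd.Series) -> np.ndarray:
    d = pd.get_dummies(labels.astype(str), drop_first=True, dtype=float)
    return d.to_numpy()


def _residual_sscp(Y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, int]:
    """Residual cross-product matrix of Y on X (with intercept), and rank used."""
    Xi = np.column_stack([np.ones(len(Y)), X]) if X.size else np.ones((len(Y), 1))
    beta, _, rank, _ = np.linalg.lstsq(Xi, Y, rcond=None)
    resid = Y - Xi @ beta
    return resid.T @ resid, int(rank)


def pillai_manova(
    table: pd.DataFrame,
    traits,
    factor: str = "sex",
    covariate_factor: str | None = "subspecies",
) -> dict:
    """Pillai's trace for ``factor``, adjusted for ``covariate_factor``.

    Fits the additive two-factor linear model and forms the Type II
    hypothesis SSCP for the factor as the drop in residual cross-products
    between the covariate-only and the full model; the error SSCP is the full
    model's residual cross-products.  Then V = tr[H (H+E)^-1] with the
    standard approximate-F transformation.
    """
    Y = _trait_array(table, traits)
    p = Y.shape[1]
    fac = table[factor].astype(str)
    levels = fac[fac != "unknown"].unique() if factor == "sex" else fac.unique()
    keep = fac.isin(levels)
    Y, fac = Y[keep.to_numpy()], fac[keep]
    if len(np.unique(fac)) < 2 or (pd.Series(fac).value_counts() < 2).any():
        raise ValueError(f"need >= 2 levels of {factor!r} with >= 2 specimens each")

    X_fac = _design(fac)
    if covariate_factor is not None:
        X_cov = _design(table.loc[keep, covariate_factor])
        X_full = np.column_stack([X_cov, X_fac])
    else:
        X_cov = np.empty((len(Y), 0))
        X_full = X_fac
    E, rank_full = _residual_sscp(Y, X_full)
    E_reduced, rank_red = _residual_sscp(Y, X_cov)
    H = E_reduced - E
    df_h = rank_full - rank_red
    df_e = len(Y) - rank_full
    if df_h < 1:
        raise ValueError(f"factor {factor!r} adds no estimable contrasts")
    if np.linalg.matrix_rank(E) < p:
        corr = np.corrcoef(Y, rowvar=False)
        pairs = [
            (traits[i], traits[j])
            for i in range(p)
            for j in range(i + 1, p)
            if abs(corr[i, j]) > 1 - 1e-10
        ]
        raise DegenerateInputError(f"singular error matrix; collinear traits: {pairs}")

    V = float(np.trace(H @ np.linalg.inv(H + E)))
    s = min(p, df_h)
    m = (abs(p - df_h) - 1) / 2.0
    n_ = (df_e - p - 1) / 2.0
    df1 = s * (2 * m + s + 1)
    df2 = s * (2 * n_ + s + 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (df2 / df1) * (V / (s - V)) if s > V else np.inf
    pval = float(f_dist.sf(F, df1, df2))
    return {
        "pillai": V,
        "approx_F": float(F),
        "df_pair": (float(df1), float(df2)),
        "p": pval,
        "df_h": df_h,
        "df_e": df_e,
    }


# ---------------------------------------------------------------- outlier screen

def mahalanobis_screen(table: pd.DataFrame, traits) -> pd.DataFrame:
    """Squared Mahalanobis distances from the centroid vs chi-square quantiles.

    Returns a table (specimen_id, squared_distance, chi2_quantile) sorted by
    distance, with quantiles at plotting positions (i - 0.5)/n on
    chi-square(#traits) df.  A screening aid: no specimen is rejected here.
    """
    X = _trait_array(table, traits)
    n, p = X.shape
    S = np.cov(X, rowvar=False)
    if np.linalg.matrix_rank(S) < p:
        corr = np.corrcoef(X, rowvar=False)
        pairs = [
            (traits[i], traits[j])
            for i in range(p)
            for j in range(i + 1, p)
            if abs(corr[i, j]) > 1 - 1e-10
        ]
        raise DegenerateInputError(f"singular covariance; collinear traits: {pairs}")
    dev = X - X.mean(axis=0)
    d2 = np.einsum("ij,jk,ik->i", dev, np.linalg.inv(S), dev)
    order = np.argsort(d2, kind="stable")
    quantiles = np.empty(n)
    quantiles[order] = chi2.ppf((np.arange(1, n + 1) - 0.5) / n, df=p)
    ids = (
        table["specimen_id"].to_numpy()
        if "specimen_id" in table.columns
        else table.index.to_numpy()
    )
    out = pd.DataFrame(
        {"specimen_id": ids, "squared_distance": d2, "chi2_quantile": quantiles}
    )
    return out.sort_values("squared_distance", ascending=False, ignore_index=True)


# ---------------------------------------------------------------- clustering

@dataclass(frozen=True)
class Dendrogram:
    """Complete-linkage merge tree over Euclidean distances.

    ``linkage`` is the (n-1) x 4 scipy linkage matrix; ``ids`` maps leaf
    indices back to specimen ids.
    """

    linkage: np.ndarray
    ids: tuple[str, ...]

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    def cut(self, k: int) -> np.ndarray:
        """Labels (1..k) from cutting the tree into k clusters."""
        return fcluster(self.linkage, t=k, criterion="maxclust")


def cluster_complete(table: pd.DataFrame, traits) -> Dendrogram:
    """Agglomerative complete linkage on Euclidean distances over raw traits.

    Merge heights are non-decreasing (guaranteed for complete linkage); ties
    resolve deterministically toward the earliest-formed clusters.
    """
    X = _trait_array(table, traits)
    if len(X) < 2:
        raise ValueError("need >= 2 specimens to cluster")
    Z = linkage(X, method="complete", metric="euclidean")
    ids = (
        tuple(table["specimen_id"].astype(str))
        if "specimen_id" in table.columns
        else tuple(map(str, table.index))
    )
    return Dendrogram(linkage=Z, ids=ids)


def _duda_hart_vote(dend: Dendrogram, X: np.ndarray, k_range) -> int | None:
    """Smallest k whose refinement to k+1 is not a justified split.

    For the cluster that splits between the k- and (k+1)-solutions, compares
    the two-subcluster within-SSE to the parent's within-SSE; the split is
    justified when the ratio falls below the Duda-Hart critical value
    (normal-theory approximation, z = 3.20).
    """
    d = X.shape[1]
    ks = sorted(k_range)
    for k in ks:
        if k + 1 > len(X):
            break
        lab_k = dend.cut(k)
        lab_k1 = dend.cut(k + 1)
        parent = None
        for c in np.unique(lab_k):
            children = np.unique(lab_k1[lab_k == c])
            if len(children) > 1:
                parent = c
                break
        if parent is None:
            continue
        members = lab_k == parent
        n_m = int(members.sum())
        je1 = ((X[members] - X[members].mean(axis=0)) ** 2).sum()
        je2 = 0.0
        for c in np.unique(lab_k1[members]):
            sub = X[lab_k1 == c]
            je2 += ((sub - sub.mean(axis=0)) ** 2).sum()
        if je1 == 0:
            ratio = 1.0
        else:
            ratio = je2 / je1
        crit = 1 - 2 / (np.pi * d) - 3.20 * np.sqrt(
            2 * (1 - 8 / (np.pi**2 * d)) / (n_m * d)
        )
        if ratio >= crit:
            return k
    return ks[-1] if ks else None


def optimal_k(
    dend: Dendrogram, table: pd.DataFrame, traits, k_range=range(2, 11)
) -> dict:
    """Choose a cluster count by majority vote of three internal indices.

    Calinski-Harabasz and mean silhouette vote for their arg-best k over
    ``k_range``; a Duda-Hart split-ratio rule votes for the smallest k whose
    further refinement is unjustified.  Majority wins; ties go to the
    smallest voted k.  Degenerate partitions (a k at or beyond the specimen
    count) are skipped with a log entry.
    """
    X = _trait_array(table, traits)
    n = len(X)
    ks = [k for k in k_range if 2 <= k < n]
    skipped = [k for k in k_range if k not in ks]
    if skipped:
        logger.info("optimal_k: skipped degenerate k values %s", skipped)
    if not ks:
        raise ValueError("no usable k in range")
    ch_scores, sil_scores = {}, {}
    for k in ks:
        labels = dend.cut(k)
        if len(np.unique(labels)) < 2:
            logger.info("optimal_k: k=%d produced a single cluster; skipped", k)
            continue
        ch_scores[k] = calinski_harabasz_score(X, labels)
        sil_scores[k] = silhouette_score(X, labels)
    votes = {
        "calinski_harabasz": max(ch_scores, key=ch_scores.get),
        "silhouette": max(sil_scores, key=sil_scores.get),
    }
    dh = _duda_hart_vote(dend, X, ks)
    if dh is not None:
        votes["duda_hart"] = dh
    counts = pd.Series(list(votes.values())).value_counts()
    best = counts[counts == counts.max()].index.min()
    return {"k_best": int(best), "votes": votes,
            "scores": {"calinski_harabasz": ch_scores, "silhouette": sil_scores}}


# ---------------------------------------------------------------- LDA

@dataclass(frozen=True)
class LDAResult:
    """Canonical discriminant axes and resubstitution classification.

    ``coefficients`` are the raw canonical coefficients (traits x axes),
    each axis oriented so the bill-depth coefficient is positive;
    ``between_group_ratio`` the per-axis shares of between-group variance
    (sums to 1); ``confusion`` the actual x predicted proportion matrix
    (rows sum to 1).
    """

    groups: tuple[str, ...]
    coefficients: pd.DataFrame
    between_group_ratio: np.ndarray
    scores: pd.DataFrame
    confusion: pd.DataFrame
    predictions: pd.Series = field(repr=False, default=None)


def lda_fit(
    table: pd.DataFrame,
    traits,
    grouping: str,
    priors: str = "proportional",
) -> LDAResult:
    """Canonical LDA with classification by largest posterior.

    Axes come from the between- versus pooled-within-group eigenproblem;
    classification uses proportional priors by default (``priors="uniform"``
    for flat priors) and the confusion matrix is resubstitution on the
    training specimens.
    """
    X = _trait_array(table, traits)
    y = table[grouping].astype(str).to_numpy()
    labels, counts = np.unique(y, return_counts=True)
    if len(labels) < 2:
        raise ValueError("need >= 2 groups")
    if (counts <= len(traits)).any():
        small = labels[counts <= len(traits)]
        warnings.warn(
            f"group(s) with <= {len(traits)} specimens: {list(small)}; "
            "pooled-covariance estimates may be unstable",
            stacklevel=2,
        )
    prior_vec = None if priors == "proportional" else np.full(len(labels), 1 / len(labels))
    model = LinearDiscriminantAnalysis(solver="eigen", priors=prior_vec)
    try:
        model.fit(X, y)
    except np.linalg.LinAlgError as exc:  # singular pooled covariance
        raise DegenerateInputError(f"singular pooled covariance: {exc}") from exc

    n_axes = min(len(traits), len(labels) - 1)
    coef = np.asarray(model.scalings_)[:, :n_axes].copy()
    ratio = np.asarray(model.explained_variance_ratio_)[:n_axes]
    ratio = ratio / ratio.sum()
    anchor = list(traits).index("bill_depth_mm") if "bill_depth_mm" in traits else 0
    for j in range(coef.shape[1]):
        if coef[anchor, j] < 0:
            coef[:, j] *= -1
    axis_names = [f"LD{j + 1}" for j in range(n_axes)]
    scores = pd.DataFrame(
        (X - X.mean(axis=0)) @ coef, index=table.index, columns=axis_names
    )
    pred = model.predict(X)
    confusion = (
        pd.crosstab(pd.Series(y, name="actual"), pd.Series(pred, name="predicted"))
        .reindex(index=labels, columns=labels, fill_value=0)
        .astype(float)
    )
    confusion = confusion.div(confusion.sum(axis=1), axis=0)
    return LDAResult(
        groups=tuple(labels),
        coefficients=pd.DataFrame(coef, index=list(traits), columns=axis_names),
        between_group_ratio=ratio,
        scores=scores,
        confusion=confusion,
        predictions=pd.Series(pred, index=table.index, name="predicted"),
    )


# ---------------------------------------------------------------- correlations

def rank_correlations(table: pd.DataFrame, traits) -> pd.DataFrame:
    """Spearman rank-correlation matrix (average ranks for ties).

    Constant columns yield undefined coefficients: NaN entries plus a
    warning naming the columns.
    """
    X = _trait_array(table, traits)
    if len(X) < 3:
        raise ValueError("need >= 3 specimens")
    constant = [t for t, s in zip(traits, X.std(axis=0)) if s == 0]
    if constant:
        warnings.warn(f"constant column(s), rho undefined: {constant}", stacklevel=2)
    rho = table[list(traits)].astype(float).corr(method="spearman")
    for t in traits:  # constant columns still correlate perfectly with themselves
        rho.loc[t, t] = 1.0
    return rho
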