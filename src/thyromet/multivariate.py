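"""Projection stages: PCA with loading clustering, and PLS-DA with VIP scores.

PCA is a singular-value decomposition of the column-centered (already
Pareto-scaled) matrix with a deterministic sign convention: within each
component, the largest-magnitude loading entry is made positive. Feature
loading vectors over the first ``n_pcs`` components are Ward-clustered to
group features by their contribution pattern to the components, and each
feature's point-biserial correlation with the binary outcome provides the
ordering used by the correlation heatmap (most positive to most negative
within each cluster).

PLS-DA fits latent variables one at a time (NIPALS-style, single centered
response column for the two classes): the weight vector is the covariance of
the deflated predictors with the centered response, unit-normalized; scores
are the deflated predictors projected on the weights; predictors and response
are deflated by regression on the scores. Per-LV explained-variance
percentages come from the deflation sums of squares. The variable importance
in projection is

    VIP_j = sqrt( P * sum_a[ SSY_a * (w_ja / ||w_a||)^2 ] / sum_a SSY_a )

over the retained LVs, so mean(VIP^2) = 1 by construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage

from .containers import FeatureTable, SampleInfo, validate_cohort
from .errors import InvalidArgumentError
from .network import _relabel_by_size

__all__ = [
    "PCAResult",
    "PLSDAResult",
    "pca",
    "n_components_for_variance",
    "cluster_loadings",
    "feature_outcome_correlations",
    "heatmap_order",
    "plsda",
]


@dataclass
class PCAResult:
    loadings: pd.DataFrame  # features x components, orthonormal columns
    scores: pd.DataFrame  # samples x components
    explained_ratio: np.ndarray  # non-increasing, sums to <= 1
    loading_clusters: pd.Series | None = None


@dataclass
class PLSDAResult:
    weights: pd.DataFrame  # features x LVs, unit-norm columns
    x_loadings: pd.DataFrame  # features x LVs
    scores: pd.DataFrame  # samples x LVs, mutually orthogonal
    x_var_pct: np.ndarray  # % of predictor SS per LV
    y_var_pct: np.ndarray  # % of response SS per LV
    vip: pd.Series  # per-feature, mean(vip^2) = 1


def pca(table: FeatureTable) -> PCAResult:
    """SVD-based principal components of the column-centered table."""
    table.require_stage("pareto", "log")
    if table.n_samples < 2 or table.n_features < 2:
        raise InvalidArgumentError("PCA needs at least 2 samples and 2 features")
    x = table.values.to_numpy(dtype=float)
    xc = x - x.mean(axis=0)
    if not np.any(xc):
        raise InvalidArgumentError("degenerate input: centered matrix is all zero")
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    # deterministic sign: largest-|.| loading entry positive per component
    flip = np.sign(vt[np.arange(vt.shape[0]), np.abs(vt).argmax(axis=1)])
    flip[flip == 0] = 1.0
    vt = vt * flip[:, None]
    u = u * flip[None, :]
    comps = [f"PC{i + 1}" for i in range(len(s))]
    return PCAResult(
        loadings=pd.DataFrame(vt.T, index=table.feature_ids, columns=comps),
        scores=pd.DataFrame(u * s, index=table.values.index, columns=comps),
        explained_ratio=s**2 / (s**2).sum(),
    )


def n_components_for_variance(result: PCAResult, fraction: float) -> int:
    """Smallest component count whose cumulative explained ratio reaches ``fraction``."""
    if not (0 < fraction <= 1):
        raise InvalidArgumentError("fraction must be in (0, 1]")
    cum = np.cumsum(result.explained_ratio)
    if fraction >= cum[-1]:
        return int(np.sum(result.explained_ratio > 1e-12))
    return int(np.searchsorted(cum, fraction - 1e-12) + 1)


def cluster_loadings(result: PCAResult, n_pcs: int, k: int = 15) -> pd.Series:
    """Ward clustering of per-feature loading vectors on the first n_pcs components.

    Cluster ids 1..k ordered by decreasing size (ties by smallest member index).
    """
    p = result.loadings.shape[0]
    if not (1 <= n_pcs <= result.loadings.shape[1]):
        raise InvalidArgumentError("n_pcs out of range")
    if not (2 <= k <= p):
        raise InvalidArgumentError(f"k must be in [2, {p}], got {k}")
    sub = result.loadings.iloc[:, :n_pcs].to_numpy(dtype=float)
    labels = fcluster(linkage(sub, method="ward"), t=k, criterion="maxclust")
    labels = _relabel_by_size(np.asarray(labels))
    return pd.Series(labels, index=result.loadings.index, name="loading_cluster")


def feature_outcome_correlations(
    table: FeatureTable, cohort: Sequence[SampleInfo]
) -> pd.Series:
    """Point-biserial Pearson correlation of each feature with the outcome."""
    validate_cohort(cohort)
    groups = {s.sample_id: s.group for s in cohort}
    y = np.array([groups[s] for s in table.sample_ids], dtype=float)
    x = table.values.to_numpy(dtype=float)
    xc = x - x.mean(axis=0)
    yc = y - y.mean()
    denom = np.sqrt((xc**2).sum(axis=0) * (yc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc * yc[:, None]).sum(axis=0) / denom
    return pd.Series(np.where(denom > 0, r, 0.0), index=table.feature_ids, name="r")


def heatmap_order(clusters: pd.Series, r: pd.Series) -> pd.DataFrame:
    """Long-format heatmap input: features ordered within each cluster from the
    most positive to the most negative outcome correlation."""
    df = pd.DataFrame({"cluster": clusters, "r": r.loc[clusters.index]})
    df = df.sort_values(["cluster", "r"], ascending=[True, False], kind="stable")
    df.index.name = "feature_id"
    return df.reset_index()


def plsda(
    table: FeatureTable, cohort: Sequence[SampleInfo], n_lv: int = 2
) -> PLSDAResult:
    """Two-class PLS-DA by sequential NIPALS components with VIP scores."""
    table.require_stage("pareto", "log")
    validate_cohort(cohort)
    groups = {s.sample_id: s.group for s in cohort}
    y = np.array([groups[s] for s in table.sample_ids], dtype=float)
    n, p = table.values.shape
    if not (1 <= n_lv <= min(n - 1, p)):
        raise InvalidArgumentError("n_lv must be in [1, min(samples-1, features)]")
    x = table.values.to_numpy(dtype=float)
    X = x - x.mean(axis=0)
    yv = y - y.mean()
    ssy_total = float(yv @ yv)
    ssx_total = float((X**2).sum())
    if ssy_total == 0:
        raise InvalidArgumentError("response has zero variance")

    W, P_, T = [], [], []
    ssx_pct, ssy_pct, ssy_per_lv = [], [], []
    Xd, yd = X.copy(), yv.copy()
    for _ in range(n_lv):
        w = Xd.T @ yd
        nw = np.linalg.norm(w)
        if nw == 0:
            break
        w = w / nw
        t = Xd @ w
        tt = float(t @ t)
        if tt == 0:
            break
        pvec = Xd.T @ t / tt
        q = float(yd @ t / tt)
        ssx_pct.append(100.0 * tt * float(pvec @ pvec) / ssx_total)
        ssy_pct.append(100.0 * q * q * tt / ssy_total)
        ssy_per_lv.append(q * q * tt)
        Xd = Xd - np.outer(t, pvec)
        yd = yd - q * t
        W.append(w)
        P_.append(pvec)
        T.append(t)

    W = np.column_stack(W)
    P_ = np.column_stack(P_)
    T = np.column_stack(T)
    a = W.shape[1]
    ssy = np.asarray(ssy_per_lv)
    wn = W / np.linalg.norm(W, axis=0, keepdims=True)
    vip = np.sqrt(p * (wn**2 @ ssy) / ssy.sum())
    lvs = [f"LV{i + 1}" for i in range(a)]
    return PLSDAResult(
        weights=pd.DataFrame(W, index=table.feature_ids, columns=lvs),
        x_loadings=pd.DataFrame(P_, index=table.feature_ids, columns=lvs),
        scores=pd.DataFrame(T, index=table.values.index, columns=lvs),
        x_var_pct=np.asarray(ssx_pct),
        y_var_pct=np.asarray(ssy_pct),
        vip=pd.Series(vip, index=table.feature_ids, name="vip"),
    )
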