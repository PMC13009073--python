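"""Weighted sub-network analysis of the metabolome.

The pipeline mirrors weighted correlation network analysis as used for
module discovery in omics data, with metabolite features as nodes:

1. pairwise Pearson correlation ``r`` across samples;
2. signed soft-power adjacency ``a_ij = sign(r_ij) |r_ij|^beta`` with weak
   links (|r| < tau) hard-thresholded to zero and a zero diagonal;
3. a topological overlap measure computed on the unsigned weights
   ``u = |a|``:  ``tom_ij = (sum_l u_il u_lj + u_ij) / (min(k_i, k_j) + 1 -
   u_ij)`` where ``k_i = sum_u u_iu`` is the node connectivity — two nodes
   overlap strongly when they share neighbours, not merely when they are
   directly linked;
4. the dissimilarity ``1 - tom``, max-scaled to [0, 1] with the diagonal
   forced to zero, clustered with Ward's method and cut into ``k`` modules
   (default 5);
5. a module eigenmetabolite — the first principal-component score vector of
   the module's member submatrix, unit-normalized and oriented so its mean
   correlation with member features is positive;
6. eigenmetabolite-outcome association: point-biserial Pearson correlation
   and a univariate logistic regression (eigenmetabolite standardized to
   unit variance, so odds ratios are per SD) with Wald statistics and a 95%
   Wald confidence interval.

The power exponent (beta = 6) and threshold (tau = 0.1) are conventional
soft-thresholding defaults; both are exposed as parameters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .containers import FeatureTable, SampleInfo, validate_cohort
from .errors import InvalidArgumentError

__all__ = [
    "NetworkModel",
    "ModuleSet",
    "ModuleAssociation",
    "correlation_matrix",
    "signed_power_adjacency",
    "tom_dissimilarity",
    "cluster_modules",
    "eigenmetabolites",
    "module_outcome_association",
    "build_network",
]


@dataclass
class NetworkModel:
    """All matrices of the weighted network construction."""

    r: pd.DataFrame
    beta: float
    tau: float
    a: pd.DataFrame
    k: pd.Series
    tom: pd.DataFrame
    diss: pd.DataFrame


@dataclass
class ModuleSet:
    labels: pd.Series  # feature_id -> module id 1..K
    eigenmetabolite: pd.DataFrame  # samples x modules, unit-norm oriented scores
    var_explained: dict[int, float]
    orientation_sign: dict[int, int]
    singleton_modules: list[int] = field(default_factory=list)


@dataclass
class ModuleAssociation:
    module: int
    pearson_r: float
    pearson_p: float
    logit_coef: float
    logit_se: float
    or_: float
    wald_chi2: float
    wald_p: float
    ci95: tuple[float, float]
    separated: bool = False


def correlation_matrix(table: FeatureTable) -> pd.DataFrame:
    """Feature-by-feature Pearson correlation on the Pareto-scaled table.

    Zero-variance features (flagged all-zero by Pareto scaling) are excluded
    with a warning; the result is symmetric with unit diagonal.
    """
    table.require_stage("pareto")
    if table.n_samples < 3:
        raise InvalidArgumentError("correlation needs at least 3 samples")
    sd = table.values.std(axis=0, ddof=1)
    keep = sd[sd > 0].index.tolist()
    dropped = [f for f in table.feature_ids if f not in set(keep)]
    if dropped:
        warnings.warn(
            f"excluding {len(dropped)} zero-variance feature(s) from the network",
            stacklevel=2,
        )
    x = table.values.loc[:, keep].to_numpy(dtype=float)
    r = np.corrcoef(x, rowvar=False)
    r = np.clip((r + r.T) / 2, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return pd.DataFrame(r, index=keep, columns=keep)


def signed_power_adjacency(
    r: pd.DataFrame, beta: float = 6.0, tau: float = 0.1
) -> pd.DataFrame:
    """``a_ij = sign(r_ij) |r_ij|^beta`` when |r_ij| >= tau, else 0; zero diagonal."""
    if not beta > 0:
        raise InvalidArgumentError("beta must be > 0")
    if not (0 <= tau < 1):
        raise InvalidArgumentError("tau must be in [0, 1)")
    rv = r.to_numpy(dtype=float)
    a = np.sign(rv) * np.abs(rv) ** beta
    a[np.abs(rv) < tau] = 0.0
    np.fill_diagonal(a, 0.0)
    return pd.DataFrame(a, index=r.index, columns=r.columns)


def tom_dissimilarity(a: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Topological overlap matrix and normalized dissimilarity.

    TOM is computed on the unsigned weights u = |a| (the overlap formula
    requires non-negative weights; the sign information stays in r and a).
    The raw dissimilarity 1 - TOM is divided by its maximum off-diagonal
    entry (identity map if that maximum is 0) and the diagonal forced to 0.
    """
    av = a.to_numpy(dtype=float)
    if av.shape[0] != av.shape[1] or not np.allclose(av, av.T, atol=1e-12):
        raise InvalidArgumentError("adjacency must be square and symmetric")
    if np.abs(av).max(initial=0.0) > 1 + 1e-12:
        raise InvalidArgumentError("adjacency entries must satisfy |a_ij| <= 1")
    u = np.abs(av)
    np.fill_diagonal(u, 0.0)
    k = u.sum(axis=1)
    shared = u @ u  # diagonal of u is 0, so l = i and l = j contribute nothing
    kmin = np.minimum.outer(k, k)
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = (shared + u) / (kmin + 1.0 - u)
    np.fill_diagonal(tom, 1.0)
    tom = np.clip(tom, 0.0, 1.0)
    raw = 1.0 - tom
    np.fill_diagonal(raw, 0.0)
    off_max = raw.max(initial=0.0)
    diss = raw / off_max if off_max > 0 else raw.copy()
    np.fill_diagonal(diss, 0.0)
    ids = a.index
    return (
        pd.DataFrame(tom, index=ids, columns=ids),
        pd.DataFrame(diss, index=ids, columns=ids),
    )


def _relabel_by_size(labels: np.ndarray) -> np.ndarray:
    """Relabel 1..K by decreasing cluster size; ties broken by smallest member index."""
    uniq = np.unique(labels)
    order = sorted(
        uniq,
        key=lambda lab: (-int((labels == lab).sum()), int(np.flatnonzero(labels == lab)[0])),
    )
    mapping = {old: new for new, old in enumerate(order, start=1)}
    return np.array([mapping[v] for v in labels], dtype=int)


def cluster_modules(diss: pd.DataFrame, k: int = 5) -> pd.Series:
    """Ward hierarchical clustering of the dissimilarity, cut to exactly k modules."""
    n = diss.shape[0]
    if not (2 <= k <= n):
        raise InvalidArgumentError(f"k must be in [2, {n}], got {k}")
    d = diss.to_numpy(dtype=float)
    condensed = squareform((d + d.T) / 2, checks=False)
    z = linkage(condensed, method="ward")
    labels = fcluster(z, t=k, criterion="maxclust")
    if len(np.unique(labels)) != k:
        # maxclust can undershoot when merge heights tie; cut by count instead
        from scipy.cluster.hierarchy import cut_tree

        labels = cut_tree(z, n_clusters=k).ravel() + 1
    labels = _relabel_by_size(np.asarray(labels))
    return pd.Series(labels, index=diss.index, name="module")


def eigenmetabolites(table: FeatureTable, labels: pd.Series) -> ModuleSet:
    """First principal-component score vector of each module's member submatrix.

    Scores are unit-normalized and oriented so the mean Pearson correlation
    with member features is positive; var_explained is the first singular
    value's share of the module's total variance. Single-feature modules fall
    back to the standardized feature itself, with a warning.
    """
    table.require_stage("pareto")
    ids = set(table.feature_ids)
    missing = [f for f in labels.index if f not in ids]
    if missing:
        raise InvalidArgumentError(f"labeled features not in table: {missing[:5]}")
    scores = {}
    var_explained: dict[int, float] = {}
    signs: dict[int, int] = {}
    singletons: list[int] = []
    for mod in sorted(labels.unique()):
        members = labels.index[labels == mod].tolist()
        sub = table.values.loc[:, members].to_numpy(dtype=float)
        sub = sub - sub.mean(axis=0)
        if len(members) == 1:
            warnings.warn(
                f"module {mod} has a single feature; eigenmetabolite is the "
                "standardized feature itself",
                stacklevel=2,
            )
            singletons.append(int(mod))
            v = sub[:, 0]
            score = v / np.linalg.norm(v) if np.linalg.norm(v) > 0 else v
            var_explained[int(mod)] = 1.0
        else:
            u, s, _ = np.linalg.svd(sub, full_matrices=False)
            score = u[:, 0]
            tot = (s**2).sum()
            var_explained[int(mod)] = float(s[0] ** 2 / tot) if tot > 0 else 0.0
        # orient: mean correlation with member features positive
        with np.errstate(invalid="ignore"):
            cors = [
                np.corrcoef(score, sub[:, j])[0, 1]
                for j in range(sub.shape[1])
                if sub[:, j].std() > 0
            ]
        sign = -1 if cors and np.nanmean(cors) < 0 else 1
        signs[int(mod)] = sign
        scores[int(mod)] = sign * score
    em = pd.DataFrame(scores, index=table.values.index)
    return ModuleSet(
        labels=labels.astype(int),
        eigenmetabolite=em,
        var_explained=var_explained,
        orientation_sign=signs,
        singleton_modules=singletons,
    )


def _logistic_fit(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Newton (IRLS) fit of logit(P(y=1)) = b0 + b1 x; returns (beta, se).

    Converged to a score (gradient) norm below 1e-8.
    """
    import statsmodels.api as sm

    X = sm.add_constant(x)
    res = sm.Logit(y, X).fit(method="newton", tol=1e-12, maxiter=200, disp=False)
    grad = res.model.score(res.params)
    if np.linalg.norm(grad) > 1e-8:
        warnings.warn("logistic fit did not reach gradient norm < 1e-8", stacklevel=3)
    return np.asarray(res.params), np.asarray(res.bse)


def module_outcome_association(
    modules: ModuleSet, cohort: list[SampleInfo]
) -> list[ModuleAssociation]:
    """Pearson and logistic association of each eigenmetabolite with the outcome.

    The eigenmetabolite is standardized to unit variance before the logistic
    fit, so the odds ratio is per SD of the module score. Perfectly separated
    modules are flagged and reported with an unbounded confidence interval
    rather than crashing.
    """
    validate_cohort(cohort)
    groups = {s.sample_id: s.group for s in cohort}
    samples = [str(s) for s in modules.eigenmetabolite.index]
    missing = [s for s in samples if s not in groups]
    if missing:
        raise InvalidArgumentError(f"samples without cohort metadata: {missing[:5]}")
    y = np.array([groups[s] for s in samples], dtype=float)
    out = []
    for mod in modules.eigenmetabolite.columns:
        x = modules.eigenmetabolite[mod].to_numpy(dtype=float)
        r, p = stats.pearsonr(x, y)
        xs = x / x.std(ddof=1) if x.std(ddof=1) > 0 else x
        separated = bool(
            xs[y == 1].min() > xs[y == 0].max() or xs[y == 1].max() < xs[y == 0].min()
        )
        if separated:
            warnings.warn(
                f"module {mod}: outcome perfectly separated; logistic CI unbounded",
                stacklevel=2,
            )
            sign = 1.0 if xs[y == 1].mean() > xs[y == 0].mean() else -1.0
            out.append(
                ModuleAssociation(
                    module=int(mod),
                    pearson_r=float(r),
                    pearson_p=float(p),
                    logit_coef=float(sign * np.inf),
                    logit_se=np.inf,
                    or_=float(np.inf if sign > 0 else 0.0),
                    wald_chi2=np.nan,
                    wald_p=np.nan,
                    ci95=(0.0, np.inf),
                    separated=True,
                )
            )
            continue
        beta, se = _logistic_fit(xs, y)
        coef, s1 = float(beta[1]), float(se[1])
        wald = (coef / s1) ** 2 if s1 > 0 and np.isfinite(s1) else np.nan
        wald_p = float(stats.chi2.sf(wald, df=1)) if np.isfinite(wald) else np.nan
        out.append(
            ModuleAssociation(
                module=int(mod),
                pearson_r=float(r),
                pearson_p=float(p),
                logit_coef=coef,
                logit_se=s1,
                or_=float(np.exp(coef)),
                wald_chi2=float(wald),
                wald_p=wald_p,
                ci95=(float(np.exp(coef - 1.96 * s1)), float(np.exp(coef + 1.96 * s1))),
            )
        )
    return out


def build_network(
    table: FeatureTable, beta: float = 6.0, tau: float = 0.1
) -> NetworkModel:
    """Correlation -> signed power adjacency -> TOM -> normalized dissimilarity."""
    r = correlation_matrix(table)
    a = signed_power_adjacency(r, beta=beta, tau=tau)
    tom, diss = tom_dissimilarity(a)
    k = pd.Series(np.abs(a.to_numpy()).sum(axis=1), index=a.index, name="connectivity")
    return NetworkModel(r=r, beta=beta, tau=tau, a=a, k=k, tom=tom, diss=diss)
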