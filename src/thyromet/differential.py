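"""Per-feature two-group inference with BH FDR and the pipeline fold-change convention.

Each feature is tested with a classical (equal-variance) one-way ANOVA between
the two outcome groups; with two groups the F statistic equals the square of
the pooled-variance t statistic. Group means are reported on the
``log(value + 1)`` scale regardless of whether the input table is at the log
or Pareto stage (the Pareto map is affine per feature and is inverted using
the stored center/SD — which also makes the F statistic identical between the
two stages).

Fold changes follow a log-mean convention: with ``d`` the case-minus-control
difference of mean log-transformed intensities, ``FC = exp(d)`` and
``L2FC = d / ln 2``, so an L2FC of 1 corresponds to a doubling. Because the
means are taken on the log scale, FC is a ratio of (shifted) geometric means,
not of arithmetic means — a known bias for near-zero intensities.

Benjamini-Hochberg adjustment is offered in two flavours: the standard
monotone step-up (default) and a non-monotone ``p * m / rank`` variant without
the step-up minimum, which some legacy report tables use.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import FLOAT_FMT, FeatureTable, SampleInfo, validate_cohort
from .errors import DomainError, InvalidArgumentError

__all__ = [
    "oneway_anova_per_feature",
    "fold_change",
    "bh_adjust",
    "differential_analysis",
]

LN2 = np.log(2.0)


def fold_change(mean_log_case: float, mean_log_control: float) -> tuple[float, float]:
    """(FC, L2FC) from group means on the natural-log scale.

    ``d = case - control``; ``FC = exp(d)``; ``L2FC = d / ln 2`` (so FC ==
    2**L2FC identically).
    """
    d = mean_log_case - mean_log_control
    return float(np.exp(d)), float(d / LN2)


def _log_scale_means(table: FeatureTable, mask: np.ndarray) -> np.ndarray:
    """Group means on the log(value+1) scale, inverting Pareto if needed."""
    m = table.values.to_numpy()[mask].mean(axis=0)
    if table.stage == "pareto":
        center = table.pareto_center.loc[table.feature_ids].to_numpy()
        sd = table.pareto_sd.loc[table.feature_ids].to_numpy()
        m = m * np.sqrt(sd) + center
    return m


def oneway_anova_per_feature(
    table: FeatureTable, cohort: Sequence[SampleInfo]
) -> pd.DataFrame:
    """One-way ANOVA per feature between the two outcome groups.

    Returns a DataFrame with columns feature_id, mean_log_control,
    mean_log_case, fc, l2fc, f, p_raw (no BH column; see :func:`bh_adjust`).
    Features with zero within-group variance get p = 0 when the group means
    differ and p = 1 otherwise, with a warning.
    """
    table.require_stage("log", "pareto")
    validate_cohort(cohort)
    groups = {s.sample_id: s.group for s in cohort}
    missing = [s for s in table.sample_ids if s not in groups]
    if missing:
        raise InvalidArgumentError(f"samples without cohort metadata: {missing[:5]}")
    g = np.array([groups[s] for s in table.sample_ids])
    n0, n1 = int((g == 0).sum()), int((g == 1).sum())
    if n0 < 2 or n1 < 2:
        raise InvalidArgumentError("each group needs at least 2 samples")

    x = table.values.to_numpy(dtype=float)
    x0, x1 = x[g == 0], x[g == 1]
    m0, m1 = x0.mean(axis=0), x1.mean(axis=0)
    n = n0 + n1
    grand = x.mean(axis=0)
    ssb = n0 * (m0 - grand) ** 2 + n1 * (m1 - grand) ** 2
    ssw = ((x0 - m0) ** 2).sum(axis=0) + ((x1 - m1) ** 2).sum(axis=0)
    df1, df2 = 1, n - 2
    msw = ssw / df2
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ssb / df1) / msw
    p = stats.f.sf(f, df1, df2)

    degenerate = msw == 0
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} feature(s) with zero within-group variance; "
            "p set to 0 if group means differ, else 1",
            stacklevel=2,
        )
        diff_means = m0 != m1
        f = np.where(degenerate, np.where(diff_means, np.inf, 0.0), f)
        p = np.where(degenerate, np.where(diff_means, 0.0, 1.0), p)

    ml0 = _log_scale_means(table, g == 0)
    ml1 = _log_scale_means(table, g == 1)
    d = ml1 - ml0
    return pd.DataFrame(
        {
            "feature_id": table.feature_ids,
            "mean_log_control": ml0,
            "mean_log_case": ml1,
            "fc": np.exp(d),
            "l2fc": d / LN2,
            "f": f,
            "p_raw": p,
        }
    )


def bh_adjust(p, monotone: bool = True) -> np.ndarray:
    """Benjamini-Hochberg adjusted values, in the input order.

    ``monotone=True``: the standard step-up ``q(i) = min_{j>=i} p(j) * m / j``
    capped at 1. ``monotone=False``: ``q(i) = min(p(i) * m / rank(i), 1)``
    without the step-up minimum (ordinal ranks by ascending p), matching some
    legacy report tables.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise InvalidArgumentError("p must be a non-empty 1-D array")
    if (p < 0).any() or (p > 1).any() or not np.isfinite(p).all():
        raise DomainError("p-values must lie in [0, 1]")
    if monotone:
        return multipletests(p, method="fdr_bh")[1]
    order = np.argsort(p, kind="stable")
    ranks = np.empty(p.size)
    ranks[order] = np.arange(1, p.size + 1)
    return np.minimum(p * p.size / ranks, 1.0)


def differential_analysis(
    table: FeatureTable,
    cohort: Sequence[SampleInfo],
    alpha: float = 0.05,
    monotone: bool = True,
) -> pd.DataFrame:
    """ANOVA + BH in one call; adds q_bh and a significant flag (q < alpha)."""
    res = oneway_anova_per_feature(table, cohort)
    res["q_bh"] = bh_adjust(res["p_raw"].to_numpy(), monotone=monotone)
    res["significant"] = res["q_bh"] < alpha
    return res


def write_diff_csv(res: pd.DataFrame, path) -> None:
    cols = ["feature_id", "mean_log_control", "mean_log_case", "fc", "l2fc", "f", "p_raw"]
    if "q_bh" in res.columns:
        cols.append("q_bh")
    res[cols].to_csv(path, index=False, float_format=FLOAT_FMT)
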