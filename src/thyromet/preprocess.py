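"""Post-acquisition feature filtering and normalization.

Four stages, applied in a fixed order to a :class:`~thyromet.containers.FeatureTable`:

1. **Blank filter** — a feature is removed when its maximum intensity across
   samples is less than ``threshold`` (default 10) times the instrument-blank
   average for that feature. A feature absent from the blank (blank mean 0)
   has an infinite ratio and is always kept.
2. **mTIC normalization** — each value is divided by its sample's summed
   intensity over the annotated ("known") features, the metabolite total ion
   chromatogram; afterwards every sample sums to exactly 1 over the annotated
   features. A flag widens the divisor to all features.
3. **Log transform** — ``y = ln(x + 1)`` (natural log; the pipeline's
   fold-change convention divides a log-mean difference by ln 2, which yields
   a base-2 exponent only under the natural log).
4. **Pareto scaling** — per feature, mean-center and divide by the square
   root of the sample standard deviation (n-1 denominator): intermediate
   between plain centering and unit-variance scaling, damping the dominance
   of high-variance features without flattening them entirely.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .containers import FLOAT_FMT, FeatureTable
from .errors import DegenerateSampleError, DomainError, InvalidArgumentError

__all__ = ["FilterReport", "blank_filter", "mtic_normalize", "log_transform", "pareto_scale"]


@dataclass
class FilterReport:
    """Outcome of the blank filter: per-feature ratio and keep/remove split."""

    kept_feature_ids: list[str]
    removed_feature_ids: list[str]
    ratio: pd.Series  # sample max / blank average, inf where blank = 0

    def to_csv(self, path: str | Path) -> None:
        kept = set(self.kept_feature_ids)
        df = pd.DataFrame(
            {
                "feature_id": self.ratio.index,
                "ratio": self.ratio.to_numpy(),
                "kept": [f in kept for f in self.ratio.index],
            }
        )
        df.to_csv(path, index=False, float_format=FLOAT_FMT)


def blank_filter(
    table: FeatureTable,
    blank_means: pd.Series,
    threshold: float = 10.0,
) -> tuple[FeatureTable, FilterReport]:
    """Remove features whose sample max / blank average falls below ``threshold``.

    The rule removes strictly-below ratios, so a feature exactly at the
    threshold is kept. Column order of survivors is preserved. Filtering an
    already-filtered table with the same blanks is a no-op (idempotent).
    """
    table.require_stage("raw", "blank_filtered")
    missing = [f for f in table.feature_ids if f not in blank_means.index]
    if missing:
        raise KeyError(f"blank mean missing for features: {missing[:5]}")
    blanks = blank_means.loc[table.feature_ids].astype(float)
    if (blanks < 0).any():
        raise InvalidArgumentError("blank means must be >= 0")
    smax = table.values.max(axis=0)
    with np.errstate(divide="ignore"):
        ratio = pd.Series(
            np.where(blanks.to_numpy() == 0, np.inf, smax.to_numpy() / blanks.to_numpy()),
            index=table.feature_ids,
            name="ratio",
        )
    keep_mask = ratio >= threshold
    kept = [f for f, k in keep_mask.items() if k]
    removed = [f for f, k in keep_mask.items() if not k]
    out = FeatureTable(values=table.values.loc[:, kept], stage="blank_filtered")
    return out, FilterReport(kept, removed, ratio)


def mtic_normalize(
    table: FeatureTable,
    annotated_ids: Sequence[str] | None = None,
    all_features: bool = False,
) -> FeatureTable:
    """Divide each sample by its summed intensity over annotated features.

    ``annotated_ids`` selects the "known" (putatively annotated) features that
    define the mTIC divisor; with ``all_features=True`` (or ``annotated_ids``
    None) every feature contributes, i.e. a plain TIC normalization.
    """
    table.require_stage("raw", "blank_filtered")
    if all_features or annotated_ids is None:
        annotated = list(table.feature_ids)
    else:
        annotated = [str(a) for a in annotated_ids]
        if not annotated:
            raise InvalidArgumentError("annotated_ids must be non-empty")
        missing = [a for a in annotated if a not in table.values.columns]
        if missing:
            raise KeyError(f"annotated features not in table: {missing[:5]}")
    divisor = table.values.loc[:, annotated].sum(axis=1)
    zero = divisor[divisor <= 0]
    if len(zero):
        raise DegenerateSampleError(
            str(zero.index[0]), "sum over annotated features is not positive"
        )
    return FeatureTable(values=table.values.div(divisor, axis=0), stage="mtic")


def log_transform(table: FeatureTable) -> FeatureTable:
    """Apply ``y = ln(x + 1)`` elementwise (variance stabilization)."""
    table.require_stage("raw", "blank_filtered", "mtic")
    arr = table.values.to_numpy()
    if (arr <= -1).any():
        raise DomainError("log(value + 1) requires values > -1")
    return FeatureTable(values=np.log1p(table.values), stage="log")


def pareto_scale(table: FeatureTable) -> tuple[FeatureTable, list[str]]:
    """Mean-center each feature and divide by the square root of its SD.

    Uses the sample standard deviation (n-1 denominator). Zero-variance
    features cannot be scaled; they are set to all-zero and returned in the
    warning list. The per-feature mean and SD are stored on the output table
    so the affine map can be inverted downstream.
    """
    table.require_stage("log")
    if table.n_samples < 2:
        raise InvalidArgumentError("Pareto scaling needs at least 2 samples")
    mean = table.values.mean(axis=0)
    sd = table.values.std(axis=0, ddof=1)
    flat = sd[sd == 0].index.tolist()
    if flat:
        warnings.warn(
            f"{len(flat)} zero-variance feature(s) set to all-zero by Pareto scaling",
            stacklevel=2,
        )
    denom = np.sqrt(sd.replace(0, 1.0))
    scaled = (table.values - mean) / denom
    scaled.loc[:, flat] = 0.0
    out = FeatureTable(
        values=scaled, stage="pareto", pareto_center=mean, pareto_sd=sd
    )
    return out, [str(f) for f in flat]
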