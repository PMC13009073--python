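"""Core data containers: the sample-by-feature intensity table and cohort metadata.

A :class:`FeatureTable` is a dense samples x features matrix of peak-height
intensities (arbitrary units) tagged with the processing stage it has reached.
The tag advances monotonically through the pipeline
``raw -> blank_filtered -> mtic -> log -> pareto`` and every operation checks
it, so a table can never be log-transformed twice or Pareto-scaled before the
log step.

Cohort metadata is a list of :class:`SampleInfo` records: a binary outcome
code (0 = euthyroid control, 1 = hyperthyroid case) and the urine creatinine
concentration (mg/dL) used for dilution adjustment of urinary analytes.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import InvalidArgumentError, StageError

STAGES = ("raw", "blank_filtered", "mtic", "log", "pareto")

# 17 significant digits round-trips IEEE doubles exactly.
FLOAT_FMT = "%.17g"


@dataclass(frozen=True)
class SampleInfo:
    """One cohort member.

    Parameters
    ----------
    sample_id
        Unique sample identifier.
    group
        Binary outcome code: 0 = control (euthyroid), 1 = case (hyperthyroid).
    urine_creatinine
        Urine creatinine concentration in mg/dL; must be positive.
    """

    sample_id: str
    group: int
    urine_creatinine: float

    def __post_init__(self):
        if self.group not in (0, 1):
            raise InvalidArgumentError(f"group must be 0 or 1, got {self.group}")
        if not self.urine_creatinine > 0:
            raise InvalidArgumentError(
                f"urine_creatinine must be > 0, got {self.urine_creatinine}"
            )


def validate_cohort(cohort: Sequence[SampleInfo], require_both_groups: bool = True) -> None:
    ids = [s.sample_id for s in cohort]
    if len(set(ids)) != len(ids):
        raise InvalidArgumentError("sample_ids must be unique")
    if require_both_groups:
        groups = {s.group for s in cohort}
        if groups != {0, 1}:
            raise InvalidArgumentError(
                "cohort used for inference must contain both group codes"
            )


def cohort_to_frame(cohort: Sequence[SampleInfo]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in cohort],
            "group": [s.group for s in cohort],
            "urine_creatinine": [s.urine_creatinine for s in cohort],
        }
    )


def write_cohort_csv(cohort: Sequence[SampleInfo], path: str | Path) -> None:
    cohort_to_frame(cohort).to_csv(path, index=False, float_format=FLOAT_FMT)


def read_cohort_csv(path: str | Path) -> list[SampleInfo]:
    df = pd.read_csv(path)
    return [
        SampleInfo(str(r.sample_id), int(r.group), float(r.urine_creatinine))
        for r in df.itertuples(index=False)
    ]


@dataclass
class FeatureTable:
    """Dense sample x feature intensity matrix with a processing-stage tag.

    ``values`` is a pandas DataFrame indexed by sample_id with feature_ids as
    columns. ``stage`` records how far through the normalization chain the
    table has advanced. After Pareto scaling, ``pareto_center`` and
    ``pareto_sd`` store the per-feature log-scale mean and standard deviation
    so downstream consumers can invert the affine map (e.g. to report group
    means on the log scale).
    """

    values: pd.DataFrame
    stage: str = "raw"
    pareto_center: pd.Series | None = None
    pareto_sd: pd.Series | None = None

    def __post_init__(self):
        if self.stage not in STAGES:
            raise StageError(f"unknown stage {self.stage!r}; expected one of {STAGES}")
        if self.values.index.has_duplicates or self.values.columns.has_duplicates:
            raise InvalidArgumentError("sample_ids and feature_ids must be unique")
        arr = self.values.to_numpy()
        if arr.size and not np.isfinite(arr).all():
            raise InvalidArgumentError(
                "FeatureTable must not contain missing or non-finite values; "
                "imputation is explicit, never silent"
            )
        if self.stage == "raw" and arr.size and (arr < 0).any():
            raise InvalidArgumentError("raw-stage intensities must be >= 0")

    # -- convenience -------------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.values.index]

    @property
    def feature_ids(self) -> list[str]:
        return [str(f) for f in self.values.columns]

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def with_values(self, values: pd.DataFrame, stage: str, **kw) -> "FeatureTable":
        return FeatureTable(values=values, stage=stage, **kw)

    def require_stage(self, *allowed: str) -> None:
        if self.stage not in allowed:
            raise StageError(
                f"operation requires stage in {allowed}, table is at {self.stage!r}"
            )

    # -- I/O ---------------------------------------------------------------
    def to_tsv(self, path: str | Path) -> None:
        """Write as TSV: first column ``sample_id``, header row of feature ids."""
        out = self.values.copy()
        out.insert(0, "sample_id", self.values.index)
        out.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)

    @classmethod
    def from_tsv(cls, path: str | Path, stage: str = "raw") -> "FeatureTable":
        df = pd.read_csv(path, sep="\t")
        df = df.set_index("sample_id")
        df.index = df.index.astype(str)
        df.index.name = None
        df.columns = df.columns.astype(str)
        return cls(values=df.astype(float), stage=stage)


def subset_features(table: FeatureTable, feature_ids: Sequence[str]) -> FeatureTable:
    """Column subset preserving order of ``feature_ids``; stage unchanged."""
    missing = [f for f in feature_ids if f not in table.values.columns]
    if missing:
        raise KeyError(f"features not in table: {missing[:5]}")
    kw = {}
    for attr in ("pareto_center", "pareto_sd"):
        s = getattr(table, attr)
        if s is not None:
            kw[attr] = s.loc[list(feature_ids)]
    return replace(table, values=table.values.loc[:, list(feature_ids)], **kw)
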