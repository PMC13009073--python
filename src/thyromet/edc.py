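"""Targeted urinary endocrine-disruptor processing.

Three steps, applied to long-format measurements (sample_id, analyte,
value_ng_ml):

1. **LOQ imputation** — a value strictly below the analyte's limit of
   quantitation is replaced by LOQ/sqrt(2), the standard single-value
   substitution for left-censored biomonitoring data.
2. **Creatinine adjustment** — concentrations are divided by urine
   creatinine to correct for dilution; with analyte in ng/mL and creatinine
   in mg/dL the adjusted value is ``100 * value / creatinine`` in µg analyte
   per g creatinine (ng/mg == µg/g).
3. **Molar-sum indices** — creatinine-adjusted concentrations divided by
   molar mass (µg/µmol) and summed into exposure indices: sum PCP (personal
   care products: MBP + MEP), sum DEHP (MECPP + MEHHP + MEOHP + MEHP) and
   sum AA (anti-androgenic activity: MBP + MBzP + MiBP), each in µmol/g
   creatinine, plus mass-based family totals sum_paraben and sum_phthalate
   (µg/g creatinine).

The default analyte panel (14 analytes with their LOQs and molar masses)
ships with the package and is loaded by :func:`default_panel`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .containers import SampleInfo
from .errors import InvalidArgumentError

__all__ = [
    "AnalytePanel",
    "default_panel",
    "impute_below_loq",
    "creatinine_adjust",
    "molar_sums",
    "MOLAR_SUM_DEFINITIONS",
]

# Constituents of each molar-sum exposure index.
MOLAR_SUM_DEFINITIONS: dict[str, tuple[str, ...]] = {
    "sum_pcp": ("MBP", "MEP"),
    "sum_dehp": ("MECPP", "MEHHP", "MEOHP", "MEHP"),
    "sum_aa": ("MBP", "MBzP", "MiBP"),
}


@dataclass
class AnalytePanel:
    """Registry of EDC analytes: LOQ (ng/mL), molar mass (µg/µmol), family.

    ``molar_mass`` may omit analytes that never enter a molar sum; requesting
    a molar sum whose constituent lacks a mass raises.
    """

    loq: dict[str, float]
    molar_mass: dict[str, float] = field(default_factory=dict)
    parent: dict[str, str] = field(default_factory=dict)
    family: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        for a, v in self.loq.items():
            if not v > 0:
                raise InvalidArgumentError(f"LOQ must be > 0, got {v} for {a!r}")
        for a, v in self.molar_mass.items():
            if not v > 0:
                raise InvalidArgumentError(f"molar mass must be > 0, got {v} for {a!r}")

    @property
    def analytes(self) -> list[str]:
        return list(self.loq)

    @classmethod
    def from_csv(cls, path) -> "AnalytePanel":
        df = pd.read_csv(path)
        loq, mm, parent, family = {}, {}, {}, {}
        for r in df.itertuples(index=False):
            a = str(r.analyte)
            loq[a] = float(r.loq_ng_ml)
            if not pd.isna(r.molar_mass_ug_per_umol):
                mm[a] = float(r.molar_mass_ug_per_umol)
            parent[a] = str(r.parent)
            family[a] = str(r.family)
        return cls(loq=loq, molar_mass=mm, parent=parent, family=family)

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {
                "analyte": self.analytes,
                "parent": [self.parent.get(a, "") for a in self.analytes],
                "loq_ng_ml": [self.loq[a] for a in self.analytes],
                "molar_mass_ug_per_umol": [
                    self.molar_mass.get(a, np.nan) for a in self.analytes
                ],
                "family": [self.family.get(a, "") for a in self.analytes],
            }
        ).to_csv(path, index=False)


def default_panel() -> AnalytePanel:
    """The packaged 14-analyte paraben/phthalate panel."""
    ref = resources.files("thyromet.data").joinpath("analyte_panel.csv")
    with resources.as_file(ref) as path:
        return AnalytePanel.from_csv(path)


def _check_analytes(meas: pd.DataFrame, panel: AnalytePanel) -> None:
    unknown = sorted(set(meas["analyte"]) - set(panel.loq))
    if unknown:
        raise KeyError(f"analytes not in panel: {unknown}")


def impute_below_loq(meas: pd.DataFrame, panel: AnalytePanel) -> pd.DataFrame:
    """Replace values strictly below the analyte LOQ by LOQ/sqrt(2).

    Input columns: sample_id, analyte, value_ng_ml. Output adds/overwrites a
    ``below_loq`` flag; values at or above the LOQ pass through untouched.
    """
    _check_analytes(meas, panel)
    out = meas.copy()
    loq = out["analyte"].map(panel.loq).astype(float)
    below = out["value_ng_ml"] < loq
    out["below_loq"] = below.to_numpy()
    out.loc[below, "value_ng_ml"] = loq[below] / math.sqrt(2)
    return out


def creatinine_adjust(
    meas: pd.DataFrame, cohort: Sequence[SampleInfo]
) -> pd.DataFrame:
    """Convert ng/mL to µg analyte per g creatinine.

    adjusted (µg/g) = 100 * raw (ng/mL) / creatinine (mg/dL); doubling a
    sample's creatinine halves all its adjusted values.
    """
    creat = {s.sample_id: s.urine_creatinine for s in cohort}
    out = meas.copy()
    missing = sorted(set(out["sample_id"]) - set(creat))
    if missing:
        raise InvalidArgumentError(
            f"sample {missing[0]!r}: missing creatinine (and {len(missing) - 1} more)"
            if len(missing) > 1
            else f"sample {missing[0]!r}: missing creatinine"
        )
    c = out["sample_id"].map(creat).astype(float)
    if (c <= 0).any():
        bad = out.loc[c <= 0, "sample_id"].iloc[0]
        raise InvalidArgumentError(f"sample {bad!r}: non-positive creatinine")
    out["adjusted_ug_per_g"] = 100.0 * out["value_ng_ml"] / c
    return out


def molar_sums(
    adjusted: pd.DataFrame,
    panel: AnalytePanel,
    definitions: Mapping[str, Sequence[str]] = MOLAR_SUM_DEFINITIONS,
) -> pd.DataFrame:
    """Per-sample exposure indices from creatinine-adjusted concentrations.

    Molar indices (µmol/g creatinine) sum adjusted concentration / molar mass
    over each definition's constituents; family totals sum_paraben and
    sum_phthalate are mass sums (µg/g creatinine) over the panel families. A
    sample missing any constituent of an index gets NaN for that index rather
    than a silently truncated sum.
    """
    if "adjusted_ug_per_g" not in adjusted.columns:
        raise InvalidArgumentError("run creatinine_adjust first")
    _check_analytes(adjusted, panel)
    wide = adjusted.pivot(index="sample_id", columns="analyte", values="adjusted_ug_per_g")
    out = pd.DataFrame(index=wide.index)
    for name, constituents in definitions.items():
        cols = []
        for a in constituents:
            if a not in panel.molar_mass:
                raise InvalidArgumentError(
                    f"analyte {a!r} in index {name!r} has no molar mass in the panel"
                )
            if a in wide.columns:
                cols.append(wide[a] / panel.molar_mass[a])
            else:
                cols.append(pd.Series(np.nan, index=wide.index))
        out[name] = sum(cols)
    for fam, col in (("paraben", "sum_paraben"), ("phthalate_metabolite", "sum_phthalate")):
        members = [a for a in panel.analytes if panel.family.get(a) == fam]
        present = [a for a in members if a in wide.columns]
        if present:
            block = wide[present]
            # NaN (not zero) when any measured constituent is absent for a sample
            out[col] = block.sum(axis=1, min_count=len(present))
    out.index.name = "sample_id"
    return out
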