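"""Synthetic cohorts, metabolomes, blank profiles and EDC panels with known truth.

The study this pipeline targets deposited no data, so every downstream stage
is exercised on simulated inputs whose ground truth is recorded explicitly:

* a two-group cohort (default 19 controls, 16 cases) with log-normal urine
  creatinine;
* a metabolome of ~389 features whose natural-log intensities are Gaussian
  with optional per-feature group shifts ``d_j`` and block-exchangeable
  within-module correlation (constant correlation inside each planted module,
  zero between modules) — the structure the network stage is built to detect;
* an instrument-blank profile in which a chosen fraction of features carries
  enough blank signal to fail the ratio-10 blank filter;
* a urinary EDC panel drawn log-normally per analyte, with draws below the
  analyte's limit of quantitation flagged as censored (the true value is kept
  in the truth object so imputation error is measurable).

Intensities are generated on the natural-log scale and exponentiated, so the
pipeline's log transform approximately recovers normality; the ``+1`` in
``log(value + 1)`` makes that recovery inexact, which is accepted because it
is the convention the pipeline itself uses.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .containers import FeatureTable, SampleInfo, validate_cohort
from .errors import InvalidArgumentError

__all__ = [
    "SyntheticTruth",
    "generate_cohort",
    "generate_metabolome",
    "generate_blank_profile",
    "generate_edc",
]

# Defaults chosen once as the study conditions: peak heights around 1e5
# arbitrary units (ln 1e5 ~ 11.5) with log-scale spread 0.7.
DEFAULT_BASE_LOG_MEAN = 11.5
DEFAULT_NOISE_SD = 0.7


@dataclass
class SyntheticTruth:
    """Ground truth recorded by the generators for parameter-recovery tests.

    ``effect`` is the per-feature log-scale group shift d_j; ``module_label``
    assigns each feature to a planted correlation module (0 = background);
    ``pathway_label`` assigns each feature to one of nine pathway groups;
    ``censored_flags`` (EDC only) marks sample x analyte draws below the LOQ,
    and ``true_edc_values`` keeps the uncensored draws.
    """

    effect: pd.Series | None = None
    module_label: pd.Series | None = None
    pathway_label: pd.Series | None = None
    enriched_pathway: int | None = None
    contaminated_features: list[str] = field(default_factory=list)
    censored_flags: pd.DataFrame | None = None
    true_edc_values: pd.DataFrame | None = None
    case_multiplier: dict[str, float] | None = None

    def to_json(self, path: str | Path) -> None:
        def ser(obj):
            if obj is None:
                return None
            if isinstance(obj, pd.Series):
                return {str(k): (float(v) if np.isreal(v) else v) for k, v in obj.items()}
            if isinstance(obj, pd.DataFrame):
                return {
                    "index": [str(i) for i in obj.index],
                    "columns": [str(c) for c in obj.columns],
                    "values": obj.to_numpy().tolist(),
                }
            return obj

        payload = {
            "effect": ser(self.effect),
            "module_label": ser(self.module_label),
            "pathway_label": ser(self.pathway_label),
            "enriched_pathway": self.enriched_pathway,
            "contaminated_features": self.contaminated_features,
            "censored_flags": ser(self.censored_flags),
            "true_edc_values": ser(self.true_edc_values),
            "case_multiplier": self.case_multiplier,
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def generate_cohort(
    n_control: int,
    n_case: int,
    creat_log_mean: float = np.log(80.0),
    creat_log_sd: float = 0.5,
    seed: int = 0,
) -> list[SampleInfo]:
    """Simulate a two-group cohort with log-normal urine creatinine.

    ``creat_log_mean`` / ``creat_log_sd`` parameterize the natural-log of
    creatinine (mg/dL); the default geometric mean of 80 mg/dL is typical of
    feline urine. Identical seeds give identical cohorts.
    """
    if n_control < 2 or n_case < 2:
        raise InvalidArgumentError("each group needs at least 2 samples")
    if creat_log_sd < 0:
        raise InvalidArgumentError("creat_log_sd must be >= 0")
    rng = np.random.default_rng(seed)
    n = n_control + n_case
    creat = np.exp(rng.normal(creat_log_mean, creat_log_sd, size=n))
    cohort = []
    for i in range(n):
        group = 0 if i < n_control else 1
        cohort.append(SampleInfo(f"S{i + 1:03d}", group, float(creat[i])))
    validate_cohort(cohort)
    return cohort


def _assign_pathways(
    n_features: int,
    pathway_sizes: Sequence[int],
    enriched_pathway: int,
    effect_idx: np.ndarray,
    enriched_effect_fraction: float,
    rng: np.random.Generator,
    align_to_modules: bool = False,
) -> np.ndarray:
    """Pathway labels 1..9 with the stated sizes.

    By default labels are a seeded random permutation (independent of module
    blocks), then planted-effect features are swapped into the enriched
    pathway until it holds ``enriched_effect_fraction`` of them (capacity
    permitting). With ``align_to_modules`` labels are assigned in feature
    order so pathway blocks coincide with module blocks.
    """
    labels = np.repeat(np.arange(1, len(pathway_sizes) + 1), pathway_sizes)
    if not align_to_modules:
        rng.shuffle(labels)
    if len(effect_idx) and enriched_effect_fraction > 0:
        want_in = int(round(enriched_effect_fraction * len(effect_idx)))
        in_already = [i for i in effect_idx if labels[i] == enriched_pathway]
        need = want_in - len(in_already)
        if need > 0:
            movable = [i for i in effect_idx if labels[i] != enriched_pathway]
            rng.shuffle(movable)
            # swap labels with non-effect features currently in the enriched pathway
            effect_set = set(effect_idx.tolist())
            slots = [
                i
                for i in np.flatnonzero(labels == enriched_pathway)
                if i not in effect_set
            ]
            rng.shuffle(slots)
            for src, dst in zip(movable[:need], slots):
                labels[src], labels[dst] = labels[dst], labels[src]
    return labels


def generate_metabolome(
    cohort: Sequence[SampleInfo],
    n_features: int,
    modules: Sequence[tuple[int, float]] = (),
    effects: Sequence[tuple[int, float]] = (),
    base_log_mean: float = DEFAULT_BASE_LOG_MEAN,
    noise_sd: float = DEFAULT_NOISE_SD,
    pathway_sizes: Sequence[int] | None = None,
    enriched_pathway: int = 1,
    enriched_effect_fraction: float = 0.4,
    align_pathways_to_modules: bool = False,
    seed: int = 0,
) -> tuple[FeatureTable, SyntheticTruth]:
    """Simulate a raw-stage feature table with planted effects and modules.

    Latent log intensities are ``z_ij ~ N(base_log_mean + d_j * group_i, S)``
    with ``S`` block-exchangeable: correlation ``within_corr`` inside each
    module (realized by a shared standard-normal module factor), zero between
    modules and for background features. Observed intensities are
    ``x_ij = exp(z_ij)``. Features are ordered module-first: module 1 occupies
    the first block of columns, then module 2, ..., then background.

    ``effects`` is a list of ``(feature_index, d_j)`` log-scale group shifts.
    ``pathway_sizes`` must list nine counts summing to ``n_features``; labels
    are drawn independently of module blocks unless
    ``align_pathways_to_modules`` is set.
    """
    validate_cohort(cohort)
    if n_features < 1:
        raise InvalidArgumentError("n_features must be >= 1")
    sizes = [m[0] for m in modules]
    if sum(sizes) > n_features:
        raise InvalidArgumentError("module sizes must sum to <= n_features")
    for _, rho in modules:
        if not (0 <= rho < 1):
            raise InvalidArgumentError(
                f"within_corr must be in [0, 1) for a positive-definite "
                f"block-exchangeable covariance, got {rho}"
            )
    if pathway_sizes is None:
        # nine near-equal groups by default
        base = n_features // 9
        pathway_sizes = [base] * 9
        pathway_sizes[-1] += n_features - 9 * base
    if len(pathway_sizes) != 9 or sum(pathway_sizes) != n_features:
        raise InvalidArgumentError(
            "pathway_sizes must list 9 counts summing to n_features"
        )
    if not (1 <= enriched_pathway <= 9):
        raise InvalidArgumentError("enriched_pathway must be in 1..9")

    rng = np.random.default_rng(seed)
    n = len(cohort)
    group = np.array([s.group for s in cohort], dtype=float)

    effect = np.zeros(n_features)
    for idx, d in effects:
        if not (0 <= idx < n_features):
            raise InvalidArgumentError(f"effect feature_index {idx} out of range")
        effect[idx] = d

    module_label = np.zeros(n_features, dtype=int)
    pos = 0
    for k, (size, _) in enumerate(modules, start=1):
        module_label[pos : pos + size] = k
        pos += size

    # shared-factor construction: z = sqrt(rho)*g_module + sqrt(1-rho)*eps
    z = rng.standard_normal((n, n_features))
    pos = 0
    for (size, rho) in modules:
        if rho > 0:
            g = rng.standard_normal((n, 1))
            z[:, pos : pos + size] = np.sqrt(rho) * g + np.sqrt(1 - rho) * z[
                :, pos : pos + size
            ]
        pos += size
    z = base_log_mean + np.outer(group, effect) + noise_sd * z
    x = np.exp(z)

    feature_ids = [f"M{j + 1:04d}" for j in range(n_features)]
    sample_ids = [s.sample_id for s in cohort]
    table = FeatureTable(
        values=pd.DataFrame(x, index=sample_ids, columns=feature_ids), stage="raw"
    )

    effect_idx = np.flatnonzero(effect != 0)
    pathway_label = _assign_pathways(
        n_features,
        pathway_sizes,
        enriched_pathway,
        effect_idx,
        enriched_effect_fraction,
        rng,
        align_to_modules=align_pathways_to_modules,
    )
    truth = SyntheticTruth(
        effect=pd.Series(effect, index=feature_ids),
        module_label=pd.Series(module_label, index=feature_ids),
        pathway_label=pd.Series(pathway_label, index=feature_ids),
        enriched_pathway=enriched_pathway,
    )
    return table, truth


def generate_blank_profile(
    table: FeatureTable,
    fraction_contaminated: float,
    seed: int = 0,
    threshold: float = 10.0,
) -> tuple[pd.Series, list[str]]:
    """Per-feature instrument-blank averages paired with ``table``.

    A seeded random fraction of features receives a blank average high enough
    that ``sample_max / blank`` falls below ``threshold`` (they will be
    removed by the blank filter); the rest receive near-zero blanks that pass
    comfortably. Returns ``(blank_means, contaminated_feature_ids)``.
    """
    if not (0 <= fraction_contaminated <= 1):
        raise InvalidArgumentError("fraction_contaminated must be in [0, 1]")
    rng = np.random.default_rng(seed)
    fids = table.feature_ids
    n = len(fids)
    n_bad = int(round(fraction_contaminated * n))
    bad = rng.choice(n, size=n_bad, replace=False)
    bad_mask = np.zeros(n, dtype=bool)
    bad_mask[bad] = True
    smax = table.values.max(axis=0).to_numpy()
    # contaminated: ratio uniform in [2, threshold*0.9); clean: ratio >= 20*threshold
    blanks = smax / (threshold * rng.uniform(20.0, 200.0, size=n))
    blanks[bad_mask] = smax[bad_mask] / rng.uniform(2.0, 0.9 * threshold, size=n_bad)
    series = pd.Series(blanks, index=fids, name="blank_mean")
    return series, [fids[i] for i in np.flatnonzero(bad_mask)]


def generate_edc(
    cohort: Sequence[SampleInfo],
    panel,
    geo_mean: Mapping[str, float],
    geo_sd: Mapping[str, float],
    case_multiplier: Mapping[str, float] | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Simulate raw urinary EDC concentrations (ng/mL) with LOQ censoring flags.

    Per analyte, concentrations are log-normal with geometric mean
    ``geo_mean[a]`` (multiplied by ``case_multiplier[a]`` in the case group)
    and geometric SD ``geo_sd[a] > 1``. Draws below the analyte's LOQ are
    flagged censored; the measurements frame keeps the true draw (imputation
    is the pipeline's job, and truth retains the value so imputation error is
    measurable).

    Returns a long-format DataFrame ``(sample_id, analyte, value_ng_ml,
    below_loq)`` and the truth object.
    """
    validate_cohort(cohort, require_both_groups=False)
    case_multiplier = dict(case_multiplier or {})
    rng = np.random.default_rng(seed)
    records = []
    analytes = list(geo_mean)
    for a in analytes:
        if a not in panel.loq:
            raise KeyError(f"analyte {a!r} not in panel")
        if not geo_sd[a] > 1:
            raise InvalidArgumentError(f"geo_sd must be > 1, got {geo_sd[a]} for {a!r}")
    for s in cohort:
        for a in analytes:
            mult = case_multiplier.get(a, 1.0) if s.group == 1 else 1.0
            mu = np.log(geo_mean[a] * mult)
            sigma = np.log(geo_sd[a])
            val = float(np.exp(rng.normal(mu, sigma)))
            records.append(
                {
                    "sample_id": s.sample_id,
                    "analyte": a,
                    "value_ng_ml": val,
                    "below_loq": val < panel.loq[a],
                }
            )
    meas = pd.DataFrame.from_records(records)
    flags = meas.pivot(index="sample_id", columns="analyte", values="below_loq")
    true_vals = meas.pivot(index="sample_id", columns="analyte", values="value_ng_ml")
    truth = SyntheticTruth(
        censored_flags=flags,
        true_edc_values=true_vals,
        case_multiplier={a: case_multiplier.get(a, 1.0) for a in analytes},
    )
    return meas, truth
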