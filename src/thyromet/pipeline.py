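"""End-to-end orchestration: simulate -> preprocess -> edc -> differential ->
enrichment -> network -> multivariate, driven by one flat config.

Every stage writes its artifacts under ``out_dir`` in the documented CSV/TSV
dialects, and the run ends with a JSON manifest (config, seed, per-stage
dimensions) plus a line-per-stage log. Identical config + seed regenerates
byte-identical numeric artifacts.

:func:`reproduce_table2` recomputes the pathway-enrichment summary (Fisher
raw p and BH values) directly from a CSV of the nine per-pathway
significant/non-significant count pairs; a copy of those printed counts ships
with the package (``thyromet.data/table2_counts.csv``).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .containers import FLOAT_FMT, FeatureTable, read_cohort_csv, write_cohort_csv
from .differential import differential_analysis, write_diff_csv
from .edc import creatinine_adjust, default_panel, impute_below_loq, molar_sums
from .enrichment import (
    EnrichmentRow,
    enrichment_from_counts,
    fisher_enrichment,
    write_enrichment_csv,
)
from .errors import InvalidArgumentError
from .multivariate import (
    cluster_loadings,
    feature_outcome_correlations,
    heatmap_order,
    n_components_for_variance,
    pca,
    plsda,
)
from .network import (
    build_network,
    cluster_modules,
    eigenmetabolites,
    module_outcome_association,
)
from .preprocess import blank_filter, log_transform, mtic_normalize, pareto_scale
from .simulate import generate_blank_profile, generate_cohort, generate_edc, generate_metabolome

__all__ = ["PipelineConfig", "run_pipeline", "reproduce_table2", "packaged_table2_counts"]

STAGE_NAMES = ("simulate", "preprocess", "edc", "diff", "enrich", "network", "multivar")


@dataclass
class PipelineConfig:
    """Flat configuration shared by all stages (CLI flags mirror these keys)."""

    seed: int = 0
    out_dir: str = "thyromet_run"
    stages: tuple[str, ...] = STAGE_NAMES
    # simulation
    n_control: int = 19
    n_case: int = 16
    n_features: int = 389
    n_modules: int = 5
    module_size: int = 20
    within_corr: float = 0.8
    n_effects: int = 20
    effect_size: float = 1.0
    fraction_contaminated: float = 0.1
    # thresholds
    blank_ratio_threshold: float = 10.0
    fdr_alpha: float = 0.05
    bh_monotone: bool = True
    beta: float = 6.0
    tau: float = 0.1
    k_modules: int = 5
    k_loading_clusters: int = 15
    n_pcs_rule: float = 0.90
    n_lv: int = 2
    # optional external inputs (used when the simulate stage is off)
    table_tsv: str | None = None
    cohort_csv: str | None = None
    blank_csv: str | None = None
    pathway_csv: str | None = None

    def __post_init__(self):
        if not (0 < self.fdr_alpha < 1):
            raise InvalidArgumentError("fdr_alpha must be in (0, 1)")
        for name in ("blank_ratio_threshold", "beta"):
            if not getattr(self, name) > 0:
                raise InvalidArgumentError(f"{name} must be positive")
        if not (0 < self.n_pcs_rule <= 1):
            raise InvalidArgumentError("n_pcs_rule must be in (0, 1]")
        if "simulate" in self.stages and self.n_modules * self.module_size > self.n_features:
            raise InvalidArgumentError(
                "n_modules * module_size must not exceed n_features"
            )
        unknown = set(self.stages) - set(STAGE_NAMES)
        if unknown:
            raise InvalidArgumentError(f"unknown stages: {sorted(unknown)}")
        need = {"enrich": "diff", "diff": "preprocess", "network": "preprocess",
                "multivar": "preprocess"}
        for stage, dep in need.items():
            if stage in self.stages and dep not in self.stages:
                raise InvalidArgumentError(
                    f"stage {stage!r} requires stage {dep!r} to be enabled"
                )
        if "preprocess" in self.stages and "simulate" not in self.stages:
            if not (self.table_tsv and self.cohort_csv):
                raise InvalidArgumentError(
                    "without the simulate stage, table_tsv and cohort_csv are required"
                )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["stages"] = list(self.stages)
        return d


def _config_hash(cfg: PipelineConfig) -> str:
    blob = json.dumps(cfg.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _logger(out: Path) -> logging.Logger:
    logger = logging.getLogger(f"thyromet.run.{out}")
    logger.setLevel(logging.INFO)
    logger.handlers.clear()
    fmt = logging.Formatter("%(asctime)s %(levelname)s %(message)s")
    for h in (logging.StreamHandler(sys.stderr), logging.FileHandler(out / "run.log")):
        h.setFormatter(fmt)
        logger.addHandler(h)
    logger.propagate = False
    return logger


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages in order; return the run manifest (also
    written to ``out_dir/manifest.json``)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log = _logger(out)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "config_hash": _config_hash(config),
        "stages": {},
    }
    rng_seed = int(config.seed)

    cohort = None
    table = None
    truth = None
    blanks = None
    pathway = None
    diff = None

    current = "setup"
    try:
        if "simulate" in config.stages:
            current = "simulate"
            cohort = generate_cohort(config.n_control, config.n_case, seed=rng_seed)
            modules = [(config.module_size, config.within_corr)] * config.n_modules
            effects = [(j, config.effect_size) for j in range(config.n_effects)]
            table, truth = generate_metabolome(
                cohort,
                config.n_features,
                modules=modules,
                effects=effects,
                seed=rng_seed + 1,
            )
            blanks, contaminated = generate_blank_profile(
                table, config.fraction_contaminated, seed=rng_seed + 2,
                threshold=config.blank_ratio_threshold,
            )
            write_cohort_csv(cohort, out / "cohort.csv")
            table.to_tsv(out / "metabolome_raw.tsv")
            blanks.to_csv(out / "blank_means.csv", float_format=FLOAT_FMT)
            truth.contaminated_features = contaminated
            truth.to_json(out / "truth.json")
            pathway = truth.pathway_label
            pathway.rename("pathway_group").to_csv(out / "pathways.csv")
            manifest["stages"]["simulate"] = {
                "samples": table.n_samples, "features": table.n_features,
            }
            log.info("simulate: %d samples x %d features", table.n_samples, table.n_features)
        else:
            cohort = read_cohort_csv(config.cohort_csv)
            table = FeatureTable.from_tsv(config.table_tsv, stage="raw")
            if config.blank_csv:
                blanks = pd.read_csv(config.blank_csv, index_col=0).iloc[:, 0]
            if config.pathway_csv:
                pw = pd.read_csv(config.pathway_csv, index_col=0)
                pathway = pw.iloc[:, 0]

        if "preprocess" in config.stages:
            current = "preprocess"
            if blanks is not None:
                table, report = blank_filter(
                    table, blanks, threshold=config.blank_ratio_threshold
                )
                report.to_csv(out / "blank_filter_report.csv")
            table = mtic_normalize(table, all_features=True)
            table = log_transform(table)
            table, flat = pareto_scale(table)
            table.to_tsv(out / "metabolome_pareto.tsv")
            manifest["stages"]["preprocess"] = {
                "samples": table.n_samples,
                "features": table.n_features,
                "zero_variance_features": len(flat),
            }
            log.info("preprocess: %d samples x %d features kept", table.n_samples,
                     table.n_features)

        if "edc" in config.stages:
            current = "edc"
            panel = default_panel()
            gm = {a: 4.0 * panel.loq[a] for a in panel.analytes}
            gs = {a: 3.0 for a in panel.analytes}
            meas, edc_truth = generate_edc(cohort, panel, gm, gs, seed=rng_seed + 3)
            meas = impute_below_loq(meas.drop(columns=["below_loq"]), panel)
            adjusted = creatinine_adjust(meas, cohort)
            sums = molar_sums(adjusted, panel)
            adjusted.to_csv(out / "edc_adjusted.csv", index=False, float_format=FLOAT_FMT)
            sums.to_csv(out / "edc_molar_sums.csv", float_format=FLOAT_FMT)
            manifest["stages"]["edc"] = {
                "samples": int(sums.shape[0]),
                "analytes": len(panel.analytes),
                "censored": int(meas["below_loq"].sum()),
            }
            log.info("edc: %d samples x %d analytes (%d censored draws)",
                     sums.shape[0], len(panel.analytes), int(meas["below_loq"].sum()))

        if "diff" in config.stages:
            current = "diff"
            diff = differential_analysis(
                table, cohort, alpha=config.fdr_alpha, monotone=config.bh_monotone
            )
            write_diff_csv(diff, out / "differential.csv")
            manifest["stages"]["diff"] = {
                "features": int(len(diff)),
                "significant": int(diff["significant"].sum()),
            }
            log.info("diff: %d features, %d significant at q < %g",
                     len(diff), int(diff["significant"].sum()), config.fdr_alpha)

        if "enrich" in config.stages:
            current = "enrich"
            if pathway is None:
                raise InvalidArgumentError("enrich stage needs pathway assignments")
            sig = pd.Series(
                diff["significant"].to_numpy(), index=diff["feature_id"]
            )
            pw = pathway.loc[sig.index]
            rows = fisher_enrichment(sig, pw, monotone=config.bh_monotone)
            write_enrichment_csv(rows, out / "enrichment.csv")
            manifest["stages"]["enrich"] = {"pathways": len(rows)}
            log.info("enrich: %d pathway tests", len(rows))

        if "network" in config.stages:
            current = "network"
            net = build_network(table, beta=config.beta, tau=config.tau)
            labels = cluster_modules(net.diss, k=config.k_modules)
            mods = eigenmetabolites(table, labels)
            assoc = module_outcome_association(mods, cohort)
            net.tom.to_csv(out / "tom.tsv", sep="\t", float_format=FLOAT_FMT)
            labels.rename("module").to_csv(out / "modules.csv")
            payload = {
                str(m.module): {
                    "pearson_r": m.pearson_r, "pearson_p": m.pearson_p,
                    "or": m.or_, "wald_chi2": m.wald_chi2, "wald_p": m.wald_p,
                    "ci95": list(m.ci95), "separated": m.separated,
                    "var_explained": mods.var_explained[m.module],
                    "eigenmetabolite": mods.eigenmetabolite[m.module].tolist(),
                }
                for m in assoc
            }
            (out / "module_associations.json").write_text(json.dumps(payload, indent=1))
            manifest["stages"]["network"] = {
                "features": int(net.r.shape[0]), "modules": int(labels.nunique()),
            }
            log.info("network: %d features -> %d modules", net.r.shape[0],
                     labels.nunique())

        if "multivar" in config.stages:
            current = "multivar"
            pc = pca(table)
            n_pcs = n_components_for_variance(pc, config.n_pcs_rule)
            clusters = cluster_loadings(pc, n_pcs, k=config.k_loading_clusters)
            r = feature_outcome_correlations(table, cohort)
            heat = heatmap_order(clusters, r)
            pls = plsda(table, cohort, n_lv=config.n_lv)
            pc.scores.to_csv(out / "pca_scores.csv", float_format=FLOAT_FMT)
            heat.to_csv(out / "heatmap_input.csv", index=False, float_format=FLOAT_FMT)
            pls.vip.to_csv(out / "vip.csv", float_format=FLOAT_FMT)
            manifest["stages"]["multivar"] = {
                "n_pcs_90": int(n_pcs),
                "loading_clusters": int(clusters.nunique()),
                "x_var_pct": [float(v) for v in pls.x_var_pct],
                "y_var_pct": [float(v) for v in pls.y_var_pct],
            }
            log.info("multivar: %d PCs reach %.0f%% variance; PLS-DA y-var %s",
                     n_pcs, 100 * config.n_pcs_rule,
                     np.round(pls.y_var_pct, 1).tolist())
    except Exception:
        log.error("stage %r failed; partial artifacts retained", current)
        partial = out / "manifest.json.partial"
        partial.write_text(json.dumps(manifest, indent=1))
        raise

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    log.info("run complete: %s", out / "manifest.json")
    return manifest


def packaged_table2_counts() -> pd.DataFrame:
    """The packaged nine-pathway count triples (sig, notsig per pathway)."""
    ref = resources.files("thyromet.data").joinpath("table2_counts.csv")
    with resources.as_file(ref) as path:
        return pd.read_csv(path)


def reproduce_table2(
    counts_csv: str | Path | None = None, monotone: bool = True
) -> list[EnrichmentRow]:
    """Recompute the pathway-enrichment table from printed count triples.

    ``counts_csv`` needs columns pathway, sig_count, notsig_count (nine rows);
    defaults to the packaged fixture.
    """
    df = pd.read_csv(counts_csv) if counts_csv is not None else packaged_table2_counts()
    if len(df) != 9:
        raise InvalidArgumentError(f"expected 9 pathway rows, got {len(df)}")
    counts = [
        (str(r.pathway), int(r.sig_count), int(r.notsig_count))
        for r in df.itertuples(index=False)
    ]
    return enrichment_from_counts(counts, monotone=monotone)
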