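"""End-to-end orchestration: simulate -> root-filter -> scan -> enrich -> report.

A single :class:`PipelineConfig` (YAML-serialisable) drives every stage; one
global seed deterministically derives independent per-stage seeds, so a rerun
with the same config is bit-identical.  Each stage writes its tables under
the output directory and contributes to ``summary.json``.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import biomarker, great, root_filter, scan, synthetic
from .io import (
    GenomicInterval,
    write_bed,
    write_genes,
    write_gmt,
    write_panel,
    write_variants_tsv,
    write_variants_vcf,
)

log = logging.getLogger("regionburden.pipeline")

STAGES = ("simulate", "root_filter", "window_scan", "enrichment", "biomarker")


class PipelineStageError(RuntimeError):
    """A stage failed; the message is tagged with the stage name."""


@dataclass
class PipelineConfig:
    seed: int = 0
    region: str = str(synthetic.DEFAULT_REGION)
    stages: dict = field(default_factory=lambda: {s: True for s in STAGES})

    # synthetic population
    n_common_sites: int = 400
    rare_site_rate: float = synthetic.DEFAULT_RARE_RATE
    cohort_size: int = 33
    control_size: int = 100
    enrichment_window: str | None = None  # e.g. "chr3:181409714-181449713"
    enrichment_fold: float = 5.0

    # islet call sets
    n_islets: int = 30
    root_variants: int = 750
    root_presence: float = 0.97
    private_rate: float = 25.0
    germline_variants: int = 200

    # window scan
    window_size: int = 40_000
    step: int = 100
    n_sim: int = 200
    n_control_subsets: int = 100
    max_samples: int = 5

    # domain enrichment
    n_genes: int = 40
    ontology_sizes: tuple = (5, 10, 15)
    n_perm: int = 2000

    # biomarker
    ihc_groups: dict = field(
        default_factory=lambda: {"benign": (3.0, 4.0, 40), "hgsoc": (14.0, 10.0, 40)}
    )
    power: float = 0.90
    alpha: float = 0.05

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        if "ihc_groups" in raw:
            cfg.ihc_groups = {k: tuple(v) for k, v in raw["ihc_groups"].items()}
        if "ontology_sizes" in raw:
            cfg.ontology_sizes = tuple(raw["ontology_sizes"])
        return cfg

    def to_yaml(self, path) -> None:
        raw = dataclasses.asdict(self)
        raw["ontology_sizes"] = list(self.ontology_sizes)
        raw["ihc_groups"] = {k: list(v) for k, v in self.ihc_groups.items()}
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=True)

    def genomic_region(self) -> GenomicInterval:
        return GenomicInterval.parse(self.region)


def _round_floats(obj, ndigits: int = 10):
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    if isinstance(obj, (np.floating,)):
        return round(float(obj), ndigits)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    return obj


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Execute enabled stages in dependency order; return the summary dict.

    Writes per-stage TSV/BED outputs, ``summary.json`` and ``pipeline.log``
    under ``outdir``.  A rerun with the same config and seed is bit-identical.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "pipeline.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)

    region = config.genomic_region()
    seeds = {name: s for name, s in zip(
        ("population", "islets", "genes", "ihc", "scan", "enrichment"),
        np.random.SeedSequence(config.seed).spawn(6),
    )}
    summary: dict = {"seed": config.seed, "region": str(region), "stages_run": []}
    data: dict = {}

    try:
        if config.stages.get("simulate", False):
            _stage_simulate(config, region, seeds, outdir, data, summary)
        if config.stages.get("root_filter", False):
            _stage_root_filter(config, outdir, data, summary)
        if config.stages.get("window_scan", False):
            _stage_window_scan(config, region, seeds, outdir, data, summary)
        if config.stages.get("enrichment", False):
            _stage_enrichment(config, seeds, outdir, data, summary)
        if config.stages.get("biomarker", False):
            _stage_biomarker(config, outdir, data, summary)
    finally:
        log.removeHandler(handler)
        handler.close()

    config.to_yaml(outdir / "config.yaml")
    with open(outdir / "summary.json", "w") as fh:
        json.dump(_round_floats(summary), fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary


def _require(data: dict, key: str, stage: str):
    if key not in data:
        raise PipelineStageError(
            f"[{stage}] missing input {key!r}: enable the simulate stage or provide it"
        )
    return data[key]


def _stage_simulate(config, region, seeds, outdir, data, summary):
    try:
        rng = np.random.default_rng(seeds["population"])
        common = synthetic.random_common_sites(region, config.n_common_sites, rng)
        enrichment = []
        if config.enrichment_window:
            enrichment = [(GenomicInterval.parse(config.enrichment_window), config.enrichment_fold)]
        model = synthetic.PopulationModel(
            region=region, common_sites=common, rare_site_rate=config.rare_site_rate,
            enrichment_windows=enrichment,
        )
        control_model = synthetic.PopulationModel(
            region=region, common_sites=common, rare_site_rate=config.rare_site_rate,
        )
        data["panel"] = model.panel()
        data["cancer"] = synthetic.simulate_rare_variant_cohort(model, config.cohort_size, rng)
        data["control"] = synthetic.simulate_rare_variant_cohort(control_model, config.control_size, rng)
        islet_model = synthetic.IsletModel(
            n_islets=config.n_islets, root_variants=config.root_variants,
            root_presence=config.root_presence, private_rate=config.private_rate,
            germline_variants=config.germline_variants, region=region,
        )
        data["islets"], data["normal"] = synthetic.simulate_islet_callsets(
            islet_model, np.random.default_rng(seeds["islets"])
        )
        genes, gene_sets = synthetic.simulate_gene_annotation(
            config.n_genes, region.length, list(config.ontology_sizes),
            np.random.default_rng(seeds["genes"]), chrom=region.chrom,
        )
        genes["tss"] = genes["tss"] + region.start - 1
        data["genes"], data["gene_sets"] = genes, gene_sets
        ihc_model = synthetic.IHCModel(groups=dict(config.ihc_groups))
        data["ihc"] = synthetic.simulate_ihc_scores(ihc_model, np.random.default_rng(seeds["ihc"]))

        write_panel(data["panel"], outdir / "panel.tsv")
        write_variants_tsv(data["cancer"], outdir / "cancer_cohort.tsv")
        write_variants_vcf(data["cancer"], outdir / "cancer_cohort.vcf")
        write_variants_tsv(data["control"], outdir / "control_cohort.tsv")
        islet_dir = outdir / "islets"
        islet_dir.mkdir(exist_ok=True)
        for j, table in enumerate(data["islets"]):
            write_variants_tsv(table, islet_dir / f"islet{j + 1:02d}.tsv")
        write_variants_tsv(data["normal"], outdir / "normal.tsv")
        write_genes(data["genes"], outdir / "genes.tsv")
        write_gmt(data["gene_sets"], outdir / "gene_sets.gmt")
        data["ihc"].to_csv(outdir / "ihc_scores.tsv", sep="\t", index=False)
        if enrichment:
            bed = pd.DataFrame(
                {"chrom": [w.chrom for w, _ in enrichment],
                 "start": [w.start for w, _ in enrichment],
                 "end": [w.end for w, _ in enrichment],
                 "name": [f"fold_{f:g}" for _, f in enrichment]}
            )
            write_bed(bed, outdir / "enrichment_windows.bed")
        summary["stages_run"].append("simulate")
        summary["simulate"] = {
            "n_common_sites": len(common),
            "n_cancer_variants": int(len(data["cancer"])),
            "n_control_variants": int(len(data["control"])),
            "n_islets": config.n_islets,
        }
        log.info("simulate: %d cancer carrier calls, %d control", len(data["cancer"]), len(data["control"]))
    except PipelineStageError:
        raise
    except Exception as exc:
        raise PipelineStageError(f"[simulate] {exc}") from exc


def _stage_root_filter(config, outdir, data, summary):
    try:
        islets = _require(data, "islets", "root_filter")
        normal = data.get("normal")
        ancestors = root_filter.identify_ancestor_variants(islets, normal)
        ancestors.to_csv(outdir / "ancestor_variants.tsv", sep="\t", index=False)
        data["ancestors"] = ancestors
        summary["stages_run"].append("root_filter")
        summary["root_filter"] = {
            "n_ancestor_variants": int(len(ancestors)),
            "threshold": root_filter.AncestorCallConfig().islet_presence_threshold,
        }
        log.info("root_filter: %d ancestor variants", len(ancestors))
    except PipelineStageError:
        raise
    except Exception as exc:
        raise PipelineStageError(f"[root_filter] {exc}") from exc


def _stage_window_scan(config, region, seeds, outdir, data, summary):
    try:
        cancer = _require(data, "cancer", "window_scan")
        panel = _require(data, "panel", "window_scan")
        scan_config = scan.WindowScanConfig(
            window_size=config.window_size, step=config.step, n_sim=config.n_sim,
            cohort_size=config.cohort_size, n_control_subsets=config.n_control_subsets,
        )
        filter_config = scan.RareVariantFilterConfig(max_samples=config.max_samples)
        model = scan.RegionalBurdenScan(
            cancer, region, panel, control_variants=data.get("control"),
            filter_config=filter_config, config=scan_config,
        )
        seed_int = int(np.random.default_rng(seeds["scan"]).integers(2**31))
        results = model.fit(seed=seed_int)
        results.frame.to_csv(outdir / "window_scan.tsv", sep="\t", index=False)
        results.to_bed(outdir / "top_windows.bed", n=10)
        (outdir / "window_scan_summary.txt").write_text(results.summary() + "\n")
        data["scan_results"] = results
        top = results.top_windows(5)
        summary["stages_run"].append("window_scan")
        summary["window_scan"] = {
            "n_windows": int(len(results.frame)),
            "n_rare_variants": int(results.n_rare),
            "top_windows": [
                {
                    "start": int(r.start), "end": int(r.end),
                    "observed": int(r.observed), "ratio": float(r.ratio),
                    "poisson_p": float(r.poisson_p),
                    **({"order_p": float(r.order_p)} if "order_p" in top.columns else {}),
                }
                for r in top.itertuples()
            ],
        }
        log.info("window_scan: %d windows, %d rare variants", len(results.frame), results.n_rare)
    except PipelineStageError:
        raise
    except Exception as exc:
        raise PipelineStageError(f"[window_scan] {exc}") from exc


def _stage_enrichment(config, seeds, outdir, data, summary):
    try:
        genes = _require(data, "genes", "enrichment")
        gene_sets = _require(data, "gene_sets", "enrichment")
        ancestors = _require(data, "ancestors", "enrichment")
        background = _require(data, "cancer", "enrichment")
        fg = ancestors[["chrom", "pos", "ref", "alt"]].copy()
        model = great.GreatEnrichment(fg, background, genes, gene_sets, n_perm=config.n_perm)
        seed_int = int(np.random.default_rng(seeds["enrichment"]).integers(2**31))
        results = model.fit(seed=seed_int)
        results.frame.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
        results.domains.to_csv(outdir / "regulatory_domains.tsv", sep="\t", index=False)
        summary["stages_run"].append("enrichment")
        summary["enrichment"] = {
            "n_gene_sets": len(gene_sets),
            "hits": results.hits["gene_set"].tolist(),
            "results": [
                {"gene_set": r.gene_set, "enrichment": None if pd.isna(r.enrichment) else float(r.enrichment),
                 "permutation_p": None if pd.isna(r.permutation_p) else float(r.permutation_p),
                 "q_value": None if pd.isna(r.q_value) else float(r.q_value)}
                for r in results.frame.itertuples()
            ],
        }
        log.info("enrichment: %d sets, %d hits", len(gene_sets), len(results.hits))
    except PipelineStageError:
        raise
    except Exception as exc:
        raise PipelineStageError(f"[enrichment] {exc}") from exc


def _stage_biomarker(config, outdir, data, summary):
    try:
        ihc = _require(data, "ihc", "biomarker")
        groups = list(config.ihc_groups)
        model = biomarker.IHCBiomarker(ihc, positive=groups[-1], negative=groups[0])
        results = model.fit()
        results.anova.tukey.to_csv(outdir / "tukey.tsv", sep="\t", index=False)
        results.logistic.roc.to_csv(outdir / "roc.tsv", sep="\t", index=False)
        (outdir / "biomarker_summary.txt").write_text(results.summary() + "\n")
        (m1, s1, _), (m2, s2, _) = config.ihc_groups[groups[0]], config.ihc_groups[groups[-1]]
        n_per_group = biomarker.sample_size_two_groups(m1, s1, m2, s2, config.power, config.alpha)
        summary["stages_run"].append("biomarker")
        summary["biomarker"] = {
            "anova_f": float(results.anova.f_statistic),
            "anova_p": float(results.anova.p_value),
            "auc": float(results.auc),
            "power_n_per_group": int(n_per_group),
        }
        log.info("biomarker: AUC %.3f, power n=%d", results.auc, n_per_group)
    except PipelineStageError:
        raise
    except Exception as exc:
        raise PipelineStageError(f"[biomarker] {exc}") from exc
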