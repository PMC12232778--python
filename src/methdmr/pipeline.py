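"""End-to-end orchestration: simulate -> qc -> regions -> test -> annotate ->
integrate -> go -> validate, from a single seeded configuration.

Every stage communicates through the standard-format files of
:mod:`methdmr.io_formats`; a JSON manifest records the configuration, seed
and per-stage counts. With a fixed seed the whole output directory is
byte-identical across runs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import annotate as annotate_mod
from . import diffmeth, go_cluster, integrate, qc, regions, validation
from .intervals import GenomicInterval
from .io_formats import (write_bed, write_expression, write_gene_models,
                         write_gmt, write_manifest, write_metadata,
                         write_methylation_calls, write_obo,
                         write_results_table)
from .synthetic import (SimulatedBundle, SimulationConfig,
                        simulate_clone_bisulfite, simulate_dataset,
                        simulate_haplotype_records)

COMPARISON_LABELS = ("TDP-A", "TDP-B", "TDP-C", "TDP-GRN", "TDP-C9",
                     "ABC", "TDP")


@dataclass
class RunConfig:
    """Thresholds and scope of one pipeline run (defaults follow the study:
    FDR 0.05, GO p 0.05, 25-term cluster limit, 4-term visualization floor,
    ±500 bp promoters, 500/250 bp windows, 5x coverage floor)."""

    seed: int = 0
    levels: tuple[str, ...] = ("cpg", "promoter", "window", "cluster")
    comparisons: tuple[str, ...] = COMPARISON_LABELS
    covariates: tuple[str, ...] = ("sex", "age")
    fdr_threshold: float = 0.05
    go_alpha: float = 0.05
    cluster_limit: int = 25
    min_viz: int = 4
    promoter_flank: int = 500
    window_width: int = 500
    window_step: int = 250
    min_coverage: int = 5
    cluster_min_cov: int = 5
    cluster_max_gap: int = 100
    cluster_min_cpgs: int = 3
    cluster_max_len: int = 500
    stratified_k: int = 10
    small: bool = True
    sim: SimulationConfig = field(default_factory=SimulationConfig)

    def __post_init__(self):
        for name in ("fdr_threshold", "go_alpha", "cluster_limit", "min_viz",
                     "promoter_flank", "window_width", "min_coverage"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def simulation_config(self) -> SimulationConfig:
        cfg = self.sim
        return cfg.small() if self.small else cfg

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim_raw = raw.pop("sim", None)
        cfg = cls(**{k: tuple(v) if isinstance(v, list) else v
                     for k, v in raw.items()})
        if sim_raw:
            cfg.sim = SimulationConfig(**sim_raw)
        return cfg


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Run every stage in dependency order; returns the manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "seed": config.seed,
                      "config": _config_dict(config), "stages": {}}

    # -- simulate ----------------------------------------------------------
    sim_cfg = config.simulation_config()
    bundle = simulate_dataset(sim_cfg, seed=config.seed)
    inputs = outdir / "inputs"
    write_bundle(bundle, inputs)
    manifest["stages"]["simulate"] = {
        "n_samples": len(bundle.callsets),
        "n_cpgs": int(sum(len(cs.calls) for cs in bundle.callsets)),
        "n_planted_dmrs": int(bundle.truth["is_planted_dmr"].sum()),
    }

    # -- qc ----------------------------------------------------------------
    report = qc.run_qc(bundle.callsets, bundle.metadata,
                       min_coverage=config.min_coverage)
    report.samples.to_csv(outdir / "qc_report.tsv", sep="\t", index=False,
                          float_format="%.6g")
    manifest["stages"]["qc"] = {
        "n_common_sites": len(report.sites),
        "n_flagged": int((report.samples["outlier_reasons"] != "").sum()),
        "sex_concordance": float(report.samples["sex_concordant"].mean()),
    }

    # -- regions + counts --------------------------------------------------
    chrom_lengths = sim_cfg.chrom_lengths
    locus_sets = {}
    for level in config.levels:
        if level == "cpg":
            ls = regions.cpg_sites(bundle.callsets)
        elif level == "promoter":
            ls = regions.make_promoters(bundle.gene_models,
                                        flank=config.promoter_flank,
                                        chrom_lengths=chrom_lengths)
        elif level == "window":
            ls = regions.tile_windows(chrom_lengths, bundle.callsets,
                                      width=config.window_width,
                                      step=config.window_step)
        elif level == "cluster":
            ls = regions.build_clusters(bundle.callsets,
                                        min_cov=config.cluster_min_cov,
                                        max_gap=config.cluster_max_gap,
                                        min_cpgs=config.cluster_min_cpgs,
                                        max_len=config.cluster_max_len)
        else:
            raise ValueError(f"unknown level {level!r}")
        locus_sets[level] = ls
    matrices = {lvl: regions.aggregate_counts(ls, bundle.callsets)
                for lvl, ls in locus_sets.items()}
    manifest["stages"]["regions"] = {
        lvl: len(ls.loci) for lvl, ls in locus_sets.items()}

    # -- differential methylation -----------------------------------------
    all_results = []
    for level in config.levels:
        matrix = matrices[level]
        for tissue in sim_cfg.tissues:
            for label in config.comparisons:
                design = diffmeth.DesignSpec.from_label(
                    label, tissue=tissue, covariates=config.covariates)
                res = diffmeth.run_comparison(matrix, bundle.metadata, design,
                                              level=level)
                if len(res):
                    res.insert(0, "tissue", tissue)
                    all_results.append(res)
    dm = (pd.concat(all_results, ignore_index=True) if all_results
          else diffmeth._empty_result())
    write_results_table(dm, outdir / "differential_methylation.tsv")
    significant = dm[dm["fdr"] < config.fdr_threshold].copy() if len(dm) else dm
    manifest["stages"]["test"] = {
        "n_tests": int(len(dm)),
        "n_significant": int(len(significant)),
    }

    # -- annotation --------------------------------------------------------
    sig_loci = sorted({(r.chrom, r.start, r.end)
                       for r in significant.itertuples(index=False)})
    loci = [GenomicInterval(c, s, e) for c, s, e in sig_loci]
    annotated = annotate_mod.annotate_loci(
        loci, bundle.gene_models, bundle.cgi, bundle.enhancers,
        bundle.variants, flank=config.promoter_flank)
    ann_rows = []
    for region in annotated:
        for gene, ctx in region.records:
            ann_rows.append({
                "chrom": region.locus.chrom, "start": region.locus.start,
                "end": region.locus.end, "gene": gene or "",
                "context": ctx, "in_cgi": region.in_cgi,
                "in_enhancer": region.in_enhancer,
                "overlaps_common_variant": region.overlaps_common_variant})
    ann = pd.DataFrame(ann_rows, columns=["chrom", "start", "end", "gene",
                                          "context", "in_cgi", "in_enhancer",
                                          "overlaps_common_variant"])
    ann.to_csv(outdir / "annotated_loci.tsv", sep="\t", index=False)
    manifest["stages"]["annotate"] = {"n_loci": len(loci),
                                      "n_records": len(ann)}

    # -- integration -------------------------------------------------------
    gene_dmrs: dict[str, list[GenomicInterval]] = {}
    locus_ann = {(r.chrom, r.start, r.end): r.gene
                 for r in ann.itertuples(index=False) if r.gene}
    region_levels = [lvl for lvl in config.levels if lvl != "cpg"]
    for r in significant.itertuples(index=False):
        if r.level not in region_levels:
            continue
        genes = locus_ann.get((r.chrom, r.start, r.end), "")
        for g in filter(None, genes.split(",")):
            gene_dmrs.setdefault(g, []).append(
                GenomicInterval(r.chrom, r.start, r.end))
    corr_rows = []
    patients = bundle.metadata[bundle.metadata["group"] != "CTRL"]
    patient_ids = set(patients["sample_id"])
    for gene in sorted(gene_dmrs):
        if gene not in bundle.expression.values.index:
            continue
        merged = integrate.merge_gene_dmrs(
            sorted(set(gene_dmrs[gene])))
        expr = bundle.expression.values.loc[gene]
        for md in merged:
            meth = _dmr_methylation_series(bundle, md.representative)
            for cohort, idx in (("all", meth.index),
                                ("patients_only",
                                 [s for s in meth.index if s in patient_ids])):
                sub = meth.loc[idx].dropna()
                if len(sub.index.intersection(expr.index)) < 3:
                    continue
                res = integrate.correlate_methylation_expression(
                    sub, expr, cohort=cohort, gene=gene,
                    dmr=md.representative)
                corr_rows.append({
                    "gene": gene, "dmr": md.representative.format_position(),
                    "dmr_union": md.union.format_position(),
                    "cohort": cohort, "pearson_r": res.pearson_r,
                    "p_value": res.p_value, "n": res.n, "reason": res.reason})
    corr = pd.DataFrame(corr_rows, columns=["gene", "dmr", "dmr_union",
                                            "cohort", "pearson_r", "p_value",
                                            "n", "reason"])
    corr.to_csv(outdir / "methylation_expression_correlation.tsv", sep="\t",
                index=False, float_format="%.6g")
    manifest["stages"]["integrate"] = {"n_gene_dmrs": len(gene_dmrs),
                                       "n_correlations": len(corr)}

    # -- GO enrichment + clustering ---------------------------------------
    universe = sorted({g for gs in bundle.annotation.values() for g in gs})
    results = {}
    for tissue in sim_cfg.tissues:
        for label in config.comparisons:
            sub = significant[(significant["group"] == label)
                              & (significant["tissue"] == tissue)] \
                if len(significant) else significant
            genes = set()
            for r in sub.itertuples(index=False):
                g = locus_ann.get((r.chrom, r.start, r.end), "")
                genes.update(filter(None, g.split(",")))
            genes &= set(universe)
            if genes:
                results[(label, tissue)] = go_cluster.enrich(
                    genes, bundle.annotation, universe,
                    alpha=config.go_alpha)
    selected = go_cluster.select_terms(results, alpha=config.go_alpha)
    clusters = go_cluster.gograph_clust(selected["term"], bundle.ontology,
                                        bundle.annotation,
                                        limit=config.cluster_limit)
    viz = go_cluster.export_clusters(clusters, selected,
                                     min_viz=config.min_viz)
    viz.to_csv(outdir / "go_clusters.tsv", sep="\t", index=False,
               float_format="%.6g")
    manifest["stages"]["go"] = {
        "n_selected_terms": int(len(selected)),
        "n_clusters": len(clusters),
        "max_cluster_size": max((c.size for c in clusters), default=0),
    }

    # -- validation --------------------------------------------------------
    val = _validation_stage(bundle, config, outdir)
    manifest["stages"]["validate"] = val

    write_manifest(manifest, outdir / "manifest.json")
    return manifest


def _dmr_methylation_series(bundle: SimulatedBundle,
                            region: GenomicInterval) -> pd.Series:
    vals = {}
    for cs in bundle.callsets:
        df = cs.calls
        sel = ((df["chrom"] == region.chrom) & (df["start"] >= region.start)
               & (df["start"] < region.end))
        tot = int((df.loc[sel, "n_meth"] + df.loc[sel, "n_unmeth"]).sum())
        vals[cs.sample_id] = (df.loc[sel, "n_meth"].sum() / tot
                              if tot else np.nan)
    return pd.Series(vals)


def _validation_stage(bundle: SimulatedBundle, config: RunConfig,
                      outdir: Path) -> dict:
    """Clone-bisulfite and long-read checks on the first planted DMR."""
    out = {}
    planted = [d for d in bundle.dmr_genes.values()]
    clone = simulate_clone_bisulfite(6, 45, 0.5, conversion_error=0.01,
                                     seed=config.seed)
    pct, lollipop = validation.clone_methylation_percent(clone)
    lollipop.to_csv(outdir / "clone_lollipop.tsv", sep="\t",
                    index_label="clone")
    conv = validation.conversion_qc(clone)
    out["clone_methylation_percent"] = round(pct, 4)
    out["clone_conversion_pass"] = int((conv["status"] == "pass").sum())
    if planted:
        dmr = planted[0]
        tissue = bundle.config.tissues[0]
        meta = bundle.metadata[
            (bundle.metadata["tissue"] == tissue)
            & bundle.metadata["group"].isin(dmr.groups + ("CTRL",))]
        records = simulate_haplotype_records(
            meta, dmr.region, baseline=0.5, delta=dmr.delta,
            case_groups=dmr.groups, seed=config.seed + 1)
        percpg = validation.ont_percpg_tests(records, meta, dmr.region,
                                             dmr.groups)
        percpg.to_csv(outdir / "ont_percpg_tests.tsv", sep="\t", index=False,
                      float_format="%.6g")
        fit = validation.ont_region_test(records, meta, dmr.region,
                                         dmr.groups)
        out["ont_region_logFC"] = round(fit.logFC, 4)
        out["ont_region_p"] = float(f"{fit.p_value:.4g}")
        out["ont_n_significant_cpgs"] = int(
            (percpg["p_value"] < 0.05).sum())
    return out


def write_bundle(bundle: SimulatedBundle, outdir) -> None:
    """Emit every standard-format file of a simulated bundle."""
    outdir = Path(outdir)
    calls_dir = outdir / "calls"
    calls_dir.mkdir(parents=True, exist_ok=True)
    for cs in bundle.callsets:
        write_methylation_calls(cs, calls_dir / f"{cs.sample_id}.bedGraph")
    write_metadata(bundle.metadata, outdir / "metadata.tsv")
    write_gene_models(bundle.gene_models, outdir / "genes.bed12")
    write_bed(bundle.cgi, outdir / "cgi.bed")
    write_bed(bundle.enhancers, outdir / "enhancers.bed")
    write_bed(bundle.variants, outdir / "variants.bed")
    write_expression(bundle.expression, outdir / "expression.tsv",
                     outdir / "expression_counts.tsv")
    write_obo(bundle.ontology, outdir / "ontology.obo")
    write_gmt(bundle.annotation, outdir / "annotation.gmt")
    bundle.truth.to_csv(outdir / "truth.tsv", sep="\t", index=False,
                        float_format="%.6g")


def _config_dict(config: RunConfig) -> dict:
    d = dataclasses.asdict(config)
    d["sim"] = {k: v for k, v in d["sim"].items()
                if not isinstance(v, (dict,))}
    return _jsonable(d)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
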