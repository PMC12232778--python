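"""Seeded synthetic datasets with the statistical structure the analysis
assumes, plus ground-truth tables.

The generator emulates the cohort design of the study the pipeline targets:
five patient groups of 25 subjects plus 42 controls, paired frontal-cortex
and cerebellum tissue, per-CpG bisulfite counts with negative-binomial
coverage and beta-binomial biological overdispersion, a bimodal methylation
landscape (hypomethylated CpG islands over a hypermethylated background),
planted group-specific DMRs with logit-scale effects, sex effects on chrX,
age slopes on a subset of loci, toy gene models and regulatory features, an
expression matrix linked to planted DMRs, and a toy GO DAG with gene
annotations. A TruthTable records every planted effect for downstream
recovery tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np
import pandas as pd

from .intervals import GenomicInterval
from .io_formats import ExpressionMatrix, GeneModel, MethylationCallSet
from .validation import CloneCallTable

#: Group sizes, % female, and age ranges bracketing the study demographics.
GROUP_SIZES = {"TDP-A": 25, "TDP-B": 25, "TDP-C": 25,
               "TDP-GRN": 25, "TDP-C9": 25, "CTRL": 42}
FEMALE_FRACTION = {"TDP-A": 0.52, "TDP-B": 0.48, "TDP-C": 0.40,
                   "TDP-GRN": 0.56, "TDP-C9": 0.44, "CTRL": 0.643}
AGE_RANGE = {"TDP-A": (79, 87), "TDP-B": (60, 72), "TDP-C": (68, 78),
             "TDP-GRN": (64, 76), "TDP-C9": (61, 80), "CTRL": (79, 90)}

DEFAULT_CHROM_LENGTHS = {"chr1": 1_000_000, "chr2": 1_000_000,
                         "chr3": 1_000_000, "chrX": 1_000_000,
                         "chrY": 500_000}
DEFAULT_CPGS = {"chr1": 300, "chr2": 300, "chr3": 300,
                "chrX": 120, "chrY": 40}


@dataclass(frozen=True)
class PlantedDMR:
    """One planted differential region: a logit-scale shift ``delta`` in the
    affected group(s) and tissue(s)."""

    region: GenomicInterval
    groups: tuple[str, ...]
    delta: float
    tissues: tuple[str, ...] = ("FCX", "CER")


@dataclass
class SimulationConfig:
    """All knobs of the generator; the defaults are the emulated study
    conditions (sample sizes per the published demographics table, coverage
    ~20x, overdispersion 0.02, hypomethylated islands over a hypermethylated
    background)."""

    chrom_lengths: dict = field(default_factory=lambda: dict(DEFAULT_CHROM_LENGTHS))
    n_cpgs: dict = field(default_factory=lambda: dict(DEFAULT_CPGS))
    group_sizes: dict = field(default_factory=lambda: dict(GROUP_SIZES))
    tissues: tuple[str, ...] = ("FCX", "CER")
    island_fraction: float = 0.2
    island_beta: tuple[float, float] = (2.0, 18.0)
    background_beta: tuple[float, float] = (17.0, 3.0)
    coverage_mean: float = 20.0
    coverage_dispersion: float = 5.0
    phi: float = 0.02
    planted_dmrs: list[PlantedDMR] | None = None
    n_auto_dmrs: int = 12
    dmr_n_cpgs: int = 8
    dmr_delta: float = 2.0
    sex_effect: float = 0.5
    age_slope: float = 0.02
    age_effect_fraction: float = 0.1
    n_background_genes: int = 30
    expression_slope: float = -4.0
    expression_noise: float = 0.5
    expression_baseline: float = 8.0
    n_go_terms: int = 60
    seed: int = 0

    def validate(self) -> None:
        for name, val in (("island_fraction", self.island_fraction),
                          ("age_effect_fraction", self.age_effect_fraction)):
            if not 0.0 <= val <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if not 0.0 <= self.phi < 1.0:
            raise ValueError("phi must lie in [0, 1)")
        if self.planted_dmrs:
            for dmr in self.planted_dmrs:
                length = self.chrom_lengths.get(dmr.region.chrom)
                if length is None or dmr.region.end > length:
                    raise ValueError(
                        f"planted DMR {dmr.region} outside simulated genome")
                unknown = set(dmr.groups) - set(self.group_sizes)
                if unknown:
                    raise ValueError(f"unknown DMR groups {sorted(unknown)}")

    def small(self) -> "SimulationConfig":
        """A reduced variant for smoke runs: 1 tissue, 6-8 per group."""
        return replace(
            self,
            group_sizes={g: (8 if g == "CTRL" else 6)
                         for g in self.group_sizes},
            tissues=("FCX",),
            n_cpgs={c: max(20, n // 3) for c, n in self.n_cpgs.items()},
            n_auto_dmrs=4,
            n_go_terms=30,
            n_background_genes=12,
        )


@dataclass
class SimulatedBundle:
    """Everything one pipeline run consumes, plus the ground truth."""

    config: SimulationConfig
    callsets: list[MethylationCallSet]
    metadata: pd.DataFrame
    gene_models: list[GeneModel]
    cgi: list[GenomicInterval]
    enhancers: list[GenomicInterval]
    variants: list[GenomicInterval]
    expression: ExpressionMatrix
    ontology: nx.MultiDiGraph
    annotation: dict[str, set[str]]
    truth: pd.DataFrame
    dmr_genes: dict[str, PlantedDMR]


def beta_binomial(rng: np.random.Generator, n: np.ndarray, p: np.ndarray,
                  phi: float) -> np.ndarray:
    """Draw counts with mean ``n*p`` and beta-binomial overdispersion.

    The mixing Beta has shape (p(1-phi)/phi, (1-p)(1-phi)/phi); phi = 0
    degenerates to the plain binomial.
    """
    p = np.clip(p, 1e-9, 1 - 1e-9)
    if phi <= 0.0:
        return rng.binomial(n.astype(np.int64), p)
    a = (1.0 - phi) / phi
    mix = rng.beta(p * a, (1.0 - p) * a)
    return rng.binomial(n.astype(np.int64), mix)


def _logit(x):
    return np.log(x / (1.0 - x))


def _draw_metadata(config: SimulationConfig,
                   rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    for group in sorted(config.group_sizes):
        n = config.group_sizes[group]
        lo, hi = AGE_RANGE.get(group, (60, 90))
        f_frac = FEMALE_FRACTION.get(group, 0.5)
        for i in range(n):
            subject = f"{group}-{i + 1:03d}"
            sex = "F" if rng.random() < f_frac else "M"
            age = float(np.round(rng.uniform(lo, hi), 1))
            for tissue in config.tissues:
                rows.append({"sample_id": f"{subject}_{tissue}",
                             "subject": subject, "group": group,
                             "sex": sex, "age_at_death": age,
                             "tissue": tissue})
    return pd.DataFrame(rows)


def _draw_sites(config: SimulationConfig, rng: np.random.Generator):
    """CpG positions, island intervals, and per-CpG baselines.

    CpGs come in dense clumps (4-12 sites, 5-60 bp apart), mirroring the
    enzyme-enriched site distribution of reduced-representation libraries;
    a fraction of clumps are CpG islands with hypomethylated baselines over
    the hypermethylated background.
    """
    positions: dict[str, np.ndarray] = {}
    islands: list[GenomicInterval] = []
    baseline: dict[str, np.ndarray] = {}
    is_island: dict[str, np.ndarray] = {}
    ia, ib = config.island_beta
    ba, bb = config.background_beta
    for chrom in sorted(config.chrom_lengths):
        n = config.n_cpgs.get(chrom, 0)
        length = config.chrom_lengths[chrom]
        pos_list: list[int] = []
        flag_list: list[bool] = []
        while len(pos_list) < n:
            size = int(rng.integers(4, 13))
            anchor = int(rng.integers(100, length - 2000))
            gaps = rng.integers(5, 61, size=size)
            clump = anchor + np.cumsum(gaps)
            island = bool(rng.random() < config.island_fraction)
            pos_list.extend(int(p) for p in clump)
            flag_list.extend([island] * size)
        order = np.argsort(pos_list, kind="stable")[:]
        pos = np.asarray(pos_list)[order][:n]
        flags = np.asarray(flag_list)[order][:n]
        pos, uniq_idx = np.unique(pos, return_index=True)
        flags = flags[uniq_idx]
        positions[chrom] = pos
        idx = np.where(flags)[0]
        if idx.size:
            breaks = np.where(np.diff(idx) > 1)[0]
            for seg in np.split(idx, breaks + 1):
                islands.append(GenomicInterval(chrom, int(pos[seg[0]]) - 10,
                                               int(pos[seg[-1]]) + 11))
        m = len(pos)
        b = np.where(flags, rng.beta(ia, ib, size=m),
                     rng.beta(ba, bb, size=m))
        baseline[chrom] = np.clip(b, 0.01, 0.99)
        is_island[chrom] = flags
    return positions, islands, baseline, is_island


def _auto_plant_dmrs(config: SimulationConfig, positions, rng) -> list[PlantedDMR]:
    """Place ``n_auto_dmrs`` regions of ``dmr_n_cpgs`` consecutive CpGs on
    the autosomes, cycling through the patient groups, alternating sign."""
    groups = [g for g in sorted(config.group_sizes) if g != "CTRL"]
    autosomes = [c for c in sorted(positions)
                 if c not in ("chrX", "chrY") and len(positions[c])]
    dmrs = []
    used: dict[str, set[int]] = {c: set() for c in autosomes}
    k = config.dmr_n_cpgs
    for i in range(config.n_auto_dmrs):
        chrom = autosomes[i % len(autosomes)]
        pos = positions[chrom]
        for _ in range(500):
            start_idx = int(rng.integers(0, len(pos) - k))
            span = set(range(start_idx, start_idx + k))
            compact = pos[start_idx + k - 1] - pos[start_idx] <= 450
            if compact and not span & used[chrom]:
                used[chrom].update(span)
                break
        else:
            continue
        region = GenomicInterval(chrom, int(pos[start_idx]),
                                 int(pos[start_idx + k - 1]) + 1)
        delta = config.dmr_delta * (1 if i % 2 == 0 else -1)
        dmrs.append(PlantedDMR(region, (groups[i % len(groups)],), delta))
    return dmrs


def _toy_gene_models(config: SimulationConfig, dmrs: list[PlantedDMR],
                     rng) -> tuple[list[GeneModel], dict[str, PlantedDMR]]:
    """Toy transcripts: one promoter-anchored gene per planted DMR (so the
    DMR annotates to it) plus background genes tiling the autosomes."""
    models = []
    dmr_genes: dict[str, PlantedDMR] = {}
    for i, dmr in enumerate(dmrs):
        gid = f"DMRG{i + 1:03d}"
        tss = dmr.region.start + dmr.region.width // 2
        exon1 = GenomicInterval(dmr.region.chrom, tss, tss + 400)
        exon2 = GenomicInterval(dmr.region.chrom, tss + 1000, tss + 1600)
        models.append(GeneModel(gid, f"{gid}.1", dmr.region.chrom, "+",
                                [exon1, exon2], tss + 150, tss + 1400))
        dmr_genes[gid] = dmr
    autosomes = [c for c in sorted(config.chrom_lengths)
                 if c not in ("chrX", "chrY")]
    for j in range(config.n_background_genes):
        chrom = autosomes[j % len(autosomes)]
        length = config.chrom_lengths[chrom]
        tss = int(rng.integers(5_000, length - 5_000))
        strand = "+" if rng.random() < 0.5 else "-"
        exons = [GenomicInterval(chrom, tss, tss + 300),
                 GenomicInterval(chrom, tss + 800, tss + 1200),
                 GenomicInterval(chrom, tss + 1900, tss + 2400)]
        if strand == "-":
            end = tss  # re-anchor so the TSS sits at the right edge
            exons = [GenomicInterval(chrom, end - 2400, end - 1900, strand),
                     GenomicInterval(chrom, end - 1200, end - 800, strand),
                     GenomicInterval(chrom, end - 300, end, strand)]
        else:
            exons = [GenomicInterval(chrom, e.start, e.end, strand)
                     for e in exons]
        gid = f"BG{j + 1:03d}"
        cds_lo = exons[0].start + 100
        cds_hi = exons[-1].end - 100
        models.append(GeneModel(gid, f"{gid}.1", chrom, strand, exons,
                                cds_lo, cds_hi))
    return models, dmr_genes


def _toy_ontology(config: SimulationConfig, genes: list[str], rng):
    """Random DAG: each term attaches to one or two earlier terms; leaf
    terms get random gene sets, propagated to ancestors (true-path rule)."""
    graph = nx.MultiDiGraph()
    terms = [f"GO:{i + 1:07d}" for i in range(config.n_go_terms)]
    root = terms[0]
    graph.add_node(root, name="root", namespace="biological_process")
    for i, term in enumerate(terms[1:], start=1):
        graph.add_node(term, name=f"term {i}",
                       namespace="biological_process")
        parent = terms[int(rng.integers(0, i))]
        graph.add_edge(term, parent, key="is_a")
        if i > 3 and rng.random() < 0.25:
            extra = terms[int(rng.integers(0, i))]
            if extra != parent and not graph.has_edge(term, extra, "is_a"):
                graph.add_edge(term, extra, key="part_of")
    annotation: dict[str, set[str]] = {t: set() for t in terms}
    gene_arr = np.array(genes)
    dmr_genes = np.array([g for g in genes if g.startswith("DMRG")])
    for i, term in enumerate(terms[1:], start=1):
        size = int(rng.integers(1, max(2, len(genes) // 6)))
        chosen = rng.choice(gene_arr, size=size, replace=False)
        annotation[term].update(chosen.tolist())
        # a subset of terms concentrates the DMR-linked genes so planted
        # effects propagate into the enrichment stage
        if i % 5 == 0 and len(dmr_genes) >= 2:
            extra = rng.choice(dmr_genes,
                               size=int(rng.integers(2, len(dmr_genes) + 1)),
                               replace=False)
            annotation[term].update(extra.tolist())
    for term in terms[::-1]:  # children were added after parents
        for parent in graph.successors(term):
            annotation[parent] |= annotation[term]
    return graph, annotation


def simulate_dataset(config: SimulationConfig | None = None,
                     seed: int | None = None) -> SimulatedBundle:
    """Generate a complete seeded dataset bundle.

    With a fixed seed the output is byte-identical across runs. See the
    module docstring for the generative model.
    """
    config = config or SimulationConfig()
    config.validate()
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)

    meta = _draw_metadata(config, rng)
    positions, islands, baseline, _ = _draw_sites(config, rng)
    dmrs = config.planted_dmrs
    if dmrs is None:
        dmrs = _auto_plant_dmrs(config, positions, rng)
    # per-chrom planted annotations; DMR member CpGs share one mid-range
    # baseline so the region-level pooled shift equals the planted delta
    delta_map: dict[str, np.ndarray] = {
        c: np.zeros(len(p)) for c, p in positions.items()}
    dmr_index: dict[str, np.ndarray] = {
        c: np.full(len(p), -1, dtype=int) for c, p in positions.items()}
    for d_i, dmr in enumerate(dmrs):
        c = dmr.region.chrom
        sel = ((positions[c] >= dmr.region.start)
               & (positions[c] < dmr.region.end))
        baseline[c][sel] = rng.uniform(0.3, 0.7)
        delta_map[c][sel] = dmr.delta
        dmr_index[c][sel] = d_i
    age_set: dict[str, np.ndarray] = {}
    for c, p in positions.items():
        age_set[c] = rng.random(len(p)) < config.age_effect_fraction

    nb_size = config.coverage_dispersion
    nb_p = nb_size / (nb_size + config.coverage_mean)
    callsets = []
    group_of = dict(zip(meta["sample_id"], meta["group"]))
    for row in meta.itertuples(index=False):
        frames = []
        male = row.sex == "M"
        for chrom in sorted(positions):
            pos = positions[chrom]
            if len(pos) == 0:
                continue
            if chrom == "chrY" and not male:
                continue  # females carry no chrY coverage
            cov = rng.negative_binomial(nb_size, nb_p, size=len(pos))
            if chrom == "chrX" and male:
                cov = rng.binomial(cov, 0.5)  # one X
            eta = _logit(baseline[chrom]).copy()
            d_idx = dmr_index[chrom]
            for d_i in np.unique(d_idx[d_idx >= 0]):
                dmr = dmrs[d_i]
                if row.group in dmr.groups and row.tissue in dmr.tissues:
                    eta[d_idx == d_i] += dmr.delta
            if chrom == "chrX" and male:
                eta += config.sex_effect
            eta = np.where(age_set[chrom],
                           eta + config.age_slope * (row.age_at_death - 75.0),
                           eta)
            p = 1.0 / (1.0 + np.exp(-eta))
            k = beta_binomial(rng, cov, p, config.phi)
            keep = cov >= 1
            frames.append(pd.DataFrame({
                "chrom": chrom, "start": pos[keep], "end": pos[keep] + 1,
                "n_meth": k[keep], "n_unmeth": (cov - k)[keep]}))
        calls = (pd.concat(frames, ignore_index=True) if frames
                 else pd.DataFrame(columns=["chrom", "start", "end",
                                            "n_meth", "n_unmeth"]))
        callsets.append(MethylationCallSet(row.sample_id, calls))

    gene_models, dmr_genes = _toy_gene_models(config, dmrs, rng)

    # regulatory features and common variants
    enhancers = []
    variants = []
    for chrom in sorted(positions):
        pos = positions[chrom]
        if len(pos) == 0:
            continue
        for _ in range(max(1, len(pos) // 60)):
            s = int(rng.choice(pos))
            enhancers.append(GenomicInterval(chrom, max(0, s - 200), s + 200))
        var_idx = rng.random(len(pos)) < 0.05
        for s in pos[var_idx]:
            variants.append(GenomicInterval(chrom, int(s), int(s) + 1))
    enhancers.sort()
    variants.sort()

    # expression linked to planted DMRs through per-sample DMR methylation
    sample_ids = meta["sample_id"].tolist()
    expr_rows = {}
    count_rows = {}
    meth_by_sample = {cs.sample_id: cs for cs in callsets}
    for m in gene_models:
        gid = m.gene_id
        base = config.expression_baseline + rng.normal(0.0, 1.0)
        noise = rng.normal(0.0, config.expression_noise, size=len(sample_ids))
        if gid in dmr_genes:
            dmr = dmr_genes[gid]
            mm = np.array([_region_methylation(meth_by_sample[s], dmr.region)
                           for s in sample_ids])
            mm = np.where(np.isfinite(mm), mm, 0.5)
            vals = base + config.expression_slope * mm + noise
        else:
            vals = base + noise
        expr_rows[gid] = np.maximum(vals, 0.0)
        lam = 60.0 if rng.random() > 0.15 else 4.0  # some low-support genes
        count_rows[gid] = rng.poisson(lam, size=len(sample_ids))
    values = pd.DataFrame(expr_rows, index=sample_ids).T
    counts = pd.DataFrame(count_rows, index=sample_ids).T
    expression = ExpressionMatrix(values, counts)

    ontology, annotation = _toy_ontology(
        config, [m.gene_id for m in gene_models], rng)

    truth_rows = []
    for chrom in sorted(positions):
        pos = positions[chrom]
        for j, p in enumerate(pos):
            d_i = dmr_index[chrom][j]
            planted = d_i >= 0
            truth_rows.append({
                "chrom": chrom, "pos": int(p),
                "is_planted_dmr": bool(planted),
                "groups": ",".join(dmrs[d_i].groups) if planted else "",
                "delta": float(delta_map[chrom][j]),
                "baseline": float(baseline[chrom][j]),
                "age_effect": bool(age_set[chrom][j]),
            })
    truth = pd.DataFrame(truth_rows)

    return SimulatedBundle(config, callsets, meta, gene_models, islands,
                           enhancers, variants, expression, ontology,
                           annotation, truth, dmr_genes)


def _region_methylation(callset: MethylationCallSet,
                        region: GenomicInterval) -> float:
    df = callset.calls
    sel = ((df["chrom"] == region.chrom) & (df["start"] >= region.start)
           & (df["start"] < region.end))
    tot = (df.loc[sel, "n_meth"] + df.loc[sel, "n_unmeth"]).sum()
    if tot == 0:
        return float("nan")
    return float(df.loc[sel, "n_meth"].sum() / tot)


def simulate_count_matrix(n_loci: int, n_case: int = 20, n_ctrl: int = 20,
                          coverage_mean: float = 20.0,
                          coverage_dispersion: float = 5.0,
                          phi: float = 0.02, delta: float = 0.0,
                          planted_fraction: float = 0.0,
                          n_cpgs_per_locus: int = 1,
                          baseline_range: tuple[float, float] = (0.3, 0.7),
                          bimodal_baseline: bool = True,
                          sex_effect: float = 0.5, sex_fraction: float = 0.1,
                          age_slope: float = 0.02, age_fraction: float = 0.1,
                          seed: int = 0):
    """Direct loci x samples count matrix for calibration and recovery runs.

    Returns ``(matrix, meta, true_delta)`` where ``matrix`` is a
    RegionCountMatrix of ``n_loci`` synthetic loci over a two-arm cohort,
    ``meta`` carries group/sex/age columns, and ``true_delta`` is the
    per-locus planted logit shift (0 for null loci). Null loci draw
    baselines from the bimodal island/background mixture (or uniformly over
    ``baseline_range``); planted loci always draw mid-range baselines. Sex
    and age effects act on random locus subsets, so covariate adjustment is
    exercised even under the null.
    """
    from .regions import RegionCountMatrix  # local import avoids a cycle

    rng = np.random.default_rng(seed)
    n_samples = n_case + n_ctrl
    case = np.zeros(n_samples, dtype=bool)
    case[:n_case] = True
    sex = rng.random(n_samples) < 0.5
    age = rng.uniform(55.0, 95.0, size=n_samples)
    groups = np.where(case, "CASE", "CTRL")
    sample_ids = [f"s{i:03d}" for i in range(n_samples)]
    meta = pd.DataFrame({"sample_id": sample_ids, "group": groups,
                         "sex": np.where(sex, "M", "F"),
                         "age_at_death": np.round(age, 1),
                         "tissue": "FCX"})

    planted = rng.random(n_loci) < planted_fraction
    signs = np.where(rng.random(n_loci) < 0.5, 1.0, -1.0)
    true_delta = np.where(planted, delta * signs, 0.0)
    if bimodal_baseline:
        island = rng.random(n_loci) < 0.2
        base = np.where(island, rng.beta(2, 18, n_loci),
                        rng.beta(17, 3, n_loci))
        base = np.clip(base, 0.02, 0.98)
    else:
        base = rng.uniform(*baseline_range, size=n_loci)
    base = np.where(planted, rng.uniform(0.3, 0.7, size=n_loci), base)
    sex_set = rng.random(n_loci) < sex_fraction
    age_set = rng.random(n_loci) < age_fraction

    eta = (_logit(base)[:, None]
           + true_delta[:, None] * case[None, :]
           + sex_effect * sex_set[:, None] * sex[None, :]
           + age_slope * age_set[:, None] * (age - 75.0)[None, :])
    p = 1.0 / (1.0 + np.exp(-eta))
    nb_size = coverage_dispersion
    nb_p = nb_size / (nb_size + coverage_mean)
    K = np.zeros((n_loci, n_samples), dtype=np.int64)
    N = np.zeros_like(K)
    for _ in range(n_cpgs_per_locus):
        cov = rng.negative_binomial(nb_size, nb_p, size=(n_loci, n_samples))
        K += beta_binomial(rng, cov, p, phi)
        N += cov
    loci = [GenomicInterval("chrS", 1000 * i, 1000 * i + 1)
            for i in range(n_loci)]
    matrix = RegionCountMatrix(
        loci=loci,
        meth=pd.DataFrame(K, columns=sample_ids),
        total=pd.DataFrame(N, columns=sample_ids),
        n_cpgs=np.full(n_loci, n_cpgs_per_locus),
        level="window" if n_cpgs_per_locus > 1 else "cpg")
    return matrix, meta, true_delta


# ---------------------------------------------------------------------------
# Clone bisulfite and haplotype simulators
# ---------------------------------------------------------------------------


def simulate_clone_bisulfite(n_clones: int, n_cpgs: int, true_pattern,
                             conversion_error: float = 0.0,
                             n_noncpg: int = 20, seed: int = 0,
                             sample_id: str = "sample") -> CloneCallTable:
    """Per-clone binary CpG calls plus non-CpG conversion outcomes.

    ``true_pattern`` gives per-CpG methylation probabilities (a scalar
    broadcasts). A failed conversion (probability ``conversion_error``)
    reads an unmethylated cytosine as methylated; the same error rate
    drives the non-CpG cytosine QC tally.
    """
    pattern = np.broadcast_to(np.asarray(true_pattern, dtype=float),
                              (n_cpgs,))
    if ((pattern < 0) | (pattern > 1)).any():
        raise ValueError("pattern probabilities must lie in [0, 1]")
    if not 0.0 <= conversion_error <= 1.0:
        raise ValueError("conversion_error must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    truly = rng.random((n_clones, n_cpgs)) < pattern
    failed = rng.random((n_clones, n_cpgs)) < conversion_error
    calls = (truly | failed).astype(float)
    positions = [f"CpG_{i + 1}" for i in range(n_cpgs)]
    clones = [f"clone_{i + 1}" for i in range(n_clones)]
    call_df = pd.DataFrame(calls, index=clones, columns=positions)
    unconverted = rng.binomial(n_noncpg, conversion_error, size=n_clones)
    conv = pd.DataFrame({"clone": clones,
                         "converted": n_noncpg - unconverted,
                         "unconverted": unconverted})
    return CloneCallTable(sample_id, call_df, conv)


def simulate_haplotype_records(meta: pd.DataFrame, region: GenomicInterval,
                               n_cpgs: int = 10, baseline: float = 0.5,
                               delta: float = 0.0,
                               case_groups: tuple[str, ...] = ("TDP-A",),
                               coverage_mean: float = 20.0,
                               phi: float = 0.02,
                               seed: int = 0) -> pd.DataFrame:
    """Per-haplotype (n_mod, n_total) count tables for a target region,
    emulating phased long-read methylation extraction."""
    rng = np.random.default_rng(seed)
    pos = np.sort(rng.choice(np.arange(region.start, region.end),
                             size=min(n_cpgs, region.width), replace=False))
    rows = []
    eta0 = math.log(baseline / (1.0 - baseline))
    for row in meta.itertuples(index=False):
        shift = delta if row.group in case_groups else 0.0
        p = 1.0 / (1.0 + math.exp(-(eta0 + shift)))
        for hap in (1, 2):
            cov = rng.poisson(coverage_mean / 2.0, size=len(pos)) + 1
            k = beta_binomial(rng, cov, np.full(len(pos), p), phi)
            for pp, cc, kk in zip(pos, cov, k):
                rows.append({"sample_id": row.sample_id, "haplotype": hap,
                             "chrom": region.chrom, "pos": int(pp),
                             "n_mod": int(kk), "n_total": int(cc)})
    return pd.DataFrame(rows)
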