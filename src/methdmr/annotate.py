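"""Genomic-context annotation of significant loci.

Each locus is resolved against gene models under a fixed priority
hierarchy — promoter > 5'-UTR > 3'-UTR > CDS > exon > intron > intergenic —
with CDS/exon/intron collapsed to "gene body" only after per-gene priority
resolution. If several transcripts of one gene overlap, the single
highest-priority context is retained; across genes, one record is kept when
all genes yield the same final context, otherwise one record per gene.
Loci are additionally flagged for >= 1 bp overlap with CpG islands,
enhancers, and common-variant positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from intervaltree import IntervalTree

from .intervals import GenomicInterval
from .io_formats import GeneModel

#: Raw contexts in priority order (lower index wins).
RAW_PRIORITY = ("promoter", "5utr", "3utr", "cds", "exon", "intron",
                "intergenic")
_RANK = {c: i for i, c in enumerate(RAW_PRIORITY)}

#: Final labels after the gene-body merge.
FINAL_LABELS = ("promoter", "5utr", "3utr", "gene_body", "intergenic")

_GENE_BODY = {"cds", "exon", "intron"}


def resolve_priority(contexts: Iterable[str]) -> str:
    """Highest-priority raw context among those observed (total order)."""
    best = "intergenic"
    for c in contexts:
        if _RANK[c] < _RANK[best]:
            best = c
    return best


def merge_gene_body(context: str) -> str:
    """Collapse CDS/exon/intron to gene_body (applied after resolution)."""
    return "gene_body" if context in _GENE_BODY else context


@dataclass
class AnnotatedRegion:
    """A locus with resolved per-gene context labels and feature flags."""

    locus: GenomicInterval
    records: list[tuple[str | None, str]]  # (gene_id or None, final context)
    in_cgi: bool = False
    in_enhancer: bool = False
    overlaps_common_variant: bool = False

    @property
    def contexts(self) -> list[str]:
        return [c for _, c in self.records]


def transcript_features(model: GeneModel,
                        flank: int = 500) -> list[tuple[GenomicInterval, str]]:
    """Raw-context feature intervals of one transcript.

    Promoter = ±flank of the TSS; UTRs are the exonic sequence strand-up/
    downstream of the CDS bounds; introns fill the gaps between exons;
    non-coding transcripts contribute exon/intron only.
    """
    chrom = model.chrom
    feats: list[tuple[GenomicInterval, str]] = []
    p_start = max(0, model.tss - flank)
    p_end = model.tss + flank
    if p_end > p_start:
        feats.append((GenomicInterval(chrom, p_start, p_end), "promoter"))
    for ex in model.exons:
        feats.append((ex, "exon"))
    for a, b in zip(model.exons, model.exons[1:]):
        if b.start > a.end:
            feats.append((GenomicInterval(chrom, a.end, b.start), "intron"))
    if model.is_coding:
        cs, ce = model.cds_start, model.cds_end
        left_label = "5utr" if model.strand != "-" else "3utr"
        right_label = "3utr" if model.strand != "-" else "5utr"
        for ex in model.exons:
            lo = max(ex.start, cs)
            hi = min(ex.end, ce)
            if hi > lo:
                feats.append((GenomicInterval(chrom, lo, hi), "cds"))
            if ex.start < cs:
                feats.append((GenomicInterval(chrom, ex.start,
                                              min(ex.end, cs)), left_label))
            if ex.end > ce:
                feats.append((GenomicInterval(chrom, max(ex.start, ce),
                                              ex.end), right_label))
    return feats


def transcript_context(locus: GenomicInterval, model: GeneModel,
                       flank: int = 500) -> str | None:
    """Highest-priority raw context of the locus on one transcript, or None
    when the locus misses the transcript (and its promoter) entirely."""
    hits = [label for iv, label in transcript_features(model, flank)
            if locus.overlaps(iv)]
    if not hits:
        return None
    return resolve_priority(hits)


def assign_context(locus: GenomicInterval, models: Sequence[GeneModel],
                   flank: int = 500) -> AnnotatedRegion:
    """Resolve a locus to final per-gene context records.

    Within a gene the highest-priority raw context across transcripts wins;
    the gene-body merge happens after resolution so an intron hit can never
    outrank a promoter hit. Across genes, identical final contexts collapse
    to a single record carrying all gene ids.
    """
    per_gene: dict[str, str] = {}
    for m in models:
        if m.chrom != locus.chrom:
            continue
        raw = transcript_context(locus, m, flank)
        if raw is None:
            continue
        prev = per_gene.get(m.gene_id)
        if prev is None or _RANK[raw] < _RANK[prev]:
            per_gene[m.gene_id] = raw
    if not per_gene:
        return AnnotatedRegion(locus, [(None, "intergenic")])
    final = {g: merge_gene_body(c) for g, c in per_gene.items()}
    contexts = set(final.values())
    if len(contexts) == 1:
        ctx = contexts.pop()
        genes = ",".join(sorted(final))
        return AnnotatedRegion(locus, [(genes, ctx)])
    records = [(g, final[g]) for g in sorted(final)]
    return AnnotatedRegion(locus, records)


# ---------------------------------------------------------------------------
# Feature-overlap flags
# ---------------------------------------------------------------------------


def _build_trees(intervals: Sequence[GenomicInterval]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for iv in intervals:
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end)
    return trees


def overlap_flags(locus: GenomicInterval,
                  cgi: Sequence[GenomicInterval] = (),
                  enhancers: Sequence[GenomicInterval] = (),
                  variants: Sequence[GenomicInterval] = (),
                  trees: dict | None = None) -> dict[str, bool]:
    """True iff the locus shares >= 1 bp with any interval of each set.

    Pass ``trees`` (from :func:`build_feature_trees`) to reuse indexes over
    many loci.
    """
    if trees is None:
        trees = build_feature_trees(cgi, enhancers, variants)
    out = {}
    for name in ("in_cgi", "in_enhancer", "overlaps_common_variant"):
        tree = trees[name].get(locus.chrom)
        out[name] = bool(tree.overlap(locus.start, locus.end)) if tree else False
    return out


def build_feature_trees(cgi, enhancers, variants) -> dict[str, dict]:
    return {"in_cgi": _build_trees(cgi),
            "in_enhancer": _build_trees(enhancers),
            "overlaps_common_variant": _build_trees(variants)}


def annotate_loci(loci: Sequence[GenomicInterval], models: Sequence[GeneModel],
                  cgi=(), enhancers=(), variants=(),
                  flank: int = 500) -> list[AnnotatedRegion]:
    """Annotate many loci, sharing the feature indexes."""
    trees = build_feature_trees(cgi, enhancers, variants)
    out = []
    for locus in loci:
        region = assign_context(locus, models, flank)
        flags = overlap_flags(locus, trees=trees)
        region.in_cgi = flags["in_cgi"]
        region.in_enhancer = flags["in_enhancer"]
        region.overlaps_common_variant = flags["overlaps_common_variant"]
        out.append(region)
    return out
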