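"""Readers and writers for every external table the pipeline touches.

Supported formats: bedGraph-like methylation call tables (MethylDackel
dialect), BED3/BED6 feature intervals, BED12 gene models, TSV sample
metadata, TSV expression matrices, OBO ontologies (via :mod:`obonet`),
GMT gene-set annotation, and the TSV result tables shaped like the
published differential-methylation tables.

All readers produce 0-based half-open coordinates; the result-table writer
converts to the 1-based inclusive printed style at the boundary.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import obonet
import pandas as pd

from .intervals import GenomicInterval

GROUPS = ("TDP-A", "TDP-B", "TDP-C", "TDP-GRN", "TDP-C9", "CTRL")
TISSUES = ("FCX", "CER")
SEXES = ("F", "M")


class ParseError(ValueError):
    """A malformed line in an input table; carries the 1-based line number."""

    def __init__(self, path, lineno: int, message: str):
        super().__init__(f"{path}:{lineno}: {message}")
        self.path = str(path)
        self.lineno = lineno


# ---------------------------------------------------------------------------
# Methylation calls
# ---------------------------------------------------------------------------


@dataclass
class MethylationCallSet:
    """One sample's per-CpG methylated/unmethylated read counts.

    ``calls`` holds columns ``chrom, start, end, n_meth, n_unmeth`` sorted by
    (chrom, start); every retained site has coverage >= 1.
    """

    sample_id: str
    calls: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.calls
        if len(df):
            if (df["n_meth"] < 0).any() or (df["n_unmeth"] < 0).any():
                raise ValueError(f"{self.sample_id}: negative counts")
            if ((df["n_meth"] + df["n_unmeth"]) < 1).any():
                raise ValueError(f"{self.sample_id}: zero-coverage site stored")

    @property
    def n_sites(self) -> int:
        return len(self.calls)

    def coverage(self) -> pd.Series:
        return self.calls["n_meth"] + self.calls["n_unmeth"]

    def fractions(self) -> pd.Series:
        return self.calls["n_meth"] / self.coverage()

    def chromosomes(self) -> list[str]:
        return list(dict.fromkeys(self.calls["chrom"]))


_CALL_COLUMNS = ["chrom", "start", "end", "n_meth", "n_unmeth"]


def read_methylation_calls(path, min_coverage: int = 5,
                           sample_id: str | None = None) -> MethylationCallSet:
    """Read a bedGraph-like methylation call table.

    The MethylDackel dialect has six columns (chrom, start, end, percent,
    n_meth, n_unmeth) after an optional ``track`` header. A four-column
    percent-only bedGraph carries no counts and is rejected, since the
    likelihood model needs counts. Sites with coverage below ``min_coverage``
    are dropped (the study applied a floor of 5 at extraction).
    """
    path = Path(path)
    rows = []
    unsorted = False
    prev = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "#")):
                continue
            parts = line.split("\t")
            if len(parts) == 4:
                raise ParseError(
                    path, lineno,
                    "4-column percent-only bedGraph carries no read counts; "
                    "a 6-column count table is required")
            if len(parts) != 6:
                raise ParseError(path, lineno,
                                 f"expected 6 columns, found {len(parts)}")
            try:
                chrom = parts[0]
                start, end = int(parts[1]), int(parts[2])
                n_meth, n_unmeth = int(parts[4]), int(parts[5])
            except ValueError as exc:
                raise ParseError(path, lineno, f"bad field: {exc}") from None
            if end <= start:
                raise ParseError(path, lineno, f"end {end} <= start {start}")
            if n_meth < 0 or n_unmeth < 0:
                raise ParseError(path, lineno, "negative count")
            key = (chrom, start)
            if prev is not None and key < prev:
                unsorted = True
            prev = key
            rows.append((chrom, start, end, n_meth, n_unmeth))
    df = pd.DataFrame(rows, columns=_CALL_COLUMNS)
    if unsorted:
        warnings.warn(f"{path}: input not sorted; re-sorting", stacklevel=2)
        df = df.sort_values(["chrom", "start"], kind="mergesort",
                            ignore_index=True)
    if len(df):
        df = df[(df["n_meth"] + df["n_unmeth"]) >= min_coverage]
        df = df.reset_index(drop=True)
    return MethylationCallSet(sample_id or path.stem, df)


def write_methylation_calls(callset: MethylationCallSet, path) -> None:
    """Write the six-column count bedGraph dialect read back by the reader."""
    with open(path, "w") as fh:
        fh.write('track type="bedGraph" description="methylation calls"\n')
        for row in callset.calls.itertuples(index=False):
            cov = row.n_meth + row.n_unmeth
            pct = 100.0 * row.n_meth / cov
            fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t{pct:.4f}"
                     f"\t{row.n_meth}\t{row.n_unmeth}\n")


# ---------------------------------------------------------------------------
# Sample metadata
# ---------------------------------------------------------------------------


def read_metadata(path, groups: Sequence[str] = GROUPS,
                  tissues: Sequence[str] = TISSUES) -> pd.DataFrame:
    """Read the sample sheet: sample_id, group, sex, age_at_death, tissue."""
    meta = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    required = {"sample_id", "group", "sex", "age_at_death", "tissue"}
    missing = required - set(meta.columns)
    if missing:
        raise ValueError(f"{path}: missing metadata columns {sorted(missing)}")
    for col, vocab in (("group", groups), ("sex", SEXES), ("tissue", tissues)):
        bad = set(meta[col]) - set(vocab)
        if bad:
            raise ValueError(f"{path}: invalid {col} values {sorted(bad)}")
    if (meta["age_at_death"] <= 0).any():
        raise ValueError(f"{path}: non-positive age_at_death")
    if meta["sample_id"].duplicated().any():
        raise ValueError(f"{path}: duplicate sample ids")
    return meta


def write_metadata(meta: pd.DataFrame, path) -> None:
    meta.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Gene models (BED12)
# ---------------------------------------------------------------------------


@dataclass
class GeneModel:
    """One transcript: strand-aware TSS, exon blocks and optional CDS span."""

    gene_id: str
    transcript_id: str
    chrom: str
    strand: str
    exons: list[GenomicInterval]
    cds_start: int | None = None
    cds_end: int | None = None

    @property
    def tss(self) -> int:
        if self.strand == "-":
            return self.exons[-1].end
        return self.exons[0].start

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.exons[0].start,
                               self.exons[-1].end, self.strand)

    @property
    def is_coding(self) -> bool:
        return self.cds_start is not None


def read_gene_models(path) -> list[GeneModel]:
    """Read BED12 transcripts. The ``name`` field is ``gene_id|transcript_id``
    (a bare name serves as both)."""
    models = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "#")):
                continue
            p = line.split("\t")
            if len(p) < 12:
                raise ParseError(path, lineno,
                                 f"expected 12 columns, found {len(p)}")
            chrom, start, end, name = p[0], int(p[1]), int(p[2]), p[3]
            strand = p[5]
            thick_start, thick_end = int(p[6]), int(p[7])
            n_blocks = int(p[9])
            sizes = [int(x) for x in p[10].rstrip(",").split(",")]
            offsets = [int(x) for x in p[11].rstrip(",").split(",")]
            if len(sizes) != n_blocks or len(offsets) != n_blocks:
                raise ParseError(path, lineno,
                                 f"{name}: blockCount {n_blocks} inconsistent "
                                 f"with blockSizes/blockStarts")
            exons = []
            for off, size in zip(offsets, sizes):
                ex = GenomicInterval(chrom, start + off, start + off + size,
                                     strand)
                if ex.end > end:
                    raise ParseError(path, lineno,
                                     f"{name}: block extends past chromEnd")
                exons.append(ex)
            for a, b in zip(exons, exons[1:]):
                if b.start < a.end:
                    raise ParseError(path, lineno,
                                     f"{name}: unsorted/overlapping blocks")
            gene_id, _, tx_id = name.partition("|")
            cds_s = cds_e = None
            if thick_end > thick_start:  # equal bounds mark non-coding
                cds_s, cds_e = thick_start, thick_end
            models.append(GeneModel(gene_id, tx_id or gene_id, chrom, strand,
                                    exons, cds_s, cds_e))
    return models


def write_gene_models(models: Iterable[GeneModel], path) -> None:
    with open(path, "w") as fh:
        for m in models:
            start = m.exons[0].start
            end = m.exons[-1].end
            sizes = ",".join(str(e.width) for e in m.exons)
            offsets = ",".join(str(e.start - start) for e in m.exons)
            ts = m.cds_start if m.is_coding else start
            te = m.cds_end if m.is_coding else start
            name = f"{m.gene_id}|{m.transcript_id}"
            fh.write(f"{m.chrom}\t{start}\t{end}\t{name}\t0\t{m.strand}"
                     f"\t{ts}\t{te}\t0\t{len(m.exons)}\t{sizes}\t{offsets}\n")


# ---------------------------------------------------------------------------
# Plain BED features
# ---------------------------------------------------------------------------


def read_bed(path) -> list[GenomicInterval]:
    """Read BED3/BED6 feature intervals (CpG islands, enhancers, variants)."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "#")):
                continue
            p = line.split("\t")
            if len(p) < 3:
                raise ParseError(path, lineno, "fewer than 3 columns")
            strand = p[5] if len(p) >= 6 else "."
            try:
                iv = GenomicInterval(p[0], int(p[1]), int(p[2]), strand)
            except ValueError as exc:
                raise ParseError(path, lineno, str(exc)) from None
            out.append(iv)
    return sorted(out)


def write_bed(intervals: Iterable[GenomicInterval], path,
              names: Sequence[str] | None = None) -> None:
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            if names is not None:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{names[i]}"
                         f"\t0\t{iv.strand}\n")
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """Genes x samples normalized expression, optionally with raw counts."""

    values: pd.DataFrame
    counts: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if (self.values.to_numpy() < 0).any():
            raise ValueError("negative expression values")
        if self.counts is not None:
            if not self.counts.columns.equals(self.values.columns):
                raise ValueError("counts/values sample mismatch")

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)


def read_expression(values_path, counts_path=None) -> ExpressionMatrix:
    values = pd.read_csv(values_path, sep="\t", index_col=0)
    counts = None
    if counts_path is not None:
        counts = pd.read_csv(counts_path, sep="\t", index_col=0)
        counts = counts.loc[values.index, values.columns]
    return ExpressionMatrix(values, counts)


def write_expression(expr: ExpressionMatrix, values_path,
                     counts_path=None) -> None:
    expr.values.to_csv(values_path, sep="\t", float_format="%.6g",
                       index_label="gene_id")
    if counts_path is not None and expr.counts is not None:
        expr.counts.to_csv(counts_path, sep="\t", index_label="gene_id")


# ---------------------------------------------------------------------------
# Ontology + annotation
# ---------------------------------------------------------------------------


def read_obo(path) -> nx.MultiDiGraph:
    """Read an OBO ontology; edges run child -> parent (is_a / part_of)."""
    graph = obonet.read_obo(path)
    drop = [(u, v, k) for u, v, k in graph.edges(keys=True)
            if k not in ("is_a", "part_of")]
    graph.remove_edges_from(drop)
    return graph


def write_obo(graph: nx.MultiDiGraph, path) -> None:
    """Write a minimal OBO stanza file obonet can read back."""
    with open(path, "w") as fh:
        fh.write("format-version: 1.2\nontology: synthetic\n")
        for term in sorted(graph.nodes):
            data = graph.nodes[term]
            fh.write(f"\n[Term]\nid: {term}\n")
            fh.write(f"name: {data.get('name', term)}\n")
            fh.write(f"namespace: {data.get('namespace', 'biological_process')}\n")
            for _, parent, key in sorted(graph.out_edges(term, keys=True)):
                if key == "is_a":
                    fh.write(f"is_a: {parent}\n")
                else:
                    fh.write(f"relationship: part_of {parent}\n")


def read_gmt(path) -> dict[str, set[str]]:
    """Read GMT gene-set annotation: term, description, genes..."""
    annotation: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            p = line.split("\t")
            if len(p) < 3:
                raise ParseError(path, lineno, "GMT line needs >= 3 columns")
            annotation[p[0]] = set(g for g in p[2:] if g)
    return annotation


def write_gmt(annotation: Mapping[str, Iterable[str]], path) -> None:
    with open(path, "w") as fh:
        for term in sorted(annotation):
            genes = "\t".join(sorted(annotation[term]))
            fh.write(f"{term}\t{term}\t{genes}\n")


# ---------------------------------------------------------------------------
# Result tables
# ---------------------------------------------------------------------------

RESULT_COLUMNS = ["chrom", "start", "end", "position", "level", "group",
                  "gene", "context", "logFC", "lrt_stat", "p_value", "fdr",
                  "direction", "n_case", "n_control", "flag"]


def write_results_table(results: pd.DataFrame, path) -> None:
    """Write a differential-methylation result table.

    Rows are sorted by (chrom, start, group); the ``position`` column is the
    1-based inclusive printed form of the internal half-open coordinates.
    """
    df = results.copy()
    for col in RESULT_COLUMNS:
        if col not in df.columns:
            df[col] = "" if col in ("gene", "context", "flag", "position") else pd.NA
    if len(df):
        df["position"] = [
            GenomicInterval(c, s, e).format_position()
            for c, s, e in zip(df["chrom"], df["start"], df["end"])
        ]
        df = df.sort_values(["chrom", "start", "group"], kind="mergesort",
                            ignore_index=True)
    df = df[RESULT_COLUMNS]
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_results_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t",
                       dtype={"gene": str, "context": str, "flag": str},
                       keep_default_na=True)


def write_manifest(manifest: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_manifest(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
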