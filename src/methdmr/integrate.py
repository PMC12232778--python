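"""Post-test integration of differential methylation with expression.

Covers: per-gene merging of overlapping DMRs (represented by the largest
member's coordinates), Pearson correlation between per-sample DMR
methylation and normalized expression (all samples and patients-only
cohorts), group expression comparisons under a normality-gated test policy
(Shapiro-Wilk / Kolmogorov-Smirnov -> t / ANOVA vs Mann-Whitney /
Kruskal-Wallis with Bonferroni post-hoc), the methylation-stratified
expression comparison (top-k vs bottom-k samples), and the supporting-read
gene filter for the expression matrix.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import GenomicInterval
from .io_formats import ExpressionMatrix


# ---------------------------------------------------------------------------
# DMR merging
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MergedDMR:
    """A group of transitively overlapping DMRs within one gene.

    ``representative`` is the largest member's own coordinates (width ties
    broken toward the smaller start); ``union`` is the full span, kept as an
    auxiliary column.
    """

    representative: GenomicInterval
    union: GenomicInterval
    members: tuple[GenomicInterval, ...]


def merge_gene_dmrs(dmrs: list[GenomicInterval]) -> list[MergedDMR]:
    """Merge overlapping DMRs of one gene by transitive overlap.

    Non-overlapping DMRs pass through as their own (singleton) groups.
    Idempotent and order-invariant.
    """
    if not dmrs:
        return []
    chroms = {d.chrom for d in dmrs}
    if len(chroms) > 1:
        raise ValueError("DMRs of one gene must share a chromosome")
    ordered = sorted(dmrs, key=lambda d: (d.start, d.end))
    groups: list[list[GenomicInterval]] = []
    current = [ordered[0]]
    reach = ordered[0].end
    for d in ordered[1:]:
        if d.start < reach:  # half-open: touching intervals do not overlap
            current.append(d)
            reach = max(reach, d.end)
        else:
            groups.append(current)
            current = [d]
            reach = d.end
    groups.append(current)
    out = []
    for members in groups:
        rep = max(members, key=lambda d: (d.width, -d.start))
        union = GenomicInterval(rep.chrom, min(d.start for d in members),
                                max(d.end for d in members))
        out.append(MergedDMR(rep, union, tuple(sorted(members))))
    return out


# ---------------------------------------------------------------------------
# Methylation-expression correlation
# ---------------------------------------------------------------------------


@dataclass
class CorrelationResult:
    gene: str
    dmr: GenomicInterval
    cohort: str
    pearson_r: float
    p_value: float
    n: int
    reason: str = ""


def dmr_methylation(meth: pd.Series | np.ndarray,
                    total: pd.Series | np.ndarray) -> np.ndarray:
    """Per-sample DMR methylation: pooled n_meth/n_total over member CpGs
    (count-weighted, consistent with count aggregation elsewhere)."""
    meth = np.asarray(meth, dtype=float)
    total = np.asarray(total, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(total > 0, meth / total, np.nan)


def correlate_methylation_expression(methylation: pd.Series,
                                     expression: pd.Series,
                                     cohort: str = "all",
                                     gene: str = "",
                                     dmr: GenomicInterval | None = None
                                     ) -> CorrelationResult:
    """Pearson correlation between DMR methylation and expression.

    Both series are indexed by sample id; only samples present in both with
    finite values enter. The p-value is the two-sided t transform with
    n - 2 df. Zero variance in either vector yields NA with a reason.
    """
    common = methylation.index.intersection(expression.index)
    x = methylation.loc[common].to_numpy(dtype=float)
    y = expression.loc[common].to_numpy(dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = len(x)
    if dmr is None:
        dmr = GenomicInterval("NA", 0, 1)
    if n < 3:
        raise ValueError(f"need >= 3 paired samples, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationResult(gene, dmr, cohort, np.nan, np.nan, n,
                                 reason="zero_variance")
    r, p = stats.pearsonr(x, y)
    return CorrelationResult(gene, dmr, cohort, float(r), float(p), n)


# ---------------------------------------------------------------------------
# Group comparisons with the normality-gated test policy
# ---------------------------------------------------------------------------


@dataclass
class ComparisonResult:
    test_name: str
    statistic: float
    p_value: float
    normal: bool
    flags: str = ""
    posthoc: pd.DataFrame | None = None


def _is_normal(x: np.ndarray, alpha: float, sw_cutoff: int) -> tuple[bool, bool]:
    """(normal, constant): Shapiro-Wilk for n <= cutoff, else KS vs fitted
    normal. Constant groups force the nonparametric branch."""
    if np.ptp(x) == 0:
        return False, True
    if len(x) <= sw_cutoff:
        p = stats.shapiro(x).pvalue
    else:
        p = stats.kstest(x, "norm", args=(x.mean(), x.std(ddof=1))).pvalue
    return p >= alpha, False


def compare_groups(values_by_group: dict[str, np.ndarray],
                   alpha: float = 0.05, sw_cutoff: int = 50) -> ComparisonResult:
    """Compare >= 2 groups under the normality-gated test-selection policy.

    All groups normal (gate at ``alpha``) -> unpaired t-test (2 groups) or
    ordinary one-way ANOVA (> 2); otherwise Mann-Whitney / Kruskal-Wallis.
    For > 2 groups, pairwise post-hoc tests of the same family are
    Bonferroni-adjusted. The chosen branch is recorded.
    """
    groups = {g: np.asarray(v, dtype=float) for g, v in values_by_group.items()}
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    for g, v in groups.items():
        if len(v) < 3:
            raise ValueError(f"group {g!r} has n < 3")
    checks = {g: _is_normal(v, alpha, sw_cutoff) for g, v in groups.items()}
    constant = [g for g, (_, c) in checks.items() if c]
    normal = all(nrm for nrm, _ in checks.values()) and not constant
    flags = "constant_group" if constant else ""
    arrays = list(groups.values())
    labels = list(groups)
    if len(groups) == 2:
        a, b = arrays
        if normal:
            res = stats.ttest_ind(a, b)
            name = "t-test"
        else:
            res = stats.mannwhitneyu(a, b, alternative="two-sided",
                                     method="asymptotic")
            name = "mann-whitney"
        return ComparisonResult(name, float(res.statistic),
                                float(min(res.pvalue, 1.0)), normal, flags)
    if normal:
        res = stats.f_oneway(*arrays)
        name = "anova"
    else:
        res = stats.kruskal(*arrays)
        name = "kruskal-wallis"
    m = len(labels) * (len(labels) - 1) // 2
    rows = []
    for ga, gb in itertools.combinations(labels, 2):
        if normal:
            pr = stats.ttest_ind(groups[ga], groups[gb])
        else:
            pr = stats.mannwhitneyu(groups[ga], groups[gb],
                                    alternative="two-sided",
                                    method="asymptotic")
        rows.append({"group_a": ga, "group_b": gb,
                     "statistic": float(pr.statistic),
                     "p_value": float(pr.pvalue),
                     "p_bonferroni": float(min(1.0, pr.pvalue * m))})
    posthoc = pd.DataFrame(rows)
    return ComparisonResult(name, float(res.statistic),
                            float(min(res.pvalue, 1.0)), normal, flags, posthoc)


def stratified_expression_test(methylation: pd.Series, expression: pd.Series,
                               k: int = 10) -> ComparisonResult:
    """Compare expression of the k highest- vs k lowest-methylation samples.

    Samples are ranked by DMR mean methylation; ties spanning the k-th rank
    are broken deterministically by sample id (flagged). Delegates to
    :func:`compare_groups`; arms of n < 3 are rejected.
    """
    common = methylation.index.intersection(expression.index)
    meth = methylation.loc[common]
    expr = expression.loc[common]
    if len(common) < 2 * k:
        raise ValueError(f"need >= {2 * k} samples, got {len(common)}")
    if k < 3:
        raise ValueError("k < 3 leaves arms below the minimum group size")
    order = sorted(common, key=lambda s: (-meth.loc[s], s))
    top, bottom = order[:k], order[-k:]
    flags = ""
    vals = meth.loc[order].to_numpy()
    if vals[k - 1] == vals[k] or vals[-k] == vals[-k - 1]:
        flags = "tie_at_cutoff"
    result = compare_groups({
        "high_methylation": expr.loc[top].to_numpy(),
        "low_methylation": expr.loc[bottom].to_numpy(),
    })
    result.flags = ";".join(filter(None, [result.flags, flags]))
    result.test_name += " (top-%d vs bottom-%d)" % (k, k)
    return result


# ---------------------------------------------------------------------------
# Expression gene filter
# ---------------------------------------------------------------------------


def filter_expression_genes(expr: ExpressionMatrix, min_samples: int = 20,
                            min_reads: int = 10) -> ExpressionMatrix:
    """Drop genes with fewer than ``min_samples`` samples having at least
    ``min_reads`` supporting reads."""
    if expr.counts is None:
        raise ValueError("raw supporting-read counts are required")
    enough = (expr.counts >= min_reads).sum(axis=1) >= min_samples
    kept = expr.counts.index[enough]
    return ExpressionMatrix(expr.values.loc[kept],
                            expr.counts.loc[kept])
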