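"""Orthogonal validation statistics: clone bisulfite sequencing and
per-haplotype long-read methylation.

Clone-based targeted bisulfite sequencing summarizes a sample as the ratio
of methylated CpGs to all scored CpGs across all clones and positions
(the study picked 6 clones per sample and scored 45 cytosines), with a
per-clone x per-position matrix for lollipop-style display and a
bisulfite-conversion QC on non-CpG cytosines.

Long-read (ONT) validation extracts per-haplotype (n_mod, n_total) CpG
counts within a target region, filters sites below 5x coverage, compares
groups per CpG with a rank-based two-sample test (haplotypes are the
plotted units), and runs the covariate-adjusted region-level test on
per-sample haplotype-pooled counts through the same beta-binomial engine
as the genome-wide analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .diffmeth import DesignSpec, LocusFit, fit_locus
from .intervals import GenomicInterval


@dataclass
class CloneCallTable:
    """Binary methylation calls, clones x CpG positions, for one sample.

    ``calls`` values are 1 (methylated), 0 (unmethylated) or NaN (missing).
    ``conversion`` has per-clone converted/unconverted non-CpG cytosine
    tallies for QC.
    """

    sample_id: str
    calls: pd.DataFrame  # index: clone ids; columns: CpG positions
    conversion: pd.DataFrame | None = None  # clone, converted, unconverted

    @property
    def n_clones(self) -> int:
        return len(self.calls)


def clone_methylation_percent(table: CloneCallTable) -> tuple[float, pd.DataFrame]:
    """Sample methylation percentage and the lollipop matrix.

    percent = 100 * (methylated CpGs) / (non-missing CpG calls), pooled over
    all positions and all clones. Returns NaN when every call is missing.
    The lollipop matrix is the raw clone x position call table (one row per
    clone, one dot per profiled cytosine).
    """
    values = table.calls.to_numpy(dtype=float)
    n_scored = np.isfinite(values).sum()
    if n_scored == 0:
        return float("nan"), table.calls.copy()
    pct = 100.0 * np.nansum(values) / n_scored
    return float(pct), table.calls.copy()


def conversion_qc(table: CloneCallTable,
                  threshold: float = 0.95) -> pd.DataFrame:
    """Per-clone bisulfite conversion rate on non-CpG cytosines.

    rate = converted / (converted + unconverted); a clone passes at
    rate >= ``threshold``. Clones with no scored non-CpG cytosine are
    "undetermined".
    """
    if table.conversion is None:
        raise ValueError("non-CpG cytosine tallies are required for QC")
    rows = []
    for row in table.conversion.itertuples(index=False):
        total = row.converted + row.unconverted
        if total == 0:
            rows.append({"clone": row.clone, "rate": np.nan,
                         "status": "undetermined"})
        else:
            rate = row.converted / total
            rows.append({"clone": row.clone, "rate": rate,
                         "status": "pass" if rate >= threshold else "fail"})
    return pd.DataFrame(rows)


def read_clone_table(path) -> list[CloneCallTable]:
    """Read pre-called clone methylation calls from TSV.

    Columns: sample, clone, position, call (1/0/NA for CpGs) and an optional
    ``context`` column where rows with context ``non_cpg`` feed the
    conversion tally (call 0 = converted, 1 = unconverted).
    """
    df = pd.read_csv(path, sep="\t")
    required = {"sample", "clone", "position", "call"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if "context" not in df.columns:
        df["context"] = "cpg"
    tables = []
    for sample, sub in df.groupby("sample", sort=True):
        cpg = sub[sub["context"] != "non_cpg"]
        calls = cpg.pivot_table(index="clone", columns="position",
                                values="call", aggfunc="first")
        non = sub[sub["context"] == "non_cpg"]
        conv_rows = []
        for clone in calls.index:
            cn = non[non["clone"] == clone]["call"].dropna()
            conv_rows.append({"clone": clone,
                              "converted": int((cn == 0).sum()),
                              "unconverted": int((cn == 1).sum())})
        tables.append(CloneCallTable(str(sample), calls,
                                     pd.DataFrame(conv_rows)))
    return tables


# ---------------------------------------------------------------------------
# ONT per-haplotype methylation
# ---------------------------------------------------------------------------

HAPLOTYPE_COLUMNS = ["sample_id", "haplotype", "chrom", "pos", "n_mod",
                     "n_total"]


def filter_haplotype_records(records: pd.DataFrame,
                             min_coverage: int = 5) -> pd.DataFrame:
    """Keep per-haplotype CpG records with ``n_total >= min_coverage``."""
    missing = set(HAPLOTYPE_COLUMNS) - set(records.columns)
    if missing:
        raise ValueError(f"missing columns {sorted(missing)}")
    if (records["n_mod"] > records["n_total"]).any():
        raise ValueError("n_mod exceeds n_total")
    return records[records["n_total"] >= min_coverage].reset_index(drop=True)


def _stars(p: float) -> str:
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def ont_percpg_tests(records: pd.DataFrame, meta: pd.DataFrame,
                     region: GenomicInterval, case_groups: tuple[str, ...],
                     control_group: str = "CTRL", min_coverage: int = 5,
                     paired: bool = False) -> pd.DataFrame:
    """Per-CpG group comparison of haplotype methylation fractions.

    Each haplotype contributes one fraction (the plotted unit). The default
    test is the unpaired rank-sum (Mann-Whitney) test: although the source
    figure names the signed-rank test, the patients-vs-controls contrast is
    between independent samples; ``paired=True`` forces the signed-rank
    variant for genuinely paired designs. Significance stars mark p < 0.05
    and p < 0.01. CpGs informative in only one group are skipped with a
    reason column.
    """
    recs = filter_haplotype_records(records, min_coverage)
    recs = recs[(recs["chrom"] == region.chrom)
                & (recs["pos"] >= region.start) & (recs["pos"] < region.end)]
    m = meta.set_index("sample_id") if "sample_id" in meta.columns else meta
    rows = []
    for pos, sub in recs.groupby("pos", sort=True):
        groups = m.loc[sub["sample_id"], "group"].to_numpy()
        frac = (sub["n_mod"] / sub["n_total"]).to_numpy()
        case = frac[np.isin(groups, case_groups)]
        ctrl = frac[groups == control_group]
        if len(case) < 3 or len(ctrl) < 3:
            rows.append({"chrom": region.chrom, "pos": int(pos),
                         "n_case": len(case), "n_control": len(ctrl),
                         "statistic": np.nan, "p_value": np.nan,
                         "stars": "", "skipped": "insufficient haplotypes"})
            continue
        if paired:
            n = min(len(case), len(ctrl))
            res = stats.wilcoxon(case[:n], ctrl[:n], zero_method="zsplit")
        else:
            res = stats.mannwhitneyu(case, ctrl, alternative="two-sided",
                                     method="asymptotic")
        p = float(min(res.pvalue, 1.0))
        rows.append({"chrom": region.chrom, "pos": int(pos),
                     "n_case": len(case), "n_control": len(ctrl),
                     "statistic": float(res.statistic), "p_value": p,
                     "stars": _stars(p), "skipped": ""})
    return pd.DataFrame(rows)


def ont_region_test(records: pd.DataFrame, meta: pd.DataFrame,
                    region: GenomicInterval, case_groups: tuple[str, ...],
                    control_group: str = "CTRL",
                    covariates: tuple[str, ...] = ("sex", "age"),
                    min_coverage: int = 5, phi: float = 0.02) -> LocusFit:
    """Covariate-adjusted differential methylation of the whole region.

    Haplotypes are pooled per sample (samples are the independent units) and
    counts summed over the region's CpGs, then the beta-binomial GLM
    likelihood-ratio test runs exactly as for the genome-wide data.
    """
    recs = filter_haplotype_records(records, min_coverage)
    recs = recs[(recs["chrom"] == region.chrom)
                & (recs["pos"] >= region.start) & (recs["pos"] < region.end)]
    per_sample = recs.groupby("sample_id")[["n_mod", "n_total"]].sum()
    m = meta.set_index("sample_id") if "sample_id" in meta.columns else meta
    wanted = m[m["group"].isin(case_groups + (control_group,))]
    samples = [s for s in wanted.index if s in per_sample.index]
    design = DesignSpec(case_groups=tuple(case_groups),
                        control_group=control_group, covariates=covariates)
    sub = m.loc[samples]
    cov = {}
    if "sex" in covariates:
        cov["sex"] = (sub["sex"] == "M").astype(float).to_numpy()
    if "age" in covariates:
        cov["age"] = sub["age_at_death"].to_numpy(dtype=float)
    return fit_locus(per_sample.loc[samples, "n_mod"].to_numpy(),
                     per_sample.loc[samples, "n_total"].to_numpy(),
                     pd.DataFrame(cov, index=samples),
                     sub["group"].isin(case_groups).to_numpy(),
                     phi=phi, design=design)
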