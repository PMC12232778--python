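"""Post-alignment sample QC: common-site selection, PCA outlier review and
X/Y-coverage sex approximation.

The study reviewed the first six principal components of methylation
fractions at sites covered >= 5x in all samples, and approximated sex from
X/Y coverage maps. Visual outlier review is replaced here by a fixed rule:
a sample is flagged when any of its first-six PC scores exceeds
``sd_threshold`` standard deviations, or when its nearest tissue centroid in
PC space disagrees with its metadata tissue.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .intervals import GenomicInterval
from .io_formats import MethylationCallSet

OUTLIER_REASONS = ("sex_discordant", "pca_outlier", "pca_tissue_mismatch")


@dataclass
class QCReport:
    """Per-sample QC outcomes plus the retained common-site list."""

    samples: pd.DataFrame  # sample_id, inferred_sex, sex_concordant, PC*, flags
    sites: list[GenomicInterval]

    def flagged(self) -> pd.DataFrame:
        return self.samples[self.samples["outlier_reasons"] != ""]


def common_sites(callsets: list[MethylationCallSet],
                 min_coverage: int = 5) -> list[GenomicInterval]:
    """Sites covered at >= ``min_coverage`` in every sample, sorted."""
    if len(callsets) < 2:
        raise ValueError("need at least two call sets")
    common: set | None = None
    for cs in callsets:
        cov = cs.coverage()
        ok = cs.calls[cov >= min_coverage]
        sites = set(zip(ok["chrom"], ok["start"]))
        common = sites if common is None else common & sites
        if not common:
            break
    if not common:
        warnings.warn("no site passes the coverage floor in every sample")
        return []
    return [GenomicInterval(c, s, s + 1) for c, s in sorted(common)]


def fraction_matrix(callsets: list[MethylationCallSet],
                    sites: list[GenomicInterval]) -> pd.DataFrame:
    """Sites x samples methylation fractions at the given single-CpG sites."""
    keys = [(iv.chrom, iv.start) for iv in sites]
    data = {}
    for cs in callsets:
        idx = pd.MultiIndex.from_arrays([cs.calls["chrom"], cs.calls["start"]])
        frac = pd.Series(cs.fractions().to_numpy(), index=idx)
        data[cs.sample_id] = frac.reindex(keys).to_numpy()
    return pd.DataFrame(data, index=pd.MultiIndex.from_tuples(keys))


def pca_outliers(fractions: pd.DataFrame, meta: pd.DataFrame | None = None,
                 n_components: int = 6, sd_threshold: float = 4.0,
                 logit: bool = False) -> pd.DataFrame:
    """PC scores and outlier flags for each sample.

    ``fractions`` is sites x samples with no missing values (restrict to
    common sites first). PCs are computed on centered per-site fractions;
    a sample is a ``pca_outlier`` when any of its first ``n_components``
    scores exceeds ``sd_threshold`` score-SDs, and a ``pca_tissue_mismatch``
    when its nearest tissue centroid in PC space differs from metadata.
    """
    X = fractions.to_numpy(dtype=float).T  # samples x sites
    if np.isnan(X).any():
        raise ValueError("missing values; restrict to common sites first")
    if logit:
        eps = 1e-3
        Xc = np.clip(X, eps, 1 - eps)
        X = np.log(Xc / (1 - Xc))
    n_samples = X.shape[0]
    k = min(n_components, n_samples - 1, X.shape[1])
    if k < n_components:
        warnings.warn(f"only {k} components available; truncating")
    samples = list(fractions.columns)
    out = pd.DataFrame({"sample_id": samples})
    if k < 1:
        out["outlier_reasons"] = ""
        return out
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(X - X.mean(axis=0))
    sds = scores.std(axis=0, ddof=1)
    reasons = [[] for _ in samples]
    with np.errstate(invalid="ignore"):
        extreme = np.abs(scores) > sd_threshold * np.where(sds > 0, sds, np.inf)
    for i in np.where(extreme.any(axis=1))[0]:
        reasons[i].append("pca_outlier")
    if meta is not None:
        m = meta.set_index("sample_id") if "sample_id" in meta.columns else meta
        tissues = m.loc[samples, "tissue"].to_numpy()
        centroids = {t: scores[tissues == t].mean(axis=0)
                     for t in np.unique(tissues)}
        if len(centroids) > 1:
            for i, t in enumerate(tissues):
                dists = {u: np.linalg.norm(scores[i] - c)
                         for u, c in centroids.items()}
                if min(dists, key=dists.get) != t:
                    reasons[i].append("pca_tissue_mismatch")
    for j in range(k):
        out[f"PC{j + 1}"] = scores[:, j]
    out["outlier_reasons"] = [";".join(r) for r in reasons]
    return out


def approximate_sex(callsets: list[MethylationCallSet],
                    chrX: str = "chrX", chrY: str = "chrY",
                    threshold: float = 0.1,
                    meta: pd.DataFrame | None = None) -> pd.DataFrame:
    """Infer sex from the chrY share of sex-chromosome coverage.

    rho = total chrY coverage / (chrX + chrY coverage); rho > threshold
    infers male. Zero sex-chromosome coverage yields "undetermined".
    """
    rows = []
    for cs in callsets:
        cov = cs.coverage()
        x_cov = int(cov[cs.calls["chrom"] == chrX].sum())
        y_cov = int(cov[cs.calls["chrom"] == chrY].sum())
        denom = x_cov + y_cov
        if denom == 0:
            rho, inferred = np.nan, "undetermined"
        else:
            rho = y_cov / denom
            inferred = "M" if rho > threshold else "F"
        rows.append({"sample_id": cs.sample_id, "chrx_cov": x_cov,
                     "chry_cov": y_cov, "rho": rho, "inferred_sex": inferred})
    out = pd.DataFrame(rows)
    if meta is not None:
        m = meta.set_index("sample_id") if "sample_id" in meta.columns else meta
        out["reported_sex"] = m.loc[out["sample_id"], "sex"].to_numpy()
        out["sex_concordant"] = out["inferred_sex"] == out["reported_sex"]
    return out


def run_qc(callsets: list[MethylationCallSet], meta: pd.DataFrame,
           min_coverage: int = 5, n_components: int = 6,
           sd_threshold: float = 4.0, sex_threshold: float = 0.1) -> QCReport:
    """Full QC pass combining the three checks into one report."""
    sites = common_sites(callsets, min_coverage=min_coverage)
    sex = approximate_sex(callsets, meta=meta, threshold=sex_threshold)
    if sites:
        fractions = fraction_matrix(callsets, sites)
        pca = pca_outliers(fractions, meta=meta, n_components=n_components,
                           sd_threshold=sd_threshold)
    else:
        pca = pd.DataFrame({"sample_id": [cs.sample_id for cs in callsets],
                            "outlier_reasons": ""})
    report = sex.merge(pca, on="sample_id", how="left")
    discord = ~report["sex_concordant"].fillna(True).astype(bool)
    reasons = report["outlier_reasons"].fillna("")
    report["outlier_reasons"] = [
        ";".join(filter(None, ["sex_discordant" if d else "", r]))
        for d, r in zip(discord, reasons)
    ]
    return QCReport(report, sites)
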