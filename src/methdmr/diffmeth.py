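"""Covariate-adjusted differential methylation of (methylated, total) counts.

The engine fits, per locus, a beta-binomial regression with logit link on the
methylation proportion::

    E[k_j / n_j] = logistic(b0 + b_grp * case_j + b_sex * sex_j + b_age * age_j)

with a fixed per-locus overdispersion ``phi`` (beta-binomial with Beta shape
``(p(1-phi)/phi, (1-p)(1-phi)/phi)``; ``phi = 0`` degenerates to the
binomial). Group significance is a likelihood-ratio test of the model with
and without the case indicator, referred to chi-square with one degree of
freedom. The reported ``logFC`` is the group coefficient divided by ln 2,
i.e. the log2 odds ratio of methylation in cases versus controls; negative
values denote hypomethylation in cases.

Benjamini-Hochberg adjustment is applied across all loci tested within one
(comparison, level, tissue) stratum, with significance read at FDR < 0.05.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln, polygamma, psi
from scipy.stats import chi2
from statsmodels.stats.multitest import multipletests

LN2 = math.log(2.0)

#: Combined case-group aliases: ABC pools the genetically unexplained
#: subtypes, TDP pools every patient subtype.
COMBINED_GROUPS = {
    "ABC": ("TDP-A", "TDP-B", "TDP-C"),
    "TDP": ("TDP-A", "TDP-B", "TDP-C", "TDP-GRN", "TDP-C9"),
}


@dataclass(frozen=True)
class DesignSpec:
    """One comparison: case group(s) versus a control group, per tissue.

    ``case_groups`` may name several metadata groups (the combined "ABC" and
    "TDP" comparisons); they enter the model as a single case indicator.
    """

    case_groups: tuple[str, ...]
    control_group: str = "CTRL"
    covariates: tuple[str, ...] = ("sex", "age")
    tissue: str | None = None
    label: str | None = None
    min_informative_frac: float = 0.8

    def __post_init__(self):
        if self.control_group in self.case_groups:
            raise ValueError("case and control groups must be disjoint")
        bad = set(self.covariates) - {"sex", "age"}
        if bad:
            raise ValueError(f"unknown covariates {sorted(bad)}")

    @property
    def name(self) -> str:
        return self.label or "+".join(self.case_groups)

    @classmethod
    def from_label(cls, label: str, **kw) -> "DesignSpec":
        groups = COMBINED_GROUPS.get(label, (label,))
        return cls(case_groups=tuple(groups), label=label, **kw)


@dataclass
class LocusFit:
    """Pre-FDR outcome of one locus test."""

    logFC: float
    lrt_stat: float
    p_value: float
    n_case: int
    n_control: int
    flag: str = ""
    skipped: str | None = None

    @property
    def direction(self) -> str:
        if self.logFC < 0:
            return "hypo"
        if self.logFC > 0:
            return "hyper"
        return "none"


# ---------------------------------------------------------------------------
# Beta-binomial log-likelihood, gradient and Hessian on the linear predictor
# ---------------------------------------------------------------------------


def _bb_loglik_terms(k, n, p, phi):
    """Per-observation log-likelihood (dropping terms free of p)."""
    if phi <= 0.0:
        return k * np.log(p) + (n - k) * np.log1p(-p)
    a = (1.0 - phi) / phi
    alpha = p * a
    beta = (1.0 - p) * a
    return (gammaln(k + alpha) - gammaln(alpha)
            + gammaln(n - k + beta) - gammaln(beta))


def _bb_eta_derivs(k, n, p, phi):
    """First and second derivative of the log-likelihood wrt eta = logit(p)."""
    w = p * (1.0 - p)
    if phi <= 0.0:
        g = k - n * p
        h = -n * w
        return g, h
    a = (1.0 - phi) / phi
    alpha = p * a
    beta = (1.0 - p) * a
    dldp = a * (psi(k + alpha) - psi(alpha) - psi(n - k + beta) + psi(beta))
    d2ldp2 = a * a * (polygamma(1, k + alpha) - polygamma(1, alpha)
                      + polygamma(1, n - k + beta) - polygamma(1, beta))
    g = dldp * w
    h = d2ldp2 * w * w + dldp * w * (1.0 - 2.0 * p)
    return g, h

_PCLIP = 1e-10


def _fit_glm(X, k, n, phi, beta0=None, ridge=0.0, max_iter=100, tol=1e-10):
    """Newton fit with step-halving; returns (beta, loglik, converged).

    Deterministic start: supplied ``beta0`` or the pooled-proportion
    intercept. ``ridge`` adds a penalty ``-ridge/2 * |beta|^2`` used for
    separation handling.
    """
    ncol = X.shape[1]
    if beta0 is None:
        beta = np.zeros(ncol)
        pool = (k.sum() + 0.5) / (n.sum() + 1.0)
        beta[0] = math.log(pool / (1.0 - pool))
    else:
        beta = beta0.copy()

    def penalized_ll(b):
        p = 1.0 / (1.0 + np.exp(-(X @ b)))
        p = np.clip(p, _PCLIP, 1.0 - _PCLIP)
        return _bb_loglik_terms(k, n, p, phi).sum() - 0.5 * ridge * b @ b

    ll = penalized_ll(beta)
    converged = False
    for _ in range(max_iter):
        eta = X @ beta
        p = np.clip(1.0 / (1.0 + np.exp(-eta)), _PCLIP, 1.0 - _PCLIP)
        g_obs, h_obs = _bb_eta_derivs(k, n, p, phi)
        grad = X.T @ g_obs - ridge * beta
        hess = (X * h_obs[:, None]).T @ X - ridge * np.eye(ncol)
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(hess, grad, rcond=None)[0]
        new_beta = beta - step
        new_ll = penalized_ll(new_beta)
        halvings = 0
        while not np.isfinite(new_ll) or new_ll < ll - 1e-12:
            step *= 0.5
            new_beta = beta - step
            new_ll = penalized_ll(new_beta)
            halvings += 1
            if halvings > 50:
                break
        if halvings > 50:
            break
        delta = new_ll - ll
        beta, ll = new_beta, new_ll
        if abs(delta) < tol:
            converged = True
            break
    return beta, ll, converged


def fit_locus(n_meth, n_total, covariates: pd.DataFrame, case_mask,
              phi: float = 0.0, design: DesignSpec | None = None,
              ridge: float = 1e-4) -> LocusFit:
    """Test one locus for differential methylation between case and control.

    Parameters
    ----------
    n_meth, n_total : arrays over samples
        Aggregated methylated / total counts; samples with ``n_total == 0``
        are non-informative and dropped.
    covariates : DataFrame
        Numeric covariate columns (subset of ``sex`` coded 0/1 and ``age``),
        aligned with the count arrays.
    case_mask : boolean array
        True for case-arm samples.
    phi : float
        Beta-binomial overdispersion; 0 gives the binomial model.
    """
    k = np.asarray(n_meth, dtype=float)
    n = np.asarray(n_total, dtype=float)
    case = np.asarray(case_mask, dtype=bool)
    informative = n >= 1
    min_frac = design.min_informative_frac if design is not None else 0.8
    n_case_inf = int((informative & case).sum())
    n_ctrl_inf = int((informative & ~case).sum())
    for arm_total, arm_inf, name in ((case.sum(), n_case_inf, "case"),
                                     ((~case).sum(), n_ctrl_inf, "control")):
        if arm_total == 0 or arm_inf < min_frac * arm_total or arm_inf < 2:
            return LocusFit(np.nan, np.nan, np.nan, n_case_inf, n_ctrl_inf,
                            skipped=f"insufficient informative {name} samples")

    cols = [np.ones(informative.sum()), case[informative].astype(float)]
    for c in covariates.columns:
        v = covariates[c].to_numpy(dtype=float)[informative]
        if c == "age":
            v = v - v.mean()  # centering: location-invariant, aids conditioning
        cols.append(v)
    X_full = np.column_stack(cols)
    X_null = np.delete(X_full, 1, axis=1)
    k_i, n_i = k[informative], n[informative]

    beta_null, ll_null, conv_null = _fit_glm(X_null, k_i, n_i, phi)
    start_full = np.insert(beta_null, 1, 0.0)
    beta_full, ll_full, conv_full = _fit_glm(X_full, k_i, n_i, phi,
                                             beta0=start_full)

    flag = ""
    separated = (not conv_full or not conv_null
                 or np.abs(beta_full).max() > 12.0)
    if separated:
        beta_null, ll_null, _ = _fit_glm(X_null, k_i, n_i, phi, ridge=ridge)
        start_full = np.insert(beta_null, 1, 0.0)
        beta_full, ll_full, _ = _fit_glm(X_full, k_i, n_i, phi,
                                         beta0=start_full, ridge=ridge)
        flag = "ridge"
        # compare unpenalized likelihoods at the penalized optima
        def unpen(b, X):
            p = np.clip(1.0 / (1.0 + np.exp(-(X @ b))), _PCLIP, 1.0 - _PCLIP)
            return _bb_loglik_terms(k_i, n_i, p, phi).sum()
        ll_full = unpen(beta_full, X_full)
        ll_null = unpen(beta_null, X_null)

    lrt = max(0.0, 2.0 * (ll_full - ll_null))
    if lrt <= 1e-12:
        lrt = 0.0
        p_value = 1.0
    else:
        p_value = float(chi2.sf(lrt, df=1))
        p_value = min(max(p_value, np.nextafter(0, 1)), 1.0)
    logfc = float(beta_full[1] / LN2)
    if lrt == 0.0:
        logfc = 0.0 if abs(logfc) < 1e-8 else logfc
    return LocusFit(logfc, lrt, p_value, n_case_inf, n_ctrl_inf, flag=flag)


# ---------------------------------------------------------------------------
# Dispersion
# ---------------------------------------------------------------------------


def estimate_dispersion(meth: pd.DataFrame, total: pd.DataFrame,
                        groups: pd.Series, prior_weight: float = 20.0,
                        default_prior: float = 0.02,
                        trim: float = 0.2) -> tuple[np.ndarray, float]:
    """Per-locus beta-binomial overdispersion, shrunk across loci.

    A method-of-moments estimate is formed within each sample group (so
    group mean differences do not inflate it) from the Pearson statistic of
    the pooled-proportion fit, then combined across groups and shrunk toward
    the across-locus trimmed mean with weight proportional to the number of
    informative samples. Values are clamped to [0, 0.5]. Loci with fewer
    than four informative samples carry no own estimate and receive the
    prior. Returns ``(phi_per_locus, prior)``.
    """
    K = meth.to_numpy(dtype=float)
    N = total.to_numpy(dtype=float)
    n_loci = K.shape[0]
    raw = np.full(n_loci, np.nan)
    weight = np.zeros(n_loci)
    grp = np.asarray(groups)
    labels = pd.unique(grp)
    for i in range(n_loci):
        num = 0.0
        den = 0.0
        m_tot = 0
        for lab in labels:
            sel = (grp == lab) & (N[i] >= 1)
            m = int(sel.sum())
            if m < 2:
                continue
            k_g, n_g = K[i, sel], N[i, sel]
            p_hat = k_g.sum() / n_g.sum()
            if p_hat <= 0.0 or p_hat >= 1.0:
                continue
            x2 = float(((k_g - n_g * p_hat) ** 2
                        / (p_hat * (1 - p_hat) * n_g)).sum())
            # E[X^2] ~ (m-1) * (1 + (nbar-1) phi)
            nbar = n_g.mean()
            if nbar > 1:
                num += (x2 / (m - 1) - 1.0) * (m - 1)
                den += (nbar - 1.0) * (m - 1)
                m_tot += m
        if den > 0 and m_tot >= 4:
            raw[i] = num / den
            weight[i] = m_tot - 3
    valid = np.isfinite(raw)
    if valid.sum() == 0:
        prior = default_prior
    else:
        vals = np.sort(np.clip(raw[valid], 0.0, 0.5))
        lo = int(math.floor(trim * len(vals)))
        hi = len(vals) - lo
        prior = float(vals[lo:hi].mean()) if hi > lo else float(vals.mean())
    phi = np.where(valid,
                   (weight * np.clip(raw, 0.0, 0.5) + prior_weight * prior)
                   / (weight + prior_weight),
                   prior)
    return np.clip(phi, 0.0, 0.5), prior


# ---------------------------------------------------------------------------
# Full comparison with BH-FDR
# ---------------------------------------------------------------------------


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def run_comparison(matrix, meta: pd.DataFrame, design: DesignSpec,
                   phi=None, level: str = "cpg") -> pd.DataFrame:
    """Test every locus of a RegionCountMatrix for one comparison.

    ``matrix`` is a :class:`methdmr.regions.RegionCountMatrix`. Samples are
    restricted to the design tissue and to the case/control groups. BH-FDR
    is computed across all tested loci of this stratum; rows are sorted by
    FDR then position. Returns a DMResult table (possibly empty).
    """
    meta = meta.set_index("sample_id") if "sample_id" in meta.columns else meta
    sel = meta["group"].isin(design.case_groups + (design.control_group,))
    if design.tissue is not None:
        sel &= meta["tissue"] == design.tissue
    samples = [s for s in matrix.samples if s in meta.index[sel]]
    if not samples:
        warnings.warn("no samples match the design; empty result")
        return _empty_result()
    sub = meta.loc[samples]
    case_mask = sub["group"].isin(design.case_groups).to_numpy()
    cov_cols = {}
    if "sex" in design.covariates:
        cov_cols["sex"] = (sub["sex"] == "M").astype(float).to_numpy()
    if "age" in design.covariates:
        cov_cols["age"] = sub["age_at_death"].to_numpy(dtype=float)
    covariates = pd.DataFrame(cov_cols, index=samples)

    K = matrix.meth[samples]
    N = matrix.total[samples]
    if phi is None:
        phi_arr, _ = estimate_dispersion(K, N, sub["group"])
    elif np.isscalar(phi):
        phi_arr = np.full(len(matrix.loci), float(phi))
    else:
        phi_arr = np.asarray(phi, dtype=float)

    rows = []
    Kv = K.to_numpy(dtype=float)
    Nv = N.to_numpy(dtype=float)
    for i, locus in enumerate(matrix.loci):
        fit = fit_locus(Kv[i], Nv[i], covariates, case_mask,
                        phi=float(phi_arr[i]), design=design)
        if fit.skipped:
            continue
        rows.append({
            "chrom": locus.chrom, "start": locus.start, "end": locus.end,
            "level": level, "group": design.name, "logFC": fit.logFC,
            "lrt_stat": fit.lrt_stat, "p_value": fit.p_value,
            "direction": fit.direction, "n_case": fit.n_case,
            "n_control": fit.n_control, "flag": fit.flag,
        })
    if not rows:
        warnings.warn("zero testable loci for this comparison")
        return _empty_result()
    out = pd.DataFrame(rows)
    out["fdr"] = bh_adjust(out["p_value"].to_numpy())
    out = out.sort_values(["fdr", "chrom", "start"], kind="mergesort",
                          ignore_index=True)
    return out


def _empty_result() -> pd.DataFrame:
    cols = ["chrom", "start", "end", "level", "group", "logFC", "lrt_stat",
            "p_value", "direction", "n_case", "n_control", "flag", "fdr"]
    return pd.DataFrame(columns=cols)
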