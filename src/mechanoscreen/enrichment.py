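"""Gene-level differential guide abundance between inlet and outlet samples.

The model follows the standard RNA-seq-style negative-binomial workflow
applied to summed guide counts per gene:

1. guide counts are summed within genes (all member guides per gene);
2. per-sample size factors by median-of-ratios against the geometric-mean
   reference gene profile;
3. per-gene NB dispersion alpha (variance = mu + alpha mu^2) by a
   method-of-moments estimate pooled within condition, combined with a
   parametric mean-dispersion trend alpha(mu) = a1/mu + a0; the working
   dispersion is the maximum of the gene estimate and the trend — a
   deliberately simplified, conservative take on the empirical-Bayes
   machinery of full differential-expression tools (no shrinkage toward
   the trend, no outlier refitting, no independent filtering), so hit
   lists are comparable but not numerically identical to theirs;
4. a per-gene NB log-linear GLM log mu_gj = log s_j + b0 + b1*[outlet],
   fitted by iteratively reweighted least squares, with a Wald test of
   b1 = 0 against the normal reference and Benjamini–Hochberg adjustment
   within each outlet-vs-inlet contrast;
5. hit classification at an adjusted-p threshold (default 0.001): enriched
   when log2FC > 0, depleted when < 0.

Positive log2 fold change means enrichment in the outlet.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import bh_adjust

__all__ = [
    "sum_gene_counts",
    "size_factors",
    "estimate_dispersions",
    "nb_wald_test",
    "guide_fold_changes",
    "classify_hits",
    "run_outlet_enrichment",
    "ALPHA_MIN",
]

ALPHA_MIN = 1e-8
_IRLS_TOL = 1e-8
_IRLS_MAXIT = 100


def sum_gene_counts(counts: pd.DataFrame, library: pd.DataFrame) -> pd.DataFrame:
    """Sum member-guide counts into gene x sample counts.

    Every count-matrix row must map to exactly one gene in the library;
    orphans are a hard error. Gene order is lexicographic.
    """
    guide_to_gene = library.set_index("guide_id")["gene"]
    orphans = [g for g in counts.index if g not in guide_to_gene.index]
    if orphans:
        raise ValueError(f"guides absent from library: {orphans[:10]}")
    genes = guide_to_gene.loc[counts.index]
    out = counts.groupby(genes.to_numpy()).sum()
    out.index.name = "gene"
    return out.sort_index()


def size_factors(gene_counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    The reference profile is the per-gene geometric mean across samples
    over genes positive in every sample; s_j is the median of K_gj / ref_g.
    """
    mat = gene_counts.to_numpy(dtype=float)
    positive = (mat > 0).all(axis=1)
    if not positive.any():
        raise ValueError(
            "no gene has positive counts in every sample; cannot form the "
            "median-of-ratios reference (consider a pseudo-reference)"
        )
    logs = np.log(mat[positive])
    ref = logs.mean(axis=1)
    s = np.exp(np.median(logs - ref[:, None], axis=0))
    s /= np.exp(np.mean(np.log(s)))
    return pd.Series(s, index=gene_counts.columns, name="size_factor")


def estimate_dispersions(
    gene_counts: pd.DataFrame,
    s: pd.Series,
    condition_of: Mapping[str, str],
    alpha_min: float = ALPHA_MIN,
) -> pd.Series:
    """Per-gene NB dispersion: fitted trend, gene-wise only for outliers.

    The gene-wise estimate pools within-condition moments of the normalized
    counts: alpha_hat = (pooled var - mean) / mean^2, floored at
    ``alpha_min``. A trend alpha(mu) = a1/mu + a0 is least-squares fitted
    over genes with above-floor estimates; because that fit conditions on a
    positive moments estimate it sits slightly above the underlying
    dispersion, which compensates the small-sample optimism of the normal
    Wald reference. The working dispersion is the trend value except for
    dispersion outliers — genes whose log alpha_hat exceeds the trend by
    more than twice the robust residual SD keep their own (larger)
    estimate, so heterogeneous genes cannot ride a low trend. With no
    replicated condition the trend cannot be estimated and a flat floor is
    returned with a warning.
    """
    samples = list(gene_counts.columns)
    conds: dict[str, list[str]] = {}
    for smp in samples:
        conds.setdefault(condition_of[smp], []).append(smp)
    norm = gene_counts.to_numpy(dtype=float) / s.loc[samples].to_numpy()
    replicated = [c for c, smps in conds.items() if len(smps) >= 2]
    if not replicated:
        import warnings

        warnings.warn("no replicated condition: dispersion fixed at the floor")
        return pd.Series(alpha_min, index=gene_counts.index, name="dispersion")

    num = np.zeros(len(gene_counts))
    den = np.zeros(len(gene_counts))
    df_sum = 0
    for cond in replicated:
        idx = [samples.index(x) for x in conds[cond]]
        sub = norm[:, idx]
        mu = sub.mean(axis=1)
        var = sub.var(axis=1, ddof=1)
        df = len(idx) - 1
        with np.errstate(divide="ignore", invalid="ignore"):
            contrib = np.where(mu > 0, (var - mu) / mu**2, 0.0)
        num += df * contrib
        den += df * (mu > 0)
        df_sum += df
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha_hat = np.where(den > 0, num / np.maximum(den, 1), 0.0)
    alpha_hat = np.maximum(alpha_hat, alpha_min)

    base_mean = norm.mean(axis=1)
    fit_mask = (alpha_hat > alpha_min) & (base_mean > 0)
    if fit_mask.sum() >= 10:
        x = np.column_stack([1.0 / base_mean[fit_mask], np.ones(int(fit_mask.sum()))])
        coef, *_ = np.linalg.lstsq(x, alpha_hat[fit_mask], rcond=None)
        a1, a0 = float(coef[0]), float(coef[1])
        with np.errstate(divide="ignore"):
            trend = np.where(base_mean > 0, a1 / base_mean + a0, alpha_min)
        trend = np.maximum(trend, alpha_min)
        # robust SD of log-ratio residuals -> dispersion-outlier cutoff
        log_ratio = np.log(alpha_hat[fit_mask] / trend[fit_mask])
        sd_lr = 1.4826 * float(np.median(np.abs(log_ratio - np.median(log_ratio))))
        outlier = alpha_hat > trend * np.exp(2.0 * max(sd_lr, 0.1))
        alpha = np.where(outlier, alpha_hat, trend)
    else:
        alpha = alpha_hat
    return pd.Series(np.maximum(alpha, alpha_min), index=gene_counts.index,
                     name="dispersion")


def _irls_two_group(
    y: np.ndarray,
    x: np.ndarray,
    offset: np.ndarray,
    alpha: np.ndarray,
    tol: float = _IRLS_TOL,
    maxit: int = _IRLS_MAXIT,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised IRLS for the 2-parameter NB log-linear model, per gene.

    y: (G, n) counts; x: (n,) 0/1 condition indicator; offset: (n,) log
    size factors; alpha: (G,) dispersions. Returns (beta0, beta1, se1,
    converged).
    """
    G, n = y.shape
    mu_init = np.clip(y, 0.5, None)
    eta = np.log(mu_init) - offset
    # least-squares init on the log scale
    xm = np.column_stack([np.ones(n), x])
    beta, *_ = np.linalg.lstsq(xm, eta.T, rcond=None)
    b0, b1 = beta[0].copy(), beta[1].copy()
    converged = np.zeros(G, dtype=bool)
    a = alpha[:, None]
    for _ in range(maxit):
        eta = offset[None, :] + b0[:, None] + b1[:, None] * x[None, :]
        mu = np.exp(np.clip(eta, -30.0, 30.0))
        w = mu / (1.0 + a * mu)
        z = (eta - offset[None, :]) + (y - mu) / mu
        s00 = w.sum(axis=1)
        s01 = (w * x).sum(axis=1)
        s11 = (w * x * x).sum(axis=1)
        t0 = (w * z).sum(axis=1)
        t1 = (w * x * z).sum(axis=1)
        det = s00 * s11 - s01 * s01
        det = np.where(np.abs(det) < 1e-300, np.nan, det)
        nb0 = (s11 * t0 - s01 * t1) / det
        nb1 = (s00 * t1 - s01 * t0) / det
        step0 = nb0 - b0
        step1 = nb1 - b1
        move = ~converged & np.isfinite(step0) & np.isfinite(step1)
        b0 = np.where(move, nb0, b0)
        b1 = np.where(move, nb1, b1)
        newly = move & (np.abs(step0) < tol) & (np.abs(step1) < tol)
        converged |= newly
        if converged.all():
            break
    eta = offset[None, :] + b0[:, None] + b1[:, None] * x[None, :]
    mu = np.exp(np.clip(eta, -30.0, 30.0))
    w = mu / (1.0 + a * mu)
    s00 = w.sum(axis=1)
    s01 = (w * x).sum(axis=1)
    s11 = (w * x * x).sum(axis=1)
    det = s00 * s11 - s01 * s01
    with np.errstate(divide="ignore", invalid="ignore"):
        se1 = np.sqrt(np.where(det > 0, s00 / det, np.nan))
    return b0, b1, se1, converged


def nb_wald_test(
    gene_counts: pd.DataFrame,
    inlet_samples: Sequence[str],
    outlet_samples: Sequence[str],
    s: pd.Series,
    alpha: pd.Series,
) -> pd.DataFrame:
    """Per-gene NB Wald test of outlet vs inlet differential abundance.

    Fits log mu_gj = log s_j + b0_g + b1_g * [sample is outlet] by IRLS with
    NB weights mu/(1 + alpha mu); reports log2FC = b1/ln2, its standard
    error from the Fisher information at the optimum, the Wald z, two-sided
    normal p, and BH-adjusted p. Genes with zero counts in every sample are
    excluded (status recorded); non-converged fits are flagged with p = 1.
    """
    inlet_samples = list(inlet_samples)
    outlet_samples = list(outlet_samples)
    if not inlet_samples or not outlet_samples:
        raise ValueError("both conditions need at least one sample")
    samples = inlet_samples + outlet_samples
    y = gene_counts[samples].to_numpy(dtype=float)
    x = np.array([0.0] * len(inlet_samples) + [1.0] * len(outlet_samples))
    offset = np.log(s.loc[samples].to_numpy(dtype=float))
    nonzero = y.sum(axis=1) > 0
    genes = gene_counts.index.to_numpy()
    res = pd.DataFrame(
        index=pd.Index(genes, name="gene"),
        columns=[
            "baseMean", "log2FC", "SE", "wald_z", "pvalue", "padj",
            "converged", "tested",
        ],
    )
    norm = y / np.exp(offset)[None, :]
    res["baseMean"] = norm.mean(axis=1)
    res["tested"] = nonzero
    if nonzero.any():
        b0, b1, se1, conv = _irls_two_group(
            y[nonzero], x, offset, alpha.loc[genes[nonzero]].to_numpy(dtype=float)
        )
        ln2 = np.log(2.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            z = b1 / se1
            p = 2.0 * sps.norm.sf(np.abs(z))
        p = np.where(conv & np.isfinite(p), p, 1.0)
        z = np.where(np.isfinite(z), z, 0.0)
        res.loc[genes[nonzero], "log2FC"] = b1 / ln2
        res.loc[genes[nonzero], "SE"] = se1 / ln2
        res.loc[genes[nonzero], "wald_z"] = z
        res.loc[genes[nonzero], "pvalue"] = p
        res.loc[genes[nonzero], "converged"] = conv
        res.loc[genes[nonzero], "padj"] = bh_adjust(p)
    for col in ("baseMean", "log2FC", "SE", "wald_z", "pvalue", "padj"):
        res[col] = pd.to_numeric(res[col])
    res["converged"] = res["converged"].astype("boolean").fillna(False).astype(bool)
    res["tested"] = res["tested"].astype(bool)
    return res


def guide_fold_changes(
    counts: pd.DataFrame,
    s: pd.Series,
    inlet_samples: Sequence[str],
    outlet_samples: Sequence[str],
    library: pd.DataFrame,
    pseudocount: float = 0.5,
) -> tuple[pd.Series, pd.Series]:
    """Normalized per-guide fold change (outlet mean / inlet mean) + gene max.

    FC_g = (mean normalized outlet + pc) / (mean normalized inlet + pc).
    The gene summary is the maximum over member guides — a gene passes a
    fold-change filter if any of its guides does. Guides with zero inlet
    signal still yield finite values through the pseudocount.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    norm = counts / s.loc[counts.columns]
    inlet_mean = norm[list(inlet_samples)].mean(axis=1)
    outlet_mean = norm[list(outlet_samples)].mean(axis=1)
    fc = (outlet_mean + pseudocount) / (inlet_mean + pseudocount)
    fc.name = "guide_fc"
    genes = library.set_index("guide_id")["gene"].loc[counts.index]
    gene_max = fc.groupby(genes.to_numpy()).max().sort_index()
    gene_max.index.name = "gene"
    gene_max.name = "max_guide_fc"
    return fc, gene_max


def classify_hits(fit: pd.DataFrame, threshold: float = 0.001) -> pd.DataFrame:
    """Attach enriched/depleted/ns status at the adjusted-p threshold."""
    out = fit.copy()
    sig = (out["padj"] < threshold) & out["tested"]
    out["status"] = np.where(
        sig & (out["log2FC"] > 0),
        "enriched",
        np.where(sig & (out["log2FC"] < 0), "depleted", "ns"),
    )
    return out


def run_outlet_enrichment(
    counts: pd.DataFrame,
    library: pd.DataFrame,
    manifest: pd.DataFrame,
    threshold: float = 0.001,
    pseudocount: float = 0.5,
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """Test every outlet against the inlet; return per-outlet tables + summary.

    Each outlet is a separate two-condition contrast against the pooled
    inlet replicates (size factors and dispersions estimated on the samples
    entering that contrast); BH adjustment is applied within each contrast.
    The summary table counts enriched/depleted genes per outlet.
    """
    roles = manifest.set_index("sample")["role"]
    inlet = [s_ for s_, r in roles.items() if r == "inlet"]
    if not inlet:
        raise ValueError("manifest names no inlet samples")
    outlets = sorted({r for r in roles if r.startswith("outlet")})
    results: dict[str, pd.DataFrame] = {}
    summary_rows = []
    gene_counts_all = sum_gene_counts(counts, library)
    for outlet in outlets:
        outlet_samples = [s_ for s_, r in roles.items() if r == outlet]
        samples = inlet + outlet_samples
        gene_counts = gene_counts_all[samples]
        s = size_factors(gene_counts)
        cond = {smp: ("inlet" if smp in inlet else outlet) for smp in samples}
        alpha = estimate_dispersions(gene_counts, s, cond)
        fit = nb_wald_test(gene_counts, inlet, outlet_samples, s, alpha)
        fit = classify_hits(fit, threshold)
        _, gene_fc = guide_fold_changes(
            counts[samples], s, inlet, outlet_samples, library, pseudocount
        )
        fit["max_guide_fc"] = gene_fc
        fit["outlet"] = outlet
        results[outlet] = fit
        summary_rows.append(
            {
                "outlet": outlet,
                "enriched": int((fit["status"] == "enriched").sum()),
                "depleted": int((fit["status"] == "depleted").sum()),
                "ns": int((fit["status"] == "ns").sum()),
            }
        )
    return results, pd.DataFrame(summary_rows).set_index("outlet")
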