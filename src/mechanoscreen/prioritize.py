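"""Hit-prioritization cascade for screen candidates.

Enriched genes from the stiff-outlet contrast are narrowed by a conjunction
of filters: membership in mechanics-relevant functional categories,
top-tercile expression in the screened cell line, >100-fold guide-level
enrichment, enrichment in the designated outlet, and a significant
bottom-vs-top expression-tercile split (log-rank p < 0.05) in both overall
and progression-free patient survival. Every filter records an explicit
pass/fail per gene; genes missing from a lookup table fail that filter
with the reason recorded rather than being silently dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .stats import SurvivalComparison, km_estimate, logrank_test

__all__ = [
    "CandidateFilterConfig",
    "expression_terciles",
    "survival_tercile_test",
    "filter_candidates",
    "read_expression",
    "read_categories",
    "read_clinical",
]

DEFAULT_CATEGORIES = frozenset(
    {
        "cytoskeleton",
        "adhesion & migration",
        "cell cycle",
        "MAPK signaling",
        "Wnt signaling",
        "Notch signaling",
        "PI3K signaling",
        "JNK signaling",
        "TGFb signaling",
    }
)


@dataclass(frozen=True)
class CandidateFilterConfig:
    """Thresholds of the prioritization cascade."""

    categories: frozenset[str] = DEFAULT_CATEGORIES
    expression_tercile: str = "top"
    min_fold_change: float = 100.0
    required_outlet: str = "outlet4"
    survival_alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.expression_tercile not in {"top", "middle", "bottom"}:
            raise ValueError("expression tercile must be top/middle/bottom")
        if self.min_fold_change <= 0 or self.survival_alpha <= 0:
            raise ValueError("thresholds must be positive")


def expression_terciles(expr: pd.Series) -> pd.Series:
    """Label genes bottom/middle/top by expression tercile.

    Rank-based: genes are stably sorted by value (ties keep input order and
    fall toward the lower tercile) and split into three groups whose sizes
    differ by at most one, extras going to the lower terciles first.
    Invariant under monotone transforms of the values.
    """
    vals = expr.dropna()
    if len(vals) < 3:
        raise ValueError("need at least 3 genes with finite expression")
    if vals.nunique() == 1:
        raise ValueError("all expression values equal: terciles undefined")
    order = vals.to_numpy().argsort(kind="stable")
    n = len(vals)
    q, r = divmod(n, 3)
    sizes = [q + (1 if i < r else 0) for i in range(3)]
    labels = np.empty(n, dtype=object)
    start = 0
    for size, name in zip(sizes, ("bottom", "middle", "top")):
        labels[order[start:start + size]] = name
        start += size
    return pd.Series(labels, index=vals.index, name="tercile")


def survival_tercile_test(
    expr: pd.Series,
    clinical: pd.DataFrame,
    endpoint: str,
) -> SurvivalComparison:
    """Bottom- vs top-expression-tercile survival contrast for one gene.

    ``expr`` holds one expression value per patient; ``clinical`` must have
    ``time_months`` and ``event`` columns on the same patient index. The
    middle tercile is discarded. Reports the log-rank chi-square/p and the
    difference of KM medians, median(low) - median(high), in months;
    undefined medians are flagged but the test is still reported.
    """
    common = expr.index.intersection(clinical.index)
    expr = expr.loc[common]
    clin = clinical.loc[common]
    terciles = expression_terciles(expr)
    low = terciles.index[terciles == "bottom"]
    high = terciles.index[terciles == "top"]
    if len(low) < 2 or len(high) < 2:
        raise ValueError("need >= 2 patients per tercile group")
    t_low = clin.loc[low, "time_months"].to_numpy(dtype=float)
    e_low = clin.loc[low, "event"].to_numpy(dtype=int)
    t_high = clin.loc[high, "time_months"].to_numpy(dtype=float)
    e_high = clin.loc[high, "event"].to_numpy(dtype=int)
    lr = logrank_test(t_low, e_low, t_high, e_high)
    km_low = km_estimate(t_low, e_low)
    km_high = km_estimate(t_high, e_high)
    flags = [f for f in (lr.flag,) if f]
    if not np.isfinite(km_low.median) or not np.isfinite(km_high.median):
        flags.append("undefined-median")
        diff = float("nan")
    else:
        diff = km_low.median - km_high.median
    return SurvivalComparison(
        endpoint=endpoint,
        median_low=km_low.median,
        median_high=km_high.median,
        median_difference=diff,
        logrank_chi2=lr.statistic,
        logrank_p=lr.p,
        n_low=len(low),
        n_high=len(high),
        flags=tuple(flags),
    )


def filter_candidates(
    results: Mapping[str, pd.DataFrame],
    categories: Mapping[str, set[str]] | pd.DataFrame,
    terciles: pd.Series,
    survival: Mapping[str, Mapping[str, SurvivalComparison]],
    config: CandidateFilterConfig = CandidateFilterConfig(),
) -> pd.DataFrame:
    """Apply the full prioritization cascade; one row per gene considered.

    ``results`` maps outlet -> enrichment table (from classify_hits);
    ``categories`` maps gene -> set of category labels (or a two-column
    gene/category DataFrame); ``survival`` maps gene -> {"OS": ..., "PFS":
    ...}. The candidate set is the genes of the required outlet's table;
    each filter contributes a boolean column and ``candidate`` is their
    conjunction. Missing lookups fail the corresponding filter and are
    listed in ``missing``.
    """
    if config.required_outlet not in results:
        if not results:
            return _empty_candidate_table()
        raise KeyError(f"no enrichment results for {config.required_outlet}")
    table = results[config.required_outlet]
    if isinstance(categories, pd.DataFrame):
        categories = {
            g: set(grp["category"]) for g, grp in categories.groupby("gene")
        }
    rows = []
    for gene, row in table.iterrows():
        missing = []
        enriched = row.get("status") == "enriched"
        cats = categories.get(gene)
        if cats is None:
            missing.append("category")
            cat_ok = False
        else:
            cat_ok = bool(cats & config.categories)
        if gene in terciles.index:
            terc = terciles.loc[gene]
            terc_ok = terc == config.expression_tercile
        else:
            missing.append("expression")
            terc, terc_ok = None, False
        fc = row.get("max_guide_fc")
        fc_ok = bool(pd.notna(fc) and fc > config.min_fold_change)
        surv = survival.get(gene)
        if surv is None or "OS" not in surv or "PFS" not in surv:
            missing.append("survival")
            os_p = pfs_p = float("nan")
            os_diff = pfs_diff = float("nan")
            surv_ok = False
        else:
            os_p = surv["OS"].logrank_p
            pfs_p = surv["PFS"].logrank_p
            os_diff = surv["OS"].median_difference
            pfs_diff = surv["PFS"].median_difference
            surv_ok = (os_p < config.survival_alpha) and (pfs_p < config.survival_alpha)
        rows.append(
            {
                "gene": gene,
                "outlet": config.required_outlet,
                "log2FC": row.get("log2FC"),
                "padj": row.get("padj"),
                "max_guide_fc": fc,
                "expression_tercile": terc,
                "os_p": os_p,
                "os_median_diff_months": os_diff,
                "pfs_p": pfs_p,
                "pfs_median_diff_months": pfs_diff,
                "pass_enriched": bool(enriched),
                "pass_category": cat_ok,
                "pass_expression": bool(terc_ok),
                "pass_fold_change": fc_ok,
                "pass_survival": surv_ok,
                "missing": ";".join(missing),
            }
        )
    out = pd.DataFrame(rows, columns=_CANDIDATE_COLUMNS).set_index("gene")
    passes = [c for c in out.columns if c.startswith("pass_")]
    out["candidate"] = out[passes].all(axis=1)
    return out


_CANDIDATE_COLUMNS = [
    "gene", "outlet", "log2FC", "padj", "max_guide_fc", "expression_tercile",
    "os_p", "os_median_diff_months", "pfs_p", "pfs_median_diff_months",
    "pass_enriched", "pass_category", "pass_expression", "pass_fold_change",
    "pass_survival", "missing",
]


def _empty_candidate_table() -> pd.DataFrame:
    out = pd.DataFrame(columns=_CANDIDATE_COLUMNS).set_index("gene")
    out["candidate"] = pd.Series(dtype=bool)
    return out


# ---------------------------------------------------------------------------
# file readers
# ---------------------------------------------------------------------------

def read_expression(path: str | Path) -> pd.Series:
    """gene,value CSV -> expression Series."""
    df = pd.read_csv(path)
    if not {"gene", "value"} <= set(df.columns):
        raise ValueError(f"{path}: expected columns gene,value")
    return df.set_index("gene")["value"].astype(float)


def read_categories(path: str | Path) -> pd.DataFrame:
    """gene,category CSV (multi-row per gene)."""
    df = pd.read_csv(path)
    if not {"gene", "category"} <= set(df.columns):
        raise ValueError(f"{path}: expected columns gene,category")
    return df


def read_clinical(path: str | Path) -> pd.DataFrame:
    """patient survival CSV: patient_id,time_months,event[,<gene> columns].

    Gene-named columns carry per-patient expression used for tercile splits.
    """
    df = pd.read_csv(path)
    required = {"patient_id", "time_months", "event"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(required)}")
    return df.set_index("patient_id")
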