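"""Genome-wide screen correlating baseline expression with FOS change.

For every gene (or ISH experiment of a gene) the screen computes the
Pearson correlation between its baseline regional expression density
(%-pixel) and the per-region log-fold change of FOS counts between
treatment and control, tests it two-sided, and controls the family-wise
false discovery rate with the Benjamini-Hochberg step-up at q = 0.05.
Atlas rows are incomplete, so missing regions are removed pairwise per
row and rows with fewer than four usable regions are reported as untested
rather than non-significant.  The frontal pole cerebral cortex is excluded
by default as an outlier.

The nicotinic-receptor panel (Chrna1-10, Chrnb1-3, Chrnd, Chat) is carried
as a named gene set; multi-experiment genes are summarized by centering
and scaling each experiment over its regions before averaging.
"""

from __future__ import annotations

from collections.abc import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "NACHR_PANEL",
    "DEFAULT_SCREEN_EXCLUSIONS",
    "standardize_and_average",
    "screen",
    "bh_fdr",
    "summarize_by_gene",
]

#: Cholinergic-related genes tracked as a panel through the screen.
NACHR_PANEL: tuple[str, ...] = tuple(
    [f"Chrna{i}" for i in range(1, 11)]
    + [f"Chrnb{i}" for i in range(1, 4)]
    + ["Chrnd", "Chat"]
)

#: Frontal pole cerebral cortex, excluded as an outlier region.
DEFAULT_SCREEN_EXCLUSIONS: tuple[str, ...] = ("FRP",)


def standardize_and_average(
    expr: pd.DataFrame, gene_of: Mapping[str, str] | None = None
) -> pd.DataFrame:
    """Z-score each experiment row over its regions, then average per gene.

    ``gene_of`` maps experiment row IDs to gene symbols; rows without an
    entry (or when the map is omitted) are treated as single-experiment
    genes under their own ID.  Zero-variance rows carry no profile
    information and are dropped with a warning.
    """
    import warnings

    gene_of = dict(gene_of or {})
    z_rows, genes = [], []
    for row_id, row in expr.iterrows():
        vals = row.dropna()
        if vals.size < 2 or vals.std(ddof=1) == 0:
            warnings.warn(
                f"dropping zero-variance/short experiment row {row_id!r}",
                stacklevel=2,
            )
            continue
        z = (row - vals.mean()) / vals.std(ddof=1)
        z_rows.append(z)
        genes.append(gene_of.get(row_id, row_id))
    if not z_rows:
        raise ValueError("no usable experiment rows")
    z = pd.DataFrame(z_rows)
    z["__gene__"] = genes
    return z.groupby("__gene__").mean().rename_axis("gene")


def bh_fdr(p_values: Sequence[float], q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: adjusted q-values and discovery flags.

    q_(i) = min_{j >= i} p_(j) * m / j, capped at 1; discovery iff the
    adjusted value is <= q (boundary inclusive).
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    _, qvals, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return qvals, qvals <= q


def _row_correlation(x: pd.Series, lfc: pd.Series, min_regions: int):
    both = x.notna() & lfc.notna()
    n = int(both.sum())
    if n < min_regions:
        return n, np.nan, np.nan, f"only {n} overlapping regions (< {min_regions})"
    xv = x[both].to_numpy(dtype=float)
    yv = lfc[both].to_numpy(dtype=float)
    if np.ptp(xv) == 0:
        return n, np.nan, np.nan, "constant expression over overlap"
    if np.ptp(yv) == 0:
        return n, np.nan, np.nan, "constant log-fold change over overlap"
    res = stats.pearsonr(xv, yv)
    return n, float(res.statistic), float(res.pvalue), ""


def screen(
    expr: pd.DataFrame,
    lfc: pd.Series,
    *,
    exclude_regions: Sequence[str] = DEFAULT_SCREEN_EXCLUSIONS,
    fdr_q: float = 0.05,
    min_regions: int = 4,
) -> pd.DataFrame:
    """Correlate every expression row with the regional FOS log-fold change.

    Returns a DataFrame indexed like ``expr`` with columns ``n_regions``,
    ``r``, ``p``, ``q``, ``significant`` and ``untested_reason``; rows
    failing the minimum-overlap precondition stay untested (NaN r/p/q) and
    never count as significant.  BH adjustment runs across all tested rows
    as one family.
    """
    excluded = {str(r).strip() for r in exclude_regions}
    common = [c for c in expr.columns if c in set(lfc.index) and c not in excluded]
    if len(common) < min_regions:
        raise ValueError(
            f"only {len(common)} regions shared between expression matrix and "
            f"log-fold-change vector after exclusions; need >= {min_regions}"
        )
    sub_lfc = lfc[common]

    rows = []
    for row_id, row in expr[common].iterrows():
        n, r, p, reason = _row_correlation(row, sub_lfc, min_regions)
        rows.append((row_id, n, r, p, reason))
    out = pd.DataFrame(
        rows, columns=["row", "n_regions", "r", "p", "untested_reason"]
    ).set_index("row")
    out.index.name = expr.index.name or "row"

    tested = out["p"].notna()
    out["q"] = np.nan
    out["significant"] = False
    if tested.any():
        qvals, reject = bh_fdr(out.loc[tested, "p"].to_numpy(), q=fdr_q)
        out.loc[tested, "q"] = qvals
        out.loc[tested, "significant"] = reject
    return out[["n_regions", "r", "p", "q", "significant", "untested_reason"]]


def summarize_by_gene(
    result: pd.DataFrame, gene_of: Mapping[str, str] | None = None
) -> pd.DataFrame:
    """Collapse per-experiment screen rows to genes.

    A gene is flagged significant when any of its experiments is (the most
    permissive reading); ``best_q`` and ``mean_r`` summarize across its
    tested experiments.
    """
    gene_of = dict(gene_of or {})
    genes = [gene_of.get(i, i) for i in result.index]
    grouped = result.assign(gene=genes).groupby("gene")
    summary = pd.DataFrame(
        {
            "n_experiments": grouped.size(),
            "n_tested": grouped["p"].count(),
            "mean_r": grouped["r"].mean(),
            "best_q": grouped["q"].min(),
            "significant": grouped["significant"].any(),
        }
    )
    return summary


def significance_switch_point(result: pd.DataFrame) -> float:
    """Smallest |r| among significant rows: the screen's |r| cutoff.

    With a single FDR family the BH step-up induces an effective
    absolute-correlation threshold (|r| ~ 0.23 in the study's full-atlas
    screen); NaN when nothing is significant.
    """
    sig = result.loc[result["significant"], "r"]
    return float(sig.abs().min()) if len(sig) else float("nan")
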