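"""Per-group functional connectome: normalization, correlation, modules.

A functional connectome here is the region x region matrix of Pearson
correlations of log10(count + 1)-normalized FOS counts across the subjects
of one treatment group.  Regions are hierarchically clustered on the
Euclidean distances between rows of that correlation matrix (each region
represented by its correlation profile to every region, as heatmap
clustering does) and modules are read off by cutting the dendrogram at a
fraction of its maximum merge height -- half height by default.

The linkage method defaults to complete linkage; ``average`` and ``ward``
are available, and ``1 - R`` can be used as the distance instead of
row-profile distances, via keyword arguments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

from .io_core import FosCountTable

__all__ = [
    "GroupConnectome",
    "normalize_counts",
    "group_correlation",
    "cluster_and_cut",
    "build_connectome",
    "log_fold_change",
    "dendrogram_to_newick",
]

LINKAGE_METHODS = ("complete", "average", "ward")


class IncompleteCorrelationError(ValueError):
    """R contains missing entries (a region had zero variance in its group)."""


def normalize_counts(table: FosCountTable) -> pd.DataFrame:
    """log10(count + 1) per cell; the variance-stabilizing normalization."""
    return np.log10(table.counts.astype(float) + 1.0)


def group_correlation(
    normalized: pd.DataFrame,
    group_of,
    group: str,
) -> pd.DataFrame:
    """Region x region Pearson correlation within one treatment group.

    A region whose normalized counts are constant within the group has no
    defined correlation; its off-diagonal entries are set to NaN (never
    silently zeroed) and downstream stages must drop it or refuse.
    """
    subjects = [s for s in normalized.columns if group_of[s] == group]
    if len(subjects) < 3:
        raise ValueError(
            f"group {group!r} has {len(subjects)} subjects; need >= 3 for correlation"
        )
    sub = normalized[subjects].to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        R = np.corrcoef(sub)
    flat = sub.std(axis=1) == 0
    if flat.any():
        R[flat, :] = np.nan
        R[:, flat] = np.nan
    np.fill_diagonal(R, 1.0)
    R = np.clip(R, -1.0, 1.0)
    return pd.DataFrame(R, index=normalized.index, columns=normalized.index)


def _distance_condensed(R: pd.DataFrame, metric: str) -> np.ndarray:
    if metric == "rows":
        return pdist(R.to_numpy(), metric="euclidean")
    if metric == "one-minus-r":
        return squareform(1.0 - R.to_numpy(), checks=False)
    raise ValueError(f"unknown distance metric {metric!r}; use 'rows' or 'one-minus-r'")


def cluster_and_cut(
    R: pd.DataFrame,
    *,
    method: str = "complete",
    cut_fraction: float = 0.5,
    metric: str = "rows",
) -> tuple[np.ndarray, pd.Series]:
    """Agglomerative clustering of R plus the half-height module partition.

    Returns the scipy linkage matrix and a region -> module Series.  A
    merge survives the cut iff its height is <= ``cut_fraction`` times the
    maximum merge height; module IDs are contiguous integers numbered by
    first occurrence in dendrogram leaf order.
    """
    if R.isna().to_numpy().any():
        bad = list(R.index[R.isna().any(axis=1)])
        raise IncompleteCorrelationError(
            f"R has missing entries for regions {bad}; these regions had zero "
            "variance within the group -- drop them before clustering"
        )
    if method not in LINKAGE_METHODS:
        raise ValueError(f"linkage method must be one of {LINKAGE_METHODS}")
    if not 0.0 <= cut_fraction <= 1.0:
        raise ValueError("cut_fraction must be in [0, 1]")
    if len(R) == 1:
        return np.empty((0, 4)), pd.Series([0], index=R.index, name="module")

    Z = hierarchy.linkage(_distance_condensed(R, metric), method=method)
    height = float(Z[:, 2].max())
    raw = hierarchy.fcluster(Z, t=cut_fraction * height, criterion="distance")

    leaf_order = hierarchy.leaves_list(Z)
    relabel: dict[int, int] = {}
    for leaf in leaf_order:
        relabel.setdefault(raw[leaf], len(relabel))
    modules = pd.Series(
        [relabel[c] for c in raw], index=R.index, name="module", dtype=int
    )
    return Z, modules


@dataclass(frozen=True)
class GroupConnectome:
    """One treatment group's functional connectome and its module partition."""

    group: str
    R: pd.DataFrame = field(repr=False)
    linkage: np.ndarray = field(repr=False)
    modules: pd.Series = field(repr=False)
    method: str = "complete"
    cut_fraction: float = 0.5
    metric: str = "rows"

    @property
    def regions(self) -> list[str]:
        return list(self.R.index)

    @property
    def n_modules(self) -> int:
        return int(self.modules.nunique())

    def distance_matrix(self) -> pd.DataFrame:
        """Euclidean distances between rows of R (the clustering input)."""
        D = squareform(pdist(self.R.to_numpy(), metric="euclidean"))
        return pd.DataFrame(D, index=self.R.index, columns=self.R.index)


def build_connectome(
    table: FosCountTable,
    group: str,
    *,
    method: str = "complete",
    cut_fraction: float = 0.5,
    metric: str = "rows",
) -> GroupConnectome:
    """Normalize, correlate and cluster one group's counts in one call."""
    normalized = normalize_counts(table)
    R = group_correlation(normalized, table.group_of, group)
    Z, modules = cluster_and_cut(
        R, method=method, cut_fraction=cut_fraction, metric=metric
    )
    return GroupConnectome(
        group=group,
        R=R,
        linkage=Z,
        modules=modules,
        method=method,
        cut_fraction=cut_fraction,
        metric=metric,
    )


def log_fold_change(
    table: FosCountTable,
    treatment: str | None = None,
    control: str | None = None,
) -> pd.Series:
    """Per-region log10 fold change of group-mean counts, +1-stabilized.

    lfc[r] = log10(mean_treatment[r] + 1) - log10(mean_control[r] + 1),
    means taken over raw counts within each group.  If the table's labels
    are exactly {"control", "treatment"} the roles are inferred; otherwise
    both must be given explicitly so signs cannot silently flip.
    """
    groups = set(table.groups)
    if treatment is None and control is None:
        if groups == {"control", "treatment"}:
            treatment, control = "treatment", "control"
        else:
            raise ValueError(
                f"group labels {sorted(groups)} are not the default pair; "
                "pass treatment= and control= explicitly"
            )
    if treatment not in groups or control not in groups or treatment == control:
        raise ValueError(
            f"treatment={treatment!r}, control={control!r} must be the two "
            f"distinct labels among {sorted(groups)}"
        )
    counts = table.counts.astype(float)
    mean_t = counts[table.subjects_in(treatment)].mean(axis=1)
    mean_c = counts[table.subjects_in(control)].mean(axis=1)
    lfc = np.log10(mean_t + 1.0) - np.log10(mean_c + 1.0)
    lfc.name = "lfc"
    return lfc


def dendrogram_to_newick(Z: np.ndarray, labels: list[str]) -> str:
    """Serialize a linkage matrix as Newick with branch lengths.

    Branch length of a child = parent merge height minus the child's own
    merge height (0 for leaves at height 0).
    """
    n = len(labels)
    if n == 1:
        return f"{labels[0]};"

    def height(node: int) -> float:
        return 0.0 if node < n else float(Z[node - n, 2])

    def render(node: int, parent_h: float) -> str:
        if node < n:
            return f"{labels[node]}:{parent_h:.6g}"
        left, right = int(Z[node - n, 0]), int(Z[node - n, 1])
        h = height(node)
        return f"({render(left, h)},{render(right, h)}):{parent_h - h:.6g}"

    root = n + len(Z) - 1
    left, right = int(Z[-1, 0]), int(Z[-1, 1])
    h = height(root)
    return f"({render(left, h)},{render(right, h)});"
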