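"""Tabular I/O and region metadata for the FOS connectomics pipeline.

The pipeline's raw signal is a table of FOS-positive cell counts per brain
region for a panel of subjects split into exactly two treatment groups
(e.g. nicotine withdrawal vs. saline control).  This module owns that
container (:class:`FosCountTable`), the region-metadata table that assigns
each region an anatomical group and, for the seven long-range cholinergic
regions, a cholinergic cell-group (Ch1-Ch7) and subsystem label, and the
delimited-text readers/writers everything downstream uses.

All readers are total on valid files and fail loudly on invalid ones;
region-name matching is exact string comparison after trimming surrounding
whitespace.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable, Mapping
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "FosCountTable",
    "RegionMetadata",
    "DEFAULT_EXCLUDED_REGIONS",
    "read_fos_counts",
    "write_fos_counts",
    "apply_region_exclusions",
    "read_expression_matrix",
    "write_expression_matrix",
    "write_graph",
    "write_table",
    "load_default_metadata",
]

#: Acronyms of the three regions dropped from the raw panel during quality
#: control: dorsal premammillary nucleus (PMd), parabigeminal nucleus (PBG)
#: and suprachiasmatic nucleus (SCH) -- regions with low-to-no FOS counts.
DEFAULT_EXCLUDED_REGIONS: tuple[str, ...] = ("PMd", "PBG", "SCH")

_FLOAT_FMT = "%.6g"


class TableValidationError(ValueError):
    """A delimited input failed structural validation."""


@dataclass(frozen=True)
class FosCountTable:
    """Region x subject FOS+ cell counts plus a subject -> group map.

    Parameters
    ----------
    counts
        DataFrame indexed by region acronym with one column per subject;
        entries are non-negative integers (number of FOS+ cells detected
        in that region for that subject).
    group_of
        Mapping from subject ID to treatment-group label.  Exactly two
        groups are allowed and each needs at least three subjects, the
        minimum for a Pearson correlation to be defined downstream.
    """

    counts: pd.DataFrame
    group_of: Mapping[str, str]

    def __post_init__(self) -> None:
        counts = self.counts
        if counts.index.has_duplicates:
            dupes = counts.index[counts.index.duplicated()].unique().tolist()
            raise TableValidationError(f"duplicate region acronyms: {dupes}")
        if counts.columns.has_duplicates:
            dupes = counts.columns[counts.columns.duplicated()].unique().tolist()
            raise TableValidationError(f"duplicate subject IDs: {dupes}")
        values = counts.to_numpy()
        if values.size == 0:
            raise TableValidationError("empty count table")
        if not np.issubdtype(values.dtype, np.number):
            raise TableValidationError("non-numeric entries in count table")
        bad = np.argwhere(~np.isfinite(values) | (values < 0) | (values != np.floor(values)))
        if bad.size:
            i, j = bad[0]
            raise TableValidationError(
                f"count for region {counts.index[i]!r}, subject {counts.columns[j]!r} "
                f"is {values[i, j]!r}; counts must be non-negative integers"
            )
        missing = [s for s in counts.columns if s not in self.group_of]
        if missing:
            raise TableValidationError(f"subjects without a group label: {missing}")
        groups = pd.Series({s: self.group_of[s] for s in counts.columns})
        labels = sorted(groups.unique())
        if len(labels) != 2:
            raise TableValidationError(
                f"expected exactly 2 treatment groups, found {len(labels)}: {labels}"
            )
        sizes = groups.value_counts()
        small = sizes[sizes < 3]
        if not small.empty:
            raise TableValidationError(
                "each group needs >= 3 subjects for inter-regional correlation; "
                f"too small: {small.to_dict()}"
            )

    @property
    def regions(self) -> list[str]:
        return list(self.counts.index)

    @property
    def subjects(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def groups(self) -> list[str]:
        """The two group labels, sorted."""
        return sorted({self.group_of[s] for s in self.counts.columns})

    def subjects_in(self, group: str) -> list[str]:
        return [s for s in self.counts.columns if self.group_of[s] == group]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FosCountTable):
            return NotImplemented
        return self.counts.equals(other.counts) and {
            s: self.group_of[s] for s in self.subjects
        } == {s: other.group_of[s] for s in other.subjects}


@dataclass(frozen=True)
class RegionMetadata:
    """Per-region anatomical and cholinergic annotation.

    ``table`` is indexed by region acronym with columns ``name``,
    ``anatomical_group``, ``cholinergic_group`` (Ch1..Ch7 or empty) and
    ``subsystem`` (``BFCS``/``BCS`` or empty).  The basal forebrain
    cholinergic system (BFCS) comprises MA, NDB and SI; the
    brainstem-thalamic cholinergic system (BCS) comprises MS, PPN, MH
    and LH -- cardinalities 3 and 4, which fix the within/between pair
    counts (3, 6, 12) used by the subsystem contrasts.
    """

    table: pd.DataFrame = field(repr=False)

    ANATOMICAL_GROUPS = (
        "cortical plate",
        "cortical subplate",
        "striatum",
        "pallidum",
        "thalamus",
        "hypothalamus",
        "midbrain",
        "hindbrain",
        "cerebellum",
    )

    def __post_init__(self) -> None:
        required = {"name", "anatomical_group", "cholinergic_group", "subsystem"}
        missing = required - set(self.table.columns)
        if missing:
            raise TableValidationError(f"metadata missing columns: {sorted(missing)}")
        bad_anat = (
            set(self.table["anatomical_group"].dropna())
            - set(self.ANATOMICAL_GROUPS)
            - {""}
        )
        if bad_anat:
            raise TableValidationError(f"unknown anatomical groups: {sorted(bad_anat)}")

    @property
    def bfcs(self) -> list[str]:
        """Basal forebrain cholinergic regions (MA, NDB, SI)."""
        return list(self.table.index[self.table["subsystem"] == "BFCS"])

    @property
    def bcs(self) -> list[str]:
        """Brainstem-thalamic cholinergic regions (MS, PPN, MH, LH)."""
        return list(self.table.index[self.table["subsystem"] == "BCS"])

    @property
    def cholinergic(self) -> list[str]:
        """All seven long-range cholinergic regions."""
        return self.bfcs + self.bcs

    def anatomical_group(self, region: str) -> str:
        try:
            value = self.table.at[region, "anatomical_group"]
        except KeyError:
            raise KeyError(f"region {region!r} not in metadata") from None
        if not isinstance(value, str) or not value:
            raise KeyError(f"region {region!r} has no anatomical group")
        return value

    def regions_in_group(self, anatomical_group: str) -> list[str]:
        return list(
            self.table.index[self.table["anatomical_group"] == anatomical_group]
        )


def _sniff_sep(path: Path) -> str:
    """Delimiter auto-detection between comma and tab on the header line."""
    with open(path) as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


def _strip_labels(frame: pd.DataFrame) -> pd.DataFrame:
    frame.index = frame.index.astype(str).str.strip()
    frame.columns = frame.columns.astype(str).str.strip()
    return frame


def read_fos_counts(counts_path: str | Path, groups_path: str | Path) -> FosCountTable:
    """Read a region x subject count file and a subject -> group file.

    The counts file has region acronyms in the first column and one column
    per subject (header row = subject IDs).  The groups file has two
    columns, subject and group; a header row ``subject,group`` is accepted
    and ignored.  Comma and tab delimiters are auto-detected.
    """
    counts_path, groups_path = Path(counts_path), Path(groups_path)
    counts = pd.read_csv(counts_path, sep=_sniff_sep(counts_path), index_col=0)
    counts = _strip_labels(counts)

    raw = pd.read_csv(
        groups_path, sep=_sniff_sep(groups_path), header=None, dtype=str
    )
    if raw.shape[1] != 2:
        raise TableValidationError(
            f"{groups_path}: expected two columns (subject, group), got {raw.shape[1]}"
        )
    if raw.iloc[0, 0].strip().lower() == "subject":
        raw = raw.iloc[1:]
    group_of = {
        str(s).strip(): str(g).strip() for s, g in zip(raw.iloc[:, 0], raw.iloc[:, 1])
    }
    return FosCountTable(counts=counts, group_of=group_of)


def write_fos_counts(
    table: FosCountTable, counts_path: str | Path, groups_path: str | Path
) -> None:
    """Write the count table and group map in the dialect ``read_fos_counts`` reads."""
    table.counts.to_csv(counts_path)
    pd.DataFrame(
        {"subject": table.subjects, "group": [table.group_of[s] for s in table.subjects]}
    ).to_csv(groups_path, index=False)


def apply_region_exclusions(
    table: FosCountTable,
    excluded: Iterable[str] = DEFAULT_EXCLUDED_REGIONS,
) -> FosCountTable:
    """Drop named regions from the panel; absent names are logged, not fatal."""
    excluded = [str(r).strip() for r in excluded]
    present = [r for r in excluded if r in table.counts.index]
    absent = sorted(set(excluded) - set(present))
    if present:
        logger.info("excluding regions: %s", present)
    if absent:
        logger.info("exclusion names not in table (ignored): %s", absent)
    if not present:
        return table
    return FosCountTable(
        counts=table.counts.drop(index=present), group_of=dict(table.group_of)
    )


def read_expression_matrix(path: str | Path) -> pd.DataFrame:
    """Read a gene/experiment x region expression-density matrix (%-pixel).

    Rows are gene or ISH-experiment identifiers (a gene may appear once per
    experiment), columns are region acronyms.  Empty cells become NaN and
    are treated as missing downstream (pairwise deletion).
    """
    path = Path(path)
    if path.stat().st_size == 0:
        raise TableValidationError(f"{path}: empty expression file")
    expr = pd.read_csv(path, sep=_sniff_sep(path), index_col=0)
    expr = _strip_labels(expr)
    if expr.shape[1] == 0:
        raise TableValidationError(f"{path}: no region columns")
    non_numeric = expr.columns[
        [not np.issubdtype(dt, np.number) for dt in expr.dtypes]
    ]
    for col in non_numeric:
        try:
            expr[col] = pd.to_numeric(expr[col])
        except (TypeError, ValueError) as exc:
            raise TableValidationError(f"{path}: non-numeric column {col!r}: {exc}") from None
    expr = expr.astype(float)
    if np.nanmin(expr.to_numpy(), initial=0.0) < 0:
        raise TableValidationError(f"{path}: negative expression densities")
    return expr


def write_expression_matrix(expr: pd.DataFrame, path: str | Path) -> None:
    expr.to_csv(path, float_format=_FLOAT_FMT)


def write_table(frame: pd.DataFrame, path: str | Path, *, index: bool = True) -> None:
    """Write any result table with >= 6 significant digits."""
    frame.to_csv(path, float_format=_FLOAT_FMT, index=index)


def write_graph(graph: nx.Graph, edges_path: str | Path, nodes_path: str | Path) -> None:
    """Write a graph as a two-column edge list plus a node-attribute table."""
    edges = pd.DataFrame(sorted(graph.edges()), columns=["source", "target"])
    edges.to_csv(edges_path, index=False)
    nodes = pd.DataFrame.from_dict(dict(graph.nodes(data=True)), orient="index")
    nodes.index.name = "region"
    nodes.sort_index().to_csv(nodes_path, float_format=_FLOAT_FMT)


def load_default_metadata() -> RegionMetadata:
    """Load the packaged region-metadata table.

    Covers the seven long-range cholinergic regions (Ch1-Ch7 with BFCS/BCS
    membership), the addiction-panel regions and the named hub regions with
    Allen-CCF anatomical groups.  It is a partial panel: full-brain
    anatomical contrasts over a complete region list require a user-supplied
    metadata file in the same format.
    """
    with resources.files("fosnet").joinpath("data/region_metadata.csv").open() as fh:
        table = pd.read_csv(fh, index_col=0).fillna("")
    return RegionMetadata(table=_strip_labels(table))


def read_region_metadata(path: str | Path) -> RegionMetadata:
    """Read a user metadata file (same columns as the packaged default)."""
    path = Path(path)
    table = pd.read_csv(path, sep=_sniff_sep(path), index_col=0).fillna("")
    return RegionMetadata(table=_strip_labels(table))
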