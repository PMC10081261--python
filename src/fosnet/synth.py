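"""Synthetic FOS count tables and expression matrices with planted structure.

Real input to the pipeline is a region x subject table of FOS+ cell counts
acquired by whole-brain imaging, and a gene x region matrix of baseline
expression densities from an ISH atlas.  Neither is redistributable here,
so every downstream stage is exercised on synthetic data with *known*
ground truth:

* :func:`gen_fos_counts` samples per-subject region vectors from a
  multivariate normal on the log10 scale whose correlation matrix is
  block-constant over a planted partition of regions, shifts the treatment
  group by a per-region amount, exponentiates and rounds to counts.
  Because the pipeline normalizes counts as log10(x+1), the planted
  correlation structure survives the forward transform essentially intact,
  which makes parameter-recovery tests sharp.
* :func:`gen_expression_matrix` plants genes whose regional profile has an
  exact, chosen Pearson correlation with a given log-fold-change vector
  (noise is orthogonalized against the standardized LFC), plus independent
  null genes, so screen power and false-discovery behaviour can be measured
  against ground truth.
"""

from __future__ import annotations

from collections.abc import Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_core import FosCountTable

__all__ = ["SyntheticDesign", "gen_fos_counts", "gen_expression_matrix", "block_correlation"]

_PSD_TOL = -1e-10  # slack on the smallest eigenvalue of block-constant matrices


def block_correlation(
    n_regions: int, partition: Sequence[Sequence[int]], within_r: float, between_r: float
) -> np.ndarray:
    """Block-constant correlation matrix: ``within_r`` inside a block,
    ``between_r`` across blocks, unit diagonal."""
    C = np.full((n_regions, n_regions), float(between_r))
    for block in partition:
        idx = np.asarray(block)
        C[np.ix_(idx, idx)] = within_r
    np.fill_diagonal(C, 1.0)
    return C


@dataclass(frozen=True)
class SyntheticDesign:
    """Ground-truth description of a synthetic FOS experiment.

    Parameters
    ----------
    n_regions
        Number of brain regions in the panel.
    partition
        Disjoint blocks of region indices covering ``0..n_regions-1``; the
        planted modules.
    within_r, between_r
        Target Pearson correlation of log-scale activity inside a block /
        across blocks.  ``within_r`` in [0, 1); ``between_r`` strictly
        below ``within_r`` and above -1.  The implied block-constant
        matrix must be positive semi-definite.
    n_subjects_per_group
        Subjects per treatment group (>= 3; correlation is degenerate below).
    group_log_shift
        Additive per-region shift on the log10 scale applied to the
        treatment group (scalar or length-``n_regions`` vector); the
        planted treatment effect whose per-region log-fold change it is.
    base_log_mean
        Mean log10 count level (2.5 ~ a few hundred FOS+ cells).
    noise_sd
        Log10-scale standard deviation of regional activity.
    seed
        RNG seed; identical seed + design reproduce the table bit for bit.
    """

    n_regions: int
    partition: tuple[tuple[int, ...], ...]
    within_r: float = 0.8
    between_r: float = 0.0
    n_subjects_per_group: int = 5
    group_log_shift: float | tuple[float, ...] = 0.3
    base_log_mean: float = 2.5
    noise_sd: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_regions < 1:
            raise ValueError("n_regions must be positive")
        covered = sorted(i for block in self.partition for i in block)
        if covered != list(range(self.n_regions)):
            raise ValueError(
                "partition blocks must be disjoint and cover 0..n_regions-1; "
                f"got indices {covered}"
            )
        if not 0.0 <= self.within_r < 1.0:
            raise ValueError(f"within_r must be in [0, 1), got {self.within_r}")
        if not -1.0 < self.between_r < self.within_r:
            raise ValueError(
                f"between_r must be in (-1, within_r), got {self.between_r}"
            )
        if self.n_subjects_per_group < 3:
            raise ValueError(
                "n_subjects_per_group must be >= 3 (inter-regional correlation "
                "is undefined or degenerate below that)"
            )
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        shift = np.atleast_1d(np.asarray(self.group_log_shift, dtype=float))
        if shift.size not in (1, self.n_regions):
            raise ValueError(
                f"group_log_shift must be scalar or length {self.n_regions}"
            )
        eigmin = np.linalg.eigvalsh(self.correlation_matrix()).min()
        if eigmin < _PSD_TOL:
            raise ValueError(
                "implied block-constant correlation matrix is not positive "
                f"semi-definite (smallest eigenvalue {eigmin:.3e}); choose "
                "within_r/between_r so the block structure is a valid correlation"
            )

    def correlation_matrix(self) -> np.ndarray:
        return block_correlation(
            self.n_regions, self.partition, self.within_r, self.between_r
        )

    def module_labels(self) -> np.ndarray:
        """Planted module label per region index."""
        labels = np.empty(self.n_regions, dtype=int)
        for m, block in enumerate(self.partition):
            labels[list(block)] = m
        return labels

    @property
    def shift_vector(self) -> np.ndarray:
        shift = np.atleast_1d(np.asarray(self.group_log_shift, dtype=float))
        return np.broadcast_to(shift, (self.n_regions,)).copy() if shift.size == 1 else shift


def gen_fos_counts(design: SyntheticDesign) -> FosCountTable:
    """Sample a two-group FOS count table from a :class:`SyntheticDesign`.

    Each subject's region vector is drawn from MVN(mean, noise_sd**2 * C)
    on the log10 scale, with ``mean = base_log_mean`` for controls and
    ``base_log_mean + group_log_shift`` for treated subjects; values are
    exponentiated and rounded half away from zero, clipped at zero.
    """
    rng = np.random.default_rng(design.seed)
    C = design.correlation_matrix()
    cov = design.noise_sd**2 * C
    n = design.n_subjects_per_group
    base = np.full(design.n_regions, design.base_log_mean)

    log_ctrl = rng.multivariate_normal(base, cov, size=n, method="eigh")
    log_trt = rng.multivariate_normal(base + design.shift_vector, cov, size=n, method="eigh")

    def to_counts(log_vals: np.ndarray) -> np.ndarray:
        raw = 10.0**log_vals
        # round half away from zero; values are positive so floor(x + .5)
        return np.maximum(np.floor(raw + 0.5), 0.0).astype(np.int64)

    regions = [f"R{i:03d}" for i in range(design.n_regions)]
    ctrl_ids = [f"ctrl{j + 1}" for j in range(n)]
    trt_ids = [f"trt{j + 1}" for j in range(n)]
    counts = pd.DataFrame(
        np.hstack([to_counts(log_ctrl).T, to_counts(log_trt).T]),
        index=regions,
        columns=ctrl_ids + trt_ids,
    )
    group_of = {s: "control" for s in ctrl_ids} | {s: "treatment" for s in trt_ids}
    return FosCountTable(counts=counts, group_of=group_of)


def _standardize(x: np.ndarray) -> np.ndarray:
    return (x - x.mean()) / x.std(ddof=1)


def gen_expression_matrix(
    lfc: pd.Series,
    target_r: Sequence[float] = (),
    n_null_genes: int = 0,
    noise_seed: int = 0,
) -> pd.DataFrame:
    """Gene x region expression matrix with planted LFC correlations.

    Each signal gene ``i`` is built as ``target_r[i] * z(lfc) +
    sqrt(1 - r**2) * e`` where ``e`` is standardized noise orthogonalized
    against ``z(lfc)``, so its realized Pearson correlation with ``lfc``
    equals ``target_r[i]`` exactly.  Null genes are independent noise.
    Every row is then shifted to be non-negative (expression densities);
    an affine map with positive scale preserves Pearson correlations.

    Parameters
    ----------
    lfc
        Per-region log-fold-change vector (index = region acronyms),
        at least 4 regions, non-constant.
    target_r
        Planted correlation per signal gene, each in [-1, 1].
    n_null_genes
        Number of independent-noise genes appended after the signal genes.
    noise_seed
        RNG seed for all noise draws.
    """
    lfc = pd.Series(lfc).astype(float)
    n_regions = lfc.size
    if n_regions < 4:
        raise ValueError(f"need >= 4 regions, got {n_regions}")
    if lfc.nunique() == 1:
        raise ValueError("constant log-fold-change vector: correlation undefined")
    for r in target_r:
        if not -1.0 <= r <= 1.0:
            raise ValueError(f"target_r must be in [-1, 1], got {r}")

    rng = np.random.default_rng(noise_seed)
    z = _standardize(lfc.to_numpy())
    rows: list[np.ndarray] = []
    names: list[str] = []
    for i, r in enumerate(target_r):
        if abs(r) == 1.0:
            profile = r * z
        else:
            e = rng.standard_normal(n_regions)
            e = e - e.mean()
            e = e - (e @ z) / (z @ z) * z  # orthogonalize against z(lfc)
            e = _standardize(e)
            profile = r * z + np.sqrt(1.0 - r**2) * e
        rows.append(profile)
        names.append(f"sig{i:03d}")
    for i in range(n_null_genes):
        rows.append(_standardize(rng.standard_normal(n_regions)))
        names.append(f"null{i:04d}")
    if not rows:
        raise ValueError("no genes requested")
    mat = np.vstack(rows)
    mat = mat - mat.min(axis=1, keepdims=True)  # per-row shift to densities >= 0
    return pd.DataFrame(mat, index=names, columns=lfc.index)
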