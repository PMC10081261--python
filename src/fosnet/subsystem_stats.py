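"""Cholinergic-subsystem and anatomical correlation contrasts.

The seven long-range cholinergic regions split into a basal forebrain
system (BFCS: MA, NDB, SI) and a brainstem-thalamic system (BCS: MS, PPN,
MH, LH).  For each treatment group this module collects the pairwise
R values within BFCS (C(3,2) = 3 pairs), within BCS (C(4,2) = 6 pairs)
and between the systems (3 x 4 = 12 pairs) -- 21 observations per
treatment, 42 in total, so a two-way fixed-effects ANOVA of R on
treatment x comparison has denominator df 42 - 6 = 36.

The same machinery contrasts the cholinergic regions' correlations with
each major anatomical division of the brain (cortical plate ...
cerebellum).  ANOVA uses Type II sums of squares by default (the layouts
are mildly unbalanced) with Tukey-HSD post-hoc comparisons over the cells;
a Shapiro-Wilk gate records whether a parametric path is defensible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .io_core import RegionMetadata

__all__ = [
    "PairCorrelationSample",
    "AnovaResult",
    "subsystem_pair_samples",
    "anatomical_pair_samples",
    "two_way_anova",
    "normality_gate",
    "NormalityRecord",
]

COMPARISONS = ("within-BFCS", "within-BCS", "between")


@dataclass(frozen=True)
class PairCorrelationSample:
    """R values for one treatment x comparison cell (self-pairs excluded)."""

    treatment: str
    comparison: str
    pairs: tuple[tuple[str, str], ...]
    values: tuple[float, ...]

    @property
    def mean(self) -> float:
        return float(np.mean(self.values))


def _pair_values(R: pd.DataFrame, pairs) -> tuple[tuple, tuple]:
    pairs = tuple(pairs)
    values = tuple(float(R.at[a, b]) for a, b in pairs)
    return pairs, values


def subsystem_pair_samples(
    R_by_group: dict[str, pd.DataFrame], metadata: RegionMetadata
) -> list[PairCorrelationSample]:
    """The six treatment x {within-BFCS, within-BCS, between} cells.

    Cell sizes are fixed by the subsystem cardinalities: 3, 6 and 12
    pair correlations per treatment.
    """
    bfcs, bcs = metadata.bfcs, metadata.bcs
    samples = []
    for treatment, R in R_by_group.items():
        missing = [r for r in bfcs + bcs if r not in R.index]
        if missing:
            raise KeyError(
                f"cholinergic regions missing from {treatment!r} correlation "
                f"matrix: {missing}"
            )
        for comparison, pair_iter in (
            ("within-BFCS", combinations(bfcs, 2)),
            ("within-BCS", combinations(bcs, 2)),
            ("between", ((a, b) for a in bfcs for b in bcs)),
        ):
            pairs, values = _pair_values(R, pair_iter)
            samples.append(
                PairCorrelationSample(treatment, comparison, pairs, values)
            )
    return samples


def anatomical_pair_samples(
    R_by_group: dict[str, pd.DataFrame],
    metadata: RegionMetadata,
    *,
    include_seed_partners: bool = False,
) -> list[PairCorrelationSample]:
    """Cholinergic-seed x anatomical-group correlation cells per treatment.

    Each cell holds the R values between every cholinergic region and every
    region of one anatomical division.  ``include_seed_partners`` keeps the
    cholinergic regions themselves on the partner side (self-pairs always
    excluded); the resulting total N pins the ANOVA's denominator df, so
    both conventions are exposed.
    """
    seeds = metadata.cholinergic
    samples = []
    for treatment, R in R_by_group.items():
        missing = [r for r in seeds if r not in R.index]
        if missing:
            raise KeyError(f"cholinergic regions missing from R: {missing}")
        for group in metadata.ANATOMICAL_GROUPS:
            members = [r for r in metadata.regions_in_group(group) if r in R.index]
            if not include_seed_partners:
                members = [r for r in members if r not in seeds]
            pairs = [
                (s, r) for s in seeds for r in members if s != r
            ]
            if not pairs:
                continue
            pairs, values = _pair_values(R, pairs)
            samples.append(PairCorrelationSample(treatment, group, pairs, values))
    return samples


@dataclass(frozen=True)
class AnovaResult:
    """Two-way fixed-effects ANOVA table plus Tukey post-hoc comparisons."""

    table: pd.DataFrame = field(repr=False)  # effect x (sum_sq, df, F, p)
    tukey: pd.DataFrame = field(repr=False)
    cell_means: pd.DataFrame = field(repr=False)
    degenerate: bool = False

    def effect(self, name: str) -> tuple[float, int, int, float]:
        """(F, df_num, df_den, p) for 'treatment', 'comparison' or 'interaction'."""
        row = self.table.loc[name]
        resid = self.table.loc["residual"]
        return float(row["F"]), int(row["df"]), int(resid["df"]), float(row["p"])


def samples_to_frame(samples: list[PairCorrelationSample]) -> pd.DataFrame:
    records = [
        {"treatment": s.treatment, "comparison": s.comparison, "value": v}
        for s in samples
        for v in s.values
    ]
    return pd.DataFrame.from_records(records)


def two_way_anova(
    samples: list[PairCorrelationSample], *, ss_type: int = 2
) -> AnovaResult:
    """Two-way ANOVA of R on treatment x comparison with interaction.

    Correlations are used raw as the response.  Type II sums of squares by
    default; Types I and III are available for cross-checking against
    tools with other defaults.  Tukey HSD runs over the crossed cells.
    """
    data = samples_to_frame(samples)
    if data.empty:
        raise ValueError("no samples")
    counts = data.groupby(["treatment", "comparison"]).size()
    n_t = data["treatment"].nunique()
    n_c = data["comparison"].nunique()
    if n_t < 2 or n_c < 2:
        raise ValueError("need >= 2 levels of each factor")
    if len(counts) < n_t * n_c:
        full = {(t, c) for t in data["treatment"].unique() for c in data["comparison"].unique()}
        empty = sorted(full - set(counts.index))
        raise ValueError(f"empty cells {empty}; two-way ANOVA needs every cell filled")

    model = smf.ols("value ~ C(treatment) * C(comparison)", data=data).fit()
    degenerate = model.ssr <= 1e-12 * max(model.centered_tss, 1.0)
    if ss_type == 1:
        raw = sm.stats.anova_lm(model)
    else:
        raw = sm.stats.anova_lm(model, typ=ss_type)
    raw = raw.rename(
        index={
            "C(treatment)": "treatment",
            "C(comparison)": "comparison",
            "C(treatment):C(comparison)": "interaction",
            "Residual": "residual",
        }
    )
    table = pd.DataFrame(
        {
            "sum_sq": raw["sum_sq"],
            "df": raw["df"].astype(int),
            "F": raw.get("F"),
            "p": raw.get("PR(>F)"),
        }
    )

    cell = data["treatment"].astype(str) + " / " + data["comparison"].astype(str)
    tk = pairwise_tukeyhsd(data["value"].to_numpy(), cell.to_numpy(), alpha=0.05)
    tukey = pd.DataFrame(
        tk.summary().data[1:], columns=[str(c) for c in tk.summary().data[0]]
    )
    cell_means = (
        data.groupby(["treatment", "comparison"])["value"]
        .agg(["mean", "size"])
        .reset_index()
    )
    return AnovaResult(
        table=table, tukey=tukey, cell_means=cell_means, degenerate=bool(degenerate)
    )


@dataclass(frozen=True)
class NormalityRecord:
    """Shapiro-Wilk gate outcome for one sample of values."""

    n: int
    statistic: float
    p_value: float
    decision: str  # "normal" | "non-normal" | "degenerate"

    @property
    def parametric(self) -> bool:
        return self.decision == "normal"


def normality_gate(values, alpha: float = 0.05) -> NormalityRecord:
    """Shapiro-Wilk test deciding the parametric vs. rank-based path."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size < 3:
        raise ValueError(f"normality gate needs >= 3 values, got {arr.size}")
    if np.unique(arr).size == 1:
        return NormalityRecord(n=arr.size, statistic=float("nan"), p_value=0.0, decision="degenerate")
    w, p = stats.shapiro(arr)
    decision = "normal" if p > alpha else "non-normal"
    return NormalityRecord(n=int(arr.size), statistic=float(w), p_value=float(p), decision=decision)
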