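# Methods

## The model

FOS is an immediate-early gene whose protein accumulates in neurons
active during roughly the preceding 1–2 hours; the number of FOS+ cells
per brain region is therefore a per-animal snapshot of regional
reactivity. Two regions whose counts co-vary across animals of a
treatment group are taken to be functionally coupled in that state. The
pipeline's object of study is the per-group *functional connectome*

    R_g[i, j] = Pearson( log10(counts[i] + 1), log10(counts[j] + 1) )

computed over the subjects of group `g` (sample formula, no small-sample
correction; group sizes of 4–6 animals are typical and the package
refuses fewer than 3). The `+1` stabilizes empty regions
(`log10(0 + 1) = 0`) and the log tames the heavy right tail of count
data. A region with zero within-group variance has no defined
correlation; its off-diagonal entries become NaN and clustering/graph
stages refuse until it is dropped — silent zeroing would fabricate
decorrelation.

## Modules

Regions are clustered agglomeratively on the Euclidean distances between
*rows of R*: each region is represented by its correlation profile to
every region, which is what clustering a correlation heatmap does. The
alternative metric `1 − R` is available (`metric="one-minus-r"`).
Linkage is **complete** by default — the default of the heatmap
clustering tools this analysis style comes from — with `average` and
`ward` exposed for sensitivity sweeps. Modules are the connected
subtrees left after cutting every merge whose height exceeds
`cut_fraction × max merge height`, `cut_fraction = 0.5` ("half height",
equivalent to `cutree(h = max/2)`). Module IDs are renumbered
contiguously in dendrogram leaf order so labelings are reproducible
across region orderings (partition equality is the invariant; the test
suite checks order-invariance up to relabeling).

Degenerate geometry is worth stating: if all region pairs are
equidistant, every merge happens at the same height and the half-height
cut yields all-singleton modules; only `cut_fraction = 1.0` returns one
module. Module count is monotonically non-increasing in `cut_fraction`.

## Graph construction and centralities

Edges are the strict exceedances `R[i, j] > threshold` with
`threshold = 0.75`; negative correlations never create edges, and
isolated regions remain nodes so that rankings run over the full panel.
Degree and betweenness come from networkx; betweenness is unnormalized,
counts unordered pairs, and splits credit fractionally across tied
shortest paths (disconnected pairs contribute nothing) — a
normalization toggle exists. The participation coefficient
`P_i = 1 − Σ_s (κ_is/k_i)²` (κ_is = edges from i into module s) and the
within-module degree z-score (sample sd; z = 0 for singleton or
zero-spread modules) are implemented directly from per-module edge
counts, using the module assignment of the *same* group's connectome.
Both are validated against brute-force oracles (all-pairs BFS path
enumeration; explicit per-module counting) on hundreds of random graphs.

Hubs are the intersection of the top-k by degree and by betweenness
(k = 20 by default). Ties at the k-th rank are all included and the
effective k reported, so results cannot depend on sort order. Connector
hubs are the top-k by participation coefficient.

## Subsystem contrasts

BFCS = {MA, NDB, SI}, BCS = {MS, PPN, MH, LH}. The cell design is fixed
by those cardinalities: per treatment, C(3,2) = 3 within-BFCS pairs,
C(4,2) = 6 within-BCS pairs and 3 × 4 = 12 between pairs; with two
treatments that is 42 observations in 6 cells and a two-way ANOVA
denominator df of 36. Correlations enter the ANOVA raw (no Fisher z):
the contrast mirrors how the field reports "average R". Sums of squares
are Type II (the anatomical layouts are unbalanced; Type I/III are
options), with Tukey HSD over the crossed cells. A Shapiro–Wilk gate at
α = 0.05 records whether the parametric path is defensible; centrality
comparisons always report the two-sided Mann–Whitney U (those
distributions are heavy-tailed) together with the gate's verdict.
Note the pair-correlation observations within a group share subjects and
are not independent — the ANOVA p-values are descriptive in the same way
the field uses them, and the package's null-calibration tests therefore
generate independent cell values rather than pipeline correlations.

For anatomical contrasts (each cholinergic seed against every region of
an anatomical division), whether the seven seeds may appear on the
partner side changes the observation count and hence the df; both
conventions are exposed (`include_seed_partners`) so the reproducing
setting can be pinned against a known df.

## Gene screen

Response: per-region `lfc[r] = log10(mean_t[r] + 1) − log10(mean_c[r] + 1)`
over raw within-group mean counts — the `+1` matches the pipeline's own
normalization; the choice rescales the x-variable monotonically and does
not reorder the screen. Predictor: each gene/experiment row of a
(%-pixel) expression matrix. Per row, a two-sided Pearson test over the
regions where both vectors are present (pairwise deletion; minimum
overlap 4, below which the row is reported *untested*, never
non-significant), with the frontal pole (FRP) excluded by default as an
outlier. Benjamini–Hochberg step-up runs once across all tested rows;
discovery at adjusted q ≤ 0.05. At a fixed region count the p-value is
monotone in |r|, so BH induces an effective absolute-correlation cutoff
(`significance_switch_point`); its location depends on the family's
p-distribution, hence on how many and how strong the true signals are.
Experiments of one gene can be collapsed by z-scoring each experiment
over its regions (ddof = 1) and averaging, and the gene-level summary
flags a gene significant when *any* of its experiments is — the most
permissive aggregation, stated in the output.

## Synthetic data: what it does and does not emulate

`gen_fos_counts` draws each subject's region vector from
MVN(μ, σ²C) on the log10 scale, where C is block-constant over a planted
partition (`within_r` inside, `between_r` across, PSD enforced with an
eigenvalue tolerance of −1e−10), μ = `base_log_mean` (default 2.5, a few
hundred cells) plus `group_log_shift` (default 0.3) for treated subjects,
σ = `noise_sd` (default 0.3). Counts are `10^x` rounded half away from
zero and floored at 0. Because the pipeline re-applies `log10(x + 1)`,
the planted correlations survive the round trip up to rounding noise
(empirically within 0.1 of the design at 500 subjects/group), making
parameter-recovery tests sharp. Not emulated: spatial autocorrelation
between adjacent regions, per-region overdispersion, imaging/registration
noise, region-size effects. Passing tests therefore demonstrate
correctness of the estimators on exchangeable log-normal counts, not
robustness to those real-data features.

`gen_expression_matrix` builds signal genes as
`r·z(lfc) + sqrt(1 − r²)·e` with `e` standardized noise *orthogonalized
against* `z(lfc)`, so the realized (not merely expected) correlation
equals the target exactly — a deliberate choice that makes recovery and
switch-point tests exact. Null genes are independent noise; every row is
shifted to non-negative densities (an affine map with positive scale,
which preserves Pearson correlations).

## Numerical and procedural choices

- Thresholds are strict (`>`); a correlation exactly at 0.75 is not an
  edge. BH discovery at the boundary `q = 0.05` is inclusive (`≤`).
- Pearson r values are clipped into [−1, 1] after computation to absorb
  last-bit float excess.
- Rounding ties in the generator go half away from zero — any fixed rule
  suffices; this one is stated.
- Delimiters are auto-detected (comma vs. tab) on the header line; region
  names are matched exactly after trimming surrounding whitespace, never
  fuzzily.
- All numeric outputs are written with ≥ 6 significant digits.
- Reproducibility: every stochastic routine takes an explicit seed;
  identical seed + design reproduce count tables bit for bit.

## Problem sizes

The test suite and the acceptance script run on panels of 8–30 regions
with 5–500 subjects per group, 200-gene to 500-gene screens over 170
regions, 200-instance random-graph oracle sweeps and 200-seed null
calibrations — sizes at which the planted structure identifies the
correct behaviour unambiguously while the whole suite completes in a few
minutes on one core.

## Known limitations

- The packaged region metadata covers the cholinergic, addiction-panel
  and hub regions only; full-brain anatomical contrasts need a
  user-supplied metadata table for the complete region panel.
- Correlation-derived observations are dependent within group; see the
  subsystem-contrast note above.
- No partial correlations, covariance regularization, weighted
  centralities, rich-club analysis or pathway enrichment — out of scope
  by design.
- With 4–6 subjects per group, individual correlations are extremely
  noisy; the pipeline reproduces the field's estimator, it does not fix
  its sampling variance.
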