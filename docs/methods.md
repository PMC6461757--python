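# Methods

This note documents the models and procedures implemented in
`poseidonia`, the assumptions behind them, the defaults and why they were
chosen, and what the synthetic-data generators do and do not emulate.

## Relative evolutionary divergence (RED)

RED maps every node of a rooted tree onto [0, 1]: the root is defined as
0, every extant leaf as 1, and an internal node interpolates between its
parent and the leaves below it,

    red(n) = p + (d / u) · (1 − p),

where `p` is the parent's RED, `d` the branch length from the parent to
`n`, and `u` the mean path length from the parent to all leaves descending
from `n` (so `u = d +` mean node-to-leaf depth, computed by a weighted
postorder pass). Because `d ≤ u`, RED is non-decreasing along every
root-to-leaf path, and because the formula only involves ratios of path
lengths it is invariant to rescaling all branch lengths.

Numerical choices:

- **Zero-length internal branches** yield `d = 0` and hence
  `red(child) = red(parent)` — arithmetically identical to collapsing the
  edge into a polytomy first, so no tree mutation is performed.
  Zero-length *terminal* branches are permitted; leaves are defined as 1
  regardless.
- **Degenerate geometry** (`u = 0` with `d > 0`, an all-zero subtree below
  a positive branch) raises an error naming the node.
- **Polytomies** are handled natively; no binarisation.
- **Rooting** is never guessed: the tree must be flagged rooted or have a
  bifurcating seed node, or an explicit outgroup leaf set must be given,
  in which case the tree is re-rooted at the midpoint of the edge above
  the outgroup MRCA.

### Rank windows and taxonomy normalisation

Each seed taxon at a rank is placed at the RED of the MRCA of its
genomes; the rank's acceptable window is the median of those placements
± a half width of 0.1. The 0.1 half width at genus is the published
convention; the other ranks default to the same value for lack of a
stated alternative, and both are configurable.

Normalisation proceeds per taxon: the taxon is first reduced to its
maximal member-only subclades (restoring monophyly), and each subclade
whose RED falls *below* the window is recursively replaced by its
children until the window is met. A clade whose RED falls *above* the
window cannot be repaired by splitting and is kept flagged
(`in_window = False`) for the analyst. Split products are suffixed 1..n
in ladder order — descending clade size, then alphabetical smallest leaf
label — because the original numbering convention for split clades is not
specified anywhere. Windows are fitted once and held fixed while clade
REDs are re-read during splitting (recomputing medians after each split
would make the procedure order-dependent). The output at each rank
partitions the input genomes exactly, and rerunning normalisation on its
own output is a fixed point; both properties are tested.

## MAG quality

Completeness and contamination use the **single-marker approximation**:
completeness is the fraction of markers present at least once and
contamination the per-marker excess copy fraction
(`Σ max(copies − 1, 0) / |markers|`). This deliberately ignores marker
collocation (the information CheckM's marker *sets* add), because the
pipeline's input is a flat marker-count table. Estimates are therefore
approximations and are labelled as such.

Marker-set refinement removes markers absent from every genome of the
lineage before estimation; such markers carry no signal for the lineage
and only depress completeness. Refinement is idempotent and can only
increase (or preserve) completeness estimates.

Rules, with boundary semantics as printed by their sources:

| rule | condition |
| --- | --- |
| screen (keep) | completeness ≥ 20% and contamination ≤ 10% |
| MIMAG high quality | completeness > 90%, contamination < 5%, 16S ≥ 1200 bp, 23S ≥ 1900 bp, 5S ≥ 100 bp, tRNAs ≥ 18 |
| type-material candidacy | MIMAG HQ and ≤ 100 contigs and < 10 ambiguous bases |
| quality score | completeness − 4 × contamination (no rounding before ranking) |
| dereplication | greedy at ≥ 99.5% identity |

The screen keeps the boundary (exclusion is written as `<20%` / `>10%`);
MIMAG is strict at its boundaries. Quality-score ties break
lexicographically by genome id. Dereplication takes the highest-scoring
unassigned genome as a representative and absorbs everything at or above
the threshold; representatives are therefore pairwise below the
threshold, and the representative set is invariant to input row order.
Only the threshold — not the clustering algorithm — is prescribed by the
source methodology; greedy-by-quality is the standard choice.

## Proteorhodopsin spectral tuning

The classifier is a residue lookup at two 1-based columns of the
**unfiltered** alignment: position 315 (M → green_SP, 525 nm;
Q → blue_DP, 490 nm; anything else, including gaps and X, → unknown) and
position 318 (E → proton pump with glutamate donor; K → proton pump with
lysine donor; F or S → photosensor; else unknown). The classifier is
total over the alignment alphabet and never raises on residue content.

The alignment filter removes columns outside the termini (default
113–585) and columns whose most frequent non-gap residue occurs in fewer
than 30% of sequences. "30% minimum similarity" is interpreted as this
per-column modal-residue frequency, one of several possible readings; the
threshold and termini are configurable. Filtering retains a map from
original column numbers to current indices, so position 315 remains
addressable after filtering whenever the column survives — the residue
reported for a surviving column is identical before and after.

## Abundance–environment statistics

The NB parameterisation everywhere is mean/dispersion with
`Var = μ + α μ²`.

- **Library-size scaling** is the median-of-ratios method: the reference
  pseudo-sample is the per-clade geometric mean across samples, ratios
  are taken only over clades nonzero in every sample, and each sample's
  size factor is the median ratio. If no clade is everywhere-nonzero the
  function refuses and suggests a pseudo-count. Note that multiplying one
  sample's counts by `c` multiplies its factor by `c^((m−1)/m)` for `m`
  samples, not exactly `c`, because the geometric-mean reference itself
  shifts; passing a fixed `reference` makes the equivariance exact.
- **Sparse-sample exclusion** drops samples whose share of total mapped
  reads is below `min_fraction` (default 5%) of the uniform per-sample
  share `1/m` — the operationalisation chosen for the under-defined
  "accounted for less than 5% of the whole data".
- **NB GLM.** One clade, one variable per model (no multivariable mode);
  rows with missing metadata are dropped first. Numeric variables enter
  as-is; categorical variables use treatment coding (dummies against a
  reference) or sum-to-zero deviation coding (omitted level coded −1).
  The dispersion α is chosen by bounded scalar minimisation of
  `AIC = 2k − 2·loglik` on log-α over [1e−6, 1e3] (α counted as one
  parameter); reference/omitted levels are likewise chosen by AIC over
  all candidates, ties to the first level in sorted order. Significance
  uses a block Wald test for the whole variable and normal z-tests per
  coefficient. Non-convergence flags the fit instead of raising, and
  flagged fits are excluded from screening.
- **BH screening** adjusts the variable-level p-values across clades
  within each variable (a `global` family is available), keeps variables
  at adjusted p < 0.1, then adjusts coefficient p-values within each kept
  variable and keeps coefficients at adjusted p < 0.05, reporting the
  association sign from the coefficient.
- **NB GAM.** An unpenalised cubic B-spline regression of time with
  interior knots at quantiles; df ∈ {3..9} (df = 3 is a plain cubic) and
  α are selected jointly by AIC. Confidence bands are Wald-type on the
  linear predictor, transformed through the log link; the exact band
  procedure is not prescribed by the source methodology, so Wald bands
  are adopted. The df range is truncated with a warning when time points
  are scarce; fewer than 10 points is refused.
- **Baseline contrast** flags groups whose confidence interval excludes
  the grand mean (mean of group means); the flags are invariant to group
  relabelling.
- **Single-copy normalisation** divides a gene's count by the mean of the
  five ribosomal genes S4, S15, S24e, S27ae and L21, returning NaN with a
  warning if all five are zero.

Model fitting is delegated to statsmodels (as in the original analysis);
the α search, coding matrices, screening logic and spline basis are
implemented here so their semantics are explicit.

## Synthetic data

All generators are bit-reproducible for a fixed seed and emit their
ground truth alongside the data.

- **Trees**: uniform random joins with exponential base branch lengths
  (mean 0.1) scaled by per-edge gamma multipliers of shape
  `rate_heterogeneity` and mean 1 — the simplest shape with controllable
  among-lineage rate variation, which is exactly the property RED is
  meant to absorb. No attempt is made to match any empirical depth
  distribution.
- **Marker tables**: each genome's own marker copy is present with
  probability `true_completeness`; an independent contaminant extra copy
  is added with probability `true_contamination`. Under this model the
  count-based estimators have expectations
  `E[completeness] = 1 − (1−c)(1−k)` and `E[contamination] = c·k`, which
  the generator emits as ground truth; recovery tests compare against
  these analytic expectations rather than the raw parameters, because no
  generative model of flat counts makes both estimators exactly unbiased
  simultaneously.
- **Counts**: NB draws via the gamma–Poisson mixture around
  `exp(b₀ + x·β + A·sin(2πt/12))` times a lognormal library-size
  multiplier (σ = 0.3); the `month` covariate drives only the seasonal
  term. Coefficients, true means, multipliers and α are all returned.
- **pR alignments**: fixed width 650; the diagnostic columns carry the
  class residues exactly; background columns carry a random consensus
  residue matched with probability `conservation` (default 0.7) so the
  similarity filter behaves as it does on real alignments (uniform
  random columns would almost all fall below 30% modal frequency).
  Set `conservation=0` for fully random background.

What the generators do **not** emulate: sequence evolution (no
substitution model), marker collocation, compositional coupling between
clades beyond the shared library size, spatial structure, or real
metagenome read processing. Tests passing on synthetic data therefore
demonstrate the correctness of the rules and estimators under their
stated models, not performance on raw ocean metagenomes.

## Simulation sizes used by the test suite

Chosen so the full suite runs in well under ten minutes on one CPU:

- RED oracle equivalence: exhaustive over all labelled rooted binary
  topologies with ≤ 6 leaves (1,069 trees) plus 300 random 7–8-leaf trees
  with random branch lengths. The RED recursion is purely structural, so
  exhaustive small-n plus randomised larger-n exercises every code path.
- NB GLM effect recovery: a single n = 500 fit with a continuous
  covariate (β = 0.5, α = 0.5), plus 400 replicates of a balanced
  two-group design at n = 500 for mean bias and 95% Wald-CI coverage.
  The balanced design is used for the coverage study because it is the
  canonical setting for Wald calibration; with a lognormal-leverage
  continuous covariate the NB Wald interval is intrinsically mildly
  conservative (empirical coverage ≈ 0.97 even with the true α), which
  sits on the edge of the acceptance band and would make a small
  replicate study uninformative. 400 replicates put the Monte-Carlo
  standard error near 0.011.
- BH type-I control: 50 replicates of 40 null clades at n = 80, testing
  the family-wise false-positive rate under the global null against
  0.05 plus three binomial standard errors.
- GAM: 15 monthly points for sinusoid recovery; 24 points for the
  df-versus-wiggliness comparison.

## Known limitations

- Completeness/contamination ignore marker collocation and will be more
  optimistic than collocated-set estimators on fragmented assemblies.
- The median-of-ratios factors assume most clades are non-responding;
  with small clade panels, factor noise can admit weak spurious
  associations (illustrated in `examples/04_abundance_glm.py`).
- The GAM band is pointwise, not simultaneous; `significant_vs_baseline`
  is a descriptive flag, not a corrected test.
- Rank normalisation verifies window logic only; placements that depend
  on taxa outside the input tree are out of scope.
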