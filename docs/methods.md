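# Methods

This note documents the models implemented in `metabodyn`, their
assumptions, the defaults that matter, and the design choices made where
the design was genuinely open.  It states no empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Preprocessing chain

The chain targets normalized GC-MS peak-area tables: positive,
right-skewed, heteroscedastic values with occasional technically missing
cells.  Stages are enforced in order (`raw → normalized → logged →
scaled`), each returning a new table:

1. **Median normalization.**  Each sample is divided by its median over
   observed metabolites and re-multiplied by the grand median of the
   per-sample medians.  The re-multiplication is a pure convenience —
   it keeps values on the original scale; dividing alone would be an
   equivalent normalization.
2. **Log transform.**  Natural log.  The base is immaterial downstream
   because autoscaling absorbs any constant factor.  Zeros are floored
   to half the metabolite's smallest positive value (the standard
   half-minimum floor); negatives are an error.
3. **Autoscaling.**  Per-metabolite z-scoring (sample SD, ddof = 1).
   Constant columns become all-zero and are flagged rather than
   rejected, since unit-variance scaling is undefined for them.
4. **KNN imputation.**  Neighbour space is metabolite (feature) rows,
   following the convention of the classic microarray `impute`
   approach: for a metabolite with missing cells, Euclidean distance to
   every complete metabolite row is computed over the samples where the
   target is observed, and each missing cell takes the mean of the k
   nearest rows' values at that sample.  Default k = 10, capped at the
   number of complete rows; k larger than the complete-row count is an
   error.  Observed values are never altered.  Imputation runs after
   scaling; whether scaling-then-imputing or the reverse is the better
   order is debatable for this data type, so the order is fixed by the
   stage machine and declared here rather than asserted as the only
   correct one.

Imputation presumes each missing cell has at least one observed
replicate in its (metabolite, day) group — missingness is treated as a
technical dropout, not biological absence.  The synthetic generator
enforces this by construction.

## OPLS-DA

Two-group discriminant analysis with the response encoded ±1.  The
algorithm is the standard NIPALS PLS1 with orthogonal signal
correction: in each round the PLS weight w ∝ Xᵀy is computed, the
loading of the corresponding score is split into its y-predictive and
y-orthogonal parts, and the orthogonal component (scores t_o, loadings
p_o) is deflated from X.  After `n_ortho` rounds (default 1;
`"auto"` stops when a component would explain < 1% of X-variance) a
single predictive component (t_p, p_p) is fitted to the filtered
matrix.

Variance bookkeeping: all fractions are denominated in the total
sum of squares of the centered input matrix.  Because predictive and
orthogonal scores are mutually orthogonal, R²X_pred + Σ R²X_orth +
residual = 1 exactly; this identity is tested.  The predictive variance
fraction R²X_pred is the quantity quoted per contrast.  Note it depends
mildly on the number of orthogonal components removed.

Sign convention: the model is oriented so the second day-set of the
contrast has positive mean predictive score, which fixes the up/down
reading of loadings and differential directions.

**VIP.**  With a single predictive component, VIP_j = √(J·w_j²/Σw²),
hence ΣVIP² = J and mean VIP² = 1.  VIP > 1 is the conventional
importance flag; 0.9 < VIP ≤ 1 is reported as a weak band.

**Univariate companion tests.**  Two-sided Mann–Whitney (exact when
sample sizes and ties permit, via scipy's auto policy) or Welch t,
with Benjamini–Hochberg adjustment across metabolites.  All-tied
metabolites get p = 1 and a flag.  Cross-validated Q² and label
permutation testing are out of scope.

## Preranked MSEA

The enrichment statistic is the weighted Kolmogorov–Smirnov running
sum: walking the list ranked by OPLS-DA predictive loading, members
add |score|^weight (normalized over members, weight default 1) and
non-members subtract 1/(N − n_members); ES is the signed extremum.
The implementation evaluates the walk in closed form at hit positions
(the sum is linear between hits) and is cross-checked in the test suite
against a brute-force walk and against an independent preranked GSEA
implementation.

The null distribution is built from random member sets of equal size
drawn from the profile — a metabolite-label permutation.  Sample-label
permutation is not possible for a preranked analysis, since the
loadings come from one fitted model; this is a known limitation of the
preranked approach and is stated openly.  NES = ES / mean(|null ES| of
matching sign); p is the matching-sign tail with a +1 pseudo-count;
BH adjustment across pathways.  Sets smaller than `min_size` (default
3, below which the null is degenerate) or covering the whole profile
are skipped and reported.  Pathway membership is taken from a GMT-like
TSV, with an optional add/remove override table for manual curation
(e.g. placing class-annotated compounds into class-level pathways).

## Covariation mapping

Mean temporal profiles (replicate means per day) are correlated
metabolite-against-metabolite.  Pearson is the default for the network
map; Spearman is the default for the inside/outside contrast.  Edges
connect pairs with |r| above the threshold (default 0.85), keeping the
sign: thresholding on |r| rather than r is the only reading consistent
with a map that displays both positive and negative strong edges.

The layout starts from a 2-D spectral embedding of the correlation
matrix (seeded jitter breaks symmetry) and is refined by a
Fruchterman–Reingold-style loop in which positive edges attract
proportionally to r and negative edges repel more strongly than
non-edges.  The warm start makes the layout nearly deterministic in
structure; the seed only perturbs it.  k-means (default k = 4, 50
restarts, seeded, labels renumbered by cluster size) on the 2-D
coordinates yields the temporal clusters; per-cluster median dynamics,
interquartile bands and chemical-class compositions summarize them.

The pathway contrast partitions metabolite pairs into "inside" (share
at least one pathway), "outside" (both annotated, share none) and
unannotated-touching pairs (kept only in "all"); the summary statistic
is median(inside) − median(outside).

## Variability fingerprints

For every day, each unordered metabolite pair gets the Canberra
distance Σ|uᵢ−vᵢ|/(|uᵢ|+|vᵢ|) between the two metabolites' replicate
vectors (0/0 terms contribute 0, the common convention).  Days are
then clustered by Canberra distance between their pair-distance rows
(average linkage by default — a robust choice for a non-Euclidean
distance; the linkage is configurable).

Canberra is scale-sensitive and meant for non-negative data.  Both
input choices are exposed and tagged in the output: standardized values
(the end of the preprocessing chain) and positive normalized-stage
values.  On standardized data the |·| form makes the distance depend
mostly on sign disagreement, which aliases the culture's earliest and
latest days (both extreme, with opposite signs); the phase-structure
analysis and the pipeline therefore default to the positive
normalized-stage values, where pair distances vary smoothly with the
developmental trajectory and the day dendrogram resolves the
early-phase vs late-phase division.

## Synthetic-data generator

The generator emulates the statistical structure the analysis assumes,
with the study design fixed at the real experiment's dimensions:
sampling days (1, 2, 3, 4, 7, 14, 18, 21, 23, 26), 5 biological
replicates, 360 metabolites in the observed class proportions (≈ 25%
sugars + glycosides, 7.5% amino acids, 8.5% carboxylates, a few percent
each of FFAs and sterols, the rest unclassified), and ≈ 55% of
metabolites identified or class-annotated.

- **Archetypes.**  Four unit-variance temporal shapes on the day axis:
  (1) early-high logistic decline; (2) humps at inoculation, elongation
  and death; (3) monotone logistic rise; (4) transient mid-culture
  Gaussian peak (days 7–14).  The fourth shape is not constrained by
  the observed cluster descriptions (only three are); a mid-culture
  transient was chosen to complete a near-orthogonal basis.  Class
  labels are biased so the declining archetype is enriched for amino
  acids and sterols, the rising one for sugars, the multi-hump one for
  FFAs and carboxylates.
- **Trajectories.**  log mean(d) = log(baseline) + amp × (archetype +
  0.35 × perturbation), with baseline log-normal (peak-area scale) and
  amp log-normal around 0.9 (≈ e-fold dynamic range).  Pathway members
  share their perturbation and amplitude at strength
  `within_pathway_coupling` (default 0.6); at coupling 1 members of a
  pathway have affinely identical noiseless trajectories.  Pathway
  membership (default 20 pathways of 5–15 members, annotated
  metabolites only) is drawn independently of archetype, so at coupling
  0 inside and outside pairs are exchangeable; an option aligns
  pathways with archetypes for constructing fully coupled fixtures.
- **Replicate noise.**  Multiplicative log-normal with SD 0.25 — a
  ≈ 25% CV, a realistic biological-replicate spread for GC-MS peak
  areas (the real study does not report its CV; this is a convention,
  not a measured fact).  Within a pathway the log-noise shares a
  per-sample component whose weight differs between early (days ≤ 7,
  ρ = 0.7) and late (ρ = 0.15) phases, giving each growth phase its own
  pair-covariation fingerprint.
- **Missingness.**  Cells are blanked uniformly at random (default 2%),
  never blanking all replicates of a (metabolite, day) group, so the
  imputation precondition holds.
- **Medium kinetics.**  A discrete-step model (4 Euler steps/day,
  daily output) with three fluxes: direct sucrose uptake, extracellular
  hydrolysis (1.053 g hexose per g sucrose, the water-gain factor),
  and hexose uptake feeding logistic dry-biomass growth with Monod-type
  sugar limitation.  Defaults (30 g/L initial sucrose, hydrolysis
  0.35/day, uptake constants 0.05 and 0.20 L·mL/mg/day, μ = 0.33/day,
  capacity 11 mg/mL) reproduce the known milestones: sucrose halved by
  day 2 and < 10% by day 7, hexoses peaking around day 7–10 and
  declining to near zero by day 26.  pH follows a phenomenological
  dip-then-rise curve solved to pass through its minimum (5.1 at day 2)
  and relax to the death-phase plateau (6.3).

What the generator does **not** emulate: instrument drift and batch
effects, censoring at the detection limit (missingness is uniform, not
intensity-dependent), heavy-tailed or metabolite-specific noise,
cross-pathway regulatory couplings, and any chromatographic/spectral
layer.  Tests passing on this generator therefore demonstrate the
correctness and sensitivity of the analysis chain under clean planted
structure, not its robustness to instrumental artifacts.

## Problem sizes and numerical choices

The test suite and acceptance script run the generator at 100–360
metabolites and the default 50-sample design, with 10–20 seeds for the
recovery checks and 1000 permutations for enrichment — sizes chosen so
the planted effects are measured with comfortable margins while the
whole suite stays fast.  Degenerate inputs are handled explicitly:
constant metabolites (zeroed and flagged at scaling; distance 2 in
correlation clustering; correlation 0 in the network), all-tied test
groups (p = 1, flagged), singular score covariances (degenerate
ellipse flag), days with a single replicate (skipped in fingerprints),
and pathways below the minimum size (skipped, reported).  Ties in the
enrichment walk resolve toward the positive extremum; k-means cluster
labels are made deterministic by renumbering in order of decreasing
size.
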