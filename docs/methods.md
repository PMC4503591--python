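# Methods

## Problem and model

The package couples two analyses. The first is an ecological niche model
(ENM) built for *transferability* — the ability to predict outside the
spatial domain of fitting — rather than raw in-sample fit. The second is a
population-genetics layer that treats projected range contraction as a
filter on the gene pool: for a low-dispersal coastal species on a decadal
horizon, mutation, lineage sorting and long-range rescue are negligible, so
the diversity carried by populations projected to persist is taken as a
proxy for future global diversity, and anything confined to extirpated
populations is counted as lost.

## Niche-model engine

**Suitability surface and pseudo-absences.** Predictors are standardized to
mean 0 / sd 1 using population (divide-by-*n*) moments; the transform is
stored and re-applied to projection grids so that present and future
surfaces share the training frame. A habitat-suitability surface is derived
from the Mahalanobis distance of every cell to the presence centroid,
`D² = (x−μ)' S⁻¹ (x−μ)` with μ and S estimated from the presence predictor
vectors, converted to [0, 1] via the upper χ² tail with dof = number of
predictors. The χ² rescaling is the standard presence-only convention; it
is needed because pseudo-absence exclusion is defined on a bounded
suitability scale. Pseudo-absences are drawn uniformly without replacement
from cells with suitability ≤ 0.2, excluding presence cells, in equal
number to the presences. Only presence cells are excluded (no buffer): the
exclusion threshold already keeps pseudo-absences out of the presence
envelope.

**Evaluation.** Every predictor combination admissible under a Spearman
screen (all pairwise |R| < 0.7, strict) is evaluated by repeated 70/30
stratified split-sampling — fresh pseudo-absences and a fresh split per
repeat (50 repeats at production scale). Learner hyperparameters are tuned
per repeat by 10-fold cross-validated binomial deviance on the training
side; ties resolve to the simplest model (grids are ordered simplest
first). The held-out 30% is scored with the True Skill Statistic at the
threshold maximizing sensitivity + specificity; candidate thresholds are
the observed scores plus {0, 1}, and ties resolve to the lowest threshold
(the more inclusive range map).

**Learners.** Two families satisfy a minimal contract
(`fit(X, y, params, seed) → model with predict_proba`): gradient-boosted
classification trees (bag fraction fixed at 0.5; hyperparameters: tree
complexity 1..p, number of trees, learning rate) and an adaptive-spline
classifier (cubic spline basis per predictor, interaction features up to a
maximum degree in {1, 2, 3}, logistic link). The production boosted-tree
grid (trees 1000..10000 by 50; learning rates 0.05/0.01/0.005/0.001) is
available behind `full_grid=True`; the default desk-scale grid
(trees 200..1000 by 200; rates 0.05/0.01) exercises the same tuning
machinery at a small fraction of the cost.

**Model-set selection.** Combinations are sorted by decreasing mean TSS and
replicate TSS samples are pooled into successive Kruskal–Wallis tests: the
next-ranked combination joins the selection while the pooled test has
p ≥ α (0.05); the first p < α stops the scan. The pooling scheme is
isolated in one function (`select_top_combos`) because a defensible
alternative reading — repeated two-sample tests of best-vs-next — exists;
swapping it requires changing only that function. A fully tied pool is
treated as p = 1 (identical replicate vectors must not separate the
models). Selection is invariant to input order.

**Ensemble and range geometry.** Selected (combination, family) pairs are
refitted on the full record set and combined cell-wise by the median (an
even member count averages the two central values). The default
binarization threshold is the median of the members' own
sensitivity+specificity-maximizing thresholds; it is configurable. Range
limits are the extreme occupied cell-center latitudes; a marginal-habitat
mask flags 0.3 < P < 0.4. Land/sea masking is deliberately out of scope —
an optional validity mask is accepted and coastline handling is the
caller's responsibility.

## Genetic estimators

Haplotype diversity uses the unbiased `H = n/(n−1)(1 − Σp²)`; nucleotide
diversity `π = n/(n−1) Σ 2 p_i p_j k_ij / L`, which equals the plain mean
pairwise difference per site over sequence pairs. Gene diversity H_E uses
the small-sample correction `2n/(2n−1)` (the convention of the classical
microsatellite packages); the uncorrected variant is a documented flag-off.
Allelic richness A is the plain mean allele count per locus (sample sizes
in the emulated design are near-constant, so rarefaction is offered but off
by default). F_IS and θ are Weir & Cockerham (1984) estimators with
variance components summed over loci and alleles before the ratio; negative
estimates are reported as computed, never floored — for identical finite
samples θ is slightly negative by construction. F_IS significance is a
one-sided (heterozygote-deficit) permutation test shuffling alleles among
individuals within the group, per locus, with the +1 continuity correction.
Jost's D is offered in parametric and Nei–Chesser bias-corrected modes;
the multilocus value is the harmonic mean of per-locus D with negatives
clamped to zero (a zero locus therefore zeroes the multilocus value — the
variance-based correction used by some software is out of scope and noted
as a limitation). Haplotype networks are minimum-spanning networks
(weight-tied alternative links retained) with edges longer than one
substitution decomposed into unit steps through inferred, unsampled
intermediate nodes. Repeat-length variants of spacer regions are scored as
single differences by default (configurable), since indel steps are one
mutational event.

## Impact accounting

Persistence is assessed at the single cell containing each population
(inclusive threshold: P ≥ t persists), with a nearest-valid-cell fallback
within a configurable radius for coastal populations whose coordinates fall
just off the grid; the radius also bounds how far outside the grid a
population may lie. The neighborhood option exists because micro-refugia
can keep populations alive in cells scored unsuitable — assessing a single
cell is the conservative default. Lineage membership is an explicit
haplotype → lineage map supplied by the caller, not inferred: phylogroup
assignment is an interpretive judgement made on the network, not a
computation. A lineage is lost iff every population carrying any of its
haplotypes is extirpated. Loss tallies are monotone in the extirpation set
and invariant to population ordering.

## Synthetic data: what it emulates and what it does not

Environmental grids are latitudinal gradients plus optionally smoothed
Gaussian noise; a shared-noise mixing weight manufactures rank-correlated
predictor pairs for testing the correlation screen. Virtual species combine
per-predictor Gaussian (or logistic, for threshold-like limits) responses
by product; presences are sampled proportionally to truth suitability above
a threshold. Future climates are uniform additive offsets. The genetic
generator draws diploid genotypes from
`P(hom i) = p_i² + f·p_i(1−p_i)`, `P(het ij) = 2p_i p_j(1−f)` — a single
inbreeding parameter f that directly targets the F_IS estimator — and
haplotypes multinomially per population. The default 18-population design
mirrors the motivating survey's structure: two southern populations carry
an endemic organelle phylogroup, southern regions concentrate private
alleles and allelic evenness, f = 0.35 reflects the pervasive heterozygote
deficits of low-dispersal selfing-prone seaweeds, and sample sizes are 24
genotyped / 8 sequenced per population.

Not emulated: spatially explicit gene flow, coalescent history, dispersal
limitation in range tracking (projection assumes perfect niche tracking),
sequence-level mutation, and real coastline geometry. Passing tests
therefore demonstrate estimator correctness and pipeline behavior under
known truth, not predictive skill on real climate products.

A packaged reference dataset stores the published 18-population haplotype
survey exactly as printed, including one internally inconsistent row
(Tarfaya, cox3: printed counts 7:1 imply H = 0.250, but the printed
H = 0.286 corresponds to counts 6:1 with n = 7). The row is flagged and
excluded from exact regression checks. The printed π values imply an
effective alignment length shorter than the printed fragment lengths
(likely alignment trimming in the original analysis), so π checks are
oracle-based rather than table-exact.

## Numerical choices and test-scale conventions

Cells are half-open `[west, west+res) × [south, south+res)` with values at
centers; occurrences snap to cell centers and duplicates within a cell
collapse to one record. Deviance probabilities are clipped at 1e-15. A
singular presence covariance is ridge-regularized (1e-6 diagonal) with a
warning. Constant predictors get R = 0 in the Spearman screen, flagged.
Per-repeat randomness derives from a single pipeline seed through
`SeedSequence(seed, spawn_key=(counter,))`, making every repeat
independently reproducible.

End-to-end tests run at a deliberate desk scale chosen as a realistic
miniature of a regional study: a 60×40 one-degree grid, 150 presences,
10 evaluation repeats, and reduced learner grids. One property worth
knowing when designing null experiments: with *spatially smoothed* noise
predictors, a single noise realization can correlate by chance with the
species' spatially clustered range, inflating null TSS well above zero —
this is a genuine feature of spatial SDM evaluation, not an estimator bug.
Null checks therefore use spatially unstructured (iid) noise and build the
pseudo-absence surface from the truth predictors only, making labels
exchangeable with respect to the evaluated features.

## Known limitations

- No spatial-block cross-validation; transferability is assessed by random
  splits as in the emulated workflow.
- Only TSS is scored (no AUC/Kappa); only the 0.3–0.4 marginal band is
  reproduced.
- Raster I/O is ESRI ASCII only; no CRS reprojection.
- The Kruskal–Wallis pooling reading is one of two defensible
  interpretations (see above).
- The multilocus Jost's D harmonic mean is undefined under non-positive
  per-locus values and is conservatively reported as 0 there.
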