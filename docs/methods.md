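# Methods

## The experimental system being modeled

A pool of ~500,000 uniquely DNA-barcoded diploid yeast lineages evolves by
serial batch transfer through a schedule of growth environments. Each
passage spans 8 generations of growth to saturation followed by a 1/256
dilution; schedules are written as strings over `F` (glucose +
fluconazole), `G` (glycerol/ethanol), and `P` (both), one letter per
passage. Sequencing the barcode locus at sampled timepoints yields a
lineages × timepoints count matrix from which all analyses proceed.

## Simulation model (`evo_simulator`)

State is a set of clones, each defined by its cell count, its lineage
(barcode), and an additive per-generation selection coefficient per
environment. Every stochastic step is a Poisson draw:

* **Growth.** Each generation, a clone of size *n* and coefficient *s* is
  redrawn as Poisson(*n* · 2eˢ). A neutral clone doubles in expectation,
  so eight doublings exactly offset the 1/256 bottleneck and neutral
  lineage frequencies are martingales. Selection coefficients are in
  natural-log units: the log-frequency of a clone drifts at *s − s̄* per
  generation against the population mean fitness *s̄*. (An equivalent
  base-2 parameterization differs only by a factor ln 2 in the units of
  *s*; the natural-log convention keeps the simulator consistent with the
  slope-based estimators.)
* **Mutation supply.** New beneficial mutants arise as
  Poisson(feeder size × μ) per lineage per generation, founded at one
  cell, with effects drawn from the current environment's uniform DFE
  (default bounds [0, 0.125] per generation). Within a lineage that
  already carries mutants, new mutations arise only on the background of
  the *feeder* — the clone that was most frequent in the lineage at the
  start of the current environment period. Effects are strictly additive;
  there is no epistasis, diploidy, or DNA-level model.
* **Environment switches.** On first exposure to an environment, every
  carried mutation is independently assigned a sign — neutral,
  deleterious, or beneficial with probabilities (Pn, Pd, Pb), default
  (⅓, ⅓, ⅓) — and a magnitude from that environment's DFE. Effects in
  different environments are uncorrelated by construction. Extinct clones
  are pruned; pruning is exactly output-invariant (verified seed-paired
  in the tests).
* **Passage.** After 8 generations each clone is redrawn as
  Poisson(frequency × Ns), with saturation size Ns = 256 × 5e7 (≈5e7
  cells transferred, doubling 8 times), then Poisson(size/256).
* **Observation.** Reads per lineage are Poisson(frequency × depth),
  depth 3e7 per timepoint. Reads and richness are measured on the
  *saturated* culture — after the rescale to Ns, before the transfer
  bottleneck that begins the next cycle — because that is the culture an
  experimenter harvests; measuring after the bottleneck would charge the
  next cycle's transfer deaths to the current timepoint.
* **Library prep.** Founder sizes are Poisson draws around the
  post-bottleneck mean (Ns/256/n_barcodes ≈ 100 cells) and are held
  constant through 16 prep generations, during which mutations arrive at
  1e-5 per cell per generation with effects from the first environment's
  DFE. Prep mutants start at one cell.

Per-environment fitness is resolved lazily: a mutation's effect in an
environment is drawn on first exposure, and additive totals propagate
parent-first through the append-only clone table (a parent always
predates its children's environment period, so one chronological pass per
switch suffices). A full-scale 192-generation run takes ~25 s and ~1 GB.

`planted_fitness` seeds chosen founder lineages with exact per-environment
coefficients; these are the ground truth for the closed-loop recovery
tests. The hidden-truth output records the per-generation population mean
fitness and an end-state per-lineage summary, including an oracle neutral
flag (no surviving clone with any nonzero effect) that stands in for the
spiked-in known-neutral barcodes of a real assay.

## Fitness estimation (`fitness_assay`)

The per-cycle fitness of a lineage is an inverse-variance-weighted average
of its per-interval log-frequency slopes, each corrected by the interval's
mean-fitness increment and rescaled to one 8-generation cycle:

* mean-fitness increments come from the decay of the flagged neutral
  cohort, x̄ᵢ = −Δ ln(total neutral frequency);
* the interval variance model is var(slope) = κ(1/n₁ + 1/n₂) with n the
  endpoint read counts and κ fitted from neutral interval slopes by
  method of moments. κ absorbs both sequencing noise (κ ≈ 1) and the
  demographic noise of finite lineages (κ ≫ 1 for ~100-cell lineages);
  on all-neutral simulations the resulting 2-SE interval covers zero for
  ~95% of lineages;
* intervals with fewer than 20 summed endpoint reads are skipped
  (log-slope variance explodes at low counts); lineages with no usable
  interval are flagged unreliable, never imputed;
* pseudocount 0.5 keeps log-frequencies finite (0 is used for diversity
  statistics);
* *block-restricted* estimates use only intervals whose environment label
  matches, with κ refitted on the same restriction — this is what makes
  "fitness in fluconazole, measured between glycerol/ethanol residences"
  well defined in the 1:1 and 1:3 switching assays. A cycle is 8
  generations everywhere; switching designs report one value per cycle.
* a lineage is called neutral when |fitness| < 2 SE; replicates combine
  by inverse-variance averaging.

## Lineage-model inference (`ml_inference`)

Within one environment segment a well-read lineage trajectory is explained
by one of four deterministic-expectation models with Poisson read noise:
a single clone of fitness *s* (1 parameter); a neutral background plus a
mutant of fitness *s* establishing at generation τ (2); a background of
fitness *s₀* plus a mutant (3); or two founder clones with initial mix
fraction φ (3). Clones grow as exp(*s − s̄*) per generation; an
establishing mutant enters at the branching-process establishment size
1/*s* at time τ (τ before the segment = pre-existing). The lineage's
initial background size is a nuisance parameter common to all models and
is profiled out of the likelihood at every evaluation (Newton iteration on
the concave profile); pinning it to the noisy first observation instead
would propagate a correlated error across all timepoints and break the
χ² calibration of likelihood-ratio regions.

Fitting is bounded L-BFGS-B from deterministic multi-starts plus a coarse
(s, τ) grid seed; finite-difference steps are matched to each parameter's
scale (τ lives on a generations scale where default steps vanish).
Optima of simpler models seed the richer ones, so maximized likelihoods
are monotone over nested pairs by construction. Model selection is by
AIC = 2k − 2 lnL (default) or by the parsimony rule that accepts the
lowest-parameter model whose implied average lineage fitness matches the
measured log-slope within 2 counting-noise SEs.

Two physical constraints arbitrate the otherwise-equivalent "pre-existing
mutant" and "founder mix" readings of a trajectory: a founder clone is at
least one cell (φ ≥ 1/n₀), and an establishment time is *feasible* only if
it is neither earlier than ln(Ns·s)/s generations before the segment (the
mutant would already have swept) nor earlier than the lineage's own
existence (`tau_floor`, e.g. the start of library prep). Selection prefers
feasible fits. For the environment that follows, the maximum-likelihood
clone composition at the boundary is frozen and only the clones' new
coefficients are refitted, yielding the cross-environment class
(neutral/adaptive/deleterious per environment).

Population mean fitness can be estimated four ways: **thread** (largest
agglomerative group of similarly shaped, monotonically decaying
standardized log-trajectories; correlation distance, average linkage —
the exact published grouping rule is not reproduced in the available
text, so this is a documented stand-in), **slopes** (negated read-weighted
median lineage log-slope; biased once most survivors are adaptive),
**decaying neutrals** (the reference above), and **known lineages**
(frequency-weighted average of known coefficients). On simulations the
thread estimate tracks the truth with a bounded upward bias and the
known-lineage estimate is strictly more accurate — both behaviors are
pinned by tests.

## Diversity and phenotype analyses

The Shannon–Wiener index is returned as the standard −Σ fₖ ln fₖ ≥ 0
(zero frequencies contribute 0). Colony-sampling statistics draw k = 336
clones multinomially (a without-replacement mode exists) and report mean
distinct barcodes and mean non-neutral fraction with counting-statistics
errors.

Experiment relatedness uses the two-sample KS statistic per remeasurement
condition, combined in quadrature, D = √Σⱼ Dⱼ² (each Dⱼ ∈ [0,1], so
D ≤ √5), and hierarchically clustered with median linkage into at most 4
groups. Clone profiles (five per-cycle fitness values) are PCA-projected
(centered, unscaled; deterministic sign convention; incomplete profiles
dropped, not imputed); clones inside the ellipse centered on the
known-neutral centroid with semi-axes 2 SD along PC1/PC2 are labeled
neutral and removed; the rest are clustered on pairwise Euclidean
distance (average linkage — the published account fixes only the 2.5 cut)
cut at 2.5, singletons reassigned to their nearest cluster, with a
threshold-sensitivity report. A 5-D mode standardizes each condition and
cuts at 1.5. Cluster characteristics are the percentile (weak rank) of
each cluster's median fitness within the pooled distribution per
condition, plus per-experiment cluster-usage fractions.

Note a statistical ceiling worth knowing: for Gaussian neutral scatter a
2-SD ellipse removes at most 1 − e⁻² ≈ 86.5% of true neutrals. Realistic
pooled assays have strongly heterogeneous per-clone precision (SE tracks
read support), making the neutral cloud leptokurtic; the planted-recovery
tests model this with a 95%/5% two-scale precision mixture, under which
≥95% removal is attained.

## What the synthetic data does and does not emulate

The generator reproduces the statistical structure the analyses assume:
Poisson growth/sampling noise, uniform DFEs, uncorrelated fitness
reassignment, bottlenecks, and realistic read depths. It does not emulate
PCR/UMI artifacts, barcode sequencing errors or chimeras, lag-phase or
passage-duration physiology (the 24 h vs 48 h difference is recorded but
unused), frequency-dependent selection, or epistasis. Passing recovery
tests therefore validate the estimators under the stated noise model, not
robustness to those artifacts.

## Problem sizes and defaults used in tests

Unit tests run reduced scales chosen to keep per-lineage cell counts at
the full experiment's ~100 cells (e.g. 300–2,000 barcodes with Ns scaled
as 256 × 100 × n_barcodes) so demographic noise is representative; read
depth stays at 3e7 where estimator calibration is the point. The
diversity-collapse check and the acceptance script run the full 500,000-
barcode configuration. The model-recovery panel uses 200 lineages at
high signal (s = 0.15/generation establishing mid-segment; founder mixes
of 10% at s = 0.08) with the three-way candidate set the discrimination
task is defined over.

## Known limitations

* The four lineage models allow at most one arising mutant (or two
  founders) per lineage per environment; multi-mutant lineages degrade
  the fit (flagged by likelihood, not modeled).
* The thread mean-fitness method carries an upward bias on adapting
  populations; prefer the neutral- or known-lineage references when
  available.
* AIC cannot reliably separate models that coincide on the observable
  window (e.g. a pre-existing mutant vs a founder mix with matching
  fraction) — the feasibility constraints arbitrate these cases, and
  genuinely ambiguous fits remain ambiguous.
* Fitness-estimate standard errors are calibrated by the neutral cohort;
  with fewer than ~10 neutral lineages κ and the mean-fitness reference
  become unreliable and estimation refuses to proceed.
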