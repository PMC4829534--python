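# Methods

## Coverage model and coordinate conventions

All coordinates are 0-based half-open (BED convention).  The genome is
tiled with non-overlapping 200-bp windows; trailing chromosome ends
shorter than one window are dropped, so every window has identical length
and coverage fractions share a uniform denominator.  A sequenced fragment
(a read pair counted once) is assigned to the window containing the
strict majority of its span, implemented as midpoint containment — for a
fragment spanning two windows this is exactly the majority window, and it
remains well defined for any span.  Strand is ignored: transcription is
assayed as presence of poly-A+ coverage.

The *common genome* is the window set with at least `min_count` genomic
fragments (default 1) in every designated taxon.  It guarantees that a
window's absence of transcription in a taxon is not merely absence or
unmappability of the locus.  The definition of "covered" is configurable
because a depth threshold above 1 is defensible; 1 is the default.

Depth normalization subsamples fragments, not windows, without
replacement: each sample column is replaced by a multivariate
hypergeometric draw summing exactly to the target, which is the in-memory
equivalent of subsampling an alignment file.

## Presence, sharing and the singleton problem

Per-taxon counts are the sum of that taxon's (normalized) sample columns
across tissues before thresholding; a per-tissue mode exists because the
alternative order (threshold then combine) is also defensible.  Presence
at threshold τ means count ≥ τ.  Sharing classes are assigned on the τ=1
matrix — single, intermediate (2..T−1 taxa), all — and then
cross-tabulated by the higher thresholds, so a window's class never
depends on its coverage level.

A window observed once is fragile evidence.  Under Poisson sampling with
mean λ fragments per sample, the probability of seeing nothing in k
independent samples is exp(−λk); at λ=1 this is e⁻¹ ≈ 37% for one
resample and e⁻⁹ ≈ 0.01% across nine taxa.  This motivates both the
singleton re-detection report (is a count-1 window seen in any other
sample?) and the use of ten taxa as mutual corroboration.

## Sharing phylogeny

The phi coefficient — Pearson correlation specialized to binary variables,
computed from the 2×2 contingency table of two taxon columns — measures
shared presence/absence.  Distances are Manhattan distances between rows
of the correlation matrix, not 1−φ: two taxa are close when they relate to
*every* taxon similarly.  This profile distance is what lets deeply
diverged outgroups (whose pairwise correlations with everything are near
zero) still resolve correctly: their profiles are similar to each other
and dissimilar to the ingroup's.

Neighbor joining is the canonical Saitou–Nei agglomeration with the
Studier–Keppler Q-criterion.  Determinism is guaranteed by a tie-break
(among minimal Q, join the lexicographically smallest label pair).
Negative branch lengths, which NJ can produce on non-additive input, are
clamped to zero and recorded on the tree's `clamped` attribute.  NJ is
exact on additive matrices; the test suite verifies topology and branch
lengths against path-length oracles and cross-checks topology against
scikit-bio's independent implementation.

Degenerate phi (a taxon present everywhere or nowhere in a bootstrap
resample) is recorded as 0 with a warning; profile terms where both taxa's
entries are degenerate are excluded from that pair's distance sum.  This
keeps the pipeline total on pathological resamples while flagging them.

Bootstrap supports resample windows — the only exchangeable unit in this
design — with replacement, rerun the full correlation → distance → NJ
pipeline, and report for each internal edge of the point-estimate tree
the percentage of replicates containing the same bipartition (not a
majority-rule consensus).  Nodes below 70% are flagged in the report.

The sampling-variance partition splits each taxon's terminal branch over
replicate trees (built from disjoint equal-size fragment subsets) into a
robust component — the minimum terminal length across replicates, the
portion every independent subset agrees on — and a variable component
(mean − minimum).  The overall percentage is Σ variable / Σ mean over
terminal branches.  Min/mean is a declared operationalization of "the
branch portion shared across sets"; other readings (e.g. pairwise
intersections) would be monotone transformations of the same discordance.

## Saturation models

Two models are fitted to rarefaction curves:

* logarithmic, y = a + b·ln x (ever increasing), by ordinary least
  squares;
* asymptotic, y = A + (R₀ − A)·exp(−eᶜ·x) (saturating at A), by nonlinear
  least squares with a deterministic self-start
  (A₀ = max y + 0.05·range, R₀ = min y, c₀ = ln(1/median x)) and up to 20
  jittered restarts.  Non-convergence is never silent: the comparison is
  flagged and the logarithmic model wins by default.

Model choice is by minimum BIC under a Gaussian likelihood, with the
error variance counted as a parameter (k = p + 1), the Bayes factor
approximated as exp(|ΔBIC|/2), and Kass–Raftery labels (≤3 barely worth a
mention, 3–20 positive, 20–150 strong, >150 very strong).  The winner's
extrapolation at twice the current sampling is reported, and an asymptote
outside (0, 1] is flagged implausible.

By default `fit_saturation` fits curve means (n = number of curve
points).  For the taxa-accumulation analysis the pipeline fits
*per-replicate points* (all orders × positions): with 100 random orders
the mean curve carries correlated Monte-Carlo error of the same magnitude
as the model-misfit residuals, and the BIC winner can flip on the order
sample alone; stacking the replicate points makes the choice reflect the
dataset rather than the order draw.  Depth-curve points above 50%
retained reads share fragments and are not statistically independent; no
correction is applied and the caveat is recorded in the fit notes.

## Run lengths and enrichment

Run lengths are maximal stretches of equal union-presence state over
consecutive common-genome windows, broken at mask gaps and chromosome
boundaries; per contiguous masked block the transcribed and
non-transcribed lengths sum exactly to the block span.  The maximum
non-transcribed run is the largest transcriptional desert.

Enrichment shuffles each feature to a uniform random start on its own
chromosome, preserving length and allowing shuffled features to overlap,
recomputes the bp overlap with the target window class per shuffle, and
reports the two-sided empirical p with add-one correction,
p ≥ 1/(n_shuffles+1).  Benjamini–Hochberg FDR is applied once across the
whole feature × target family.  Because the shuffling null is itself an
approximation, a method-bias band is computed from each feature class
against total transcription across all taxa (where near-total overlap is
expected); downstream ratios inside the band are flagged as within
method bias.  Shuffling is within the full chromosome span by default;
restricting to masked space is equivalent here because overlap is
measured against targets that live in masked space.

## The turnover simulator

The generator produces the statistical structure the analysis assumes,
with full ground truth:

* **Tree** — ten taxa on a fixed ultrametric phylogeny (three western
  house-mouse populations splitting 3–12 kyr ago, two eastern populations
  at 10 kyr, castaneus at 0.4 Myr, the domesticus/musculus split at
  0.5 Myr, then sister and outgroup species at 1.2, 1.7, 6.6 and
  10.6 Myr).  Branch lengths are in Myr and both daughter lineages evolve,
  so two taxa separated t Myr ago are 2t apart.
* **Turnover** — per window, presence evolves as a two-state CTMC with
  gain 0.21 and loss 0.39 per Myr (stationary presence 0.35); the root
  state is stationary.
* **Core** — 20% of windows are loss-immune (present in every taxon) with
  a 10× expression multiplier, producing the conserved highly-expressed
  class.
* **Expression and sequencing** — each transcribed window draws one
  log-normal(ln 2, 0.8) expression level shared across taxa; each sample
  (taxon × tissue × replicate; default 3 tissues × 1 replicate) draws
  Poisson(λ·depth) counts with depth 3, i.e. a median transcribed window
  yields ~6 fragments per sample — squarely in the low-coverage regime
  where singleton effects matter.
* **Genomic coverage** — an independent per-taxon window dropout (default
  5%) generates the genomic count matrix for common-genome masking.

The rate defaults are free parameters, not estimates: they were fixed
once, by a design calibration, so that the simulator reproduces the
qualitative regime the analysis targets — a single total rate must stay
below ~1/Myr or the deep splits saturate (the outgroups decorrelate from
everything, including each other), while the stationary presence around
0.3–0.35 keeps the taxa-accumulation curve in its logarithmic regime.  A
per-window rate-heterogeneity variant was evaluated and rejected: it made
the accumulation curve more linear, not more logarithmic.

What the simulator does **not** model: spatial autocorrelation of
transcription along chromosomes (windows are exchangeable, so simulated
transcriptional deserts are short), mappability structure beyond uniform
dropout, per-taxon expression divergence (λ is shared; a jitter would
weaken but not restructure the signal), tissue-specific presence states
(tissues differ only in Poisson noise), and any mapping-error layer
(counts are zero wherever the true state is absent, unless the optional
background-noise knob is set).  Passing tests therefore demonstrate
correctness of the machinery and internal consistency of the inference on
data satisfying its assumptions — not robustness to the full messiness of
real cross-species mapping.

## Problem sizes and numerical choices

Default test/acceptance scale: 10,000 windows (5,000 for the
variance-partition analysis), 100 bootstrap/permutation-style replicates
per analysis, 100 seeds per Monte-Carlo acceptance check, 200 null
datasets × 200 shuffles for enrichment calibration.  These sizes put
Monte-Carlo standard errors well below the decision margins they feed.
All randomness flows through explicit integer seeds (numpy Generator /
SeedSequence); identical configuration and seeds reproduce bit-identical
artifacts, which the pipeline manifest verifies by checksum.

Known numerical conventions: phi on zero-variance columns is 0 with a
warning; NJ negative branches clamp to 0; the hypergeometric subsampler
requires the target not to exceed the available total; empirical p-values
are add-one corrected; SDs of degenerate (identical-draw) rarefaction
points are exactly 0.
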