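# Methods

This note documents the models and procedures implemented in `rcgs`,
the assumptions behind them, the defaults and why they were chosen, and
what the synthetic data can and cannot establish.

## Forward simulation (`rcgs.simpop`)

**Genome and meiosis.** The default genome is 21 chromosomes of 1
Morgan each (a wheat-like chromosome count), with marker positions
uniform within chromosomes.  Meiosis follows the Haldane model: the
crossover count per chromosome is Poisson(map length), crossover
positions are uniform, and there is no interference.  This is the
simplest standard recombination model and is sufficient for testing
prediction machinery; chiasma interference, structural variation and
telomere-biased recombination of real wheat are not modelled.

**Founders.** Founder allele frequencies are drawn Uniform(0.1, 0.9)
per marker so that the MAF filter has non-trivial action downstream, and
founders are fully homozygous by default, as elite inbred breeding
parents are.  A heterozygous-founder option exists for generality.

**Population design.** The default training-population design is 16
founders crossed into 14 bi-parental F2 families, selfed to F4 lines,
with the family-size vector (94, 190, 190, 95, ×9, 94, ×1, 186)
totalling 1,609 lines — eleven families of 94–95 lines and three of
186–190.  Every size is configurable; tests and examples run reduced
versions (same structure, smaller counts) so the suite completes on a
single CPU in minutes.

**Selfing.** `self_advance` implements single-seed descent
(`bulk_policy=1`) or a "selected bulk" stand-in (`bulk_policy=k`):
k selfed candidates are produced each generation and one is kept *at
random*.  Real selected-bulk advancement involves visual selection that
is not quantified anywhere usable, so no within-bulk phenotypic
selection is applied; expected heterozygosity halves per generation
either way.

**Traits.** Breeding values are additive over a configurable number of
QTL (default 300 of the markers), with optional additive×additive terms
on centred dosages.  Effects are rescaled so the founder-population
genetic SD matches a target (default 0.45 ton/ha on an intercept of
~6.7 ton/ha, a plausible elite spring-wheat yield scale).  Phenotypes
add i.i.d. Gaussian noise per replicate and year; there is no G×E
beyond i.i.d. year effects and no spatial field structure.

**Per-family heritability calibration.** When per-family h² targets are
given (default: a 14-vector spanning 0.01–0.73, the spread observed
across real bi-parental yield families), the per-observation error
variance of family *f* is solved from that family's realized genetic
variance: σ²ₑ = r·σ²g·(1−h²)/h², so that the line-mean heritability at
r replicates matches the target in expectation.  This mirrors the
variance-component framing in which per-family trial heritabilities are
reported.

## Marker QC (`rcgs.genotypes`)

The processing order is fixed: intersect platforms → impute → filter.
Imputation draws missing genotypes from Hardy–Weinberg proportions
{(1−f)², 2f(1−f), f²} at the marker's observed frequency f; for
unphased dosage data this coincides with drawing two Bernoulli(f)
alleles, and either reading preserves f in expectation (a property
test).  Markers are removed when monomorphic (MAF = 0) or when
0 < MAF < 0.05; the cut is strict (MAF exactly at the threshold is
kept) with an `inclusive` switch, since either convention is defensible.
Multi-allelic sites are rejected outright.

## Relationship matrices and kernels (`rcgs.kinship`)

**G.** VanRaden-style: columns of the dosage matrix centred and scaled
to unit SD, G = MM′/p.  Zero-variance columns raise an error directing
the user to QC rather than silently dropping markers.

**A.** Tabular method with topological ordering and cycle detection.
Unknown parents are unrelated and non-inbred.  A per-record selfing
count g accumulates inbreeding as F = 1 − (1 − F₀)/2ᵍ with
F₀ = A(p1,p2)/2, so an F4 line recorded against its family F1 carries
g = 2.  Off-diagonals are unaffected by selfing, matching expected
identity-by-descent.  A/2 gives the coefficient-of-parentage view used
for family summaries.  The correctness gate is a gene-dropping Monte
Carlo oracle in the test suite.

**Kernels.** Squared Euclidean distances are computed on the *same*
centred/standardised matrix as G, so G and the kernels share one
preprocessing path.  Bandwidths are h = c/m with c ∈ {1/5, 1, 5} and m
the median off-diagonal squared distance: dimensional analysis requires
h ∝ 1/m for h·d² to be scale-free, and this bracket of a broad, a
matched and a local kernel is the usual kernel-averaging choice.
Multipliers are configurable.  Kernel diagonals are exactly 1.

**Nei distance.** For biallelic loci, Jx = mean(x² + (1−x)²), likewise
Jy, Jxy = mean(xy + (1−x)(1−y)), D = −ln(Jxy/√(Jx·Jy)).  An individual
inbred line enters as the frequency profile dosage/2 — an interpretive
convention (a line treated as a tiny population) that matches common
practice when population distances are applied to lines.  Jxy = 0 is
reported as +∞, and an infinite pair makes the group SD undefined (NaN)
rather than being dropped silently.

## The Gibbs engine (`rcgs.models`)

All presets are instances of y = μ1 + Σₜ uₜ + e with uₜ ~ N(0, σ²ₜKₜ).
Each term is reparameterised on the eigenbasis of its covariance matrix
(eigenpairs below 1e-8 of the largest eigenvalue are dropped), making
the conditional update of its coefficients a set of independent
normals; one sweep costs O(n²) per term.  Variances have
scaled-inverse-χ² full conditionals; the intercept has a flat prior;
missing phenotypes are imputed from their conditional normal each sweep
(data augmentation), which is how unphenotyped selection candidates are
predicted jointly with the training set.

**Priors.** df₀ = 5 for every variance.  Scales are set so the prior
*mode* of each random term equals an equal share of 50% of the observed
phenotypic variance and the error prior mode gets the other 50% — the
documented default convention of standard Bayesian genomic-prediction
software.  The chain settings actually used in the original experiment
are not public; these defaults are declared, not reproduced.

**Chains.** Default 12,000 iterations, 2,000 burn-in, thinning 5.
Tests use desk-scale chains (hundreds to a few thousand iterations)
chosen so that Monte-Carlo error is far below each test's tolerance;
the closed-form-BLUP agreement test uses a longer clamped-variance
chain because its tolerance (0.01 RMS) is tight.  A non-finite variance
draw aborts with a diagnostic rather than continuing a divergent chain.

**Determinism.** Every stochastic routine takes an explicit seed; a fit
is bit-reproducible given (data, spec).  Ranking ties in truncation
selection break lexicographically by id for reproducibility.

## Evaluation (`rcgs.evaluation`)

Line-mean heritability is the exact formula
h² = σ²g/(σ²g + σ²ge/e + σ²e/(r·e)).  Per-family trial heritabilities
are consistent with r = e = 1 (the line-mean basis on which they are
reported); the final multi-year trial uses r = 2, e = 2.

Cross-validation: *within* mode partitions each family into k folds
(default 5-fold × 10 repeats) and by default trains only on that
family's remainder, isolating within-family accuracy; a flag adds the
other families to the training set, since either protocol is seen in
practice.  *Between* mode is leave-one-family-out.  Ability is the
Pearson correlation of predicted vs observed line values; zero-variance
folds are skipped.

Cycle means combine years as the average of per-year means (the
balanced-design convention: year means 6.11 and 7.65 combine to 6.88).
Realized gain is (last − first)/n_cycles and 100·(last − first)/first;
per-year gain is (n_cycles·gain)/elapsed_years, the formula itself —
published per-year figures derived from it are known to be internally
inconsistent with their own inputs, so only the formula is claimed.

## The scheme engine (`rcgs.scheme`)

C0 family selection is a rank-sum over (mean yield, h², within-family
ability, between-family ability), ties broken by family id; the
criteria list is pluggable because the original weighting is not
specified.  Within each chosen family the top lines by BLUE become
parents.

The C1-style crossing plan makes a fixed number of random non-self
pairs within every family plus a fixed number of crosses for each of a
chosen set of family pairs (default 6 within per family and 10 per pair
over 11 pairs → 36 + 110 crosses), with every family required to join
at least 3 intercross pairs.  Pair choice prefers high between-family
prediction ability when available — the study states the criterion but
not the chosen pairs, so top-scored pairs subject to the intercross
floor is an interpretation.  Selection of the pair set is greedy on the
unmet floor with randomized restarts; infeasible configurations raise
an error naming the constraint.

In cycles ≥ 1 a candidate's "family" is its cross of origin (the
natural definition for F1s, though no published definition exists);
most selected F1s are sole representatives of their cross, so requested
within-family crosses that are infeasible shift to between-family
crosses and the executed plan records what actually happened.

F1 candidates are genotyped as bulks: the mean dosage of 3–6 sibling
plants (real-valued), standardised with *training-set* marker moments
when extending G and the kernels, with the kernel bandwidth median m
also computed on the training block only.  A for candidates extends the
pedigree recursion.  The training set is never updated across cycles,
matching the fixed-training-population design.  Realized F1 counts per
cross are drawn to hit the configured planted totals, since only totals
are ever known.

Advancement to the final trial samples each cycle's inbred-line set
from a GEBV rank band (default ranks 1–58) rather than strictly the
top, reflecting that seed availability, not rank alone, decides which
F1s can be selfed.  The final trial phenotypes all advanced lines plus
a sample of C0 parents over 2 years × 2 replicates at a configurable
trial-level h² (default 0.5).

**What the trial-based gain shows.** Because the C0 entries in the
final trial are the *selected parents* (already the best of their
families), trial-based gain is compressed relative to the
population-level truth-based gain; both are reported.  Truth-based gain
uses the full training population as the C0 reference.

## Problem sizes used by the test suite

The acceptance-style checks run at deliberately reduced scale, chosen
as the smallest sizes at which each statistical property is
well-powered: closed-form-BLUP agreement on a 200-line panel;
gene-dropping on a 30-member pedigree with 100,000 drops; heritability
recovery on 400-line panels over 10 seeds; scheme direction and null
behaviour on a 14-family × 14-line design over 20 seeds each.  The
entrywise gene-dropping comparison uses a 3·SE band with the binomial
allowance appropriate to ~460 simultaneous entries (at most 5
excursions, none beyond 5·SE), since a joint 3·SE band would fail by
chance even for an exact tabular A.

## Known limitations

* No LD structure or array-content realism: founder genotypes are
  exchangeable draws, so marker-density conclusions do not transfer.
* No G×E beyond i.i.d. year effects; no multi-trait selection or
  indices; no optimal-contribution selection — truncation only.
* No dominance or single-step (H-matrix) relationship variants; no
  REML path (the engine is fully Bayesian).
* Pedigree A treats founders as non-inbred even though simulated
  founders are homozygous; A is a model of expected relatedness under
  the standard convention, and the models let the data weigh A against
  G and the kernels.
* Passing tests on synthetic data show the machinery is correct under
  the stated generative model; they do not validate prediction accuracy
  for any real germplasm.
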