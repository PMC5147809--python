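# Methods

## Genetic model

An F2 intercross between two inbred founders is modelled on autosomes
only.  At each locus a mouse carries AA, AB or BB (A = B6-type allele,
B = BTBR-type allele) with stationary distribution (¼, ½, ¼).  Crossovers
follow the Haldane no-interference model: a Poisson process along the
chromosome with rate 1 per 100 cM, so the recombination fraction over
d cM is r(d) = (1 − e^(−2d/100))/2.  Restricted to marker positions the
gamete allele sequence is a two-state Markov chain with switch
probability r; the simulator draws genotypes that way, and the inference
engine assumes exactly the same model, keeping simulator and smoother
consistent by construction.  No crossover interference, no X chromosome,
no sex-specific maps.

## Genotype probabilities

Observed calls are noisy emissions from the hidden genotype chain: a call
equals the truth with probability 1 − ε and each other code with ε/2;
missing calls are uninformative (uniform emission).  Posterior
probabilities at every marker and pseudomarker are computed by
forward–backward smoothing, independently per mouse and chromosome.
Numerical notes:

- forward and backward messages are renormalized at every locus; the
  posterior is invariant to the scaling scheme (verified against
  exhaustive path enumeration to 1e-10),
- markers typed at identical cM positions are separated by a 1e-6 cM
  jitter in input order, so the chain ordering is strict and
  deterministic,
- pseudomarkers subdivide each inter-marker gap evenly into the smallest
  number of pieces with spacing ≤ the step; physical positions are
  interpolated linearly in cM between flanking markers.

Defaults: step Δ = 2 cM, ε = 0.002.  Both are conventional values for a
dense F2 SNP map and are exposed in the configuration; with a median
marker spacing below 1 cM the default grid usually equals the marker set.

## Genome scans

Each trait is first mapped to normal quantiles, Φ⁻¹((rank − ½)/m) over
its m non-missing values, with ties receiving the average of their ranks'
quantiles.  The scan regresses the transformed trait at every grid locus
on the expected additive dosage s = P(BB) − P(AA) and dominance dosage
h = P(AB) — regression on probabilities rather than mixture-model
interval mapping; the two coincide at fully informative markers, where
the regression reproduces the one-way ANOVA LOD exactly.

Covariate contract: additive covariates (microarray batch, one-hot with
the first level dropped) enter both models; interactive covariates (sex)
enter both models additively, and their products with *both* s and h
enter the QTL model only.  LOD = (n/2)·log10(RSS₀/RSS₁), computed via
rank-revealing (pivoted) QR so collinear or constant columns are dropped
rather than inflating the fit; an RSS below 1e-12 × the trait's total sum
of squares is floored and the LOD capped at 9999.  Missingness is handled
per trait by listwise deletion; traits sharing a missingness pattern are
fit in one vectorized pass.

Peaks: one per chromosome at the maximum-LOD locus (ties broken
leftmost), significant when LOD ≥ 5 — the threshold is taken as given as
an approximate 5% trait-wise genome-wide criterion rather than re-derived
by permutation (permutation simply means rescanning shuffled traits with
`scanone`, which the tests do).  On the default design the measured null
exceedance rate of LOD ≥ 5 over 500 null traits is 5–7%, consistent with
that reading.  Support intervals are the conservative outer 1.5-LOD
interval: the outermost grid loci within 1.5 LOD of the chromosome
maximum, spanning internal dips.

## eQTL catalog and hotspot profile

cis means: peak on the gene's chromosome and within 2.5 cM *or* 5 Mbp of
the gene.  The OR lets either coordinate system suffice when the other is
unavailable.  Clinical traits carry no genomic position and are excluded
from the catalog (they are QTL, not eQTL).  The hotspot profile is
computed on the scan grid itself rather than fixed-width bins: at every
grid locus it counts the traits (optionally restricted to GWAS-flagged or
trans-only records) whose significant peak's support interval covers the
locus, each trait at most once per locus.  This avoids bin-edge
artifacts and matches the interval-coverage definition of co-mapping.

## Mediation

A candidate mediator's expression is quantile-transformed and appended to
the additive covariates — adjustment, not interaction — and each target
is rescanned on the hotspot chromosome.  Both the conditional and its
paired unconditional scan run on the same mice (those with a non-missing
mediator), with traits transformed after that subsetting, so the two
maxima are nested-model comparable.  The candidate's summary score is
(# targets with LOD ≥ 5 after) − (# before), restricted to the hotspot
chromosome; candidates are ranked ascending by score, ties broken by
larger mean LOD drop, then label.  A candidate appearing among its own
targets is flagged and its trivially self-conditioned row is excluded
from the score.  The full profile is re-maximized after conditioning (not
evaluated at the frozen unconditional peak).  No causal-model selection
statistics are attempted: the procedure is conditioning plus counting.

## Synthetic-cross generator

The generator's defaults define the study conditions all end-to-end tests
run under: 491 mice; 19 mouse-like autosomes (~1,400 cM) carrying 1,997
evenly spaced markers; genotyping error 0.002 and missingness 0.02;
4 microarray batches assigned round-robin (batch effects N(0, 0.02²)) and
Bernoulli(½) sex with a +0.01 additive effect.  Trait architecture, all
in log10-ratio units:

| component | count | generative model | default |
|---|---|---|---|
| driver | 1 | μ + a·s + d·h + batch + sex + N(0, σ²) | a = −log10(2)/2, d = 0.015, σ = 0.10 |
| mediated targets | 50 | b_j·y_driver + N(0, σ_med²) | b_j = ±U(0.8, 1.2), σ_med = 0.30 |
| direct trans targets | 10 | a_dir·s at an unlinked locus + noise | a_dir = ±0.075, σ = 0.15 |
| decoy cis genes | 36 | a_cis·s at their own chr-2 locus + noise | a_cis = ±0.10, σ = 0.12 |
| null transcripts | 200 | pure noise | σ = 0.12 |
| clinical (insulin) | 1 | c·y_driver + noise | c = 0.8, σ = 0.25 |

Rationale for the key values: the driver's additive effect encodes a
2-fold expression difference between parental homozygotes; its residual
sd of 0.10 is what the per-genotype SEMs of such a driver imply for the
within-class spread (SEM·√n ≈ 0.09, rounded up), and together they put
the driver's cis-eQTL LOD in the 70–85 range at n = 491.  The mediated
noise of 0.30 gives target trans-LODs of roughly 5–15, so the hotspot is
strong (≈ 48–50 of 60 GWAS targets co-mapping) without being trivial.
Mediated targets carry *no* direct genotype term — the two classes are
disjoint by construction, and requesting both raises an error.  Direct
trans targets are linked at loci unlinked to the driver, so conditioning
on the driver leaves them intact; they model the minority of GWAS eQTLs a
true mediator cannot explain.  Half of the mediated/direct coefficients
are negative, mirroring hotspot targets that rise and fall with the
driver allele.  One global seed fans out to per-stage substreams
(covariates, driver, mediated, direct, decoys, nulls, clinical,
placement), so each stage is individually reproducible.

What the generator does **not** emulate: X-linked loci, crossover
interference, genotyping-platform artifacts, array normalization (traits
are drawn directly on the log-ratio scale), correlated residuals among
targets beyond what the shared driver induces, linkage between the genes
encoding different targets, and cis-effects for the mediated targets
themselves.  Passing tests therefore demonstrate the statistical
machinery under the stated generative model, not robustness to every
property of real islet expression data.

## Problem sizes and determinism

The test suite runs the full design (491 × ~2,000) where the claim is
about the study scale — null calibration over 500 traits, driver recovery
over 20 seeded crosses — and compact 4-chromosome crosses everywhere a
property is scale-free.  `scripts/acceptance.py` uses one full-design
pipeline run, 500 null traits, and 50 randomized HMM-oracle cases; every
random draw derives from the `--seed` argument through named substreams,
and identical seeds give bit-identical outputs (the run manifest excludes
wall-clock timing for exactly that reason).

## Known limitations

- Autosomes only; crosses with X-linked drivers are out of scope.
- Single-QTL scans: no multiple-QTL models, epistasis, or FDR across
  traits; the per-chromosome single-peak convention makes a trait with
  two linked hotspot eQTLs on one chromosome appear as one.
- The LOD ≥ 5 threshold is fixed, not re-derived per dataset.
- Dosage regression slightly underestimates LOD relative to full interval
  mapping in regions of high genotype uncertainty (wide marker gaps or
  heavy missingness); at the default marker density the difference is
  negligible.
- The mediation score counts threshold crossings; two candidates that
  reduce target LODs by very different amounts can tie if neither crosses
  LOD 5, which is why mean LOD drop is the tie-breaker.
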