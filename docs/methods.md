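# Methods

This note documents the models, estimators, numerical choices and known
limitations of `kinlow`.

## Generative model

All computation is restricted to a synthetic SNP panel: biallelic
autosomal sites at regular spacing (default 2,500 bp over 22
chromosomes) with population alternate-allele frequencies drawn from a
configurable sampler (default uniform on [0.05, 0.95]). The regular
spacing makes 1 Mbp windows contain predictable site counts, which keeps
windowed statistics reproducible. The panel is a scaled-down analogue of
the ~1.24M-site capture panels standard in degraded-DNA work; panel
sizes of 10k–50k sites are used throughout the tests and the acceptance
script because they put every estimator in its asymptotic regime while
keeping runtimes in minutes on one CPU.

Genotypes descend through an outbred pedigree: founders draw two alleles
independently with Bernoulli(alt_freq) (Hardy-Weinberg), each
non-founder receives one uniformly chosen allele from each parent,
independently per site, and duplicate ids (monozygotic twins or repeated
sampling of one individual) copy a genome verbatim. Only outbred
pedigrees are supported: the recursive kinship computation and all
estimator expectations (normalized P0 → 1 − φ, r → 2φ, hrc → φ) assume
the three-coefficient outbred IBD model, under which the general
nine-coefficient (Jacquard) parameterization collapses to (k0, k1, k2).

Sequencing is modeled at the read-count level, not the read level. Per
individual and site: depth ~ Poisson(λ), each read copies one of the two
alleles uniformly and flips to the other allele with base-error
probability ε; at sites whose allele pair is {C,T} or {G,A} a
ref-carrying read additionally flips to alt with probability δ. The δ
term is a deliberately scalar, strand-agnostic stand-in for terminal
cytosine deamination — enough to probe robustness to damage-like noise,
not a position-in-read damage profile. Poisson depth (rather than
negative-binomial) matches the "mean coverage" parameterization; library
overdispersion, contamination, indels, sex chromosomes and reference
bias are out of scope.

Parameters and defaults: λ (`mean_coverage`, fold, default 2.0 — the
boundary between "low" and "intermediate" coverage in the field's
usage), ε (`base_error` ∈ [0, 0.1], default 0.001, a typical
post-quality-filter error rate), δ (`deamination_rate` ∈ [0, 0.3],
default 0 — damage off unless asked for), and a mandatory integer seed.
All randomness flows from that single seed through named sub-streams
(stage, fraction, method), so adding a method or level never perturbs
another's draws, and every operation is bit-reproducible.

Coverage titration keeps each read independently with probability f
(binomial thinning of the ref and alt counts), the count-level analogue
of subsampling a read file; thinning a Poisson pileup by f is again
Poisson with mean fλ, so mean coverage scales exactly proportionally.
Mean coverage is defined over panel sites — total reads divided by
(individuals × panel sites) — since all computation is panel-restricted.

## Shipped pedigrees

Four fixture pedigrees define the benchmark conditions: `trios` (five
independent father-mother-offspring trios, 15 ids), `family` (a 15-id
three-generation family containing identical, first-, second-,
third-degree and unrelated pairs, including a duplicated genome),
`unrelated5` (five mutually unrelated individuals) and `village` (28
ids, mostly unrelated, with one small nuclear cluster). They mirror the
sample sizes and relatedness structures typical of published ancient
cohorts: several discrete families, a heavily intermarried group, a
small all-unrelated group, and a large mostly-unrelated one.

## Genotype representations

Pseudohaploid calls sample one read uniformly per covered site
(equivalently: ALT with probability n_alt/depth), the random draw
avoiding the reference bias of consensus calling; zero-depth sites are
missing. Genotype likelihoods use the per-read binomial error model
L(g) ∝ e_g^n_alt (1 − e_g)^n_ref with e_g = (g/2)(1−ε) + (1−g/2)ε,
computed in log space and normalized per site. The GL error rate
defaults to the simulator's ε but is a separate knob, so
mis-specification experiments are possible.

## Estimators

**Windowed P0.** Per pair and 1 Mbp window (half-open, 1-based), P0 is
the mismatch proportion at co-covered sites. The pair's unweighted mean
over windows is divided by the cohort mean of all pairs' means — the
data-driven estimate of the unrelated expectation. The standard error
comes from a delete-one-window jackknife with the cohort normalizer held
fixed (its resampling contribution is second-order: it averages over
many pairs). Degrees are assigned by nearest expected normalized value
among {0.5, 0.75, 0.875, 1.0} with midpoint boundaries; a pair is
*related* only if its degree is second or closer **and** its normalized
P0 sits significantly below 1 (z > 1.96, configurable). Pairs with fewer
than 10 windows are flagged insufficient.

**Mismatch-rate normalization.** Genome-wide pairwise mismatch rates,
no windows. A screen first asks whether any rate differs significantly
from the maximum observed rate (per-pair binomial z against m_max,
default threshold z = 3): if not, the cohort is assumed to contain no
relatives. Otherwise r = 2(1 − m/m_max) with m_max the maximum observed
rate (an optional user-supplied normalization value is exposed for
cohorts too small to estimate it). Degrees by nearest expected r among
{1, 0.5, 0.25, 0.125, 0} with midpoint boundaries. Two caveats the
tests document: the max-z screen statistic exceeds 3 in roughly half of
all-unrelated cohorts of ~10 pairs (the expected range of 10
standardized rates is ≈ 3.1 σ), so the screen is a guard against gross
overprediction, not a calibrated test; and at ultra-low coverage the
normalizer is estimated from a handful of shared sites, which is
exactly why this estimator overpredicts there.

**Frequency-conditioned agreement (HRC).** With u = p² + q² the
expected agreement of two unrelated haploid draws at a site,
hrc = Σ(S − u)/Σ(1 − u) over co-covered sites; E[hrc] = φ for outbred
pairs, so the related threshold is the second/third-degree midpoint
0.09375. Minimum 500 co-covered sites. The estimator depends on the
frequencies only through sums of u over shared sites; frequencies from
the wrong population that understate u bias hrc upward on unrelated
pairs (spurious relatedness), whereas a permutation of correct
frequencies across sites is — at near-complete coverage — exactly a
no-op. Both facts are asserted in the tests.

**Maximum-likelihood IBD coefficients.** The composite likelihood
Σ_s log Σ_m k_m A_m(s), with A_m(s) the IBD-conditional joint genotype
table (m = 0: independent HWE margins; m = 1: HWE margin times the
shared-allele transmission row; m = 2: diagonal HWE) contracted against
both triples, is maximized over the k-simplex by EM on the latent IBD
class. The plain EM update crawls near the simplex boundary (the
parent-offspring optimum has k1 → 1) and has absorbing zeros, so the
implementation accelerates it with squared extrapolation (SQUAREM
steplength, falling back to the plain double step whenever the
extrapolated point fails to improve the log-likelihood — ascent is
monotone by construction and asserted), floors components at 1e-6
inside the loop, and finishes with a constrained gradient polish
(SLSQP). Three fixed starts (unrelated, parent-offspring-like,
uniform); tolerance 1e-6 in log-likelihood; at most 500 EM-step
evaluations per start. The solution is validated against an exhaustive
simplex enumeration (0.01 lattice, the winning cell re-swept at 5e-4)
that shares no code with the EM path. φ = k1/4 + k2/2; the binary
related call uses the 0.09375 midpoint; minimum 500 co-covered sites.

**Allele-sharing statistics.** Per co-covered site each individual's
posterior genotype distribution (likelihood × HWE prior at the site
frequency) is formed and the 3×3 joint mass table X accumulates outer
products — a deliberate simplification of a joint 2D-SFS EM that is
unbiased under the simulator's generative model. R0 = IBS0/HETHET,
R1 = HETHET/(sum of discordant classes), KING = (HETHET − 2·IBS0) /
(HET_i + HET_j). Degrees use the standard powers-of-two KING bins
(0.354, 0.177, 0.0884, 0.0442); the benchmark's binary call is
KING > 0.0884, since the R0/R1-ratio route inflates fastest with
missing data. At moderate depth the posterior weighting attenuates KING
toward 0 (posteriors are softer than true genotypes), which is visible
in the benchmark as a smaller full-coverage reference set than the ML
method's.

## Benchmark and evaluation

The sweep thins the pileup to each retention fraction, re-calls
pseudohaploid genotypes and GLs, runs every requested method, and
reduces each (pair, method, fraction) to a binary related/unrelated call
at the second-degree threshold. Against the fraction-1.0 reference:
accuracy = |calls ∩ reference|/|calls|, consistency =
|calls ∩ reference|/|reference|, false positives = calls \ reference,
false negatives = reference \ calls. Insufficient-data pairs are
excluded from the accuracy/consistency numerators and denominators (no
data is not evidence of unrelatedness), but the set-difference FP/FN
counts treat them as simply not identified. When pedigree truth is
available, FP/FN against truth are reported separately. No
multiple-testing correction is applied to per-pair decisions.

A relative kinship score maps every method onto a common scale —
windowed P0: 1 − normalized P0; mismatch r: r/2; hrc, φ, KING: as is —
then divides by 0.5 so identical pairs score 1. Mantel tests correlate
|score_u − score_v| against |coverage_u − coverage_v| over (pair,
fraction) observations, where an observation's coverage is the mean of
its two individuals' fold coverages at that fraction; p values use the
two-sided permutation convention (1 + exceedances)/(n_perm + 1), with
exact enumeration of all n! permutations when n ≤ 6.

## What passing tests do and do not show

The simulator produces exactly the statistical structure the estimators
assume: sites independent given the pedigree (no linkage
disequilibrium), frequencies known and correct, HWE founders, no
contamination, no structure or admixture, damage as a scalar flip rate.
Parameter recovery under these conditions demonstrates internal
correctness of the estimators and the relative behaviour of the two
families under coverage loss; it does not certify accuracy on real
degraded data, where ascertainment bias, LD, population mismatch of the
frequency panel and reference bias all act. The coverage-asymmetry
result (pseudohaploid type I vs GL type II error growth) is exercised at
25k sites / 2x / 20 replicate seeds — problem sizes chosen so the full
benchmark runs in minutes while each estimator still has thousands of
co-covered sites at the levels where it remains defined.

One desk-scale artifact deserves note: with 25k sites the φ-estimate
noise at intermediate retention (~0.02 SE at 0.5x) is large enough that
third-degree pairs (φ = 0.0625) occasionally cross the second-degree
call boundary (0.09375). On a 1.24M-site panel this essentially never
happens. Consequently the "reduced-coverage GL calls are a subset of
full-coverage calls" property is tested where it is identifiable: on
cohorts without boundary pairs at intermediate fractions, and on the
boundary-rich family cohort at 1% retention.

## Degenerate inputs and tie-breaks

Zero-depth sites are missing everywhere by construction. Pairs below
the data floors (500 co-covered sites; 10 windows) are flagged, never
silently dropped or called. A mismatch matrix whose maximum is 0 (e.g.
identical rows everywhere) is a degenerate-input error for the
r-normalization. Mantel tests on a constant matrix return a degenerate
flag rather than a correlation. Degree bins are half-open at midpoints;
exact boundary values resolve to the closer-kin side only via strict
inequality of the stated bounds. Floats are serialized at 6 significant
digits and all tabular formats re-parse stably.
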