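# kinlow

Kinship inference from low-coverage genome data, with a benchmark that
measures how the two standard estimator families degrade as coverage
drops.

Archaeogenetic studies routinely need to decide whether two skeletons
from the same site were close biological kin, from sequence data far too
sparse for diploid genotype calls (often < 1 fold coverage). Two
families of estimators dominate the field: **pseudohaploid** methods,
which sample a single random read per site and compare haploid allele
mismatch rates between individuals, and **genotype-likelihood (GL)**
methods, which retain per-site call uncertainty and fit identity-by-
descent (IBD) models. The two families fail differently as coverage
drops — pseudohaploid methods keep producing calls but accumulate false
positives (type I error), GL methods go quiet and accumulate false
negatives (type II error) — and `kinlow` packages estimators from both
families together with a pedigree/read simulator and a coverage-
titration benchmark so that this asymmetry can be measured on synthetic
data of known truth.

## The statistics

The target quantity is the kinship coefficient φ: the probability that
one allele drawn from each of two individuals at an autosomal locus is
identical by descent (0.5 identical genomes, 0.25 parent-offspring or
full siblings, 0.125 second degree, 0.0625 third degree, 0 unrelated).

Pseudohaploid estimators (per pair, over co-covered panel sites with alt
frequency *p*, *q* = 1 − *p*):

* **windowed P0** — per 1 Mbp window, the proportion P0 of mismatching
  haploid calls; the pair's mean P0 divided by the cohort mean
  (an estimate of the unrelated expectation) has expectation 1 − φ.
* **mismatch-rate normalization** — genome-wide mismatch rate m per
  pair; after a screen for any significant spread of rates, the maximum
  observed rate m_max (taken to be an unrelated pair) normalizes
  r = 2(1 − m/m_max), with expectation 2φ.
* **frequency-conditioned agreement (HRC)** — with u = p² + q² the
  agreement probability of two unrelated haploid draws,
  hrc = Σ(S − u) / Σ(1 − u) has expectation φ for outbred pairs.

GL estimators, from per-site likelihood triples L(g), g ∈ {0,1,2} under
a per-read binomial error model:

* **maximum-likelihood IBD coefficients** — (k0, k1, k2), the
  probabilities of sharing 0/1/2 alleles IBD, maximize
  Σ_s log Σ_m k_m · A_m(s) where A_m(s) sums the IBD-conditional joint
  genotype table against both likelihood triples; φ = k1/4 + k2/2.
* **allele-sharing statistics** — posterior-weighted joint genotype
  masses X(a,b) give R0 = IBS0/HETHET, R1 = HETHET/(discordant classes)
  and the KING-robust estimator (HETHET − 2·IBS0)/(HET_i + HET_j) ≈ φ.

The benchmark thins read pileups binomially to retention fractions
(100%…1%), re-calls genotypes, reduces every estimator to a binary
related/unrelated verdict at the second-degree threshold, and scores
reduced-coverage call sets against the full-coverage reference:
accuracy, consistency, false positives and false negatives, plus Mantel
permutation tests of kinship-score distance against pairwise-coverage
distance.

## Worked example

```sh
kinlow simulate --pedigree trios --n-sites 20000 --coverage 5 --seed 7 --out-dir demo
kinlow call --pileup demo/pileup.tsv --panel demo/panel.snp --mode gl --seed 7 --out demo/gls.tsv
kinlow kin --method lcmlkin --gls demo/gls.tsv --panel demo/panel.snp \
           --freqs demo/freqs.tsv --out demo/kin.tsv
```

`demo/kin.tsv` then holds one row per pair; for the first trio:

```
individual_1  individual_2  k0        k1           k2           phi          loglik    converged  n_sites  flag
T1_father     T1_mother     0.998729  4.83119e-13  0.00127073   0.000635366  -33915.1  True       19691    ok
T1_child      T1_father     0         1            9.21485e-13  0.25         -31960.4  True       19711    ok
T1_child      T1_mother     0         1            0            0.25         -31894.7  True       19733    ok
```

Both parent-offspring pairs recover φ ≈ 0.25 with k1 ≈ 1 (sharing
exactly one allele IBD at every locus, as parent-offspring pairs must),
while the founder couple sits at φ ≈ 0 with k0 ≈ 1. The same pileup can
be pushed through the pseudohaploid methods (`--mode pseudohaploid`,
`--method read|kennett|tkgwv2`), and `kinlow benchmark --config
<yaml> --out-dir <dir>` runs the full coverage sweep and writes
`calls.tsv`, `metrics.tsv` and `mantel.tsv`.

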