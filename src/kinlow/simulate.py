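"""Forward simulation: Mendelian genotypes, sequencing reads, thinning.

The generative model, per individual and panel site:

* founders draw two alleles independently, alt with probability equal to
  the panel frequency (Hardy-Weinberg equilibrium);
* non-founders receive one uniformly chosen allele from each parent;
* read depth is Poisson(lambda) around the target fold coverage;
* each read copies one of the two alleles uniformly, then flips to the
  other allele with base-error probability epsilon; at sites whose allele
  pair is {C,T} or {G,A}, a ref-carrying read additionally flips to alt
  with probability delta (a strand-agnostic stand-in for terminal
  cytosine deamination);
* coverage titration keeps each read independently with probability f
  (binomial thinning), the in-silico analogue of subsampling a read file.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from ._rng import substream
from .errors import InputError
from .panel import SitePanel, simulate_panel
from .pedigree import Pedigree

__all__ = [
    "SimConfig",
    "GenotypeMatrix",
    "ReadPileup",
    "simulate_pedigree_genotypes",
    "simulate_reads",
    "downsample_reads",
    "mean_coverage",
    "per_individual_coverage",
    "round_coverage",
    "simulate_dataset",
]


@dataclass
class SimConfig:
    """Simulation parameters.

    mean_coverage
        Target fold coverage lambda (Poisson mean reads per site).
    base_error
        Per-read allele-flip probability epsilon, in [0, 0.1].
    deamination_rate
        Extra ref->alt flip probability delta at C/T- and G/A-type sites,
        in [0, 0.3].
    seed
        Mandatory root seed; all draws are sub-streams of it.
    """

    n_sites: int = 10_000
    freq_sampler: Callable | None = None
    mean_coverage: float = 2.0
    base_error: float = 0.001
    deamination_rate: float = 0.0
    seed: int = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.seed is None:
            raise InputError("SimConfig.seed is mandatory")
        if self.n_sites < 1:
            raise InputError("n_sites must be >= 1")
        if self.mean_coverage < 0:
            raise InputError("mean_coverage must be >= 0")
        if not 0 <= self.base_error <= 0.1:
            raise InputError("base_error must lie in [0, 0.1]")
        if not 0 <= self.deamination_rate <= 0.3:
            raise InputError("deamination_rate must lie in [0, 0.3]")


@dataclass
class GenotypeMatrix:
    """Latent diploid truth: individuals x sites alt-allele dosages {0,1,2}."""

    individuals: list[str]
    genotypes: np.ndarray  # (n_ind, n_sites) int8
    panel: SitePanel

    def __post_init__(self):
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.shape != (len(self.individuals), self.panel.n_sites):
            raise InputError("genotype matrix shape does not match individuals x panel")
        if self.genotypes.min() < 0 or self.genotypes.max() > 2:
            raise InputError("genotypes must be dosages in {0, 1, 2}")

    def row(self, ind: str) -> np.ndarray:
        return self.genotypes[self.individuals.index(ind)]


@dataclass
class ReadPileup:
    """Per-individual, per-site reference/alternate read counts."""

    individuals: list[str]
    n_ref: np.ndarray  # (n_ind, n_sites) int32
    n_alt: np.ndarray
    panel: SitePanel

    def __post_init__(self):
        self.n_ref = np.asarray(self.n_ref, dtype=np.int32)
        self.n_alt = np.asarray(self.n_alt, dtype=np.int32)
        shape = (len(self.individuals), self.panel.n_sites)
        if self.n_ref.shape != shape or self.n_alt.shape != shape:
            raise InputError("pileup shape does not match individuals x panel")
        if self.n_ref.min() < 0 or self.n_alt.min() < 0:
            raise InputError("read counts must be non-negative")

    @property
    def depth(self) -> np.ndarray:
        return self.n_ref + self.n_alt


def simulate_pedigree_genotypes(panel: SitePanel, pedigree: Pedigree, seed: int) -> GenotypeMatrix:
    """Drop genotypes through a pedigree: HWE founders, Mendelian descent.

    Founder alleles are independent Bernoulli(alt_freq); each non-founder
    receives one uniformly chosen allele from each parent, independently
    per site.  Duplicate ids copy their source genome verbatim.
    """
    rng = substream(seed, "genotypes")
    n = panel.n_sites
    p = panel.alt_freq
    geno: dict[str, np.ndarray] = {}
    for ind in pedigree.topological_order():
        src = pedigree.genome_source(ind)
        if src != ind:
            geno[ind] = geno[src]
            continue
        par = pedigree.parents[ind]
        if par is None:
            geno[ind] = rng.binomial(1, p, size=n) + rng.binomial(1, p, size=n)
        else:
            # A parent transmits alt with probability dosage/2: hom parents
            # transmit deterministically, hets a fair coin per site.
            gm, gf = geno[par[0]], geno[par[1]]
            a_m = rng.random(n) < gm / 2.0
            a_f = rng.random(n) < gf / 2.0
            geno[ind] = a_m.astype(np.int8) + a_f.astype(np.int8)
    individuals = pedigree.members
    return GenotypeMatrix(
        individuals=individuals,
        genotypes=np.stack([geno[i] for i in individuals]).astype(np.int8),
        panel=panel,
    )


def simulate_reads(genotypes: GenotypeMatrix, config: SimConfig) -> ReadPileup:
    """Generate a read pileup from latent genotypes under ``config``.

    Depth is Poisson(mean_coverage) per site; each read carries the alt
    allele with probability g/2 adjusted for base error and, at
    damage-prone sites, the extra ref->alt deamination flip.
    """
    rng = substream(config.seed, "reads")
    g = genotypes.genotypes.astype(np.float64)
    eps, delta = config.base_error, config.deamination_rate
    p_alt = (g / 2.0) * (1 - eps) + (1 - g / 2.0) * eps
    if delta > 0:
        dam = genotypes.panel.damage_prone()
        p_alt = np.where(dam[None, :], p_alt + (1 - p_alt) * delta, p_alt)
    depth = rng.poisson(config.mean_coverage, size=g.shape)
    n_alt = rng.binomial(depth, p_alt)
    return ReadPileup(
        individuals=list(genotypes.individuals),
        n_ref=depth - n_alt,
        n_alt=n_alt,
        panel=genotypes.panel,
    )


def downsample_reads(pileup: ReadPileup, fraction: float, seed: int) -> ReadPileup:
    """Binomial thinning: keep each read independently with probability f."""
    if not 0 <= fraction <= 1:
        raise InputError("retention fraction must lie in [0, 1]")
    if fraction == 1.0:
        return ReadPileup(
            individuals=list(pileup.individuals),
            n_ref=pileup.n_ref.copy(),
            n_alt=pileup.n_alt.copy(),
            panel=pileup.panel,
        )
    rng = substream(seed, "thin", f"{fraction:.6g}")
    return ReadPileup(
        individuals=list(pileup.individuals),
        n_ref=rng.binomial(pileup.n_ref, fraction),
        n_alt=rng.binomial(pileup.n_alt, fraction),
        panel=pileup.panel,
    )


def mean_coverage(pileup: ReadPileup) -> float:
    """Mean fold coverage over panel sites: total reads / (inds x sites)."""
    n = pileup.n_ref.size
    if n == 0:
        raise InputError("empty pileup")
    return float(pileup.n_ref.sum(dtype=np.int64) + pileup.n_alt.sum(dtype=np.int64)) / n


def per_individual_coverage(pileup: ReadPileup) -> np.ndarray:
    """Mean fold coverage per individual over panel sites."""
    if pileup.n_ref.size == 0:
        raise InputError("empty pileup")
    total = pileup.n_ref.sum(axis=1, dtype=np.int64) + pileup.n_alt.sum(axis=1, dtype=np.int64)
    return total / pileup.panel.n_sites


def round_coverage(x: float) -> float:
    """Coverage rounded to 2 decimals, the precision used in reports."""
    return round(float(x), 2)


def simulate_dataset(
    pedigree: Pedigree, config: SimConfig, panel: SitePanel | None = None
) -> tuple[SitePanel, GenotypeMatrix, ReadPileup]:
    """Convenience pipeline: panel -> genotypes -> reads for one pedigree."""
    if panel is None:
        panel = simulate_panel(config.n_sites, config.freq_sampler, seed=config.seed)
    genotypes = simulate_pedigree_genotypes(panel, pedigree, seed=config.seed)
    return panel, genotypes, simulate_reads(genotypes, config)
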