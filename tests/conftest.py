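"""Shared fixtures: small simulated datasets reused across test modules.

Everything is generated at run time from fixed seeds; nothing is read
from disk.
"""

from __future__ import annotations

import numpy as np
import pytest

from kinlow import (
    Pedigree,
    SimConfig,
    call_pseudohaploid,
    fixture_pedigree,
    genotype_likelihoods,
    simulate_dataset,
)


def recovery_pedigree() -> Pedigree:
    """Pairs at phi 0 (founders), 0.125 (P-G), 0.25 (P-C), 0.5 (P-T).

    Eight unrelated founders A1..A8 double as the "unrelated cohort" for
    normalization-based estimators.
    """
    parents = {f"A{k}": None for k in range(1, 9)}
    parents.update({"P": None, "Q": None, "C": ("P", "Q"), "G": ("C", "A8")})
    return Pedigree(parents, duplicates={"T": "P"})


@pytest.fixture(scope="session")
def deep_dataset():
    """Error-free, deep (20x) reads at 50k sites over the recovery pedigree.

    Pseudohaploid calls from these reads sit in the closed-form regime
    where E[per-site mismatch] = 2 (1 - phi) p q.
    """
    ped = recovery_pedigree()
    cfg = SimConfig(n_sites=50_000, mean_coverage=20.0, base_error=0.0, seed=42)
    panel, genotypes, pileup = simulate_dataset(ped, cfg)
    calls = call_pseudohaploid(pileup, seed=42)
    return {"pedigree": ped, "panel": panel, "genotypes": genotypes,
            "pileup": pileup, "calls": calls}


@pytest.fixture(scope="session")
def trio_gl_5x():
    """One trio at 50k sites, 5x, base error 0.001, with its GL matrix."""
    ped = fixture_pedigree("trios")
    cfg = SimConfig(n_sites=50_000, mean_coverage=5.0, base_error=0.001, seed=11)
    panel, genotypes, pileup = simulate_dataset(ped, cfg)
    gl = genotype_likelihoods(pileup, error_rate=0.001)
    return {"pedigree": ped, "panel": panel, "pileup": pileup, "gl": gl}


def subset_calls(calls_matrix, individuals):
    """Restrict a pseudohaploid matrix to a sub-cohort (copy)."""
    from kinlow import PseudohaploidMatrix

    idx = [calls_matrix.individuals.index(i) for i in individuals]
    return PseudohaploidMatrix(
        list(individuals), calls_matrix.calls[idx].copy(), calls_matrix.panel
    )


def mismatch_expectation(panel, phi):
    """Closed-form E[pairwise mismatch] and its SE over panel sites."""
    pq = panel.alt_freq * (1 - panel.alt_freq)
    per_site = 2 * (1 - phi) * pq
    mean = per_site.mean()
    se = np.sqrt((per_site * (1 - per_site)).sum()) / panel.n_sites
    return float(mean), float(se)
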