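"""Genotype representations for the two estimator families.

Pseudohaploid calling draws a single read per site and uses its allele as
a haploid genotype — the standard degraded-DNA workaround that keeps a
site usable at depth 1 but discards call uncertainty.  Genotype
likelihoods instead retain, per site, the likelihood of each diploid
genotype under a per-read binomial error model, so downstream estimators
can weight sites by their information content.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._rng import substream
from .errors import InputError
from .panel import SitePanel
from .simulate import ReadPileup

__all__ = ["MISSING", "PseudohaploidMatrix", "GLMatrix", "call_pseudohaploid", "genotype_likelihoods"]

MISSING = 9  # call code for zero-depth sites


@dataclass
class PseudohaploidMatrix:
    """Individuals x sites haploid calls: 0 = REF, 1 = ALT, 9 = MISSING."""

    individuals: list[str]
    calls: np.ndarray  # (n_ind, n_sites) int8
    panel: SitePanel

    def __post_init__(self):
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.individuals), self.panel.n_sites):
            raise InputError("call matrix shape does not match individuals x panel")
        ok = np.isin(self.calls, (0, 1, MISSING))
        if not ok.all():
            raise InputError("pseudohaploid calls must be 0, 1 or 9")

    def covered(self) -> np.ndarray:
        return self.calls != MISSING


@dataclass
class GLMatrix:
    """Individuals x sites genotype-likelihood triples (L0, L1, L2).

    Non-missing triples are normalized to sum to 1; zero-depth sites are
    flagged in ``missing`` and their triples are NaN.
    """

    individuals: list[str]
    likelihoods: np.ndarray  # (n_ind, n_sites, 3) float64
    missing: np.ndarray  # (n_ind, n_sites) bool
    panel: SitePanel

    def __post_init__(self):
        self.likelihoods = np.asarray(self.likelihoods, dtype=np.float64)
        self.missing = np.asarray(self.missing, dtype=bool)
        shape = (len(self.individuals), self.panel.n_sites)
        if self.likelihoods.shape != shape + (3,) or self.missing.shape != shape:
            raise InputError("GL matrix shape does not match individuals x panel")
        present = self.likelihoods[~self.missing]
        if len(present):
            if np.any(present < 0):
                raise InputError("likelihoods must be non-negative")
            if np.any(np.abs(present.sum(axis=-1) - 1.0) > 1e-9):
                raise InputError("likelihood triples must sum to 1")

    def covered(self) -> np.ndarray:
        return ~self.missing


def call_pseudohaploid(pileup: ReadPileup, seed: int) -> PseudohaploidMatrix:
    """Random-read pseudohaploid calls.

    At each site with depth d >= 1 the call is ALT with probability
    n_alt/d — exactly the law of sampling one read uniformly at random
    (the random draw, rather than a consensus, avoids reference bias).
    Depth-0 sites are MISSING.  Deterministic given ``seed``.
    """
    rng = substream(seed, "pseudohaploid")
    depth = pileup.depth
    with np.errstate(divide="ignore", invalid="ignore"):
        p_alt = np.where(depth > 0, pileup.n_alt / np.maximum(depth, 1), 0.0)
    draw = (rng.random(depth.shape) < p_alt).astype(np.int8)
    calls = np.where(depth > 0, draw, np.int8(MISSING)).astype(np.int8)
    return PseudohaploidMatrix(list(pileup.individuals), calls, pileup.panel)


def genotype_likelihoods(pileup: ReadPileup, error_rate: float = 0.001) -> GLMatrix:
    """Per-site genotype likelihoods under a per-read binomial error model.

    With genotype g in {0,1,2} and error rate eps, each read is alt with
    probability e_g = (g/2)(1-eps) + (1-g/2)eps, so

        L(g) ∝ e_g^n_alt (1 - e_g)^n_ref.

    Triples are normalized to sum to 1; depth-0 sites are missing.
    """
    if not 0 <= error_rate < 0.5:
        raise InputError("error_rate must lie in [0, 0.5)")
    e = np.array([error_rate, 0.5, 1.0 - error_rate])  # alt-read prob per genotype
    n_alt = pileup.n_alt.astype(np.float64)[..., None]
    n_ref = pileup.n_ref.astype(np.float64)[..., None]
    with np.errstate(divide="ignore", invalid="ignore"):
        log_e = np.log(e)
        log_1me = np.log1p(-e)
        # 0 * log(0) is a no-read term and contributes nothing.
        ll = np.where(n_alt > 0, n_alt * log_e, 0.0) + np.where(n_ref > 0, n_ref * log_1me, 0.0)
    ll -= ll.max(axis=-1, keepdims=True)
    lik = np.exp(ll)
    lik /= lik.sum(axis=-1, keepdims=True)
    missing = pileup.depth == 0
    lik[missing] = np.nan
    return GLMatrix(list(pileup.individuals), lik, missing, pileup.panel)
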