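"""Biallelic SNP site panels with population allele frequencies.

A panel emulates an ascertained capture array (a scaled-down analogue of
the ~1.24M-site panels standard in ancient-DNA work): a fixed list of
biallelic autosomal positions at which all genotyping and kinship
computation is performed, each carrying the population alternate-allele
frequency used by frequency-aware estimators.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd

from ._rng import substream
from .errors import InputError

__all__ = ["SitePanel", "simulate_panel", "uniform_freq_sampler"]

_NUCS = np.array(["A", "C", "G", "T"])


@dataclass
class SitePanel:
    """Ordered biallelic sites over 22 autosomes.

    Positions are 1-based and strictly increasing within a chromosome;
    ``alt_freq`` is the population alternate-allele frequency, open
    interval (0, 1).
    """

    site_id: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    alt_freq: np.ndarray

    def __post_init__(self):
        self.chrom = np.asarray(self.chrom, dtype=np.int16)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.alt_freq = np.asarray(self.alt_freq, dtype=np.float64)
        self.site_id = np.asarray(self.site_id)
        self.ref = np.asarray(self.ref)
        self.alt = np.asarray(self.alt)
        self.validate()

    def validate(self) -> None:
        n = len(self.site_id)
        for name in ("chrom", "pos", "ref", "alt", "alt_freq"):
            if len(getattr(self, name)) != n:
                raise InputError(f"panel column {name!r} length mismatch")
        if n == 0:
            raise InputError("panel has no sites")
        if len(np.unique(self.site_id)) != n:
            raise InputError("panel site_ids are not unique")
        if np.any(self.alt_freq <= 0) or np.any(self.alt_freq >= 1):
            raise InputError("alt_freq must lie in the open interval (0, 1)")
        if np.any(self.pos < 1) or np.any(self.chrom < 1):
            raise InputError("positions and chromosomes are 1-based positive integers")
        for c in np.unique(self.chrom):
            p = self.pos[self.chrom == c]
            if np.any(np.diff(p) <= 0):
                raise InputError(f"positions not strictly increasing on chromosome {c}")
        bad = self.ref == self.alt
        if np.any(bad):
            raise InputError("ref and alt alleles must differ")

    @property
    def n_sites(self) -> int:
        return len(self.site_id)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "site_id": self.site_id,
                "chrom": self.chrom,
                "pos": self.pos,
                "ref": self.ref,
                "alt": self.alt,
                "alt_freq": self.alt_freq,
            }
        )

    def damage_prone(self) -> np.ndarray:
        """Boolean mask of sites whose allele pair is {C,T} or {G,A}.

        These are the site classes affected by cytosine-deamination-style
        damage in the simulator (strand-agnostic simplification).
        """
        r, a = self.ref, self.alt
        ct = ((r == "C") & (a == "T")) | ((r == "T") & (a == "C"))
        ga = ((r == "G") & (a == "A")) | ((r == "A") & (a == "G"))
        return ct | ga

    def window_index(self, window_bp: int = 1_000_000):
        """Assign each site to a (chrom, window-start) bin.

        Windows are half-open ``[start, start + window_bp)`` with 1-based
        starts.  Returns ``(labels, index)`` where ``labels`` is the list
        of (chrom, start) keys and ``index`` maps each site to its label.
        """
        start = (self.pos - 1) // window_bp * window_bp + 1
        keys = np.stack([self.chrom.astype(np.int64), start], axis=1)
        uniq, index = np.unique(keys, axis=0, return_inverse=True)
        labels = [(int(c), int(s)) for c, s in uniq]
        return labels, index


def uniform_freq_sampler(low: float = 0.05, high: float = 0.95) -> Callable:
    """Alternate-allele frequency sampler: uniform on [low, high]."""
    if not (0 < low < high < 1):
        raise InputError("frequency sampler bounds must satisfy 0 < low < high < 1")

    def sample(rng: np.random.Generator, n: int) -> np.ndarray:
        return rng.uniform(low, high, size=n)

    return sample


def simulate_panel(
    n_sites: int,
    freq_sampler: Callable | None = None,
    seed: int = 0,
    spacing: int = 2500,
    n_chrom: int = 22,
) -> SitePanel:
    """Simulate a site panel of ``n_sites`` biallelic SNPs.

    Sites are spread over ``n_chrom`` autosomes in contiguous blocks at
    regular ``spacing`` (bp), so fixed-width windows contain predictable
    site counts.  Ref/alt nucleotides are drawn uniformly (distinct), and
    alternate-allele frequencies from ``freq_sampler`` (default uniform on
    [0.05, 0.95]).  Deterministic given ``seed``.
    """
    if n_sites < 1:
        raise InputError("n_sites must be >= 1")
    if freq_sampler is None:
        freq_sampler = uniform_freq_sampler()
    rng = substream(seed, "panel")

    counts = np.full(n_chrom, n_sites // n_chrom, dtype=int)
    counts[: n_sites % n_chrom] += 1
    chrom = np.repeat(np.arange(1, n_chrom + 1), counts)
    pos = np.concatenate([spacing * (np.arange(c) + 1) for c in counts]).astype(np.int64)

    ref_idx = rng.integers(0, 4, size=n_sites)
    alt_idx = (ref_idx + rng.integers(1, 4, size=n_sites)) % 4
    freqs = np.asarray(freq_sampler(rng, n_sites), dtype=np.float64)
    if np.any(freqs <= 0) or np.any(freqs >= 1):
        raise InputError("freq_sampler produced frequencies outside (0, 1)")

    site_id = np.array([f"snp_{c}_{p}" for c, p in zip(chrom, pos)])
    return SitePanel(
        site_id=site_id,
        chrom=chrom,
        pos=pos,
        ref=_NUCS[ref_idx],
        alt=_NUCS[alt_idx],
        alt_freq=freqs,
    )
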