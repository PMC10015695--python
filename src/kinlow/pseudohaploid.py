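"""Pseudohaploid kinship estimators.

Three estimators operate on random-read haploid calls:

* a windowed mismatch estimator: per 1 Mbp window, the proportion P0 of
  differing calls at co-covered sites; the pair's mean P0 is normalized
  by the cohort mean (the expected P0 of an unrelated pair drawn from the
  same group), so normalized P0 ≈ 1 - phi in expectation;
* a genome-wide mismatch-rate estimator: pairwise mismatch rates m are
  screened for significant spread, then normalized by the maximum
  observed rate (taken to be an unrelated pair) into a relatedness
  coefficient r = 2 (1 - m / m_max) ≈ 2 phi;
* a frequency-conditioned haploid agreement estimator: with u = p^2 + q^2
  the unrelated-expected agreement at a site with alt frequency p, the
  halved relatedness coefficient hrc = sum(S - u) / sum(1 - u) over
  co-covered sites has expectation phi for outbred pairs.

All classification boundaries are midpoints between the theoretical
expectations of adjacent degrees.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np

from .errors import InputError
from .genotyping import PseudohaploidMatrix
from .pedigree import Degree

__all__ = [
    "WindowP0",
    "ReadStyleResult",
    "MismatchMatrix",
    "KennettScreen",
    "KennettResult",
    "HRCResult",
    "pairwise_window_p0",
    "read_classify",
    "kennett_mismatch",
    "kennett_screen",
    "kennett_r",
    "hrc_estimate",
]

RELATED_DEGREES = frozenset({Degree.IDENTICAL, Degree.FIRST, Degree.SECOND})


@dataclass(frozen=True)
class WindowP0:
    """Mismatch proportion for one pair in one 1 Mbp window."""

    pair: tuple[str, str]
    window: tuple[int, int]  # (chrom, 1-based window start)
    p0: float
    n_shared: int


@dataclass
class ReadStyleResult:
    pair: tuple[str, str]
    mean_p0: float
    normalized_p0: float
    se: float
    degree: Degree
    z_unrelated: float
    n_windows: int
    n_shared: int
    related: bool
    flag: str  # "ok" | "insufficient"


@dataclass
class MismatchMatrix:
    """Genome-wide pairwise mismatch rates over co-covered sites."""

    individuals: list[str]
    m: np.ndarray  # (n, n) float, NaN where undefined
    n_shared: np.ndarray  # (n, n) int

    def pairs(self):
        n = len(self.individuals)
        for i, j in itertools.combinations(range(n), 2):
            yield (i, j), _pair_key(self.individuals[i], self.individuals[j])


@dataclass
class KennettScreen:
    any_relatives: bool
    m_max: float
    z_vs_max: dict[tuple[str, str], float]


@dataclass
class KennettResult:
    pair: tuple[str, str]
    mismatch: float
    r: float
    n_shared: int
    z_vs_max: float
    degree: Degree
    related: bool
    flag: str


@dataclass
class HRCResult:
    pair: tuple[str, str]
    hrc: float
    n_shared: int
    degree: Degree
    related: bool
    flag: str


def _pair_key(a: str, b: str) -> tuple[str, str]:
    return tuple(sorted((a, b)))  # type: ignore[return-value]


def pairwise_window_p0(
    ph: PseudohaploidMatrix, window_bp: int = 1_000_000
) -> dict[tuple[str, str], list[WindowP0]]:
    """Per-pair, per-window proportion of non-matching haploid calls.

    Windows with zero co-covered sites are omitted.
    """
    if len(ph.individuals) < 2:
        raise InputError("need at least two individuals")
    labels, widx = ph.panel.window_index(window_bp)
    n_windows = len(labels)
    covered = ph.covered()
    out: dict[tuple[str, str], list[WindowP0]] = {}
    n = len(ph.individuals)
    for i, j in itertools.combinations(range(n), 2):
        shared = covered[i] & covered[j]
        diff = shared & (ph.calls[i] != ph.calls[j])
        n_shared = np.bincount(widx[shared], minlength=n_windows)
        n_diff = np.bincount(widx[diff], minlength=n_windows)
        key = _pair_key(ph.individuals[i], ph.individuals[j])
        out[key] = [
            WindowP0(key, labels[w], n_diff[w] / n_shared[w], int(n_shared[w]))
            for w in range(n_windows)
            if n_shared[w] > 0
        ]
    return out


# Expected normalized P0 per degree: 1 - phi.
_P0_EXPECTED = (
    (Degree.IDENTICAL, 0.5),
    (Degree.FIRST, 0.75),
    (Degree.SECOND, 0.875),
    (Degree.UNRELATED, 1.0),
)


def _nearest_degree(value: float, expected) -> Degree:
    return min(expected, key=lambda kv: abs(value - kv[1]))[0]


def read_classify(
    window_p0s: dict[tuple[str, str], list[WindowP0]],
    normalization: str | float = "mean",
    min_windows: int = 10,
    z_crit: float = 1.96,
) -> list[ReadStyleResult]:
    """Normalize mean P0 by the cohort and classify each pair.

    The cohort normalizer (default ``"mean"``) estimates the expected P0
    of an unrelated pair from the data themselves; a numeric value may be
    supplied instead when an external normalization is trusted.  The SE
    of a pair's mean P0 comes from a delete-one-window jackknife; a pair
    counts as related only if its degree is second or closer *and* its
    normalized P0 sits significantly below 1 (z > z_crit).
    """
    if len(window_p0s) < 3:
        raise InputError("cohort normalization needs at least 3 pairs")
    means: dict[tuple[str, str], float] = {}
    for pair, wins in window_p0s.items():
        if len(wins) >= 1:
            means[pair] = float(np.mean([w.p0 for w in wins]))
    if isinstance(normalization, str):
        if normalization != "mean":
            raise InputError(f"unknown normalization {normalization!r}")
        usable = [m for pair, m in means.items() if len(window_p0s[pair]) >= min_windows]
        if not usable:
            raise InputError("no pair has enough windows to form a cohort normalizer")
        norm = float(np.mean(usable))
    else:
        norm = float(normalization)
    if norm <= 0:
        raise InputError("normalization value must be positive")

    results = []
    for pair, wins in window_p0s.items():
        p0s = np.array([w.p0 for w in wins])
        n_shared = int(sum(w.n_shared for w in wins))
        k = len(p0s)
        if k < min_windows:
            results.append(
                ReadStyleResult(pair, float(np.mean(p0s)) if k else math.nan, math.nan,
                                math.nan, Degree.UNRELATED, math.nan, k, n_shared,
                                related=False, flag="insufficient")
            )
            continue
        mean_p0 = float(p0s.mean())
        # Delete-one-window jackknife on the pair's mean P0; the cohort
        # normalizer is held fixed (its resampling variance is second order).
        loo = (p0s.sum() - p0s) / (k - 1)
        se_mean = math.sqrt((k - 1) / k * np.sum((loo - loo.mean()) ** 2))
        normalized = mean_p0 / norm
        se = se_mean / norm
        degree = _nearest_degree(normalized, _P0_EXPECTED)
        z = (1.0 - normalized) / se if se > 0 else math.inf
        related = degree in RELATED_DEGREES and z > z_crit
        results.append(
            ReadStyleResult(pair, mean_p0, normalized, se, degree, z, k, n_shared,
                            related=related, flag="ok")
        )
    return results


def kennett_mismatch(ph: PseudohaploidMatrix) -> MismatchMatrix:
    """Genome-wide pairwise mismatch rates (no windowing)."""
    if len(ph.individuals) < 2:
        raise InputError("need at least two individuals")
    covered = ph.covered().astype(np.float64)
    calls = np.where(ph.covered(), ph.calls, 0).astype(np.float64)
    # Over co-covered sites, a mismatch is |c_i - c_j| for 0/1 calls:
    # n_diff = sum over sites of covered_i * covered_j * (c_i XOR c_j).
    n_shared = covered @ covered.T
    alt = calls * covered
    ref = (1 - calls) * covered
    n_diff = alt @ ref.T + ref @ alt.T
    with np.errstate(invalid="ignore", divide="ignore"):
        m = np.where(n_shared > 0, n_diff / np.maximum(n_shared, 1), np.nan)
    np.fill_diagonal(m, np.nan)
    return MismatchMatrix(list(ph.individuals), m, n_shared.astype(np.int64))


def kennett_screen(mm: MismatchMatrix, z_screen: float = 3.0) -> KennettScreen:
    """Screen the mismatch matrix for any significant rate differences.

    The highest observed rate m_max is taken to be an unrelated pair;
    each pair's rate is compared to it with a binomial z statistic.  If
    no pair deviates (all z <= z_screen), the cohort is assumed to
    contain no relatives.
    """
    pairs = list(mm.pairs())
    valid = [((i, j), key) for (i, j), key in pairs if np.isfinite(mm.m[i, j])]
    if len(valid) < 3:
        raise InputError("screen needs at least 3 pairs with shared sites")
    m_max = max(mm.m[i, j] for (i, j), _ in valid)
    z_vs_max: dict[tuple[str, str], float] = {}
    for (i, j), key in valid:
        m = mm.m[i, j]
        n = mm.n_shared[i, j]
        se = math.sqrt(m * (1 - m) / n) if n > 0 else math.nan
        if se > 0:
            z = (m_max - m) / se
        else:
            z = math.inf if m_max > m else 0.0
        z_vs_max[key] = z
    any_relatives = any(z > z_screen for z in z_vs_max.values())
    return KennettScreen(any_relatives, float(m_max), z_vs_max)


# Expected relatedness coefficient r = 2 phi per degree.
_R_EXPECTED = (
    (Degree.IDENTICAL, 1.0),
    (Degree.FIRST, 0.5),
    (Degree.SECOND, 0.25),
    (Degree.THIRD, 0.125),
    (Degree.UNRELATED, 0.0),
)


def kennett_r(
    mm: MismatchMatrix, screen: KennettScreen, apply_screen: bool = True
) -> list[KennettResult]:
    """Relatedness coefficients r = 2 (1 - m / m_max), classified by degree.

    With ``apply_screen`` the no-relatives screen zeroes all calls when no
    significant mismatch spread was found; switching it off exposes the
    normalizer's tendency to manufacture relatives in all-unrelated
    cohorts (the max rate is then just the upper tail of sampling noise).
    """
    if screen.m_max == 0:
        raise InputError("degenerate mismatch matrix: maximum rate is 0")
    results = []
    for (i, j), key in mm.pairs():
        m = mm.m[i, j]
        n = int(mm.n_shared[i, j])
        if not np.isfinite(m):
            results.append(
                KennettResult(key, math.nan, math.nan, n, math.nan,
                              Degree.UNRELATED, related=False, flag="insufficient")
            )
            continue
        r = 2.0 * (1.0 - m / screen.m_max)
        degree = _nearest_degree(r, _R_EXPECTED)
        related = degree in RELATED_DEGREES
        if apply_screen and not screen.any_relatives:
            related = False
            degree = Degree.UNRELATED
        results.append(
            KennettResult(key, float(m), float(r), n, screen.z_vs_max.get(key, math.nan),
                          degree, related=related, flag="ok")
        )
    return results


def hrc_estimate(
    ph: PseudohaploidMatrix,
    alt_freqs: np.ndarray | None = None,
    min_sites: int = 500,
    related_threshold: float = 0.09375,
) -> list[HRCResult]:
    """Frequency-conditioned halved relatedness coefficient per pair.

    At a site with alt frequency p, two unrelated haploid draws agree
    with probability u = p^2 + q^2; the excess agreement of a pair,

        hrc = sum_s (S_s - u_s) / sum_s (1 - u_s),

    has expectation phi for outbred pairs.  Pairs with fewer than
    ``min_sites`` co-covered sites are flagged insufficient.  The default
    related threshold is the midpoint of the second- and third-degree
    expectations (0.125 and 0.0625).
    """
    p = ph.panel.alt_freq if alt_freqs is None else np.asarray(alt_freqs, dtype=float)
    if len(p) != ph.panel.n_sites:
        raise InputError("frequency vector length does not match panel")
    if np.any(p <= 0) or np.any(p >= 1):
        raise InputError("allele frequencies must lie in (0, 1)")
    u = p**2 + (1 - p) ** 2
    covered = ph.covered()
    results = []
    n = len(ph.individuals)
    for i, j in itertools.combinations(range(n), 2):
        key = _pair_key(ph.individuals[i], ph.individuals[j])
        shared = covered[i] & covered[j]
        n_shared = int(shared.sum())
        if n_shared < min_sites:
            results.append(HRCResult(key, math.nan, n_shared, Degree.UNRELATED,
                                     related=False, flag="insufficient"))
            continue
        agree = (ph.calls[i] == ph.calls[j]) & shared
        num = float(agree.sum() - u[shared].sum())
        den = float((1.0 - u[shared]).sum())
        hrc = num / den
        results.append(HRCResult(key, hrc, n_shared, degree_from_hrc(hrc),
                                 related=hrc >= related_threshold, flag="ok"))
    return results


_HRC_EXPECTED = (
    (Degree.IDENTICAL, 0.5),
    (Degree.FIRST, 0.25),
    (Degree.SECOND, 0.125),
    (Degree.THIRD, 0.0625),
    (Degree.UNRELATED, 0.0),
)


def degree_from_hrc(hrc: float) -> Degree:
    """Nearest-expectation degree for an HRC value (phi scale)."""
    return _nearest_degree(hrc, _HRC_EXPECTED)
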