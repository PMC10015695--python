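"""Genotype-likelihood kinship estimators.

Two estimators consume genotype-likelihood matrices:

* a maximum-likelihood IBD-coefficient estimator: the probability that an
  outbred pair shares 0/1/2 alleles identical by descent at a locus,
  (k0, k1, k2), maximizes a composite likelihood that sums the
  IBD-conditional joint genotype tables over both individuals' genotype
  likelihoods.  The kinship coefficient follows as phi = k1/4 + k2/2.
  Estimation is by EM on the latent IBD class, with multiple starts.
* allele-sharing summary statistics: joint genotype class masses X(a, b)
  accumulated as products of per-individual posterior genotype
  probabilities (HWE prior), from which R0 = IBS0/HETHET,
  R1 = HETHET/(all discordant classes) and the KING-robust kinship
  estimator king = (HETHET - 2 IBS0)/(HET_i + HET_j) are formed.  Degrees
  come from the standard powers-of-two KING bins.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np

from .errors import InputError
from .genotyping import GLMatrix
from .pedigree import Degree

__all__ = [
    "KCoefficients",
    "KinshipML",
    "AlleleSharingStats",
    "ibd_joint_tables",
    "ml_k_estimate",
    "ml_k_from_arrays",
    "phi_from_k",
    "allele_sharing_stats",
    "grid_k_search",
    "KING_BINS",
]


@dataclass(frozen=True)
class KCoefficients:
    """IBD-sharing probabilities (k0, k1, k2) on the simplex."""

    k0: float
    k1: float
    k2: float

    def __post_init__(self):
        k = np.array([self.k0, self.k1, self.k2])
        if np.any(k < -1e-9) or abs(k.sum() - 1.0) > 1e-9:
            raise InputError("k coefficients must be non-negative and sum to 1")

    def as_array(self) -> np.ndarray:
        return np.array([self.k0, self.k1, self.k2])


@dataclass
class KinshipML:
    pair: tuple[str, str]
    k: KCoefficients | None
    phi: float
    n_sites_used: int
    log_likelihood: float
    converged: bool
    flag: str  # "ok" | "insufficient"


@dataclass
class AlleleSharingStats:
    pair: tuple[str, str]
    x_masses: np.ndarray  # 3x3 posterior-weighted joint genotype masses
    r0: float
    r1: float
    king: float
    n_sites: int
    degree: Degree
    related: bool
    flag: str


def phi_from_k(k: KCoefficients) -> float:
    """Kinship coefficient from IBD-sharing probabilities: k1/4 + k2/2."""
    return k.k1 / 4.0 + k.k2 / 2.0


def ibd_joint_tables(p: float | np.ndarray) -> np.ndarray:
    """Joint genotype-pair probabilities conditional on sharing m alleles IBD.

    Returns an array of shape (..., 3, 3, 3): axis -3 is m in {0, 1, 2},
    the last two axes are the genotypes of the two individuals.  Under
    HWE with alt frequency p:

    * m = 0: independent HWE margins;
    * m = 2: identical genotypes, HWE on the diagonal;
    * m = 1: HWE margin for one individual times the transmission of the
      shared allele — from genotype 0: (q, p, 0); from 1: (q/2, 1/2, p/2);
      from 2: (0, q, p).
    """
    p = np.asarray(p, dtype=np.float64)
    if np.any(p <= 0) or np.any(p >= 1):
        raise InputError("allele frequency must lie in (0, 1)")
    q = 1.0 - p
    shape = p.shape
    hwe = np.empty(shape + (3,))
    hwe[..., 0] = q**2
    hwe[..., 1] = 2 * p * q
    hwe[..., 2] = p**2

    t = np.zeros(shape + (3, 3, 3))
    # m = 0
    t[..., 0, :, :] = hwe[..., :, None] * hwe[..., None, :]
    # m = 2
    for g in range(3):
        t[..., 2, g, g] = hwe[..., g]
    # m = 1: one shared allele; the unshared allele of the second
    # individual is a fresh population draw.
    trans = np.zeros(shape + (3, 3))
    trans[..., 0, 0] = q
    trans[..., 0, 1] = p
    trans[..., 1, 0] = q / 2
    trans[..., 1, 1] = 0.5
    trans[..., 1, 2] = p / 2
    trans[..., 2, 1] = q
    trans[..., 2, 2] = p
    t[..., 1, :, :] = hwe[..., :, None] * trans
    return t


def _site_class_likelihoods(li: np.ndarray, lj: np.ndarray, p: np.ndarray) -> np.ndarray:
    """A[s, m] = sum_{gi,gj} L_i(gi) L_j(gj) T_m(gi, gj | p_s)."""
    t = ibd_joint_tables(p)  # (n, 3, 3, 3)
    return np.einsum("sa,sb,smab->sm", li, lj, t, optimize=True)


_EM_STARTS = (
    np.array([1.0, 0.0, 0.0]),
    np.array([0.25, 0.5, 0.25]),
    np.array([1 / 3, 1 / 3, 1 / 3]),
)

# Components are floored away from exact zero inside the EM loop: a zero
# coordinate is an absorbing fixed point of the multiplicative update, so
# flooring lets the iteration re-enter the interior when the optimum is
# not on that face.
_K_FLOOR = 1e-6


def _em_step(a: np.ndarray, k: np.ndarray) -> np.ndarray:
    # Mean posterior over the latent class: k_m * sum_s a[s,m]/lik_s / n,
    # written as one mat-vec instead of materializing the posterior.
    w = 1.0 / np.maximum(a @ k, 1e-300)
    kn = k * (a.T @ w)
    return kn / kn.sum()


def _loglik(a: np.ndarray, k: np.ndarray) -> float:
    return float(np.log(np.maximum(a @ k, 1e-300)).sum())


def _em(a: np.ndarray, k0: np.ndarray, tol: float, max_iter: int):
    """Squared-extrapolation-accelerated EM on the latent IBD class.

    Each cycle takes two EM steps, extrapolates along the step direction
    (SQUAREM steplength), and falls back to the plain double step if the
    extrapolated point does not improve the log-likelihood, so ascent is
    monotone by construction.  ``max_iter`` counts EM-step evaluations.
    """
    k = np.clip(k0, _K_FLOOR, None)
    k /= k.sum()
    ll_old = _loglik(a, k)
    steps = 0
    while steps < max_iter:
        k1 = _em_step(a, k)
        k2 = _em_step(a, k1)
        steps += 2
        r = k1 - k
        v = k2 - k1 - r
        nv = np.linalg.norm(v)
        if nv < 1e-14:
            k_new = k2
        else:
            alpha = min(-np.linalg.norm(r) / nv, -1.0)
            k_new = np.clip(k - 2 * alpha * r + alpha**2 * v, _K_FLOOR, None)
            k_new /= k_new.sum()
            k_new = _em_step(a, k_new)
            steps += 1
            if _loglik(a, k_new) < _loglik(a, k2):
                k_new = k2
        ll = _loglik(a, k_new)
        assert ll >= ll_old - 1e-9, "EM log-likelihood decreased"
        k = k_new
        if ll - ll_old < tol:
            return k, ll, True
        ll_old = ll
    return k, _loglik(a, k), False


def _polish(a: np.ndarray, k0: np.ndarray) -> tuple[np.ndarray, float]:
    """Constrained gradient polish (SLSQP) from the EM solution."""
    from scipy.optimize import minimize

    def negll_grad(k01):
        k = np.clip(np.array([k01[0], k01[1], 1.0 - k01.sum()]), 1e-12, None)
        lik = np.maximum(a @ k, 1e-300)
        g = -(a / lik[:, None]).sum(axis=0)
        return -np.log(lik).sum(), np.array([g[0] - g[2], g[1] - g[2]])

    res = minimize(
        negll_grad, k0[:2], jac=True, method="SLSQP",
        bounds=[(0.0, 1.0), (0.0, 1.0)],
        constraints=({"type": "ineq", "fun": lambda x: 1.0 - x.sum()},),
        options={"maxiter": 100, "ftol": 1e-10},
    )
    k = np.clip(np.array([res.x[0], res.x[1], 1.0 - res.x.sum()]), 0.0, None)
    k /= k.sum()
    return k, _loglik(a, k)


def ml_k_from_arrays(
    li: np.ndarray,
    lj: np.ndarray,
    freqs: np.ndarray,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> tuple[np.ndarray, float, bool]:
    """Maximize the IBD-class composite likelihood (accelerated EM).

    ``li``/``lj`` are (n_sites, 3) normalized genotype-likelihood rows at
    co-covered sites, ``freqs`` the matching alt frequencies.  Runs
    accelerated EM from three fixed starts (unrelated,
    parent-offspring-like, uniform), keeps the best, and finishes with a
    constrained gradient polish.  Returns (k, log_likelihood, converged).
    """
    a = _site_class_likelihoods(li, lj, freqs)
    best = None
    for start in _EM_STARTS:
        k, ll, conv = _em(a, start, tol, max_iter)
        if best is None or ll > best[1]:
            best = (k, ll, conv)
    k, ll, conv = best
    kp, llp = _polish(a, k)
    if llp >= ll:
        k, ll = kp, llp
    return k, ll, conv or llp >= ll


def ml_k_estimate(
    gl: GLMatrix,
    ind_i: str,
    ind_j: str,
    freqs: np.ndarray | None = None,
    min_sites: int = 500,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> KinshipML:
    """Maximum-likelihood (k0, k1, k2) and phi for one pair."""
    i = gl.individuals.index(ind_i)
    j = gl.individuals.index(ind_j)
    p = gl.panel.alt_freq if freqs is None else np.asarray(freqs, dtype=float)
    shared = gl.covered()[i] & gl.covered()[j]
    pair = tuple(sorted((ind_i, ind_j)))
    n_used = int(shared.sum())
    if n_used < min_sites:
        return KinshipML(pair, None, math.nan, n_used, math.nan, False, "insufficient")
    k, ll, conv = ml_k_from_arrays(
        gl.likelihoods[i][shared], gl.likelihoods[j][shared], p[shared],
        tol=tol, max_iter=max_iter,
    )
    kc = KCoefficients(*np.clip(k, 0, 1) / np.clip(k, 0, 1).sum())
    return KinshipML(pair, kc, phi_from_k(kc), n_used, ll, conv, "ok")


def grid_k_search(
    li: np.ndarray,
    lj: np.ndarray,
    freqs: np.ndarray,
    step: float = 0.01,
    refine: float | None = 0.0005,
) -> tuple[np.ndarray, float]:
    """Exhaustive simplex grid maximization of the same likelihood.

    Brute-force reference for the EM path: evaluates the composite
    log-likelihood at every (k0, k1, k2) on a ``step`` lattice, then (if
    ``refine`` is set) sweeps a finer exhaustive lattice over the winning
    cell so the argmax resolves below the coarse lattice spacing.  Pure
    enumeration throughout — independent of the EM code path.
    """
    a = _site_class_likelihoods(li, lj, freqs)
    n = int(round(1.0 / step))
    best_k, best_ll = None, -np.inf
    for i0 in range(n + 1):
        for i1 in range(n + 1 - i0):
            k = np.array([i0, i1, n - i0 - i1], dtype=float) / n
            ll = _loglik(a, k)
            if ll > best_ll:
                best_k, best_ll = k, ll
    if refine is not None:
        c0, c1 = best_k[0], best_k[1]
        for a0 in np.arange(max(0.0, c0 - step), min(1.0, c0 + step) + 1e-12, refine):
            for a1 in np.arange(max(0.0, c1 - step), min(1.0 - a0, c1 + step) + 1e-12, refine):
                k = np.array([a0, a1, max(1.0 - a0 - a1, 0.0)])
                k /= k.sum()
                ll = _loglik(a, k)
                if ll > best_ll:
                    best_k, best_ll = k, ll
    return best_k, best_ll


# KING kinship bins: powers-of-two boundaries 2^(-3/2)/2^d scaled to phi.
KING_BINS = (
    (Degree.IDENTICAL, 0.5 / math.sqrt(2)),   # > 0.3536
    (Degree.FIRST, 0.25 / math.sqrt(2)),      # > 0.1768
    (Degree.SECOND, 0.125 / math.sqrt(2)),    # > 0.0884
    (Degree.THIRD, 0.0625 / math.sqrt(2)),    # > 0.0442
)


def _king_degree(king: float) -> Degree:
    for degree, bound in KING_BINS:
        if king > bound:
            return degree
    return Degree.UNRELATED


def allele_sharing_stats(
    gl: GLMatrix,
    ind_i: str,
    ind_j: str,
    freqs: np.ndarray | None = None,
    min_sites: int = 500,
) -> AlleleSharingStats:
    """Posterior-weighted joint genotype masses and R0/R1/KING statistics.

    Per co-covered site the posterior genotype distribution of each
    individual is its likelihood triple reweighted by the HWE prior at
    the site frequency; the 3x3 mass table X accumulates the outer
    products.  ``related`` uses the KING second-degree boundary.
    """
    i = gl.individuals.index(ind_i)
    j = gl.individuals.index(ind_j)
    p = gl.panel.alt_freq if freqs is None else np.asarray(freqs, dtype=float)
    shared = gl.covered()[i] & gl.covered()[j]
    pair = tuple(sorted((ind_i, ind_j)))
    n_sites = int(shared.sum())
    if n_sites < min_sites:
        return AlleleSharingStats(pair, np.full((3, 3), np.nan), math.nan, math.nan,
                                  math.nan, n_sites, Degree.UNRELATED, False, "insufficient")
    ps = p[shared]
    hwe = np.stack([(1 - ps) ** 2, 2 * ps * (1 - ps), ps**2], axis=1)
    post_i = gl.likelihoods[i][shared] * hwe
    post_i /= post_i.sum(axis=1, keepdims=True)
    post_j = gl.likelihoods[j][shared] * hwe
    post_j /= post_j.sum(axis=1, keepdims=True)
    x = post_i.T @ post_j  # (3, 3), sums to n_sites

    ibs0 = x[0, 2] + x[2, 0]
    hethet = x[1, 1]
    het_i = x[1, 0] + x[1, 1] + x[1, 2]
    het_j = x[0, 1] + x[1, 1] + x[2, 1]
    discordant = ibs0 + x[0, 1] + x[1, 0] + x[1, 2] + x[2, 1]
    r0 = ibs0 / hethet if hethet > 0 else math.nan
    r1 = hethet / discordant if discordant > 0 else math.nan
    denom = het_i + het_j
    king = (hethet - 2 * ibs0) / denom if denom > 0 else math.nan
    degree = _king_degree(king) if np.isfinite(king) else Degree.UNRELATED
    related = bool(np.isfinite(king) and king > KING_BINS[2][1])
    return AlleleSharingStats(pair, x, float(r0), float(r1), float(king),
                              n_sites, degree, related, "ok")


def all_pairs_ml(gl: GLMatrix, freqs: np.ndarray | None = None, **kw) -> list[KinshipML]:
    """ml_k_estimate over every unordered pair in the matrix."""
    return [
        ml_k_estimate(gl, a, b, freqs=freqs, **kw)
        for a, b in itertools.combinations(gl.individuals, 2)
    ]


def all_pairs_king(gl: GLMatrix, freqs: np.ndarray | None = None, **kw) -> list[AlleleSharingStats]:
    """allele_sharing_stats over every unordered pair in the matrix."""
    return [
        allele_sharing_stats(gl, a, b, freqs=freqs, **kw)
        for a, b in itertools.combinations(gl.individuals, 2)
    ]
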