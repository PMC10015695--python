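"""Coverage-titration benchmark and evaluation machinery.

The experimental design: thin a full pileup to a grid of retention
fractions, re-call genotypes at each level, run every estimator, reduce
each pair to a binary related/unrelated call at the second-degree
threshold, and score reduced-coverage call sets against the
maximum-coverage reference:

    accuracy    = |calls_f intersect calls_max| / |calls_f|
    consistency = |calls_f intersect calls_max| / |calls_max|
    false positives = |calls_f  \\ calls_max|
    false negatives = |calls_max \\ calls_f|

A relative kinship score maps every estimator onto a common phi-derived
scale (identical pairs score 1), and a Mantel permutation test correlates
score distances with pairwise-coverage distances across (pair, fraction)
observations.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._rng import substream
from .errors import InputError
from .genotyping import call_pseudohaploid, genotype_likelihoods
from .likelihood import all_pairs_king, all_pairs_ml
from .pseudohaploid import (
    hrc_estimate,
    kennett_mismatch,
    kennett_r,
    kennett_screen,
    pairwise_window_p0,
    read_classify,
)
from .simulate import ReadPileup, downsample_reads, per_individual_coverage

__all__ = [
    "PSEUDOHAPLOID_METHODS",
    "GL_METHODS",
    "ALL_METHODS",
    "RelationshipCall",
    "EvaluationMetrics",
    "MantelResult",
    "SweepResult",
    "run_sweep",
    "relative_kinship_score",
    "evaluate",
    "mantel_test",
    "build_mantel_matrices",
    "calls_to_frame",
    "metrics_to_frame",
]

PSEUDOHAPLOID_METHODS = ("read", "kennett", "tkgwv2")
GL_METHODS = ("lcmlkin", "king")
ALL_METHODS = PSEUDOHAPLOID_METHODS + GL_METHODS

DEFAULT_FRACTIONS = (1.0, 0.5, 0.25, 0.1, 0.05, 0.01)


@dataclass(frozen=True)
class RelationshipCall:
    """One estimator's binary verdict for one pair at one retention level."""

    pair: tuple[str, str]
    method: str
    fraction: float
    related: bool
    raw_stat: float
    relative_score: float
    n_shared: int
    flag: str  # "ok" | "insufficient"


@dataclass
class EvaluationMetrics:
    method: str
    fraction: float
    n_identified: int
    n_reference: int
    accuracy: float  # NaN when undefined
    consistency: float
    false_positives: int
    false_negatives: int
    fp_truth: int | None = None
    fn_truth: int | None = None


@dataclass
class MantelResult:
    r: float
    p: float
    n_perm: int
    n: int
    exact: bool
    degenerate: bool = False


@dataclass
class SweepResult:
    """Calls plus per-individual coverage bookkeeping for one sweep."""

    calls: list[RelationshipCall]
    coverage: dict[tuple[str, float], float] = field(default_factory=dict)
    seed: int = 0

    def for_method(self, method: str) -> list[RelationshipCall]:
        return [c for c in self.calls if c.method == method]


def relative_kinship_score(raw_stat: float, method: str) -> float:
    """Map an estimator's raw statistic onto a common kinship scale.

    Every method is first brought to the phi scale (windowed-P0:
    1 - normalized P0; mismatch-rate r: r/2; hrc, phi, king: as is) and
    then divided by 0.5 so a duplicated genome scores 1.
    """
    if method == "read":
        phi_like = 1.0 - raw_stat
    elif method == "kennett":
        phi_like = raw_stat / 2.0
    elif method in ("tkgwv2", "lcmlkin", "king"):
        phi_like = raw_stat
    else:
        raise InputError(f"unknown method {method!r}")
    return phi_like / 0.5


def _run_method(
    method: str,
    pileup: ReadPileup,
    fraction: float,
    seed: int,
    gl_error: float,
    min_sites: int,
    min_windows: int,
    apply_kennett_screen: bool,
) -> list[RelationshipCall]:
    calls: list[RelationshipCall] = []
    if method in PSEUDOHAPLOID_METHODS:
        ph_seed = substream(seed, "sweep", f"{fraction:.6g}", method).integers(2**31)
        ph = call_pseudohaploid(pileup, seed=int(ph_seed))
        if method == "read":
            wp0 = pairwise_window_p0(ph)
            for res in read_classify(wp0, min_windows=min_windows):
                calls.append(RelationshipCall(res.pair, method, fraction, res.related,
                                              res.normalized_p0, relative_kinship_score(res.normalized_p0, method),
                                              res.n_shared, res.flag))
        elif method == "kennett":
            mm = kennett_mismatch(ph)
            screen = kennett_screen(mm)
            for res in kennett_r(mm, screen, apply_screen=apply_kennett_screen):
                calls.append(RelationshipCall(res.pair, method, fraction, res.related,
                                              res.r, relative_kinship_score(res.r, method),
                                              res.n_shared, res.flag))
        else:  # tkgwv2
            for res in hrc_estimate(ph, min_sites=min_sites):
                calls.append(RelationshipCall(res.pair, method, fraction, res.related,
                                              res.hrc, relative_kinship_score(res.hrc, method),
                                              res.n_shared, res.flag))
    elif method in GL_METHODS:
        gl = genotype_likelihoods(pileup, error_rate=gl_error)
        if method == "lcmlkin":
            for ml in all_pairs_ml(gl, min_sites=min_sites):
                related = ml.flag == "ok" and ml.phi > 0.09375  # second/third midpoint
                calls.append(RelationshipCall(ml.pair, method, fraction, related,
                                              ml.phi, relative_kinship_score(ml.phi, method),
                                              ml.n_sites_used, ml.flag))
        else:  # king
            for st in all_pairs_king(gl, min_sites=min_sites):
                calls.append(RelationshipCall(st.pair, method, fraction, st.related,
                                              st.king, relative_kinship_score(st.king, method),
                                              st.n_sites, st.flag))
    else:
        raise InputError(f"unknown method {method!r}")
    return calls


def run_sweep(
    pileup: ReadPileup,
    methods=ALL_METHODS,
    fractions=DEFAULT_FRACTIONS,
    seed: int = 0,
    gl_error: float = 0.001,
    min_sites: int = 500,
    min_windows: int = 10,
    apply_kennett_screen: bool = True,
) -> SweepResult:
    """Thin, re-call and re-estimate at every retention fraction.

    Fraction 1.0 means the original pileup.  Each (fraction, method) cell
    uses its own deterministic sub-seed so methods and levels can be
    added without perturbing one another.
    """
    if len(pileup.individuals) < 3:
        raise InputError("sweep needs at least 3 individuals")
    if not methods:
        raise InputError("no methods requested")
    for m in methods:
        if m not in ALL_METHODS:
            raise InputError(f"unknown method {m!r}; known: {', '.join(ALL_METHODS)}")
    fractions = tuple(fractions)
    if any(not (0 < f <= 1) for f in fractions):
        raise InputError("retention fractions must lie in (0, 1]")

    result = SweepResult(calls=[], seed=seed)
    for f in fractions:
        if f == 1.0:
            thinned = pileup
        else:
            thin_seed = substream(seed, "sweep-thin", f"{f:.6g}").integers(2**31)
            thinned = downsample_reads(pileup, f, seed=int(thin_seed))
        cov = per_individual_coverage(thinned)
        for ind, c in zip(thinned.individuals, cov):
            result.coverage[(ind, f)] = float(c)
        for method in methods:
            result.calls.extend(
                _run_method(method, thinned, f, seed, gl_error, min_sites,
                            min_windows, apply_kennett_screen)
            )
    return result


def _related_set(calls: list[RelationshipCall]) -> set[tuple[str, str]]:
    return {c.pair for c in calls if c.related and c.flag == "ok"}


def evaluate(
    calls: list[RelationshipCall],
    reference: list[RelationshipCall] | None = None,
    truth: set[tuple[str, str]] | None = None,
) -> list[EvaluationMetrics]:
    """Score each (method, fraction) cell against the max-coverage reference.

    ``reference`` defaults to the fraction-1.0 calls inside ``calls``.
    Accuracy and consistency exclude pairs flagged insufficient at the
    reduced level from both numerator and denominator; false positives /
    negatives follow the set definitions verbatim (an insufficient pair
    is simply not identified).  When a ground-truth related-pair set is
    supplied, fp_truth / fn_truth are reported additionally.
    """
    methods = sorted({c.method for c in calls})
    out: list[EvaluationMetrics] = []
    for method in methods:
        mcalls = [c for c in calls if c.method == method]
        if reference is None:
            ref_calls = [c for c in mcalls if c.fraction == 1.0]
        else:
            ref_calls = [c for c in reference if c.method == method]
        ref = _related_set(ref_calls)
        for f in sorted({c.fraction for c in mcalls}, reverse=True):
            fcalls = [c for c in mcalls if c.fraction == f]
            identified = _related_set(fcalls)
            ok_pairs = {c.pair for c in fcalls if c.flag == "ok"}
            ref_usable = ref & ok_pairs
            accuracy = len(identified & ref_usable) / len(identified) if identified else math.nan
            consistency = len(identified & ref_usable) / len(ref_usable) if ref_usable else math.nan
            fp = len(identified - ref)
            fn = len(ref - identified)
            fp_t = len(identified - truth) if truth is not None else None
            fn_t = len(truth - identified) if truth is not None else None
            out.append(EvaluationMetrics(method, f, len(identified), len(ref),
                                         accuracy, consistency, fp, fn, fp_t, fn_t))
    return out


def _upper(mat: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(mat.shape[0], k=1)
    return mat[iu]


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        return math.nan
    return float(np.corrcoef(x, y)[0, 1])


def mantel_test(
    matrix_a: np.ndarray,
    matrix_b: np.ndarray,
    n_perm: int = 9999,
    seed: int = 0,
    exact: bool | None = None,
) -> MantelResult:
    """Mantel permutation test between two distance matrices.

    r is the Pearson correlation of the vectorized upper triangles; the
    two-sided p value counts joint row/column permutations of matrix_b
    with |r_perm| >= |r_obs|, with the +1 convention.  For n <= 6 the
    full permutation distribution is enumerated exactly (override with
    ``exact=False`` to force sampling, e.g. for calibration checks).
    """
    a = np.asarray(matrix_a, dtype=float)
    b = np.asarray(matrix_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise InputError("matrices must be square and of equal size")
    n = a.shape[0]
    if n < 4:
        raise InputError("mantel test needs matrices of size >= 4")
    for m, name in ((a, "matrix_a"), (b, "matrix_b")):
        if not np.allclose(m, m.T):
            raise InputError(f"{name} is not symmetric")
        if not np.allclose(np.diag(m), 0):
            raise InputError(f"{name} diagonal is not zero")

    xa = _upper(a)
    r_obs = _pearson(xa, _upper(b))
    if math.isnan(r_obs):
        return MantelResult(math.nan, math.nan, 0, n, exact=False, degenerate=True)

    if exact is None:
        exact = n <= 6
    if exact:
        perms = list(itertools.permutations(range(n)))
        count = 0
        for perm in perms:
            idx = np.array(perm)
            r_p = _pearson(xa, _upper(b[np.ix_(idx, idx)]))
            if abs(r_p) >= abs(r_obs) - 1e-12:
                count += 1
        return MantelResult(float(r_obs), count / len(perms), len(perms), n, exact=True)

    rng = substream(seed, "mantel")
    count = 1  # the identity permutation
    for _ in range(n_perm):
        idx = rng.permutation(n)
        r_p = _pearson(xa, _upper(b[np.ix_(idx, idx)]))
        if abs(r_p) >= abs(r_obs) - 1e-12:
            count += 1
    return MantelResult(float(r_obs), count / (n_perm + 1), n_perm, n, exact=False)


def build_mantel_matrices(
    calls: list[RelationshipCall],
    coverage: dict[tuple[str, float], float],
):
    """Distance matrices over (pair, fraction) observations for one method.

    Entry (u, v) of the first matrix is |relative score_u - score_v|; of
    the second, |pairwise mean coverage_u - coverage_v| where a pairwise
    coverage is the mean of the two individuals' fold coverages at that
    fraction.  Observations flagged insufficient are dropped.
    """
    methods = {c.method for c in calls}
    if len(methods) != 1:
        raise InputError("build_mantel_matrices expects calls from exactly one method")
    obs = [c for c in calls if c.flag == "ok" and np.isfinite(c.relative_score)]
    if len(obs) < 4:
        raise InputError("need at least 4 usable (pair, fraction) observations")
    scores = np.array([c.relative_score for c in obs])
    covs = np.array([
        0.5 * (coverage[(c.pair[0], c.fraction)] + coverage[(c.pair[1], c.fraction)])
        for c in obs
    ])
    d_score = np.abs(scores[:, None] - scores[None, :])
    d_cov = np.abs(covs[:, None] - covs[None, :])
    labels = [(c.pair, c.fraction) for c in obs]
    return d_score, d_cov, labels


def calls_to_frame(calls: list[RelationshipCall]) -> pd.DataFrame:
    """Tidy DataFrame of sweep calls (one row per pair x method x fraction)."""
    return pd.DataFrame(
        {
            "individual_1": [c.pair[0] for c in calls],
            "individual_2": [c.pair[1] for c in calls],
            "method": [c.method for c in calls],
            "fraction": [c.fraction for c in calls],
            "related": [c.related for c in calls],
            "raw_stat": [c.raw_stat for c in calls],
            "relative_score": [c.relative_score for c in calls],
            "n_shared": [c.n_shared for c in calls],
            "flag": [c.flag for c in calls],
        }
    )


def metrics_to_frame(metrics: list[EvaluationMetrics]) -> pd.DataFrame:
    return pd.DataFrame([m.__dict__ for m in metrics])
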