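"""Sweep orchestration, evaluation metrics, relative scores, Mantel tests."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kinlow import (
    InputError,
    RelationshipCall,
    SimConfig,
    evaluate,
    fixture_pedigree,
    mantel_test,
    related_pairs,
    relative_kinship_score,
    run_sweep,
    simulate_dataset,
)
from kinlow.benchmark import build_mantel_matrices


def _call(pair, method="tkgwv2", f=1.0, related=False, stat=0.0, score=0.0,
          n=1000, flag="ok"):
    return RelationshipCall(tuple(sorted(pair)), method, f, related, stat, score, n, flag)


class TestRelativeScore:
    @pytest.mark.parametrize(
        "stat, method, score",
        [
            (1.0, "read", 0.0),      # normalized P0 of an unrelated pair
            (0.75, "read", 0.5),     # parent-offspring
            (1.0, "kennett", 1.0),   # duplicate r
            (0.5, "kennett", 0.5),
            (0.25, "tkgwv2", 0.5),
            (0.25, "lcmlkin", 0.5),  # phi = 0.25
            (0.5, "king", 1.0),
        ],
    )
    def test_mapping(self, stat, method, score):
        assert relative_kinship_score(stat, method) == pytest.approx(score)

    def test_unknown_method(self):
        with pytest.raises(InputError):
            relative_kinship_score(0.1, "plink")


class TestEvaluate:
    def test_identity_at_full_coverage(self):
        calls = [_call(("a", "b"), f=1.0, related=True), _call(("a", "c"), f=1.0)]
        m = evaluate(calls)[0]
        assert m.accuracy == 1.0
        assert m.consistency == 1.0
        assert m.false_positives == m.false_negatives == 0

    def test_four_of_five_plus_one_novel(self):
        ref_pairs = [("a", "b"), ("a", "c"), ("b", "c"), ("c", "d"), ("d", "e")]
        novel = ("a", "e")
        calls = [_call(p, f=1.0, related=True) for p in ref_pairs]
        calls += [_call(p, f=0.1, related=True) for p in ref_pairs[:4]]
        calls += [_call(ref_pairs[4], f=0.1, related=False)]
        calls += [_call(novel, f=0.1, related=True)]
        m = {x.fraction: x for x in evaluate(calls)}[0.1]
        assert m.accuracy == pytest.approx(4 / 5)
        assert m.consistency == pytest.approx(4 / 5)
        assert m.false_positives == 1
        assert m.false_negatives == 1

    def test_empty_calls_consistency_zero_accuracy_undefined(self):
        ref_pairs = [("a", "b"), ("a", "c"), ("b", "c"), ("c", "d"), ("d", "e")]
        calls = [_call(p, f=1.0, related=True) for p in ref_pairs]
        calls += [_call(p, f=0.05, related=False) for p in ref_pairs]
        m = {x.fraction: x for x in evaluate(calls)}[0.05]
        assert np.isnan(m.accuracy)
        assert m.consistency == 0.0
        assert m.false_negatives == 5

    def test_insufficient_pairs_excluded_from_rates(self):
        calls = [
            _call(("a", "b"), f=1.0, related=True),
            _call(("a", "c"), f=1.0, related=True),
            _call(("a", "b"), f=0.1, related=True),
            _call(("a", "c"), f=0.1, related=False, flag="insufficient"),
        ]
        m = {x.fraction: x for x in evaluate(calls)}[0.1]
        # (a,c) is unjudgeable at f=0.1: consistency denominator shrinks to 1
        assert m.consistency == 1.0
        assert m.accuracy == 1.0
        # but the set-difference FN count still sees it as not identified
        assert m.false_negatives == 1

    def test_truth_comparison(self):
        calls = [
            _call(("a", "b"), f=1.0, related=True),
            _call(("a", "c"), f=1.0, related=True),
        ]
        m = evaluate(calls, truth={("a", "b"), ("b", "c")})[0]
        assert m.fp_truth == 1
        assert m.fn_truth == 1


class TestMantel:
    @staticmethod
    def _dist(vals):
        v = np.asarray(vals, dtype=float)
        return np.abs(v[:, None] - v[None, :])

    def test_self_correlation_is_one(self):
        d = self._dist([0.1, 0.9, 0.4, 0.7, 0.2])
        res = mantel_test(d, d.copy())
        assert res.r == pytest.approx(1.0)
        assert res.exact

    def test_exact_enumeration_matches_sampling(self):
        rng = np.random.default_rng(1)
        a = self._dist(rng.random(5))
        b = self._dist(rng.random(5) + 0.5 * np.diag(a @ a.T))  # loosely related
        exact = mantel_test(a, b)
        sampled = mantel_test(a, b, n_perm=9999, seed=3, exact=False)
        assert exact.exact and not sampled.exact
        assert exact.n_perm == 120
        assert abs(exact.p - sampled.p) < 0.02

    def test_null_p_values_roughly_uniform(self):
        # independent matrices: p should not pile up near 0
        rng = np.random.default_rng(5)
        ps = []
        for _ in range(120):
            a = self._dist(rng.random(7))
            b = self._dist(rng.random(7))
            ps.append(mantel_test(a, b, n_perm=199, seed=int(rng.integers(2**31))).p)
        from scipy.stats import kstest

        assert kstest(ps, "uniform").pvalue > 0.01

    def test_degenerate_matrix_flagged(self):
        a = np.zeros((5, 5))
        b = self._dist([1, 2, 3, 4, 5])
        res = mantel_test(a, b)
        assert res.degenerate

    def test_input_validation(self):
        d = self._dist([1, 2, 3, 4])
        with pytest.raises(InputError):
            mantel_test(d, d[:3, :3])
        asym = d.copy()
        asym[0, 1] = 99
        with pytest.raises(InputError):
            mantel_test(asym, d)
        with pytest.raises(InputError):
            mantel_test(d[:3, :3], d[:3, :3])

    @settings(max_examples=20, deadline=None)
    @given(seed=st.integers(0, 2**20))
    def test_p_value_bounds(self, seed):
        rng = np.random.default_rng(seed)
        a = self._dist(rng.random(5))
        b = self._dist(rng.random(5))
        res = mantel_test(a, b)
        if not res.degenerate:
            assert 1 / res.n_perm <= res.p <= 1.0


class TestBuildMantelMatrices:
    def test_hand_computed_toy(self):
        calls = [
            _call(("a", "b"), f=1.0, score=1.0),
            _call(("a", "c"), f=1.0, score=0.2),
            _call(("a", "b"), f=0.5, score=0.6),
            _call(("a", "c"), f=0.5, score=0.0),
        ]
        coverage = {("a", 1.0): 2.0, ("b", 1.0): 1.0, ("c", 1.0): 3.0,
                    ("a", 0.5): 1.0, ("b", 0.5): 0.5, ("c", 0.5): 1.5}
        d_score, d_cov, labels = build_mantel_matrices(calls, coverage)
        # pairwise coverages: ab@1=1.5, ac@1=2.5, ab@.5=0.75, ac@.5=1.25
        assert d_score[0, 1] == pytest.approx(0.8)
        assert d_score[0, 2] == pytest.approx(0.4)
        assert d_cov[0, 1] == pytest.approx(1.0)
        assert d_cov[0, 3] == pytest.approx(0.25)
        assert labels[0] == (("a", "b"), 1.0)

    def test_monotone_scores_give_positive_r(self):
        calls, coverage = [], {}
        for f, score in ((1.0, 0.9), (0.5, 0.5), (0.25, 0.2)):
            for k, pair in enumerate((("a", "b"), ("a", "c"), ("b", "c"))):
                calls.append(_call(pair, f=f, score=score + 0.01 * k))
                for ind in pair:
                    coverage[(ind, f)] = 2.0 * f
        d_score, d_cov, _ = build_mantel_matrices(calls, coverage)
        res = mantel_test(d_score, d_cov, n_perm=499, seed=1)
        assert res.r > 0

    def test_too_few_observations(self):
        calls = [_call(("a", "b"), f=1.0, score=1.0)]
        with pytest.raises(InputError):
            build_mantel_matrices(calls, {("a", 1.0): 1.0, ("b", 1.0): 1.0})

    def test_mixed_methods_rejected(self):
        calls = [_call(("a", "b"), method="read"), _call(("a", "b"), method="king")]
        with pytest.raises(InputError):
            build_mantel_matrices(calls, {})


class TestRunSweep:
    @pytest.fixture(scope="class")
    def small_sweep(self):
        ped = fixture_pedigree("unrelated5")
        cfg = SimConfig(n_sites=6_000, mean_coverage=3.0, base_error=0.001, seed=37)
        _, _, pile = simulate_dataset(ped, cfg)
        sweep = run_sweep(pile, methods=("tkgwv2", "king"), fractions=(1.0, 0.5), seed=37)
        return ped, sweep

    def test_unrelated_cohort_yields_no_calls(self, small_sweep):
        _, sweep = small_sweep
        assert not any(c.related for c in sweep.calls)

    def test_full_coverage_metrics_are_identities(self, small_sweep):
        ped, sweep = small_sweep
        for m in evaluate(sweep.calls, truth=related_pairs(ped)):
            if m.fraction == 1.0 and m.n_identified:
                assert m.accuracy == 1.0 and m.consistency == 1.0

    def test_coverage_bookkeeping(self, small_sweep):
        _, sweep = small_sweep
        full = [sweep.coverage[(i, 1.0)] for i in "U1 U2 U3 U4 U5".split()]
        half = [sweep.coverage[(i, 0.5)] for i in "U1 U2 U3 U4 U5".split()]
        assert np.mean(half) == pytest.approx(0.5 * np.mean(full), rel=0.05)

    def test_input_validation(self, small_sweep):
        ped = fixture_pedigree("unrelated5")
        cfg = SimConfig(n_sites=500, mean_coverage=1.0, seed=1)
        _, _, pile = simulate_dataset(ped, cfg)
        with pytest.raises(InputError):
            run_sweep(pile, methods=("plink",), seed=1)
        with pytest.raises(InputError):
            run_sweep(pile, fractions=(1.0, 0.0), seed=1)
        with pytest.raises(InputError):
            run_sweep(pile, methods=(), seed=1)

    def test_determinism(self):
        ped = fixture_pedigree("unrelated5")
        cfg = SimConfig(n_sites=2_000, mean_coverage=2.0, seed=41)
        _, _, pile = simulate_dataset(ped, cfg)
        a = run_sweep(pile, methods=("tkgwv2",), fractions=(0.5,), seed=8)
        b = run_sweep(pile, methods=("tkgwv2",), fractions=(0.5,), seed=8)
        assert [(c.pair, c.raw_stat) for c in a.calls] == [(c.pair, c.raw_stat) for c in b.calls]


def test_ml_reduced_coverage_calls_subset_of_full():
    """Relationships the ML method keeps inferring at reduced coverage are
    among those inferred at full coverage (trio cohort: no pairs sit on the
    second/third-degree boundary, so the property is identifiable)."""
    ped = fixture_pedigree("trios")
    ok = 0
    n_seeds = 8
    for s in range(n_seeds):
        cfg = SimConfig(n_sites=10_000, mean_coverage=2.0, base_error=0.001,
                        seed=400 + s)
        _, _, pile = simulate_dataset(ped, cfg)
        sweep = run_sweep(pile, methods=("lcmlkin",), fractions=(1.0, 0.25, 0.05),
                          seed=400 + s)
        ref = {c.pair for c in sweep.calls if c.fraction == 1.0 and c.related}
        reduced = {c.pair for c in sweep.calls if c.fraction < 1.0 and c.related}
        if reduced <= ref:
            ok += 1
    assert ok >= 0.9 * n_seeds


def test_mantel_cross_check_against_skbio():
    """Independent implementation check: scikit-bio's Mantel test on the
    same matrices gives the same r and a compatible p value."""
    pytest.importorskip("skbio")
    from skbio.stats.distance import DistanceMatrix, mantel as skbio_mantel

    rng = np.random.default_rng(9)
    base = rng.random(8)
    a = np.abs(base[:, None] - base[None, :])
    noise = base + rng.normal(0, 0.3, 8)
    b = np.abs(noise[:, None] - noise[None, :])
    ours = mantel_test(a, b, n_perm=9999, seed=2)
    r_sk, p_sk, _ = skbio_mantel(DistanceMatrix(a), DistanceMatrix(b),
                                 method="pearson", permutations=9999,
                                 alternative="two-sided")
    assert ours.r == pytest.approx(r_sk, abs=1e-12)
    assert abs(ours.p - p_sk) < 0.02
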