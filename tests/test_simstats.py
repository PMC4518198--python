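"""The RV transform, fold-change filter, overlap counts, Fisher test,
correlations, and the combined PM score."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phenometer import (
    AlignedPair,
    OverlapCounts,
    align,
    bicor,
    fisher_two_tailed,
    passes_filter,
    pearson_r,
    pm_score,
    score_pair,
    sir_to_rv,
)
from phenometer.simstats import FET2P_FLOOR

from conftest import make_phenotype


def exact_fisher_two_sided(a, b, c, d, rel_tol=1e-7):
    """Independent oracle: exact-rational enumeration of the two-sided
    Fisher p for table [[a, c], [d, b]] (small-p-values method, ties
    admitted within the stated relative tolerance)."""
    if a + b + c + d == 0:
        return 1.0
    r1, r2, c1 = a + c, d + b, a + d
    lo, hi = max(0, c1 - r2), min(r1, c1)
    weights = [math.comb(r1, k) * math.comb(r2, c1 - k) for k in range(lo, hi + 1)]
    w_obs = weights[a - lo]
    scale = 10**9
    num = sum(w for w in weights if w * scale <= w_obs * (scale + int(scale * rel_tol)))
    return num / sum(weights)


def _pair(x, y):
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    a = int(np.sum((x >= 0) & (y >= 0)))
    b = int(np.sum((x < 0) & (y < 0)))
    c = int(np.sum((x >= 0) & (y < 0)))
    d = int(np.sum((x < 0) & (y >= 0)))
    from phenometer import MetaboliteKey

    keys = tuple(MetaboliteKey(f"m{i}") for i in range(len(x)))
    return AlignedPair(keys, x, y, OverlapCounts(a, b, c, d))


class TestRvTransform:
    @pytest.mark.parametrize(
        "sir, rv", [(2.0, 1.0), (1.0, 0.0), (0.5, -1.0), (4.0, 3.0), (0.25, -3.0)]
    )
    def test_examples(self, sir, rv):
        assert sir_to_rv(sir) == pytest.approx(rv)

    @pytest.mark.parametrize("bad", [0.0, -1.0, math.inf, math.nan])
    def test_domain(self, bad):
        with pytest.raises(ValueError):
            sir_to_rv(bad)

    @given(st.floats(min_value=-6, max_value=6))
    @settings(max_examples=200, deadline=None)
    def test_antisymmetric_under_inversion(self, log_sir):
        s = 10.0**log_sir
        assert sir_to_rv(1.0 / s) == pytest.approx(-sir_to_rv(s), rel=1e-9, abs=1e-12)


class TestFilter:
    @pytest.mark.parametrize(
        "sir, expected",
        [(1.6, True), (1.5, True), (1.4, False), (1.0, False),
         (1 / 1.5, True), (0.68, False), (0.6, True)],
    )
    def test_boundary_semantics(self, sir, expected):
        assert passes_filter(sir, 1.5) is expected

    def test_threshold_one_keeps_everything(self):
        assert passes_filter(1.0, 1.0) and passes_filter(2.0, 1.0)

    def test_threshold_below_one_rejected(self):
        with pytest.raises(ValueError):
            passes_filter(2.0, 0.5)


class TestAlign:
    def test_intersection_filter_and_counts(self):
        q = make_phenotype("q", {"A": 2.0, "B": 0.5, "C": 1.2})
        r = make_phenotype("r", {"A": 3.0, "B": 2.0, "D": 0.5})
        pair = align(q, r, threshold=1.5)
        assert [k.canonical for k in pair.metabolites] == ["a", "b"]
        assert (pair.counts.a, pair.counts.b, pair.counts.c, pair.counts.d) == (1, 0, 0, 1)

    def test_disjoint_phenotypes_empty(self):
        q = make_phenotype("q", {"A": 2.0})
        r = make_phenotype("r", {"B": 2.0})
        assert align(q, r).n == 0

    def test_self_alignment_no_opposed_counts(self):
        p = make_phenotype("p", {"A": 2.0, "B": 0.4, "C": 3.0})
        pair = align(p, p)
        assert pair.counts.c == pair.counts.d == 0
        assert pair.counts.a + pair.counts.b == pair.n

    def test_unknowns_drop_policy(self):
        from phenometer import MetaboliteKey, Phenotype

        known = MetaboliteKey("serine", known=True)
        unknown = MetaboliteKey("x123", known=False)
        q = Phenotype("q", {known: 2.0, unknown: 2.0})
        r = Phenotype("r", {known: 2.0, unknown: 2.0})
        assert align(q, r, unknowns="keep").n == 2
        assert align(q, r, unknowns="drop").n == 1

    def test_order_is_sorted_canonical(self):
        q = make_phenotype("q", {"zeta": 2.0, "alpha": 2.0, "mid": 2.0})
        pair = align(q, q)
        assert [k.canonical for k in pair.metabolites] == ["alpha", "mid", "zeta"]


class TestFisher:
    def test_balanced_diagonal_table(self):
        # margins (5,5)/(5,5): only a=5 and a=0 are as extreme, 2/C(10,5)
        assert fisher_two_tailed(OverlapCounts(5, 5, 0, 0)) == pytest.approx(
            0.007936507936, rel=1e-7
        )

    def test_uniform_table_is_one(self):
        assert fisher_two_tailed(OverlapCounts(1, 1, 1, 1)) == 1.0

    def test_empty_table_convention(self):
        assert fisher_two_tailed(OverlapCounts(0, 0, 0, 0)) == 1.0

    def test_transposition_invariance(self):
        c = OverlapCounts(7, 2, 1, 4)
        assert fisher_two_tailed(c) == pytest.approx(
            fisher_two_tailed(c.transposed()), rel=1e-12
        )

    @given(st.tuples(*(st.integers(0, 12) for _ in range(4))))
    @settings(max_examples=300, deadline=None)
    def test_matches_rational_oracle(self, counts):
        a, b, c, d = counts
        got = fisher_two_tailed(OverlapCounts(a, b, c, d))
        want = exact_fisher_two_sided(a, b, c, d)
        assert got == pytest.approx(max(want, FET2P_FLOOR), rel=1e-7)


class TestCorrelations:
    def test_pearson_examples(self):
        p = _pair([1, 2, 3], [1, 2, 3])
        assert pearson_r(p) == pytest.approx(1.0)
        p = _pair([1, 2, 3], [-1, -2, -3])
        assert pearson_r(p) == pytest.approx(-1.0)
        p = _pair([1, 2, 3], [1, 2, 4])
        assert pearson_r(p) == pytest.approx(0.9819805061, rel=1e-9)

    @pytest.mark.parametrize("x, y", [([], []), ([1.0], [2.0]), ([1, 1, 1], [1, 2, 3])])
    def test_pearson_degenerate_is_zero(self, x, y):
        assert pearson_r(_pair(x, y)) == 0.0

    def test_bicor_perfect_self_correlation(self):
        x = [1.0, -2.0, 3.0, -0.5, 4.0]
        assert bicor(_pair(x, x)) == pytest.approx(1.0)

    def test_bicor_agrees_with_pearson_without_outliers(self):
        rng = np.random.default_rng(7)
        z = rng.multivariate_normal([0, 0], [[1, 0.8], [0.8, 1]], size=500)
        p = _pair(z[:, 0], z[:, 1])
        assert abs(bicor(p) - pearson_r(p)) < 0.1

    def test_bicor_robust_to_gross_outlier(self):
        rng = np.random.default_rng(3)
        x = rng.normal(0, 1, 20)
        y = x.copy()  # perfectly correlated 20-vectors
        clean = _pair(x, y)
        dirty = _pair(np.append(x, 50.0), np.append(y, -50.0))
        assert abs(bicor(dirty) - bicor(clean)) < 0.05
        assert pearson_r(clean) - pearson_r(dirty) > 0.2

    def test_bicor_zero_mad_falls_back_to_pearson(self, caplog):
        # >half the values identical -> MAD 0
        x = [1.0, 1.0, 1.0, 1.0, 5.0]
        y = [1.0, 2.0, 3.0, 4.0, 5.0]
        with caplog.at_level("WARNING"):
            got = bicor(_pair(x, y))
        assert got == pytest.approx(pearson_r(_pair(x, y)))
        assert any("MAD" in r.message for r in caplog.records)

    def test_bicor_matches_independent_implementation(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(11)
        for _ in range(5):
            x = rng.normal(0, 1, 40)
            y = 0.6 * x + rng.normal(0, 1, 40)
            ours = bicor(_pair(x, y))
            theirs = float(pingouin.corr(x, y, method="bicor")["r"].iloc[0])
            assert ours == pytest.approx(theirs, abs=1e-10)


class TestPmScore:
    def test_benchmark_constant(self):
        sp = pm_score(math.sqrt(0.8), 0.05)
        assert sp.pm_score == pytest.approx(1.040824, abs=5e-7)

    def test_strong_match_reference_value(self):
        sp = pm_score(0.73, 8.6e-13)
        assert sp.pm_score == pytest.approx(6.4, abs=0.15)

    def test_fet_one_gives_zero(self):
        assert pm_score(0.9, 1.0).pm_score == 0.0
        assert pm_score(-0.9, 1.0).pm_score == 0.0

    def test_sign_follows_correlation(self):
        assert pm_score(-0.5, 0.01).pm_score < 0
        assert pm_score(0.5, 0.01).pm_score > 0
        assert pm_score(0.0, 0.01).pm_score == 0.0

    def test_magnitude_equals_ranking_metric(self):
        sp = pm_score(-0.7, 1e-5)
        assert abs(sp.pm_score) == sp.ranking_metric

    def test_monotone_in_fet2p(self):
        ps = [pm_score(0.6, p).pm_score for p in (1e-10, 1e-5, 1e-2, 0.5, 1.0)]
        assert ps == sorted(ps, reverse=True)

    def test_floor_prevents_overflow(self):
        sp = pm_score(1.0, FET2P_FLOOR)
        assert math.isfinite(sp.pm_score)
        assert sp.pm_score == pytest.approx(300.0)

    @pytest.mark.parametrize("bad_r, bad_p", [(1.5, 0.05), (0.5, 0.0), (0.5, 1.5)])
    def test_domain(self, bad_r, bad_p):
        with pytest.raises(ValueError):
            pm_score(bad_r, bad_p)


class TestSymmetry:
    def _random_phenotype(self, rng, pid, n=30):
        sirs = np.exp(rng.normal(0, 0.8, n))
        names = rng.choice(50, size=n, replace=False)
        return make_phenotype(pid, {f"m{i:02d}": s for i, s in zip(names, sirs)})

    def test_swapping_query_and_reference(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            p = self._random_phenotype(rng, "p")
            q = self._random_phenotype(rng, "q")
            pair_pq, sp_pq = score_pair(p, q)
            pair_qp, sp_qp = score_pair(q, p)
            assert pair_pq.n == pair_qp.n
            assert pair_pq.counts.a == pair_qp.counts.a
            assert pair_pq.counts.b == pair_qp.counts.b
            assert pair_pq.counts.c == pair_qp.counts.d
            assert sp_pq.FET2p == pytest.approx(sp_qp.FET2p, rel=1e-10)
            assert abs(sp_pq.pm_score - sp_qp.pm_score) < 1e-10
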