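import numpy as np
import pytest

from mfselector import (
    ExpressionMatrix,
    build_null_pool,
    canonicalize_design,
    p_value,
    p_values,
    q_values,
    rank_and_filter,
    scan_gene,
    score_matrix,
    svde,
    svde_matrix,
)
from mfselector.core import MonotoneScore
from mfselector.significance import (
    DegenerateGeneError,
    NullPool,
    SignificanceResult,
    significance_table,
)


def _design_5x2():
    labels = [f"S{i}" for i in (1, 1, 2, 2, 3, 3, 4, 4, 5, 5)]
    samples = [f"u{i}" for i in range(10)]
    return canonicalize_design(
        dict(zip(samples, labels)), tuple(f"S{i}" for i in range(1, 6)), samples
    )


def _matrix(design, values):
    values = np.atleast_2d(values)
    return ExpressionMatrix(
        [f"g{i}" for i in range(values.shape[0])], design.canonical_order, values
    )


def _pool(asc, B):
    asc = np.asarray(asc)
    return NullPool(
        gene_ids=tuple(f"g{i}" for i in range(asc.shape[0])),
        B=B,
        seed=None,
        ascending=asc,
        descending=asc,
    )


class TestBuildNullPool:
    def test_pool_dimensions(self):
        design = _design_5x2()
        matrix = _matrix(design, np.random.default_rng(0).normal(size=(3, 10)))
        pool = build_null_pool(matrix, design, B=2, seed=0)
        assert pool.ascending.shape == (3, 2)
        assert pool.descending.shape == (3, 2)
        assert pool.pooled("ascending").size == 6

    def test_deterministic_under_seed(self):
        design = _design_5x2()
        matrix = _matrix(design, np.random.default_rng(1).normal(size=(4, 10)))
        a = build_null_pool(matrix, design, B=5, seed=99)
        b = build_null_pool(matrix, design, B=5, seed=99)
        assert np.array_equal(a.ascending, b.ascending)
        assert np.array_equal(a.descending, b.descending)

    def test_null_of_ordered_gene_mostly_positive(self):
        design = _design_5x2()
        matrix = _matrix(design, np.arange(10.0))
        pool = build_null_pool(matrix, design, B=200, seed=3)
        nulls = pool.pooled("ascending")
        assert nulls.min() >= 0
        assert np.mean(nulls > 0) > 0.9

    def test_b_below_one_rejected(self):
        design = _design_5x2()
        with pytest.raises(ValueError, match="B"):
            build_null_pool(_matrix(design, np.zeros((1, 10)) + np.arange(10)), design, B=0)


class TestPValue:
    def test_hand_enumerated_pool(self):
        pool = _pool([[1, 3], [4, 6]], B=2)
        assert p_value(3, pool, "ascending") == pytest.approx(2 / 4)

    def test_observed_below_everything(self):
        pool = _pool([[1, 3], [4, 6]], B=2)
        with pytest.warns(UserWarning, match="resolution"):
            assert p_value(0, pool, "ascending") == 0.0

    def test_observed_at_or_above_everything(self):
        pool = _pool([[1, 3], [4, 6]], B=2)
        assert p_value(6, pool, "ascending") == 1.0

    def test_vectorised_matches_scalar(self):
        pool = _pool([[0, 2, 5], [1, 1, 7]], B=3)
        obs = [0, 1, 2, 8]
        vec = p_values(obs, pool, "ascending")
        for o, p in zip(obs, vec):
            if p > 0:
                assert p == pytest.approx(p_value(o, pool, "ascending"))

    def test_monotone_in_observed(self):
        pool = _pool(np.random.default_rng(0).integers(0, 10, size=(5, 20)), B=20)
        p = p_values(np.arange(11), pool, "ascending")
        assert np.all(np.diff(p) >= 0)


class TestQValue:
    def test_hand_enumerated(self):
        # pooled nulls {1,4,2,5,0,3}; observed (2, 1, 5)
        pool = _pool([[1, 4], [2, 5], [0, 3]], B=2)
        q = q_values([2, 1, 5], pool, "ascending")
        assert q == pytest.approx([3 / 4, 1.0, 1.0])

    def test_unique_best_gene(self):
        # observed 0 is uniquely best; 1 pooled null <= 0 -> q = 1/B
        pool = _pool([[0, 4], [3, 5], [6, 7]], B=2)
        q = q_values([0, 3, 6], pool, "ascending")
        assert q[0] == pytest.approx(1 / 2)

    def test_all_observed_equal_gives_q_equal_p(self):
        pool = _pool([[1, 4], [2, 5], [0, 3]], B=2)
        q = q_values([3, 3, 3], pool, "ascending")
        p = p_values([3, 3, 3], pool, "ascending")
        assert q == pytest.approx(p)

    def test_capped_at_one(self):
        pool = _pool([[0, 0], [0, 0]], B=2)
        assert np.all(q_values([5, 9], pool, "ascending") <= 1.0)

    def test_wrong_length_rejected(self):
        pool = _pool([[1, 2], [3, 4]], B=2)
        with pytest.raises(ValueError, match="observed"):
            q_values([1], pool, "ascending")


class TestSVDE:
    def test_wide_gaps_are_stable(self):
        design = _design_5x2()
        values = np.repeat(np.arange(5.0) * 50.0, 2) + np.tile([0.0, 0.1], 5)
        res = svde(values, design, "ascending", M=100, seed=0)
        assert res.de_org == 0
        assert res.svde == 0.0

    def test_single_matching_replicate(self):
        design = _design_5x2()
        values = np.repeat(np.arange(5.0) * 50.0, 2) + np.tile([0.0, 0.1], 5)
        res = svde(values, design, "ascending", M=1, seed=1)
        assert res.perturbed == (res.de_org,)
        assert res.svde == 0.0

    def test_narrow_gaps_less_stable_than_wide(self):
        design = _design_5x2()
        base = np.tile([-0.02, 0.02], 5)
        wide = np.repeat([0.0, 2.0, 4.0, 6.0, 8.0], 2) + base
        narrow = np.repeat([0.0, 0.1, 0.2, 0.3, 8.0], 2) + base
        s_wide = svde(wide, design, "ascending", M=100, seed=5)
        s_narrow = svde(narrow, design, "ascending", M=100, seed=5)
        assert s_wide.de_org == s_narrow.de_org == 0
        assert s_wide.svde < s_narrow.svde

    def test_degenerate_gene_refused(self):
        design = _design_5x2()
        with pytest.raises(DegenerateGeneError):
            svde(np.ones(10), design, "ascending", M=10, seed=0)

    def test_shift_invariance_exact(self):
        design = _design_5x2()
        rng = np.random.default_rng(8)
        values = np.sort(rng.normal(size=10))
        a = svde(values, design, "ascending", M=50, seed=4)
        b = svde(values + 123.25, design, "ascending", M=50, seed=4)
        assert a.svde == b.svde
        assert a.perturbed == b.perturbed

    def test_positive_scaling_invariance_exact(self):
        design = _design_5x2()
        rng = np.random.default_rng(9)
        values = np.sort(rng.normal(size=10))
        a = svde(values, design, "ascending", M=50, seed=4)
        b = svde(values * 4.0, design, "ascending", M=50, seed=4)
        assert a.perturbed == b.perturbed

    def test_matrix_helper_independent_of_selection(self):
        design = _design_5x2()
        rng = np.random.default_rng(10)
        matrix = _matrix(design, rng.normal(size=(4, 10)))
        full = svde_matrix(matrix, design, "ascending", M=20, seed=1)
        sub = svde_matrix(matrix, design, "ascending", M=20, seed=1, gene_ids=["g2"])
        assert sub["g2"].svde == full["g2"].svde
        assert sub["g2"].perturbed == full["g2"].perturbed


def _score(gene, de, distinct=4, degenerate=False, levels=None):
    levels = levels if levels is not None else (de, 0, 0, 0)
    return MonotoneScore(
        gene_id=gene,
        direction="ascending",
        de_total=de,
        level_errors=tuple(levels),
        line_samples=("a", "b", "c", "d"),
        distinct_lines=distinct,
        degenerate=degenerate,
    )


class TestRankAndFilter:
    def test_svde_breaks_de_ties(self):
        scores = [_score("g1", 0), _score("g2", 0)]
        records = rank_and_filter(
            scores, None, {"g1": 1.5, "g2": 0.2}, de_max=None, p_max=None,
            require_distinct=False,
        )
        assert [r["gene_id"] for r in records] == ["g2", "g1"]
        assert [r["rank"] for r in records] == [1, 2]

    def test_distinct_lines_filter(self):
        scores = [_score("g1", 3, distinct=3), _score("g2", 3, distinct=4)]
        records = rank_and_filter(
            scores, None, {}, de_max=None, p_max=None,
            require_distinct=True, n_stages=5,
        )
        assert [r["gene_id"] for r in records] == ["g2"]

    def test_de_and_p_filters(self):
        scores = [_score("g1", 2), _score("g2", 9)]
        sig = {
            "g1": SignificanceResult("g1", "ascending", 2, 1e-7, 1e-6),
            "g2": SignificanceResult("g2", "ascending", 9, 0.2, 0.4),
        }
        records = rank_and_filter(scores, sig, {}, de_max=7, p_max=1e-5,
                                  require_distinct=False)
        assert [r["gene_id"] for r in records] == ["g1"]
        assert records[0]["p"] == 1e-7 and records[0]["q"] == 1e-6

    def test_degenerate_removed(self):
        scores = [_score("flat", 0, degenerate=True), _score("g2", 0)]
        records = rank_and_filter(scores, None, {}, de_max=None, p_max=None,
                                  require_distinct=False)
        assert [r["gene_id"] for r in records] == ["g2"]

    def test_missing_svde_reported_incomplete(self):
        scores = [_score("g1", 0), _score("g2", 0)]
        records = rank_and_filter(scores, None, {"g2": 0.5}, de_max=None,
                                  p_max=None, require_distinct=False)
        assert [r["gene_id"] for r in records] == ["g2", "g1"]
        assert records[1]["svde"] is None


class TestSignificanceTable:
    def test_end_to_end_consistency(self):
        design = _design_5x2()
        rng = np.random.default_rng(12)
        matrix = _matrix(design, rng.normal(size=(5, 10)))
        scores = score_matrix(matrix, design, ["ascending"])
        pool = build_null_pool(matrix, design, B=30, seed=2)
        table = significance_table(scores, pool, "ascending")
        assert [t.gene_id for t in table] == list(matrix.gene_ids)
        for t, s in zip(table, scores):
            assert t.observed == s.de_total
            assert 0.0 <= t.p <= 1.0 and 0.0 <= t.q <= 1.0
            assert t.q >= t.p * 0  # capped, never negative
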