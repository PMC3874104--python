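"""Mann-Whitney set test, BH correction, z-scores, GSEA and GBA."""

from itertools import combinations

import numpy as np
import pytest
from scipy import stats

from lincscreen.enrichment import (
    bh_correct,
    gba,
    gsea,
    mannwhitney_set_test,
    rank_by_statistic,
    set_zscore,
)
from lincscreen.io_formats import GeneSet, GeneSetCollection
from lincscreen.synthetic import PlantedModule, gen_expression_compendium

from conftest import make_diff_record


def exhaustive_two_sided_p(values, membership):
    """Permutation oracle: rank-sum U over every label split of the same size."""
    values = np.asarray(values, dtype=float)
    membership = np.asarray(membership, dtype=bool)
    n, k = len(values), int(membership.sum())
    ranks = stats.rankdata(values)
    base = k * (k + 1) / 2.0
    u_obs = ranks[membership].sum() - base
    us = [ranks[list(c)].sum() - base for c in combinations(range(n), k)]
    us = np.asarray(us)
    lo = np.mean(us <= u_obs + 1e-12)
    hi = np.mean(us >= u_obs - 1e-12)
    return min(1.0, 2.0 * min(lo, hi))


class TestRankByStatistic:
    def test_tie_break_by_gene_id(self):
        table = [
            make_diff_record("A", stat=2.0),
            make_diff_record("B", stat=-1.0),
            make_diff_record("C", stat=2.0),
        ]
        ranking = rank_by_statistic(table)
        assert ranking.gene_ids == ["A", "C", "B"]

    def test_notest_rows_dropped(self):
        table = [
            make_diff_record("A", stat=2.0),
            make_diff_record("B", stat=5.0, status="NOTEST"),
        ]
        assert rank_by_statistic(table).gene_ids == ["A"]

    def test_empty_table_errors(self):
        with pytest.raises(ValueError):
            rank_by_statistic([])

    def test_matches_sort_oracle(self, rng):
        stats_ = rng.normal(size=100)
        table = [make_diff_record(f"g{i:03d}", stat=s) for i, s in enumerate(stats_)]
        ranking = rank_by_statistic(table)
        oracle = sorted(range(100), key=lambda i: (-stats_[i], f"g{i:03d}"))
        assert ranking.gene_ids == [f"g{i:03d}" for i in oracle]


class TestMannWhitney:
    def test_top_pair_exact_p(self):
        u, p = mannwhitney_set_test([1, 2, 3, 4], [False, False, True, True])
        assert u == 4.0
        assert p == pytest.approx(1 / 3)

    def test_degenerate_identical_values(self):
        u, p = mannwhitney_set_test([5, 5, 5, 5], [True, True, False, False])
        assert p == 1.0

    def test_tail_set_more_significant_than_interior(self, rng):
        values = np.arange(100, dtype=float)
        tail = np.zeros(100, bool)
        tail[-10:] = True
        interior = np.zeros(100, bool)
        interior[45:55] = True
        _, p_tail = mannwhitney_set_test(values, tail)
        _, p_interior = mannwhitney_set_test(values, interior)
        assert p_tail < p_interior

    def test_exact_matches_exhaustive_permutation_small_n(self, rng):
        for n in range(4, 9):
            for _ in range(5):
                values = rng.integers(0, 6, size=n).astype(float)  # ties likely
                for k in range(1, n):
                    membership = np.zeros(n, bool)
                    membership[rng.choice(n, size=k, replace=False)] = True
                    if np.all(values == values[0]):
                        continue
                    _, p = mannwhitney_set_test(values, membership)
                    assert p == pytest.approx(
                        exhaustive_two_sided_p(values, membership), abs=1e-12
                    )

    def test_exact_and_normal_modes_agree_at_moderate_n(self, rng):
        """|p_exact - p_asymptotic| <= 0.02 once n >= 200."""
        values = rng.normal(size=240)
        membership = np.zeros(240, bool)
        membership[rng.choice(240, size=40, replace=False)] = True  # 40*200 <= 10000
        _, p_exact = mannwhitney_set_test(values, membership)
        x, y = values[membership], values[~membership]
        p_norm = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic").pvalue
        assert abs(p_exact - p_norm) <= 0.02

    def test_null_calibration_uniform(self, rng):
        """p uniform when the set is a random half of iid values.

        Run at n=400 where the p distribution is effectively continuous; at
        small n the exact two-sided p is discrete and a KS test against the
        continuous uniform rejects for that reason alone.
        """
        pvals = []
        for _ in range(2000):
            values = rng.normal(size=400)
            membership = np.zeros(400, bool)
            membership[rng.choice(400, size=200, replace=False)] = True
            pvals.append(mannwhitney_set_test(values, membership)[1])
        assert stats.kstest(pvals, "uniform").pvalue > 0.01


class TestBhCorrect:
    def hand_step_up(self, p):
        """Literal q_(i) = min_{j>=i} m*p_(j)/j, returned in input order."""
        p = np.asarray(p, dtype=float)
        m = len(p)
        order = np.argsort(p, kind="mergesort")
        q_sorted = np.empty(m)
        running = np.inf
        for rank in range(m - 1, -1, -1):
            running = min(running, m * p[order[rank]] / (rank + 1))
            q_sorted[rank] = running
        q = np.empty(m)
        q[order] = np.minimum(q_sorted, 1.0)
        return q

    def test_step_up_example(self):
        assert bh_correct([0.01, 0.02, 0.03, 0.04]) == pytest.approx(
            [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_and_constant_vectors(self):
        assert bh_correct([0.3]) == pytest.approx([0.3])
        assert bh_correct([0.2, 0.2, 0.2]) == pytest.approx([0.2, 0.2, 0.2])

    def test_matches_hand_rule_on_random_vectors(self, rng):
        for _ in range(100):
            p = rng.uniform(size=int(rng.integers(1, 40)))
            assert bh_correct(p) == pytest.approx(self.hand_step_up(p))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_correct([0.5, 1.5])

    def test_monotone_and_never_below_p(self, rng):
        p = rng.uniform(size=50)
        q = bh_correct(p)
        assert (q >= p - 1e-12).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()


class TestSetZscore:
    def test_hand_arithmetic(self):
        z = set_zscore([0, 0, 0, 0, 10, 10], [False] * 4 + [True] * 2)
        assert z == pytest.approx(2.0)

    def test_zero_when_set_mean_equals_global_mean(self):
        assert set_zscore([1, 2, 3], [False, True, False]) == pytest.approx(0.0)

    def test_affine_invariance(self, rng):
        v = rng.normal(size=40)
        m = np.zeros(40, bool)
        m[:8] = True
        assert set_zscore(3.5 * v + 7.0, m) == pytest.approx(set_zscore(v, m))

    def test_zero_background_sd_is_undefined(self):
        assert set_zscore([2, 2, 2], [True, False, False]) is None


class TestGsea:
    def build_table(self, rng, n=400):
        stats_ = np.sort(rng.normal(size=n))[::-1]
        return [make_diff_record(f"g{i:03d}", stat=s) for i, s in enumerate(stats_)]

    def test_planted_top_decile_set_is_significant(self, rng):
        table = self.build_table(rng)
        top = tuple(f"g{i:03d}" for i in range(40))
        coll = GeneSetCollection()
        coll.add(GeneSet("TOP", top))
        for s in range(5):
            coll.add(
                GeneSet(f"R{s}", tuple(f"g{i:03d}" for i in rng.choice(400, 40, replace=False)))
            )
        results = {r.set_name: r for r in gsea(table, coll)}
        assert results["TOP"].significant
        assert results["TOP"].z > 0

    def test_duplicate_set_under_two_names_identical(self, rng):
        table = self.build_table(rng)
        members = tuple(f"g{i:03d}" for i in rng.choice(400, 30, replace=False))
        coll = GeneSetCollection()
        coll.add(GeneSet("X", members))
        coll.add(GeneSet("Y", members))
        res = {r.set_name: r for r in gsea(table, coll)}
        assert (res["X"].U, res["X"].p, res["X"].z) == (res["Y"].U, res["Y"].p, res["Y"].z)

    def test_invariant_to_collection_and_row_order(self, rng):
        table = self.build_table(rng, n=100)
        sets = [
            GeneSet(f"S{j}", tuple(f"g{i:03d}" for i in rng.choice(100, 15, replace=False)))
            for j in range(4)
        ]
        coll_a, coll_b = GeneSetCollection(), GeneSetCollection()
        for s in sets:
            coll_a.add(s)
        for s in reversed(sets):
            coll_b.add(s)
        shuffled = list(table)
        rng.shuffle(shuffled)
        ra = {r.set_name: (r.U, r.p, r.q, r.z) for r in gsea(table, coll_a)}
        rb = {r.set_name: (r.U, r.p, r.q, r.z) for r in gsea(shuffled, coll_b)}
        assert ra == rb

    def test_undersized_sets_skipped_with_reason(self, rng):
        table = self.build_table(rng, n=50)
        coll = GeneSetCollection()
        coll.add(GeneSet("TINY", ("g001", "g002")))
        coll.add(GeneSet("OK", tuple(f"g{i:03d}" for i in range(10))))
        res = {r.set_name: r for r in gsea(table, coll)}
        assert res["TINY"].skipped_reason is not None and res["TINY"].p is None
        assert res["OK"].p is not None

    def test_no_overlapping_set_errors(self, rng):
        table = self.build_table(rng, n=20)
        coll = GeneSetCollection()
        coll.add(GeneSet("ALIEN", ("x1", "x2", "x3", "x4", "x5")))
        with pytest.raises(ValueError):
            gsea(table, coll)


class TestGba:
    def planted(self, seed=7):
        members = tuple(f"g{i:05d}" for i in range(25))
        pm = PlantedModule("linc_x", members, r=0.9)
        expr = gen_expression_compendium(300, 200, planted=pm, noise_sd=0.0, seed=seed)
        coll = GeneSetCollection()
        coll.add(GeneSet("PLANTED", members))
        rng = np.random.default_rng(seed)
        for s in range(5):
            coll.add(
                GeneSet(
                    f"R{s}",
                    tuple(f"g{i:05d}" for i in rng.choice(300, 25, replace=False)),
                )
            )
        return expr, coll

    def test_planted_module_recovered(self):
        expr, coll = self.planted()
        profile, results = gba(expr, "linc_x", coll)
        tested = [r for r in results if r.p is not None]
        best = min(tested, key=lambda r: r.p)
        assert best.set_name == "PLANTED"
        assert best.p < 1e-6 and best.significant

    def test_independent_focal_has_no_significant_set(self):
        hits = 0
        for seed in range(5):
            expr = gen_expression_compendium(300, 100, seed=seed)
            # make one extra independent row the focal lincRNA
            import pandas as pd

            focal = np.abs(np.random.default_rng(seed).normal(8, 2, size=100))
            values = pd.concat(
                [expr.values, pd.DataFrame([focal], index=["linc_x"],
                                           columns=expr.values.columns)]
            )
            from lincscreen.io_formats import ExpressionMatrix

            matrix = ExpressionMatrix(values)
            coll = GeneSetCollection()
            rng = np.random.default_rng(seed)
            for s in range(6):
                coll.add(
                    GeneSet(f"R{s}", tuple(f"g{i:05d}" for i in rng.choice(300, 25, replace=False)))
                )
            _, results = gba(matrix, "linc_x", coll)
            hits += any(r.significant for r in results)
        assert hits == 0

    def test_constant_focal_profile_errors(self):
        import pandas as pd

        from lincscreen.io_formats import ExpressionMatrix

        values = pd.DataFrame(
            {"s1": [1.0, 2.0], "s2": [1.0, 3.0], "s3": [1.0, 4.0]},
            index=["linc_x", "g1"],
        )
        coll = GeneSetCollection()
        coll.add(GeneSet("S", ("g1",)))
        with pytest.raises(ValueError, match="zero variance"):
            gba(ExpressionMatrix(values), "linc_x", coll, min_set_size=1)

    def test_too_few_samples_errors(self):
        import pandas as pd

        from lincscreen.io_formats import ExpressionMatrix

        values = pd.DataFrame({"s1": [1.0, 2.0], "s2": [2.0, 3.0]}, index=["a", "b"])
        coll = GeneSetCollection()
        coll.add(GeneSet("S", ("b",)))
        with pytest.raises(ValueError, match="samples"):
            gba(ExpressionMatrix(values), "a", coll, min_set_size=1)
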