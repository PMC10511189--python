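import numpy as np
import pandas as pd
import pytest
from scipy import stats

from optionvalue import (
    CaptureSummary,
    SelectionResult,
    compare_distinctiveness,
    count_captured,
    order_overrepresentation,
    ses_between,
    summarize_capture,
    top_set_overlap,
)
from optionvalue.errors import DegenerateSetError, VocabularyError
from optionvalue.evaluation import dunn_posthoc, pearson_correlation, welch_test
from optionvalue.treeio import SpeciesTable

from test_treeio import make_table_frame


def selection(taxa, strategy="greedy_pd", fraction=0.5):
    return SelectionResult(strategy=strategy, fraction=fraction, taxa=frozenset(taxa))


def species_table(n=10, orders=None, food=()):
    species = [f"x{i}" for i in range(n)]
    orders = orders or ["X" if i < 2 else "Y" for i in range(n)]
    return SpeciesTable.from_frame(
        pd.DataFrame(
            {
                "species": species,
                "order": orders,
                "rl_category": ["LC"] * n,
                "use_food": [int(s in food) for s in species],
                "use_materials": [0] * n,
                "use_medicine": [0] * n,
                "use_pets": [0] * n,
                "use_other": [0] * n,
                "fdist": np.linspace(0.1, 1, n),
            }
        )
    )


class TestCountCaptured:
    def test_simple_intersection(self):
        table = SpeciesTable.from_frame(make_table_frame())
        assert count_captured(selection({"A", "B"}), table, "food") == 1

    def test_all_is_union_of_main_categories(self):
        table = SpeciesTable.from_frame(make_table_frame())
        # A: food+pets, B: pets, C: materials, D: food
        assert count_captured(selection({"A", "C"}), table, "all") == 2

    def test_disjoint_sets(self):
        table = SpeciesTable.from_frame(make_table_frame())
        assert count_captured(selection({"B"}), table, "food") == 0


class TestSESBetween:
    def summary(self, counts, strategy="greedy_pd"):
        return CaptureSummary(
            strategy=strategy, fraction=0.5, category="food", counts=tuple(counts)
        )

    def test_arithmetic_and_tier(self):
        obs = self.summary([10] * 5)
        null = self.summary([8 - 1, 8, 8 + 1, 8, 8], strategy="random_uniform")
        rep = ses_between(obs, null)
        assert rep.ses == pytest.approx(
            2.0 / np.std([7, 8, 9, 8, 8], ddof=1), rel=1e-12
        )
        rep2 = ses_between(
            self.summary([10] * 4),
            CaptureSummary("random_uniform", 0.5, "food", (7, 9, 8, 8)),
        )
        assert rep2.ses > 0

    def test_sign_convention(self):
        obs = self.summary([8] * 3)
        null = self.summary([9, 10, 11], strategy="random_uniform")
        assert ses_between(obs, null).ses < 0

    def test_identical_distributions_ns(self):
        counts = [5, 6, 7, 5, 6, 7]
        rep = ses_between(self.summary(counts), self.summary(counts, "random_uniform"))
        assert abs(rep.ses) < 1e-12 and rep.tier == "ns"

    def test_degenerate_null_rejected(self):
        with pytest.raises(DegenerateSetError):
            ses_between(self.summary([5, 6]), self.summary([4, 4, 4], "r"))

    def test_ci_brackets_mean(self):
        s = self.summary([1, 2, 3, 4, 10])
        assert s.ci95_low <= s.mean <= s.ci95_high


class TestSummarizeCapture:
    def test_counts_per_replicate(self):
        table = SpeciesTable.from_frame(make_table_frame())
        sels = [selection({"A", "B"}), selection({"A", "D"}), selection({"B", "C"})]
        summary = summarize_capture(sels, table, "food")
        assert summary.counts == (1, 2, 0)

    def test_mixed_strategies_rejected(self):
        table = SpeciesTable.from_frame(make_table_frame())
        with pytest.raises(ValueError):
            summarize_capture(
                [selection({"A"}), selection({"B"}, strategy="random_uniform")],
                table,
                "food",
            )


class TestOrderOverrepresentation:
    def test_fully_concentrated_category_flagged_over(self):
        # order X = {x0, x1} and both flagged: P(null count = 2) = 1/45 < 0.025
        table = species_table(food=("x0", "x1"))
        report = order_overrepresentation(table, "food", n_perm=999, seed=1)
        assert report.verdict["X"] == "over"

    def test_single_order_universe_is_ns(self):
        table = species_table(orders=["X"] * 10, food=("x0", "x1", "x2"))
        report = order_overrepresentation(table, "food", n_perm=199, seed=2)
        assert (report.verdict == "ns").all()

    def test_empty_category_rejected(self):
        table = species_table(food=())
        with pytest.raises(VocabularyError):
            order_overrepresentation(table, "food", n_perm=9, seed=0)

    def test_null_size_calibration(self):
        # a random category should flag a given order 'over' at ~2.5% (plus a
        # little slack from count discreteness at the percentile cutoff)
        rng = np.random.default_rng(77)
        n = 200
        species = [f"x{i}" for i in range(n)]
        orders = ["X" if i < 60 else "Y" for i in range(n)]
        over = 0
        repeats = 100
        for r in range(repeats):
            food = tuple(rng.choice(species, size=60, replace=False))
            table = species_table(n=n, orders=orders, food=food)
            rep = order_overrepresentation(table, "food", n_perm=199, seed=(78, r))
            over += rep.verdict["X"] == "over"
        assert over / repeats <= 0.10


class TestTopSetOverlap:
    def test_identical_scores_full_overlap(self):
        scores = {f"s{i}": float(i) for i in range(100)}
        rep = top_set_overlap(scores, scores, scores.keys(), 0.05)
        assert rep.k == 5 and len(rep.both) == 5
        assert not rep.a_only and not rep.b_only

    def test_antitone_scores_no_overlap(self):
        scores = {f"s{i:03d}": float(i) for i in range(100)}
        neg = {s: -v for s, v in scores.items()}
        rep = top_set_overlap(scores, neg, scores.keys(), 0.05)
        assert len(rep.both) == 0
        assert len(rep.a_only) == rep.k == len(rep.b_only)

    def test_partition_identity(self):
        rng = np.random.default_rng(9)
        universe = [f"s{i}" for i in range(50)]
        a = dict(zip(universe, rng.random(50)))
        b = dict(zip(universe, rng.random(50)))
        rep = top_set_overlap(a, b, universe, 0.2)
        assert len(rep.a_only) + len(rep.both) == rep.k
        assert len(rep.b_only) + len(rep.both) == rep.k

    def test_independent_scores_hypergeometric_mean(self):
        # E[|top-k(a) ∩ top-k(b)|] = k^2 / N for independent rankings
        rng = np.random.default_rng(10)
        universe = [f"s{i}" for i in range(200)]
        k_over_n = 10 * 10 / 200
        means = []
        for r in range(300):
            a = dict(zip(universe, rng.random(200)))
            b = dict(zip(universe, rng.random(200)))
            means.append(top_set_overlap(a, b, universe, 0.05).n_both)
        assert np.mean(means) == pytest.approx(k_over_n, abs=0.15)


class TestDistinctivenessStats:
    def test_welch_identical_samples(self):
        t, p = welch_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_pearson_perfect(self):
        x = np.linspace(0, 1, 30)
        r, df, p = pearson_correlation(x, 2 * x + 1)
        assert r == pytest.approx(1.0) and df == 28

    def test_dunn_zero_for_identical_groups(self):
        values = list(range(10)) * 2
        groups = ["a"] * 10 + ["b"] * 10
        frame = dunn_posthoc(values, groups)
        assert abs(frame["z"].iloc[0]) < 1e-9
        assert frame["p_adj"].iloc[0] == pytest.approx(1.0)

    def test_dunn_sign_follows_mean_ranks(self):
        rng = np.random.default_rng(12)
        lo = rng.normal(0, 1, 30)
        hi = rng.normal(3, 1, 30)
        frame = dunn_posthoc(
            np.concatenate([lo, hi]), ["lo"] * 30 + ["hi"] * 30
        )
        row = frame.iloc[0]
        # group_a = 'hi' (lexicographic) has the higher mean rank
        assert row["group_a"] == "hi" and row["z"] > 0
        assert row["p_adj"] < 0.01

    def test_kruskal_type_one_error_calibrated(self):
        rng = np.random.default_rng(13)
        rejections = 0
        sims = 400
        for _ in range(sims):
            h, p = stats.kruskal(*[rng.normal(size=20) for _ in range(3)])
            rejections += p < 0.05
        assert 0.02 <= rejections / sims <= 0.09

    def test_compare_distinctiveness_report(self, small_table, small_ensemble):
        from optionvalue import ed_table

        ed = ed_table(small_ensemble).median(axis=1)
        flagged = small_table.flagged("pets")
        groups = pd.Series(
            ["pets" if s in flagged else "rest" for s in ed.index], index=ed.index
        )
        rep = compare_distinctiveness(
            ed, groups, two_group_pairs=[("pets", "rest")],
            correlate_with=small_table.fdist,
        )
        assert rep.kruskal_p >= 0 and len(rep.dunn) == 1
        assert rep.welch is not None and len(rep.welch) == 1
        r, df, p = rep.pearson
        assert -1 <= r <= 1 and df == len(ed) - 2

    def test_too_small_groups_rejected(self):
        with pytest.raises(ValueError):
            compare_distinctiveness(
                pd.Series([1.0, 2.0], index=["a", "b"]),
                pd.Series(["g1", "g2"], index=["a", "b"]),
            )
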