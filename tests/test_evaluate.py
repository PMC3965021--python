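"""Precision-recall curves, LOO-GBA AUC, tail-set extraction, Wilcoxon."""

import itertools

import numpy as np
import pytest
from scipy import stats

from funclink import (DataNetwork, EvaluationError, GeneSetCollection,
                      GoldStandard, TailSetConfig, ValidationError, auc_batch,
                      extreme_tail_sets, loo_gba_scores, pr_area, pr_curve,
                      wilcoxon_signed_rank)


def net_of(edges: dict) -> DataNetwork:
    return DataNetwork(tag="t", edges=edges)


class TestPRCurve:
    def test_hand_counted_precisions(self):
        # ranked labels [+, -, +, +] with bin size 2
        edges = {("A", "B"): 4.0, ("C", "D"): 3.0, ("E", "F"): 2.0,
                 ("G", "H"): 1.0}
        gold = GoldStandard(
            positives={("A", "B"), ("E", "F"), ("G", "H")},
            negatives={("C", "D")})
        curve = pr_curve(net_of(edges), gold, bin_size=2, genome_size=8)
        assert [(n, p) for n, p, _ in curve.points] == [(2, 0.5), (4, 0.75)]

    def test_terminal_recall_is_gene_coverage(self):
        edges = {("A", "B"): 4.0, ("C", "D"): 3.0, ("A", "C"): 2.0,
                 ("E", "F"): 1.0}
        gold = GoldStandard(positives={("A", "B")}, negatives={("C", "D")})
        curve = pr_curve(net_of(edges), gold, bin_size=1, genome_size=6)
        assert curve.points[-1][2] == pytest.approx(1.0)

    def test_all_positive_edges_precision_one(self):
        edges = {("A", "B"): 2.0, ("C", "D"): 1.0}
        gold = GoldStandard(positives=set(edges), negatives={("X", "Y")})
        curve = pr_curve(net_of(edges), gold, bin_size=1, genome_size=10)
        assert all(p == 1.0 for _, p, _ in curve.points)

    def test_recall_non_decreasing(self):
        rng = np.random.default_rng(0)
        genes = [f"G{i}" for i in range(20)]
        pairs = list(itertools.combinations(genes, 2))
        edges = {p: float(s) for p, s in zip(pairs, rng.random(len(pairs)))}
        labels = rng.random(len(pairs)) < 0.3
        gold = GoldStandard(
            positives={p for p, lab in zip(pairs, labels) if lab},
            negatives={p for p, lab in zip(pairs, labels) if not lab})
        curve = pr_curve(net_of(edges), gold, bin_size=10, genome_size=25)
        recalls = [r for _, _, r in curve.points]
        assert recalls == sorted(recalls)

    def test_unevaluable_edges_advance_recall_only(self):
        edges = {("A", "B"): 3.0, ("X", "Y"): 2.0, ("C", "D"): 1.0}
        gold = GoldStandard(positives={("A", "B"), ("C", "D")},
                            negatives={("A", "C")})
        curve = pr_curve(net_of(edges), gold, bin_size=1, genome_size=6)
        # precision stays 1 throughout; recall grows past the unlabeled edge
        assert [p for _, p, _ in curve.points] == [1.0, 1.0, 1.0]
        assert [r for _, _, r in curve.points] == \
            pytest.approx([2 / 6, 4 / 6, 1.0])

    def test_no_evaluable_edges_rejected(self):
        gold = GoldStandard(positives={("X", "Y")}, negatives={("X", "Z")})
        with pytest.raises(EvaluationError):
            pr_curve(net_of({("A", "B"): 1.0}), gold, bin_size=1,
                     genome_size=5)


def brute_force_loo_auc(edges: dict, members: set, genes: list) -> float:
    """Fold-by-fold LOO-GBA AUC by explicit enumeration.

    For each held-out member, both it and every non-member are scored
    against the remaining members; wins count 1, ties half.
    """
    def w(a, b):
        key = (a, b) if a < b else (b, a)
        return edges.get(key, 0.0)

    members = sorted(members)
    non = [g for g in genes if g not in set(members)]
    wins = 0.0
    for m in members:
        ref = [x for x in members if x != m]
        s_m = sum(w(m, x) for x in ref)
        for v in non:
            s_v = sum(w(v, x) for x in ref)
            wins += 1.0 if s_m > s_v else 0.5 if s_m == s_v else 0.0
    return wins / (len(members) * len(non))


class TestLooGba:
    def test_disconnected_clique_perfect_auc(self):
        members = [f"M{i}" for i in range(5)]
        edges = {(a, b): 1.0 for a, b in itertools.combinations(members, 2)}
        edges[("X1", "X2")] = 1.0
        edges[("X3", "X4")] = 1.0
        res = loo_gba_scores(net_of(edges), set(members))
        assert res.auc == 1.0

    def test_uniform_scores_auc_half(self):
        # complete graph with equal weights: in every fold the held-out
        # member and each non-member tie, so the AUC is exactly chance
        genes = ["A", "B", "C", "D", "E"]
        edges = {(a, b): 1.0 for a, b in itertools.combinations(genes, 2)}
        res = loo_gba_scores(net_of(edges), {"A", "B", "C"})
        assert res.auc == pytest.approx(0.5)

    def test_hand_enumerated_auc(self):
        # fold enumeration: M1 beats both non-members (2 wins); M2 loses to
        # N1 and beats N2 (1); M3 ties N1 and beats N2 (1.5) -> 4.5/6 = 3/4
        edges = {
            ("M1", "M2"): 1.0,
            ("M1", "M3"): 2.0,
            ("M1", "N1"): 2.0,
            ("N1", "N2"): 0.5,
        }
        res = loo_gba_scores(net_of(edges), {"M1", "M2", "M3"})
        scores = dict(res.ranked)
        assert (scores["M1"], scores["M2"], scores["M3"],
                scores["N1"], scores["N2"]) == (3.0, 1.0, 2.0, 2.0, 0.0)
        assert res.auc == pytest.approx(0.75)

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            n_genes = int(rng.integers(8, 20))
            genes = [f"G{i}" for i in range(n_genes)]
            pairs = list(itertools.combinations(genes, 2))
            keep = rng.random(len(pairs)) < 0.4
            edges = {p: float(rng.uniform(0, 2))
                     for p, k in zip(pairs, keep) if k}
            if not edges:
                continue
            net = net_of(edges)
            present = sorted(net.genes)
            if len(present) < 4:
                continue
            members = set(rng.choice(present, size=3, replace=False))
            res = loo_gba_scores(net, members)
            assert res.auc == pytest.approx(
                brute_force_loo_auc(net.edges, members, present))

    def test_self_membership_does_not_change_own_score(self):
        edges = {("A", "B"): 1.0, ("A", "C"): 2.0, ("B", "C"): 0.5,
                 ("C", "D"): 1.0}
        without = loo_gba_scores(net_of(edges), {"B", "C"})
        with_a = loo_gba_scores(net_of(edges), {"A", "B", "C"})
        assert dict(without.ranked)["A"] == dict(with_a.ranked)["A"]

    def test_missing_members_named_in_error(self):
        with pytest.raises(EvaluationError, match="ZZ1"):
            loo_gba_scores(net_of({("A", "B"): 1.0}), {"A", "ZZ1"})


class TestAucBatch:
    def test_identical_sets_identical_aucs(self, toy_net):
        coll = GeneSetCollection(sets={"s1": {"A", "B"}, "s2": {"A", "B"}})
        aucs = auc_batch(toy_net, coll)
        assert aucs["s1"] == aucs["s2"]

    def test_unusable_set_skipped(self, toy_net):
        coll = GeneSetCollection(sets={"ok": {"A", "B"}, "bad": {"A", "Z9"}})
        aucs = auc_batch(toy_net, coll)
        assert set(aucs) == {"ok"}

    def test_all_unusable_rejected(self, toy_net):
        coll = GeneSetCollection(sets={"bad": {"X1", "X2"}})
        with pytest.raises(EvaluationError):
            auc_batch(toy_net, coll)


class TestExtremeTailSets:
    def values_with_outliers(self, n_up: int, n_down: int) -> dict:
        rng = np.random.default_rng(1)
        vals = {f"G{i}": float(v) for i, v in
                enumerate(rng.normal(0, 1, 200))}
        for i in range(n_up):
            vals[f"UP{i}"] = 25.0 + i
        for i in range(n_down):
            vals[f"DN{i}"] = -25.0 - i
        return vals

    def test_both_tails_emitted(self):
        coll = extreme_tail_sets(
            self.values_with_outliers(6, 6),
            TailSetConfig(p_threshold=1e-4, min_size=5), name="hdm1")
        assert set(coll.sets) == {"hdm1_upper", "hdm1_lower"}
        assert {f"UP{i}" for i in range(6)} <= coll.sets["hdm1_upper"]

    def test_min_size_drops_thin_tail(self):
        coll = extreme_tail_sets(
            self.values_with_outliers(6, 3),
            TailSetConfig(p_threshold=1e-4, min_size=5), name="p")
        assert set(coll.sets) == {"p_upper"}

    def test_single_extreme_gene_min_size_one(self):
        vals = {f"G{i}": 0.0 + i * 1e-6 for i in range(20)}
        vals["OUT"] = 100.0
        coll = extreme_tail_sets(vals, TailSetConfig(p_threshold=0.01,
                                                     min_size=1), name="x")
        assert coll.sets.get("x_upper") == frozenset({"OUT"})

    def test_zero_variance_rejected(self):
        with pytest.raises(EvaluationError):
            extreme_tail_sets({f"G{i}": 1.0 for i in range(20)},
                              TailSetConfig())

    def test_at_most_two_sets_per_parameter(self):
        coll = extreme_tail_sets(
            self.values_with_outliers(8, 8),
            TailSetConfig(p_threshold=1e-3, min_size=1), name="p")
        assert len(coll) <= 2

    def test_config_validation(self):
        with pytest.raises(ValidationError):
            TailSetConfig(p_threshold=0.6)
        with pytest.raises(ValidationError):
            TailSetConfig(min_size=0)


class TestWilcoxon:
    def test_all_positive_differences_exact(self):
        a = [0.5, 0.5, 0.5, 0.5, 0.5]
        b = [0.6, 0.7, 0.8, 0.9, 0.95]
        assert wilcoxon_signed_rank(a, b) == pytest.approx(1 / 32)

    def test_equal_lists_degenerate(self):
        a = [0.5, 0.6, 0.7, 0.8, 0.9]
        with pytest.raises(EvaluationError):
            wilcoxon_signed_rank(a, list(a))

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValidationError):
            wilcoxon_signed_rank([0.1] * 5, [0.2] * 6)

    def test_null_p_values_roughly_uniform(self):
        """With no true paired shift, one-sided p-values are ~ Uniform(0,1)."""
        rng = np.random.default_rng(12)
        pvals = []
        for _ in range(400):
            a = rng.normal(0.7, 0.1, 20)
            b = a + rng.normal(0, 0.05, 20)
            pvals.append(wilcoxon_signed_rank(list(a), list(b)))
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01
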