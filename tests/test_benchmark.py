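"""Co-annotation benchmarking against exhaustive enumeration on toy standards."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from onionnorm import (CoAnnotationStandard, ExclusionList, SimilarityNetwork,
                       auprc_delta_counts, build_pair_labels,
                       diversity_breakdown, per_complex_auprc, pr_curve,
                       read_gmt, read_standard_tsv, write_gmt)
from onionnorm.benchmark import ComplexAuprcTable


def _toy_net(weights_by_pair, genes):
    n = len(genes)
    W = np.zeros((n, n))
    np.fill_diagonal(W, 1.0)
    idx = {g: i for i, g in enumerate(genes)}
    for (a, b), w in weights_by_pair.items():
        W[idx[a], idx[b]] = W[idx[b], idx[a]] = w
    return SimilarityNetwork(W, list(genes))


class TestStandardIO:
    def test_gmt_round_trip(self, tmp_path):
        std = CoAnnotationStandard({"C1": {"g1", "g2", "g3"}, "C2": {"g4", "g5"}})
        path = tmp_path / "std.gmt"
        write_gmt(std, path)
        assert path.read_text().count("\n") == 2
        assert read_gmt(path).complexes == std.complexes

    def test_two_column_tsv(self, tmp_path):
        p = tmp_path / "std.tsv"
        p.write_text("C1\tg1\nC1\tg2\nC2\tg3\nC2\tg4\n")
        std = read_standard_tsv(p)
        assert std.complexes == {"C1": {"g1", "g2"}, "C2": {"g3", "g4"}}

    def test_singleton_complex_rejected(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            CoAnnotationStandard({"C1": {"g1"}})


class TestPairLabels:
    def test_basic_labeling(self):
        std = CoAnnotationStandard({"A": {"g1", "g2", "g3"}})
        labels = build_pair_labels(std, {"g1", "g2", "g3", "g4"})
        assert labels.positives == {("g1", "g2"), ("g1", "g3"), ("g2", "g3")}
        assert labels.negatives == set()  # g4 is not in the standard

    def test_negatives_require_no_shared_complex(self):
        std = CoAnnotationStandard({"A": {"g1", "g2"}, "B": {"g3", "g4"}})
        labels = build_pair_labels(std, {"g1", "g2", "g3", "g4"})
        assert ("g1", "g2") in labels.positives
        assert ("g1", "g3") in labels.negatives
        assert len(labels.negatives) == 4

    def test_exclusion_removes_only_double_member_pairs(self):
        std = CoAnnotationStandard({"A": {"g1", "g2", "g3"}})
        excl = ExclusionList({"g1", "g2"})
        labels = build_pair_labels(std, {"g1", "g2", "g3"}, excl)
        assert ("g1", "g2") in labels.excluded
        assert ("g1", "g3") in labels.positives  # one excluded member kept
        assert labels.positives.isdisjoint(labels.excluded)

    def test_overlapping_complexes_count_pair_once(self):
        std = CoAnnotationStandard({"A": {"g1", "g2"}, "B": {"g1", "g2", "g3"}})
        labels = build_pair_labels(std, {"g1", "g2", "g3"})
        assert sum(1 for p in labels.positives if p == ("g1", "g2")) == 1

    def test_empty_overlap_rejected(self):
        std = CoAnnotationStandard({"A": {"g1", "g2"}})
        with pytest.raises(ValueError, match="no overlap"):
            build_pair_labels(std, {"x1", "x2"})


class TestPrCurve:
    def test_perfect_ranking_precision_one(self):
        std = CoAnnotationStandard({"A": {"g1", "g2", "g3"}, "B": {"g4", "g5"}})
        genes = ["g1", "g2", "g3", "g4", "g5"]
        weights = {("g1", "g2"): 0.9, ("g1", "g3"): 0.8, ("g2", "g3"): 0.7,
                   ("g4", "g5"): 0.6}
        net = _toy_net(weights, genes)
        labels = build_pair_labels(std, set(genes))
        curve = pr_curve(net, labels)
        n_pos = len(labels.positives)
        assert (curve.precision[:n_pos] == 1.0).all()

    def test_interleaved_labels_hand_enumeration(self):
        std = CoAnnotationStandard({"A": {"g1", "g2"}, "B": {"g3", "g4"}})
        genes = ["g1", "g2", "g3", "g4"]
        weights = {("g1", "g2"): 0.9, ("g1", "g3"): 0.8, ("g3", "g4"): 0.7,
                   ("g1", "g4"): 0.1, ("g2", "g3"): 0.05, ("g2", "g4"): 0.02}
        curve = pr_curve(_toy_net(weights, genes),
                        build_pair_labels(std, set(genes)))
        np.testing.assert_allclose(curve.precision[:3], [1.0, 0.5, 2 / 3])
        np.testing.assert_array_equal(curve.cum_tp[:3], [1, 1, 2])

    def test_reversed_weights_give_worst_case(self):
        std = CoAnnotationStandard({"A": {"g1", "g2"}, "B": {"g3", "g4"}})
        genes = ["g1", "g2", "g3", "g4"]
        weights = {("g1", "g2"): 0.9, ("g1", "g3"): 0.8, ("g3", "g4"): 0.7,
                   ("g1", "g4"): 0.1, ("g2", "g3"): 0.05, ("g2", "g4"): 0.02}
        labels = build_pair_labels(std, set(genes))
        reversed_net = _toy_net({k: -v for k, v in weights.items()}, genes)
        curve = pr_curve(reversed_net, labels)
        # positives now sit at the bottom of the ranking
        assert curve.precision[0] == 0.0
        assert curve.cum_tp[-1] == len(labels.positives)

    def test_final_precision_equals_positive_fraction(self, tiny_synth):
        from onionnorm import pcc_network
        mat, truth = tiny_synth
        net = pcc_network(mat)
        labels = build_pair_labels(truth.standard(), set(net.node_ids))
        curve = pr_curve(net, labels)
        frac = len(labels.positives) / (len(labels.positives) + len(labels.negatives))
        assert curve.precision[-1] == pytest.approx(frac, abs=1e-12)

    def test_excluded_pairs_do_not_change_any_output(self):
        std = CoAnnotationStandard({"A": {"g1", "g2", "g3"},
                                    "B": {"m1", "m2"}})
        genes = ["g1", "g2", "g3", "m1", "m2"]
        # excluded pair (m1, m2) gets the top score; outputs must not move
        weights = {("g1", "g2"): 0.9, ("g1", "g3"): 0.5, ("g2", "g3"): 0.3,
                   ("m1", "m2"): 0.99, ("g1", "m1"): 0.2}
        net = _toy_net(weights, genes)
        excl = ExclusionList({"m1", "m2"})
        with_excl = build_pair_labels(std, set(genes), excl)
        manual = build_pair_labels(
            CoAnnotationStandard({"A": {"g1", "g2", "g3"}}),
            {"g1", "g2", "g3"})
        # drop cross pairs involving m-genes from the comparison set
        g_weights = {p: w for p, w in weights.items()
                     if p[0].startswith("g") and p[1].startswith("g")}
        manual_curve = pr_curve(_toy_net(g_weights, ["g1", "g2", "g3"]), manual)
        curve = pr_curve(net, with_excl)
        keep = [i for i, p in enumerate(curve.pairs)
                if p[0][0] == "g" and p[1][0] == "g"]
        np.testing.assert_allclose(
            curve.is_positive[keep].astype(int),
            manual_curve.is_positive.astype(int))
        tbl = per_complex_auprc(net, std, excl)
        assert "B" not in tbl.auprc  # all of B's pairs are excluded

    def test_no_positives_raises(self):
        std = CoAnnotationStandard({"A": {"g1", "g2"}})
        net = _toy_net({("g1", "g2"): 0.5}, ["g1", "g2"])
        labels = build_pair_labels(std, {"g1", "g2"})
        labels.positives.clear()
        with pytest.raises(ValueError, match="no positive"):
            pr_curve(net, labels)

    @settings(deadline=None, derandomize=True, max_examples=20)
    @given(seed=st.integers(0, 10**6))
    def test_monotone_transform_invariance(self, seed):
        rng = np.random.default_rng(seed)
        genes = [f"g{i}" for i in range(6)]
        std = CoAnnotationStandard({"A": set(genes[:3]), "B": set(genes[3:])})
        W = rng.random((6, 6))
        W = (W + W.T) / 2
        np.fill_diagonal(W, 1.0)
        net = SimilarityNetwork(W, genes)
        transformed = SimilarityNetwork(np.exp(3 * W) / 50.0, genes)
        labels = build_pair_labels(std, set(genes))
        a, b = pr_curve(net, labels), pr_curve(transformed, labels)
        assert a.pairs == b.pairs
        np.testing.assert_array_equal(a.precision, b.precision)


class TestDiversity:
    def test_single_complex_fraction_one(self):
        std = CoAnnotationStandard({"A": {"g1", "g2", "g3"}})
        weights = {("g1", "g2"): 0.9, ("g1", "g3"): 0.8, ("g2", "g3"): 0.7}
        net = _toy_net(weights, ["g1", "g2", "g3"])
        labels = build_pair_labels(std, {"g1", "g2", "g3"})
        df = diversity_breakdown(net, labels, std, [0.9, 0.5])
        assert (df["fraction"] == 1.0).all()
        assert set(df["complex_id"]) == {"A"}

    def test_three_to_one_contribution_fractions(self):
        std = CoAnnotationStandard({"A": {"a1", "a2", "a3"}, "B": {"b1", "b2"}})
        genes = ["a1", "a2", "a3", "b1", "b2"]
        weights = {("a1", "a2"): 0.9, ("a1", "a3"): 0.8, ("a2", "a3"): 0.7,
                   ("b1", "b2"): 0.6}
        net = _toy_net(weights, genes)
        labels = build_pair_labels(std, set(genes))
        df = diversity_breakdown(net, labels, std, [0.5])
        by_id = dict(zip(df["complex_id"], df["fraction"]))
        assert by_id["A"] == pytest.approx(0.75)
        assert by_id["B"] == pytest.approx(0.25)

    def test_multi_complex_pair_split_fractionally(self):
        std = CoAnnotationStandard({"A": {"g1", "g2"}, "B": {"g1", "g2", "g3"}})
        weights = {("g1", "g2"): 0.9, ("g1", "g3"): 0.8, ("g2", "g3"): 0.7}
        net = _toy_net(weights, ["g1", "g2", "g3"])
        labels = build_pair_labels(std, {"g1", "g2", "g3"})
        df = diversity_breakdown(net, labels, std, [0.5])
        assert df.groupby("cutoff")["fraction"].sum().iloc[0] == pytest.approx(1.0)
        by_id = dict(zip(df["complex_id"], df["fraction"]))
        # (g1,g2) splits 1/2-1/2; B additionally owns (g1,g3) and (g2,g3)
        assert by_id["A"] == pytest.approx(0.5 / 3)
        assert by_id["B"] == pytest.approx(2.5 / 3)

    def test_unattained_cutoff_yields_empty(self):
        std = CoAnnotationStandard({"A": {"g1", "g2"}, "B": {"g3", "g4"}})
        genes = ["g1", "g2", "g3", "g4"]
        weights = {("g1", "g3"): 0.9, ("g1", "g2"): 0.5}
        net = _toy_net(weights, genes)
        labels = build_pair_labels(std, set(genes))
        df = diversity_breakdown(net, labels, std, [0.99])
        assert df.empty

    def test_fractions_sum_to_one_at_every_cutoff(self, tiny_synth):
        from onionnorm import pcc_network
        mat, truth = tiny_synth
        net = pcc_network(mat)
        std = truth.standard()
        labels = build_pair_labels(std, set(net.node_ids))
        df = diversity_breakdown(net, labels, std, [0.9, 0.5, 0.2, 0.05])
        sums = df.groupby("cutoff")["fraction"].sum()
        np.testing.assert_allclose(sums.to_numpy(), 1.0, atol=1e-12)


class TestPerComplexAuprc:
    def test_dominant_complex_has_highest_auprc(self):
        std = CoAnnotationStandard({"A": {"a1", "a2", "a3"}, "B": {"b1", "b2"}})
        genes = ["a1", "a2", "a3", "b1", "b2"]
        weights = {("a1", "a2"): 0.9, ("a1", "a3"): 0.85, ("a2", "a3"): 0.8,
                   ("b1", "b2"): 0.1}
        tbl = per_complex_auprc(_toy_net(weights, genes), std)
        assert tbl.auprc["A"] >= tbl.auprc["B"]
        assert tbl.auprc["A"] == pytest.approx(1.0)

    def test_matches_sklearn_average_precision(self, rng):
        # independent oracle: same ranking, distinct weights, three complexes
        from sklearn.metrics import average_precision_score
        std = CoAnnotationStandard({
            "A": {"g0", "g1", "g2"}, "B": {"g3", "g4", "g5"},
            "C": {"g6", "g7"}})
        genes = [f"g{i}" for i in range(8)]
        W = rng.random((8, 8))
        W = (W + W.T) / 2
        np.fill_diagonal(W, 1.0)
        net = SimilarityNetwork(W, genes)
        tbl = per_complex_auprc(net, std)
        idx = {g: i for i, g in enumerate(genes)}
        within = {
            cid: [(a, b) for a in sorted(m) for b in sorted(m)
                  if a < b]
            for cid, m in std.complexes.items()
        }
        all_pairs = sorted({p for ps in within.values() for p in ps})
        for cid, pos in within.items():
            y = np.array([p in set(pos) for p in all_pairs])
            scores = np.array([W[idx[a], idx[b]] for a, b in all_pairs])
            expected = average_precision_score(y, scores)
            assert tbl.auprc[cid] == pytest.approx(expected, abs=1e-12)

    def test_random_ranking_approaches_prevalence(self, rng):
        std = CoAnnotationStandard({"A": {f"a{i}" for i in range(6)},
                                    "B": {f"b{i}" for i in range(12)}})
        genes = sorted(std.gene_universe)
        n = len(genes)
        vals = []
        for _ in range(100):
            W = rng.random((n, n))
            W = (W + W.T) / 2
            np.fill_diagonal(W, 1.0)
            vals.append(per_complex_auprc(SimilarityNetwork(W, genes),
                                          std).auprc["A"])
        n_pos, n_all = 15, 15 + 66
        prevalence = n_pos / n_all
        assert abs(np.mean(vals) - prevalence) < 3 * np.std(vals) / np.sqrt(100) + 0.02


class TestDeltaCounts:
    def test_identical_tables_all_zero(self):
        t = ComplexAuprcTable({"A": 0.3, "B": 0.6}, {"A": 3, "B": 11})
        df = auprc_delta_counts(t, t, 0.5)
        assert (df["count"] == 0).all()

    def test_single_increase_in_correct_bin(self):
        raw = ComplexAuprcTable({"A": 0.05}, {"A": 7})
        norm = ComplexAuprcTable({"A": 0.6}, {"A": 7})
        df = auprc_delta_counts(norm, raw, 0.5)
        row = df[(df.size_bin == "6-9") & (df.direction == "increase")]
        assert row["count"].iloc[0] == 1
        assert df["count"].sum() == 1

    def test_randomized_tables_match_enumeration(self, rng):
        ids = [f"C{i}" for i in range(40)]
        sizes = {c: int(rng.integers(2, 15)) for c in ids}
        raw = ComplexAuprcTable({c: float(rng.random()) for c in ids}, sizes)
        norm = ComplexAuprcTable({c: float(rng.random()) for c in ids}, sizes)
        for t in (0.1, 0.5, 0.7):
            df = auprc_delta_counts(norm, raw, t)
            inc = sum(1 for c in ids if raw.auprc[c] < t <= norm.auprc[c])
            dec = sum(1 for c in ids if norm.auprc[c] < t <= raw.auprc[c])
            assert df[df.direction == "increase"]["count"].sum() == inc
            assert df[df.direction == "decrease"]["count"].sum() == dec
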