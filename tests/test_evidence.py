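"""The seven evidence features on hand-built inputs and on the synthetic world."""

import numpy as np
import pandas as pd
import pytest

from cyanonet.core_io import (AnnotationTable, ExpressionMatrix, GenomeTable,
                              Ontology, Pair, PairSet)
from cyanonet.evidence import (cluster_feature, coexpression_feature,
                               domain_feature, fusion_feature,
                               neighborhood_feature, phylo_profile_feature,
                               predict_operons, ssbp_feature)


def expr(rows: dict[str, list[float]], dataset_id="d1") -> ExpressionMatrix:
    df = pd.DataFrame.from_dict(rows, orient="index",
                                columns=[f"s{i}" for i in
                                         range(len(next(iter(rows.values()))))])
    return ExpressionMatrix(dataset_id=dataset_id, values=df.astype(float))


class TestCoexpression:
    def gold(self):
        gsp = PairSet(pairs={Pair("a", "b")}, label="GSP")
        gsn = PairSet(pairs={Pair("c", "d")}, label="GSN")
        return gsp, gsn

    def test_identical_rows_give_r_one(self):
        x = [1.0, 2.0, 3.0, 4.0, 2.5]
        mat = expr({"a": x, "b": x, "c": [5, 1, 4, 2, 3], "d": [1, 5, 2, 4, 3]})
        gsp, gsn = self.gold()
        # force retention aside: compute through the per-dataset helper
        from cyanonet.evidence import _pairwise_pearson
        r = _pairwise_pearson(mat, [Pair("a", "b")])
        assert r[Pair("a", "b")] == pytest.approx(1.0)

    def test_negated_rows_give_r_minus_one(self):
        from cyanonet.evidence import _pairwise_pearson
        x = [1.0, 2.0, 3.0, 4.0, 2.5]
        mat = expr({"a": x, "b": [-v for v in x]})
        r = _pairwise_pearson(mat, [Pair("a", "b")])
        assert r[Pair("a", "b")] == pytest.approx(-1.0)

    def test_constant_rows_are_missing(self):
        from cyanonet.evidence import _pairwise_pearson
        mat = expr({"a": [1, 1, 1, 1], "b": [1, 2, 3, 4]})
        assert _pairwise_pearson(mat, [Pair("a", "b")]) == {}

    def test_informative_dataset_retained_on_world(self, default_study):
        # the pure-noise dataset must be rejected, the module-driven ones kept
        assert default_study["retained"] == ["expr_info0", "expr_info1"]

    def test_gsp_exceeds_gsn_in_retained_dataset(self, default_world,
                                                 default_study):
        from cyanonet.evidence import _pairwise_pearson
        gs = default_study["gs"]
        mat = default_world.expression[0]
        r_pos = list(_pairwise_pearson(mat, gs.gsp.sorted()).values())
        r_neg = list(_pairwise_pearson(mat, gs.gsn.sorted()).values())
        assert np.mean(r_pos) > np.mean(r_neg)

    def test_no_retained_dataset_yields_empty_feature(self):
        rng = np.random.default_rng(0)
        genes = [f"g{i}" for i in range(10)]
        mat = ExpressionMatrix(
            "noise", pd.DataFrame(rng.normal(size=(10, 6)), index=genes))
        gsp = PairSet(pairs={Pair("g0", "g1"), Pair("g2", "g3"),
                             Pair("g4", "g5")}, label="GSP")
        gsn = PairSet(pairs={Pair("g6", "g7"), Pair("g8", "g9"),
                             Pair("g0", "g9")}, label="GSN")
        with pytest.warns(UserWarning, match="no expression dataset"):
            table, retained = coexpression_feature(
                [mat], [Pair("g0", "g1")], gsp, gsn)
        assert len(table) == 0 and retained == []


def toy_bp_ontology():
    """root annotated by 10, tX by 4, tY by 2 (after propagation)."""
    parents = {"root": frozenset(), "tX": frozenset({"root"}),
               "tY": frozenset({"tX"})}
    ns = {t: "biological_process" for t in parents}
    return Ontology(parents=parents, namespace=ns)


class TestSSBP:
    def test_propagation_and_count(self):
        onto = toy_bp_ontology()
        assign = {f"p{i}": frozenset({"root"}) for i in range(6)}
        assign.update({"p6": frozenset({"tX"}), "p7": frozenset({"tX"})})
        assign.update({"p8": frozenset({"tY"}), "p9": frozenset({"tY"})})
        annot = AnnotationTable(assignments=assign)
        table = ssbp_feature(annot, onto, [Pair("p8", "p9"), Pair("p6", "p8"),
                                           Pair("p0", "p6")])
        assert table.values[Pair("p8", "p9")] == 2    # share tY (2 proteins)
        assert table.values[Pair("p6", "p8")] == 4    # most specific shared: tX
        assert table.values[Pair("p0", "p6")] == 10   # only the root

    def test_minimum_over_shared_terms(self):
        onto = toy_bp_ontology()
        annot = AnnotationTable(assignments={
            "a": frozenset({"tY"}), "b": frozenset({"tY"}),
            **{f"x{i}": frozenset({"root"}) for i in range(5)}})
        table = ssbp_feature(annot, onto, [Pair("a", "b")])
        # shared terms are {tY(2), tX(2), root(7)}; minimum size wins
        assert table.values[Pair("a", "b")] == 2

    def test_no_shared_term_is_missing(self):
        parents = {"root": frozenset(), "u": frozenset({"root"}),
                   "v": frozenset({"root"})}
        ns = {t: "biological_process" for t in parents}
        onto = Ontology(parents=parents, namespace=ns)
        # b unannotated: pair must be missing even though a shares root with itself
        annot = AnnotationTable(assignments={"a": frozenset({"u"})})
        assert len(ssbp_feature(annot, onto, [Pair("a", "b")])) == 0

    def test_monotone_under_ancestor_replacement(self):
        """Moving an annotation up the DAG can only grow the shared-term size."""
        onto = toy_bp_ontology()
        base = {f"x{i}": frozenset({"root"}) for i in range(5)}
        deep = AnnotationTable(assignments={
            "a": frozenset({"tY"}), "b": frozenset({"tY"}), **base})
        shallow = AnnotationTable(assignments={
            "a": frozenset({"tX"}), "b": frozenset({"tX"}), **base})
        v_deep = ssbp_feature(deep, onto, [Pair("a", "b")]).values[Pair("a", "b")]
        v_shallow = shallow_v = ssbp_feature(
            shallow, onto, [Pair("a", "b")]).values[Pair("a", "b")]
        assert v_shallow >= v_deep


class TestDomain:
    def test_single_match(self):
        t = domain_feature({"a": {"D1"}, "b": {"D2"}}, {("D1", "D2")},
                           [Pair("a", "b")])
        assert t.values[Pair("a", "b")] == 1

    def test_combination_count(self):
        t = domain_feature({"a": {"D1", "D2"}, "b": {"D1", "D2"}},
                           {("D1", "D1"), ("D1", "D2")}, [Pair("a", "b")])
        # combos: (D1,D1)+, (D1,D2)+, (D2,D1)+ (unordered = D1-D2), (D2,D2)-
        assert t.values[Pair("a", "b")] == 3

    def test_domainless_protein_is_missing(self):
        t = domain_feature({"a": {"D1"}, "b": set()}, {("D1", "D2")},
                           [Pair("a", "b")])
        assert len(t) == 0

    def test_zero_count_is_a_value(self):
        t = domain_feature({"a": {"D1"}, "b": {"D3"}}, {("D1", "D2")},
                           [Pair("a", "b")])
        assert t.values[Pair("a", "b")] == 0


class TestPhyloProfile:
    def profiles(self, rows):
        return pd.DataFrame(rows, columns=["g1", "g2", "g3", "g4"]).rename(
            index={0: "a", 1: "b"})

    def test_identical_profiles(self):
        df = self.profiles([[1, 1, 0, 0], [1, 1, 0, 0]])
        t = phylo_profile_feature(df, [Pair("a", "b")])
        assert t.values[Pair("a", "b")] == pytest.approx(1.0)

    def test_disjoint_profiles(self):
        df = self.profiles([[1, 1, 0, 0], [0, 0, 1, 1]])
        t = phylo_profile_feature(df, [Pair("a", "b")])
        assert t.values[Pair("a", "b")] == pytest.approx(0.0)

    def test_jaccard_half(self):
        df = self.profiles([[1, 1, 1, 0], [0, 1, 1, 1]])
        t = phylo_profile_feature(df, [Pair("a", "b")])
        assert t.values[Pair("a", "b")] == pytest.approx(0.5)

    def test_all_zero_profile_missing(self):
        df = self.profiles([[0, 0, 0, 0], [1, 1, 0, 0]])
        assert len(phylo_profile_feature(df, [Pair("a", "b")])) == 0


def genome(genome_id, rows):
    df = pd.DataFrame(rows, columns=["gene_id", "replicon", "start", "end",
                                     "strand"])
    return GenomeTable(genome_id=genome_id, genes=df)


class TestNeighborhood:
    def test_adjacent_everywhere(self):
        genomes = []
        orthologs = {}
        for i in range(4):
            gid = f"r{i}"
            genomes.append(genome(gid, [(f"{gid}_a", "chr", 100, 200, "+"),
                                        (f"{gid}_b", "chr", 300, 400, "+")]))
            orthologs[("a", gid)] = f"{gid}_a"
            orthologs[("b", gid)] = f"{gid}_b"
        t = neighborhood_feature(genomes, orthologs, [Pair("a", "b")])
        assert t.values[Pair("a", "b")] == pytest.approx(1.0)

    def test_different_replicons_everywhere(self):
        genomes = [genome("r0", [("r0_a", "chr", 100, 200, "+"),
                                 ("r0_b", "plasmid", 100, 200, "+")])]
        orthologs = {("a", "r0"): "r0_a", ("b", "r0"): "r0_b"}
        t = neighborhood_feature(genomes, orthologs, [Pair("a", "b")])
        assert t.values[Pair("a", "b")] == pytest.approx(0.0)

    def test_fraction_two_of_five(self):
        genomes = []
        orthologs = {}
        for i in range(5):
            gid = f"r{i}"
            rows = [(f"{gid}_a", "chr", 100, 200, "+")]
            # close in genomes 0,1; separated by 10 intervening genes elsewhere
            n_between = 0 if i < 2 else 10
            pos = 300
            for j in range(n_between):
                rows.append((f"{gid}_x{j}", "chr", pos, pos + 50, "+"))
                pos += 100
            rows.append((f"{gid}_b", "chr", pos, pos + 50, "+"))
            genomes.append(genome(gid, rows))
            orthologs[("a", gid)] = f"{gid}_a"
            orthologs[("b", gid)] = f"{gid}_b"
        t = neighborhood_feature(genomes, orthologs, [Pair("a", "b")],
                                 max_intervening=5)
        assert t.values[Pair("a", "b")] == pytest.approx(0.4)

    def test_missing_below_min_genomes(self):
        genomes = [genome("r0", [("r0_a", "chr", 100, 200, "+")])]
        orthologs = {("a", "r0"): "r0_a"}
        t = neighborhood_feature(genomes, orthologs, [Pair("a", "b")])
        assert len(t) == 0


class TestFusion:
    def hits(self, rows):
        return pd.DataFrame(rows, columns=["query", "target", "target_start",
                                           "target_end"])

    def test_disjoint_spans_fuse(self):
        h = self.hits([("a", "T", 1, 100), ("b", "T", 120, 200)])
        t = fusion_feature(h, [Pair("a", "b")])
        assert t.values[Pair("a", "b")] == 1

    def test_overlapping_spans_do_not(self):
        h = self.hits([("a", "T", 1, 100), ("b", "T", 50, 150)])
        t = fusion_feature(h, [Pair("a", "b")])
        assert t.values[Pair("a", "b")] == 0  # overlap 51/100 >= 20%

    def test_no_shared_target(self):
        h = self.hits([("a", "T1", 1, 100), ("b", "T2", 1, 100)])
        t = fusion_feature(h, [Pair("a", "b")])
        assert t.values[Pair("a", "b")] == 0


class TestCluster:
    def test_same_strand_small_gap(self):
        g = genome("study", [("a", "chr", 100, 200, "+"),
                             ("b", "chr", 251, 350, "+")])
        t = cluster_feature(g, [Pair("a", "b")])
        assert t.values[Pair("a", "b")] == 1

    def test_opposite_strands(self):
        g = genome("study", [("a", "chr", 100, 200, "+"),
                             ("b", "chr", 251, 350, "-")])
        t = cluster_feature(g, [Pair("a", "b")])
        assert t.values[Pair("a", "b")] == 0

    def test_transitive_run_membership(self):
        g = genome("study", [("a", "chr", 100, 200, "+"),
                             ("b", "chr", 301, 400, "+"),
                             ("c", "chr", 501, 600, "+")])
        t = cluster_feature(g, [Pair("a", "c")])
        assert t.values[Pair("a", "c")] == 1

    def test_large_gap_splits_operon(self):
        g = genome("study", [("a", "chr", 100, 200, "+"),
                             ("b", "chr", 1000, 1100, "+")])
        ops = predict_operons(g)
        assert ops["a"] != ops["b"]


def test_features_invariant_to_pair_orientation(default_study):
    """Canonicalization means orientation can never matter downstream."""
    for table in default_study["features"]:
        for pair in list(table.values)[:50]:
            assert table.get(Pair(pair.b, pair.a)) == table.get(pair)


def test_true_pairs_separate_from_false_on_world(default_world, default_study):
    """Each informative feature's true-pair distribution dominates (SSBP:
    is dominated by) its false-pair distribution, by rank comparison."""
    from scipy import stats
    world = default_world
    truth = world.truth.pairs
    for table in default_study["features"]:
        pos = [v for p, v in table.values.items() if p in truth]
        neg = [v for p, v in table.values.items() if p not in truth]
        if len(pos) < 20 or len(neg) < 20:
            continue
        alt = "less" if table.feature_name == "ssbp" else "greater"
        res = stats.mannwhitneyu(pos, neg, alternative=alt)
        assert res.pvalue < 1e-4, table.feature_name
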