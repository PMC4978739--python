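import numpy as np
import networkx as nx
import pytest

from nlr_evolkit.core_io import ProteinRecord, RunConfig
from nlr_evolkit.classify import (
    NONE_GROUP,
    Tree,
    TreeNode,
    assign_subgroups,
    backfill_nb_lineage,
    bootstrap_tree,
    build_similarity_graph,
    local_align,
    mcl_cluster,
    neighbor_joining,
    progressive_msa,
    protein_distance_matrix,
    self_score,
    upgma_tree,
)

AA = "ACDEFGHIKLMNPQRSTVWY"


def _rand_prot(rng, n):
    return "".join(AA[i] for i in rng.integers(0, 20, size=n))


def _tree_distances(tree: Tree) -> dict:
    """Leaf-to-leaf path lengths of a Tree (for additive-recovery checks)."""
    dists = {}

    def walk(node, acc):
        if node.is_leaf:
            return {node.name: acc}
        out = {}
        for c in node.children:
            out.update(walk(c, acc + c.length))
        return out

    # distances via root paths and lowest common ancestor accumulation
    def collect(node):
        if node.is_leaf:
            return {node.name: node.length}
        sub = [collect(c) for c in node.children]
        for i in range(len(sub)):
            for j in range(i + 1, len(sub)):
                for a, da in sub[i].items():
                    for b, db in sub[j].items():
                        dists[frozenset((a, b))] = da + db
        merged = {}
        for s in sub:
            for k, v in s.items():
                merged[k] = v + node.length
        return merged

    collect(tree.root)
    return dists


class TestLocalAlign:
    def test_identical_sequences_score_diagonal_sum(self):
        seq = "MKVLWAALLGABBD".replace("B", "N")
        aln = local_align(seq, seq)
        assert aln.score == self_score(seq)
        assert aln.match_frac_a == aln.match_frac_b == 1.0

    def test_agrees_with_quadratic_dp_oracle_at_linear_gaps(self):
        from Bio.Align import substitution_matrices
        m = substitution_matrices.load("BLOSUM62")
        alpha = m.alphabet

        def sw_oracle(a, b, gap=-4.0):
            best = 0.0
            F = np.zeros((len(a) + 1, len(b) + 1))
            for i in range(1, len(a) + 1):
                for j in range(1, len(b) + 1):
                    s = m[alpha.index(a[i - 1]), alpha.index(b[j - 1])]
                    F[i, j] = max(0.0, F[i - 1, j - 1] + s,
                                  F[i - 1, j] + gap, F[i, j - 1] + gap)
                    best = max(best, F[i, j])
            return best

        rng = np.random.default_rng(0)
        pairs = [("HEAGAWGHEE", "PAWHEAE")] + [
            (_rand_prot(rng, 25), _rand_prot(rng, 30)) for _ in range(5)
        ]
        for a, b in pairs:
            aln = local_align(a, b, gap_open=-4.0, gap_extend=-4.0)
            assert aln.score == pytest.approx(sw_oracle(a, b))

    def test_unalignable_sequences_give_empty_alignment(self):
        aln = local_align("WWWWW", "PPPPP")
        assert aln.score == 0.0 and aln.aligned_a == ""


class TestSimilarityGraph:
    def test_identical_proteins_edge_weight_one(self):
        cfg = RunConfig()
        p = ProteinRecord("a", "MKVLWAALLGMKVLWAALLG")
        q = ProteinRecord("b", p.sequence)
        g = build_similarity_graph([p, q], cfg)
        assert g["a"]["b"]["weight"] == pytest.approx(1.0)

    def test_shuffled_unrelated_proteins_have_no_edge(self):
        cfg = RunConfig()
        missed = 0
        for trial in range(50):
            rng = np.random.default_rng(trial)
            a = ProteinRecord("a", _rand_prot(rng, 250))
            b = ProteinRecord("b", _rand_prot(rng, 250))
            if build_similarity_graph([a, b], cfg).number_of_edges():
                missed += 1
        assert missed == 0

    def test_low_coverage_repeat_match_rejected(self):
        # 40% of b matches a perfectly; the 50% coverage rule must reject it
        rng = np.random.default_rng(5)
        shared = _rand_prot(rng, 80)
        a = ProteinRecord("a", shared + _rand_prot(rng, 20))
        b = ProteinRecord("b", shared + _rand_prot(rng, 120))
        aln = local_align(a, b)
        assert aln.match_frac_b < 0.5  # fixture sanity
        g = build_similarity_graph([a, b], RunConfig())
        assert g.number_of_edges() == 0


class TestMcl:
    def _clique(self, names, w=1.0):
        g = nx.Graph()
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                g.add_edge(names[i], names[j], weight=w)
        return g

    def test_disconnected_cliques_stay_separate(self):
        g = nx.compose(self._clique("abcd"), self._clique("efgh"))
        assert sorted(map(sorted, mcl_cluster(g, 1.5))) == [list("abcd"), list("efgh")]

    def test_single_edgeless_node_is_a_singleton(self):
        g = nx.Graph()
        g.add_node("solo")
        assert mcl_cluster(g, 1.5) == [{"solo"}]

    def test_weak_bridge_is_cut_at_default_inflation(self):
        g = nx.compose(self._clique("abcd"), self._clique("efgh"))
        g.add_edge("a", "e", weight=0.01)
        clusters = mcl_cluster(g, 1.5)
        assert sorted(map(sorted, clusters)) == [list("abcd"), list("efgh")]

    def test_never_merges_disconnected_components(self):
        rng = np.random.default_rng(8)
        for _ in range(10):
            g = nx.Graph()
            comps = []
            for c in range(3):
                names = [f"c{c}n{i}" for i in range(int(rng.integers(2, 6)))]
                comps.append(set(names))
                for i in range(len(names)):
                    for j in range(i + 1, len(names)):
                        if rng.random() < 0.7:
                            g.add_edge(names[i], names[j],
                                       weight=float(rng.uniform(0.1, 1.0)))
                g.add_nodes_from(names)
            clusters = mcl_cluster(g, 1.5)
            for cl in clusters:
                assert any(cl <= comp for comp in comps)


class TestJttDistances:
    def test_identical_rows_have_zero_distance(self):
        aln = {"a": "MKVLWAALLG" * 16, "b": "MKVLWAALLG" * 16}
        ids, D, unreliable = protein_distance_matrix(aln)
        assert D[0, 1] == 0.0
        assert not unreliable

    def test_distance_grows_with_substitution_load(self):
        rng = np.random.default_rng(3)
        base = _rand_prot(rng, 160)
        dists = []
        for frac in (0.05, 0.10, 0.20):
            seq = list(base)
            k = int(frac * len(seq))
            pos = rng.choice(len(seq), size=k, replace=False)
            for p in pos:
                seq[p] = AA[(AA.index(seq[p]) + 1) % 20]
            _, D, _ = protein_distance_matrix({"a": base, "b": "".join(seq)})
            dists.append(D[0, 1])
        assert dists[0] < dists[1] < dists[2]

    def test_small_divergence_approaches_p_distance(self):
        rng = np.random.default_rng(4)
        base = _rand_prot(rng, 400)
        seq = list(base)
        pos = rng.choice(len(seq), size=12, replace=False)  # 3% divergence
        for p in pos:
            seq[p] = AA[(AA.index(seq[p]) + 7) % 20]
        _, D, _ = protein_distance_matrix({"a": base, "b": "".join(seq)})
        p_dist = 12 / 400
        assert D[0, 1] == pytest.approx(p_dist, rel=0.20)

    def test_sparse_overlap_flagged_unreliable(self):
        aln = {"a": "MKVLWAALLG" + "-" * 90, "b": "-" * 90 + "MKVLWAALLG"}
        _, D, unreliable = protein_distance_matrix(aln)
        assert ("a", "b") in unreliable


class TestNeighborJoining:
    def test_additive_four_taxon_matrix_recovered_exactly(self):
        # generating tree: ((A:1,B:2):3,(C:4,D:5)) with internal branch 3
        D = np.array([[0, 3, 8, 9], [3, 0, 9, 10],
                      [8, 9, 0, 9], [9, 10, 9, 0]], float)
        tree = neighbor_joining(D, list("ABCD"))
        assert tree.bipartitions() == {frozenset("AB")}
        dists = _tree_distances(tree)
        for i, a in enumerate("ABCD"):
            for j, b in enumerate("ABCD"):
                if i < j:
                    assert dists[frozenset((a, b))] == pytest.approx(D[i, j])

    def test_three_taxa_closed_form(self):
        D = np.array([[0, 2, 3], [2, 0, 5], [3, 5, 0]], float)
        tree = neighbor_joining(D, list("ABC"))
        lengths = {l.name: l.length for l in tree.root.leaves()}
        assert lengths["A"] == pytest.approx(0.0)
        assert lengths["B"] == pytest.approx(2.0)
        assert lengths["C"] == pytest.approx(3.0)

    @pytest.mark.parametrize("n_taxa,seed", [(5, 0), (8, 1), (10, 2), (12, 3)])
    def test_random_additive_matrices_recovered(self, n_taxa, seed):
        rng = np.random.default_rng(seed)
        # random binary tree -> additive distances
        nodes = [TreeNode(name=f"t{i}", length=float(rng.uniform(0.5, 2.0)))
                 for i in range(n_taxa)]
        while len(nodes) > 3:
            i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
            parent = TreeNode(length=float(rng.uniform(0.5, 2.0)),
                              children=[nodes[i], nodes[j]])
            nodes = [nodes[k] for k in range(len(nodes)) if k not in (i, j)]
            nodes.append(parent)
        truth = Tree(root=TreeNode(children=nodes))
        td = _tree_distances(truth)
        names = sorted(truth.leaf_names())
        D = np.zeros((n_taxa, n_taxa))
        for i, a in enumerate(names):
            for j, b in enumerate(names):
                if i != j:
                    D[i, j] = td[frozenset((a, b))]
        rec = neighbor_joining(D, names)
        assert rec.bipartitions() == truth.bipartitions()
        rd = _tree_distances(rec)
        for key, val in td.items():
            assert rd[key] == pytest.approx(val, abs=1e-9)

    def test_matches_scikit_bio_on_random_matrix(self):
        skbio = pytest.importorskip("skbio")
        from skbio import DistanceMatrix
        from skbio.tree import nj as skbio_nj

        rng = np.random.default_rng(7)
        n = 7
        X = rng.uniform(0.1, 1.0, size=(n, 12))
        D = np.array([[np.abs(X[i] - X[j]).sum() for j in range(n)]
                      for i in range(n)])
        ids = [f"t{i}" for i in range(n)]
        mine = neighbor_joining(D, ids)
        theirs = skbio_nj(DistanceMatrix(D, ids))
        their_biparts = set()
        for node in theirs.non_tips():
            side = frozenset(t.name for t in node.tips())
            other = frozenset(ids) - side
            if len(side) >= 2 and len(other) >= 2:
                their_biparts.add(min(side, other, key=lambda s: (len(s), sorted(s))))
        assert mine.bipartitions() == their_biparts

    def test_ultrametric_matrix_gives_upgma_topology(self):
        rng = np.random.default_rng(11)
        X = rng.normal(size=(8, 4))
        # build an ultrametric matrix from a UPGMA tree of random data
        from scipy.cluster.hierarchy import average, cophenet
        from scipy.spatial.distance import pdist, squareform
        Z = average(pdist(X))
        D = squareform(cophenet(Z))
        ids = [f"t{i}" for i in range(8)]
        nj_tree = neighbor_joining(D, ids)
        up_tree = upgma_tree(D, ids)
        assert nj_tree.bipartitions() == up_tree.bipartitions()


class TestBootstrap:
    def _clade_alignment(self, rng, n_per_clade=5, length=120, div=0.4, noise=0.02):
        anc1 = _rand_prot(rng, length)
        anc2 = list(anc1)
        for p in rng.choice(length, size=int(div * length), replace=False):
            anc2[p] = AA[(AA.index(anc2[p]) + 3) % 20]
        anc2 = "".join(anc2)

        def noisy(base, tag, k):
            out = {}
            for i in range(k):
                seq = list(base)
                for p in range(length):
                    if rng.random() < noise:
                        seq[p] = AA[int(rng.integers(0, 20))]
                out[f"{tag}{i}"] = "".join(seq)
            return out

        aln = noisy(anc1, "a", n_per_clade)
        aln.update(noisy(anc2, "b", n_per_clade))
        return aln

    def test_separated_clades_get_high_support(self):
        rng = np.random.default_rng(21)
        aln = self._clade_alignment(rng)
        tree = bootstrap_tree(aln, reps=100, seed=5)
        clade_a = frozenset(k for k in aln if k.startswith("a"))
        clade_b = frozenset(k for k in aln if k.startswith("b"))
        supports = {}
        for node in tree.internal_nodes():
            supports[node.leaf_names()] = node.support
        hit = supports.get(clade_a, supports.get(clade_b))
        assert hit is not None and hit >= 0.95

    def test_identical_sequences_collapse_to_a_star(self):
        aln = {f"t{i}": "MKVLWAALLG" * 12 for i in range(6)}
        tree = bootstrap_tree(aln, reps=25, seed=1)
        assert tree.internal_nodes() == []

    def test_supports_invariant_under_taxon_relabeling(self):
        rng = np.random.default_rng(22)
        aln = self._clade_alignment(rng, n_per_clade=3, length=80)
        tree1 = bootstrap_tree(aln, reps=50, seed=9)
        mapping = {k: f"x_{k}" for k in aln}
        aln2 = {mapping[k]: v for k, v in aln.items()}
        tree2 = bootstrap_tree(aln2, reps=50, seed=9)
        sup1 = {frozenset(mapping[n] for n in node.leaf_names()): node.support
                for node in tree1.internal_nodes()}
        sup2 = {node.leaf_names(): node.support
                for node in tree2.internal_nodes()}
        assert sup1 == sup2


class TestProgressiveMsa:
    def test_alignment_columns_equal_and_ungapping_recovers_inputs(self):
        rng = np.random.default_rng(31)
        base = _rand_prot(rng, 100)
        records = []
        for i in range(6):
            seq = list(base)
            if i % 2:
                del seq[40:43]  # indel
            records.append(ProteinRecord(f"t{i}", "".join(seq)))
        msa = progressive_msa(records)
        lengths = {len(v) for v in msa.values()}
        assert len(lengths) == 1
        for rec in records:
            assert msa[rec.id].replace("-", "") == rec.sequence


class TestAssignSubgroups:
    def _toy_tree(self):
        # supported clades: {a1,a2,b1,b2} (0.95) with children {a1,a2} (0.9)
        # and {b1,b2} (0.4, unsupported); {c1,c2} (0.95)
        a = TreeNode(support=0.9, children=[TreeNode(name="a1"), TreeNode(name="a2")])
        b = TreeNode(support=0.4, children=[TreeNode(name="b1"), TreeNode(name="b2")])
        ab = TreeNode(support=0.95, children=[a, b])
        c = TreeNode(support=0.95, children=[TreeNode(name="c1"), TreeNode(name="c2")])
        return Tree(root=TreeNode(children=[ab, c, TreeNode(name="out")]))

    def test_clusters_sharing_a_supported_clade_merge(self):
        # three clusters; the b-cluster's smallest supported envelope is the
        # {a,b} clade, which is also the a-cluster's envelope once b1 joins it
        tree = self._toy_tree()
        clusters = [{"a1", "a2", "b1"}, {"b2"}, {"c1", "c2"}]
        cfg = RunConfig(subgroup_support=0.7)
        full = {g: True for g in "a1 a2 b1 b2 c1 c2 out".split()}
        assign = assign_subgroups(clusters, tree, full, cfg)
        # hand application: cluster1 spans a1,a2,b1 -> envelope {a1,a2,b1,b2};
        # singleton b2 has no cluster >= 2 so it is assigned by best hit /
        # none; c-cluster envelope {c1,c2}.  Two seeded subgroups result.
        labels = assign.labels
        assert labels["a1"] == labels["a2"] == labels["b1"]
        assert labels["c1"] == labels["c2"] != labels["a1"]

    def test_leftover_without_hits_goes_to_none_grouping(self):
        tree = self._toy_tree()
        clusters = [{"a1", "a2"}, {"c1", "c2"}, {"b1"}]
        cfg = RunConfig()
        full = {g: True for g in "a1 a2 c1 c2 b1".split()}
        assign = assign_subgroups(clusters, tree, full, cfg, proteins=None)
        assert assign.labels["b1"] == NONE_GROUP
        assert assign.provenance["b1"] == "none"

    def test_partial_gene_assigned_by_best_hit(self):
        tree = self._toy_tree()
        rng = np.random.default_rng(41)
        seq_a = _rand_prot(rng, 120)
        seq_c = _rand_prot(rng, 120)
        prots = {
            "a1": ProteinRecord("a1", seq_a),
            "a2": ProteinRecord("a2", seq_a),
            "c1": ProteinRecord("c1", seq_c),
            "c2": ProteinRecord("c2", seq_c),
            "p1": ProteinRecord("p1", seq_c[:80]),  # partial copy of the c core
        }
        clusters = [{"a1", "a2"}, {"c1", "c2"}, {"p1"}]
        cfg = RunConfig()
        full = {g: g != "p1" for g in prots}
        assign = assign_subgroups(clusters, tree, full, cfg, proteins=prots)
        assert assign.labels["p1"] == assign.labels["c1"]
        assert assign.provenance["p1"] == "best-hit"

    def test_labels_partition_every_input_gene(self, pipeline_result):
        assign = pipeline_result["assignment"]
        calls = pipeline_result["calls"]
        assert set(assign.labels) == set(calls)
        assert all(isinstance(v, str) and v for v in assign.labels.values())


class TestBackfill:
    def test_cn_gene_in_tir_subgroup_becomes_tn(self):
        from nlr_evolkit.motif_scan import NbDomainCall, classify_architecture
        from nlr_evolkit.classify import SubgroupAssignment

        nb = NbDomainCall(True, (1, 200), 4, 4)
        calls = {
            "t1": classify_architecture("t1", nb, True, False, False, "tir"),
            "t2": classify_architecture("t2", nb, True, False, False, "tir"),
            "x": classify_architecture("x", nb, False, True, False, "cc"),
        }
        assign = SubgroupAssignment(
            labels={"t1": "G1", "t2": "G1", "x": "G1"},
            provenance={k: "cluster" for k in calls},
        )
        updated = backfill_nb_lineage(assign, calls)
        assert updated["x"].type_label == "TN"
        assert updated["x"].nb_lineage == "tir"

    def test_lrr_less_gene_gets_subgroup_lineage(self):
        from nlr_evolkit.motif_scan import NbDomainCall, classify_architecture
        from nlr_evolkit.classify import SubgroupAssignment

        nb = NbDomainCall(True, (1, 200), 4, 4)
        calls = {
            "c1": classify_architecture("c1", nb, False, True, True, "cc"),
            "n1": classify_architecture("n1", nb, False, False, False),
        }
        assert calls["n1"].type_label == "N_unassigned"
        assign = SubgroupAssignment(
            labels={"c1": "G1", "n1": "G1"},
            provenance={"c1": "cluster", "n1": "cluster"},
        )
        updated = backfill_nb_lineage(assign, calls)
        assert updated["n1"].type_label == "N_cc"

    def test_none_grouping_gene_is_untouched(self):
        from nlr_evolkit.motif_scan import NbDomainCall, classify_architecture
        from nlr_evolkit.classify import SubgroupAssignment

        nb = NbDomainCall(True, (1, 200), 4, 4)
        calls = {"n1": classify_architecture("n1", nb, False, False, False)}
        assign = SubgroupAssignment(labels={"n1": NONE_GROUP},
                                    provenance={"n1": "none"})
        updated = backfill_nb_lineage(assign, calls)
        assert updated["n1"].type_label == "N_unassigned"
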