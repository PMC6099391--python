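"""IUPAC-aware distances, NJ reconstruction, bootstrap, clade partition."""

import numpy as np
import pytest
from skbio import TreeNode

from codonits import phylogeny as ph


@pytest.fixture(scope="module")
def type_tree(type_sequences):
    return ph.nj_tree(ph.distance_matrix(type_sequences))


def random_additive_tree(labels, rng):
    """Random binary topology with positive branch lengths (newick text)."""
    nodes = [(lbl, {lbl}) for lbl in labels]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        (na, sa), (nb, sb) = nodes[j], nodes[i]
        la, lb = rng.uniform(0.05, 1.0, size=2)
        merged = (f"({na}:{la:.4f},{nb}:{lb:.4f})", sa | sb)
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)]
        nodes.append(merged)
    return TreeNode.read([nodes[0][0] + ";"])


class TestDistances:
    def test_site_mismatch_cases(self):
        assert ph.site_mismatch("A", "A") == 0.0
        assert ph.site_mismatch("A", "G") == 1.0
        assert ph.site_mismatch("C", "Y") == 0.5  # one of two alleles shared
        assert ph.site_mismatch("Y", "Y") == 0.0

    def test_published_example_distances(self, type_sequences):
        d = ph.pairwise_distance
        assert d(type_sequences["P0"], type_sequences["P0"]) == 0.0
        assert d(type_sequences["P0"], type_sequences["S0"]) == pytest.approx(2 / 655)
        assert d(type_sequences["P0"], type_sequences["P1"]) == pytest.approx(1 / 655)

    def test_metric_axioms_on_the_full_panel(self, type_sequences):
        labels = sorted(type_sequences)
        dm = ph.distance_matrix(type_sequences)
        m = dm.data
        assert np.allclose(m, m.T)
        assert np.all(np.diag(m) == 0)
        assert np.all(m >= 0)
        for i in range(len(labels)):
            for j in range(len(labels)):
                for k in range(len(labels)):
                    assert m[i, j] <= m[i, k] + m[k, j] + 1e-12

    def test_jc69_exceeds_p_distance(self, type_sequences):
        p = ph.pairwise_distance(type_sequences["P0"], type_sequences["T0"], "p")
        jc = ph.pairwise_distance(type_sequences["P0"], type_sequences["T0"],
                                  "jc69")
        assert jc > p > 0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ph.pairwise_distance("ACGT", "ACG")


class TestNJ:
    def test_three_taxa_star(self):
        dm = ph.distance_matrix({"a": "AAAA", "b": "AATT", "c": "TTTT"})
        tree = ph.nj_tree(dm)
        assert {t.name for t in tree.tips()} == {"a", "b", "c"}
        assert ph.bipartitions(tree) == set()  # no internal edge on 3 taxa

    def test_recovers_random_additive_trees(self):
        # oracle: NJ is exact on additive (tree-realizable) distances
        rng = np.random.default_rng(7)
        labels = [f"x{i}" for i in range(8)]
        for _ in range(200):
            true_tree = random_additive_tree(labels, rng)
            dm = true_tree.tip_tip_distances(labels)
            est = ph.nj_tree(dm)
            assert ph.robinson_foulds(est, true_tree) == 0

    def test_label_order_invariance_on_generic_distances(self):
        # generic (tie-free) branch lengths make the NJ topology unique,
        # so the input ordering of the taxa must not matter
        from skbio import DistanceMatrix
        rng = np.random.default_rng(11)
        labels = [f"x{i}" for i in range(8)]
        true_tree = random_additive_tree(labels, rng)
        dm = true_tree.tip_tip_distances(labels)
        base = ph.bipartitions(ph.nj_tree(dm))
        perm = list(reversed(labels))
        data = [[dm[a, b] for b in perm] for a in perm]
        other = ph.bipartitions(ph.nj_tree(DistanceMatrix(data, perm)))
        assert base == other

    def test_tangshen_types_are_siblings(self, type_tree):
        assert frozenset({"T0", "T1"}) in ph.bipartitions(type_tree)

    def test_rf_zero_iff_same_topology(self, type_tree, type_sequences):
        assert ph.robinson_foulds(type_tree, type_tree) == 0
        star = ph.nj_tree(ph.distance_matrix(
            {k: type_sequences[k] for k in ("P0", "S0", "T0")}))
        # different leaf sets are a usage error
        with pytest.raises(ValueError):
            ph.robinson_foulds(type_tree, star)


class TestBootstrap:
    def test_identical_sequence_pair_gets_full_support(self):
        rng = np.random.default_rng(3)
        base = "".join(rng.choice(list("ACGT"), size=200))
        seqs = {"a": base, "b": base,
                "c": base[:100] + base[:100][::-1],
                "d": "".join(rng.choice(list("ACGT"), size=200)),
                "e": "".join(rng.choice(list("ACGT"), size=200))}
        _, support = ph.bootstrap_support(seqs, replicates=100, seed=0)
        assert support[frozenset({"a", "b"})] == 100.0

    def test_single_replicate_support_is_binary(self, type_sequences):
        _, support = ph.bootstrap_support(type_sequences, replicates=1, seed=5)
        assert set(support.values()) <= {0.0, 100.0}

    def test_tangshen_cherry_strongly_supported(self, type_sequences):
        tree, support = ph.bootstrap_support(type_sequences, replicates=200,
                                             seed=1)
        assert support[frozenset({"T0", "T1"})] > 50.0
        # the support value is painted onto the tree as a node label
        labels = {n.name for n in tree.non_tips()} - {None}
        assert f"{support[frozenset({'T0', 'T1'})]:.0f}" in labels

    def test_zero_replicates_rejected(self, type_sequences):
        with pytest.raises(ValueError):
            ph.bootstrap_support(type_sequences, replicates=0)


class TestCladePartition:
    def test_tangshen_partition(self, type_tree, type_sequences):
        inside, outside = ph.clade_partition(type_tree, {"T0", "T1"})
        assert inside == {"T0", "T1"}
        assert outside == set(type_sequences) - {"T0", "T1"}

    def test_inside_plus_outside_cover_all_leaves(self, type_tree,
                                                  type_sequences):
        inside, outside = ph.clade_partition(type_tree, {"P0", "S0"})
        assert inside | outside == set(type_sequences)
        assert inside & outside == set()
        assert {"P0", "S0"} <= inside

    def test_reference_validation(self, type_tree, type_sequences):
        with pytest.raises(ValueError, match="non-empty"):
            ph.clade_partition(type_tree, set())
        with pytest.raises(ValueError, match="unknown"):
            ph.clade_partition(type_tree, {"ZZ"})
        with pytest.raises(ValueError, match="every leaf"):
            ph.clade_partition(type_tree, set(type_sequences))


class TestWriters:
    def test_newick_round_trip(self, type_tree, tmp_path):
        path = tmp_path / "tree.nwk"
        ph.write_newick(type_tree, path)
        back = TreeNode.read(str(path))
        assert ph.robinson_foulds(back, type_tree) == 0

    def test_phylip_matrix_is_text_and_complete(self, type_sequences,
                                                tmp_path):
        path = tmp_path / "d.phylip"
        ph.write_phylip(ph.distance_matrix(type_sequences), path)
        lines = path.read_text().splitlines()
        assert lines[0].strip() == str(len(type_sequences))
        assert len(lines) == len(type_sequences) + 1
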