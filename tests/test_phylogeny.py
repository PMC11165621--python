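import itertools

import numpy as np
import pandas as pd
import pytest

from phagetax.phylogeny import (Alignment, bootstrap, concatenate, distance_matrix,
                                midpoint_root, nj_tree, progressive_align,
                                sum_of_pairs, support_of_clade)


def brute_force_3way_sp(s1, s2, s3):
    """Exhaustive 3-sequence alignment DP maximising identity sum-of-pairs."""
    n1, n2, n3 = len(s1), len(s2), len(s3)
    NEG = -1e9
    D = np.full((n1 + 1, n2 + 1, n3 + 1), NEG)
    D[0, 0, 0] = 0.0
    moves = [m for m in itertools.product((0, 1), repeat=3) if any(m)]
    for i in range(n1 + 1):
        for j in range(n2 + 1):
            for k in range(n3 + 1):
                if D[i, j, k] == NEG:
                    continue
                for a, b, c in moves:
                    ni, nj, nk = i + a, j + b, k + c
                    if ni > n1 or nj > n2 or nk > n3:
                        continue
                    col = [s1[i] if a else None, s2[j] if b else None, s3[k] if c else None]
                    score = sum(1 for x, y in itertools.combinations(col, 2)
                                if x is not None and y is not None and x == y)
                    if D[i, j, k] + score > D[ni, nj, nk]:
                        D[ni, nj, nk] = D[i, j, k] + score
    return D[n1, n2, n3]


class TestProgressiveAlign:
    def test_single_sequence(self):
        aln = progressive_align({"a": "MKLV"})
        assert aln.ids == ["a"] and aln.rows == ["MKLV"]

    def test_identical_sequences_gapless(self):
        aln = progressive_align({"a": "MKLVD", "b": "MKLVD", "c": "MKLVD"})
        assert set(aln.rows) == {"MKLVD"}

    def test_degapping_recovers_inputs(self):
        seqs = {"a": "MKLVDERT", "b": "MKLDERT", "c": "MKLVDGERT"}
        aln = progressive_align(seqs)
        for taxon, seq in seqs.items():
            assert aln.degapped(taxon) == seq

    def test_sum_of_pairs_near_optimal(self):
        # short peptides keep the exhaustive 3D DP oracle tractable
        cases = [
            ("MKLVDE", "MKLDE", "MKLVDG"),
            ("ACDEFG", "ACEFG", "ACDEG"),
            ("MWYYKL", "MWYKL", "WYYKLD"),
        ]
        for s1, s2, s3 in cases:
            aln = progressive_align({"a": s1, "b": s2, "c": s3})
            got = sum_of_pairs(aln)
            best = brute_force_3way_sp(s1, s2, s3)
            assert got >= 0.9 * best, (s1, s2, s3, got, best)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            progressive_align({})


class TestConcatenate:
    def test_full_blocks(self):
        a1 = Alignment(ids=["g1|p1", "g2|p2"], rows=["MKL", "MKL"])
        a2 = Alignment(ids=["g1|p3", "g2|p4"], rows=["DERT", "DE-T"])
        gmap = {"g1|p1": "g1", "g2|p2": "g2", "g1|p3": "g1", "g2|p4": "g2"}
        cat, parts = concatenate([("c1", a1), ("c2", a2)], gmap)
        assert cat.ids == ["g1", "g2"]
        assert cat.rows == ["MKLDERT", "MKLDE-T"]
        assert parts.to_dict("records") == [
            {"cluster_id": "c1", "start": 1, "end": 3},
            {"cluster_id": "c2", "start": 4, "end": 7},
        ]

    def test_missing_genome_gets_gap_block(self):
        a1 = Alignment(ids=["g1|p1", "g2|p2"], rows=["MKL", "MKL"])
        a2 = Alignment(ids=["g1|p3"], rows=["DERT"])
        gmap = {"g1|p1": "g1", "g2|p2": "g2", "g1|p3": "g1"}
        cat, _ = concatenate([("c1", a1), ("c2", a2)], gmap)
        assert cat.row("g2") == "MKL----"

    def test_genome_absent_everywhere_errors(self):
        # a genome in the universe but in no cluster would be an all-gap row
        a1 = Alignment(ids=["g1|p1"], rows=["MKL"])
        with pytest.raises(ValueError, match="absent from every cluster"):
            concatenate([("c1", a1)], {"g1|p1": "g1"}, genomes=["g1", "g2"])
        # duplicate representative is also rejected
        bad = Alignment(ids=["g1|p1", "g1|p2"], rows=["MKL", "MKL"])
        with pytest.raises(ValueError, match="multiple representatives"):
            concatenate([("c1", bad)], {"g1|p1": "g1", "g1|p2": "g1"})


class TestDistances:
    def test_identical_rows_zero(self):
        aln = Alignment(ids=["a", "b"], rows=["MKLV", "MKLV"])
        assert distance_matrix(aln).loc["a", "b"] == 0.0

    def test_poisson_closed_form(self):
        # 1 mismatch over 10 comparable columns: d = -ln(0.9)
        aln = Alignment(ids=["a", "b"], rows=["MKLVDERTWY", "MKLVDERTWF"])
        d = distance_matrix(aln).loc["a", "b"]
        assert d == pytest.approx(-np.log(0.9), abs=1e-9)

    def test_pairwise_deletion_ignores_gap_columns(self):
        aln = Alignment(ids=["a", "b"], rows=["MK-VD", "MKLVD"])
        assert distance_matrix(aln).loc["a", "b"] == 0.0

    def test_no_comparable_columns_errors(self):
        aln = Alignment(ids=["a", "b"], rows=["M-", "-K"])
        with pytest.raises(ValueError, match="no comparable columns"):
            distance_matrix(aln)

    def test_symmetric_zero_diagonal(self):
        aln = Alignment(ids=["a", "b", "c"], rows=["MKLV", "MKIV", "MRIV"])
        D = distance_matrix(aln)
        assert np.allclose(D, D.T) and np.allclose(np.diag(D), 0)


def random_additive_matrix(n_taxa, rng):
    """Distances from a random binary tree with positive branch lengths."""
    import dendropy

    taxa = [f"t{i}" for i in range(n_taxa)]
    ns = dendropy.TaxonNamespace(taxa)
    tree = dendropy.simulate.treesim.birth_death_tree(
        birth_rate=1.0, death_rate=0.0, num_extant_tips=n_taxa, taxon_namespace=ns,
        rng=rng)
    for e in tree.preorder_edge_iter():
        if e.head_node.parent_node is not None:
            e.length = rng.uniform(0.05, 0.5)
    pdm = tree.phylogenetic_distance_matrix()
    D = pd.DataFrame(0.0, index=taxa, columns=taxa)
    for a, b in itertools.combinations(ns, 2):
        d = pdm.patristic_distance(a, b)
        D.loc[a.label, b.label] = D.loc[b.label, a.label] = d
    return D, tree


class TestNeighborJoining:
    def test_two_taxa(self):
        D = pd.DataFrame([[0, 0.3], [0.3, 0]], index=["a", "b"], columns=["a", "b"])
        tree = nj_tree(D)
        tips = list(tree.tips())
        assert sum(t.length for t in tips) == pytest.approx(0.3)

    def test_three_taxa_closed_form(self):
        dab, dac, dbc = 0.4, 0.6, 0.8
        D = pd.DataFrame([[0, dab, dac], [dab, 0, dbc], [dac, dbc, 0]],
                         index=list("abc"), columns=list("abc"))
        tree = nj_tree(D)
        dist_a = tree.find("a").length + (tree.find("a").parent.length or 0)
        # terminal branch of a = (d_ab + d_ac - d_bc) / 2 = 0.1
        lengths = {t.name: t.length for t in tree.tips()}
        # path a-b must equal d_ab exactly (NJ is exact for 3 taxa)
        assert tree.find("a").distance(tree.find("b")) == pytest.approx(dab)
        assert tree.find("a").distance(tree.find("c")) == pytest.approx(dac)
        assert tree.find("b").distance(tree.find("c")) == pytest.approx(dbc)

    @pytest.mark.parametrize("n_taxa", [5, 8])
    def test_additive_matrix_recovered_exactly(self, n_taxa):
        import random as pyrandom

        rng = pyrandom.Random(42 + n_taxa)
        D, true_tree = random_additive_matrix(n_taxa, rng)
        tree = nj_tree(D)
        # additivity: every pairwise path length is reproduced exactly
        for a, b in itertools.combinations(D.columns, 2):
            assert tree.find(a).distance(tree.find(b)) == pytest.approx(D.loc[a, b], abs=1e-9)

    def test_matches_independent_nj_topology(self):
        from skbio import DistanceMatrix
        from skbio.tree import nj as skbio_nj

        rng = np.random.default_rng(11)
        n = 7
        ids = [f"t{i}" for i in range(n)]
        X = rng.uniform(0.1, 1.0, size=(n, 3))
        D = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(-1))
        np.fill_diagonal(D, 0)
        ours = nj_tree(pd.DataFrame(D, index=ids, columns=ids))
        theirs = skbio_nj(DistanceMatrix(D, ids))
        assert ours.compare_rfd(theirs) == 0.0

    def test_asymmetric_input_errors(self):
        D = pd.DataFrame([[0, 1.0], [2.0, 0]], index=["a", "b"], columns=["a", "b"])
        with pytest.raises(ValueError, match="symmetric"):
            nj_tree(D)


def two_clade_alignment(n_cols=1000, seed=0):
    """Six taxa in two clearly separated 3-taxon clades."""
    rng = np.random.default_rng(seed)
    aas = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
    anc1 = rng.choice(aas, size=n_cols)
    anc2 = rng.choice(aas, size=n_cols)  # unrelated ancestor: long internal edge

    def descend(anc, p):
        child = anc.copy()
        mask = rng.random(n_cols) < p
        child[mask] = rng.choice(aas, size=int(mask.sum()))
        return child

    rows = [descend(anc1, 0.05) for _ in range(3)] + [descend(anc2, 0.05) for _ in range(3)]
    return Alignment(ids=[f"a{i}" for i in range(3)] + [f"b{i}" for i in range(3)],
                     rows=["".join(r) for r in rows])


class TestBootstrap:
    def test_clear_split_gets_full_support(self):
        aln = two_clade_alignment()
        tree = bootstrap(aln, n_reps=50, seed=3)
        assert support_of_clade(tree, {"a0", "a1", "a2"}) == 100.0 or \
            support_of_clade(tree, {"b0", "b1", "b2"}) == 100.0

    def test_supports_in_range_and_deterministic(self):
        aln = two_clade_alignment(n_cols=300, seed=5)
        t1 = bootstrap(aln, n_reps=30, seed=9)
        t2 = bootstrap(aln, n_reps=30, seed=9)
        assert str(t1) == str(t2)
        for node in t1.non_tips():
            if node.name:
                assert 0.0 <= float(node.name) <= 100.0

    def test_invalid_reps(self):
        with pytest.raises(ValueError):
            bootstrap(two_clade_alignment(n_cols=50), n_reps=0)


class TestMidpointRoot:
    def test_two_leaf_symmetric(self):
        from skbio import TreeNode

        tree = TreeNode.read(["(a:1.0,b:1.0);"])
        rooted = midpoint_root(tree)
        lengths = sorted(t.length for t in rooted.tips())
        assert lengths == pytest.approx([1.0, 1.0])

    def test_caterpillar_diameter(self):
        from skbio import TreeNode

        # diameter path a-d of length 0.5+1+1+0.5 = 3; midpoint at 1.5 from a
        tree = TreeNode.read(["((a:0.5,b:0.1):1.0,(c:0.1,d:0.5):1.0);"])
        rooted = midpoint_root(tree)
        depths = {t.name: rooted.find(t.name).accumulate_to_ancestor(rooted)
                  for t in rooted.tips()}
        assert depths["a"] == pytest.approx(1.5)
        assert depths["d"] == pytest.approx(1.5)

    def test_rerooting_preserves_pairwise_distances(self):
        aln = two_clade_alignment(n_cols=200, seed=8)
        tree = nj_tree(distance_matrix(aln))
        rooted = midpoint_root(tree.copy())
        for a, b in itertools.combinations([t.name for t in tree.tips()], 2):
            before = tree.find(a).distance(tree.find(b))
            after = rooted.find(a).distance(rooted.find(b))
            assert after == pytest.approx(before, abs=1e-9)


class TestNewickRoundTrip:
    def test_topology_lengths_supports_preserved(self, tmp_path):
        aln = two_clade_alignment(n_cols=300, seed=12)
        tree = midpoint_root(bootstrap(aln, n_reps=20, seed=1))
        path = tmp_path / "t.nwk"
        tree.write(str(path))
        from skbio import TreeNode

        back = TreeNode.read(str(path))
        assert back.compare_rfd(tree) == 0.0
        assert sorted(round(t.length, 6) for t in back.tips()) == \
            sorted(round(t.length, 6) for t in tree.tips())
        assert {n.name for n in back.non_tips() if n.name} == \
            {n.name for n in tree.non_tips() if n.name}
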