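import itertools

import numpy as np
import pytest
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from pansv.haplotypes import MISSING_IDX
from pansv.phylogeny import (
    Dendrogram, classify_topology, intersection_sets,
    pairwise_discordance, upgma,
)

from _oracles import (
    all_rooted_topologies, nested_clades, triple_loop_discordance,
)
from test_haplotypes import mk_matrix


class TestDiscordance:
    def test_identical_columns_give_zero(self):
        mat = mk_matrix([[1, 1], [0, 0], [2, 2]])
        d = pairwise_discordance(mat)
        assert np.all(d.D == 0)
        assert np.all(d.n_sites_used == [[0, 3], [3, 0]])

    def test_single_differing_bubble_counts_once(self):
        mat = mk_matrix([[0, 1]])
        d = pairwise_discordance(mat)
        assert d.D[0, 1] == d.D[1, 0] == 1

    def test_missing_entries_are_pairwise_skipped(self):
        mat = mk_matrix([[0, MISSING_IDX], [0, 1]])
        d = pairwise_discordance(mat)
        assert d.D[0, 1] == 1 and d.n_sites_used[0, 1] == 1

    def test_equals_triple_loop_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(20):
            ent = rng.integers(0, 3, size=(200, 5))
            ent[rng.random((200, 5)) < 0.10] = MISSING_IDX
            got = pairwise_discordance(mk_matrix(ent))
            assert np.array_equal(got.D, triple_loop_discordance(ent))

    def test_restrict_chrom(self):
        keys = [("chr1", 0, 5), ("chr2", 0, 5)]
        mat = mk_matrix([[0, 1], [0, 1]])
        mat.bubble_keys = keys
        d = pairwise_discordance(mat, restrict_chrom="chr2")
        assert d.D[0, 1] == 1
        with pytest.raises(ValueError, match="unknown chromosome"):
            pairwise_discordance(mat, restrict_chrom="chrX")

    def test_normalized_mode(self):
        mat = mk_matrix([[0, 1], [0, 1], [0, 0], [0, 0]])
        d = pairwise_discordance(mat, normalize=True)
        assert d.D[0, 1] == pytest.approx(0.5)


class TestUpgma:
    def test_two_leaves_merge_at_half_distance(self):
        t = upgma(np.array([[0.0, 10.0], [10.0, 0.0]]), labels=["A", "B"])
        assert t.merges == [(0, 1, 5.0)]

    def test_hand_computed_four_leaf_merge_sequence(self):
        # d(AB)=2, d(AC)=d(BC)=8, d(A/B/C, D)=12
        D = np.array([[0, 2, 8, 12],
                      [2, 0, 8, 12],
                      [8, 8, 0, 12],
                      [12, 12, 12, 0]], dtype=float)
        t = upgma(D, labels=list("ABCD"))
        heights = {frozenset(c): h for c, h in t.clade_heights().items()}
        assert heights[frozenset("AB")] == 1
        assert heights[frozenset("ABC")] == 4
        assert heights[frozenset("ABCD")] == 6

    def test_ultrametric_input_recovered_exactly(self):
        rng = np.random.default_rng(23)
        for _ in range(20):
            # random ultrametric: random topology with increasing heights
            labels = list("ABCDEF")
            rng.shuffle(labels)
            clusters = [[x] for x in labels]
            heights = np.cumsum(rng.uniform(0.5, 2.0, size=len(labels) - 1))
            true_h = {}
            k = 0
            while len(clusters) > 1:
                i, j = sorted(rng.choice(len(clusters), 2, replace=False))
                merged = clusters[i] + clusters[j]
                for a in clusters[i]:
                    for b in clusters[j]:
                        true_h[frozenset((a, b))] = heights[k]
                clusters = [c for idx, c in enumerate(clusters)
                            if idx not in (i, j)] + [merged]
                k += 1
            labs = sorted(labels)
            D = np.zeros((6, 6))
            for x, y in itertools.combinations(range(6), 2):
                D[x, y] = D[y, x] = 2 * true_h[frozenset((labs[x], labs[y]))]
            t = upgma(D, labels=labs)
            # cophenetic distances of the recovered tree equal the input
            heights = t.clade_heights()
            for x, y in itertools.combinations(range(6), 2):
                pair = {labs[x], labs[y]}
                coph = min(h for c, h in heights.items() if pair <= c)
                assert 2 * coph == pytest.approx(D[x, y])

    def test_matches_scipy_average_linkage(self):
        """On distance matrices without ties the merge heights and clades
        agree with scipy's average-linkage implementation."""
        rng = np.random.default_rng(31)
        for _ in range(20):
            n = 6
            d = rng.uniform(1, 100, size=n * (n - 1) // 2)
            D = squareform(d)
            labels = [f"L{i}" for i in range(n)]
            ours = upgma(D, labels=labels)
            Z = hierarchy.linkage(d, method="average")
            scipy_heights = sorted(Z[:, 2] / 2.0)
            our_heights = sorted(h for _, _, h in ours.merges)
            assert np.allclose(our_heights, scipy_heights)
            scipy_clades = set()
            members = [frozenset([labels[i]]) for i in range(n)]
            for a, b, _h, _c in Z:
                members.append(members[int(a)] | members[int(b)])
                scipy_clades.add(members[-1])
            assert {c for c in ours.clades() if len(c) > 1} == scipy_clades

    def test_deterministic_tie_break(self):
        D = np.array([[0, 4, 4], [4, 0, 4], [4, 4, 0]], dtype=float)
        t = upgma(D, labels=["C", "A", "B"])
        # ties resolved toward the lexicographically smallest label pair
        mem = t.members()
        first_merge = mem[3]
        assert first_merge == frozenset(("A", "B"))

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            upgma(np.array([[0.0, 1.0], [2.0, 0.0]]), labels=["A", "B"])

    def test_newick_round_trips_through_dendropy(self):
        import dendropy

        D = np.array([[0, 2, 8], [2, 0, 8], [8, 8, 0]], dtype=float)
        t = upgma(D, labels=["A", "B", "C"])
        tree = dendropy.Tree.get(data=t.newick(), schema="newick")
        assert {lf.taxon.label for lf in tree.leaf_node_iter()} == {"A", "B", "C"}


def dendrogram_from_nested(nested, leaves):
    """Build a Dendrogram (heights by subtree depth) from nested tuples."""
    labels = list(leaves)
    merges = []
    counter = [len(labels)]

    def rec(node):
        if isinstance(node, str):
            return labels.index(node), 0
        (ia, ha), (ib, hb) = rec(node[0]), rec(node[1])
        h = max(ha, hb) + 1
        merges.append((ia, ib, float(h)))
        cid = counter[0]
        counter[0] += 1
        return cid, h

    rec(nested)
    order = sorted(range(len(merges)), key=lambda i: merges[i][2])
    remap = {}
    for new, old in enumerate(order):
        remap[len(labels) + old] = len(labels) + new
    fixed = [(remap.get(a, a), remap.get(b, b), h)
             for a, b, h in (merges[i] for i in order)]
    return Dendrogram(labels, fixed)


class TestTopology:
    OUT = ["G", "N"]
    IN = ["O", "P", "B"]

    def test_o_out_arrangement(self):
        t = dendrogram_from_nested(((("O", ("P", "B")), "N"), "G"), "OPBNG")
        assert classify_topology(t, self.OUT, self.IN) == "O_OUT"

    def test_n_outermost_is_other(self):
        t = dendrogram_from_nested(((("O", ("P", "B")), "G"), "N"), "OPBNG")
        assert classify_topology(t, self.OUT, self.IN) == "OTHER"

    def test_label_mismatch_raises(self):
        t = dendrogram_from_nested((("X", "Y"), "Z"), "XYZ")
        with pytest.raises(ValueError):
            classify_topology(t, self.OUT, self.IN)

    def test_exhaustive_over_all_105_topologies(self):
        """Classification agrees with a direct clade-membership check on
        every labeled rooted 5-leaf topology."""
        tops = all_rooted_topologies("OPBNG")
        assert len(tops) == 105
        for nested in tops:
            t = dendrogram_from_nested(nested, "OPBNG")
            clades = nested_clades(nested)
            if frozenset("OPBN") in clades and frozenset("OPB") in clades:
                rest = [x for x in "OPB"
                        if frozenset(set("OPB") - {x}) in clades]
                want = f"{rest[0]}_OUT"
            else:
                want = "OTHER"
            assert classify_topology(t, self.OUT, self.IN) == want


class TestIntersectionSets:
    def test_full_set_and_all_reference(self):
        mat = mk_matrix([[1, 1, 1, 1], [0, 0, 0, 0]],
                        assemblies=list("WXYZ"))
        s = intersection_sets(mat)
        assert s.counts == {frozenset("WXYZ"): 1}
        assert s.total == 1

    def test_missing_entries_rejected(self):
        mat = mk_matrix([[MISSING_IDX, 1]])
        with pytest.raises(ValueError, match="filter_complete"):
            intersection_sets(mat)

    def test_counts_equal_brute_force(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            ent = rng.integers(0, 2, size=(100, 4))
            mat = mk_matrix(ent, assemblies=list("WXYZ"))
            got = intersection_sets(mat)
            want = {}
            for row in ent:
                s = frozenset(a for a, v in zip("WXYZ", row) if v != 0)
                if s:
                    want[s] = want.get(s, 0) + 1
            assert got.counts == want
            assert got.total == sum(1 for row in ent if row.any())

    def test_discordance_consistency_on_biallelic_matrix(self):
        """D[i,j] decomposes into the intersection-set categories."""
        rng = np.random.default_rng(9)
        ent = rng.integers(0, 2, size=(300, 4))
        mat = mk_matrix(ent, assemblies=list("WXYZ"))
        D = pairwise_discordance(mat).D
        sets = intersection_sets(mat).counts
        labels = list("WXYZ")
        for i, j in itertools.combinations(range(4), 2):
            a, b = labels[i], labels[j]
            want = sum(c for s, c in sets.items()
                       if (a in s) != (b in s))
            assert D[i, j] == want
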