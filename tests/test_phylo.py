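"""Distance matrices, NJ, newick I/O, MSA, bootstrap and tree comparison."""

import itertools

import dendropy
import numpy as np
import pytest
from Bio.Align import substitution_matrices

from capsidphylo.phylo import (
    DistanceMatrix,
    Msa,
    all_vs_all_matrix,
    bootstrap_support,
    host_monophyly,
    nj_build,
    pdistance_matrix,
    progressive_msa,
    read_newick,
    rf_distance,
    write_newick,
)
from capsidphylo.simdata import (
    evolve_sequences,
    evolve_structures,
    helix_fold,
    sample_tree,
)
from capsidphylo.structio import SequenceRecord

BLOSUM62 = substitution_matrices.load("BLOSUM62")


def additive_matrix(tree):
    """Patristic distances of a tree, labels sorted (independent of NJ)."""
    dt = tree.dendropy_tree
    pdm = dt.phylogenetic_distance_matrix()
    labels = sorted(l.taxon.label for l in dt.leaf_node_iter())
    tx = {t.label: t for t in dt.taxon_namespace}
    n = len(labels)
    d = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        d[i, j] = d[j, i] = pdm.patristic_distance(tx[labels[i]], tx[labels[j]])
    return DistanceMatrix(labels, d)


class TestDistanceMatrix:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            DistanceMatrix(["a", "b"], np.array([[0, 1], [2, 0]]))  # asymmetric
        with pytest.raises(ValueError):
            DistanceMatrix(["a", "b"], np.array([[0, -1], [-1, 0]]))  # negative
        with pytest.raises(ValueError):
            DistanceMatrix(["a", "a"], np.zeros((2, 2)))  # duplicate labels

    def test_phylip_round_trip(self, rng):
        n = 5
        m = rng.uniform(0.1, 3, size=(n, n))
        d = (m + m.T) / 2
        np.fill_diagonal(d, 0)
        dm = DistanceMatrix([f"L{i}" for i in range(n)], d)
        back = DistanceMatrix.from_phylip(dm.to_phylip())
        assert back.labels == dm.labels
        np.testing.assert_allclose(back.d, dm.d, rtol=1e-6)


class TestNj:
    def test_three_taxon_analytic_case(self):
        dm = DistanceMatrix(["A", "B", "C"], np.array([[0, 2, 3], [2, 0, 4], [3, 4, 0.0]]))
        tree = nj_build(dm)
        lengths = {
            lf.taxon.label: lf.edge.length
            for lf in tree.dendropy_tree.leaf_node_iter()
        }
        assert lengths == pytest.approx({"A": 0.5, "B": 1.5, "C": 2.5})

    def test_recovers_random_additive_trees_exactly(self, rng):
        for _ in range(50):
            n = int(rng.integers(6, 11))
            true = sample_tree(n, int(rng.integers(0, 2**31)))
            dm = additive_matrix(true)
            rec = nj_build(dm)
            assert rf_distance(rec, true) == 0
            np.testing.assert_allclose(additive_matrix(rec).d, dm.d, atol=1e-9)

    def test_tie_broken_toward_earliest_label_pair(self):
        # all distances equal: every Q tied; A and B must be joined first
        d = np.ones((4, 4)) - np.eye(4)
        tree = nj_build(DistanceMatrix(["A", "B", "C", "D"], d))
        sides = tree.bipartitions()
        assert frozenset({"C", "D"}) in sides or frozenset({"A", "B"}) in sides
        # A,B are siblings: their parent's leaf set is exactly {A, B}
        dt = tree.dendropy_tree
        parents = {
            lf.taxon.label: lf.parent_node for lf in dt.leaf_node_iter()
        }
        assert parents["A"] is parents["B"]

    def test_matches_independent_nj_implementation(self, rng):
        # noisy (non-additive) matrix: same topology as scikit-bio's NJ
        import skbio

        n = 8
        true = sample_tree(n, 99)
        dm = additive_matrix(true)
        noise = rng.uniform(0, 0.02, size=dm.d.shape)
        d = dm.d + (noise + noise.T) / 2
        np.fill_diagonal(d, 0)
        mine = nj_build(DistanceMatrix(dm.labels, d))
        sk = skbio.tree.nj(skbio.DistanceMatrix(d, ids=dm.labels))
        theirs = read_newick(str(sk))
        assert rf_distance(mine, theirs) == 0

    def test_rejects_small_or_invalid_input(self):
        with pytest.raises(ValueError):
            nj_build(DistanceMatrix(["a", "b"], np.zeros((2, 2))))


class TestNewick:
    def test_basic_round_trip(self):
        t = read_newick("(A:1,B:2,C:3);")
        assert sorted(t.leaf_labels) == ["A", "B", "C"]
        t2 = read_newick(write_newick(t))
        assert rf_distance(t, t2) == 0

    def test_support_values_preserved(self):
        s = "((A:1,B:1)95:0.5,C:1,D:1);"
        t = read_newick(s)
        assert t.supports() == {frozenset({"C", "D"}): 95.0}
        assert read_newick(write_newick(t)).supports() == t.supports()

    def test_fuzzed_trees_canonical_round_trip(self):
        for seed in range(20):
            t = sample_tree(int(5 + seed % 6), seed)
            s1 = write_newick(t)
            s2 = write_newick(read_newick(s1))
            assert s1 == s2
            assert rf_distance(t, read_newick(s1)) == 0

    def test_unbalanced_parentheses_rejected(self):
        with pytest.raises(ValueError):
            read_newick("((A:1,B:2;")

    def test_duplicate_leaves_rejected(self):
        with pytest.raises(Exception):
            read_newick("(A:1,A:2,B:1);")


class TestRfDistance:
    def test_identical_trees_zero(self):
        t = sample_tree(8, 3)
        assert rf_distance(t, read_newick(write_newick(t))) == 0

    def test_binary_vs_star_four_taxa(self):
        b = read_newick("((A:1,B:1):1,C:1,D:1);")
        star = read_newick("(A:1,B:1,C:1,D:1);")
        assert rf_distance(b, star) == 1

    def test_nni_neighbors_differ_by_two(self):
        # one nearest-neighbor interchange across the A,B|C edge:
        # {A,B} and {A,C} differ, {D,E} is shared
        t1 = read_newick("((A:1,B:1):1,C:1,(D:1,E:1):1);")
        t2 = read_newick("((A:1,C:1):1,B:1,(D:1,E:1):1);")
        assert rf_distance(t1, t2) == 2

    def test_symmetric_and_bounded(self):
        t1, t2 = sample_tree(9, 5), sample_tree(9, 6)
        assert rf_distance(t1, t2) == rf_distance(t2, t1) <= 2 * (9 - 3)

    def test_matches_dendropy_symmetric_difference(self):
        from dendropy.calculate import treecompare

        for s1, s2 in [(11, 12), (13, 14)]:
            t1, t2 = sample_tree(8, s1), sample_tree(8, s2)
            tns = dendropy.TaxonNamespace()
            d1 = dendropy.Tree.get(data=write_newick(t1), schema="newick",
                                   taxon_namespace=tns)
            d2 = dendropy.Tree.get(data=write_newick(t2), schema="newick",
                                   taxon_namespace=tns)
            d1.encode_bipartitions()
            d2.encode_bipartitions()
            assert rf_distance(t1, t2) == treecompare.symmetric_difference(d1, d2)

    def test_leaf_set_mismatch_rejected(self):
        with pytest.raises(ValueError):
            rf_distance(sample_tree(5, 1), sample_tree(6, 1))


class TestHostMonophyly:
    def test_all_singleton_hosts_trivially_monophyletic(self):
        t = sample_tree(5, 7)
        hosts = {lab: f"h_{lab}" for lab in t.leaf_labels}
        df = host_monophyly(t, hosts)
        assert df["monophyletic"].all()
        assert (df["purity"] == 1.0).all()

    def test_clean_split_both_monophyletic(self):
        t = read_newick("(((a1:1,a2:1):1,a3:1):1,(b1:1,b2:1):1,b3:1);")
        hosts = {"a1": "A", "a2": "A", "a3": "A", "b1": "B", "b2": "B", "b3": "B"}
        df = host_monophyly(t, hosts).set_index("host")
        assert df.loc["A", "monophyletic"] and df.loc["B", "monophyletic"]

    def test_intruder_breaks_monophyly_purity_from_brute_force(self):
        # one A leaf sits inside the B clade
        t = read_newick("((a1:1,a2:1):1,((b1:1,a3:1):1,b2:1):1,b3:1);")
        hosts = {"a1": "A", "a2": "A", "a3": "A", "b1": "B", "b2": "B", "b3": "B"}
        df = host_monophyly(t, hosts).set_index("host")
        assert not df.loc["A", "monophyletic"]
        # brute force: every edge of the tree, both sides; smallest side
        # containing all of A is everything except {b2, b3} -> 3/4
        dt = dendropy.Tree.get(data=write_newick(t), schema="newick")
        dt.encode_bipartitions()
        leaves = frozenset(hosts)
        members = frozenset({"a1", "a2", "a3"})
        best = len(members) / len(leaves)
        for edge in dt.preorder_edge_iter():
            if edge.head_node is dt.seed_node:
                continue
            side = frozenset(
                lf.taxon.label for lf in edge.head_node.leaf_iter()
            )
            for s in (side, leaves - side):
                if members <= s and s:
                    best = max(best, len(members) / len(s))
        assert df.loc["A", "purity"] == pytest.approx(best)
        assert df.loc["A", "purity"] < 1.0

    def test_unknown_leaf_rejected(self):
        t = sample_tree(4, 2)
        hosts = {lab: "h" for lab in t.leaf_labels}
        hosts["ghost"] = "h"
        with pytest.raises(ValueError):
            host_monophyly(t, hosts)


def brute_force_pairwise(sa, sb, gap_open, gap_extend):
    """Exhaustive optimum over all monotone match sets (affine gap runs)."""
    def gap(k):
        return 0.0 if k == 0 else gap_open + gap_extend * (k - 1)

    best = -np.inf
    na, nb = len(sa), len(sb)
    idx_a = list(range(na))
    for k in range(min(na, nb) + 1):
        for ma in itertools.combinations(idx_a, k):
            for mb in itertools.combinations(range(nb), k):
                score = sum(BLOSUM62[sa[i]][sb[j]] for i, j in zip(ma, mb))
                prev_a, prev_b = -1, -1
                for i, j in zip(ma, mb):
                    score += gap(i - prev_a - 1) + gap(j - prev_b - 1)
                    prev_a, prev_b = i, j
                score += gap(na - 1 - prev_a) + gap(nb - 1 - prev_b)
                best = max(best, score)
    return best


def msa_pair_score(msa, la, lb, gap_open, gap_extend):
    rows = {r.label: r.seq for r in msa.records}
    a, b = rows[la], rows[lb]
    score = 0.0
    state = None
    for ca, cb in zip(a, b):
        if ca == "-" and cb == "-":
            continue
        if ca == "-" or cb == "-":
            which = "a" if ca == "-" else "b"
            score += gap_extend if state == which else gap_open
            state = which
        else:
            score += BLOSUM62[ca][cb]
            state = None
    return score


class TestProgressiveMsa:
    def test_identical_sequences_gap_free(self):
        recs = [SequenceRecord(f"s{i}", "MKVLAW") for i in range(3)]
        msa = progressive_msa(recs)
        assert all(r.seq == "MKVLAW" for r in msa.records)

    def test_pairwise_matches_exhaustive_oracle(self):
        go, ge = -10.0, -0.5
        for sa, sb in [("ACDE", "ACE"), ("MKV", "MV"), ("WWF", "WF")]:
            msa = progressive_msa(
                [SequenceRecord("a", sa), SequenceRecord("b", sb)], go, ge
            )
            achieved = msa_pair_score(msa, "a", "b", go, ge)
            assert achieved == pytest.approx(brute_force_pairwise(sa, sb, go, ge))

    def test_duplicate_sequence_does_not_move_other_rows(self):
        base = [
            SequenceRecord("a", "MKVAWLL"),
            SequenceRecord("b", "MKVWLL"),
            SequenceRecord("c", "MRVAWIL"),
        ]
        msa1 = progressive_msa(base)
        dup = base + [SequenceRecord("c2", "MRVAWIL")]
        msa2 = progressive_msa(dup)
        cols1 = {r.label: r.seq.replace("-", "") for r in msa1.records}
        cols2 = {r.label: r.seq.replace("-", "") for r in msa2.records}
        assert cols1 == {k: v for k, v in cols2.items() if k != "c2"}
        # pairwise induced alignments of a/b unchanged by the duplicate
        go, ge = -10.0, -0.5
        assert msa_pair_score(msa1, "a", "b", go, ge) == pytest.approx(
            msa_pair_score(msa2, "a", "b", go, ge)
        )

    def test_illegal_characters_rejected(self):
        with pytest.raises(ValueError):
            progressive_msa([SequenceRecord("a", "MKB?"), SequenceRecord("b", "MK")])


class TestPDistance:
    def test_identical_rows_zero(self):
        msa = Msa([SequenceRecord("a", "MKVL"), SequenceRecord("b", "MKVL")])
        assert pdistance_matrix(msa)[("a", "b")] == 0.0

    def test_half_of_ten_columns(self):
        msa = Msa(
            [SequenceRecord("a", "AAAAAAAAAA"), SequenceRecord("b", "CCCCCAAAAA")]
        )
        assert pdistance_matrix(msa)[("a", "b")] == pytest.approx(0.5)

    def test_gapped_columns_excluded(self):
        msa = Msa([SequenceRecord("a", "A-CD"), SequenceRecord("b", "ABCD")])
        # compared over 3 columns, 0 mismatches
        assert pdistance_matrix(msa)[("a", "b")] == 0.0
        msa2 = Msa([SequenceRecord("a", "A-CD"), SequenceRecord("b", "ABCE")])
        assert pdistance_matrix(msa2)[("a", "b")] == pytest.approx(1 / 3)

    def test_no_comparable_columns_rejected(self):
        msa = Msa([SequenceRecord("a", "A--"), SequenceRecord("b", "-AA")])
        with pytest.raises(ValueError):
            pdistance_matrix(msa)

    def test_poisson_correction(self):
        msa = Msa(
            [SequenceRecord("a", "AAAAAAAAAA"), SequenceRecord("b", "CCAAAAAAAA")]
        )
        d = pdistance_matrix(msa, correction="poisson")[("a", "b")]
        assert d == pytest.approx(-np.log(1 - 0.2))


def congruent_msa(n_cols=60):
    """Two clades of near-identical sequences: every replicate separates them."""
    a = "A" * n_cols
    b = "C" * n_cols
    return Msa(
        [
            SequenceRecord("a1", a),
            SequenceRecord("a2", "G" + a[1:]),
            SequenceRecord("b1", b),
            SequenceRecord("b2", "G" + b[1:]),
        ]
    )


class TestBootstrap:
    def test_congruent_signal_full_support(self):
        tree = bootstrap_support(congruent_msa(), n_reps=100, seed=3)
        assert tree.supports() == {frozenset({"b1", "b2"}): 100.0}

    def test_deterministic_given_seed(self):
        m = congruent_msa()
        t1 = bootstrap_support(m, 100, seed=7)
        t2 = bootstrap_support(m, 100, seed=7)
        assert write_newick(t1) == write_newick(t2)

    def test_supports_within_range_on_noisy_msas(self, rng):
        for _ in range(3):
            rows = [
                SequenceRecord(
                    f"s{i}", "".join(rng.choice(list("ACDE"), size=30))
                )
                for i in range(6)
            ]
            tree = bootstrap_support(Msa(rows), 30, seed=int(rng.integers(1e6)))
            assert all(0.0 <= v <= 100.0 for v in tree.supports().values())


class TestAllVsAll:
    def test_identical_structures_zero_matrix(self):
        structs = [
            helix_fold(40, lab) for lab in ("s1", "s2", "s3")
        ]
        dm = all_vs_all_matrix(structs)
        assert dm.d.shape == (3, 3)
        assert np.abs(dm.d).max() < 1e-6

    def test_shape_and_labels(self):
        tree = sample_tree(5, 21)
        structs = evolve_structures(tree, helix_fold(60), 0.3, seed=21)
        dm = all_vs_all_matrix(structs)
        assert dm.d.shape == (5, 5)
        assert sorted(dm.labels) == sorted(tree.leaf_labels)

    def test_brownian_divergence_scales_as_sqrt_of_branch_scale(self):
        # doubling all branch lengths multiplies RMSD entries by ~sqrt(2):
        # squared deviations, not deviations, are additive along the tree
        base_tree = read_newick(
            "((T1:0.2,T2:0.2):0.2,(T3:0.2,T4:0.2):0.2,T5:0.4);"
        )
        double = read_newick(
            "((T1:0.4,T2:0.4):0.4,(T3:0.4,T4:0.4):0.4,T5:0.8);"
        )
        fold = helix_fold(150)
        ratios = []
        for seed in range(5):
            d1 = all_vs_all_matrix(
                evolve_structures(base_tree, fold, 0.3, seed=seed)
            ).d
            d2 = all_vs_all_matrix(
                evolve_structures(double, fold, 0.3, seed=seed + 1000)
            ).d
            iu = np.triu_indices(5, 1)
            ratios.append(np.mean(d2[iu] / d1[iu]))
        assert np.mean(ratios) == pytest.approx(np.sqrt(2), rel=0.12)

    def test_too_few_structures_rejected(self):
        with pytest.raises(ValueError):
            all_vs_all_matrix([helix_fold(40, "a"), helix_fold(40, "b")])


class TestPipelineRecovery:
    def test_structure_and_sequence_trees_recover_homogeneous_tree(self):
        # low-noise family on a tree with long, equal internal edges:
        # both the RMSD tree and the p-distance tree match the truth
        nwk = ("((T1:0.3,T2:0.3):0.3,(T3:0.3,T4:0.3):0.3,"
               "((T5:0.3,T6:0.3):0.3,(T7:0.3,T8:0.3):0.3):0.3);")
        tree = read_newick(nwk)
        structs = evolve_structures(tree, helix_fold(120), 0.3, seed=0)
        st = nj_build(all_vs_all_matrix(structs))
        assert rf_distance(st, tree) == 0
        seqs = evolve_sequences(tree, "ACDEFGHIKLMNPQRSTVWY" * 6, 0.5, seed=0)
        sq = nj_build(pdistance_matrix(progressive_msa(seqs)))
        assert rf_distance(sq, tree) == 0
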