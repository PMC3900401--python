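"""Evolutionary-trace scoring, tree building and spatial clustering."""

import math
from collections import Counter

import numpy as np
import pytest

from phenokit import evotrace as et
from phenokit import synthetic_data as syn
from phenokit.constants import AMINO_ACIDS, GAP


def make_alignment(rows, ids=None):
    ids = ids or [f"s{k}" for k in range(len(rows))]
    return et.Alignment(ids, np.array([list(r) for r in rows]))


# ---------------------------------------------------------------------------
# FASTA reading


class TestReadAlignment:
    def test_two_identical_sequences(self, tmp_path):
        path = tmp_path / "a.fasta"
        path.write_text(">a\nACDEFGHIKL\n>b\nACDEFGHIKL\n")
        aln = et.read_alignment(path)
        assert aln.n_sequences == 2
        assert aln.n_columns == 10

    def test_trailing_whitespace_tolerated(self, tmp_path):
        path = tmp_path / "a.fasta"
        path.write_text(">a\nACDE   \n>b\nACDF\n")
        aln = et.read_alignment(path)
        assert aln.n_columns == 4

    def test_ragged_alignment_names_offender(self, tmp_path):
        path = tmp_path / "a.fasta"
        path.write_text(">a\nACDE\n>bad_seq\nACD\n")
        with pytest.raises(ValueError, match="bad_seq"):
            et.read_alignment(path)

    def test_fasta_round_trip(self, tmp_path):
        aln = make_alignment(["AC-E", "ACDE"])
        aln.to_fasta(tmp_path / "rt.fasta")
        back = et.read_alignment(tmp_path / "rt.fasta")
        assert back.ids == aln.ids
        assert np.array_equal(back.residues, aln.residues)


# ---------------------------------------------------------------------------
# Distances


class TestIdentityDistance:
    def test_identical_sequences_distance_zero(self):
        d = et.identity_distance(make_alignment(["ACDE", "ACDE"]))
        assert d.values[0, 1] == 0.0

    def test_all_columns_differ(self):
        d = et.identity_distance(make_alignment(["AAAA", "CCCC"]))
        assert d.values[0, 1] == 1.0

    def test_gap_columns_excluded_from_denominator(self):
        # "AAAA" vs "AA-T": 3 co-non-gap columns, 2 matches
        d = et.identity_distance(make_alignment(["AAAA", "AA-T"]))
        assert d.values[0, 1] == pytest.approx(1.0 - 2.0 / 3.0)

    def test_no_shared_columns_distance_one_with_warning(self, caplog):
        with caplog.at_level("WARNING", logger="phenokit.evotrace"):
            d = et.identity_distance(make_alignment(["A-", "-C"]))
        assert d.values[0, 1] == 1.0
        assert "no co-non-gap" in caplog.text


# ---------------------------------------------------------------------------
# UPGMA


class TestBuildTree:
    def test_two_leaves_single_root(self):
        aln = make_alignment(["AA", "AC"], ids=["x", "y"])
        tree = et.build_tree(et.identity_distance(aln))
        assert tree.n_leaves == 2
        assert {c.name for c in tree.root.children} == {"x", "y"}

    def test_forced_topology_three_leaves(self):
        d = et.DistanceMatrix(
            ["A", "B", "C"],
            np.array([[0.0, 0.1, 0.8], [0.1, 0.0, 0.8], [0.8, 0.8, 0.0]]),
        )
        tree = et.build_tree(d)
        # A and B join first (closest pair)
        kids = sorted(tree.root.children, key=lambda nd: len(nd.leaves))
        assert kids[0].leaves == frozenset({"C"})
        assert kids[1].leaves == frozenset({"A", "B"})

    def test_equal_distances_tie_break_lexicographic(self):
        ids = ["A", "B", "C", "D"]
        vals = np.full((4, 4), 0.5)
        np.fill_diagonal(vals, 0.0)
        tree = et.build_tree(et.DistanceMatrix(ids, vals))
        # first merge is (A, B); it then absorbs C, then D (caterpillar)
        node = tree.root
        assert node.leaves == frozenset(ids)
        inner = [c for c in node.children if not c.is_leaf][0]
        assert inner.leaves == frozenset({"A", "B", "C"})
        inner2 = [c for c in inner.children if not c.is_leaf][0]
        assert inner2.leaves == frozenset({"A", "B"})

    def test_heights_match_scipy_average_linkage(self):
        rng = np.random.default_rng(7)
        from scipy.cluster.hierarchy import average
        from scipy.spatial.distance import squareform

        n = 8
        condensed = rng.random(n * (n - 1) // 2) + 0.01
        d = squareform(condensed)
        tree = et.build_tree(et.DistanceMatrix([f"s{k}" for k in range(n)], d))
        link = average(condensed)
        ours = sorted(nd.height for nd in tree.nodes() if not nd.is_leaf)
        scipys = sorted(link[:, 2] / 2.0)
        assert np.allclose(ours, scipys)

    def test_newick_round_trip(self):
        aln = make_alignment(["AAC", "AAA", "CCC", "CCA"])
        tree = et.build_tree(et.identity_distance(aln))
        text = tree.to_newick()
        import io, tempfile, os

        with tempfile.TemporaryDirectory() as tmp:
            path = os.path.join(tmp, "t.nwk")
            tree.write_newick(path)
            back = et.read_tree(path)
        assert back.leaf_names == tree.leaf_names
        heights = sorted(nd.height for nd in tree.nodes() if not nd.is_leaf)
        back_heights = sorted(nd.height for nd in back.nodes() if not nd.is_leaf)
        assert np.allclose(heights, back_heights)


# ---------------------------------------------------------------------------
# Partitions


class TestPartitionAt:
    @pytest.fixture
    def tree(self):
        aln = make_alignment(["AAAA", "AAAC", "CCCA", "CCCC"], ids=list("abcd"))
        return et.build_tree(et.identity_distance(aln))

    def test_level_one_single_group(self, tree):
        p = et.partition_at(tree, 1)
        assert p.groups == [frozenset("abcd")]

    def test_level_n_singletons(self, tree):
        p = et.partition_at(tree, 4)
        assert sorted(map(min, p.groups)) == ["a", "b", "c", "d"]
        assert all(len(g) == 1 for g in p.groups)

    def test_level_two_root_children(self, tree):
        p = et.partition_at(tree, 2)
        assert sorted(p.groups, key=min) == [frozenset("ab"), frozenset("cd")]

    def test_out_of_range_rejected(self, tree):
        with pytest.raises(ValueError):
            et.partition_at(tree, 0)
        with pytest.raises(ValueError):
            et.partition_at(tree, 5)


class TestGroupFrequencies:
    def test_uniform_column(self):
        aln = make_alignment(["H", "H", "H", "H"])
        p = et.Partition(level=1, groups=[frozenset(aln.ids)])
        (freqs,) = et.group_frequencies(aln, p, 1)
        assert freqs == {"H": 1.0}

    def test_half_half(self):
        aln = make_alignment(["H", "H", "A", "A"])
        p = et.Partition(level=1, groups=[frozenset(aln.ids)])
        (freqs,) = et.group_frequencies(aln, p, 1)
        assert freqs == {"H": 0.5, "A": 0.5}

    def test_gap_rows_dropped(self):
        aln = make_alignment(["H", "-"])
        p = et.Partition(level=1, groups=[frozenset(aln.ids)])
        (freqs,) = et.group_frequencies(aln, p, 1)
        assert freqs == {"H": 1.0}


# ---------------------------------------------------------------------------
# Trace scores: oracle and properties


def naive_trace_oracle(aln, tree):
    """Brute-force rho: materialize every partition level explicitly.

    Independent plain-Python walk: at each level the highest subtree
    root (ties: smallest leaf id) is expanded, and every group's column
    entropy is recomputed from a Counter over its non-gap residues.
    """
    N = aln.n_sequences
    row_of = {sid: k for k, sid in enumerate(aln.ids)}
    rho = [1.0] * aln.n_columns
    forest = [tree.root]
    for n in range(1, N):
        for col in range(1, aln.n_columns + 1):
            level = 0.0
            for node in forest:
                chars = [
                    aln.column(col)[row_of[s]]
                    for s in node.leaves
                    if aln.column(col)[row_of[s]] != GAP
                ]
                counts = Counter(chars)
                total = sum(counts.values())
                ent = 0.0
                for c in counts.values():
                    f = c / total
                    ent -= f * math.log(f)
                level += ent
            rho[col - 1] += level / n
        internal = [nd for nd in forest if not nd.is_leaf]
        if internal:
            pick = sorted(internal, key=lambda nd: (-nd.height, min(nd.leaves)))[0]
            forest = [nd for nd in forest if nd is not pick] + list(pick.children)
    return np.array(rho)


class TestTraceScores:
    def test_invariant_column_scores_one(self):
        aln = make_alignment(["HAC", "HGC", "HTC", "HWC"])
        tree = et.build_tree(et.identity_distance(aln))
        tr = et.trace_scores(aln, tree)
        assert tr.scores[0] == 1.0
        assert tr.scores[2] == 1.0
        assert tr.ranks[0] == 1

    def test_two_sequence_divergent_column(self):
        aln = make_alignment(["A", "G"])
        tree = et.build_tree(et.identity_distance(aln))
        tr = et.trace_scores(aln, tree)
        assert tr.scores[0] == pytest.approx(1.0 + math.log(2.0), abs=1e-12)

    @pytest.mark.parametrize("n_seq", [2, 3, 4, 5, 6])
    def test_matches_bruteforce_oracle(self, n_seq, rng):
        letters = list(AMINO_ACIDS[:6]) + [GAP]
        rows = [
            "".join(rng.choice(letters, size=12)) for _ in range(n_seq)
        ]
        aln = make_alignment(rows)
        tree = et.build_tree(et.identity_distance(aln))
        tr = et.trace_scores(aln, tree)
        oracle = naive_trace_oracle(aln, tree)
        assert np.max(np.abs(tr.scores - oracle)) <= 1e-9

    def test_scores_at_least_one(self, rng):
        rows = ["".join(rng.choice(list(AMINO_ACIDS), size=20)) for _ in range(6)]
        aln = make_alignment(rows)
        tree = et.build_tree(et.identity_distance(aln))
        assert np.all(et.trace_scores(aln, tree).scores >= 1.0)

    def test_row_permutation_invariance(self, rng):
        rows = ["".join(rng.choice(list("ACDEF"), size=15)) for _ in range(5)]
        ids = [f"s{k}" for k in range(5)]
        aln = et.Alignment(ids, np.array([list(r) for r in rows]))
        perm = [3, 0, 4, 1, 2]
        aln2 = et.Alignment(
            [ids[k] for k in perm], np.array([list(rows[k]) for k in perm])
        )
        t1 = et.trace_scores(aln, et.build_tree(et.identity_distance(aln)))
        t2 = et.trace_scores(aln2, et.build_tree(et.identity_distance(aln2)))
        assert np.allclose(t1.scores, t2.scores, atol=1e-12)

    def test_duplicate_sequence_keeps_invariant_at_minimum(self):
        rows = ["HACDE", "HGCDF", "HTCDA"]
        aln = make_alignment(rows)
        t1 = et.trace_scores(aln, et.build_tree(et.identity_distance(aln)))
        dup = make_alignment(rows + [rows[-1]])
        t2 = et.trace_scores(dup, et.build_tree(et.identity_distance(dup)))
        assert t1.scores[0] == 1.0
        assert t2.scores[0] == 1.0

    def test_leaf_mismatch_rejected(self):
        aln = make_alignment(["AC", "AG"])
        other = make_alignment(["AC", "AG"], ids=["x", "y"])
        tree = et.build_tree(et.identity_distance(other))
        with pytest.raises(ValueError):
            et.trace_scores(aln, tree)


class TestRankResidues:
    def test_tie_rule(self):
        tr = et.ResidueTrace(
            columns=np.array([1, 2, 3]),
            scores=np.array([1.0, 5.0, 1.0]),
            ranks=et._competition_ranks(np.array([1.0, 5.0, 1.0])),
        )
        assert list(tr.ranks) == [1, 3, 1]

    def test_strictly_increasing_scores(self):
        scores = np.array([1.0, 1.5, 2.0, 3.0])
        assert list(et._competition_ranks(scores)) == [1, 2, 3, 4]

    def test_planted_invariant_columns_outrank_all(self):
        spec = syn.FamilySimSpec(
            n_sequences=16,
            n_columns=60,
            invariant_positions=[5, 20, 40, 55],
            substitution_rate=0.08,
            seed=42,
        )
        aln, _, truth = syn.simulate_family_alignment(spec)
        tree = et.build_tree(et.identity_distance(aln))
        tr = et.trace_scores(aln, tree)
        top = set(tr.columns[tr.ranks == 1])
        assert top == set(truth.invariant)


# ---------------------------------------------------------------------------
# Structure mapping and clustering


class TestStructure:
    def test_pdb_round_trip(self, tmp_path):
        model = syn.simulate_toy_structure(20, [2, 5, 9], 8.0, seed=3)
        model.to_pdb(tmp_path / "m.pdb")
        back = et.read_structure(tmp_path / "m.pdb")
        assert back.residue_numbers == model.residue_numbers
        for res in model.coords:
            assert np.allclose(back.coords[res], model.coords[res], atol=1e-3)

    def test_map_full_coverage_is_bijection(self):
        scores = np.array([1.0, 2.0, 3.0])
        tr = et.ResidueTrace(
            columns=np.arange(1, 4), scores=scores, ranks=et._competition_ranks(scores)
        )
        model = syn.simulate_toy_structure(3, [], 8.0, seed=0)
        mapped = et.map_to_structure(tr, model, offset=0)
        assert mapped["mapped"].all()
        assert sorted(mapped["residue"]) == [1, 2, 3]

    def test_missing_residue_flagged(self):
        scores = np.array([1.0, 2.0, 3.0])
        tr = et.ResidueTrace(
            columns=np.arange(1, 4), scores=scores, ranks=et._competition_ranks(scores)
        )
        model = syn.simulate_toy_structure(3, [], 8.0, seed=0)
        del model.coords[2]
        mapped = et.map_to_structure(tr, model, offset=0)
        assert list(mapped["mapped"]) == [True, False, True]

    def test_offset_carries_rank_to_numbered_residue(self):
        # column 12 mapped onto residue 662 with offset 650
        scores = np.linspace(1.0, 2.0, 20)
        tr = et.ResidueTrace(
            columns=np.arange(1, 21), scores=scores, ranks=et._competition_ranks(scores)
        )
        model = syn.simulate_toy_structure(20, [], 8.0, seed=1)
        model.coords = {k + 650: v for k, v in model.coords.items()}
        mapped = et.map_to_structure(tr, model, offset=650)
        row = mapped[mapped["column"] == 12].iloc[0]
        assert row["residue"] == 662
        assert row["mapped"]


class TestClusterZscore:
    def test_planted_cluster_positive_z(self):
        model = syn.simulate_toy_structure(80, [10, 11, 12, 13], 6.0, seed=5)
        stats = et.cluster_zscore(model, [10, 11, 12, 13], cutoff_A=12.0, n_perm=500, seed=1)
        assert stats.observed == 6  # all 4*(4-1)/2 pairs in contact
        assert stats.zscore > 2.0

    def test_far_pair_observed_zero(self):
        coords = {1: [0.0, 0.0, 0.0], 2: [100.0, 0.0, 0.0], 3: [0.0, 50.0, 0.0],
                  4: [3.0, 50.0, 0.0], 5: [0.0, 0.0, 70.0]}
        model = et.StructureModel(coords)
        stats = et.cluster_zscore(model, [1, 2], cutoff_A=12.0, n_perm=100, seed=0)
        assert stats.observed == 0

    def test_null_draws_center_on_zero(self):
        model = syn.simulate_toy_structure(60, [], 8.0, seed=9)
        rng = np.random.default_rng(11)
        zs = []
        for rep in range(20):
            sel = rng.choice(model.residue_numbers, size=6, replace=False)
            zs.append(
                et.cluster_zscore(model, sel, 12.0, n_perm=300, seed=rep).zscore
            )
        assert abs(np.mean(zs)) < 0.8

    def test_selection_validation(self):
        model = syn.simulate_toy_structure(5, [], 8.0, seed=0)
        with pytest.raises(ValueError):
            et.cluster_zscore(model, [1], n_perm=100)
        with pytest.raises(ValueError):
            et.cluster_zscore(model, [1, 99], n_perm=100)
        with pytest.raises(ValueError):
            et.cluster_zscore(model, list(range(1, 8)), n_perm=100)
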