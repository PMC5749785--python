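import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from plastodecay import parsimony as p
from plastodecay import trees as t
from oracles import acctran_oracle, fitch_length_oracle


def random_matrix(rng, taxa, n_char, alphabet="01", missing_prob=0.0):
    rows = {}
    for taxon in taxa:
        rows[taxon] = "".join(
            "?" if rng.random() < missing_prob
            else alphabet[rng.integers(len(alphabet))]
            for _ in range(n_char))
    return p.CharacterMatrix(rows)


class TestCharacterMatrix:
    def test_rectangular_required(self):
        with pytest.raises(ValueError):
            p.CharacterMatrix({"A": "01", "B": "0"})

    def test_missing_and_gap_fully_ambiguous(self):
        m = p.CharacterMatrix({"A": "0", "B": "1", "C": "?", "D": "-"})
        full = (1 << 2) - 1
        assert m.masks[2, 0] == full and m.masks[3, 0] == full

    def test_gap_as_state(self):
        m = p.CharacterMatrix({"A": "0", "B": "1", "C": "-"},
                              gap_as_state=True)
        assert m.alphabets[0] == ("-", "0", "1")

    def test_tsv_round_trip(self, tmp_path):
        m = p.CharacterMatrix({"tx a": "012-?", "tx b": "11010"})
        path = tmp_path / "m.tsv"
        path.write_text("taxon\t" + "\t".join(f"c{i}" for i in range(5)) + "\n"
                        + "tx a\t0\t1\t2\t-\t?\n" + "tx b\t1\t1\t0\t1\t0\n")
        again = p.CharacterMatrix.from_tsv(path)
        assert again.taxa == m.taxa
        assert all(again.row(t) == m.row(t) for t in m.taxa)

    def test_nexus_round_trip(self, tmp_path):
        m = p.CharacterMatrix({"ta": "0120", "tb": "110?", "tc": "2-01"})
        path = tmp_path / "m.nex"
        path.write_text(m.to_nexus())
        again = p.CharacterMatrix.from_nexus(path)
        assert set(again.taxa) == set(m.taxa)
        assert all(again.row(t) == m.row(t) for t in m.taxa)


class TestFitch:
    def test_constant_character_zero(self):
        tree = t.from_newick("((A,B),(C,D));")
        m = p.CharacterMatrix({x: "0" for x in "ABCD"})
        assert p.fitch_length(tree, m) == 0

    def test_hand_example(self):
        m = p.CharacterMatrix({"A": "0", "B": "0", "C": "1", "D": "1"})
        assert p.fitch_length(t.from_newick("((A,B),(C,D));"), m) == 1
        assert p.fitch_length(t.from_newick("((A,C),(B,D));"), m) == 2

    def test_leaf_mismatch_raises(self):
        m = p.CharacterMatrix({"A": "0", "B": "1", "C": "0", "X": "1"})
        with pytest.raises(ValueError):
            p.fitch_length(t.from_newick("((A,B),(C,D));"), m)

    def test_invariant_under_rerooting(self):
        rng = np.random.default_rng(3)
        labels = [f"x{i}" for i in range(7)]
        tree = t.random_topology(labels, rng)
        m = random_matrix(rng, labels, 12, "ACGT", missing_prob=0.1)
        base = p.fitch_length(tree, m)
        for leaf in labels:
            assert p.fitch_length(t.root_on_leaf_edge(tree, leaf), m) == base

    @given(st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None)
    def test_matches_oracle_property(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 7))
        labels = [f"x{i}" for i in range(n)]
        tree = t.random_topology(labels, rng)
        m = random_matrix(rng, labels, int(rng.integers(1, 8)), "01",
                          missing_prob=0.15)
        rows = {taxon: "".join(m.row(taxon)) for taxon in labels}
        assert p.fitch_length(tree, m) == fitch_length_oracle(tree, rows)


class TestSearch:
    def test_four_taxa_examines_three(self):
        rng = np.random.default_rng(0)
        m = random_matrix(rng, list("ABCD"), 6)
        res = p.search_mp(m, method="exhaustive")
        assert res.n_trees_examined == 3
        lengths = [p.fitch_length(tr, m) for tr in t.all_topologies("ABCD")]
        assert res.min_length == min(lengths)

    def test_too_few_taxa(self):
        m = p.CharacterMatrix({"A": "0", "B": "1", "C": "0"})
        with pytest.raises(ValueError):
            p.search_mp(m, method="exhaustive")

    def test_bb_refuses_large(self):
        rng = np.random.default_rng(1)
        m = random_matrix(rng, [f"t{i}" for i in range(17)], 4)
        with pytest.raises(ValueError, match="heuristic"):
            p.search_mp(m, method="branch_and_bound")

    def test_bb_matches_exhaustive(self):
        rng = np.random.default_rng(2)
        for _ in range(8):
            labels = [f"x{i}" for i in range(6)]
            m = random_matrix(rng, labels, 10, "012")
            r_ex = p.search_mp(m, method="exhaustive")
            r_bb = p.search_mp(m, method="branch_and_bound")
            assert r_ex.min_length == r_bb.min_length
            assert ({tr.topology_key() for tr in r_ex.trees}
                    == {tr.topology_key() for tr in r_bb.trees})

    def test_heuristic_finds_exact_optimum_small(self):
        rng = np.random.default_rng(4)
        labels = [f"x{i}" for i in range(6)]
        m = random_matrix(rng, labels, 15, "ACGT")
        r_ex = p.search_mp(m, method="exhaustive")
        r_h = p.search_mp(m, method="heuristic", seed=0, n_replicates=5)
        assert r_h.min_length == r_ex.min_length

    def test_simulation_recovery(self):
        # low-homoplasy matrices on a known tree recover that topology
        from plastodecay import simulate as sim

        hits = 0
        n_rep = 20
        for seed in range(n_rep):
            tree = sim.generate_tree(8, seed=seed)
            rows = sim.evolve_alignment(tree, 500, rate=1.0, seed=seed)
            m = p.CharacterMatrix.from_alignment(rows)
            res = p.search_mp(m, method="branch_and_bound")
            if len(res.trees) == 1 and \
                    res.trees[0].topology_key() == tree.topology_key():
                hits += 1
        assert hits >= 0.95 * n_rep


class TestCiRi:
    def test_no_homoplasy_gives_ones(self):
        tree = t.from_newick("((A,B),(C,D),E);")
        m = p.CharacterMatrix({"A": "11", "B": "11", "C": "00",
                               "D": "00", "E": "00"})
        ci, ri = p.ci_ri(m, tree)
        assert ci == 1.0 and ri == 1.0

    def test_two_origins_hand_case(self):
        # m=1, s=2, g=3 -> CI=0.5, RI=0.5
        tree = t.from_newick("((A,(B,C)),(D,(E,F)));")
        m = p.CharacterMatrix({"A": "0", "B": "1", "C": "1",
                               "D": "0", "E": "1", "F": "0"})
        assert p.ci_ri(m, tree) == (0.5, 0.5)

    def test_bounds(self):
        rng = np.random.default_rng(9)
        for _ in range(10):
            labels = [f"x{i}" for i in range(6)]
            tree = t.random_topology(labels, rng)
            m = random_matrix(rng, labels, 10, "01")
            ci, ri = p.ci_ri(m, tree)
            assert 0 < ci <= 1
            if ri is not None:
                assert 0 <= ri <= 1
            if ci == 1.0 and ri is not None:
                assert ri == 1.0


class TestBootstrap:
    def test_unanimous_split_full_support(self):
        rows = {"A": "1" * 20, "B": "1" * 20, "C": "0" * 20, "D": "0" * 20,
                "E": "0" * 20}
        m = p.CharacterMatrix(rows)
        support = p.bootstrap_support(m, n_reps=30, seed=0)
        key = frozenset([frozenset("AB"), frozenset("CDE")])
        assert support[key] == 100.0

    def test_seed_stability(self):
        rng = np.random.default_rng(12)
        m = random_matrix(rng, [f"x{i}" for i in range(6)], 30)
        s1 = p.bootstrap_support(m, n_reps=100, seed=1)
        s2 = p.bootstrap_support(m, n_reps=100, seed=2)
        shared = set(s1) & set(s2)
        assert shared
        for split in shared:
            if s1[split] > 70 and s2[split] > 70:
                assert abs(s1[split] - s2[split]) <= 15


class TestAcctran:
    def test_constant_character_no_changes(self):
        tree = t.from_newick("(((A,B),C),O);")
        m = p.CharacterMatrix({"A": "1", "B": "1", "C": "1", "O": "1"})
        assert p.acctran_map(tree, m, outgroup="O") == [[]]

    def test_single_clade_derivation(self):
        tree = t.from_newick("((((A,B),C),D),O);")
        m = p.CharacterMatrix({"A": "1", "B": "1", "C": "0",
                               "D": "0", "O": "0"})
        (changes,) = p.acctran_map(tree, m, outgroup="O")
        assert len(changes) == 1
        assert changes[0].branch == frozenset({"A", "B"})
        assert (changes[0].from_state, changes[0].to_state) == ("0", "1")

    def test_prefers_reversal_over_parallelism(self):
        # A,B,D derived; C not: early gain + reversal beats two gains
        tree = t.from_newick("((((A,B),C),D),O);")
        m = p.CharacterMatrix({"A": "1", "B": "1", "C": "0",
                               "D": "1", "O": "0"})
        (changes,) = p.acctran_map(tree, m, outgroup="O")
        moves = sorted((ch.depth, ch.from_state, ch.to_state)
                       for ch in changes)
        assert len(changes) == 2
        assert moves[0] == (1, "0", "1")       # gain on the ingroup stem
        assert moves[1][1:] == ("1", "0")      # later reversal in C

    def test_outgroup_required(self):
        tree = t.from_newick("((A,B),(C,D),E);")
        m = p.CharacterMatrix({x: "0" for x in "ABCDE"})
        with pytest.raises(ValueError):
            p.acctran_map(tree, m)

    def test_total_changes_equal_fitch_and_depths_match_oracle(self):
        rng = np.random.default_rng(21)
        for _ in range(30):
            n = int(rng.integers(5, 8))
            labels = [f"x{i}" for i in range(n)]
            tree = t.random_topology(labels, rng)
            m = random_matrix(rng, labels, 4, "012", missing_prob=0.1)
            rooted = t.root_on_outgroup(tree, labels[0])
            per_char_fitch = p.fitch_length(tree, m, per_character=True)
            changes = p.acctran_map(tree, m, outgroup=labels[0])
            for j in range(m.n_characters):
                column = {taxon: m.row(taxon)[j] for taxon in labels}
                steps, depths = acctran_oracle(rooted, column)
                assert len(changes[j]) == per_char_fitch[j] == steps
                got = tuple(sorted(ch.depth for ch in changes[j]))
                assert got == depths
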