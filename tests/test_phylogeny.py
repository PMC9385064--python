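"""Polarization, compatibility, perfect phylogeny and Fitch assignment.

The Fitch implementation is checked against an exhaustive oracle that
minimizes change counts over every assignment of states to internal nodes
(and to missing tips).
"""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ychrono.errors import InputError
from ychrono.phylogeny import (ANCESTRAL, DERIVED, STATE_MISSING,
                               BinaryMatrix, assign_snps_to_branches,
                               build_tree, check_pairwise_compatibility,
                               fitch_score, polarize)
from ychrono.simulate import SimConfig, simulate_dataset

from .conftest import A, M, R, mk_matrix, tree_from_spec


def exhaustive_min_changes(tree, site_states):
    """Oracle: brute-force minimum change count over all labelings of the
    internal nodes and of unconstrained tips, root fixed ancestral."""
    nodes = list(tree.preorder())
    free = [n for n in nodes
            if (not n.is_tip and n.parent is not None)
            or (n.is_tip and site_states.get(n.name, STATE_MISSING)
                == STATE_MISSING)]
    fixed = {id(tree.root): 0}
    for n in nodes:
        if n.is_tip and site_states.get(n.name, STATE_MISSING) != STATE_MISSING:
            fixed[id(n)] = site_states[n.name]
    best = None
    for combo in itertools.product((0, 1), repeat=len(free)):
        lab = dict(fixed)
        for n, s in zip(free, combo):
            lab[id(n)] = s
        changes = sum(1 for n in nodes if n.parent is not None
                      and lab[id(n)] != lab[id(n.parent)])
        best = changes if best is None else min(best, changes)
    return best


def bmatrix_from_sets(sample_ids, derived_sets, positions=None):
    """BinaryMatrix whose site j is derived exactly in derived_sets[j]."""
    positions = positions or list(range(1, len(derived_sets) + 1))
    states = np.array([[DERIVED if s in d else ANCESTRAL
                        for d in derived_sets] for s in sample_ids],
                      dtype=np.int8)
    return BinaryMatrix(sample_ids=list(sample_ids),
                        positions=np.asarray(positions, dtype=np.int64),
                        states=states, outgroup_id="OUT")


class TestPolarize:
    def test_orientation_and_flip(self):
        # site 1: outgroup REF -> ALT is derived
        # site 2: outgroup ALT -> REF is derived (polarity flipped)
        m = mk_matrix(["x", "y", "OUT"], [1, 2],
                      [[A, R], [R, A], [R, A]])
        bm = polarize(m, "OUT")
        assert bm.sample_ids == ["x", "y"]
        assert bm.states.tolist() == [[1, 1], [0, 0]]
        assert bm.report.flipped_polarity == 1

    def test_outgroup_missing_site_dropped_and_counted(self):
        m = mk_matrix(["x", "y", "OUT"], [1, 2, 3],
                      [[A, A, A], [R, R, R], [R, M, R]])
        bm = polarize(m, "OUT")
        assert bm.positions.tolist() == [1, 3]
        assert bm.report.dropped_outgroup_missing == 1

    def test_uninformative_sites_dropped(self):
        # site 2: everyone matches the outgroup -> no derived call
        m = mk_matrix(["x", "y", "OUT"], [1, 2],
                      [[A, R], [R, R], [R, R]])
        bm = polarize(m, "OUT")
        assert bm.positions.tolist() == [1]
        assert bm.report.dropped_no_derived == 1

    def test_absent_outgroup_rejected(self):
        m = mk_matrix(["x"], [1], [[A]])
        with pytest.raises(InputError):
            polarize(m, "nope")


class TestCompatibility:
    @pytest.mark.parametrize("set_a,set_b,expect_bad", [
        ({"a", "b"}, {"a"}, False),   # nested
        ({"a"}, {"b"}, False),        # disjoint
        ({"a", "b"}, {"b", "c"}, True),  # overlapping, neither contains
    ])
    def test_three_gamete_cases(self, set_a, set_b, expect_bad):
        bm = bmatrix_from_sets(["a", "b", "c"], [set_a, set_b])
        bad = check_pairwise_compatibility(bm)
        assert bool(bad) == expect_bad

    def test_bruteforce_over_forbidden_gametes(self):
        samples = ["a", "b", "c", "d"]
        subsets = [set(c) for r in (1, 2, 3)
                   for c in itertools.combinations(samples, r)]
        for sa, sb in itertools.combinations(subsets, 2):
            bm = bmatrix_from_sets(samples, [sa, sb])
            expected = bool(sa & sb) and bool(sa - sb) and bool(sb - sa)
            assert bool(check_pairwise_compatibility(bm)) == expected


class TestBuildTree:
    def test_caterpillar_from_nested_sets(self):
        bm = bmatrix_from_sets(["a", "b", "c", "d"],
                               [{"a", "b", "c"}, {"a", "b"}, {"a"}])
        tree = build_tree(bm)
        assert tree.clade_sets() == {frozenset({"a", "b", "c"}),
                                     frozenset({"a", "b"})}

    def test_identical_samples_share_a_node(self):
        bm = bmatrix_from_sets(["a", "b", "c"],
                               [{"a", "b"}, {"a", "b"}, {"c"}])
        tree = build_tree(bm)
        ab = tree.find("a").parent
        assert tree.find("b").parent is ab
        assert tree.tipset(ab) == frozenset({"a", "b"})

    def test_clades_equal_distinct_derived_sets(self):
        sets = [{"a", "b"}, {"c", "d", "e"}, {"c", "d"}, {"a"}]
        bm = bmatrix_from_sets(["a", "b", "c", "d", "e"], sets)
        tree = build_tree(bm)
        expected = {frozenset(s) for s in sets if len(s) > 1}
        assert tree.clade_sets() == expected

    def test_simulated_truth_recovered(self):
        cfg = SimConfig(n_tips=20, seed=42)
        truth, matrix = simulate_dataset(cfg)
        bm = polarize(matrix, "OUTGROUP")
        tree = build_tree(bm)
        assign_snps_to_branches(tree, bm)
        assert tree.clade_sets(supported_only=True) == \
            truth.tree.clade_sets(supported_only=True)

    def test_empty_matrix_rejected(self):
        bm = bmatrix_from_sets(["a"], [])
        with pytest.raises(InputError):
            build_tree(bm)


class TestAssignment:
    def test_clade_concordant_site_one_event_on_stem(self):
        tree = tree_from_spec((("a", "b"), ("c", "d")))
        bm = bmatrix_from_sets(["a", "b", "c", "d"], [{"a", "b"}])
        assign_snps_to_branches(tree, bm)
        stem = tree.find("a").parent
        assert stem.events == [(1, "gain")]
        assert tree.total_events() == 1
        assert tree.recurrent == {}

    def test_recurrent_pattern_two_events(self):
        tree = tree_from_spec((("a", "b"), ("c", "d")))
        # derived in two non-sister tips: needs two independent gains
        bm = bmatrix_from_sets(["a", "b", "c", "d"], [{"a", "c"}])
        assign_snps_to_branches(tree, bm)
        assert tree.recurrent == {1: 2}
        assert tree.total_events() == 2
        carriers = [n.name for n in tree.preorder()
                    if any(d == "gain" for _, d in n.events)]
        assert sorted(carriers) == ["a", "c"]

    def test_missing_tips_are_wildcards(self):
        tree = tree_from_spec((("a", "b"), ("c", "d")))
        states = np.array([[DERIVED], [STATE_MISSING],
                           [ANCESTRAL], [ANCESTRAL]], dtype=np.int8)
        bm = BinaryMatrix(["a", "b", "c", "d"], np.array([7]),
                          states, "OUT")
        assign_snps_to_branches(tree, bm)
        assert tree.recurrent == {}  # b free -> single gain suffices
        assert tree.total_events() == 1

    def test_tip_without_data_rejected(self):
        tree = tree_from_spec(("a", "zzz"))
        bm = bmatrix_from_sets(["a", "b"], [{"a"}])
        with pytest.raises(InputError):
            assign_snps_to_branches(tree, bm)

    def test_event_counts_invariant_to_sample_order(self):
        cfg = SimConfig(n_tips=10, seed=3)
        truth, matrix = simulate_dataset(cfg)
        bm = polarize(matrix, "OUTGROUP")
        perm = np.random.default_rng(0).permutation(bm.n_samples)
        bm2 = BinaryMatrix([bm.sample_ids[i] for i in perm],
                           bm.positions.copy(), bm.states[perm, :], "OUT")
        t1 = assign_snps_to_branches(build_tree(bm), bm)
        t2 = assign_snps_to_branches(build_tree(bm2), bm2)
        counts1 = {tuple(sorted(t1.tipset(n))): len(n.events)
                   for n in t1.preorder() if n.parent is not None}
        counts2 = {tuple(sorted(t2.tipset(n))): len(n.events)
                   for n in t2.preorder() if n.parent is not None}
        assert counts1 == counts2

    def test_compatible_sites_each_placed_exactly_once(self):
        cfg = SimConfig(n_tips=12, seed=11)
        truth, matrix = simulate_dataset(cfg)
        bm = polarize(matrix, "OUTGROUP")
        tree = assign_snps_to_branches(build_tree(bm), bm)
        assert tree.total_events() == bm.n_sites
        assert tree.recurrent == {}

    def test_recovered_branch_counts_equal_truth(self):
        cfg = SimConfig(n_tips=15, seed=5)
        truth, matrix = simulate_dataset(cfg)
        bm = polarize(matrix, "OUTGROUP")
        tree = assign_snps_to_branches(build_tree(bm), bm)
        got = {}
        for n in tree.preorder():
            if n.parent is not None and n.events:
                got[tree.tipset(n)] = sorted(p for p, _ in n.events)
        want = {}
        for n in truth.tree.preorder():
            if n.parent is not None and truth.branch_mutations[n.name]:
                key = truth.tree.tipset(n)
                want[key] = sorted(set(want.get(key, []))
                                   | set(truth.branch_mutations[n.name]))
        assert got == want


class TestFitchScore:
    def test_constant_derived_is_one_event_on_stem(self):
        # root with a single-child stem: one gain on the stem suffices
        tree = tree_from_spec(((("a", "b"), "c"),))
        states = {"a": 1, "b": 1, "c": 1}
        assert fitch_score(tree, states) == 1

    def test_clade_concordant_is_one(self):
        tree = tree_from_spec((("a", "b"), "c"))
        assert fitch_score(tree, {"a": 1, "b": 1, "c": 0}) == 1

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.integers(0, 3 ** 6 - 1))
    def test_matches_exhaustive_oracle_on_six_tips(self, code):
        tree = tree_from_spec(((("a", "b"), ("c", "d")), ("e", "f")))
        tips = ["a", "b", "c", "d", "e", "f"]
        states = {}
        for t in tips:
            code, r = divmod(code, 3)
            states[t] = (STATE_MISSING, ANCESTRAL, DERIVED)[r]
        assert fitch_score(tree, states) == \
            exhaustive_min_changes(tree, states)

    def test_polytomy_tree_against_oracle(self):
        tree = tree_from_spec((("a", "b", "c"), ("d", "e"), "f"))
        rng = np.random.default_rng(123)
        tips = tree.tip_names
        for _ in range(100):
            states = {t: int(s) for t, s in
                      zip(tips, rng.integers(0, 2, len(tips)))}
            assert fitch_score(tree, states) == \
                exhaustive_min_changes(tree, states)
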