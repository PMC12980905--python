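"""Minimum-event copy-number distances, trees, monophyly, branch events."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from crcrelapse import cnphylo
from crcrelapse.cnphylo import (CNEvent, CNProfile, apply_events,
                                bfs_event_cost, check_monophyly,
                                decompose_difference, diploid_profile,
                                med_transform_cost,
                                pairwise_distance_matrix)


def prof(major, minor=None, sample="s", chroms=None):
    major = np.asarray(major)
    minor = np.ones_like(major) if minor is None else np.asarray(minor)
    chroms = chroms or ("chr1",) * len(major)
    return CNProfile(sample, tuple(chroms), major, minor)


class TestMedCost:
    def test_single_spanning_gain(self):
        assert med_transform_cost(prof([2, 2, 2]), prof([3, 3, 2])) == 1

    def test_identity_costs_zero(self):
        p = prof([2, 1, 0], [1, 1, 0])
        assert med_transform_cost(p, p) == 0

    def test_zero_absorption_is_infeasible_even_with_wgd(self):
        src, tgt = prof([0, 2]), prof([1, 2])
        assert math.isinf(med_transform_cost(src, tgt, allow_wgd=False))
        assert math.isinf(med_transform_cost(src, tgt, allow_wgd=True))

    def test_wgd_route_saves_events(self):
        src = prof([1, 1, 1, 1], [1, 1, 1, 1])
        tgt = prof([2, 2, 2, 2], [2, 2, 2, 2])
        assert med_transform_cost(src, tgt, allow_wgd=False) == 2
        assert med_transform_cost(src, tgt, allow_wgd=True) == 1

    def test_events_do_not_span_chromosomes(self):
        chroms = ("chr1", "chr2")
        src = prof([1, 1], chroms=chroms)
        tgt = prof([2, 2], chroms=chroms)
        assert med_transform_cost(src, tgt) == 2

    def test_mismatched_segmentation_rejected(self):
        with pytest.raises(ValueError, match="segmentation"):
            med_transform_cost(prof([1, 1]), prof([1, 1, 1]))

    def test_exhaustive_oracle_small(self):
        # the full-size sweep runs in the acceptance suite
        pairs, mismatches = cnphylo.oracle_sweep(2, 3)
        assert mismatches == 0 and pairs == 512

    def test_joint_cost_equals_reference_bfs_with_wgd(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            src = prof(rng.integers(0, 3, 3), rng.integers(0, 3, 3))
            tgt = prof(rng.integers(0, 3, 3), rng.integers(0, 3, 3))
            for wgd in (False, True):
                assert med_transform_cost(src, tgt, wgd) == \
                    bfs_event_cost(src, tgt, wgd, max_value=7)


class TestEventApplication:
    def test_loss_below_zero_rejected(self):
        with pytest.raises(ValueError, match="zero-copy"):
            apply_events(prof([1, 0]), [CNEvent("major", "chr1", 0, 1, "loss")])

    def test_gain_of_zero_segment_rejected(self):
        with pytest.raises(ValueError, match="zero-copy"):
            apply_events(prof([0, 1]), [CNEvent("major", "chr1", 0, 1, "gain")])

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_decomposition_replays_exactly(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 6))
        chroms = tuple(f"chr{1 + i // 3}" for i in range(n))
        src = prof(rng.integers(1, 4, n), rng.integers(0, 3, n),
                   chroms=chroms)
        tgt_major = rng.integers(0, 4, n)
        tgt_minor = np.where(src.minor == 0, 0, rng.integers(0, 4, n))
        tgt = prof(tgt_major, tgt_minor, chroms=chroms)
        events = decompose_difference(src, tgt, allow_wgd=True)
        replay = apply_events(src, events)
        assert (replay.major == tgt.major).all()
        assert (replay.minor == tgt.minor).all()
        assert len(events) == med_transform_cost(src, tgt, allow_wgd=True)


class TestDistanceMatrix:
    def test_identical_profiles_give_zero_matrix(self):
        ps = [prof([2, 1], sample=f"s{i}") for i in range(3)]
        d = pairwise_distance_matrix(ps)
        assert (d.to_numpy() == 0).all()

    def test_symmetry_and_zero_diagonal(self):
        rng = np.random.default_rng(5)
        ps = [prof(rng.integers(0, 4, 5), rng.integers(0, 3, 5),
                   sample=f"s{i}") for i in range(4)]
        d = pairwise_distance_matrix(ps, allow_wgd=True)
        assert np.allclose(d.to_numpy(), d.to_numpy().T)
        assert np.allclose(np.diag(d.to_numpy()), 0.0)

    def test_doubly_infeasible_pair_gets_sentinel(self):
        a = prof([0, 2], sample="a")
        b = prof([2, 0], sample="b")
        c = prof([2, 2], sample="c")
        d = pairwise_distance_matrix([a, b, c])
        finite_max = d.loc["a", "c"]
        assert d.loc["a", "b"] == 10 * max(finite_max, d.loc["b", "c"], 1)


class TestCnTree:
    def test_two_clades_of_identical_profiles(self):
        ps = ([prof([3, 3, 1, 1], sample=f"m{i}") for i in range(2)]
              + [prof([1, 1, 3, 3], sample=f"r{i}") for i in range(2)]
              + [diploid_profile("N", ("chr1",) * 4)])
        tree = cnphylo.build_cn_tree(pairwise_distance_matrix(ps), "N")
        assert check_monophyly(tree, {"m0", "m1"})
        assert check_monophyly(tree, {"r0", "r1"})

    def test_four_point_additive_distances_recovered(self):
        # additive tree ((a,b),(c,d)) with internal edge length 2
        names = ["a", "b", "c", "d"]
        dm = pd.DataFrame(
            [[0, 2, 5, 5], [2, 0, 5, 5], [5, 5, 0, 2], [5, 5, 2, 0]],
            index=names, columns=names, dtype=float)
        dm["N"] = [6.0, 6.0, 5.0, 5.0]
        dm.loc["N"] = [6.0, 6.0, 5.0, 5.0, 0.0]
        tree = cnphylo.build_cn_tree(dm, "N")
        assert check_monophyly(tree, {"a", "b"})
        assert check_monophyly(tree, {"c", "d"})

    def test_adding_normal_keeps_ingroup_topology(self):
        rng = np.random.default_rng(8)
        ps = [prof(rng.integers(1, 4, 6), rng.integers(0, 2, 6),
                   sample=f"s{i}") for i in range(5)]
        d_in = pairwise_distance_matrix(ps)
        from skbio import DistanceMatrix
        from skbio.tree import nj
        order = sorted(d_in.index)
        ingroup = nj(DistanceMatrix(d_in.loc[order, order].to_numpy(),
                                    ids=order))
        in_splits = {frozenset(t.name for t in n.tips())
                     for n in ingroup.non_tips()}
        full = ps + [diploid_profile("N", ps[0].chroms)]
        tree = cnphylo.build_cn_tree(pairwise_distance_matrix(full), "N")
        full_splits = {frozenset(t.name for t in n.tips()) - {"N"}
                       for n in tree.non_tips(include_self=True)}
        informative = {s for s in in_splits if 2 <= len(s) <= 3}
        assert all(s in full_splits or (set(order) - s) in full_splits
                   for s in informative)

    def test_all_zero_matrix_gives_star(self):
        names = ["a", "b", "c", "N"]
        dm = pd.DataFrame(0.0, index=names, columns=names)
        tree = cnphylo.build_cn_tree(dm, "N")
        assert len(tree.children) == 4


class TestMonophyly:
    def make_tree(self):
        ps = ([prof([3, 1], sample="a"), prof([3, 1], sample="b"),
               prof([1, 3], sample="c"), prof([1, 3], sample="d"),
               diploid_profile("N", ("chr1", "chr1"))])
        return cnphylo.build_cn_tree(pairwise_distance_matrix(ps), "N")

    def test_full_leaf_set_and_singletons(self):
        tree = self.make_tree()
        assert check_monophyly(tree, {"a", "b", "c", "d", "N"})
        assert check_monophyly(tree, {"a"})

    def test_cherry_splitting_set_is_not_monophyletic(self):
        tree = self.make_tree()
        assert not check_monophyly(tree, {"a", "c"})

    def test_unknown_sample_rejected(self):
        with pytest.raises(ValueError, match="unknown sample"):
            check_monophyly(self.make_tree(), {"nope"})


class TestBranchEvents:
    def build_case(self, wgd=False):
        chroms = ("chr1",) * 4 + ("chr2",) * 2
        base = np.array([2, 2, 1, 1, 2, 2])
        minor = np.ones(6, int)
        rel_major = base.copy()
        rel_major[0:2] += 1  # planted relapse-branch gain on chr1
        if wgd:
            rel_major = rel_major * 2
            rel_minor = minor * 2
        else:
            rel_minor = minor
        ps = ([CNProfile(f"m{i}", chroms, base, minor) for i in range(2)]
              + [CNProfile(f"r{i}", chroms, rel_major, rel_minor)
                 for i in range(3)]
              + [diploid_profile("N", chroms)])
        tree = cnphylo.build_cn_tree(
            pairwise_distance_matrix(ps, allow_wgd=True), "N")
        return tree, ps

    def test_planted_gain_recovered_on_ancestral_branch(self):
        tree, ps = self.build_case()
        events, parent, mrca = cnphylo.map_branch_events(
            tree, {"r0", "r1", "r2"}, ps, allow_wgd=True)
        assert len(events) == 1
        ev = events[0]
        assert (ev.allele, ev.chrom, ev.start, ev.end, ev.direction) == \
            ("major", "chr1", 0, 1, "gain")

    def test_planted_wgd_reported_as_single_event(self):
        tree, ps = self.build_case(wgd=True)
        events, parent, mrca = cnphylo.map_branch_events(
            tree, {"r0", "r1", "r2"}, ps, allow_wgd=True)
        assert sum(e.direction == "wgd" for e in events) == 1
        replay = apply_events(parent, events)
        assert (replay.major == mrca.major).all()
        assert (replay.minor == mrca.minor).all()

    def test_zero_planted_events_gives_empty_list(self):
        # metastases carry a private gain; the relapse branch carries none
        chroms = ("chr1",) * 3
        ps = ([CNProfile(f"m{i}", chroms, np.array([3, 1, 1]),
                         np.ones(3, int)) for i in range(2)]
              + [CNProfile(f"r{i}", chroms, np.array([2, 1, 1]),
                           np.ones(3, int)) for i in range(2)]
              + [diploid_profile("N", chroms)])
        tree = cnphylo.build_cn_tree(pairwise_distance_matrix(ps), "N")
        events, _, _ = cnphylo.map_branch_events(tree, {"r0", "r1"}, ps)
        assert events == []

    def test_non_monophyletic_clade_is_an_explicit_exclusion(self):
        tree, ps = self.build_case()
        with pytest.raises(cnphylo.NonMonophyleticCladeError):
            cnphylo.map_branch_events(tree, {"m0", "r0"}, ps)
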