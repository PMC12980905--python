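"""Clone-tree search, relapsing-clone rule and parsimony sample trees."""

import itertools

import numpy as np
import pandas as pd
import pytest

from conftest import make_meta
from crcrelapse import lineage
from crcrelapse.lineage import GERMLINE

LIVER = ["L_A", "L_B", "L_C", "LR_A", "LR_B", "LR_C"]


def prev(rows, columns=("s1", "s2")):
    return pd.DataFrame(rows, columns=list(columns),
                        index=list(range(len(rows))))


class TestConstraintGraph:
    def test_edge_allowed_within_epsilon(self):
        p = prev([[1.0, 1.0], [0.5, 0.4]])
        g = lineage.build_constraint_graph(p, 0.25)
        assert g.has_edge(0, 1)

    def test_edge_disallowed_when_child_exceeds_parent(self):
        p = prev([[0.1, 0.9], [0.5, 0.4]])
        g = lineage.build_constraint_graph(p, 0.25)
        assert not g.has_edge(0, 1)  # 0.1 < 0.5 - 0.25

    def test_every_cluster_reachable_from_root(self):
        rng = np.random.default_rng(0)
        p = prev(rng.uniform(size=(5, 3)), columns=["a", "b", "c"])
        g = lineage.build_constraint_graph(p, 0.25)
        import networkx as nx
        assert all(nx.has_path(g, GERMLINE, c) for c in p.index)


class TestTreeSearch:
    def test_chain_truth_recovered_with_score_zero(self):
        # any non-chain placement of cluster 2 overflows the sum condition
        # in sample s1, so the zero-score chain is unique
        p = prev([[1.0, 1.0], [0.9, 0.1], [0.6, 0.05]])
        g = lineage.build_constraint_graph(p, 0.25)
        tree = lineage.search_best_tree(g, p, 0.25)
        assert tree.score == 0
        assert tree.parent == {0: GERMLINE, 1: 0, 2: 1}

    def test_two_children_within_sum_slack(self):
        # children sums 1.1 and 0.3 against parent 1.0 with eps 0.25
        p = prev([[1.0, 1.0], [0.6, 0.1], [0.5, 0.2]])
        g = lineage.build_constraint_graph(p, 0.25)
        tree = lineage.search_best_tree(g, p, 0.25)
        assert tree.score == 0
        assert tree.parent[1] == 0 and tree.parent[2] == 0

    def test_branch_and_bound_equals_bruteforce_enumeration(self):
        rng = np.random.default_rng(42)
        for trial in range(25):
            k = int(rng.integers(3, 7))
            p = prev(np.round(rng.uniform(size=(k, 3)), 2),
                     columns=["a", "b", "c"])
            p.iloc[0] = 1.0  # truncal cluster
            g = lineage.build_constraint_graph(p, 0.25)
            best_bb = lineage.search_best_tree(g, p, 0.25)
            all_trees = lineage.enumerate_trees_bruteforce(g, p, 0.25)
            best_bf = min(score for _, score in all_trees)
            assert best_bb.score == pytest.approx(best_bf)

    def test_disconnected_dag_is_an_explicit_failure(self):
        import networkx as nx
        g = nx.DiGraph()
        g.add_node(GERMLINE)
        g.add_node(0)  # no edge from root
        p = prev([[0.5, 0.5]])
        with pytest.raises(ValueError, match="feasible parent"):
            lineage.search_best_tree(g, p, 0.25)


def presence_df(rows):
    return pd.DataFrame(rows, columns=LIVER,
                        index=list(range(len(rows))))


class TestRelapsingClone:
    def make_tree(self, prevalences):
        g = lineage.build_constraint_graph(prevalences, 0.25)
        return lineage.search_best_tree(g, prevalences, 0.25)

    def test_shared_pattern_cluster(self):
        p = pd.DataFrame([[1.0] * 6, [0, 0, 0.3, 0.6, 0.6, 0.6]],
                         columns=LIVER)
        tree = self.make_tree(p)
        presence = p >= 0.1
        call = lineage.identify_relapsing_clone(tree, presence,
                                                make_meta(LIVER))
        assert call.relapsing_cluster == 1
        assert call.pattern == "shared"
        assert call.containing_metastases == ("L_C",)

    def test_private_pattern_cluster(self):
        p = pd.DataFrame([[1.0] * 6, [0, 0, 0, 0.5, 0.5, 0.5]],
                         columns=LIVER)
        tree = self.make_tree(p)
        call = lineage.identify_relapsing_clone(tree, p >= 0.1,
                                                make_meta(LIVER))
        assert call.pattern == "private"

    def test_most_ancestral_candidate_selected(self):
        p = pd.DataFrame([[1.0] * 6,
                          [0, 0, 0, 0.8, 0.8, 0.8],
                          [0, 0, 0, 0.5, 0.5, 0.5]], columns=LIVER)
        tree = self.make_tree(p)
        assert tree.parent[2] == 1  # nested lineage (sum condition forces it)
        call = lineage.identify_relapsing_clone(tree, p >= 0.1,
                                                make_meta(LIVER))
        assert call.relapsing_cluster == 1

    def test_classify_pattern_from_presence(self):
        p = pd.DataFrame([[1.0] * 6, [0, 0, 0.3, 0.6, 0.6, 0.6]],
                         columns=LIVER)
        tree = self.make_tree(p)
        meta = make_meta(LIVER)
        call = lineage.identify_relapsing_clone(tree, p >= 0.1, meta)
        assert lineage.classify_relapse_pattern(call, p >= 0.1, meta) \
            == "shared"
        private = p.copy()
        private.loc[1, "L_C"] = 0.0
        assert lineage.classify_relapse_pattern(call, private >= 0.1, meta) \
            == "private"

    def test_no_candidate_gives_no_call_with_diagnostic(self):
        p = pd.DataFrame([[1.0] * 6], columns=LIVER)
        tree = self.make_tree(p)
        call = lineage.identify_relapsing_clone(tree, p >= 0.1,
                                                make_meta(LIVER))
        assert not call.is_call and call.reason

    def test_presence_threshold_boundary_governs_pattern(self):
        p = pd.DataFrame([[1.0] * 6,
                          [0, 0, 0.10, 0.6, 0.6, 0.6],
                          [0, 0, 0, 0, 0, 0]], columns=LIVER)
        tree = self.make_tree(p.iloc[:2])
        call = lineage.identify_relapsing_clone(tree, p.iloc[:2] >= 0.1,
                                                make_meta(LIVER))
        assert call.pattern == "shared"
        p.loc[1, "L_C"] = 0.0999
        call = lineage.identify_relapsing_clone(tree, p.iloc[:2] >= 0.1,
                                                make_meta(LIVER))
        assert call.pattern == "private"


# --- sample trees ----------------------------------------------------------

def oracle_min_fitch(presence: pd.DataFrame) -> int:
    """Independent brute force: recursive bipartitions + set-based Fitch."""
    samples = list(presence.columns)
    chars = [tuple(presence[s].iloc[i] for s in samples)
             for i in range(len(presence))]

    def fitch(tree, char_by_leaf):
        # tree: leaf name or (left, right); returns (state set, changes)
        if isinstance(tree, str):
            return {char_by_leaf[tree]}, 0
        (ls, lc), (rs, rc) = (fitch(t, char_by_leaf) for t in tree)
        inter = ls & rs
        if inter:
            return inter, lc + rc
        return ls | rs, lc + rc + 1

    def all_rooted_trees(leaves):
        if len(leaves) == 1:
            yield leaves[0]
            return
        first, rest = leaves[0], leaves[1:]
        for r in range(0, (1 << len(rest)) - 1):
            left = [first] + [rest[i] for i in range(len(rest))
                              if r & (1 << i)]
            right = [x for x in rest if x not in left]
            for lt in all_rooted_trees(left):
                for rt in all_rooted_trees(right):
                    yield (lt, rt)

    best = None
    for tree in all_rooted_trees(samples):
        total = 0
        for i in range(len(presence)):
            char_by_leaf = dict(zip(samples, (bool(x) for x in
                                              presence.iloc[i])))
            _, c = fitch(tree, char_by_leaf)
            total += c
        best = total if best is None else min(best, total)
    return best


class TestSampleTree:
    def make_presence(self, rows, samples):
        return pd.DataFrame(rows, columns=samples,
                            index=[f"m{i}" for i in range(len(rows))])

    def test_nested_presence_gives_caterpillar(self):
        samples = ["L_A", "L_B", "L_C", "N"]
        # S1 contains S2 contains S3: L_A+L_B+L_C, L_B+L_C, L_C
        rows = ([[1, 1, 1, 0]] * 3 + [[0, 1, 1, 0]] * 3 + [[0, 0, 1, 0]] * 3)
        pres = self.make_presence(rows, samples)
        st = lineage.build_sample_tree(pres, make_meta(samples))
        # the all-tumor class costs nothing; each nested class costs one
        # change per mutation: 3 + 3
        assert st.score == 6
        leaf_sets = set(st.leaf_sets().values())
        assert frozenset({"L_B", "L_C"}) in leaf_sets

    def test_identical_samples_score_counts_no_changes(self):
        samples = ["L_A", "L_B", "LR_A", "N"]
        pres = self.make_presence([[1, 1, 1, 0]] * 5, samples)
        st = lineage.build_sample_tree(pres, make_meta(samples))
        assert st.score == 0  # public mutations need no change among tumors

    def test_exhaustive_search_matches_independent_bruteforce(self):
        rng = np.random.default_rng(11)
        samples = ["L_A", "L_B", "L_C", "LR_A", "LR_B"]
        for _ in range(5):
            rows = rng.integers(0, 2, size=(12, 5))
            pres = self.make_presence(rows, samples + [])
            st = lineage.build_sample_tree(
                pres.assign(N=0), make_meta(samples + ["N"]))
            assert st.score == oracle_min_fitch(pres)

    def test_too_few_samples_rejected(self):
        pres = self.make_presence([[1, 0]], ["L_A", "N"])
        with pytest.raises(ValueError, match="at least 3"):
            lineage.build_sample_tree(pres, make_meta(["L_A", "N"]))


class TestCrossValidation:
    def build(self, rows, samples):
        pres = pd.DataFrame(rows, columns=samples,
                            index=[f"m{i}" for i in range(len(rows))])
        return lineage.build_sample_tree(pres, make_meta(samples))

    def test_shared_scenario_met_groups_with_relapses(self):
        samples = ["L_A", "L_B", "L_C", "LR_A", "LR_B", "LR_C", "N"]
        rows = ([[1] * 6 + [0]] * 4                     # truncal
                + [[1, 1, 0, 0, 0, 0, 0]] * 4           # met lineage
                + [[0, 0, 1, 1, 1, 1, 0]] * 6)          # relapsing lineage
        st = self.build(rows, samples)
        presence = pd.DataFrame(
            [[False, False, True, True, True, True]],
            columns=samples[:-1], index=["rc"])
        call = lineage.RelapseCall(relapsing_cluster="rc", pattern="shared")
        assert lineage.crossvalidate_sampletree(call, st, presence)

    def test_split_carriers_fail_crossvalidation(self):
        # carriers {L_A, LR_A} cannot be a clade in any optimal topology:
        # separating L_A from the metastasis clade or LR_A from the relapse
        # clade costs extra changes on the lineage characters
        samples = ["L_A", "L_B", "L_C", "LR_A", "LR_B", "LR_C", "N"]
        rows = ([[1] * 6 + [0]] * 4
                + [[1, 1, 1, 0, 0, 0, 0]] * 5           # metastasis lineage
                + [[0, 1, 1, 0, 0, 0, 0]] * 5
                + [[0, 0, 0, 1, 1, 1, 0]] * 5)
        st = self.build(rows, samples)
        presence = pd.DataFrame(
            [[True, False, False, True, False, False]],
            columns=samples[:-1], index=["rc"])
        call = lineage.RelapseCall(relapsing_cluster="rc", pattern="shared")
        assert not lineage.crossvalidate_sampletree(call, st, presence)

    def test_private_relapse_clade(self):
        samples = ["L_A", "L_B", "L_C", "LR_A", "LR_B", "LR_C", "N"]
        rows = ([[1] * 6 + [0]] * 4
                + [[0, 0, 0, 1, 1, 1, 0]] * 6)
        st = self.build(rows, samples)
        presence = pd.DataFrame(
            [[False, False, False, True, True, True]],
            columns=samples[:-1], index=["rc"])
        call = lineage.RelapseCall(relapsing_cluster="rc", pattern="private")
        assert lineage.crossvalidate_sampletree(call, st, presence)
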