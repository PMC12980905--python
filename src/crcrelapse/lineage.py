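"""Clone trees, relapsing-clone identification, and parsimony sample trees.

Cluster prevalences constrain ancestry under the infinite-sites assumption:
a cluster can only descend from a cluster whose prevalence is at least as
large in every sample (up to a slack epsilon), and the children of a node
cannot jointly exceed the parent's prevalence (again up to epsilon). Trees
are spanning arborescences of the resulting ancestry DAG rooted at an
implicit germline node; the retained tree minimizes the total sum-condition
overflow (score 0 = fully consistent), found by branch-and-bound with a
monotone partial score.

The relapsing cluster is the most ancestral cluster present in every
relapse sample but absent from at least one metastasis sample; the clone
introducing it is the relapsing clone, and the pattern is ``shared`` when
any metastasis sample carries it and ``private`` otherwise.

Sample trees cross-validate the clone-level calls: binary presence
characters are scored with Fitch small parsimony over an exhaustive
enumeration of unrooted leaf topologies, rooted at the matched normal.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

GERMLINE = "germline"


# ---------------------------------------------------------------------------
# Constraint DAG and tree search
# ---------------------------------------------------------------------------

def build_constraint_graph(prevalences: pd.DataFrame,
                           epsilon: float = 0.25) -> nx.DiGraph:
    """Ancestry DAG over clusters: i -> j allowed iff phi_i >= phi_j - eps
    in every sample; the germline root connects to everything."""
    if len(prevalences) < 1:
        raise ValueError("need at least one retained cluster")
    g = nx.DiGraph()
    g.add_node(GERMLINE)
    for c in prevalences.index:
        g.add_node(c)
        g.add_edge(GERMLINE, c)
    for i in prevalences.index:
        for j in prevalences.index:
            if i == j:
                continue
            if (prevalences.loc[i] >= prevalences.loc[j] - epsilon).all():
                g.add_edge(i, j)
    return g


@dataclass
class LineageTree:
    """Rooted clone tree over retained clusters plus the germline root."""

    parent: dict            # cluster -> parent (cluster or GERMLINE)
    score: float
    prevalences: pd.DataFrame
    epsilon: float
    n_trees_scored: int = 0

    def children(self, node) -> list:
        return sorted((c for c, p in self.parent.items() if p == node),
                      key=str)

    def root_children(self) -> list:
        return self.children(GERMLINE)

    def depth(self, node) -> int:
        d = 0
        while node != GERMLINE:
            node = self.parent[node]
            d += 1
        return d

    def to_newick(self) -> str:
        def render(node) -> str:
            kids = self.children(node)
            label = str(node)
            if not kids:
                return label
            return "(" + ",".join(render(k) for k in kids) + ")" + label
        return render(GERMLINE) + ";"


def _tree_score(parent: dict, prevalences: pd.DataFrame,
                epsilon: float) -> float:
    """Sum over (node, sample) of max(0, sum children phi - parent phi - eps)."""
    score = 0.0
    root_phi = pd.Series(1.0, index=prevalences.columns)
    nodes = [GERMLINE, *prevalences.index]
    for node in nodes:
        kids = [c for c, p in parent.items() if p == node]
        if not kids:
            continue
        child_sum = prevalences.loc[kids].sum(axis=0)
        parent_phi = root_phi if node == GERMLINE else prevalences.loc[node]
        score += float(np.maximum(0.0, child_sum - parent_phi - epsilon).sum())
    return score


def enumerate_trees_bruteforce(dag: nx.DiGraph, prevalences: pd.DataFrame,
                               epsilon: float) -> list[tuple[dict, float]]:
    """All spanning arborescences of the DAG with scores (small inputs)."""
    clusters = sorted((n for n in dag.nodes if n != GERMLINE), key=str)
    choices = [sorted(dag.predecessors(c), key=str) for c in clusters]
    out = []
    for combo in itertools.product(*choices):
        parent = dict(zip(clusters, combo))
        g = nx.DiGraph((p, c) for c, p in parent.items())
        if not nx.is_directed_acyclic_graph(g):
            continue
        out.append((parent, _tree_score(parent, prevalences, epsilon)))
    return out


def search_best_tree(dag: nx.DiGraph, prevalences: pd.DataFrame,
                     epsilon: float = 0.25) -> LineageTree:
    """Minimum-overflow spanning arborescence by branch-and-bound.

    Parents are assigned cluster by cluster (lexicographic order, candidate
    parents in sorted order, so ties resolve to the lexicographically first
    assignment). The partial score only grows as children are added, which
    makes it a valid bound. Raises when the DAG admits no arborescence.
    """
    clusters = sorted((n for n in dag.nodes if n != GERMLINE), key=str)
    if not clusters:
        raise ValueError("no clusters to arrange")
    choices = {c: sorted(dag.predecessors(c), key=str) for c in clusters}
    unreachable = [c for c in clusters if not choices[c]]
    if unreachable:
        raise ValueError(f"clusters without a feasible parent: {unreachable}")
    root_phi = np.ones(prevalences.shape[1])
    phi = {c: prevalences.loc[c].to_numpy() for c in clusters}
    phi[GERMLINE] = root_phi

    best: dict = {"score": math.inf, "parent": None, "count": 0}

    def creates_cycle(parent: dict, child, cand) -> bool:
        node = cand
        while node in parent:
            if node == child:
                return True
            node = parent[node]
        return node == child

    def node_overflow(parent: dict, node) -> float:
        kids = [c for c, p in parent.items() if p == node]
        if not kids:
            return 0.0
        s = np.sum([phi[k] for k in kids], axis=0)
        return float(np.maximum(0.0, s - phi[node] - epsilon).sum())

    def recurse(i: int, parent: dict, partial: float) -> None:
        if partial >= best["score"]:
            return
        if i == len(clusters):
            best["count"] += 1
            if partial < best["score"]:
                best["score"] = partial
                best["parent"] = dict(parent)
            return
        child = clusters[i]
        for cand in choices[child]:
            if creates_cycle(parent, child, cand):
                continue
            old = node_overflow(parent, cand)
            parent[child] = cand
            new_partial = partial - old + node_overflow(parent, cand)
            recurse(i + 1, parent, new_partial)
            del parent[child]

    recurse(0, {}, 0.0)
    if best["parent"] is None:
        raise ValueError("no spanning arborescence exists for the "
                         "constraint DAG")
    return LineageTree(parent=best["parent"], score=best["score"],
                       prevalences=prevalences, epsilon=epsilon,
                       n_trees_scored=best["count"])


# ---------------------------------------------------------------------------
# Relapsing clone
# ---------------------------------------------------------------------------

@dataclass
class RelapseCall:
    """The identified relapsing cluster/clone and its seeding pattern."""

    relapsing_cluster: object | None
    pattern: str | None                     # 'shared' | 'private' | None
    containing_metastases: tuple = ()
    candidates: tuple = ()
    reason: str = ""

    @property
    def is_call(self) -> bool:
        return self.relapsing_cluster is not None


def identify_relapsing_clone(tree: LineageTree, cluster_presence: pd.DataFrame,
                             meta: pd.DataFrame,
                             candidate_rule: str = "results") -> RelapseCall:
    """Find the relapsing cluster and classify the seeding pattern.

    Candidates are clusters present in every relapse sample and absent from
    at least one metastasis sample (default rule). ``candidate_rule=
    'methods'`` additionally requires presence in all non-metastasis tumor
    samples. The most ancestral candidate wins (minimum root distance; ties
    to larger mean prevalence, then lower cluster index). The clone
    introducing the winning cluster is the tree node of that cluster.
    """
    tissue = meta.loc[cluster_presence.columns, "tissue"]
    rel = [s for s in cluster_presence.columns if tissue[s] == "relapse"]
    met = [s for s in cluster_presence.columns if tissue[s] == "metastasis"]
    if not rel or not met:
        raise ValueError("need metastasis and relapse samples")
    cands = []
    for c in cluster_presence.index:
        row = cluster_presence.loc[c]
        if not row[rel].all() or row[met].all():
            continue
        if candidate_rule == "methods":
            other = [s for s in cluster_presence.columns
                     if tissue[s] not in ("metastasis", "normal")]
            if not row[other].all():
                continue
        elif candidate_rule != "results":
            raise ValueError(f"unknown candidate rule {candidate_rule!r}")
        cands.append(c)
    if not cands:
        return RelapseCall(relapsing_cluster=None, pattern=None,
                           reason="no cluster present in all relapse samples "
                                  "and absent from a metastasis sample")
    def sort_key(c):
        return (tree.depth(c),
                -float(tree.prevalences.loc[c].mean()),
                str(c))
    winner = min(cands, key=sort_key)
    containing = tuple(s for s in met if cluster_presence.loc[winner, s])
    pattern = "shared" if containing else "private"
    return RelapseCall(relapsing_cluster=winner, pattern=pattern,
                       containing_metastases=containing,
                       candidates=tuple(cands))


def classify_relapse_pattern(call: RelapseCall,
                             cluster_presence: pd.DataFrame,
                             meta: pd.DataFrame) -> str:
    """'shared' iff the relapsing cluster is present (prevalence >= the
    presence threshold baked into ``cluster_presence``) in >= 1 metastasis."""
    if not call.is_call:
        raise ValueError("no relapse call to classify")
    tissue = meta.loc[cluster_presence.columns, "tissue"]
    met = [s for s in cluster_presence.columns if tissue[s] == "metastasis"]
    return ("shared"
            if cluster_presence.loc[call.relapsing_cluster, met].any()
            else "private")


# ---------------------------------------------------------------------------
# Parsimony sample trees (Fitch on binary presence characters)
# ---------------------------------------------------------------------------

@dataclass
class SampleTree:
    """Rooted (at the normal) binary sample tree with its parsimony score."""

    children: dict           # node id -> (left, right) or () for leaves
    labels: dict             # node id -> sample name for leaves
    root: int
    score: int
    per_mutation: np.ndarray

    def leaf_sets(self) -> dict[int, frozenset]:
        out: dict[int, frozenset] = {}

        def walk(node: int) -> frozenset:
            kids = self.children[node]
            if not kids:
                out[node] = frozenset({self.labels[node]})
            else:
                out[node] = frozenset().union(*(walk(k) for k in kids))
            return out[node]

        walk(self.root)
        return out

    def to_newick(self) -> str:
        def render(node: int) -> str:
            kids = self.children[node]
            if not kids:
                return self.labels[node]
            return "(" + ",".join(render(k) for k in kids) + ")"
        return render(self.root) + ";"


def _enumerate_topologies(n_leaves: int):
    """All unrooted binary topologies by stepwise addition.

    Yields edge lists over nodes 0..n_leaves-1 (leaves) and internal ids
    >= n_leaves; enumeration order is deterministic.
    """
    if n_leaves < 3:
        raise ValueError("need >= 3 leaves")
    center = n_leaves  # internal node ids start above the leaf ids
    base = [(0, center), (1, center), (2, center)]
    trees = [(base, center + 1)]
    for leaf in range(3, n_leaves):
        nxt = []
        for edges, next_id in trees:
            for i, (a, b) in enumerate(edges):
                new_edges = edges[:i] + edges[i + 1:]
                new_edges = new_edges + [(a, next_id), (b, next_id),
                                         (leaf, next_id)]
                nxt.append((new_edges, next_id + 1))
        trees = nxt
    for edges, _ in trees:
        yield edges


def _root_edges(edges: list[tuple[int, int]], root_leaf: int
                ) -> tuple[dict, int, int]:
    """Orient an unrooted edge list away from a leaf; returns (children,
    root_internal, next_id). The root leaf's neighbor becomes the root."""
    adj: dict[int, list[int]] = {}
    for a, b in edges:
        adj.setdefault(a, []).append(b)
        adj.setdefault(b, []).append(a)
    start = adj[root_leaf][0]
    children: dict[int, tuple] = {}

    def walk(node: int, parent: int) -> None:
        kids = tuple(sorted(k for k in adj[node] if k != parent))
        children[node] = kids if len(adj[node]) > 1 else ()
        for k in kids:
            walk(k, node)

    walk(start, root_leaf)
    children[root_leaf] = ()
    return children, start, max(adj) + 1


def fitch_score(children: dict, root: int, leaf_states: dict[int, np.ndarray]
                ) -> np.ndarray:
    """Vectorized Fitch small parsimony over binary characters.

    ``leaf_states``: leaf node -> uint8 array of 0/1 states per mutation.
    Returns the per-mutation change counts. States are bitmasks (1 = {0},
    2 = {1}); intersection empty => union and one change.
    """
    n_char = len(next(iter(leaf_states.values())))
    score = np.zeros(n_char, dtype=np.int32)

    def walk(node: int) -> np.ndarray:
        kids = children[node]
        if not kids:
            return (leaf_states[node] + 1).astype(np.uint8)  # 0->1, 1->2
        sets = [walk(k) for k in kids]
        acc = sets[0]
        for s in sets[1:]:
            inter = acc & s
            union = acc | s
            miss = inter == 0
            score[miss] += 1
            acc = np.where(miss, union, inter).astype(np.uint8)
        return acc
    walk(root)
    return score


def build_sample_tree(presence: pd.DataFrame, meta: pd.DataFrame
                      ) -> SampleTree:
    """Maximum-parsimony sample tree over one patient's samples.

    Exhaustive search over unrooted topologies with the normal sample as
    outgroup root; binary presence characters scored by Fitch. The normal
    is treated as mutation-free. Deterministic: the first minimum in
    enumeration order is kept.
    """
    tissue = meta.loc[[s for s in presence.columns], "tissue"]
    tumor = [s for s in presence.columns if tissue[s] != "normal"]
    normals = [s for s in meta.index
               if meta.loc[s, "tissue"] == "normal"]
    if not normals:
        raise ValueError("no normal sample in metadata")
    if len(tumor) > 8:
        raise ValueError("exhaustive topology search limited to 8 tumor "
                         "samples")
    leaves = tumor + [normals[0]]
    if len(leaves) < 3:
        raise ValueError("need at least 3 samples")
    states = {}
    arr = presence[tumor].to_numpy(dtype=np.uint8).T
    for i, s in enumerate(tumor):
        states[i] = arr[i]
    states[len(tumor)] = np.zeros(presence.shape[0], dtype=np.uint8)
    root_leaf = len(tumor)
    best = None
    for edges in _enumerate_topologies(len(leaves)):
        children, start, _ = _root_edges(edges, root_leaf)
        per_mut = fitch_score(children, start, states)
        total = int(per_mut.sum())
        if best is None or total < best[0]:
            best = (total, children, start, per_mut)
    total, children, start, per_mut = best
    # attach the normal leaf under a new root above `start`
    root_id = max(children) + 1 if children else root_leaf + 1
    children = dict(children)
    children[root_id] = (start, root_leaf)
    labels = {i: s for i, s in enumerate(leaves)}
    return SampleTree(children=children, labels=labels, root=root_id,
                      score=total, per_mutation=per_mut)


def crossvalidate_sampletree(call: RelapseCall, sample_tree: SampleTree,
                             cluster_presence: pd.DataFrame,
                             ignore: tuple[str, ...] = ()) -> bool:
    """True iff the samples carrying the relapsing cluster form a clade.

    ``ignore`` lists samples (e.g. the FFPE primary) pruned from both the
    carrier set and the clade comparison.
    """
    if not call.is_call:
        raise ValueError("no relapse call to cross-validate")
    carriers = {s for s in cluster_presence.columns
                if cluster_presence.loc[call.relapsing_cluster, s]
                and s not in ignore}
    leaf_sets = sample_tree.leaf_sets()
    normal = sample_tree.labels[max(k for k, v in sample_tree.labels.items())]
    for nodes, ls in leaf_sets.items():
        pruned = ls - set(ignore) - {normal}
        if pruned == carriers and pruned:
            return True
    # the carrier set may also be the complement clade next to the root
    all_tumor = (set(sample_tree.labels.values()) - {normal}) - set(ignore)
    return carriers == all_tumor
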