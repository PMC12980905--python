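"""Minimum-event copy-number phylogenies.

Allele-specific integer copy-number profiles over a shared segmentation are
compared under a segmental event model:

* an event is a +/-1 change over a contiguous run of segments of one allele
  within one chromosome;
* a loss event requires every segment in its run to be >= 1 (no loss below
  zero), and a gain event likewise (a segment at zero copies cannot be
  regained -- zero absorption);
* optionally a whole-genome duplication (WGD) doubling both alleles of all
  segments may be applied once, before any other event, at cost 1.

The minimum-event distance (MED) between two profiles is the length of the
shortest event sequence transforming one into the other. A breadth-first
search over profile states (:func:`bfs_event_cost`) is the defining
reference; :func:`med_transform_cost` is the closed form (per-allele,
per-chromosome adjacent differences of the gain and loss components), which
the test suite proves equal to the BFS on an exhaustive sweep.

Sample trees are built by neighbor joining on symmetrized MED distances,
rooted at the diploid normal; monophyly of the relapsing-clone samples is
required before copy-number events are mapped onto the ancestral branch of
that clade.
"""

from __future__ import annotations

import itertools
import math
from collections import deque
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj


class NonMonophyleticCladeError(ValueError):
    """The queried samples do not form a clade; event mapping is undefined."""


@dataclass
class CNProfile:
    """Allele-specific integer copy numbers over an ordered segmentation."""

    sample: str
    chroms: tuple[str, ...]
    major: np.ndarray
    minor: np.ndarray

    def __post_init__(self) -> None:
        self.major = np.asarray(self.major, dtype=int)
        self.minor = np.asarray(self.minor, dtype=int)
        if not (len(self.chroms) == len(self.major) == len(self.minor)):
            raise ValueError("chroms/major/minor lengths differ")
        if (self.major < 0).any() or (self.minor < 0).any():
            raise ValueError("copy numbers must be >= 0")

    def same_segmentation(self, other: "CNProfile") -> bool:
        return self.chroms == other.chroms

    def total(self) -> np.ndarray:
        return self.major + self.minor


def diploid_profile(sample: str, chroms: tuple[str, ...]) -> CNProfile:
    n = len(chroms)
    return CNProfile(sample, chroms, np.ones(n, int), np.ones(n, int))


@dataclass(frozen=True)
class CNEvent:
    """A segmental +/-1 event, or a WGD.

    ``start``/``end`` are inclusive global segment indices; for a WGD both
    are -1, ``allele`` is 'both' and ``chrom`` is '*'.
    """

    allele: str          # 'major' | 'minor' | 'both'
    chrom: str
    start: int
    end: int
    direction: str       # 'gain' | 'loss' | 'wgd'

    @staticmethod
    def wgd() -> "CNEvent":
        return CNEvent("both", "*", -1, -1, "wgd")


def apply_event(major: np.ndarray, minor: np.ndarray,
                chroms: tuple[str, ...], event: CNEvent
                ) -> tuple[np.ndarray, np.ndarray]:
    """Apply one event, enforcing the model's validity rules."""
    major, minor = major.copy(), minor.copy()
    if event.direction == "wgd":
        return major * 2, minor * 2
    sl = slice(event.start, event.end + 1)
    if len(set(chroms[sl])) != 1 or chroms[event.start] != event.chrom:
        raise ValueError(f"event {event} spans chromosome boundaries")
    target = major if event.allele == "major" else minor
    if (target[sl] < 1).any():
        verb = "lose" if event.direction == "loss" else "gain"
        raise ValueError(f"cannot {verb} a zero-copy segment: {event}")
    target[sl] += 1 if event.direction == "gain" else -1
    return major, minor


def apply_events(profile: CNProfile, events: list[CNEvent],
                 sample: str | None = None) -> CNProfile:
    major, minor = profile.major, profile.minor
    for ev in events:
        major, minor = apply_event(major, minor, profile.chroms, ev)
    return CNProfile(sample or profile.sample, profile.chroms, major, minor)


# ---------------------------------------------------------------------------
# Minimum-event distance: closed form and BFS reference
# ---------------------------------------------------------------------------

def _adjacent_diff(component: np.ndarray) -> int:
    """Number of interval +/-1 events to realize a nonnegative component."""
    prev = 0
    total = 0
    for value in component:
        if value > prev:
            total += value - prev
        prev = value
    return int(total)


def _allele_cost(src: np.ndarray, tgt: np.ndarray,
                 chroms: tuple[str, ...]) -> float:
    """Minimum events transforming one allele's vector into another."""
    if ((src == 0) & (tgt > 0)).any():
        return math.inf
    cost = 0
    chrom_arr = np.asarray(chroms)
    for chrom in dict.fromkeys(chroms):  # preserve order
        sel = chrom_arr == chrom
        d = tgt[sel].astype(int) - src[sel].astype(int)
        cost += _adjacent_diff(np.maximum(d, 0))
        cost += _adjacent_diff(np.maximum(-d, 0))
    return cost


def med_transform_cost(src: CNProfile, tgt: CNProfile,
                       allow_wgd: bool = False) -> float:
    """Minimum number of events transforming ``src`` into ``tgt``.

    Returns ``math.inf`` when infeasible (a zero-copy segment in the source
    with positive target copies; a WGD cannot rescue it since doubling zero
    is zero).
    """
    if not src.same_segmentation(tgt):
        raise ValueError("profiles are on different segmentations")
    plain = (_allele_cost(src.major, tgt.major, src.chroms)
             + _allele_cost(src.minor, tgt.minor, src.chroms))
    if not allow_wgd:
        return plain
    doubled = 1 + (_allele_cost(src.major * 2, tgt.major, src.chroms)
                   + _allele_cost(src.minor * 2, tgt.minor, src.chroms))
    return min(plain, doubled)


def _interval_moves(state: tuple[int, ...], blocks: list[tuple[int, int]]
                    ) -> list[tuple[int, ...]]:
    out = []
    for lo, hi in blocks:
        for i in range(lo, hi + 1):
            for j in range(i, hi + 1):
                seg = state[i:j + 1]
                if min(seg) >= 1:
                    out.append(state[:i] + tuple(v + 1 for v in seg)
                               + state[j + 1:])
                    out.append(state[:i] + tuple(v - 1 for v in seg)
                               + state[j + 1:])
    return out


def bfs_allele_cost(src, tgt, chroms: tuple[str, ...] | None = None,
                    max_value: int | None = None) -> float:
    """Defining BFS shortest-path cost for a single allele vector.

    Exhaustive breadth-first search over bounded copy-number states under
    the interval event rules. Exponential in length; intended for small
    reference computations.
    """
    src, tgt = tuple(int(v) for v in src), tuple(int(v) for v in tgt)
    if chroms is None:
        chroms = ("chr1",) * len(src)
    if max_value is None:
        max_value = max(max(src, default=0), max(tgt, default=0)) + 1
    blocks = []
    chrom_arr = list(chroms)
    start = 0
    for i in range(1, len(chrom_arr) + 1):
        if i == len(chrom_arr) or chrom_arr[i] != chrom_arr[start]:
            blocks.append((start, i - 1))
            start = i
    if src == tgt:
        return 0
    seen = {src}
    queue = deque([(src, 0)])
    while queue:
        state, cost = queue.popleft()
        for nxt in _interval_moves(state, blocks):
            if max(nxt) > max_value or nxt in seen:
                continue
            if nxt == tgt:
                return cost + 1
            seen.add(nxt)
            queue.append((nxt, cost + 1))
    return math.inf


def bfs_event_cost(src: CNProfile, tgt: CNProfile,
                   allow_wgd: bool = False,
                   max_value: int | None = None) -> float:
    """Defining BFS cost on a full profile (both alleles, optional WGD).

    Without a WGD, events touch one allele only, so the joint cost is the
    sum of per-allele BFS costs; the WGD route doubles both alleles first
    at cost 1.
    """
    plain = (bfs_allele_cost(src.major, tgt.major, src.chroms, max_value)
             + bfs_allele_cost(src.minor, tgt.minor, src.chroms, max_value))
    if not allow_wgd:
        return plain
    doubled = 1 + (bfs_allele_cost(src.major * 2, tgt.major, src.chroms,
                                   max_value)
                   + bfs_allele_cost(src.minor * 2, tgt.minor, src.chroms,
                                     max_value))
    return min(plain, doubled)


def _bfs_all_costs(src: tuple[int, ...], bound: int,
                   neighbor_cache: dict) -> dict[tuple[int, ...], int]:
    """BFS distances from one source to every reachable bounded state."""
    dist = {src: 0}
    queue = deque([src])
    while queue:
        state = queue.popleft()
        key = (state, bound)
        nbrs = neighbor_cache.get(key)
        if nbrs is None:
            nbrs = [s for s in _interval_moves(state,
                                               [(0, len(state) - 1)])
                    if max(s) <= bound]
            neighbor_cache[key] = nbrs
        for nxt in nbrs:
            if nxt not in dist:
                dist[nxt] = dist[state] + 1
                queue.append(nxt)
    return dist


def oracle_sweep(n_segments: int, max_value: int,
                 check_wgd_sources: bool = True) -> tuple[int, int]:
    """Exhaustively compare the closed-form allele cost with the BFS oracle.

    Sweeps every ordered pair of single-chromosome vectors of the given
    length with values in 0..max_value (and, when ``check_wgd_sources``,
    every doubled source against the same targets, which is the WGD route
    of the full distance). Returns (pairs checked, mismatches). Intermediate
    states are allowed one unit of overshoot beyond the sweep maximum.
    """
    chroms = ("chr1",) * n_segments
    values = range(max_value + 1)
    vectors = list(itertools.product(values, repeat=n_segments))
    pairs = 0
    mismatches = 0
    sources = [(v, 1) for v in vectors]
    if check_wgd_sources:
        sources += [(tuple(2 * x for x in v), 2) for v in vectors]
    cache: dict = {}
    for src, mult in sources:
        bound = max(max(src, default=0), max_value) + 1
        dist = _bfs_all_costs(src, bound, cache)
        src_arr = np.array(src)
        for tgt in vectors:
            fast = _allele_cost(src_arr, np.array(tgt), chroms)
            slow = dist.get(tgt, math.inf)
            pairs += 1
            if fast != slow:
                mismatches += 1
    return pairs, mismatches


# ---------------------------------------------------------------------------
# Distances and trees
# ---------------------------------------------------------------------------

def pairwise_distance_matrix(profiles: list[CNProfile],
                             allow_wgd: bool = False) -> pd.DataFrame:
    """Symmetrized MED matrix: d(a,b) = min of the two directed costs.

    When both directions are infeasible, a sentinel of 10x the largest
    finite distance in the matrix is used.
    """
    if len(profiles) < 2:
        raise ValueError("need at least 2 profiles")
    names = [p.sample for p in profiles]
    n = len(profiles)
    d = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        ab = med_transform_cost(profiles[i], profiles[j], allow_wgd)
        ba = med_transform_cost(profiles[j], profiles[i], allow_wgd)
        d[i, j] = d[j, i] = min(ab, ba)
    finite = d[np.isfinite(d)]
    sentinel = 10.0 * (finite.max() if finite.size else 1.0)
    d[~np.isfinite(d)] = max(sentinel, 10.0)
    return pd.DataFrame(d, index=names, columns=names)


def build_cn_tree(distance_matrix: pd.DataFrame, normal_id: str) -> TreeNode:
    """Neighbor-joining tree over samples, rooted at the diploid normal.

    Samples are ordered lexicographically before agglomeration so ties
    resolve deterministically. An all-zero matrix yields a star tree.
    """
    if normal_id not in distance_matrix.index:
        raise ValueError(f"normal sample {normal_id!r} not in matrix")
    if len(distance_matrix) < 3:
        raise ValueError("need at least 3 samples")
    order = sorted(distance_matrix.index)
    dm = distance_matrix.loc[order, order]
    if np.allclose(dm.to_numpy(), 0.0):
        root = TreeNode(name="root")
        for s in order:
            root.append(TreeNode(name=s, length=0.0))
        return root
    tree = nj(DistanceMatrix(dm.to_numpy(), ids=order))
    return root_at_leaf(tree, normal_id)


def root_at_leaf(tree: TreeNode, leaf_name: str) -> TreeNode:
    """Root an unrooted tree so that ``leaf_name`` hangs off the root."""
    tree = tree.copy()
    leaf = tree.find(leaf_name)
    parent = leaf.parent
    if parent is None:  # already the root
        return tree
    rooted = tree.root_at(parent)
    return rooted


def clade_leafsets(tree: TreeNode) -> list[frozenset]:
    return [frozenset(t.name for t in node.tips()) or frozenset({node.name})
            for node in tree.traverse(include_self=True)
            if not node.is_tip()] + \
           [frozenset({t.name}) for t in tree.tips()]


def check_monophyly(tree: TreeNode, sample_set) -> bool:
    """True iff ``sample_set`` is exactly the leaf set of some clade."""
    wanted = frozenset(sample_set)
    tips = {t.name for t in tree.tips()}
    unknown = wanted - tips
    if unknown:
        raise ValueError(f"unknown sample id(s): {sorted(unknown)}")
    return wanted in set(clade_leafsets(tree))


# ---------------------------------------------------------------------------
# Ancestral states and branch events
# ---------------------------------------------------------------------------

def _sankoff_states(tree: TreeNode, leaf_values: dict[str, int],
                    root_value: int = 1) -> dict[int, int]:
    """Minimum total |delta| assignment of one segment/allele over the tree.

    Candidate states are the values observed at leaves plus ``root_value``
    (the diploid-normal state, always a candidate). The root state is not
    pinned: the normal leaf anchors the estimate through its zero-cost
    state. Returns ``id(node) -> state``; ties break toward the smaller
    state.
    """
    states = sorted(set(leaf_values.values()) | {root_value})
    cost: dict[int, dict[int, float]] = {}
    for node in tree.postorder(include_self=True):
        if node.is_tip():
            v = leaf_values[node.name]
            cost[id(node)] = {s: (0.0 if s == v else math.inf) for s in states}
        else:
            cost[id(node)] = {
                s: sum(min(cost[id(ch)][t] + abs(s - t) for t in states)
                       for ch in node.children)
                for s in states
            }
    assign: dict[int, int] = {}
    for node in tree.preorder(include_self=True):
        if node.parent is None:
            assign[id(node)] = min(states,
                                   key=lambda s: (cost[id(node)][s], s))
        else:
            parent_state = assign[id(node.parent)]
            assign[id(node)] = min(
                states, key=lambda s: (cost[id(node)][s]
                                       + abs(parent_state - s), s))
    return assign


def decompose_difference(src: CNProfile, tgt: CNProfile,
                         allow_wgd: bool = False) -> list[CNEvent]:
    """Minimal explicit event list transforming ``src`` into ``tgt``.

    A WGD is emitted as a single leading event when it strictly reduces the
    total event count. Replaying the returned list from ``src`` reproduces
    ``tgt`` exactly (validated).
    """
    if not src.same_segmentation(tgt):
        raise ValueError("profiles are on different segmentations")
    plain = med_transform_cost(src, tgt, allow_wgd=False)
    use_wgd = False
    if allow_wgd:
        doubled = 1 + (_allele_cost(src.major * 2, tgt.major, src.chroms)
                       + _allele_cost(src.minor * 2, tgt.minor, src.chroms))
        use_wgd = doubled < plain
    if not use_wgd and math.isinf(plain):
        raise ValueError("infeasible transformation (zero-copy segment "
                         "with positive target)")
    events: list[CNEvent] = []
    base_major, base_minor = src.major.copy(), src.minor.copy()
    if use_wgd:
        events.append(CNEvent.wgd())
        base_major, base_minor = base_major * 2, base_minor * 2
    chrom_arr = np.asarray(src.chroms)
    for allele, base, target in (("major", base_major, tgt.major),
                                 ("minor", base_minor, tgt.minor)):
        d = target.astype(int) - base.astype(int)
        for direction, comp in (("gain", np.maximum(d, 0)),
                                ("loss", np.maximum(-d, 0))):
            for layer in range(1, int(comp.max(initial=0)) + 1):
                active = comp >= layer
                i = 0
                n = len(active)
                while i < n:
                    if not active[i]:
                        i += 1
                        continue
                    j = i
                    while (j + 1 < n and active[j + 1]
                           and chrom_arr[j + 1] == chrom_arr[i]):
                        j += 1
                    events.append(CNEvent(allele, str(chrom_arr[i]), i, j,
                                          direction))
                    i = j + 1
    # gains first, then losses, preserving relative order (validity proof
    # relies on applying gains before losses)
    order = {"wgd": 0, "gain": 1, "loss": 2}
    events.sort(key=lambda e: order[e.direction])
    replayed = apply_events(src, events)
    if not (np.array_equal(replayed.major, tgt.major)
            and np.array_equal(replayed.minor, tgt.minor)):  # pragma: no cover
        raise AssertionError("event decomposition failed replay check")
    return events


def map_branch_events(tree: TreeNode, clade_samples, profiles: list[CNProfile],
                      allow_wgd: bool = False
                      ) -> tuple[list[CNEvent], CNProfile, CNProfile]:
    """Events on the ancestral branch of a monophyletic sample clade.

    Ancestral profiles at the clade MRCA and its parent are estimated per
    segment and allele by minimum total |change| over the rooted tree
    (candidate states = values observed at leaves; segments independent).
    Returns ``(events, parent_profile, mrca_profile)``.

    Raises :class:`NonMonophyleticCladeError` when the samples do not form
    a clade (such patients are excluded from branch-event mapping).
    """
    clade = sorted(clade_samples)
    if not check_monophyly(tree, clade):
        raise NonMonophyleticCladeError(
            f"samples {clade} do not form a monophyletic clade")
    by_name = {p.sample: p for p in profiles}
    tips = [t.name for t in tree.tips()]
    missing = set(tips) - set(by_name)
    if missing:
        raise ValueError(f"profiles missing for samples: {sorted(missing)}")
    chroms = profiles[0].chroms
    n_seg = len(chroms)
    if len(clade) == 1:
        mrca = tree.find(clade[0])
    else:
        mrca = tree.lca(clade)
    parent = mrca.parent
    if parent is None:
        raise ValueError("clade ancestral branch undefined: clade spans "
                         "the whole tree")
    mrca_major = np.zeros(n_seg, int)
    mrca_minor = np.zeros(n_seg, int)
    par_major = np.zeros(n_seg, int)
    par_minor = np.zeros(n_seg, int)
    for seg in range(n_seg):
        for allele, mrca_vec, par_vec in (("major", mrca_major, par_major),
                                          ("minor", mrca_minor, par_minor)):
            leaf_values = {
                name: int(getattr(by_name[name], allele)[seg]) for name in tips
            }
            assign = _sankoff_states(tree, leaf_values, root_value=1)
            mrca_vec[seg] = assign[id(mrca)]
            par_vec[seg] = assign[id(parent)]
    parent_profile = CNProfile("ancestor", chroms, par_major, par_minor)
    mrca_profile = CNProfile("clade_mrca", chroms, mrca_major, mrca_minor)
    events = decompose_difference(parent_profile, mrca_profile,
                                  allow_wgd=allow_wgd)
    return events, parent_profile, mrca_profile
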