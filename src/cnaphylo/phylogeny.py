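"""Per-patient tree inference from fragmented copy-number profiles.

A pseudo-sample with CN 2 everywhere ("diploid") is appended to the matrix,
pairwise relaxed minimum-event distances are computed, an unrooted
neighbour-joining tree is built (ties broken lexicographically so the result
is independent of input order), and the tree is rooted at the diploid
pseudo-leaf — encoding the assumption that every tumour lineage starts from
a normal diploid genome.  Negative NJ branch lengths are clamped to zero and
zero-length internal edges are collapsed: an ancestor separated from its
parent by no events is not a distinct ancestral population.

Integer ancestral profiles are reconstructed per fragment by a Sankoff
dynamic programme with per-edge cost |child - parent| and the root fixed at
CN 2; co-optimal states resolve to the smallest copy number.  Branch event
counts are then the strict directed minimum-event distances along each edge
(falling back to the relaxed symmetric count where the strict model deems
the child unreachable).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import UsageError
from .io_segments import FragmentedMatrix
from .med_distance import (
    UNREACHABLE,
    CNVector,
    cn_vector,
    directed_event_count,
    pairwise_symmetric,
    symmetric_distance,
)

DIPLOID_ID = "diploid"

_ROMAN = (
    (1000, "m"), (900, "cm"), (500, "d"), (400, "cd"), (100, "c"), (90, "xc"),
    (50, "l"), (40, "xl"), (10, "x"), (9, "ix"), (5, "v"), (4, "iv"),
    (1, "i"),
)


def to_roman(n: int) -> str:
    out = []
    for value, numeral in _ROMAN:
        while n >= value:
            out.append(numeral)
            n -= value
    return "".join(out)


@dataclass
class PhyloTree:
    """Rooted tree over one patient's samples.

    The root is the diploid pseudo-sample; internal nodes carry roman-numeral
    labels assigned in pre-order.  ``branch_lengths``/``branch_events`` map a
    node id to the length/events of the edge *into* that node.
    """

    root: str
    children: dict[str, list[str]]
    parent: dict[str, str | None]
    branch_lengths: dict[str, float] = field(default_factory=dict)
    branch_events: dict[str, float] = field(default_factory=dict)
    ancestral_profiles: dict[str, CNVector] = field(default_factory=dict)
    clade_support: dict[str, float] = field(default_factory=dict)

    # -- structure ---------------------------------------------------------
    def nodes(self) -> list[str]:
        return self.preorder()

    def is_leaf(self, node: str) -> bool:
        return not self.children.get(node)

    def leaves(self) -> list[str]:
        return [n for n in self.preorder() if self.is_leaf(n)]

    def internal_nodes(self) -> list[str]:
        return [n for n in self.preorder() if n != self.root and not self.is_leaf(n)]

    def role(self, node: str) -> str:
        if node == self.root:
            return "root"
        return "leaf" if self.is_leaf(node) else "ancestor"

    def preorder(self) -> list[str]:
        out: list[str] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(reversed(self.children.get(node, [])))
        return out

    def postorder(self) -> list[str]:
        out: list[str] = []

        def walk(node: str) -> None:
            for child in self.children.get(node, []):
                walk(child)
            out.append(node)

        walk(self.root)
        return out

    def leaves_under(self, node: str) -> frozenset[str]:
        acc = set()
        stack = [node]
        while stack:
            cur = stack.pop()
            kids = self.children.get(cur, [])
            if kids:
                stack.extend(kids)
            else:
                acc.add(cur)
        return frozenset(acc)

    def depth(self, node: str) -> int:
        d = 0
        while self.parent.get(node) is not None:
            node = self.parent[node]  # type: ignore[assignment]
            d += 1
        return d

    def copy(self) -> "PhyloTree":
        return PhyloTree(
            self.root,
            {k: list(v) for k, v in self.children.items()},
            dict(self.parent),
            dict(self.branch_lengths),
            dict(self.branch_events),
            dict(self.ancestral_profiles),
            dict(self.clade_support),
        )

    # -- output ------------------------------------------------------------
    def newick(self, lengths: str = "events", include_support: bool = False) -> str:
        use = self.branch_events if lengths == "events" and self.branch_events else self.branch_lengths

        def fmt(node: str) -> str:
            kids = self.children.get(node, [])
            label = node
            if include_support and node in self.clade_support:
                label += f"[&support={self.clade_support[node]:.3f}]"
            body = f"({','.join(fmt(k) for k in kids)}){label}" if kids else label
            if node != self.root:
                length = use.get(node, 0.0)
                body += f":{length:g}"
            return body

        return fmt(self.root) + ";"


# ---------------------------------------------------------------------------
# Neighbour joining
# ---------------------------------------------------------------------------

def _neighbor_joining(dist: np.ndarray, labels: list[str]):
    """Unrooted NJ; deterministic tie-breaks on each cluster's smallest leaf.

    Returns (adjacency {node: {neighbour: length}}, internal node counter).
    """
    n = len(labels)
    if n < 3:
        raise UsageError("neighbour joining needs at least 3 taxa")
    active = list(labels)
    d = {a: {b: float(dist[i, j]) for j, b in enumerate(labels)} for i, a in enumerate(labels)}
    key = {a: a for a in labels}  # smallest leaf label in each cluster
    adj: dict[str, dict[str, float]] = {a: {} for a in labels}
    counter = 0

    while len(active) > 3:
        m = len(active)
        r = {a: sum(d[a][b] for b in active if b != a) for a in active}
        best = None
        for ii in range(m):
            for jj in range(ii + 1, m):
                a, b = active[ii], active[jj]
                q = (m - 2) * d[a][b] - r[a] - r[b]
                pair_key = tuple(sorted((key[a], key[b])))
                cand = (q, pair_key)
                if best is None or cand < best[0:2]:
                    best = (q, pair_key, a, b)
        _, _, a, b = best  # type: ignore[misc]
        la = 0.5 * d[a][b] + (r[a] - r[b]) / (2 * (m - 2))
        lb = d[a][b] - la
        new = f"_nj{counter}"
        counter += 1
        adj[new] = {}
        adj[new][a] = la
        adj[a][new] = la
        adj[new][b] = lb
        adj[b][new] = lb
        d[new] = {}
        for c in active:
            if c in (a, b):
                continue
            dc = 0.5 * (d[a][c] + d[b][c] - d[a][b])
            d[new][c] = dc
            d[c][new] = dc
        d[new][new] = 0.0
        key[new] = min(key[a], key[b])
        active = [c for c in active if c not in (a, b)] + [new]

    a, b, c = sorted(active, key=lambda x: key[x])
    centre = f"_nj{counter}"
    counter += 1
    adj[centre] = {}
    key[centre] = min(key[a], key[b], key[c])
    la = 0.5 * (d[a][b] + d[a][c] - d[b][c])
    lb = 0.5 * (d[a][b] + d[b][c] - d[a][c])
    lc = 0.5 * (d[a][c] + d[b][c] - d[a][b])
    for node, length in ((a, la), (b, lb), (c, lc)):
        adj[centre][node] = length
        adj[node][centre] = length
    return adj, key


def build_tree(matrix: FragmentedMatrix) -> PhyloTree:
    """Diploid-rooted NJ tree from a fragmented matrix (one patient)."""
    samples = list(matrix.sample_ids)
    if len(samples) < 3:
        raise UsageError("build_tree needs at least 3 samples")
    if len(set(samples)) != len(samples):
        raise UsageError("duplicate sample ids")
    if DIPLOID_ID in samples:
        raise UsageError(f"sample id {DIPLOID_ID!r} is reserved for the pseudo-root")

    order = sorted(samples)
    breaks = matrix.chromosome_breaks()
    vectors = [matrix.cn_vector(s) for s in order]
    vectors.append(cn_vector([2] * matrix.n_fragments, breaks))
    labels = order + [DIPLOID_ID]
    dist = pairwise_symmetric(vectors)

    adj, key = _neighbor_joining(dist, labels)

    # Root at the diploid pseudo-leaf: direct all edges away from it.
    children: dict[str, list[str]] = {}
    parent: dict[str, str | None] = {DIPLOID_ID: None}
    lengths: dict[str, float] = {}
    stack = [DIPLOID_ID]
    seen = {DIPLOID_ID}
    while stack:
        node = stack.pop()
        kids = sorted((k for k in adj[node] if k not in seen), key=lambda x: key[x])
        children[node] = kids
        for k in kids:
            parent[k] = node
            lengths[k] = max(0.0, adj[node][k])  # clamp negative NJ lengths
            seen.add(k)
            stack.append(k)

    tree = PhyloTree(DIPLOID_ID, children, parent, lengths)
    _collapse_zero_internal_edges(tree)
    _relabel_internal(tree)
    return tree


def _collapse_zero_internal_edges(tree: PhyloTree, eps: float = 1e-6) -> None:
    changed = True
    while changed:
        changed = False
        for node in tree.postorder():
            if node == tree.root or tree.is_leaf(node):
                continue
            if tree.branch_lengths.get(node, 0.0) <= eps:
                _remove_internal(tree, node)
                changed = True
                break


def _remove_internal(tree: PhyloTree, node: str) -> None:
    par = tree.parent[node]
    assert par is not None
    kids = tree.children.pop(node)
    slot = tree.children[par].index(node)
    tree.children[par][slot : slot + 1] = kids
    for k in kids:
        tree.parent[k] = par
    for store in (tree.branch_lengths, tree.branch_events, tree.clade_support):
        store.pop(node, None)
    tree.ancestral_profiles.pop(node, None)
    tree.parent.pop(node)


def _relabel_internal(tree: PhyloTree) -> None:
    """Assign roman-numeral labels to internal nodes in pre-order."""
    mapping: dict[str, str] = {}
    idx = 0
    for node in tree.preorder():
        if node != tree.root and not tree.is_leaf(node):
            idx += 1
            mapping[node] = to_roman(idx)
    taken = set(tree.preorder())
    clash = set(mapping.values()) & (taken - set(mapping))
    if clash:
        raise UsageError(f"sample ids collide with internal labels: {sorted(clash)}")
    tree.children = {
        mapping.get(k, k): [mapping.get(c, c) for c in v] for k, v in tree.children.items()
    }
    tree.parent = {
        mapping.get(k, k): (mapping.get(v, v) if v is not None else None)
        for k, v in tree.parent.items()
    }
    for store_name in ("branch_lengths", "branch_events", "clade_support", "ancestral_profiles"):
        store = getattr(tree, store_name)
        setattr(tree, store_name, {mapping.get(k, k): v for k, v in store.items()})


# ---------------------------------------------------------------------------
# Ancestral reconstruction (per-fragment Sankoff, root fixed diploid)
# ---------------------------------------------------------------------------

def reconstruct_ancestors(tree: PhyloTree, matrix: FragmentedMatrix) -> PhyloTree:
    """Minimum |delta|-cost integer states at internal nodes; root fixed at 2.

    Among co-optimal states the smallest copy number wins.  Branch events are
    annotated with the strict directed event count (relaxed count where the
    strict model is unreachable).
    """
    if tree.parent.get(tree.root, "missing") is not None:
        raise UsageError("reconstruct_ancestors requires a rooted tree")
    breaks = matrix.chromosome_breaks()
    n_frag = matrix.n_fragments
    max_state = int(max(2, matrix.values.max())) + 1
    n_states = max_state + 1
    states = np.arange(n_states)
    trans = np.abs(states[:, None] - states[None, :]).astype(float)  # (s, s')

    big = 1e18
    cost: dict[str, np.ndarray] = {}
    for node in tree.postorder():
        if tree.is_leaf(node) and node != tree.root:
            obs = matrix.values[matrix.sample_index(node)]
            c = np.full((n_states, n_frag), big)
            c[obs, np.arange(n_frag)] = 0.0
        else:
            c = np.zeros((n_states, n_frag))
            for child in tree.children.get(node, []):
                # min over child state s' of cost_child[s'] + |s - s'|
                c += (cost[child][None, :, :] + trans[:, :, None]).min(axis=1)
        cost[node] = c

    profiles: dict[str, np.ndarray] = {tree.root: np.full(n_frag, 2, dtype=np.int64)}
    for node in tree.preorder():
        if node == tree.root:
            continue
        par_state = profiles[tree.parent[node]]  # type: ignore[index]
        if tree.is_leaf(node):
            profiles[node] = matrix.values[matrix.sample_index(node)].copy()
        else:
            total = cost[node] + np.abs(states[:, None] - par_state[None, :])
            profiles[node] = np.argmin(total, axis=0).astype(np.int64)  # first = smallest CN

    tree.ancestral_profiles = {
        node: cn_vector(vals, breaks) for node, vals in profiles.items()
    }
    for node in tree.preorder():
        if node == tree.root:
            continue
        p = tree.ancestral_profiles[tree.parent[node]]  # type: ignore[index]
        c = tree.ancestral_profiles[node]
        events = directed_event_count(p, c)
        if events == UNREACHABLE:
            events = symmetric_distance(p, c)
        tree.branch_events[node] = float(events)
    return tree


def clade_bipartitions(tree: PhyloTree) -> set[frozenset[str]]:
    """Leaf sets of internal nodes (excluding root, singletons, full set)."""
    all_leaves = tree.leaves_under(tree.root)
    out = set()
    for node in tree.internal_nodes():
        clade = tree.leaves_under(node)
        if 1 < len(clade) < len(all_leaves):
            out.add(clade)
    return out


def node_ploidy(tree: PhyloTree, node: str, fragment_lengths: np.ndarray) -> float:
    """Length-weighted mean copy number of a node's profile."""
    prof = tree.ancestral_profiles[node].as_array()
    return float(np.average(prof, weights=fragment_lengths))


def write_ancestral_profiles(tree: PhyloTree, matrix: FragmentedMatrix, path) -> None:
    import pandas as pd

    rows = {
        node: tree.ancestral_profiles[node].as_array()
        for node in tree.preorder()
        if node in tree.ancestral_profiles
    }
    df = pd.DataFrame.from_dict(rows, orient="index",
                                columns=[f.label for f in matrix.fragments])
    df.to_csv(path, sep="\t", index_label="node")
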