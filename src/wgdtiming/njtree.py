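"""Neighbour-joining tree construction, bootstrap support, outgroup rooting
and the path/MRCA queries the timing statistic consumes.

The agglomeration is the Saitou-Nei scheme with
``Q(i,j) = (n-2) d(i,j) - R_i - R_j``; ties in Q are broken by the
lexicographically smallest pair of cluster keys (a cluster is keyed by the
smallest tip label it contains), so the whole construction is deterministic
without a seed.  Negative branch lengths are clamped to zero with the
deficit transferred to the sister branch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .distances import DistanceMatrix, SubstitutionModelSpec, distance_matrix
from .errors import (NonMonophyleticOutgroupError, SaturatedMatrixError,
                     TreeError, UncomparablePairError, WgdTimingError)
from .io_formats import Alignment
from .tree import Node, PhyloTree


# ---------------------------------------------------------------------------
# Neighbour joining
# ---------------------------------------------------------------------------

def neighbor_joining(dm: DistanceMatrix) -> PhyloTree:
    """Build an unrooted NJ tree (trifurcating basal node) from a distance
    matrix without saturated cells."""
    if dm.has_saturation:
        bad = [(dm.labels[i], dm.labels[j])
               for i, j in zip(*np.nonzero(np.triu(dm.saturated)))]
        raise SaturatedMatrixError(
            f"matrix has saturated cells, NJ refused: {bad}")
    if dm.n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")

    # active clusters: parallel lists of key (min tip label), Node, and a
    # growing distance matrix indexed by position
    keys = list(dm.labels)
    nodes = [Node(label) for label in dm.labels]
    d = dm.values.astype(float).copy()

    while len(keys) > 3:
        m = len(keys)
        r = d.sum(axis=1)
        best = None
        best_pair = None
        for i in range(m):
            for j in range(i + 1, m):
                q = (m - 2) * d[i, j] - r[i] - r[j]
                pair = (min(keys[i], keys[j]), max(keys[i], keys[j]))
                if best is None or q < best or (q == best and pair < best_pair):
                    best, best_pair, bi, bj = q, pair, i, j
        li = d[bi, bj] / 2.0 + (r[bi] - r[bj]) / (2.0 * (m - 2))
        lj = d[bi, bj] - li
        li, lj = _clamp_pair(li, lj)
        parent = Node()
        child_i, child_j = nodes[bi], nodes[bj]
        child_i.length = li
        child_j.length = lj
        parent.add_child(child_i)
        parent.add_child(child_j)
        new_row = (d[bi] + d[bj] - d[bi, bj]) / 2.0
        keep = [k for k in range(m) if k not in (bi, bj)]
        d_new = np.zeros((m - 1, m - 1))
        d_new[:-1, :-1] = d[np.ix_(keep, keep)]
        d_new[-1, :-1] = d_new[:-1, -1] = new_row[keep]
        d = d_new
        nodes = [nodes[k] for k in keep] + [parent]
        keys = [keys[k] for k in keep] + [min(best_pair)]

    # final three clusters join at the basal (unrooted) node
    root = Node()
    (la, lb, lc) = _three_point(d[0, 1], d[0, 2], d[1, 2])
    for node, length in zip(nodes, (la, lb, lc)):
        node.length = max(length, 0.0)
        root.add_child(node)
    return PhyloTree(root, rooted=False)


def _clamp_pair(li: float, lj: float) -> tuple[float, float]:
    if li < 0:
        lj = max(lj + li, 0.0)
        li = 0.0
    if lj < 0:
        li = max(li + lj, 0.0)
        lj = 0.0
    return li, lj


def _three_point(dab: float, dac: float, dbc: float) -> tuple[float, float, float]:
    la = (dab + dac - dbc) / 2.0
    lb = dab - la
    lc = dac - la
    return la, lb, lc


# ---------------------------------------------------------------------------
# Bootstrap
# ---------------------------------------------------------------------------

@dataclass
class BootstrapResult:
    """Bipartition support fractions from column-resampled NJ replicates."""

    support: dict[frozenset, float]
    replicates: int
    dropped: int

    def __post_init__(self):
        for split, value in self.support.items():
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"support out of [0,1] for {sorted(split)}")


def bootstrap_support(alignment: Alignment, model: SubstitutionModelSpec,
                      replicates: int = 500, *, seed: int) -> BootstrapResult:
    """Resample columns with replacement, rebuild the NJ tree per replicate
    and count bipartitions.  Replicates yielding an uncomparable pair or a
    saturated matrix are dropped (and counted); more than 20% dropped is an
    error.  Bit-for-bit reproducible for a fixed seed."""
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    rng = np.random.default_rng(seed)
    length = alignment.length
    counts: dict[frozenset, int] = {}
    dropped = 0
    for _ in range(replicates):
        cols = rng.integers(0, length, size=length)
        resampled = alignment.take_columns(cols.tolist())
        try:
            tree = neighbor_joining(distance_matrix(resampled, model))
        except (UncomparablePairError, SaturatedMatrixError):
            dropped += 1
            continue
        for split in tree.bipartitions():
            counts[split] = counts.get(split, 0) + 1
    if dropped > 0.2 * replicates:
        raise WgdTimingError(
            f"{dropped}/{replicates} bootstrap replicates dropped (> 20%)")
    used = replicates - dropped
    support = {split: c / used for split, c in counts.items()}
    return BootstrapResult(support, replicates=replicates, dropped=dropped)


def annotate_support(tree: PhyloTree, result: BootstrapResult,
                     percent: bool = True) -> PhyloTree:
    """Copy of ``tree`` with bootstrap supports written onto internal nodes."""
    out = tree.copy()
    all_tips = frozenset(out.tip_labels)
    ref = min(all_tips)
    tipsets = out.tipsets()
    for node in out.root.preorder():
        if node.parent is None or node.is_leaf:
            continue
        side = tipsets[id(node)]
        if ref in side:
            side = all_tips - side
        if side in result.support:
            value = result.support[side]
            node.support = round(100 * value) if percent else value
    return out


# ---------------------------------------------------------------------------
# Rooting and queries
# ---------------------------------------------------------------------------

def root_with_outgroup(tree: PhyloTree, outgroup_tips) -> PhyloTree:
    """Root on the branch separating a monophyletic outgroup from the
    ingroup, splitting that branch 50/50."""
    og = frozenset(outgroup_tips)
    tips = frozenset(tree.tip_labels)
    if not og:
        raise TreeError("outgroup must be non-empty")
    unknown = og - tips
    if unknown:
        raise TreeError(f"unknown outgroup tips: {sorted(unknown)}")
    if og == tips:
        raise TreeError("outgroup cannot contain every tip")

    work = tree.copy()
    tipsets = work.tipsets()
    ingroup = tips - og
    # an input tree whose root already separates exactly the outgroup keeps
    # its root: that root is a real divergence node, not an inserted one
    if len(work.root.children) == 2:
        sides = [tipsets[id(c)] for c in work.root.children]
        if og in sides:
            work.rooted = True
            if sides[0] == og:
                work.root.children.reverse()
            return work
    attach = None
    for node in work.root.preorder():
        if node.parent is None:
            continue
        below = tipsets[id(node)]
        if below == og or below == ingroup:
            attach = node
            break
    if attach is None:
        # name the tips breaking monophyly: extras under the outgroup MRCA
        mrca = work.mrca(sorted(og))
        conflicting = tipsets[id(mrca)] - og
        raise NonMonophyleticOutgroupError(og, conflicting or og)

    _reroot_on_edge(work, attach)
    work.rooted = True
    work.root_is_insertion = True
    # orient so that the first root child is the ingroup side
    tipsets = work.tipsets()
    if tipsets[id(work.root.children[0])] & og:
        work.root.children.reverse()
    return work


def _reroot_on_edge(tree: PhyloTree, node: Node) -> None:
    """Place a new root at the midpoint of the branch above ``node``."""
    parent = node.parent
    half = node.length / 2.0
    # record the upward chain and its edge attributes before mutating
    chain: list[Node] = []
    cur = parent
    while cur is not None:
        chain.append(cur)
        cur = cur.parent
    old_edge = {id(n): (n.length, n.support) for n in chain}

    parent.children.remove(node)
    new_root = Node()
    new_root.add_child(node)
    node.length = half

    new_root.add_child(parent)
    parent.length = half
    parent.support = node.support  # the split edge keeps its bipartition support

    prev = parent
    for nxt in chain[1:]:
        # edge prev<->nxt flips orientation: it keeps prev's old length/support
        nxt.children.remove(prev)
        prev.add_child(nxt)
        nxt.length, nxt.support = old_edge[id(prev)]
        prev = nxt

    # the old root may now be unary: splice it out, merging branch lengths
    old_root = chain[-1] if chain else None
    if old_root is not None and len(old_root.children) == 1 and old_root is not new_root:
        child = old_root.children[0]
        child.length += old_root.length
        if child.support is None:
            child.support = old_root.support
        up = old_root.parent
        up.children[up.children.index(old_root)] = child
        child.parent = up
    tree.root = new_root


def mrca(tree: PhyloTree, tips) -> Node:
    """Deepest node ancestral to every tip in ``tips`` (rooted tree)."""
    return tree.mrca(tips)


def path_length(tree: PhyloTree, u, v) -> float:
    """Sum of branch lengths on the unique u-v path."""
    return tree.path_length(u, v)


def nj_from_alignment(alignment: Alignment, model: SubstitutionModelSpec,
                      bootstrap_replicates: int = 0,
                      seed: int | None = None) -> tuple[PhyloTree, BootstrapResult | None]:
    """Distance matrix -> NJ tree, optionally with bootstrap annotations."""
    tree = neighbor_joining(distance_matrix(alignment, model))
    boot = None
    if bootstrap_replicates:
        if seed is None:
            raise ValueError("bootstrap requires a seed")
        boot = bootstrap_support(alignment, model, bootstrap_replicates, seed=seed)
        tree = annotate_support(tree, boot)
    return tree, boot
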