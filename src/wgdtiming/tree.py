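"""Phylogenetic tree structure with Newick parsing/writing and path queries.

Trees are stored as rooted data structures; a trifurcating (or higher-degree)
root is the conventional representation of an unrooted tree.  Branch lengths
are in substitutions/site (or time units for simulated truth trees) and live
on the child end of each edge.  Internal "labels" that parse as numbers are
interpreted as bootstrap support annotations.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Iterator

from .errors import NewickParseError, TreeError

_LABEL_FORBIDDEN = set("(),:;[]' \t\n\r")


class Node:
    """A tree node; ``length`` is the branch to the parent (0.0 at the root)."""

    __slots__ = ("label", "length", "support", "parent", "children")

    def __init__(self, label: str | None = None, length: float = 0.0,
                 support: float | None = None):
        self.label = label
        self.length = length
        self.support = support
        self.parent: Node | None = None
        self.children: list[Node] = []

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    def preorder(self) -> Iterator["Node"]:
        stack = [self]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self) -> Iterator["Node"]:
        out = list(self.preorder())
        return reversed(out)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        kind = "leaf" if self.is_leaf else f"internal({len(self.children)})"
        return f"<Node {self.label or '?'} {kind} len={self.length}>"


class PhyloTree:
    """Rooted container tree; ``rooted`` records whether the root is a true
    bifurcating root (outgroup-rooted) rather than an arbitrary basal node."""

    def __init__(self, root: Node, rooted: bool = False,
                 root_is_insertion: bool = False):
        self.root = root
        self.rooted = rooted
        # True when the root was inserted mid-branch (outgroup rooting), so
        # its position along that branch is arbitrary rather than a real
        # divergence node
        self.root_is_insertion = root_is_insertion
        self._validate()

    # -- construction / IO -------------------------------------------------

    @classmethod
    def from_newick(cls, text: str) -> "PhyloTree":
        root = _parse_newick(text)
        return cls(root, rooted=len(root.children) == 2)

    def to_newick(self, precision: int = 6) -> str:
        return _write_newick(self.root, precision)

    def copy(self) -> "PhyloTree":
        def clone(node: Node) -> Node:
            c = Node(node.label, node.length, node.support)
            for child in node.children:
                c.add_child(clone(child))
            return c

        return PhyloTree(clone(self.root), rooted=self.rooted,
                         root_is_insertion=self.root_is_insertion)

    # -- basic queries -----------------------------------------------------

    def nodes(self) -> list[Node]:
        return list(self.root.preorder())

    def tips(self) -> list[Node]:
        return [n for n in self.root.preorder() if n.is_leaf]

    @property
    def tip_labels(self) -> list[str]:
        return [t.label for t in self.tips()]

    def find(self, label: str) -> Node:
        for node in self.root.preorder():
            if node.label == label:
                return node
        raise TreeError(f"unknown node label: {label!r}")

    def total_branch_length(self) -> float:
        return sum(n.length for n in self.root.preorder() if n.parent is not None)

    def scale(self, factor: float) -> "PhyloTree":
        if factor <= 0:
            raise TreeError("scale factor must be positive")
        out = self.copy()
        for node in out.root.preorder():
            node.length *= factor
        return out

    # -- path queries ------------------------------------------------------

    def _resolve(self, node: "Node | str") -> Node:
        return self.find(node) if isinstance(node, str) else node

    def mrca(self, tips: Iterable[str]) -> Node:
        labels = list(tips)
        if not labels:
            raise TreeError("mrca of an empty tip set is undefined")
        nodes = [self._resolve(lbl) for lbl in labels]
        paths = []
        for node in nodes:
            path = []
            while node is not None:
                path.append(node)
                node = node.parent
            paths.append(path[::-1])  # root ... node
        anc = None
        for level in zip(*paths):
            if all(n is level[0] for n in level):
                anc = level[0]
            else:
                break
        assert anc is not None  # all paths share the root
        return anc

    def path_length(self, u: "Node | str", v: "Node | str") -> float:
        a, b = self._resolve(u), self._resolve(v)
        anc_a = {}
        d = 0.0
        node = a
        while node is not None:
            anc_a[id(node)] = d
            d += node.length
            node = node.parent
        d = 0.0
        node = b
        while node is not None:
            if id(node) in anc_a:
                return anc_a[id(node)] + d
            d += node.length
            node = node.parent
        raise TreeError("nodes do not share a tree")  # pragma: no cover

    def depths(self) -> dict[int, float]:
        """Map id(node) -> distance from the root."""
        out = {id(self.root): 0.0}
        for node in self.root.preorder():
            for child in node.children:
                out[id(child)] = out[id(node)] + child.length
        return out

    # -- splits ------------------------------------------------------------

    def tipsets(self) -> dict[int, frozenset]:
        """Map id(node) -> frozenset of descendant tip labels."""
        out: dict[int, frozenset] = {}
        for node in self.root.postorder():
            if node.is_leaf:
                out[id(node)] = frozenset([node.label])
            else:
                s = frozenset()
                for child in node.children:
                    s |= out[id(child)]
                out[id(node)] = s
        return out

    def bipartitions(self) -> set[frozenset]:
        """Non-trivial splits, each canonicalized as the side that does NOT
        contain the lexicographically smallest tip label."""
        all_tips = frozenset(self.tip_labels)
        ref = min(all_tips)
        splits = set()
        tipsets = self.tipsets()
        for node in self.root.preorder():
            if node.parent is None or node.is_leaf:
                continue
            side = tipsets[id(node)]
            if ref in side:
                side = all_tips - side
            if 0 < len(side) < len(all_tips) - 1:
                splits.add(side)
        return splits

    # -- editing -----------------------------------------------------------

    def prune_tips(self, labels: Iterable[str]) -> "PhyloTree":
        """Remove the given tips, suppressing resulting unary nodes (their
        branch lengths are merged)."""
        doomed = set(labels)
        unknown = doomed - set(self.tip_labels)
        if unknown:
            raise TreeError(f"cannot prune unknown tips: {sorted(unknown)}")
        if doomed >= set(self.tip_labels):
            raise TreeError("cannot prune every tip")
        out = self.copy()
        for label in sorted(doomed):
            tip = out.find(label)
            parent = tip.parent
            if parent is None:
                raise TreeError("cannot prune the root")
            parent.children.remove(tip)
            # suppress unary chain upward
            node = parent
            while node is not None and len(node.children) == 1 and node.parent is not None:
                child = node.children[0]
                child.length += node.length
                if child.support is None:
                    child.support = node.support
                grand = node.parent
                grand.children[grand.children.index(node)] = child
                child.parent = grand
                node = grand
        # a root left with a single child is replaced by that child
        while len(out.root.children) == 1 and not out.root.is_leaf:
            new_root = out.root.children[0]
            new_root.parent = None
            new_root.length = 0.0
            out.root = new_root
        return out

    # -- internal ----------------------------------------------------------

    def _validate(self) -> None:
        seen: set[str] = set()
        for node in self.root.preorder():
            if node.length < 0:
                raise TreeError(f"negative branch length on {node.label!r}")
            if not _isfinite(node.length):
                raise TreeError(f"non-finite branch length on {node.label!r}")
            if node.is_leaf:
                if not node.label:
                    raise TreeError("unlabeled tip")
                if node.label in seen:
                    raise TreeError(f"duplicate tip label: {node.label!r}")
                seen.add(node.label)


def _isfinite(x: float) -> bool:
    return x == x and x not in (float("inf"), float("-inf"))


# ---------------------------------------------------------------------------
# Newick grammar (unquoted labels, no comments)
# ---------------------------------------------------------------------------

def _parse_newick(text: str) -> Node:
    s = text.strip()
    if not s:
        raise NewickParseError("empty input")
    if not s.endswith(";"):
        raise NewickParseError("Newick string must end with ';'", len(s))
    s = s[:-1]
    pos = 0
    missing_length = [False]

    def peek() -> str:
        return s[pos] if pos < len(s) else ""

    def skip_ws() -> None:
        nonlocal pos
        while pos < len(s) and s[pos] in " \t\n\r":
            pos += 1

    def read_label() -> str:
        nonlocal pos
        start = pos
        while pos < len(s) and s[pos] not in _LABEL_FORBIDDEN:
            pos += 1
        return s[start:pos]

    def read_length(node: Node) -> None:
        nonlocal pos
        skip_ws()
        if peek() == ":":
            pos += 1
            start = pos
            while pos < len(s) and s[pos] not in "(),:;":
                pos += 1
            token = s[start:pos].strip()
            try:
                value = float(token)
            except ValueError:
                raise NewickParseError(f"bad branch length {token!r}", start) from None
            if value < 0:
                raise NewickParseError(f"negative branch length {value}", start)
            node.length = value
        else:
            missing_length[0] = True
            node.length = 0.0

    def parse_clade(at_root: bool) -> Node:
        nonlocal pos
        skip_ws()
        node = Node()
        if peek() == "(":
            opening = pos
            pos += 1
            while True:
                node.add_child(parse_clade(False))
                skip_ws()
                if peek() == ",":
                    pos += 1
                    continue
                if peek() == ")":
                    pos += 1
                    break
                raise NewickParseError("unbalanced parentheses", opening)
            label = read_label()
            if label:
                try:
                    node.support = float(label)
                except ValueError:
                    node.label = label
        else:
            label = read_label()
            if not label:
                raise NewickParseError("expected a tip label", pos)
            node.label = label
        if at_root:
            skip_ws()
            if peek() == ":":
                read_length(node)  # tolerated, kept
            return node
        read_length(node)
        return node

    root = parse_clade(True)
    skip_ws()
    if pos != len(s):
        raise NewickParseError(f"trailing characters: {s[pos:]!r}", pos)
    if missing_length[0]:
        warnings.warn("Newick input has branches without lengths; set to 0",
                      stacklevel=3)
    # duplicate-tip check via PhyloTree._validate happens in the caller
    return root


def _write_newick(root: Node, precision: int) -> str:
    if precision < 0:
        raise TreeError("precision must be >= 0")

    def fmt(node: Node, at_root: bool) -> str:
        if node.is_leaf:
            body = node.label
        else:
            inner = ",".join(fmt(c, False) for c in node.children)
            ann = ""
            if node.support is not None:
                ann = ("%g" % node.support)
            elif node.label:
                ann = node.label
            body = f"({inner}){ann}"
        if at_root:
            return body
        return f"{body}:{node.length:.{precision}f}"

    if root.is_leaf:
        return f"{root.label}:{root.length:.{precision}f};"
    return fmt(root, True) + ";"
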