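import numpy as np
import pytest

from wgdtiming.distances import DistanceMatrix
from wgdtiming.io_formats import Alignment, GeneNeighborhood, Molecule, SequenceRecord
from wgdtiming.tree import Node, PhyloTree


@pytest.fixture
def protein_alignment():
    return Alignment((
        SequenceRecord("a", Molecule.PROTEIN, "MKVLSD"),
        SequenceRecord("b", Molecule.PROTEIN, "MKVLTD"),
        SequenceRecord("c", Molecule.PROTEIN, "MRVITD"),
    ))


@pytest.fixture
def timing_tree_ancient():
    return PhyloTree.from_newick("((P1:4.0,P2:4.0):1.0,OG:5.0);")


@pytest.fixture
def timing_tree_recent():
    return PhyloTree.from_newick("((P1:0.3,P2:0.3):2.0,OG:2.3);")


def random_additive_tree(rng: np.random.Generator, n_tips: int,
                         lo: float = 0.01, hi: float = 1.0):
    """Random binary unrooted-style tree with uniform branch lengths;
    independent of the NJ code under test."""
    nodes = [Node(f"t{i}") for i in range(n_tips)]
    for node in nodes:
        node.length = rng.uniform(lo, hi)
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = Node(length=rng.uniform(lo, hi))
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes = [nodes[k] for k in range(len(nodes)) if k not in (i, j)]
        nodes.append(parent)
    root = Node()
    for node in nodes:
        root.add_child(node)
    return PhyloTree(root, rooted=False)


def path_matrix(tree: PhyloTree) -> tuple[list[str], np.ndarray]:
    labels = sorted(tree.tip_labels)
    n = len(labels)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = tree.path_length(labels[i], labels[j])
    return labels, out


def matrix_from_tree(tree: PhyloTree) -> DistanceMatrix:
    labels, values = path_matrix(tree)
    return DistanceMatrix(labels, values, np.zeros_like(values, dtype=bool))


def make_neighborhood(focal, symbols, chromosome="chr1"):
    """Symbols listed nearest-first, alternating -1, +1, -2, +2, ..."""
    neighbors = []
    for k, sym in enumerate(symbols):
        off = (k // 2 + 1) * (-1 if k % 2 == 0 else 1)
        neighbors.append((sym, off))
    return GeneNeighborhood(focal, chromosome, neighbors)
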