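"""Synthetic test-data generators: sequences, trees, evolved alignments.

Everything the benchmark needs can be produced locally: random nucleotide
sequences with a controlled GC fraction, random tree topologies grown by a
birth process (each step splits a uniformly chosen leaf, the standard null
model for species trees) with exponential branch lengths, and gap-free
alignments evolved down the tree under the one-parameter equal-rates
(Jukes–Cantor) substitution model.  No indels are simulated, so damaged
reads remain trivially aligned to the reference — matching the
damage-after-alignment design of the benchmark loop.

All generators are deterministic given their random generator / seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import dendropy
import numpy as np

from .io import Alignment, SequenceRecord, write_fasta
from .tree import ReferenceTree

__all__ = [
    "FixtureSpec",
    "random_sequence",
    "random_tree",
    "evolve_alignment",
    "make_fixture",
]

_BASES = np.array(["A", "C", "G", "T"])
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for one synthetic benchmark dataset."""

    n_taxa: int = 32
    alignment_length: int = 1500
    gc_content: float = 0.4
    substitution_scale: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_taxa < 4:
            raise ValueError("n_taxa must be >= 4")
        if self.alignment_length < 1:
            raise ValueError("alignment_length must be >= 1")
        if not 0.0 <= self.gc_content <= 1.0:
            raise ValueError("gc_content must be in [0, 1]")
        if self.substitution_scale < 0:
            raise ValueError("substitution_scale must be >= 0")


def random_sequence(
    length: int,
    gc: float,
    rng: np.random.Generator,
    seq_id: str = "random",
) -> SequenceRecord:
    """I.i.d. nucleotides: G or C with probability ``gc`` (split evenly
    between the two), otherwise A or T (split evenly)."""
    if not 0.0 <= gc <= 1.0:
        raise ValueError("gc must be in [0, 1]")
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    draws = rng.choice(4, size=length, p=probs)
    return SequenceRecord(seq_id, "".join(_BASES[draws]))


def random_tree(
    n_taxa: int,
    rng: np.random.Generator,
    branch_length_mean: float = 0.1,
) -> ReferenceTree:
    """Random topology grown by sequentially splitting a uniformly chosen
    leaf, starting from a three-leaf star; exponential branch lengths.
    Yields an unrooted-style tree (trifurcating root, 2n-3 branches) with
    post-order edge numbers.
    """
    if n_taxa < 3:
        raise ValueError("n_taxa must be >= 3")
    taxa = [f"t{i:03d}" for i in range(1, n_taxa + 1)]
    ns = dendropy.TaxonNamespace(taxa)
    tree = dendropy.Tree(taxon_namespace=ns)
    leaves: list[dendropy.Node] = []
    for label in taxa[:3]:
        child = dendropy.Node(taxon=ns.get_taxon(label))
        tree.seed_node.add_child(child)
        leaves.append(child)
    for label in taxa[3:]:
        victim = leaves[int(rng.integers(len(leaves)))]
        # split the chosen leaf into a cherry
        inner_child = dendropy.Node(taxon=victim.taxon)
        new_leaf = dendropy.Node(taxon=ns.get_taxon(label))
        victim.taxon = None
        victim.add_child(inner_child)
        victim.add_child(new_leaf)
        leaves.remove(victim)
        leaves.extend([inner_child, new_leaf])
    for node in tree.preorder_node_iter():
        if node.parent_node is not None:
            node.edge.length = float(rng.exponential(branch_length_mean))
    return ReferenceTree.from_dendropy(tree, renumber=True)


def evolve_alignment(
    tree: ReferenceTree,
    root_sequence: SequenceRecord | str,
    rate: float,
    rng: np.random.Generator,
) -> Alignment:
    """Evolve a gap-free alignment down the tree under the equal-rates
    model: along a branch of length ``t * rate`` each site substitutes
    with probability ``(3/4)(1 - exp(-4 t rate / 3))``, the new base
    uniform among the other three.  Non-ACGT root characters (gaps,
    ambiguity codes) are passed through unchanged.

    Sites and branches are visited in a fixed (pre-)order, so output is
    deterministic given the generator state.
    """
    if rate < 0:
        raise ValueError("rate must be >= 0")
    residues = (
        root_sequence.residues
        if isinstance(root_sequence, SequenceRecord)
        else root_sequence
    )
    root = np.array([_BASE_INDEX.get(c.upper(), -1) for c in residues], dtype=np.int8)
    literal = np.array(list(residues))

    states: dict[int, np.ndarray] = {}
    dtree = tree.dendropy_tree
    states[id(dtree.seed_node)] = root
    records = []
    for node in dtree.preorder_node_iter():
        if node.parent_node is not None:
            parent_state = states[id(node.parent_node)]
            t = (node.edge.length or 0.0) * rate
            p_sub = 0.75 * (1.0 - np.exp(-4.0 * t / 3.0))
            child = parent_state.copy()
            mask = (rng.random(child.size) < p_sub) & (child >= 0)
            n_sub = int(mask.sum())
            if n_sub:
                shift = rng.integers(1, 4, size=n_sub)
                child[mask] = (child[mask] + shift) % 4
            states[id(node)] = child
        if node.is_leaf():
            state = states[id(node)]
            chars = np.where(state >= 0, _BASES[np.clip(state, 0, 3)], literal)
            records.append(
                SequenceRecord(ReferenceTree._node_label(node), "".join(chars))
            )
    return Alignment(records)


def make_fixture(
    spec: FixtureSpec,
    out_dir: str | Path | None = None,
) -> tuple[ReferenceTree, Alignment]:
    """Materialize one synthetic dataset (tree + evolved alignment).

    With ``out_dir`` set, writes ``tree.nwk`` and ``alignment.fasta``.
    """
    rng = np.random.default_rng(spec.seed)
    tree = random_tree(spec.n_taxa, rng)
    root = random_sequence(spec.alignment_length, spec.gc_content, rng, seq_id="root")
    alignment = evolve_alignment(tree, root, spec.substitution_scale, rng)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "tree.nwk").write_text(tree.to_newick() + "\n")
        (out / "alignment.fasta").write_text(write_fasta(alignment.records))
    return tree, alignment
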