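"""Prune–damage–place–assess benchmark loop.

This recreates, at desk scale, the placement-accuracy experiment design:
prune a random subtree from a reference tree (its sequences become the
queries with a known true attachment branch), inject ancient-DNA damage
into the *aligned* query sequences (so alignment error cannot confound the
measurement), place the damaged reads back on the pruned tree, and score
the placements with node-distance metrics.

No external placement tool is required: a deliberately naive
Hamming-distance placer stands in so the loop is self-contained.  It is a
benchmark harness component, not a scientific placement method; real
placements can be supplied per scenario as parsed jplace files instead.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .damage import DamageParameters, ReadFilters, reads_to_records, simulate
from .io import (
    Alignment,
    PlacementSet,
    SequenceRecord,
    write_fasta,
    write_truth_table,
)
from .metrics import assess
from .tree import ReferenceTree

__all__ = [
    "PruningScenario",
    "ParameterGrid",
    "prune_random_subtree",
    "eligible_prune_subtrees",
    "naive_placer",
    "run_experiment",
    "write_scenario",
]

GAP = "-"


@dataclass
class PruningScenario:
    """One pruning experiment: the pruned tree, the remaining reference
    alignment, the removed (query) sequences still aligned to the reference
    columns, and the true attachment branch in the pruned tree."""

    pruned_tree: ReferenceTree
    reference_msa: Alignment
    query_records: list[SequenceRecord]
    true_edge: int
    removed_labels: list[str] = field(default_factory=list)


@dataclass(frozen=True)
class ParameterGrid:
    """Cartesian grid over the four damage parameters."""

    nu: tuple[float, ...]
    lam: tuple[float, ...]
    delta_ss: tuple[float, ...]
    delta_ds: tuple[float, ...]

    def __len__(self) -> int:
        return len(self.nu) * len(self.lam) * len(self.delta_ss) * len(self.delta_ds)

    def points(self):
        for nu, lam, dss, dds in itertools.product(
            self.nu, self.lam, self.delta_ss, self.delta_ds
        ):
            yield DamageParameters(nu=nu, lam=lam, delta_ss=dss, delta_ds=dds)


# --------------------------------------------------------------------- #
# pruning


def eligible_prune_subtrees(
    tree: ReferenceTree,
    min_remaining_taxa: int = 4,
    max_removed_frac: float = 0.25,
) -> list[frozenset[str]]:
    """Leaf-label sets of subtrees eligible for pruning.

    A subtree qualifies when removing it leaves at least
    ``min_remaining_taxa`` tips and removes at most ``max_removed_frac`` of
    them; subtrees hanging directly off the root are excluded because the
    attachment node could not be suppressed into a single merged branch.
    Order is deterministic (post-order of the tree).
    """
    n_tips = tree.tip_count
    max_removed = int(np.floor(max_removed_frac * n_tips))
    out = []
    dtree = tree.dendropy_tree
    for node in dtree.postorder_node_iter():
        parent = node.parent_node
        if parent is None or parent.parent_node is None:
            continue
        leaves = frozenset(
            ReferenceTree._node_label(leaf) for leaf in node.leaf_iter()
        )
        if len(leaves) > max_removed:
            continue
        if n_tips - len(leaves) < min_remaining_taxa:
            continue
        out.append(leaves)
    return out


def prune_random_subtree(
    tree: ReferenceTree,
    msa: Alignment,
    rng: np.random.Generator,
    min_remaining_taxa: int = 4,
    max_removed_frac: float = 0.25,
) -> PruningScenario:
    """Prune a uniformly chosen eligible subtree.

    The pruned taxa's aligned sequences become the queries.  The attachment
    node is suppressed: its two remaining incident branches merge (branch
    lengths summed) and the merged branch is the true placement edge.  The
    pruned tree's edges are renumbered 0..E-1 in post-order.
    """
    tip_labels = set(tree.leaf_labels)
    missing = tip_labels - set(msa.ids)
    if missing:
        raise ValueError(f"tree tips absent from alignment: {sorted(missing)}")
    candidates = eligible_prune_subtrees(tree, min_remaining_taxa, max_removed_frac)
    if not candidates:
        raise ValueError("no subtree satisfies the pruning constraints")
    removed = candidates[int(rng.integers(len(candidates)))]

    work = tree.dendropy_tree.clone(depth=1)
    target = None
    for node in work.postorder_node_iter():
        leaves = frozenset(
            ReferenceTree._node_label(leaf) for leaf in node.leaf_iter()
        )
        if leaves == removed:
            target = node
            break
    if target is None:  # pragma: no cover - defensive
        raise RuntimeError("selected subtree not found in cloned tree")

    attachment = target.parent_node
    attachment.remove_child(target)
    siblings = attachment.child_nodes()
    if len(siblings) == 1:
        merged_child = siblings[0]
        work.suppress_unifurcations()
    else:
        # the original node was part of a polytomy; the attachment branch
        # itself is the closest surviving branch to the truth
        merged_child = attachment
    pruned = ReferenceTree.from_dendropy(work, renumber=True)
    true_edge = merged_child.edge.edge_num

    removed_sorted = sorted(removed)
    reference_msa = Alignment([r for r in msa.records if r.id not in removed])
    query_records = [r for r in msa.records if r.id in removed]
    return PruningScenario(
        pruned_tree=pruned,
        reference_msa=reference_msa,
        query_records=query_records,
        true_edge=true_edge,
        removed_labels=removed_sorted,
    )


# --------------------------------------------------------------------- #
# the built-in naive placer


def naive_placer(
    query_records,
    reference_msa: Alignment,
    pruned_tree: ReferenceTree,
    top_k: int = 3,
) -> PlacementSet:
    """Hamming-distance stand-in for a phylogenetic placement tool.

    Per query: normalized Hamming distance to every reference row over
    columns where both are non-gap; the candidate branches are the pendant
    branches of the ``top_k`` closest leaves (ties broken by lowest edge
    number) and their weights are a softmax of the negative distances
    scaled by the overlap size — i.e. of negative mismatch counts, the
    log-likelihood analogue under a uniform error model, so that a long
    unambiguous query yields a near-one-hot weight vector while a short
    noisy one spreads its weight.  Queries overlapping no reference row
    are skipped with a warning, the same rationale as premasking: they
    could not be aligned either.
    """
    records = list(query_records)
    ref_rows = reference_msa.records
    ref_matrix = np.array([list(r.residues.upper()) for r in ref_rows])
    ref_nongap = ref_matrix != GAP
    pendant = {r.id: pruned_tree.pendant_edge_num(r.id) for r in ref_rows}

    placements: dict[str, list[tuple[int, float]]] = {}
    for query in records:
        arr = np.array(list(query.residues.upper()))
        if arr.size != ref_matrix.shape[1]:
            raise ValueError(
                f"query {query.id!r} length {arr.size} does not match "
                f"alignment width {ref_matrix.shape[1]}"
            )
        q_nongap = arr != GAP
        both = ref_nongap & q_nongap
        overlap = both.sum(axis=1)
        mismatch = ((ref_matrix != arr) & both).sum(axis=1)
        usable = overlap > 0
        if not usable.any():
            warnings.warn(
                f"query {query.id!r} shares no non-gap column with the "
                "reference alignment; skipped",
                stacklevel=2,
            )
            continue
        with np.errstate(invalid="ignore"):
            dist = np.where(usable, mismatch / np.maximum(overlap, 1), np.inf)
        order = sorted(
            (i for i in range(len(ref_rows)) if usable[i]),
            key=lambda i: (dist[i], pendant[ref_rows[i].id]),
        )[:top_k]
        scores = np.array([float(mismatch[i]) for i in order])
        weights = np.exp(-(scores - scores.min()))
        weights /= weights.sum()
        placements[query.id] = [
            (pendant[ref_rows[i].id], float(w)) for i, w in zip(order, weights)
        ]
    return PlacementSet(placements=placements, tree_text=pruned_tree.to_newick())


# --------------------------------------------------------------------- #
# full experiment


def run_experiment(
    msa: Alignment,
    tree: ReferenceTree,
    grid: ParameterGrid,
    filters: ReadFilters | None = None,
    n_prunings: int = 10,
    seed: int | None = None,
    top_k: int = 3,
    min_remaining_taxa: int = 4,
    max_removed_frac: float = 0.25,
    placements_provider=None,
) -> pd.DataFrame:
    """Run the full Pruning -> Damage -> Placement -> Assessment loop.

    Damage is injected into the already-aligned query sequences (alignment
    is the identity step), with premasking against the remaining reference
    alignment.  ``placements_provider(scenario, params)``, when given,
    replaces the built-in placer — e.g. to ingest jplace output of an
    external tool per grid point.  Returns one row per
    pruning x grid point x read.
    """
    if filters is None:
        filters = ReadFilters()
    rng = np.random.default_rng(seed)
    rows = []
    for pruning_index in range(n_prunings):
        scenario = prune_random_subtree(
            tree, msa, rng,
            min_remaining_taxa=min_remaining_taxa,
            max_removed_frac=max_removed_frac,
        )
        width = scenario.reference_msa.length
        for params in grid.points():
            reads, _ = simulate(
                scenario.query_records,
                params,
                filters=filters,
                reference=scenario.reference_msa,
                rng=rng,
            )
            aligned_reads = reads_to_records(reads, aligned=True, source_length=width)
            if placements_provider is not None:
                placements = placements_provider(scenario, params)
            else:
                placements = naive_placer(
                    aligned_reads, scenario.reference_msa,
                    scenario.pruned_tree, top_k=top_k,
                )
            truth = {rid: scenario.true_edge for rid in placements.placements}
            records, _ = assess(placements, truth, scenario.pruned_tree)
            for rec in records:
                rows.append(
                    dict(
                        pruning=pruning_index,
                        nu=params.nu,
                        lam=params.lam,
                        delta_ss=params.delta_ss,
                        delta_ds=params.delta_ds,
                        read_id=rec.read_id,
                        nd=rec.nd,
                        end=rec.end,
                        normalized_end=rec.normalized_end,
                    )
                )
    return pd.DataFrame(
        rows,
        columns=[
            "pruning", "nu", "lam", "delta_ss", "delta_ds",
            "read_id", "nd", "end", "normalized_end",
        ],
    )


def write_scenario(scenario: PruningScenario, out_dir: str | Path) -> None:
    """Materialize a scenario directory: pruned.nwk, reference.fasta,
    queries.fasta, truth.tsv (true branch per query id)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "pruned.nwk").write_text(scenario.pruned_tree.to_newick() + "\n")
    (out / "reference.fasta").write_text(write_fasta(scenario.reference_msa.records))
    (out / "queries.fasta").write_text(write_fasta(scenario.query_records))
    truth = {r.id: scenario.true_edge for r in scenario.query_records}
    (out / "truth.tsv").write_text(write_truth_table(truth))
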