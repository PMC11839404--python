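"""Placement accuracy metrics: node distance and expected node distance.

The node distance (ND) between two branches of the reference tree is their
topological distance: 0 for the same branch, 1 for branches sharing a node,
and in general the shortest-path length in the branch-adjacency graph.  The
expected node distance (eND) of a read is the sum of node distances of all
its reported placements to the true branch, each weighted by the
placement's likelihood weight ratio (LWR); LWRs are used as reported, not
renormalized.  Normalizing eND by the number of tips makes values
comparable across reference trees of different sizes.
"""

from __future__ import annotations

from dataclasses import dataclass
from statistics import mean, median

from .io import PlacementSet
from .tree import ReferenceTree

__all__ = [
    "AccuracyRecord",
    "node_distance",
    "expected_node_distance",
    "best_placement",
    "assess",
]

_LWR_SUM_TOLERANCE = 1e-6


@dataclass
class AccuracyRecord:
    """Per-read accuracy: best-placement ND, eND, and tip-normalized eND."""

    read_id: str
    nd: int
    end: float
    normalized_end: float


def node_distance(tree: ReferenceTree, edge_a: int, edge_b: int) -> int:
    """Topological distance between two numbered branches (symmetric)."""
    return tree.node_distance(edge_a, edge_b)


def expected_node_distance(
    placements_for_read: list[tuple[int, float]],
    true_edge: int,
    tree: ReferenceTree,
    strict_lwr: bool = False,
) -> float:
    """LWR-weighted sum of node distances to the true branch.

    With ``strict_lwr`` the call fails when the reported LWRs sum to more
    than 1 (beyond numerical tolerance); by default they are used as given.
    """
    if not placements_for_read:
        raise ValueError("read has no reported placements")
    if strict_lwr:
        total = sum(lwr for _, lwr in placements_for_read)
        if total > 1.0 + _LWR_SUM_TOLERANCE:
            raise ValueError(f"likelihood weight ratios sum to {total} > 1")
    return float(
        sum(lwr * tree.node_distance(edge, true_edge)
            for edge, lwr in placements_for_read)
    )


def best_placement(placements_for_read: list[tuple[int, float]]) -> int:
    """Branch of the highest-LWR placement (ties: lowest edge number)."""
    if not placements_for_read:
        raise ValueError("read has no reported placements")
    return min(placements_for_read, key=lambda p: (-p[1], p[0]))[0]


def assess(
    placement_set: PlacementSet,
    truth: dict[str, int],
    tree: ReferenceTree,
    strict_lwr: bool = False,
) -> tuple[list[AccuracyRecord], dict[str, float]]:
    """Score every placed read against its true branch.

    Returns one :class:`AccuracyRecord` per read plus a summary with the
    mean and median of ND, eND, and tip-normalized eND.  Every placed read
    must have a truth entry.
    """
    missing = [q for q in placement_set.placements if q not in truth]
    if missing:
        raise KeyError(
            "reads without a truth entry: " + ", ".join(sorted(missing))
        )
    tips = tree.tip_count
    records = []
    for read_id, rows in placement_set.placements.items():
        true_edge = truth[read_id]
        nd = tree.node_distance(best_placement(rows), true_edge)
        end = expected_node_distance(rows, true_edge, tree, strict_lwr=strict_lwr)
        records.append(
            AccuracyRecord(
                read_id=read_id, nd=nd, end=end, normalized_end=end / tips
            )
        )
    summary: dict[str, float] = {}
    if records:
        for name, values in (
            ("nd", [r.nd for r in records]),
            ("end", [r.end for r in records]),
            ("normalized_end", [r.normalized_end for r in records]),
        ):
            summary[f"mean_{name}"] = float(mean(values))
            summary[f"median_{name}"] = float(median(values))
    return records, summary
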