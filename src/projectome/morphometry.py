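"""Per-neuron cable-length and topology metrics.

Three metrics are reported per structure class (axon, dendrite): total
cable length, number of terminal tips, and number of branches.  The
"branch" convention is the condensed-tree one — a branch is a maximal
unbranched path between a stem, branch point or tip — under which a
single-stem strictly bifurcating axon with T tips has 2T - 1 branches,
the relation observed between published tip and branch counts for this
neuron type.  Edge class follows the CHILD node, so the soma-to-axon stem
edge counts as axonal cable, and tip/branch-point child counts are taken
within the class-restricted forest (an axonal node is a tip when it has
no axonal children).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from typing import Dict, Iterable, List

from .swc import Morphology, StructureClass

__all__ = [
    "MorphometricRecord",
    "cable_length",
    "count_tips",
    "count_branches",
    "count_branchpoints",
    "summarize_neuron",
]


@dataclass(frozen=True)
class MorphometricRecord:
    """One neuron's row of summary metrics; lengths in millimeters."""

    name: str
    axonal_length_mm: float
    axonal_branches: int
    axonal_tips: int
    dendritic_length_mm: float
    dendritic_branches: int
    dendritic_tips: int
    no_axon: bool = False  # warning flag: morphology carries no axonal cable

    def as_dict(self) -> Dict:
        return asdict(self)


def _class_nodes(m: Morphology, cls: StructureClass) -> List[int]:
    return [n.node_id for n in m.nodes if n.structure_class is cls]


def _class_children(m: Morphology, node_id: int, cls: StructureClass) -> List[int]:
    return [c for c in m.children(node_id) if m.node(c).structure_class is cls]


def cable_length(m: Morphology, cls: StructureClass) -> float:
    """Total Euclidean cable length (μm) of class ``cls``.

    An edge belongs to ``cls`` when its child node does, so the stem edge
    from a soma node to the first axonal node is axonal cable.
    """
    total = 0.0
    for n in m.nodes:
        if n.parent_id == -1 or n.structure_class is not cls:
            continue
        p = m.node(n.parent_id)
        total += math.dist((n.x, n.y, n.z), (p.x, p.y, p.z))
    return total


def count_tips(m: Morphology, cls: StructureClass) -> int:
    """Number of class-``cls`` nodes with no class-``cls`` children."""
    return sum(
        1
        for nid in _class_nodes(m, cls)
        if not _class_children(m, nid, cls)
    )


def count_branchpoints(m: Morphology, cls: StructureClass) -> int:
    """Number of class-``cls`` nodes with >= 2 class-``cls`` children.

    A multifurcation counts once regardless of its degree.
    """
    return sum(
        1
        for nid in _class_nodes(m, cls)
        if len(_class_children(m, nid, cls)) >= 2
    )


def count_branches(m: Morphology, cls: StructureClass) -> int:
    """Number of maximal unbranched class-``cls`` paths (condensed-tree edges).

    Counted directly by walking the class-restricted forest: every branch
    terminates at exactly one node that is a tip or a branch point, so the
    walk counts path terminations.
    """
    count = 0
    for nid in _class_nodes(m, cls):
        kids = _class_children(m, nid, cls)
        if len(kids) == 0 or len(kids) >= 2:
            count += 1
    return count


def summarize_neuron(m: Morphology) -> MorphometricRecord:
    """Summary record with lengths in mm and axon/dendrite counts."""
    ax_len = cable_length(m, StructureClass.AXON)
    de_len = cable_length(m, StructureClass.DENDRITE)
    return MorphometricRecord(
        name=m.name,
        axonal_length_mm=ax_len / 1000.0,
        axonal_branches=count_branches(m, StructureClass.AXON),
        axonal_tips=count_tips(m, StructureClass.AXON),
        dendritic_length_mm=de_len / 1000.0,
        dendritic_branches=count_branches(m, StructureClass.DENDRITE),
        dendritic_tips=count_tips(m, StructureClass.DENDRITE),
        no_axon=(ax_len == 0.0),
    )


def records_to_frame(records: Iterable[MorphometricRecord]):
    """MorphometricRecords as a pandas DataFrame (one row per neuron)."""
    import pandas as pd

    return pd.DataFrame([r.as_dict() for r in records])
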