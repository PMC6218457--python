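"""Programmatic morphology builders and independent brute-force oracles.

The oracles deliberately avoid the library's own code paths: cable
length is an explicit loop over parent-child pairs, tip/branch-point
counts are adjacency recounts, and branch counts come from an explicitly
constructed condensed graph (networkx), so agreement with the library is
a real cross-check.
"""

from __future__ import annotations

import math
from typing import Dict, List, Sequence, Tuple

import networkx as nx
import numpy as np

from projectome.swc import MorphNode, Morphology, StructureClass


def make_morph(rows: Sequence[Tuple], name: str = "m") -> Morphology:
    """Rows of (id, type, x, y, z, parent) with radius 1."""
    return Morphology(
        [MorphNode(r[0], r[1], float(r[2]), float(r[3]), float(r[4]), 1.0, r[5]) for r in rows],
        name=name,
    )


def y_tree() -> Morphology:
    """Soma with an axonal Y: stem A, daughters B and C."""
    return make_morph(
        [
            (1, 1, 0, 0, 0, -1),
            (2, 2, 0, 0, 10, 1),  # stem A
            (3, 2, 5, 0, 20, 2),  # B
            (4, 2, -5, 0, 20, 2),  # C
        ]
    )


def random_tree(seed: int, n: int, type_codes=(1, 2, 2, 2, 3, 4, 6)) -> Morphology:
    """Random rooted tree with shuffled, non-consecutive node ids."""
    rng = np.random.default_rng(seed)
    ids = rng.permutation(np.arange(1, 3 * n, 3))[:n] + 1  # arbitrary ids
    nodes = []
    for i in range(n):
        parent = -1 if i == 0 else int(ids[rng.integers(i)])
        code = 1 if i == 0 else int(rng.choice(type_codes))
        x, y, z = rng.uniform(-500, 500, 3)
        nodes.append(MorphNode(int(ids[i]), code, x, y, z, float(rng.uniform(0, 3)), parent))
    return Morphology(nodes, name=f"rand{seed}")


def random_bifurcating_axon(seed: int, tips: int) -> Morphology:
    """Single-stem strictly bifurcating axon with exactly ``tips`` tips."""
    rng = np.random.default_rng(seed)
    nodes = [MorphNode(1, 1, 0.0, 0.0, 0.0, 5.0, -1), MorphNode(2, 2, 0.0, 0.0, 10.0, 1.0, 1)]
    open_tips = [2]
    next_id = 3
    while len(open_tips) < tips:
        idx = int(rng.integers(len(open_tips)))
        parent = open_tips.pop(idx)
        for _ in range(2):
            x, y, z = rng.uniform(-100, 100, 3)
            nodes.append(MorphNode(next_id, 2, x, y, z, 1.0, parent))
            open_tips.append(next_id)
            next_id += 1
    return Morphology(nodes, name=f"bif{seed}")


# ---------------------------------------------------------------------------
# brute-force oracles
# ---------------------------------------------------------------------------


def oracle_cable_length(m: Morphology, cls: StructureClass) -> float:
    total = 0.0
    by_id = {n.node_id: n for n in m.nodes}
    for n in m.nodes:
        if n.parent_id != -1 and StructureClass.from_type_code(n.type_code) is cls:
            p = by_id[n.parent_id]
            total += math.sqrt((n.x - p.x) ** 2 + (n.y - p.y) ** 2 + (n.z - p.z) ** 2)
    return total


def _class_children_map(m: Morphology, cls: StructureClass) -> Dict[int, List[int]]:
    kids: Dict[int, List[int]] = {
        n.node_id: [] for n in m.nodes if StructureClass.from_type_code(n.type_code) is cls
    }
    for n in m.nodes:
        if (
            StructureClass.from_type_code(n.type_code) is cls
            and n.parent_id != -1
            and n.parent_id in kids
        ):
            kids[n.parent_id].append(n.node_id)
    return kids


def oracle_tips(m: Morphology, cls: StructureClass) -> int:
    return sum(1 for v in _class_children_map(m, cls).values() if len(v) == 0)


def oracle_branchpoints(m: Morphology, cls: StructureClass) -> int:
    return sum(1 for v in _class_children_map(m, cls).values() if len(v) >= 2)


def oracle_branches(m: Morphology, cls: StructureClass) -> int:
    """Edges of the explicitly built condensed graph of the class forest.

    Every tip and branch point walks up to the nearest branch point or
    class-forest root parent; each walk contributes one condensed edge.
    A virtual parent node caps each stem so stem paths count too.
    """
    kids = _class_children_map(m, cls)
    by_id = {n.node_id: n for n in m.nodes}
    g = nx.MultiDiGraph()
    for nid, v in kids.items():
        if len(v) == 1:
            continue  # pass-through node, not a condensed-graph vertex
        # walk up from nid to the nearest condensed vertex above it
        cur = by_id[nid].parent_id
        while cur != -1 and cur in kids and len(kids[cur]) == 1:
            cur = by_id[cur].parent_id
        top = cur if (cur != -1 and cur in kids) else f"virtual-root-of-{nid}"
        g.add_edge(top, nid)
    return g.number_of_edges()
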