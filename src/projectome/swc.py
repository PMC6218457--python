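"""Reading, validating and writing neuron reconstructions in SWC format.

The SWC dialect accepted here is the common 7-column one::

    <id> <type> <x> <y> <z> <radius> <parent>

with ``#`` comment lines, arbitrary (not necessarily consecutive) integer
ids, and exactly one root node whose parent is ``-1``.  Coordinates are
micrometers.  Type codes follow the de-facto standard: 1 soma, 2 axon,
3 basal dendrite, 4 apical dendrite; basal and apical dendrites are folded
into a single DENDRITE class because the downstream morphometrics never
separate them.  Soma contour chains (several type-1 nodes) are allowed:
the root is the unique parent ``-1`` node and the remaining soma nodes are
ordinary tree nodes of class SOMA.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Iterator, List, Optional, TextIO, Union

from .errors import (
    CycleDetected,
    DuplicateId,
    MalformedLine,
    MissingParent,
    MultipleRoots,
    NoRoot,
)

__all__ = [
    "StructureClass",
    "MorphNode",
    "Morphology",
    "Violation",
    "read_swc",
    "write_swc",
    "validate",
]


class StructureClass(Enum):
    """Coarse structure classes used by every downstream metric."""

    SOMA = "soma"
    AXON = "axon"
    DENDRITE = "dendrite"
    OTHER = "other"

    @staticmethod
    def from_type_code(code: int) -> "StructureClass":
        if code == 1:
            return StructureClass.SOMA
        if code == 2:
            return StructureClass.AXON
        if code in (3, 4):
            return StructureClass.DENDRITE
        return StructureClass.OTHER


@dataclass(frozen=True)
class MorphNode:
    """One SWC sample point."""

    node_id: int
    type_code: int
    x: float
    y: float
    z: float
    radius: float
    parent_id: int  # -1 for the root

    @property
    def structure_class(self) -> StructureClass:
        return StructureClass.from_type_code(self.type_code)

    @property
    def position(self) -> tuple:
        return (self.x, self.y, self.z)


@dataclass(frozen=True)
class Violation:
    """A single invariant violation reported by :func:`validate`."""

    kind: str  # MissingParent | DuplicateId | MultipleRoots | NoRoot | CycleDetected
    node_id: int
    detail: str = ""


class Morphology:
    """A rooted tree of 3D sample points: one reconstructed neuron.

    ``nodes`` preserves input order (so writing is byte-stable), while
    equality compares node *content* keyed by id, which makes parsing
    order-independent: any line permutation of a valid file parses to an
    equal morphology.
    """

    def __init__(self, nodes: Iterable[MorphNode], name: str = ""):
        self.nodes: List[MorphNode] = list(nodes)
        self.name = name
        self._by_id = {}
        for n in self.nodes:
            if n.node_id in self._by_id:
                raise DuplicateId(n.node_id)
            self._by_id[n.node_id] = n
        self._children: dict = {n.node_id: [] for n in self.nodes}
        roots = []
        for n in self.nodes:
            if n.parent_id == -1:
                roots.append(n.node_id)
            else:
                if n.parent_id not in self._by_id:
                    raise MissingParent(n.node_id, n.parent_id)
                self._children[n.parent_id].append(n.node_id)
        if not roots:
            raise NoRoot()
        if len(roots) > 1:
            raise MultipleRoots(roots)
        self.root_id: int = roots[0]
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        # Iterative ancestor walk with memoized "reaches root" marks.
        ok: set = {self.root_id}
        for n in self.nodes:
            chain = []
            cur = n.node_id
            seen = set()
            while cur not in ok:
                if cur in seen:
                    raise CycleDetected(cur)
                seen.add(cur)
                chain.append(cur)
                cur = self._by_id[cur].parent_id
                if cur == -1:
                    break
            ok.update(chain)

    # -- accessors -------------------------------------------------------
    def node(self, node_id: int) -> MorphNode:
        return self._by_id[node_id]

    def children(self, node_id: int) -> List[int]:
        return self._children[node_id]

    @property
    def root(self) -> MorphNode:
        return self._by_id[self.root_id]

    def __len__(self) -> int:
        return len(self.nodes)

    def __iter__(self) -> Iterator[MorphNode]:
        return iter(self.nodes)

    def __eq__(self, other) -> bool:
        if not isinstance(other, Morphology):
            return NotImplemented
        if set(self._by_id) != set(other._by_id):
            return False
        return all(self._by_id[i] == other._by_id[i] for i in self._by_id)

    def __repr__(self) -> str:
        return f"<Morphology {self.name!r}: {len(self.nodes)} nodes, root {self.root_id}>"


def _parse_line(line_no: int, line: str):
    parts = line.split()
    if len(parts) != 7:
        raise MalformedLine(line_no, line, "expected 7 columns")
    try:
        return MorphNode(
            node_id=int(parts[0]),
            type_code=int(parts[1]),
            x=float(parts[2]),
            y=float(parts[3]),
            z=float(parts[4]),
            radius=float(parts[5]),
            parent_id=int(parts[6]),
        )
    except ValueError as exc:
        raise MalformedLine(line_no, line, str(exc)) from None


def read_swc(source: Union[str, os.PathLike, TextIO], name: Optional[str] = None) -> Morphology:
    """Parse an SWC file (path or open text stream) into a :class:`Morphology`.

    Parsing is two-pass — all nodes are collected before parentage is
    resolved — so forward parent references are accepted.  Raises
    :class:`MalformedLine`, :class:`MissingParent`, :class:`DuplicateId`,
    :class:`MultipleRoots` or :class:`CycleDetected` on invalid input.
    """
    close = False
    if isinstance(source, (str, os.PathLike)):
        if name is None:
            name = os.path.splitext(os.path.basename(os.fspath(source)))[0]
        stream: TextIO = open(source, "r")
        close = True
    else:
        stream = source
    try:
        nodes = []
        for line_no, raw in enumerate(stream, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            nodes.append(_parse_line(line_no, line))
    finally:
        if close:
            stream.close()
    return Morphology(nodes, name=name or "")


def _fmt(v: float) -> str:
    # repr of a Python float is the shortest string that round-trips.
    return repr(float(v))


def write_swc(m: Morphology, target: Union[str, os.PathLike, TextIO]) -> None:
    """Write ``m`` as standard SWC; re-reading reproduces it exactly.

    Output is deterministic: the node order of ``m`` and shortest
    round-tripping float representations.
    """
    lines = [f"# {m.name}\n"] if m.name else []
    for n in m.nodes:
        lines.append(
            f"{n.node_id} {n.type_code} {_fmt(n.x)} {_fmt(n.y)} {_fmt(n.z)} "
            f"{_fmt(n.radius)} {n.parent_id}\n"
        )
    text = "".join(lines)
    if isinstance(target, (str, os.PathLike)):
        with open(target, "w") as fh:
            fh.write(text)
    else:
        target.write(text)


def swc_string(m: Morphology) -> str:
    """The exact text :func:`write_swc` would emit."""
    buf = io.StringIO()
    write_swc(m, buf)
    return buf.getvalue()


def validate(nodes: Union[Morphology, Iterable[MorphNode]]) -> List[Violation]:
    """Check the morphology invariants, returning violations instead of raising.

    Accepts either a built :class:`Morphology` (always valid by
    construction, so the report is empty) or a raw node iterable, which is
    the useful case: it lets broken topologies be diagnosed without the
    constructor rejecting them.  Each violation names the offending node.
    """
    if isinstance(nodes, Morphology):
        nodes = nodes.nodes
    nodes = list(nodes)
    report: List[Violation] = []

    by_id: dict = {}
    for n in nodes:
        if n.node_id in by_id:
            report.append(Violation("DuplicateId", n.node_id, "node id occurs more than once"))
        else:
            by_id[n.node_id] = n

    roots = [n.node_id for n in nodes if n.parent_id == -1]
    if len(roots) > 1:
        for r in roots:
            report.append(Violation("MultipleRoots", r, f"roots: {roots}"))
    elif not roots:
        report.append(Violation("NoRoot", -1, "no node with parent -1"))

    for nid, n in by_id.items():
        if n.parent_id != -1 and n.parent_id not in by_id:
            report.append(Violation("MissingParent", nid, f"parent {n.parent_id} absent"))

    # Cycle scan: a node is on a loop iff its ancestor chain revisits itself
    # before hitting -1 or a missing parent.
    terminates: dict = {}
    cycle_members: set = set()
    for nid in by_id:
        path: List[int] = []
        local: dict = {}
        cur = nid
        while True:
            if cur in terminates:
                reach = terminates[cur]
                break
            if cur in local:
                cycle_members.update(path[local[cur]:])
                reach = False
                break
            local[cur] = len(path)
            path.append(cur)
            parent = by_id[cur].parent_id
            if parent == -1 or parent not in by_id:
                reach = True
                break
            cur = parent
        for c in path:
            terminates[c] = reach
    for c in sorted(cycle_members):
        report.append(Violation("CycleDetected", c, "node is on an ancestor loop"))
    return report
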