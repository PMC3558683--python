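"""Neuronal morphology container and SWC serialization.

A :class:`Morphology` is a rooted tree of :class:`MorphNode` objects with
SWC semantics: consecutive 1-based ids in topological order (every parent
precedes its children), a single root whose ``parent_id`` is -1, and strictly
positive radii and segment lengths.  The root is the soma, written as a
single point of SWC type 1; dendritic nodes carry type 3 (basal dendrite).

The SWC dialect is the classic 7-column layout::

    id type x y z radius parent

with ``#`` comment lines.  Floats are written with full (shortest round-trip)
precision so a write/read cycle reproduces coordinates exactly.
"""

from __future__ import annotations

import io
import math
import os
from collections import deque
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence, TextIO

import numpy as np

__all__ = [
    "SOMA",
    "BASAL_DENDRITE",
    "MorphNode",
    "Segment",
    "Morphology",
    "MorphologyError",
    "SWCParseError",
    "read_swc",
    "write_swc",
    "iter_segments",
]

SOMA = 1
BASAL_DENDRITE = 3


class MorphologyError(ValueError):
    """A structural invariant of a morphology is violated."""


class SWCParseError(MorphologyError):
    """An SWC source cannot be parsed into a valid morphology."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


@dataclass(frozen=True)
class MorphNode:
    """One point of a reconstruction (SWC semantics).

    Positions and radii are in micrometres.  ``parent_id`` is -1 for the
    root (soma) and otherwise must reference an earlier node.
    """

    node_id: int
    type_code: int
    position: np.ndarray
    radius: float
    parent_id: int

    def __post_init__(self):
        object.__setattr__(
            self, "position", np.asarray(self.position, dtype=float).reshape(3)
        )


@dataclass(frozen=True)
class Segment:
    """Directed segment from a parent node to one of its children."""

    start: np.ndarray
    end: np.ndarray
    start_radius: float
    end_radius: float

    def __post_init__(self):
        object.__setattr__(self, "start", np.asarray(self.start, dtype=float).reshape(3))
        object.__setattr__(self, "end", np.asarray(self.end, dtype=float).reshape(3))

    @property
    def length(self) -> float:
        return float(np.linalg.norm(self.end - self.start))

    @property
    def midpoint(self) -> np.ndarray:
        return 0.5 * (self.start + self.end)

    @property
    def mean_radius(self) -> float:
        return 0.5 * (self.start_radius + self.end_radius)


class Morphology:
    """A single-soma neuronal tree.

    Parameters
    ----------
    nodes:
        Nodes with consecutive ids ``1..N`` in topological order.
    metadata:
        Free-form annotations (e.g. ``seed``, ``config_hash``); persisted
        as ``#`` header comments in SWC output.
    """

    def __init__(self, nodes: Sequence[MorphNode], metadata: Mapping[str, object] | None = None):
        self.nodes: list[MorphNode] = list(nodes)
        self.metadata: dict[str, object] = dict(metadata or {})
        self._validate()
        self._children: dict[int, list[int]] | None = None

    # -- invariants -----------------------------------------------------

    def _validate(self) -> None:
        if not self.nodes:
            raise MorphologyError("morphology has no nodes")
        roots = 0
        for i, node in enumerate(self.nodes, start=1):
            if node.node_id != i:
                raise MorphologyError(
                    f"node ids must be consecutive from 1; found id {node.node_id} at position {i}"
                )
            if node.radius <= 0 or not math.isfinite(node.radius):
                raise MorphologyError(f"node {node.node_id}: radius must be positive, got {node.radius}")
            if not np.all(np.isfinite(node.position)):
                raise MorphologyError(f"node {node.node_id}: non-finite position")
            if node.parent_id == -1:
                roots += 1
            elif not (1 <= node.parent_id < node.node_id):
                raise MorphologyError(
                    f"node {node.node_id}: parent_id {node.parent_id} must precede the node"
                )
            else:
                parent = self.nodes[node.parent_id - 1]
                if float(np.linalg.norm(node.position - parent.position)) <= 0.0:
                    raise MorphologyError(
                        f"node {node.node_id}: zero-length segment to parent {node.parent_id}"
                    )
        if roots != 1:
            raise MorphologyError(f"expected exactly one root node, found {roots}")
        if self.nodes[0].parent_id != -1:
            raise MorphologyError("the first node must be the root (parent_id -1)")

    # -- basic accessors ------------------------------------------------

    def __len__(self) -> int:
        return len(self.nodes)

    @property
    def root(self) -> MorphNode:
        return self.nodes[0]

    @property
    def soma_position(self) -> np.ndarray:
        return self.root.position

    @property
    def soma_radius(self) -> float:
        return self.root.radius

    @property
    def positions(self) -> np.ndarray:
        """(N, 3) array of node positions, row i for node id i+1."""
        return np.array([n.position for n in self.nodes])

    @property
    def parents(self) -> np.ndarray:
        return np.array([n.parent_id for n in self.nodes], dtype=int)

    @property
    def radii(self) -> np.ndarray:
        return np.array([n.radius for n in self.nodes])

    # -- topology -------------------------------------------------------

    def children(self, node_id: int) -> list[int]:
        if self._children is None:
            table: dict[int, list[int]] = {n.node_id: [] for n in self.nodes}
            for n in self.nodes:
                if n.parent_id != -1:
                    table[n.parent_id].append(n.node_id)
            self._children = table
        return self._children[node_id]

    def tips(self) -> list[int]:
        """Ids of terminal nodes (no children; the soma never counts)."""
        return [n.node_id for n in self.nodes[1:] if not self.children(n.node_id)]

    def bifurcations(self) -> list[int]:
        """Ids of non-root nodes with exactly two children."""
        out = []
        for n in self.nodes[1:]:
            k = len(self.children(n.node_id))
            if k == 2:
                out.append(n.node_id)
            elif k > 2:
                raise MorphologyError(f"node {n.node_id} has {k} children; trees must be binary")
        return out

    def path_to_root(self, node_id: int) -> list[int]:
        """Node ids from the root (inclusive) to ``node_id`` (inclusive)."""
        path = []
        nid = node_id
        while nid != -1:
            path.append(nid)
            nid = self.nodes[nid - 1].parent_id
        path.reverse()
        return path

    def path_positions(self, node_id: int) -> np.ndarray:
        return np.array([self.nodes[i - 1].position for i in self.path_to_root(node_id)])

    def total_length(self) -> float:
        return float(sum(seg.length for seg in iter_segments(self)))


# -- segment iteration ---------------------------------------------------


def iter_segments(morphology: Morphology) -> Iterator[Segment]:
    """Yield one :class:`Segment` per non-root node (count = N - 1)."""
    for node in morphology.nodes[1:]:
        parent = morphology.nodes[node.parent_id - 1]
        yield Segment(parent.position, node.position, parent.radius, node.radius)


# -- SWC I/O --------------------------------------------------------------


def _format_float(x: float) -> str:
    """Shortest decimal string that round-trips the float (>= 6 sig. digits)."""
    return repr(float(x))


def write_swc(morphology: Morphology, destination: str | os.PathLike | TextIO) -> None:
    """Write a morphology as classic 7-column SWC.

    One line per node, parent always before child, ids consecutive from 1.
    Metadata is emitted as ``# key: value`` header comments.
    """
    if hasattr(destination, "write"):
        _write_swc_stream(morphology, destination)  # type: ignore[arg-type]
    else:
        with open(destination, "w", encoding="ascii") as fh:
            _write_swc_stream(morphology, fh)


def _write_swc_stream(morphology: Morphology, fh: TextIO) -> None:
    for key in sorted(morphology.metadata):
        fh.write(f"# {key}: {morphology.metadata[key]}\n")
    for node in morphology.nodes:
        x, y, z = node.position
        fh.write(
            f"{node.node_id} {node.type_code} {_format_float(x)} {_format_float(y)} "
            f"{_format_float(z)} {_format_float(node.radius)} {node.parent_id}\n"
        )


def read_swc(source: str | os.PathLike | TextIO) -> Morphology:
    """Parse SWC text into a :class:`Morphology`.

    Ids need not be consecutive nor topologically ordered in the input;
    the result is re-indexed to consecutive topological order.  Comment
    lines (``#``) and blank lines are ignored.  Cycles, dangling parents,
    duplicate ids and non-positive radii raise :class:`SWCParseError`
    with the offending line number.
    """
    if hasattr(source, "read"):
        text = source.read()  # type: ignore[union-attr]
    else:
        with open(source, "r", encoding="ascii") as fh:
            text = fh.read()
    records: dict[int, tuple[int, int, np.ndarray, float, int]] = {}
    # record: (line_no, type, position, radius, parent)
    root_id: int | None = None
    for line_no, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        if len(fields) != 7:
            raise SWCParseError(f"expected 7 fields, got {len(fields)}", line_no)
        try:
            nid = int(fields[0])
            type_code = int(fields[1])
            pos = np.array([float(fields[2]), float(fields[3]), float(fields[4])])
            radius = float(fields[5])
            parent = int(fields[6])
        except ValueError as exc:
            raise SWCParseError(f"malformed field ({exc})", line_no) from None
        if nid in records:
            raise SWCParseError(f"duplicate node id {nid}", line_no)
        if radius <= 0:
            raise SWCParseError(f"node {nid}: non-positive radius {radius}", line_no)
        if parent == nid:
            raise SWCParseError(f"node {nid} is its own parent", line_no)
        if parent == -1:
            if root_id is not None:
                raise SWCParseError(f"second root node {nid}", line_no)
            root_id = nid
        records[nid] = (line_no, type_code, pos, radius, parent)
    if root_id is None:
        raise SWCParseError("no root node (parent_id -1) found")
    children: dict[int, list[int]] = {nid: [] for nid in records}
    for nid, (line_no, _, _, _, parent) in records.items():
        if parent == -1:
            continue
        if parent not in records:
            raise SWCParseError(f"node {nid} references absent parent {parent}", line_no)
        children[parent].append(nid)
    # breadth-first renumbering from the root; anything unreached is in a
    # cycle or a disconnected component
    order: list[int] = []
    queue = deque([root_id])
    while queue:
        nid = queue.popleft()
        order.append(nid)
        queue.extend(sorted(children[nid]))
    if len(order) != len(records):
        stray = min(set(records) - set(order))
        raise SWCParseError(
            f"node {stray} is not connected to the root (cycle or orphan)",
            records[stray][0],
        )
    new_id = {nid: i + 1 for i, nid in enumerate(order)}
    nodes = []
    for nid in order:
        line_no, type_code, pos, radius, parent = records[nid]
        nodes.append(
            MorphNode(
                node_id=new_id[nid],
                type_code=type_code,
                position=pos,
                radius=radius,
                parent_id=-1 if parent == -1 else new_id[parent],
            )
        )
    return Morphology(nodes)
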