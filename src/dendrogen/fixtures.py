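"""Deterministic toy morphologies with analytically known metric values.

Straight lines (contraction 1, fractal dimension 1), semicircular arcs
(contraction 2/pi), planar random walks (fractal dimension 2 in
expectation), perfect binary trees (partition asymmetry 0), caterpillars
(asymmetry (n-2)/(n-1)) and Y-trees.  Every fixture is a valid
:class:`~dendrogen.morphology.Morphology` and survives an SWC roundtrip.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field

import numpy as np

from .morphology import BASAL_DENDRITE, SOMA, MorphNode, Morphology, write_swc

__all__ = [
    "FixtureSpec",
    "make_fixture",
    "straight_line",
    "semicircle",
    "random_walk_2d",
    "perfect_binary",
    "caterpillar",
    "y_tree",
    "emit_fixture_files",
]

_SOMA_RADIUS = 1.0
_FIBER_RADIUS = 0.5


def _build(positions, parents, soma_radius=_SOMA_RADIUS, radius=_FIBER_RADIUS, metadata=None):
    nodes = [
        MorphNode(
            node_id=i + 1,
            type_code=SOMA if i == 0 else BASAL_DENDRITE,
            position=positions[i],
            radius=soma_radius if i == 0 else radius,
            parent_id=parents[i],
        )
        for i in range(len(positions))
    ]
    return Morphology(nodes, metadata=metadata)


def straight_line(n: int = 100, step: float = 1.0) -> Morphology:
    """Soma at the origin plus ``n`` collinear unit (or ``step``) segments."""
    if n < 1 or step <= 0:
        raise ValueError("need n >= 1 and step > 0")
    positions = [np.array([i * step, 0.0, 0.0]) for i in range(n + 1)]
    parents = [-1] + list(range(1, n + 1))
    return _build(positions, parents, metadata={"fixture": f"straight_line n={n}"})


def semicircle(radius: float = 50.0, step_deg: float = 1.0) -> Morphology:
    """Semicircular arc from the soma: contraction = diameter / half-circumference = 2/pi."""
    if radius <= 0 or step_deg <= 0:
        raise ValueError("need radius > 0 and step_deg > 0")
    n_steps = int(round(180.0 / step_deg))
    angles = np.linspace(math.pi, 0.0, n_steps + 1)
    positions = [
        np.array([radius + radius * math.cos(a), radius * math.sin(a), 0.0])
        for a in angles
    ]
    parents = [-1] + list(range(1, n_steps + 1))
    return _build(positions, parents, metadata={"fixture": f"semicircle r={radius}"})


def random_walk_2d(n_steps: int = 10000, seed: int = 0, step: float = 1.0) -> Morphology:
    """Unbiased planar walk of unit steps with uniform headings."""
    if n_steps < 1 or step <= 0:
        raise ValueError("need n_steps >= 1 and step > 0")
    rng = np.random.default_rng(seed)
    headings = rng.uniform(0.0, 2.0 * math.pi, n_steps)
    deltas = step * np.column_stack(
        [np.cos(headings), np.sin(headings), np.zeros(n_steps)]
    )
    pts = np.vstack([np.zeros(3), np.cumsum(deltas, axis=0)])
    parents = [-1] + list(range(1, n_steps + 1))
    return _build(list(pts), parents, metadata={"fixture": f"random_walk_2d seed={seed}"})


def perfect_binary(depth: int = 3, branch_len: float = 10.0) -> Morphology:
    """Soma, one stem, then a complete binary tree of the given depth.

    2^depth tips, 2^depth - 1 bifurcations, partition asymmetry 0; laid
    out in the xy plane with geometrically shrinking arms so segments
    never have zero length.
    """
    if depth < 1 or branch_len <= 0:
        raise ValueError("need depth >= 1 and branch_len > 0")
    positions = [np.zeros(3), np.array([branch_len, 0.0, 0.0])]
    parents = [-1, 1]

    def grow(parent_idx: int, direction: float, level: int) -> None:
        if level > depth:
            return
        length = branch_len / (1.6 ** level)
        for sign in (+1.0, -1.0):
            angle = direction + sign * (math.pi / 2 ** (level + 1))
            pos = positions[parent_idx - 1] + length * np.array(
                [math.cos(angle), math.sin(angle), 0.0]
            )
            positions.append(pos)
            parents.append(parent_idx)
            grow(len(positions), angle, level + 1)

    grow(2, 0.0, 1)
    return _build(positions, parents, metadata={"fixture": f"perfect_binary depth={depth}"})


def caterpillar(tips: int = 4, spine_step: float = 5.0, side_len: float = 2.0) -> Morphology:
    """Maximally unbalanced binary tree: a spine shedding one tip per node.

    ``tips`` terminal segments, ``tips - 1`` bifurcations, partition
    asymmetry (tips - 2) / (tips - 1).
    """
    if tips < 2 or spine_step <= 0 or side_len <= 0:
        raise ValueError("need tips >= 2 and positive lengths")
    positions = [np.zeros(3), np.array([spine_step, 0.0, 0.0])]
    parents = [-1, 1]
    spine_idx = 2
    for k in range(tips - 1):
        x = positions[spine_idx - 1][0]
        # side tip
        positions.append(positions[spine_idx - 1] + np.array([side_len, side_len, 0.0]))
        parents.append(spine_idx)
        if k < tips - 2:
            positions.append(np.array([x + spine_step, 0.0, 0.0]))
            parents.append(spine_idx)
            spine_idx = len(positions)
        else:
            positions.append(positions[spine_idx - 1] + np.array([side_len, -side_len, 0.0]))
            parents.append(spine_idx)
    return _build(positions, parents, metadata={"fixture": f"caterpillar tips={tips}"})


def y_tree(stem_len: float = 10.0, arm_len: float = 8.0, half_angle_deg: float = 40.0) -> Morphology:
    """One stem, one bifurcation, two tips (partition asymmetry 0)."""
    if stem_len <= 0 or arm_len <= 0:
        raise ValueError("need positive lengths")
    a = math.radians(half_angle_deg)
    base = np.array([stem_len, 0.0, 0.0])
    positions = [
        np.zeros(3),
        base,
        base + arm_len * np.array([math.cos(a), math.sin(a), 0.0]),
        base + arm_len * np.array([math.cos(a), -math.sin(a), 0.0]),
    ]
    parents = [-1, 1, 2, 2]
    return _build(positions, parents, metadata={"fixture": "y_tree"})


_KINDS = {
    "straight_line": straight_line,
    "semicircle": semicircle,
    "random_walk_2d": random_walk_2d,
    "perfect_binary": perfect_binary,
    "caterpillar": caterpillar,
    "y_tree": y_tree,
}


@dataclass(frozen=True)
class FixtureSpec:
    """Named toy geometry plus its size parameters and seed."""

    kind: str
    params: dict = field(default_factory=dict)
    seed: int = 0


def make_fixture(spec: FixtureSpec) -> Morphology:
    """Build the morphology named by a :class:`FixtureSpec`."""
    if spec.kind not in _KINDS:
        raise ValueError(f"unknown fixture kind {spec.kind!r}; known: {sorted(_KINDS)}")
    params = dict(spec.params)
    if spec.kind == "random_walk_2d":
        params.setdefault("seed", spec.seed)
    return _KINDS[spec.kind](**params)


def emit_fixture_files(directory, specs=None) -> list[str]:
    """Write fixture SWC files into a directory; returns the paths."""
    if specs is None:
        specs = [
            FixtureSpec("straight_line"),
            FixtureSpec("semicircle"),
            FixtureSpec("perfect_binary"),
            FixtureSpec("caterpillar"),
            FixtureSpec("y_tree"),
        ]
    os.makedirs(directory, exist_ok=True)
    paths = []
    for spec in specs:
        path = os.path.join(directory, f"{spec.kind}.swc")
        write_swc(make_fixture(spec), path)
        paths.append(path)
    return paths
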