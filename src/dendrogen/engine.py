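"""The morphogenetic algorithm: stochastic dendrite growth under homotypic biases.

Topology follows a modified Galton--Watson process: after every segment of
growth a front bifurcates with the probability of at least one branching
event over that segment's length.  Geometry is shaped by three
self-referential directional biases -- inertial stiffness (continue the
previous segment), soma-tropism (radial push along the soma-to-tip axis,
decaying with distance), and self-avoidance (summed repulsion from all
existing segments) -- each added as an offset to the mean of a 3-D Gaussian
from which only the *direction* of growth is sampled.

Branch-level termination (checked in priority order): minimum radius,
proximity to another branch, collision with the bounding shape.
Neuron-level termination: all fronts terminated, maximum total fiber
length, or maximum bifurcation count.

Growth is a pure function of ``(config, seed)``: a single counter-based
random stream drives every draw in a fixed order (per front update:
direction components x, y, z; branch decision; on branching: bifurcation
angle, azimuth draws in 3-D mode, daughter side swap).
"""

from __future__ import annotations

import math
from collections import Counter, deque
from dataclasses import dataclass, field

import numpy as np

from .config import GrowthConfig
from .morphology import (
    BASAL_DENDRITE,
    SOMA,
    MorphNode,
    Morphology,
    Segment,
    iter_segments,
)

__all__ = [
    "DISTANCE_FLOOR",
    "SOMA_RADIUS",
    "GrowthFront",
    "sample_gaussian_offset",
    "polar_gaussian",
    "inertial_bias",
    "soma_tropic_bias",
    "self_avoidance_bias",
    "compose_direction",
    "segment_length",
    "should_branch",
    "bifurcate",
    "apply_taper",
    "initialize_stems",
    "check_branch_termination",
    "check_neuron_termination",
    "grow_neuron",
]

# Distance floor for the inverse-power force laws, avoids the singularity
# at contact (um).
DISTANCE_FLOOR = 0.1

# The soma is a point source with a fixed surface: stems emerge on this
# sphere (um).
SOMA_RADIUS = 5.0


@dataclass
class GrowthFront:
    """An active growing tip.

    ``direction`` is the unit direction of the last segment (or the
    assigned bifurcation direction), ``radius`` the current segment
    radius, ``path_length_from_soma`` the cumulative length grown.
    """

    tip_node_id: int
    position: np.ndarray
    direction: np.ndarray
    radius: float
    path_length_from_soma: float = 0.0
    status: str = "active"
    reason: str | None = None

    @property
    def active(self) -> bool:
        return self.status == "active"

    def terminate(self, reason: str) -> None:
        self.status = "terminated"
        self.reason = reason


# -- Gaussian sampling (Marsaglia's polar method) -------------------------


def polar_gaussian(rng: np.random.Generator, n: int, sigma: float = 1.0) -> np.ndarray:
    """Draw ``n`` independent N(0, sigma^2) samples by the polar method.

    Each sample is s = sigma * v1 * sqrt(-2 ln(v1^2+v2^2) / (v1^2+v2^2))
    with (v1, v2) uniform on (-1, 1) and 0 < v1^2+v2^2 < 1; rejected pairs
    are redrawn.  Batched for speed; the draw sequence is a pure function
    of the generator state.
    """
    if sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    out = np.empty(n)
    filled = 0
    while filled < n:
        need = n - filled
        k = max(8, int(need / 0.7) + 4)  # acceptance rate is pi/4
        v1 = rng.uniform(-1.0, 1.0, k)
        v2 = rng.uniform(-1.0, 1.0, k)
        s = v1 * v1 + v2 * v2
        ok = (s > 0.0) & (s < 1.0)
        s_ok = s[ok]
        vals = v1[ok] * np.sqrt(-2.0 * np.log(s_ok) / s_ok)
        take = min(vals.size, need)
        out[filled : filled + take] = vals[:take]
        filled += take
    return sigma * out


def sample_gaussian_offset(sigma: float, rng: np.random.Generator) -> np.ndarray:
    """A 3-vector of independent N(0, sigma^2) components (polar method)."""
    return polar_gaussian(rng, 3, sigma)


def _random_unit(rng: np.random.Generator, flatness: float) -> np.ndarray:
    """Unit direction from the growth Gaussian with z scaled by flatness."""
    while True:
        v = polar_gaussian(rng, 3, 1.0)
        v[2] *= flatness
        norm = float(np.linalg.norm(v))
        if norm > 1e-12:
            return v / norm


# -- homotypic bias vectors ----------------------------------------------


def inertial_bias(front: GrowthFront, strength: float) -> np.ndarray:
    """Continuation of the previous segment, scaled by the stiffness strength."""
    return strength * np.asarray(front.direction, dtype=float)


def soma_tropic_bias(
    front_origin: np.ndarray,
    soma: np.ndarray,
    strength: float,
    decay: float,
) -> np.ndarray:
    """Radial bias along the soma-to-tip axis, inverse-power distance decay.

    Positive strength pushes away from the soma; negative pulls toward it.
    """
    diff = np.asarray(front_origin, dtype=float) - np.asarray(soma, dtype=float)
    d = float(np.linalg.norm(diff))
    if d <= 1e-12:
        return np.zeros(3)
    u = diff / d
    return (strength / max(d, DISTANCE_FLOOR) ** decay) * u


def self_avoidance_bias(
    front_origin: np.ndarray,
    segments,
    strength: float,
    decay: float,
    exclude=(),
) -> np.ndarray:
    """Summed repulsion from existing segments (reference point: midpoint).

    Each segment contributes a unit vector from its midpoint toward the
    front origin, weighted by strength / max(d, floor)^decay.  Segments in
    ``exclude`` (compared by identity) do not contribute.
    """
    origin = np.asarray(front_origin, dtype=float)
    total = np.zeros(3)
    for seg in segments:
        if any(seg is e for e in exclude):
            continue
        diff = origin - seg.midpoint
        d = float(np.linalg.norm(diff))
        if d <= 1e-12:
            continue
        total += diff / d * (1.0 / max(d, DISTANCE_FLOOR) ** decay)
    return strength * total


def _adjacent_node_ids(morphology: Morphology, tip_node_id: int, hops: int) -> set[int]:
    """Ids of the tip node and its ancestors up to ``hops`` edges back."""
    ids = set()
    nid = tip_node_id
    for _ in range(hops + 1):
        if nid == -1:
            break
        ids.add(nid)
        nid = morphology.nodes[nid - 1].parent_id
    return ids


def compose_direction(
    front: GrowthFront,
    config: GrowthConfig,
    morphology: Morphology,
    rng: np.random.Generator,
) -> np.ndarray:
    """Sample the next unit growth direction for an active front.

    The mean of the growth Gaussian is displaced by the sum of the three
    homotypic bias vectors; the z component of the Gaussian draw is scaled
    by ``flatness`` (0 pins growth to the xy plane).  Only the direction of
    the resultant is kept.
    """
    bias = inertial_bias(front, config.inertial_force)
    if config.soma_tropic_force != 0.0:
        bias = bias + soma_tropic_bias(
            front.position,
            morphology.soma_position,
            config.soma_tropic_force,
            config.soma_tropic_decay,
        )
    if config.self_avoidance_force != 0.0:
        segs = list(iter_segments(morphology))
        own = _adjacent_node_ids(morphology, front.tip_node_id, hops=1)
        # segment k corresponds to node id k + 2 (children of the root on)
        exclude = [segs[i] for i in range(len(segs)) if (i + 2) in own]
        bias = bias + self_avoidance_bias(
            front.position,
            segs,
            config.self_avoidance_force,
            config.self_avoidance_decay,
            exclude=exclude,
        )
    while True:
        g = sample_gaussian_offset(config.sigma, rng)
        g[2] *= config.flatness
        v = bias + g
        norm = float(np.linalg.norm(v))
        if norm > 1e-12:
            return v / norm


# -- extension, branching, taper -----------------------------------------


def segment_length(front: GrowthFront, config: GrowthConfig) -> float:
    """Length of the next segment.

    ``front_extension = 0`` gives the fixed length of the pure
    Galton--Watson regime; otherwise length scales as
    (start_radius / radius)^front_extension, so positive exponents make
    segments longer as branches taper and negative exponents make them
    shorter (raising the effective branching frequency).
    """
    if config.front_extension == 0.0:
        return config.base_segment_length
    ratio = config.start_radius / front.radius
    return config.base_segment_length * ratio**config.front_extension

def should_branch(p: float, L: float, rng: np.random.Generator) -> bool:
    """Bifurcate iff at least one Poisson branching event falls in length L.

    The acceptance probability is 1 - exp(-p L), compared against one
    uniform draw.
    """
    if p < 0 or L <= 0:
        raise ValueError("need p >= 0 and L > 0")
    return rng.random() < -math.expm1(-p * L)


def _rotate_about_z(v: np.ndarray, angle: float) -> np.ndarray:
    c, s = math.cos(angle), math.sin(angle)
    return np.array([c * v[0] - s * v[1], s * v[0] + c * v[1], v[2]])


def bifurcate(
    front: GrowthFront,
    config: GrowthConfig,
    rng: np.random.Generator,
) -> tuple[GrowthFront, GrowthFront]:
    """Split an active front into two daughters.

    The inter-daughter angle is uniform on ``angle_limit``; daughters sit
    symmetrically at +-theta/2 about the parent direction, in the xy plane
    for near-flat growth (flatness <= 0.5) or in a uniformly random plane
    containing the parent direction otherwise.  Daughter radii satisfy
    r1 + r2 = ralls_ratio * r_parent, split by ``daughter_asymmetry``.
    """
    lo, hi = config.angle_limit
    theta = rng.uniform(lo, hi) if hi > lo else lo
    d = np.asarray(front.direction, dtype=float)
    if config.planar_bifurcations:
        d1 = _rotate_about_z(d, +theta / 2.0)
        d2 = _rotate_about_z(d, -theta / 2.0)
    else:
        while True:
            v = polar_gaussian(rng, 3, 1.0)
            e = v - np.dot(v, d) * d
            norm = float(np.linalg.norm(e))
            if norm > 1e-9:
                e /= norm
                break
        c, s = math.cos(theta / 2.0), math.sin(theta / 2.0)
        d1 = c * d + s * e
        d2 = c * d - s * e
    if rng.random() < 0.5:
        d1, d2 = d2, d1
    total = config.ralls_ratio * front.radius
    f = config.daughter_asymmetry
    r1, r2 = f * total, (1.0 - f) * total
    mk = lambda direction, radius: GrowthFront(
        tip_node_id=front.tip_node_id,
        position=front.position.copy(),
        direction=direction / np.linalg.norm(direction),
        radius=radius,
        path_length_from_soma=front.path_length_from_soma,
    )
    return mk(d1, r1), mk(d2, r2)


def apply_taper(radius: float, L: float, taper_rate: float) -> float:
    """Exponential radius decay over one segment: r * exp(-taper_rate * L)."""
    if radius <= 0 or L < 0:
        raise ValueError("need radius > 0 and L >= 0")
    return radius * math.exp(-taper_rate * L)


# -- initialization -------------------------------------------------------


def initialize_stems(
    config: GrowthConfig,
    rng: np.random.Generator,
    soma_position: np.ndarray | None = None,
    soma_radius: float = SOMA_RADIUS,
) -> list[GrowthFront]:
    """Place ``nbr_stems`` fronts on the soma surface.

    Directions are sampled one by one; a candidate is accepted when its
    angle to every prior stem exceeds an adaptive threshold that starts at
    2 pi / (nbr_stems + 1) and relaxes by 10% after 50 consecutive
    rejections, which guarantees termination.  Returned fronts carry a
    placeholder ``tip_node_id`` of -1 until nodes are created.
    """
    soma = np.zeros(3) if soma_position is None else np.asarray(soma_position, dtype=float)
    min_angle = 2.0 * math.pi / (config.nbr_stems + 1)
    directions: list[np.ndarray] = []
    rejections = 0
    while len(directions) < config.nbr_stems:
        d = _random_unit(rng, config.flatness)
        ok = all(
            math.acos(float(np.clip(np.dot(d, e), -1.0, 1.0))) >= min_angle
            for e in directions
        )
        if ok:
            directions.append(d)
            rejections = 0
        else:
            rejections += 1
            if rejections >= 50:
                min_angle *= 0.9
                rejections = 0
    return [
        GrowthFront(
            tip_node_id=-1,
            position=soma + soma_radius * d,
            direction=d,
            radius=config.start_radius,
        )
        for d in directions
    ]


# -- termination ----------------------------------------------------------


def check_branch_termination(
    front: GrowthFront,
    morphology: Morphology,
    config: GrowthConfig,
) -> str:
    """Branch-level stop check, in priority order.

    Returns ``'min_radius'``, ``'proximity'``, ``'boundary'`` or
    ``'active'``.  Proximity is surface-to-surface: distance from the tip
    to a non-adjacent segment's midpoint minus both radii; segments within
    two edges of the tip are exempt (a front does not collide with itself
    or its sibling at the branch point).
    """
    if front.radius < config.min_radius:
        return "min_radius"
    if config.intersection_proximity > 0 and len(morphology) > 1:
        own = _adjacent_node_ids(morphology, front.tip_node_id, hops=2)
        segs = list(iter_segments(morphology))
        for i, seg in enumerate(segs):
            child_id = i + 2
            parent_id = morphology.nodes[child_id - 1].parent_id
            if child_id in own or parent_id in own:
                continue
            d = float(np.linalg.norm(front.position - seg.midpoint))
            if d - front.radius - seg.mean_radius < config.intersection_proximity:
                return "proximity"
    if not config.bounding_shape.contains(front.position):
        return "boundary"
    return "active"


def check_neuron_termination(
    morphology: Morphology,
    fronts,
    config: GrowthConfig,
) -> bool:
    """Neuron-level stop: no active fronts, or length/bifurcation cap hit."""
    if not any(f.active for f in fronts):
        return True
    if morphology.total_length() >= config.max_fiber_length:
        return True
    if len(morphology.bifurcations()) >= config.max_bifurcations:
        return True
    return False


# -- the main loop --------------------------------------------------------


class _Grower:
    """Array-backed growth state for one neuron (fast path of grow_neuron)."""

    def __init__(self, config: GrowthConfig, seed: int):
        self.config = config
        self.seed = int(seed)
        self.rng = np.random.default_rng(self.seed)
        self.soma = np.zeros(3)
        # node storage
        self.node_pos: list[np.ndarray] = [self.soma]
        self.node_radius: list[float] = [SOMA_RADIUS]
        self.node_parent: list[int] = [-1]
        self.node_type: list[int] = [SOMA]
        # segment storage (grown numpy arrays for vectorized scans)
        cap = 1024
        self.seg_mid = np.empty((cap, 3))
        self.seg_rad = np.empty(cap)
        self.seg_child = np.empty(cap, dtype=np.int64)
        self.seg_pnode = np.empty(cap, dtype=np.int64)
        self.n_seg = 0
        # totals
        self.fiber_length = 0.0
        self.n_bifurcations = 0
        self.reasons: Counter = Counter()

    # node/segment bookkeeping

    def _add_node(self, pos: np.ndarray, radius: float, parent: int) -> int:
        self.node_pos.append(pos)
        self.node_radius.append(radius)
        self.node_parent.append(parent)
        self.node_type.append(BASAL_DENDRITE)
        nid = len(self.node_pos)
        if parent != -1 and parent != 1:  # soma->stem offsets are not fiber
            self._add_segment(pos, radius, nid, parent)
        return nid

    def _add_segment(self, pos: np.ndarray, radius: float, child: int, parent: int) -> None:
        if self.n_seg == self.seg_mid.shape[0]:
            cap = self.seg_mid.shape[0] * 2
            self.seg_mid = np.resize(self.seg_mid, (cap, 3))
            self.seg_rad = np.resize(self.seg_rad, cap)
            self.seg_child = np.resize(self.seg_child, cap)
            self.seg_pnode = np.resize(self.seg_pnode, cap)
        ppos = self.node_pos[parent - 1]
        prad = self.node_radius[parent - 1]
        i = self.n_seg
        self.seg_mid[i] = 0.5 * (pos + ppos)
        self.seg_rad[i] = 0.5 * (radius + prad)
        self.seg_child[i] = child
        self.seg_pnode[i] = parent
        self.n_seg += 1

    def _ancestors(self, nid: int, hops: int) -> list[int]:
        out = []
        for _ in range(hops + 1):
            if nid == -1:
                break
            out.append(nid)
            nid = self.node_parent[nid - 1]
        return out

    # physics

    def _check_termination(self, front: GrowthFront) -> str:
        cfg = self.config
        if front.radius < cfg.min_radius:
            return "min_radius"
        if cfg.intersection_proximity > 0 and self.n_seg:
            own = self._ancestors(front.tip_node_id, hops=2)
            mids = self.seg_mid[: self.n_seg]
            d = np.linalg.norm(mids - front.position, axis=1)
            surf = d - front.radius - self.seg_rad[: self.n_seg]
            mask = np.isin(self.seg_child[: self.n_seg], own) | np.isin(
                self.seg_pnode[: self.n_seg], own
            )
            surf[mask] = np.inf
            if surf.size and float(surf.min()) < cfg.intersection_proximity:
                return "proximity"
        if not cfg.bounding_shape.contains(front.position):
            return "boundary"
        return "active"

    def _avoidance(self, front: GrowthFront) -> np.ndarray:
        cfg = self.config
        if cfg.self_avoidance_force == 0.0 or self.n_seg == 0:
            return np.zeros(3)
        mids = self.seg_mid[: self.n_seg]
        diff = front.position - mids
        d = np.linalg.norm(diff, axis=1)
        own = self._ancestors(front.tip_node_id, hops=1)
        mask = np.isin(self.seg_child[: self.n_seg], own)
        w = 1.0 / (np.maximum(d, DISTANCE_FLOOR) ** cfg.self_avoidance_decay * np.maximum(d, 1e-12))
        w[mask] = 0.0
        return cfg.self_avoidance_force * (diff * w[:, None]).sum(axis=0)

    def _direction(self, front: GrowthFront) -> np.ndarray:
        cfg = self.config
        bias = cfg.inertial_force * front.direction
        if cfg.soma_tropic_force != 0.0:
            bias = bias + soma_tropic_bias(
                front.position, self.soma, cfg.soma_tropic_force, cfg.soma_tropic_decay
            )
        bias = bias + self._avoidance(front)
        while True:
            g = polar_gaussian(self.rng, 3, cfg.sigma)
            g[2] *= cfg.flatness
            v = bias + g
            norm = float(np.linalg.norm(v))
            if norm > 1e-12:
                return v / norm

    def _extend(self, front: GrowthFront, fronts: deque) -> None:
        cfg = self.config
        L = segment_length(front, cfg)
        direction = self._direction(front)
        new_pos = front.position + L * direction
        new_radius = apply_taper(front.radius, L, cfg.taper_rate)
        nid = self._add_node(new_pos, new_radius, front.tip_node_id)
        self.fiber_length += L
        front.tip_node_id = nid
        front.position = new_pos
        front.direction = direction
        front.radius = new_radius
        front.path_length_from_soma += L
        if should_branch(cfg.branch_probability, L, self.rng):
            self.n_bifurcations += 1
            d1, d2 = bifurcate(front, cfg, self.rng)
            front.status = "terminated"
            front.reason = "bifurcated"
            fronts.append(d1)
            fronts.append(d2)
        else:
            fronts.append(front)

    def _neuron_stopped(self) -> bool:
        return (
            self.fiber_length >= self.config.max_fiber_length
            or self.n_bifurcations >= self.config.max_bifurcations
        )

    def run(self) -> Morphology:
        cfg = self.config
        stems = initialize_stems(cfg, self.rng)
        fronts: deque[GrowthFront] = deque()
        for stem in stems:
            nid = self._add_node(stem.position, stem.radius, 1)
            stem.tip_node_id = nid
            fronts.append(stem)
        done: list[GrowthFront] = []
        while fronts:
            front = fronts.popleft()
            reason = self._check_termination(front)
            if reason != "active":
                front.terminate(reason)
                self.reasons[reason] += 1
                done.append(front)
                continue
            self._extend(front, fronts)
            if self._neuron_stopped():
                for f in fronts:
                    if f.active:
                        f.terminate("neuron_stop")
                        self.reasons["neuron_stop"] += 1
                break
        nodes = [
            MorphNode(
                node_id=i + 1,
                type_code=self.node_type[i],
                position=self.node_pos[i],
                radius=self.node_radius[i],
                parent_id=self.node_parent[i],
            )
            for i in range(len(self.node_pos))
        ]
        metadata = {
            "seed": self.seed,
            "config_hash": cfg.config_hash(),
            "total_fiber_length_um": round(self.fiber_length, 6),
            "terminations": " ".join(f"{k}={v}" for k, v in sorted(self.reasons.items())),
        }
        return Morphology(nodes, metadata=metadata)


def grow_neuron(config: GrowthConfig, seed: int | None = None) -> Morphology:
    """Grow one virtual dendritic morphology.

    Deterministic in ``(config, seed)``; ``seed`` defaults to
    ``config.seed``.  The soma-to-stem offsets (length ``SOMA_RADIUS``) are
    part of the tree but not counted toward ``max_fiber_length``, which may
    be overshot by at most one segment because the cap is checked between
    front updates.
    """
    return _Grower(config, config.seed if seed is None else seed).run()
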