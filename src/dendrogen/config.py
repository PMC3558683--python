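"""Growth-model configuration: parameter schema, validation, text parsing.

The configuration file is plain text, one ``key value`` pair per line with
``#`` comments.  Keys name the homotypic force strengths and their distance
decays, the branching and front-extension rules, the termination conditions,
and auxiliary initial conditions; unknown keys are rejected.  Angles are in
radians, lengths in micrometres.
"""

from __future__ import annotations

import hashlib
import math
import os
from dataclasses import dataclass, field, fields, replace
from typing import TextIO

__all__ = [
    "ConfigError",
    "BoundingShape",
    "Sphere",
    "Box",
    "Rectangle",
    "GrowthConfig",
    "parse_config",
    "load_config",
]


class ConfigError(ValueError):
    """A configuration value violates the schema; names the offending key."""

    def __init__(self, key: str, message: str):
        self.key = key
        super().__init__(f"{key}: {message}")


# -- bounding shapes ------------------------------------------------------


@dataclass(frozen=True)
class BoundingShape:
    def contains(self, point) -> bool:  # pragma: no cover - abstract
        raise NotImplementedError

    def spec_string(self) -> str:  # pragma: no cover - abstract
        raise NotImplementedError


@dataclass(frozen=True)
class Sphere(BoundingShape):
    radius: float

    def contains(self, point) -> bool:
        x, y, z = point
        return x * x + y * y + z * z <= self.radius * self.radius

    def spec_string(self) -> str:
        return f"sphere {self.radius}"


@dataclass(frozen=True)
class Box(BoundingShape):
    lx: float
    ly: float
    lz: float

    def contains(self, point) -> bool:
        x, y, z = point
        return abs(x) <= self.lx / 2 and abs(y) <= self.ly / 2 and abs(z) <= self.lz / 2

    def spec_string(self) -> str:
        return f"box {self.lx} {self.ly} {self.lz}"


@dataclass(frozen=True)
class Rectangle(BoundingShape):
    """Planar bound: constrains x and y only (the 2-D growth domain)."""

    lx: float
    ly: float

    def contains(self, point) -> bool:
        x, y, _ = point
        return abs(x) <= self.lx / 2 and abs(y) <= self.ly / 2

    def spec_string(self) -> str:
        return f"rectangle {self.lx} {self.ly}"


def _parse_shape(value: str) -> BoundingShape:
    parts = value.split()
    kind = parts[0].lower() if parts else ""
    try:
        dims = [float(p) for p in parts[1:]]
    except ValueError:
        raise ConfigError("bounding_shape", f"non-numeric dimension in {value!r}") from None
    if any(d <= 0 for d in dims):
        raise ConfigError("bounding_shape", "dimensions must be positive")
    if kind == "sphere" and len(dims) == 1:
        return Sphere(dims[0])
    if kind == "box" and len(dims) == 3:
        return Box(*dims)
    if kind == "rectangle" and len(dims) == 2:
        return Rectangle(*dims)
    raise ConfigError(
        "bounding_shape",
        f"expected 'sphere r', 'box lx ly lz' or 'rectangle lx ly', got {value!r}",
    )


# -- schema ---------------------------------------------------------------


@dataclass(frozen=True)
class GrowthConfig:
    """All parameters of the morphogenetic algorithm.

    Force strengths are in arbitrary units on the same scale as ``sigma``
    (the growth-direction Gaussian's standard deviation); decays are
    exponents of an inverse power law of distance.  ``branch_probability``
    is the bifurcation probability per micrometre of front extension.
    """

    # main: homotypic forces and branching
    self_avoidance_force: float = 0.0
    self_avoidance_decay: float = 2.0
    soma_tropic_force: float = 0.0
    soma_tropic_decay: float = 1.0
    inertial_force: float = 0.0
    branch_probability: float = 0.05
    front_extension: float = 0.0
    # termination conditions
    bounding_shape: BoundingShape = field(default_factory=lambda: Sphere(100.0))
    intersection_proximity: float = 0.5
    max_fiber_length: float = 50000.0
    max_bifurcations: int = 100000
    min_radius: float = 0.05
    # auxiliary initial conditions
    nbr_stems: int = 1
    start_radius: float = 0.5
    taper_rate: float = 0.0
    ralls_ratio: float = 1.0
    angle_limit: tuple[float, float] = (0.5, 1.5)
    flatness: float = 1.0
    # sampling and extension scale
    sigma: float = 1.0
    base_segment_length: float = 2.0
    daughter_asymmetry: float = 0.5
    seed: int = 0

    def __post_init__(self):
        def check(key: str, ok: bool, why: str) -> None:
            if not ok:
                raise ConfigError(key, why)

        check("self_avoidance_decay", self.self_avoidance_decay >= 0, "must be >= 0")
        check("soma_tropic_decay", self.soma_tropic_decay >= 0, "must be >= 0")
        check("inertial_force", self.inertial_force >= 0, "must be >= 0")
        check("branch_probability", self.branch_probability >= 0, "must be >= 0")
        check("intersection_proximity", self.intersection_proximity >= 0, "must be >= 0")
        check("max_fiber_length", self.max_fiber_length > 0, "must be > 0")
        check("max_bifurcations", self.max_bifurcations >= 0, "must be >= 0")
        check("min_radius", self.min_radius > 0, "must be > 0")
        check("nbr_stems", self.nbr_stems >= 1, "must be >= 1")
        check("start_radius", self.start_radius > 0, "must be > 0")
        check("taper_rate", self.taper_rate >= 0, "must be >= 0")
        check("ralls_ratio", self.ralls_ratio > 0, "must be > 0")
        lo, hi = self.angle_limit
        check("angle_limit", 0 <= lo <= hi <= math.pi, "need 0 <= lo <= hi <= pi")
        check("flatness", 0 <= self.flatness <= 1, "must be in [0, 1]")
        check("sigma", self.sigma > 0, "must be > 0")
        check("base_segment_length", self.base_segment_length > 0, "must be > 0")
        check("daughter_asymmetry", 0 < self.daughter_asymmetry < 1, "must be in (0, 1)")
        for key in (
            "self_avoidance_force",
            "soma_tropic_force",
            "front_extension",
        ):
            check(key, math.isfinite(getattr(self, key)), "must be finite")

    @property
    def planar_bifurcations(self) -> bool:
        """Bifurcation planes are restricted to xy when growth is near-flat."""
        return self.flatness <= 0.5

    def with_overrides(self, **kwargs) -> "GrowthConfig":
        return replace(self, **kwargs)

    def to_text(self) -> str:
        lines = []
        for f in fields(self):
            value = getattr(self, f.name)
            if f.name == "bounding_shape":
                value = value.spec_string()
            elif f.name == "angle_limit":
                value = f"{value[0]} {value[1]}"
            lines.append(f"{f.name} {value}")
        return "\n".join(lines) + "\n"

    def config_hash(self) -> str:
        """Stable short hash of the full parameter set (seed excluded)."""
        text = "\n".join(
            line for line in self.to_text().splitlines() if not line.startswith("seed ")
        )
        return hashlib.sha256(text.encode()).hexdigest()[:12]


_INT_KEYS = {"max_bifurcations", "nbr_stems", "seed"}
_VALID_KEYS = {f.name for f in fields(GrowthConfig)}


def parse_config(text: str) -> GrowthConfig:
    """Parse ``key value`` configuration text into a validated config."""
    values: dict[str, object] = {}
    for line_no, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split(None, 1)
        if len(parts) != 2:
            raise ConfigError(parts[0] if parts else f"line {line_no}", "missing value")
        key, value = parts
        if key not in _VALID_KEYS:
            raise ConfigError(key, "unknown parameter")
        if key in values:
            raise ConfigError(key, "duplicate parameter")
        if key == "bounding_shape":
            values[key] = _parse_shape(value)
        elif key == "angle_limit":
            try:
                lo, hi = (float(v) for v in value.split())
            except ValueError:
                raise ConfigError(key, f"expected two numbers, got {value!r}") from None
            values[key] = (lo, hi)
        elif key in _INT_KEYS:
            try:
                values[key] = int(value)
            except ValueError:
                raise ConfigError(key, f"expected integer, got {value!r}") from None
        else:
            try:
                values[key] = float(value)
            except ValueError:
                raise ConfigError(key, f"expected number, got {value!r}") from None
    return GrowthConfig(**values)


def load_config(path: str | os.PathLike | TextIO) -> GrowthConfig:
    if hasattr(path, "read"):
        return parse_config(path.read())  # type: ignore[union-attr]
    with open(path, "r", encoding="ascii") as fh:
        return parse_config(fh.read())
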