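"""Shared fixtures: tiny configs and hand-built morphologies."""

import numpy as np
import pytest

from dendrogen import GrowthConfig, MorphNode, Morphology, Rectangle


@pytest.fixture
def chain3():
    """Soma plus two collinear 1-um segments."""
    return Morphology(
        [
            MorphNode(1, 1, (0, 0, 0), 1.0, -1),
            MorphNode(2, 3, (1, 0, 0), 0.5, 1),
            MorphNode(3, 3, (2, 0, 0), 0.5, 2),
        ]
    )


@pytest.fixture
def soma_only():
    return Morphology([MorphNode(1, 1, (0, 0, 0), 5.0, -1)])


@pytest.fixture
def small_config():
    """A fast-growing 2-D config for engine behaviour tests."""
    return GrowthConfig(
        inertial_force=1.0,
        soma_tropic_force=1.0,
        soma_tropic_decay=0.5,
        self_avoidance_force=1.0,
        self_avoidance_decay=2.0,
        branch_probability=0.077,
        bounding_shape=Rectangle(60.0, 60.0),
        intersection_proximity=0.2,
        nbr_stems=4,
        start_radius=0.25,
        min_radius=0.05,
        ralls_ratio=2.0,
        taper_rate=0.0,
        sigma=0.8,
        flatness=0.0,
        base_segment_length=2.0,
        seed=7,
    )


def build_tree(edges, positions, radii=None):
    """Morphology from (child, parent) edges over consecutive 1-based ids."""
    n = len(positions)
    parent = {c: p for c, p in edges}
    radii = radii or {}
    nodes = [
        MorphNode(
            i,
            1 if i == 1 else 3,
            positions[i - 1],
            radii.get(i, 1.0 if i == 1 else 0.5),
            parent.get(i, -1),
        )
        for i in range(1, n + 1)
    ]
    return Morphology(nodes)
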