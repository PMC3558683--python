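"""Growth mechanics: extension, branching, termination, whole-neuron runs."""

import io
import math

import numpy as np
import pytest

from dendrogen import (
    GrowthConfig,
    GrowthFront,
    Rectangle,
    Sphere,
    apply_taper,
    bifurcate,
    check_branch_termination,
    check_neuron_termination,
    grow_neuron,
    initialize_stems,
    report,
    segment_length,
    should_branch,
    write_swc,
)
from tests.conftest import build_tree


def _front(position=(0, 0, 0), direction=(1, 0, 0), radius=0.5, tip=2):
    return GrowthFront(
        tip_node_id=tip,
        position=np.asarray(position, float),
        direction=np.asarray(direction, float),
        radius=radius,
    )


class TestExtension:
    def test_fixed_regime_ignores_radius(self):
        cfg = GrowthConfig(front_extension=0.0, base_segment_length=2.0, start_radius=0.5)
        assert segment_length(_front(radius=0.05), cfg) == 2.0
        assert segment_length(_front(radius=0.5), cfg) == 2.0

    def test_positive_extension_lengthens_as_radius_drops(self):
        cfg = GrowthConfig(front_extension=1.0, base_segment_length=2.0, start_radius=0.5)
        assert segment_length(_front(radius=0.25), cfg) == pytest.approx(4.0)

    def test_negative_extension_shortens_as_radius_drops(self):
        cfg = GrowthConfig(front_extension=-1.0, base_segment_length=2.0, start_radius=0.5)
        assert segment_length(_front(radius=0.25), cfg) == pytest.approx(1.0)

    def test_taper_closed_form(self):
        assert apply_taper(1.0, 5.0, 0.0) == 1.0
        assert apply_taper(1.0, 1.0, math.log(2.0)) == pytest.approx(0.5)
        lengths = np.linspace(0, 10, 20)
        radii = [apply_taper(1.0, L, 0.3) for L in lengths]
        assert all(a > b for a, b in zip(radii, radii[1:]))


class TestBranching:
    def test_zero_probability_never_branches(self):
        rng = np.random.default_rng(0)
        assert not any(should_branch(0.0, 2.0, rng) for _ in range(1000))

    def test_huge_probability_always_branches(self):
        rng = np.random.default_rng(0)
        assert all(should_branch(1e9, 2.0, rng) for _ in range(1000))

    def test_radius_conservation_equal_split(self):
        cfg = GrowthConfig(ralls_ratio=1.0, daughter_asymmetry=0.5)
        d1, d2 = bifurcate(_front(radius=2.0), cfg, np.random.default_rng(1))
        assert d1.radius == pytest.approx(1.0)
        assert d2.radius == pytest.approx(1.0)

    def test_asymmetric_split_keeps_ralls_ratio(self):
        cfg = GrowthConfig(ralls_ratio=1.0, daughter_asymmetry=0.7)
        d1, d2 = bifurcate(_front(radius=1.0), cfg, np.random.default_rng(1))
        assert sorted([d1.radius, d2.radius]) == [pytest.approx(0.3), pytest.approx(0.7)]

    @pytest.mark.parametrize("flatness", [0.0, 1.0])
    def test_degenerate_angle_limit_is_exact(self, flatness):
        theta0 = 0.8
        cfg = GrowthConfig(angle_limit=(theta0, theta0), flatness=flatness)
        rng = np.random.default_rng(9)
        for _ in range(20):
            d1, d2 = bifurcate(_front(), cfg, rng)
            angle = math.acos(float(np.clip(np.dot(d1.direction, d2.direction), -1, 1)))
            assert angle == pytest.approx(theta0, abs=1e-9)
            for d in (d1, d2):
                off = math.acos(float(np.clip(np.dot(d.direction, [1, 0, 0]), -1, 1)))
                assert off == pytest.approx(theta0 / 2, abs=1e-9)

    def test_planar_mode_keeps_daughters_in_plane(self):
        cfg = GrowthConfig(angle_limit=(0.5, 1.5), flatness=0.0)
        d1, d2 = bifurcate(_front(direction=(0.6, 0.8, 0.0)), cfg, np.random.default_rng(4))
        assert d1.direction[2] == 0.0 and d2.direction[2] == 0.0


class TestStems:
    def test_single_stem(self):
        cfg = GrowthConfig(nbr_stems=1)
        stems = initialize_stems(cfg, np.random.default_rng(0))
        assert len(stems) == 1
        assert np.linalg.norm(stems[0].direction) == pytest.approx(1.0)
        assert np.linalg.norm(stems[0].position) == pytest.approx(5.0)  # soma surface

    @pytest.mark.parametrize("n", [2, 6])
    def test_count_and_pairwise_separation(self, n):
        cfg = GrowthConfig(nbr_stems=n, flatness=1.0)
        stems = initialize_stems(cfg, np.random.default_rng(12))
        assert len(stems) == n
        angles = [
            math.acos(float(np.clip(np.dot(a.direction, b.direction), -1, 1)))
            for i, a in enumerate(stems)
            for b in stems[i + 1 :]
        ]
        assert min(angles) > 0.2  # the adaptive threshold never collapses

    def test_reproducible_under_seed(self):
        cfg = GrowthConfig(nbr_stems=6)
        a = initialize_stems(cfg, np.random.default_rng(5))
        b = initialize_stems(cfg, np.random.default_rng(5))
        assert all(np.array_equal(x.direction, y.direction) for x, y in zip(a, b))


class TestBranchTermination:
    def _t_shape(self):
        # branch along x plus a second stem ending 1.45 um above the
        # x-branch's middle segment (midpoint (7.5, 0, 0), radius 0.5)
        return build_tree(
            edges=[(2, 1), (3, 2), (4, 3), (5, 4), (6, 1)],
            positions=[
                (0, 0, 0),
                (5, 0, 0),
                (10, 0, 0),
                (15, 0, 0),
                (20, 0, 0),
                (7.5, 1.45, 0),
            ],
        )

    def test_min_radius_takes_priority_over_boundary(self):
        cfg = GrowthConfig(min_radius=0.1, bounding_shape=Sphere(10.0))
        front = _front(position=(50, 0, 0), radius=0.01)
        morphology = build_tree([(2, 1)], [(0, 0, 0), (50, 0, 0)])
        assert check_branch_termination(front, morphology, cfg) == "min_radius"

    def test_isolated_front_stays_active(self, chain3):
        cfg = GrowthConfig(bounding_shape=Sphere(1e6), min_radius=0.01)
        front = _front(position=(2, 0, 0), radius=0.5, tip=3)
        assert check_branch_termination(front, chain3, cfg) == "active"

    def test_proximity_to_unrelated_segment(self):
        cfg = GrowthConfig(
            intersection_proximity=0.5, min_radius=0.01, bounding_shape=Sphere(1e6)
        )
        m = self._t_shape()
        front = _front(position=(7.5, 1.45, 0), radius=0.5, tip=6)
        # surface-to-surface: 1.45 - 0.5 - 0.5 = 0.45 < 0.5
        assert check_branch_termination(front, m, cfg) == "proximity"
        roomy = cfg.with_overrides(intersection_proximity=0.3)
        assert check_branch_termination(front, m, roomy) == "active"

    def test_boundary_collision(self, chain3):
        cfg = GrowthConfig(bounding_shape=Rectangle(2.0, 2.0), min_radius=0.01,
                           intersection_proximity=0.0)
        front = _front(position=(2, 0, 0), radius=0.5, tip=3)
        assert check_branch_termination(front, chain3, cfg) == "boundary"


class TestNeuronTermination:
    def test_no_active_fronts(self, chain3):
        cfg = GrowthConfig()
        done = _front()
        done.terminate("boundary")
        assert check_neuron_termination(chain3, [done], cfg)
        assert check_neuron_termination(chain3, [], cfg)

    def test_below_length_cap_keeps_growing(self, chain3):
        cfg = GrowthConfig(max_fiber_length=100.0)
        assert not check_neuron_termination(chain3, [_front()], cfg)

    def test_length_cap_stops(self, chain3):
        cfg = GrowthConfig(max_fiber_length=1.5)  # chain3 holds 2 um of fiber
        assert check_neuron_termination(chain3, [_front()], cfg)


class TestGrowNeuron:
    def test_deterministic_swc_bytes(self, small_config):
        files = []
        for _ in range(2):
            buf = io.StringIO()
            write_swc(grow_neuron(small_config, 5), buf)
            files.append(buf.getvalue())
        assert files[0] == files[1]

    def test_different_seeds_differ(self, small_config):
        a = grow_neuron(small_config, 1)
        b = grow_neuron(small_config, 2)
        assert len(a) != len(b) or not np.allclose(a.positions, b.positions)

    def test_bifurcation_cap_respected(self, small_config):
        cfg = small_config.with_overrides(max_bifurcations=5)
        m = grow_neuron(cfg, 3)
        assert len(m.bifurcations()) <= 5
        cfg0 = small_config.with_overrides(max_bifurcations=0)
        assert len(grow_neuron(cfg0, 3).bifurcations()) == 0

    def test_flat_growth_stays_in_plane(self, small_config):
        m = grow_neuron(small_config, 4)  # flatness 0
        assert np.all(m.positions[:, 2] == 0.0)

    def test_three_d_growth_leaves_plane(self, small_config):
        cfg = small_config.with_overrides(
            flatness=1.0, bounding_shape=Sphere(30.0)
        )
        m = grow_neuron(cfg, 4)
        assert np.ptp(m.positions[:, 2]) > 1.0

    def test_tips_equal_bifurcations_plus_stems(self, small_config):
        for seed in (1, 2, 3):
            r = report(grow_neuron(small_config, seed), sholl_radii=[])
            assert r.n_tips == r.n_bifurcations + r.n_stems

    def test_nodes_inside_bounding_shape_up_to_last_segment(self, small_config):
        m = grow_neuron(small_config, 6)
        half = np.array([30.0, 30.0])
        outside = np.sum(np.any(np.abs(m.positions[:, :2]) > half[None, :], axis=1))
        # only final colliding segments may protrude, one per terminated front
        assert outside <= int(m.metadata["terminations"].count("boundary")) + len(m.tips())

    def test_radius_monotone_when_daughters_shrink(self, small_config):
        cfg = small_config.with_overrides(ralls_ratio=1.0, taper_rate=0.01,
                                          min_radius=0.02)
        m = grow_neuron(cfg, 8)
        radii = m.radii
        for tip in m.tips():
            path = m.path_to_root(tip)[1:]  # soma radius is not a fiber radius
            r = radii[[i - 1 for i in path]]
            assert np.all(np.diff(r) <= 1e-12)

    def test_zero_forces_resemble_diffusion(self, small_config):
        """Unforced growth is markedly more tortuous than the forced baseline."""
        free = small_config.with_overrides(
            inertial_force=0.0, soma_tropic_force=0.0, self_avoidance_force=0.0
        )
        def mean_contraction(cfg):
            vals = [
                report(grow_neuron(cfg, s), sholl_radii=[]).contraction_mean
                for s in range(1, 9)
            ]
            return float(np.nanmean(vals))
        assert mean_contraction(free) < mean_contraction(small_config) - 0.1
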