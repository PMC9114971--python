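import dataclasses as dc

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rudimorph.growth import (
    GrowthField,
    GrowthParams,
    accumulate_stimulus,
    apply_growth,
    extrapolate,
    grow_one_cycle,
    grow_from_history,
    point_surface_distance,
    surface_growth_maps,
)
from rudimorph.mesh import HexMesh
from rudimorph.poro import BoundaryConditions, FieldState, History, PoroMaterial
from rudimorph.synthetic import make_column_mesh


def synthetic_history(mesh, material, p_of_t, times):
    states = [FieldState(t, np.zeros((mesh.n_nodes, 3)), np.full(mesh.n_nodes, p_of_t(t)))
              for t in times]
    return History(mesh, material, None, states)


class TestStimulus:
    def test_zero_history(self, material):
        mesh = make_column_mesh(1, 1, 2, (1, 1, 2))
        hist = synthetic_history(mesh, material, lambda t: 0.0, np.linspace(0, 1, 11))
        assert np.abs(accumulate_stimulus(hist)).max() == 0.0

    def test_constant_pressure_closed_form(self, material):
        mesh = make_column_mesh(1, 1, 2, (1, 1, 2))
        hist = synthetic_history(mesh, material, lambda t: 2.0, np.linspace(0, 1, 101))
        np.testing.assert_allclose(accumulate_stimulus(hist), 2.0, rtol=1e-12)

    def test_sine_positive_part_integral(self, material):
        """int_0^1 max(sin 2 pi t, 0) dt = 1/pi."""
        mesh = make_column_mesh(1, 1, 2, (1, 1, 2))
        t = np.linspace(0, 1, 2001)
        hist = synthetic_history(mesh, material, lambda tt: np.sin(2 * np.pi * tt), t)
        np.testing.assert_allclose(accumulate_stimulus(hist), 1.0 / np.pi, rtol=1e-5)

    def test_unknown_stimulus_rejected(self, cycle_history):
        with pytest.raises(ValueError, match="stimulus"):
            accumulate_stimulus(cycle_history, "von_mises")


class TestGrowthLaw:
    def test_biological_only_is_uniform(self):
        g = grow_one_cycle(np.random.default_rng(0).uniform(0, 5, 30),
                           GrowthParams(k_bio=0.003, k_mech=0.0))
        np.testing.assert_allclose(g.theta, 1.003)

    def test_arithmetic_example(self):
        g = grow_one_cycle(np.array([2.0]), GrowthParams(k_bio=0.001, k_mech=0.01))
        assert g.theta[0] == pytest.approx(1.021)

    @settings(deadline=None, max_examples=25)
    @given(st.lists(st.floats(0, 10), min_size=2, max_size=20))
    def test_theta_ordering_matches_stimulus(self, svals):
        S = np.array(svals)
        g = grow_one_cycle(S, GrowthParams(k_bio=0.001, k_mech=0.02))
        order = np.argsort(S)
        assert (np.diff(g.theta[order]) >= -1e-15).all()

    def test_negative_rates_rejected(self):
        with pytest.raises(ValueError):
            GrowthParams(k_bio=-0.1)

    def test_growth_field_must_be_positive(self):
        with pytest.raises(ValueError):
            GrowthField(theta=np.array([1.0, -0.5]))


class TestExtrapolate:
    def test_zero_cycles_identity(self):
        g = extrapolate(GrowthField(np.array([1.05, 1.2])), 0)
        np.testing.assert_allclose(g.theta, 1.0)

    def test_compound_arithmetic(self):
        g = extrapolate(GrowthField(np.array([1.01])), 100)
        assert g.theta[0] == pytest.approx(1.01**100)
        assert g.theta[0] == pytest.approx(2.7048, abs=1e-3)

    def test_compound_close_to_linear_for_small_total_growth(self):
        theta = GrowthField(np.array([1.0002]))
        for n in (10, 50, 99):  # n*g < 0.02
            c = extrapolate(theta, n).theta[0]
            l = extrapolate(theta, n, mode="linear").theta[0]
            assert abs(c - l) / l < 0.01

    def test_negative_cycles_rejected(self):
        with pytest.raises(ValueError):
            extrapolate(GrowthField(np.array([1.01])), -1)


class TestApplyGrowth:
    def test_identity_for_unit_theta(self, material):
        mesh = make_column_mesh(2, 2, 4, (100.0, 100.0, 200.0))
        grown = apply_growth(mesh, GrowthField(np.ones(mesh.n_elems)), material)
        np.testing.assert_allclose(grown.nodes, mesh.nodes, atol=1e-8)

    def test_uniform_growth_of_free_body_is_uniform_scaling(self, material):
        """theta = 1.331 everywhere: edges x1.1, volume x1.331."""
        mesh = make_column_mesh(2, 2, 4, (100.0, 100.0, 200.0))
        grown = apply_growth(mesh, GrowthField(np.full(mesh.n_elems, 1.331)), material)
        assert grown.volume() == pytest.approx(1.331 * mesh.volume(), rel=1e-6)
        c0 = mesh.nodes.mean(axis=0)
        c1 = grown.nodes.mean(axis=0)
        ratio = np.linalg.norm(grown.nodes - c1, axis=1)[1:] / np.linalg.norm(mesh.nodes - c0, axis=1)[1:]
        np.testing.assert_allclose(ratio[np.isfinite(ratio)], 1.1, rtol=1e-6)

    def test_local_growth_moves_local_surface_most(self, humerus_mesh, material, humerus_bc):
        # cluster at the distal end: nothing lies above it, so the largest
        # surface motion must occur over the grown elements themselves
        cent = humerus_mesh.element_centroids()
        az = np.arctan2(cent[:, 1], cent[:, 0]) % (2 * np.pi)
        cluster = (np.abs(az - np.pi / 2) < 0.5) & (cent[:, 2] > 520)
        assert cluster.sum() > 0
        theta = np.ones(humerus_mesh.n_elems)
        theta[cluster] = 1.3
        grown = apply_growth(humerus_mesh, GrowthField(theta), material, bc=humerus_bc)
        disp = np.linalg.norm(grown.nodes - humerus_mesh.nodes, axis=1)
        surf = np.unique(humerus_mesh.boundary_quads())
        top_node = surf[np.argmax(disp[surf])]
        pos = humerus_mesh.nodes[top_node]
        t_az = np.arctan2(pos[1], pos[0]) % (2 * np.pi)
        assert pos[2] > 450
        assert abs(((t_az - np.pi / 2 + np.pi) % (2 * np.pi)) - np.pi) < 1.0

    def test_volume_consistency_bounds(self, cycle_history, humerus_bc):
        grown, total = grow_from_history(cycle_history, GrowthParams(), bc=humerus_bc)
        ratio = grown.volume() / cycle_history.mesh.volume()
        assert total.theta.min() <= ratio <= total.theta.max()

    def test_mechanically_impaired_theta_uniform(self, cycle_history, humerus_bc):
        _, total = grow_from_history(cycle_history, GrowthParams(k_mech=0.0), bc=humerus_bc)
        assert np.ptp(total.theta) == pytest.approx(0.0, abs=1e-12)

    def test_monotone_in_k_mech(self, cycle_history):
        S = accumulate_stimulus(cycle_history)
        t1 = grow_one_cycle(S, GrowthParams(k_mech=0.01)).theta
        t2 = grow_one_cycle(S, GrowthParams(k_mech=0.02)).theta
        assert (t2 >= t1 - 1e-15).all()


class TestSurfaceGrowthMaps:
    def test_identical_meshes_give_zero_map(self, humerus_mesh):
        maps, _ = surface_growth_maps(humerus_mesh, {"a": humerus_mesh.copy(),
                                                     "b": humerus_mesh.copy()})
        for m in maps.values():
            assert np.abs(m.values[m.mask]).max() == 0.0

    def test_uniform_normal_offset_maps_to_one(self, humerus_mesh):
        verts, tris = humerus_mesh.surface_triangles()
        surf = np.unique(tris)
        normals = np.zeros((humerus_mesh.n_nodes, 3))
        v = humerus_mesh.nodes[surf]
        # outward-ish direction: radial on the shaft, from cap center above
        L = 600.0
        rel = np.where((v[:, 2] >= L)[:, None], v - [0, 0, L],
                       np.column_stack([v[:, 0], v[:, 1], np.zeros(len(v))]))
        bottom = v[:, 2] < 1e-9
        rel[bottom] = [0, 0, -1.0]
        normals[surf] = rel / np.linalg.norm(rel, axis=1, keepdims=True)
        delta = 5.0
        grown = humerus_mesh.copy(nodes=humerus_mesh.nodes + delta * normals)
        maps, _ = surface_growth_maps(humerus_mesh, {"offset": grown})
        m = maps["offset"]
        np.testing.assert_allclose(m.values[m.mask], 1.0, atol=1e-9)

    def test_mismatched_meshes_rejected(self, humerus_mesh, material):
        other = make_column_mesh(1, 1, 2, (1, 1, 2))
        from rudimorph.growth import surface_growth_displacement
        with pytest.raises(ValueError):
            surface_growth_displacement(humerus_mesh, other)


def test_point_surface_distance_matches_analytic_sphere():
    import trimesh

    sph = trimesh.creation.icosphere(3, 1.0)
    pts = np.random.default_rng(0).normal(size=(40, 3)) * 1.5
    d = point_surface_distance(pts, np.asarray(sph.vertices), np.asarray(sph.faces))
    np.testing.assert_allclose(d, np.abs(np.linalg.norm(pts, axis=1) - 1.0), atol=5e-3)
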