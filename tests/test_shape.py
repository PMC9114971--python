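import dataclasses as dc
import warnings

import numpy as np
import pytest
import trimesh

from rudimorph.shape import (
    FlatMap,
    analyze_limb,
    build_reference,
    extract_condyles,
    fit_shaft_cylinder,
    map_to_reference,
    mean_map,
    mirror_right,
    principal_axis_align,
)
from rudimorph.synthetic import BumpSpec, LimbSpec, make_limb_surface

TWO_PI = 2 * np.pi


def capped_cylinder_surface():
    spec = LimbSpec(
        dorsal_condyle=BumpSpec(2 * np.pi / 3, 1.9, 0.0, 0.9),
        ventral_condyle=BumpSpec(4 * np.pi / 3, 1.9, 0.0, 0.9),
        concavities=(),
    )
    return make_limb_surface(spec, resolution=96)


class TestAlignment:
    def test_axis_aligned_input_stays_aligned(self, limb_surface):
        al = principal_axis_align(limb_surface.mesh)
        # rotation close to identity up to the small bump-induced tilt
        R = al.transform[:3, :3]
        assert abs(R[2, 2]) > 0.999
        # distal (condyle) end up
        v = al.mesh.vertices
        rho = np.hypot(v[:, 0], v[:, 1])
        top = v[:, 2] > v[:, 2].max() - 0.3 * np.ptp(v[:, 2])
        bot = v[:, 2] < v[:, 2].min() + 0.3 * np.ptp(v[:, 2])
        assert rho[top].max() > rho[bot].max()

    def test_known_rotation_recovered(self, limb_surface):
        ref = principal_axis_align(limb_surface.mesh).mesh.vertices
        rot = limb_surface.mesh.copy()
        rot.apply_transform(trimesh.transformations.rotation_matrix(np.deg2rad(30), [1, 0, 0]))
        back = principal_axis_align(rot).mesh.vertices
        # same principal frame up to an azimuthal rotation: compare the
        # axial profile of the radial extremes
        assert np.ptp(back[:, 2]) == pytest.approx(np.ptp(ref[:, 2]), rel=0.01)
        assert np.hypot(back[:, 0], back[:, 1]).max() == pytest.approx(
            np.hypot(ref[:, 0], ref[:, 1]).max(), rel=0.01)

    def test_sphere_has_degenerate_axis(self):
        with pytest.raises(ValueError, match="degenerate"):
            principal_axis_align(trimesh.creation.icosphere(3, 50.0))

    def test_flat_end_identified_as_proximal(self):
        # even with no condyles, the rounded cap must end up distal (+z)
        surf = capped_cylinder_surface()
        al = principal_axis_align(surf.mesh)
        v = al.mesh.vertices
        slab = 0.03 * np.ptp(v[:, 2])
        top_w = np.hypot(v[:, 0], v[:, 1])[v[:, 2] > v[:, 2].max() - slab].max()
        bot_w = np.hypot(v[:, 0], v[:, 1])[v[:, 2] < v[:, 2].min() + slab].max()
        assert top_w < bot_w  # tapered cap up, flat amputation face down


class TestMirror:
    def test_left_unchanged(self, limb_surface):
        out, flag = mirror_right(limb_surface.mesh, "left")
        assert out is limb_surface.mesh and not flag

    def test_involution(self, limb_surface):
        once, _ = mirror_right(limb_surface.mesh, "right")
        twice, _ = mirror_right(once, "right")
        np.testing.assert_array_equal(twice.vertices, limb_surface.mesh.vertices)

    def test_unknown_handedness(self, limb_surface):
        with pytest.raises(ValueError):
            mirror_right(limb_surface.mesh, "ambidextrous")

    def test_mirrored_right_twin_reproduces_left_metrics(self, default_spec, limb_surface):
        _, m_left, _ = analyze_limb(limb_surface.mesh, "left")
        right = make_limb_surface(dc.replace(default_spec, handedness="right"), resolution=96)
        _, m_right, _ = analyze_limb(right.mesh, "right")
        for s in ("ventral", "dorsal"):
            a = m_left[m_left.structure == s]
            b = m_right[m_right.structure == s]
            assert abs(a.area.iloc[0] - b.area.iloc[0]) < 1e-6
            assert abs(a.volume.iloc[0] - b.volume.iloc[0]) < 1e-6


class TestCylinderFit:
    def test_exact_cylinder(self):
        surf = capped_cylinder_surface()
        ref = fit_shaft_cylinder(surf.mesh)
        assert ref.radius == pytest.approx(150.0, abs=1e-6)
        assert np.degrees(np.arccos(min(1.0, abs(ref.axis_dir[2])))) < 0.1

    def test_noisy_cylinder_monte_carlo(self):
        rng = np.random.default_rng(42)
        n, r = 10_000, 150.0
        phi = rng.uniform(0, TWO_PI, n)
        z = rng.uniform(0, 1000.0, n)
        pts = np.column_stack([r * np.cos(phi), r * np.sin(phi), z])
        pts += rng.normal(0, 0.01 * r, pts.shape)
        mesh = trimesh.Trimesh(vertices=pts, faces=[[0, 1, 2]], process=False)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ref = fit_shaft_cylinder(mesh)
        assert abs(ref.radius - r) / r < 0.005

    def test_coplanar_points_rejected(self):
        pts = np.random.default_rng(0).uniform(0, 1, (100, 3))
        pts[:, 0] = 0.3 * pts[:, 2]  # still need z spread for the band
        pts[:, 1] = 0.0
        mesh = trimesh.Trimesh(vertices=pts, faces=[[0, 1, 2]], process=False)
        with pytest.raises(ValueError, match="coplanar"):
            fit_shaft_cylinder(mesh)

    def test_too_few_points_rejected(self):
        mesh = trimesh.Trimesh(vertices=np.random.rand(5, 3), faces=[[0, 1, 2]], process=False)
        with pytest.raises(ValueError):
            fit_shaft_cylinder(mesh)


class TestReference:
    def test_capped_cylinder_has_zero_shift(self):
        surf = capped_cylinder_surface()
        ref = build_reference(fit_shaft_cylinder(surf.mesh), surf.mesh)
        assert abs(ref.vertical_shift) < 2.0  # um, mesh-resolution tolerance

    def test_apex_bump_shift_equals_height(self):
        h_frac = 0.15
        spec = LimbSpec(
            dorsal_condyle=BumpSpec(0.0, 0.0, h_frac, 0.5),
            ventral_condyle=BumpSpec(np.pi, 1.9, 0.0, 0.5),
            concavities=(),
        )
        surf = make_limb_surface(spec, resolution=96)
        ref = build_reference(fit_shaft_cylinder(surf.mesh), surf.mesh)
        assert ref.vertical_shift == pytest.approx(h_frac * 300.0, abs=2.0)

    def test_shift_invariant_to_proximal_noise(self):
        surf = capped_cylinder_surface()
        ref0 = build_reference(fit_shaft_cylinder(surf.mesh), surf.mesh)
        noisy = surf.mesh.copy()
        v = noisy.vertices.copy()
        rng = np.random.default_rng(0)
        prox = (v[:, 2] > 10) & (v[:, 2] < 250)
        rho = np.hypot(v[prox, 0], v[prox, 1])
        jitter = rng.normal(0, 1.0, prox.sum())
        v[prox, 0] *= 1 + jitter / rho
        v[prox, 1] *= 1 + jitter / rho
        noisy = trimesh.Trimesh(vertices=v, faces=noisy.faces, process=False)
        ref1 = build_reference(fit_shaft_cylinder(noisy), noisy)
        assert abs(ref1.vertical_shift - ref0.vertical_shift) < 0.02 * ref0.radius


class TestFlatMap:
    def test_reference_surface_maps_to_zero(self):
        surf = capped_cylinder_surface()
        ref = build_reference(fit_shaft_cylinder(surf.mesh), surf.mesh)
        flat = map_to_reference(surf.mesh, ref)
        assert np.abs(flat.values[flat.mask]).max() < 0.01

    def test_condyle_peak_value_matches_height_fraction(self, default_spec, limb_surface):
        ref = build_reference(fit_shaft_cylinder(limb_surface.mesh), limb_surface.mesh)
        flat = map_to_reference(limb_surface.mesh, ref)
        assert flat.values[flat.mask].max() == pytest.approx(
            default_spec.ventral_condyle.height_frac, abs=0.01)

    def test_uniform_scaling_leaves_map_unchanged(self, limb_surface):
        ref1 = build_reference(fit_shaft_cylinder(limb_surface.mesh), limb_surface.mesh)
        f1 = map_to_reference(limb_surface.mesh, ref1)
        big = limb_surface.mesh.copy()
        big.apply_scale(2.0)
        ref2 = build_reference(fit_shaft_cylinder(big), big)
        f2 = map_to_reference(big, ref2)
        m = f1.mask & f2.mask
        np.testing.assert_allclose(f1.values[m], f2.values[m], atol=1e-9)


def synthetic_flatmap(n_m=64, n_az=128, diameter=300.0):
    """A blank shaft-only FlatMap for direct metric tests."""
    r = diameter / 2
    y_max = 600.0
    dy, dphi = y_max / n_m, TWO_PI / n_az
    return FlatMap(
        values=np.zeros((n_m, n_az)),
        mask=np.ones((n_m, n_az), dtype=bool),
        cell_area=np.full(n_m, dy * r * dphi / diameter**2),
        azimuth_centers=(np.arange(n_az) + 0.5) * dphi,
        meridian_centers=(np.arange(n_m) + 0.5) * dy,
        diameter=diameter,
        junction_meridian=y_max,
    )


class TestCondyleMetrics:
    def test_zero_map_has_no_structures(self):
        assert len(extract_condyles(synthetic_flatmap())) == 0

    def test_analytic_disk_region(self):
        """A disk of value 0.5 and radius rho: area pi rho^2, volume half that."""
        flat = synthetic_flatmap()
        r = flat.diameter / 2
        rho_norm = 0.15  # in units of d
        cy, cphi = 300.0, np.pi
        Y, PHI = np.meshgrid(flat.meridian_centers, flat.azimuth_centers, indexing="ij")
        dist2 = ((Y - cy) / flat.diameter) ** 2 + ((PHI - cphi) * r / flat.diameter) ** 2
        flat.values[dist2 < rho_norm**2] = 0.5
        met = extract_condyles(flat, threshold=0.2)
        assert len(met) == 1
        area = float(met.area.iloc[0])
        assert area == pytest.approx(np.pi * rho_norm**2, rel=0.03)
        assert float(met.volume.iloc[0]) == pytest.approx(0.5 * np.pi * rho_norm**2, rel=0.03)

    def test_unequal_bumps_keep_planted_ordering(self, limb_surface, default_spec):
        _, met, _ = analyze_limb(limb_surface.mesh)
        v = met[met.structure == "ventral"]
        d = met[met.structure == "dorsal"]
        assert v.area.iloc[0] > d.area.iloc[0]
        assert v.volume.iloc[0] > d.volume.iloc[0]

    def test_wraparound_region_counted_once(self):
        flat = synthetic_flatmap()
        # region straddling the azimuthal seam
        flat.values[30:34, :4] = 0.5
        flat.values[30:34, -4:] = 0.5
        met = extract_condyles(flat, threshold=0.2)
        assert len(met) == 1

    def test_concavities_extracted_analogously(self):
        flat = synthetic_flatmap()
        flat.values[20:24, 10:16] = -0.5
        met = extract_condyles(flat, threshold=0.2)
        assert list(met.kind) == ["concavity"]
        assert met.volume.iloc[0] > 0


class TestMeanMap:
    def test_single_map_is_identity(self, limb_surface):
        flat, _, _ = analyze_limb(limb_surface.mesh)
        m = mean_map([flat])
        np.testing.assert_allclose(m.values[m.mask], flat.values[flat.mask])

    def test_azimuthally_shifted_copies_average_to_original(self, limb_surface):
        flat, _, _ = analyze_limb(limb_surface.mesh)
        shifted = FlatMap(
            values=np.roll(flat.values, 13, axis=1),
            mask=np.roll(flat.mask, 13, axis=1),
            cell_area=flat.cell_area.copy(),
            azimuth_centers=flat.azimuth_centers.copy(),
            meridian_centers=flat.meridian_centers.copy(),
            diameter=flat.diameter,
            junction_meridian=flat.junction_meridian,
        )
        m = mean_map([flat, shifted])
        common = m.mask & flat.mask
        np.testing.assert_allclose(m.values[common], flat.values[common], atol=1e-9)

    def test_noisy_copies_converge_to_truth(self, limb_surface):
        flat, _, _ = analyze_limb(limb_surface.mesh)
        rng = np.random.default_rng(11)
        noisy = []
        for _ in range(10):
            nm = FlatMap(
                values=flat.values + rng.normal(0, 0.05, flat.values.shape),
                mask=flat.mask.copy(),
                cell_area=flat.cell_area.copy(),
                azimuth_centers=flat.azimuth_centers.copy(),
                meridian_centers=flat.meridian_centers.copy(),
                diameter=flat.diameter,
                junction_meridian=flat.junction_meridian,
            )
            noisy.append(nm)
        m = mean_map(noisy)
        common = m.mask & flat.mask
        err = np.abs(m.values[common] - flat.values[common])
        assert (err < 0.02 + 3 * 0.05 / np.sqrt(10)).mean() > 0.95

    def test_map_without_dorsal_condyle_excluded(self):
        with pytest.raises(ValueError):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                mean_map([synthetic_flatmap()])
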