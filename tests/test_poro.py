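import numpy as np
import pytest

from rudimorph.mesh import HexMesh
from rudimorph.poro import (
    BiphasicSolver,
    BoundaryConditions,
    FieldState,
    LoadProgram,
    PoroMaterial,
    load_at_time,
    net_boundary_seepage,
    seepage_fields,
    terzaghi_pressure,
    traction_forces,
)
from rudimorph.synthetic import make_column_mesh


@pytest.fixture(scope="module")
def column20():
    return make_column_mesh(1, 1, 20, (50.0, 50.0, 1000.0))


class TestLoadProgram:
    def test_amplitude_zero_at_cycle_ends(self):
        prog = LoadProgram()
        assert prog.amplitude(0.0) == pytest.approx(0.0, abs=1e-12)
        assert prog.amplitude(prog.cycle_duration) == pytest.approx(0.0, abs=1e-9)
        assert prog.amplitude(prog.cycle_duration / 2) == pytest.approx(1.0)

    def test_noninteger_step_count_rejected(self):
        with pytest.raises(ValueError):
            LoadProgram(cycle_duration=1.0, dt=0.03)

    def test_patch_selection_matches_geometry(self, humerus_mesh):
        prog = LoadProgram(polar=0.3, patch_radius=70.0)
        sel, mag = load_at_time(prog, humerus_mesh, prog.cycle_duration / 2)
        assert mag == pytest.approx(prog.peak_traction)
        # independent containment check at the same instant
        quads = humerus_mesh.facet_sets["distal"]
        pts = humerus_mesh.nodes[np.unique(quads)]
        zc = pts[:, 2].min()
        a_cap = pts[:, 2].max() - zc
        az = prog.center_azimuth(prog.cycle_duration / 2)
        center = np.array([
            a_cap * np.sin(0.3) * np.cos(az),
            a_cap * np.sin(0.3) * np.sin(az),
            zc + a_cap * np.cos(0.3),
        ])
        cent = humerus_mesh.nodes[quads].mean(axis=1)
        expect = np.nonzero(np.linalg.norm(cent - center, axis=1) <= 70.0)[0]
        np.testing.assert_array_equal(np.sort(sel), expect)

    def test_zero_amplitude_at_start(self, humerus_mesh):
        _, mag = load_at_time(LoadProgram(), humerus_mesh, 0.0)
        assert mag == 0.0

    def test_off_cap_path_rejected(self):
        with pytest.raises(ValueError):
            LoadProgram(polar=2.0)


class TestStep:
    def test_zero_traction_keeps_zero_fields(self, column20, material):
        bc = BoundaryConditions.terzaghi_column(column20)
        solver = BiphasicSolver(column20, material, bc)
        state = FieldState(0.0, np.zeros((column20.n_nodes, 3)), np.zeros(column20.n_nodes))
        for _ in range(3):
            state = solver.step(state, np.zeros((column20.n_nodes, 3)), 0.1)
        assert np.abs(state.u).max() == pytest.approx(0.0, abs=1e-14)
        assert np.abs(state.p).max() == pytest.approx(0.0, abs=1e-14)

    def test_terzaghi_series_oracle(self, column20, material):
        """Pore pressure matches the closed-form consolidation series to <= 2%."""
        bc = BoundaryConditions.terzaghi_column(column20)
        solver = BiphasicSolver(column20, material, bc)
        q, H = 1.0, 1000.0
        cv = material.consolidation_coefficient
        tchar = H * H / cv
        dt = 0.001 * tchar
        f = traction_forces(column20, column20.facet_sets["top"], q)
        state = FieldState(0.0, np.zeros((column20.n_nodes, 3)), np.zeros(column20.n_nodes))
        t = 0.0
        z = column20.nodes[:, 2]
        for Tv_target in (0.05, 0.2):
            while t < Tv_target * tchar - 1e-9:
                state = solver.step(state, f, dt)
                t += dt
            exact = terzaghi_pressure(H - z, t, q, cv, H)
            err = np.linalg.norm(state.p - exact) / np.linalg.norm(exact)
            assert err < 0.02

    def test_undrained_initial_pressure_equals_load(self, column20, material):
        bc = BoundaryConditions.terzaghi_column(column20)
        solver = BiphasicSolver(column20, material, bc)
        cv = material.consolidation_coefficient
        f = traction_forces(column20, column20.facet_sets["top"], 2.5)
        state = FieldState(0.0, np.zeros((column20.n_nodes, 3)), np.zeros(column20.n_nodes))
        state = solver.step(state, f, 1e-5 * 1000.0**2 / cv)
        # away from the drained top the instantaneous pressure carries the load
        deep = column20.nodes[:, 2] < 500.0
        np.testing.assert_allclose(state.p[deep], 2.5, rtol=1e-3)

    def test_unconstrained_system_raises(self, column20, material):
        bc = BoundaryConditions(drainage_quads=column20.facet_sets["top"], fixed=[])
        with pytest.warns(UserWarning, match="singular"):
            solver = BiphasicSolver(column20, material, bc)
        state = FieldState(0.0, np.zeros((column20.n_nodes, 3)), np.zeros(column20.n_nodes))
        f = traction_forces(column20, column20.facet_sets["top"], 1.0)
        with pytest.raises(RuntimeError):
            solver.step(state, f, 0.1)


class TestCycle:
    def test_state_count(self, cycle_history):
        prog = cycle_history.program
        assert len(cycle_history.states) == prog.n_steps + 1

    def test_zero_peak_traction_keeps_initial_state(self, humerus_mesh, material, humerus_bc):
        solver = BiphasicSolver(humerus_mesh, material, humerus_bc)
        hist = solver.solve_cycle(LoadProgram(peak_traction=0.0))
        for s in hist.states:
            assert np.abs(s.u).max() == pytest.approx(0.0, abs=1e-14)

    def test_compressive_pressure_under_patch_not_antipodal(self, cycle_history):
        """Time-integrated compressive p concentrates beneath the swept patch."""
        mesh = cycle_history.mesh
        pe = np.maximum(cycle_history.element_pressure(), 0.0)
        S = np.trapezoid(pe, cycle_history.times, axis=0)
        cent = mesh.element_centroids()
        az = np.arctan2(cent[:, 1], cent[:, 0]) % (2 * np.pi)
        distal = cent[:, 2] > 450.0
        sweep_c = 4 * np.pi / 3 - 0.2
        under = distal & (np.abs(((az - sweep_c + np.pi) % (2 * np.pi)) - np.pi) < 0.6)
        anti = distal & (np.abs(((az - sweep_c) % (2 * np.pi)) - np.pi) < 0.6)
        assert S[under].mean() > S[anti].mean()

    def test_time_step_self_convergence(self, humerus_mesh, material, humerus_bc):
        """Halving dt changes the per-element integrated stimulus by < 2%."""
        sols = {}
        for dt in (0.01, 0.005):
            solver = BiphasicSolver(humerus_mesh, material, humerus_bc)
            hist = solver.solve_cycle(LoadProgram(dt=dt))
            pe = np.maximum(hist.element_pressure(), 0.0)
            sols[dt] = np.trapezoid(pe, hist.times, axis=0)
        scale = np.abs(sols[0.005]).max()
        assert np.abs(sols[0.01] - sols[0.005]).max() / scale < 0.02


class TestSeepage:
    def test_uniform_pressure_no_flow(self, column20, material):
        state = FieldState(0.0, np.zeros((column20.n_nodes, 3)), np.full(column20.n_nodes, 3.0))
        w, div = seepage_fields(column20, material, state)
        assert np.abs(w).max() == pytest.approx(0.0, abs=1e-12)
        assert np.abs(div).max() == pytest.approx(0.0, abs=1e-10)

    def test_manufactured_quadratic_pressure(self, column20, material):
        """p = z^2 gives w = -2kz and constant div(w) = -2k."""
        z = column20.nodes[:, 2]
        state = FieldState(0.0, np.zeros((column20.n_nodes, 3)), z**2)
        w, div = seepage_fields(column20, material, state)
        k = material.hydraulic_conductivity
        zc = column20.element_centroids()[:, 2]
        np.testing.assert_allclose(w[:, 2], -2 * k * zc, rtol=1e-9)
        np.testing.assert_allclose(div, -2 * k, rtol=1e-9)

    def test_discrete_divergence_theorem(self, material):
        """Sum of div(w) x volume matches the net boundary flux within 1%
        at resolution, and the mismatch shrinks under mesh refinement."""
        mismatch = {}
        for n in (20, 80):
            mesh = make_column_mesh(1, 1, n, (50.0, 50.0, 1000.0))
            bc = BoundaryConditions.terzaghi_column(mesh)
            solver = BiphasicSolver(mesh, material, bc)
            tchar = 1000.0**2 / material.consolidation_coefficient
            f = traction_forces(mesh, mesh.facet_sets["top"], 1.0)
            state = FieldState(0.0, np.zeros((mesh.n_nodes, 3)), np.zeros(mesh.n_nodes))
            for _ in range(50):
                state = solver.step(state, f, 0.002 * tchar)
            _, div = seepage_fields(mesh, material, state)
            total = float(div @ mesh.element_volumes())
            flux = net_boundary_seepage(mesh, material, state)
            mismatch[n] = abs(total - flux) / abs(flux)
        assert mismatch[80] < 0.01
        assert mismatch[80] < mismatch[20]


class TestObjectivity:
    def test_rotated_problem_gives_rotated_solution(self, material):
        mesh = make_column_mesh(2, 2, 6, (100.0, 100.0, 400.0))
        bc = BoundaryConditions(
            drainage_quads=mesh.facet_sets["top"],
            fixed=[(mesh.node_sets["bottom"], (True, True, True))],
        )
        solver = BiphasicSolver(mesh, material, bc)
        f = traction_forces(mesh, mesh.facet_sets["top"], 1.0)
        s0 = FieldState(0.0, np.zeros((mesh.n_nodes, 3)), np.zeros(mesh.n_nodes))
        s1 = solver.step(s0, f, 0.5)

        th = np.deg2rad(30.0)
        R = np.array([[1, 0, 0], [0, np.cos(th), -np.sin(th)], [0, np.sin(th), np.cos(th)]])
        rmesh = HexMesh(mesh.nodes @ R.T, mesh.elems.copy(),
                        facet_sets={k: v.copy() for k, v in mesh.facet_sets.items()},
                        node_sets={k: v.copy() for k, v in mesh.node_sets.items()})
        rbc = BoundaryConditions(
            drainage_quads=rmesh.facet_sets["top"],
            fixed=[(rmesh.node_sets["bottom"], (True, True, True))],
        )
        rsolver = BiphasicSolver(rmesh, material, rbc)
        rf = traction_forces(rmesh, rmesh.facet_sets["top"], 1.0)
        r1 = rsolver.step(s0, rf, 0.5)
        np.testing.assert_allclose(r1.p, s1.p, atol=1e-10 * np.abs(s1.p).max())
        np.testing.assert_allclose(r1.u, s1.u @ R.T, atol=1e-10 * np.abs(s1.u).max())
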