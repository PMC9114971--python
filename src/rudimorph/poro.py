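"""Quasi-static biphasic (poroelastic) finite elements on hexahedral meshes.

The tissue is a fluid-saturated porous solid: an isotropic linear-elastic
skeleton (effective stress) plus Darcy flow of the interstitial fluid, with
incompressible constituents.  Unknowns are nodal displacements u and pore
pressure p (positive in compression), discretized with trilinear (Q1/Q1)
elements and polynomial-pressure-projection stabilization, integrated in
time with backward Euler:

    div(sigma'(u) - p I) = 0,        sigma' = 2 mu eps + lambda tr(eps) I
    d/dt tr(eps) + div w = 0,        w = -k grad p      (Darcy / seepage)

Boundary conditions: prescribed traction patches, p = 0 on drainage facets,
zero flux elsewhere, per-component displacement fixities.

Units are set by the mesh: with lengths in micrometres, stresses in kPa and
time in seconds, the hydraulic conductivity k is in um^2/(kPa s)
(equivalently 1e-3 um^2/(Pa s) = 1e-15 m^4/(N s), a typical order for soft
embryonic cartilage).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import splu

from .mesh import GAUSS_POINTS, HexMesh, quad_area_normals, shape_functions, shape_gradients

TWO_PI = 2.0 * np.pi


@dataclass(frozen=True)
class PoroMaterial:
    """Biphasic material: elastic skeleton + Darcy fluid.

    ``hydraulic_conductivity`` is intrinsic permeability over fluid
    viscosity, in mesh-length^2 / (stress * time).  ``porosity`` (initial
    fluid volume fraction, ~0.8 for cartilage) is carried as tissue
    metadata; in the incompressible-constituent linear theory it does not
    enter the u-p equations.
    """

    shear_modulus: float = 5.0  # kPa
    poisson_ratio: float = 0.3
    porosity: float = 0.8
    hydraulic_conductivity: float = 10.0  # um^2/(kPa s)

    def __post_init__(self) -> None:
        if self.shear_modulus <= 0:
            raise ValueError("shear_modulus must be positive")
        if not -1.0 < self.poisson_ratio < 0.5:
            raise ValueError("poisson_ratio must be in (-1, 0.5)")
        if not 0.0 < self.porosity < 1.0:
            raise ValueError("porosity must be in (0, 1)")
        if self.hydraulic_conductivity <= 0:
            raise ValueError("hydraulic_conductivity must be positive")

    @property
    def lame_lambda(self) -> float:
        nu = self.poisson_ratio
        return 2.0 * self.shear_modulus * nu / (1.0 - 2.0 * nu)

    @property
    def confined_modulus(self) -> float:
        """Aggregate (oedometric) modulus lambda + 2 mu."""
        return self.lame_lambda + 2.0 * self.shear_modulus

    @property
    def consolidation_coefficient(self) -> float:
        """c_v = k (lambda + 2 mu); sets the consolidation time L^2/c_v."""
        return self.hydraulic_conductivity * self.confined_modulus


@dataclass
class BoundaryConditions:
    """Drainage facets (p = 0), fixities; undeclared exterior is sealed."""

    drainage_quads: np.ndarray  # (F, 4) node quads with p = 0
    fixed: list[tuple[np.ndarray, tuple[bool, bool, bool]]] = field(default_factory=list)

    @classmethod
    def terzaghi_column(cls, mesh: HexMesh) -> "BoundaryConditions":
        """Confined consolidation: drained loaded top, rigid sealed rest."""
        all_nodes = np.arange(mesh.n_nodes)
        return cls(
            drainage_quads=mesh.facet_sets["top"],
            fixed=[
                (all_nodes, (True, True, False)),  # laterally confined
                (mesh.node_sets["bottom"], (False, False, True)),
            ],
        )

    @classmethod
    def humerus(cls, mesh: HexMesh) -> "BoundaryConditions":
        """Free flow across all surfaces except the fully fixed bottom."""
        drainage = np.vstack([mesh.facet_sets["side"], mesh.facet_sets["distal"]])
        return cls(
            drainage_quads=drainage,
            fixed=[(mesh.node_sets["bottom"], (True, True, True))],
        )


@dataclass(frozen=True)
class LoadProgram:
    """One flexion-extension cycle: a traction patch swept over the cap.

    The patch center moves on the distal articular surface from
    ``azimuth_start`` (extension) to ``azimuth_end`` (peak flexion at
    mid-cycle) and back, at fixed polar angle; the amplitude profile is
    sine-like, zero at both ends of the cycle and maximal at peak flexion.
    ``profile='constant'`` holds a static patch at ``azimuth_start``.
    """

    cycle_duration: float = 1.0  # s
    dt: float = 0.01  # s
    patch_radius: float = 100.0  # mesh length units
    peak_traction: float = 1.0  # stress units (kPa), applied inward
    azimuth_start: float = 4 * np.pi / 3 - 0.4
    azimuth_end: float = 4 * np.pi / 3  # peak flexion over the ventral condyle
    polar: float = 1.2  # rad from the distal apex (articular margin)
    profile: str = "sine"

    def __post_init__(self) -> None:
        n = self.cycle_duration / self.dt
        if abs(n - round(n)) > 1e-9:
            raise ValueError("cycle_duration must be an integer multiple of dt")
        if self.profile not in ("sine", "constant"):
            raise ValueError(f"unknown profile {self.profile!r}")
        if not 0 <= self.polar <= np.pi / 2:
            raise ValueError("sweep path polar angle must lie on the distal cap")

    @property
    def n_steps(self) -> int:
        return int(round(self.cycle_duration / self.dt))

    def amplitude(self, t: float) -> float:
        if self.profile == "constant":
            return 1.0
        return float(np.sin(np.pi * (t % self.cycle_duration) / self.cycle_duration)) if t > 0 else max(
            0.0, float(np.sin(np.pi * t / self.cycle_duration))
        )

    def center_azimuth(self, t: float) -> float:
        if self.profile == "constant":
            return self.azimuth_start
        tc = (t % self.cycle_duration) if t % self.cycle_duration or t == 0 else self.cycle_duration
        half = self.cycle_duration / 2.0
        frac = tc / half if tc <= half else (self.cycle_duration - tc) / half
        return self.azimuth_start + frac * (self.azimuth_end - self.azimuth_start)


@dataclass
class FieldState:
    """Converged nodal fields at one time instant."""

    time: float
    u: np.ndarray  # (N, 3)
    p: np.ndarray  # (N,)


@dataclass
class History:
    """A solved load program: mesh, material and the state sequence."""

    mesh: HexMesh
    material: PoroMaterial
    program: LoadProgram | None
    states: list[FieldState]

    @property
    def times(self) -> np.ndarray:
        return np.array([s.time for s in self.states])

    def element_pressure(self) -> np.ndarray:
        """(T, E) pressure at element centers over the history."""
        conn = self.mesh.elems
        return np.array([s.p[conn].mean(axis=1) for s in self.states])

    def write_vtk_series(self, directory, basename: str = "state") -> None:
        import os

        os.makedirs(directory, exist_ok=True)
        for i, s in enumerate(self.states):
            w, divw = seepage_fields(self.mesh, self.material, s)
            self.mesh.write_vtk(
                os.path.join(directory, f"{basename}_{i:04d}.vtk"),
                point_data={"displacement": s.u, "pressure": s.p},
                cell_data={"seepage_velocity": w, "div_seepage": divw},
            )


# ---------------------------------------------------------------------------
# load selection


def load_at_time(
    program: LoadProgram, mesh: HexMesh, t: float
) -> tuple[np.ndarray, float]:
    """Facets under the contact patch at time t, and traction magnitude.

    Returns (indices into mesh.facet_sets['distal'], magnitude).  The patch
    is the set of distal facets whose centroid lies within ``patch_radius``
    of the swept center point on the articular cap.
    """
    if not 0 <= t <= program.cycle_duration * 1e9:
        raise ValueError("time outside the load program")
    if "distal" not in mesh.facet_sets:
        raise ValueError("mesh has no tagged distal articular surface")
    mag = program.peak_traction * program.amplitude(t)
    quads = mesh.facet_sets["distal"]
    # cap geometry from the tagged facets themselves
    pts = mesh.nodes[np.unique(quads)]
    zc = pts[:, 2].min()  # junction height ~ cap center height
    a_cap = pts[:, 2].max() - zc
    az = program.center_azimuth(t)
    pol = program.polar
    center = np.array(
        [a_cap * np.sin(pol) * np.cos(az), a_cap * np.sin(pol) * np.sin(az), zc + a_cap * np.cos(pol)]
    )
    cent = mesh.nodes[quads].mean(axis=1)
    sel = np.nonzero(np.linalg.norm(cent - center, axis=1) <= program.patch_radius)[0]
    if mag > 0 and len(sel) == 0:
        raise ValueError("contact patch selects no facets; increase patch_radius")
    return sel, mag


def traction_forces(mesh: HexMesh, quads: np.ndarray, magnitude: float) -> np.ndarray:
    """Consistent nodal forces for an inward pressure on the given quads."""
    f = np.zeros((mesh.n_nodes, 3))
    if len(quads) == 0 or magnitude == 0.0:
        return f
    area, normal = quad_area_normals(mesh.nodes, quads)
    load = -magnitude * area[:, None] * normal  # inward
    for c in range(4):
        np.add.at(f, quads[:, c], 0.25 * load)
    return f


# ---------------------------------------------------------------------------
# solver


class BiphasicSolver:
    """Assembled linear biphasic system with backward-Euler stepping.

    The monolithic symmetric system per step is

        [ K   -Q ] [u]   [ f            ]
        [-Q^T -(dt H + S)] [p] = [-Q^T u_n - S p_n]

    with K elasticity, Q displacement-pressure coupling, H the Darcy
    conduction matrix and S the pressure-projection stabilization
    (tau = 1/(2 mu), element-mean projection), which suppresses the
    spurious checkerboard pressure modes of the equal-order pairing.
    """

    def __init__(self, mesh: HexMesh, material: PoroMaterial, bc: BoundaryConditions):
        self.mesh = mesh
        self.material = material
        self.bc = bc
        self._factor_cache: dict[float, object] = {}
        self._assemble()

    # -- element precomputation ------------------------------------------

    def _assemble(self) -> None:
        mesh, mat = self.mesh, self.material
        E, N = mesh.n_elems, mesh.n_nodes
        xe = mesh.nodes[mesh.elems]  # (E, 8, 3)
        dN = shape_gradients(GAUSS_POINTS)  # (G, 8, 3)
        NN = shape_functions(GAUSS_POINTS)  # (G, 8)
        J = np.einsum("eni,gnj->egij", xe, dN)  # (E, G, 3, 3)
        detJ = np.linalg.det(J)
        if detJ.min() <= 0:
            raise ValueError("mesh contains non-positive Jacobians")
        Jinv = np.linalg.inv(J)
        gradN = np.einsum("egji,gnj->egni", Jinv, dN)  # (E, G, 8, 3) physical
        w = detJ  # unit Gauss weights

        lam, mu = mat.lame_lambda, mat.shear_modulus
        # K_e = sum_G [ lam (B_vol)(B_vol)^T + mu (grad sym) ] — assembled
        # directly from gradN:  K[ai, bj] = lam dNa_i dNb_j
        #   + mu (dNa_j dNb_i + delta_ij sum_k dNa_k dNb_k)
        g = gradN
        K_e = (
            lam * np.einsum("egai,egbj,eg->eaibj", g, g, w)
            + mu * np.einsum("egaj,egbi,eg->eaibj", g, g, w)
            + mu * np.einsum("ij,egak,egbk,eg->eaibj", np.eye(3), g, g, w)
        ).reshape(E, 24, 24)
        Q_e = np.einsum("egai,egb,eg->eaib", g, NN[None], w).reshape(E, 24, 8)
        H_e = mat.hydraulic_conductivity * np.einsum("egai,egbi,eg->eab", g, g, w)
        M_e = np.einsum("ega,egb,eg->eab", NN[None], NN[None], w)
        v_e = np.einsum("ega,eg->ea", NN[None], w)
        V_e = w.sum(axis=1)
        tau = 1.0 / (2.0 * mu)
        S_e = tau * (M_e - v_e[:, :, None] * v_e[:, None, :] / V_e[:, None, None])

        conn = mesh.elems
        udof = (3 * conn[:, :, None] + np.arange(3)[None, None, :]).reshape(E, 24)
        rows = np.repeat(udof, 24, axis=1).ravel()
        cols = np.tile(udof, (1, 24)).ravel()
        K = sparse.coo_matrix((K_e.ravel(), (rows, cols)), shape=(3 * N, 3 * N)).tocsr()
        rows = np.repeat(udof, 8, axis=1).ravel()
        cols = np.tile(conn, (1, 24)).ravel()
        Q = sparse.coo_matrix((Q_e.ravel(), (rows, cols)), shape=(3 * N, N)).tocsr()
        rows = np.repeat(conn, 8, axis=1).ravel()
        cols = np.tile(conn, (1, 8)).ravel()
        H = sparse.coo_matrix((H_e.ravel(), (rows, cols)), shape=(N, N)).tocsr()
        S = sparse.coo_matrix((S_e.ravel(), (rows, cols)), shape=(N, N)).tocsr()
        self.K, self.Q, self.H, self.S = K, Q, H, S
        self._gradN, self._detJ, self._NN = gradN, detJ, NN

        # constrained dofs
        fixed_u = np.zeros((N, 3), dtype=bool)
        for nodes, flags in self.bc.fixed:
            for d in range(3):
                if flags[d]:
                    fixed_u[nodes, d] = True
        self.fixed_u = fixed_u.ravel()
        fixed_p = np.zeros(N, dtype=bool)
        if len(self.bc.drainage_quads):
            fixed_p[np.unique(self.bc.drainage_quads)] = True
        self.fixed_p = fixed_p
        self.free = np.concatenate([~self.fixed_u, ~fixed_p])
        if not self.fixed_u.any():
            warnings.warn("no displacement constraints; system may be singular")

    def _system(self, dt: float):
        key = round(dt, 12)
        if key not in self._factor_cache:
            A = sparse.bmat(
                [[self.K, -self.Q], [-self.Q.T, -(dt * self.H + self.S)]], format="csr"
            )
            free = self.free
            Aff = A[free][:, free].tocsc()
            self._factor_cache[key] = (splu(Aff), A)
        return self._factor_cache[key]

    def step(self, state: FieldState, f_ext: np.ndarray, dt: float) -> FieldState:
        """Advance one backward-Euler step under nodal forces ``f_ext``."""
        if dt <= 0:
            raise ValueError("dt must be positive")
        lu, A = self._system(dt)
        N = self.mesh.n_nodes
        rhs = np.concatenate(
            [f_ext.ravel(), -self.Q.T @ state.u.ravel() - self.S @ state.p]
        )
        free = self.free
        x = np.zeros(4 * N)
        sol = lu.solve(rhs[free])
        if not np.all(np.isfinite(sol)):
            raise RuntimeError("singular biphasic system (check constraints/drainage)")
        x[free] = sol
        u = x[: 3 * N].reshape(N, 3)
        p = x[3 * N:]
        # residual check on free dofs (direct solve: should be tiny)
        res = np.linalg.norm((A @ x - rhs)[free])
        scale = max(np.linalg.norm(rhs[free]), 1.0)
        if res / scale > 1e-8:
            raise RuntimeError(f"step residual {res / scale:.2e} above tolerance")
        return FieldState(time=state.time + dt, u=u, p=p)

    def solve_cycle(self, program: LoadProgram, n_cycles: int = 1) -> History:
        """Run ``n_cycles`` of the flexion-extension program."""
        state = FieldState(0.0, np.zeros((self.mesh.n_nodes, 3)), np.zeros(self.mesh.n_nodes))
        states = [state]
        quads_all = self.mesh.facet_sets["distal"]
        for c in range(n_cycles):
            for k in range(program.n_steps):
                t_next = c * program.cycle_duration + (k + 1) * program.dt
                sel, mag = load_at_time(program, self.mesh, t_next % program.cycle_duration
                                        if t_next % program.cycle_duration else program.cycle_duration)
                f = traction_forces(self.mesh, quads_all[sel], mag)
                state = self.step(state, f, program.dt)
                state.time = t_next
                states.append(state)
        return History(self.mesh, self.material, program, states)

    def solve_hold(self, quads: np.ndarray, magnitude: float, times: np.ndarray) -> History:
        """Sustained (static) traction on fixed facets, sampled at ``times``."""
        state = FieldState(0.0, np.zeros((self.mesh.n_nodes, 3)), np.zeros(self.mesh.n_nodes))
        f = traction_forces(self.mesh, quads, magnitude)
        states = [state]
        t_prev = 0.0
        for t in times:
            state = self.step(state, f, t - t_prev)
            states.append(state)
            t_prev = t
        return History(self.mesh, self.material, None, states)


# ---------------------------------------------------------------------------
# module-level operations


def step(
    state: FieldState,
    mesh: HexMesh,
    material: PoroMaterial,
    bc: BoundaryConditions,
    load: tuple[np.ndarray, float],
    dt: float,
) -> FieldState:
    """Single time step (convenience wrapper; re-assembles the system)."""
    solver = BiphasicSolver(mesh, material, bc)
    f = traction_forces(mesh, load[0], load[1])
    return solver.step(state, f, dt)


def solve_cycle(
    mesh: HexMesh,
    material: PoroMaterial,
    bc: BoundaryConditions,
    program: LoadProgram,
    n_cycles: int = 1,
) -> History:
    return BiphasicSolver(mesh, material, bc).solve_cycle(program, n_cycles)


def _element_neighbors(mesh: HexMesh) -> list[np.ndarray]:
    node_to_elems: list[list[int]] = [[] for _ in range(mesh.n_nodes)]
    for e, conn in enumerate(mesh.elems):
        for n in conn:
            node_to_elems[n].append(e)
    out = []
    for e, conn in enumerate(mesh.elems):
        s: set[int] = set()
        for n in conn:
            s.update(node_to_elems[n])
        out.append(np.fromiter(s, dtype=np.int64))
    return out


def seepage_fields(
    mesh: HexMesh, material: PoroMaterial, state: FieldState
) -> tuple[np.ndarray, np.ndarray]:
    """Per-element seepage velocity w = -k grad p and its divergence.

    w is the Gauss-point average of -k grad p.  With trilinear pressure the
    in-element gradient cannot curve, so the divergence uses the element
    patch: a least-squares linear fit of w over the centers of the
    node-connected neighbour elements (exact for fields whose velocity is
    linear in position).
    """
    xe = mesh.nodes[mesh.elems]
    dN = shape_gradients(GAUSS_POINTS)
    J = np.einsum("eni,gnj->egij", xe, dN)
    Jinv = np.linalg.inv(J)
    gradN = np.einsum("egji,gnj->egni", Jinv, dN)
    pe = state.p[mesh.elems]  # (E, 8)
    gradp = np.einsum("egni,en->egi", gradN, pe)  # (E, G, 3)
    w_gp = -material.hydraulic_conductivity * gradp
    w_mean = w_gp.mean(axis=1)

    centers = mesh.element_centroids()
    neighbors = _element_neighbors(mesh)
    div = np.zeros(mesh.n_elems)
    for e, nb in enumerate(neighbors):
        X = centers[nb] - centers[e]
        A = np.column_stack([np.ones(len(nb)), X])  # affine fit w = a + B x
        coef, *_ = np.linalg.lstsq(A, w_mean[nb], rcond=None)
        div[e] = coef[1, 0] + coef[2, 1] + coef[3, 2]
    return w_mean, div


def seepage_divergence(history: History) -> np.ndarray:
    """(T, E) time series of div(w) over a solved history."""
    if len(history.states) < 2:
        raise ValueError("history needs at least two states")
    return np.array(
        [seepage_fields(history.mesh, history.material, s)[1] for s in history.states]
    )


FACE_CENTERS = np.array(
    [[0, 0, -1], [0, 0, 1], [0, -1, 0], [1, 0, 0], [0, 1, 0], [-1, 0, 0]], dtype=float
)


def net_boundary_seepage(mesh: HexMesh, material: PoroMaterial, state: FieldState) -> float:
    """Net outward Darcy flux through the exterior surface.

    grad p is evaluated at each boundary facet's center in the owning
    element's local coordinates.
    """
    quads, qelem, qface = mesh.facet_quads_elements()
    area, normal = quad_area_normals(mesh.nodes, quads)
    xe = mesh.nodes[mesh.elems[qelem]]
    dN_face = shape_gradients(FACE_CENTERS)  # (6, 8, 3)
    dN = dN_face[qface]  # (F, 8, 3)
    J = np.einsum("fni,fnj->fij", xe, dN)
    Jinv = np.linalg.inv(J)
    gradN = np.einsum("fji,fnj->fni", Jinv, dN)
    pe = state.p[mesh.elems[qelem]]
    gradp = np.einsum("fni,fn->fi", gradN, pe)
    w = -material.hydraulic_conductivity * gradp
    return float(np.sum(area * np.einsum("fi,fi->f", w, normal)))


def terzaghi_pressure(z: np.ndarray, t: float, q: float, c_v: float, height: float, n_terms: int = 200) -> np.ndarray:
    """Closed-form consolidation pressure for a column drained at the top.

    ``z`` is depth below the drained surface, ``height`` the drainage path
    length.  Series solution of the 1D diffusion of excess pore pressure
    after a step load q.
    """
    Z = np.asarray(z, dtype=float) / height
    Tv = c_v * t / height**2
    p = np.zeros_like(Z)
    for m in range(n_terms):
        M = 0.5 * np.pi * (2 * m + 1)
        p += (2.0 / M) * np.sin(M * Z) * np.exp(-(M**2) * Tv)
    return q * p
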