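"""Tissue growth driven by a solved load-cycle history.

Per-element growth rate is the sum of a constant biological contribution
(k_bio per cycle, spatially uniform — chondrocyte density is approximately
constant in the rudiment at this stage) and a mechanical contribution
proportional to a cycle-integrated stimulus: either the compressive part of
the pore pressure or the positive divergence of the seepage velocity.
Setting k_mech = 0 is the mechanosensitively impaired case.

The per-cycle volumetric growth factor theta_e = 1 + k_bio + k_mech S_e is
extrapolated over n cycles (compound by default) and applied as an
isotropic growth tensor Fg = theta^(1/3) I: the grown configuration is the
elastic equilibrium of the mesh with the growth eigenstrain under the
original displacement constraints.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import spsolve

from .mesh import GAUSS_POINTS, HexMesh, shape_gradients
from .poro import BoundaryConditions, History, PoroMaterial, seepage_divergence

STIMULI = ("compressive_pore_pressure", "positive_div_seepage")


@dataclass(frozen=True)
class GrowthParams:
    """Growth law parameters.

    k_bio: biological growth per cycle (volume fraction, 1/cycle).
    k_mech: mechanical growth per unit stimulus; for the pressure stimulus
        the stimulus unit is kPa*s per cycle, for the seepage-divergence
        stimulus it is dimensionless (1/s integrated over the cycle).
    """

    k_bio: float = 0.002
    k_mech: float = 0.02
    stimulus: str = "compressive_pore_pressure"
    n_cycles: int = 100

    def __post_init__(self) -> None:
        if self.k_bio < 0 or self.k_mech < 0:
            raise ValueError("growth rates must be >= 0")
        if self.stimulus not in STIMULI:
            raise ValueError(f"unknown stimulus {self.stimulus!r}; choose from {STIMULI}")
        if self.n_cycles < 0:
            raise ValueError("n_cycles must be >= 0")


@dataclass
class GrowthField:
    """Per-element volumetric growth factor theta (volume ratio >= 0)."""

    theta: np.ndarray

    def __post_init__(self) -> None:
        self.theta = np.asarray(self.theta, dtype=float)
        if np.any(self.theta <= 0):
            raise ValueError("non-physical growth: theta must be positive")


def accumulate_stimulus(history: History, stimulus: str = "compressive_pore_pressure") -> np.ndarray:
    """Cycle-integrated positive-part stimulus per element.

    S_e = int max(x_e(t), 0) dt by the trapezoidal rule, with x the element
    pore pressure (compression positive) or the seepage-velocity
    divergence.
    """
    if stimulus not in STIMULI:
        raise ValueError(f"unknown stimulus {stimulus!r}; choose from {STIMULI}")
    if len(history.states) < 2:
        raise ValueError("history must contain at least two states")
    t = history.times
    if stimulus == "compressive_pore_pressure":
        x = history.element_pressure()
    else:
        x = seepage_divergence(history)
    pos = np.maximum(x, 0.0)
    return np.trapezoid(pos, t, axis=0)


def grow_one_cycle(S: np.ndarray, params: GrowthParams) -> GrowthField:
    """theta_e = 1 + k_bio + k_mech S_e (linearized per-cycle update)."""
    g = params.k_bio + params.k_mech * np.asarray(S, dtype=float)
    return GrowthField(theta=1.0 + g)


def extrapolate(growth: GrowthField, n_cycles: int, mode: str = "compound") -> GrowthField:
    """Extrapolate the single-cycle growth over n cycles.

    compound (default): theta_total = theta_cycle ** n;
    linear: theta_total = 1 + n (theta_cycle - 1).
    """
    if n_cycles < 0:
        raise ValueError("n_cycles must be >= 0")
    if mode == "compound":
        return GrowthField(theta=growth.theta**n_cycles)
    if mode == "linear":
        return GrowthField(theta=1.0 + n_cycles * (growth.theta - 1.0))
    raise ValueError(f"unknown extrapolation mode {mode!r}")


# ---------------------------------------------------------------------------
# growing the mesh


def _elastic_stiffness(mesh: HexMesh, mat: PoroMaterial):
    E, N = mesh.n_elems, mesh.n_nodes
    xe = mesh.nodes[mesh.elems]
    dN = shape_gradients(GAUSS_POINTS)
    J = np.einsum("eni,gnj->egij", xe, dN)
    detJ = np.linalg.det(J)
    if detJ.min() <= 0:
        raise ValueError("mesh contains non-positive Jacobians")
    Jinv = np.linalg.inv(J)
    g = np.einsum("egji,gnj->egni", Jinv, dN)
    lam, mu = mat.lame_lambda, mat.shear_modulus
    K_e = (
        lam * np.einsum("egai,egbj,eg->eaibj", g, g, detJ)
        + mu * np.einsum("egaj,egbi,eg->eaibj", g, g, detJ)
        + mu * np.einsum("ij,egak,egbk,eg->eaibj", np.eye(3), g, g, detJ)
    ).reshape(E, 24, 24)
    conn = mesh.elems
    udof = (3 * conn[:, :, None] + np.arange(3)[None, None, :]).reshape(E, 24)
    rows = np.repeat(udof, 24, axis=1).ravel()
    cols = np.tile(udof, (1, 24)).ravel()
    K = sparse.coo_matrix((K_e.ravel(), (rows, cols)), shape=(3 * N, 3 * N)).tocsr()
    return K, g, detJ


def apply_growth(
    mesh: HexMesh,
    growth: GrowthField,
    mat: PoroMaterial,
    bc: BoundaryConditions | None = None,
) -> HexMesh:
    """Grow the mesh: isotropic eigenstrain equilibrium under the original
    displacement constraints (drained, no pore pressure).

    The growth stretch theta^(1/3) enters as a stress-free strain
    (theta^(1/3) - 1) I per element; nodes move to the equilibrium
    configuration.  With no constraints, rigid-body modes are removed by
    zero-mean / zero-moment conditions (Lagrange multipliers), so uniform
    growth of a free body is exact uniform scaling.
    """
    theta = growth.theta
    if len(theta) == 1:
        theta = np.full(mesh.n_elems, theta[0])
    if len(theta) != mesh.n_elems:
        raise ValueError("growth field length does not match element count")
    K, g, detJ = _elastic_stiffness(mesh, mat)
    N = mesh.n_nodes
    bulk3 = 3.0 * mat.lame_lambda + 2.0 * mat.shear_modulus  # D : I = (3 lam + 2 mu) I
    eps_g = theta ** (1.0 / 3.0) - 1.0
    # f[a, i] = sum_e (3lam+2mu) eps_g_e int dN_a/dx_i
    fe = bulk3 * eps_g[:, None, None] * np.einsum("egai,eg->eai", g, detJ)
    f = np.zeros((N, 3))
    np.add.at(f, mesh.elems, fe)
    f = f.ravel()

    fixed = np.zeros((N, 3), dtype=bool)
    if bc is not None:
        for nodes, flags in bc.fixed:
            for d in range(3):
                if flags[d]:
                    fixed[nodes, d] = True
    fixed = fixed.ravel()
    if fixed.any():
        free = ~fixed
        u = np.zeros(3 * N)
        u[free] = spsolve(K[free][:, free].tocsc(), f[free])
    else:
        # free body: remove translations and rotations via Lagrange multipliers
        x = mesh.nodes - mesh.nodes.mean(axis=0)
        C = np.zeros((6, 3 * N))
        for d in range(3):
            C[d, d::3] = 1.0
        C[3, 1::3], C[3, 2::3] = -x[:, 2], x[:, 1]
        C[4, 0::3], C[4, 2::3] = x[:, 2], -x[:, 0]
        C[5, 0::3], C[5, 1::3] = -x[:, 1], x[:, 0]
        A = sparse.bmat([[K, sparse.csr_matrix(C.T)], [sparse.csr_matrix(C), None]], format="csc")
        sol = spsolve(A, np.concatenate([f, np.zeros(6)]))
        u = sol[: 3 * N]
    if not np.all(np.isfinite(u)):
        raise RuntimeError("growth equilibrium solve failed (singular system)")
    grown = mesh.copy(nodes=mesh.nodes + u.reshape(N, 3))
    if grown.min_jacobian() <= 0:
        raise RuntimeError("growth inverted elements; reduce per-cycle growth or n_cycles")
    return grown


# ---------------------------------------------------------------------------
# surface growth maps


def surface_growth_displacement(mesh: HexMesh, grown: HexMesh) -> tuple[np.ndarray, np.ndarray]:
    """(surface node ids, per-node displacement magnitude).

    Node correspondence between the original and grown configurations is
    exact (same topology); the growth measure at each surface node is the
    magnitude of its displacement.  For the perpendicular (sliding-blind)
    alternative see :func:`point_surface_distance`.
    """
    if mesh.n_nodes != grown.n_nodes:
        raise ValueError("mesh and grown mesh must share nodes")
    surf_nodes = np.unique(mesh.boundary_quads())
    d = np.linalg.norm(grown.nodes[surf_nodes] - mesh.nodes[surf_nodes], axis=1)
    return surf_nodes, d


def point_surface_distance(points: np.ndarray, verts: np.ndarray, faces: np.ndarray,
                           chunk: int = 128) -> np.ndarray:
    """Unsigned distance from each point to a triangulated surface.

    Exact point-triangle distances (barycentric clamping), minimized over
    all triangles; brute force in chunks, adequate for FE surface sizes.
    """
    tri = verts[faces]  # (T, 3, 3)
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
    ab, ac = b - a, c - a
    out = np.empty(len(points))
    for lo in range(0, len(points), chunk):
        p = points[lo: lo + chunk]  # (P, 3)
        ap = p[:, None, :] - a[None, :, :]  # (P, T, 3)
        d1 = np.einsum("tj,ptj->pt", ab, ap)
        d2 = np.einsum("tj,ptj->pt", ac, ap)
        aa = np.einsum("tj,tj->t", ab, ab)[None]
        bb = np.einsum("tj,tj->t", ac, ac)[None]
        abdot = np.einsum("tj,tj->t", ab, ac)[None]
        det = np.maximum(aa * bb - abdot**2, 1e-300)
        v = (bb * d1 - abdot * d2) / det
        w = (aa * d2 - abdot * d1) / det
        # clamp barycentric coordinates onto the triangle
        v = np.clip(v, 0.0, 1.0)
        w = np.clip(w, 0.0, 1.0)
        over = v + w > 1.0
        s = np.where(over, (v + w - 1.0) / 2.0, 0.0)
        v = v - s
        w = w - s
        v = np.clip(v, 0.0, 1.0)
        w = np.clip(w, 0.0, 1.0 - v)
        proj = a[None] + v[..., None] * ab[None] + w[..., None] * ac[None]
        dist = np.linalg.norm(p[:, None, :] - proj, axis=2)
        # clamped projection is approximate near edges; refine with the
        # exact edge distances
        for e0, e1 in ((a, b), (a, c), (b, c)):
            ev = (e1 - e0)[None]
            t = np.clip(
                np.einsum("ptj,ptj->pt", p[:, None, :] - e0[None], np.broadcast_to(ev, ap.shape))
                / np.maximum(np.einsum("tj,tj->t", e1 - e0, e1 - e0)[None], 1e-300),
                0.0, 1.0,
            )
            q = e0[None] + t[..., None] * ev
            dist = np.minimum(dist, np.linalg.norm(p[:, None, :] - q, axis=2))
        out[lo: lo + chunk] = dist.min(axis=1)
    return out


def surface_growth_maps(
    mesh: HexMesh,
    grown_cases: dict[str, HexMesh],
    n_azimuth: int = 96,
    n_meridian: int = 48,
):
    """Normalized surface-growth maps for a set of grown cases.

    Per surface node, the distance between original and grown surface;
    all cases are normalized by the shared maximum (so values lie in [0, 1]
    and the most-grown node across cases equals 1), then flattened onto a
    reference surface fitted to the original mesh surface.
    Returns (dict name -> FlatMap, reference).
    """
    from . import shape as shape_mod
    import trimesh

    verts, tris = mesh.surface_triangles()
    surf_ids = np.unique(tris)
    remap = np.full(len(verts), -1)
    remap[surf_ids] = np.arange(len(surf_ids))
    surf = trimesh.Trimesh(vertices=verts[surf_ids], faces=remap[tris], process=False)
    ref = shape_mod.fit_shaft_cylinder(surf)
    ref = shape_mod.build_reference(ref, surf)
    mags = {}
    for name, gmesh in grown_cases.items():
        ids, d = surface_growth_displacement(mesh, gmesh)
        full = np.zeros(mesh.n_nodes)
        full[ids] = d
        mags[name] = full
    norm = max(v.max() for v in mags.values())
    norm = norm if norm > 0 else 1.0
    maps = {
        name: shape_mod.flatten_node_values(
            verts, v / norm, ref, n_azimuth=n_azimuth, n_meridian=n_meridian, faces=tris
        )
        for name, v in mags.items()
    }
    return maps, ref


def grow_from_history(
    history: History,
    params: GrowthParams,
    bc: BoundaryConditions | None = None,
    extrapolation: str = "compound",
) -> tuple[HexMesh, GrowthField]:
    """Full growth step: stimulus -> per-cycle growth -> extrapolate -> grow."""
    S = accumulate_stimulus(history, params.stimulus)
    per_cycle = grow_one_cycle(S, params)
    total = extrapolate(per_cycle, params.n_cycles, mode=extrapolation)
    grown = apply_growth(history.mesh, total, history.material, bc=bc)
    return grown, total
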