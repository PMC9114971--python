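"""3D morphometry of limb rudiments via reference-surface flattening.

Pipeline (per limb): align the segmented humerus to its proximo-distal axis
(minimum principal axis of inertia), mirror right limbs so condyles share a
common arrangement, fit a cylinder to the shaft, place a hemispherical cap
tangent to the distal end (cylinder + cap = reference surface), map the
signed radial distance from the reference to the limb surface, normalize by
the fitted cylinder diameter d, and flatten to a 2D (azimuth x meridian)
map.  Condyles are the connected map regions above a threshold (0.2 by
convention); their normalized areas (d^2 units) and volumes (map integral,
dimensionless) are the shape metrics.  Concavities are the analogous
regions below -threshold.

The map is built by projecting every surface vertex onto the reference
(each vertex has a unique (azimuth, meridian) coordinate for star-shaped
rudiment geometries) and bin-averaging; cells no vertex falls in are
masked.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import trimesh
from scipy import ndimage, optimize

TWO_PI = 2.0 * np.pi


@dataclass
class AlignedSurface:
    """Surface in the canonical frame: proximo-distal axis = +z, distal up."""

    mesh: trimesh.Trimesh
    transform: np.ndarray  # 4x4 applied to the input
    mirrored: bool = False
    principal_moments: np.ndarray | None = None


@dataclass
class ReferenceSurface:
    """Fitted shaft cylinder + tangent hemispherical cap (axis frame)."""

    axis_point: np.ndarray  # point on the axis (world coords)
    axis_dir: np.ndarray  # unit vector, ~ +z
    radius: float
    cap_center_z: float = np.nan  # axis coordinate of the cap center
    z_bottom: float = np.nan  # proximal end of the mapped region
    vertical_shift: float = np.nan  # cap lift relative to the shaft junction
    fit_rms: float = np.nan

    @property
    def diameter(self) -> float:
        return 2.0 * self.radius

    def to_axis_frame(self, points: np.ndarray) -> np.ndarray:
        """Express points in the cylinder-axis frame (axis = +z)."""
        w = self.axis_dir / np.linalg.norm(self.axis_dir)
        ref = np.array([1.0, 0.0, 0.0])
        if abs(w @ ref) > 0.9:
            ref = np.array([0.0, 1.0, 0.0])
        e1 = ref - (ref @ w) * w  # azimuth origin follows the frame's x axis
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(w, e1)
        R = np.vstack([e1, e2, w])
        return (points - self.axis_point) @ R.T


@dataclass
class FlatMap:
    """2D standardized limb-surface representation.

    Rows are meridian positions (shaft axial coordinate continuing into the
    cap polar arc), columns azimuth.  Values are signed distance normalized
    by the cylinder diameter (positive = outside the reference).
    ``cell_area`` holds the physical area of each row's cells in d^2 units.
    """

    values: np.ndarray  # (n_merid, n_azim)
    mask: np.ndarray  # valid cells
    cell_area: np.ndarray  # (n_merid,)
    azimuth_centers: np.ndarray
    meridian_centers: np.ndarray  # physical units (same as mesh)
    diameter: float
    junction_meridian: float = np.nan  # meridian arc where the cap begins

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_csv(self, path) -> None:
        df = pd.DataFrame(np.where(self.mask, self.values, np.nan),
                          index=self.meridian_centers, columns=self.azimuth_centers)
        df.to_csv(path, index_label="meridian_um")

    def save_png(self, path, contour_threshold: float | None = 0.2) -> None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(7, 4))
        shown = np.where(self.mask, self.values, np.nan)
        im = ax.pcolormesh(self.azimuth_centers, self.meridian_centers, shown,
                           cmap="RdBu_r", vmin=-0.5, vmax=0.5)
        if contour_threshold is not None and np.isfinite(shown).any():
            ax.contour(self.azimuth_centers, self.meridian_centers,
                       np.nan_to_num(shown), levels=[contour_threshold],
                       colors="k", linestyles="--")
        ax.set_xlabel("azimuth (rad)")
        ax.set_ylabel("meridian arc (um)")
        fig.colorbar(im, ax=ax, label="distance / d")
        fig.tight_layout()
        fig.savefig(path, dpi=120)
        plt.close(fig)


# ---------------------------------------------------------------------------
# alignment


def _inertia_axes(mesh: trimesh.Trimesh) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    if mesh.is_watertight:
        inertia = mesh.moment_inertia
        center = mesh.center_mass
    else:
        warnings.warn("surface not watertight; using vertex covariance for alignment")
        center = mesh.vertices.mean(axis=0)
        v = mesh.vertices - center
        cov = v.T @ v / len(v)
        # inertia from covariance: I = tr(C) I3 - C
        inertia = np.trace(cov) * np.eye(3) - cov
    vals, vecs = np.linalg.eigh(inertia)
    return vals, vecs, center


def principal_axis_align(surface: trimesh.Trimesh, degenerate_rtol: float = 0.01) -> AlignedSurface:
    """Rotate so the minimum principal axis of inertia maps to +z, distal up.

    The long axis of an elongated solid has the smallest moment of inertia.
    The distal end is identified geometrically: the end whose vertices
    protrude radially beyond the shaft (condyles) or, failing that, the
    rounded (tapering) end rather than the flat amputation face.
    """
    vals, vecs, center = _inertia_axes(surface)
    if (vals[1] - vals[0]) < degenerate_rtol * max(vals[1], 1e-300):
        raise ValueError("degenerate axis: principal moments nearly equal")
    axis = vecs[:, 0]
    # deterministic sign (largest component positive) keeps the minimal
    # rotation well-conditioned and reproducible
    axis = axis * np.sign(axis[np.argmax(np.abs(axis))])
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(axis, z)
    s, c = np.linalg.norm(v), float(axis @ z)
    if s < 1e-12:
        R = np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
    else:
        vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
        R = np.eye(3) + vx + vx @ vx * ((1 - c) / s**2)
    verts = (surface.vertices - center) @ R.T

    if _distal_is_down(verts):
        flip = np.diag([1.0, -1.0, -1.0])  # rotate pi about x
        R = flip @ R
        verts = verts @ flip.T

    T = np.eye(4)
    T[:3, :3] = R
    T[:3, 3] = -R @ center
    out = trimesh.Trimesh(vertices=verts, faces=surface.faces.copy(), process=False)
    return AlignedSurface(mesh=out, transform=T, principal_moments=vals)


def _distal_is_down(verts: np.ndarray) -> bool:
    """True if the condyle-bearing (distal) end currently points to -z."""
    z = verts[:, 2]
    zmin, zmax = z.min(), z.max()
    extent = zmax - zmin
    rho = np.hypot(verts[:, 0], verts[:, 1])
    r_med = np.median(rho)

    def protrusion(band):
        p = rho[band] - r_med
        return np.percentile(p, 95) if band.any() else 0.0

    top = protrusion(z > zmax - 0.35 * extent)
    bot = protrusion(z < zmin + 0.35 * extent)
    if abs(top - bot) > 0.02 * r_med:
        return bot > top
    # tie-break: the rounded end tapers, the amputation face stays wide
    slab = 0.03 * extent
    top_w = rho[z > zmax - slab].max() if (z > zmax - slab).any() else 0.0
    bot_w = rho[z < zmin + slab].max() if (z < zmin + slab).any() else 0.0
    return bot_w < top_w


def mirror_right(surface: trimesh.Trimesh, handedness: str) -> tuple[trimesh.Trimesh, bool]:
    """Reflect right limbs through the y = 0 plane; left limbs untouched."""
    if handedness == "left":
        return surface, False
    if handedness != "right":
        raise ValueError(f"unknown handedness {handedness!r}")
    v = surface.vertices.copy()
    v[:, 1] = -v[:, 1]
    return trimesh.Trimesh(vertices=v, faces=surface.faces[:, ::-1], process=False), True


# ---------------------------------------------------------------------------
# reference surface


def fit_shaft_cylinder(
    aligned: AlignedSurface | trimesh.Trimesh,
    shaft_fraction: float = 0.5,
    exclude_base_fraction: float = 0.05,
) -> ReferenceSurface:
    """Least-squares cylinder through the proximal shaft vertices.

    Minimizes radial residuals (distance to axis minus radius) over the
    proximal ``shaft_fraction`` of the axial extent, excluding the very
    bottom (amputation face).  Parameters: axis point (x0, y0), small axis
    tilts, radius.
    """
    mesh = aligned.mesh if isinstance(aligned, AlignedSurface) else aligned
    v = mesh.vertices
    z = v[:, 2]
    zmin, extent = z.min(), z.max() - z.min()
    band = (z > zmin + exclude_base_fraction * extent) & (z < zmin + shaft_fraction * extent)
    pts = v[band]
    if len(pts) < 6:
        raise ValueError("too few shaft points to fit a cylinder")
    if np.linalg.matrix_rank(pts - pts.mean(axis=0), tol=1e-9 * max(extent, 1.0)) < 3:
        raise ValueError("shaft points are coplanar; cylinder fit is degenerate")
    z0 = pts[:, 2].mean()
    r0 = np.median(np.hypot(pts[:, 0], pts[:, 1]))

    def residual(q):
        x0, y0, ax, ay, r = q
        d = np.array([ax, ay, 1.0])
        d /= np.linalg.norm(d)
        rel = pts - np.array([x0, y0, z0])
        radial = rel - np.outer(rel @ d, d)
        return np.linalg.norm(radial, axis=1) - r

    sol = optimize.least_squares(residual, x0=[0.0, 0.0, 0.0, 0.0, r0], method="lm")
    x0, y0, ax, ay, r = sol.x
    d = np.array([ax, ay, 1.0])
    d /= np.linalg.norm(d)
    rms = float(np.sqrt(np.mean(sol.fun**2)))
    if rms > 0.2 * r:
        warnings.warn(f"poor cylindricity: residual RMS {rms:.3g} > 0.2 r")
    return ReferenceSurface(
        axis_point=np.array([x0, y0, z0]), axis_dir=d, radius=float(abs(r)), fit_rms=rms
    )


def build_reference(ref: ReferenceSurface, aligned: AlignedSurface | trimesh.Trimesh) -> ReferenceSurface:
    """Place the hemispherical cap tangent to the distal end.

    The cap (radius = cylinder radius r) slides up the axis until it just
    touches the surface: its center height is the maximum over surface
    points within the cap footprint (axial distance < r) of
    z - sqrt(r^2 - rho^2).  The recorded ``vertical_shift`` is relative to
    the shaft junction (the highest full-radius point).
    """
    mesh = aligned.mesh if isinstance(aligned, AlignedSurface) else aligned
    pa = ref.to_axis_frame(mesh.vertices)
    rho = np.hypot(pa[:, 0], pa[:, 1])
    z = pa[:, 2]
    r = ref.radius
    on_shaft = rho >= 0.9999 * r
    if not on_shaft.any():
        raise ValueError("no full-radius shaft points; cannot locate the junction")
    z_junction = z[on_shaft].max()
    inside = rho < 0.999 * r
    if not (inside & (z > z_junction - 0.5 * r)).any():
        raise ValueError("no surface points distal to the cylinder top")
    cap_c = np.max(z[inside] - np.sqrt(np.maximum(r**2 - rho[inside] ** 2, 0.0)))
    out = ReferenceSurface(
        axis_point=ref.axis_point.copy(),
        axis_dir=ref.axis_dir.copy(),
        radius=r,
        cap_center_z=float(cap_c),
        z_bottom=float(z.min()),
        vertical_shift=float(cap_c - z_junction),
        fit_rms=ref.fit_rms,
    )
    return out


# ---------------------------------------------------------------------------
# flattening


def _reference_coordinates(ref: ReferenceSurface, points: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(azimuth, meridian arc, signed normalized distance) per point."""
    pa = ref.to_axis_frame(points)
    rho = np.hypot(pa[:, 0], pa[:, 1])
    z = pa[:, 2]
    azim = np.arctan2(pa[:, 1], pa[:, 0]) % TWO_PI
    r, zc, zb, d = ref.radius, ref.cap_center_z, ref.z_bottom, ref.diameter
    on_cap = z >= zc
    merid = np.empty(len(pa))
    value = np.empty(len(pa))
    merid[~on_cap] = z[~on_cap] - zb
    value[~on_cap] = (rho[~on_cap] - r) / d
    rel_z = z[on_cap] - zc
    dist = np.hypot(rho[on_cap], rel_z)
    polar = np.arccos(np.clip(np.where(dist > 0, rel_z / np.maximum(dist, 1e-300), 1.0), -1, 1))
    merid[on_cap] = (zc - zb) + r * (np.pi / 2 - polar)
    value[on_cap] = (dist - r) / d
    return azim, merid, value


def sample_surface_points(
    vertices: np.ndarray,
    faces: np.ndarray,
    spacing: float,
    values: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray | None]:
    """Deterministic dense point samples on a triangulated surface.

    Each triangle is subdivided barycentrically so sample spacing is at
    most ``spacing``; optional per-vertex values are interpolated to the
    samples.  Guarantees map-cell coverage independent of mesh resolution.
    """
    tri = vertices[faces]  # (F, 3, 3)
    e = np.maximum(
        np.linalg.norm(tri[:, 1] - tri[:, 0], axis=1),
        np.maximum(
            np.linalg.norm(tri[:, 2] - tri[:, 1], axis=1),
            np.linalg.norm(tri[:, 0] - tri[:, 2], axis=1),
        ),
    )
    n_sub = np.clip(np.ceil(e / spacing).astype(int), 1, 12)
    pts_out, val_out = [], []
    vals_tri = values[faces] if values is not None else None
    for n in np.unique(n_sub):
        sel = n_sub == n
        # barycentric grid: cell-centered samples of the n-fold subdivision
        bary = []
        for i in range(n):
            for j in range(n - i):
                k = n - 1 - i - j
                bary.append([(i + 1.0 / 3), (j + 1.0 / 3), (k + 1.0 / 3)])
                if i + j + 1 < n:  # "down" triangle of the subdivision
                    bary.append([(i + 2.0 / 3), (j + 2.0 / 3), (n - i - j - 4.0 / 3)])
        bary = np.array(bary) / n  # (S, 3), rows sum to 1
        pts = np.einsum("sb,fbi->fsi", bary, tri[sel]).reshape(-1, 3)
        pts_out.append(pts)
        if vals_tri is not None:
            val_out.append(np.einsum("sb,fb->fs", bary, vals_tri[sel]).ravel())
    points = np.vstack(pts_out)
    vals = np.concatenate(val_out) if vals_tri is not None else None
    return points, vals


def _bin_to_grid(
    points: np.ndarray,
    values: np.ndarray,
    ref: ReferenceSurface,
    n_azimuth: int,
    n_meridian: int,
    base_exclude_rows: int = 2,
) -> FlatMap:
    r, zc, zb, d = ref.radius, ref.cap_center_z, ref.z_bottom, ref.diameter
    azim, merid, _ = _reference_coordinates(ref, points)
    y_max = (zc - zb) + r * np.pi / 2
    ia = np.clip((azim / TWO_PI * n_azimuth).astype(int), 0, n_azimuth - 1)
    im = np.clip((merid / y_max * n_meridian).astype(int), 0, n_meridian - 1)
    acc = np.zeros((n_meridian, n_azimuth))
    cnt = np.zeros((n_meridian, n_azimuth))
    np.add.at(acc, (im, ia), values)
    np.add.at(cnt, (im, ia), 1.0)
    mask = cnt > 0
    # the flat proximal (amputation) face projects onto the lowest rows and
    # is not part of the standardized surface
    mask[:base_exclude_rows, :] = False
    vals = np.where(mask, acc / np.maximum(cnt, 1.0), 0.0)
    dy = y_max / n_meridian
    dphi = TWO_PI / n_azimuth
    merid_centers = (np.arange(n_meridian) + 0.5) * dy
    width = np.where(merid_centers < (zc - zb), r,
                     r * np.cos(np.clip((merid_centers - (zc - zb)) / r, 0, np.pi / 2)))
    return FlatMap(
        values=vals, mask=mask, cell_area=dy * width * dphi / d**2,
        azimuth_centers=(np.arange(n_azimuth) + 0.5) * dphi,
        meridian_centers=merid_centers, diameter=d, junction_meridian=zc - zb,
    )


def map_to_reference(
    aligned: AlignedSurface | trimesh.Trimesh,
    ref: ReferenceSurface,
    n_azimuth: int = 256,
    n_meridian: int = 128,
    coverage_warn: float = 0.2,
) -> FlatMap:
    """Flatten the surface onto the reference as a binned (meridian, azimuth) map.

    Dense deterministic samples on the surface triangles project along the
    reference normal (radially from the axis on the shaft, radially from
    the cap center on the cap) to signed normalized distances; cells
    average their samples, cells receiving none are masked.
    """
    mesh = aligned.mesh if isinstance(aligned, AlignedSurface) else aligned
    r, zc, zb = ref.radius, ref.cap_center_z, ref.z_bottom
    y_max = (zc - zb) + r * np.pi / 2
    spacing = 0.7 * min(TWO_PI * r / n_azimuth, y_max / n_meridian)
    pts, _ = sample_surface_points(mesh.vertices, mesh.faces, spacing)
    _, _, value = _reference_coordinates(ref, pts)
    flat = _bin_to_grid(pts, value, ref, n_azimuth, n_meridian)
    if 1.0 - flat.mask.mean() > coverage_warn:
        warnings.warn(f"mapping coverage low: {100 * (1 - flat.mask.mean()):.0f}% cells empty")
    return flat


def flatten_node_values(
    points: np.ndarray,
    values: np.ndarray,
    ref: ReferenceSurface,
    n_azimuth: int = 128,
    n_meridian: int = 64,
    faces: np.ndarray | None = None,
) -> FlatMap:
    """Flatten a per-point scalar field (e.g. surface growth) onto the grid.

    If ``faces`` index into ``points``, samples are densified on the
    triangles with interpolated values; otherwise the raw points are
    binned.
    """
    if faces is not None:
        r, zc, zb = ref.radius, ref.cap_center_z, ref.z_bottom
        y_max = (zc - zb) + r * np.pi / 2
        spacing = 0.7 * min(TWO_PI * r / n_azimuth, y_max / n_meridian)
        points, values = sample_surface_points(points, faces, spacing, values=values)
    return _bin_to_grid(points, values, ref, n_azimuth, n_meridian)


# ---------------------------------------------------------------------------
# condyle metrics


def _labelled_regions(flat: FlatMap, selector: np.ndarray) -> tuple[np.ndarray, int]:
    """Connected components with azimuthal wrap-around."""
    lab, n = ndimage.label(selector)
    if n > 1:
        # merge labels touching across the azimuthal seam
        left, right = lab[:, 0], lab[:, -1]
        for i in range(lab.shape[0]):
            a, b = left[i], right[i]
            if a > 0 and b > 0 and a != b:
                lab[lab == b] = a
        labels = np.unique(lab[lab > 0])
        n = len(labels)
    return lab, n


def extract_condyles(flat: FlatMap, threshold: float = 0.2) -> pd.DataFrame:
    """Condyle (and concavity) regions and their normalized metrics.

    Condyles: connected cells with value >= threshold; the two largest are
    labelled dorsal/ventral by their azimuthal arrangement (the companion
    region lies counter-clockwise of the dorsal one, within half a turn).
    Concavities: analogous with value <= -threshold, labelled
    anterior/posterior.  Areas are in units of d^2, volumes are the map
    integral (value x area / d^2), dimensionless.
    """
    rows = []
    for kind, sel in (
        ("condyle", flat.mask & (flat.values >= threshold)),
        ("concavity", flat.mask & (flat.values <= -threshold)),
    ):
        lab, _ = _labelled_regions(flat, sel)
        ids, sizes = np.unique(lab[lab > 0], return_counts=True)
        if len(ids) == 0:
            continue
        area_of = {}
        for rid in ids:
            cells = lab == rid
            area_of[rid] = float((cells * flat.cell_area[:, None]).sum())
        order = sorted(area_of, key=area_of.get, reverse=True)
        if len(order) > 2:
            warnings.warn(f"more than two {kind} regions; keeping the two largest")
        keep = order[:2]
        feats = []
        for rid in keep:
            cells = lab == rid
            aw = cells * flat.cell_area[:, None]
            area = aw.sum()
            volume = float((np.abs(flat.values) * aw).sum())
            # periodic azimuthal centroid
            az = flat.azimuth_centers[None, :]
            wsum = aw.sum()
            cx = np.arctan2((np.sin(az) * aw).sum(), (np.cos(az) * aw).sum()) % TWO_PI
            cy = float((flat.meridian_centers[:, None] * aw).sum() / wsum)
            feats.append({"kind": kind, "area": float(area), "volume": volume,
                          "centroid_azimuth": float(cx), "centroid_meridian": cy})
        names = _assign_pair_names(kind, feats)
        for name, f in zip(names, feats):
            f["structure"] = name
            rows.append(f)
    cols = ["structure", "kind", "area", "volume", "centroid_azimuth", "centroid_meridian"]
    return pd.DataFrame(rows, columns=cols)


def _assign_pair_names(kind: str, feats: list[dict]) -> list[str]:
    first, second = ("dorsal", "ventral") if kind == "condyle" else ("anterior", "posterior")
    if len(feats) == 1:
        return [first]
    d_az = (feats[1]["centroid_azimuth"] - feats[0]["centroid_azimuth"]) % TWO_PI
    if d_az < np.pi:
        return [first, second]
    return [second, first]


def mean_map(maps: list[FlatMap], threshold: float = 0.2) -> FlatMap:
    """Average maps after aligning dorsal condyle centroids in azimuth.

    Each map is rolled periodically in azimuth so its dorsal centroid
    matches the first usable map's; cells are averaged over the maps in
    which they are valid.  Maps without a detectable dorsal condyle are
    excluded with a warning.
    """
    usable = []
    ref_az = None
    for i, m in enumerate(maps):
        met = extract_condyles(m, threshold)
        dorsal = met[met.structure == "dorsal"]
        if len(dorsal) == 0:
            warnings.warn(f"map {i} lacks a dorsal condyle; excluded from the mean")
            continue
        az = float(dorsal.iloc[0].centroid_azimuth)
        if ref_az is None:
            ref_az = az
        n_az = m.shape[1]
        shift = int(round(((ref_az - az) % TWO_PI) / TWO_PI * n_az))
        usable.append(
            (np.roll(np.where(m.mask, m.values, np.nan), shift, axis=1), m)
        )
    if not usable:
        raise ValueError("no maps with a detectable dorsal condyle")
    stack = np.array([v for v, _ in usable])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(stack, axis=0)
    mask = np.isfinite(mean)
    proto = usable[0][1]
    return FlatMap(
        values=np.nan_to_num(mean),
        mask=mask,
        cell_area=proto.cell_area.copy(),
        azimuth_centers=proto.azimuth_centers.copy(),
        meridian_centers=proto.meridian_centers.copy(),
        diameter=proto.diameter,
        junction_meridian=proto.junction_meridian,
    )


# ---------------------------------------------------------------------------
# one-call pipeline


def analyze_limb(
    surface: trimesh.Trimesh,
    handedness: str = "left",
    threshold: float = 0.2,
    shaft_fraction: float = 0.5,
    n_azimuth: int = 256,
    n_meridian: int = 128,
) -> tuple[FlatMap, pd.DataFrame, ReferenceSurface]:
    """Full morphometry for one limb surface: align, map, extract metrics."""
    mirrored, was_mirrored = mirror_right(surface, handedness)
    aligned = principal_axis_align(mirrored)
    aligned.mirrored = was_mirrored
    ref = fit_shaft_cylinder(aligned, shaft_fraction=shaft_fraction)
    ref = build_reference(ref, aligned)
    flat = map_to_reference(aligned, ref, n_azimuth=n_azimuth, n_meridian=n_meridian)
    metrics = extract_condyles(flat, threshold=threshold)
    metrics.insert(0, "shaft_diameter", ref.diameter)
    return flat, metrics, ref
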