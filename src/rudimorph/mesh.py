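"""Hexahedral meshes for rudiment growth simulations.

The mesh container carries reference nodal coordinates, 8-node hexahedral
connectivity (VTK ordering: bottom quad counter-clockwise, then top quad),
named facet sets (boundary quads used for loading, drainage and fixity) and
named node sets.  Grown/deformed configurations are represented by a second
coordinate array on a copy of the same topology.

File formats: legacy ASCII VTK unstructured grids (readable by ParaView) and
a plain-text node/element format documented in :func:`write_text`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

# local corner coordinates of the reference hexahedron, VTK node order
CORNERS = np.array(
    [
        [-1, -1, -1],
        [1, -1, -1],
        [1, 1, -1],
        [-1, 1, -1],
        [-1, -1, 1],
        [1, -1, 1],
        [1, 1, 1],
        [-1, 1, 1],
    ],
    dtype=float,
)

# local node indices of the six faces, outward-oriented
HEX_FACES = np.array(
    [
        [0, 3, 2, 1],  # zeta = -1
        [4, 5, 6, 7],  # zeta = +1
        [0, 1, 5, 4],  # eta = -1
        [1, 2, 6, 5],  # xi = +1
        [2, 3, 7, 6],  # eta = +1
        [3, 0, 4, 7],  # xi = -1
    ]
)

_GP = 1.0 / np.sqrt(3.0)
GAUSS_POINTS = np.array(
    [[sx * _GP, sy * _GP, sz * _GP] for sz in (-1, 1) for sy in (-1, 1) for sx in (-1, 1)]
)


def shape_functions(xi: np.ndarray) -> np.ndarray:
    """Trilinear shape functions at local points ``xi`` (M, 3) -> (M, 8)."""
    xi = np.atleast_2d(xi)
    return 0.125 * np.prod(1.0 + xi[:, None, :] * CORNERS[None, :, :], axis=2)


def shape_gradients(xi: np.ndarray) -> np.ndarray:
    """Local gradients dN/dxi at points ``xi`` (M, 3) -> (M, 8, 3)."""
    xi = np.atleast_2d(xi)
    g = np.empty((xi.shape[0], 8, 3))
    for d in range(3):
        others = [i for i in range(3) if i != d]
        term = 0.125 * CORNERS[None, :, d]
        for o in others:
            term = term * (1.0 + xi[:, None, o] * CORNERS[None, :, o])
        g[:, :, d] = term
    return g


@dataclass
class HexMesh:
    nodes: np.ndarray  # (N, 3) reference coordinates
    elems: np.ndarray  # (E, 8) int connectivity, VTK order
    facet_sets: dict[str, np.ndarray] = field(default_factory=dict)  # name -> (F, 4) node quads
    node_sets: dict[str, np.ndarray] = field(default_factory=dict)
    facet_data: dict[str, dict[str, np.ndarray]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.nodes = np.asarray(self.nodes, dtype=float)
        self.elems = np.asarray(self.elems, dtype=np.int64)
        if self.nodes.ndim != 2 or self.nodes.shape[1] != 3:
            raise ValueError("nodes must be (N, 3)")
        if self.elems.ndim != 2 or self.elems.shape[1] != 8:
            raise ValueError("elems must be (E, 8)")

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    @property
    def n_elems(self) -> int:
        return self.elems.shape[0]

    def copy(self, nodes: np.ndarray | None = None) -> "HexMesh":
        return HexMesh(
            nodes=self.nodes.copy() if nodes is None else np.asarray(nodes, dtype=float).copy(),
            elems=self.elems.copy(),
            facet_sets={k: v.copy() for k, v in self.facet_sets.items()},
            node_sets={k: v.copy() for k, v in self.node_sets.items()},
            facet_data={k: {kk: vv.copy() for kk, vv in d.items()} for k, d in self.facet_data.items()},
        )

    # -- geometry ---------------------------------------------------------

    def corner_jacobians(self) -> np.ndarray:
        """det(J) at the 8 corners of every element, shape (E, 8)."""
        grads = shape_gradients(CORNERS)  # (8, 8, 3)
        xe = self.nodes[self.elems]  # (E, 8, 3)
        J = np.einsum("eni,cnj->ecij", xe, grads)
        return np.linalg.det(J)

    def min_jacobian(self) -> float:
        return float(self.corner_jacobians().min())

    def element_volumes(self) -> np.ndarray:
        grads = shape_gradients(GAUSS_POINTS)  # (8, 8, 3)
        xe = self.nodes[self.elems]
        J = np.einsum("eni,cnj->ecij", xe, grads)
        return np.abs(np.linalg.det(J)).sum(axis=1)

    def volume(self) -> float:
        return float(self.element_volumes().sum())

    def element_centroids(self) -> np.ndarray:
        return self.nodes[self.elems].mean(axis=1)

    def boundary_quads(self) -> np.ndarray:
        """All exterior quads (outward-oriented), shape (F, 4)."""
        quads = self.elems[:, HEX_FACES].reshape(-1, 4)
        key = np.sort(quads, axis=1)
        _, inv, counts = np.unique(key, axis=0, return_inverse=True, return_counts=True)
        return quads[counts[inv] == 1]

    def facet_quads_elements(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(quads, element index, local face index) for all exterior facets."""
        quads = self.elems[:, HEX_FACES].reshape(-1, 4)
        key = np.sort(quads, axis=1)
        _, inv, counts = np.unique(key, axis=0, return_inverse=True, return_counts=True)
        mask = counts[inv] == 1
        idx = np.nonzero(mask)[0]
        return quads[mask], idx // 6, idx % 6

    def surface_triangles(self) -> tuple[np.ndarray, np.ndarray]:
        """Boundary as a triangle soup: (vertices = all mesh nodes, faces)."""
        quads = self.boundary_quads()
        tris = np.concatenate([quads[:, [0, 1, 2]], quads[:, [0, 2, 3]]])
        return self.nodes, tris

    # -- I/O --------------------------------------------------------------

    def write_vtk(
        self,
        path,
        point_data: dict[str, np.ndarray] | None = None,
        cell_data: dict[str, np.ndarray] | None = None,
    ) -> None:
        """Write a legacy ASCII VTK unstructured grid with optional fields."""
        with open(path, "w") as f:
            f.write("# vtk DataFile Version 3.0\nrudimorph mesh\nASCII\n")
            f.write("DATASET UNSTRUCTURED_GRID\n")
            f.write(f"POINTS {self.n_nodes} double\n")
            np.savetxt(f, self.nodes, fmt="%.10g")
            f.write(f"CELLS {self.n_elems} {self.n_elems * 9}\n")
            cells = np.column_stack([np.full(self.n_elems, 8), self.elems])
            np.savetxt(f, cells, fmt="%d")
            f.write(f"CELL_TYPES {self.n_elems}\n")
            np.savetxt(f, np.full(self.n_elems, 12), fmt="%d")
            if point_data:
                f.write(f"POINT_DATA {self.n_nodes}\n")
                for name, arr in point_data.items():
                    _write_vtk_field(f, name, np.asarray(arr))
            if cell_data:
                f.write(f"CELL_DATA {self.n_elems}\n")
                for name, arr in cell_data.items():
                    _write_vtk_field(f, name, np.asarray(arr))

    def write_text(self, path) -> None:
        """Plain-text format: node count + xyz rows, element count + 8 ids,
        then one ``facetset <name> <count>`` block of quads per facet set."""
        with open(path, "w") as f:
            f.write(f"nodes {self.n_nodes}\n")
            np.savetxt(f, self.nodes, fmt="%.10g")
            f.write(f"elements {self.n_elems}\n")
            np.savetxt(f, self.elems, fmt="%d")
            for name, quads in self.facet_sets.items():
                f.write(f"facetset {name} {len(quads)}\n")
                np.savetxt(f, quads, fmt="%d")

    @classmethod
    def read_text(cls, path) -> "HexMesh":
        with open(path) as f:
            tokens = f.read().split("\n")
        i = 0

        def block(n, dtype):
            nonlocal i
            rows = [tokens[i + k].split() for k in range(n)]
            i += n
            return np.array(rows, dtype=dtype)

        assert tokens[i].startswith("nodes")
        n = int(tokens[i].split()[1])
        i += 1
        nodes = block(n, float)
        assert tokens[i].startswith("elements")
        e = int(tokens[i].split()[1])
        i += 1
        elems = block(e, np.int64)
        facet_sets = {}
        while i < len(tokens) and tokens[i].startswith("facetset"):
            _, name, cnt = tokens[i].split()
            i += 1
            facet_sets[name] = block(int(cnt), np.int64)
        return cls(nodes, elems, facet_sets=facet_sets)


def _write_vtk_field(f, name: str, arr: np.ndarray) -> None:
    if arr.ndim == 1:
        f.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
        np.savetxt(f, arr, fmt="%.10g")
    else:
        f.write(f"VECTORS {name} double\n")
        np.savetxt(f, arr, fmt="%.10g")


def quad_area_normals(nodes: np.ndarray, quads: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-quad (area, unit outward normal) via the cross-diagonal formula."""
    p = nodes[quads]
    n = 0.5 * np.cross(p[:, 2] - p[:, 0], p[:, 3] - p[:, 1])
    area = np.linalg.norm(n, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        unit = np.where(area[:, None] > 0, n / area[:, None], 0.0)
    return area, unit
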