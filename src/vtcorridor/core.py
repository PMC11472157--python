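"""Core geometry containers shared by every pipeline stage.

All coordinates are millimetres in a single right-handed world frame shared
by the SI volume (through its affine) and the surface meshes.  Areas are
reported in cm**2, the unit used for scar and corridor quantification.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import trimesh
from scipy.sparse import coo_matrix, csr_matrix
from scipy.sparse.csgraph import connected_components, dijkstra

MM2_PER_CM2 = 100.0


class ValidationError(ValueError):
    """Raised when an input violates a structural invariant."""


@dataclass
class TriSurface:
    """Triangulated surface with optional per-vertex scalars and region flags.

    Parameters
    ----------
    vertices : (n, 3) float array, positions in mm.
    faces : (m, 3) int array of vertex indices, consistently wound so that
        face normals point outward.
    scalar_channels : named per-vertex scalar arrays (length n).
    region_flags : named per-vertex boolean tags (e.g. ``valve``).
    """

    vertices: np.ndarray
    faces: np.ndarray
    scalar_channels: dict = field(default_factory=dict)
    region_flags: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=np.float64).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        self._cache: dict = {}

    # ------------------------------------------------------------------ basic
    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def validate(self, require_connected: bool = False) -> None:
        if self.n_faces == 0 or self.n_vertices < 3:
            raise ValidationError("surface has no triangles")
        if self.faces.min() < 0 or self.faces.max() >= self.n_vertices:
            raise ValidationError("face indices out of range")
        areas = self.face_areas()
        if np.any(areas <= 0):
            idx = int(np.flatnonzero(areas <= 0)[0])
            raise ValidationError(f"zero-area face at index {idx}")
        for name, arr in self.scalar_channels.items():
            if len(arr) != self.n_vertices:
                raise ValidationError(f"scalar channel {name!r} has wrong length")
        if require_connected:
            n_comp, _ = connected_components(self.vertex_adjacency(), directed=False)
            if n_comp != 1:
                raise ValidationError(f"surface has {n_comp} connected components")

    # --------------------------------------------------------------- geometry
    def face_areas(self) -> np.ndarray:
        if "face_areas" not in self._cache:
            v = self.vertices
            f = self.faces
            cross = np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]])
            self._cache["face_areas"] = 0.5 * np.linalg.norm(cross, axis=1)
        return self._cache["face_areas"]

    def vertex_areas(self) -> np.ndarray:
        """Barycentric vertex areas in mm^2 (one third of incident triangles)."""
        if "vertex_areas" not in self._cache:
            fa = self.face_areas() / 3.0
            va = np.zeros(self.n_vertices)
            for k in range(3):
                np.add.at(va, self.faces[:, k], fa)
            self._cache["vertex_areas"] = va
        return self._cache["vertex_areas"]

    def vertex_normals(self) -> np.ndarray:
        """Area-weighted outward vertex normals (unit length)."""
        if "vertex_normals" not in self._cache:
            v, f = self.vertices, self.faces
            fn = np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]])
            vn = np.zeros_like(v)
            for k in range(3):
                np.add.at(vn, f[:, k], fn)
            norm = np.linalg.norm(vn, axis=1)
            norm[norm == 0] = 1.0
            self._cache["vertex_normals"] = vn / norm[:, None]
        return self._cache["vertex_normals"]

    def edges(self) -> np.ndarray:
        """Unique undirected edges as a (k, 2) index array."""
        if "edges" not in self._cache:
            e = np.vstack(
                [self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]]
            )
            e = np.sort(e, axis=1)
            self._cache["edges"] = np.unique(e, axis=0)
        return self._cache["edges"]

    def vertex_adjacency(self) -> csr_matrix:
        """Symmetric boolean vertex adjacency (CSR)."""
        if "adjacency" not in self._cache:
            e = self.edges()
            n = self.n_vertices
            data = np.ones(len(e), dtype=bool)
            m = coo_matrix((data, (e[:, 0], e[:, 1])), shape=(n, n))
            self._cache["adjacency"] = (m + m.T).tocsr()
        return self._cache["adjacency"]

    def edge_length_graph(self) -> csr_matrix:
        """Vertex graph weighted by Euclidean edge length (mm)."""
        if "edge_graph" not in self._cache:
            e = self.edges()
            w = np.linalg.norm(self.vertices[e[:, 0]] - self.vertices[e[:, 1]], axis=1)
            n = self.n_vertices
            m = coo_matrix((w, (e[:, 0], e[:, 1])), shape=(n, n))
            self._cache["edge_graph"] = (m + m.T).tocsr()
        return self._cache["edge_graph"]

    def as_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(
            vertices=self.vertices.copy(), faces=self.faces.copy(), process=False
        )

    def area_cm2(self, vertex_ids: Iterable[int] | np.ndarray | None = None) -> float:
        """Barycentric area of a vertex subset (whole surface when None)."""
        va = self.vertex_areas()
        if vertex_ids is None:
            return float(va.sum() / MM2_PER_CM2)
        idx = np.asarray(list(vertex_ids) if not isinstance(vertex_ids, np.ndarray) else vertex_ids, dtype=np.int64)
        if idx.size == 0:
            return 0.0
        return float(va[idx].sum() / MM2_PER_CM2)


@dataclass
class SIVolume:
    """3D signal-intensity volume with a world affine (mm).

    ``affine`` maps voxel indices (i, j, k, 1) to world mm, nibabel-style.
    """

    array: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.array = np.asarray(self.array, dtype=np.float64)
        self.affine = np.asarray(self.affine, dtype=np.float64).reshape(4, 4)

    def validate(self) -> None:
        if self.array.ndim != 3:
            raise ValidationError("volume must be 3D")
        if not np.all(np.isfinite(self.array)):
            raise ValidationError("volume contains non-finite values")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValidationError("affine is singular")
        if np.any(self.spacing <= 0):
            raise ValidationError("non-positive voxel spacing")

    @property
    def spacing(self) -> np.ndarray:
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    def world_to_voxel(self, points: np.ndarray) -> np.ndarray:
        """Continuous voxel coordinates of world-space points."""
        inv = np.linalg.inv(self.affine)
        pts = np.asarray(points, dtype=np.float64)
        return pts @ inv[:3, :3].T + inv[:3, 3]

    def voxel_to_world(self, ijk: np.ndarray) -> np.ndarray:
        ijk = np.asarray(ijk, dtype=np.float64)
        return ijk @ self.affine[:3, :3].T + self.affine[:3, 3]


@dataclass
class RigidTransform:
    """Rigid (optionally similarity) transform: x -> scale * R x + t."""

    rotation: np.ndarray
    translation: np.ndarray
    scale: float = 1.0

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=np.float64).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=np.float64).reshape(3)

    def validate(self, tol: float = 1e-8) -> None:
        err = np.abs(self.rotation @ self.rotation.T - np.eye(3)).max()
        if err > tol:
            raise ValidationError(f"rotation not orthonormal (max error {err:.2e})")
        if np.linalg.det(self.rotation) < 0:
            raise ValidationError("rotation is a reflection")

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=np.float64)
        return self.scale * pts @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        r_inv = self.rotation.T
        s_inv = 1.0 / self.scale
        return RigidTransform(r_inv, -s_inv * r_inv @ self.translation, s_inv)

    @staticmethod
    def identity() -> "RigidTransform":
        return RigidTransform(np.eye(3), np.zeros(3), 1.0)


# ----------------------------------------------------------------- geodesics
def geodesic_distances(
    surface: TriSurface, seed_vertices: np.ndarray, limit: float = np.inf
) -> np.ndarray:
    """Graph-geodesic distance (mm) from the nearest seed vertex.

    Dijkstra on the edge-length graph; vertices beyond ``limit`` get inf.
    """
    seeds = np.atleast_1d(np.asarray(seed_vertices, dtype=np.int64))
    if seeds.size == 0:
        return np.full(surface.n_vertices, np.inf)
    return dijkstra(
        surface.edge_length_graph(),
        directed=False,
        indices=seeds,
        min_only=True,
        limit=limit,
    )


def geodesic_path(surface: TriSurface, source: int, target: int) -> np.ndarray:
    """Vertex ids along the shortest edge path from source to target."""
    _, pred = dijkstra(
        surface.edge_length_graph(),
        directed=False,
        indices=int(source),
        return_predecessors=True,
    )
    path = [int(target)]
    while path[-1] != int(source):
        p = pred[path[-1]]
        if p < 0:
            raise ValidationError("no path between vertices (disconnected surface)")
        path.append(int(p))
    return np.asarray(path[::-1], dtype=np.int64)


def connected_vertex_components(adjacency: csr_matrix, mask: np.ndarray) -> list:
    """Connected components of the subgraph induced on ``mask`` vertices.

    Returns a list of int arrays of vertex ids, deterministically ordered by
    their smallest member.
    """
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return []
    sub = adjacency[idx][:, idx]
    n_comp, labels = connected_components(sub, directed=False)
    comps = [idx[labels == c] for c in range(n_comp)]
    comps.sort(key=lambda a: int(a.min()))
    return comps
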