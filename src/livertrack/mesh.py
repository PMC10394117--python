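"""Triangulated surface meshes with fixed node correspondence.

All coordinates are patient coordinates in mm with axes (LR, AP, SI) and the
origin at the machine iso-center.  Liver meshes are deformed, never re-meshed,
so one node index always refers to the same anatomical point across breathing
phases.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh as _tm

__all__ = ["TriMesh", "icosphere", "MeshError"]


class MeshError(ValueError):
    """Raised for degenerate or topologically invalid meshes."""


@dataclass
class TriMesh:
    """A triangulated surface: node coordinates plus triangle connectivity.

    Parameters
    ----------
    nodes : (N, 3) float array, mm, axes (LR, AP, SI).
    faces : (F, 3) int array of node index triples.
    """

    nodes: np.ndarray
    faces: np.ndarray
    _cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self):
        self.nodes = np.asarray(self.nodes, dtype=np.float64)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.nodes.ndim != 2 or self.nodes.shape[1] != 3:
            raise MeshError(f"nodes must be (N, 3), got {self.nodes.shape}")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise MeshError(f"faces must be (F, 3), got {self.faces.shape}")

    # -- basic properties -------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    @property
    def n_faces(self) -> int:
        return self.faces.shape[0]

    def to_trimesh(self) -> _tm.Trimesh:
        return _tm.Trimesh(vertices=self.nodes, faces=self.faces, process=False)

    @classmethod
    def from_trimesh(cls, mesh: _tm.Trimesh) -> "TriMesh":
        return cls(np.asarray(mesh.vertices, float), np.asarray(mesh.faces, np.int64))

    # -- derived geometry -------------------------------------------------
    def face_areas(self) -> np.ndarray:
        v = self.nodes[self.faces]
        return 0.5 * np.linalg.norm(
            np.cross(v[:, 1] - v[:, 0], v[:, 2] - v[:, 0]), axis=1
        )

    def area(self) -> float:
        return float(self.face_areas().sum())

    def edge_lengths(self) -> np.ndarray:
        v = self.nodes[self.faces]
        e = np.concatenate(
            [v[:, 1] - v[:, 0], v[:, 2] - v[:, 1], v[:, 0] - v[:, 2]], axis=0
        )
        return np.linalg.norm(e, axis=1)

    def circumradii(self) -> np.ndarray:
        """Per-face circumradius R = abc / 4A (inf for degenerate faces)."""
        v = self.nodes[self.faces]
        a = np.linalg.norm(v[:, 1] - v[:, 0], axis=1)
        b = np.linalg.norm(v[:, 2] - v[:, 1], axis=1)
        c = np.linalg.norm(v[:, 0] - v[:, 2], axis=1)
        area = self.face_areas()
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(area > 0, a * b * c / (4.0 * area), np.inf)

    # -- adjacency --------------------------------------------------------
    @property
    def adjacency(self) -> list:
        """Per-node sorted neighbor index arrays N(p) from shared edges."""
        if "adjacency" not in self._cache:
            nbr = [set() for _ in range(self.n_nodes)]
            for f in self.faces:
                a, b, c = int(f[0]), int(f[1]), int(f[2])
                nbr[a].update((b, c))
                nbr[b].update((a, c))
                nbr[c].update((a, b))
            self._cache["adjacency"] = [
                np.array(sorted(s), dtype=np.int64) for s in nbr
            ]
        return self._cache["adjacency"]

    def neighbor_mean_matrix(self) -> np.ndarray:
        """Dense (N, N) matrix M with M @ x = per-node mean over neighbors.

        Row p holds 1/|N(p)| on the columns of p's neighbors.  Used by the
        Laplacian-coordinate and deformation-energy losses.
        """
        if "nbr_mean" not in self._cache:
            M = np.zeros((self.n_nodes, self.n_nodes))
            for p, nb in enumerate(self.adjacency):
                if len(nb):
                    M[p, nb] = 1.0 / len(nb)
            self._cache["nbr_mean"] = M
        return self._cache["nbr_mean"]

    def is_watertight(self) -> bool:
        return bool(self.to_trimesh().is_watertight)

    def validate(self) -> None:
        """Check TriMesh invariants: positive face areas, symmetric adjacency."""
        if np.any(self.face_areas() <= 0):
            raise MeshError("mesh contains degenerate (zero-area) triangles")
        adj = self.adjacency
        for p, nb in enumerate(adj):
            for q in nb:
                if p not in adj[q]:
                    raise MeshError("adjacency is not symmetric")

    # -- transforms -------------------------------------------------------
    def with_nodes(self, nodes: np.ndarray) -> "TriMesh":
        """Same topology with new node coordinates (shares the face array)."""
        nodes = np.asarray(nodes, float)
        if nodes.shape != self.nodes.shape:
            raise MeshError("node array shape must be preserved")
        out = TriMesh(nodes, self.faces)
        # adjacency depends only on topology, safe to share
        out._cache = self._cache
        return out

    def translated(self, t) -> "TriMesh":
        return self.with_nodes(self.nodes + np.asarray(t, float))

    def subdivision_operator(self, max_edge_mm: float):
        """Linear operator refining this topology to edges <= ``max_edge_mm``.

        Returns ``(S, faces)`` where ``S`` is a (Nf, N) sparse matrix such that
        ``S @ nodes`` are the refined node positions for *any* deformation of
        this mesh (midpoint subdivision is linear in the coarse nodes).  Used
        so surface-distance metrics can be computed on a refined surface while
        predictions stay on the coarse correspondence mesh.
        """
        import scipy.sparse as sp

        key = ("subdiv", float(max_edge_mm))
        if key not in self._cache:
            S = sp.identity(self.n_nodes, format="csr")
            faces = self.faces.copy()
            nodes = self.nodes.copy()
            while True:
                tm = _tm.Trimesh(vertices=nodes, faces=faces, process=False)
                if tm.edges_unique_length.max() <= max_edge_mm:
                    break
                edges = tm.edges_unique  # (E, 2)
                n = nodes.shape[0]
                # midpoint matrix: new nodes = old nodes + edge midpoints
                E = edges.shape[0]
                rows = np.repeat(np.arange(E), 2)
                cols = edges.ravel()
                mid = sp.csr_matrix(
                    (np.full(2 * E, 0.5), (rows, cols)), shape=(E, n)
                )
                step = sp.vstack([sp.identity(n, format="csr"), mid]).tocsr()
                # faces: split every triangle into 4 using edge midpoint ids
                edge_id = {tuple(sorted(e)): n + i for i, e in enumerate(map(tuple, edges))}
                new_faces = []
                for a, b, c in faces:
                    ab = edge_id[tuple(sorted((a, b)))]
                    bc = edge_id[tuple(sorted((b, c)))]
                    ca = edge_id[tuple(sorted((c, a)))]
                    new_faces += [[a, ab, ca], [ab, b, bc], [ca, bc, c], [ab, bc, ca]]
                faces = np.array(new_faces, dtype=np.int64)
                nodes = step @ nodes
                S = step @ S
            self._cache[key] = (S, faces)
        return self._cache[key]


def icosphere(subdivisions: int, radius: float = 1.0, center=(0.0, 0.0, 0.0),
              scale=(1.0, 1.0, 1.0)) -> TriMesh:
    """Subdivided icosahedron with 10 * 4**s + 2 nodes, optionally anisotropic.

    ``scale`` multiplies the three semi-axes so organs can be mildly
    ellipsoidal while keeping a fixed node budget.
    """
    tm = _tm.creation.icosphere(subdivisions=subdivisions, radius=radius)
    nodes = np.asarray(tm.vertices) * np.asarray(scale, float) + np.asarray(center, float)
    return TriMesh(nodes, np.asarray(tm.faces, np.int64))
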