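"""Unstructured linear-tetrahedra meshes with tagged boundary faces.

All coordinates are in cm.  Tetrahedra follow the positive-signed-volume
convention ``6V = det(x1-x0, x2-x0, x3-x0) > 0``; boundary faces are stored
with outward orientation (right-hand normal points out of the fluid domain).
Node and element indexing is 0-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

#: Canonical boundary tags for the cavopulmonary junction test section.
KNOWN_TAGS = (
    "inlet_svc",
    "inlet_ivc",
    "outlet_rpa",
    "outlet_lpa",
    "wall_housing",
    "wall_rotor",
    "wall_strut",
    "inlet",
    "outlet",
    "wall",
)

# local face numbering: face i is opposite node i, ordered so that the
# right-hand normal points away from node i for a positive tet
_TET_FACES = np.array([[1, 2, 3], [0, 3, 2], [0, 1, 3], [0, 2, 1]])


class MeshError(ValueError):
    """Raised for topologically or geometrically invalid meshes."""


@dataclass
class Mesh:
    """Tetrahedral volume mesh with a tagged, watertight boundary surface."""

    nodes: np.ndarray          # (n_nodes, 3) float64, cm
    tets: np.ndarray           # (n_tets, 4) int, positive orientation
    boundary_faces: np.ndarray  # (n_faces, 3) int, outward orientation
    face_tags: np.ndarray      # (n_faces,) unicode labels
    provenance: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.nodes = np.ascontiguousarray(self.nodes, dtype=np.float64)
        self.tets = np.ascontiguousarray(self.tets, dtype=np.int64)
        self.boundary_faces = np.ascontiguousarray(self.boundary_faces, dtype=np.int64)
        self.face_tags = np.asarray(self.face_tags)
        if self.nodes.ndim != 2 or self.nodes.shape[1] != 3:
            raise MeshError("nodes must be (n, 3)")
        if self.tets.ndim != 2 or self.tets.shape[1] != 4:
            raise MeshError("tets must be (m, 4)")
        if len(self.face_tags) != len(self.boundary_faces):
            raise MeshError("face_tags and boundary_faces length mismatch")

    # -- basic metrics -------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_tets(self) -> int:
        return len(self.tets)

    def tet_volumes(self) -> np.ndarray:
        x = self.nodes[self.tets]
        d = x[:, 1:] - x[:, :1]
        return np.einsum("ij,ij->i", d[:, 0], np.cross(d[:, 1], d[:, 2])) / 6.0

    def total_volume(self) -> float:
        return float(self.tet_volumes().sum())

    def edge_lengths(self) -> np.ndarray:
        """(n_tets, 6) lengths of the six tet edges."""
        x = self.nodes[self.tets]
        pairs = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
        return np.stack(
            [np.linalg.norm(x[:, a] - x[:, b], axis=1) for a, b in pairs], axis=1
        )

    def face_areas_normals(self) -> tuple[np.ndarray, np.ndarray]:
        """Areas (cm^2) and outward unit normals of the boundary faces."""
        x = self.nodes[self.boundary_faces]
        cr = np.cross(x[:, 1] - x[:, 0], x[:, 2] - x[:, 0])
        a2 = np.linalg.norm(cr, axis=1)
        return a2 / 2.0, cr / np.where(a2 > 0, a2, 1.0)[:, None]

    def face_centroids(self) -> np.ndarray:
        return self.nodes[self.boundary_faces].mean(axis=1)

    # -- tags ----------------------------------------------------------

    @property
    def tags(self) -> list[str]:
        return sorted(set(self.face_tags.tolist()))

    def faces_of(self, tag: str | Iterable[str]) -> np.ndarray:
        """Indices into boundary_faces carrying ``tag`` (or any of several)."""
        tags = {tag} if isinstance(tag, str) else set(tag)
        return np.flatnonzero(np.isin(self.face_tags, sorted(tags)))

    def nodes_of(self, tag: str | Iterable[str]) -> np.ndarray:
        f = self.faces_of(tag)
        return np.unique(self.boundary_faces[f])

    def retag(self, tag_map: dict[str, str]) -> "Mesh":
        """Normalize foreign tag names via an explicit map (copy)."""
        missing = set(self.face_tags.tolist()) - set(tag_map)
        if missing:
            raise MeshError(f"tag map does not cover tags: {sorted(missing)}")
        new = np.array([tag_map[t] for t in self.face_tags])
        return Mesh(self.nodes.copy(), self.tets.copy(),
                    self.boundary_faces.copy(), new, dict(self.provenance))

    # -- topology audits ------------------------------------------------

    def extract_boundary(self) -> tuple[np.ndarray, np.ndarray]:
        """Recompute (faces, parent_tets) of faces used by exactly one tet.

        Faces are returned with outward orientation.
        """
        faces = self.tets[:, _TET_FACES]                    # (m, 4, 3)
        flat = faces.reshape(-1, 3)
        key = np.sort(flat, axis=1)
        _, inv, counts = np.unique(
            key, axis=0, return_inverse=True, return_counts=True
        )
        once = counts[inv] == 1
        return flat[once], np.repeat(np.arange(self.n_tets), 4)[once]

    def boundary_parent_tets(self) -> np.ndarray:
        """Parent tet index for each stored boundary face (order preserved)."""
        bfaces, parents = self.extract_boundary()
        lut = {tuple(sorted(f)): p for f, p in zip(bfaces.tolist(), parents.tolist())}
        try:
            return np.array(
                [lut[tuple(sorted(f))] for f in self.boundary_faces.tolist()],
                dtype=np.int64,
            )
        except KeyError as exc:  # pragma: no cover - defensive
            raise MeshError(f"stored boundary face {exc} is not on the boundary")

    def unmatched_boundary_edges(self) -> int:
        """Number of boundary edges not shared by exactly two boundary faces."""
        if len(self.boundary_faces) == 0:
            return 0
        e = self.boundary_faces[:, [[0, 1], [1, 2], [2, 0]]].reshape(-1, 2)
        e = np.sort(e, axis=1)
        _, counts = np.unique(e, axis=0, return_counts=True)
        return int(np.sum(counts != 2))

    def validate(self, require_tags: bool = True) -> None:
        """Raise MeshError on inverted tets, open boundaries or missing tags."""
        if self.n_tets == 0:
            raise MeshError("empty mesh")
        vols = self.tet_volumes()
        if (vols <= 0).any():
            raise MeshError(f"{int((vols <= 0).sum())} non-positive tet volumes")
        bfaces, _ = self.extract_boundary()
        if len(bfaces) != len(self.boundary_faces):
            raise MeshError(
                f"stored boundary has {len(self.boundary_faces)} faces, "
                f"topology implies {len(bfaces)}"
            )
        if self.unmatched_boundary_edges():
            raise MeshError("boundary surface is not watertight")
        if require_tags:
            bad = [t for t in self.tags if not str(t)]
            if bad or len(self.face_tags) != len(self.boundary_faces):
                raise MeshError("boundary faces missing tags")

    # -- quality ---------------------------------------------------------


def _dihedral_angles(nodes: np.ndarray, tets: np.ndarray) -> np.ndarray:
    """(n_tets, 6) interior dihedral angles in degrees."""
    x = nodes[tets]
    # inward normals of the four faces
    n = np.empty((len(tets), 4, 3))
    for i in range(4):
        f = _TET_FACES[i]
        cr = np.cross(x[:, f[1]] - x[:, f[0]], x[:, f[2]] - x[:, f[0]])
        n[:, i] = -cr / np.linalg.norm(cr, axis=1, keepdims=True)
    # edge (i,j) is shared by the two faces opposite the *other* two nodes
    pairs = [(2, 3), (1, 3), (1, 2), (0, 3), (0, 2), (0, 1)]
    ang = np.empty((len(tets), 6))
    for k, (a, b) in enumerate(pairs):
        c = np.clip(np.einsum("ij,ij->i", n[:, a], n[:, b]), -1.0, 1.0)
        ang[:, k] = np.degrees(np.pi - np.arccos(c))
    return ang


def mesh_quality(mesh: Mesh) -> dict:
    """Element-quality summary of a tetrahedral mesh.

    Conventions (stated here because several exist in the literature):

    * ``aspect_ratio`` = longest edge / (2*sqrt(6) * inradius); equals 1 for
      the regular tetrahedron and grows without bound for slivers.
    * ``min_dihedral_deg`` = smallest interior dihedral angle over all
      elements (regular tet: arccos(1/3) ~ 70.53 deg).
    * ``shape`` = mean-ratio metric 12*(3V)^(2/3) / sum(edge^2), in (0, 1],
      equal to 1 for the regular tetrahedron.
    """
    if mesh.n_tets == 0:
        raise MeshError("empty mesh")
    vols = mesh.tet_volumes()
    el = mesh.edge_lengths()
    # inradius r = 3V / (sum of face areas)
    x = mesh.nodes[mesh.tets]
    fa = np.zeros(mesh.n_tets)
    for i in range(4):
        f = _TET_FACES[i]
        cr = np.cross(x[:, f[1]] - x[:, f[0]], x[:, f[2]] - x[:, f[0]])
        fa += np.linalg.norm(cr, axis=1) / 2.0
    inradius = 3.0 * vols / fa
    aspect = el.max(axis=1) / (2.0 * np.sqrt(6.0) * inradius)
    shape = 12.0 * np.cbrt((3.0 * vols) ** 2) / (el**2).sum(axis=1)
    dihedrals = _dihedral_angles(mesh.nodes, mesh.tets)
    return {
        "n_nodes": mesh.n_nodes,
        "n_tets": mesh.n_tets,
        "mean_aspect_ratio": float(aspect.mean()),
        "max_aspect_ratio": float(aspect.max()),
        "min_dihedral_deg": float(dihedrals.min()),
        "mean_shape": float(shape.mean()),
        "min_shape": float(shape.min()),
    }


def orient_tets(nodes: np.ndarray, tets: np.ndarray) -> np.ndarray:
    """Return tets with vertex order fixed so all signed volumes are positive."""
    tets = np.asarray(tets).copy()
    x = nodes[tets]
    d = x[:, 1:] - x[:, :1]
    vol6 = np.einsum("ij,ij->i", d[:, 0], np.cross(d[:, 1], d[:, 2]))
    flip = vol6 < 0
    tets[flip] = tets[flip][:, [0, 2, 1, 3]]
    return tets
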