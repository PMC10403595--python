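"""Shared P1-tetrahedron finite-element machinery.

Everything here is geometry-only and real-valued; the solvers evaluate
their element kernels on top of these arrays, possibly in complex
arithmetic (complex-step differentiation of the kernels yields Jacobians
that are exactly consistent with the residuals).
"""

from __future__ import annotations

import numpy as np

from .mesh import Mesh

# 4-point Gauss rule on the tetrahedron, exact for quadratic integrands
_QA = 0.5854101966249685
_QB = 0.13819660112501052
QUAD_POINTS = np.array([
    [_QA, _QB, _QB, _QB],
    [_QB, _QA, _QB, _QB],
    [_QB, _QB, _QA, _QB],
    [_QB, _QB, _QB, _QA],
])          # (4 qp, 4 barycentric shape values)
QUAD_WEIGHTS = np.full(4, 0.25)


class ElementData:
    """Precomputed per-element geometry for a tetrahedral mesh.

    Attributes
    ----------
    vols : (nel,) element volumes (cm^3)
    grads : (nel, 4, 3) constant shape-function gradients (1/cm)
    metric : (nel, 3, 3) covariant element metric ``xi = A^T A`` with
        ``A = d(parent)/d(x)`` from the iso-parametric map; enters the
        stabilization parameters as ``v^T xi v`` and ``xi : xi``.
    """

    def __init__(self, mesh: Mesh):
        self.mesh = mesh
        x = mesh.nodes[mesh.tets]                     # (nel, 4, 3)
        J = np.transpose(x[:, 1:] - x[:, :1], (0, 2, 1))   # dx/dxi (nel,3,3)
        detJ = np.linalg.det(J)
        self.vols = detJ / 6.0
        A = np.linalg.inv(J)                          # dxi/dx
        self.metric = np.einsum("eki,ekj->eij", A, A)
        # gradients: N0 = 1-xi1-xi2-xi3, Ni = xi_i; dN_i/dx is row i of A
        g = np.empty((len(mesh.tets), 4, 3))
        g[:, 1:] = A
        g[:, 0] = -A.sum(axis=1)
        self.grads = g
        self.metric_dd = np.einsum("eij,eij->e", self.metric, self.metric)

    @property
    def n_nodes(self) -> int:
        return self.mesh.n_nodes

    @property
    def n_elems(self) -> int:
        return len(self.mesh.tets)


def gather(nodal: np.ndarray, tets: np.ndarray) -> np.ndarray:
    """Nodal field (n, ...) -> element-local (nel, 4, ...)."""
    return nodal[tets]


def scatter_add(global_vec: np.ndarray, tets: np.ndarray,
                local: np.ndarray) -> None:
    """Accumulate element-local (nel, 4, ...) into nodal (n, ...)."""
    np.add.at(global_vec, tets, local)


def face_geometry(mesh: Mesh, face_idx: np.ndarray):
    """Areas and outward unit normals for a subset of boundary faces."""
    areas, normals = mesh.face_areas_normals()
    return areas[face_idx], normals[face_idx]


def boundary_flux_vector(mesh: Mesh, face_idx: np.ndarray) -> np.ndarray:
    """Assemble b with b[a, i] = int_Gamma N_a n_i dGamma over given faces.

    The discrete flux through the faces is ``sum_ai b[a,i] v[a,i]`` and the
    same vector weights a uniform traction: both sides of the resistance
    boundary condition use it.
    """
    b = np.zeros((mesh.n_nodes, 3))
    areas, normals = face_geometry(mesh, face_idx)
    faces = mesh.boundary_faces[face_idx]
    contrib = (areas[:, None] / 3.0) * normals      # (nf, 3)
    for corner in range(3):
        np.add.at(b, faces[:, corner], contrib)
    return b


def interpolate_nodal(mesh: Mesh, nodal: np.ndarray,
                      points: np.ndarray) -> np.ndarray:
    """Linear FE interpolation of a nodal field at arbitrary points.

    Vectorized containing-element search: candidate tets come from a
    KD-tree on element centroids and barycentric coordinates are evaluated
    for all candidates at once.  Points outside the mesh return NaN.
    """
    from scipy.spatial import cKDTree

    points = np.atleast_2d(points)
    x = mesh.nodes[mesh.tets]
    v0 = x[:, 0]
    T = np.transpose(x[:, 1:] - x[:, :1], (0, 2, 1))     # (nel, 3, 3)
    Tinv = np.linalg.inv(T)
    cents = x.mean(axis=1)
    tree = cKDTree(cents)
    k = min(64, mesh.n_tets)
    _, cand = tree.query(points, k=k)
    cand = np.atleast_2d(cand)
    d = points[:, None, :] - v0[cand]                    # (np, k, 3)
    lam = np.einsum("pkij,pkj->pki", Tinv[cand], d)
    l0 = 1.0 - lam.sum(axis=2)
    ok = (lam.min(axis=2) >= -1e-9) & (l0 >= -1e-9)
    first = ok.argmax(axis=1)
    found = ok.any(axis=1)
    out = np.full(len(points), np.nan)
    rows = np.flatnonzero(found)
    e = cand[rows, first[rows]]
    w = np.concatenate([l0[rows, first[rows], None],
                        lam[rows, first[rows]]], axis=1)
    out[rows] = np.einsum("pa,pa->p", w, nodal[mesh.tets[e]])
    return out
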