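"""Parametric test-section geometries and tetrahedral mesh generation.

Two mesh generators are provided:

* structured extruded meshes for straight circular pipes and cone frustums
  (verification geometries with analytically known volume), and
* a level-set based generator for the planar cruciform cavopulmonary
  junction: coaxial vertical caval inlets (±y), coaxial horizontal pulmonary
  outlets (±x), a biconical housing bulge at the center, and an optional
  suspended biconical rotor stand-in with blade-like fins and support struts.

The junction mesher samples interior and surface points at a spatially
varying target size, projects surface candidates onto the zero level set,
adds graded boundary-layer sheets, and tetrahedralizes with a Delaunay
triangulation filtered by the level-set sign at element centroids.  Points
are generated in one quadrant and mirrored across the x=0 and y=0 planes, so
the vertex set is exactly reflection-symmetric whenever the geometry is.

Coordinates are cm; the origin is the junction center.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Callable

import numpy as np
from scipy.spatial import Delaunay, cKDTree

from .mesh import Mesh, MeshError, orient_tets


# ----------------------------------------------------------------------
# specifications
# ----------------------------------------------------------------------

@dataclass
class MeshSizing:
    """Target element sizes (cm) and boundary-layer layer counts.

    ``h_iso`` is the general isotropic size; surface sizes apply on the
    tubing/housing walls, the rotor (impeller) surface and the struts.  In a
    boundary layer with ``n`` layers the mesh size at the n-th innermost
    layer is ``h_iso / 2**n``.
    """

    h_iso: float = 0.2
    h_tubing_surface: float = 0.09
    h_impeller_surface: float = 0.03
    h_strut_surface: float = 0.06
    bl_layers_central: int = 3
    bl_layers_peripheral: int = 1

    def __post_init__(self) -> None:
        for name in ("h_iso", "h_tubing_surface", "h_impeller_surface",
                     "h_strut_surface"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("h_tubing_surface", "h_impeller_surface",
                     "h_strut_surface"):
            if getattr(self, name) > self.h_iso + 1e-12:
                raise ValueError(f"{name} must not exceed h_iso")

    def scaled(self, factor: float) -> "MeshSizing":
        """All length targets multiplied by ``factor`` (layer counts kept)."""
        if factor <= 0:
            raise ValueError("scale factor must be positive")
        return replace(
            self,
            h_iso=self.h_iso * factor,
            h_tubing_surface=self.h_tubing_surface * factor,
            h_impeller_surface=self.h_impeller_surface * factor,
            h_strut_surface=self.h_strut_surface * factor,
        )

    @classmethod
    def desk_scale(cls) -> "MeshSizing":
        """Coarse sizing for interactive desk-scale runs.

        Roughly 2-5x the reference surface sizes with a single graded
        boundary layer; yields junction meshes of a few thousand nodes.
        """
        return cls(h_iso=0.40, h_tubing_surface=0.28, h_impeller_surface=0.15,
                   h_strut_surface=0.18, bl_layers_central=1,
                   bl_layers_peripheral=1)


@dataclass
class GeometrySpec:
    """Parameters of the idealized cruciform test section and rotor stand-in.

    The housing is a biconical solid of revolution about the caval (y) axis
    whose radius tapers linearly from ``housing_max_diameter/2`` at the
    equator back to the tube radius at ``±housing_half_length``.  The
    optional obstacle is a biconical rotor body (apexes toward the two
    inlets) carrying ``blade_count_per_side`` raised blade-like fins on each
    conical face and supported by radial equatorial struts.  The rotor cone
    angles, hub radius and strut cross-section are stand-in parameters, not
    measured device dimensions.
    """

    tube_radius: float = 0.955
    housing_max_diameter: float = 3.4
    arm_length: float = 6.0
    obstacle: str = "none"              # "none" | "biconical"
    blade_height: float = 0.109
    blade_count_per_side: int = 4
    fillets: bool = False
    strut_count: int = 6
    secondary_gap: float | None = None
    # stand-in shape parameters (exposed, not asserted as faithful)
    housing_half_length: float = 2.0
    hub_radius: float = 1.1
    hub_half_length: float = 1.6
    strut_radius: float = 0.08
    blade_halfwidth_rad: float = 0.16
    resolve_blades: bool = True

    def __post_init__(self) -> None:
        if self.tube_radius <= 0:
            raise ValueError("tube_radius must be positive")
        if self.housing_max_diameter < 2 * self.tube_radius:
            raise ValueError("housing_max_diameter must be >= tube diameter")
        if self.arm_length < 4.0:
            raise ValueError("arm_length must be >= 4 cm so that cut planes "
                             "at 4 cm lie in straight tubing")
        if self.obstacle not in ("none", "biconical"):
            raise ValueError("obstacle must be 'none' or 'biconical'")
        if self.strut_count < 0 or self.strut_count % 2:
            raise ValueError("strut_count must be a non-negative even "
                             "number (mirror-symmetric strut pattern)")
        if self.obstacle == "biconical":
            gap = self.housing_max_diameter / 2 - self.hub_radius
            if self.blade_height >= gap:
                raise ValueError(
                    "blade_height must be smaller than the rotor-housing gap")
            self._check_clearance()

    def _check_clearance(self, margin: float = 0.05) -> None:
        y = np.linspace(-self.hub_half_length, self.hub_half_length, 201)
        rh = _housing_radius(y, self)
        rr = _rotor_radius_max(y, self)
        if np.min(rh - rr) <= margin:
            raise ValueError("obstacle intersects (or nearly touches) the "
                             "housing wall")


# ----------------------------------------------------------------------
# level-set primitives for the junction
# ----------------------------------------------------------------------

def _housing_radius(y: np.ndarray, spec: GeometrySpec) -> np.ndarray:
    """Housing radius about the y axis (biconical bulge, linear taper)."""
    r_t, r_max, hh = spec.tube_radius, spec.housing_max_diameter / 2, \
        spec.housing_half_length
    return r_t + (r_max - r_t) * np.clip(1.0 - np.abs(y) / hh, 0.0, None)


def _smoothstep(t: np.ndarray) -> np.ndarray:
    t = np.clip(t, 0.0, 1.0)
    return t * t * (3.0 - 2.0 * t)


def _blade_bump(theta, y, spec: GeometrySpec):
    """Angular blade profile times a meridional envelope, in cm."""
    nb = spec.blade_count_per_side
    pitch = 2.0 * np.pi / nb
    # lower-cone blades are offset by half a pitch
    off = np.where(np.real(y) < 0, 0.5 * pitch, 0.0)
    d = np.abs((theta + off + 0.5 * pitch) % pitch - 0.5 * pitch)
    smooth = 0.10 if spec.fillets else 0.04
    s_ang = _smoothstep((spec.blade_halfwidth_rad - d) / smooth + 0.5)
    ay = np.abs(y) / spec.hub_half_length
    env = _smoothstep((ay - 0.12) / 0.1) * _smoothstep((0.92 - ay) / 0.1)
    return spec.blade_height * s_ang * env


def _rotor_radius(y, theta, spec: GeometrySpec):
    """Rotor surface radius at (y, theta); zero beyond the apexes."""
    base = spec.hub_radius * np.clip(1.0 - np.abs(y) / spec.hub_half_length,
                                     0.0, None)
    if spec.resolve_blades and spec.blade_height > 0:
        base = base + _blade_bump(theta, y, spec)
    return base


def _rotor_radius_max(y: np.ndarray, spec: GeometrySpec) -> np.ndarray:
    r = spec.hub_radius * np.clip(1.0 - np.abs(y) / spec.hub_half_length,
                                  0.0, None)
    if spec.resolve_blades and spec.blade_height > 0:
        ay = np.abs(y) / spec.hub_half_length
        env = _smoothstep((ay - 0.12) / 0.1) * _smoothstep((0.92 - ay) / 0.1)
        r = r + spec.blade_height * env
    return r


def _strut_angle(j: int, n: int) -> float:
    """Strut azimuths: mirror-symmetric in x and never lying in the x=0
    plane (which would create a degenerate tangency with the symmetry
    plane used by the mesher)."""
    off = np.pi / n if n % 4 == 0 else 0.0
    return 2.0 * np.pi * j / n + off


class JunctionDomain:
    """Level-set description of the junction fluid domain.

    ``f(x) < 0`` inside the fluid, ``> 0`` outside; the zero set is the
    boundary.  Component fields are kept separate for boundary tagging.
    """

    def __init__(self, spec: GeometrySpec):
        self.spec = spec

    # component level functions (negative inside the respective solid)
    def f_arm_x(self, p):
        s = self.spec
        rad = np.sqrt(p[:, 1] ** 2 + p[:, 2] ** 2)
        return np.maximum(rad - s.tube_radius, np.abs(p[:, 0]) - s.arm_length)

    def f_arm_y(self, p):
        s = self.spec
        rad = np.sqrt(p[:, 0] ** 2 + p[:, 2] ** 2)
        return np.maximum(rad - s.tube_radius, np.abs(p[:, 1]) - s.arm_length)

    def f_housing(self, p):
        s = self.spec
        rad = np.sqrt(p[:, 0] ** 2 + p[:, 2] ** 2)
        return np.maximum(rad - _housing_radius(p[:, 1], s),
                          np.abs(p[:, 1]) - s.housing_half_length)

    def f_rotor(self, p):
        s = self.spec
        rad = np.sqrt(p[:, 0] ** 2 + p[:, 2] ** 2)
        theta = np.arctan2(p[:, 2], p[:, 0])
        f = np.maximum(rad - _rotor_radius(p[:, 1], theta, s),
                       np.abs(p[:, 1]) - s.hub_half_length)
        if s.secondary_gap:
            # thin annular film channel through the rotor near its axis
            r_mid = 0.35 * s.hub_radius
            ann = np.maximum(np.abs(rad - r_mid) - 0.5 * s.secondary_gap,
                             np.abs(p[:, 1]) - s.hub_half_length)
            f = np.maximum(f, -ann)
        return f

    def f_struts(self, p):
        s = self.spec
        if s.strut_count <= 0:
            return np.full(len(p), np.inf)
        r0 = 0.5 * s.hub_radius          # embedded in the rotor
        r1 = _housing_radius(np.zeros(1), s)[0] + 0.05
        d = np.full(len(p), np.inf)
        for j in range(s.strut_count):
            th = _strut_angle(j, s.strut_count)
            a = np.array([r0 * np.cos(th), 0.0, r0 * np.sin(th)])
            b = np.array([r1 * np.cos(th), 0.0, r1 * np.sin(th)])
            ab = b - a
            t = np.clip((p - a) @ ab / (ab @ ab), 0.0, 1.0)
            d = np.minimum(d, np.linalg.norm(p - (a + t[:, None] * ab),
                                             axis=1))
        return d - s.strut_radius

    def f(self, p) -> np.ndarray:
        p = np.atleast_2d(np.asarray(p, dtype=float))
        f = np.minimum(np.minimum(self.f_arm_x(p), self.f_arm_y(p)),
                       self.f_housing(p))
        if self.spec.obstacle == "biconical":
            f = np.maximum(f, -self.f_rotor(p))
            if self.spec.strut_count > 0:
                f = np.maximum(f, -self.f_struts(p))
        return f

    def local_size(self, p, sizing: MeshSizing) -> np.ndarray:
        """Surface-size target: surface sizes near walls, growing to h_iso."""
        p = np.atleast_2d(np.asarray(p, dtype=float))
        grow = 0.7
        d_wall = np.abs(np.minimum(np.minimum(self.f_arm_x(p),
                                              self.f_arm_y(p)),
                                   self.f_housing(p)))
        s = np.minimum(sizing.h_iso,
                       sizing.h_tubing_surface + grow * d_wall)
        if self.spec.obstacle == "biconical":
            s = np.minimum(s, sizing.h_impeller_surface
                           + grow * np.abs(self.f_rotor(p)))
            if self.spec.strut_count > 0:
                # thin cylindrical features need sizes below their radius
                h_strut = min(sizing.h_strut_surface,
                              0.9 * self.spec.strut_radius)
                s = np.minimum(s, h_strut
                               + grow * np.abs(self.f_struts(p)))
        return s

    def wall_distance(self, p) -> np.ndarray:
        """Distance-like field to the no-slip walls (port discs excluded)."""
        p = np.atleast_2d(np.asarray(p, dtype=float))
        s = self.spec
        rad_y = np.sqrt(p[:, 0] ** 2 + p[:, 2] ** 2)
        rad_x = np.sqrt(p[:, 1] ** 2 + p[:, 2] ** 2)
        d = np.minimum(np.abs(rad_x - s.tube_radius),
                       np.abs(rad_y - _housing_radius(p[:, 1], s)))
        if s.obstacle == "biconical":
            d = np.minimum(d, np.abs(self.f_rotor(p)))
            if s.strut_count > 0:
                d = np.minimum(d, np.abs(self.f_struts(p)))
        return d

    def volume_size(self, p, sizing: MeshSizing) -> np.ndarray:
        """Interior spacing target, including the graded near-wall layers.

        Within the boundary layer the isotropic target at the n-th innermost
        layer is ``h_iso / 2**n`` (n layers in the central test section,
        ``bl_layers_peripheral`` in the tubing).
        """
        p = np.atleast_2d(np.asarray(p, dtype=float))
        s = np.asarray(self.local_size(p, sizing)).copy()
        d = self.wall_distance(p)
        central = np.maximum(np.abs(p[:, 0]), np.abs(p[:, 1])) < \
            self.spec.housing_half_length + 1.0
        for region, nlay in ((central, sizing.bl_layers_central),
                             (~central, sizing.bl_layers_peripheral)):
            if nlay <= 0 or not region.any():
                continue
            sizes = sizing.h_iso / 2.0 ** np.arange(nlay, 0, -1)
            edges = np.cumsum(sizes)
            idx = np.searchsorted(edges, d[region], side="right")
            graded = np.where(idx < nlay, sizes[np.minimum(idx, nlay - 1)],
                              np.inf)
            s[region] = np.minimum(s[region], graded)
        return s

    def grad(self, p, h: float = 1e-4) -> np.ndarray:
        p = np.atleast_2d(np.asarray(p, dtype=float))
        g = np.empty_like(p)
        for k in range(3):
            e = np.zeros(3)
            e[k] = h
            g[:, k] = (self.f(p + e) - self.f(p - e)) / (2 * h)
        return g

    def project(self, p, iters: int = 7) -> np.ndarray:
        """Newton projection of points onto the zero level set."""
        p = np.array(np.atleast_2d(p), dtype=float)
        for _ in range(iters):
            fv = self.f(p)
            g = self.grad(p)
            g2 = np.einsum("ij,ij->i", g, g)
            step = fv / np.where(g2 > 1e-12, g2, 1.0)
            p = p - step[:, None] * g
        return p


# ----------------------------------------------------------------------
# structured pipe / frustum meshes
# ----------------------------------------------------------------------

def _disk_points(radius: float, h_wall: float, h_core: float,
                 bl_layers: int, h_bl_base: float) -> np.ndarray:
    """2D point layout for a circular cross-section: center + rings.

    Ring gaps shrink toward the wall as ``h_bl_base / 2**n`` for the graded
    boundary layer; circumferential spacing interpolates from ``h_wall`` at
    the rim to ``h_core`` inside.
    """
    radii = [radius]
    r = radius
    for n in range(bl_layers, 0, -1):
        r -= h_bl_base / 2.0 ** n
        if r <= 0.3 * h_core:
            break
        radii.append(r)
    while r > 0.85 * h_core:
        r -= h_core
        if r <= 0.45 * h_core:
            break
        radii.append(r)
    pts = [np.zeros((1, 2))]
    for k, rk in enumerate(radii):
        frac = 1.0 - rk / radius
        ds = h_wall + (h_core - h_wall) * min(1.0, 2.5 * frac)
        m = max(6, int(round(2.0 * np.pi * rk / ds)))
        th = 2.0 * np.pi * (np.arange(m) + 0.5 * (k % 2)) / m
        pts.append(np.stack([rk * np.cos(th), rk * np.sin(th)], axis=1))
    return np.concatenate(pts, axis=0)


def _extrude_disk(pts2d: np.ndarray, tris: np.ndarray,
                  z_levels: np.ndarray,
                  radius_of_z: Callable[[float], float],
                  base_radius: float) -> Mesh:
    """Extrude a triangulated disk along z into prisms split into tets."""
    nsec = len(pts2d)
    nlev = len(z_levels)
    nodes = np.empty((nsec * nlev, 3))
    for j, z in enumerate(z_levels):
        sc = radius_of_z(z) / base_radius
        nodes[j * nsec:(j + 1) * nsec, :2] = pts2d * sc
        nodes[j * nsec:(j + 1) * nsec, 2] = z
    tets = []
    order = np.argsort(tris, axis=1)
    tris_sorted = np.take_along_axis(tris, order, axis=1)
    for j in range(nlev - 1):
        b = tris_sorted + j * nsec
        t = tris_sorted + (j + 1) * nsec
        p0b, p1b, p2b = b[:, 0], b[:, 1], b[:, 2]
        p0t, p1t, p2t = t[:, 0], t[:, 1], t[:, 2]
        tets.append(np.stack([p0b, p1b, p2b, p0t], axis=1))
        tets.append(np.stack([p1b, p2b, p0t, p1t], axis=1))
        tets.append(np.stack([p2b, p0t, p1t, p2t], axis=1))
    tets = orient_tets(nodes, np.concatenate(tets, axis=0))
    mesh = Mesh(nodes, tets, np.empty((0, 3), dtype=int), np.empty(0))
    bfaces, _ = mesh.extract_boundary()
    cent = nodes[bfaces].mean(axis=1)
    z0, z1 = z_levels[0], z_levels[-1]
    tol = 1e-9 + 1e-6 * (z1 - z0)
    tags = np.where(cent[:, 2] < z0 + tol, "inlet",
                    np.where(cent[:, 2] > z1 - tol, "outlet", "wall"))
    return Mesh(nodes, tets, bfaces, tags)


def _pipe_layout(radius: float, sizing: MeshSizing):
    h_wall = sizing.h_tubing_surface
    h_core = min(sizing.h_iso, 0.6 * radius)
    if h_wall >= radius or sizing.h_iso >= 2.0 * radius:
        raise ValueError("mesh sizing is too coarse for this pipe radius")
    pts2d = _disk_points(radius, h_wall, h_core,
                         sizing.bl_layers_peripheral, sizing.h_iso)
    tris = Delaunay(pts2d).simplices
    return pts2d, tris


def make_pipe(radius: float, length: float, sizing: MeshSizing,
              tags: tuple[str, str, str] = ("inlet", "outlet", "wall"),
              axial_spacing: float | None = None) -> Mesh:
    """Structured mesh of a straight circular pipe along +z.

    The inlet face is at z=0, the outlet at z=length.  ``axial_spacing``
    decouples the extrusion step from ``h_iso`` (useful for resolving
    axial fronts without refining the cross-section).
    """
    if radius <= 0 or length <= 0:
        raise ValueError("radius and length must be positive")
    pts2d, tris = _pipe_layout(radius, sizing)
    dz = axial_spacing or sizing.h_iso
    nz = max(2, int(round(length / dz)))
    z = np.linspace(0.0, length, nz + 1)
    mesh = _extrude_disk(pts2d, tris, z, lambda _z: radius, radius)
    ren = {"inlet": tags[0], "outlet": tags[1], "wall": tags[2]}
    mesh.face_tags = np.array([ren[t] for t in mesh.face_tags])
    mesh.provenance = {
        "generator": "pipe", "radius": radius, "length": length,
        "sizing": sizing, "tags": tags, "axial_spacing": axial_spacing,
    }
    mesh.validate()
    return mesh


def make_frustum(r0: float, r1: float, length: float,
                 sizing: MeshSizing) -> Mesh:
    """Structured mesh of a cone frustum along +z (radius r0 -> r1)."""
    if min(r0, r1, length) <= 0:
        raise ValueError("radii and length must be positive")
    rmax = max(r0, r1)
    pts2d, tris = _pipe_layout(rmax, sizing)
    nz = max(2, int(round(length / sizing.h_iso)))
    z = np.linspace(0.0, length, nz + 1)
    mesh = _extrude_disk(pts2d, tris, z,
                         lambda zz: r0 + (r1 - r0) * zz / length, rmax)
    mesh.provenance = {"generator": "frustum", "r0": r0, "r1": r1,
                       "length": length, "sizing": sizing}
    mesh.validate()
    return mesh


# ----------------------------------------------------------------------
# junction mesh generation
# ----------------------------------------------------------------------

def _lattice(bbox, h, rng=None, jitter=0.0, bcc=False):
    lo, hi = bbox
    ns = [max(1, int(np.ceil((hi[k] - lo[k]) / h))) for k in range(3)]
    axes = [lo[k] + (np.arange(ns[k]) + 0.5) * (hi[k] - lo[k]) / ns[k]
            for k in range(3)]
    pts = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    if bcc:
        # body-centered arrangement: Delaunay of BCC points is far better
        # conditioned than that of a simple cubic lattice
        pts = np.concatenate([pts, pts + 0.5 * h], axis=0)
    if jitter > 0:
        pts = pts + rng.uniform(-jitter * h, jitter * h, size=pts.shape)
    return pts


def _smooth_interior(nodes: np.ndarray, tets: np.ndarray,
                     fixed_mask: np.ndarray, iters: int = 8,
                     relax: float = 0.5) -> np.ndarray:
    """Guarded Laplacian smoothing of non-fixed nodes.

    Each sweep moves free nodes toward the mean of their edge neighbors and
    reverts any move that would create a non-positive or near-degenerate
    element.
    """
    from scipy import sparse

    n = len(nodes)
    e = tets[:, [[0, 1], [0, 2], [0, 3], [1, 2], [1, 3], [2, 3]]].reshape(-1, 2)
    adj = sparse.coo_matrix(
        (np.ones(2 * len(e)), (np.concatenate([e[:, 0], e[:, 1]]),
                               np.concatenate([e[:, 1], e[:, 0]]))),
        shape=(n, n)).tocsr()
    adj.data[:] = 1.0
    deg = np.asarray(adj.sum(axis=1)).ravel()
    deg[deg == 0] = 1.0
    pos = nodes.copy()
    vol_floor = 0.05 * np.median(_tet_vols(pos, tets))
    for _ in range(iters):
        target = adj @ pos / deg[:, None]
        new = pos.copy()
        new[~fixed_mask] += relax * (target[~fixed_mask] - pos[~fixed_mask])
        # revert nodes whose incident tets would invert or collapse
        for _rep in range(4):
            vols = _tet_vols(new, tets)
            badt = vols < vol_floor
            if not badt.any():
                break
            bad_nodes = np.unique(tets[badt])
            new[bad_nodes] = pos[bad_nodes]
        pos = new
    return pos


def _greedy_thin(pts: np.ndarray, radii: np.ndarray,
                 fixed: np.ndarray | None = None,
                 fixed_radii: np.ndarray | None = None) -> np.ndarray:
    """Greedy Poisson-disk thinning with per-point radii.

    Points are visited in order of increasing radius; a point is accepted if
    no previously accepted (or fixed) point lies within its radius.
    Returns indices of accepted points.
    """
    if len(pts) == 0:
        return np.empty(0, dtype=int)
    order = np.argsort(radii, kind="stable")
    cell = max(np.max(radii), 1e-6)
    if fixed is not None and len(fixed):
        tree = cKDTree(fixed)
        dmin, jmin = tree.query(pts)
        # candidates need clearance on their own scale only: graded
        # near-wall points legitimately sit closer to a wall point than the
        # (tangential) wall spacing
        ok = dmin > 0.8 * radii
    else:
        ok = np.ones(len(pts), dtype=bool)
    grid: dict[tuple, list[int]] = {}
    accepted: list[int] = []
    inv = 1.0 / cell
    keys = np.floor(pts * inv).astype(np.int64)
    for i in order:
        if not ok[i]:
            continue
        k0, k1, k2 = keys[i]
        r2 = radii[i] ** 2
        good = True
        for a in (-1, 0, 1):
            for b in (-1, 0, 1):
                for c in (-1, 0, 1):
                    for j in grid.get((k0 + a, k1 + b, k2 + c), ()):
                        d = pts[i] - pts[j]
                        if d @ d < r2:
                            good = False
                            break
                    if not good:
                        break
                if not good:
                    break
            if not good:
                break
        if good:
            accepted.append(i)
            grid.setdefault((k0, k1, k2), []).append(i)
    return np.array(accepted, dtype=int)


def _reflect_quadrant_mesh(pts: np.ndarray, tets: np.ndarray,
                           mirror_y: bool = True
                           ) -> tuple[np.ndarray, np.ndarray]:
    """Reflect a quadrant (x>=0, y>=0) or half (x>=0) tet mesh across x=0
    and, when ``mirror_y``, across y=0.

    Nodes lying exactly on a symmetry plane are shared between copies, so
    the reflected meshes glue conformally: the Delaunay triangulation
    restricted to the plane is the same 2D triangulation on both sides.
    """
    nq = len(pts)
    on_x = pts[:, 0] == 0.0
    on_y = (pts[:, 1] == 0.0) if mirror_y else np.zeros(nq, bool)

    def fresh_ids(mask_shared, shared_ids, start):
        ids = np.empty(nq, dtype=np.int64)
        ids[mask_shared] = shared_ids[mask_shared]
        n_new = int((~mask_shared).sum())
        ids[~mask_shared] = start + np.arange(n_new)
        return ids, start + n_new

    base = np.arange(nq)
    nxt = nq
    id_mx, nxt = fresh_ids(on_x, base, nxt)          # (-x, +y)
    if not mirror_y:
        nodes = np.zeros((nxt, 3))
        nodes[base] = pts
        nodes[id_mx] = pts * np.array([-1.0, 1.0, 1.0])
        all_tets = np.concatenate([tets, id_mx[tets]], axis=0)
        all_tets = orient_tets(nodes, all_tets)
        key = np.sort(all_tets, axis=1)
        _, uniq = np.unique(key, axis=0, return_index=True)
        return nodes, all_tets[np.sort(uniq)]
    id_my, nxt = fresh_ids(on_y, base, nxt)          # (+x, -y)
    # (-x, -y): shares with (+x,-y) when on_x, with (-x,+y) when on_y
    id_mxy = np.empty(nq, dtype=np.int64)
    id_mxy[on_x] = id_my[on_x]
    id_mxy[on_y & ~on_x] = id_mx[on_y & ~on_x]
    rest = ~(on_x | on_y)
    id_mxy[rest] = nxt + np.arange(int(rest.sum()))
    nxt += int(rest.sum())

    nodes = np.zeros((nxt, 3))
    nodes[base] = pts
    for ids, sx, sy in ((id_mx, -1, 1), (id_my, 1, -1), (id_mxy, -1, -1)):
        nodes[ids] = pts * np.array([sx, sy, 1.0])
    all_tets = np.concatenate([
        tets, id_mx[tets], id_my[tets], id_mxy[tets]
    ], axis=0)
    all_tets = orient_tets(nodes, all_tets)
    # drop duplicated tets whose nodes all lie on a symmetry plane copy
    key = np.sort(all_tets, axis=1)
    _, uniq = np.unique(key, axis=0, return_index=True)
    return nodes, all_tets[np.sort(uniq)]


def make_junction(spec: GeometrySpec, sizing: MeshSizing,
                  seed: int = 0) -> Mesh:
    """Tetrahedral mesh of the cruciform junction test section.

    Boundary tags: ``inlet_svc`` (+y), ``inlet_ivc`` (-y), ``outlet_rpa``
    (+x), ``outlet_lpa`` (-x), ``wall_housing`` and, with an obstacle,
    ``wall_rotor`` / ``wall_strut``.
    """
    dom = JunctionDomain(spec)
    for attempt in range(5):
        try:
            return _make_junction_once(dom, sizing, seed + 101 * attempt)
        except MeshError as exc:
            last = exc
    raise MeshError(f"junction meshing failed after 5 attempts: {last}")


def _surface_candidates(dom: JunctionDomain, sizing: MeshSizing,
                        spec: GeometrySpec, rng,
                        mirror_y: bool) -> np.ndarray:
    """Surface point candidates per component, before thinning.

    Candidates cover x >= 0; the y range is halved too when the geometry is
    mirrored about y=0.
    """
    L = spec.arm_length
    r_b = spec.housing_max_diameter / 2
    y0 = 0.0 if mirror_y else None
    cands = []
    # walls of the two arms + housing
    h = 0.7 * sizing.h_tubing_surface
    rt = spec.tube_radius
    for lo, hi in (((0, -rt, -rt), (L, rt + 0.01, rt)),
                   ((0, -L, -rt), (rt + 0.01, L, rt)),
                   ((0, -spec.housing_half_length - 0.01, -r_b),
                    (r_b, spec.housing_half_length + 0.01, r_b))):
        lo = np.array(lo, float)
        hi = np.array(hi, float)
        if mirror_y:
            lo[1] = 0.0
        pts = _lattice((lo, hi), h, rng, jitter=0.3)
        fv = dom.f(pts)
        cands.append(pts[np.abs(fv) < 1.2 * h])
    if spec.obstacle == "biconical":
        h = 0.7 * sizing.h_impeller_surface
        rmax = spec.hub_radius + spec.blade_height + 0.05
        ylo = 0.0 if mirror_y else -spec.hub_half_length - 0.01
        bbox = (np.array([0, ylo, -rmax]),
                np.array([rmax, spec.hub_half_length + 0.01, rmax]))
        pts = _lattice(bbox, h, rng, jitter=0.3)
        fr = dom.f_rotor(pts)
        cands.append(pts[np.abs(fr) < 1.2 * h])
        if spec.strut_count > 0:
            h = 0.7 * min(sizing.h_strut_surface, 0.9 * spec.strut_radius)
            r1 = r_b + 0.05
            bbox = (np.array([0, -3 * spec.strut_radius, -r1]),
                    np.array([r1, 3 * spec.strut_radius, r1]))
            pts = _lattice(bbox, h, rng, jitter=0.3)
            fs = dom.f_struts(pts)
            cands.append(pts[np.abs(fs) < 1.2 * h])
    return np.concatenate(cands, axis=0)


def _port_rim_points(spec: GeometrySpec, sizing: MeshSizing,
                     mirror_y: bool) -> np.ndarray:
    """Exact sample points on the port rim circles (port plane ∩ wall).

    Projection of lattice candidates lands on either smooth surface but
    never on the crease itself, so the rims are sampled explicitly.
    Endpoint nodes on the symmetry planes are placed exactly on them.
    """
    rt, L = spec.tube_radius, spec.arm_length
    step = 0.62 * sizing.h_tubing_surface
    n_half = max(4, int(np.ceil(np.pi * rt / step)))
    out = []
    t = np.linspace(-0.5 * np.pi, 0.5 * np.pi, n_half + 1)
    # +x port: circle in the x=L plane; keep y >= 0 if mirrored
    y, z = rt * np.cos(t), rt * np.sin(t)
    y[np.abs(y) < 1e-12] = 0.0
    ring = np.stack([np.full_like(y, L), y, z], axis=1)
    out.append(ring if mirror_y else np.concatenate(
        [ring, ring * np.array([1.0, -1.0, 1.0])]))
    # +y (and, without mirroring, -y) ports: circles in y = ±L planes
    x, z = rt * np.cos(t), rt * np.sin(t)
    x[np.abs(x) < 1e-12] = 0.0
    ring = np.stack([x, np.full_like(x, L), z], axis=1)
    out.append(ring)
    if not mirror_y:
        out.append(ring * np.array([1.0, -1.0, 1.0]))
    pts = np.concatenate(out, axis=0)
    return np.unique(np.round(pts, 12), axis=0)


def _make_junction_once(dom: JunctionDomain, sizing: MeshSizing,
                        seed: int) -> Mesh:
    spec = dom.spec
    rng = np.random.default_rng(seed)
    L = spec.arm_length
    snap = 0.3 * sizing.h_tubing_surface
    # the rotor stand-in (blade phasing, equatorial struts) is not
    # symmetric about the equator plane, so only x=0 is used as a mirror
    # plane for obstacle-bearing geometries
    mirror_y = spec.obstacle != "biconical"
    axes = (0, 1) if mirror_y else (0,)

    def fold(p):
        for k in axes:
            p[:, k] = np.abs(p[:, k])
        return p

    # ---- surface points ------------------------------------------------
    cand = fold(_surface_candidates(dom, sizing, spec, rng, mirror_y))
    for k in axes:
        cand[np.abs(cand[:, k]) < snap, k] = 0.0
    surf = fold(dom.project(cand))
    keep = np.abs(dom.f(surf)) < 0.05 * sizing.h_tubing_surface
    surf = surf[keep]
    s_surf = dom.local_size(surf, sizing)
    # snap near-plane points back to the symmetry planes and re-project
    for k in axes:
        m = np.abs(surf[:, k]) < 0.35 * s_surf
        surf[m, k] = 0.0
    surf = fold(dom.project(surf, iters=3))
    s_surf = dom.local_size(surf, sizing)
    idx = _greedy_thin(surf, 0.62 * s_surf)
    surf = surf[idx]
    s_surf = s_surf[idx]
    # the port rim circles carry explicit, exact sample points; clear a
    # band around them first
    rim = _port_rim_points(spec, sizing, mirror_y)
    d_rim, _ = cKDTree(rim).query(surf)
    keep_r = d_rim > 0.55 * sizing.h_tubing_surface
    surf = np.concatenate([surf[keep_r], rim], axis=0)
    s_surf = np.concatenate(
        [s_surf[keep_r], np.full(len(rim), sizing.h_tubing_surface)])

    # ---- interior points (graded near-wall refinement) ------------------
    hs = [sizing.h_iso]
    n_max = max(sizing.bl_layers_central, sizing.bl_layers_peripheral)
    hmin = min(sizing.h_tubing_surface, sizing.h_impeller_surface,
               sizing.h_strut_surface, sizing.h_iso / 2.0 ** n_max)
    while hs[-1] > 1.6 * hmin:
        hs.append(hs[-1] / 1.7)
    min_arm = min(sizing.h_tubing_surface,
                  sizing.h_iso / 2.0 ** max(sizing.bl_layers_peripheral, 1))
    r_b = spec.housing_max_diameter / 2
    interior = []
    for lev, hk in enumerate(hs):
        if lev == 0 or hk >= 0.7 * min_arm:
            zmax = max(spec.tube_radius, r_b) + 0.01
            bbox = (np.array([0.0, 0.0 if mirror_y else -L, -zmax]),
                    np.array([L, L, zmax]))
        else:
            yb = spec.housing_half_length + 0.5
            bbox = (np.array([0.0, 0.0 if mirror_y else -yb, -r_b]),
                    np.array([r_b + 0.5, yb, r_b]))
        pts = fold(_lattice(bbox, hk, rng, jitter=0.18, bcc=True))
        s_loc = dom.volume_size(pts, sizing)
        band = s_loc > 1.25 * hs[lev + 1] if lev < len(hs) - 1 else \
            np.ones(len(pts), dtype=bool)
        if lev:
            band &= s_loc <= 1.25 * hk
        inside = dom.f(pts) < -0.6 * np.minimum(s_loc, hk)
        pts = pts[band & inside]
        interior.append(pts)
    interior = np.concatenate(interior, axis=0)
    for k in axes:
        interior[np.abs(interior[:, k]) < snap, k] = 0.0
    s_int = dom.volume_size(interior, sizing)
    idx = _greedy_thin(interior, 0.8 * s_int, surf, s_surf)
    interior = interior[idx]

    # ---- triangulate the quadrant, drive out slivers, reflect ----------
    quad = np.concatenate([surf, interior], axis=0)
    kind = np.concatenate([np.zeros(len(surf), dtype=np.int8),
                           np.full(len(interior), 2, dtype=np.int8)])
    for k in axes:
        quad[:, k] = np.maximum(quad[:, k], 0.0)
    quad, uniq = np.unique(np.round(quad, 9), axis=0, return_index=True)
    kind = kind[uniq]
    quad, tets = _sliver_drive_out(quad, kind, dom, sizing, rng,
                                   mirror_y=mirror_y)
    nodes, tets = _reflect_quadrant_mesh(quad, tets, mirror_y=mirror_y)
    mesh = _finalize_junction(nodes, tets, dom, sizing, seed)
    min_ang = _dihedral_min(mesh.nodes, mesh.tets).min()
    if min_ang < 10.0:
        raise MeshError(f"quality gate missed: min dihedral {min_ang:.2f} deg")
    mesh.provenance = {"generator": "junction", "spec": spec,
                       "sizing": sizing, "seed": seed}
    return mesh


def _triangulate_filtered(quad: np.ndarray, kind: np.ndarray,
                          dom: JunctionDomain,
                          sizing: MeshSizing) -> np.ndarray:
    """Delaunay triangulation restricted to the fluid domain.

    Keeps tets whose centroid is inside the zero level set, except flat
    "caps" riding on the curved wall (all four nodes on the surface,
    centroid depth a small fraction of the local size).  Dropping a cap may
    occasionally pinch the boundary; such caps are restored.
    """
    tets_all = orient_tets(quad, Delaunay(quad).simplices)
    cent = quad[tets_all].mean(axis=1)
    depth = -dom.f(cent)
    inside = depth > 0.0
    # flat tets riding the planar port discs are legitimate boundary
    # elements; the cap filter applies to the curved walls only
    L = dom.spec.arm_length
    on_port = (np.abs(cent[:, 0]) > L - 0.08) | \
              (np.abs(cent[:, 1]) > L - 0.08)
    shallow = (kind[tets_all] == 0).all(axis=1) & ~on_port & \
        (depth < 0.12 * dom.local_size(cent, sizing))
    tets = tets_all[inside & ~shallow]
    spares = tets_all[inside & shallow]
    for _ in range(6):
        bad_edges = _unmatched_edges(tets)
        if not len(bad_edges):
            break
        eset = {tuple(e) for e in bad_edges}
        restore = np.array([
            any(tuple(sorted((t[a], t[b]))) in eset
                for a in range(4) for b in range(a + 1, 4))
            for t in spares]) if len(spares) else np.zeros(0, dtype=bool)
        if not restore.any():
            break
        tets = np.concatenate([tets, spares[restore]], axis=0)
        spares = spares[~restore]
    return tets


def _sliver_drive_out(quad: np.ndarray, kind: np.ndarray,
                      dom: JunctionDomain, sizing: MeshSizing, rng,
                      gate: float = 11.0, lloyd_iters: int = 8,
                      climb_iters: int = 250, mirror_y: bool = True):
    """Lloyd-style relaxation plus targeted sliver removal on the quadrant.

    Delaunay meshes of quasi-random point sets contain slivers (near
    cospherical, near coplanar elements).  Three mechanisms drive them out:

    1. Lloyd passes: nodes relax toward the average of their like-kind
       neighbors and the mesh is re-triangulated -- surface nodes (kind 0)
       move tangentially and are re-projected onto the zero level set,
       interior nodes (kind 2) move freely but stay inside.
    2. Hill-climbing: nodes of remaining sub-gate tets receive small random
       perturbations; a proposal is kept only if the global count of bad
       non-cap tets does not increase.
    3. Cap peeling: flat all-surface-node tets riding on the curved wall
       (centroid barely inside) cannot be repaired by tangential motion and
       are removed from the final element set.

    Nodes on the symmetry planes stay on them; port-plane nodes are frozen.
    """
    L = dom.spec.arm_length
    r_t = dom.spec.tube_radius
    h_t = sizing.h_tubing_surface

    def masks(q):
        on_px = q[:, 0] == 0.0
        on_py = (q[:, 1] == 0.0) if mirror_y else np.zeros(len(q), bool)
        port_x = q[:, 0] > L - 0.05
        port_y = np.abs(q[:, 1]) > L - 0.05
        # only the port rim ring is pinned; inner port-disc nodes may
        # slide within the port plane
        rim = (port_x & (np.hypot(q[:, 1], q[:, 2]) > r_t - 0.35 * h_t)) | \
              (port_y & (np.hypot(q[:, 0], q[:, 2]) > r_t - 0.35 * h_t))
        return on_px, on_py, port_x, port_y, rim

    on_px, on_py, port_x, port_y, frozen = masks(quad)

    def constrain(q):
        q[:, 0] = np.maximum(q[:, 0], 0.0)
        if mirror_y:
            q[:, 1] = np.maximum(q[:, 1], 0.0)
        q[on_px, 0] = 0.0
        q[on_py, 1] = 0.0
        q[port_x, 0] = L
        q[port_y, 1] = np.sign(q[port_y, 1]) * L
        return q

    from scipy import sparse

    for _ in range(lloyd_iters):
        tets = _triangulate_filtered(quad, kind, dom, sizing)
        e = tets[:, [[0, 1], [0, 2], [0, 3], [1, 2], [1, 3], [2, 3]]]
        e = e.reshape(-1, 2)
        i = np.concatenate([e[:, 0], e[:, 1]])
        j = np.concatenate([e[:, 1], e[:, 0]])
        n = len(quad)
        A = sparse.coo_matrix((np.ones(len(i)), (i, j)), shape=(n, n)).tocsr()
        A.data[:] = 1.0
        new = quad.copy()
        for kk, damp in ((2, 0.6), (0, 0.4)):
            mask = (kind == kk) & ~frozen
            if kk == 2:
                deg = np.asarray(A.sum(axis=1)).ravel()
                avg = (A @ quad) / np.maximum(deg, 1)[:, None]
                new[mask] = quad[mask] + damp * (avg[mask] - quad[mask])
            else:
                Ak = A.multiply((kind == kk).astype(float)[None, :])
                deg = np.asarray(Ak.sum(axis=1)).ravel()
                good = deg > 2
                avg = np.zeros_like(quad)
                nz = deg > 0
                avg[nz] = (Ak @ quad)[nz] / deg[nz, None]
                m2 = mask & good
                new[m2] = quad[m2] + damp * (avg[m2] - quad[m2])
        ms = (kind == 0) & ~frozen
        new[ms] = dom.project(new[ms], iters=3)
        new = constrain(new)
        viol = np.zeros(len(quad), dtype=bool)
        mi = kind == 2
        viol[mi] = dom.f(new[mi]) > -0.35 * dom.volume_size(new[mi], sizing)
        # nothing but genuine port nodes may approach the port planes
        drift = ((new[:, 0] > L - 0.1) & ~port_x) | \
                ((np.abs(new[:, 1]) > L - 0.1) & ~port_y)
        new[viol | drift] = quad[viol | drift]
        quad = new

    tets = _triangulate_filtered(quad, kind, dom, sizing)
    ang = _dihedral_min(quad, tets)
    best = int((ang < gate).sum())
    # on large meshes the climb's global re-triangulations dominate the
    # cost; cap the iterations and hand the remaining slivers to the
    # deletion finisher and the fixed-topology local optimizer
    if len(quad) > 15000:
        climb_iters = min(climb_iters, 80)
    for it in range(climb_iters):
        if best == 0:
            break
        bad_ids = np.flatnonzero(ang < gate)
        # smaller, annealed proposals on a random subset are accepted far
        # more often than bulk moves once few bad elements remain
        take = max(1, len(bad_ids) // 3)
        bad_ids = rng.choice(bad_ids, size=take, replace=False)
        sel = np.unique(tets[bad_ids])
        sel = sel[~frozen[sel]]
        if len(sel) == 0:
            break
        s = dom.volume_size(quad[sel], sizing)
        step = rng.normal(size=(len(sel), 3))
        step /= np.linalg.norm(step, axis=1, keepdims=True)
        step *= (0.12 * 0.985 ** it * s)[:, None]
        tangential = kind[sel] == 0
        if tangential.any():
            g = dom.grad(quad[sel][tangential])
            nrm = g / (np.linalg.norm(g, axis=1, keepdims=True) + 1e-30)
            st = step[tangential]
            st -= np.einsum("ij,ij->i", st, nrm)[:, None] * nrm
            step[tangential] = st
        step[on_px[sel], 0] = 0.0
        step[on_py[sel], 1] = 0.0
        step[port_x[sel], 0] = 0.0
        step[port_y[sel], 1] = 0.0
        cand = quad.copy()
        cand[sel] = cand[sel] + step
        is_surf = sel[kind[sel] == 0]
        cand[is_surf] = dom.project(cand[is_surf], iters=3)
        cand = constrain(cand)
        inter = sel[kind[sel] == 2]
        if len(inter):
            viol = dom.f(cand[inter]) > -0.3 * dom.volume_size(cand[inter],
                                                               sizing)
            cand[inter[viol]] = quad[inter[viol]]
        drift = ((cand[:, 0] > L - 0.1) & ~port_x) | \
                ((np.abs(cand[:, 1]) > L - 0.1) & ~port_y)
        cand[drift] = quad[drift]
        t2 = _triangulate_filtered(cand, kind, dom, sizing)
        a2 = _dihedral_min(cand, t2)
        b2 = int((a2 < gate).sum())
        if b2 <= best:
            quad, tets, ang, best = cand, t2, a2, b2

    # finisher: delete an expendable node of each worst sliver and
    # re-triangulate; a batch is kept only if the bad count decreases.
    # Sampling density tolerates isolated deletions, so cap the total.
    deleted = 0
    budget = max(10, len(quad) // 30)
    for _ in range(15):
        ang = _dihedral_min(quad, tets)
        bad_ids = np.flatnonzero(ang < gate)
        if not len(bad_ids) or deleted >= budget:
            break
        worst = bad_ids[np.argsort(ang[bad_ids])][:max(2, len(bad_ids) // 4)]
        victims = []
        for tt in tets[worst]:
            cand = [v for v in tt if not frozen[v]]
            if not cand:
                continue
            cand.sort(key=lambda v: -kind[v])   # interior preferred
            if cand[0] not in victims:
                victims.append(cand[0])
        victims = victims[:max(0, budget - deleted)]
        if not victims:
            break
        keep = np.ones(len(quad), dtype=bool)
        keep[victims] = False
        q2, k2 = quad[keep], kind[keep]
        t2 = _triangulate_filtered(q2, k2, dom, sizing)
        a2 = _dihedral_min(q2, t2)
        if int((a2 < gate).sum()) < len(bad_ids):
            deleted += len(victims)
            quad, kind, tets = q2, k2, t2
            on_px, on_py = on_px[keep], on_py[keep]
            port_x, port_y = port_x[keep], port_y[keep]
            frozen = frozen[keep]

    quad = _local_optimize(quad, kind, tets, dom, sizing, frozen,
                           on_px, on_py, port_x, port_y, rng, gate=gate)
    tets = _repair_pinches(tets)
    return quad, tets


def _local_optimize(quad, kind, tets, dom, sizing, frozen, on_px, on_py,
                    port_x, port_y, rng, gate=11.0, sweeps=6):
    """Fixed-topology quality smoothing: greedily move nodes of sub-gate
    tets to the trial position that maximizes the minimum dihedral angle of
    their incident elements.

    Because connectivity is frozen, every accepted move is a strict local
    improvement; surface nodes are moved tangentially and re-projected, and
    symmetry/port-plane constraints are preserved.
    """
    from .mesh import _dihedral_angles

    n_t = len(tets)
    # node -> incident tets (build once; topology is fixed)
    inc: dict[int, list[int]] = {}
    for ti in range(n_t):
        for v in tets[ti]:
            inc.setdefault(int(v), []).append(ti)

    def tet_min_ang(tet_ids, pos_override=None, node=None):
        sub = tets[tet_ids]
        pts = quad
        if pos_override is not None:
            pts = quad.copy()
            pts[node] = pos_override
        return _dihedral_angles(pts, sub).min()

    for _ in range(sweeps):
        ang = _dihedral_min(quad, tets)
        bad = np.flatnonzero(ang < gate)
        if not len(bad):
            break
        improved = False
        for ti in bad[np.argsort(ang[bad])]:
            if _dihedral_angles(quad, tets[[ti]]).min() >= gate:
                continue
            order = sorted(tets[ti], key=lambda v: -kind[v])
            for v in order:
                v = int(v)
                if frozen[v]:
                    continue
                ids = inc[v]
                base = _dihedral_angles(quad, tets[ids]).min()
                s = float(dom.volume_size(quad[v][None], sizing)[0])
                trials = quad[v] + np.concatenate([
                    rng.normal(size=(10, 3)) * 0.10 * s,
                    rng.normal(size=(6, 3)) * 0.03 * s,
                ])
                if kind[v] == 0:
                    g = dom.grad(trials)
                    nrm = g / (np.linalg.norm(g, axis=1, keepdims=True)
                               + 1e-30)
                    d = trials - quad[v]
                    d -= np.einsum("ij,ij->i", d, nrm)[:, None] * nrm
                    trials = dom.project(quad[v] + d, iters=3)
                if on_px[v]:
                    trials[:, 0] = 0.0
                if on_py[v]:
                    trials[:, 1] = 0.0
                if port_x[v]:
                    trials[:, 0] = quad[v, 0]
                if port_y[v]:
                    trials[:, 1] = quad[v, 1]
                if kind[v] == 2:
                    okc = dom.f(trials) < -0.3 * dom.volume_size(trials,
                                                                 sizing)
                    trials = trials[okc]
                if not len(trials):
                    continue
                best_pos, best_val = None, base
                pts = quad.copy()
                for tr in trials:
                    pts[v] = tr
                    val = _dihedral_angles(pts, tets[ids]).min()
                    if val > best_val + 1e-9:
                        best_val, best_pos = val, tr.copy()
                if best_pos is not None:
                    quad[v] = best_pos
                    improved = True
                    if best_val >= gate:
                        break
        if not improved:
            break
    return quad


def _unmatched_edges(tets: np.ndarray) -> np.ndarray:
    """Boundary edges not shared by exactly two boundary faces."""
    faces = tets[:, [[1, 2, 3], [0, 3, 2], [0, 1, 3], [0, 2, 1]]].reshape(-1, 3)
    key = np.sort(faces, axis=1)
    _, inv, counts = np.unique(key, axis=0, return_inverse=True,
                               return_counts=True)
    bfaces = faces[counts[inv] == 1]
    if not len(bfaces):
        return np.empty((0, 2), dtype=np.int64)
    e = np.sort(bfaces[:, [[0, 1], [1, 2], [2, 0]]].reshape(-1, 2), axis=1)
    ue, counts = np.unique(e, axis=0, return_counts=True)
    return ue[counts != 2]


def _repair_pinches(tets: np.ndarray, max_rounds: int = 5) -> np.ndarray:
    """Remove tets incident to non-manifold (pinched) boundary edges.

    A pinch -- a boundary edge shared by more than two boundary faces --
    arises when the filtered element set touches itself along an edge;
    deleting the incident elements widens the touch into a proper notch.
    Returns the repaired set (possibly unchanged if already clean).
    """
    for _ in range(max_rounds):
        bad = _unmatched_edges(tets)
        if not len(bad):
            return tets
        eset = {tuple(e) for e in bad}
        edges = np.sort(
            tets[:, [[0, 1], [0, 2], [0, 3], [1, 2], [1, 3], [2, 3]]],
            axis=2)
        hit = np.zeros(len(tets), dtype=bool)
        for k in range(6):
            hit |= np.array([tuple(e) in eset for e in edges[:, k]])
        if not hit.any():
            return tets
        tets = tets[~hit]
    return tets



def _tet_vols(nodes, tets):
    x = nodes[tets]
    d = x[:, 1:] - x[:, :1]
    return np.einsum("ij,ij->i", d[:, 0], np.cross(d[:, 1], d[:, 2])) / 6.0


def _finalize_junction(pts, tets, dom: JunctionDomain, sizing: MeshSizing,
                       seed: int) -> Mesh:
    tets = _repair_pinches(tets)
    # drop unreferenced nodes (the repair may orphan some, and an orphan
    # would carry all-zero rows in any assembled system)
    used = np.unique(tets)
    remap = -np.ones(len(pts), dtype=np.int64)
    remap[used] = np.arange(len(used))
    pts = pts[used]
    tets = remap[tets]

    bfaces, _ = Mesh(pts, tets, np.empty((0, 3), dtype=int),
                     np.empty(0)).extract_boundary()
    if Mesh(pts, tets, bfaces,
            np.full(len(bfaces), "wall")).unmatched_boundary_edges():
        raise MeshError("non-watertight boundary after filtering")
    tags = _tag_junction_faces(pts, bfaces, dom)
    mesh = Mesh(pts, tets, bfaces, tags)
    mesh.validate()
    return mesh


def _dihedral_min(nodes: np.ndarray, tets: np.ndarray) -> np.ndarray:
    from .mesh import _dihedral_angles
    return _dihedral_angles(nodes, tets).min(axis=1)


def _tag_junction_faces(pts, bfaces, dom: JunctionDomain) -> np.ndarray:
    spec = dom.spec
    cent = pts[bfaces].mean(axis=1)
    L = spec.arm_length
    tol = 0.05
    tags = np.full(len(bfaces), "wall_housing", dtype="<U16")
    tags[cent[:, 0] > L - tol] = "outlet_rpa"
    tags[cent[:, 0] < -L + tol] = "outlet_lpa"
    tags[cent[:, 1] > L - tol] = "inlet_svc"
    tags[cent[:, 1] < -L + tol] = "inlet_ivc"
    if spec.obstacle == "biconical":
        wallish = tags == "wall_housing"
        c = cent[wallish]
        d_rot = np.abs(dom.f_rotor(c))
        d_str = (np.abs(dom.f_struts(c)) if spec.strut_count > 0
                 else np.full(len(c), np.inf))
        d_house = np.abs(np.minimum(np.minimum(dom.f_arm_x(c),
                                               dom.f_arm_y(c)),
                                    dom.f_housing(c)))
        sub = np.full(len(c), "wall_housing", dtype="<U16")
        sub[(d_rot < d_house) & (d_rot <= d_str)] = "wall_rotor"
        sub[(d_str < d_house) & (d_str < d_rot)] = "wall_strut"
        tags[wallish] = sub
    return tags


# ----------------------------------------------------------------------
# boundary layer as a standalone operation
# ----------------------------------------------------------------------

def apply_boundary_layer(mesh: Mesh, sizing: MeshSizing) -> Mesh:
    """Regenerate a generated mesh with graded near-wall layers.

    Works on meshes produced by this module (the generator parameters are
    carried in ``mesh.provenance``); the near-wall element size at layer n
    targets ``h_iso / 2**n``.  With zero layers the mesh is returned
    unchanged (with a warning).
    """
    if sizing.bl_layers_central <= 0 and sizing.bl_layers_peripheral <= 0:
        warnings.warn("boundary layer with n <= 0 layers requested: no-op")
        return mesh
    prov = mesh.provenance
    gen = prov.get("generator")
    if gen == "pipe":
        return make_pipe(prov["radius"], prov["length"], sizing,
                         prov.get("tags", ("inlet", "outlet", "wall")),
                         prov.get("axial_spacing"))
    if gen == "frustum":
        return make_frustum(prov["r0"], prov["r1"], prov["length"], sizing)
    if gen == "junction":
        return make_junction(prov["spec"], sizing, prov.get("seed", 0))
    raise MeshError("mesh has no generator provenance; cannot rebuild "
                    "boundary layers for an external mesh")


# ----------------------------------------------------------------------
# analytic helpers
# ----------------------------------------------------------------------

def obstacle_surface_area(spec: GeometrySpec, n_y: int = 400,
                          n_theta: int = 720) -> float:
    """Wetted surface area (cm^2) of the rotor stand-in by quadrature.

    The rotor surface is parameterized as r(y, theta) about the y axis; the
    area element is integrated on a fine (y, theta) grid.  Strut area is
    added as lateral cylinder area (junction with rotor/housing ignored).
    """
    if spec.obstacle != "biconical":
        return 0.0
    y = np.linspace(-spec.hub_half_length + 1e-6,
                    spec.hub_half_length - 1e-6, n_y)
    th = np.linspace(0, 2 * np.pi, n_theta, endpoint=False)
    Y, T = np.meshgrid(y, th, indexing="ij")
    R = _rotor_radius(Y, T, spec)
    dy = y[1] - y[0]
    dth = th[1] - th[0]
    dr_dy = np.gradient(R, dy, axis=0)
    dr_dth = np.gradient(R, dth, axis=1)
    dA = np.sqrt(R**2 * (1.0 + dr_dy**2) + dr_dth**2) * dy * dth
    area = float(dA.sum())
    if spec.strut_count > 0:
        r0 = _rotor_radius(np.array(0.0), np.array(0.0), spec)
        r1 = _housing_radius(np.array([0.0]), spec)[0]
        area += spec.strut_count * 2 * np.pi * spec.strut_radius * (r1 - r0)
    return area
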