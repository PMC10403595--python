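"""Post-processing of flow fields into hemodynamic endpoints.

Shear-based thrombosis surrogates and hydraulic performance measures:

* wall traction  tau = sigma.n - (sigma.n.n) n  with
  sigma = -p I + 2 mu strain-rate, evaluated per boundary face from the
  single adjacent element's (constant) velocity gradient;
* TAWSS = |time average of the traction vector| (vector average, not the
  average of magnitudes) over the analysis window;
* OSI = (1/2) (1 - |int tau dt| / int |tau| dt), in [0, 1/2];
* low-WSS area fraction: area-weighted fraction of wall with TAWSS below
  an empirical threshold (default 5 dyn/cm^2);
* cut-plane pressure drops (area-averaged static pressure, time-averaged),
  energy-flux power loss, and outlet flow splits.

Pressures are reported in mmHg and power in mW; everything internal stays
in CGS.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fem import boundary_flux_vector, interpolate_nodal
from .mesh import Mesh
from .solver import FlowField
from .units import dyncm2_to_mmhg, ergs_to_mw

WALL_TAG_PREFIX = "wall"
LOW_WSS_THRESHOLD = 5.0        # dyn/cm^2, empirical low-shear cutoff


# ----------------------------------------------------------------------
# wall traction
# ----------------------------------------------------------------------

@dataclass
class SurfaceField:
    """Per-face wall traction time series on a subset of boundary faces."""

    face_idx: np.ndarray       # indices into mesh.boundary_faces
    areas: np.ndarray          # cm^2
    normals: np.ndarray        # outward unit normals
    tags: np.ndarray           # per-face labels
    times: np.ndarray          # s
    tractions: np.ndarray      # (nt, nf, 3) dyn/cm^2, tangential


def _wall_face_idx(mesh: Mesh, tags=None) -> np.ndarray:
    if tags is None:
        tags = [t for t in mesh.tags if t.startswith(WALL_TAG_PREFIX)]
    return mesh.faces_of(tags)


def wall_traction(mesh: Mesh, v: np.ndarray, p: np.ndarray, mu: float,
                  face_idx: np.ndarray | None = None,
                  parent_tets: np.ndarray | None = None) -> np.ndarray:
    """Tangential wall traction per boundary face for one snapshot.

    The stress is evaluated from the single adjacent element (P1 gradients
    are constant per element); the wall-normal component is projected out,
    so ``tau . n = 0`` holds exactly.
    """
    if face_idx is None:
        face_idx = _wall_face_idx(mesh)
    if parent_tets is None:
        parent_tets = mesh.boundary_parent_tets()[face_idx]
    _, normals = mesh.face_areas_normals()
    n = normals[face_idx]
    tets = mesh.tets[parent_tets]
    x = mesh.nodes[tets]
    J = np.transpose(x[:, 1:] - x[:, :1], (0, 2, 1))
    A = np.linalg.inv(J)
    G = np.empty((len(tets), 4, 3))
    G[:, 1:] = A
    G[:, 0] = -A.sum(axis=1)
    grad_v = np.einsum("eai,eaj->eij", v[tets], G)
    S = mu * (grad_v + np.swapaxes(grad_v, 1, 2))
    p_face = p[mesh.boundary_faces[face_idx]].mean(axis=1)
    tn = np.einsum("eij,ej->ei", S, n) - p_face[:, None] * n
    tn -= np.einsum("ei,ei->e", tn, n)[:, None] * n
    return tn


def surface_traction_series(field: FlowField, mu: float,
                            tags=None) -> SurfaceField:
    """Traction time series on the tagged walls of a saved flow field."""
    mesh = field.mesh
    face_idx = _wall_face_idx(mesh, tags)
    parents = mesh.boundary_parent_tets()[face_idx]
    areas, normals = mesh.face_areas_normals()
    tr = np.stack([
        wall_traction(mesh, v, p, mu, face_idx, parents)
        for v, p in zip(field.velocities, field.pressures)
    ], axis=0)
    return SurfaceField(face_idx=face_idx, areas=areas[face_idx],
                        normals=normals[face_idx],
                        tags=mesh.face_tags[face_idx],
                        times=np.array(field.times), tractions=tr)


def _window_mask(times: np.ndarray, window) -> np.ndarray:
    t0, t1 = window
    mask = (times >= t0 - 1e-9) & (times <= t1 + 1e-9)
    if mask.sum() < 1:
        raise ValueError(f"no snapshots inside window {window}")
    return mask


def _time_average(times: np.ndarray, series: np.ndarray, window
                  ) -> np.ndarray:
    """Trapezoidal time average of (nt, ...) over the window."""
    m = _window_mask(times, window)
    t = times[m]
    s = series[m]
    if len(t) == 1:
        return s[0]
    return np.trapezoid(s, t, axis=0) / (t[-1] - t[0])


def tawss(surface: SurfaceField, window) -> np.ndarray:
    """Magnitude of the time-averaged traction vector per face."""
    mean_vec = _time_average(surface.times, surface.tractions, window)
    return np.linalg.norm(mean_vec, axis=1)


def osi(surface: SurfaceField, window) -> np.ndarray:
    """Oscillatory shear index per face, in [0, 1/2].

    Faces with (numerically) zero traction are assigned OSI = 0.
    """
    mean_vec = _time_average(surface.times, surface.tractions, window)
    mean_mag = _time_average(surface.times,
                             np.linalg.norm(surface.tractions, axis=2),
                             window)
    num = np.linalg.norm(mean_vec, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        val = 0.5 * (1.0 - num / mean_mag)
    val[mean_mag <= 1e-12] = 0.0
    return np.clip(val, 0.0, 0.5)


def low_wss_area_fraction(tawss_vals: np.ndarray, surface: SurfaceField,
                          tags=None,
                          threshold: float = LOW_WSS_THRESHOLD) -> float:
    """Area-weighted % of the selected wall with TAWSS below threshold."""
    sel = np.ones(len(surface.face_idx), dtype=bool) if tags is None else \
        np.isin(surface.tags, list(np.atleast_1d(tags)))
    if not sel.any():
        raise ValueError("no faces matching the requested tags")
    a = surface.areas[sel]
    return float(100.0 * a[tawss_vals[sel] < threshold].sum() / a.sum())


# ----------------------------------------------------------------------
# cut-plane pressures, power, splits
# ----------------------------------------------------------------------

def plane_average_pressure(mesh: Mesh, p: np.ndarray, axis: int,
                           value: float, radius: float,
                           n_samples: int = 200) -> float:
    """Area-averaged static pressure on a circular cut plane.

    The plane is ``x[axis] = value`` with samples on a polar grid of the
    given radius; pressure is interpolated linearly within the containing
    tetrahedra.
    """
    # polar sampling grid (area-uniform)
    rr = radius * np.sqrt((np.arange(n_samples) + 0.5) / n_samples)
    th = np.pi * (3.0 - np.sqrt(5.0)) * np.arange(n_samples)  # golden angle
    uv = np.stack([rr * np.cos(th), rr * np.sin(th)], axis=1)
    pts = np.zeros((n_samples, 3))
    other = [k for k in range(3) if k != axis]
    pts[:, axis] = value
    pts[:, other[0]] = uv[:, 0]
    pts[:, other[1]] = uv[:, 1]
    vals = interpolate_nodal(mesh, p, pts)
    if np.isnan(vals).all():
        raise ValueError(f"cut plane x[{axis}]={value} lies outside the mesh")
    return float(np.nanmean(vals))


def pressure_drop(field: FlowField, window, plane_offset: float = 4.0,
                  radius: float | None = None) -> dict:
    """Time-averaged cut-plane pressure drops (mmHg) per inlet-outlet pair.

    Planes sit at +/- ``plane_offset`` from the junction center in the
    straight tubing: inlets on the y axis (SVC +y, IVC -y), outlets on the
    x axis (RPA +x, LPA -x).
    """
    mesh = field.mesh
    if radius is None:
        radius = 0.92 * _infer_tube_radius(mesh)
    times = np.array(field.times)
    p_mean = _time_average(times, np.stack(field.pressures, axis=0), window)
    planes = {
        "svc": (1, +plane_offset), "ivc": (1, -plane_offset),
        "rpa": (0, +plane_offset), "lpa": (0, -plane_offset),
    }
    pavg = {k: plane_average_pressure(mesh, p_mean, ax, val, radius)
            for k, (ax, val) in planes.items()}
    out = {}
    for inlet in ("ivc", "svc"):
        for outlet in ("rpa", "lpa"):
            out[f"dP_{inlet}_{outlet}_mmHg"] = dyncm2_to_mmhg(
                pavg[inlet] - pavg[outlet])
    out["plane_pressures_dyncm2"] = pavg
    return out


def _infer_tube_radius(mesh: Mesh) -> float:
    """Tube radius from the port-disc node sets (max distance to axis)."""
    nodes = mesh.nodes_of([t for t in mesh.tags
                           if t.startswith(("inlet", "outlet"))])
    pts = mesh.nodes[nodes]
    r_about_y = np.hypot(pts[:, 0], pts[:, 2])
    r_about_x = np.hypot(pts[:, 1], pts[:, 2])
    return float(min(r_about_x.max(), r_about_y.max()))


def power_loss(field: FlowField, window, props) -> float:
    """Net energy-flux loss between inlets and outlets, in mW.

    Per snapshot, ``sum_ports int (p + rho |v|^2 / 2) (v . n) dGamma`` with
    outward normals; the negative of the sum (influx minus efflux) is the
    dissipated power.
    """
    mesh = field.mesh
    rho = props.density
    ports = [t for t in mesh.tags if t.startswith(("inlet", "outlet"))]
    areas, normals = mesh.face_areas_normals()
    series = []
    for v, p in zip(field.velocities, field.pressures):
        total = 0.0
        for tag in ports:
            fidx = mesh.faces_of(tag)
            faces = mesh.boundary_faces[fidx]
            a, nrm = areas[fidx], normals[fidx]
            e_nodal = p + 0.5 * rho * np.einsum("ni,ni->n", v, v)
            for corner in range(3):
                nd = faces[:, corner]
                vn = np.einsum("fi,fi->f", v[nd], nrm)
                total += float(np.sum((a / 3.0) * e_nodal[nd] * vn))
        series.append(-total)
    times = np.array(field.times)
    return ergs_to_mw(float(_time_average(times, np.array(series), window)))


def flow_split(field: FlowField, window, outlet_tags=None) -> dict:
    """Windowed mean outlet fluxes normalized to percentages."""
    mesh = field.mesh
    if outlet_tags is None:
        outlet_tags = [t for t in mesh.tags if t.startswith("outlet")]
    if not outlet_tags:
        raise ValueError("no outlet tags")
    times = np.array(field.times)
    fluxes = {}
    for tag in outlet_tags:
        b = boundary_flux_vector(mesh, mesh.faces_of(tag))
        q = np.array([np.sum(b * v) for v in field.velocities])
        fluxes[tag] = float(_time_average(times, q, window))
    total = sum(fluxes.values())
    if abs(total) < 1e-12:
        raise ValueError("near-zero total outflow")
    return {tag: 100.0 * q / total for tag, q in fluxes.items()}


# ----------------------------------------------------------------------
# case report
# ----------------------------------------------------------------------

def endpoint_report(field: FlowField, props, window,
                    washout: dict | None = None,
                    plane_offset: float = 4.0) -> dict:
    """Full per-case endpoint table as a flat dict (CSV/JSON friendly)."""
    rep: dict = {}
    rep.update({k: v for k, v in pressure_drop(
        field, window, plane_offset).items() if k.startswith("dP_")})
    rep["power_loss_mw"] = power_loss(field, window, props)
    for tag, pct in flow_split(field, window).items():
        rep[f"split_{tag}_pct"] = pct
    surface = surface_traction_series(field, props.viscosity)
    ta = tawss(surface, window)
    oi = osi(surface, window)
    wall_tags = sorted(set(surface.tags.tolist()))
    a = surface.areas
    rep["tawss_mean_dyncm2"] = float(np.sum(ta * a) / a.sum())
    rep["low_wss_fraction_pct"] = low_wss_area_fraction(ta, surface)
    rep["osi_max"] = float(oi.max())
    for tag in wall_tags:
        sel = surface.tags == tag
        rep[f"tawss_mean_{tag}_dyncm2"] = float(
            np.sum(ta[sel] * a[sel]) / a[sel].sum())
        rep[f"low_wss_{tag}_pct"] = low_wss_area_fraction(
            ta, surface, tags=tag)
        rep[f"osi_mean_{tag}"] = float(
            np.sum(oi[sel] * a[sel]) / a[sel].sum())
    if washout:
        rep["mean_washout_s"] = washout["mean_washout_s"]
        rep["washout_censored_fraction"] = washout["censored_fraction"]
    return rep
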