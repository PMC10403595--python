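"""Stabilized P1-P1 finite-element solver for incompressible Newtonian flow.

The weak form comprises the Galerkin terms (inertia, advection, pressure,
viscous stress, continuity, Neumann traction) augmented with residual-based
SUPG/PSPG stabilization and an optional grad-div (LSIC) term, discretized
with equal-order linear tetrahedra.  Time integration is the second-order
generalized-alpha method for first-order systems; the nonlinear system of
each step is solved by Newton-Raphson with a Jacobian obtained by
complex-step differentiation of the element kernel, which makes the tangent
exactly consistent with the residual (including the dependence of the
stabilization parameter on the velocity).

Boundary conditions: parabolic Dirichlet inflow profiles, no-slip walls,
resistance outlets ``h = -R Q n`` with the flux coupling treated implicitly
as a rank-one update (Woodbury), and convective backflow stabilization on
the outlets.

Units are CGS throughout: cm, s, g, dyn; pressure in dyn/cm^2.

Stabilization parameters (the precise formulas, stated because variants
abound):

    tau_M = ( c_t/dt^2  +  v^T xi v  +  C_I nu^2 (xi:xi) )^(-1/2)
    tau_C = 1 / (tau_M * tr(xi))

with the covariant element metric ``xi`` from :class:`fontanflow.fem.ElementData`,
``c_t = 4`` (0 when the transient term is disabled), ``C_I = 3``, and
kinematic viscosity ``nu``.  The momentum stabilization weight is
``rho (v . grad w) tau_M`` and the continuity weight ``(grad q) tau_M / rho``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import splu

from .fem import ElementData, QUAD_POINTS, QUAD_WEIGHTS, boundary_flux_vector
from .mesh import Mesh

_CSTEP = 1e-30      # complex-step size


class SolverError(RuntimeError):
    pass


# ----------------------------------------------------------------------
# configuration dataclasses
# ----------------------------------------------------------------------

@dataclass
class FluidProperties:
    """Newtonian fluid: blood-analog defaults (40/60 glycerol/water)."""

    density: float = 1.06          # g/cm^3
    viscosity: float = 0.035       # Poise = g/(cm s)
    body_force: tuple = (0.0, 0.0, 0.0)   # dyn/cm^3

    def __post_init__(self):
        if self.density <= 0 or self.viscosity <= 0:
            raise ValueError("density and viscosity must be positive")

    @property
    def nu(self) -> float:
        return self.viscosity / self.density


@dataclass
class BCSet:
    """Boundary-condition assignment by boundary tag.

    ``inlet_flows`` maps inlet tags to volumetric flow rates Q (cm^3/s,
    positive into the domain, imposed as parabolic Dirichlet profiles);
    ``outlet_resistances`` maps outlet tags to R (dyn s/cm^5), giving the
    outlet traction ``h = -R Q n``; every remaining tag must appear in
    ``wall_tags`` (no-slip).  ``beta`` scales the convective backflow
    penalty on outlets; ``ramp_time`` smoothly brings the inflow from zero
    to its target to avoid an impulsive start.
    """

    inlet_flows: dict = field(default_factory=dict)
    outlet_resistances: dict = field(default_factory=dict)
    wall_tags: tuple = ()
    beta: float = 0.2
    ramp_time: float = 0.3

    def validate(self, mesh: Mesh) -> None:
        assigned = (set(self.inlet_flows) | set(self.outlet_resistances)
                    | set(self.wall_tags))
        tags = set(mesh.tags)
        if assigned != tags:
            raise ValueError(
                f"boundary tags {sorted(tags - assigned)} unassigned, "
                f"{sorted(assigned - tags)} unknown")
        if any(q < 0 for q in self.inlet_flows.values()):
            raise ValueError("inlet flows must be non-negative")
        if any(r < 0 for r in self.outlet_resistances.values()):
            raise ValueError("outlet resistances must be non-negative")
        if self.beta < 0:
            raise ValueError("beta must be non-negative")


@dataclass
class SolverParams:
    """Time integration and Newton-solve parameters."""

    dt: float = 0.001              # s
    t_end: float = 5.0             # s
    save_interval: float = 0.02    # s
    averaging_window: tuple = (2.0, 5.0)
    rho_inf: float = 0.5           # generalized-alpha spectral radius
    newton_tol: float = 1e-3       # relative residual
    newton_max_iter: int = 5
    tau_dt_term: bool = True       # include c_t/dt^2 in tau_M
    tau_time_ref: float = 0.05     # fixed tau time scale when disabled (s)
    c_tau_i: float = 3.0           # C_I viscous coefficient in tau_M
    grad_div: float = 1.0          # LSIC coefficient (0 disables)
    picard_tangent: bool = True    # cheap analytic tangent for stepping

    def __post_init__(self):
        if not (0 < self.dt < self.t_end):
            raise ValueError("require 0 < dt < t_end")
        if not (0.0 <= self.rho_inf <= 1.0):
            raise ValueError("rho_inf must lie in [0, 1]")

    @property
    def alphas(self) -> tuple[float, float, float]:
        """(alpha_m, alpha_f, gamma) of generalized-alpha for 1st-order ODE.

        rho_inf = 1 recovers the trapezoidal (midpoint) limit
        alpha_m = alpha_f = gamma = 1/2.
        """
        am = 0.5 * (3.0 - self.rho_inf) / (1.0 + self.rho_inf)
        af = 1.0 / (1.0 + self.rho_inf)
        return am, af, 0.5 + am - af


@dataclass
class FlowState:
    """Nodal velocity (cm/s), pressure (dyn/cm^2) and time (s)."""

    v: np.ndarray
    p: np.ndarray
    t: float = 0.0

    def copy(self) -> "FlowState":
        return FlowState(self.v.copy(), self.p.copy(), self.t)


class FlowField:
    """Saved snapshots plus per-step monitors of a transient run."""

    def __init__(self, mesh: Mesh):
        self.mesh = mesh
        self.times: list[float] = []
        self.velocities: list[np.ndarray] = []
        self.pressures: list[np.ndarray] = []
        self.monitors: dict[str, list] = {}
        self.status: dict = {"converged": False, "failed": False}

    def add_snapshot(self, state: FlowState) -> None:
        self.times.append(state.t)
        self.velocities.append(state.v.copy())
        self.pressures.append(state.p.copy())

    def log(self, **kv) -> None:
        for k, v in kv.items():
            self.monitors.setdefault(k, []).append(v)

    def window_snapshots(self, window) -> list[int]:
        t0, t1 = window
        return [i for i, t in enumerate(self.times)
                if t0 - 1e-9 <= t <= t1 + 1e-9]

    def monitor_frame(self):
        import pandas as pd
        return pd.DataFrame(self.monitors)


# ----------------------------------------------------------------------
# inflow profile
# ----------------------------------------------------------------------

def parabolic_inflow(mesh: Mesh, tag: str, Q: float
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Nodal Dirichlet velocities for a parabolic profile of flow rate Q.

    The profile ``2 (Q/A) (1 - (r/R)^2)`` is evaluated at the inlet nodes
    (direction: inward normal) and rescaled so the discrete flux integral
    equals Q within 0.5%.  Returns ``(node_indices, velocities)``.
    """
    fidx = mesh.faces_of(tag)
    if len(fidx) == 0:
        raise ValueError(f"no faces tagged {tag!r}")
    areas, normals = mesh.face_areas_normals()
    areas, normals = areas[fidx], normals[fidx]
    A = areas.sum()
    n_in = -(normals * areas[:, None]).sum(axis=0)
    n_in /= np.linalg.norm(n_in)
    nodes = mesh.nodes_of(tag)
    xy = mesh.nodes[nodes]
    centroid = (mesh.nodes[mesh.boundary_faces[fidx]].mean(axis=1)
                * areas[:, None, None][:, 0]).sum(axis=0) / A
    r = xy - centroid
    r -= np.outer(r @ n_in, n_in)
    rr = np.linalg.norm(r, axis=1)
    R_eff = np.sqrt(A / np.pi)
    circular = abs(rr.max() / R_eff - 1.0) < 0.2
    if not circular:
        warnings.warn(f"inlet {tag!r} is not close to a circular disc; "
                      "using a flux-matched blunt profile")
        prof = np.ones(len(nodes))
    else:
        prof = np.clip(1.0 - (rr / max(rr.max(), R_eff)) ** 2, 0.0, None)
    vel = (2.0 * Q / A) * prof[:, None] * n_in
    if Q == 0.0:
        return nodes, np.zeros_like(vel)
    # rescale so the discrete flux equals Q exactly
    vfield = np.zeros((mesh.n_nodes, 3))
    vfield[nodes] = vel
    b = boundary_flux_vector(mesh, fidx)
    flux = -np.sum(b * vfield)          # inward positive
    if flux <= 0:
        raise SolverError(f"degenerate inflow profile on {tag!r}")
    return nodes, vel * (Q / flux)


# ----------------------------------------------------------------------
# the solver
# ----------------------------------------------------------------------

class NavierStokesSolver:
    """Assembles and advances the stabilized Navier-Stokes system.

    Degrees of freedom are interleaved: node i owns dofs ``4i..4i+2``
    (velocity) and ``4i+3`` (pressure).
    """

    def __init__(self, mesh: Mesh, props: FluidProperties, bcs: BCSet,
                 params: SolverParams):
        bcs.validate(mesh)
        self.mesh = mesh
        self.props = props
        self.bcs = bcs
        self.params = params
        self.ed = ElementData(mesh)
        self.n = mesh.n_nodes
        self.ndof = 4 * self.n

        # Dirichlet sets: inlet profiles, then walls (walls win on overlap)
        self.inlet_profiles = {}
        dir_mask = np.zeros((self.n, 3), dtype=bool)
        wall_nodes = mesh.nodes_of(bcs.wall_tags) if bcs.wall_tags else \
            np.empty(0, dtype=int)
        for tag, Q in bcs.inlet_flows.items():
            nodes, vel = parabolic_inflow(mesh, tag, Q)
            # the no-slip override zeroes rim (and any shared) nodes;
            # rescale so the imposed discrete influx is exactly Q
            if Q > 0:
                vel = vel.copy()
                vel[np.isin(nodes, wall_nodes)] = 0.0
                vf = np.zeros((self.n, 3))
                vf[nodes] = vel
                b = boundary_flux_vector(mesh, mesh.faces_of(tag))
                flux = -np.sum(b * vf)
                if flux <= 0:
                    raise SolverError(f"inflow on {tag!r} lost to no-slip")
                vel *= Q / flux
            self.inlet_profiles[tag] = (nodes, vel)
            dir_mask[nodes] = True
        dir_mask[wall_nodes] = True
        self.wall_nodes = wall_nodes
        self.dir_mask = dir_mask
        dof_mask = np.zeros(self.ndof, dtype=bool)
        dof_mask.reshape(self.n, 4)[:, :3] = dir_mask
        self.dir_dofs = np.flatnonzero(dof_mask)
        self.free_dofs = np.flatnonzero(~dof_mask)

        # outlet data
        self.outlets = {}
        for tag, R in bcs.outlet_resistances.items():
            fidx = mesh.faces_of(tag)
            areas, normals = mesh.face_areas_normals()
            self.outlets[tag] = {
                "faces": mesh.boundary_faces[fidx],
                "areas": areas[fidx],
                "normals": normals[fidx],
                "R": R,
                "b": boundary_flux_vector(mesh, fidx),
            }

        self._lu = None
        self._lu_lowrank = None
        self._newton_iters_last = 0

    # -- dirichlet values ------------------------------------------------

    def _ramp(self, t: float) -> float:
        tr = self.bcs.ramp_time
        if tr <= 0:
            return 1.0
        s = min(1.0, t / tr)
        return s * s * (3.0 - 2.0 * s)

    def apply_dirichlet(self, v: np.ndarray, t: float) -> None:
        scale = self._ramp(t)
        for tag, (nodes, vel) in self.inlet_profiles.items():
            v[nodes] = scale * vel
        v[self.wall_nodes] = 0.0

    # -- element kernel (complex-safe) -----------------------------------

    def _element_residual(self, v_np1_e, p_e, v_n_e, vdot_n_e):
        pr, pa = self.props, self.params
        am, af, gam = pa.alphas
        dt = pa.dt
        rho, mu = pr.density, pr.viscosity
        fb = np.asarray(pr.body_force)
        ed = self.ed
        G, V, K = ed.grads, ed.vols, ed.metric

        v_f = v_n_e + af * (v_np1_e - v_n_e)
        vdot_np1 = (v_np1_e - v_n_e) / (gam * dt) + (1.0 - 1.0 / gam) \
            * vdot_n_e
        vdot_m = vdot_n_e + am * (vdot_np1 - vdot_n_e)

        grad_v = np.einsum("eai,eaj->eij", v_f, G)
        div_v = np.trace(grad_v, axis1=1, axis2=2)
        grad_p = np.einsum("ea,eaj->ej", p_e, G)
        p_bar = p_e.mean(axis=1)

        N, w = QUAD_POINTS, QUAD_WEIGHTS
        v_q = np.einsum("qa,eai->eqi", N, v_f)
        vdot_q = np.einsum("qa,eai->eqi", N, vdot_m)
        conv_q = np.einsum("eqj,eij->eqi", v_q, grad_v)
        inert_q = rho * (vdot_q + conv_q) - rho * fb
        rm_q = inert_q + grad_p[:, None, :]

        # stabilization parameters (element-wise, mean advection velocity)
        vbar = v_f.mean(axis=1)
        vKv = np.einsum("ei,eij,ej->e", vbar, K, vbar)
        # with the transient term disabled, a fixed reference time keeps
        # tau bounded (and the discrete operator independent of dt)
        t_tau = dt if pa.tau_dt_term else pa.tau_time_ref
        nu = mu / rho
        tau = 1.0 / np.sqrt(4.0 / t_tau ** 2 + vKv
                            + pa.c_tau_i * nu ** 2 * ed.metric_dd)

        Rm = np.einsum("q,qa,eqi->eai", w, N, inert_q, optimize=True)
        S = mu * (grad_v + np.swapaxes(grad_v, 1, 2))
        Rm = Rm + np.einsum("eij,eaj->eai", S, G) - \
            p_bar[:, None, None] * G
        advw = rho * np.einsum("eqj,eaj->eqa", v_q, G)
        Rm = Rm + np.einsum("q,eqa,eqi,e->eai", w, advw, rm_q, tau, optimize=True)
        if pa.grad_div:
            tau_c = pa.grad_div / (tau * np.trace(K, axis1=1, axis2=2))
            Rm = Rm + (rho * tau_c * div_v)[:, None, None] * G
        Rc = 0.25 * div_v[:, None] * np.ones((1, 4)) + \
            np.einsum("q,eaj,eqj,e->ea", w, G, rm_q, tau, optimize=True) / rho
        return V[:, None, None] * Rm, V[:, None] * Rc

    # -- boundary terms ---------------------------------------------------

    def _backflow_residual(self, v_f: np.ndarray):
        """Convective inflow penalty on outlets, nodal-quadrature form."""
        beta, rho = self.bcs.beta, self.props.density
        out = np.zeros_like(v_f)
        if beta == 0.0:
            return out
        for o in self.outlets.values():
            faces, areas, normals = o["faces"], o["areas"], o["normals"]
            for corner in range(3):
                nd = faces[:, corner]
                vn = np.einsum("fi,fi->f", v_f[nd], normals)
                active = np.real(vn) < 0.0
                coef = -rho * beta * (areas / 3.0) * vn * active
                np.add.at(out, nd, coef[:, None] * v_f[nd])
        return out

    def _backflow_jacobian_blocks(self, v_f: np.ndarray):
        """COO entries of the backflow tangent (w.r.t. v at n+1)."""
        beta, rho = self.bcs.beta, self.props.density
        _, af, _ = self.params.alphas
        rows, cols, vals = [], [], []
        if beta == 0.0:
            return rows, cols, vals
        eye = np.eye(3)
        for o in self.outlets.values():
            faces, areas, normals = o["faces"], o["areas"], o["normals"]
            for corner in range(3):
                nd = faces[:, corner]
                vn = np.einsum("fi,fi->f", v_f[nd], normals)
                act = vn < 0.0
                if not act.any():
                    continue
                nda = nd[act]
                coef = -rho * beta * (areas[act] / 3.0) * af
                blk = coef[:, None, None] * (
                    vn[act, None, None] * eye
                    + np.einsum("fi,fj->fij", v_f[nda], normals[act]))
                for i in range(3):
                    for j in range(3):
                        rows.append(4 * nda + i)
                        cols.append(4 * nda + j)
                        vals.append(blk[:, i, j])
        return rows, cols, vals

    def outlet_flux(self, v: np.ndarray, tag: str) -> float:
        return float(np.sum(self.outlets[tag]["b"] * v))

    def outlet_pressure(self, p: np.ndarray, tag: str) -> float:
        o = self.outlets[tag]
        pf = p[o["faces"]].mean(axis=1)
        return float((pf * o["areas"]).sum() / o["areas"].sum())

    def inlet_flux(self, v: np.ndarray, tag: str) -> float:
        fidx = self.mesh.faces_of(tag)
        b = boundary_flux_vector(self.mesh, fidx)
        return -float(np.sum(b * v))       # positive into the domain

    def _element_jacobian_picard(self, v_np1_e):
        """Analytic Picard-linearized element tangent (nel, 16, 16).

        Advection velocity and the stabilization parameters are frozen at
        the current iterate; the neglected terms (tau', full advection
        linearization, backflow handled separately) only affect the Newton
        path, not the converged solution.  Roughly an order of magnitude
        cheaper than the exact complex-step tangent.
        """
        pr, pa = self.props, self.params
        am, af, gam = pa.alphas
        dt = pa.dt
        rho, mu = pr.density, pr.viscosity
        ed = self.ed
        G, V, K = ed.grads, ed.vols, ed.metric
        nel = ed.n_elems
        N, w = QUAD_POINTS, QUAD_WEIGHTS

        cdot = am / (gam * dt)
        v_f_e = v_np1_e  # advective field frozen at current iterate
        v_q = np.einsum("qa,eai->eqi", N, v_f_e)
        vbar = v_f_e.mean(axis=1)
        vKv = np.einsum("ei,eij,ej->e", vbar, K, vbar)
        t_tau = dt if pa.tau_dt_term else pa.tau_time_ref
        nu = mu / rho
        tau = 1.0 / np.sqrt(4.0 / t_tau ** 2 + vKv
                            + pa.c_tau_i * nu ** 2 * ed.metric_dd)

        # scalar building blocks
        M = np.einsum("q,qa,qb->ab", w, N, N)                   # (4,4)
        adv = np.einsum("q,qa,eqj,ebj->eab", w, N, v_q, G, optimize=True)       # N_a v.Gb
        advw = np.einsum("q,eqi,eai,qb->eab", w, v_q, G, N, optimize=True)      # (v.Ga) N_b
        advw_adv = np.einsum("q,eqi,eai,eqj,ebj->eab",
                             w, v_q, G, v_q, G, optimize=True)                  # (v.Ga)(v.Gb)
        GG = np.einsum("eai,ebi->eab", G, G)

        Jl = np.zeros((nel, 4, 4, 4, 4))   # (e, a, i, b, j) with 3=pressure
        eye = np.eye(3)
        Vx = V[:, None, None]

        # momentum rows (i < 3)
        mom_scalar = (rho * cdot * M[None] + rho * af * adv
                      + rho * tau[:, None, None] * (
                          rho * cdot * advw + rho * af * advw_adv))
        Jl[:, :, :3, :, :3] += mom_scalar[:, :, None, :, None] \
            * eye[None, None, :, None, :] * Vx[..., None, None]
        # viscous: mu af (Ga.Gb delta_ij + Gb_i Ga_j)
        visc = mu * af * (GG[:, :, None, :, None] * eye[None, None, :, None, :]
                          + np.einsum("ebi,eaj->eaibj", G, G))
        Jl[:, :, :3, :, :3] += visc * Vx[..., None, None]
        # grad-div
        if pa.grad_div:
            tau_c = pa.grad_div / (tau * np.trace(K, axis1=1, axis2=2))
            Jl[:, :, :3, :, :3] += (rho * af * tau_c)[:, None, None, None,
                                                      None] * \
                np.einsum("eai,ebj->eaibj", G, G) * Vx[..., None, None]
        # pressure column in momentum: -(1/4) Ga_i + SUPG tau (v.Ga) Gb_i
        Jl[:, :, :3, :, 3] += (-0.25) * G[:, :, :, None] * Vx[..., None] \
            * np.ones((1, 1, 1, 4))
        supg_p = (rho * tau)[:, None, None, None] * np.einsum(
            "q,eqk,eak,ebi->eaib", w, v_q, G, G, optimize=True)
        Jl[:, :, :3, :, 3] += supg_p * Vx[..., None]
        # continuity rows: d(div)/dv + PSPG
        Jl[:, :, 3, :, :3] += af * 0.25 * G[:, None, :, :] * Vx[..., None] \
            * np.ones((1, 4, 1, 1))
        pspg_v = (tau / rho)[:, None, None, None] * (
            rho * cdot * np.einsum("q,eaj,qb->eabj", w, G, N, optimize=True)
            + rho * af * np.einsum("q,eaj,eqi,ebi->eabj", w, G, v_q, G, optimize=True))
        Jl[:, :, 3, :, :3] += pspg_v * Vx[..., None]
        # continuity wrt pressure: PSPG (tau/rho) Ga.Gb
        Jl[:, :, 3, :, 3] += (tau / rho)[:, None, None] * GG * Vx
        return Jl.reshape(nel, 16, 16)

    # -- global residual / jacobian ---------------------------------------

    def assemble_residual(self, v_np1, p_np1, v_n, vdot_n) -> np.ndarray:
        tets = self.mesh.tets
        cplx = np.iscomplexobj(v_np1) or np.iscomplexobj(p_np1)
        dtype = complex if cplx else float
        Rm_e, Rc_e = self._element_residual(
            v_np1[tets], p_np1[tets], v_n[tets], vdot_n[tets])
        R = np.zeros((self.n, 4), dtype=dtype)
        np.add.at(R[:, :3], tets, Rm_e)
        np.add.at(R[:, 3], tets, Rc_e)

        _, af, _ = self.params.alphas
        v_f = v_n + af * (v_np1 - v_n)
        R[:, :3] += self._backflow_residual(v_f)
        for o in self.outlets.values():
            Q = np.sum(o["b"] * v_f)
            R[:, :3] += o["R"] * Q * o["b"]
        return R.ravel()

    def assemble_jacobian(self, v_np1, p_np1, v_n, vdot_n):
        """Exact tangent by complex-step differentiation of the element
        kernel, plus low-rank resistance couplings [(u, w)] such that
        J_total = J + sum u w^T."""
        tets = self.mesh.tets
        nel = len(tets)
        v_e = v_np1[tets].astype(complex)
        p_e = p_np1[tets].astype(complex)
        v_n_e = v_n[tets]
        vdot_n_e = vdot_n[tets]

        Jloc = np.empty((nel, 16, 16))
        for a in range(4):
            for c in range(4):
                col = 4 * a + c
                if c < 3:
                    v_e[:, a, c] += 1j * _CSTEP
                else:
                    p_e[:, a] += 1j * _CSTEP
                Rm, Rc = self._element_residual(v_e, p_e, v_n_e, vdot_n_e)
                if c < 3:
                    v_e[:, a, c] -= 1j * _CSTEP
                else:
                    p_e[:, a] -= 1j * _CSTEP
                loc = np.concatenate(
                    [Rm.imag, Rc.imag[:, :, None]], axis=2)  # (nel,4,4)
                Jloc[:, :, col] = (loc / _CSTEP).reshape(nel, 16)
        return self._finish_jacobian(Jloc, v_np1, v_n)

    def _finish_jacobian(self, Jloc, v_np1, v_n):
        tets = self.mesh.tets
        nel = len(tets)
        dofs = (4 * tets[:, :, None] + np.arange(4)).reshape(nel, 16)
        rows = np.repeat(dofs, 16, axis=1).ravel()
        cols = np.tile(dofs, (1, 16)).ravel()
        _, af, _ = self.params.alphas
        v_f = v_n + af * (v_np1 - v_n)
        br, bc, bv = self._backflow_jacobian_blocks(v_f)
        if br:
            rows = np.concatenate([rows, np.concatenate(br)])
            cols = np.concatenate([cols, np.concatenate(bc)])
            vals = np.concatenate([Jloc.ravel(), np.concatenate(bv)])
        else:
            vals = Jloc.ravel()
        J = sparse.coo_matrix((vals, (rows, cols)),
                              shape=(self.ndof, self.ndof)).tocsr()
        lowrank = []
        for o in self.outlets.values():
            bvec = np.zeros(self.ndof)
            bvec.reshape(self.n, 4)[:, :3] = o["b"]
            lowrank.append((o["R"] * bvec, af * bvec))
        return J, lowrank

    def _stepping_tangent(self, v_np1, p_np1, v_n, vdot_n):
        """Tangent used for factorization in time stepping."""
        if self.params.picard_tangent:
            Jloc = self._element_jacobian_picard(v_np1[self.mesh.tets])
            return self._finish_jacobian(Jloc, v_np1, v_n)
        return self.assemble_jacobian(v_np1, p_np1, v_n, vdot_n)

    # -- linear solve with Woodbury low-rank correction -------------------

    def _factorize(self, J, lowrank):
        free = self.free_dofs
        Jff = J[free][:, free].tocsc()
        self._lu = splu(Jff)
        self._lu_lowrank = [(u[free], w[free]) for u, w in lowrank]

    def _solve(self, r_free: np.ndarray) -> np.ndarray:
        lu = self._lu
        x = lu.solve(r_free)
        lr = self._lu_lowrank
        if lr:
            k = len(lr)
            U = np.stack([u for u, _ in lr], axis=1)
            W = np.stack([w for _, w in lr], axis=1)
            AinvU = np.stack([lu.solve(U[:, j]) for j in range(k)], axis=1)
            S = np.eye(k) + W.T @ AinvU
            x = x - AinvU @ np.linalg.solve(S, W.T @ x)
        return x

    # -- time stepping -----------------------------------------------------

    def step_generalized_alpha(self, state: FlowState, vdot: np.ndarray,
                               allow_dt_halving: bool = True):
        """Advance one time step; returns (new_state, new_vdot, info)."""
        pa = self.params
        am, af, gam = pa.alphas
        dt = pa.dt
        t_np1 = state.t + dt

        v_n, p_n = state.v, state.p
        v_np1 = v_n.copy()
        p_np1 = p_n.copy()
        self.apply_dirichlet(v_np1, t_np1)

        free = self.free_dofs
        norm0 = None
        converged = False
        iters = 0
        rebuilt = self._lu is None
        if rebuilt:
            J, lr = self._stepping_tangent(v_np1, p_np1, v_n, vdot)
            self._factorize(J, lr)
        it = 0
        it_cap = max(2 * pa.newton_max_iter, 12)
        rounds = 0
        prev_round_norm = None
        while it < it_cap:
            R = self.assemble_residual(v_np1, p_np1, v_n, vdot)
            rf = R[free]
            norm = float(np.linalg.norm(rf))
            if not np.isfinite(norm):
                raise SolverError(f"NaN residual at t={t_np1:.4f}")
            if norm0 is None:
                norm0 = max(norm, 1e-14)
            if norm <= pa.newton_tol * norm0 and it > 0:
                converged = True
                break
            # stale-tangent iterations are much cheaper than a
            # refactorization on large systems: give the reused LU a few
            # extra tries before rebuilding
            if it >= max(pa.newton_max_iter, 7) and not rebuilt:
                J, lr = self._stepping_tangent(v_np1, p_np1, v_n, vdot)
                self._factorize(J, lr)
                rebuilt = True
            dx = self._solve(rf)
            full = np.zeros(self.ndof)
            full[free] = dx
            upd = full.reshape(self.n, 4)
            v_np1 = v_np1 - upd[:, :3]
            p_np1 = p_np1 - upd[:, 3]
            iters = it + 1
            it += 1
            if it == it_cap and rounds < 3:
                # still descending (e.g. a rough interpolated start):
                # refresh the tangent and allow another round
                ref = prev_round_norm if prev_round_norm is not None \
                    else norm0
                if norm < 0.5 * ref:
                    prev_round_norm = norm
                    J, lr = self._stepping_tangent(v_np1, p_np1, v_n,
                                                   vdot)
                    self._factorize(J, lr)
                    it_cap += max(pa.newton_max_iter, 6)
                    rounds += 1
        if not converged:
            if norm <= 10 * pa.newton_tol * norm0:
                pass            # accept a mildly unconverged step
            elif allow_dt_halving:
                sub = SolverParams(**{**self.params.__dict__,
                                      "dt": dt / 2.0})
                saved = self.params
                self.params = sub
                self._lu = None
                try:
                    mid, vdot_mid, _ = self.step_generalized_alpha(
                        state, vdot, allow_dt_halving=False)
                    out, vdot_out, info = self.step_generalized_alpha(
                        mid, vdot_mid, allow_dt_halving=False)
                finally:
                    self.params = saved
                    self._lu = None
                info["halved_dt"] = True
                return out, vdot_out, info
            else:
                raise SolverError(
                    f"Newton diverged at t={t_np1:.4f}: |R|={norm:.3e} "
                    f"(|R0|={norm0:.3e})")
        vdot_np1 = (v_np1 - v_n) / (gam * dt) + (1.0 - 1.0 / gam) * vdot
        self._newton_iters_last = iters
        info = {"iters": iters, "residual": norm, "residual0": norm0,
                "halved_dt": False}
        return FlowState(v_np1, p_np1, t_np1), vdot_np1, info


def run_steady(mesh: Mesh, props: FluidProperties, bcs: BCSet,
               params: SolverParams,
               initial_state: FlowState | None = None) -> FlowField:
    """March the flow to ``t_end`` and report stationarity of the monitors.

    Snapshots are saved every ``save_interval``; per-step monitors include
    the Newton residual and the per-outlet flux and mean pressure.  The
    run is flagged converged when the windowed means of the monitored
    quantities drift by less than 1% between the two halves of the
    averaging window; persistent fluctuations are reported, not
    suppressed.
    """
    solver = NavierStokesSolver(mesh, props, bcs, params)
    n = mesh.n_nodes
    if initial_state is None:
        state = FlowState(np.zeros((n, 3)), np.zeros(n), 0.0)
    else:
        state = initial_state.copy()
    solver.apply_dirichlet(state.v, state.t)
    vdot = np.zeros((n, 3))

    field = FlowField(mesh)
    field.add_snapshot(state)
    next_save = params.save_interval
    nsteps = int(round(params.t_end / params.dt))
    try:
        for k in range(nsteps):
            state, vdot, info = solver.step_generalized_alpha(state, vdot)
            mon = {"t": state.t, "newton_iters": info["iters"],
                   "residual": info["residual"]}
            for tag in bcs.outlet_resistances:
                mon[f"Q_{tag}"] = solver.outlet_flux(state.v, tag)
                mon[f"P_{tag}"] = solver.outlet_pressure(state.p, tag)
            for tag in bcs.inlet_flows:
                mon[f"Q_{tag}"] = solver.inlet_flux(state.v, tag)
            field.log(**mon)
            if state.t >= next_save - 1e-9:
                field.add_snapshot(state)
                next_save += params.save_interval
    except SolverError as exc:
        field.status.update(failed=True, error=str(exc))
        return field

    # stationarity: drift of windowed means between window halves
    t = np.array(field.monitors["t"])
    t0, t1 = params.averaging_window
    t1 = min(t1, t[-1])
    tm = 0.5 * (t0 + t1)
    first = (t >= t0) & (t < tm)
    second = (t >= tm) & (t <= t1)
    drifts = {}
    if first.any() and second.any():
        for key, series in field.monitors.items():
            if not key.startswith(("Q_", "P_")):
                continue
            s = np.array(series)
            m1, m2 = s[first].mean(), s[second].mean()
            scale = max(abs(m1), abs(m2), 1e-12)
            drifts[key] = abs(m2 - m1) / scale
        field.status["drift"] = drifts
        field.status["converged"] = bool(max(drifts.values()) < 0.01) \
            if drifts else False
    field.status["solver"] = solver
    return field


def apply_resistance_bc(mesh: Mesh, tag: str, R: float,
                        v: np.ndarray) -> tuple[np.ndarray, float]:
    """Nodal traction contribution of a resistance outlet, h = -R Q n.

    Returns ``(forces, Q)`` where ``forces[a, i] = R Q \int N_a n_i`` is the
    residual contribution of the outlet (as added to the momentum rows) and
    ``Q`` the discrete outlet flux of ``v``.  At steady state the windowed
    mean outlet pressure satisfies ``P = R Q``.
    """
    b = boundary_flux_vector(mesh, mesh.faces_of(tag))
    Q = float(np.sum(b * v))
    return R * Q * b, Q


def backflow_stabilization(mesh: Mesh, tags, v: np.ndarray,
                           beta: float = 0.2,
                           rho: float = 1.06) -> np.ndarray:
    """Convective inflow-penalty term on nominally outflow faces.

    Active only where ``v . n < 0``; returns the nodal residual
    contribution ``-rho beta (v.n)_- N_a v`` in lumped (nodal-quadrature)
    form.  With no incoming flux the term vanishes identically.
    """
    out = np.zeros_like(v)
    if beta == 0.0:
        return out
    areas, normals = mesh.face_areas_normals()
    fidx = mesh.faces_of(tags)
    faces = mesh.boundary_faces[fidx]
    a, nrm = areas[fidx], normals[fidx]
    for corner in range(3):
        nd = faces[:, corner]
        vn = np.einsum("fi,fi->f", v[nd], nrm)
        coef = -rho * beta * (a / 3.0) * vn * (vn < 0.0)
        np.add.at(out, nd, coef[:, None] * v[nd])
    return out


def transfer_state(src_mesh: Mesh, state: FlowState,
                   dst_mesh: Mesh) -> FlowState:
    """Interpolate a flow state onto another mesh of the same domain.

    Used for mesh sequencing: starting a refined-mesh run from the
    interpolated coarse solution shortens its transient substantially.
    Destination nodes outside the source mesh (boundary roughness
    differences) fall back to zero velocity and the nearest-sample
    pressure.
    """
    from .fem import interpolate_nodal

    pts = dst_mesh.nodes
    v = np.stack([interpolate_nodal(src_mesh, state.v[:, i], pts)
                  for i in range(3)], axis=1)
    p = interpolate_nodal(src_mesh, state.p, pts)
    v[~np.isfinite(v)] = 0.0
    if np.isnan(p).any():
        fill = float(np.nanmean(p)) if np.isfinite(p).any() else 0.0
        p[~np.isfinite(p)] = fill
    return FlowState(v, p, state.t)


def assemble_residual_jacobian(mesh: Mesh, props: FluidProperties,
                               bcs: BCSet, params: SolverParams,
                               state_np1: FlowState, state_n: FlowState,
                               vdot_n: np.ndarray):
    """One-shot residual and tangent of the discrete system.

    Returns ``(R, J, lowrank)`` where the full tangent is
    ``J + sum_k u_k w_k^T`` over the low-rank resistance couplings.
    """
    solver = NavierStokesSolver(mesh, props, bcs, params)
    R = solver.assemble_residual(state_np1.v, state_np1.p,
                                 state_n.v, vdot_n)
    J, lowrank = solver.assemble_jacobian(state_np1.v, state_np1.p,
                                          state_n.v, vdot_n)
    return R, J, lowrank
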