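"""Endpoint post-processing verified on analytic flow fields (no solves)."""

import numpy as np
import pytest

from fontanflow import (FluidProperties, flow_split, low_wss_area_fraction,
                        osi, power_loss,
                        surface_traction_series, tawss, wall_traction)
from fontanflow.endpoints import SurfaceField, _time_average
from fontanflow.solver import FlowField, FlowState

MU = 0.035
R_PIPE = 0.955
L_PIPE = 8.0
Q = 116.67
# Hagen-Poiseuille references for the verification pipe
DP_ANALYTIC = 8 * MU * L_PIPE * Q / (np.pi * R_PIPE ** 4)      # ~100 dyn/cm2
WSS_ANALYTIC = 4 * MU * Q / (np.pi * R_PIPE ** 3)              # ~5.97


def poiseuille_field(mesh, q=Q, n_snaps=2):
    """Analytic developed-flow snapshots on the structured pipe mesh."""
    r2 = mesh.nodes[:, 0] ** 2 + mesh.nodes[:, 1] ** 2
    v = np.zeros((mesh.n_nodes, 3))
    v[:, 2] = 2.0 * q / (np.pi * R_PIPE ** 2) * \
        np.clip(1.0 - r2 / R_PIPE ** 2, 0.0, None)
    dpdz = -8.0 * MU * q / (np.pi * R_PIPE ** 4)
    p = dpdz * (mesh.nodes[:, 2] - L_PIPE)
    field = FlowField(mesh)
    for k in range(n_snaps):
        field.add_snapshot(FlowState(v, p, float(k)))
    return field


@pytest.fixture(scope="module")
def pipe_field(verification_pipe):
    return poiseuille_field(verification_pipe)


class TestWallTraction:
    def test_poiseuille_wall_shear(self, verification_pipe, pipe_field):
        tr = wall_traction(verification_pipe, pipe_field.velocities[0],
                           pipe_field.pressures[0], MU)
        mag = np.linalg.norm(tr, axis=1)
        assert np.median(mag) == pytest.approx(WSS_ANALYTIC, rel=0.10)

    def test_traction_is_tangential(self, verification_pipe, pipe_field):
        face_idx = verification_pipe.faces_of("wall")
        tr = wall_traction(verification_pipe, pipe_field.velocities[0],
                           pipe_field.pressures[0], MU, face_idx)
        _, normals = verification_pipe.face_areas_normals()
        dots = np.einsum("fi,fi->f", tr, normals[face_idx])
        assert np.abs(dots).max() < 1e-10

    def test_hydrostatic_rest_state(self, verification_pipe):
        n = verification_pipe.n_nodes
        tr = wall_traction(verification_pipe, np.zeros((n, 3)),
                           np.full(n, 123.0), MU)
        assert np.abs(tr).max() < 1e-9


class TestTawssOsi:
    def _synthetic_surface(self, tractions, times):
        nf = tractions.shape[1]
        return SurfaceField(
            face_idx=np.arange(nf), areas=np.ones(nf),
            normals=np.tile([0.0, 0.0, 1.0], (nf, 1)),
            tags=np.array(["wall"] * nf), times=np.asarray(times, float),
            tractions=tractions)

    def test_constant_traction(self):
        tau = np.tile([3.0, 4.0, 0.0], (3, 5, 1))
        s = self._synthetic_surface(tau, np.arange(3.0))
        assert tawss(s, (0, 2)) == pytest.approx([5.0] * 5)
        assert osi(s, (0, 2)) == pytest.approx([0.0] * 5)

    def test_perfectly_reversing_traction(self):
        t = np.linspace(0, 1, 41)
        sign = np.where(np.arange(41) % 2 == 0, 1.0, -1.0)
        tau = np.zeros((41, 2, 3))
        tau[:, :, 0] = 2.0 * sign[:, None]
        s = self._synthetic_surface(tau, t)
        # trapezoid average of a +/- alternating series is ~0
        assert np.all(tawss(s, (0, 1)) < 0.2)
        assert osi(s, (0, 1)) == pytest.approx([0.5, 0.5], abs=0.01)

    def test_osi_bounds_and_jensen(self, verification_pipe, pipe_field,
                                   rng):
        surface = surface_traction_series(pipe_field, MU)
        # perturb into a pseudo-transient series
        surface.tractions = surface.tractions * \
            (1.0 + 0.3 * rng.normal(size=surface.tractions.shape))
        o = osi(surface, (0, 1))
        assert np.all((o >= 0.0) & (o <= 0.5))
        ta = tawss(surface, (0, 1))
        mean_mag = _time_average(surface.times,
                                 np.linalg.norm(surface.tractions, axis=2),
                                 (0, 1))
        assert np.all(ta <= mean_mag + 1e-9)

    def test_steady_flow_zero_osi(self, pipe_field):
        surface = surface_traction_series(pipe_field, MU)
        assert np.abs(osi(surface, (0, 1))).max() < 1e-12


class TestLowWss:
    def test_threshold_scaling_with_flow(self, verification_pipe):
        # wall shear ~5.97 at Q: all above the 5 dyn/cm2 threshold;
        # at Q/2 the shear halves and the whole wall is low-WSS
        high = poiseuille_field(verification_pipe, q=Q)
        low = poiseuille_field(verification_pipe, q=Q / 2)
        for field, expected in ((high, 0.0), (low, 100.0)):
            s = surface_traction_series(field, MU)
            frac = low_wss_area_fraction(tawss(s, (0, 1)), s)
            assert frac == pytest.approx(expected, abs=2.0)


class TestIntegralEndpoints:
    def test_pressure_drop_cut_planes(self, verification_pipe, pipe_field):
        from fontanflow.endpoints import plane_average_pressure
        p = pipe_field.pressures[0]
        p_in = plane_average_pressure(verification_pipe, p, 2, 0.5,
                                      0.9 * R_PIPE)
        p_out = plane_average_pressure(verification_pipe, p, 2, L_PIPE - 0.5,
                                       0.9 * R_PIPE)
        expected = DP_ANALYTIC * (L_PIPE - 1.0) / L_PIPE
        assert p_in - p_out == pytest.approx(expected, rel=0.02)

    def test_power_loss_dissipation_identity(self, verification_pipe,
                                             pipe_field):
        """Fully developed flow: loss = dP * Q (kinetic fluxes cancel).

        Q is the discrete flux of the sampled profile, so the identity
        isolates the energy-flux integration from quadrature of the
        analytic parabola.
        """
        from fontanflow.fem import boundary_flux_vector
        props = FluidProperties()
        loss = power_loss(pipe_field, (0, 1), props)
        b = boundary_flux_vector(verification_pipe,
                                 verification_pipe.faces_of("outlet"))
        q_disc = float(np.sum(b * pipe_field.velocities[0]))
        assert loss == pytest.approx(DP_ANALYTIC * q_disc / 1.0e4,
                                     rel=0.01)

    def test_zero_flow_zero_power(self, verification_pipe):
        field = FlowField(verification_pipe)
        n = verification_pipe.n_nodes
        for k in range(2):
            field.add_snapshot(FlowState(np.zeros((n, 3)), np.zeros(n),
                                         float(k)))
        assert power_loss(field, (0, 1), FluidProperties()) == 0.0

    def test_single_outlet_split(self, verification_pipe, pipe_field):
        split = flow_split(pipe_field, (0, 1), outlet_tags=["outlet"])
        assert split["outlet"] == pytest.approx(100.0)

    def test_near_zero_outflow_rejected(self, verification_pipe):
        from fontanflow.solver import FlowField, FlowState
        field = FlowField(verification_pipe)
        n = verification_pipe.n_nodes
        for k in range(2):
            field.add_snapshot(FlowState(np.zeros((n, 3)), np.zeros(n),
                                         float(k)))
        with pytest.raises(ValueError, match="near-zero"):
            flow_split(field, (0, 1), outlet_tags=["outlet"])
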