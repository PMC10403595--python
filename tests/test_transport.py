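"""Dye transport: invariances, conservation, washout-time logic."""

import numpy as np
import pytest

from fontanflow import (MeshSizing, init_dye_cube, make_pipe, mean_washout,
                        solve_advection_diffusion, washout_time)
from fontanflow.mesh import Mesh
from fontanflow.transport import (ScalarSeries, ScalarState, TransportParams,
                                  nodal_volumes)


@pytest.fixture(scope="module")
def transport_pipe():
    """Short pipe with fine axial spacing for front propagation checks."""
    sz = MeshSizing(h_iso=0.2, h_tubing_surface=0.18,
                    h_impeller_surface=0.15, h_strut_surface=0.15,
                    bl_layers_central=1, bl_layers_peripheral=1)
    return make_pipe(0.25, 4.0, sz, axial_spacing=0.08)


@pytest.fixture(scope="module")
def slab_series(transport_pipe):
    """Dye slab advected by a uniform plug flow at 10 cm/s."""
    m = transport_pipe
    v = np.zeros((m.n_nodes, 3))
    v[:, 2] = 10.0
    phi0 = (m.nodes[:, 2] <= 1.5 + 1e-9).astype(float)
    params = TransportParams(dt=0.004, t_end=0.45, save_interval=0.01,
                             kappa=0.001)
    return solve_advection_diffusion(m, v, ScalarState(phi0, 0.0),
                                     params, inlet_tags=("inlet",))


class TestInitDyeCube:
    def test_geometric_bound_and_determinism(self, blank_junction):
        s1 = init_dye_cube(blank_junction, side=3.5)
        s2 = init_dye_cube(blank_junction, side=3.5)
        vol = float(nodal_volumes(blank_junction) @ s1.phi)
        assert vol <= 3.5 ** 3
        assert vol > 5.0          # a junction-center cube is mostly fluid
        assert np.array_equal(s1.phi, s2.phi)

    def test_degenerate_cube_rejected(self, blank_junction):
        with pytest.raises(ValueError):
            init_dye_cube(blank_junction, side=0.0)
        with pytest.raises(ValueError, match="intersect"):
            init_dye_cube(blank_junction, center=(50, 50, 50), side=0.5)


class TestTransportInvariants:
    def test_zero_velocity_keeps_phi(self, transport_pipe):
        m = transport_pipe
        phi0 = (np.abs(m.nodes[:, 2] - 2.0) < 0.5).astype(float)
        params = TransportParams(dt=0.02, t_end=0.2, save_interval=0.05,
                                 kappa=0.0)
        series = solve_advection_diffusion(
            m, np.zeros((m.n_nodes, 3)), ScalarState(phi0, 0.0), params,
            inlet_tags=())
        assert np.abs(series.phis[-1] - phi0).max() < 1e-9

    def test_bounded_overshoot(self, slab_series):
        assert slab_series.overshoot <= 0.05

    def test_mass_conserved_before_outflow(self, slab_series,
                                           transport_pipe):
        """Total dye is conserved while the slab is interior (small kappa)."""
        w = nodal_volumes(transport_pipe)
        masses = [float(w @ phi) for phi in slab_series.phis]
        times = slab_series.times
        # slab front reaches the outlet (z=4) after (4-1.5)/10 = 0.25 s
        early = [m for m, t in zip(masses, times) if t <= 0.2]
        assert abs(early[-1] - early[0]) / early[0] < 0.02

    def test_center_of_mass_advects_at_flow_speed(self, slab_series,
                                                  transport_pipe):
        m = transport_pipe
        w = nodal_volumes(m)
        z = m.nodes[:, 2]

        def com(phi):
            return float((w * phi) @ z / (w @ phi))

        i0 = slab_series.times.index(0.0)
        i1 = min(range(len(slab_series.times)),
                 key=lambda i: abs(slab_series.times[i] - 0.2))
        speed = (com(slab_series.phis[i1]) - com(slab_series.phis[i0])) / \
            (slab_series.times[i1] - slab_series.times[i0])
        assert speed == pytest.approx(10.0, rel=0.02)


class TestWashoutTime:
    def _series_from_curves(self, curves, times):
        """Build a ScalarSeries over a dummy 2-tet mesh from nodal curves."""
        nodes = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1],
                          [1, 1, 1]], dtype=float)
        tets = np.array([[0, 1, 2, 3], [1, 2, 3, 4]])
        from fontanflow.mesh import Mesh, orient_tets
        tets = orient_tets(nodes, tets)
        m = Mesh(nodes, tets, np.empty((0, 3), dtype=int), np.empty(0))
        bf, _ = m.extract_boundary()
        m = Mesh(nodes, tets, bf, np.full(len(bf), "wall"))
        s = ScalarSeries(m)
        for k, t in enumerate(times):
            s.add(ScalarState(np.array([c[k] for c in curves]), t))
        return m, s

    def test_linear_decay_crossing_interpolated(self):
        times = [0.0, 1.0, 2.0]
        # node 0: peak 1 at t=0, linear to 0 at t=2 -> crosses 0.01 at 1.98
        curves = [[1.0, 0.5, 0.0],
                  [0.0, 0.0, 0.0],          # never dyed: undefined
                  [1.0, 1.0, 1.0],          # never decays: censored
                  [0.5, 1.0, 0.0],          # peak at t=1
                  [1.0, 0.004, 0.0]]        # crosses within first interval
        m, s = self._series_from_curves(curves, times)
        with pytest.warns(UserWarning, match="censored"):
            wf = washout_time(s)
        assert wf.T[0] == pytest.approx(1.98, abs=1e-9)
        assert not wf.defined[1]
        assert wf.censored[2] and wf.defined[2]
        assert wf.t_max[3] == 1.0
        assert wf.T[3] == pytest.approx(0.99, abs=1e-9)
        assert wf.T[4] == pytest.approx(1.0 * (1 - 0.01) / (1 - 0.004),
                                        abs=1e-6)

    def test_halving_threshold_never_decreases_t(self, slab_series):
        wf1 = washout_time(slab_series, threshold=0.01)
        wf2 = washout_time(slab_series, threshold=0.005)
        both = wf1.defined & ~wf1.censored & ~wf2.censored
        assert np.all(wf2.T[both] >= wf1.T[both] - 1e-12)

    def test_mean_of_uniform_field(self):
        times = [0.0, 1.0, 2.0]
        curves = [[1.0, 0.5, 0.0]] * 5
        m, s = self._series_from_curves(curves, times)
        wf = washout_time(s)
        out = mean_washout(wf, m)
        assert out["mean_washout_s"] == pytest.approx(1.98)
        assert out["censored_fraction"] == 0.0

    def test_all_censored_errors(self):
        times = [0.0, 1.0]
        curves = [[1.0, 1.0]] * 5
        m, s = self._series_from_curves(curves, times)
        with pytest.warns(UserWarning):
            wf = washout_time(s)
        with pytest.raises(ValueError, match="censored"):
            mean_washout(wf, m)
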