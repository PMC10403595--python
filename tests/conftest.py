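"""Shared fixtures: small meshes built once per session."""

import numpy as np
import pytest

from fontanflow import GeometrySpec, MeshSizing, make_junction, make_pipe


@pytest.fixture(scope="session")
def coarse_sizing():
    return MeshSizing(h_iso=0.5, h_tubing_surface=0.4,
                      h_impeller_surface=0.35, h_strut_surface=0.35,
                      bl_layers_central=1, bl_layers_peripheral=1)


@pytest.fixture(scope="session")
def tiny_pipe(coarse_sizing):
    """~50-node pipe for algebraic checks (Jacobians, kernels)."""
    return make_pipe(0.5, 1.5, MeshSizing(
        h_iso=0.5, h_tubing_surface=0.45, h_impeller_surface=0.4,
        h_strut_surface=0.4, bl_layers_central=1, bl_layers_peripheral=1))


@pytest.fixture(scope="session")
def verification_pipe():
    """Pipe with the test-section tube radius, wall-refined."""
    sz = MeshSizing(h_iso=0.35, h_tubing_surface=0.22,
                    h_impeller_surface=0.2, h_strut_surface=0.2,
                    bl_layers_central=1, bl_layers_peripheral=2)
    return make_pipe(0.955, 8.0, sz)


@pytest.fixture(scope="session")
def desk_sizing():
    return MeshSizing.desk_scale()


@pytest.fixture(scope="session")
def blank_junction(desk_sizing):
    """Blank-housing cruciform junction at desk-scale sizing."""
    return make_junction(GeometrySpec(), desk_sizing, seed=0)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
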