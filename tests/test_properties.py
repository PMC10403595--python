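"""Property-based checks of the pure post-processing functions."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fontanflow import bland_altman, osi, tawss
from fontanflow.endpoints import SurfaceField

settings.register_profile("ci", deadline=None, derandomize=True,
                          max_examples=40)
settings.load_profile("ci")

finite = st.floats(min_value=-1e3, max_value=1e3, allow_nan=False)


def _surface(tractions):
    nt, nf, _ = tractions.shape
    return SurfaceField(face_idx=np.arange(nf), areas=np.ones(nf),
                        normals=np.tile([0.0, 0.0, 1.0], (nf, 1)),
                        tags=np.array(["wall"] * nf),
                        times=np.linspace(0.0, 1.0, nt),
                        tractions=tractions)


@given(st.lists(finite, min_size=2, max_size=20), finite)
def test_bland_altman_constant_offset_recovered(ref, c):
    """sim = ref + c gives mean difference c and zero-width limits."""
    ref = np.asarray(ref)
    t = bland_altman(ref + c, ref)
    assert t.mean_difference == pytest.approx(c, abs=1e-9)
    assert t.sd_difference == pytest.approx(0.0, abs=1e-9)


@given(st.lists(st.tuples(finite, finite), min_size=2, max_size=20))
def test_bland_altman_antisymmetry(pairs):
    """Swapping sim and ref negates differences and mirrors the limits."""
    sim = np.array([p[0] for p in pairs])
    ref = np.array([p[1] for p in pairs])
    a = bland_altman(sim, ref)
    b = bland_altman(ref, sim)
    assert a.mean_difference == pytest.approx(-b.mean_difference, abs=1e-9)
    assert a.loa_upper == pytest.approx(-b.loa_lower, abs=1e-9)


@given(st.integers(min_value=2, max_value=12),
       st.integers(min_value=3, max_value=15),
       st.integers(min_value=0, max_value=2 ** 31 - 1))
def test_osi_bounds_and_tawss_jensen(nf, nt, seed):
    """OSI stays in [0, 1/2]; TAWSS never exceeds the mean |traction|."""
    rng = np.random.default_rng(seed)
    tr = rng.normal(scale=5.0, size=(nt, nf, 3))
    s = _surface(tr)
    o = osi(s, (0.0, 1.0))
    assert np.all((o >= 0.0) & (o <= 0.5))
    ta = tawss(s, (0.0, 1.0))
    mean_mag = np.trapezoid(np.linalg.norm(tr, axis=2), s.times, axis=0)
    assert np.all(ta <= mean_mag + 1e-9)
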