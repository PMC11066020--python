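"""Wall shear stress estimation and derived indices (TAWSS, OSI, RRT)."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from bulbflow import geometry, synthetic as syn, wall
from bulbflow.core import FluidProperties
from bulbflow.errors import EmptyRegionError
from bulbflow.wall import WallScalarField, WallShearSeries
from tests.conftest import steady_waveform


def make_series(vectors, period=1.0, areas=None):
    """WallShearSeries from an explicit (F, M, 3) vector array."""
    vectors = np.asarray(vectors, dtype=float)
    F, M, _ = vectors.shape
    return WallShearSeries(
        face_indices=np.arange(M),
        vectors=vectors,
        areas=np.ones(M) if areas is None else np.asarray(areas, dtype=float),
        frame_times=np.arange(F) * period / F,
        period=period,
        valid=np.ones(M, dtype=bool),
    )


class FakeROI:
    def __init__(self, faces):
        self.face_indices = np.asarray(faces)


class TestComputeWSS:
    def test_poiseuille_oracle(self, tube_mesh, steady_field, fluid):
        wss = wall.compute_wss(steady_field, tube_mesh, fluid)
        ta = wall.tawss(wss)
        exact = 4 * fluid.viscosity * 6.0 / (np.pi * 0.3 ** 3)
        assert np.abs(ta.values[ta.valid] / exact - 1).max() < 0.05

    def test_zero_field_zero_wss(self, tube_mesh, steady_field, fluid):
        import dataclasses

        zero = dataclasses.replace(steady_field, values=np.zeros_like(steady_field.values))
        wss = wall.compute_wss(zero, tube_mesh, fluid)
        assert np.abs(wss.vectors).max() == 0.0

    def test_linear_shear_exact(self, fluid):
        """A linear near-wall profile v_t = k delta is recovered exactly."""
        m = syn.make_tube_mesh(syn.TubeSpec(radius=0.3, length=2.0, n_axial=12,
                                            n_radial=6, n_circumferential=24))
        k = 50.0   # s^-1
        r = np.hypot(m.vertices[:, 0], m.vertices[:, 1])
        speed = k * (0.3 - r)
        values = np.zeros((8, len(m.vertices), 3))
        values[:, :, 2] = speed
        import bulbflow.core as core

        f = core.VelocityField(frame_times=np.arange(8) * 0.1, values=values, period=0.9)
        wss = wall.compute_wss(f, m, fluid)
        mags = np.linalg.norm(wss.vectors[0][wss.valid], axis=1)
        assert mags == pytest.approx(fluid.viscosity * k, rel=0.02)

    def test_shear_rate_is_wss_over_mu(self, tube_mesh, steady_field, fluid):
        wss = wall.compute_wss(steady_field, tube_mesh, fluid)
        gamma = wall.shear_rate(wss, fluid)
        ta = wall.tawss(wss)
        assert np.allclose(gamma.values * fluid.viscosity, ta.values, rtol=1e-12)


class TestTAWSS:
    def test_constant(self):
        v = np.zeros((8, 3, 3))
        v[:, :, 0] = 2.5
        ta = wall.tawss(make_series(v))
        assert np.allclose(ta.values, 2.5)

    def test_rectified_cosine(self):
        F = 256
        t = np.arange(F) / F
        v = np.zeros((F, 1, 3))
        v[:, 0, 0] = 3.0 * np.cos(2 * np.pi * t)
        ta = wall.tawss(make_series(v))
        assert ta.values[0] == pytest.approx(2 * 3.0 / np.pi, rel=1e-3)

    def test_quadrature_error_shrinks(self):
        def err(F):
            t = np.arange(F) / F
            v = np.zeros((F, 1, 3))
            v[:, 0, 0] = np.cos(2 * np.pi * t)
            return abs(wall.tawss(make_series(v)).values[0] - 2 / np.pi)

        assert err(64) < err(16)


class TestOSI:
    def test_unidirectional_zero(self):
        F = 32
        v = np.zeros((F, 2, 3))
        v[:, :, 1] = 1.0 + 0.8 * np.sin(2 * np.pi * np.arange(F) / F)[:, None]
        assert np.all(wall.osi(make_series(v)).values == 0.0)

    def test_full_reversal_half(self):
        F = 64
        v = np.zeros((F, 1, 3))
        v[:, 0, 0] = np.sin(2 * np.pi * np.arange(F) / F)
        assert wall.osi(make_series(v)).values[0] == pytest.approx(0.5, abs=1e-9)

    def test_biased_sinusoid_closed_form(self):
        # tau(t) = (1 + 2 cos) e: OSI = 0.5 (1 - 1/(1/3 + 2 sqrt(3)/pi))
        F = 512
        v = np.zeros((F, 1, 3))
        v[:, 0, 2] = 1.0 + 2.0 * np.cos(2 * np.pi * np.arange(F) / F)
        expected = 0.5 * (1 - 1 / (1 / 3 + 2 * np.sqrt(3) / np.pi))
        assert wall.osi(make_series(v)).values[0] == pytest.approx(expected, abs=1e-4)

    def test_zero_field_defined_zero(self):
        v = np.zeros((16, 2, 3))
        assert np.all(wall.osi(make_series(v)).values == 0.0)

    @given(st.integers(min_value=0, max_value=10_000))
    def test_bounds_for_random_series(self, seed):
        rng = np.random.default_rng(seed)
        v = rng.normal(size=(12, 5, 3))
        vals = wall.osi(make_series(v)).values
        assert np.all((vals >= 0.0) & (vals <= 0.5))


class TestRRT:
    def test_formula(self):
        ta = WallScalarField(np.arange(2), np.array([2.0, 1.0]), np.ones(2), "tawss",
                             np.ones(2, dtype=bool))
        os_ = WallScalarField(np.arange(2), np.array([0.0, 0.25]), np.ones(2), "osi",
                              np.ones(2, dtype=bool))
        r = wall.rrt(ta, os_)
        assert r.values[0] == pytest.approx(0.5)
        assert r.values[1] == pytest.approx(2.0)

    def test_unbounded_sentinel(self):
        ta = WallScalarField(np.arange(2), np.array([2.0, 0.0]), np.ones(2), "tawss",
                             np.ones(2, dtype=bool))
        os_ = WallScalarField(np.arange(2), np.array([0.5, 0.1]), np.ones(2), "osi",
                              np.ones(2, dtype=bool))
        r = wall.rrt(ta, os_)
        assert not r.valid[0] and not r.valid[1]
        assert np.isinf(r.values[0])


class TestAreaFractions:
    def field(self, values, areas=None):
        values = np.asarray(values, dtype=float)
        return WallScalarField(
            np.arange(len(values)), values,
            np.ones(len(values)) if areas is None else np.asarray(areas, float),
            "shear_rate", np.ones(len(values), dtype=bool),
        )

    def test_low_shear_trivials(self):
        roi = FakeROI([0, 1])
        assert wall.low_shear_area_pct(self.field([5.0, 5.0]), roi, 10.0) == 100.0
        assert wall.low_shear_area_pct(self.field([20.0, 20.0]), roi, 10.0) == 0.0
        assert wall.low_shear_area_pct(self.field([5.0, 20.0]), roi, 10.0) == 50.0

    def test_strict_inequality_at_boundary(self):
        roi = FakeROI([0])
        assert wall.low_shear_area_pct(self.field([10.0]), roi, 10.0) == 0.0
        assert wall.high_osi_area_pct(self.field([0.38]), roi, 0.38) == 0.0

    def test_area_weighting(self):
        roi = FakeROI([0, 1])
        f = self.field([5.0, 20.0], areas=[3.0, 1.0])
        assert wall.low_shear_area_pct(f, roi, 10.0) == 75.0

    def test_high_osi_trivials(self):
        roi = FakeROI([0, 1])
        assert wall.high_osi_area_pct(self.field([0.0, 0.0]), roi, 0.1) == 0.0
        assert wall.high_osi_area_pct(self.field([0.5, 0.5]), roi, 0.38) == 100.0

    @given(st.lists(st.floats(min_value=0, max_value=100), min_size=3, max_size=12))
    def test_monotone_in_threshold(self, values):
        roi = FakeROI(list(range(len(values))))
        f = self.field(values)
        pcts = [wall.low_shear_area_pct(f, roi, thr) for thr in (1, 5, 10, 50)]
        assert all(a <= b for a, b in zip(pcts, pcts[1:]))
        osis = [wall.high_osi_area_pct(f, roi, thr) for thr in (1, 5, 10, 50)]
        assert all(a >= b for a, b in zip(osis, osis[1:]))

    def test_empty_roi_rejected(self):
        with pytest.raises(EmptyRegionError):
            wall.low_shear_area_pct(self.field([1.0]), FakeROI([]), 10.0)
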