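"""Domain types, unit conventions and file round-trips."""

import numpy as np
import pytest

import bulbflow.io as bfio
from bulbflow import mmhg_to_cgs, cgs_to_mmhg
from bulbflow.core import FlowWaveform, FluidProperties, SubjectVitals, VelocityField
from bulbflow.errors import (
    MeshFormatError,
    OrderError,
    ParameterError,
    SizeError,
    TopologyError,
    UnsupportedCellError,
)
from bulbflow import synthetic as syn
from hypothesis import given, strategies as st


class TestUnits:
    def test_conversion_constant(self):
        assert mmhg_to_cgs(1.0) == 1333.22
        assert mmhg_to_cgs(0.0) == 0.0
        # Table-1-scale MAP in CGS
        assert mmhg_to_cgs(91.4) == pytest.approx(121856.3, abs=0.1)

    @given(st.floats(min_value=1e-3, max_value=1e3))
    def test_round_trip_identity(self, p):
        assert cgs_to_mmhg(mmhg_to_cgs(p)) == pytest.approx(p, rel=1e-12)


class TestTypes:
    def test_fluid_positive(self):
        with pytest.raises(ParameterError):
            FluidProperties(viscosity=-0.1)

    def test_vitals_ordering(self):
        with pytest.raises(ParameterError):
            SubjectVitals(systolic=70, diastolic=80, heart_rate=60, stroke_volume=70)

    def test_pulse_pressure_derived(self):
        v = SubjectVitals(systolic=126.9, diastolic=73.6, heart_rate=67,
                          stroke_volume=70, group_label="caw", event_label=True)
        assert v.pulse_pressure == pytest.approx(53.3)

    def test_waveform_contracts(self):
        with pytest.raises(SizeError):
            FlowWaveform(times=[0, 0.1, 0.2], flows=[1, 2, 3], period=0.9)
        with pytest.raises(ParameterError):
            FlowWaveform(times=[0, 0.2, 0.1, 0.3], flows=[1, 2, 3, 4], period=0.9)
        wf = FlowWaveform(times=[0, 0.2, 0.4, 0.6], flows=[2, 4, 4, 2], period=0.8)
        # periodic interpolation wraps around
        assert wf(0.8) == wf(0.0)

    def test_velocity_field_uniform_spacing(self):
        with pytest.raises(ParameterError):
            VelocityField(
                frame_times=np.array([0, 0.1, 0.25, 0.3, 0.4, 0.5, 0.6, 0.7]),
                values=np.zeros((8, 4, 3)),
                period=0.9,
            )


class TestMeshIO:
    def test_round_trip_exact(self, small_tube_mesh, tmp_path):
        p = tmp_path / "m.vtk"
        bfio.write_mesh(small_tube_mesh, p)
        m2 = bfio.read_mesh(p)
        assert np.array_equal(m2.vertices, small_tube_mesh.vertices)
        assert len(m2.tetrahedra) == len(small_tube_mesh.tetrahedra)
        assert len(m2.boundary.triangles) == len(small_tube_mesh.boundary.triangles)
        assert sorted(set(m2.boundary.face_labels)) == sorted(
            set(small_tube_mesh.boundary.face_labels)
        )

    def test_field_round_trip(self, small_tube_mesh, waveform, tmp_path):
        f = syn.sample_parabolic_field(small_tube_mesh, waveform, 20)
        p = tmp_path / "f.vtk"
        bfio.write_field(small_tube_mesh, f, p)
        _, f2 = bfio.read_field(p)
        assert np.array_equal(f2.values, f.values)
        assert f2.period == f.period

    def test_deterministic_bytes(self, small_tube_mesh, waveform, tmp_path):
        f = syn.sample_parabolic_field(small_tube_mesh, waveform, 20)
        p1, p2 = tmp_path / "a.vtk", tmp_path / "b.vtk"
        bfio.write_mesh(small_tube_mesh, p1, field=f)
        bfio.write_mesh(small_tube_mesh, p2, field=f)
        assert p1.read_bytes() == p2.read_bytes()

    def test_pyramid_cell_rejected(self, tmp_path):
        p = tmp_path / "bad.vtk"
        p.write_text(
            "# vtk DataFile Version 3.0\nbad\nASCII\nDATASET UNSTRUCTURED_GRID\n"
            "POINTS 5 double\n0 0 0\n1 0 0\n1 1 0\n0 1 0\n0.5 0.5 1\n"
            "CELLS 1 6\n5 0 1 2 3 4\nCELL_TYPES 1\n14\n"
        )
        with pytest.raises(UnsupportedCellError):
            bfio.read_mesh(p)

    def test_parse_error_names_line(self, tmp_path):
        p = tmp_path / "trunc.vtk"
        p.write_text(
            "# vtk DataFile Version 3.0\nbad\nASCII\nDATASET UNSTRUCTURED_GRID\n"
            "POINTS 4 double\n0 0 0\n1 0 0\n"
        )
        with pytest.raises(MeshFormatError, match="line"):
            bfio.read_mesh(p)

    def test_stl_round_trip_and_unmatched_vertex(self, small_tube_mesh, tmp_path):
        vol, stl, lab = tmp_path / "v.vtk", tmp_path / "s.stl", tmp_path / "l.csv"
        bfio.write_mesh(small_tube_mesh, vol)
        bfio.write_surface_stl(small_tube_mesh.boundary, stl, lab)
        m2 = bfio.read_mesh_with_stl(vol, stl, lab)
        assert len(m2.boundary.triangles) == len(small_tube_mesh.boundary.triangles)
        # perturb one surface vertex beyond the matching tolerance
        txt = stl.read_text().splitlines()
        for i, line in enumerate(txt):
            if line.strip().startswith("vertex"):
                parts = line.split()
                parts[1] = str(float(parts[1]) + 1e-3)
                txt[i] = " ".join(parts)
                break
        stl.write_text("\n".join(txt))
        with pytest.raises(TopologyError):
            bfio.read_mesh_with_stl(vol, stl, lab)


class TestWaveformIO:
    def test_round_trip_and_shift(self, tmp_path):
        p = tmp_path / "w.csv"
        p.write_text(
            "time_s,flow_mL_s\n0.1,5\n0.2,8\n0.3,6\n0.4,5\n"
        )
        wf = bfio.read_waveform(p, period=0.9)
        assert wf.times[0] == 0.0
        assert wf.flows[1] == 8.0

    def test_duplicate_time_rejected(self, tmp_path):
        p = tmp_path / "w.csv"
        p.write_text("time_s,flow_mL_s\n0,5\n0.1,8\n0.1,6\n0.2,5\n")
        with pytest.raises(OrderError):
            bfio.read_waveform(p, period=0.9)

    def test_too_few_rows(self, tmp_path):
        p = tmp_path / "w.csv"
        p.write_text("time_s,flow_mL_s\n0,5\n0.1,8\n")
        with pytest.raises(SizeError):
            bfio.read_waveform(p, period=0.9)


class TestVitalsIO:
    def test_round_trip(self, tmp_path):
        v = SubjectVitals(systolic=120, diastolic=80, heart_rate=65,
                          stroke_volume=72, group_label="atherosclerosis")
        p = tmp_path / "v.yaml"
        bfio.write_vitals(v, p)
        v2 = bfio.read_vitals(p)
        assert v2 == v
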