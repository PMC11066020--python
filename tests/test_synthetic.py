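"""Synthetic flow generator: meshes, fields, pockets, cohorts."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from bulbflow import geometry, synthetic as syn, volumetric
from bulbflow.core import FlowWaveform
from bulbflow.errors import GeometryError, ParameterError
from tests.conftest import steady_waveform


class TestWaveform:
    def test_postconditions(self, waveform):
        assert waveform.mean_flow == pytest.approx(6.0, rel=0.005)
        assert waveform.peak_flow == pytest.approx(18.0, rel=0.005)
        assert waveform.flows.min() > 0

    def test_near_flat_limit(self):
        wf = syn.make_carotid_waveform(0.9, 6.0, 6.01, 40)
        assert wf.flows.min() > 0
        assert wf.peak_flow == pytest.approx(6.01, rel=1e-9)
        assert np.ptp(wf.flows) <= 2 * (6.01 - 6.0)   # near-flat

    def test_peak_below_mean_rejected(self):
        with pytest.raises(ParameterError):
            syn.make_carotid_waveform(0.9, 6.0, 5.0, 40)

    @given(
        mean=st.floats(min_value=2.0, max_value=12.0),
        ratio=st.floats(min_value=1.3, max_value=3.0),
    )
    def test_mean_and_peak_met_across_parameters(self, mean, ratio):
        wf = syn.make_carotid_waveform(0.9, mean, mean * ratio, 50)
        assert wf.mean_flow == pytest.approx(mean, rel=0.005)
        assert wf.peak_flow == pytest.approx(mean * ratio, rel=0.005)


class TestTubeMesh:
    def test_volume_and_inlet_area(self, tube_mesh):
        assert tube_mesh.total_volume == pytest.approx(np.pi * 0.09 * 3.0, rel=0.02)
        inlet = tube_mesh.boundary.faces_with_label("inlet")
        assert tube_mesh.boundary.face_areas[inlet].sum() == pytest.approx(
            np.pi * 0.09, rel=0.02
        )

    def test_refinement_halves_volume_error(self):
        def err(nc):
            m = syn.make_tube_mesh(
                syn.TubeSpec(radius=0.3, length=3.0, n_circumferential=nc)
            )
            return abs(m.total_volume / (np.pi * 0.09 * 3.0) - 1)

        assert err(64) <= 0.5 * err(32)

    def test_labels_partition_boundary(self, tube_mesh):
        labels = set(tube_mesh.boundary.face_labels)
        assert labels == {"wall", "inlet", "outlet_ica"}

    def test_resolution_invariant(self):
        with pytest.raises(ParameterError):
            syn.TubeSpec(n_radial=3)


class TestBifurcationMesh:
    def test_no_web_min_radius(self):
        m = syn.make_bifurcation_mesh(syn.BifurcationSpec())
        cl = geometry.extract_centerline(m)
        after = cl.local_radius[cl.bifurcation_index + 2:]
        # ICA branch radius holds its nominal value within mesh tolerance
        assert after.min() == pytest.approx(0.24, rel=0.05)

    def test_web_reduces_min_diameter(self):
        web = syn.WebSpec(narrowing_fraction=0.3, shelf_axial_position=1.2)
        m = syn.make_bifurcation_mesh(syn.BifurcationSpec(web=web, n_axial=40))
        cl = geometry.extract_centerline(m)
        after = cl.local_radius[cl.bifurcation_index + 2:]
        assert after.min() == pytest.approx(0.7 * 0.24, rel=0.05)

    def test_web_outside_branch_rejected(self):
        with pytest.raises(ParameterError):
            syn.make_bifurcation_mesh(
                syn.BifurcationSpec(
                    web=syn.WebSpec(narrowing_fraction=0.3, shelf_axial_position=5.0)
                )
            )


class TestParabolicField:
    def test_flux_conservation_every_frame(self, tube_mesh, waveform):
        f = syn.sample_parabolic_field(tube_mesh, waveform, 20)
        for k in range(0, 20, 4):
            q = syn.inlet_flux(tube_mesh, f, k)
            assert q == pytest.approx(waveform(f.frame_times[k]), rel=0.02)

    def test_no_slip_exact(self, tube_mesh, steady_field):
        wall_faces = tube_mesh.boundary.faces_with_label("wall")
        wall_verts = tube_mesh.boundary_vertex_map[
            np.unique(tube_mesh.boundary.triangles[wall_faces])
        ]
        assert np.abs(steady_field.values[:, wall_verts, :]).max() == 0.0

    def test_centerline_peak_speed(self, tube_mesh):
        q_peak = 10.0
        f = syn.sample_parabolic_field(tube_mesh, steady_waveform(q_peak), 20)
        axis_vertex = int(np.argmin(np.linalg.norm(tube_mesh.vertices[:, :2], axis=1)
                                    + np.abs(tube_mesh.vertices[:, 2] - 1.5)))
        speed = np.linalg.norm(f.values[0, axis_vertex])
        assert speed == pytest.approx(2 * q_peak / (np.pi * 0.09), rel=1e-6)

    def test_requires_axis_metadata(self, tube_mesh, waveform):
        from bulbflow.errors import UnsupportedGeometryError
        import dataclasses

        bare = dataclasses.replace(tube_mesh, axis_info=None)
        with pytest.raises(UnsupportedGeometryError):
            syn.sample_parabolic_field(bare, waveform, 20)


@pytest.fixture(scope="module")
def cohort_tube():
    spec = syn.TubeSpec(radius=0.25, length=3.0, n_axial=16, n_radial=4,
                        n_circumferential=16, wall_grading=1.0)
    mesh = syn.make_tube_mesh(spec)
    wf = syn.make_carotid_waveform(0.9, 8.0, 20.0, 40)
    return mesh, syn.sample_parabolic_field(mesh, wf, 20)


class TestRecirculationPocket:

    def test_dwell_frame_rounding(self):
        assert syn.dwell_frame_count(0.3, 20) == 6
        assert syn.dwell_frame_count(0.325, 20) == 7   # ties toward more frames
        assert syn.dwell_frame_count(1.0, 20) == 20
        assert syn.dwell_frame_count(0.0, 20) == 0

    def test_dwell_one_below_cap_everywhere(self, cohort_tube):
        mesh, f = cohort_tube
        spec = syn.RecirculationSpec(pocket_center=(0, 0, 1.5), pocket_radius=0.15,
                                     peak_speed=2.5, dwell_fraction=1.0)
        out = syn.add_recirculation_pocket(f, mesh, spec)
        d = np.linalg.norm(mesh.vertices - np.array([0, 0, 1.5]), axis=1)
        mask = d < 0.15
        speeds = np.linalg.norm(out.values[:, mask, :], axis=2)
        assert speeds.max() < 2.5

    def test_dwell_fraction_counts_frames(self, cohort_tube):
        mesh, f = cohort_tube
        spec = syn.RecirculationSpec(pocket_center=(0, 0, 1.5), pocket_radius=0.15,
                                     peak_speed=2.5, dwell_fraction=0.3)
        out = syn.add_recirculation_pocket(f, mesh, spec)
        d = np.linalg.norm(mesh.vertices - np.array([0, 0, 1.5]), axis=1)
        mask = d < 0.15
        max_speed = np.linalg.norm(out.values[:, mask, :], axis=2).max(axis=1)
        assert int((max_speed < 2.5).sum()) == 6

    def test_outside_field_unchanged(self, cohort_tube):
        mesh, f = cohort_tube
        spec = syn.RecirculationSpec(pocket_center=(0, 0, 1.5), pocket_radius=0.15,
                                     peak_speed=2.5, dwell_fraction=0.5)
        out = syn.add_recirculation_pocket(f, mesh, spec)
        d = np.linalg.norm(mesh.vertices - np.array([0, 0, 1.5]), axis=1)
        outside = d >= 0.15
        assert np.array_equal(out.values[:, outside, :], f.values[:, outside, :])

    def test_pocket_outside_mesh_rejected(self, cohort_tube):
        mesh, f = cohort_tube
        with pytest.raises(GeometryError):
            syn.add_recirculation_pocket(
                f, mesh,
                syn.RecirculationSpec(pocket_center=(2.0, 0, 1.5),
                                      pocket_radius=0.1, peak_speed=2.5,
                                      dwell_fraction=0.5),
            )
        with pytest.raises(GeometryError):
            syn.add_recirculation_pocket(
                f, mesh,
                syn.RecirculationSpec(pocket_center=(0.2, 0, 1.5),
                                      pocket_radius=0.1, peak_speed=2.5,
                                      dwell_fraction=0.5),
            )


class TestCohort:
    def test_seeded_determinism(self):
        spec = syn.CohortSpec(seed=7, n_caw=2, n_atherosclerosis=2, n_normal=2)
        a = syn.make_cohort(spec)
        b = syn.make_cohort(spec)
        for sa, sb in zip(a, b):
            assert sa.subject_id == sb.subject_id
            assert sa.vitals == sb.vitals
            assert np.array_equal(sa.mesh.vertices, sb.mesh.vertices)
            assert np.array_equal(sa.field.values, sb.field.values)

    def test_group_sizes_and_labels(self):
        subs = syn.make_cohort(syn.CohortSpec(seed=1))
        groups = [s.group for s in subs]
        assert groups.count("caw") == 13
        assert groups.count("atherosclerosis") == 7
        assert groups.count("normal") == 6
        assert all(s.vitals.event_label == (s.group == "caw") for s in subs)

    def test_dwell_recovery_across_cohorts(self):
        """Programmed group-mean dwell is recovered by the volumetric
        pipeline within 2 standard errors over repeated cohorts."""
        from bulbflow import pipeline

        recovered = {"caw": [], "atherosclerosis": [], "normal": []}
        programmed = {"caw": [], "atherosclerosis": [], "normal": []}
        for seed in range(6):
            spec = syn.CohortSpec(seed=seed, n_caw=3, n_atherosclerosis=3, n_normal=3)
            subs = syn.make_cohort(spec)
            for s in subs:
                res = pipeline.analyze_subject(
                    s, pipeline.PipelineConfig(), compute_wall_metrics=False
                )
                curve = res.curves[3.0]
                recovered[s.group].append(volumetric.stasis_pct(curve) / 100.0)
                programmed[s.group].append(s.info["dwell_fraction"])
        for g in recovered:
            rec, prog = np.array(recovered[g]), np.array(programmed[g])
            se = rec.std(ddof=1) / np.sqrt(len(rec)) + 1.0 / 20  # + frame quantum
            assert abs(rec.mean() - prog.mean()) < 2 * se + 1.0 / 20

    def test_write_read_cohort(self, tmp_path):
        spec = syn.CohortSpec(seed=3, n_caw=1, n_atherosclerosis=1, n_normal=1)
        subs = syn.make_cohort(spec)
        syn.write_cohort(subs, tmp_path, seed=3)
        loaded, failures = syn.read_cohort(tmp_path)
        assert not failures
        assert [s.subject_id for s in loaded] == [s.subject_id for s in subs]
        assert np.array_equal(loaded[0].field.values, subs[0].field.values)
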