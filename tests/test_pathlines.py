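"""Pathline tracing accuracy and blood-pool containment grading."""

import numpy as np
import pytest

from pc4dflow import EmitterSpec, grade_containment, trace_pathlines
from pc4dflow.errors import GeometryError, ParameterError
from pc4dflow.fields import VelocityField4D
from pc4dflow.pathlines import PathlineSet

from conftest import make_rotation_field


def uniform_flow_field(v0, shape=(16, 16, 16), h=2.0):
    origin = -(np.array(shape) - 1) / 2.0 * h
    vel = np.zeros((3, 2) + shape)
    for c in range(3):
        vel[c] = v0[c]
    return VelocityField4D(
        velocity=vel, magnitude=np.full((2,) + shape, 100.0),
        voxel_size=[h] * 3, origin=origin,
        trigger_times_ms=[0.0, 500.0], cycle_ms=1000.0, venc=1e6,
    )


class TestTracePathlines:
    def test_constant_field_translation_exact(self):
        # v = (10, 0, 0) mm/s for 100 ms -> displacement (1, 0, 0) mm; RK4 is
        # exact on constant fields.
        field = uniform_flow_field([10.0, 0.0, 0.0])
        em = EmitterSpec(position=(0.0, 0.0, 0.0), release_interval_ms=2000.0)
        paths = trace_pathlines(field, [em], step_ms=1.0, t_end_ms=100.0,
                                record_every_ms=100.0)
        disp = paths.positions[0, -1] - paths.positions[0, 0]
        assert np.allclose(disp, [1.0, 0.0, 0.0], atol=1e-12)

    def test_rigid_rotation_closes_orbit(self):
        # omega = 2 pi rad/s about z: one cycle returns to start; radius drift
        # stays at RK4 rounding level.
        field = make_rotation_field()
        r0 = 10.0
        em = EmitterSpec(position=(r0, 0.0, 0.0), release_interval_ms=2000.0)
        paths = trace_pathlines(field, [em], step_ms=1.0, t_end_ms=1000.0,
                                record_every_ms=10.0)
        start = paths.positions[0, 0]
        end = paths.positions[0, -1]
        assert np.linalg.norm(end - start) < 1e-6 * r0
        radii = np.linalg.norm(paths.positions[0, :, :2], axis=1)
        assert np.abs(radii - r0).max() < 1e-6 * r0

    def test_fourth_order_convergence(self):
        field = make_rotation_field()
        start = np.array([10.0, 0.0, 0.0])
        em = EmitterSpec(position=tuple(start), release_interval_ms=2000.0)
        errs = []
        for step in (8.0, 4.0, 2.0):
            p = trace_pathlines(field, [em], step_ms=step, t_end_ms=1000.0,
                                record_every_ms=1000.0)
            errs.append(np.linalg.norm(p.positions[0, -1] - start))
        orders = [np.log2(errs[i] / errs[i + 1]) for i in range(2)]
        for order in orders:
            assert order == pytest.approx(4.0, abs=0.3)

    def test_time_reversal(self):
        # Forward one half-turn then backward (negated field) returns to start.
        field = make_rotation_field()
        em = EmitterSpec(position=(10.0, 0.0, 0.0), release_interval_ms=2000.0)
        fwd = trace_pathlines(field, [em], step_ms=1.0, t_end_ms=500.0,
                              record_every_ms=500.0)
        mid = fwd.positions[0, -1]
        back_field = field.copy()
        back_field.velocity = -back_field.velocity
        em2 = EmitterSpec(position=tuple(mid), release_interval_ms=2000.0)
        bwd = trace_pathlines(back_field, [em2], step_ms=1.0, t_end_ms=500.0,
                              record_every_ms=500.0)
        assert np.linalg.norm(bwd.positions[0, -1] - [10.0, 0.0, 0.0]) < 2e-6 * 10.0

    def test_particles_leaving_volume_frozen_and_flagged(self):
        field = uniform_flow_field([1000.0, 0.0, 0.0], shape=(8, 8, 8))
        em = EmitterSpec(position=(0.0, 0.0, 0.0), release_interval_ms=2000.0)
        paths = trace_pathlines(field, [em], step_ms=1.0, t_end_ms=1000.0,
                                record_every_ms=10.0)
        assert paths.left_volume[0]
        final = paths.positions[0, -1]
        assert np.all(np.isfinite(final))
        lo = field.origin
        hi = field.origin + (np.array(field.grid_shape) - 1) * field.voxel_size
        assert np.all(final >= lo) and np.all(final <= hi)

    def test_emitter_outside_volume_rejected(self):
        field = uniform_flow_field([10.0, 0.0, 0.0], shape=(8, 8, 8))
        with pytest.raises(GeometryError):
            trace_pathlines(field, [EmitterSpec(position=(500.0, 0.0, 0.0))])

    def test_deterministic_with_sphere_emitters(self):
        field = make_rotation_field()
        em = EmitterSpec(position=(8.0, 0.0, 0.0), release_interval_ms=100.0,
                         particles_per_release=3, radius_mm=2.0)
        p1 = trace_pathlines(field, [em], step_ms=2.0, seed=5)
        p2 = trace_pathlines(field, [em], step_ms=2.0, seed=5)
        assert np.array_equal(p1.positions, p2.positions, equal_nan=True)


class TestGradeContainment:
    def _grade(self, paths, mask):
        return grade_containment(paths, mask)

    def test_closed_recirculation_grades_ideal(self):
        # All particles orbit inside a generous pool: every emitter grade 0.
        field = make_rotation_field()
        ems = [
            EmitterSpec(position=(6.0, 0.0, 0.0), label="a"),
            EmitterSpec(position=(0.0, 8.0, 0.0), label="b"),
            EmitterSpec(position=(-10.0, 0.0, 0.0), label="c"),
            EmitterSpec(position=(0.0, -5.0, 0.0), label="d"),
        ]
        paths = trace_pathlines(field, ems, step_ms=2.0)
        mask = np.ones(field.grid_shape, bool)
        report = grade_containment(paths, mask)
        assert np.all(report.grades == 0)
        assert report.mean_score == 0.0
        assert np.all(report.fraction_escaped == 0.0)

    def test_uniform_outflow_grades_unusable(self):
        # Field points uniformly out of the pool: all particles escape, grade 3.
        field = uniform_flow_field([500.0, 0.0, 0.0])
        em = EmitterSpec(position=(0.0, 0.0, 0.0), release_interval_ms=100.0)
        paths = trace_pathlines(field, [em], step_ms=1.0)
        mask = np.zeros(field.grid_shape, bool)
        mask[7:9, 7:9, 7:9] = True  # small pool around the emitter
        report = grade_containment(paths, mask)
        assert report.grades[0] == 3
        assert report.fraction_escaped[0] == 1.0

    def test_mean_score_is_emitter_mean(self):
        # grades 0, 1, 1, 1 -> mean quality score 0.75
        positions = np.zeros((40, 2, 3))
        emitter_ids = np.repeat(np.arange(4), 10)
        escaped_particles = [10, 20, 30]  # one escape (10%) in emitters 1..3
        for p in escaped_particles:
            positions[p, 1] = [100.0, 0.0, 0.0]  # outside the mask
        paths = PathlineSet(
            positions=positions,
            record_times_ms=np.array([0.0, 10.0]),
            release_times_ms=np.zeros(40),
            emitter_ids=emitter_ids,
            emitter_labels=["lv", "rv", "la", "ra"],
            left_volume=np.zeros(40, bool),
            grid_origin=np.array([-10.0, -10.0, -10.0]),
            grid_voxel_size=np.array([1.0, 1.0, 1.0]),
            grid_shape=(21, 21, 21),
        )
        mask = np.ones((21, 21, 21), bool)
        report = grade_containment(paths, mask, thresholds=(0.15, 0.5))
        assert list(report.grades) == [0, 1, 1, 1]
        assert report.mean_score == pytest.approx(0.75)

    def test_grading_monotone_in_escapes(self):
        # Adding escaped particles never lowers the grade.
        rng = np.random.default_rng(0)
        base = np.zeros((20, 2, 3))
        grades = []
        for n_escaped in (0, 1, 4, 10, 20):
            positions = base.copy()
            positions[:n_escaped, 1] = [500.0, 0.0, 0.0]
            paths = PathlineSet(
                positions=positions,
                record_times_ms=np.array([0.0, 10.0]),
                release_times_ms=np.zeros(20),
                emitter_ids=np.zeros(20, int),
                emitter_labels=["lv"],
                left_volume=np.zeros(20, bool),
                grid_origin=np.array([-10.0, -10.0, -10.0]),
                grid_voxel_size=np.array([1.0, 1.0, 1.0]),
                grid_shape=(21, 21, 21),
            )
            report = grade_containment(paths, np.ones((21, 21, 21), bool))
            grades.append(report.grades[0])
        assert all(g2 >= g1 for g1, g2 in zip(grades, grades[1:]))
        assert grades[0] == 0 and grades[-1] == 3

    def test_empty_mask_rejected(self):
        field = make_rotation_field()
        em = EmitterSpec(position=(5.0, 0.0, 0.0), release_interval_ms=500.0)
        paths = trace_pathlines(field, [em], step_ms=5.0)
        with pytest.raises(ParameterError):
            grade_containment(paths, np.zeros(field.grid_shape, bool))
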