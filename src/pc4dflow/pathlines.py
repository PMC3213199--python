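"""Time-resolved particle tracing and blood-pool containment grading.

Pathlines integrate x'(t) = v(x, t) through the time-varying velocity field
with a fixed-step classical Runge-Kutta (RK4) scheme, trilinear interpolation
in space and linear interpolation in time (periodic over the cardiac cycle
for full-coverage data; truncated data clamp to the last frame). Particles
are released from emitters at fixed intervals over the cycle, the convention
used for intra-cardiac flow visualization, and data quality is graded 0-3
per emitter from the fraction of particles that ever leave the blood pool:

    0 ideal (none escape), 1 few, 2 moderate, 3 large amount / unusable.

The verbal scale is operationalized by configurable escape-fraction
thresholds (defaults 0 / 5% / 20%); the mean quality score is the unweighted
mean of the emitter grades.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import map_coordinates

from .errors import GeometryError, ParameterError
from .fields import VelocityField4D

#: Escape-fraction upper bounds for grades 1 and 2 (grade 0 requires zero
#: escapes; anything above the grade-2 bound is grade 3). Declared
#: configuration: the underlying scale is a human reading.
DEFAULT_GRADE_THRESHOLDS = (0.05, 0.20)


@dataclass
class EmitterSpec:
    """A timed particle source.

    Particles are released every ``release_interval_ms`` (default 10 ms, the
    standard release cadence over the full cycle), ``particles_per_release``
    at a time, uniformly distributed in a sphere of ``radius_mm`` around
    ``position`` (all at the center when the radius is 0).
    """

    position: tuple[float, float, float]
    label: str = "emitter"
    release_interval_ms: float = 10.0
    particles_per_release: int = 1
    radius_mm: float = 0.0

    def __post_init__(self) -> None:
        if not self.release_interval_ms > 0:
            raise ParameterError("release_interval_ms must be positive")
        if self.radius_mm < 0:
            raise ParameterError("radius_mm must be nonnegative")
        if self.particles_per_release < 1:
            raise ParameterError("particles_per_release must be >= 1")


@dataclass
class PathlineSet:
    """Traced particle trajectories plus containment bookkeeping.

    ``positions[p, k]`` is particle p's position (mm) at ``record_times_ms[k]``,
    NaN before the particle's release; particles that leave the volume are
    frozen at their exit position and flagged in ``left_volume``.
    """

    positions: np.ndarray  # (P, K, 3) mm
    record_times_ms: np.ndarray  # (K,)
    release_times_ms: np.ndarray  # (P,)
    emitter_ids: np.ndarray  # (P,) int
    emitter_labels: list[str]
    left_volume: np.ndarray  # (P,) bool
    grid_origin: np.ndarray
    grid_voxel_size: np.ndarray
    grid_shape: tuple[int, int, int]
    inside_pool: np.ndarray | None = None  # (P, K) bool, filled by grading

    @property
    def n_particles(self) -> int:
        return self.positions.shape[0]


@dataclass
class ContainmentReport:
    """Per-emitter escape statistics and 0-3 grades."""

    emitter_labels: list[str]
    n_particles: np.ndarray
    fraction_escaped: np.ndarray
    grades: np.ndarray
    mean_score: float
    thresholds: tuple[float, float] = DEFAULT_GRADE_THRESHOLDS

    def to_dict(self) -> dict:
        return {
            "emitters": [
                {
                    "label": lab,
                    "n_particles": int(n),
                    "fraction_escaped": float(f),
                    "grade": int(g),
                }
                for lab, n, f, g in zip(
                    self.emitter_labels, self.n_particles,
                    self.fraction_escaped, self.grades,
                )
            ],
            "mean_score": float(self.mean_score),
            "grade_thresholds": list(self.thresholds),
        }


def _sample_velocity(field: VelocityField4D, pos_mm: np.ndarray, t_ms: float) -> np.ndarray:
    """Velocity (mm/s) at positions (N, 3) and time t, shape (N, 3).

    Linear in time (periodic for full coverage, clamped for truncated),
    trilinear in space; zero outside the volume.
    """
    times = field.trigger_times_ms
    nt = field.n_frames
    if field.coverage == "full":
        t = t_ms % field.cycle_ms
        if t < times[0]:
            t = t + field.cycle_ms
        k0 = int(np.searchsorted(times, t, side="right") - 1)
        if k0 >= nt - 1 and t >= times[-1]:
            k1 = 0
            dt_seg = field.cycle_ms - times[-1] + times[0]
            w = (t - times[-1]) / dt_seg
            k0 = nt - 1
        else:
            k1 = k0 + 1
            w = (t - times[k0]) / (times[k1] - times[k0])
    else:
        t = np.clip(t_ms, times[0], times[-1])
        k0 = min(int(np.searchsorted(times, t, side="right") - 1), nt - 2)
        k1 = k0 + 1
        w = (t - times[k0]) / (times[k1] - times[k0])

    idx = ((pos_mm - field.origin) / field.voxel_size).T  # (3, N)
    out = np.empty((pos_mm.shape[0], 3))
    for c in range(3):
        v0 = map_coordinates(field.velocity[c, k0], idx, order=1,
                             mode="constant", cval=0.0, prefilter=False)
        v1 = map_coordinates(field.velocity[c, k1], idx, order=1,
                             mode="constant", cval=0.0, prefilter=False)
        out[:, c] = (1.0 - w) * v0 + w * v1
    return out


def trace_pathlines(
    field: VelocityField4D,
    emitters: list[EmitterSpec],
    step_ms: float = 1.0,
    t_end_ms: float | None = None,
    record_every_ms: float | None = None,
    seed: int = 0,
) -> PathlineSet:
    """Advect particles from timed emitters through the 4D field.

    Releases run over the covered cycle; every particle is integrated by
    fixed-step RK4 from its release time to ``t_end_ms`` (default: one cycle).
    Positions are recorded every ``record_every_ms`` (default: the release
    interval granularity, 10 ms, or ``step_ms`` if larger). Deterministic for
    given inputs and seed.
    """
    if not step_ms > 0:
        raise ParameterError("step_ms must be positive")
    if not emitters:
        raise ParameterError("at least one emitter is required")
    if t_end_ms is None:
        t_end_ms = field.cycle_ms
    if record_every_ms is None:
        record_every_ms = max(step_ms, 10.0)
    record_stride = max(int(round(record_every_ms / step_ms)), 1)

    # Velocity is defined on the voxel-center hull; beyond it interpolation
    # has no data, so leaving the hull counts as leaving the volume.
    lo = field.origin
    hi = field.origin + (np.array(field.grid_shape) - 1) * field.voxel_size

    if field.coverage == "truncated":
        warnings.warn(
            "tracing through a truncated-coverage field: velocities are "
            "clamped to the last frame beyond the covered window",
            stacklevel=2,
        )

    rng = np.random.default_rng(seed)
    positions0, release_times, emitter_ids = [], [], []
    for e_id, em in enumerate(emitters):
        center = np.asarray(em.position, dtype=float)
        if np.any(center < lo) or np.any(center > hi):
            raise GeometryError(
                f"emitter {em.label!r} at {center.tolist()} lies outside the volume"
            )
        releases = np.arange(0.0, field.covered_ms, em.release_interval_ms)
        # Align releases to the integration grid to keep steps uniform.
        releases = np.round(releases / step_ms) * step_ms
        for t_rel in releases:
            if em.radius_mm > 0:
                offs = rng.normal(size=(em.particles_per_release, 3))
                offs /= np.linalg.norm(offs, axis=1, keepdims=True)
                offs *= em.radius_mm * rng.uniform(size=(em.particles_per_release, 1)) ** (1 / 3)
                pts = center[None, :] + offs
            else:
                pts = np.repeat(center[None, :], em.particles_per_release, axis=0)
            for p in pts:
                positions0.append(p)
                release_times.append(t_rel)
                emitter_ids.append(e_id)

    pos = np.array(positions0)  # (P, 3)
    release_times = np.array(release_times)
    emitter_ids = np.array(emitter_ids, dtype=int)
    P = pos.shape[0]

    n_steps = int(round(t_end_ms / step_ms))
    record_idx = np.arange(0, n_steps + 1, record_stride)
    record_times = record_idx * step_ms
    K = len(record_times)
    out = np.full((P, K, 3), np.nan)
    left_volume = np.zeros(P, dtype=bool)

    released = np.zeros(P, dtype=bool)
    dt_s = step_ms / 1000.0
    rec_ptr = 0
    for step in range(n_steps + 1):
        t = step * step_ms
        released |= release_times <= t + 1e-9
        if rec_ptr < K and step == record_idx[rec_ptr]:
            out[released, rec_ptr] = pos[released]
            rec_ptr += 1
        if step == n_steps:
            break
        active = released & ~left_volume
        if active.any():
            p = pos[active]
            k1 = _sample_velocity(field, p, t)
            k2 = _sample_velocity(field, p + 0.5 * dt_s * k1, t + 0.5 * step_ms)
            k3 = _sample_velocity(field, p + 0.5 * dt_s * k2, t + 0.5 * step_ms)
            k4 = _sample_velocity(field, p + dt_s * k3, t + step_ms)
            p_new = p + dt_s / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
            outside = np.any((p_new < lo) | (p_new > hi), axis=1)
            # Freeze leavers at their last in-volume position.
            p_next = np.where(outside[:, None], p, p_new)
            pos[active] = p_next
            idx_active = np.flatnonzero(active)
            left_volume[idx_active[outside]] = True

    return PathlineSet(
        positions=out,
        record_times_ms=record_times,
        release_times_ms=release_times,
        emitter_ids=emitter_ids,
        emitter_labels=[em.label for em in emitters],
        left_volume=left_volume,
        grid_origin=field.origin.copy(),
        grid_voxel_size=field.voxel_size.copy(),
        grid_shape=field.grid_shape,
    )


def grade_containment(
    paths: PathlineSet,
    blood_pool_mask: np.ndarray,
    thresholds: tuple[float, float] = DEFAULT_GRADE_THRESHOLDS,
) -> ContainmentReport:
    """Per-emitter escape fractions and 0-3 grades from blood-pool containment.

    A particle counts as escaped if any recorded sample after its release
    falls outside the mask (nearest-voxel lookup; leaving the volume counts
    as escape). Escape is sticky: re-entering the pool does not un-escape a
    particle. Grade 0 requires zero escapes; fractions up to the first /
    second threshold give grades 1 / 2; larger fractions grade 3. The mean
    score is the unweighted mean over emitters.
    """
    mask = np.asarray(blood_pool_mask, dtype=bool)
    if mask.shape != tuple(paths.grid_shape):
        raise GeometryError(
            f"mask shape {mask.shape} does not match grid {paths.grid_shape}"
        )
    if not mask.any():
        raise ParameterError("blood-pool mask is empty")
    t1, t2 = thresholds
    if not 0 < t1 < t2:
        raise ParameterError("grade thresholds must satisfy 0 < t1 < t2")

    P, K, _ = paths.positions.shape
    valid_sample = ~np.isnan(paths.positions[..., 0])
    ii = np.round((paths.positions - paths.grid_origin) / paths.grid_voxel_size)
    inside = np.zeros((P, K), dtype=bool)
    in_grid = valid_sample & np.all(
        (ii >= 0) & (ii < np.array(paths.grid_shape)), axis=-1
    )
    if in_grid.any():
        flat = ii[in_grid].astype(int)
        inside[in_grid] = mask[flat[:, 0], flat[:, 1], flat[:, 2]]
    # Pre-release samples do not count against containment.
    escaped = np.any(valid_sample & ~inside, axis=1) | paths.left_volume

    n_emitters = len(paths.emitter_labels)
    n_particles = np.zeros(n_emitters, dtype=int)
    frac = np.zeros(n_emitters)
    grades = np.zeros(n_emitters, dtype=int)
    for e in range(n_emitters):
        sel = paths.emitter_ids == e
        n_particles[e] = sel.sum()
        frac[e] = escaped[sel].mean() if sel.any() else 0.0
        if frac[e] == 0:
            grades[e] = 0
        elif frac[e] <= t1:
            grades[e] = 1
        elif frac[e] <= t2:
            grades[e] = 2
        else:
            grades[e] = 3

    paths.inside_pool = inside & valid_sample
    return ContainmentReport(
        emitter_labels=list(paths.emitter_labels),
        n_particles=n_particles,
        fraction_escaped=frac,
        grades=grades,
        mean_score=float(grades.mean()),
        thresholds=thresholds,
    )
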