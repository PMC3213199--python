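import numpy as np
import pytest

from pc4dflow import PhantomSpec, generate_phantom, reformat_plane
from pc4dflow.fields import PlaneDefinition, VelocityField4D
from pc4dflow.flowquant import VesselContour

#: Oblique tube axis used across tests (not aligned with any grid axis).
OBLIQUE_AXIS = np.array([0.25, 0.15, 1.0]) / np.linalg.norm([0.25, 0.15, 1.0])


@pytest.fixture(scope="session")
def oblique_axis():
    return OBLIQUE_AXIS.copy()


@pytest.fixture(scope="session")
def phantom_noise_free(oblique_axis):
    """Default-geometry noise-free pulsatile phantom with an oblique tube."""
    spec = PhantomSpec(tube_axis=tuple(oblique_axis))
    field, truth = generate_phantom(spec)
    return spec, field, truth


@pytest.fixture(scope="session")
def tube_plane(oblique_axis):
    """Reformat plane perpendicular to the oblique tube, 1.5 mm pixels."""
    return PlaneDefinition.from_normal(
        origin=(0.0, 0.0, 0.0), normal=tuple(oblique_axis),
        pixel_size=1.5, extent=(41, 41),
    )


@pytest.fixture(scope="session")
def tube_series(phantom_noise_free, tube_plane):
    _, field, _ = phantom_noise_free
    return reformat_plane(field, tube_plane)


def make_disc_contour(radius_mm: float, n_vertices: int = 100) -> VesselContour:
    """Circular ROI centered on the plane origin."""
    th = np.linspace(0, 2 * np.pi, n_vertices, endpoint=False)
    verts = np.column_stack([radius_mm * np.cos(th), radius_mm * np.sin(th)])
    return VesselContour(polygons=[verts])


def make_rotation_field(
    omega_rad_s: float = 2 * np.pi,
    n: int = 21,
    nz: int = 5,
    h: float = 2.0,
) -> VelocityField4D:
    """Steady rigid-rotation field about the z axis (closed recirculation).

    v = omega x r with omega along +z; trajectories are circles, so this is
    the analytic benchmark for pathline accuracy and for fully contained flow.
    """
    origin = -(np.array([n, n, nz]) - 1) / 2.0 * h
    x = origin[0] + np.arange(n) * h
    y = origin[1] + np.arange(n) * h
    X, Y = np.meshgrid(x, y, indexing="ij")
    vel = np.zeros((3, 2, n, n, nz))
    vel[0] = (-omega_rad_s * Y)[None, :, :, None]
    vel[1] = (omega_rad_s * X)[None, :, :, None]
    return VelocityField4D(
        velocity=vel,
        magnitude=np.full((2, n, n, nz), 100.0),
        voxel_size=[h, h, h],
        origin=origin,
        trigger_times_ms=[0.0, 500.0],
        cycle_ms=1000.0,
        venc=1e6,
    )
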