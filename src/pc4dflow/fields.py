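"""Core in-memory containers for 4D phase-contrast flow data.

Coordinate convention (stated in every metadata file written by :mod:`pc4dflow.io`):
right-handed Cartesian axes, millimetres, voxel centers at
``origin + index * voxel_size`` with 0-based indices; time in milliseconds from
the R-wave. Velocities are stored in mm/s (phase has already been converted via
``v = (phi / pi) * VENC``).
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Literal

import numpy as np

from .errors import FormatError, GeometryError, TimingError

Coverage = Literal["full", "truncated"]
Stage = Literal["wrapped", "unwrapped"]

#: Human-readable statement of the geometry convention, embedded in metadata.
COORDINATE_CONVENTION = (
    "right-handed, millimetres, voxel centers at origin + index*voxel_size, "
    "0-based indices; time in ms from R-wave; velocity in mm/s"
)


@dataclass
class VelocityField4D:
    """Time-resolved, three-directionally velocity-encoded volume.

    Attributes
    ----------
    velocity : ndarray, shape (3, nt, nx, ny, nz)
        Cartesian velocity components in mm/s (axis 0 is x, y, z component).
    magnitude : ndarray, shape (nt, nx, ny, nz)
        Magnitude (modulus) image in arbitrary units.
    voxel_size : ndarray, shape (3,)
        Voxel edge lengths in mm.
    origin : ndarray, shape (3,)
        World position (mm) of the center of voxel (0, 0, 0).
    trigger_times_ms : ndarray, shape (nt,)
        Time of each frame after the R-wave; strictly increasing, < cycle_ms.
    cycle_ms : float
        Cardiac cycle length (RR interval).
    venc : float
        Velocity-encoding limit in mm/s; stored (wrapped) velocities lie in
        [-venc, venc).
    coverage : {"full", "truncated"}
        Whether the frames span the whole cycle or a prospectively gated
        (late-diastole-truncated) window.
    covered_ms : float
        Temporal window the frames represent: ``cycle_ms`` for full coverage,
        the retained window for truncated data.
    stage : {"wrapped", "unwrapped"}
        Processing-stage tag: wrapped data obey |v| <= venc, unwrapped data
        are unbounded.
    notes : dict
        Free-form processing reports (not persisted by the writers).
    """

    velocity: np.ndarray
    magnitude: np.ndarray
    voxel_size: np.ndarray
    origin: np.ndarray
    trigger_times_ms: np.ndarray
    cycle_ms: float
    venc: float
    coverage: Coverage = "full"
    covered_ms: float | None = None
    stage: Stage = "wrapped"
    notes: dict = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        self.velocity = np.asarray(self.velocity, dtype=float)
        self.magnitude = np.asarray(self.magnitude, dtype=float)
        self.voxel_size = np.asarray(self.voxel_size, dtype=float).reshape(3)
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.trigger_times_ms = np.asarray(self.trigger_times_ms, dtype=float)
        if self.covered_ms is None:
            self.covered_ms = float(self.cycle_ms)
        self.validate()

    # -- validation ----------------------------------------------------------
    def validate(self) -> None:
        if self.velocity.ndim != 5 or self.velocity.shape[0] != 3:
            raise FormatError(
                f"velocity must have shape (3, nt, nx, ny, nz), got {self.velocity.shape}"
            )
        if self.magnitude.shape != self.velocity.shape[1:]:
            raise FormatError(
                f"magnitude shape {self.magnitude.shape} does not match velocity "
                f"frames {self.velocity.shape[1:]}"
            )
        nt = self.velocity.shape[1]
        if nt < 2:
            raise TimingError(f"need at least 2 frames, got {nt}")
        if self.trigger_times_ms.shape != (nt,):
            raise TimingError(
                f"trigger_times_ms has {self.trigger_times_ms.size} entries for {nt} frames"
            )
        if np.any(np.diff(self.trigger_times_ms) <= 0):
            raise TimingError("trigger_times_ms must be strictly increasing")
        if np.any(self.trigger_times_ms >= self.cycle_ms):
            raise TimingError("all trigger times must be < cycle_ms")
        if not self.venc > 0:
            raise FormatError(f"venc must be positive, got {self.venc}")
        if np.any(self.voxel_size <= 0):
            raise FormatError(f"voxel_size must be positive, got {self.voxel_size}")

    # -- geometry helpers ----------------------------------------------------
    @property
    def n_frames(self) -> int:
        return self.velocity.shape[1]

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.velocity.shape[2:]

    def voxel_centers(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """World coordinates (mm) of voxel centers, as three broadcastable axes."""
        nx, ny, nz = self.grid_shape
        x = self.origin[0] + np.arange(nx) * self.voxel_size[0]
        y = self.origin[1] + np.arange(ny) * self.voxel_size[1]
        z = self.origin[2] + np.arange(nz) * self.voxel_size[2]
        return x[:, None, None], y[None, :, None], z[None, None, :]

    def world_to_index(self, points_mm: np.ndarray) -> np.ndarray:
        """Continuous (fractional) voxel indices for world points (..., 3)."""
        return (np.asarray(points_mm, dtype=float) - self.origin) / self.voxel_size

    def copy(self) -> "VelocityField4D":
        return VelocityField4D(
            velocity=self.velocity.copy(),
            magnitude=self.magnitude.copy(),
            voxel_size=self.voxel_size.copy(),
            origin=self.origin.copy(),
            trigger_times_ms=self.trigger_times_ms.copy(),
            cycle_ms=float(self.cycle_ms),
            venc=float(self.venc),
            coverage=self.coverage,
            covered_ms=float(self.covered_ms),
            stage=self.stage,
            notes=dict(self.notes),
        )


@dataclass
class PlaneDefinition:
    """An oriented, uniformly sampled 2D plane through the volume.

    Pixel (iu, iv) lies at ``origin + (iu - (nu-1)/2)*pixel_size*u
    + (iv - (nv-1)/2)*pixel_size*v``, i.e. the plane is centered on ``origin``.
    ``(u, v, normal)`` must form a right-handed orthonormal triad.
    """

    origin: np.ndarray
    normal: np.ndarray
    in_plane_u: np.ndarray
    in_plane_v: np.ndarray
    pixel_size: float
    extent: tuple[int, int]

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.normal = np.asarray(self.normal, dtype=float).reshape(3)
        self.in_plane_u = np.asarray(self.in_plane_u, dtype=float).reshape(3)
        self.in_plane_v = np.asarray(self.in_plane_v, dtype=float).reshape(3)
        self.extent = (int(self.extent[0]), int(self.extent[1]))
        self.validate()

    def validate(self) -> None:
        tol = 1e-12
        triad = np.stack([self.in_plane_u, self.in_plane_v, self.normal])
        gram = triad @ triad.T
        if not np.allclose(gram, np.eye(3), atol=tol):
            raise GeometryError("(u, v, normal) must be orthonormal to 1e-12")
        if not np.allclose(np.cross(self.in_plane_u, self.in_plane_v), self.normal, atol=tol):
            raise GeometryError("(u, v, normal) must be right-handed (u x v = normal)")
        if self.extent[0] < 2 or self.extent[1] < 2:
            raise GeometryError(f"plane extent must be at least 2x2, got {self.extent}")
        if not self.pixel_size > 0:
            raise GeometryError(f"pixel_size must be positive, got {self.pixel_size}")

    @classmethod
    def from_normal(
        cls,
        origin,
        normal,
        pixel_size: float,
        extent: tuple[int, int],
    ) -> "PlaneDefinition":
        """Build a plane from origin + normal, choosing in-plane axes deterministically.

        ``u`` is the unit projection of the world axis least aligned with the
        normal; ``v = normal x u``.
        """
        n = np.asarray(normal, dtype=float)
        n = n / np.linalg.norm(n)
        seed_axis = np.eye(3)[np.argmin(np.abs(n))]
        u = seed_axis - n * (seed_axis @ n)
        u = u / np.linalg.norm(u)
        v = np.cross(n, u)
        return cls(origin=origin, normal=n, in_plane_u=u, in_plane_v=v,
                   pixel_size=float(pixel_size), extent=extent)

    def pixel_coords_mm(self) -> tuple[np.ndarray, np.ndarray]:
        """In-plane pixel-center coordinates (u_mm, v_mm), each shape (nu, nv)."""
        nu, nv = self.extent
        iu = (np.arange(nu) - (nu - 1) / 2.0) * self.pixel_size
        iv = (np.arange(nv) - (nv - 1) / 2.0) * self.pixel_size
        return np.broadcast_arrays(iu[:, None], iv[None, :])

    def pixel_positions(self) -> np.ndarray:
        """World positions (mm) of all pixel centers, shape (nu, nv, 3)."""
        u_mm, v_mm = self.pixel_coords_mm()
        return (
            self.origin[None, None, :]
            + u_mm[..., None] * self.in_plane_u[None, None, :]
            + v_mm[..., None] * self.in_plane_v[None, None, :]
        )

    def to_dict(self) -> dict:
        return {
            "origin": self.origin.tolist(),
            "normal": self.normal.tolist(),
            "in_plane_u": self.in_plane_u.tolist(),
            "in_plane_v": self.in_plane_v.tolist(),
            "pixel_size": float(self.pixel_size),
            "extent": list(self.extent),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PlaneDefinition":
        return cls(
            origin=d["origin"],
            normal=d["normal"],
            in_plane_u=d["in_plane_u"],
            in_plane_v=d["in_plane_v"],
            pixel_size=d["pixel_size"],
            extent=tuple(d["extent"]),
        )


@dataclass
class Series2D:
    """A 2D through-plane velocity series (acquired or reformatted).

    ``v_through`` holds the velocity component along the plane normal per frame
    and pixel; pixels outside the source volume are NaN and flagged invalid.
    """

    v_through: np.ndarray  # (nt, nu, nv) mm/s
    magnitude: np.ndarray  # (nt, nu, nv)
    valid: np.ndarray  # (nu, nv) bool
    plane: PlaneDefinition
    trigger_times_ms: np.ndarray
    cycle_ms: float
    venc: float
    coverage: Coverage = "full"
    covered_ms: float | None = None

    def __post_init__(self) -> None:
        self.v_through = np.asarray(self.v_through, dtype=float)
        self.magnitude = np.asarray(self.magnitude, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        self.trigger_times_ms = np.asarray(self.trigger_times_ms, dtype=float)
        if self.covered_ms is None:
            self.covered_ms = float(self.cycle_ms)
        if self.v_through.ndim != 3:
            raise FormatError(f"v_through must be (nt, nu, nv), got {self.v_through.shape}")
        if self.v_through.shape[0] < 2:
            raise TimingError("Series2D needs at least 2 frames")
        if self.v_through.shape[1:] != tuple(self.plane.extent):
            raise FormatError("v_through spatial shape does not match plane extent")
        if self.magnitude.shape != self.v_through.shape:
            raise FormatError("magnitude shape does not match v_through")
        if self.valid.shape != self.v_through.shape[1:]:
            raise FormatError("valid-mask shape does not match plane extent")
        if np.any(np.diff(self.trigger_times_ms) <= 0):
            raise TimingError("trigger_times_ms must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.v_through.shape[0]

    @property
    def pixel_size(self) -> float:
        return self.plane.pixel_size


@dataclass
class FlowCurve:
    """Volumetric flow (ml/s) through one vessel ROI per cardiac phase."""

    time_ms: np.ndarray
    flow_ml_s: np.ndarray
    stroke_volume_ml: float
    peak_flow_ml_s: float
    coverage: Coverage = "full"
    covered_ms: float | None = None
    vessel_label: str = "other"

    def __post_init__(self) -> None:
        self.time_ms = np.asarray(self.time_ms, dtype=float)
        self.flow_ml_s = np.asarray(self.flow_ml_s, dtype=float)
        if self.time_ms.shape != self.flow_ml_s.shape:
            raise FormatError("time_ms and flow_ml_s must have equal length")
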