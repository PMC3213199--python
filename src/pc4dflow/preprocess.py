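"""Background phase correction and velocity unwrapping.

Eddy currents leave a slowly varying spurious velocity offset across the
field of view. It is modeled here, per velocity component, as a first-order
polynomial c0 + c1*x + c2*y + c3*z fitted by least squares to the
time-averaged velocity of static tissue; subtracting the fitted field removes
the offset everywhere (offsets are assumed time-stationary).

Velocities beyond the encoding limit alias by multiples of 2*VENC. Unwrapping
is temporal and per-voxel: each voxel's time series is rewound starting from
its frame of minimum |velocity| (assumed alias-free, since flow is near zero
in diastole) and 2*VENC multiples are added wherever a frame-to-frame jump
exceeds VENC. This recovers the true series whenever true frame-to-frame
jumps stay below VENC; no spatial unwrapping is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import CorrectionError
from .fields import VelocityField4D


@dataclass
class BackgroundModel:
    """First-order background velocity model per Cartesian component.

    ``coefficients[c] = (c0, c1, c2, c3)``: offset (mm/s) and gradients
    (mm/s per mm) for component ``c``; evaluates to c0 + c1*x + c2*y + c3*z.
    """

    coefficients: np.ndarray  # (3, 4)
    static_mask_used: np.ndarray
    fit_residual_rms: float

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float).reshape(3, 4)
        if not np.all(np.isfinite(self.coefficients)):
            raise CorrectionError("background coefficients must be finite")

    def evaluate(self, field: VelocityField4D) -> np.ndarray:
        """Background velocity at every voxel center, shape (3, nx, ny, nz)."""
        X, Y, Z = np.broadcast_arrays(*field.voxel_centers())
        c = self.coefficients
        return (
            c[:, 0, None, None, None]
            + c[:, 1, None, None, None] * X[None]
            + c[:, 2, None, None, None] * Y[None]
            + c[:, 3, None, None, None] * Z[None]
        )


def detect_static_tissue(
    field: VelocityField4D,
    speed_sd_threshold: float | None = None,
    magnitude_threshold: float | None = None,
) -> np.ndarray:
    """Mask voxels that are tissue (signal-bearing) but do not move.

    A voxel is static when the temporal standard deviation of its speed |v|
    is below ``speed_sd_threshold`` (default: 10% of VENC) and its time-mean
    magnitude is above ``magnitude_threshold`` (default: half the 99th
    percentile of the time-mean magnitude, separating body from air). The
    mask is returned, never applied silently.
    """
    if field.n_frames < 2:
        raise CorrectionError("static-tissue detection needs at least 2 frames")
    if speed_sd_threshold is None:
        speed_sd_threshold = 0.10 * field.venc
    mean_mag = field.magnitude.mean(axis=0)
    if magnitude_threshold is None:
        magnitude_threshold = 0.5 * np.percentile(mean_mag, 99)
    speed = np.linalg.norm(field.velocity, axis=0)  # (nt, nx, ny, nz)
    sd = speed.std(axis=0)
    mask = (sd < speed_sd_threshold) & (mean_mag > magnitude_threshold)
    if not mask.any():
        raise CorrectionError(
            "no static tissue found; supply a static mask explicitly to fit_background"
        )
    return mask


def fit_background(field: VelocityField4D, static_mask: np.ndarray) -> BackgroundModel:
    """Least-squares first-order background fit over static voxels.

    Fits c0 + c1*x + c2*y + c3*z per velocity component to the time-averaged
    velocity of the masked voxels. Requires at least 4 non-coplanar voxels.
    """
    static_mask = np.asarray(static_mask, dtype=bool)
    if static_mask.shape != field.grid_shape:
        raise CorrectionError(
            f"static mask shape {static_mask.shape} does not match grid {field.grid_shape}"
        )
    n = int(static_mask.sum())
    if n < 4:
        raise CorrectionError(f"need >= 4 static voxels for a first-order fit, got {n}")

    X, Y, Z = np.broadcast_arrays(*field.voxel_centers())
    design = np.column_stack(
        [np.ones(n), X[static_mask], Y[static_mask], Z[static_mask]]
    )
    if np.linalg.matrix_rank(design) < 4:
        raise CorrectionError(
            "static voxels are coplanar/degenerate: first-order fit is rank-deficient"
        )

    mean_v = field.velocity.mean(axis=1)  # (3, nx, ny, nz)
    targets = mean_v[:, static_mask].T  # (n, 3)
    coeffs, _, _, _ = np.linalg.lstsq(design, targets, rcond=None)
    residual = targets - design @ coeffs
    rms = float(np.sqrt(np.mean(residual**2)))
    return BackgroundModel(
        coefficients=coeffs.T, static_mask_used=static_mask, fit_residual_rms=rms
    )


def correct_background(field: VelocityField4D, model: BackgroundModel) -> VelocityField4D:
    """Subtract the fitted background from every frame (exactly invertible)."""
    out = field.copy()
    out.velocity = out.velocity - model.evaluate(field)[:, None]
    out.notes["background_coefficients"] = model.coefficients.tolist()
    out.notes["background_fit_residual_rms"] = model.fit_residual_rms
    out.notes["background_n_static_voxels"] = int(model.static_mask_used.sum())
    return out


def unwrap_velocity(field: VelocityField4D) -> VelocityField4D:
    """Temporal per-voxel velocity unwrapping.

    Each voxel/component time series is scanned cyclically starting from its
    frame of minimum |velocity|; whenever the frame-to-frame jump exceeds
    VENC, multiples of 2*VENC are added to bring it back. Jumps of exactly
    VENC are ambiguous and resolved toward the smaller (zero) correction;
    they are counted in ``notes['n_ambiguous_jumps']``. Idempotent on data
    without jumps above VENC; always satisfies wrap(unwrap(x)) = wrap(x).
    """
    venc = field.venc
    v = field.velocity  # (3, nt, nx, ny, nz)
    nt = field.n_frames
    flat = v.reshape(3, nt, -1)

    i0 = np.argmin(np.abs(flat), axis=1)  # (3, nvox) start frame per series
    order = (i0[:, None, :] + np.arange(nt)[None, :, None]) % nt
    chained = np.take_along_axis(flat, order, axis=1)

    unwrapped = np.unwrap(chained, axis=1, period=2.0 * venc)
    n_ambiguous = int(np.sum(np.isclose(np.abs(np.diff(chained, axis=1)), venc)))

    out_flat = np.empty_like(flat)
    np.put_along_axis(out_flat, order, unwrapped, axis=1)

    out = field.copy()
    out.velocity = out_flat.reshape(v.shape)
    out.stage = "unwrapped"
    changed = np.any(out.velocity != field.velocity, axis=(0, 1))
    out.notes["n_unwrapped_voxels"] = int(changed.sum())
    out.notes["n_ambiguous_jumps"] = n_ambiguous
    return out
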