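"""Synthetic pulsatile-flow phantom with analytic ground truth.

The phantom is a rigid straight tube carrying pulsatile laminar (Poiseuille)
flow through a static "tissue" ellipse surrounded by air. The axial velocity
profile is

    v(r, t) = v_max(t) * (1 - (r/R)^2),      v_max(t) = 2 Q(t) / (pi R^2),

so the volumetric flow through any cross-section equals the prescribed
waveform Q(t) exactly. The waveform is a truncated Fourier series

    Q(t) = Q_mean + sum_k A_k cos(2 pi k t / T + phi_k)

whose mean alone determines the stroke volume (SV = Q_mean * T), since every
harmonic integrates to zero over a full cycle.

Acquisition-artifact operators emulate, at the velocity-image level, the
effects this kind of accelerated cardiac acquisition introduces:

* complex-noise-equivalent Gaussian velocity noise and a Rician/Rayleigh
  magnitude image (so the 0.655-corrected SNR estimate is consistent);
* a first-order (linear in x, y, z) background velocity offset along the tube
  axis, standing in for eddy-current phase offsets;
* phase wrapping of velocities beyond +/-VENC by multiples of 2*VENC;
* temporal low-pass blurring of each voxel's velocity time-series (the
  k-t-undersampling style of temporal transfer loss);
* prospective-gating truncation that removes late-diastolic frames.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy.ndimage import convolve1d

from .errors import GeometryError, ParameterError, TimingError
from .fields import VelocityField4D

#: Default aortic-like waveform: truncated (3-harmonic) Fourier series fitted
#: to a 475 ms sin^2 systolic pulse with 400 ml/s peak; Q_mean = 95 ml/s gives
#: SV = 95 ml at a 1000 ms cycle, matching normal adult aortic values.
DEFAULT_WAVEFORM_MEAN_ML_S = 95.0
DEFAULT_WAVEFORM_HARMONICS: tuple[tuple[float, float], ...] = (
    (163.9147, -1.492257),
    (102.1428, -2.984513),
    (40.0424, 1.806416),
)

#: Magnitude-image signal level inside the body (arbitrary units).
BODY_SIGNAL = 100.0


@dataclass
class Waveform:
    """Volumetric flow waveform Q(t), ml/s, as mean + cosine harmonics."""

    mean_ml_s: float = DEFAULT_WAVEFORM_MEAN_ML_S
    harmonics: tuple[tuple[float, float], ...] = DEFAULT_WAVEFORM_HARMONICS

    def __call__(self, t_ms: np.ndarray, cycle_ms: float) -> np.ndarray:
        """Evaluate Q(t) in ml/s at times ``t_ms`` for cycle length ``cycle_ms``."""
        t = np.asarray(t_ms, dtype=float)
        q = np.full_like(t, self.mean_ml_s, dtype=float)
        for k, (amp, phase) in enumerate(self.harmonics, start=1):
            q = q + amp * np.cos(2 * np.pi * k * t / cycle_ms + phase)
        return q

    def peak_ml_s(self, cycle_ms: float, n_samples: int = 4096) -> float:
        """Peak of the analytic waveform, from a dense uniform sampling."""
        t = np.linspace(0.0, cycle_ms, n_samples, endpoint=False)
        return float(self(t, cycle_ms).max())


@dataclass
class PhantomSpec:
    """Full description of one synthetic acquisition.

    Geometry defaults follow a 3 mm isotropic whole-heart protocol: 3 mm
    voxels, 20 frames over a 1000 ms cycle (50 ms temporal resolution),
    a 15 mm tube radius (aortic caliber) and a 1500 mm/s VENC.
    """

    tube_axis: tuple[float, float, float] = (0.0, 0.0, 1.0)
    tube_center: tuple[float, float, float] = (0.0, 0.0, 0.0)
    radius: float = 15.0
    grid_shape: tuple[int, int, int] = (40, 40, 16)
    voxel_size: float = 3.0
    cycle_ms: float = 1000.0
    n_frames: int = 20
    waveform: Waveform = dc_field(default_factory=Waveform)
    venc: float = 1500.0
    noise_sd: float = 0.0
    background_coeffs: tuple[float, float, float, float] = (0.0, 0.0, 0.0, 0.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.radius > 0:
            raise GeometryError(f"radius must be positive, got {self.radius}")
        if not self.venc > 0:
            raise ParameterError(f"venc must be positive, got {self.venc}")
        if self.n_frames < 2:
            raise TimingError(f"need at least 2 frames, got {self.n_frames}")
        if not self.voxel_size > 0:
            raise GeometryError(f"voxel_size must be positive, got {self.voxel_size}")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be nonnegative")
        axis = np.asarray(self.tube_axis, dtype=float)
        norm = np.linalg.norm(axis)
        if norm == 0:
            raise GeometryError("tube_axis must be a nonzero vector")
        self.tube_axis = tuple(axis / norm)

    @property
    def trigger_times_ms(self) -> np.ndarray:
        return np.arange(self.n_frames) * (self.cycle_ms / self.n_frames)

    def peak_centerline_speed(self) -> float:
        """Peak |v_max(t)| in mm/s implied by waveform and radius."""
        q_peak = max(
            abs(self.waveform.peak_ml_s(self.cycle_ms)),
            abs(float(self.waveform(np.linspace(0, self.cycle_ms, 4096, endpoint=False),
                                    self.cycle_ms).min())),
        )
        return 2.0 * q_peak * 1000.0 / (np.pi * self.radius**2)


@dataclass
class GroundTruth:
    """Analytic truth accompanying a generated phantom."""

    flow_curve_ml_s: np.ndarray
    stroke_volume_ml: float
    peak_flow_ml_s: float
    blood_pool_mask: np.ndarray
    static_mask: np.ndarray
    trigger_times_ms: np.ndarray
    cycle_ms: float


def wrap_velocity(v: np.ndarray, venc: float) -> np.ndarray:
    """Phase-wrap velocities into [-venc, venc) by multiples of 2*venc."""
    return np.mod(np.asarray(v, dtype=float) + venc, 2.0 * venc) - venc


def noise_sd_for_snr(snr: float, venc: float) -> float:
    """Velocity-noise SD (mm/s) equivalent to a magnitude SNR.

    Phase-difference velocity noise in phase-contrast MRI is
    sigma_v = sqrt(2) * VENC / (pi * SNR).
    """
    if not snr > 0:
        raise ParameterError("snr must be positive")
    return float(np.sqrt(2.0) * venc / (np.pi * snr))


def _magnitude_noise_sd(noise_sd: float, venc: float) -> float:
    # Inverse of noise_sd_for_snr: complex-channel sigma for the magnitude image.
    return float(np.pi * BODY_SIGNAL * noise_sd / (np.sqrt(2.0) * venc))


def generate_phantom(spec: PhantomSpec) -> tuple[VelocityField4D, GroundTruth]:
    """Generate one synthetic 4D dataset plus its analytic ground truth.

    The stored velocity is built as: clean Poiseuille field -> + Gaussian noise
    per component -> + linear background offset along the tube axis ->
    phase wrap into [-venc, venc). Identical spec (including seed) reproduces
    the dataset bit-exactly.
    """
    nx, ny, nz = spec.grid_shape
    nt = spec.n_frames
    h = spec.voxel_size
    origin = -(np.array([nx, ny, nz], dtype=float) - 1) / 2.0 * h

    x = origin[0] + np.arange(nx) * h
    y = origin[1] + np.arange(ny) * h
    z = origin[2] + np.arange(nz) * h
    X, Y, Z = np.meshgrid(x, y, z, indexing="ij")

    axis = np.asarray(spec.tube_axis, dtype=float)
    center = np.asarray(spec.tube_center, dtype=float)
    dx, dy, dz = X - center[0], Y - center[1], Z - center[2]
    along = dx * axis[0] + dy * axis[1] + dz * axis[2]
    r2 = dx**2 + dy**2 + dz**2 - along**2
    r2 = np.maximum(r2, 0.0)

    blood = r2 < spec.radius**2
    if not blood.any():
        raise GeometryError("grid too small: tube cross-section contains no voxel centers")
    edge = np.zeros_like(blood)
    edge[0, :, :] = edge[-1, :, :] = True
    edge[:, 0, :] = edge[:, -1, :] = True
    if (blood & edge).any():
        raise GeometryError("grid too small to contain the tube: blood pool touches the "
                            "transverse grid boundary")

    # Body ellipse (in x, y; full z extent) containing the tube; air outside.
    semi_x, semi_y = 0.45 * nx * h, 0.45 * ny * h
    body = (X / semi_x) ** 2 + (Y / semi_y) ** 2 <= 1.0
    body |= blood
    # Static tissue: inside the body, clear of the tube wall by one voxel.
    static = body & (r2 >= (spec.radius + h) ** 2)

    t_ms = spec.trigger_times_ms
    q = spec.waveform(t_ms, spec.cycle_ms)  # ml/s per frame
    v_max = 2.0 * q * 1000.0 / (np.pi * spec.radius**2)  # mm/s

    profile = np.where(blood, 1.0 - r2 / spec.radius**2, 0.0)
    velocity = np.zeros((3, nt, nx, ny, nz))
    for c in range(3):
        velocity[c] = axis[c] * v_max[:, None, None, None] * profile[None]

    rng = np.random.default_rng(spec.seed)
    if spec.noise_sd > 0:
        velocity += rng.normal(0.0, spec.noise_sd, size=velocity.shape)

    a0, a1, a2, a3 = spec.background_coeffs
    bg = a0 + a1 * X + a2 * Y + a3 * Z
    velocity += axis[:, None, None, None, None] * bg[None, None]

    velocity = wrap_velocity(velocity, spec.venc)

    magnitude = np.where(body, BODY_SIGNAL, 0.0)[None].repeat(nt, axis=0)
    if spec.noise_sd > 0:
        sigma_m = _magnitude_noise_sd(spec.noise_sd, spec.venc)
        # Body: high-SNR Rician ~ Gaussian; air: Rayleigh (modulus of complex noise).
        g1 = rng.normal(0.0, sigma_m, size=magnitude.shape)
        g2 = rng.normal(0.0, sigma_m, size=magnitude.shape)
        magnitude = np.where(
            body[None], magnitude + g1, np.hypot(g1, g2)
        )

    field = VelocityField4D(
        velocity=velocity,
        magnitude=magnitude,
        voxel_size=np.full(3, h),
        origin=origin,
        trigger_times_ms=t_ms,
        cycle_ms=spec.cycle_ms,
        venc=spec.venc,
        coverage="full",
        stage="wrapped",
    )

    sv = cyclic_trapezoid_ml(t_ms, q, spec.cycle_ms)
    truth = GroundTruth(
        flow_curve_ml_s=q,
        stroke_volume_ml=sv,
        peak_flow_ml_s=spec.waveform.peak_ml_s(spec.cycle_ms),
        blood_pool_mask=blood,
        static_mask=static,
        trigger_times_ms=t_ms,
        cycle_ms=spec.cycle_ms,
    )
    return field, truth


def cyclic_trapezoid_ml(t_ms: np.ndarray, q_ml_s: np.ndarray, cycle_ms: float) -> float:
    """Integrate a flow curve (ml/s) over one full cycle by cyclic trapezoid.

    The curve is closed from the last frame back to the first across the
    period wrap; returns millilitres.
    """
    t = np.asarray(t_ms, dtype=float) / 1000.0
    q = np.asarray(q_ml_s, dtype=float)
    period = cycle_ms / 1000.0
    inner = float(np.trapezoid(q, t))
    wrap_dt = period - t[-1] + t[0]
    return inner + wrap_dt * (q[-1] + q[0]) / 2.0


def _hann_kernel(width_frames: float) -> np.ndarray:
    """Normalized raised-cosine (Hann) kernel with taps at integer offsets.

    Tap j in [-J, J] carries weight 0.5*(1 + cos(2 pi j / (w+1))), which
    vanishes at |j| = (w+1)/2; width 1 is the identity.
    """
    if width_frames < 1:
        raise ParameterError(f"kernel_width_frames must be >= 1, got {width_frames}")
    J = int(np.ceil((width_frames - 1) / 2.0 - 1e-12))
    j = np.arange(-J, J + 1, dtype=float)
    k = 0.5 * (1.0 + np.cos(2.0 * np.pi * j / (width_frames + 1.0)))
    k = np.maximum(k, 0.0)
    return k / k.sum()


def temporal_kernel_gain(width_frames: float, harmonic: int, n_frames: int) -> float:
    """Closed-form gain of the blur kernel at a given discrete harmonic."""
    k = _hann_kernel(width_frames)
    J = (len(k) - 1) // 2
    j = np.arange(-J, J + 1)
    return float(np.sum(k * np.cos(2.0 * np.pi * harmonic * j / n_frames)))


def apply_temporal_blur(field: VelocityField4D, kernel_width_frames: float) -> VelocityField4D:
    """Circularly low-pass filter every voxel's time series (k-t-style blur).

    The kernel is a normalized Hann window of the stated width, applied
    periodically along the cardiac cycle; each voxel's temporal mean is
    preserved exactly (unit DC gain), so full-cycle stroke volume is
    unaffected while peaks are attenuated.
    """
    if field.coverage != "full":
        raise ParameterError("temporal blur requires full-cycle coverage "
                             "(circular convolution assumes periodicity)")
    kernel = _hann_kernel(kernel_width_frames)
    if len(kernel) > field.n_frames:
        raise ParameterError(
            f"kernel ({len(kernel)} taps) wider than the cycle ({field.n_frames} frames)"
        )
    out = field.copy()
    if len(kernel) > 1:
        out.velocity = convolve1d(out.velocity, kernel, axis=1, mode="wrap")
        out.magnitude = convolve1d(out.magnitude, kernel, axis=0, mode="wrap")
    return out


def apply_prospective_truncation(
    field: VelocityField4D, retained_fraction: float
) -> VelocityField4D:
    """Drop late-diastolic frames, emulating prospective ECG gating.

    Frames with trigger time >= retained_fraction * cycle_ms are removed
    (frames strictly inside the retained window are kept). The output's
    ``covered_ms`` records the retained window so downstream integration can
    stop at the coverage end rather than assume a full cycle.
    """
    if not 0 < retained_fraction <= 1:
        raise ParameterError(
            f"retained_fraction must be in (0, 1], got {retained_fraction}"
        )
    if retained_fraction == 1.0:
        return field.copy()
    keep = field.trigger_times_ms < retained_fraction * field.cycle_ms
    if keep.sum() < 2:
        raise TimingError(
            f"retained_fraction={retained_fraction} leaves fewer than 2 frames"
        )
    out = field.copy()
    out.velocity = out.velocity[:, keep]
    out.magnitude = out.magnitude[keep]
    out.trigger_times_ms = out.trigger_times_ms[keep]
    out.coverage = "truncated"
    out.covered_ms = float(retained_fraction * field.cycle_ms)
    return out
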