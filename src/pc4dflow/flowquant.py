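"""Flow quantification: vessel ROIs, flow curves, SV, SNR and QP/QS.

Flow through a plane ROI is the sum of through-plane velocity times pixel
area over pixels whose centers fall inside the vessel contour, converted to
ml/s. Stroke volume integrates the flow curve over the cardiac cycle: for
full-coverage series by cyclic trapezoid (the curve is closed from the last
frame back to the first across the period wrap); for prospectively gated
(truncated) series the integral runs over the covered window only, holding
the last sample to the coverage end, and the truncation is flagged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
import shapely
from shapely.geometry import Polygon
from scipy import ndimage
from skimage import measure

from .errors import FormatError, ParameterError, SegmentationError
from .fields import FlowCurve, Series2D, VelocityField4D

#: Rayleigh correction: the SD of background (air) magnitude noise is
#: 0.655 x the per-channel noise sigma, so SNR = 0.655 * mean(vessel) / sd(air).
SNR_RAYLEIGH_FACTOR = 0.655


@dataclass
class VesselContour:
    """Closed vessel outline(s) in plane coordinates (mm).

    A single polygon applies to all frames (static contour, the default);
    per-frame polygons may be supplied as a list with one entry per frame.
    """

    polygons: list[np.ndarray]  # each (m, 2): (u_mm, v_mm) vertices
    vessel_label: str = "other"
    static: bool = True

    def __post_init__(self) -> None:
        self.polygons = [np.asarray(p, dtype=float) for p in self.polygons]
        for p in self.polygons:
            if p.ndim != 2 or p.shape[1] != 2 or p.shape[0] < 3:
                raise FormatError("each contour needs >= 3 (u, v) vertices")
            poly = Polygon(p)
            if not poly.is_valid:
                raise FormatError("contour polygon must be simple (non-self-intersecting)")
            if not poly.area > 0:
                raise FormatError("contour polygon must have positive area")

    def polygon_for_frame(self, t: int) -> Polygon:
        if self.static or len(self.polygons) == 1:
            return Polygon(self.polygons[0])
        return Polygon(self.polygons[t])

    def area_mm2(self, t: int = 0) -> float:
        return float(self.polygon_for_frame(t).area)


def segment_vessel(
    series: Series2D,
    seed_point: tuple[float, float],
    threshold_fraction: float = 0.1,
) -> VesselContour:
    """Threshold-grown vessel ROI from a seed at the peak-flow frame.

    Grows a 4-connected region from the seed pixel over pixels whose
    peak-frame |v_through| is at least ``threshold_fraction`` times the seed's,
    then polygonizes its boundary (marching squares at the 0.5 level). The
    contour is static across frames and can be edited via the contour CSV.
    Deterministic: same inputs, same contour.
    """
    if not 0 < threshold_fraction <= 1:
        raise ParameterError("threshold_fraction must be in (0, 1]")
    u_mm, v_mm = series.plane.pixel_coords_mm()
    speed = np.where(series.valid, np.abs(series.v_through), 0.0)
    peak_frame = int(np.nanargmax(speed.sum(axis=(1, 2))))
    frame = speed[peak_frame]

    iu = int(np.argmin(np.abs(u_mm[:, 0] - seed_point[0])))
    iv = int(np.argmin(np.abs(v_mm[0, :] - seed_point[1])))
    if not series.valid[iu, iv]:
        raise SegmentationError("seed point falls on an invalid (out-of-volume) pixel")
    seed_speed = frame[iu, iv]
    if seed_speed <= 0:
        raise SegmentationError(
            "seed velocity is zero at the peak-flow frame: empty region "
            "(is the seed inside the vessel?)"
        )

    region = frame >= threshold_fraction * seed_speed
    labels, _ = ndimage.label(region, structure=np.array(
        [[0, 1, 0], [1, 1, 1], [0, 1, 0]]))
    region = labels == labels[iu, iv]
    if not region.any():
        raise SegmentationError("empty region grown from seed")
    if (region[0, :].any() or region[-1, :].any()
            or region[:, 0].any() or region[:, -1].any()):
        warnings.warn("segmented region touches the image border", stacklevel=2)

    contours = measure.find_contours(region.astype(float), 0.5)
    if not contours:
        raise SegmentationError("could not polygonize the segmented region")
    # Keep the boundary enclosing the seed (the longest such ring).
    best = None
    for c in contours:
        poly = Polygon(np.column_stack([c[:, 0], c[:, 1]]))
        if poly.is_valid and poly.contains(shapely.points(iu, iv)):
            if best is None or poly.area > best.area:
                best = c
    if best is None:
        best = max(contours, key=len)
    ps = series.pixel_size
    nu, nv = series.plane.extent
    verts = np.column_stack([
        (best[:, 0] - (nu - 1) / 2.0) * ps,
        (best[:, 1] - (nv - 1) / 2.0) * ps,
    ])
    return VesselContour(polygons=[verts], static=True)


def _pixels_inside(contour: VesselContour, series: Series2D, t: int) -> np.ndarray:
    poly = contour.polygon_for_frame(t)
    u_mm, v_mm = series.plane.pixel_coords_mm()
    pts = shapely.points(u_mm.ravel(), v_mm.ravel())
    # covers(): boundary ties count as inside (deterministic, convergent).
    inside = shapely.covers(poly, pts).reshape(u_mm.shape)
    return inside


def compute_flow_curve(series: Series2D, contour: VesselContour) -> FlowCurve:
    """Flow (ml/s) per frame through the contour plus SV and peak flow."""
    nt = series.n_frames
    px_area = series.pixel_size**2  # mm^2
    flows = np.empty(nt)
    inside = _pixels_inside(contour, series, 0)
    for t in range(nt):
        if not (contour.static or len(contour.polygons) == 1):
            inside = _pixels_inside(contour, series, t)
        bad = inside & ~series.valid
        if bad.any():
            ij = np.argwhere(bad)[:10].tolist()
            raise ParameterError(
                f"contour covers invalid (out-of-volume) pixels at indices {ij}"
            )
        # mm/s * mm^2 = mm^3/s; 1 ml = 1000 mm^3.
        flows[t] = np.sum(series.v_through[t][inside]) * px_area / 1000.0

    t_ms = series.trigger_times_ms
    if series.coverage == "full":
        sv = _cyclic_sv_ml(t_ms, flows, series.cycle_ms)
    else:
        sv = _truncated_sv_ml(t_ms, flows, series.covered_ms)
    return FlowCurve(
        time_ms=t_ms.copy(),
        flow_ml_s=flows,
        stroke_volume_ml=sv,
        peak_flow_ml_s=float(flows.max()),
        coverage=series.coverage,
        covered_ms=float(series.covered_ms),
    )


def _cyclic_sv_ml(t_ms: np.ndarray, q_ml_s: np.ndarray, cycle_ms: float) -> float:
    t = t_ms / 1000.0
    inner = float(np.trapezoid(q_ml_s, t))
    wrap_dt = (cycle_ms - t_ms[-1] + t_ms[0]) / 1000.0
    return inner + wrap_dt * (q_ml_s[-1] + q_ml_s[0]) / 2.0


def _truncated_sv_ml(t_ms: np.ndarray, q_ml_s: np.ndarray, covered_ms: float) -> float:
    # Open-ended: integrate the sampled support, then hold the last sample to
    # the end of the covered window (each frame represents a temporal bin).
    t = t_ms / 1000.0
    inner = float(np.trapezoid(q_ml_s, t))
    tail_dt = max(covered_ms - t_ms[-1], 0.0) / 1000.0
    return inner + tail_dt * q_ml_s[-1]


def compute_snr(
    data: Series2D | VelocityField4D,
    roi_vessel: np.ndarray,
    roi_outside: np.ndarray,
) -> float:
    """Magnitude SNR: 0.655 x mean(ROI_vessel) / sd(noise in ROI_outside).

    ``roi_outside`` must contain only air/background pixels; the 0.655 factor
    converts the Rayleigh-distributed background SD to the underlying noise
    sigma. ROIs are boolean masks over the spatial grid; all frames are pooled.
    """
    roi_vessel = np.asarray(roi_vessel, dtype=bool)
    roi_outside = np.asarray(roi_outside, dtype=bool)
    if not roi_vessel.any() or not roi_outside.any():
        raise ParameterError("both ROIs must be nonempty")
    mag = data.magnitude
    spatial_shape = mag.shape[1:]
    if roi_vessel.shape != spatial_shape or roi_outside.shape != spatial_shape:
        raise ParameterError(
            f"ROI shapes must match the spatial grid {spatial_shape}"
        )
    signal = float(np.nanmean(mag[:, roi_vessel]))
    noise_sd = float(np.nanstd(mag[:, roi_outside], ddof=1))
    if noise_sd == 0:
        raise ParameterError(
            "background magnitude has zero variance (noise-free data): SNR undefined"
        )
    return SNR_RAYLEIGH_FACTOR * signal / noise_sd


def compute_qp_qs(pulmonary: FlowCurve, systemic: FlowCurve) -> float:
    """Pulmonary-to-systemic flow ratio (QP/QS = SV_pulmonary / SV_systemic)."""
    if pulmonary.stroke_volume_ml <= 0 or systemic.stroke_volume_ml <= 0:
        raise ParameterError("QP/QS requires positive stroke volumes")
    return pulmonary.stroke_volume_ml / systemic.stroke_volume_ml
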