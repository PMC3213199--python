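# Methods

This note documents the models, parameter choices and numerical conventions
behind `pc4dflow`, stage by stage, and what the synthetic phantom does and
does not emulate.

## Coordinate and data conventions

All geometry is right-handed Cartesian in millimetres; voxel centers sit at
`origin + index · voxel_size` with 0-based indices; time is milliseconds from
the R-wave. Velocities are stored in mm/s; phase images are assumed already
converted via v = (φ/π)·VENC, so external phase data can be ingested by
declaring a VENC. A dataset carries a processing-stage tag: `wrapped` data
obey |v| ≤ VENC, `unwrapped` data are unbounded. Datasets are persisted as
one 4D NIfTI per velocity component plus magnitude, with a JSON metadata
sidecar that repeats the coordinate convention; writers and readers
round-trip bit-exactly, and readers reject inconsistent geometry rather than
reinterpreting it.

## Synthetic phantom

The phantom is a rigid straight tube of radius R (default 15 mm, aortic
caliber) through a static-tissue ellipse surrounded by air, carrying laminar
pulsatile flow with the parabolic (Poiseuille) profile

    v(r, t) = v_max(t) · (1 − (r/R)²),   v_max(t) = 2 Q(t) / (π R²),

so the flux through any cross-section equals the prescribed waveform Q(t)
exactly — the analytic ground truth for every downstream measurement. The
waveform is a truncated Fourier series; the default (mean 95 ml/s plus three
harmonics, derived once by projecting a 475 ms sin² systolic pulse of 400 ml/s
peak onto three harmonics of a 1000 ms cycle) gives a stroke volume of
exactly 95 ml (only the mean survives full-cycle integration) and a peak flow
of 401 ml/s, matching normal adult aortic values. The default acquisition
geometry is a 3 mm isotropic grid of 40×40×16 voxels with 20 frames over a
1000 ms cycle (50 ms temporal resolution) and a 1500 mm/s VENC, i.e. a
whole-heart protocol at typical scan parameters.

Voxels take the analytic profile value at their center; blood-pool membership
is center-inside-radius. This is deliberately simple and converges under grid
refinement; it does not model partial-volume averaging inside a voxel.

Acquisition artifacts are applied in a physically motivated order: Gaussian
velocity noise per component, then the linear background offset
a₀ + a₁x + a₂y + a₃z along the tube axis (eddy-current offsets corrupt the
measured phase, so they are added before wrapping), then phase wrapping of
every stored velocity into [−VENC, VENC) by multiples of 2·VENC. The
magnitude image is 100 (arbitrary units) inside the body with Gaussian noise
of the complex-channel σ implied by the velocity noise (σ_v = √2·VENC/(π·SNR)),
and Rayleigh-distributed |complex noise| in air — which is exactly why the
0.655 factor appears in the SNR estimate: the SD of Rayleigh background noise
is 0.655 σ. A nominal SNR of 15 therefore corresponds to a velocity noise SD
of 45 mm/s at VENC 1500 mm/s, and the pipeline's SNR measurement recovers the
nominal value (15.0 measured).

Two operators emulate accelerated-acquisition effects at the velocity-image
level rather than in k-space:

* **Temporal blur** — circular convolution of every voxel's time series with
  a normalized Hann window of configurable width (default width 5 frames in
  the validation runs). The kernel has unit DC gain, so each voxel's temporal
  mean — and hence full-cycle stroke volume — is preserved exactly, while
  temporal peaks are attenuated. The true temporal transfer function of
  k-t-undersampled reconstructions is data-dependent and not publicly
  specified; only the *direction* of this operator's effect (peak-flow loss
  without SV loss) is claimed to be faithful.
* **Prospective-gating truncation** — frames with trigger time ≥
  f·cycle (f = retained fraction) are dropped and the covered window f·cycle
  is recorded. Downstream integration of truncated data runs over the covered
  window only (trapezoid over the frames, holding the last sample to the
  window end — each frame represents a temporal bin) and flags the curve; no
  extrapolation into the missing diastole is attempted, so missing
  late-diastolic flow is simply lost, as with prospective ECG triggering.

Everything is seeded; identical spec + seed reproduces a dataset bit-exactly.

## Background correction

Eddy-current offsets are modeled as time-stationary and first-order in space.
Static tissue is detected as voxels whose temporal SD of speed is below a
threshold (default 10% of VENC) and whose magnitude is above a body
threshold; the mask is always returned to the caller, never applied silently,
because slow near-wall blood can enter an SD-only mask. Per velocity
component, c₀ + c₁x + c₂y + c₃z is least-squares fitted to the time-averaged
velocity over the masked voxels (≥ 4 non-coplanar voxels required; rank
checked) and subtracted from every frame. The operation is exactly
invertible, and on noise-free synthetic data the injected coefficients are
recovered to ~1e-14 (the fit is exact for a linear field). Higher-order or
per-frame background models are out of scope.

## Velocity unwrapping

Unwrapping is temporal and per voxel: each voxel's series is scanned
cyclically starting from its frame of minimum |v| — flow is near zero in
diastole, so that frame is assumed alias-free — and 2·VENC multiples are
added wherever a frame-to-frame jump exceeds VENC (numpy's periodic unwrap
with period 2·VENC). Jumps of exactly VENC are ambiguous; they are resolved
toward the smaller (zero) correction and counted in the processing report.
The algorithm recovers the true series whenever true frame-to-frame jumps
stay below VENC; series that violate that premise are unrecoverable by any
temporal method and only the projection property wrap(unwrap(x)) = wrap(x)
is guaranteed. Spatial (Laplacian) unwrapping is not attempted.

## Plane reformatting

For each frame and plane pixel the three Cartesian components are
interpolated at the pixel's 3D position and projected onto the plane normal.
Trilinear interpolation is the default: it is exact for affine velocity
fields (verified to 1e-9) and cannot overshoot at vessel edges;
nearest-neighbour is available for sensitivity checks. Pixels outside the
volume are NaN plus an invalid flag and are never silently zero-filled; flow
quantification refuses contours that cover invalid pixels. The plane keeps
the 4D trigger times — no temporal interpolation happens at this stage.

## Flow quantification

Vessel ROIs come from a deterministic threshold region-grower: a 4-connected
region around the seed where peak-frame |v_through| ≥ threshold_fraction
(default 0.1) times the seed value, polygonized by marching squares and held
static across frames (vessel motion is out of the phantom's scope; per-frame
contours can be supplied via CSV). Pixels belong to a contour when their
center is covered by the polygon (boundary ties inside — deterministic and
convergent). Flow is Σ v·n ΔA in ml/s; stroke volume integrates the curve
with the cyclic trapezoid rule (closing the cycle from the last frame back to
the first) for full-coverage data, or over the covered window only for
truncated data.

Two ROI styles are used in validation. Threshold segmentation, the end-to-end
pipeline configuration, carries a small negative bias (≈ −2.5% SV at 3 mm
voxels) because the 10% threshold stops at r ≈ 0.95 R and trilinear
partial-volume smoothing spreads flux across the wall. When a stage other
than segmentation is being isolated (background correction, unwrapping,
artifact-direction checks), flow is measured over a fixed circular ROI drawn
with a two-voxel margin around the lumen — standard practice, since
velocities outside the vessel are near zero while the margin captures the
partial-volume spillover; this ROI recovers SV to ≈ +0.2% and so does not
confound the stage under test.

SNR follows the magnitude-image convention 0.655 · mean(ROI_vessel) /
SD(ROI_air); it is refused on noise-free data (zero background variance).
QP/QS is the ratio of two stroke volumes.

## Pathline tracing and quality grading

Particles obey x′(t) = v(x, t), integrated with fixed-step classical RK4
(default 1 ms, ten times finer than the 10 ms release cadence), trilinear in
space and linear in time, periodic over the cycle for full-coverage data and
clamped to the last frame (with a warning) for truncated data. Velocity is
defined on the voxel-center hull; a particle leaving the hull is frozen at
its exit position and flagged, since no data exist beyond it. On a rigid
rotation the tracer closes a full orbit to 8e-11 of the radius at 1 ms steps
and shows clean 4th-order convergence.

Containment grading operationalizes the visual 0–3 reading scale (ideal /
few / moderate / large amount of particles leaving the blood pool): per
emitter, the escape fraction is the share of particles ever sampled outside
the blood-pool mask (escape is sticky; leaving the volume counts), and grades
are 0 for zero escapes, 1 up to 5%, 2 up to 20%, 3 above. The thresholds are
declared configuration — the underlying scale is a human judgement and these
defaults are this package's operationalization, not a reproduction of any
observer. The mean quality score is the unweighted mean over emitters.

## Agreement statistics

Regression is ordinary least squares of test on reference with r² (equal to
the squared sample correlation). Percent bias is reported with the reference
value as denominator — the reference method defines truth in a validation
setting — and the classical pair-mean-denominator variant is always computed
alongside, since conventions differ. The Wilcoxon signed-rank test drops zero
differences, mid-ranks ties, uses the exact null distribution for n ≤ 25
(computed by convolving the signed-rank generating function over doubled
ranks, so mid-ranks stay integral) and a normal approximation with continuity
correction above; the two-sided p is P(|W − μ| ≥ |w − μ|) under the symmetric
null. These conventions match full sign-assignment enumeration to < 1e-10 on
randomized small samples and scipy's exact method on tie-free data.

## Validation problem sizes and limitations

The validation suite and the acceptance script run the default 40×40×16-voxel
phantom (25,600 voxels, 20 frames), 20 noise seeds for the SNR-15 recovery
check, 100 randomized datasets (n ≤ 12) against the statistics oracles, and
a 21×21×5 rotation field for pathline accuracy — sizes chosen so the full
chain remains an interactive-scale computation while discretization errors
stay at the few-percent level being measured.

The phantom validates the analysis chain, not the scanner: it has no cardiac
chamber geometry, no moving vessel walls, no k-space/SENSE/k-t reconstruction
(artifacts are emulated at the velocity-image level), no concomitant-gradient
fields, and white Gaussian velocity noise rather than spatially varying
parallel-imaging noise amplification. Passing tests therefore demonstrate
correctness of the processing algorithms and the mechanistic direction of the
acquisition-artifact biases (temporal blur suppresses peak flow but not
full-cycle SV; gating truncation and velocity underestimation suppress SV),
not in-vivo accuracy. DICOM ingestion of vendor 4D-flow data is future work.
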