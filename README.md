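# pc4dflow

Quantitative analysis of time-resolved, three-directionally velocity-encoded
phase-contrast MRI ("4D flow") for cardiovascular flow measurement, together
with a synthetic pulsatile-flow phantom for validating every stage of the
analysis chain.

4D flow acquisitions measure the full velocity vector field **v**(x, t) of the
blood pool over the cardiac cycle. Turning those volumes into clinically
meaningful numbers — stroke volume, peak flow, shunt ratios, flow
visualizations — requires a chain of processing steps, each of which can bias
the result. This package implements that chain for researchers who want a
tested, scriptable reference implementation:

* **Phantom** (`pc4dflow.phantom`) — straight-tube Poiseuille phantom with a
  truncated-Fourier pulsatile waveform Q(t) and analytic ground truth, plus
  operators for the acquisition artifacts that matter in accelerated cardiac
  imaging: velocity noise at a prescribed SNR, a first-order eddy-current
  background offset, phase wrapping beyond ±VENC, k-t-style temporal blurring,
  and prospective-gating truncation of late diastole.
* **Preprocessing** (`pc4dflow.preprocess`) — first-order (linear in x, y, z)
  background phase correction fitted to static tissue, and temporal per-voxel
  velocity unwrapping (aliased velocities are restored by ±2·VENC whenever a
  frame-to-frame jump exceeds VENC).
* **Reformatting** (`pc4dflow.reformat`) — resampling the 4D dataset onto any
  oblique 2D plane; through-plane velocity is the trilinear interpolation of
  **v** projected onto the plane normal.
* **Flow quantification** (`pc4dflow.flowquant`) — threshold-grown vessel
  ROIs, flow curves Q(t) = Σ v·n ΔA, stroke volume SV = ∮ Q dt over the cycle,
  peak flow, QP/QS, and magnitude SNR = 0.655·mean(ROI_vessel)/SD(ROI_air).
* **Pathlines** (`pc4dflow.pathlines`) — fixed-step RK4 particle tracing
  through the time-varying field with timed emitters (releases every 10 ms),
  and 0–3 data-quality grading from the fraction of particles that leave the
  blood pool.
* **Agreement statistics** (`pc4dflow.compare`) — ordinary least-squares
  regression with r², Bland-Altman percent bias (mean ± SD), and a paired
  two-sided Wilcoxon signed-rank test with an exact null distribution for
  n ≤ 25 (ties mid-ranked, zeros dropped).

## Worked example

The `run` subcommand chains phantom generation, background correction,
unwrapping, oblique-plane reformatting, threshold segmentation and flow
integration, and reports recovery against the analytic truth:

```sh
pc4dflow run --out demo_run
```

```json
{
  "analytic_sv_ml": 94.99999999999999,
  "measured_sv_ml": 93.17376002440209,
  "sv_error_percent": -1.9223578690504217,
  "analytic_peak_flow_ml_s": 401.0998561124714,
  "measured_peak_flow_ml_s": 390.57526852815334,
  "background_fit_residual_rms_mm_s": 0.0
}
```

The default phantom carries an aortic-scale waveform (stroke volume 95 ml,
peak flow ≈ 400 ml/s, 1000 ms cycle) through a 15 mm-radius tube sampled at
3 mm isotropic voxels and 20 frames (50 ms temporal resolution). The measured
stroke volume of 93.2 ml (−1.9%) reflects the discretization bias of
threshold segmentation at this voxel size; the measured peak flow of
391 ml/s is the analytic peak attenuated by the 50 ms frame spacing. Each
stage is also available separately (`pc4dflow phantom / preprocess /
reformat / flow / trace / compare`) and as plain library functions.

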