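# Methods

## Motor and filament model

Each myosin motor domain is a two-state Markov (telegraph) process:
detached → attached at rate `k_att = 1/((1−r)·t_cycle)` and attached →
detached at rate `k_det = 1/(r·t_cycle)`, so its stationary bound
probability equals the duty ratio `r`. Motors are independent; NM2
molecules engage actin through one head at a time, so no intramolecular
gating correction is applied. The ensemble duty ratio of `n` motors is
`r_f = 1 − (1−r)^n`.

A bipolar filament engages one actin filament with the motors of a
single half filament (perpendicular-mode geometry); the distal half is
tracked only for its fluorophore content. A half filament carries
`molecules_per_filament / 2` molecules (default 30 per filament, i.e.
60 motor domains, the electron-microscopy estimate), each contributing
`heads_per_molecule` (default 2) motor domains if full-length and none
if it is a headless tail fragment. Co-filament composition is binomial:
every molecule is assigned a species independently with probability
proportional to the mixing-ratio parts.

Default species parameters:

| species | duty ratio r | unloaded speed v₀ (nm/s) | step (nm) | cycle time (s) |
|---|---|---|---|---|
| NM2-B | 0.23 | 43 | 8 | 0.809 |
| NM2-A | 0.05 | 133 | 8 | 1.203 |
| NM2-B tail | 0 | — | — | — |

Duty ratios and speeds are the published single-molecule/single-filament
values; cycle times are not directly reported and are derived from the
consistency relation `v0 = step / (r · t_cycle)` with an 8 nm working
stroke. All four numbers are configuration, not constants.

With `r_f ≥ 0.9` as the processivity requirement the closed form gives
9 motors for NM2-B and 45 for NM2-A. (Discussion-level statements of
"more than 50" NM2-A motors circulate; the criterion behind that number
is not stated, and this package reports the value the equation
produces, 45.)

## Stochastic simulation

Runs are simulated with an exact event-driven (Gillespie) algorithm on
the per-species bound counts; position is integrated analytically
between events. A run starts at the first attachment (time 0,
position 0). While at least one motor is bound the filament advances at
the unloaded speed of the slowest species currently bound — this
reproduces the observation that mixed-paralog filaments move at nearly
the speed of the slower NM2-B, and it makes single-species velocity
independent of motor number.

When the bound count reaches zero, a rescue window
`τ = τ0 · viscosity` opens: an attachment inside the window continues
the run, otherwise the filament is considered to have diffused away
(`all_detached`). This single parameter is the minimal mechanism for
the methylcellulose effect (≈25 mPa·s, 25-fold above water). `τ0`
(default 10 ms at 1 mPa·s) is a free parameter not constrained by any
published measurement; the default was chosen once so that NM2-A
ensembles are non-processive in aqueous buffer but robustly processive
at 25 mPa·s, which also reproduces the near-complete run-to-actin-end
behavior of NM2-B in methylcellulose. Runs are censored (flagged, and
excluded from run-length fits) on reaching the actin end or the maximum
observation time. Run duration excludes the final unsuccessful rescue
window.

Under these defaults pure NM2-B filaments (30 motors/half) produce an
exponential run-length distribution with a characteristic length of
≈3.5 µm at 43 nm/s — the same order as, though not tuned to, the
measured ≈2 µm. No parameter was adjusted per-observable; the run
length is an emergent property of `r`, `n`, `v0` and `τ0`.

Seeds: every ensemble derives per-run seeds below 2³¹ from the master
seed via `numpy.random.SeedSequence([master, index])`; the recorded
per-run seed replays that run bit-for-bit.

## Synthetic imaging

Filaments are rendered as diffraction-limited 2-D Gaussian spots
(filaments are only ~300 nm long, barely above the resolution limit;
elongation is not modeled). Defaults emulate a 100× TIRF system with a
13 µm-pixel EMCCD: 130 nm/px, PSF σ = 140 nm, 256×256 px fields, 2 s
frame interval. Pixel values are Poisson draws on (signal +
background) plus Gaussian read noise, quantized to uint16; the Poisson
draw is split into a constant background part and a sparse signal part,
which is distributionally identical. Spot photon counts are
(labeled molecules) × (photons per fluorophore per frame); each
molecule carries exactly one fluorophore of its species' color (ideal
HaloTag labeling; a labeling-efficiency knob exists). There is no
photobleaching by default (an optional exponential bleaching rate
exists for robustness tests). The exposure/SNR of the original movies
is unreported; the default 30 photons/fluorophore/frame gives a
peak-pixel SNR ≈ 8.5 for a 30-molecule filament over a background of
200 counts (read noise 3 counts).

The generator emulates: diffraction-limited spots moving
unidirectionally along straight actin segments, exponential run
lengths, binomial co-filament composition with intensity proportional
to labeled-molecule count, and shot + read noise. It does not emulate:
filament stacking/merging, parallel/perpendicular orientation
switching, actin curvature or treadmilling, camera EM-gain statistics,
or spatially varying illumination — so tests passing on synthetic data
validate the estimators and the pipeline plumbing, not robustness to
those real-data complications.

## Tracking

Detection is Laplacian-of-Gaussian at the scale of a 1 µm blob
diameter (σ_LoG = radius/√2), scale-normalized, with 3×3 local-maximum
selection, quadratic sub-pixel refinement, and a quality threshold.
The published analysis settings are kept verbatim in
`tracking.trackmate_compat`: blob diameter 1 µm, threshold range
50–200 (default 100, the geometric midpoint), linking max distance
1 µm, gap-closing max distance 0.5 µm, max frame gap 2, track
displacement filter 150 nm. `quality_gain` (default 6.0) rescales the
raw LoG response into those detector units for the synthetic camera's
count scale; with it, a default 30-molecule spot scores ≈144 and the
worst-case blank-frame response stays below ≈70, so the printed
threshold of 100 separates them.

Linking solves an optimal bipartite assignment per frame pair
(squared-distance cost, opt-out at the distance cap), followed by a
second assignment joining track ends to later starts (gap closing).
Ties are broken by sorting spots within frames (row-major), making the
linker permutation-invariant.

Background subtraction averages a 20-frame signal-free stack and
subtracts it per channel, clipping negatives to zero as in unsigned
image workflows. Because clipping adds a positive bias
(≈ noise·√(1/2π) per pixel) to integrated intensities, photometry (spot
integrals and the 1 µm² two-color ROI sums) is performed on the signed
difference image, with a surrounding annulus/ring subtracted as local
background. The clipped image is used for detection only.

Kinematics: run length is the net start-to-end displacement projected
on the actin direction; mean velocity is run length over track
duration. The displacement filter is applied to net (not path)
displacement. A track is censored when its final position lies within
one PSF σ of the forward actin-segment end, or when it persists to the
last movie frame.

## Estimators

Reference intensities average the per-track mean total intensity of
100%-labeled filaments, each track weighted equally. The motor-bearing
fraction of a co-filament is `R = I_cof / I_ref`; its motor count is
`n = R · n_c` with `n_c = 60`. The NM2-A fraction uses both channels,
each normalized by its pure-filament reference, and is scale-invariant.

Run-length fits exclude censored tracks and values below the 150 nm
filter. The default is histogram least squares (`A·exp(−x/λ)`,
Freedman–Diaconis bins, first edge at the filter), matching how such
distributions are usually displayed; the maximum-likelihood estimate
`λ = mean(x − x_min)` (exact for the truncated exponential by
memorylessness, SE `λ/√n`) is available and is used where an unbinned
estimate is preferable. Because censoring only truncates runs, both the
exclusion rule and a censored-as-complete fit underestimate the true
scale, the exclusion rule more strongly; the fitted λ is therefore a
minimum estimate, and the package's tests assert exactly that ordering.

Velocity distributions get a Gaussian histogram fit; when the fit is
poor (R² < 0.8, as for bimodal paralog mixtures) the arithmetic mean is
the reported statistic. The run-length-vs-motor-number regression is
weighted least squares; the x-intercept `−intercept/slope` estimates
the minimum motor number sustaining processivity, with SE from
first-order propagation using the parameter covariance (a parametric
bootstrap alternative is provided, since the original error estimate's
method is unstated).

## Numerical and design choices

- One filament per actin segment in rendered benchmarks ("rows"
  layout) keeps linking unambiguous; the random layout mode exercises
  placement logic.
- Pipeline `max_time` is capped at the movie span so simulated and
  tracked runs are truncated identically; comparisons of recovered vs
  generating statistics are then unbiased by observation-window
  truncation.
- Degenerate inputs: zero-motor filaments yield a zero-length
  `all_detached` run (not an error); duty ratios of exactly 0 or 1 are
  rejected by the kinetics (no finite rates).
- Problem sizes used in the shipped tests: 2000-run ensembles for
  distributional physics, ≈1150 simulated runs (≈1000 recovered
  tracks) for the full-pipeline recovery at default SNR, 320 rendered
  runs across four labeling conditions for stoichiometry recovery.

## Known limitations

- The independence model makes run length grow exponentially with
  motor number; the measured dependence over 9–18 motors/half is closer
  to linear, so the simulator is not expected to reproduce co-filament
  run-length magnitudes at low motor numbers, only the qualitative
  ordering and selection effects.
- The rescue-window treatment of diffusion is a one-parameter proxy; it
  ignores the geometry of escape and any crowding effect of
  methylcellulose on motor kinetics.
- Strain-dependent (load-dependent) detachment and ADP/actin
  concentration dependence of the duty ratio are out of scope.
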