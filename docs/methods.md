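# Methods

## The measurement model

An immobile fluorophore excited by linearly polarized light absorbs in
proportion to cos² of the angle between the excitation polarization and its
absorption dipole.  When the polarization is rotated continuously at an
angular rate ω (deg/s), the emitted intensity of a dipole at orientation θ
oscillates as

    I(t) = A · cos²(ωt − θ) + offset,

with period 180/ω in time (a dipole is apolar, so θ is defined modulo
180°).  With ω = 20.01°/s and 200-ms frames, one half-period is ≈ 9.0 s
(45 frames).  The sign convention is that the intensity is maximal when the
polarizer angle ωt is parallel to θ; any fixed convention is equivalent as
long as the simulator and the fitter share it, which they do here.  The
offset term exists in the API for completeness but defaults to zero in
fitting, because trajectories are background-subtracted before they reach
the fitter.

The biological use of this signal: a bifunctional rhodamine cross-linked to
the helical protrusion of a surface-immobilized group II chaperonin tracks
the protrusion's axis.  A UV flash photoreleases ATP from caged ATP at a
known time; molecules whose protrusion rotates respond with a step change
in θ, and the angular displacement Δθ = θ_post − θ_pre is the quantity of
interest.  Because of the 180° ambiguity, Δθ is resolved to the
smaller-magnitude representative in (−90°, +90°] (an exact ±90° tie maps
to +90°); positive angles are counterclockwise rotations.

## Phase estimation

`fit_cosine` uses the harmonic linearization
A·cos²(ωt−θ) = A/2 + (A/2)·cos(2ωt − 2θ): ordinary least squares in the
basis {1, cos 2ωt, sin 2ωt} gives coefficients (b₀, b_c, b_s), from which
A = 2·√(b_c² + b_s²) and θ = ½·atan2(b_s, b_c) mapped to [0°, 180°).  When
the offset is constrained to zero, the constant term must equal A/2 and the
linear solution seeds a bounded nonlinear least squares on (A, θ).  The
estimator is exact on noiseless data and matches a brute-force grid search
over θ (0.1° grid with two zoom levels, closed-form amplitude) to better
than 0.05° on noisy windows; both properties are under test.

Validity rules: a fit is usable only if the window spans at least one
modulation half-period (phase is unidentifiable on shorter arcs), has ≥ 6
points, and the *harmonic* amplitude exceeds an amplitude floor (3× the
robust per-point noise, estimated from first differences).  The harmonic
amplitude is the right quantity to gate on: under the offset-free
constraint a constant trace would otherwise be "fit" by a spurious cos²
of arbitrary phase.

Per the analysis procedure, trajectories are averaged over non-overlapping
5-frame blocks (1-s points) before fitting, pre- and post-flash segments
separately so no block spans the flash; frames overlapping the 500-ms UV
pulse are excluded.  The pre window is [0, flash); the post window runs
from the end of the flash to the detected photobleaching point (with a
one-block guard band, since dark frames leaking into a fit bias the phase
far more than trimming a second of signal) or the end of the movie.
Molecules whose post window is shorter than one half-period are excluded
from Δθ statistics.

## Responder classification

A molecule is a *responder* if |Δθ| exceeds a threshold **and** the
orientation switch happens within 1 s of the end of the flash.  The
threshold is 3× the fitted sd of the Δθ distribution from a no-nucleotide
calibration run (≈ 18–20° at the 50 °C photon budget; the function default
falls back to 10° when no calibration is supplied).  The switch time is
localized by a two-model change-point scan over the raw post-flash frames:
the split point minimizing (residuals to the pre-flash model before the
split) + (residuals to the post-flash model after it).  A single-point
residual test was considered and rejected: at the 50 °C brightness the
orientation-change signature on one 1-s averaged point is comparable to 3×
the residual noise, giving ~50% power, whereas the change-point scan uses
the whole post window and localizes the switch to a frame or two.

## Spot detection and trajectory extraction

Detection runs on the mean projection of the first full modulation
half-period, so every orientation contributes equally (a whole-movie
projection would bias against molecules that bleach early; a shorter one
against unlucky phases).  The projection is matched-filtered with a
Gaussian at the PSF scale (σ = 1.3 px) — without it, spots at the 50 °C
brightness (86 a.u. peak over a 20 a.u./px background) sit near the
detection floor.  Local maxima above median + 6 robust sd (MAD) of the
filtered projection are kept, pruned at edges and at < 5 px mutual
distance, refined to subpixel by centroid, and sorted by quality
(peak height in MAD units).

Per spot, `raw` is the 5×5-pixel ROI sum per frame; `background` is the
per-frame median of a surrounding square annulus (2–5 px beyond the ROI)
scaled to the ROI pixel count and smoothed over 25 frames (5 s) in time —
background varies slowly compared with the modulation, and the smoothing
removes most of the estimator's shot noise, which would otherwise be the
dominant noise term in the corrected trace; `corrected = raw − background`.

Photobleaching is located by demodulating the trace with a trailing mean
over one half-period (the mean of cos² over a half-period is exactly ½
regardless of phase): the envelope sits at A/2 while the molecule is alive
and at 0 after, and a level-shift crossing gives a coarse estimate that a
model-based change-point scan (harmonic fitted to clean pre-bleach frames
vs zero) refines to a frame or two.  Near a modulation trough a few frames
genuinely carry no information and the split is taken at the earliest
statistically indistinguishable point.  The dark level uses the envelope
minimum rather than a low percentile, so bleaches near the end of the
movie are still caught.

## The synthetic-data generator

The simulator emulates the acquisition: 300 frames of 200 ms (1 min),
polarizer at 20.01°/s, a 500-ms UV flash at 30 s, epi-illumination of
surface-immobilized molecules at 50 °C.  Defaults follow the experiment's
stated conditions:

| parameter | default | meaning |
|---|---|---|
| active_fraction | 0.10 | fraction of molecules rotating at the flash |
| rotation_means | +34°, −35° (equal weight) | upper/lower-ring rotation peaks |
| rotation_sd | 5° | width of each responder component |
| orientation_jitter_sd | 5° | null-component apparent rotation (fit-noise surrogate) |
| mean_peak_intensity | 170 a.u. at 23 °C | single-molecule ROI-collected brightness |
| intensity_sd | 40 a.u. at 23 °C | brightness spread (width not printed; ~24% CV chosen as typical for single-fluorophore distributions) |
| bleach_rate | 0.052 s⁻¹ (23 °C) / 0.051 s⁻¹ (50 °C) | exponential photobleaching |
| psf_sigma | 1.3 px | isotropic Gaussian PSF |
| background_level | 20 a.u./px | uniform background |
| pixel_noise_floor | 2 a.u. | Gaussian read noise |

Brightness is thermally quenched by I(T) = I(23 °C)·exp(−k_T·(T−23)) with
k_T = ln(170/86)/27 ≈ 0.0252 per °C, exact at both calibration
temperatures.  Brightness is parametrized as the intensity collected in
the standard 5×5 ROI (the PSF stamp is normalized so its central 5×5 sum
is 1), which makes the noiseless render → extract → fit chain an identity
and keeps the printed 170/86 a.u. values meaningful end to end.

Each frame is background plus every molecule's PSF stamp scaled by the
intensity model at the frame-midpoint time (the unbiased phase reference
under continuous rotation); responders switch orientation at the end of
the flash; molecules go dark after their exponential bleach time.  Poisson
shot noise is applied to expected counts (background and per-molecule
stamps drawn separately — Poisson additivity — which is substantially
faster), then Gaussian read noise, then clipping to 16 bit.  Positions sit
on a randomly jittered grid with ≥ 10 px pairwise separation (twice the
ROI side).  All draws derive from a single seed; per-molecule substreams
are keyed by (seed, molecule_id) so a molecule's truth is stable under
changes of population size.

What the generator does **not** model: objective depolarization and
high-NA effects, dipole wobble beyond the static jitter term, stage drift,
defocus, nonuniform background, blinking, and caged-ATP dose–response.
Passing tests therefore demonstrate correctness of the estimators under
the stated noise model, not robustness to every artifact of real
microscopy data.

### Matching the analyzed-molecule counts

Bleach times are drawn from frame 0, so only molecules surviving one
half-period past the flash (≈ 39.5 s) yield an analyzable Δθ record —
about 13% before detection and fit losses, ~10% after.  The experimental
tallies (136 molecules with caged ATP, 75 without) are counts of
*analyzed* molecules, so the condition presets simulate
n = tally / yield molecules (1347 and 743 at the measured yield of 0.101
valid records per simulated molecule) so that the expected number of
analyzable records matches the experiment.  The yield was measured once at
the defaults and is recorded as a constant.

## Population statistics

Distribution summaries are curve-on-histogram least squares — the
convention these distributions are reported in — rather than maximum
likelihood: the reported "peak" is the fitted curve's center.

* **Δθ mixtures** (`fit_gaussian_sum`): 5° bins spanning (−90°, 90°].
  For k=1 all three parameters are free.  For k>1 the component width is
  shared (a satellite component with ~7 samples cannot support a free
  width on 5° bins) and means are seeded by a short shared-width EM pass
  on the raw samples, started from the histogram's well-separated local
  modes with (−35°, 0°, +35°) as documented structural priors when fewer
  than k modes exist; the histogram fit then polishes within a one-bin
  window, so a sparse satellite can neither wander off its mass nor
  collapse onto the dominant null peak.
* **Photobleaching lifetimes** (`fit_exponential_lifetimes`): a·e^(−rt)
  fitted to 2-s bins; censored (never-bleached) molecules are excluded and
  counted; the first two bins are excluded as a boundary-bias guard (when
  lifetimes come from detected trajectories, the caller should widen the
  exclusion to the 9-s detection window).
* **Brightness distributions** (`fit_intensity_gaussian`): single Gaussian
  on Freedman–Diaconis bins; returns the fitted peak and width.
* **Thermal quenching** (`fit_thermal_quench`): I₀·exp(−k_T(T−T₀)) with T₀
  anchored at the coolest measured temperature; k_T is anchor-invariant.

## Numerical choices and degenerate inputs

* Angles are degrees everywhere in files and APIs; radians never leak out.
* Δθ resolution: (raw mod 180) mapped into (−90, 90]; ±90 ties go to +90.
* Flat or sub-floor traces yield `valid=false` fits and are excluded from
  population statistics; records with an invalid side carry NaN angles.
* `block_average` drops a trailing partial block; block time stamps are
  the mean of member times.
* An all-zero trace "bleaches" at frame 0; a constant bright trace never
  does.
* The simulator warns (and clips) if expected counts approach the 16-bit
  ceiling, and refuses molecule positions whose PSF stamp would leave the
  field.

## Problem sizes

The acceptance script and test suite run the full movie pipeline at the
study scale: 50 seeded caged-ATP replicates of 1347 molecules on a
480×480×300 stack (~11 s each), one no-nucleotide calibration run, and
sampling-level checks at n = 500–10,000 where imaging adds nothing to the
quantity under test (bleach-rate and brightness-distribution recovery use
the generator's truth draws directly).

## Known limitations

* At the 50 °C photon budget the per-molecule phase noise is ≈ 2°, so the
  measured Δθ components are ≈ 6–6.5° wide against the generator's 5°;
  with ~7 samples per satellite component the per-replicate outer-peak
  estimate scatters by ≈ 3–4°, and a fraction of replicates miss the
  generating peak by more than 5° — an information limit of n=136 with a
  10% active fraction, not an estimator defect (the mean over replicates
  is unbiased to well under a degree).
* Bleach localization degrades to ±2–3 s when the bleach falls in a
  modulation trough; the fit guard band absorbs this.
* The responder latency is quantized by the frame interval and the
  change-point scan; sub-frame kinetics are out of scope.
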