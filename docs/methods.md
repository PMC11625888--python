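# Methods

This note documents the models, conventions and numerical choices behind each
pipeline stage, what the synthetic-data generators do and do not emulate, and
the design decisions taken where the underlying assay descriptions leave the
computation open.

## Optomotor index and tuning curves

**OMI convention.** The optomotor index of a trial is the *net signed*
angular displacement (end minus start of the unwrapped trajectory) multiplied
by the stimulus direction, in radians. Net displacement — rather than path
length or summed positive increments — is used because it is antisymmetric in
stimulus direction, which is what makes averaging clockwise and
counter-clockwise trials meaningful: a fish drifting consistently one way
regardless of the grating cancels out of the four-trial mean. The unit
(radians, net) is recorded in dataset metadata since "angular movement" is
otherwise ambiguous.

**Unwrapping.** Tracked angles arrive wrapped to (-π, π]; adjacent-sample
jumps above π are corrected by ±2π (`numpy.unwrap`). This is exact whenever
the true per-sample rotation is below π — comfortably satisfied at 30 Hz
video and zebrafish swim speeds (a fish would need to spin at >15 rev/s to
break it).

**Averaging and normalization.** Per fish × spatial frequency the signed
OMIs are averaged arithmetically with the contributing trial count recorded;
missing trials are never imputed. The whole dataset is then divided by the
mean OMI of a designated reference group at a designated reference frequency
(the larval assay uses the wild-type response at 0.0155 c/°, the 2-week assay
0.0620 c/°), making the reference condition's group mean exactly 1.

**Tuning model.** g(f) = A·exp(−(log₁₀f − log₁₀p)²/(2σ²)). Base 10 for the
log is a convention (any base only rescales σ) and is recorded in output
metadata. Fitting is unweighted least squares on per-fish points. Fitting
per-fish points rather than group means keeps the F-test's N well defined
and uses all trial-averaged observations; fitting group means instead is
available by passing a response column of group means.

**Optimization.** Parameters are fit as (A, log₁₀p, σ) with
`scipy.optimize.least_squares` (trust-region reflective, xtol = ftol =
1e-12) under bounds A ∈ [0, 10·max|y|], p within the tested frequency range
extended 4× on both sides, σ ∈ [0.05, 2] log₁₀-units. The objective is
multimodal in p, so 8 starts with log-spaced initial peaks across the tested
range are used and the best solution kept; exact ties break toward smaller
σ, then smaller p, making results deterministic given input order. All-zero
responses are a legal degenerate input: A = 0 fits exactly, p and σ are
unidentifiable and are reported at nominal values with an `unidentifiable`
flag rather than as garbage estimates.

**F-tests.** Group comparison uses the extra-sum-of-squares form
F = ((RSS_R − RSS_F)/(k_F − k_R))/(RSS_F/(N − k_F)), which for a common
dataset is algebraically equivalent to comparing r² between models but does
not require a well-defined total sum of squares. The omnibus comparison fits
3 parameters per group against one pooled 3-parameter curve (df = 3(G−1),
N−3G); a nested comparison shares one named parameter across groups
(df = G−1, N−3G) and *refits the restricted model jointly* — constraining
full-fit estimates post hoc would not minimize the restricted RSS. The
restricted refit is seeded from the full fits plus a sweep of shared values
across the parameter's bounds. Because the restricted space is a subset of
the full space, RSS_R ≥ RSS_F must hold; a violation beyond round-off
(relative 1e-6) raises rather than silently reporting a negative F, while
round-off-sized violations clamp to F = 0. A perfect full fit with an
imperfect restricted fit reports F = +∞, p = 0. Significance level handling
is left to the caller: tests report F, df and p, they do not decide.

Validation (rerun by `scripts/acceptance.py` and the test suite): under the
study conditions (2 × 14 fish, six frequencies, normalized-OMI noise SD 0.1)
the omnibus test's empirical size at α = 0.05 over 500 null cohorts falls
within [0.03, 0.07], its power against a 30% amplitude deficit exceeds 0.5
(measured ≈ 1.0), median absolute recovery error is ≈ 2% for amplitude and
peak frequency, and the nested F statistic agrees with an independent
dense-grid + simplex refit oracle to ~1e-13 relative.

## ERG features

Baseline is the mean voltage over the 50 ms before stimulus onset. The
a-trough is the minimum in a search window of 3–100 ms post-onset; the
b-peak is the maximum strictly after the a-trough sample up to 300 ms
post-onset (the b-wave is defined trough-to-peak, so its search cannot start
before the trough). Extrema take the earliest sample on exact ties.
Amplitudes: a = baseline − trough, b = peak − trough; implicit times from
onset. The window bounds are not specified by the assay description; these
defaults are sized to typical zebrafish flash-ERG morphology and are
explicit parameters recorded in outputs.

A detection floor — 3× the baseline-window SD by default — separates a real
a-trough from noise minima: a flat trace yields amplitudes 0, undefined
times and a `no-response` flag instead of spurious extrema. No smoothing is
applied before extremum detection by default; an optional moving-average
width is a configuration knob recorded in the output flags.

Group averages are pointwise means with SEM = SD/√n (n−1 denominator),
computed only over traces sharing the exact time grid and intensity — no
resampling. A single trace yields an undefined (NaN) SEM, flagged, never 0.
Repeated flashes at the same intensity (the three-repeat low-intensity
protocol) are averaged per eye before tabulation into the tidy
intensity-response table.

## OCT biometry

Retinal radius follows the identity axial length − lens radius (lens centre
to RPE). This equals the optical retinal radius only when the
cornea-to-anterior-lens distance is negligible relative to the eye — the
standard small-fish-eye assumption, adopted here deliberately. Both eyes of
a fish are treated as independent observations, since axial myopia can
develop in a single eye.

Landmark detection on synthetic B-scans averages the intensity profile over
a central 10-column band, selects the four most prominent peaks
(`scipy.signal.find_peaks`, prominence threshold 10% of the profile's
dynamic range), orders them by depth, and refines each to sub-pixel by
parabolic interpolation through the peak and its neighbours. Detection
returns pixels; biometry requires an explicit pixel-to-µm calibration. This
detector is a documented stand-in validated only on synthetic images — real
OCT segmentation (speckle, curved surfaces, instrument formats) is out of
scope. The `relative_refraction` summary labels a case-minus-control mean
R/L difference as relative myopia (> 0), relative hyperopia (< 0) or
emmetropic (within 1e-3); it is descriptive, with inferential statistics
left to external tools on the tidy tables.

## Layer profiles

Profiles are columnwise means over a vertically centred band of 150 rows
(the ROI height of the original workflow). The curved-section straightening
step happens upstream in an image tool; this module starts from straightened
images, which the generator produces directly. Pixel windows are 1-based
inclusive exactly as published (2-day: 1–90 / 91–300 / 301–390; 4-week:
1–90 / 91–330 / 331–455, totalling the 390 / 455-px ROIs); internally they
are 0-based half-open slices.

IPL rescaling stretches the whole profile by factor (control mean IPL
width)/(this profile's IPL width) using linear interpolation — the behaviour
of an image-editor resize is unspecified, and linear is the minimal, exactly
testable assumption. New pixel i samples the old profile at coordinate
i/factor. The order of operations is resample **then** max-normalize (the
alternative order is not distinguishable from the published description);
the order is recorded in profile metadata. After a non-integer rescale the
profile can miss the fixed ROI width by a pixel or two; since the ROI is
anchored on the INL side, the discrepancy is reconciled at the right edge
(trim or zero-pad), also recorded in metadata. Max-normalization requires a
positive maximum; an all-zero profile raises rather than producing NaNs.

## qPCR (2^-ddCt)

Replicate Cts are averaged per sample × gene first; dCt = mean Ct(target) −
mean Ct(reference); ddCt subtracts the *calibrator group's mean* dCt (not a
single designated sample) — this makes the geometric mean of calibrator fold
changes exactly 1, a useful invariant. When a timepoint column is present
the calibrator mean is computed per timepoint stratum, matching designs that
normalize within each sampling time. Amplification efficiency is fixed at 2
(the 2^-ddCt assumption); efficiency correction is out of scope.

## Synthetic-data generators

Every generator is a pure function of its spec and seed (no global random
state; cohort-level generators derive per-item streams from the one seed),
and ground truth always travels with the data.

* **Trajectories** follow dθ/dt = gain·direction·speed plus white noise *in
  velocity* (increments N(drift·dt, noise²·dt)), a drift–diffusion view of
  swim bouts chosen because displacement variance then grows linearly with
  time and is analytically available for tests. Default stimulus: 0.5 rad/s
  for 30 s sampled at 30 Hz.
* **Cohorts** draw each fish × frequency gain once as curve + N(0, sd) and
  reuse it across that condition's four trials (2 CW + 2 CCW). Trial-to-trial
  OMI variance structure in real data is unknown; this noise model is a
  stand-in that produces exactly the "tuning point = curve + Gaussian noise"
  structure the fitting and F-test calibration studies assume, not an
  inference about real fish.
* **ERG traces** are a difference of gamma-shaped kernels
  K(t) = (t/t_p)^(k−1)·exp((k−1)(1−t/t_p)), unit peak at an explicit peak
  time (shape k = 8 by default), giving closed-form component truth; the
  stored trace-level truth is the noiseless sum's extrema on the sample
  grid, since overlapping kernels shift the summed extrema slightly.
  Defaults: 100 µV at 20 ms (a), 300 µV at 60 ms (b), 1 kHz sampling.
* **B-scans** place Gaussian axial bands (SD 3 px) at the four landmark
  rows, so sub-pixel truth is the band centre; a fixed 12-px top pad keeps a
  cornea at axial position 0 as an interior peak (it cancels in every
  biometry difference). Additive Gaussian noise stands in for speckle; real
  speckle physics is not modelled.
* **Layer images** are piecewise-constant columns plus Gaussian noise.
* **Ct tables** put the reference gene at a fixed base cycle (18) and target
  genes at base + per-gene offset − log₂(fold), so each group's true ddCt is
  −log₂(fold) exactly; the calibrator group's folds are required to be 1 so
  the attached truth equals what the pipeline recovers at zero noise.

With all noise parameters at zero, every downstream extraction recovers
ground truth exactly to grid resolution — the test suite enforces this.

What the generators deliberately do **not** emulate: real locomotor bout
statistics, ERG oscillatory potentials, OCT speckle and instrument optics,
staining variability, or PCR efficiency ≠ 2. Passing tests therefore show
that the *computations* are correct and well calibrated under their stated
assumptions, not that those assumptions hold for any particular dataset.

## Validation study sizes

The bundled studies use 200 cohorts (parameter recovery), 500 null cohorts
(test size), 200 deficit cohorts (power), 20 cohorts for the
nested-vs-oracle comparison, 200 noisy ERG traces, and 100 jittered B-scans;
each cohort is 2 groups × 14 fish × 6 frequencies × 4 trials, the design of
the assays this pipeline mirrors.

## Known limitations

* The tuning optimizer is multi-start, not provably global; the grid-refit
  oracle comparison bounds the risk under the tested conditions only.
* OCT landmark detection assumes four dominant axial peaks; pathological
  geometries (overlapping bands) raise a landmarks-not-found error rather
  than guessing.
* Layer-window sums assume the profile already matches the scheme's ROI
  width; arbitrary-length profiles need custom windows.
* The pipeline exports tidy tables for factorial ANOVA but intentionally
  does not perform those analyses itself.
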