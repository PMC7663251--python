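# Methods

## Tilt from a static accelerometer

The measurement model assumes the sensor is held still during each ~5 s
capture, so the accelerometer reads (a rotated copy of) the gravity vector
plus noise. Under that assumption pitch and roll are pure geometry:

    θ = atan( −Aₓ / √(A_y² + A_z²) ),   φ = atan2(A_y, A_z)

with X the sagittal axis, Y the frontal axis, and gravity along +Z when
level. Pitch is implemented with the four-quadrant arctangent of
(−Aₓ, √(A_y²+A_z²)); because the second argument is non-negative the result
stays in [−90°, 90°], identical to the single-quadrant form wherever that
is defined, and well behaved at ±90°. Both angles are invariant under
positive scaling of the input, so uncalibrated gains and raw sensor units
do not bias the estimate; an exactly zero vector is rejected as unphysical.
Angles are degrees at every public surface, radians internally.

Only pitch is used clinically: the reference method (lateral radiograph of
the anterior pelvic plane) measures sagittal tilt only.

## Stable-window selection

Patients sway and occasionally knock the device. Rather than averaging the
whole capture, the estimator selects the most stable fixed-length segment:

1. each channel is smoothed with a zero-phase moving average — a box filter
   run forward then backward, equivalent to one pass of the triangular
   kernel box∗box. Trace boundaries are reflect-padded, which avoids
   endpoint transients that would otherwise bias early/late windows;
2. a per-sample pitch series is computed from the smoothed channels;
3. candidate windows of length 300 ms starting at multiples of the 0.1 s
   hop are scored by the standard deviation of pitch within the window
   (population SD; the argmin is unaffected by the denominator choice);
4. the minimum-SD window wins, ties going to the earliest start
   (deterministic and reproducible); the reported tilt is the **mean**
   smoothed pitch over that window.

Three choices here were genuinely open and are deliberate defaults, all
configurable:

* **filter length 0.05 s** (10 samples at 200 Hz): the hop is prescribed
  but the filter length is not; 50 ms is long enough to suppress sensor
  noise yet short enough not to smear a 300 ms stability structure.
* **stability scored on pitch**, not on raw channels: pitch is the
  measurand, and channel-level variance can disagree with pitch variance
  under roll changes.
* **mean as the window summary**: under the static assumption the window
  samples are i.i.d. around the true tilt, so the mean is the
  minimum-variance summary.

Candidate starts are only those with a full window inside the trace — no
partial windows. A trace shorter than the window is an error naming the
required and actual durations; captures shorter than the recommended 5 s
only warn.

## Screening protocol and classification

A session is an ordered capture list following the clinical protocol:
a fresh standing capture precedes each functional capture (flexed-seated,
step-up). Each functional position is paired with its **nearest preceding**
standing baseline — the protocol interleaves standings precisely so the
baseline is current — and the tilt change is

    Δθ = θ_functional − θ_standing,   positive = more anterior tilt.

Working in changes cancels any constant sensor-mounting offset, which is
why no pelvis-to-sensor calibration is needed. A mounting that flips the
pitch sign is handled by a configuration flag.

High pelvic mobility is declared when |Δθ| ≥ 13°, boundary inclusive. The
absolute-value form is the default because clinically relevant mobility
can be anterior or posterior; a signed variant (Δθ ≥ 13° only) is provided
for sensitivity analyses. The session-level screen ORs the per-position
flags (screening favours sensitivity); `fs_only` restricts the decision to
the flexed-seated change, the position the device's published classifier
was evaluated on.

## Validation statistics

* **Bland–Altman**: bias = mean(device − reference); SD with n−1
  denominator; limits of agreement bias ± k·SD, k = 1.96 by default
  (the ~95% interval). Per-pair (mean, difference) coordinates are
  returned for plotting.
* **Diagnostics**: sensitivity TP/(TP+FN), specificity TN/(TN+FP),
  accuracy (TP+TN)/total, with the reference classification as truth. A
  zero denominator yields NaN (undefined), never 0.
* **Correlation**: Spearman by default (the validation analysis was
  rank-based), Pearson optional; the squared coefficient is reported
  alongside for comparability with R² figures. Constant inputs give NaN.
  p-values are reported but nothing in the package keys off them.
* **Error distribution**: absolute errors pooled over positions; median
  and Q3 via linear interpolation between order statistics (numpy default,
  R type 7 — stated in the output because quartiles of small samples
  depend on the rule); histogram binned to the nearest degree with a
  Poisson rate fitted by maximum likelihood (the mean of the binned
  errors), for a histogram overlay.

## Synthetic cohorts

The simulator exists so every stage is testable against known truth; its
defaults describe one plausible pre-THA population, fixed once:

| parameter | default | rationale |
|---|---|---|
| FS tilt change | N(−10°, 12°) | spans both directions, ≈40% of patients beyond 13° — comparable to published screening prevalence |
| SU tilt change | N(2°, 4°) | SU occupies a much narrower range than FS |
| standing tilt | N(0°, 5°) | baseline orientation varies modestly between patients |
| reference noise | SD 2.0° on each reference Δ | yields pooled median absolute error ≈1.3° and Q3 well under 5°, the regime the device was validated in |
| sensor white noise | 0.01 g per channel | research-grade MEMS accelerometer held still |
| sway | 0.5° sinusoid at 0.3 Hz, random phase | quiet-stance sway scale; a single sinusoid, as no sway spectrum is prescribed |
| knocks | prob 0.2/capture, 0.5 g half-sine, 0.1 s | transient artefact (device striking seat); confined so a clean final ≥1 s always remains |
| SU error slope | 0.15·&#124;Δ&#124; (SD of an extra device-side error) | reproduces the observed magnitude–error correlation for SU; a modelling device, not a claimed mechanism |
| covariates | age N(57.4, 9.4), ~53% female, BMI N(29.2, 4.6) | published cohort demographics; BMI and sex have **no** effect on simulated error, matching the null findings |

Traces are gravity-only with these disturbances; the capture sequence is
standing, FS, standing, SU at 200 Hz, 5 s each. Everything is deterministic
given the seed (one `numpy` Generator drives the whole cohort).

What the simulator does **not** model: skin-movement artefacts, multi-band
sway, spine–pelvis coupling, radiograph landmarking variability beyond
Gaussian noise, or any BMI/sex dependence of error. Passing tests on
synthetic cohorts therefore demonstrate the *pipeline's* correctness and
noise robustness under this error structure — not the device's clinical
performance, which only the published patient study speaks to. Per-patient
raw values were never published, so population defaults are stand-ins.

## Numerical and interface choices

* Window SD ties break to the earliest window; `argmin` guarantees it.
* Ingest rejects NaN/Inf and non-monotone timestamps outright.
* Sample rate is taken from the file's median timestamp spacing when not
  given; a unit scale factor converts raw sensor units to g on read.
* Angles are serialized with 3 decimal places in all reports; every CLI
  run logs its full effective configuration to stderr, and reports embed
  it, so any two runs with identical config and inputs agree byte-for-byte.
* Problem sizes in the test-suite and acceptance script (200-patient
  recovery cohorts, 40-patient noise-free controls, 50-patient end-to-end
  runs, ~100-trace brute-force sweeps) were chosen to make the Monte-Carlo
  checks stable at fixed seeds while keeping the whole suite fast.

## Known limitations

* The static (gravity-only) assumption fails for dynamic movement;
  gyroscope/magnetometer fusion is out of scope.
* Supine baselines, intra-operative use and surgical-planning outputs are
  out of scope.
* The published screening counts total 33 entries against a 32-patient
  cohort, and the FS correlation is reported as an R² from a rank
  correlation; both inconsistencies are taken as printed and surfaced
  here rather than resolved.
* The published lower limit of agreement for SU (−5.30°) is not exactly
  recoverable from the printed bias and SD (0.06 − 1.96·2.74 = −5.31°);
  the printed summary values are evidently rounded. The upper limit
  (5.43°) is recovered exactly.
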