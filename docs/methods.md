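# Methods

## Measurement model

The pipeline scores a scripted alternating-occlusion sequence recorded with a
binocular eye tracker. Both eyes are expressed on one screen-azimuth axis
(positive toward the subject's right, origin at the fixation target), which
makes the sign convention uniform: esophoria positive, exophoria negative,
for either occluded eye. Deviations are computed as angles in degrees and
converted to prism diopters once, at the end, via 100·tan θ — summing angles
before the tangent is the geometrically coherent composition; below ~15 PD
the difference from summing prism values is negligible, but it is pinned by
test.

Per occlusion, the reference is always the *immediately preceding* binocular
phase, never a pooled baseline: slow drifts of calibration or head position
then cancel to first order. The phase position is the median of the last
0.5 s of the phase (125 samples at 250 Hz), which makes the estimate robust
to uncorrected transients and independent of the occluder's 0.27 s closing
ramp and of most of the vergence transient, as only the settled end of each
5 s phase is used.

The *1-eye* method uses the occluded eye's displacement alone, mimicking the
clinical prism cover test. The *2-eyes* method adds the fixating eye's
displacement with the sign the relative-deviation definition dictates; that
term is the eye's fixation-disparity component, added when the fixating eye
moves with the occluded eye and subtracted when it moves against it. Note a
consequence of this literal formulation: a purely conjugate displacement of
both eyes *inflates* the 2-eyes value rather than cancelling. The method
relies on the validity rule — an occlusion counts only when
|Δocc| > |Δfix| — to reject such version movements; we implement the
equations literally plus that rule rather than "correcting" them, and flag
|Δfix| above a 1 PD equivalent as a possible tropia/saccade diagnostic
(`tropia_flag`) without diagnosing.

Invalid occlusions are excluded per occlusion, not per test: the aggregate
is the median of the valid subset, with a configurable minimum count
(`min_valid`, default 1) below which the result is `no_measurement`. A
strict reading of the rule means a perfectly orthophoric, noise-free subject
yields *no measurement* (0 > 0 is false); with realistic noise roughly half
the occlusions pass and the median is near zero, so the verdict is either a
near-zero value or "no measurable phoria" — both correct at orthophoria.
Direction is classified from the 2-eyes median (|het| < 1 PD → ortho), and
reported `inconsistent` when valid occlusions disagree in sign while all
exceed the orthophoria threshold in magnitude.

## Parameters that matter

| parameter | default | unit | why |
|---|---|---|---|
| blink pad | 0.100 | s | artifact guard around blinks; results are insensitive up to 200 ms, so it is configurable |
| min blink duration | 0.02 | s | shorter invalid runs are sensor dropouts, interpolated without padding |
| estimation window | 0.5 | s | settled tail of each 5 s phase |
| min window quality | 0.5 | fraction | a phase estimate is withheld when fewer than half the window samples are measured (valid and not interpolated) |
| orthophoria threshold | 1.0 | PD | deviations smaller than this are classified ortho |
| LoA multiplier | 1.96 | – | normal-theory 95% limits of agreement; t-based small-sample limits deliberately not used |

Medians with an even count use the mean of the two central values (the
conventional definition).

## Synthetic recordings

The simulator emulates the trace morphology of such tests: binocular phases
sit at per-eye fixation-disparity offsets; on occlusion the covered eye
relaxes exponentially (τ, default 1.0 s) toward its phoric angle plus its
fixation-disparity offset, gated by the occluder ramp, while the fixating
eye re-fixates the target (τ/2) and drifts with a proportional same-direction
Hering coupling (gain default 0.05 — an engineering choice; the physiology
is only qualitatively constrained). The occluded eye's noiseless endpoint
displacement equals exactly `pd_to_deg(true phoria)`, so pipeline recovery
error is attributable to the estimator. With τ = 1 s the approach term
leaves ≈1% of the deviation unreached in the scoring window, i.e. ≈0.04 PD
at 4 PD and ≈0.14 PD at 14 PD — the dominant term in the recovery error
budget and well inside the 0.3 PD recovery tolerance we test.

Conjugate saccades (Poisson; lognormal amplitude, median 1°, σ_log 0.5,
random sign) are injected as steps persisting to the end of the containing
phase; eyes re-acquire their targets at the next phase boundary. The
fixating eye's visually driven corrective saccade during occlusion is *not*
modeled — this is precisely the non-cooperative case the validity rule must
reject, and modeling the correction would hide it. Blinks are Poisson
binocular track-loss events (default 0.1/s, 150 ms). Sensor noise is i.i.d.
Gaussian per sample and eye (default 0.05°). All randomness flows from the
config seed; identical config + schedule + seed reproduce the recording bit
for bit.

Simulated clinical comparators: the prism-bar cover test brackets the
(noise-perturbed) neutralization point on the standard step ladder
(1, 2, 4–20 by 2, 25–45 by 5 PD) and returns the midpoint of the bracketing
steps (the step itself when hit exactly); the modified Thorington adds
response noise, rounds to the card's 1 PD resolution and clips at ±28 PD.
Comparator noise defaults (1.5 / 1.0 PD) put their simulated repeatability
in the 1–2 PD range reported for these clinical tests.

What the simulator does **not** emulate: calibration error and slow drift,
torsion and vertical vergence, pupil-size artifacts, realistic vergence
velocity profiles, within-test physiological variability of the phoria
itself. Consequently the simulated intrasession within-subject SD reflects
only sensor noise and the estimator (~0.05 PD at 0.1° noise), far below
clinical values — passing recovery tests demonstrates the pipeline's
correctness, not field-level precision on humans.

## Numerical and design choices

- Time is seconds internally; millisecond timestamps are converted on input.
  Rate is inferred from the median timestamp step and must agree with a
  declared rate within 1% (catches unit mistakes). A gap exceeding two
  sample periods is a format error naming the row; samples are never
  silently dropped.
- Missing gaze on input may be an empty field, `NaN` or `.`; internally a
  validity flag. The ASC reader requires an explicit screen-to-degree
  mapping because exports do not declare their gaze units.
- Overlapping padded blink spans are merged before interpolating; spans
  abutting a recording edge (no valid boundary sample) remain invalid with a
  warning, so the affected phase is rejected by the quality rule instead of
  being filled with an extrapolation.
- Interpolation is per-eye and univariate in time; applying it twice equals
  applying it once, and untouched samples are bit-identical.
- The within-subject SD is the square root of the unweighted mean of
  per-subject sample variances (n−1 within subject); subjects with fewer
  than two values are excluded with a warning.
- Bland–Altman correlation of difference vs mean is reported as missing when
  either series is constant (undefined correlation). Signed and absolute
  comparisons are both supported; the absolute transform is applied by the
  caller, never hidden inside the statistic.
- Acceptance-scale problem sizes: the recovery sweep uses 9 phoria levels ×
  20 seeds of full 60 s recordings at 250 Hz; the cohort statistics use 12
  subjects × 2 sessions. These sizes give stable estimates for the checks
  performed while keeping the whole reproduction run to a few seconds.

## Known limitations

- Paralytic or intermittent heterotropias are out of scope: the method flags
  suspicious fixating-eye movement but does not measure tropias.
- Vertical channels pass through for QC only; no vertical phoria output.
- The 2-eyes equations' conjugate-inflation ambiguity (above) is inherited
  by design; the validity rule is the sole guard.
- The EyeLink reader covers a minimal ASC dialect (sample lines and
  SBLINK/EBLINK events), not full EDF parsing.
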