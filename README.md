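# covertest

Automated, objective cover test: heterophoria measurement from binocular
eye-tracker recordings.

Heterophoria is the latent deviation of the visual axes that appears only
when binocular fusion is disrupted, e.g. by covering one eye. Clinically it
is measured with the cover-uncover test (prism bar) or the modified
Thorington test, both limited by examiner or patient subjectivity. With an
infrared-transparent occluder and a binocular eye tracker the covered eye
remains visible, so the whole test can be scripted and scored objectively.
`covertest` implements that scoring pipeline for such recordings, plus the
repeatability/agreement statistics used to validate it and a synthetic-trace
simulator so every stage is testable without recorded data.

## Method

The scripted sequence is 3 cycles of *binocular fixation → left-eye
occlusion → binocular fixation → right-eye occlusion*, 5 s per phase (60 s,
six occlusions). Processing:

1. **Blink handling** — 100 ms before and after each blink are discarded and
   bridged by per-eye linear interpolation; interpolated samples are tagged
   so window-quality checks can discount them.
2. **Phase positions** — the eye position of each phase is the median of its
   last 0.5 s.
3. **Per-occlusion phoria** — with Δocc / Δfix the occluded / fixating eye's
   displacement (degrees, screen azimuth positive rightward) from the
   immediately preceding binocular phase:

   * *1-eye* method (what a prism cover test sees):
     `het = 100·tan(+ΔL)` for left-eye occlusion, `100·tan(−ΔR)` for
     right-eye occlusion.
   * *2-eyes* method (heterophoria as a relative deviation; the fixating-eye
     term is its fixation-disparity component):
     `het = 100·tan(ΔL + ΔR)` resp. `100·tan(−ΔR − ΔL)`.

   Esophoria is positive, exophoria negative (prism diopters, PD;
   1 PD deflects a ray 1 cm at 1 m, θ degrees ↔ 100·tan θ PD).
   An occlusion is valid only when |Δocc| > |Δfix|; otherwise the movement
   is better explained by a conjugate saccade of both eyes and no phoria is
   measured for that occlusion.
4. **Aggregation** — the final heterophoria is the median across valid
   occlusions; per-eye phorias are medians over the three left- resp.
   right-eye occlusions; |het| < 1 PD is classified as orthophoria.

The `agreement` module provides Bland–Altman limits of agreement,
within-subject SD (repeatability), direction-concordance tables and the
Bonferroni level helper. The `simulate` module generates recordings with
known ground truth (exponential approach of the occluded eye to its phoric
position, Hering-coupled drift of the fixating eye, fixation-disparity
offsets, conjugate saccades, blinks, sensor noise, the occluder's 0.27 s
closing ramp) and simulated prism-bar / Thorington comparator measurements.

## Worked example

```python
import numpy as np
from covertest import (SimulationConfig, default_schedule, simulate_recording,
                       run_covertest)

schedule = default_schedule()                # 3 cycles x 5 s phases = 60 s
cfg = SimulationConfig(true_phoria=-4.0,     # 4 PD exophoria (eso positive)
                       noise_sd=0.1, seed=11)
rec, truth = simulate_recording(schedule, cfg)
result = run_covertest(rec, schedule)
print(f"status      : {result.status}")
print(f"het (2-eyes): {result.het_2eyes:+.2f} PD   ({result.direction})")
print(f"het (1-eye) : {result.het_1eye:+.2f} PD")
print(f"per eye     : LE {result.het_LE:+.2f} PD, RE {result.het_RE:+.2f} PD")
print(f"valid occlusions: {result.n_valid}/6")
```

prints

```
status      : ok
het (2-eyes): -4.14 PD   (exo)
het (1-eye) : -3.94 PD
per eye     : LE -4.18 PD, RE -4.14 PD
valid occlusions: 6/6
```

i.e. the injected 4 PD exophoria is recovered within the sensor-noise budget
(0.1° noise, six-occlusion median), all six occlusions passed the
displacement-comparison rule, and the two computation methods agree because
no fixating-eye drift was simulated beyond its default coupling.

## Command line

```
covertest run --gaze gaze.csv --out result.json --report audit.csv
covertest run --gaze export.asc --format asc --config mapping.yaml --out result.json
covertest agree --pairs pairs.csv            # Bland-Altman of columns a,b
covertest repeatability --long long.csv      # within-subject SD
covertest simulate --seed 3 --out sim/ --subjects 5
```

`covertest run` exits 0 on a measurement and 3 when every occlusion failed
the validity rule (no measurement). Gaze input is a delimited table with a
header (column mapping configurable) or a minimal EyeLink-ASC-style text
export with an explicit screen-to-degree mapping.

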