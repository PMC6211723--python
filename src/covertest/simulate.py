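"""Synthetic binocular cover-test recordings with known ground truth.

The generator emulates the trace morphology seen in automated cover tests:
during binocular fixation both eyes sit at their fixation-disparity offsets;
when one eye is occluded it relaxes exponentially toward its phoric position
while the fixating eye re-fixates the target (shedding its own fixation-
disparity component) and may drift slowly in the same direction as the
covered eye (Hering coupling).  Conjugate saccades, blinks with track loss,
the occluder's finite closing time and Gaussian sensor noise are injected on
top.  Every random element flows from the seed: identical config + schedule
+ seed reproduce the recording bit for bit.

Also provided: simulated clinical comparators (prism-bar cover test with the
standard step ladder, modified Thorington with 1 PD resolution) and a cohort
generator for end-to-end agreement/repeatability studies.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from .errors import ParameterError
from .gaze_io import GazeRecording, TestSchedule
from .preprocess import pd_to_deg

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "SubjectRecord",
    "PRISM_BAR_STEPS",
    "simulate_recording",
    "simulate_clinical",
    "simulate_cohort",
]

#: prism-bar powers (PD): 1, 2, then 4–20 in steps of 2, then 25–45 in steps
#: of 5; 0 closes the ladder from below.
PRISM_BAR_STEPS = (0, 1, 2, 4, 6, 8, 10, 12, 14, 16, 18, 20, 25, 30, 35, 40, 45)

THORINGTON_RANGE = 28.0  # PD, card limit in each direction


@dataclass
class SimulationConfig:
    """Generative parameters of one synthetic cover-test recording.

    Angles are degrees, phorias prism diopters (eso positive).  The occluded
    eye approaches (phoric angle + its fixation-disparity offset) as
    1 − exp(−t/τ), gated by the occluder's closing ramp; uncovering returns
    eyes to the binocular state with time constant τ/2.
    """

    true_phoria: float = 0.0  # PD, eso positive
    phoria_asymmetry: float = 0.0  # PD, LE-occlusion minus RE-occlusion truth
    fixation_disparity_L: float = 0.0  # deg azimuth offset during binocular viewing
    fixation_disparity_R: float = 0.0
    approach_tau: float = 1.0  # s, occluded eye's exponential time constant
    hering_gain: float = 0.05  # fixating-eye drift per unit occluded-eye movement
    saccade_rate: float = 0.0  # conjugate saccades per second
    saccade_amp_median: float = 1.0  # deg, lognormal amplitude median
    saccade_amp_sigma: float = 0.5  # lognormal sigma (log scale)
    blink_rate: float = 0.1  # blinks per second
    blink_duration: float = 0.15  # s of binocular track loss per blink
    noise_sd: float = 0.05  # deg, Gaussian sensor noise per sample per eye
    occluder_ramp: float = 0.27  # s for the occluder to close fully
    rate: float = 250.0  # Hz
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rate <= 0:
            raise ParameterError("rate must be positive")
        if self.approach_tau <= 0:
            raise ParameterError("approach_tau must be positive")
        if not 0.0 <= self.hering_gain < 1.0:
            raise ParameterError("hering_gain must lie in [0, 1)")
        if self.noise_sd < 0 or self.blink_rate < 0 or self.saccade_rate < 0:
            raise ParameterError("rates and noise must be non-negative")


@dataclass(frozen=True)
class GroundTruth:
    """What the generator actually injected, for recovery checks."""

    true_phoria: float  # PD
    true_phoria_LE: float  # PD measured at left-eye occlusions
    true_phoria_RE: float  # PD measured at right-eye occlusions
    saccades: Tuple[Tuple[float, float], ...]  # (time s, amplitude deg)
    blinks: Tuple[Tuple[float, float], ...]  # (start s, end s)


def _poisson_events(rng: np.random.Generator, rate: float, t0: float, t1: float):
    if rate <= 0:
        return np.empty(0)
    n = rng.poisson(rate * (t1 - t0))
    return np.sort(rng.uniform(t0, t1, size=n))


def simulate_recording(
    schedule: TestSchedule, cfg: SimulationConfig
) -> Tuple[GazeRecording, GroundTruth]:
    """Generate one binocular recording following ``schedule``.

    The occluded eye's noiseless endpoint displacement equals exactly
    ``pd_to_deg`` of that occlusion's true phoria, so any recovery error of
    the pipeline is attributable to the estimator, not the generator.
    """
    rng = np.random.default_rng(cfg.seed)
    n = int(round(schedule.duration * cfg.rate))
    t = schedule.start + np.arange(n) / cfg.rate

    phoria_le = cfg.true_phoria + cfg.phoria_asymmetry / 2.0  # at LE occlusion
    phoria_re = cfg.true_phoria - cfg.phoria_asymmetry / 2.0  # at RE occlusion
    fd = {"L": cfg.fixation_disparity_L, "R": cfg.fixation_disparity_R}

    # conjugate saccades and blinks over the whole recording
    sacc_times = _poisson_events(rng, cfg.saccade_rate, schedule.start, schedule.end)
    sacc_amps = (
        rng.choice([-1.0, 1.0], size=sacc_times.size)
        * cfg.saccade_amp_median
        * np.exp(rng.normal(0.0, cfg.saccade_amp_sigma, size=sacc_times.size))
    )
    blink_starts = _poisson_events(rng, cfg.blink_rate, schedule.start, schedule.end)

    xL = np.empty(n)
    xR = np.empty(n)
    tau = cfg.approach_tau
    tau_return = tau / 2.0
    x0L = fd["L"]
    x0R = fd["R"]
    for phase in schedule.phases:
        idx = np.nonzero((t >= phase.onset - 1e-9) & (t < phase.end - 1e-9))[0]
        if idx.size == 0:
            continue
        tl = t[idx] - phase.onset
        if phase.kind == "binocular":
            xL[idx] = fd["L"] + (x0L - fd["L"]) * np.exp(-tl / tau_return)
            xR[idx] = fd["R"] + (x0R - fd["R"]) * np.exp(-tl / tau_return)
        else:
            # occluder closes over the ramp; approach gated by its progress
            gate = np.minimum(tl / max(cfg.occluder_ramp, 1e-9), 1.0)
            approach = gate * (1.0 - np.exp(-tl / tau))
            refix = np.exp(-tl / tau_return)
            if phase.kind == "occlude_left":
                target = fd["L"] + pd_to_deg(phoria_le)
                occ = x0L + (target - x0L) * approach
                xL[idx] = occ
                xR[idx] = x0R * refix + cfg.hering_gain * (occ - x0L)
            else:
                target = fd["R"] - pd_to_deg(phoria_re)
                occ = x0R + (target - x0R) * approach
                xR[idx] = occ
                xL[idx] = x0L * refix + cfg.hering_gain * (occ - x0R)
        # persistent conjugate steps within this phase
        for ts, amp in zip(sacc_times, sacc_amps):
            if phase.onset <= ts < phase.end:
                step = idx[t[idx] >= ts]
                xL[step] += amp
                xR[step] += amp
        x0L = xL[idx[-1]]
        x0R = xR[idx[-1]]

    xL = xL + rng.normal(0.0, 1.0, size=n) * cfg.noise_sd
    xR = xR + rng.normal(0.0, 1.0, size=n) * cfg.noise_sd

    validL = np.ones(n, dtype=bool)
    validR = np.ones(n, dtype=bool)
    blink_list = []
    for bs in blink_starts:
        be = bs + cfg.blink_duration
        span = (t >= bs) & (t <= be)
        if not span.any():
            continue
        validL[span] = False
        validR[span] = False
        xL[span] = np.nan
        xR[span] = np.nan
        blink_list.append((float(bs), float(be)))

    rec = GazeRecording(
        t=t, xL=xL, xR=xR, validL=validL, validR=validR, rate=cfg.rate
    )
    truth = GroundTruth(
        true_phoria=cfg.true_phoria,
        true_phoria_LE=phoria_le,
        true_phoria_RE=phoria_re,
        saccades=tuple(zip(map(float, sacc_times), map(float, sacc_amps))),
        blinks=tuple(blink_list),
    )
    return rec, truth


def simulate_clinical(
    true_phoria: float,
    method: str,
    noise_sd: float = 0.0,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> float:
    """Simulate one clinical comparator measurement.

    ``prism_cover``: examiner noise is added to the neutralization point,
    which is then bracketed on the prism-bar ladder; the returned value is
    the midpoint of the bracketing steps (or the step itself when hit
    exactly), signed like the deviation.  ``thorington``: response noise,
    rounding to the card's 1 PD resolution, clipped to ±28 PD.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    noisy = true_phoria + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0)
    if method == "thorington":
        if abs(true_phoria) > THORINGTON_RANGE:
            warnings.warn("true phoria outside the Thorington card range; clipped")
        val = float(np.rint(noisy))
        return float(np.clip(val, -THORINGTON_RANGE, THORINGTON_RANGE))
    if method == "prism_cover":
        steps = np.asarray(PRISM_BAR_STEPS, dtype=float)
        sign = 1.0 if noisy >= 0 else -1.0
        mag = abs(noisy)
        if abs(true_phoria) > steps[-1]:
            warnings.warn("true phoria outside the prism-bar range; clipped")
        if mag >= steps[-1]:
            return sign * steps[-1]
        exact = np.isclose(mag, steps, atol=1e-12)
        if exact.any():
            return sign * float(steps[exact][0])
        i = int(np.searchsorted(steps, mag, side="right")) - 1
        return sign * float((steps[i] + steps[i + 1]) / 2.0)
    raise ParameterError(f"unknown clinical method {method!r}")


@dataclass(frozen=True)
class SubjectRecord:
    """One simulated subject: two eye-tracker sessions plus clinical tests."""

    subject_id: str
    true_phoria: float  # PD, subject-level truth
    session_truths: Tuple[float, float]  # PD truth realized in each session
    recordings: Tuple[GazeRecording, GazeRecording]
    truths: Tuple[GroundTruth, GroundTruth]
    prism_cover: float  # PD
    thorington: float  # PD


def simulate_cohort(
    n_subjects: int,
    phoria_mean: float = -1.0,
    phoria_sd: float = 3.5,
    session_noise: float = 0.5,
    template: Optional[SimulationConfig] = None,
    schedule: Optional[TestSchedule] = None,
    ct_noise: float = 1.5,
    th_noise: float = 1.0,
    seed: int = 0,
) -> List[SubjectRecord]:
    """Simulate a cohort: per subject a normal true phoria, two eye-tracker
    sessions (session-level truth jittered by ``session_noise``) and one
    prism-cover plus one Thorington measurement, all driven by ``seed``."""
    if n_subjects < 1:
        raise ParameterError("n_subjects must be >= 1")
    from .core import default_schedule  # local: avoid import cycle at load

    template = template or SimulationConfig()
    schedule = schedule or default_schedule()
    rng = np.random.default_rng(seed)
    cohort: List[SubjectRecord] = []
    for i in range(n_subjects):
        true = float(rng.normal(phoria_mean, phoria_sd))
        sess = tuple(
            float(true + rng.normal(0.0, session_noise)) for _ in range(2)
        )
        recs = []
        truths = []
        for s_truth in sess:
            cfg = dataclasses.replace(
                template,
                true_phoria=s_truth,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            rec, gt = simulate_recording(schedule, cfg)
            recs.append(rec)
            truths.append(gt)
        ct = simulate_clinical(true, "prism_cover", noise_sd=ct_noise, rng=rng)
        th = simulate_clinical(true, "thorington", noise_sd=th_noise, rng=rng)
        cohort.append(
            SubjectRecord(
                subject_id=f"S{i + 1:03d}",
                true_phoria=true,
                session_truths=sess,  # type: ignore[arg-type]
                recordings=tuple(recs),  # type: ignore[arg-type]
                truths=tuple(truths),  # type: ignore[arg-type]
                prism_cover=ct,
                thorington=th,
            )
        )
    return cohort
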