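"""Automated objective cover test: from a segmented binocular recording to a
heterophoria measurement.

The scripted sequence alternates binocular fixation with monocular occlusion
(default: 3 cycles of binocular → occlude left → binocular → occlude right,
5 s per phase, 60 s total).  The eye position in each phase is the median of
the last 0.5 s.  For each occlusion, with Δocc the occluded eye's displacement
from its position in the immediately preceding binocular phase and Δfix the
fixating eye's displacement over the same pair of phases (degrees, screen
azimuth positive rightward):

*1-eye* method (what a prism cover test sees — the occluded eye only)::

    het = 100·tan(+ΔL)        left-eye occlusion
    het = 100·tan(−ΔR)        right-eye occlusion

*2-eyes* method (heterophoria as a relative deviation; the fixating-eye term
is the fixation-disparity component, added when it moves with the occluded
eye, subtracted when it moves against it)::

    het = 100·tan(ΔL + ΔR)    left-eye occlusion
    het = 100·tan(−ΔR − ΔL)   right-eye occlusion

Esophoria is positive, exophoria negative.  An occlusion yields a valid
measurement only when |Δocc| > |Δfix|; otherwise the displacement is better
explained by a conjugate (version) movement of both eyes and no heterophoria
is measured for that occlusion.  The final heterophoria is the median across
the valid occlusions (six when all are usable).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence

import numpy as np

from .errors import ParameterError, ScheduleError
from .gaze_io import GazeRecording, Phase, TestSchedule
from .preprocess import deg_to_pd, detect_blinks, pad_and_interpolate, pd_to_deg

__all__ = [
    "PhaseEstimate",
    "OcclusionMeasurement",
    "PhoriaResult",
    "PipelineConfig",
    "default_schedule",
    "phase_position",
    "occlusion_phoria",
    "aggregate",
    "classify_direction",
    "run_covertest",
]

logger = logging.getLogger(__name__)

_EPS = 1e-9


@dataclass(frozen=True)
class PhaseEstimate:
    """Per-phase eye positions: median of the estimation window.

    ``posL``/``posR`` are None when fewer than ``min_quality`` of the window
    samples for that eye are valid and non-interpolated; ``qualityL``/
    ``qualityR`` report that fraction and ``quality`` is their minimum.
    """

    phase: Phase
    posL: Optional[float]
    posR: Optional[float]
    qualityL: float
    qualityR: float

    @property
    def quality(self) -> float:
        return min(self.qualityL, self.qualityR)


@dataclass(frozen=True)
class OcclusionMeasurement:
    """One occlusion's phoria under each computation method."""

    occluded_eye: str  # "left" | "right"
    het_1eye: Optional[float]  # prism diopters
    het_2eyes: Optional[float]  # prism diopters
    disp_occluded: Optional[float]  # degrees
    disp_fixating: Optional[float]  # degrees
    valid: bool
    tropia_flag: bool = False  # fixating eye moved > ~1 PD: possible tropia/saccade
    reason: Optional[str] = None  # set when invalid


@dataclass(frozen=True)
class PhoriaResult:
    """Aggregated heterophoria with per-occlusion audit trail."""

    status: str  # "ok" | "no_measurement"
    het_1eye: Optional[float]
    het_2eyes: Optional[float]
    het_LE: Optional[float]  # 2-eyes method, left-eye occlusions only
    het_RE: Optional[float]  # 2-eyes method, right-eye occlusions only
    n_valid: int
    direction: Optional[str]  # eso | exo | ortho | inconsistent
    per_occlusion: List[OcclusionMeasurement] = field(default_factory=list)


@dataclass
class PipelineConfig:
    """Tunable parameters of the end-to-end cover-test pipeline."""

    pad: float = 0.100  # s removed before/after each blink
    min_blink_duration: float = 0.02  # s; shorter invalid runs = dropouts
    window: float = 0.5  # s; estimation window at the end of each phase
    min_quality: float = 0.5  # min fraction of clean samples in the window
    min_valid: int = 1  # min valid occlusions for a measurement
    ortho_threshold: float = 1.0  # PD; |het| below this is orthophoria
    tropia_threshold: float = 1.0  # PD-equivalent fixating-eye displacement


def default_schedule(
    cycles: int = 3, phase_duration: float = 5.0, start: float = 0.0
) -> TestSchedule:
    """The scripted occlusion sequence: per cycle, binocular → occlude_left →
    binocular → occlude_right, each phase ``phase_duration`` seconds."""
    if cycles < 1:
        raise ParameterError("cycles must be >= 1")
    if phase_duration <= 0:
        raise ParameterError("phase_duration must be positive")
    kinds = ("binocular", "occlude_left", "binocular", "occlude_right")
    phases = []
    onset = start
    for _ in range(cycles):
        for kind in kinds:
            phases.append(Phase(kind=kind, onset=onset, duration=phase_duration))
            onset += phase_duration
    return TestSchedule(phases=tuple(phases), cycles=cycles)


def phase_position(
    rec: GazeRecording,
    phase: Phase,
    window: float = 0.5,
    min_quality: float = 0.5,
) -> PhaseEstimate:
    """Estimate per-eye positions as the median of the phase's last ``window`` s.

    The median is taken over valid samples (interpolated ones included), but
    an eye's estimate is withheld when fewer than ``min_quality`` of the
    window samples are valid *and* non-interpolated.
    """
    t0, t1 = rec.t[0], rec.t[-1] + 1.0 / rec.rate
    if phase.onset < t0 - _EPS or phase.end > t1 + _EPS:
        raise ScheduleError(
            f"phase [{phase.onset}, {phase.end}] s outside recording "
            f"[{t0}, {t1}] s"
        )
    lo = phase.end - window
    mask = (rec.t >= lo - _EPS) & (rec.t < phase.end - _EPS)
    if not mask.any():
        raise ScheduleError(f"no samples in estimation window of phase at {phase.onset} s")

    def one_eye(x, valid, interp):
        clean = valid[mask] & ~interp[mask]
        quality = float(np.mean(clean))
        usable = valid[mask]
        if quality < min_quality or not usable.any():
            return None, quality
        return float(np.median(x[mask][usable])), quality

    posL, qL = one_eye(rec.xL, rec.validL, rec.interpL)
    posR, qR = one_eye(rec.xR, rec.validR, rec.interpR)
    return PhaseEstimate(phase=phase, posL=posL, posR=posR, qualityL=qL, qualityR=qR)


def occlusion_phoria(
    prev_bin: PhaseEstimate,
    occ: PhaseEstimate,
    occluded_eye: str,
    tropia_threshold: float = 1.0,
) -> OcclusionMeasurement:
    """Compute one occlusion's heterophoria by the 1-eye and 2-eyes methods.

    Angular displacements are combined in degrees and converted to prism
    diopters once, via 100·tan.  The measurement is valid only when the
    occluded eye moved strictly more than the fixating eye.
    """
    if occluded_eye not in ("left", "right"):
        raise ParameterError(f"unknown occluded eye {occluded_eye!r}")
    missing = any(
        v is None for v in (prev_bin.posL, prev_bin.posR, occ.posL, occ.posR)
    )
    if missing:
        return OcclusionMeasurement(
            occluded_eye=occluded_eye,
            het_1eye=None,
            het_2eyes=None,
            disp_occluded=None,
            disp_fixating=None,
            valid=False,
            reason="missing phase",
        )
    dL = occ.posL - prev_bin.posL
    dR = occ.posR - prev_bin.posR
    if occluded_eye == "left":
        d_occ, d_fix = dL, dR
        het1 = deg_to_pd(dL)
        het2 = deg_to_pd(dL + dR)
    else:
        d_occ, d_fix = dR, dL
        het1 = deg_to_pd(-dR)
        het2 = deg_to_pd(-dR - dL)
    valid = abs(d_occ) > abs(d_fix)
    tropia = abs(deg_to_pd(d_fix)) > tropia_threshold
    return OcclusionMeasurement(
        occluded_eye=occluded_eye,
        het_1eye=het1,
        het_2eyes=het2,
        disp_occluded=d_occ,
        disp_fixating=d_fix,
        valid=valid,
        tropia_flag=tropia,
        reason=None if valid else "fixating eye moved as much as the occluded eye",
    )


def classify_direction(het: float, ortho_threshold: float = 1.0) -> str:
    """eso / exo / ortho classification of a phoria in prism diopters."""
    if not np.isfinite(het):
        raise ParameterError("heterophoria must be finite")
    if abs(het) < ortho_threshold:
        return "ortho"
    return "eso" if het > 0 else "exo"


def aggregate(
    measurements: Sequence[OcclusionMeasurement],
    min_valid: int = 1,
    ortho_threshold: float = 1.0,
) -> PhoriaResult:
    """Median-aggregate per-occlusion measurements into a PhoriaResult.

    Both methods pool the valid occlusions of both eyes; het_LE / het_RE are
    the 2-eyes medians over left- / right-eye occlusions alone.  Direction is
    ``inconsistent`` when valid occlusions disagree in sign while all exceed
    the orthophoria threshold in magnitude.
    """
    measurements = list(measurements)
    if not measurements:
        raise ParameterError("no measurements to aggregate")
    if min_valid < 1:
        raise ParameterError("min_valid must be >= 1")
    valid = [m for m in measurements if m.valid]
    n_valid = len(valid)
    if n_valid < min_valid:
        return PhoriaResult(
            status="no_measurement",
            het_1eye=None,
            het_2eyes=None,
            het_LE=None,
            het_RE=None,
            n_valid=n_valid,
            direction=None,
            per_occlusion=measurements,
        )
    vals1 = np.array([m.het_1eye for m in valid])
    vals2 = np.array([m.het_2eyes for m in valid])
    le = [m.het_2eyes for m in valid if m.occluded_eye == "left"]
    re = [m.het_2eyes for m in valid if m.occluded_eye == "right"]
    het2 = float(np.median(vals2))
    signs = np.sign(vals2[vals2 != 0.0])
    if (
        len(set(signs)) > 1
        and np.all(np.abs(vals2) >= ortho_threshold)
    ):
        direction = "inconsistent"
    else:
        direction = classify_direction(het2, ortho_threshold)
    return PhoriaResult(
        status="ok",
        het_1eye=float(np.median(vals1)),
        het_2eyes=het2,
        het_LE=float(np.median(le)) if le else None,
        het_RE=float(np.median(re)) if re else None,
        n_valid=n_valid,
        direction=direction,
        per_occlusion=measurements,
    )


def run_covertest(
    rec: GazeRecording,
    schedule: Optional[TestSchedule] = None,
    config: Optional[PipelineConfig] = None,
) -> PhoriaResult:
    """End-to-end pipeline: blink removal → phase medians → per-occlusion
    phorias (each referenced to its immediately preceding binocular phase) →
    median aggregation."""
    schedule = schedule or default_schedule()
    cfg = config or PipelineConfig()
    t_end = rec.t[-1] + 1.0 / rec.rate
    if schedule.start < rec.t[0] - _EPS or schedule.end > t_end + _EPS:
        raise ScheduleError(
            f"schedule [{schedule.start}, {schedule.end}] s does not fit "
            f"recording of {rec.duration:.3f} s"
        )
    blinks = detect_blinks(rec, min_duration=cfg.min_blink_duration)
    clean = pad_and_interpolate(rec, blinks, pad=cfg.pad)

    measurements: List[OcclusionMeasurement] = []
    last_binocular: Optional[PhaseEstimate] = None
    for phase in schedule.phases:
        est = phase_position(clean, phase, window=cfg.window, min_quality=cfg.min_quality)
        if phase.kind == "binocular":
            last_binocular = est
            continue
        eye = phase.occluded_eye
        if last_binocular is None:
            m = OcclusionMeasurement(
                occluded_eye=eye,
                het_1eye=None,
                het_2eyes=None,
                disp_occluded=None,
                disp_fixating=None,
                valid=False,
                reason="no preceding binocular phase",
            )
        else:
            m = occlusion_phoria(
                last_binocular, est, eye, tropia_threshold=cfg.tropia_threshold
            )
        if not m.valid:
            logger.info(
                "occlusion at %.1f s (%s eye) skipped: %s",
                phase.onset,
                eye,
                m.reason,
            )
        measurements.append(m)
    return aggregate(
        measurements, min_valid=cfg.min_valid, ortho_threshold=cfg.ortho_threshold
    )
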