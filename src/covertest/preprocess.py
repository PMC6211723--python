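"""Blink handling and angle-unit conversion applied before phoria computation.

Blink artifacts contaminate the gaze trace not only during the lid closure
itself but also around its onset and offset, so a guard period (default
100 ms) on each side of every blink is discarded together with the blink
and the gap is bridged by per-eye linear interpolation.  Reconstructed
samples are marked valid again but carry an ``interpolated`` provenance tag
so the downstream window-quality rule can discount them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence

import numpy as np

from .errors import ParameterError
from .gaze_io import GazeRecording

__all__ = [
    "BlinkInterval",
    "detect_blinks",
    "pad_and_interpolate",
    "deg_to_pd",
    "pd_to_deg",
]

_EPS = 1e-9


@dataclass(frozen=True)
class BlinkInterval:
    """A maximal run of invalid samples attributed to a blink, one eye."""

    eye: str  # "left" | "right"
    start: float  # seconds, time of first invalid sample
    end: float  # seconds, time just past the last invalid sample

    def __post_init__(self) -> None:
        if self.eye not in ("left", "right"):
            raise ParameterError(f"unknown eye {self.eye!r}")
        if not self.end > self.start:
            raise ParameterError("blink interval must have end > start")

    @property
    def duration(self) -> float:
        return self.end - self.start


def _invalid_runs(valid: np.ndarray) -> Iterable[tuple[int, int]]:
    """Yield (first, last) index pairs of maximal runs where valid is False."""
    invalid = ~valid
    if not invalid.any():
        return
    padded = np.concatenate(([False], invalid, [False]))
    edges = np.diff(padded.astype(np.int8))
    starts = np.nonzero(edges == 1)[0]
    ends = np.nonzero(edges == -1)[0] - 1
    yield from zip(starts, ends)


def detect_blinks(
    rec: GazeRecording, min_duration: float = 0.02
) -> List[BlinkInterval]:
    """Find blink intervals as runs of invalid samples of length ≥ min_duration.

    Shorter invalid runs are treated as isolated dropouts and left to
    interpolation without padding.  A run of k samples spans k/rate seconds.
    """
    period = 1.0 / rec.rate
    blinks: List[BlinkInterval] = []
    for eye, valid in (("left", rec.validL), ("right", rec.validR)):
        for first, last in _invalid_runs(valid):
            dur = (last - first + 1) * period
            if dur >= min_duration - _EPS:
                blinks.append(
                    BlinkInterval(eye=eye, start=rec.t[first], end=rec.t[last] + period)
                )
    blinks.sort(key=lambda b: (b.eye, b.start))
    return blinks


def _merge_spans(spans: Sequence[tuple[float, float]]) -> List[tuple[float, float]]:
    if not spans:
        return []
    spans = sorted(spans)
    merged = [list(spans[0])]
    for lo, hi in spans[1:]:
        if lo <= merged[-1][1] + _EPS:
            merged[-1][1] = max(merged[-1][1], hi)
        else:
            merged.append([lo, hi])
    return [(lo, hi) for lo, hi in merged]


def _interpolate_eye(
    t: np.ndarray,
    x: np.ndarray,
    y: Optional[np.ndarray],
    valid: np.ndarray,
    interp: np.ndarray,
    spans: Sequence[tuple[float, float]],
    eye: str,
) -> None:
    """In-place: replace samples inside spans (and leftover invalid samples)
    by linear interpolation between the nearest valid boundary samples."""
    replace = np.zeros(t.size, dtype=bool)
    for lo, hi in spans:
        replace |= (t >= lo - _EPS) & (t <= hi + _EPS)
    replace |= ~valid  # isolated dropouts not attributed to a blink
    if not replace.any():
        return
    anchor = ~replace & valid
    for first, last in _invalid_runs(~replace):
        left = first - 1
        right = last + 1
        has_left = left >= 0 and anchor[left]
        has_right = right < t.size and anchor[right]
        if not (has_left and has_right):
            # span abuts the recording edge: nothing to anchor on — leave it
            # invalid so the phase-quality rule can reject the window later
            valid[first : last + 1] = False
            warnings.warn(
                f"{eye} eye: span [{t[first]:.3f}, {t[last]:.3f}] s has no valid "
                "boundary sample; left uninterpolated",
                stacklevel=3,
            )
            continue
        idx = np.arange(first, last + 1)
        x[idx] = np.interp(t[idx], [t[left], t[right]], [x[left], x[right]])
        if y is not None:
            y[idx] = np.interp(t[idx], [t[left], t[right]], [y[left], y[right]])
        valid[idx] = True
        interp[idx] = True


def pad_and_interpolate(
    rec: GazeRecording,
    blinks: Optional[List[BlinkInterval]] = None,
    pad: float = 0.100,
    min_duration: float = 0.02,
) -> GazeRecording:
    """Remove ``pad`` seconds around each blink and bridge by linear interpolation.

    Overlapping padded spans are merged before interpolating.  Samples outside
    every padded span are returned bit-identical; replaced samples are marked
    valid with the ``interpolated`` tag set.  Spans touching a recording edge
    (no valid boundary sample on one side) stay invalid and raise a warning.
    """
    if pad < 0:
        raise ParameterError("pad must be non-negative")
    if blinks is None:
        blinks = detect_blinks(rec, min_duration=min_duration)
    out = rec.copy()
    for eye, valid, interp, x, y in (
        ("left", out.validL, out.interpL, out.xL, out.yL),
        ("right", out.validR, out.interpR, out.xR, out.yR),
    ):
        spans = _merge_spans(
            [(b.start - pad, b.end + pad) for b in blinks if b.eye == eye]
        )
        _interpolate_eye(out.t, x, y, valid, interp, spans, eye)
    return out


def deg_to_pd(theta):
    """Convert a rotation angle in degrees to prism diopters, 100·tan(θ).

    One prism diopter deflects a ray by 1 cm at 1 m distance.  Sign is
    preserved (eso positive under the package convention).
    """
    theta = np.asarray(theta, dtype=float)
    if np.any(np.abs(theta) >= 90.0):
        raise ParameterError("deg_to_pd requires |theta| < 90 degrees")
    out = 100.0 * np.tan(np.deg2rad(theta))
    return out.item() if out.ndim == 0 else out


def pd_to_deg(pd_value):
    """Inverse of :func:`deg_to_pd`: degrees of rotation for a prism power."""
    pd_value = np.asarray(pd_value, dtype=float)
    out = np.rad2deg(np.arctan(pd_value / 100.0))
    return out.item() if out.ndim == 0 else out
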