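"""Reading and writing gaze recordings, test schedules and phoria results.

All gaze positions are horizontal (and optionally vertical) rotation angles
in degrees on a single screen-azimuth axis shared by both eyes: positive is
toward the subject's right, zero is the fixation target.  Time is kept in
seconds internally; millisecond timestamps (the EyeLink convention) are
converted on input.  Missing data (blinks, track loss) are represented by a
per-eye validity flag, never by a magic number; invalid samples may hold NaN.
"""

from __future__ import annotations

import csv
import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ColumnMappingError, GazeFormatError, ScheduleError

__all__ = [
    "GazeRecording",
    "Phase",
    "TestSchedule",
    "TableDialect",
    "AscMapping",
    "read_gaze_table",
    "write_gaze_table",
    "read_eyelink_ascii",
    "read_schedule",
    "write_schedule",
    "write_result",
    "read_result",
]

#: tokens accepted as "missing" in delimited gaze tables
MISSING_TOKENS = ("", ".", "NaN", "nan", "NA")

_STEP_TOL = 1e-6  # allowed deviation of the sample step from 1/rate, seconds


@dataclass
class GazeRecording:
    """Timestamped binocular gaze samples in degrees with validity flags.

    Parameters
    ----------
    t : array of float
        Sample times in seconds, uniform step ``1/rate``.
    xL, xR : array of float
        Horizontal gaze angle of the left / right eye in degrees.
    validL, validR : array of bool
        False marks track loss or blink for that eye.
    rate : float
        Sampling rate in Hz.
    yL, yR : array of float, optional
        Vertical gaze angles (pass-through, QC only).
    interpL, interpR : array of bool, optional
        Provenance tags: True where a sample was reconstructed by
        interpolation rather than measured.
    """

    t: np.ndarray
    xL: np.ndarray
    xR: np.ndarray
    validL: np.ndarray
    validR: np.ndarray
    rate: float
    yL: Optional[np.ndarray] = None
    yR: Optional[np.ndarray] = None
    interpL: np.ndarray = None  # type: ignore[assignment]
    interpR: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.xL = np.asarray(self.xL, dtype=float)
        self.xR = np.asarray(self.xR, dtype=float)
        self.validL = np.asarray(self.validL, dtype=bool)
        self.validR = np.asarray(self.validR, dtype=bool)
        n = self.t.size
        if n < 1:
            raise GazeFormatError("recording must contain at least one sample")
        for name in ("xL", "xR", "validL", "validR"):
            if getattr(self, name).size != n:
                raise GazeFormatError(f"array {name!r} length mismatch")
        for name in ("yL", "yR"):
            arr = getattr(self, name)
            if arr is not None:
                arr = np.asarray(arr, dtype=float)
                if arr.size != n:
                    raise GazeFormatError(f"array {name!r} length mismatch")
                setattr(self, name, arr)
        if self.interpL is None:
            self.interpL = np.zeros(n, dtype=bool)
        else:
            self.interpL = np.asarray(self.interpL, dtype=bool)
        if self.interpR is None:
            self.interpR = np.zeros(n, dtype=bool)
        else:
            self.interpR = np.asarray(self.interpR, dtype=bool)
        if self.rate <= 0:
            raise GazeFormatError("sampling rate must be positive")
        if n > 1:
            dt = np.diff(self.t)
            if np.any(dt <= 0):
                row = int(np.argmax(dt <= 0)) + 1
                raise GazeFormatError(f"non-monotone timestamps at sample {row}")
            if np.any(np.abs(dt - 1.0 / self.rate) > _STEP_TOL):
                row = int(np.argmax(np.abs(dt - 1.0 / self.rate) > _STEP_TOL)) + 1
                raise GazeFormatError(
                    f"non-uniform sample step at sample {row} "
                    f"(expected {1.0 / self.rate:.6g} s)"
                )
        if np.any(~np.isfinite(self.xL[self.validL])):
            raise GazeFormatError("valid left-eye samples must be finite")
        if np.any(~np.isfinite(self.xR[self.validR])):
            raise GazeFormatError("valid right-eye samples must be finite")

    @property
    def n(self) -> int:
        return self.t.size

    @property
    def duration(self) -> float:
        """Recording length in seconds (sample count / rate)."""
        return self.n / self.rate

    def copy(self) -> "GazeRecording":
        return GazeRecording(
            t=self.t.copy(),
            xL=self.xL.copy(),
            xR=self.xR.copy(),
            validL=self.validL.copy(),
            validR=self.validR.copy(),
            rate=self.rate,
            yL=None if self.yL is None else self.yL.copy(),
            yR=None if self.yR is None else self.yR.copy(),
            interpL=self.interpL.copy(),
            interpR=self.interpR.copy(),
        )


@dataclass(frozen=True)
class Phase:
    """One period of the scripted occlusion sequence."""

    kind: str  # binocular | occlude_left | occlude_right
    onset: float  # seconds
    duration: float  # seconds

    KINDS = ("binocular", "occlude_left", "occlude_right")

    def __post_init__(self) -> None:
        if self.kind not in self.KINDS:
            raise ScheduleError(f"unknown phase kind {self.kind!r}")
        if self.duration <= 0:
            raise ScheduleError("phase duration must be positive")

    @property
    def end(self) -> float:
        return self.onset + self.duration

    @property
    def occluded_eye(self) -> Optional[str]:
        if self.kind == "occlude_left":
            return "left"
        if self.kind == "occlude_right":
            return "right"
        return None


@dataclass(frozen=True)
class TestSchedule:
    """Ordered, contiguous sequence of binocular and occlusion phases."""

    phases: tuple
    cycles: int

    def __post_init__(self) -> None:
        phases = tuple(self.phases)
        object.__setattr__(self, "phases", phases)
        for a, b in zip(phases, phases[1:]):
            if abs(a.end - b.onset) > 1e-9:
                raise ScheduleError("phases must be contiguous and non-overlapping")

    @property
    def occlusions(self) -> tuple:
        return tuple(p for p in self.phases if p.kind != "binocular")

    @property
    def start(self) -> float:
        return self.phases[0].onset

    @property
    def end(self) -> float:
        return self.phases[-1].end

    @property
    def duration(self) -> float:
        return self.end - self.start


# ---------------------------------------------------------------------------
# delimited gaze tables


@dataclass
class TableDialect:
    """Column mapping from a delimited table to canonical recording fields.

    Keys are canonical names, values the source column names.  ``time_unit``
    is ``"s"``, ``"ms"`` or ``"auto"`` (median step ≥ 0.5 ⇒ milliseconds).
    ``declared_rate`` is checked against the rate inferred from timestamps
    (must agree within 1%).
    """

    t: str = "t"
    xL: str = "xL"
    xR: str = "xR"
    yL: Optional[str] = None
    yR: Optional[str] = None
    time_unit: str = "auto"
    declared_rate: Optional[float] = None
    delimiter: Optional[str] = None


def _infer_rate(t: np.ndarray, path: str, declared: Optional[float]) -> float:
    if t.size < 2:
        if declared is None:
            raise GazeFormatError(f"{path}: cannot infer rate from one sample")
        return declared
    dt = np.diff(t)
    bad = np.nonzero(dt <= 0)[0]
    if bad.size:
        raise GazeFormatError(f"{path}: non-monotone timestamps at row {bad[0] + 2}")
    step = float(np.median(dt))
    gaps = np.nonzero(dt > 2.0 * step)[0]
    if gaps.size:
        raise GazeFormatError(
            f"{path}: gap larger than 2 sample periods at row {gaps[0] + 2}"
        )
    rate = 1.0 / step
    if declared is not None and abs(rate - declared) > 0.01 * declared:
        raise GazeFormatError(
            f"{path}: inferred rate {rate:.3f} Hz disagrees with declared "
            f"{declared:.3f} Hz by more than 1%"
        )
    return declared if declared is not None else rate


def read_gaze_table(path, dialect: Optional[TableDialect] = None) -> GazeRecording:
    """Read a delimited gaze table (CSV/TSV with header) into a recording.

    Samples whose horizontal gaze is missing (empty, ".", "NaN") are marked
    invalid for that eye; no sample is ever dropped.
    """
    dialect = dialect or TableDialect()
    path = str(path)
    sep = dialect.delimiter
    df = pd.read_csv(
        path,
        sep=sep if sep is not None else None,
        engine="python" if sep is None else "c",
        na_values=list(MISSING_TOKENS),
        keep_default_na=True,
        skipinitialspace=True,
    )
    for canon in ("t", "xL", "xR"):
        col = getattr(dialect, canon)
        if col not in df.columns:
            raise ColumnMappingError(
                f"{path}: column {col!r} (mapped to {canon!r}) not found; "
                f"available: {list(df.columns)}"
            )
    t = df[dialect.t].to_numpy(dtype=float)
    if np.any(~np.isfinite(t)):
        raise GazeFormatError(f"{path}: missing timestamp values")
    unit = dialect.time_unit
    if unit == "auto":
        unit = "ms" if (t.size > 1 and np.median(np.diff(t)) >= 0.5) else "s"
    if unit == "ms":
        t = t / 1000.0
    elif unit != "s":
        raise ColumnMappingError(f"unknown time unit {dialect.time_unit!r}")
    rate = _infer_rate(t, path, dialect.declared_rate)

    xL = df[dialect.xL].to_numpy(dtype=float)
    xR = df[dialect.xR].to_numpy(dtype=float)
    yL = df[dialect.yL].to_numpy(dtype=float) if dialect.yL else None
    yR = df[dialect.yR].to_numpy(dtype=float) if dialect.yR else None
    return GazeRecording(
        t=t,
        xL=xL,
        xR=xR,
        validL=np.isfinite(xL),
        validR=np.isfinite(xR),
        rate=rate,
        yL=yL,
        yR=yR,
    )


def write_gaze_table(rec: GazeRecording, path, dialect: Optional[TableDialect] = None) -> None:
    """Write a recording as a CSV gaze table; invalid samples become empty fields."""
    dialect = dialect or TableDialect()
    cols = {dialect.t: rec.t}
    xL = rec.xL.copy()
    xL[~rec.validL] = np.nan
    xR = rec.xR.copy()
    xR[~rec.validR] = np.nan
    cols[dialect.xL] = xL
    cols[dialect.xR] = xR
    if rec.yL is not None:
        cols[dialect.yL or "yL"] = rec.yL
    if rec.yR is not None:
        cols[dialect.yR or "yR"] = rec.yR
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# minimal EyeLink-ASC-style dialect


@dataclass
class AscMapping:
    """Declared screen-to-degree mapping for ASC sample fields.

    ``deg = (raw - center) * scale``.  If the export is already in degrees
    use the default identity mapping explicitly — the reader never guesses
    gaze geometry.
    """

    x_scale: float = 1.0
    x_center: float = 0.0
    y_scale: float = 1.0
    y_center: float = 0.0
    declared_rate: Optional[float] = None


def read_eyelink_ascii(path, mapping: Optional[AscMapping] = None) -> GazeRecording:
    """Read a minimal EyeLink-ASC-style text export.

    Sample lines: ``<t_ms> <xL> <yL> <pL> <xR> <yR> <pR>`` ("." = missing).
    ``SBLINK <eye> <t>`` / ``EBLINK <eye> <start> <end>`` spans mark the
    affected eye invalid; other event lines are ignored.
    """
    mapping = mapping or AscMapping()
    path = str(path)
    times: list[float] = []
    raw: list[list[float]] = []
    blink_spans: dict[str, list[tuple[float, float]]] = {"L": [], "R": []}
    open_blinks: dict[str, Optional[float]] = {"L": None, "R": None}

    def parse_field(tok: str) -> float:
        return np.nan if tok in MISSING_TOKENS else float(tok)

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            toks = line.split()
            if not toks:
                continue
            head = toks[0]
            if head in ("SBLINK", "EBLINK"):
                if len(toks) < 3:
                    raise GazeFormatError(f"{path}:{lineno}: malformed blink event")
                eye = toks[1]
                if eye not in ("L", "R"):
                    raise GazeFormatError(f"{path}:{lineno}: unknown eye tag {eye!r}")
                if head == "SBLINK":
                    open_blinks[eye] = float(toks[2])
                else:
                    if open_blinks[eye] is None:
                        raise GazeFormatError(
                            f"{path}:{lineno}: EBLINK {eye} without matching SBLINK"
                        )
                    start = open_blinks[eye]
                    end = float(toks[3]) if len(toks) >= 4 else float(toks[2])
                    blink_spans[eye].append((start, end))  # type: ignore[arg-type]
                    open_blinks[eye] = None
                continue
            # sample lines start with a numeric timestamp
            try:
                ts = float(head)
            except ValueError:
                continue  # other event line, ignored
            if len(toks) < 7:
                raise GazeFormatError(f"{path}:{lineno}: short sample line")
            times.append(ts)
            raw.append([parse_field(tok) for tok in toks[1:7]])

    if not times:
        raise GazeFormatError(f"{path}: no sample lines found")
    for eye, start in open_blinks.items():
        if start is not None:  # unterminated span: runs to end of recording
            blink_spans[eye].append((start, times[-1]))

    t_ms = np.asarray(times, dtype=float)
    arr = np.asarray(raw, dtype=float)
    t = t_ms / 1000.0
    rate = _infer_rate(t, path, mapping.declared_rate)
    xL = (arr[:, 0] - mapping.x_center) * mapping.x_scale
    yL = (arr[:, 1] - mapping.y_center) * mapping.y_scale
    xR = (arr[:, 3] - mapping.x_center) * mapping.x_scale
    yR = (arr[:, 4] - mapping.y_center) * mapping.y_scale
    validL = np.isfinite(xL)
    validR = np.isfinite(xR)
    for start, end in blink_spans["L"]:
        validL &= ~((t_ms >= start) & (t_ms <= end))
    for start, end in blink_spans["R"]:
        validR &= ~((t_ms >= start) & (t_ms <= end))
    return GazeRecording(
        t=t, xL=xL, xR=xR, validL=validL, validR=validR, rate=rate, yL=yL, yR=yR
    )


# ---------------------------------------------------------------------------
# schedules


def read_schedule(path, cycles: Optional[int] = None) -> TestSchedule:
    """Read a schedule CSV with columns kind,onset,duration."""
    df = pd.read_csv(path)
    for col in ("kind", "onset", "duration"):
        if col not in df.columns:
            raise ColumnMappingError(f"schedule file missing column {col!r}")
    phases = tuple(
        Phase(kind=str(r.kind), onset=float(r.onset), duration=float(r.duration))
        for r in df.itertuples()
    )
    n_occ = sum(1 for p in phases if p.kind != "binocular")
    if cycles is None:
        cycles = max(1, n_occ // 2)
    return TestSchedule(phases=phases, cycles=cycles)


def write_schedule(schedule: TestSchedule, path) -> None:
    pd.DataFrame(
        [
            {"kind": p.kind, "onset": p.onset, "duration": p.duration}
            for p in schedule.phases
        ]
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# results


def _num(x):
    """JSON-safe number: None stays None, floats pass through."""
    if x is None:
        return None
    x = float(x)
    if math.isnan(x):
        return None
    return x


def result_to_dict(result) -> dict:
    """Nested dict form of a PhoriaResult (summary / per-eye / per-occlusion)."""
    return {
        "status": result.status,
        "summary": {
            "het_1eye_pd": _num(result.het_1eye),
            "het_2eyes_pd": _num(result.het_2eyes),
            "direction": result.direction,
            "n_valid": result.n_valid,
        },
        "per_eye": {
            "het_LE_pd": _num(result.het_LE),
            "het_RE_pd": _num(result.het_RE),
        },
        "per_occlusion": [
            {
                "occluded_eye": m.occluded_eye,
                "het_1eye_pd": _num(m.het_1eye),
                "het_2eyes_pd": _num(m.het_2eyes),
                "disp_occluded_deg": _num(m.disp_occluded),
                "disp_fixating_deg": _num(m.disp_fixating),
                "valid": bool(m.valid),
                "tropia_flag": bool(m.tropia_flag),
                "reason": m.reason,
            }
            for m in result.per_occlusion
        ],
    }


def write_result(result, path, format: str = "json") -> None:
    """Write a PhoriaResult as nested JSON or a flat audit CSV.

    The JSON form round-trips losslessly through :func:`read_result`.
    """
    path = Path(path)
    if format == "json":
        path.write_text(json.dumps(result_to_dict(result), indent=2) + "\n")
    elif format == "csv":
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(
                [
                    "record_type",
                    "occluded_eye",
                    "het_1eye_pd",
                    "het_2eyes_pd",
                    "disp_occluded_deg",
                    "disp_fixating_deg",
                    "valid",
                    "tropia_flag",
                    "reason",
                    "status",
                    "direction",
                    "n_valid",
                ]
            )
            for m in result.per_occlusion:
                writer.writerow(
                    [
                        "occlusion",
                        m.occluded_eye,
                        _fmt(m.het_1eye),
                        _fmt(m.het_2eyes),
                        _fmt(m.disp_occluded),
                        _fmt(m.disp_fixating),
                        int(m.valid),
                        int(m.tropia_flag),
                        m.reason or "",
                        "",
                        "",
                        "",
                    ]
                )
            writer.writerow(
                [
                    "summary",
                    "",
                    _fmt(result.het_1eye),
                    _fmt(result.het_2eyes),
                    "",
                    "",
                    "",
                    "",
                    "",
                    result.status,
                    result.direction or "",
                    result.n_valid,
                ]
            )
    else:
        raise ColumnMappingError(f"unknown result format {format!r}")


def _fmt(x) -> str:
    return "" if x is None else repr(float(x))


def read_result(path):
    """Re-parse a JSON result file written by :func:`write_result`."""
    from .core import OcclusionMeasurement, PhoriaResult  # local: avoid cycle

    d = json.loads(Path(path).read_text())
    per_occ = [
        OcclusionMeasurement(
            occluded_eye=m["occluded_eye"],
            het_1eye=m["het_1eye_pd"],
            het_2eyes=m["het_2eyes_pd"],
            disp_occluded=m["disp_occluded_deg"],
            disp_fixating=m["disp_fixating_deg"],
            valid=m["valid"],
            tropia_flag=m.get("tropia_flag", False),
            reason=m.get("reason"),
        )
        for m in d["per_occlusion"]
    ]
    return PhoriaResult(
        status=d["status"],
        het_1eye=d["summary"]["het_1eye_pd"],
        het_2eyes=d["summary"]["het_2eyes_pd"],
        het_LE=d["per_eye"]["het_LE_pd"],
        het_RE=d["per_eye"]["het_RE_pd"],
        n_valid=d["summary"]["n_valid"],
        direction=d["summary"]["direction"],
        per_occlusion=per_occ,
    )
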