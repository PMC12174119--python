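"""Touch-event session containers and on-disk formats.

A *writing session* is the raw record of one subject writing the six-stroke
Chinese character 米 ("rice") ten times on a touch screen with a fingertip.
The device emits a stream of timestamped touch events — ``down`` when the
finger lands, ``move`` samples while it stays on the glass, ``up`` when it
lifts — and everything downstream (stroke segmentation, the 21 kinematic
biomarkers) is computed from this stream.

Conventions (fixed here, converted nowhere else):

* time is integer milliseconds since session start (0 by definition);
* coordinates are device pixels, origin top-left, y increasing downward;
* one file per session; the per-subject feature table (the *cohort table*)
  is a separate CSV with one row per subject.

Sessions whose last event exceeds the task time limit (default 3 minutes)
are *flagged* invalid rather than truncated, mirroring the exclusion rule of
the assessment paradigm.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, NamedTuple, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PHASES",
    "BIOMARKER_COLUMNS",
    "IPSDB_COLUMNS",
    "EFDB_COLUMNS",
    "TouchEvent",
    "WritingSession",
    "SessionFormatError",
    "CohortFormatError",
    "read_session",
    "write_session",
    "read_cohort",
    "write_cohort",
]

PHASES = ("down", "move", "up")
_PHASE_CODE = {p: i for i, p in enumerate(PHASES)}

IPSDB_COLUMNS = tuple(f"IPSDB_{i}" for i in range(1, 11))
EFDB_COLUMNS = tuple(f"EFDB_{i}" for i in range(1, 12))
BIOMARKER_COLUMNS = IPSDB_COLUMNS + EFDB_COLUMNS

#: columns a cohort CSV must carry besides the biomarkers
COHORT_KEY_COLUMNS = ("subject_id", "group")
COHORT_GROUPS = ("MCI", "HC")

SESSION_CSV_HEADER = ("t_ms", "x_px", "y_px", "phase")


class SessionFormatError(ValueError):
    """Malformed session stream; ``row`` is the first offending event index."""

    def __init__(self, message: str, row: int | None = None):
        self.row = row
        super().__init__(message if row is None else f"{message} (event row {row})")


class CohortFormatError(ValueError):
    pass


class TouchEvent(NamedTuple):
    """One raw device sample."""

    t: int  # milliseconds since session start
    x: float  # pixels, >= 0, origin top-left
    y: float  # pixels, >= 0, y grows downward
    phase: str  # "down" | "move" | "up"


@dataclass
class WritingSession:
    """One subject's raw touch-event record, stored as parallel arrays."""

    subject_id: str
    t_ms: np.ndarray  # int64, strictly increasing
    x: np.ndarray  # float64
    y: np.ndarray  # float64
    phase: np.ndarray  # int8 codes into PHASES
    screen_w: int = 3840
    screen_h: int = 2160
    task_char_count: int = 10
    time_limit_s: float = 180.0

    def __post_init__(self) -> None:
        self.t_ms = np.asarray(self.t_ms, dtype=np.int64)
        self.x = np.asarray(self.x, dtype=np.float64)
        self.y = np.asarray(self.y, dtype=np.float64)
        self.phase = np.asarray(self.phase, dtype=np.int8)
        n = len(self.t_ms)
        if not (len(self.x) == len(self.y) == len(self.phase) == n):
            raise SessionFormatError("event arrays have unequal lengths")
        validate_event_stream(self.t_ms, self.x, self.y, self.phase)

    # -- convenience -----------------------------------------------------
    def __len__(self) -> int:
        return len(self.t_ms)

    @property
    def events(self) -> Iterator[TouchEvent]:
        for t, x, y, p in zip(self.t_ms, self.x, self.y, self.phase):
            yield TouchEvent(int(t), float(x), float(y), PHASES[p])

    @property
    def exceeds_time_limit(self) -> bool:
        return len(self) > 0 and self.t_ms[-1] > self.time_limit_s * 1000.0

    @property
    def is_valid(self) -> bool:
        """Countable for analysis: non-empty and within the task time limit."""
        return len(self) > 0 and not self.exceeds_time_limit

    def shifted(self, dt_ms: int) -> "WritingSession":
        """Copy with all timestamps translated by ``dt_ms`` (must stay >= 0)."""
        return replace(self, t_ms=self.t_ms + int(dt_ms))

    @classmethod
    def from_events(cls, subject_id: str, events: Sequence[TouchEvent | tuple],
                    **kwargs) -> "WritingSession":
        evs = [TouchEvent(int(t), float(x), float(y), str(p)) for t, x, y, p in events]
        return cls(
            subject_id=subject_id,
            t_ms=np.array([e.t for e in evs], dtype=np.int64),
            x=np.array([e.x for e in evs]),
            y=np.array([e.y for e in evs]),
            phase=np.array([_PHASE_CODE[e.phase] for e in evs], dtype=np.int8),
            **kwargs,
        )


def validate_event_stream(t_ms: np.ndarray, x: np.ndarray, y: np.ndarray,
                          phase: np.ndarray) -> None:
    """Check ordering, coordinate and phase-language invariants.

    The phase sequence must match ``(down move* up)*`` — a single pointer,
    every ``down`` matched by a later ``up``, nothing while the finger is in
    the air. Raises :class:`SessionFormatError` naming the first bad event.
    """
    n = len(t_ms)
    if n == 0:
        return
    if t_ms[0] < 0:
        raise SessionFormatError("negative timestamp", row=0)
    bad = np.nonzero(np.diff(t_ms) <= 0)[0]
    if bad.size:
        raise SessionFormatError(
            "timestamps not strictly increasing (ties are forbidden for a "
            "single pointer)", row=int(bad[0]) + 1)
    neg = np.nonzero((x < 0) | (y < 0))[0]
    if neg.size:
        raise SessionFormatError("negative coordinate", row=int(neg[0]))
    if phase.min(initial=0) < 0 or phase.max(initial=0) > 2:
        raise SessionFormatError("unknown phase code")
    down = False
    for i, p in enumerate(phase):
        if p == 0:  # down
            if down:
                raise SessionFormatError(
                    "down while pointer already down (multi-touch is not "
                    "supported)", row=i)
            down = True
        else:  # move / up
            if not down:
                raise SessionFormatError(
                    f"'{PHASES[p]}' while pointer is up", row=i)
            if p == 2:
                down = False
    if down:
        raise SessionFormatError(
            "stream ends with the pointer still down (dangling stroke)",
            row=n - 1)


# ---------------------------------------------------------------------------
# session files
# ---------------------------------------------------------------------------

def _infer_dialect(path: Path, dialect: str | None) -> str:
    if dialect is not None:
        if dialect not in ("csv", "json"):
            raise ValueError(f"unknown dialect {dialect!r}")
        return dialect
    return "json" if path.suffix.lower() == ".json" else "csv"


def read_session(path: str | Path, dialect: str | None = None) -> WritingSession:
    """Read one session file (CSV or JSON, inferred from the suffix).

    CSV carries only the event stream (header ``t_ms,x_px,y_px,phase``); the
    subject id is the file stem and screen/task metadata take their defaults.
    JSON carries full metadata.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if _infer_dialect(path, dialect) == "csv":
        df = pd.read_csv(path, dtype={"t_ms": np.int64, "x_px": float,
                                      "y_px": float, "phase": str},
                         float_precision="round_trip")
        missing = set(SESSION_CSV_HEADER) - set(df.columns)
        if missing:
            raise SessionFormatError(f"missing columns: {sorted(missing)}")
        try:
            codes = df["phase"].map(_PHASE_CODE)
        except KeyError:  # pragma: no cover
            raise SessionFormatError("bad phase value")
        if codes.isna().any():
            raise SessionFormatError("unknown phase value",
                                     row=int(codes.isna().idxmax()))
        return WritingSession(
            subject_id=path.stem,
            t_ms=df["t_ms"].to_numpy(np.int64),
            x=df["x_px"].to_numpy(float),
            y=df["y_px"].to_numpy(float),
            phase=codes.to_numpy(np.int8),
        )
    with open(path) as fh:
        doc = json.load(fh)
    try:
        events = doc["events"]
        sid = doc["subject_id"]
    except KeyError as exc:
        raise SessionFormatError(f"missing key {exc}")
    screen = doc.get("screen", {})
    for i, ev in enumerate(events):
        if ev.get("phase") not in PHASES:
            raise SessionFormatError("unknown phase value", row=i)
    return WritingSession(
        subject_id=str(sid),
        t_ms=np.array([ev["t"] for ev in events], dtype=np.int64),
        x=np.array([ev["x"] for ev in events], dtype=float),
        y=np.array([ev["y"] for ev in events], dtype=float),
        phase=np.array([_PHASE_CODE[ev["phase"]] for ev in events], dtype=np.int8),
        screen_w=int(screen.get("w", 3840)),
        screen_h=int(screen.get("h", 2160)),
        task_char_count=int(doc.get("task_char_count", 10)),
        time_limit_s=float(doc.get("time_limit_s", 180.0)),
    )


def write_session(session: WritingSession, path: str | Path,
                  dialect: str | None = None) -> Path:
    """Write a session so that :func:`read_session` round-trips it exactly."""
    path = Path(path)
    if _infer_dialect(path, dialect) == "csv":
        df = pd.DataFrame({
            "t_ms": session.t_ms,
            "x_px": session.x,
            "y_px": session.y,
            "phase": [PHASES[p] for p in session.phase],
        })
        df.to_csv(path, index=False)
    else:
        doc = {
            "subject_id": session.subject_id,
            "screen": {"w": session.screen_w, "h": session.screen_h},
            "task_char_count": session.task_char_count,
            "time_limit_s": session.time_limit_s,
            "events": [
                {"t": int(t), "x": float(x), "y": float(y), "phase": PHASES[p]}
                for t, x, y, p in zip(session.t_ms, session.x, session.y,
                                      session.phase)
            ],
        }
        with open(path, "w") as fh:
            json.dump(doc, fh)
    return path


# ---------------------------------------------------------------------------
# cohort table
# ---------------------------------------------------------------------------

def validate_cohort(df: pd.DataFrame) -> pd.DataFrame:
    """Validate the subjects x (demographics + biomarkers) table in place."""
    for col in COHORT_KEY_COLUMNS:
        if col not in df.columns:
            raise CohortFormatError(f"cohort table lacks required column {col!r}")
    dup = df["subject_id"][df["subject_id"].duplicated()]
    if len(dup):
        raise CohortFormatError(f"duplicated subject_id: {dup.iloc[0]!r}")
    levels = set(df["group"].dropna().unique())
    if not levels <= set(COHORT_GROUPS):
        raise CohortFormatError(
            f"group column has non-binary levels {sorted(levels - set(COHORT_GROUPS))}"
            f" (expected subset of {COHORT_GROUPS})")
    present = [c for c in BIOMARKER_COLUMNS if c in df.columns]
    for col in present:
        vals = pd.to_numeric(df[col], errors="coerce")
        if df[col].notna().sum() != vals.notna().sum():
            raise CohortFormatError(f"non-numeric values in biomarker column {col}")
        df[col] = vals
    # times, lengths, speeds, counts can never be negative
    nonneg = [c for c in present if c != "EFDB_1"]
    for col in nonneg:
        if (df[col].dropna() < 0).any():
            raise CohortFormatError(f"negative value in biomarker column {col}")
    return df


def read_cohort(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    return validate_cohort(df)


def write_cohort(df: pd.DataFrame, path: str | Path,
                 metadata: dict | None = None) -> Path:
    """Write a validated cohort CSV; optional metadata goes into '#' header lines."""
    validate_cohort(df)
    path = Path(path)
    with open(path, "w") as fh:
        if metadata:
            for key, val in metadata.items():
                fh.write(f"# {key}: {val}\n")
        df.to_csv(fh, index=False)
    return path
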