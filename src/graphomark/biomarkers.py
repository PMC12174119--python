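"""Stroke segmentation and the 21 writing-process digital biomarkers.

The session stream is cut into *strokes* (one finger-down→finger-up
trajectory each) and *pauses* (the initial pause before the first touch and
the inter-stroke gaps between an up and the next down). From that
decomposition two biomarker families are computed per session:

* ``IPSDB_1..10`` — information-processing-speed markers: total task time,
  task process time, writing time, total/initial/process pause times, the
  maximum, mean and coefficient of variation of the inter-stroke gaps, and
  the count of within-stroke stationary episodes.
* ``EFDB_1..11`` — executive-function markers: task score, stroke count,
  strokes per minute, writing efficiency, total/max/mean stroke trajectory
  length and its CV, and max/mean stroke speed and its CV.

Exact identities hold by construction and are asserted in the test suite::

    IPSDB_1 = IPSDB_5 + IPSDB_2        IPSDB_2 = IPSDB_3 + IPSDB_6
    IPSDB_4 = IPSDB_5 + IPSDB_6        EFDB_5  = J * EFDB_7

Coefficients of variation use the population standard deviation (divide by
the number of values, not n-1). For single-stroke sessions the gap
statistics (IPSDB_7/8/9) are undefined and returned as NaN, never as zero.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .glyph import MI_TEMPLATE, GlyphTemplate
from .session import BIOMARKER_COLUMNS, WritingSession

__all__ = [
    "Stroke",
    "SegmentedSession",
    "ScoreResult",
    "segment_strokes",
    "count_within_stroke_pauses",
    "score_task",
    "compute_ipsdb",
    "compute_efdb",
    "extract_biomarkers",
    "extract_cohort",
    "DEFAULT_MIN_PAUSE_MS",
]

log = logging.getLogger(__name__)

#: minimum duration of a stationary within-stroke episode, milliseconds.
#: 0 reduces IPSDB_10 to a raw duplicate-coordinate-pair count; a duration
#: threshold decouples the count from the device sampling rate.
DEFAULT_MIN_PAUSE_MS = 50


class EmptySessionError(ValueError):
    pass


@dataclass
class Stroke:
    """One down→up trajectory segment (times in seconds, positions in px)."""

    index: int  # 1-based temporal index
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray

    @property
    def duration(self) -> float:
        """t_j: last sample time minus first sample time, seconds."""
        return float(self.t[-1] - self.t[0])

    @property
    def length(self) -> float:
        """D_j: polyline length of the trajectory, pixels."""
        if len(self.x) < 2:
            return 0.0
        return float(np.hypot(np.diff(self.x), np.diff(self.y)).sum())

    @property
    def mean_speed(self) -> float:
        """v_j = D_j / t_j, px/s; defined as 0 for zero-duration strokes."""
        d = self.duration
        return self.length / d if d > 0 else 0.0

    @property
    def centroid(self) -> np.ndarray:
        return np.array([self.x.mean(), self.y.mean()])

    @property
    def bbox(self) -> tuple[float, float, float, float]:
        return (float(self.x.min()), float(self.y.min()),
                float(self.x.max()), float(self.y.max()))


@dataclass
class SegmentedSession:
    """Strokes plus the pause decomposition of one session.

    ``total_time = initial_pause + sum(durations) + sum(gaps)`` exactly.
    """

    strokes: list
    inter_stroke_gaps: np.ndarray  # seconds, length J-1
    initial_pause: float  # seconds from session start to first down
    total_time: float  # seconds from session start to last up
    task_char_count: int = 10

    @property
    def n_strokes(self) -> int:
        return len(self.strokes)

    @property
    def durations(self) -> np.ndarray:
        return np.array([s.duration for s in self.strokes])

    @property
    def lengths(self) -> np.ndarray:
        return np.array([s.length for s in self.strokes])

    @property
    def speeds(self) -> np.ndarray:
        """Per-stroke mean speeds; zero-duration strokes with positive
        length are excluded (overflow guard)."""
        out = []
        for s in self.strokes:
            if s.duration <= 0 and s.length > 0:
                log.warning("stroke %d has zero duration and positive length; "
                            "excluded from speed statistics", s.index)
                continue
            out.append(s.mean_speed)
        return np.array(out)


def segment_strokes(session: WritingSession) -> SegmentedSession:
    """Pair each ``down`` with its ``up`` and compute the pause decomposition.

    Raises :class:`EmptySessionError` for sessions without any stroke; a
    ``down`` with no matching ``up`` is rejected already at session
    validation (dangling stroke).
    """
    phase = session.phase
    downs = np.nonzero(phase == 0)[0]
    ups = np.nonzero(phase == 2)[0]
    if downs.size == 0:
        raise EmptySessionError(
            f"session {session.subject_id!r} contains no stroke")
    if downs.size != ups.size:  # unreachable for validated sessions
        raise ValueError("unbalanced down/up events (dangling stroke)")
    t_s = session.t_ms / 1000.0
    strokes = [
        Stroke(index=j + 1, t=t_s[a:b + 1], x=session.x[a:b + 1],
               y=session.y[a:b + 1])
        for j, (a, b) in enumerate(zip(downs, ups))
    ]
    gaps = t_s[downs[1:]] - t_s[ups[:-1]]
    return SegmentedSession(
        strokes=strokes,
        inter_stroke_gaps=gaps,
        initial_pause=float(t_s[downs[0]]),
        total_time=float(t_s[ups[-1]]),
        task_char_count=session.task_char_count,
    )


def count_within_stroke_pauses(seg: SegmentedSession,
                               min_pause_ms: int = DEFAULT_MIN_PAUSE_MS) -> int:
    """Count stationary episodes inside strokes.

    A stationary episode is a maximal run of consecutive samples with
    identical coordinates. With ``min_pause_ms == 0`` the count degenerates
    to the number of duplicate consecutive coordinate pairs; otherwise a run
    counts once if its duration (last minus first timestamp of the run) is
    at least ``min_pause_ms``.
    """
    if min_pause_ms < 0:
        raise ValueError("min_pause_ms must be >= 0")
    total = 0
    for s in seg.strokes:
        same = (np.diff(s.x) == 0) & (np.diff(s.y) == 0)
        if min_pause_ms == 0:
            total += int(same.sum())
            continue
        i = 0
        n = len(same)
        while i < n:
            if same[i]:
                j = i
                while j < n and same[j]:
                    j += 1
                # run spans samples i..j inclusive; the 1e-6 guard keeps
                # integer-ms spans exactly at the threshold from flipping
                # on float round-off after the ms->s conversion
                if (s.t[j] - s.t[i]) * 1000.0 >= min_pause_ms - 1e-6:
                    total += 1
                i = j
            else:
                i += 1
    return total


# ---------------------------------------------------------------------------
# task score (EFDB_1)
# ---------------------------------------------------------------------------

@dataclass
class ScoreResult:
    score: int  # order_component + count_component, in [0, 2]
    order_component: int
    count_component: int
    n_characters: int
    diagnostics: str = ""


def _cluster_characters(seg: SegmentedSession) -> list:
    """Group strokes into characters by spatial clustering of centroids.

    Strokes are scanned in temporal order; a new character starts when a
    stroke's centroid is farther than 0.8 x the median glyph width from the
    running centroid of the current group. The glyph width is estimated in a
    first pass from stroke extents, then refined from the provisional
    character bounding boxes.
    """
    strokes = seg.strokes
    extents = np.array([max(b[2] - b[0], b[3] - b[1]) for s in strokes
                        for b in [s.bbox]])
    width0 = float(np.percentile(extents, 90)) if len(extents) else 1.0
    width0 = max(width0, 1.0)

    def group(threshold: float) -> list:
        chars: list[list] = []
        cur: list = []
        centroid = None
        for s in strokes:
            c = s.centroid
            if centroid is None or np.linalg.norm(c - centroid) <= threshold:
                cur.append(s)
            else:
                chars.append(cur)
                cur = [s]
            pts = np.concatenate([[st.centroid] for st in cur])
            centroid = pts.mean(axis=0)
        if cur:
            chars.append(cur)
        return chars

    chars = group(0.8 * width0)
    widths = [max(max(s.bbox[2] for s in ch) - min(s.bbox[0] for s in ch), 1.0)
              for ch in chars]
    if widths:
        chars = group(0.8 * float(np.median(widths)))
    return chars


def _resample(poly_x: np.ndarray, poly_y: np.ndarray, n: int = 16) -> np.ndarray:
    pts = np.column_stack([poly_x, poly_y]).astype(float)
    if len(pts) == 1:
        return np.repeat(pts, n, axis=0)
    seg_len = np.hypot(*np.diff(pts, axis=0).T)
    s = np.concatenate([[0.0], np.cumsum(seg_len)])
    if s[-1] == 0:
        return np.repeat(pts[:1], n, axis=0)
    target = np.linspace(0.0, s[-1], n)
    out = np.column_stack([
        np.interp(target, s, pts[:, 0]),
        np.interp(target, s, pts[:, 1]),
    ])
    return out


def _normalize_char(strokes: Sequence[Stroke]) -> list:
    """Similarity-normalize a character's strokes into the unit box."""
    xs = np.concatenate([s.x for s in strokes])
    ys = np.concatenate([s.y for s in strokes])
    x0, y0 = xs.min(), ys.min()
    scale = max(xs.max() - x0, ys.max() - y0, 1e-9)
    return [
        _resample((s.x - x0) / scale, (s.y - y0) / scale) for s in strokes
    ]


def score_task(seg: SegmentedSession, template: GlyphTemplate = MI_TEMPLATE,
               task_char_count: int | None = None) -> ScoreResult:
    """Two-component rubric for the glyph-writing task.

    * count component: 1 iff the number of detected characters equals the
      task's required repetition count;
    * order component: 1 iff every detected character has exactly the
      template's stroke count and, after similarity normalization, each of
      its strokes is nearest to its same-ranked template stroke (the
      nearest-template assignment is the identity permutation).
    """
    if task_char_count is None:
        task_char_count = seg.task_char_count
    if seg.n_strokes == 0:
        return ScoreResult(0, 0, 0, 0, "no strokes detected")
    chars = _cluster_characters(seg)
    if not chars:
        return ScoreResult(0, 0, 0, 0, "no characters detected")
    count_ok = int(len(chars) == task_char_count)

    tmpl = [_resample(s[:, 0], s[:, 1]) for s in template.strokes]
    order_ok = 1
    for ch in chars:
        if len(ch) != template.n_strokes:
            order_ok = 0
            break
        norm = _normalize_char(ch)
        for rank, stroke_pts in enumerate(norm):
            costs = [float(np.linalg.norm(stroke_pts - tp, axis=1).mean())
                     for tp in tmpl]
            if int(np.argmin(costs)) != rank:
                order_ok = 0
                break
        if not order_ok:
            break
    return ScoreResult(order_ok + count_ok, order_ok, count_ok, len(chars))


# ---------------------------------------------------------------------------
# biomarker vectors
# ---------------------------------------------------------------------------

def _population_cv(values: np.ndarray) -> float:
    m = values.mean()
    if m == 0:
        return 0.0
    return float(values.std(ddof=0) / m)


def compute_ipsdb(seg: SegmentedSession,
                  min_pause_ms: int = DEFAULT_MIN_PAUSE_MS) -> dict:
    """Information-processing-speed markers (times in seconds)."""
    if seg.n_strokes < 1:
        raise EmptySessionError("no strokes")
    gaps = seg.inter_stroke_gaps
    total = seg.total_time
    initial = seg.initial_pause
    writing = float(seg.durations.sum())
    process_pause = float(gaps.sum())
    out = {
        "IPSDB_1": total,
        "IPSDB_2": total - initial,
        "IPSDB_3": writing,
        "IPSDB_4": initial + process_pause,
        "IPSDB_5": initial,
        "IPSDB_6": process_pause,
        "IPSDB_10": float(count_within_stroke_pauses(seg, min_pause_ms)),
    }
    if len(gaps) == 0:  # single stroke: gap statistics undefined, never 0
        out["IPSDB_7"] = math.nan
        out["IPSDB_8"] = math.nan
        out["IPSDB_9"] = math.nan
    else:
        mean_gap = process_pause / len(gaps)
        out["IPSDB_7"] = float(gaps.max())
        out["IPSDB_8"] = mean_gap
        sigma_t = float(gaps.std(ddof=0))
        out["IPSDB_9"] = sigma_t / mean_gap if mean_gap > 0 else 0.0
    return out


def compute_efdb(seg: SegmentedSession, template: GlyphTemplate = MI_TEMPLATE,
                 ipsdb: dict | None = None,
                 task_char_count: int | None = None) -> dict:
    """Executive-function markers (lengths px, speeds px/s, CVs unitless)."""
    if seg.n_strokes < 1:
        raise EmptySessionError("no strokes")
    if ipsdb is None:
        ipsdb = compute_ipsdb(seg)
    J = seg.n_strokes
    lengths = seg.lengths
    speeds = seg.speeds
    total_len = float(lengths.sum())
    total_time = ipsdb["IPSDB_1"]
    score = score_task(seg, template, task_char_count)
    out = {
        "EFDB_1": float(score.score),
        "EFDB_2": float(J),
        "EFDB_3": J / total_time * 60.0 if total_time > 0 else math.nan,
        "EFDB_4": ipsdb["IPSDB_3"] / total_time if total_time > 0 else math.nan,
        "EFDB_5": total_len,
        "EFDB_6": float(lengths.max()),
        "EFDB_7": total_len / J,
        "EFDB_8": _population_cv(lengths),
    }
    if len(speeds) == 0:
        out["EFDB_9"] = math.nan
        out["EFDB_10"] = math.nan
        out["EFDB_11"] = math.nan
    else:
        out["EFDB_9"] = float(speeds.max())
        out["EFDB_10"] = float(speeds.mean())
        out["EFDB_11"] = _population_cv(speeds)
    return out


def extract_biomarkers(session: WritingSession,
                       min_pause_ms: int = DEFAULT_MIN_PAUSE_MS,
                       template: GlyphTemplate = MI_TEMPLATE) -> dict:
    """All 21 biomarkers of one session, keyed IPSDB_1..10, EFDB_1..11."""
    seg = segment_strokes(session)
    ipsdb = compute_ipsdb(seg, min_pause_ms)
    efdb = compute_efdb(seg, template, ipsdb=ipsdb)
    return {**ipsdb, **efdb}


def extract_cohort(sessions: Sequence[WritingSession],
                   metadata: pd.DataFrame | None = None,
                   min_pause_ms: int = DEFAULT_MIN_PAUSE_MS,
                   template: GlyphTemplate = MI_TEMPLATE,
                   skip_invalid: bool = True) -> pd.DataFrame:
    """Build the cohort feature table from sessions plus subject metadata.

    Sessions exceeding the task time limit are excluded (with a log record)
    when ``skip_invalid`` is set, mirroring the paradigm's exclusion rule.
    """
    rows = []
    for ses in sessions:
        if skip_invalid and not ses.is_valid:
            log.warning("session %s exceeds the time limit or is empty; "
                        "excluded", ses.subject_id)
            continue
        row = {"subject_id": ses.subject_id}
        row.update(extract_biomarkers(ses, min_pause_ms, template))
        rows.append(row)
    feats = pd.DataFrame(rows, columns=["subject_id", *BIOMARKER_COLUMNS])
    if metadata is not None:
        feats = metadata.merge(feats, on="subject_id", how="inner")
    return feats
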