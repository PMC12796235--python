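"""Event-detection evaluation of stationary-frame predictions.

The reference standard aggregates human annotations: each annotator marks
stationary US-index intervals; per-US scores (0..A, A annotators) are
averaged over each MS frame's US images, and frames with mean score at
least ``A/2`` (1.5 for three annotators) count as stationary.  Maximal runs
of stationary frames are *target events*.  A predicted frame inside any
event is a true positive (TP), outside all events a false positive (FP);
an event with no prediction is a false negative (FN).  TP1 counts at most
one credited prediction per event, so

    precision = TP / (TP + FP),     recall = TP1 / (TP1 + FN).

Sweeping the number of selected frames over the whole candidate pool gives
the precision-recall curve; its area is the average precision (AP), and the
mean over scans the mAP.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .frame_selection import candidate_minima
from .motion_score import MotionVector
from .scan_model import Scan, ms_frames

__all__ = [
    "AnnotationSet",
    "Event",
    "DetectionCounts",
    "load_annotations",
    "aggregate_annotations",
    "events_from_mask",
    "events_from_intervals",
    "precision_recall",
    "average_precision",
    "mean_average_precision",
]


Event = tuple[int, int]  # inclusive (start, end) MS-frame indices, 0-based


@dataclass
class AnnotationSet:
    """Per-annotator inclusive US-index intervals marked stationary (0-based)."""

    intervals: list[list[tuple[int, int]]]
    annotators: list[str] | None = None

    @property
    def n_annotators(self) -> int:
        return len(self.intervals)


def load_annotations(path: str | Path, one_based: bool = True) -> AnnotationSet:
    """Read annotation JSON ``[{"annotator": ..., "intervals": [[a, b], ...]}]``.

    File intervals are inclusive and 1-based by convention; they are
    converted to the internal 0-based indexing.
    """
    data = json.loads(Path(path).read_text())
    off = 1 if one_based else 0
    sets, names = [], []
    for entry in data:
        names.append(str(entry.get("annotator", f"A{len(names) + 1}")))
        sets.append([(int(a) - off, int(b) - off) for a, b in entry["intervals"]])
    return AnnotationSet(sets, names)


def aggregate_annotations(
    annots: AnnotationSet, scan: Scan
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Aggregate annotator intervals into a per-frame stationary mask.

    Returns ``(frame_mask, frame_scores, us_scores)``: per-US counts of
    covering annotators, per-frame mean of those counts over the frame's
    US images, and the boolean mask ``frame_scores >= A/2``.  Frames with
    no US images are never stationary.
    """
    a = annots.n_annotators
    us_scores = np.zeros(scan.n_us)
    for ivals in annots.intervals:
        cover = np.zeros(scan.n_us, dtype=bool)
        for lo, hi in ivals:
            if not (0 <= lo <= hi < scan.n_us):
                raise ValueError(
                    f"annotation interval ({lo}, {hi}) outside [0, {scan.n_us - 1}]"
                )
            cover[lo : hi + 1] = True
        us_scores += cover
    frames = ms_frames(scan)
    frame_scores = np.full(len(frames), np.nan)
    mask = np.zeros(len(frames), dtype=bool)
    for i, fr in enumerate(frames):
        if fr.n_us > 0:
            frame_scores[i] = float(us_scores[fr.s].mean())
            mask[i] = frame_scores[i] >= a / 2.0
    return mask, frame_scores, us_scores


def events_from_mask(mask: Sequence[bool]) -> list[Event]:
    """Maximal runs of True as inclusive (start, end) events."""
    mask = np.asarray(mask, dtype=bool)
    events: list[Event] = []
    start = None
    for i, v in enumerate(mask):
        if v and start is None:
            start = i
        elif not v and start is not None:
            events.append((start, i - 1))
            start = None
    if start is not None:
        events.append((start, len(mask) - 1))
    return events


def events_from_intervals(intervals: Iterable[Sequence[int]]) -> list[Event]:
    """Coerce inclusive (start, end) pairs into a sorted event list."""
    return sorted((int(a), int(b)) for a, b in intervals)


@dataclass
class DetectionCounts:
    tp: int
    fp: int
    fn: int
    tp1: int
    precision: float  # NaN when there are no predictions
    recall: float  # NaN when there are no events


def precision_recall(
    preds: Sequence[int], events: Sequence[Event]
) -> DetectionCounts:
    """Event-detection counts for a set of predicted frame indices."""
    preds = list(dict.fromkeys(int(p) for p in preds))  # distinct, order kept
    hit_events = set()
    tp = 0
    for p in preds:
        inside = None
        for ei, (lo, hi) in enumerate(events):
            if lo <= p <= hi:
                inside = ei
                break
        if inside is None:
            continue
        tp += 1
        hit_events.add(inside)
    fp = len(preds) - tp
    tp1 = len(hit_events)
    fn = len(events) - tp1
    precision = tp / (tp + fp) if preds else float("nan")
    recall = tp1 / (tp1 + fn) if events else float("nan")
    return DetectionCounts(tp, fp, fn, tp1, precision, recall)


def average_precision(
    m: MotionVector | np.ndarray,
    events: Sequence[Event],
    d_min: int,
) -> float:
    """Area under the precision-recall curve over all selection sizes.

    The candidate pool is every distance-respecting local minimum of the
    motion vector, ranked by ascending score; precision/recall are evaluated
    for each prefix and integrated stepwise as ``Σ ΔR · P`` (no
    interpolation).  Returns NaN when there are no events.
    """
    if len(events) == 0:
        return float("nan")
    values = m.scores if isinstance(m, MotionVector) else np.asarray(m, dtype=float)
    idx, _ = candidate_minima(values, d_min)
    ap = 0.0
    prev_recall = 0.0
    for n in range(1, len(idx) + 1):
        c = precision_recall(idx[:n], events)
        if c.recall > prev_recall:
            ap += (c.recall - prev_recall) * c.precision
            prev_recall = c.recall
    return ap


def mean_average_precision(
    scans: Iterable[tuple[MotionVector | np.ndarray, Sequence[Event]]],
    d_min: int | None = None,
) -> float:
    """Mean of per-scan AP; scans with undefined AP are excluded with a warning.

    ``d_min`` may be a fixed value or None to use the per-scan default
    ``⌊N_MS/20⌋``.
    """
    from .frame_selection import default_min_distance

    aps = []
    for mv, events in scans:
        values = mv.scores if isinstance(mv, MotionVector) else np.asarray(mv, dtype=float)
        dm = d_min if d_min is not None else default_min_distance(len(values))
        ap = average_precision(mv, events, dm)
        if np.isnan(ap):
            warnings.warn("scan with undefined AP excluded from mAP")
        else:
            aps.append(ap)
    if not aps:
        raise ValueError("no scan with a defined AP")
    return float(np.mean(aps))
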