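"""Selection of stationary MS frames as local minima of the motion vector.

The motion vector is scanned for strict local minima (endpoints excluded,
plateaus represented by their midpoint).  Minima closer than ``d_min``
frames are thinned keeping lower-valued ones first; the survivors are
sorted by ascending score and the first ``n_peaks`` returned.  The default
separation is one twentieth of the scan length, ``d_min = ⌊N_MS/20⌋``
(clamped to at least 1), and ``n_peaks = 5``; both depend on the scanning
protocol (US images per frame, scan length, expected number of holds) and
should be adapted accordingly.

Missing (NaN) scores split the vector into segments; minima are sought per
segment so gaps never create spurious candidates.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.signal import find_peaks

from .motion_score import MotionVector

__all__ = [
    "SelectionResult",
    "default_min_distance",
    "candidate_minima",
    "select_stationary_frames",
    "write_selection",
    "read_selection",
]

DEFAULT_N_PEAKS = 5


@dataclass
class SelectionResult:
    """Chosen stationary MS frames, in ascending-score order."""

    frame_indices: list[int]
    scores: list[float]
    d_min: int
    n_peaks_requested: int

    def __len__(self) -> int:
        return len(self.frame_indices)


def default_min_distance(n_ms: int) -> int:
    """``⌊N_MS/20⌋`` floored at 1."""
    if n_ms < 1:
        raise ValueError("scan must contain at least one MS frame")
    return max(1, n_ms // 20)


def _local_minima(values: np.ndarray) -> np.ndarray:
    """Strict local minima indices per NaN-free segment (plateau midpoints)."""
    values = np.asarray(values, dtype=float)
    finite = np.isfinite(values)
    out: list[int] = []
    i = 0
    n = len(values)
    while i < n:
        if not finite[i]:
            i += 1
            continue
        j = i
        while j < n and finite[j]:
            j += 1
        seg = values[i:j]
        if len(seg) >= 3:
            peaks, _ = find_peaks(-seg)
            out.extend(int(p) + i for p in peaks)
        i = j
    return np.asarray(sorted(out), dtype=int)


def candidate_minima(values: np.ndarray, d_min: int) -> tuple[np.ndarray, np.ndarray]:
    """All distance-respecting local minima, sorted by (score, index).

    Thinning follows the standard peak-finder contract: candidates are
    visited in ascending score order and kept only if at least ``d_min``
    frames away from every already kept minimum.
    """
    if d_min < 1:
        raise ValueError("d_min must be >= 1")
    minima = _local_minima(values)
    if len(minima) == 0:
        return np.empty(0, dtype=int), np.empty(0)
    vals = np.asarray(values, dtype=float)[minima]
    order = np.lexsort((minima, vals))  # ties break toward the earlier frame
    kept: list[int] = []
    for pos in order:
        idx = int(minima[pos])
        if all(abs(idx - k) >= d_min for k in kept):
            kept.append(idx)
    kept_arr = np.asarray(kept, dtype=int)
    return kept_arr, np.asarray(values, dtype=float)[kept_arr]


def select_stationary_frames(
    m: MotionVector | np.ndarray,
    d_min: int,
    n_peaks: int = DEFAULT_N_PEAKS,
) -> SelectionResult:
    """Select up to ``n_peaks`` stationary frames from a motion vector."""
    if n_peaks < 1:
        raise ValueError("n_peaks must be >= 1")
    values = m.scores if isinstance(m, MotionVector) else np.asarray(m, dtype=float)
    if not np.any(np.isfinite(values)):
        warnings.warn("motion vector has no defined scores; empty selection")
        return SelectionResult([], [], d_min, n_peaks)
    idx, vals = candidate_minima(values, d_min)
    take = min(n_peaks, len(idx))
    return SelectionResult(
        [int(i) for i in idx[:take]],
        [float(v) for v in vals[:take]],
        d_min,
        n_peaks,
    )


def write_selection(sel: SelectionResult, path: str | Path, **extra) -> None:
    payload = {
        "frame_indices": sel.frame_indices,
        "scores": sel.scores,
        "d_min": sel.d_min,
        "n_peaks": sel.n_peaks_requested,
    }
    payload.update(extra)
    Path(path).write_text(json.dumps(payload, indent=2))


def read_selection(path: str | Path) -> SelectionResult:
    data = json.loads(Path(path).read_text())
    return SelectionResult(
        [int(i) for i in data["frame_indices"]],
        [float(v) for v in data["scores"]],
        int(data["d_min"]),
        int(data["n_peaks"]),
    )
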