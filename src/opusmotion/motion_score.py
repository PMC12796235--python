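"""Motion score: banded US dissimilarity matrix, normalization, frame scores.

For a scan with ``N_US`` ultrasound images and a dissimilarity ``d``, the
banded matrix ``D`` holds

    D[i, j] = d(I_US[j], I_US[j+i])      (lag i = 1..K, defined for i+j <= N_US)

i.e. row ``i`` compares every image with its ``i``-th successor.  Only the
first ``K = max_k |s^(k)|`` rows are needed, because an MS frame spans at
most ``K`` US images.  Rows are normalized to [0, 1] either by fractional
rank (``rank``) or min-max (``minmax``) over the whole row, which makes
different measures commensurable so several can be fused.

The Motion score of an MS frame with US index sequence ``s`` (n = |s|) fuses
a set of measures Δ:

    m = 2 / (|Δ| n²) · Σ_{d∈Δ} Σ_{i=1..n} Σ_{j=s_1..s_{n-i}} M_d[i, j]

with ``M`` the rank- or min-max-normalized matrix; the inner sum is empty
for i = n.  Scores therefore lie in ``[0, (n-1)/n]``.  The naive baseline
averages only consecutive-pair dissimilarities:

    m0 = (1/n) Σ_{j=s_1..s_{n-1}} d(I_US[j], I_US[j+1])

(divisor ``n`` over ``n-1`` summands, as defined).  Frames with fewer than
two US images receive a missing (NaN) score.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .dissimilarity import Measure, resolve_measures
from .scan_model import Scan, MSFrame, ms_frames, max_us_per_frame

__all__ = [
    "DissimilarityMatrix",
    "NormalizedMatrix",
    "MotionVector",
    "build_dissimilarity_matrix",
    "rank_normalize",
    "minmax_normalize",
    "frame_score",
    "motion_vector",
    "naive_motion_vector",
    "write_scores",
    "read_scores",
]


@dataclass
class DissimilarityMatrix:
    """Banded lag-by-index matrix of pairwise US dissimilarities.

    ``values`` has shape (K, N_US - 1); entry ``values[i-1, j]`` (0-based j)
    holds ``d(us[j], us[j+i])`` and is NaN where undefined (j >= N_US - i).
    """

    measure_name: str
    values: np.ndarray
    n_us: int

    @property
    def k(self) -> int:
        return self.values.shape[0]

    def row(self, lag: int) -> np.ndarray:
        """Defined entries of the row at ``lag`` (1-based lag)."""
        return self.values[lag - 1, : self.n_us - lag]


@dataclass
class NormalizedMatrix:
    """Row-normalized band (``kind`` in {rank, minmax}); values in [0, 1]."""

    kind: str
    measure_name: str
    values: np.ndarray
    n_us: int

    def row(self, lag: int) -> np.ndarray:
        return self.values[lag - 1, : self.n_us - lag]


@dataclass
class MotionVector:
    """Per-MS-frame Motion score values for a whole scan.

    ``scores`` has length ``N_MS`` with NaN for frames with |s| < 2;
    ``frames`` keeps the MS frame descriptors for provenance.
    """

    scores: np.ndarray
    variant: str
    measures: tuple[str, ...]
    frames: list[MSFrame] | None = None

    def __len__(self) -> int:
        return len(self.scores)


def build_dissimilarity_matrix(
    us_images: Sequence[np.ndarray] | np.ndarray,
    measure: Measure,
    k: int,
) -> DissimilarityMatrix:
    """Compute the first ``k`` lag rows of the banded dissimilarity matrix."""
    n_us = len(us_images)
    if n_us < 2:
        raise ValueError("need at least two US images")
    if not 1 <= k <= n_us - 1:
        raise ValueError(f"K={k} out of range [1, {n_us - 1}]")
    values = np.full((k, n_us - 1), np.nan)
    for lag in range(1, k + 1):
        for j in range(n_us - lag):
            values[lag - 1, j] = measure(us_images[j], us_images[j + lag])
    return DissimilarityMatrix(measure.name, values, n_us)


def rank_normalize(d: DissimilarityMatrix) -> NormalizedMatrix:
    """Replace each row entry by its fractional rank in the sorted row.

    Ranks are 0-based with average ties and divided by ``N_US - i - 1`` so a
    full row spans exactly [0, 1]; single-entry rows map to 0.  Rank
    normalization is invariant under any strictly monotone transform of the
    measure, making it robust to outliers and to the measure's value scale.
    """
    values = np.full_like(d.values, np.nan)
    for lag in range(1, d.k + 1):
        row = d.row(lag)
        n = len(row)
        if n == 0:
            continue
        if n == 1:
            values[lag - 1, 0] = 0.0
        else:
            values[lag - 1, :n] = (rankdata(row, method="average") - 1.0) / (n - 1.0)
    return NormalizedMatrix("rank", d.measure_name, values, d.n_us)


def minmax_normalize(d: DissimilarityMatrix) -> NormalizedMatrix:
    """Row-wise ``(x - min) / (max - min)``; constant rows map to 0."""
    values = np.full_like(d.values, np.nan)
    for lag in range(1, d.k + 1):
        row = d.row(lag)
        if len(row) == 0:
            continue
        lo, hi = row.min(), row.max()
        if hi > lo:
            values[lag - 1, : len(row)] = (row - lo) / (hi - lo)
        else:
            values[lag - 1, : len(row)] = 0.0
    return NormalizedMatrix("minmax", d.measure_name, values, d.n_us)


def frame_score(norms: Sequence[NormalizedMatrix], s: np.ndarray) -> float:
    """Motion score of one MS frame from normalized matrices over Δ.

    Sums ``M[i, j]`` for lags ``i = 1..n-1`` and start indices
    ``j = s[0] .. s[0]+n-i-1`` (the pairs of US images both inside the
    frame), scaled by ``2 / (|Δ| n²)``.  Returns NaN with a warning when the
    frame has fewer than two US images.
    """
    s = np.asarray(s)
    n = len(s)
    if n < 2:
        warnings.warn("MS frame has fewer than 2 US images; score is missing")
        return float("nan")
    j0 = int(s[0])
    total = 0.0
    for m in norms:
        if m.values.shape[0] < n - 1:
            raise ValueError(
                f"normalized matrix has {m.values.shape[0]} lag rows; frame needs {n - 1}"
            )
        for lag in range(1, n):
            total += float(np.sum(m.values[lag - 1, j0 : j0 + n - lag]))
    return 2.0 * total / (len(norms) * n * n)


def _normalize(d: DissimilarityMatrix, variant: str) -> NormalizedMatrix:
    if variant == "ranked":
        return rank_normalize(d)
    if variant == "normalized":
        return minmax_normalize(d)
    raise ValueError(f"unknown variant '{variant}'; expected 'ranked' or 'normalized'")


def motion_vector(
    scan: Scan,
    measures: str | Sequence[str | Measure] = "znxc,ssim",
    variant: str = "ranked",
) -> MotionVector:
    """Motion score of every MS frame in a scan.

    Builds the banded dissimilarity matrix once per measure with
    ``K = max_k |s^(k)|`` rows, normalizes rows scan-wide, then aggregates
    per frame.  Default configuration is the validated one: ranked variant
    with Δ = {znxc, ssim}.
    """
    measure_objs = resolve_measures(measures)
    frames = ms_frames(scan)
    k_max = max_us_per_frame(scan)
    k_rows = min(max(k_max, 1), scan.n_us - 1) if scan.n_us >= 2 else 0
    norms: list[NormalizedMatrix] = []
    if k_rows >= 1:
        for meas in measure_objs:
            d = build_dissimilarity_matrix(scan.us_images, meas, k_rows)
            norms.append(_normalize(d, variant))
    scores = np.full(len(frames), np.nan)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i, fr in enumerate(frames):
            if fr.n_us >= 2:
                scores[i] = frame_score(norms, fr.s)
    return MotionVector(scores, variant, tuple(m.name for m in measure_objs), frames)


def naive_motion_vector(
    scan: Scan, measure: str | Measure = "l2"
) -> MotionVector:
    """Naive baseline: mean dissimilarity of consecutive US pairs per frame.

    ``m0 = (1/n) Σ d(I_US[j], I_US[j+1])`` over the ``n-1`` consecutive
    pairs inside the frame.  Cannot tell steady drift from jitter because it
    never compares images more than one step apart.
    """
    (meas,) = resolve_measures([measure] if isinstance(measure, (str, Measure)) else measure)
    frames = ms_frames(scan)
    scores = np.full(len(frames), np.nan)
    # consecutive-pair dissimilarities, computed once
    pair = np.full(max(scan.n_us - 1, 0), np.nan)
    needed = sorted({j for fr in frames if fr.n_us >= 2 for j in range(fr.s[0], fr.s[-1])})
    for j in needed:
        pair[j] = meas(scan.us_images[j], scan.us_images[j + 1])
    for i, fr in enumerate(frames):
        n = fr.n_us
        if n >= 2:
            j0 = int(fr.s[0])
            scores[i] = float(np.sum(pair[j0 : j0 + n - 1])) / n
    return MotionVector(scores, "naive", (meas.name,), frames)


# -- CSV I/O -------------------------------------------------------------

def write_scores(mv: MotionVector, path: str | Path) -> None:
    """Write a motion vector as CSV (missing scores as empty cells)."""
    frames = mv.frames or []
    df = pd.DataFrame(
        {
            "frame_index": np.arange(len(mv.scores)),
            "oa_start_index": [f.k for f in frames] if frames else np.arange(len(mv.scores)),
            "n_us": [f.n_us for f in frames] if frames else -1,
            "score": mv.scores,
            "variant": mv.variant,
            "measures": "+".join(mv.measures),
        }
    )
    df.to_csv(path, index=False)


def read_scores(path: str | Path) -> MotionVector:
    """Read a motion vector written by :func:`write_scores`."""
    df = pd.read_csv(path)
    if df.empty:
        raise ValueError(f"scores file {path} contains no rows")
    variant = str(df["variant"].iloc[0])
    measures = tuple(str(df["measures"].iloc[0]).split("+"))
    scores = df["score"].to_numpy(dtype=float)
    return MotionVector(scores, variant, measures)
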