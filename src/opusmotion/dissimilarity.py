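"""Image dissimilarity measures for ultrasound frame comparison.

A *measure* maps a pair of equally shaped images to a real dissimilarity
``d(a, b)`` with ``d(a, a)`` at the minimum of its range and ``d`` symmetric.
Similarities are converted to dissimilarities as ``1 - s`` for normalized
measures (ZNXC, SSIM) and ``-s`` for unnormalized cross-correlation.

The built-in registry resolves names ``{l2, xcorr, znxc, ssim}``; user code
may register additional measures (e.g. an optical-flow magnitude) to plug
into motion scoring.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable

import numpy as np
from skimage.metrics import structural_similarity

__all__ = [
    "Measure",
    "d_l2",
    "d_xcorr",
    "d_znxc",
    "d_ssim",
    "MEASURES",
    "get_measure",
    "resolve_measures",
    "register_measure",
]


def _check_shapes(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"image shapes differ: {a.shape} vs {b.shape}")
    return a, b


def d_l2(a: np.ndarray, b: np.ndarray) -> float:
    """Euclidean norm of the pixelwise difference."""
    a, b = _check_shapes(a, b)
    return float(np.linalg.norm(a - b))


def d_xcorr(a: np.ndarray, b: np.ndarray) -> float:
    """Negated mean elementwise product, ``-(Σ a·b)/p``.

    Unnormalized cross-correlation at zero displacement; lower values mean
    more similar for nonnegative images.
    """
    a, b = _check_shapes(a, b)
    return float(-np.mean(a * b))


def d_znxc(a: np.ndarray, b: np.ndarray) -> float:
    """Zero-normalized cross-correlation dissimilarity, ``1 - r`` in [0, 2].

    ``r`` is the Pearson correlation of the flattened pixels (zero-mean,
    unit-variance normalized correlation at zero displacement).  Degenerate
    conventions: both images constant -> 0; exactly one constant -> 1.
    """
    a, b = _check_shapes(a, b)
    da = a - a.mean()
    db = b - b.mean()
    na = np.linalg.norm(da)
    nb = np.linalg.norm(db)
    if na == 0.0 and nb == 0.0:
        return 0.0
    if na == 0.0 or nb == 0.0:
        return 1.0
    r = float(np.dot(da.ravel(), db.ravel()) / (na * nb))
    return 1.0 - max(-1.0, min(1.0, r))


def d_ssim(
    a: np.ndarray,
    b: np.ndarray,
    data_range: float | None = None,
    win_size: int = 11,
    sigma: float = 1.5,
) -> float:
    """Structural-similarity dissimilarity, ``1 - mean SSIM`` in [0, 2].

    Standard SSIM with a Gaussian window (size 11, sigma 1.5) and
    stabilizers ``C1=(0.01 L)^2``, ``C2=(0.03 L)^2`` where ``L`` is the
    dynamic range (default: max - min over the pair).
    """
    a, b = _check_shapes(a, b)
    if min(a.shape) < win_size:
        raise ValueError(
            f"image shape {a.shape} smaller than the SSIM window ({win_size})"
        )
    if data_range is None:
        data_range = float(max(a.max(), b.max()) - min(a.min(), b.min()))
        if data_range == 0.0:
            # both images are the same constant
            return 0.0
    s = structural_similarity(
        a,
        b,
        win_size=win_size,
        gaussian_weights=True,
        sigma=sigma,
        use_sample_covariance=False,
        data_range=data_range,
    )
    return float(1.0 - s)


@dataclass(frozen=True)
class Measure:
    """A named dissimilarity with its documented output range."""

    name: str
    fn: Callable[[np.ndarray, np.ndarray], float]
    range: tuple[float, float]

    def __call__(self, a: np.ndarray, b: np.ndarray) -> float:
        return self.fn(a, b)


MEASURES: dict[str, Measure] = {
    "l2": Measure("l2", d_l2, (0.0, np.inf)),
    "xcorr": Measure("xcorr", d_xcorr, (-np.inf, np.inf)),
    "znxc": Measure("znxc", d_znxc, (0.0, 2.0)),
    "ssim": Measure("ssim", d_ssim, (0.0, 2.0)),
}


def register_measure(measure: Measure) -> None:
    """Add a user-defined measure (e.g. an optical-flow plug-in) to the registry."""
    MEASURES[measure.name] = measure


def get_measure(name: str) -> Measure:
    try:
        return MEASURES[name]
    except KeyError:
        raise KeyError(
            f"unknown dissimilarity measure '{name}'; known: {sorted(MEASURES)}"
        ) from None


def resolve_measures(spec: str | Iterable[str | Measure]) -> list[Measure]:
    """Resolve a measure-set specification.

    Accepts a comma-separated string (``"znxc,ssim"``), an iterable of names,
    or Measure instances.
    """
    if isinstance(spec, str):
        spec = [s.strip() for s in spec.split(",") if s.strip()]
    out: list[Measure] = []
    for item in spec:
        out.append(item if isinstance(item, Measure) else get_measure(item))
    if not out:
        raise ValueError("empty measure set")
    return out
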