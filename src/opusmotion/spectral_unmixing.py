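"""Spectral-quality assessment of MS frames by linear unmixing residuals.

Each pixel of an MS frame carries a spectrum over the wavelength preset Λ.
Under the linear mixing model the pixel-spectra matrix
``I ∈ R^(p × |Λ|)`` decomposes as ``I ≈ C W`` with non-negative
coefficients ``C ∈ R^(p × k)`` and component spectra ``W ∈ R^(k × |Λ|)``:
either known chromophore spectra (constrained least squares, per-pixel
NNLS) or spectra learned jointly by blind non-negative matrix
factorization.  Motion during the wavelength sweep mixes spectra of
adjacent pixels, which the linear model cannot explain, so the relative
L2,1 residual

    E = Σ_pixels ‖(I - C W) pixel row‖₂ / Σ_pixels ‖I pixel row‖₂

grows with motion corruption and serves as a spectral-quality proxy
(E = 0 for a perfect fit, E = 1 for C = 0).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np
import pandas as pd
from scipy.optimize import nnls
from sklearn.decomposition import NMF

from .scan_model import Scan, MSFrame

__all__ = [
    "SpectralLibrary",
    "UnmixResult",
    "load_spectra",
    "builtin_library",
    "frame_to_matrix",
    "nnls_unmix",
    "nmf_blind_unmix",
    "unmix_residual",
    "save_unmix",
]

CLINICAL_COMPONENTS = ("hb", "hbo2", "water", "lipid")


@dataclass
class SpectralLibrary:
    """Component absorption spectra on a wavelength grid.

    ``w`` is the k × |Λ| matrix of spectra (rows = components).
    """

    names: tuple[str, ...]
    wavelengths: np.ndarray
    w: np.ndarray

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.w = np.asarray(self.w, dtype=float)
        if self.w.shape != (len(self.names), len(self.wavelengths)):
            raise ValueError("W must be (n_components, n_wavelengths)")
        if not np.all(np.isfinite(self.w)):
            raise ValueError("spectra must be finite")

    @property
    def k(self) -> int:
        return len(self.names)

    def interpolated_to(self, wavelengths: Sequence[float]) -> "SpectralLibrary":
        """Linearly interpolate every component onto a new wavelength grid."""
        grid = np.asarray(wavelengths, dtype=float)
        if grid.min() < self.wavelengths.min() or grid.max() > self.wavelengths.max():
            raise ValueError(
                "requested grid extends beyond the tabulated wavelength range"
            )
        w = np.vstack([np.interp(grid, self.wavelengths, row) for row in self.w])
        return SpectralLibrary(self.names, grid, w)


def load_spectra(path: str | Path, components: Sequence[str] | None = None) -> SpectralLibrary:
    """Load a spectra CSV with a ``wavelength_nm`` column plus one per component."""
    df = pd.read_csv(path, comment="#")
    if "wavelength_nm" not in df.columns:
        raise ValueError("spectra CSV must contain a 'wavelength_nm' column")
    names = tuple(components) if components else tuple(
        c for c in df.columns if c != "wavelength_nm"
    )
    missing = [c for c in names if c not in df.columns]
    if missing:
        raise ValueError(f"spectra CSV lacks components {missing}")
    return SpectralLibrary(
        names,
        df["wavelength_nm"].to_numpy(float),
        df[list(names)].to_numpy(float).T,
    )


def builtin_library(components: Sequence[str] = CLINICAL_COMPONENTS) -> SpectralLibrary:
    """Bundled chromophore spectra (Hb, HbO2, water, lipid) for 700-970 nm."""
    with resources.files("opusmotion.data").joinpath("chromophores.csv").open() as f:
        df = pd.read_csv(f, comment="#")
    names = tuple(components)
    return SpectralLibrary(
        names,
        df["wavelength_nm"].to_numpy(float),
        df[list(names)].to_numpy(float).T,
    )


@dataclass
class UnmixResult:
    """Non-negative unmixing of a pixel-spectra matrix."""

    c: np.ndarray  # (p, k) coefficients, >= 0
    w: np.ndarray  # (k, |Λ|) spectra used or learned
    e: float  # relative L2,1 residual
    method: str
    n_iter: int | None = None
    seed: int | None = None


def frame_to_matrix(scan: Scan, frame: MSFrame) -> np.ndarray:
    """Pixel-spectra matrix ``I ∈ R^(p × |Λ|)`` of one MS frame.

    Rows are pixels (row-major), columns the frame's OA images sorted by
    ascending wavelength.
    """
    stack = scan.oa_images[frame.oa_indices[frame.wavelength_order]]
    n_l = stack.shape[0]
    return stack.reshape(n_l, -1).T.astype(float)


def _as_w(w: SpectralLibrary | np.ndarray, n_lambda: int) -> np.ndarray:
    if isinstance(w, SpectralLibrary):
        if len(w.wavelengths) != n_lambda:
            raise ValueError(
                f"spectral library has {len(w.wavelengths)} wavelengths, frame has "
                f"{n_lambda}; interpolate the library onto the scan's grid first"
            )
        return w.w
    w = np.asarray(w, dtype=float)
    if w.shape[1] != n_lambda:
        raise ValueError(f"W has {w.shape[1]} wavelengths, frame has {n_lambda}")
    return w


def nnls_unmix(i_ms: np.ndarray, w: SpectralLibrary | np.ndarray) -> UnmixResult:
    """Constrained linear unmixing ``argmin_{C>=0} ‖I - C W‖_F``.

    The Frobenius objective separates over pixels, so each row of ``C`` is
    an independent non-negative least-squares problem (deterministic
    active-set solution).
    """
    i_ms = np.asarray(i_ms, dtype=float)
    w_arr = _as_w(w, i_ms.shape[1])
    if i_ms.shape[1] < w_arr.shape[0]:
        raise ValueError("need at least as many wavelengths as components")
    a = w_arr.T  # (|Λ|, k)
    c = np.empty((i_ms.shape[0], w_arr.shape[0]))
    for p in range(i_ms.shape[0]):
        c[p], _ = nnls(a, i_ms[p])
    return UnmixResult(c, w_arr, unmix_residual(i_ms, c, w_arr), "nnls")


def nmf_blind_unmix(
    i_ms: np.ndarray,
    k: int,
    seed: int = 0,
    max_iter: int = 1000,
    tol: float = 1e-6,
) -> UnmixResult:
    """Blind unmixing by seeded non-negative matrix factorization.

    Learns both coefficients and spectra, ``I ≈ C W`` with ``C, W >= 0``,
    minimizing the Frobenius reconstruction error by multiplicative updates
    from an NNDSVD-based initialization.  Negative intensities
    (reconstruction artifacts) are clipped to zero with a warning.
    """
    i_ms = np.asarray(i_ms, dtype=float)
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > min(i_ms.shape):
        raise ValueError(f"k={k} exceeds min(p, n_wavelengths)={min(i_ms.shape)}")
    if np.any(i_ms < 0):
        warnings.warn("negative intensities clipped to 0 for NMF")
        i_ms = np.clip(i_ms, 0.0, None)
    model = NMF(
        n_components=k,
        init="nndsvda",
        solver="mu",
        beta_loss="frobenius",
        tol=tol,
        max_iter=max_iter,
        random_state=seed,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # convergence warnings at the iteration cap
        c = model.fit_transform(i_ms)
    w = model.components_
    return UnmixResult(
        c, w, unmix_residual(i_ms, c, w), "nmf", n_iter=model.n_iter_, seed=seed
    )


def unmix_residual(i_ms: np.ndarray, c: np.ndarray, w: np.ndarray) -> float:
    """Relative L2,1 unmixing residual ``E``.

    Sum over pixels of the L2 norm of the residual spectrum, divided by the
    same sum for the measured spectra.  NaN when the frame is identically
    zero.
    """
    i_ms = np.asarray(i_ms, dtype=float)
    resid = i_ms - np.asarray(c, dtype=float) @ np.asarray(w, dtype=float)
    denom = float(np.sum(np.linalg.norm(i_ms, axis=1)))
    if denom == 0.0:
        return float("nan")
    return float(np.sum(np.linalg.norm(resid, axis=1)) / denom)


def save_unmix(result: UnmixResult, path: str | Path) -> None:
    """Write an unmixing result as HDF5 (/C, /W; attrs E, method, seed)."""
    with h5py.File(path, "w") as f:
        f.create_dataset("C", data=result.c)
        f.create_dataset("W", data=result.w)
        f.attrs["E"] = result.e
        f.attrs["method"] = result.method
        if result.seed is not None:
            f.attrs["seed"] = result.seed
        if result.n_iter is not None:
            f.attrs["n_iter"] = result.n_iter
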