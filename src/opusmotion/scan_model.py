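"""Data model and HDF5 I/O for interleaved MS-OPUS acquisitions.

An MS-OPUS scanner records two streams with one handheld probe: pulse-echo
ultrasound (US) images and single-wavelength optoacoustic (OA) images whose
illumination wavelength cycles through a fixed preset ``Λ`` (e.g. 700-970 nm
in 10 nm steps, ``N_Λ = 28``).  A *multispectral (MS) frame* is any run of
``N_Λ`` consecutive OA images; MS frames may start at any OA image, so
consecutive frames overlap in ``N_Λ - 1`` images.  Each MS frame is paired
with the US images acquired during its time span, which downstream motion
scoring compares.

All indices are 0-based internally.  Timestamps are seconds as float64.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import h5py
import numpy as np

__all__ = [
    "Scan",
    "MSFrame",
    "ScanFormatError",
    "ScanValidationError",
    "load_scan",
    "save_scan",
    "ms_frames",
    "us_indices_for_frame",
    "max_us_per_frame",
]


class ScanFormatError(ValueError):
    """The file does not follow the expected HDF5 layout."""


class ScanValidationError(ValueError):
    """The scan violates a structural invariant (e.g. non-monotone timestamps)."""


@dataclass
class Scan:
    """One MS-OPUS acquisition: paired timestamped US and OA image streams.

    Parameters
    ----------
    us_images : ndarray, shape (N_US, H, W)
    us_timestamps : ndarray, shape (N_US,), strictly increasing seconds
    oa_images : ndarray, shape (N_OA, H', W')
    oa_timestamps : ndarray, shape (N_OA,), strictly increasing seconds
    oa_wavelengths : ndarray, shape (N_OA,), nm; cycles through the
        wavelength preset with period ``N_Λ``
    meta : dict with free-form scan metadata (scan_id, f_us_hz, f_oa_hz, ...)
    """

    us_images: np.ndarray
    us_timestamps: np.ndarray
    oa_images: np.ndarray
    oa_timestamps: np.ndarray
    oa_wavelengths: np.ndarray
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.us_images = np.asarray(self.us_images)
        self.us_timestamps = np.asarray(self.us_timestamps, dtype=np.float64)
        self.oa_images = np.asarray(self.oa_images)
        self.oa_timestamps = np.asarray(self.oa_timestamps, dtype=np.float64)
        self.oa_wavelengths = np.asarray(self.oa_wavelengths, dtype=np.float64)
        self.validate()

    # -- derived sizes ---------------------------------------------------
    @property
    def n_us(self) -> int:
        return len(self.us_timestamps)

    @property
    def n_oa(self) -> int:
        return len(self.oa_timestamps)

    @property
    def wavelength_set(self) -> np.ndarray:
        """Ascending unique wavelengths Λ."""
        return np.unique(self.oa_wavelengths)

    @property
    def n_lambda(self) -> int:
        return len(self.wavelength_set)

    @property
    def n_ms(self) -> int:
        """Number of (sliding) MS frames, ``N_OA - N_Λ + 1``."""
        return self.n_oa - self.n_lambda + 1

    def validate(self) -> None:
        if self.us_images.ndim != 3 or self.oa_images.ndim != 3:
            raise ScanValidationError("image stacks must be 3-D (N, H, W)")
        if len(self.us_images) != self.n_us:
            raise ScanValidationError("us_images and us_timestamps length mismatch")
        if len(self.oa_images) != self.n_oa or len(self.oa_wavelengths) != self.n_oa:
            raise ScanValidationError("oa_images/oa_wavelengths/oa_timestamps length mismatch")
        for name, t in (("us", self.us_timestamps), ("oa", self.oa_timestamps)):
            if len(t) > 1 and not np.all(np.diff(t) > 0):
                raise ScanValidationError(f"{name}_timestamps must be strictly increasing")
        nl = self.n_lambda
        wl = self.oa_wavelengths
        if nl >= 1 and len(wl) > nl and not np.array_equal(wl[nl:], wl[:-nl]):
            raise ScanValidationError(
                "oa_wavelengths must cycle through the wavelength set with period N_lambda"
            )


@dataclass(frozen=True)
class MSFrame:
    """One sliding multispectral frame.

    Attributes
    ----------
    k : 0-based start index into the OA stream.
    oa_indices : the ``N_Λ`` consecutive OA indices ``k .. k+N_Λ-1``.
    s : ascending US indices whose timestamps fall inside the closed
        interval ``[t_OA[k], t_OA[k+N_Λ-1]]``; may be empty.
    wavelength_order : permutation of ``oa_indices`` positions sorting the
        frame's OA images by ascending wavelength.
    """

    k: int
    oa_indices: np.ndarray
    s: np.ndarray
    wavelength_order: np.ndarray

    @property
    def n_us(self) -> int:
        return len(self.s)


def us_indices_for_frame(scan: Scan, k: int) -> np.ndarray:
    """US indices acquired during MS frame ``k`` (0-based, closed time interval)."""
    if not 0 <= k < scan.n_ms:
        raise IndexError(f"frame index {k} out of range [0, {scan.n_ms})")
    t0 = scan.oa_timestamps[k]
    t1 = scan.oa_timestamps[k + scan.n_lambda - 1]
    lo = int(np.searchsorted(scan.us_timestamps, t0, side="left"))
    hi = int(np.searchsorted(scan.us_timestamps, t1, side="right"))
    return np.arange(lo, hi)


def ms_frames(scan: Scan) -> list[MSFrame]:
    """All sliding MS frames of a scan.

    Consecutive frames overlap in ``N_Λ - 1`` OA images; images within a
    frame are ordered by ascending wavelength through ``wavelength_order``
    (stable for repeated wavelengths).
    """
    nl = scan.n_lambda
    if scan.n_oa < nl:
        raise ValueError(
            f"scan has {scan.n_oa} OA images but the wavelength set has {nl}; "
            "at least one full wavelength sweep is required"
        )
    frames = []
    for k in range(scan.n_ms):
        oa_idx = np.arange(k, k + nl)
        order = np.argsort(scan.oa_wavelengths[oa_idx], kind="stable")
        frames.append(
            MSFrame(
                k=k,
                oa_indices=oa_idx,
                s=us_indices_for_frame(scan, k),
                wavelength_order=order,
            )
        )
    return frames


def max_us_per_frame(scan: Scan) -> int:
    """``K = max_k |s^(k)|`` — bounds the number of dissimilarity-matrix rows."""
    return max(len(us_indices_for_frame(scan, k)) for k in range(scan.n_ms))


# -- HDF5 I/O ------------------------------------------------------------

_REQUIRED = (
    "us/images",
    "us/timestamps",
    "oa/images",
    "oa/timestamps",
    "oa/wavelengths",
)


def save_scan(scan: Scan, path: str | Path) -> None:
    """Write a scan to the HDF5 container layout."""
    with h5py.File(path, "w") as f:
        f.create_dataset("us/images", data=scan.us_images.astype(np.float32))
        f.create_dataset("us/timestamps", data=scan.us_timestamps)
        f.create_dataset("oa/images", data=scan.oa_images.astype(np.float32))
        f.create_dataset("oa/timestamps", data=scan.oa_timestamps)
        f.create_dataset("oa/wavelengths", data=scan.oa_wavelengths)
        for key, val in scan.meta.items():
            f.attrs[key] = val


def load_scan(path: str | Path) -> Scan:
    """Read a scan from the HDF5 container layout; unknown datasets are ignored."""
    with h5py.File(path, "r") as f:
        for name in _REQUIRED:
            if name not in f:
                raise ScanFormatError(f"missing required dataset '/{name}' in {path}")
        scan = Scan(
            us_images=f["us/images"][...],
            us_timestamps=f["us/timestamps"][...],
            oa_images=f["oa/images"][...],
            oa_timestamps=f["oa/timestamps"][...],
            oa_wavelengths=f["oa/wavelengths"][...],
            meta=dict(f.attrs),
        )
    return scan
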