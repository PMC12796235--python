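"""Seeded simulator of MS-OPUS scans with ground truth.

The simulator emulates what the motion-scoring algorithm assumes about a
real handheld acquisition:

* two interleaved timestamped streams — optoacoustic (OA) images cycling
  through a wavelength preset at ``f_OA`` (default 25 Hz, 700-970 nm in
  10 nm steps) and ultrasound (US) images at ``f_US`` (default 6.25 Hz);
* speckle-textured US images rendered from a fixed scatterer field;
* wavelength-dependent OA images generated *exactly* under the linear
  mixing model from absorber concentration maps with known spectra, so a
  stationary frame unmixes with residual at the noise level;
* piecewise rigid 2-D probe/tissue motion — stationary holds, constant
  velocity drift, constant angular-velocity rotation, zero-mean jitter and
  step-like jerks — with the stationary segments recorded as ground truth.

Both streams sample one common pose trajectory at their own timestamps,
mirroring the physical probe.  All randomness flows from one root seed via
independent substreams (trajectory jitter, speckle, per-stream noise).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml
from scipy.ndimage import affine_transform, gaussian_filter

from .scan_model import Scan

__all__ = [
    "MotionSegment",
    "Absorber",
    "SimConfig",
    "SyntheticTruth",
    "absorber_spectrum",
    "motion_trajectory",
    "make_us_canvas",
    "make_concentration_canvas",
    "render_us",
    "render_oa",
    "simulate_scan",
    "default_corpus",
]

SEGMENT_KINDS = ("stationary", "drift", "rotation", "jitter", "jerk")

DEFAULT_WAVELENGTHS = tuple(float(w) for w in range(700, 971, 10))


@dataclass
class MotionSegment:
    """One piece of the pose trajectory.

    kind : one of stationary / drift / rotation / jitter / jerk
    duration : seconds
    amplitude : total translation (px, drift/jerk) or rotation (deg)
    direction : unit in-plane direction (dy, dx) for drift/jerk
    sigma : per-timestamp jitter standard deviation (px)
    """

    kind: str
    duration: float
    amplitude: float = 0.0
    direction: tuple[float, float] = (0.0, 1.0)
    sigma: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in SEGMENT_KINDS:
            raise ValueError(f"unknown motion segment kind '{self.kind}'")
        if self.duration <= 0 or self.amplitude < 0 or self.sigma < 0:
            raise ValueError("segment duration must be > 0, amplitude/sigma >= 0")


@dataclass
class Absorber:
    """A disk-shaped absorber with a named or explicit spectrum."""

    name: str
    center: tuple[float, float]  # (row, col) px in image coordinates
    radius: float
    spectrum: str | Sequence[float] = "dye"
    concentration: float = 1.0
    edge_sigma: float = 1.5  # Gaussian edge softening, px


@dataclass
class SimConfig:
    """Simulation parameters; defaults are the validated acquisition preset."""

    shape: tuple[int, int] = (64, 64)
    wavelengths: tuple[float, ...] = DEFAULT_WAVELENGTHS
    f_oa: float = 25.0
    f_us: float = 6.25
    us_offset: float = 0.02  # US stream phase shift, s (interleaving)
    segments: list[MotionSegment] = field(
        default_factory=lambda: [
            MotionSegment("jitter", 2.0, sigma=0.8),
            MotionSegment("stationary", 2.4),
            MotionSegment("drift", 3.0, amplitude=10.0),
            MotionSegment("stationary", 2.2),
            MotionSegment("jerk", 0.5, amplitude=5.0, direction=(1.0, 0.0)),
            MotionSegment("drift", 2.9, amplitude=8.0, direction=(0.7, -0.7)),
        ]
    )
    absorbers: list[Absorber] = field(
        default_factory=lambda: [
            Absorber("dye_disk", (24.0, 22.0), 9.0, "dye"),
            Absorber("oil_disk", (42.0, 44.0), 7.0, "oil"),
        ]
    )
    us_noise_sigma: float = 0.02
    oa_noise_sigma: float = 0.005
    tremor_sigma: float = 0.2  # hand-tremor micro-motion amplitude, px
    tremor_tau: float = 0.4  # tremor correlation time, s
    fluence_mu: float = 0.0  # depth decay constant, 1/px (wavelength-independent)
    psf_sigma: float = 1.0  # US point-spread smoothing, px
    scan_id: str = "synthetic"

    @property
    def duration(self) -> float:
        return float(sum(s.duration for s in self.segments))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "segments" in raw:
            raw["segments"] = [MotionSegment(**s) for s in raw["segments"]]
        if "absorbers" in raw:
            raw["absorbers"] = [Absorber(**a) for a in raw["absorbers"]]
        for key in ("shape", "wavelengths"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        raw = asdict(self)
        raw["shape"] = list(self.shape)
        raw["wavelengths"] = list(self.wavelengths)
        Path(path).write_text(yaml.safe_dump(raw, sort_keys=False))


@dataclass
class SyntheticTruth:
    """Simulator ground truth aligned with the generated scan."""

    us_pose: np.ndarray  # (N_US, 3): dx, dy, theta_deg
    oa_pose: np.ndarray  # (N_OA, 3)
    stationary_time_intervals: list[tuple[float, float]]
    stationary_us_intervals: list[tuple[int, int]]  # inclusive, 0-based
    stationary_frame_intervals: list[tuple[int, int]]  # inclusive, 0-based
    spectra: dict[str, np.ndarray]  # absorber name -> spectrum over Λ
    fluence_mu: float

    def to_json(self, path: str | Path) -> None:
        payload = {
            "stationary_us_intervals": [list(map(int, t)) for t in self.stationary_us_intervals],
            "stationary_frame_intervals": [list(map(int, t)) for t in self.stationary_frame_intervals],
            "stationary_time_intervals": [list(map(float, t)) for t in self.stationary_time_intervals],
            "pose": {"us": self.us_pose.tolist(), "oa": self.oa_pose.tolist()},
            "spectra": {k: v.tolist() for k, v in self.spectra.items()},
            "fluence_mu": self.fluence_mu,
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def absorber_spectrum(name: str, wavelengths: Sequence[float]) -> np.ndarray:
    """Built-in smooth phantom spectra, normalized to unit maximum.

    ``dye``: monotonically decaying absorption (organic-dye like);
    ``oil``: narrow absorption peak near 930 nm (lipid/oil like); chromophore
    names (hb, hbo2, water, lipid) resolve to the bundled clinical table.
    """
    wl = np.asarray(wavelengths, dtype=float)
    if name == "dye":
        spec = np.exp(-(wl - wl.min()) / 120.0)
    elif name == "oil":
        spec = 0.08 + np.exp(-(((wl - 930.0) / 20.0) ** 2))
    else:
        from .spectral_unmixing import builtin_library

        lib = builtin_library((name,)).interpolated_to(wl)
        spec = lib.w[0]
    return spec / spec.max()


def _resolve_spectrum(
    spec: str | Sequence[float], wavelengths: Sequence[float]
) -> np.ndarray:
    if isinstance(spec, str):
        return absorber_spectrum(spec, wavelengths)
    arr = np.asarray(spec, dtype=float)
    if arr.shape != (len(wavelengths),):
        raise ValueError("explicit spectrum must match the wavelength grid")
    return arr


# -- trajectory ----------------------------------------------------------

def motion_trajectory(
    segments: SimConfig | Sequence[MotionSegment],
    timestamps: Sequence[float],
    rng: np.random.Generator | int | None = 0,
) -> np.ndarray:
    """Pose (dx, dy, theta_deg) at each timestamp for a piecewise trajectory.

    The base path is continuous across segment boundaries except at jerks,
    where the pose steps by the jerk amplitude at the segment start.  Jitter
    adds an independent zero-mean Gaussian displacement at every timestamp
    (drawn in timestamp order, so a fixed rng seed gives a fixed path).
    """
    if isinstance(segments, SimConfig):
        segments = segments.segments
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    t = np.asarray(timestamps, dtype=float)
    durations = np.array([s.duration for s in segments])
    ends = np.cumsum(durations)
    starts = ends - durations

    # start pose of each segment, accumulated sequentially
    seg_start = np.zeros((len(segments), 3))
    pose = np.zeros(3)
    for i, seg in enumerate(segments):
        if seg.kind == "jerk":
            pose = pose + np.array(
                [seg.amplitude * seg.direction[1], seg.amplitude * seg.direction[0], 0.0]
            )
        seg_start[i] = pose
        if seg.kind == "drift":
            pose = pose + np.array(
                [seg.amplitude * seg.direction[1], seg.amplitude * seg.direction[0], 0.0]
            )
        elif seg.kind == "rotation":
            pose = pose + np.array([0.0, 0.0, seg.amplitude])

    out = np.zeros((len(t), 3))
    for n, tn in enumerate(t):
        i = int(np.clip(np.searchsorted(ends, tn, side="left"), 0, len(segments) - 1))
        seg = segments[i]
        tau = np.clip((tn - starts[i]) / durations[i], 0.0, 1.0)
        p = seg_start[i].copy()
        if seg.kind == "drift":
            p[0] += seg.amplitude * seg.direction[1] * tau
            p[1] += seg.amplitude * seg.direction[0] * tau
        elif seg.kind == "rotation":
            p[2] += seg.amplitude * tau
        elif seg.kind == "jitter" and seg.sigma > 0:
            p[:2] += rng.normal(0.0, seg.sigma, size=2)
        out[n] = p
    return out


def tremor_process(
    timestamps: Sequence[float],
    sigma: float,
    tau: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Correlated hand-tremor micro-motion (dx, dy) at each timestamp.

    A stationary Ornstein-Uhlenbeck process per coordinate with marginal
    standard deviation ``sigma`` px and correlation time ``tau`` s, sampled
    at the (sorted) acquisition timestamps.  Models the sub-resolution
    residual motion of a handheld probe that is present even during
    deliberate stationary holds.
    """
    t = np.asarray(timestamps, dtype=float)
    out = np.zeros((len(t), 2))
    if sigma <= 0 or len(t) == 0:
        return out
    out[0] = rng.normal(0.0, sigma, size=2)
    for n in range(1, len(t)):
        a = np.exp(-max(t[n] - t[n - 1], 0.0) / tau)
        out[n] = a * out[n - 1] + sigma * np.sqrt(1.0 - a * a) * rng.normal(size=2)
    return out


# -- rendering -----------------------------------------------------------

def make_us_canvas(
    rng: np.random.Generator,
    shape: tuple[int, int],
    pad: int,
    psf_sigma: float = 1.0,
) -> np.ndarray:
    """Fixed speckle envelope canvas: smoothed scatterers, envelope-detected."""
    field_ = rng.standard_normal((shape[0] + 2 * pad, shape[1] + 2 * pad))
    smoothed = gaussian_filter(field_, psf_sigma)
    return np.abs(smoothed)


def make_concentration_canvas(
    absorber: Absorber, shape: tuple[int, int], pad: int
) -> np.ndarray:
    """Soft-edged disk concentration map on the padded canvas."""
    h, w = shape[0] + 2 * pad, shape[1] + 2 * pad
    rr, cc = np.mgrid[0:h, 0:w]
    cy, cx = absorber.center[0] + pad, absorber.center[1] + pad
    disk = ((rr - cy) ** 2 + (cc - cx) ** 2 <= absorber.radius**2).astype(float)
    if absorber.edge_sigma > 0:
        disk = gaussian_filter(disk, absorber.edge_sigma)
    return absorber.concentration * disk


def _sample_canvas(
    canvas: np.ndarray, pose: Sequence[float], shape: tuple[int, int], pad: int
) -> np.ndarray:
    """Sample the padded canvas under a rigid pose (rotation about image center)."""
    dx, dy, theta_deg = float(pose[0]), float(pose[1]), float(pose[2])
    theta = np.deg2rad(theta_deg)
    ctr = np.array([(shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0])
    rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
    offset = ctr + np.array([dy, dx]) + pad - rot @ ctr
    return affine_transform(
        canvas, rot, offset=offset, output_shape=shape, order=1, mode="constant"
    )


def render_us(
    canvas: np.ndarray,
    pose: Sequence[float],
    noise_sigma: float,
    rng: np.random.Generator,
    shape: tuple[int, int],
    pad: int,
) -> np.ndarray:
    """One US image: rigidly transformed speckle envelope plus Gaussian noise."""
    img = _sample_canvas(canvas, pose, shape, pad)
    if noise_sigma > 0:
        img = img + rng.normal(0.0, noise_sigma, size=shape)
    return np.clip(img, 0.0, None)


def render_oa(
    conc_canvases: Sequence[np.ndarray],
    spectra: Sequence[np.ndarray],
    wavelength_index: int,
    pose: Sequence[float],
    noise_sigma: float,
    rng: np.random.Generator | None,
    shape: tuple[int, int],
    pad: int,
    fluence_mu: float = 0.0,
) -> np.ndarray:
    """One single-wavelength OA image under the linear mixing model.

    ``Σ_a concentration_map_a(pose) · spectrum_a(λ) · exp(-μ·depth)`` plus
    optional Gaussian noise.  Noise may be negative, mimicking
    reconstruction artifacts.
    """
    img = np.zeros(shape)
    for canvas, spec in zip(conc_canvases, spectra):
        img += spec[wavelength_index] * _sample_canvas(canvas, pose, shape, pad)
    if fluence_mu > 0:
        depth = np.arange(shape[0])[:, None]
        img *= np.exp(-fluence_mu * depth)
    if noise_sigma > 0 and rng is not None:
        img = img + rng.normal(0.0, noise_sigma, size=shape)
    return img


# -- full scan -----------------------------------------------------------

def _required_pad(poses: np.ndarray, shape: tuple[int, int]) -> int:
    disp = float(np.max(np.abs(poses[:, :2]))) if len(poses) else 0.0
    theta = float(np.max(np.abs(poses[:, 2]))) if len(poses) else 0.0
    diag = 0.5 * float(np.hypot(*shape))
    rot_excursion = diag * abs(np.sin(np.deg2rad(theta)))
    return int(np.ceil(disp + rot_excursion)) + 8


def simulate_scan(cfg: SimConfig, seed: int = 0) -> tuple[Scan, SyntheticTruth]:
    """Render a full interleaved MS-OPUS scan plus aligned ground truth."""
    ss = np.random.SeedSequence(seed)
    rng_traj, rng_speckle, rng_us_noise, rng_oa_noise = (
        np.random.default_rng(s) for s in ss.spawn(4)
    )

    duration = cfg.duration
    n_us = int(round(duration * cfg.f_us))
    n_oa = int(round(duration * cfg.f_oa))
    t_us = cfg.us_offset + np.arange(n_us) / cfg.f_us
    t_oa = np.arange(n_oa) / cfg.f_oa
    n_l = len(cfg.wavelengths)
    oa_wavelengths = np.asarray(cfg.wavelengths, dtype=float)[np.arange(n_oa) % n_l]

    # one trajectory sampled at both streams' timestamps, in time order
    t_all = np.concatenate([t_us, t_oa])
    order = np.argsort(t_all, kind="stable")
    poses_sorted = motion_trajectory(cfg.segments, t_all[order], rng_traj)
    poses_sorted[:, :2] += tremor_process(
        t_all[order], cfg.tremor_sigma, cfg.tremor_tau, rng_traj
    )
    poses = np.empty_like(poses_sorted)
    poses[order] = poses_sorted
    us_pose, oa_pose = poses[:n_us], poses[n_us:]

    pad = _required_pad(poses, cfg.shape)
    us_canvas = make_us_canvas(rng_speckle, cfg.shape, pad, cfg.psf_sigma)
    conc = [make_concentration_canvas(a, cfg.shape, pad) for a in cfg.absorbers]
    spectra = [_resolve_spectrum(a.spectrum, cfg.wavelengths) for a in cfg.absorbers]

    us_images = np.stack(
        [
            render_us(us_canvas, p, cfg.us_noise_sigma, rng_us_noise, cfg.shape, pad)
            for p in us_pose
        ]
    ).astype(np.float32)
    oa_images = np.stack(
        [
            render_oa(
                conc,
                spectra,
                k % n_l,
                oa_pose[k],
                cfg.oa_noise_sigma,
                rng_oa_noise,
                cfg.shape,
                pad,
                cfg.fluence_mu,
            )
            for k in range(n_oa)
        ]
    ).astype(np.float32)

    scan = Scan(
        us_images=us_images,
        us_timestamps=t_us,
        oa_images=oa_images,
        oa_timestamps=t_oa,
        oa_wavelengths=oa_wavelengths,
        meta={"scan_id": cfg.scan_id, "f_us_hz": cfg.f_us, "f_oa_hz": cfg.f_oa},
    )

    # ground truth stationary intervals
    ends = np.cumsum([s.duration for s in cfg.segments])
    starts = ends - np.array([s.duration for s in cfg.segments])
    time_ivals = [
        (float(starts[i]), float(ends[i]))
        for i, s in enumerate(cfg.segments)
        if s.kind == "stationary"
    ]
    eps = 1e-9
    us_stationary = np.zeros(n_us, dtype=bool)
    us_ivals = []
    for lo, hi in time_ivals:
        us_in = np.nonzero((t_us >= lo - eps) & (t_us <= hi + eps))[0]
        if len(us_in):
            us_ivals.append((int(us_in[0]), int(us_in[-1])))
            us_stationary[us_in] = True

    # frame-level truth mirrors the human-annotation protocol: the simulator
    # acts as one perfect annotator on the US stream, a frame is stationary
    # iff the mean stationary coverage of its US images is >= 1/2
    from .evaluation import AnnotationSet, aggregate_annotations, events_from_mask

    frame_mask, _, _ = aggregate_annotations(AnnotationSet([us_ivals]), scan)
    frame_ivals = [tuple(ev) for ev in events_from_mask(frame_mask)]

    truth = SyntheticTruth(
        us_pose=us_pose,
        oa_pose=oa_pose,
        stationary_time_intervals=time_ivals,
        stationary_us_intervals=us_ivals,
        stationary_frame_intervals=frame_ivals,
        spectra={a.name: s for a, s in zip(cfg.absorbers, spectra)},
        fluence_mu=cfg.fluence_mu,
    )
    return scan, truth


# -- study corpus --------------------------------------------------------

def _random_segments(rng: np.random.Generator, duration: float, n_stationary: int) -> list[MotionSegment]:
    """Alternating motion / stationary layout filling ``duration`` seconds."""
    stat = rng.uniform(2.0, 2.6, size=n_stationary)
    kinds = ["drift", "jitter", "rotation", "jerk"]
    rng.shuffle(kinds)
    motion_kinds = [kinds[i % len(kinds)] for i in range(n_stationary + 1)]
    # jerks are brief transitions; they get a fixed short slot
    jerk_time = sum(0.6 for k in motion_kinds if k == "jerk")
    budget = duration - float(stat.sum()) - jerk_time
    weights = rng.uniform(1.0, 2.0, size=sum(1 for k in motion_kinds if k != "jerk"))
    weights = weights / weights.sum() * budget
    segs: list[MotionSegment] = []
    wi = 0
    for i, kind in enumerate(motion_kinds):
        if kind == "drift":
            ang = rng.uniform(0, 2 * np.pi)
            dur = float(weights[wi])
            segs.append(
                MotionSegment(
                    "drift",
                    dur,
                    amplitude=float(rng.uniform(1.5, 5.0)) * dur,  # velocity draw, px/s
                    direction=(float(np.sin(ang)), float(np.cos(ang))),
                )
            )
            wi += 1
        elif kind == "jitter":
            segs.append(
                MotionSegment("jitter", float(weights[wi]), sigma=float(rng.uniform(0.6, 1.2)))
            )
            wi += 1
        elif kind == "rotation":
            dur = float(weights[wi])
            segs.append(
                MotionSegment(
                    "rotation",
                    dur,
                    amplitude=float(rng.uniform(1.5, 4.0)) * dur,  # deg/s
                )
            )
            wi += 1
        else:  # jerk
            ang = rng.uniform(0, 2 * np.pi)
            segs.append(
                MotionSegment(
                    "jerk",
                    0.6,
                    amplitude=float(rng.uniform(3.0, 8.0)),
                    direction=(float(np.sin(ang)), float(np.cos(ang))),
                )
            )
        if i < n_stationary:
            segs.append(MotionSegment("stationary", float(stat[i])))
    return segs


def default_corpus(
    n_scans: int = 10,
    seed: int = 0,
    duration: float = 36.0,
    shape: tuple[int, int] = (64, 64),
) -> list[tuple[Scan, SyntheticTruth]]:
    """The default validation corpus: seeded scans with 2-3 stationary holds.

    Each scan alternates drift / jitter / rotation / jerk motion with short
    stationary holds, under the default acquisition preset.  Used for
    end-to-end precision/recall and mAP checks.
    """
    children = np.random.SeedSequence(seed).spawn(n_scans + 1)
    layout_rng = np.random.default_rng(children[0])
    scan_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in children[1:]]
    corpus = []
    for i in range(n_scans):
        n_stat = int(layout_rng.integers(2, 4))
        cfg = SimConfig(
            shape=shape,
            segments=_random_segments(layout_rng, duration, n_stat),
            scan_id=f"synthetic-{i:02d}",
        )
        corpus.append(simulate_scan(cfg, seed=scan_seeds[i]))
    return corpus
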