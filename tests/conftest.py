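import numpy as np
import pytest

import opusmotion as om


def make_scan(
    us_values=None,
    us_t=None,
    oa_t=None,
    oa_wl=None,
    us_images=None,
    oa_shape=(4, 4),
):
    """Hand-built tiny scan for arithmetic tests.

    ``us_values`` builds 1x1 US images from scalars; alternatively pass full
    ``us_images``.  OA images are constant dummies unless the test cares.
    """
    if us_images is None:
        us_images = np.asarray(us_values, dtype=float).reshape(-1, 1, 1)
    us_images = np.asarray(us_images, dtype=float)
    n_us = len(us_images)
    if us_t is None:
        us_t = np.arange(n_us, dtype=float)
    oa_t = np.asarray(oa_t if oa_t is not None else np.arange(len(oa_wl)) * 0.1)
    oa_wl = np.asarray(oa_wl, dtype=float)
    oa_images = np.zeros((len(oa_t), *oa_shape))
    return om.Scan(
        us_images=us_images,
        us_timestamps=np.asarray(us_t, dtype=float),
        oa_images=oa_images,
        oa_timestamps=oa_t,
        oa_wavelengths=oa_wl,
        meta={"scan_id": "toy"},
    )


@pytest.fixture(scope="session")
def corpus():
    """The default 10-scan validation corpus (seeded)."""
    return om.default_corpus(n_scans=10, seed=1)


@pytest.fixture(scope="session")
def corpus_results(corpus):
    """Motion vectors (ranked + naive-L2) and truth events for every corpus scan."""
    from opusmotion.evaluation import events_from_intervals

    out = []
    for scan, truth in corpus:
        out.append(
            {
                "scan": scan,
                "truth": truth,
                "ranked": om.motion_vector(scan, "znxc,ssim", "ranked"),
                "naive_l2": om.naive_motion_vector(scan, "l2"),
                "events": events_from_intervals(truth.stationary_frame_intervals),
            }
        )
    return out


@pytest.fixture(scope="session")
def small_scan():
    """One small simulated scan with a drift and two stationary holds."""
    from opusmotion.synthetic_data import MotionSegment, SimConfig

    cfg = SimConfig(
        shape=(32, 32),
        wavelengths=tuple(float(w) for w in range(700, 900, 10)),
        segments=[
            MotionSegment("jitter", 2.0, sigma=0.8),
            MotionSegment("stationary", 2.0),
            MotionSegment("drift", 2.5, amplitude=8.0),
            MotionSegment("stationary", 2.0),
            MotionSegment("drift", 1.5, amplitude=6.0, direction=(1.0, 0.0)),
        ],
        scan_id="small",
    )
    return om.simulate_scan(cfg, seed=7)
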