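"""Independent brute-force transcriptions used as test oracles.

These deliberately mirror the written definitions line by line (1-based
indices, explicit loops, naive rank computation) and share no code with the
package implementation.
"""

import numpy as np


def oracle_dissimilarity_matrix(us_images, measure):
    """Full banded matrix as a dict {(i, j): value} with 1-based i (lag), j."""
    n_us = len(us_images)
    d = {}
    for i in range(1, n_us):
        for j in range(1, n_us + 1):
            if i + j <= n_us:
                d[(i, j)] = measure(us_images[j - 1], us_images[j - 1 + i])
    return d


def oracle_rank(row_values, x):
    """0-based position of x in the sorted row, averaging over ties."""
    s = sorted(row_values)
    positions = [i for i, v in enumerate(s) if v == x]
    return sum(positions) / len(positions)


def oracle_normalize(d, n_us, kind):
    out = {}
    for i in range(1, n_us):
        row = [d[(i, j)] for j in range(1, n_us) if (i, j) in d]
        if not row:
            continue
        for j in range(1, n_us):
            if (i, j) not in d:
                continue
            if kind == "rank":
                denom = n_us - i - 1
                out[(i, j)] = oracle_rank(row, d[(i, j)]) / denom if denom > 0 else 0.0
            else:  # minmax
                lo, hi = min(row), max(row)
                out[(i, j)] = (d[(i, j)] - lo) / (hi - lo) if hi > lo else 0.0
    return out


def oracle_frame_score(norm_mats, s_one_based):
    """Literal triple sum: 2/(|Delta| |s|^2) sum_d sum_i sum_j M[i, j]."""
    n = len(s_one_based)
    if n < 2:
        return float("nan")
    total = 0.0
    for m in norm_mats:
        for i in range(1, n + 1):
            upper = n - i  # index of s_{|s|-i}, 1-based count
            for idx in range(1, upper + 1):
                j = s_one_based[idx - 1]
                total += m[(i, j)]
    return 2.0 * total / (len(norm_mats) * n * n)


def oracle_motion_scores(scan, measures, variant):
    """Per-frame scores from the literal transcription (variant: rank|minmax)."""
    import opusmotion as om

    norm_mats = []
    for meas in measures:
        d = oracle_dissimilarity_matrix(scan.us_images, meas)
        norm_mats.append(oracle_normalize(d, scan.n_us, variant))
    scores = []
    for k in range(scan.n_ms):
        s = [int(i) + 1 for i in om.us_indices_for_frame(scan, k)]
        scores.append(oracle_frame_score(norm_mats, s))
    return np.array(scores)


def oracle_average_precision(minima_sorted_by_score, events):
    """AP by explicitly sweeping every prefix of the ranked minima."""
    def in_event(p):
        return any(lo <= p <= hi for lo, hi in events)

    ap = 0.0
    prev_r = 0.0
    for n in range(1, len(minima_sorted_by_score) + 1):
        preds = minima_sorted_by_score[:n]
        tp = sum(1 for p in preds if in_event(p))
        covered = {
            ei for ei, (lo, hi) in enumerate(events) if any(lo <= p <= hi for p in preds)
        }
        precision = tp / len(preds)
        recall = len(covered) / len(events)
        if recall > prev_r:
            ap += (recall - prev_r) * precision
            prev_r = recall
    return ap
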