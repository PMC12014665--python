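"""Brute-force re-implementation of the p1/n1 scoring rules, by definition.

Everything here is written independently of the package's vectorized /
scipy-backed route: local extrema are enumerated sample by sample,
topographic prominence is computed by walking outward to the nearest higher
sample, and the point awards are re-derived literally. Assumes waveforms
without exact ties (continuous noise), where strict local extrema are
unambiguous.
"""

from __future__ import annotations


def local_maxima(x):
    return [i for i in range(1, len(x) - 1) if x[i - 1] < x[i] > x[i + 1]]


def prominence(x, i):
    """Height of peak i above the higher of its two bases; each base is the
    minimum between the peak and the nearest strictly higher sample (or the
    trace end)."""
    h = x[i]
    left = h
    j = i - 1
    while j >= 0 and x[j] <= h:
        left = min(left, x[j])
        j -= 1
    right = h
    j = i + 1
    while j < len(x) and x[j] <= h:
        right = min(right, x[j])
        j += 1
    return h - max(left, right)


def _latency(i, onset, fs):
    return (i - onset) * 1000.0 / fs


def oracle_pick(waveform, fs, onset, prestim_rms, anchor=None,
                n1_window=(15.0, 37.0), p1_min=5.0, null_factor=1.65,
                anchor_halfwidth=5.0):
    """Returns (p1_latency, n1_latency, amplitude) or None for a null result."""
    x = list(map(float, waveform))
    neg = [-v for v in x]

    troughs = []
    for i in local_maxima(neg):
        lat = _latency(i, onset, fs)
        troughs.append((lat, i, prominence(neg, i)))
    if anchor is None:
        lo, hi = n1_window
    else:
        lo = max(n1_window[0], anchor - anchor_halfwidth)
        hi = min(n1_window[1], anchor + anchor_halfwidth)
    eligible = [t for t in troughs if lo <= t[0] <= hi]
    if not eligible:
        return None
    # max prominence, ties to earlier latency
    n1_lat, n1_idx, _ = sorted(eligible, key=lambda t: (-t[2], t[0]))[0]

    peaks = []
    for i in local_maxima(x):
        lat = _latency(i, onset, fs)
        if p1_min <= lat < n1_lat:
            peaks.append({"lat": lat, "idx": i, "prom": prominence(x, i)})
    if not peaks:
        return None

    by_prom = sorted(peaks, key=lambda p: (-p["prom"], p["lat"]))
    points = {id(p): 0 for p in peaks}
    for award, p in zip((5, 4, 3), by_prom):
        points[id(p)] += award
    top = by_prom[0]["prom"]
    for p in by_prom[:3]:
        r = p["prom"] / top if top > 0 else 1.0
        if r >= 2.0 / 3.0:
            points[id(p)] += 3
        elif r > 1.0 / 3.0:
            points[id(p)] += 2
        else:
            points[id(p)] += 1
    by_near = sorted(peaks, key=lambda p: (abs(p["lat"] - n1_lat), p["lat"]))
    for award, p in zip((5, 4, 3, 2, 1), by_near):
        points[id(p)] += award

    best = sorted(peaks, key=lambda p: (-points[id(p)],
                                        abs(p["lat"] - n1_lat), p["lat"]))[0]
    amplitude = x[best["idx"]] - x[n1_idx]
    if amplitude < null_factor * prestim_rms:
        return None
    return best["lat"], n1_lat, amplitude
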