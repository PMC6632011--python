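"""Independent brute-force re-implementation of the descriptor pipeline.

Used only as a cross-check oracle: filter coefficients are derived by hand
from the bilinear transform of the first-order analog Butterworth prototype,
and every statistic is computed with naive Python loops.  No helpers are
shared with the package.
"""

import math

import numpy as np
from scipy.signal import filtfilt


def _butter1_coeffs(cutoff_hz, fps):
    # bilinear transform of H(s) = 1 / (1 + s/wc)
    k = math.tan(math.pi * cutoff_hz / fps)
    b0 = k / (1.0 + k)
    return [b0, b0], [1.0, (k - 1.0) / (k + 1.0)]


def _smooth(x, fps):
    b, a = _butter1_coeffs(1.0, fps)
    return filtfilt(b, a, np.asarray(x, float), padlen=min(6, len(x) - 1))


def _diff(x, fps):
    d = [0.0] * len(x)
    for i in range(1, len(x)):
        d[i] = (x[i] - x[i - 1]) * fps
    d[0] = d[1]
    return d


def _percentile(sorted_vals, q):
    # linear interpolation between closest ranks (matches the default scheme)
    n = len(sorted_vals)
    pos = (n - 1) * q / 100.0
    lo = int(math.floor(pos))
    hi = min(lo + 1, n - 1)
    frac = pos - lo
    return sorted_vals[lo] * (1 - frac) + sorted_vals[hi] * frac


def _stats16(x):
    x = [float(v) for v in x]
    n = len(x)
    mean = sum(x) / n
    std = math.sqrt(sum((v - mean) ** 2 for v in x) / n)
    mn, mx = min(x), max(x)
    s = sorted(x)
    q1 = _percentile(s, 25)
    med = _percentile(s, 50)
    q3 = _percentile(s, 75)
    rms = math.sqrt(sum(v * v for v in x) / n)
    if n == 1:
        rt_max = rt_min = crossings = slope = 0.0
    else:
        rt_max = x.index(mx) / (n - 1)
        rt_min = x.index(mn) / (n - 1)
        crossings = sum(
            1 for i in range(n - 1) if (x[i] - mean) * (x[i + 1] - mean) < 0
        ) / (n - 1)
        t = [i / (n - 1) for i in range(n)]
        tbar = sum(t) / n
        slope = sum((t[i] - tbar) * (x[i] - mean) for i in range(n)) / sum(
            (ti - tbar) ** 2 for ti in t
        )
    above = sum(1 for v in x if v > mean) / n
    mad = sum(abs(v - med) for v in x) / n
    return [mean, std, mn, mx, mx - mn, med, q3 - q1, rms,
            rt_max, rt_min, above, crossings, mad, slope, q1, q3]


def oracle_fad(segment_values, fps):
    """FAD of a (n_frames, n_channels) segment: per channel, smooth ->
    two derivatives -> 16 statistics per signal, channel-major layout."""
    seg = np.asarray(segment_values, float)
    out = []
    for j in range(seg.shape[1]):
        sm = list(_smooth(seg[:, j], fps))
        d1 = _diff(sm, fps)
        d2 = _diff(d1, fps)
        for sig in (sm, d1, d2):
            out.extend(_stats16(sig))
    return np.array(out)
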