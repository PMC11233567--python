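"""Shared independent oracles for the test suite."""

import numpy as np


def oracle_gait_events(x, fs, min_cycle, prom_frac):
    """Exhaustive-scan gait-event oracle: strict local maxima, greedy
    distance culling by descending height, prominence threshold, then
    velocity minima between consecutive heel strikes."""
    x = np.asarray(x, dtype=float)
    n = x.size
    cand = [i for i in range(1, n - 1) if x[i - 1] < x[i] > x[i + 1]]
    distance = max(1, round(min_cycle * fs))
    keep = np.ones(len(cand), bool)
    order = sorted(range(len(cand)), key=lambda k: x[cand[k]], reverse=True)
    for k in order:
        if not keep[k]:
            continue
        for j in range(len(cand)):
            if j != k and keep[j] and abs(cand[j] - cand[k]) < distance:
                keep[j] = False
    cand = [c for c, k in zip(cand, keep) if k]

    def prominence(i):
        left = x[i]
        j = i
        while j > 0 and x[j - 1] <= x[i]:
            j -= 1
            left = min(left, x[j])
        right = x[i]
        j = i
        while j < n - 1 and x[j + 1] <= x[i]:
            j += 1
            right = min(right, x[j])
        return x[i] - max(left, right)

    threshold = prom_frac * np.ptp(x)
    hs = sorted(c for c in cand if prominence(c) >= threshold)
    vel = np.gradient(x) * fs
    to = [a + 1 + int(np.argmin(vel[a + 1 : b])) for a, b in zip(hs[:-1], hs[1:]) if b - a >= 2]
    return np.asarray(hs, int), np.asarray(to, int)
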