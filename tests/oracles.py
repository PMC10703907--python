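"""Independent brute-force oracles used to cross-check the fast paths.

These are written as plain-Python enumerations, deliberately sharing no code
with the package: strict local extrema by linear scan, ripple merging by
exhaustive re-scan, spectra by direct DFT summation.
"""

import math


def brute_force_waves(t, y, min_amplitude):
    """All strict local extrema, pairwise-merged, paired crest->trough.

    Returns a list of (crest_time, crest_value, trough_time, trough_value).
    Plateaus count once at their first sample; the leftmost smallest
    adjacent extremum pair below threshold is removed first.
    """
    comp = [(0, y[0])]
    for j in range(1, len(y)):
        if y[j] != comp[-1][1]:
            comp.append((j, y[j]))
    ext = []
    for k in range(1, len(comp) - 1):
        v = comp[k][1]
        if comp[k - 1][1] < v > comp[k + 1][1]:
            ext.append((comp[k][0], v, "max"))
        elif comp[k - 1][1] > v < comp[k + 1][1]:
            ext.append((comp[k][0], v, "min"))
    while len(ext) >= 2:
        best, best_d = None, None
        for k in range(len(ext) - 1):
            d = abs(ext[k + 1][1] - ext[k][1])
            if best_d is None or d < best_d:
                best, best_d = k, d
        if best_d >= min_amplitude:
            break
        ext = ext[:best] + ext[best + 2:]
    waves = []
    for k, (i, v, kind) in enumerate(ext):
        if kind == "max" and k + 1 < len(ext):
            j, w, _ = ext[k + 1]
            if v - w >= min_amplitude:
                waves.append((t[i], v, t[j], w))
    return waves


def brute_force_strength(t, y, min_amplitude):
    waves = brute_force_waves(t, y, min_amplitude)
    if not waves:
        return 0.0, 0
    amps = [cv - tv for _, cv, _, tv in waves]
    return sum(amps) / len(amps), len(amps)


def dft_peak(y, dt, f_min):
    """Peak frequency of a direct (slow) DFT amplitude spectrum above f_min."""
    n = len(y)
    mean = sum(y) / n
    best_f, best_a = None, -1.0
    # rectangular-window DFT on the native frequency grid
    for k in range(1, n // 2 + 1):
        f = k / (n * dt)
        if f < f_min:
            continue
        re = sum((y[j] - mean) * math.cos(2 * math.pi * k * j / n)
                 for j in range(n))
        im = sum((y[j] - mean) * math.sin(2 * math.pi * k * j / n)
                 for j in range(n))
        a = 2 * math.hypot(re, im) / n
        if a > best_a:
            best_f, best_a = f, a
    return best_f
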