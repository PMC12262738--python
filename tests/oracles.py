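"""Independent brute-force oracles for the sliding-window rules.

Deliberately written as plain-Python step-through simulations, separate
from the vectorized library implementations, so the two routes can be
cross-checked on arbitrary profiles.
"""

from __future__ import annotations


def screen_oracle(counts, window, upper, lower, persistence):
    """Step-through simulation of the failure screen.

    Walks the profile slice by slice keeping a buffer of the last
    ``window`` normal counts; a slice outside (lower*mean, upper*mean) is
    anomalous and excluded from the buffer.  Returns
    (label, first_flagged, last_flagged).
    """
    counts = [float(c) for c in counts]
    buffer = counts[:window]
    flags = [False] * len(counts)
    for i in range(window, len(counts)):
        mean = sum(buffer[-window:]) / window
        if counts[i] < lower * mean or counts[i] > upper * mean:
            flags[i] = True
        else:
            buffer.append(counts[i])

    runs = []
    i = 0
    while i < len(flags):
        if flags[i]:
            j = i
            while j + 1 < len(flags) and flags[j + 1]:
                j += 1
            if j - i + 1 >= persistence:
                runs.append((i, j))
            i = j + 1
        else:
            i += 1
    if not runs:
        return "normal", None, None
    return "aneurysm", runs[0][0], runs[-1][1]


def boundary_oracle(counts, window, upper, lower):
    """Step-through simulation of the boundary rule (never-frozen baseline).

    Each slice is compared with the mean of the ``window`` counts
    immediately before it; candidate starts are first slices of rise runs
    of length >= window, candidate ends last slices of drop runs of
    length >= window; the widest (start < end) pairing wins, earliest on
    ties.  Returns (start, end) or None.
    """
    counts = [float(c) for c in counts]
    n = len(counts)
    above = [False] * n
    below = [False] * n
    for i in range(window, n):
        mean = sum(counts[i - window : i]) / window
        above[i] = counts[i] > upper * mean
        below[i] = counts[i] < lower * mean

    def runs(flags):
        out = []
        i = 0
        while i < n:
            if flags[i]:
                j = i
                while j + 1 < n and flags[j + 1]:
                    j += 1
                if j - i + 1 >= window:
                    out.append((i, j))
                i = j + 1
            else:
                i += 1
        return out

    starts = [r[0] for r in runs(above)]
    ends = [r[1] for r in runs(below)]
    best = None
    for s in starts:
        for e in ends:
            if s < e:
                cand = (-(e - s + 1), s, e)
                if best is None or cand < best:
                    best = cand
    if best is None:
        return None
    return best[1], best[2]


def interval_dice_oracle(pred, truth):
    """Set-enumeration Dice on two inclusive intervals (None = absent)."""
    if pred is None and truth is None:
        return 1.0
    if pred is None or truth is None:
        return 0.0
    a = set(range(pred[0], pred[1] + 1))
    b = set(range(truth[0], truth[1] + 1))
    return 2 * len(a & b) / (len(a) + len(b))
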