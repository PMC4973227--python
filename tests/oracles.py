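"""Independent brute-force reference implementations used only by tests.

Everything here is written with explicit Python loops and no shared code
with the package internals, so agreement between the two routes is a real
cross-check rather than a tautology.
"""

from __future__ import annotations

import math


def brute_distances(points):
    """Normalized Euclidean distance matrix via explicit double loops."""
    n = len(points)
    d = [[0.0] * n for _ in range(n)]
    dmax = 0.0
    for i in range(n):
        for j in range(n):
            s = 0.0
            for a, b in zip(points[i], points[j]):
                s += (a - b) ** 2
            d[i][j] = math.sqrt(s)
            dmax = max(dmax, d[i][j])
    if dmax == 0:
        raise ValueError("degenerate point set")
    return [[v / dmax for v in row] for row in d], dmax


def brute_recurrence(points, rad_pct, theiler_w):
    """Boolean recurrence matrix with LOI + Theiler band removed."""
    nd, _ = brute_distances(points)
    n = len(points)
    return [
        [nd[i][j] <= rad_pct / 100.0 and abs(i - j) > theiler_w
         for j in range(n)]
        for i in range(n)
    ]


def brute_rec_pct(points, rad_pct, theiler_w):
    R = brute_recurrence(points, rad_pct, theiler_w)
    n = len(R)
    hits = valid = 0
    for i in range(n):
        for j in range(i + 1, n):
            if j - i > theiler_w:
                valid += 1
                if R[i][j]:
                    hits += 1
    return 100.0 * hits / valid


def brute_vertical_runs(points, rad_pct, theiler_w):
    """All maximal vertical run lengths over columns of the full matrix."""
    R = brute_recurrence(points, rad_pct, theiler_w)
    n = len(R)
    runs = []
    for j in range(n):
        length = 0
        for i in range(n):
            if R[i][j]:
                length += 1
            elif length:
                runs.append(length)
                length = 0
        if length:
            runs.append(length)
    return runs


def brute_diagonal_runs(points, rad_pct, theiler_w):
    """Maximal diagonal run lengths on upper diagonals beyond the band."""
    R = brute_recurrence(points, rad_pct, theiler_w)
    n = len(R)
    runs = []
    for k in range(theiler_w + 1, n):
        length = 0
        for i in range(n - k):
            if R[i][i + k]:
                length += 1
            elif length:
                runs.append(length)
                length = 0
        if length:
            runs.append(length)
    return runs


def brute_lam(points, rad_pct, theiler_w, v_min=2):
    runs = brute_vertical_runs(points, rad_pct, theiler_w)
    total = sum(runs)
    if total == 0:
        return 0.0
    return sum(r for r in runs if r >= v_min) / total


def brute_vmax(points, rad_pct, theiler_w):
    runs = brute_vertical_runs(points, rad_pct, theiler_w)
    return max(runs) if runs else 0


def brute_tt(points, rad_pct, theiler_w, v_min=2):
    runs = [r for r in brute_vertical_runs(points, rad_pct, theiler_w)
            if r >= v_min]
    return sum(runs) / len(runs) if runs else 0.0


def brute_det(points, rad_pct, theiler_w, l_min=5):
    runs = brute_diagonal_runs(points, rad_pct, theiler_w)
    total = sum(runs)
    if total == 0:
        return 0.0
    return sum(r for r in runs if r >= l_min) / total


def quantile_radius(points, target_rec_pct, theiler_w):
    """Reference radius: the q-th smallest valid normalized distance where
    q = ceil(target/100 * n_valid)."""
    nd, _ = brute_distances(points)
    n = len(points)
    valid = sorted(
        nd[i][j]
        for i in range(n)
        for j in range(i + 1, n)
        if j - i > theiler_w
    )
    q = math.ceil(target_rec_pct / 100.0 * len(valid))
    return 100.0 * valid[q - 1]
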