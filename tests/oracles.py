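"""Exhaustive brute-force reference implementations for the texture
matrices, used only as independent oracles on small fixtures.  Everything
here is written as plain per-voxel enumeration, deliberately sharing no
code with the package."""

from collections import deque
from itertools import product

import numpy as np

HALF_DIRECTIONS = [
    d for d in product((-1, 0, 1), repeat=3) if d != (0, 0, 0) and d > (0, 0, 0)
]


def _inside(w, shape):
    return all(0 <= w[i] < shape[i] for i in range(3))


def glcm_pairs(lev, n_levels):
    """Count every ordered in-mask voxel pair at Chebyshev distance 1."""
    out = np.zeros((n_levels, n_levels))
    shape = lev.shape
    for v in np.argwhere(lev > 0):
        for d in HALF_DIRECTIONS:
            for sign in (1, -1):
                w = tuple(v + sign * np.array(d))
                if _inside(w, shape) and lev[w] > 0:
                    out[lev[tuple(v)] - 1, lev[w] - 1] += 1
    return out


def maximal_runs(lev, d):
    """(level, length) of every maximal run along direction d."""
    shape = lev.shape
    runs = []
    for v in np.argwhere(lev > 0):
        prev = tuple(v - d)
        if _inside(prev, shape) and lev[prev] == lev[tuple(v)]:
            continue
        length, w = 1, v + d
        while _inside(tuple(w), shape) and lev[tuple(w)] == lev[tuple(v)]:
            length += 1
            w = w + d
        runs.append((int(lev[tuple(v)]), length))
    return runs


def glrlm_merged(lev, n_levels):
    runs = [r for d in HALF_DIRECTIONS for r in maximal_runs(lev, np.array(d))]
    width = max(length for _, length in runs)
    out = np.zeros((n_levels, width))
    for g, length in runs:
        out[g - 1, length - 1] += 1
    return out


def flood_fill_zones(lev):
    """(level, list of voxel tuples) for every 26-connected equal-level zone."""
    shape = lev.shape
    seen = np.zeros(shape, bool)
    zones = []
    for start in np.argwhere(lev > 0):
        start = tuple(start)
        if seen[start]:
            continue
        g = lev[start]
        stack, zone = [start], []
        seen[start] = True
        while stack:
            v = stack.pop()
            zone.append(v)
            for d in product((-1, 0, 1), repeat=3):
                if d == (0, 0, 0):
                    continue
                w = tuple(np.array(v) + d)
                if _inside(w, shape) and not seen[w] and lev[w] == g:
                    seen[w] = True
                    stack.append(w)
        zones.append((int(g), zone))
    return zones


def border_distance_bfs(mask):
    """City-block distance to outside the mask (array edge = outside)."""
    shape = mask.shape
    dist = np.full(shape, -1, int)
    queue = deque()
    six = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]
    for v in np.argwhere(mask):
        v = tuple(v)
        if any(not _inside(tuple(np.array(v) + d), shape) or not mask[tuple(np.array(v) + d)]
               for d in six):
            dist[v] = 1
            queue.append(v)
    while queue:
        v = queue.popleft()
        for d in six:
            w = tuple(np.array(v) + d)
            if _inside(w, shape) and mask[w] and dist[w] == -1:
                dist[w] = dist[v] + 1
                queue.append(w)
    return dist


def ngldm_counts(lev, n_levels, alpha=0, delta=1):
    shape = lev.shape
    entries = []
    offsets = [
        d for d in product(range(-delta, delta + 1), repeat=3) if d != (0, 0, 0)
    ]
    for v in np.argwhere(lev > 0):
        g = int(lev[tuple(v)])
        k = sum(
            1
            for d in offsets
            if _inside(tuple(np.array(v) + d), shape)
            and lev[tuple(np.array(v) + d)] > 0
            and abs(int(lev[tuple(np.array(v) + d)]) - g) <= alpha
        )
        entries.append((g, k + 1))
    width = max(j for _, j in entries)
    out = np.zeros((n_levels, width))
    for g, j in entries:
        out[g - 1, j - 1] += 1
    return out


def ngtdm_sums(lev, n_levels):
    shape = lev.shape
    n_i = np.zeros(n_levels)
    s_i = np.zeros(n_levels)
    for v in np.argwhere(lev > 0):
        g = int(lev[tuple(v)])
        neighbors = [
            int(lev[tuple(np.array(v) + d)])
            for d in product((-1, 0, 1), repeat=3)
            if d != (0, 0, 0)
            and _inside(tuple(np.array(v) + d), shape)
            and lev[tuple(np.array(v) + d)] > 0
        ]
        if neighbors:
            n_i[g - 1] += 1
            s_i[g - 1] += abs(g - float(np.mean(neighbors)))
    return n_i, s_i


def mutual_information_nats(x, y):
    """MI by exhaustive contingency counting, in nats."""
    x = np.asarray(x)
    y = np.asarray(y)
    n = len(x)
    mi = 0.0
    for xv in np.unique(x):
        for yv in np.unique(y):
            pxy = np.sum((x == xv) & (y == yv)) / n
            if pxy > 0:
                px = np.sum(x == xv) / n
                py = np.sum(y == yv) / n
                mi += pxy * np.log(pxy / (px * py))
    return mi
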