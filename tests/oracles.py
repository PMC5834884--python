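"""Independent brute-force oracles used only by the test suite.

Each function re-derives a quantity by direct enumeration or explicit
loops, deliberately avoiding the vectorised code paths of the package.
"""

from __future__ import annotations

from itertools import combinations
from math import dist

import numpy as np


def naive_nn_distances(points) -> list[float]:
    pts = [tuple(p) for p in points]
    out = []
    for i, p in enumerate(pts):
        out.append(min(dist(p, q) for j, q in enumerate(pts) if j != i))
    return out


def _boundary_dist(p, window) -> float:
    lo, hi = window.lo, window.hi
    return min(min(p[a] - lo[a], hi[a] - p[a]) for a in range(3))


def naive_g(points, window, r_grid, correction="border") -> list[float]:
    d = naive_nn_distances(points)
    b = [_boundary_dist(p, window) for p in points]
    out = []
    for r in r_grid:
        if correction == "none":
            out.append(sum(di <= r for di in d) / len(d))
        else:
            elig = [i for i in range(len(d)) if b[i] >= r]
            if not elig:
                out.append(float("nan"))
            else:
                out.append(sum(d[i] <= r for i in elig) / len(elig))
    return out


def naive_f(points, test_points, window, r_grid, correction="border") -> list[float]:
    d = [min(dist(t, tuple(p)) for p in points) for t in map(tuple, test_points)]
    b = [_boundary_dist(t, window) for t in test_points]
    out = []
    for r in r_grid:
        if correction == "none":
            out.append(sum(di <= r for di in d) / len(d))
        else:
            elig = [i for i in range(len(d)) if b[i] >= r]
            if not elig:
                out.append(float("nan"))
            else:
                out.append(sum(d[i] <= r for i in elig) / len(elig))
    return out


def naive_k(points, window, r_grid) -> list[float]:
    """Translation-corrected Ripley K by explicit double loop."""
    pts = [tuple(p) for p in points]
    n = len(pts)
    L = window.extents
    V = L[0] * L[1] * L[2]
    out = []
    for r in r_grid:
        s = 0.0
        for i in range(n):
            for j in range(n):
                if i == j:
                    continue
                dij = dist(pts[i], pts[j])
                if dij <= r:
                    w = 1.0
                    for a in range(3):
                        w *= L[a] - abs(pts[i][a] - pts[j][a])
                    s += 1.0 / w
        out.append(s * V * V / (n * (n - 1)))
    return out


def mw_u_and_exact_p(a, b) -> tuple[float, float]:
    """Mann-Whitney U of sample a and exact two-sided p by full enumeration
    of all assignments of the pooled values to the two groups (tie-free)."""
    a, b = list(a), list(b)
    na = len(a)
    pooled = a + b

    def u_of(sample_a, sample_b):
        return sum(1.0 if x > y else (0.5 if x == y else 0.0)
                   for x in sample_a for y in sample_b)

    u_obs = u_of(a, b)
    mean_u = na * len(b) / 2.0
    dev = abs(u_obs - mean_u)
    count = 0
    total = 0
    for idx in combinations(range(len(pooled)), na):
        ia = set(idx)
        sa = [pooled[i] for i in idx]
        sb = [pooled[i] for i in range(len(pooled)) if i not in ia]
        if abs(u_of(sa, sb) - mean_u) >= dev - 1e-12:
            count += 1
        total += 1
    return u_obs, count / total


def ks_d_scan(a, b) -> float:
    """Two-sample KS statistic by direct ECDF scan over all pooled values."""
    a = sorted(a)
    b = sorted(b)
    d = 0.0
    for x in a + b:
        fa = sum(v <= x for v in a) / len(a)
        fb = sum(v <= x for v in b) / len(b)
        d = max(d, abs(fa - fb))
    return d


def frame_decision_voxel(box_lo, box_hi, frame_lo, frame_hi, step) -> bool:
    """Brick counting rule evaluated on a voxelised extent: counted iff
    some voxel centre lies in the half-open frame and no voxel lies on the
    forbidden side of an exclusion plane (min-coordinate faces, extended)."""
    axes = [np.arange(box_lo[a], box_hi[a] + step / 2, step) for a in range(3)]
    pts = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    in_frame = np.all((pts >= frame_lo) & (pts < frame_hi), axis=1)
    below_exclusion = np.any(pts < frame_lo, axis=1)
    return bool(in_frame.any()) and not bool(below_exclusion.any())


def rasterized_projection_area(uv_triangles, resolution=600) -> float:
    """Area of the union of 2D triangles by rasterisation (barycentric test)."""
    tris = [np.asarray(t, dtype=float) for t in uv_triangles]
    allpts = np.concatenate(tris)
    lo = allpts.min(axis=0)
    hi = allpts.max(axis=0)
    span = max(hi - lo)
    cell = span / resolution
    xs = np.arange(lo[0] + cell / 2, hi[0], cell)
    ys = np.arange(lo[1] + cell / 2, hi[1], cell)
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    covered = np.zeros(X.shape, dtype=bool)
    for t in tris:
        (x1, y1), (x2, y2), (x3, y3) = t
        den = (y2 - y3) * (x1 - x3) + (x3 - x2) * (y1 - y3)
        if abs(den) < 1e-30:
            continue
        l1 = ((y2 - y3) * (X - x3) + (x3 - x2) * (Y - y3)) / den
        l2 = ((y3 - y1) * (X - x3) + (x1 - x3) * (Y - y3)) / den
        l3 = 1.0 - l1 - l2
        covered |= (l1 >= 0) & (l2 >= 0) & (l3 >= 0)
    return float(covered.sum()) * cell * cell
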