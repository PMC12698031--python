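"""Brute-force oracle implementations, independent of the production code paths.

Everything here is written for clarity at tiny n, not speed: explicit
double loops, LP-based vertex tests, exhaustive facet enumeration.  The
production implementations must agree with these to 1e-10 on random small
communities.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy.optimize import linprog


def rao_brute(d: np.ndarray, p: np.ndarray) -> float:
    q = 0.0
    for i in range(len(p)):
        for j in range(len(p)):
            q += p[i] * p[j] * d[i, j]
    return q


def simpson_brute(p: np.ndarray) -> float:
    return 1.0 - sum(pi * pi for pi in p)


def fdis_brute(x: np.ndarray, p: np.ndarray) -> float:
    c = np.zeros(x.shape[1])
    for i in range(len(p)):
        c += p[i] * x[i]
    total = 0.0
    for i in range(len(p)):
        total += p[i] * math.dist(x[i], c)
    return total


def kruskal_brute(x: np.ndarray) -> list[tuple[int, int, float]]:
    """Edge-sort MST; ties broken by (length, i, j) like the production rule."""
    s = len(x)
    edges = sorted(
        (math.dist(x[i], x[j]), i, j) for i in range(s) for j in range(i + 1, s)
    )
    comp = list(range(s))
    mst = []
    for d, i, j in edges:
        if comp[i] != comp[j]:
            old, new = comp[i], comp[j]
            comp = [new if c == old else c for c in comp]
            mst.append((i, j, d))
    return mst


def feve_brute(x: np.ndarray, p: np.ndarray) -> float:
    s = len(x)
    if s < 3:
        return float("nan")
    mst = kruskal_brute(x)
    ew = [d / (p[i] + p[j]) for i, j, d in mst]
    pew = [e / sum(ew) for e in ew]
    thr = 1.0 / (s - 1)
    return (sum(min(v, thr) for v in pew) - thr) / (1.0 - thr)


def hull_vertices_lp(points: np.ndarray) -> list[int]:
    """Indices of convex-hull vertices, decided per point by an LP feasibility
    test: x_i is a vertex iff it is NOT a convex combination of the others."""
    n, m = points.shape
    verts = []
    for i in range(n):
        others = np.delete(points, i, axis=0)
        a_eq = np.vstack([others.T, np.ones(n - 1)])
        b_eq = np.concatenate([points[i], [1.0]])
        res = linprog(np.zeros(n - 1), A_eq=a_eq, b_eq=b_eq,
                      bounds=[(0, None)] * (n - 1), method="highs")
        if not res.success:
            verts.append(i)
    return verts


def hull_volume_brute(points: np.ndarray) -> float:
    """Convex-hull area/volume without qhull (m = 1, 2 or 3 only)."""
    m = points.shape[1]
    verts = points[hull_vertices_lp(points)]
    if m == 1:
        return float(points.max() - points.min())
    if m == 2:
        c = verts.mean(axis=0)
        order = np.argsort(np.arctan2(verts[:, 1] - c[1], verts[:, 0] - c[0]))
        v = verts[order]
        area = 0.0
        for i in range(len(v)):
            x1, y1 = v[i]
            x2, y2 = v[(i + 1) % len(v)]
            area += x1 * y2 - x2 * y1
        return abs(area) / 2.0
    if m == 3:
        # exhaustive facet enumeration: a vertex triple is a facet iff all
        # other vertices lie strictly on one side of its plane
        c = verts.mean(axis=0)
        vol = 0.0
        for tri in itertools.combinations(range(len(verts)), 3):
            a, b, d = verts[list(tri)]
            normal = np.cross(b - a, d - a)
            if np.linalg.norm(normal) < 1e-14:
                continue
            side = [np.dot(normal, verts[k] - a)
                    for k in range(len(verts)) if k not in tri]
            if all(s > 1e-12 for s in side) or all(s < -1e-12 for s in side):
                # signed tetrahedron (facet, centroid)
                vol += abs(np.dot(np.cross(a - c, b - c), d - c)) / 6.0
        return vol
    raise NotImplementedError("brute hull only for m <= 3")


def fdiv_brute(x: np.ndarray, p: np.ndarray) -> float:
    verts = np.unique(x, axis=0)
    verts = verts[hull_vertices_lp(verts)]
    g = verts.mean(axis=0)
    dg = [math.dist(xi, g) for xi in x]
    mean_dg = sum(dg) / len(dg)
    delta_d = sum(pi * (d - mean_dg) for pi, d in zip(p, dg))
    delta_abs = sum(pi * abs(d - mean_dg) for pi, d in zip(p, dg))
    return (delta_d + mean_dg) / (delta_abs + mean_dg)
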