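"""Independent oracles used by the test suite.

These deliberately avoid the package's own code paths: polygon areas come
from ear-clipping triangulation, and rule evaluation in the audit probe is
re-implemented directly from the printed thresholds.
"""

from __future__ import annotations

import math

import numpy as np


def triangle_area(a, b, c) -> float:
    return abs((b[0] - a[0]) * (c[1] - a[1])
               - (b[1] - a[1]) * (c[0] - a[0])) / 2.0


def earclip_area(vertices) -> float:
    """Polygon area by ear-clipping triangulation (simple polygons only)."""
    verts = [tuple(map(float, v)) for v in vertices]

    def cross(o, p, q):
        return (p[0] - o[0]) * (q[1] - o[1]) - (p[1] - o[1]) * (q[0] - o[0])

    # orientation via signed area of the full ring
    signed = sum(verts[i][0] * verts[(i + 1) % len(verts)][1]
                 - verts[i][1] * verts[(i + 1) % len(verts)][0]
                 for i in range(len(verts))) / 2.0
    ccw = signed > 0

    def point_in_tri(p, a, b, c):
        d1, d2, d3 = cross(a, b, p), cross(b, c, p), cross(c, a, p)
        neg = (d1 < 0) or (d2 < 0) or (d3 < 0)
        pos = (d1 > 0) or (d2 > 0) or (d3 > 0)
        return not (neg and pos)

    area = 0.0
    idx = list(range(len(verts)))
    guard = 0
    while len(idx) > 3 and guard < 10000:
        guard += 1
        n = len(idx)
        for k in range(n):
            i0, i1, i2 = idx[(k - 1) % n], idx[k], idx[(k + 1) % n]
            a, b, c = verts[i0], verts[i1], verts[i2]
            turn = cross(a, b, c)
            if (turn > 0) != ccw or turn == 0:
                continue
            if any(point_in_tri(verts[j], a, b, c)
                   for j in idx if j not in (i0, i1, i2)):
                continue
            area += triangle_area(a, b, c)
            idx.pop(k)
            break
        else:
            raise RuntimeError("no ear found; polygon may be non-simple")
    if guard >= 10000:
        raise RuntimeError("ear clipping did not terminate")
    a, b, c = (verts[i] for i in idx)
    return area + triangle_area(a, b, c)


def random_star_polygon(rng: np.random.Generator, n_min: int = 5,
                        n_max: int = 20, radius: float = 100.0,
                        center=(150.0, 150.0)):
    """Random simple polygon: sorted angles, random radii about a center."""
    n = int(rng.integers(n_min, n_max + 1))
    # angular gaps bounded away from pi so chords stay in their wedge and
    # the polygon is simple by the star-shaped construction
    gaps = rng.uniform(0.5, 1.5, size=n)
    angles = 2 * math.pi * np.cumsum(gaps) / gaps.sum()
    radii = rng.uniform(0.2 * radius, radius, size=n)
    return [(center[0] + r * math.cos(t), center[1] + r * math.sin(t))
            for t, r in zip(angles, radii)]


def random_convex_polygon(rng: np.random.Generator, n_max: int = 12,
                          scale: float = 100.0):
    """Random convex polygon as the hull of random points."""
    from scipy.spatial import ConvexHull

    while True:
        pts = rng.uniform(0, scale, size=(int(rng.integers(4, n_max + 4)), 2))
        hull = ConvexHull(pts)
        if len(hull.vertices) >= 3:
            return [tuple(pts[i]) for i in hull.vertices]


# --- printed grading rules, re-evaluated directly (audit probe oracle) ----

def printed_rule_matches(fv: dict) -> list[int]:
    """Indices of the nine printed rules satisfied by a feature dict."""
    r_se, r_he = fv["R_SE"], fv["R_HE"]
    n_se, n_nv = fv["N_SE"], fv["N_NV"]
    conds = [
        r_se <= 0.18 and r_he <= 0.052 and n_se == 0,
        r_se <= 0.18 and r_he <= 0.052 and 1 <= n_se <= 15 and r_se <= 0.111,
        r_se <= 0.18 and r_he <= 0.052 and 1 <= n_se <= 15 and r_se > 0.111,
        r_se <= 0.18 and r_he > 0.052 and r_he <= 0.171,
        r_se <= 0.18 and r_he >= 0.052 and r_he > 0.171,
        r_se > 0.18 and n_nv == 0 and r_se <= 0.342 and r_he <= 0.343,
        r_se > 0.18 and 1 <= n_nv <= 3,
        r_se > 0.18 and n_nv == 0 and r_se > 0.342,
        r_se > 0.18 and n_nv == 0 and r_se <= 0.342 and r_he > 0.343,
    ]
    return [i for i, c in enumerate(conds) if c]
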