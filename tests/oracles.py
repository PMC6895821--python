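"""Independent brute-force oracles used only by the tests.

These deliberately avoid the package's code paths and vectorized libraries:
the detector is a pure-Python plateau BFS with explicit annulus enumeration,
and the matcher is Kuhn's augmenting-path maximum bipartite matching.
"""

from __future__ import annotations

import math


def brute_detect(
    img,
    delta: float = 10.0,
    inner: float = 3.0,
    outer: float = 7.0,
    statistic: str = "median",
    margin: int = 7,
    policy: str = "centroid",
):
    """Exhaustive punctum detection.

    Enumerates every equal-intensity plateau (8-connectivity BFS), keeps
    plateaus all of whose outside neighbours are strictly lower, takes the
    plateau representative (half-up-rounded centroid or first pixel in
    (row, col) order), discards representatives within `margin` of the
    border, and keeps those at least `delta` above the annulus background
    (inner < d <= outer, Euclidean, median or mean).  Representatives
    falling on the same pixel are deduplicated keeping the more intense.
    Returns a sorted list of (row, col, intensity, background).
    """
    h = len(img)
    w = len(img[0])
    visited = [[False] * w for _ in range(h)]
    reps: list[tuple[int, int, float]] = []

    for r0 in range(h):
        for c0 in range(w):
            if visited[r0][c0]:
                continue
            val = float(img[r0][c0])
            comp = [(r0, c0)]
            visited[r0][c0] = True
            is_max = True
            qi = 0
            while qi < len(comp):
                cr, cc = comp[qi]
                qi += 1
                for dr in (-1, 0, 1):
                    for dc in (-1, 0, 1):
                        if dr == 0 and dc == 0:
                            continue
                        nr, nc = cr + dr, cc + dc
                        if 0 <= nr < h and 0 <= nc < w:
                            nv = float(img[nr][nc])
                            if nv > val:
                                is_max = False
                            elif nv == val and not visited[nr][nc]:
                                visited[nr][nc] = True
                                comp.append((nr, nc))
            if not is_max:
                continue
            if policy == "centroid":
                rr = math.floor(sum(p[0] for p in comp) / len(comp) + 0.5)
                cc_ = math.floor(sum(p[1] for p in comp) / len(comp) + 0.5)
            else:
                rr, cc_ = min(comp)
            reps.append((rr, cc_, val))

    rad = math.ceil(outer)
    best: dict[tuple[int, int], tuple[int, int, float, float]] = {}
    for rr, cc, val in reps:
        if not (margin <= rr < h - margin and margin <= cc < w - margin):
            continue
        ann = []
        for dr in range(-rad, rad + 1):
            for dc in range(-rad, rad + 1):
                d = math.hypot(dr, dc)
                if inner < d <= outer:
                    ann.append(float(img[rr + dr][cc + dc]))
        ann.sort()
        n = len(ann)
        if statistic == "median":
            bg = ann[n // 2] if n % 2 else (ann[n // 2 - 1] + ann[n // 2]) / 2.0
        else:
            bg = sum(ann) / n
        if val - bg >= delta:
            key = (rr, cc)
            if key not in best or val > best[key][2]:
                best[key] = (rr, cc, val, bg)
    return sorted(best.values())


def optimal_match_count(points_a, points_b, radius: float) -> int:
    """Maximum one-to-one matching count on the within-radius graph
    (Kuhn's augmenting paths)."""
    r2 = radius * radius
    adj = [
        [
            j
            for j, (br, bc) in enumerate(points_b)
            if (ar - br) ** 2 + (ac - bc) ** 2 <= r2
        ]
        for (ar, ac) in points_a
    ]
    match_b: dict[int, int] = {}

    def augment(i: int, seen: set[int]) -> bool:
        for j in adj[i]:
            if j in seen:
                continue
            seen.add(j)
            if j not in match_b or augment(match_b[j], seen):
                match_b[j] = i
                return True
        return False

    return sum(augment(i, set()) for i in range(len(points_a)))
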