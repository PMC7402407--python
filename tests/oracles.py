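"""Deliberately naive reference implementations used only as test oracles.

These share no code with the package: pure-Python loops, explicit pairwise
distances, explicit half-space tests, explicit rank counting. Slow on
purpose — correctness over speed.
"""

from __future__ import annotations

import math


def naive_hse_profile(
    chain,
    radius: float = 12.0,
    tie_rule: str = "down",
    inclusive: bool = True,
    alpha_outward: bool = True,
) -> list[tuple[int, int, int, int]]:
    """Per-residue (αup, αdown, βup, βdown) by full pairwise enumeration."""
    geo = chain.geometry
    n = len(geo)
    out = []
    for i in range(n):
        neigh = []
        for j in range(n):
            if j == i:
                continue
            d = [float(geo[j].ca[k]) - float(geo[i].ca[k]) for k in range(3)]
            dist = math.sqrt(d[0] * d[0] + d[1] * d[1] + d[2] * d[2])
            inside = dist <= radius if inclusive else dist < radius
            if inside:
                neigh.append(d)

        def split(u):
            up = 0
            for d in neigh:
                dot = u[0] * d[0] + u[1] * d[1] + u[2] * d[2]
                if dot > 0.0 or (dot == 0.0 and tie_rule == "up"):
                    up += 1
            return up, len(neigh) - up

        s = [0.0, 0.0, 0.0]
        has_flank = False
        if i > 0:
            for k in range(3):
                s[k] += float(geo[i - 1].ca[k]) - float(geo[i].ca[k])
            has_flank = True
        if i < n - 1:
            for k in range(3):
                s[k] += float(geo[i + 1].ca[k]) - float(geo[i].ca[k])
            has_flank = True
        ua = [-c for c in s] if alpha_outward else s

        a_up, a_down = split(ua) if has_flank else (0, 0)
        if geo[i].cb is not None:
            ub = [float(geo[i].cb[k]) - float(geo[i].ca[k]) for k in range(3)]
        elif has_flank:
            ub = ua
        else:
            ub = None
        b_up, b_down = split(ub) if ub is not None else (0, 0)
        out.append((a_up, a_down, b_up, b_down))
    return out


def pair_count_auc(y_true, scores) -> float:
    """Mann-Whitney AUC: fraction of (pos, neg) pairs ranked correctly,
    half credit for ties."""
    pos = [float(s) for t, s in zip(y_true, scores) if t == 1]
    neg = [float(s) for t, s in zip(y_true, scores) if t == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


def naive_nearmiss_majority(X_minority, X_majority, k: int) -> list[int]:
    """Indices (into X_majority) retained by NearMiss-1: smallest mean
    distance to the k nearest minority points, ties by index."""
    k = min(k, len(X_minority))
    scored = []
    for i, xm in enumerate(X_majority):
        ds = sorted(math.dist(xm, q) for q in X_minority)
        scored.append((sum(ds[:k]) / k, i))
    scored.sort()
    return sorted(i for _, i in scored[: len(X_minority)])
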