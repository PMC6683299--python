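"""Independent oracles, implemented from first principles and kept free of
the package's internals so the two routes cannot share a bug."""

from __future__ import annotations

import itertools
import math
from decimal import Decimal, getcontext

import numpy as np

getcontext().prec = 60


def hellinger_oracle(p, q) -> float:
    """Arbitrary-precision evaluation of the Hellinger distance."""
    total = Decimal(0)
    for a, b in zip(p, q):
        diff = Decimal(a).sqrt() - Decimal(b).sqrt()
        total += diff * diff
    return float(total.sqrt() / Decimal(2).sqrt())


def dbscan_oracle(points: np.ndarray, eps: float, min_pts: int):
    """Brute-force density-reachability clustering.

    Follows the textbook definitions directly: core points have >= min_pts
    points in their closed eps-ball (self included); density-reachability is
    the transitive closure of direct reachability from core points, computed
    by iterating a boolean reachability matrix to a fixed point. Clusters are
    the mutual-reachability classes of core points; non-core points reachable
    from a core point join the cluster of their first core neighbor in
    (x, y, input index) scan order; the rest are noise.

    Returns (clusters, noise): a list of frozensets of point indices ordered
    by smallest member, and the frozenset of noise indices.
    """
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    dist = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(axis=2))
    within = dist <= eps
    core = within.sum(axis=1) >= min_pts

    # direct density-reachability: p -> q allowed only out of core points
    direct = within & core[:, None]
    reach = direct.copy()
    for _ in range(n):
        # transitive closure by boolean matrix "multiplication"
        new = reach | ((reach.astype(int) @ direct.astype(int)) > 0)
        if (new == reach).all():
            break
        reach = new

    core_idx = [i for i in range(n) if core[i]]
    assigned: dict[int, int] = {}
    clusters: list[set[int]] = []
    for i in core_idx:
        if i in assigned:
            continue
        members = {
            j for j in core_idx if (reach[i, j] and reach[j, i]) or j == i
        }
        cid = len(clusters)
        clusters.append(set(members))
        for j in members:
            assigned[j] = cid

    order = sorted(range(n), key=lambda i: (pts[i, 0], pts[i, 1], i))
    rank = {i: r for r, i in enumerate(order)}
    noise = set()
    for i in range(n):
        if core[i]:
            continue
        core_neighbors = [j for j in core_idx if within[i, j]]
        if core_neighbors:
            winner = min(core_neighbors, key=lambda j: rank[j])
            clusters[assigned[winner]].add(i)
        else:
            noise.add(i)
    cluster_sets = sorted(
        (frozenset(c) for c in clusters), key=lambda c: min(c)
    )
    return cluster_sets, frozenset(noise)


def labels_to_partition(labels: np.ndarray):
    """Canonical (clusters, noise) form of a DBSCAN label vector."""
    clusters = {}
    noise = set()
    for i, lab in enumerate(labels):
        if lab == -1:
            noise.add(i)
        else:
            clusters.setdefault(lab, set()).add(i)
    cluster_sets = sorted(
        (frozenset(c) for c in clusters.values()), key=lambda c: min(c)
    )
    return cluster_sets, frozenset(noise)


def wilcoxon_oracle(x, y) -> tuple[float, float]:
    """Exact signed-rank test by enumerating all sign patterns.

    Requires tie-free nonzero |differences| and small n. Returns V (sum of
    ranks of positive differences) and the two-sided exact p-value
    ``min(1, 2 * min(P(V <= v), P(V >= v)))``.
    """
    diffs = [a - b for a, b in zip(x, y) if a != b]
    n = len(diffs)
    if n == 0:
        raise ValueError("all differences zero")
    magnitudes = sorted(abs(d) for d in diffs)
    if len(set(magnitudes)) != n:
        raise ValueError("tie-free differences required")
    ranks = {m: r + 1 for r, m in enumerate(magnitudes)}
    v_obs = sum(ranks[abs(d)] for d in diffs if d > 0)
    rank_list = [ranks[abs(d)] for d in diffs]
    values = [
        sum(r for r, s in zip(rank_list, signs) if s)
        for signs in itertools.product([False, True], repeat=n)
    ]
    total = len(values)
    p_low = sum(v <= v_obs for v in values) / total
    p_high = sum(v >= v_obs for v in values) / total
    return float(v_obs), min(1.0, 2.0 * min(p_low, p_high))


def mcnemar_oracle(b: int, c: int) -> tuple[float, float]:
    """Continuity-corrected McNemar statistic with a chi-square(1) upper tail
    computed through the complementary error function."""
    chi2 = max(0.0, abs(b - c) - 1.0) ** 2 / (b + c)
    p = math.erfc(math.sqrt(chi2 / 2.0))
    return chi2, p


def count_pairs_oracle(sequences):
    """Dict of directed consecutive-pair counts, by literal iteration."""
    out: dict[tuple[str, str], int] = {}
    for seq in sequences:
        for a, b in zip(seq, seq[1:]):
            out[(a, b)] = out.get((a, b), 0) + 1
    return out
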