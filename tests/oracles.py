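"""Independent brute-force oracles used to check the implementation.

Everything here is deliberately naive (O(n^2) scans, set-based breadth-first
closure, scalar rejection sampling) and shares no code with the package's
vectorized implementations.
"""

import math

import numpy as np


def brute_nearest_two(coords):
    """First and second nearest other point per row, ties broken by index."""
    n = len(coords)
    nn, nn2 = [], []
    for i in range(n):
        ranked = sorted(
            (math.dist(coords[i], coords[j]), j) for j in range(n) if j != i
        )
        nn.append(ranked[0][1])
        nn2.append(ranked[1][1] if n > 2 else -1)
    return np.array(nn), np.array(nn2)


def literal_closure_partition(coords):
    """Species clusters via the literal iterative mating closure.

    Starting from a seed organism, collect everything it, its mate (nearest
    neighbour) and its second-nearest neighbour have mated with; repeat the
    same search for every organism found, until the set closes.  ``mated(x)``
    is the set of organisms x mated with in this generation: x's own mate
    plus everyone who chose x as mate.

    The per-seed closed sets can overlap (the expansion relation is not
    symmetric: x's search collects who x's second neighbour mated with, but
    that organism's own search need not reach back to x).  Since a cluster
    assignment must place every organism in exactly one cluster, closed sets
    that share an organism are the same cluster and are merged, which yields
    the unique partition regardless of seed order.  Returns a set of
    frozensets of indices.
    """
    n = len(coords)
    if n == 1:
        return {frozenset([0])}
    nn, nn2 = brute_nearest_two(coords)
    mated = {
        i: {int(nn[i])} | {j for j in range(n) if nn[j] == i} for i in range(n)
    }

    def expand(x):
        out = {x} | mated[x] | mated[int(nn[x])]
        if nn2[x] >= 0:
            out |= mated[int(nn2[x])]
        return out

    def closure(seed):
        current = expand(seed)
        frontier = set(current)
        while frontier:
            new = set()
            for x in frontier:
                new |= expand(x) - current
            current |= new
            frontier = new
        return current

    clusters: list[set] = []
    for seed in range(n):
        current = closure(seed)
        overlapping = [c for c in clusters if c & current]
        for c in overlapping:
            clusters.remove(c)
            current |= c
        clusters.append(current)
    return {frozenset(c) for c in clusters}


def greedy_thin(coords, radius, order):
    """Keep a point iff no already-kept point lies strictly within radius."""
    kept = []
    for i in order:
        if all(math.dist(coords[i], coords[j]) >= radius for j in kept):
            kept.append(i)
    return sorted(kept)


def brute_mean_pairwise(points):
    """Mean Euclidean distance over all unordered pairs."""
    pts = list(points)
    dists = [
        math.dist(pts[i], pts[j])
        for i in range(len(pts))
        for j in range(i + 1, len(pts))
    ]
    return sum(dists) / len(dists)


def rejection_normal_axis(c1, c2, mu, b, extent, rng, size):
    """Scalar rejection sampler for the normal mutation kernel, one axis."""
    lo = max(min(c1, c2) - mu, 0.0)
    hi = min(max(c1, c2) + mu, extent)
    mid = 0.5 * (c1 + c2)
    width = abs(c1 - c2) + 2.0 * mu
    out = []
    while len(out) < size:
        c = mid + rng.normal(0.0, b) * width
        if lo <= c <= hi:
            out.append(c)
    return np.array(out)


def pearson_textbook(x, y):
    """Pearson correlation straight from the definitional sums."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    return sxy / math.sqrt(sxx * syy)
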