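"""Independent brute-force oracles used by the test suite.

Everything here is written from first principles (textbook definitions,
explicit enumeration) and deliberately shares no code with the package.
"""

from itertools import combinations

import numpy as np


def brute_silhouette(dist: np.ndarray, labels) -> float:
    """Textbook mean silhouette width: s_i = (b_i - a_i) / max(a_i, b_i).

    a_i is the mean distance to the other members of i's cluster, b_i the
    smallest mean distance to any other cluster; singletons score 0.
    """
    labels = np.asarray(labels)
    scores = []
    for i in range(len(labels)):
        own = np.flatnonzero((labels == labels[i]) & (np.arange(len(labels)) != i))
        if own.size == 0:
            scores.append(0.0)
            continue
        a = dist[i, own].mean()
        b = min(
            dist[i, labels == other].mean()
            for other in np.unique(labels)
            if other != labels[i]
        )
        scores.append((b - a) / max(a, b) if max(a, b) > 0 else 0.0)
    return float(np.mean(scores))


def brute_bh(pvals) -> np.ndarray:
    """Textbook Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(pvals, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    adjusted = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adjusted[i] = running
    return adjusted


def all_contiguous_partitions(m: int):
    """Every partition of 0..m-1 into >= 2 contiguous blocks, as cut tuples.

    Cut e separates positions e and e+1.
    """
    for n_cuts in range(1, m):
        yield from combinations(range(m - 1), n_cuts)


def cuts_to_labels(cuts, m: int) -> np.ndarray:
    labels = np.zeros(m, dtype=int)
    for c in sorted(cuts):
        labels[c + 1 :] += 1
    return labels


def best_contiguous_partition(dist: np.ndarray):
    """Exhaustive silhouette-optimal contiguous partition of a region.

    Ties prefer more clusters, then leftmost cut positions.  Returns the
    cut tuple, or () when no partition has a positive silhouette.
    """
    m = dist.shape[0]
    best = None
    for cuts in all_contiguous_partitions(m):
        score = brute_silhouette(dist, cuts_to_labels(cuts, m))
        key = (score, len(cuts), tuple(-c for c in cuts))
        if best is None or key > best[:3]:
            best = (*key, cuts)
    if best is None or best[0] <= 0:
        return ()
    return best[3]


def epitope_cuts(epitopes) -> tuple:
    """Cut positions implied by an ordered list of emitted epitopes."""
    cuts, pos = [], 0
    for e in epitopes[:-1]:
        pos += e.n_probes
        cuts.append(pos - 1)
    return tuple(cuts)


def wilkinson_mc(k: int, r: int, x: float, n_draws: int, rng, largest: bool) -> float:
    """Monte-Carlo P(r-th largest/smallest of k uniforms <= x)."""
    draws = np.sort(rng.uniform(size=(n_draws, k)), axis=1)
    stat = draws[:, k - r] if largest else draws[:, r - 1]
    return float((stat <= x).mean())
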