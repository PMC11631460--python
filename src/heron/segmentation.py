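"""Epitope finding: contiguous blocks of adjacent called probes per protein.

Three segmentation methods are provided:

* ``unique`` — the union over positive samples of the per-sample runs of
  adjacent called probes, deduplicated by epitope id (overlapping blocks
  from different samples are all retained);
* ``hclust`` — candidate regions (runs of probes called in *any* positive
  sample) are split by contiguity-constrained complete-linkage hierarchical
  clustering: the linkage distance between two adjacent blocks is the
  diameter (maximum pairwise base distance) of their union, which is
  exactly complete linkage on the interval-max embedded distance matrix and
  guarantees every cluster is a contiguous block;
* ``skater`` — the candidate region is a path graph with an edge between
  every pair of rank-adjacent probes; edges are cut greedily, keeping the
  cut that gives the best average silhouette, as long as the score does not
  decrease (ties prefer more components).

Model selection for both clustering methods maximizes the average
silhouette width computed on the *base* probe-by-probe distance matrix
(binary-hamming on call vectors, or Euclidean on one-sided z-scores), with
ties broken toward more clusters; a region stays whole when no split
achieves a positive silhouette.  Everything is deterministic.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from sklearn.metrics import silhouette_score

from .types import CallMatrix, Epitope, ProbeDataset, PValueTable, SegmentationConfig

#: clipping for the one-sided z transform z = Phi^-1(1 - p); bounds |z| ~ 8.2
Z_CLIP = 1e-16


# ---------------------------------------------------------------------------
# run extraction


def _runs_from_flags(order: pd.DataFrame, flags: np.ndarray) -> list[Epitope]:
    """Maximal runs of rank-adjacent flagged probes; `order` sorted by (protein, start)."""
    epitopes: list[Epitope] = []
    protein = order["protein_id"].to_numpy()
    start = order["start"].to_numpy()
    ids = order.index.to_numpy()
    n = len(order)
    i = 0
    while i < n:
        if not flags[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and flags[j + 1] and protein[j + 1] == protein[i]:
            j += 1
        epitopes.append(
            Epitope(
                protein_id=str(protein[i]),
                first=int(start[i]),
                last=int(start[j]),
                member_probes=tuple(ids[i : j + 1]),
            )
        )
        i = j + 1
    return epitopes


def find_runs(calls: CallMatrix, data: ProbeDataset, sample: str) -> list[Epitope]:
    """Maximal runs of adjacent called probes within each protein for one sample."""
    order = data.protein_probe_order()
    flags = calls.calls.loc[order.index, sample].to_numpy()
    return _runs_from_flags(order, flags)


def segment_unique(calls: CallMatrix, data: ProbeDataset) -> list[Epitope]:
    """Union of per-sample runs across all positive samples (dedup by epitope id)."""
    seen: dict[str, Epitope] = {}
    for sample in calls.calls.columns:
        for epi in find_runs(calls, data, sample):
            seen.setdefault(epi.epitope_id, epi)
    return sorted(seen.values(), key=lambda e: (e.protein_id, e.first, e.last))


def candidate_regions(calls: CallMatrix, data: ProbeDataset) -> list[Epitope]:
    """Maximal runs over the OR across positive samples; inputs to clustering."""
    order = data.protein_probe_order()
    flags = calls.calls.loc[order.index].to_numpy().any(axis=1)
    return _runs_from_flags(order, flags)


# ---------------------------------------------------------------------------
# distances and silhouette


def probe_distance(
    region: Epitope,
    calls: CallMatrix | None = None,
    pvalues: PValueTable | None = None,
    distance: str = "binary_hamming",
) -> np.ndarray:
    """Pairwise probe distance matrix over a region's member probes.

    ``binary_hamming`` counts per-sample call disagreements between probes;
    ``zscore_euclidean`` is the Euclidean distance between the probes'
    one-sided z-score vectors z = Phi^-1(1 - p).
    """
    if distance == "binary_hamming":
        if calls is None:
            raise ValueError("binary_hamming distance needs the call matrix")
        x = calls.calls.loc[list(region.member_probes)].to_numpy(dtype=float)
        return squareform(pdist(x, metric="hamming") * x.shape[1])
    if distance == "zscore_euclidean":
        if pvalues is None:
            raise ValueError("zscore_euclidean distance needs the p-value table")
        p = pvalues.values.loc[list(region.member_probes)].to_numpy(dtype=float)
        z = stats.norm.isf(np.clip(p, Z_CLIP, 1.0 - Z_CLIP))
        return squareform(pdist(z, metric="euclidean"))
    raise ValueError(f"unknown distance mode {distance!r}")


def average_silhouette(dist: np.ndarray, labels: np.ndarray) -> float:
    """Mean silhouette width on a precomputed distance matrix.

    Singleton clusters contribute 0 (the standard convention); a partition
    of all singletons therefore scores 0.  Raises for fewer than 2 clusters
    (the caller handles the no-split case).
    """
    labels = np.asarray(labels)
    uniq, counts = np.unique(labels, return_counts=True)
    if uniq.size < 2:
        raise ValueError("silhouette needs at least 2 clusters")
    if (counts == 1).all():
        return 0.0
    return float(silhouette_score(dist, labels, metric="precomputed"))


# ---------------------------------------------------------------------------
# interval diameters and the two clustering methods


def interval_diameters(dist: np.ndarray) -> np.ndarray:
    """diam[i, j] = max pairwise distance among probes with rank in [i, j].

    This is the interval-max embedding: complete linkage between adjacent
    blocks equals the diameter of their union, which forces contiguity.
    """
    m = dist.shape[0]
    diam = np.zeros((m, m))
    for span in range(1, m):
        for i in range(m - span):
            j = i + span
            diam[i, j] = diam[j, i] = max(diam[i, j - 1], diam[i + 1, j], dist[i, j])
    return diam


def _blocks_to_labels(blocks: list[tuple[int, int]], m: int) -> np.ndarray:
    labels = np.empty(m, dtype=int)
    for idx, (lo, hi) in enumerate(blocks):
        labels[lo : hi + 1] = idx
    return labels


def _emit(region: Epitope, blocks: list[tuple[int, int]], data: ProbeDataset) -> list[Epitope]:
    starts = data.probe_meta.loc[list(region.member_probes), "start"].to_numpy()
    out = []
    for lo, hi in blocks:
        members = region.member_probes[lo : hi + 1]
        out.append(
            Epitope(
                protein_id=region.protein_id,
                first=int(starts[lo]),
                last=int(starts[hi]),
                member_probes=tuple(members),
            )
        )
    return out


def _hclust_partitions(diam: np.ndarray) -> list[list[tuple[int, int]]]:
    """Contiguity-constrained complete-linkage merge order.

    Returns the partition (list of blocks) for every cluster count from m
    down to 1.  At each step the adjacent block pair whose union has the
    smallest diameter is merged; ties merge the leftmost pair.
    """
    m = diam.shape[0]
    blocks: list[tuple[int, int]] = [(i, i) for i in range(m)]
    partitions = [list(blocks)]
    while len(blocks) > 1:
        best = None
        for i in range(len(blocks) - 1):
            d = diam[blocks[i][0], blocks[i + 1][1]]
            if best is None or d < best[0]:
                best = (d, i)
        i = best[1]
        blocks[i : i + 2] = [(blocks[i][0], blocks[i + 1][1])]
        partitions.append(list(blocks))
    return partitions  # partitions[t] has m - t blocks


def segment_hclust(region: Epitope, dist: np.ndarray, data: ProbeDataset) -> list[Epitope]:
    """Split a candidate region by constrained complete-linkage clustering.

    Every cut of the constrained tree (k = 2 .. m) is scored by average
    silhouette on the base distance matrix; the best k wins, ties broken by
    the largest k.  Regions of fewer than 3 probes, or with no positive
    silhouette at any k, are returned unsplit.
    """
    m = len(region.member_probes)
    if dist.shape != (m, m):
        raise ValueError("distance matrix does not match region size")
    if m < 3:
        return [region]
    partitions = _hclust_partitions(interval_diameters(dist))
    best_score, best_blocks = 0.0, None
    for part in partitions:
        k = len(part)
        if k < 2:
            continue
        score = average_silhouette(dist, _blocks_to_labels(part, m))
        # strict > keeps the largest k on ties (k decreases along the merge order)
        if best_blocks is None or score > best_score:
            best_score, best_blocks = score, part
    if best_blocks is None or best_score <= 0:
        return [region]
    return _emit(region, sorted(best_blocks), data)


def _cuts_to_blocks(cuts: frozenset[int], m: int) -> list[tuple[int, int]]:
    bounds = sorted(cuts)
    edges = [-1] + bounds + [m - 1]
    return [(edges[i] + 1, edges[i + 1]) for i in range(len(edges) - 1)]


#: regions up to this many probes are searched exhaustively by the skater
#: method (2**(m-1) cut subsets of the path graph); larger regions fall back
#: to greedy stepwise edge removal
SKATER_EXACT_MAX = 12


def _skater_exact(dist: np.ndarray, m: int) -> tuple[float, tuple[int, ...]] | None:
    """Best cut subset over all contiguous partitions of the path graph.

    Ties prefer more cuts, then the leftmost-lexicographic cut positions.
    Returns None when no partition scores a positive silhouette.
    """
    from itertools import combinations

    best: tuple[float, int, tuple[int, ...], tuple[int, ...]] | None = None
    for n_cuts in range(1, m):
        for cuts in combinations(range(m - 1), n_cuts):
            labels = _blocks_to_labels(_cuts_to_blocks(frozenset(cuts), m), m)
            score = average_silhouette(dist, labels)
            key = (score, n_cuts, tuple(-c for c in cuts))
            if best is None or key > best[:3]:
                best = (*key, cuts)
    if best is None or best[0] <= 0:
        return None
    return best[0], best[3]


def _skater_greedy(dist: np.ndarray, m: int) -> tuple[float, tuple[int, ...]] | None:
    """Stepwise edge removal: keep the best single cut per round while the
    average silhouette does not drop (equal-scoring cuts are accepted, so
    ties prefer more components)."""
    cuts: set[int] = set()
    incumbent: float | None = None
    while len(cuts) < m - 1:
        best_score, best_edge = None, None
        for e in range(m - 1):
            if e in cuts:
                continue
            labels = _blocks_to_labels(_cuts_to_blocks(frozenset(cuts | {e}), m), m)
            score = average_silhouette(dist, labels)
            if best_score is None or score > best_score:
                best_score, best_edge = score, e
        if incumbent is None:
            if best_score is None or best_score <= 0:
                return None
        elif best_score < incumbent:
            break
        cuts.add(best_edge)
        incumbent = best_score
    return incumbent, tuple(sorted(cuts))


def segment_skater(region: Epitope, dist: np.ndarray, data: ProbeDataset) -> list[Epitope]:
    """Split a candidate region by edge removal on its path graph.

    Edge e sits between rank-adjacent probes e and e+1; the epitopes are the
    connected components left after cutting.  All cut subsets are scored by
    the average silhouette of the resulting components (base distances) and
    the best is kept -- exhaustively for regions of up to ``SKATER_EXACT_MAX``
    probes, by greedy stepwise removal beyond that.  Ties prefer more
    components, then the leftmost cut positions.  If no cut achieves a
    positive silhouette the region stays whole.
    """
    m = len(region.member_probes)
    if dist.shape != (m, m):
        raise ValueError("distance matrix does not match region size")
    if m < 3:
        return [region]
    search = _skater_exact if m <= SKATER_EXACT_MAX else _skater_greedy
    result = search(dist, m)
    if result is None:
        return [region]
    _, cuts = result
    return _emit(region, _cuts_to_blocks(frozenset(cuts), m), data)


# ---------------------------------------------------------------------------
# orchestration


def segment(
    calls: CallMatrix,
    data: ProbeDataset,
    config: SegmentationConfig,
    pvalues: PValueTable | None = None,
) -> list[Epitope]:
    """Run the configured segmentation method over the whole call matrix.

    For the clustering methods, singleton candidate regions bypass
    clustering; ``pvalues`` (raw combined probe p-values) are required for
    the z-score distance.
    """
    if config.method == "unique":
        return segment_unique(calls, data)
    epitopes: list[Epitope] = []
    for region in candidate_regions(calls, data):
        if len(region.member_probes) < 2:
            epitopes.append(region)
            continue
        dist = probe_distance(region, calls=calls, pvalues=pvalues, distance=config.distance)
        if config.method == "hclust":
            epitopes.extend(segment_hclust(region, dist, data))
        else:
            epitopes.extend(segment_skater(region, dist, data))
    return epitopes
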