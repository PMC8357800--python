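"""Community detection across thresholds and consensus combination.

Each binarized adjacency matrix is partitioned by minimising the two-level
map equation (Infomap).  The per-threshold solutions are combined into one
consensus model: a sliding window over adjacent densities selects, within
each window, the solution with the highest mean normalized mutual
information (NMI) to its neighbours, and the final partition is the
candidate with the highest Newman-Girvan modularity on the median-density
graph.  Isolated ROIs at sparse densities keep singleton labels so all
partitions share the same ROI universe.
"""

from __future__ import annotations

import random as _pyrandom
from dataclasses import dataclass, field

import igraph as ig
import numpy as np
from sklearn.metrics import normalized_mutual_info_score


@dataclass
class Partition:
    labels: np.ndarray                  # ROI -> community id, contiguous from 0
    threshold: float | None = None      # edge density this solution came from
    quality: dict = field(default_factory=dict)   # codelength, modularity

    def __post_init__(self):
        self.labels = canonical_labels(np.asarray(self.labels, dtype=int))

    @property
    def n_communities(self) -> int:
        return int(self.labels.max()) + 1 if self.labels.size else 0


@dataclass
class ConsensusModel:
    final: Partition
    per_threshold: list
    nmi_matrix: np.ndarray
    n_networks: int
    selected_indices: list = field(default_factory=list)


def canonical_labels(labels: np.ndarray) -> np.ndarray:
    """Relabel community ids to 0..k-1 in order of first appearance."""
    seen = {}
    out = np.empty_like(labels)
    for i, l in enumerate(labels):
        if l not in seen:
            seen[l] = len(seen)
        out[i] = seen[l]
    return out


def _graph_from_adjacency(adjacency: np.ndarray) -> ig.Graph:
    adj = np.asarray(adjacency)
    n = adj.shape[0]
    iu = np.triu_indices(n, k=1)
    sel = adj[iu] != 0
    edges = list(zip(iu[0][sel].tolist(), iu[1][sel].tolist()))
    return ig.Graph(n=n, edges=edges)


def map_equation_codelength(adjacency: np.ndarray, labels: np.ndarray) -> float:
    """Two-level map-equation description length (bits) of a partition of an
    undirected, unweighted graph, using stationary visit rates deg/2E."""
    adj = np.asarray(adjacency, dtype=float)
    labels = np.asarray(labels)
    deg = adj.sum(axis=1)
    two_e = deg.sum()
    if two_e == 0:
        raise ValueError("graph has no edges")
    p = deg / two_e

    def h(x):  # -x log2 x with 0 log 0 = 0
        x = np.asarray(x, dtype=float)
        out = np.zeros_like(x)
        nz = x > 0
        out[nz] = -x[nz] * np.log2(x[nz])
        return out.sum()

    mods = np.unique(labels)
    q = np.empty(len(mods))
    inner = 0.0
    for mi, m in enumerate(mods):
        mask = labels == m
        cut = adj[np.ix_(mask, ~mask)].sum()
        q[mi] = cut / two_e
        p_circ = q[mi] + p[mask].sum()
        if p_circ > 0:
            inner += p_circ * (h(np.append(p[mask], q[mi]) / p_circ))
    q_sum = q.sum()
    index_len = q_sum * h(q / q_sum) if q_sum > 0 else 0.0
    return float(index_len + inner)


def detect_communities(adjacency: np.ndarray, seed: int = 0, trials: int = 100,
                       threshold: float | None = None) -> Partition:
    """Best-codelength Infomap partition of a binary undirected graph.

    Deterministic for a fixed seed.  Vertices with no edges become singleton
    communities (igraph already assigns them their own modules).
    """
    g = _graph_from_adjacency(adjacency)
    if g.vcount() == 0:
        raise ValueError("empty graph")
    _pyrandom.seed(seed)
    if g.ecount() == 0:
        labels = np.arange(g.vcount())
        return Partition(labels=labels, threshold=threshold,
                         quality={"codelength": float("nan"), "modularity": 0.0})
    clustering = g.community_infomap(trials=trials)
    labels = np.asarray(clustering.membership, dtype=int)
    # codelength from the textbook two-level map equation (igraph's internal
    # value uses a teleportation variant and is not comparable)
    quality = {"codelength": map_equation_codelength(adjacency, labels),
               "modularity": float(g.modularity(clustering.membership))}
    return Partition(labels=labels, threshold=threshold, quality=quality)


def pairwise_nmi(p1: Partition, p2: Partition) -> float:
    """NMI with arithmetic-mean normalization, in [0, 1]."""
    a, b = p1.labels, p2.labels
    if a.shape != b.shape:
        raise ValueError("partitions must cover the same ROI set")
    return float(normalized_mutual_info_score(a, b, average_method="arithmetic"))


def modularity(adjacency: np.ndarray, labels: np.ndarray) -> float:
    """Newman-Girvan modularity of a partition on a binary graph."""
    g = _graph_from_adjacency(adjacency)
    return float(g.modularity(list(np.asarray(labels, dtype=int))))


def consensus(per_threshold: list, eval_adjacency: np.ndarray,
              window: int = 5) -> ConsensusModel:
    """Combine per-threshold partitions into a single consensus model.

    Within each window of ``window`` adjacent densities, the solution with
    the highest mean NMI to the other window members is selected; the final
    partition is the selected candidate (the median-density solution is
    always a candidate) maximising modularity on ``eval_adjacency``.
    """
    T = len(per_threshold)
    if T < 3:
        raise ValueError("need >= 3 per-threshold solutions")
    if window > T:
        raise ValueError(f"window {window} exceeds number of solutions {T}")
    nmi = np.eye(T)
    for i in range(T):
        for j in range(i + 1, T):
            nmi[i, j] = nmi[j, i] = pairwise_nmi(per_threshold[i], per_threshold[j])
    candidates = set()
    for start in range(T - window + 1):
        block = nmi[start:start + window, start:start + window]
        means = (block.sum(axis=1) - 1.0) / (window - 1)
        candidates.add(start + int(np.argmax(means)))
    candidates.add(T // 2)  # median-density solution always competes
    scored = sorted((modularity(eval_adjacency, per_threshold[i].labels), -i)
                    for i in candidates)
    best_idx = -scored[-1][1]
    final = per_threshold[best_idx]
    final = Partition(labels=final.labels.copy(), threshold=final.threshold,
                      quality={**final.quality,
                               "consensus_modularity": scored[-1][0]})
    return ConsensusModel(final=final, per_threshold=list(per_threshold),
                          nmi_matrix=nmi, n_networks=final.n_communities,
                          selected_indices=sorted(candidates))


__all__ = ["Partition", "ConsensusModel", "detect_communities", "pairwise_nmi",
           "consensus", "modularity", "map_equation_codelength",
           "canonical_labels"]
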