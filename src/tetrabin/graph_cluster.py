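"""Two-stage similarity graph and deterministic label-propagation partitioning.

The graph is built in two stages. A *seed* graph admits only strong
composition (TNF) links — composition alone is unreliable, so only the top
tail of the sampled TNF score distribution qualifies. Then the admission
threshold on the composite score S is lowered stepwise toward ``min_s``;
each step admits newly qualifying edges and re-partitions the graph with a
modified label propagation algorithm (LPA), warm-started from the previous
labels.

Two modifications make LPA deterministic and neighborhood-size aware:

* nodes are visited in decreasing order of their strongest incident edge
  (ties broken by node id), instead of random order;
* a node picks the neighbor label whose edge scores combine to the smallest
  Fisher's-method p-value, treating 1 - S as the p-value of each link, so a
  few strong links can outweigh many weak ones and differently sized
  neighborhoods compete fairly.

Per-node degree is capped: each node retains only its ``max_edges``
highest-scoring offered links (a priority queue per node keeps memory O(N)
instead of the O(N^2) dense pair matrix), and an edge is *active* for
propagation only while both endpoints retain it, which keeps the adjacency
symmetric and the partition independent of edge insertion order.
"""

from __future__ import annotations

import heapq
import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import chi2

logger = logging.getLogger(__name__)

__all__ = [
    "BinningParams",
    "SparseGraph",
    "Labeling",
    "fisher_combined_p",
    "fisher_membership",
    "lpa_round",
    "build_seed_graph",
    "iterative_partition",
]

_LOG_FLOOR = 1e-12  # floor on 1 - S so Fisher's statistic stays finite at S = 1


@dataclass(frozen=True)
class BinningParams:
    """Tunable binning parameters.

    min_contig      smallest contig clustered directly (bp)
    max_p           percentile defining "strong" scores for graph admission
    min_s           minimum composite score (x100) of an edge kept for binning
    max_edges       per-node cap on retained links
    min_cls_size    smallest bin reported (bp); smaller bins dissolve
    min_cv          mean depth above which a sample counts as effective
    min_contig_recruit  smallest contig considered in the recruiting step (bp)
    schedule_steps  number of admission-threshold steps in stage two
    max_lpa_iters   sweep cap per propagation round
    cube_root_cor   combine TNF/ABD/COR by cube root instead of square root
    """

    min_contig: int = 2500
    max_p: float = 95.0
    min_s: float = 60.0
    max_edges: int = 200
    min_cls_size: int = 200_000
    min_cv: float = 1.0
    min_contig_recruit: int = 1000
    schedule_steps: int = 10
    max_lpa_iters: int = 50
    cube_root_cor: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.max_p <= 100):
            raise ValueError("max_p must be in (0, 100]")
        if not (0 <= self.min_s < 100):
            raise ValueError("min_s must be in [0, 100)")
        if self.max_edges < 1:
            raise ValueError("max_edges must be >= 1")


class SparseGraph:
    """Capped-degree scored graph over an ordered node universe.

    Each node retains at most ``k`` links — exactly its k best offers by
    (score desc, neighbor id asc) regardless of insertion order. An edge is
    active (returned by :meth:`neighbors`) only while both endpoints retain
    it, so eviction on either side removes it from the propagation graph.
    """

    def __init__(self, nodes: list, k: int):
        if k < 1:
            raise ValueError("k must be >= 1")
        self.k = k
        self.nodes = list(nodes)
        if len(set(self.nodes)) != len(self.nodes):
            raise ValueError("duplicate node ids")
        # lexicographic rank; heap key (score, -rank) evicts the lowest score
        # first and, on ties, the lexicographically larger neighbor
        self._rank = {u: r for r, u in enumerate(sorted(self.nodes))}
        self._store: dict = {u: {} for u in self.nodes}
        self._heap: dict = {u: [] for u in self.nodes}

    def _offer(self, u, v, s: float) -> None:
        store = self._store[u]
        if v in store:
            if s > store[v]:
                store[v] = s
                heapq.heappush(self._heap[u], (s, -self._rank[v], v))
            return
        store[v] = s
        heapq.heappush(self._heap[u], (s, -self._rank[v], v))
        heap = self._heap[u]
        while len(store) > self.k:
            s0, _, w = heapq.heappop(heap)
            if store.get(w) == s0:  # live entry
                del store[w]

    def topk_insert(self, u, v, s: float) -> None:
        """Offer edge (u, v) with score s to both endpoints."""
        if u == v:
            raise ValueError("self-loops are not allowed")
        if not (0.0 <= s <= 1.0):
            raise ValueError("edge score must lie in [0, 1]")
        self._offer(u, v, s)
        self._offer(v, u, s)

    def retained(self, u) -> dict:
        """The top-k links offered to u (neighbor -> score)."""
        return dict(self._store[u])

    def neighbors(self, u) -> dict:
        """Active links of u: retained by u *and* by the neighbor."""
        return {v: s for v, s in self._store[u].items() if u in self._store[v]}

    def degree(self, u) -> int:
        return len(self.neighbors(u))

    def n_active_edges(self) -> int:
        return sum(self.degree(u) for u in self.nodes) // 2


@dataclass
class Labeling:
    """Node -> bin label assignment evolving across propagation rounds."""

    label: dict
    round: int = 0

    @classmethod
    def singletons(cls, nodes: list) -> "Labeling":
        return cls(label={u: u for u in nodes}, round=0)


def fisher_combined_p(scores) -> float:
    """Fisher's-method combined p-value of edge scores S_1..S_m.

    Each link's p-value is 1 - S (strong scores, strong probabilities);
    X = -2 sum ln(1 - S_i) is referred to a chi-square with 2m degrees of
    freedom and the upper tail is the combined p.
    """
    s = np.asarray(scores, float)
    x = -2.0 * np.sum(np.log(np.maximum(1.0 - s, _LOG_FLOOR)))
    return float(chi2.sf(x, 2 * s.size))


def _fisher_logp(scores_by_label: dict) -> tuple[list, np.ndarray]:
    labels = sorted(scores_by_label)
    x = np.empty(len(labels))
    df = np.empty(len(labels))
    for i, lab in enumerate(labels):
        s = np.asarray(scores_by_label[lab], float)
        x[i] = -2.0 * np.sum(np.log(np.maximum(1.0 - s, _LOG_FLOOR)))
        df[i] = 2 * s.size
    return labels, chi2.logsf(x, df)


def fisher_membership(scores_by_label: dict, current_label=None):
    """Most likely membership of a node among candidate neighbor labels.

    Each candidate label's edge scores combine by Fisher's method; the label
    with the smallest combined p wins. Exact ties keep the node's current
    label when it is among the tied set, otherwise the lexicographically
    smallest tied label. Log survival values are compared directly so very
    strong neighborhoods (p underflowing double precision) still rank.
    """
    if not scores_by_label:
        raise ValueError("at least one neighbor label is required")
    labels, logp = _fisher_logp(scores_by_label)
    best = logp.min()
    tied = [lab for lab, lp in zip(labels, logp) if lp == best]
    if current_label is not None and current_label in tied:
        return current_label
    return tied[0]


def lpa_round(graph: SparseGraph, labeling: Labeling) -> Labeling:
    """One full propagation sweep.

    Nodes are visited in decreasing order of their strongest active edge
    (ties by node id); updates are applied immediately so later nodes in the
    sweep see earlier adoptions. Identical inputs give identical outputs.
    """
    strongest = {}
    neigh = {}
    for u in graph.nodes:
        nb = graph.neighbors(u)
        neigh[u] = nb
        strongest[u] = max(nb.values()) if nb else -np.inf
    order = sorted(graph.nodes, key=lambda u: (-strongest[u], u))

    labels = dict(labeling.label)
    for u in order:
        nb = neigh[u]
        if not nb:
            continue
        groups: dict = {}
        for v, s in nb.items():
            groups.setdefault(labels[v], []).append(s)
        labels[u] = fisher_membership(groups, current_label=labels[u])
    return Labeling(label=labels, round=labeling.round + 1)


def _propagate_to_fixed_point(
    graph: SparseGraph, labeling: Labeling, max_iters: int
) -> Labeling:
    for _ in range(max_iters):
        new = lpa_round(graph, labeling)
        if new.label == labeling.label:
            return new
        labeling = new
    logger.warning(
        "label propagation did not reach a fixed point within %d sweeps; "
        "accepting the current labels",
        max_iters,
    )
    return labeling


def build_seed_graph(
    node_ids: list,
    tnf_scores: np.ndarray,
    weights: np.ndarray,
    cutoff: float,
    params: BinningParams,
) -> SparseGraph:
    """Stage-one graph from strong composition links only.

    A pair qualifies when its raw TNF score reaches ``cutoff`` (the
    ``max_p``-th percentile of the sampled TNF score distribution, computed
    by the caller); the stored edge weight comes from ``weights`` (composite
    S where defined, normalized TNF for coverage-less pairs). Per-node
    degree is capped at ``max_edges``.
    """
    graph = SparseGraph(node_ids, params.max_edges)
    n = len(node_ids)
    if n == 0:
        return graph
    iu, ju = np.triu_indices(n, k=1)
    qualify = tnf_scores[iu, ju] >= cutoff
    iq, jq = iu[qualify], ju[qualify]
    admitted = 0
    for i, j in zip(iq, jq):
        w = weights[i, j]
        if np.isfinite(w):
            graph.topk_insert(node_ids[i], node_ids[j], float(np.clip(w, 0.0, 1.0)))
            admitted += 1
    if admitted == 0:
        logger.warning(
            "seed graph admitted zero edges; every contig starts as a singleton"
        )
    return graph


def iterative_partition(
    node_ids: list,
    seed_graph: SparseGraph,
    candidate_edges: list[tuple[float, object, object]],
    params: BinningParams,
    s_start: float | None = None,
) -> Labeling:
    """Stage-two iterative graph building and partitioning.

    Starting from singleton labels on the seed graph, the admission
    threshold is lowered from ``s_start`` (the ``max_p``-th percentile of
    the sampled composite-score distribution) to ``min_s``/100 over
    ``schedule_steps`` equal steps. Each step inserts the newly qualifying
    candidate edges (respecting per-node caps) and re-propagates labels to a
    fixed point, warm-started from the previous labels.

    The seed graph's links and the stage-two candidates are pooled and
    admitted together in decreasing score order: strong links bind contigs
    first, while labels are still forming, so a genome's contigs coalesce
    transitively before weaker (and potentially cross-genome) evidence
    arrives against already consolidated labels. ``candidate_edges`` must be
    (S, u, v) tuples; processing order is deterministic (descending score,
    then ids).
    """
    labeling = Labeling.singletons(node_ids)
    floor = params.min_s / 100.0

    pooled: dict[tuple, float] = {}
    for u in seed_graph.nodes:
        for v, s in seed_graph.neighbors(u).items():
            key = (u, v) if str(u) <= str(v) else (v, u)
            pooled[key] = max(pooled.get(key, 0.0), s)
    for s, u, v in candidate_edges:
        key = (u, v) if str(u) <= str(v) else (v, u)
        pooled[key] = max(pooled.get(key, 0.0), s)
    edges = sorted(
        ((s, u, v) for (u, v), s in pooled.items()),
        key=lambda e: (-e[0], str(e[1]), str(e[2])),
    )

    if s_start is None:
        s_start = edges[0][0] if edges else floor
    if s_start > floor:
        thresholds = np.linspace(s_start, floor, params.schedule_steps)
    else:
        thresholds = np.array([floor])

    graph = SparseGraph(node_ids, params.max_edges)
    pos = 0
    for thr in thresholds:
        added = 0
        while pos < len(edges) and edges[pos][0] >= thr:
            s, u, v = edges[pos]
            graph.topk_insert(u, v, float(np.clip(s, 0.0, 1.0)))
            pos += 1
            added += 1
        logger.info("threshold %.4f: admitted %d new edges", thr, added)
        labeling = _propagate_to_fixed_point(graph, labeling, params.max_lpa_iters)
    return labeling
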