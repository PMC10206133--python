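"""Per-target subgraph extraction: budgeted L-hop neighborhoods and
personalized-PageRank top-K neighborhoods.

The classifier is trained on one small subgraph per labeled residue
(decoupled, shallow-subgraph design): either the breadth-first
neighborhood up to depth L with a per-node fan-out budget, or the top-K
nodes by personalized PageRank score relative to the target with an L1
residual stopping threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional

import numpy as np

from .rin import ResidueNetwork

__all__ = [
    "LHopConfig",
    "PPRConfig",
    "Subgraph",
    "lhop_subgraph",
    "ppr_scores",
    "ppr_subgraph",
    "make_extractor",
]


@dataclass(frozen=True)
class LHopConfig:
    depth: int = 2
    budget: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth < 1 or self.budget < 1:
            raise ValueError("depth and budget must be positive")


@dataclass(frozen=True)
class PPRConfig:
    budget: int = 150  # number of neighbors kept (K)
    epsilon: float = 1e-5
    damping: float = 0.85
    max_iter: int = 1000
    weighted: bool = False

    def __post_init__(self) -> None:
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if not 0.0 < self.damping < 1.0:
            raise ValueError("damping must be in (0, 1)")
        if self.budget < 0:
            raise ValueError("budget must be non-negative")


@dataclass
class Subgraph:
    """Induced subgraph around one target node.

    `nodes` are global node ids (ascending); `edge_src`/`edge_dst` are
    local indices of the undirected induced edges (each pair stored once,
    src < dst); `target_index` locates the seed node in `nodes`.
    """

    nodes: np.ndarray
    edge_src: np.ndarray
    edge_dst: np.ndarray
    edge_weight: np.ndarray
    target_index: int

    def __post_init__(self) -> None:
        if not 0 <= self.target_index < len(self.nodes):
            raise ValueError("target index outside node set")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def target_node(self) -> int:
        return int(self.nodes[self.target_index])

    def to_tsv(self, nodes_path: str | Path, edges_path: str | Path) -> None:
        with open(nodes_path, "w") as fh:
            fh.write("local_id\tnode_id\tis_target\n")
            for i, nid in enumerate(self.nodes):
                fh.write(f"{i}\t{nid}\t{int(i == self.target_index)}\n")
        with open(edges_path, "w") as fh:
            fh.write("src\tdst\tweight\n")
            for s, d, w in zip(self.edge_src, self.edge_dst, self.edge_weight):
                fh.write(f"{s}\t{d}\t{w:.6g}\n")


def _induced(net: ResidueNetwork, node_ids: np.ndarray, target: int) -> Subgraph:
    nodes = np.array(sorted(int(n) for n in node_ids), dtype=int)
    local = {int(n): i for i, n in enumerate(nodes)}
    src, dst, wts = [], [], []
    node_set = set(local)
    for (u, v), (_, w) in net.edges.items():
        if u in node_set and v in node_set:
            a, b = local[u], local[v]
            if a > b:
                a, b = b, a
            src.append(a)
            dst.append(b)
            wts.append(w)
    order = np.lexsort((dst, src)) if src else np.empty(0, int)
    return Subgraph(
        nodes=nodes,
        edge_src=np.array(src, dtype=int)[order] if src else np.empty(0, int),
        edge_dst=np.array(dst, dtype=int)[order] if src else np.empty(0, int),
        edge_weight=np.array(wts, dtype=float)[order] if src else np.empty(0, float),
        target_index=local[int(target)],
    )


def lhop_subgraph(net: ResidueNetwork, target: int, cfg: LHopConfig) -> Subgraph:
    """Breadth-first neighborhood to depth L with per-node fan-out budget.

    When an expanded node has more neighbors than the budget b, b of them
    are sampled uniformly without replacement; randomness comes from a
    generator seeded by (cfg.seed, target), so repeat calls are identical.
    """
    if not 0 <= target < net.n_nodes:
        raise ValueError(f"invalid target node {target}")
    rng = np.random.default_rng([cfg.seed & 0x7FFFFFFF, target])
    adj = net.adjacency()
    visited = {int(target)}
    frontier = [int(target)]
    for _ in range(cfg.depth):
        next_frontier: list[int] = []
        for node in frontier:
            nbrs = adj[node]
            if len(nbrs) > cfg.budget:
                pick = rng.choice(len(nbrs), size=cfg.budget, replace=False)
                nbrs = nbrs[np.sort(pick)]
            for nb in nbrs:
                nb = int(nb)
                if nb not in visited:
                    visited.add(nb)
                    next_frontier.append(nb)
        frontier = next_frontier
        if not frontier:
            break
    return _induced(net, np.array(sorted(visited)), target)


def _transition_matrix(net: ResidueNetwork, weighted: bool) -> np.ndarray:
    """Column-stochastic random-walk matrix T with T[j, i] = P(i -> j).

    Dangling (isolated) nodes self-transition so probability is conserved.
    """
    n = net.n_nodes
    w = net.weight_matrix()
    if not weighted:
        w = (w > 0).astype(float)
    col_sums = w.sum(axis=0)
    T = np.zeros((n, n))
    for i in range(n):
        if col_sums[i] > 0:
            T[:, i] = w[:, i] / col_sums[i]
        else:
            T[i, i] = 1.0
    return T


def ppr_scores(net: ResidueNetwork, target: int, cfg: PPRConfig) -> np.ndarray:
    """Personalized PageRank with restart to the target node.

    Power iteration p <- (1-d) e + d T p, stopping when the L1 change
    falls below epsilon.  Scores are non-negative and sum to 1 (up to the
    stopping tolerance).
    """
    if not 0 <= target < net.n_nodes:
        raise ValueError(f"invalid target node {target}")
    n = net.n_nodes
    e = np.zeros(n)
    e[target] = 1.0
    if n == 1:
        return e
    T = _transition_matrix(net, cfg.weighted)
    p = e.copy()
    for _ in range(cfg.max_iter):
        p_new = (1.0 - cfg.damping) * e + cfg.damping * (T @ p)
        if np.abs(p_new - p).sum() < cfg.epsilon:
            p = p_new
            break
        p = p_new
    return p


def ppr_subgraph(net: ResidueNetwork, target: int, cfg: PPRConfig) -> Subgraph:
    """Target plus the K highest-PPR nodes (ties broken by ascending id)."""
    scores = ppr_scores(net, target, cfg)
    others = np.array(
        [i for i in range(net.n_nodes) if i != target and scores[i] > 0.0],
        dtype=int,
    )
    if cfg.budget == 0 or len(others) == 0:
        return _induced(net, np.array([target]), target)
    # sort by (-score, id): lexsort uses the last key as primary
    order = np.lexsort((others, -scores[others]))
    top = others[order[: cfg.budget]]
    nodes = np.concatenate([[target], top])
    return _induced(net, nodes, target)


def make_extractor(
    kind: str,
    lhop: Optional[LHopConfig] = None,
    ppr: Optional[PPRConfig] = None,
) -> Callable[[ResidueNetwork, int], Subgraph]:
    """Extractor callable for the training loop; kind in {"lhop", "ppr"}."""
    if kind == "lhop":
        cfg = lhop or LHopConfig()
        return lambda net, target: lhop_subgraph(net, target, cfg)
    if kind == "ppr":
        cfg = ppr or PPRConfig()
        return lambda net, target: ppr_subgraph(net, target, cfg)
    raise ValueError(f"unknown extractor kind {kind!r}")
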