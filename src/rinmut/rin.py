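"""Residue interaction network (RIN) construction and normalization.

Residues become nodes; two residues are linked when heavy atoms of one lie
within a distance cutoff of heavy atoms of the other.  Edges are typed by
the backbone/side-chain class of the contacting atoms (main-chain--main-chain,
main-chain--side-chain, side-chain--side-chain) and carry a raw contact
count.  `simplify` keeps a single maximal edge per residue pair and
`normalize_weights` min--max scales (optionally reverses) edge weights to
[0, 1].  Precomputed edge lists (e.g. probe-based contact networks) can be
imported instead of rebuilding from geometry.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .structure_io import NodeIndexMap, StructureModel

__all__ = [
    "ResidueEdge",
    "ResidueNetwork",
    "classify_atom",
    "find_contacts",
    "simplify",
    "normalize_weights",
    "import_rin",
]

MAIN_CHAIN_ATOMS = frozenset({"N", "CA", "C", "O", "OXT"})

EDGE_TYPES = ("mc_mc", "mc_sc", "sc_sc")
# Deterministic tie-break priority when equal-score edges of different
# types compete for the same residue pair (higher wins).
_TYPE_PRIORITY = {"sc_sc": 2, "mc_sc": 1, "mc_mc": 0}


@dataclass(frozen=True)
class ResidueEdge:
    u: int
    v: int
    edge_type: str
    raw_score: float

    def __post_init__(self) -> None:
        if self.u == self.v:
            raise ValueError("self-loop edge")
        if self.edge_type not in EDGE_TYPES:
            raise ValueError(f"unknown edge type {self.edge_type!r}")
        if self.raw_score < 0:
            raise ValueError("raw_score must be non-negative")


@dataclass
class ResidueNetwork:
    """Undirected residue graph; after simplify, one edge per node pair."""

    n_nodes: int
    # keyed by (u, v) with u < v -> (edge_type, weight)
    edges: dict[tuple[int, int], tuple[str, float]] = field(default_factory=dict)
    normalized: bool = False

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def edge_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(u, v, weight) arrays, u < v, sorted by (u, v)."""
        if not self.edges:
            return (np.empty(0, int), np.empty(0, int), np.empty(0, float))
        keys = sorted(self.edges)
        u = np.array([k[0] for k in keys], dtype=int)
        v = np.array([k[1] for k in keys], dtype=int)
        w = np.array([self.edges[k][1] for k in keys], dtype=float)
        return u, v, w

    def adjacency(self) -> list[np.ndarray]:
        """Sorted neighbor array per node."""
        nbrs: list[list[int]] = [[] for _ in range(self.n_nodes)]
        for (u, v) in self.edges:
            nbrs[u].append(v)
            nbrs[v].append(u)
        return [np.array(sorted(n), dtype=int) for n in nbrs]

    def degree(self) -> np.ndarray:
        deg = np.zeros(self.n_nodes, dtype=int)
        for (u, v) in self.edges:
            deg[u] += 1
            deg[v] += 1
        return deg

    def weight_matrix(self) -> "np.ndarray":
        """Dense symmetric weight matrix (small graphs / tests)."""
        w = np.zeros((self.n_nodes, self.n_nodes))
        for (u, v), (_, weight) in self.edges.items():
            w[u, v] = w[v, u] = weight
        return w

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("u\tv\ttype\tweight\n")
            for (u, v) in sorted(self.edges):
                etype, w = self.edges[(u, v)]
                fh.write(f"{u}\t{v}\t{etype}\t{w:.6g}\n")

    @classmethod
    def from_tsv(cls, path: str | Path, n_nodes: int) -> "ResidueNetwork":
        edges = {}
        with open(path) as fh:
            fh.readline()
            for line in fh:
                u, v, etype, w = line.split()
                a, b = sorted((int(u), int(v)))
                edges[(a, b)] = (etype, float(w))
        return cls(n_nodes=n_nodes, edges=edges)


def classify_atom(atom_name: str, residue_name: str = "") -> str:
    """Backbone atoms (N, CA, C, O, OXT) are main_chain; the rest side_chain."""
    return "main_chain" if atom_name.upper() in MAIN_CHAIN_ATOMS else "side_chain"


def _pair_type(class_a: str, class_b: str) -> str:
    n_side = (class_a == "side_chain") + (class_b == "side_chain")
    return ("mc_mc", "mc_sc", "sc_sc")[n_side]


def find_contacts(
    s: StructureModel,
    cutoff: float = 5.0,
    exclude_bonded_neighbors: int = 1,
    include_hydrogens: bool = False,
) -> list[ResidueEdge]:
    """Typed contact edges from heavy-atom proximity.

    An edge of type t between residues i and j scores the number of atom
    pairs (one atom from each residue, classes inducing t) within `cutoff`
    angstroms.  Residue pairs within `exclude_bonded_neighbors` legacy
    positions of each other are skipped: peptide-bonded neighbors are
    covalent, and the network models non-covalent contacts.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")

    coords = []
    res_index = []
    atom_class = []
    legacy = np.array([r.legacy_position for r in s.residues])
    for ri, res in enumerate(s.residues):
        atoms = res.atoms if include_hydrogens else res.heavy_atoms()
        for a in atoms:
            coords.append(a.xyz)
            res_index.append(ri)
            atom_class.append(classify_atom(a.name, res.name))
    if not coords:
        raise ValueError("structure has no atoms for contact search")
    xyz = np.asarray(coords)
    res_index = np.asarray(res_index)

    tree = cKDTree(xyz)
    pairs = tree.query_pairs(cutoff, output_type="ndarray")

    counts: dict[tuple[int, int, str], int] = {}
    for ai, aj in pairs:
        ri, rj = int(res_index[ai]), int(res_index[aj])
        if ri == rj or abs(legacy[ri] - legacy[rj]) <= exclude_bonded_neighbors:
            continue
        if ri > rj:
            ri, rj = rj, ri
        etype = _pair_type(atom_class[ai], atom_class[aj])
        key = (ri, rj, etype)
        counts[key] = counts.get(key, 0) + 1

    return [
        ResidueEdge(u=u, v=v, edge_type=t, raw_score=float(c))
        for (u, v, t), c in sorted(counts.items())
    ]


def simplify(edges: Iterable[ResidueEdge], n_nodes: int) -> ResidueNetwork:
    """Keep, per unordered residue pair, only the highest-scoring edge.

    Score ties across edge types are resolved by the fixed priority
    sc_sc > mc_sc > mc_mc.  Self-loops are dropped.
    """
    best: dict[tuple[int, int], tuple[str, float]] = {}
    for e in edges:
        if e.u == e.v:
            continue
        key = (e.u, e.v) if e.u < e.v else (e.v, e.u)
        prev = best.get(key)
        if (
            prev is None
            or e.raw_score > prev[1]
            or (e.raw_score == prev[1] and _TYPE_PRIORITY[e.edge_type] > _TYPE_PRIORITY[prev[0]])
        ):
            best[key] = (e.edge_type, e.raw_score)
    return ResidueNetwork(n_nodes=n_nodes, edges=best, normalized=False)


def normalize_weights(net: ResidueNetwork, reverse: bool = False) -> ResidueNetwork:
    """Min--max scale edge weights to [0, 1]; optionally reverse (w <- 1 - w).

    When every raw score is equal the scaled weight is defined as 1.0 for
    all edges (a constant network carries no ranking information).
    """
    if not net.edges:
        raise ValueError("cannot normalize an empty edge set")
    scores = np.array([w for (_, w) in net.edges.values()])
    lo, hi = scores.min(), scores.max()
    out = {}
    for key, (etype, w) in net.edges.items():
        scaled = 1.0 if hi == lo else (w - lo) / (hi - lo)
        if reverse:
            scaled = 1.0 - scaled
        out[key] = (etype, float(scaled))
    return ResidueNetwork(n_nodes=net.n_nodes, edges=out, normalized=True)


# RINerator-style node label, e.g. "A:123:_:ARG"
_RINERATOR_LABEL = re.compile(
    r"^(?P<chain>[^:]*):(?P<pos>-?\d+):(?P<ins>[^:]*):(?P<res>[^:]*)$"
)


def _parse_endpoint(token: str) -> int:
    """Legacy position from a plain integer or RINerator 'Chain:Pos:_:RES' label."""
    m = _RINERATOR_LABEL.match(token)
    if m:
        return int(m.group("pos"))
    return int(token)


def import_rin(
    path: str | Path, m: NodeIndexMap
) -> tuple[ResidueNetwork, int]:
    """Import a 3+-column edge list (TSV/SIF dialect) onto network nodes.

    Columns: residue_a, residue_b, score[, type].  Endpoints may be plain
    legacy positions or RINerator-style labels.  Edges with endpoints that
    do not resolve through the node map are skipped; the skip count is
    returned alongside the simplified network.
    """
    edges: list[ResidueEdge] = []
    skipped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: expected >= 3 columns")
            try:
                pos_a = _parse_endpoint(parts[0])
                pos_b = _parse_endpoint(parts[1])
                score = float(parts[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
            etype = parts[3] if len(parts) > 3 and parts[3] in EDGE_TYPES else "sc_sc"
            u = m.get(pos_a)
            v = m.get(pos_b)
            if u is None or v is None or u == v:
                skipped += 1
                continue
            edges.append(ResidueEdge(u=u, v=v, edge_type=etype, raw_score=score))
    net = simplify(edges, n_nodes=len(m))
    return net, skipped
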