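"""Coupling networks over residue positions.

A coupling network's nodes are residue positions and its edges the
top-ranked coupled pairs of one algorithm; composite maps intersect the
edge sets of several algorithms, and central nodes are the positions with
the most incident coupling edges.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

from .covariance import ScoreMatrix

Edge = tuple[int, int]


def _norm(edge: Edge) -> Edge:
    a, b = edge
    return (a, b) if a <= b else (b, a)


@dataclass
class CouplingNetwork:
    """Weighted undirected graph over residue positions.

    ``weights[edge]`` maps algorithm tag -> coupling score, so composite
    maps keep per-algorithm provenance.
    """

    edges: set[Edge]
    weights: dict[Edge, dict[str, float]]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.edges = {_norm(e) for e in self.edges}
        for a, b in self.edges:
            if a == b:
                raise ValueError(f"self-loop at {a}")
        self.weights = {_norm(e): dict(w) for e, w in self.weights.items()}

    @property
    def nodes(self) -> set[int]:
        return {v for e in self.edges for v in e}

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def degree(self) -> dict[int, int]:
        deg: dict[int, int] = {}
        for a, b in self.edges:
            deg[a] = deg.get(a, 0) + 1
            deg[b] = deg.get(b, 0) + 1
        return deg

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for e in sorted(self.edges):
            attrs = {f"w_{alg}": w for alg, w in self.weights.get(e, {}).items()}
            g.add_edge(*e, **attrs)
        return g

    def write_graphml(self, path: str | Path) -> None:
        nx.write_graphml(self.to_networkx(), str(path))

    def write_edge_tsv(self, path: str | Path) -> None:
        """SIF-style long edge list: pos_i, pos_j, algorithm, score."""
        lines = ["pos_i\tpos_j\talgorithm\tscore"]
        for e in sorted(self.edges):
            w = self.weights.get(e, {})
            if not w:
                lines.append(f"{e[0]}\t{e[1]}\t\t")
            for alg in sorted(w):
                lines.append(f"{e[0]}\t{e[1]}\t{alg}\t{w[alg]:.10g}")
        Path(path).write_text("\n".join(lines) + "\n")


def top_pairs(sm: ScoreMatrix, n: int = 200) -> CouplingNetwork:
    """Network of the ``n`` highest-scoring valid pairs.

    Ties are broken deterministically by (smaller position, larger
    position) ascending; if fewer than ``n`` pairs exist, all are taken and
    a warning is emitted.
    """
    pairs = list(sm.iter_pairs())
    if len(pairs) < n:
        warnings.warn(
            f"requested top {n} pairs but only {len(pairs)} available; taking all"
        )
        n = len(pairs)
    pairs.sort(key=lambda t: (-t[2], t[0], t[1]))
    chosen = pairs[:n]
    edges = {(a, b) for a, b, _ in chosen}
    weights = {(a, b): {sm.algorithm: s} for a, b, s in chosen}
    return CouplingNetwork(edges, weights,
                           {"algorithm": sm.algorithm, "top_n": n})


def central_nodes(net: CouplingNetwork, k: int = 3) -> list[int]:
    """Top-k nodes by degree, plus every node tying the k-th degree.

    Order: degree descending, then position ascending.
    """
    deg = net.degree()
    if not deg:
        raise ValueError("empty network has no central nodes")
    ranked = sorted(deg, key=lambda v: (-deg[v], v))
    if len(ranked) <= k:
        return ranked
    kth = deg[ranked[k - 1]]
    return [v for v in ranked if deg[v] >= kth]


def composite_intersection(nets: list[CouplingNetwork]) -> CouplingNetwork:
    """Edges present in every input network; per-algorithm weights merged."""
    if len(nets) < 2:
        raise ValueError("need at least 2 networks to intersect")
    common = set.intersection(*(n.edges for n in nets))
    weights: dict[Edge, dict[str, float]] = {}
    for e in common:
        merged: dict[str, float] = {}
        for net in nets:
            merged.update(net.weights.get(e, {}))
        weights[e] = merged
    prov = {"composite_of": [n.provenance.get("algorithm") for n in nets]}
    return CouplingNetwork(common, weights, prov)


def eigenvector_centrality(
    net: CouplingNetwork, tol: float = 1e-10, max_iter: int = 10000
) -> dict[int, float]:
    """Leading eigenvector of the unweighted adjacency matrix.

    Computed by power iteration on the largest connected component
    (Euclidean-normalised, all entries >= 0); nodes outside it score 0.
    """
    g = net.to_networkx()
    if g.number_of_nodes() == 0:
        raise ValueError("empty network")
    comps = sorted(nx.connected_components(g), key=lambda c: (-len(c), min(c)))
    giant = g.subgraph(comps[0])
    try:
        cent = nx.eigenvector_centrality(giant, max_iter=max_iter, tol=tol, weight=None)
    except nx.PowerIterationFailedConvergence as exc:
        raise RuntimeError(
            f"eigenvector centrality did not converge within {max_iter} iterations"
        ) from exc
    out = {int(v): 0.0 for v in g.nodes}
    norm = float(np.sqrt(sum(x * x for x in cent.values())))
    for v, x in cent.items():
        out[int(v)] = float(x) / norm
    return out


def edge_overlap_count(a: CouplingNetwork, b: CouplingNetwork) -> int:
    """Number of unordered edges shared by both networks."""
    return len(a.edges & b.edges)
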