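"""DEG-seeded protein-interaction networks and Markov clustering.

Networks are built from a STRING-style edge list: the core graph is the
induced subgraph of the DEG seeds over edges at or above the confidence
threshold, then optionally expanded by first- and second-order
interactors (iterated neighborhoods), ranking candidates by how many
connections they make into the current node set.  Partitioning uses the
Markov cluster algorithm on the column-stochastic weighted adjacency
with self-loops: alternate expansion (matrix squaring) and inflation
(elementwise power + renormalization) with entry pruning until the
matrix converges; clusters are the connected components of the attractor
support.  Modules are validated as custom gene sets with pre-ranked GSEA.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .enrichment import RankedList, gsea_prerank
from .io import GeneSetCollection

__all__ = [
    "build_seeded_network",
    "expand_network",
    "mcl",
    "ModulePartition",
    "validate_modules_gsea",
]


@dataclass
class ModulePartition:
    """Disjoint node modules plus the MCL parameters that produced them."""

    modules: dict[str, list[str]]
    inflation: float = 2.0
    prune: float = 1e-5
    converged: bool = True
    attractors: list[str] = field(default_factory=list)

    def labels(self) -> dict[str, str]:
        return {n: m for m, nodes in self.modules.items() for n in nodes}

    def __len__(self) -> int:
        return len(self.modules)


def _graph_from_edges(edges: pd.DataFrame, nodes: set[str] | None = None) -> nx.Graph:
    g = nx.Graph()
    for _, row in edges.iterrows():
        a, b = str(row["node1"]), str(row["node2"])
        if nodes is not None and (a not in nodes or b not in nodes):
            continue
        g.add_edge(a, b, weight=float(row["combined_score"]) / 1000.0)
    return g


def build_seeded_network(
    edges: pd.DataFrame, seeds: list[str], threshold: int = 400
) -> nx.Graph:
    """Induced subgraph on the seed genes over edges >= threshold."""
    present = set(seeds) & (set(edges["node1"].astype(str)) | set(edges["node2"].astype(str)))
    if not present:
        raise ValueError("no seed gene appears in the edge list")
    strong = edges.loc[edges["combined_score"] >= threshold]
    g = _graph_from_edges(strong, set(seeds))
    g.add_nodes_from(seeds)
    return g


def expand_network(
    graph: nx.Graph,
    edges: pd.DataFrame,
    order: int = 2,
    max_added: int | None = 50,
    threshold: int = 400,
) -> nx.Graph:
    """Add first- (and second-) order interactors of the current node set.

    Candidates are ranked by the number of connections into the current
    node set, ties broken by total edge score then by name, and truncated
    at ``max_added`` (applied to each expansion order).  All edges among
    retained nodes are included.
    """
    if order not in (1, 2):
        raise ValueError("order must be 1 or 2")
    strong = edges.loc[edges["combined_score"] >= threshold]
    full = _graph_from_edges(strong)
    current = set(graph.nodes)
    for _ in range(order):
        candidates: dict[str, tuple[int, float]] = {}
        for node in current:
            if node not in full:
                continue
            for nb in full.neighbors(node):
                if nb in current:
                    continue
                cnt, sc = candidates.get(nb, (0, 0.0))
                candidates[nb] = (cnt + 1, sc + full[node][nb]["weight"])
        ranked = sorted(
            candidates, key=lambda n: (-candidates[n][0], -candidates[n][1], n)
        )
        if max_added is not None:
            ranked = ranked[:max_added]
        current |= set(ranked)
    out = full.subgraph(current).copy()
    out.add_nodes_from(graph.nodes)
    return out


def mcl(
    graph: nx.Graph,
    inflation: float = 2.0,
    prune: float = 1e-5,
    max_iter: int = 100,
    tol: float = 1e-6,
) -> ModulePartition:
    """Markov clustering of a weighted undirected graph.

    Self-loops are added with weight equal to each node's maximum incident
    weight (weight 1 for isolated nodes), the matrix is column-normalized,
    and expansion/inflation alternate until the matrix change falls below
    ``tol``.  Clusters are read off as connected components of the
    attractor support, which are disjoint and cover every node.
    Non-convergence returns the current partition with a warning flag.
    """
    nodes = sorted(graph.nodes)
    if not nodes:
        raise ValueError("empty graph")
    n = len(nodes)
    index = {v: i for i, v in enumerate(nodes)}
    m = np.zeros((n, n))
    for a, b, data in graph.edges(data=True):
        w = float(data.get("weight", 1.0))
        i, j = index[a], index[b]
        if i != j:
            m[i, j] = m[j, i] = w
    loop = m.max(axis=0)
    loop[loop <= 0] = 1.0
    np.fill_diagonal(m, loop)
    m /= m.sum(axis=0, keepdims=True)
    converged = False
    for _ in range(max_iter):
        expanded = m @ m
        inflated = expanded**inflation
        inflated[inflated < prune] = 0.0
        colsum = inflated.sum(axis=0, keepdims=True)
        colsum[colsum == 0] = 1.0
        inflated /= colsum
        if np.abs(inflated - m).max() < tol:
            m = inflated
            converged = True
            break
        m = inflated
    if not converged:
        warnings.warn("MCL did not converge within max_iter; returning current state")
    # attractors: rows with surviving mass on their own diagonal; each
    # cluster is a connected component of the attractor support (a node
    # whose column feeds several attractor systems merges them, so the
    # components are disjoint and total by construction)
    attractor_rows = np.where(np.diag(m) > prune)[0]
    support = nx.Graph()
    support.add_nodes_from(range(n))
    for r in attractor_rows:
        for c in np.where(m[r] > prune)[0]:
            support.add_edge(int(r), int(c))
    # safety net for columns whose mass sits only on non-attractor rows
    for c in range(n):
        if support.degree[c] == 0:
            r = int(np.argmax(m[:, c]))
            if m[r, c] > prune and r != c:
                support.add_edge(r, c)
    comps = [sorted(comp) for comp in nx.connected_components(support)]
    clusters = [sorted(nodes[i] for i in comp) for comp in comps]
    modules = {
        f"M{k + 1}": members
        for k, members in enumerate(sorted(clusters, key=lambda ms: (-len(ms), ms[0])))
    }
    return ModulePartition(
        modules=modules,
        inflation=inflation,
        prune=prune,
        converged=converged,
        attractors=[nodes[r] for r in attractor_rows],
    )


def validate_modules_gsea(
    partition: ModulePartition,
    ranked_lists: dict[str, RankedList],
    n_perm: int = 1000,
    seed: int = 0,
    min_size: int = 5,
    max_size: int = 5000,
) -> pd.DataFrame:
    """GSEA of every module, as a custom gene set, against each ranked list."""
    sets = GeneSetCollection({m: list(g) for m, g in partition.modules.items() if g})
    frames = []
    for contrast, ranked in ranked_lists.items():
        res = gsea_prerank(
            ranked, sets, n_perm=n_perm, seed=seed, min_size=min_size, max_size=max_size
        )
        res.insert(0, "contrast", contrast)
        frames.append(res)
    if not frames:
        return pd.DataFrame(columns=["contrast", "set", "size", "es", "nes", "pvalue", "leading_edge", "fdr"])
    return pd.concat(frames, ignore_index=True)
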