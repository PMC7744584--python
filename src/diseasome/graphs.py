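"""Network construction and topology metrics.

Three network layers are built from the integrated association table:

* two bipartite gene-disease graphs (one for orphan diseases, one for
  complex diseases; dual-membership diseases enter both), with an edge
  wherever mutations in a gene are associated with a disorder;
* the diseasome projection: a disease-disease graph with an edge between
  two disorders that share at least ``min_shared`` associated genes, the
  edge weighted by the size of the shared gene set;
* (via :mod:`diseasome.enrichment`) a disease-pathway bipartite graph.

The per-node metric panel mirrors the NetworkAnalyzer conventions: degree,
eccentricity, closeness (reciprocal of the mean distance to reachable
nodes), radiality (closeness rescaled by the component diameter),
betweenness (Brandes' algorithm, normalized by (n-1)(n-2)/2 with n the
whole-graph node count even when the graph is disconnected), stress (raw
count of shortest paths passing through the node, over unordered pairs) and
the local clustering coefficient.  Betweenness and stress come out of a
single Brandes accumulation pass; networkx supplies the graph container,
components and clustering.

All node iteration is in sorted-id order so floating-point accumulations
are reproducible run to run.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, asdict
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .integrate import AssociationTable, Category

__all__ = [
    "NetworkSummary",
    "build_bipartite",
    "project_diseasome",
    "node_metrics",
    "network_summary",
    "top_nodes",
    "export_sif",
    "export_graphml",
    "write_metrics",
    "write_summary",
]

METRIC_KEYS = (
    "degree", "eccentricity", "closeness", "radiality",
    "stress", "betweenness", "clustering",
)


# ---------------------------------------------------------------------------
# Construction
# ---------------------------------------------------------------------------

def build_bipartite(table: AssociationTable, category: Category) -> nx.Graph:
    """Build the gene-disease bipartite graph for one disease category.

    Nodes are the diseases of ``category`` (diseases labeled BOTH are
    included on either side of the OD/CD split) plus every gene associated
    with them; one edge per unique (disease, gene) pair.  Diseases with no
    surviving genes never enter the graph.  The output is bipartite by
    construction and therefore triangle-free: every clustering coefficient
    is 0.
    """
    wanted = {category, Category.BOTH}
    g = nx.Graph()
    for row in table:
        if row.category not in wanted:
            continue
        g.add_node(row.disease_id, kind="disease",
                   category=row.category.value, name=row.disease_name)
        g.add_node(row.gene_symbol, kind="gene")
        g.add_edge(row.disease_id, row.gene_symbol)
    return g


def project_diseasome(table: AssociationTable, min_shared: int = 1) -> nx.Graph:
    """Project the disease-disease (diseasome) graph.

    Two diseases are linked iff they share at least ``min_shared``
    associated genes; the edge carries ``weight`` (shared-gene count) and
    ``genes`` (the shared symbols, sorted, pipe-joined for attribute
    portability).
    """
    if min_shared < 1:
        raise ValueError(f"min_shared must be >= 1, got {min_shared}")
    genes = table.disease_genes()
    cats = table.disease_categories()
    names = table.disease_names()

    g = nx.Graph()
    # index genes -> diseases to avoid the full quadratic sweep
    by_gene: dict[str, list[str]] = {}
    for did in sorted(genes):
        if genes[did]:
            g.add_node(did, kind="disease",
                       category=cats[did].value if did in cats else "",
                       name=names.get(did, ""))
            for symbol in genes[did]:
                by_gene.setdefault(symbol, []).append(did)

    shared: dict[tuple[str, str], int] = {}
    for dids in by_gene.values():
        for i, a in enumerate(dids):
            for b in dids[i + 1:]:
                key = (a, b) if a < b else (b, a)
                shared[key] = shared.get(key, 0) + 1
    for (a, b), count in shared.items():
        if count >= min_shared:
            common = sorted(genes[a] & genes[b])
            g.add_edge(a, b, weight=count, genes="|".join(common))
    return g


# ---------------------------------------------------------------------------
# Per-node metrics
# ---------------------------------------------------------------------------

def _bfs(g: nx.Graph, source, order_index: dict) -> tuple[list, dict, dict, dict]:
    """Single-source BFS returning (stack, predecessors, sigma, dist)."""
    sigma = {source: 1.0}
    dist = {source: 0}
    pred: dict = {source: []}
    stack = []
    queue = deque([source])
    while queue:
        v = queue.popleft()
        stack.append(v)
        for w in sorted(g[v], key=order_index.__getitem__):
            if w not in dist:
                dist[w] = dist[v] + 1
                sigma[w] = 0.0
                pred[w] = []
                queue.append(w)
            if dist[w] == dist[v] + 1:
                sigma[w] += sigma[v]
                pred[w].append(v)
    return stack, pred, sigma, dist


def node_metrics(g: nx.Graph) -> pd.DataFrame:
    """Compute the full per-node topology panel.

    Returns a DataFrame indexed by node id (sorted) with columns
    ``degree, eccentricity, closeness, radiality, stress, betweenness,
    clustering``.  Distances are BFS hop counts within connected
    components; isolated nodes get eccentricity 0, closeness 0 and
    radiality 1 (the component-diameter-0 limit).  Betweenness and stress
    count unordered source-target pairs; betweenness is normalized by
    (n-1)(n-2)/2 with n the total node count.
    """
    nodes = sorted(g.nodes)
    n = len(nodes)
    order_index = {v: i for i, v in enumerate(nodes)}
    betweenness = {v: 0.0 for v in nodes}
    stress = {v: 0.0 for v in nodes}
    ecc = {v: 0 for v in nodes}
    closeness = {v: 0.0 for v in nodes}
    mean_dist = {v: 0.0 for v in nodes}

    for s in nodes:
        stack, pred, sigma, dist = _bfs(g, s, order_index)
        # accumulation (Brandes); delta_b for betweenness, delta_s for stress
        delta_b = {v: 0.0 for v in stack}
        delta_s = {v: 0.0 for v in stack}
        for w in reversed(stack):
            for v in pred[w]:
                frac = sigma[v] / sigma[w]
                delta_b[v] += frac * (1.0 + delta_b[w])
                delta_s[v] += sigma[v] * (1.0 + delta_s[w] / sigma[w])
            if w != s:
                betweenness[w] += delta_b[w]
                stress[w] += delta_s[w]
        reach = len(dist) - 1
        if reach:
            total = sum(dist.values())
            ecc[s] = max(dist.values())
            mean_dist[s] = total / reach
            closeness[s] = reach / total

    # pair-wise quantities were accumulated once per endpoint
    scale = 2.0 / ((n - 1) * (n - 2)) if n > 2 else 0.0
    for v in nodes:
        betweenness[v] = betweenness[v] / 2.0 * scale
        stress[v] = stress[v] / 2.0

    # radiality needs each component's diameter
    radiality = {v: 1.0 for v in nodes}
    for comp in nx.connected_components(g):
        diam = max(ecc[v] for v in comp)
        if diam > 0:
            for v in comp:
                radiality[v] = (diam + 1.0 - mean_dist[v]) / diam

    clustering = nx.clustering(g)
    frame = pd.DataFrame(
        {
            "degree": [g.degree(v) for v in nodes],
            "eccentricity": [ecc[v] for v in nodes],
            "closeness": [closeness[v] for v in nodes],
            "radiality": [radiality[v] for v in nodes],
            "stress": [int(round(stress[v])) for v in nodes],
            "betweenness": [betweenness[v] for v in nodes],
            "clustering": [clustering[v] for v in nodes],
        },
        index=pd.Index(nodes, name="node"),
    )
    return frame


# ---------------------------------------------------------------------------
# Whole-network summary (Table-1-style panel)
# ---------------------------------------------------------------------------

@dataclass
class NetworkSummary:
    """Simple whole-network parameters.

    ``shortest_paths`` counts connected ordered (s, t) pairs, s != t, and
    ``characteristic_path_length`` averages the hop distance over exactly
    those pairs (disconnected pairs are excluded, not infinite).  The
    network clustering coefficient averages the local coefficient over
    nodes of degree >= 2.  Heterogeneity is the coefficient of variation of
    the degree distribution (population variance).
    """

    n_nodes: int
    n_edges: int
    clustering_coefficient: float
    connected_components: int
    diameter: int
    shortest_paths: int
    characteristic_path_length: float
    avg_neighbors: float
    density: float
    heterogeneity: float

    def as_dict(self) -> dict:
        return asdict(self)


def network_summary(g: nx.Graph) -> NetworkSummary:
    n = g.number_of_nodes()
    m = g.number_of_edges()
    if n == 0:
        return NetworkSummary(0, 0, 0.0, 0, 0, 0, 0.0, 0.0, 0.0, 0.0)

    nodes = sorted(g.nodes)
    diameter = 0
    total_dist = 0
    pairs = 0
    for s in nodes:
        dist = nx.single_source_shortest_path_length(g, s)
        if len(dist) > 1:
            diameter = max(diameter, max(dist.values()))
            total_dist += sum(dist.values())
            pairs += len(dist) - 1

    degrees = np.array([d for _, d in g.degree()], dtype=float)
    mean_deg = degrees.mean()
    heterogeneity = float(np.sqrt(degrees.var()) / mean_deg) if mean_deg > 0 else 0.0

    clustering = nx.clustering(g)
    eligible = [clustering[v] for v in nodes if g.degree(v) >= 2]
    cc = float(np.mean(eligible)) if eligible else 0.0

    return NetworkSummary(
        n_nodes=n,
        n_edges=m,
        clustering_coefficient=cc,
        connected_components=nx.number_connected_components(g),
        diameter=diameter,
        shortest_paths=pairs,
        characteristic_path_length=total_dist / pairs if pairs else 0.0,
        avg_neighbors=2.0 * m / n,
        density=2.0 * m / (n * (n - 1)) if n >= 2 else 0.0,
        heterogeneity=heterogeneity,
    )


def top_nodes(metrics: pd.DataFrame, key: str, k: int) -> list[tuple[str, float]]:
    """Top-k nodes by one metric, descending; ties broken by ascending id."""
    allowed = {"degree", "betweenness", "closeness", "stress", "radiality",
               "eccentricity"}
    if key not in allowed:
        raise ValueError(f"unknown metric {key!r}; expected one of {sorted(allowed)}")
    ranked = sorted(
        metrics[key].items(), key=lambda item: (-item[1], item[0])
    )
    return [(node, float(value)) for node, value in ranked[:k]]


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------

def export_sif(g: nx.Graph, path: str | Path, relation: str = "associates") -> None:
    """Write the edge list as SIF (``nodeA<TAB>relation<TAB>nodeB``)."""
    with open(path, "w", newline="") as fh:
        for a, b in sorted(tuple(sorted(e)) for e in g.edges):
            fh.write(f"{a}\t{relation}\t{b}\n")
        for v in sorted(nx.isolates(g)):
            fh.write(f"{v}\n")


def export_graphml(g: nx.Graph, path: str | Path) -> None:
    """Write GraphML with node attributes kind/category and edge weight/genes."""
    nx.write_graphml(g, str(path), infer_numeric_types=True)


def write_metrics(metrics: pd.DataFrame, path: str | Path) -> None:
    metrics.to_csv(path, sep="\t", float_format="%.10g")


def write_summary(summary: NetworkSummary, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        fh.write("parameter\tvalue\n")
        for key, value in summary.as_dict().items():
            if isinstance(value, float):
                fh.write(f"{key}\t{value:.6g}\n")
            else:
                fh.write(f"{key}\t{value}\n")
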