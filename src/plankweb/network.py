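"""Spearman co-occurrence networks, topology metrics and node-removal
(attack) fragmentation analysis.

Edges connect OTU pairs whose abundance profiles have |Spearman r| >= 0.8
at p < 0.01 (t approximation, average ranks for ties); low-abundance OTUs
(< 0.01 % mean relative abundance) are filtered first to suppress spurious
correlations.  Stability is probed by removing the highest-ranking nodes
under a strategy (betweenness centrality, degree, relative abundance, or
random) and tracking fragmentation

    f = log(CL) / log(N)

where CL is the number of connected components and N the number of nodes
remaining: f = 0 for a connected graph, f = 1 when fully atomised.
High-betweenness nodes ("gatekeepers") bridge network compartments, so
their removal fragments the graph disproportionately.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import spearmanr
from statsmodels.stats.multitest import multipletests

from .otu import OtuTable

ATTACK_STRATEGIES = ("betweenness", "degree", "abundance", "random")


@dataclass
class TopologyReport:
    n_nodes: int
    n_edges: int
    average_degree: float
    graph_density: float
    n_components: int
    diameter: int                     # of the largest component
    average_path_length: float        # over connected pairs
    average_clustering_coefficient: float
    modularity: float
    n_communities: int
    conventions: str = (
        "diameter on largest component; path length averaged over connected "
        "pairs; modularity from seeded Louvain communities on the unsigned graph"
    )

    def to_json_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items()}


@dataclass
class AttackTrajectory:
    strategy: str
    removed_nodes: list[str]
    f_values: list[float]             # length = removals + 1 (baseline first)
    n_remaining: list[int]
    n_components: list[int]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "step": range(len(self.f_values)),
                "removed_node": [""] + self.removed_nodes,
                "CL": self.n_components,
                "N": self.n_remaining,
                "f": self.f_values,
            }
        )


def filter_low_abundance(
    table: OtuTable, min_mean_rel_abundance: float = 1e-4
) -> OtuTable:
    """Drop OTUs whose mean relative abundance falls below the threshold
    (default 0.01 %)."""
    mean_rel = table.mean_relative_abundance()
    keep = mean_rel.index[mean_rel >= min_mean_rel_abundance]
    if len(keep) == 0:
        raise ValueError("abundance filter removed every OTU")
    return table.select_taxa(keep)


def spearman_edges(
    table: OtuTable,
    r_min: float = 0.8,
    p_max: float = 0.01,
    correction: str | None = None,
) -> pd.DataFrame:
    """All-pairs Spearman screen returning the edge list
    (source, target, r, p, sign).

    OTUs with constant abundance across samples have undefined rank
    correlation and yield no edges.  ``correction="fdr_bh"`` applies
    Benjamini-Hochberg to the pairwise p-values before thresholding.
    """
    if table.n_samples < 5:
        raise ValueError("need at least 5 samples for rank correlations")
    if table.n_samples < 10:
        import warnings

        warnings.warn("fewer than 10 samples: Spearman p-values are unreliable")
    data = table.counts.to_numpy().T.astype(float)
    variable = np.ptp(data, axis=0) > 0
    if variable.sum() < 2:
        raise ValueError("fewer than 2 OTUs with variable abundance")
    ids = np.asarray(table.taxon_ids)[variable]
    rho, pval = spearmanr(data[:, variable])
    if np.ndim(rho) == 0:  # scipy collapses the 2-variable case to scalars
        rho = np.array([[1.0, rho], [rho, 1.0]])
        pval = np.array([[0.0, pval], [pval, 0.0]])
    iu = np.triu_indices_from(rho, k=1)
    r, p = rho[iu], pval[iu]
    ok = np.isfinite(r)
    if correction == "fdr_bh":
        p_adj = np.full_like(p, np.nan)
        p_adj[ok] = multipletests(p[ok], method="fdr_bh")[1]
        p = p_adj
    elif correction not in (None, "none"):
        raise ValueError(f"unknown correction {correction!r}")
    keep = ok & (np.abs(r) >= r_min) & (p < p_max)
    src, dst = ids[iu[0][keep]], ids[iu[1][keep]]
    return pd.DataFrame(
        {
            "source": src,
            "target": dst,
            "r": r[keep],
            "p": p[keep],
            "sign": np.where(r[keep] >= 0, "positive", "negative"),
        }
    )


def infer_network(
    table: OtuTable,
    r_min: float = 0.8,
    p_max: float = 0.01,
    correction: str | None = None,
) -> nx.Graph:
    """Threshold-Spearman co-occurrence network.

    Nodes carry mean relative abundance and (when available) domain labels;
    isolated OTUs are not included.
    """
    edges = spearman_edges(table, r_min=r_min, p_max=p_max, correction=correction)
    graph = nx.Graph(r_min=r_min, p_max=p_max)
    mean_rel = table.mean_relative_abundance()
    for row in edges.itertuples(index=False):
        graph.add_edge(row.source, row.target, r=row.r, p=row.p, sign=row.sign)
    for node in graph.nodes:
        graph.nodes[node]["abundance"] = float(mean_rel[node])
        graph.nodes[node]["degree"] = graph.degree[node]
        if table.domain is not None:
            graph.nodes[node]["domain"] = table.domain[node]
    return graph


def topology(graph: nx.Graph, seed: int = 0) -> TopologyReport:
    """Topology metrics of a co-occurrence network."""
    if graph.number_of_nodes() == 0:
        raise ValueError("empty graph")
    n, e = graph.number_of_nodes(), graph.number_of_edges()
    components = list(nx.connected_components(graph))
    largest = graph.subgraph(max(components, key=len))
    # average shortest path over connected pairs only
    path_sum = n_pairs = 0
    for component in components:
        sub = graph.subgraph(component)
        for _, lengths in nx.all_pairs_shortest_path_length(sub):
            path_sum += sum(lengths.values())
        n_pairs += len(component) * (len(component) - 1)
    communities = nx.community.louvain_communities(graph, seed=seed)
    modularity = nx.community.modularity(graph, communities)
    return TopologyReport(
        n_nodes=n,
        n_edges=e,
        average_degree=2.0 * e / n,
        graph_density=nx.density(graph),
        n_components=len(components),
        diameter=int(nx.diameter(largest)) if largest.number_of_nodes() > 1 else 0,
        average_path_length=path_sum / n_pairs if n_pairs else 0.0,
        average_clustering_coefficient=nx.average_clustering(graph),
        modularity=float(modularity),
        n_communities=len(communities),
    )


def fragmentation(graph: nx.Graph) -> float:
    """f = log(CL)/log(N): 0 when connected, 1 when fully atomised.

    The ratio is independent of the logarithm base.  Undefined for fewer
    than two nodes.
    """
    n = graph.number_of_nodes()
    if n < 2:
        raise ValueError("fragmentation undefined for fewer than 2 nodes")
    cl = nx.number_connected_components(graph)
    return float(np.log(cl) / np.log(n))


def _rank_nodes(graph: nx.Graph, strategy: str, rng: np.random.Generator | None):
    """Nodes in removal order for a strategy; ties broken lexicographically."""
    if strategy == "random":
        nodes = sorted(graph.nodes)
        rng.shuffle(nodes)
        return nodes
    if strategy == "betweenness":
        score = nx.betweenness_centrality(graph, normalized=True)
    elif strategy == "degree":
        score = dict(graph.degree)
    elif strategy == "abundance":
        score = {v: graph.nodes[v].get("abundance", 0.0) for v in graph.nodes}
    else:
        raise ValueError(f"unknown strategy {strategy!r}; expected {ATTACK_STRATEGIES}")
    return sorted(graph.nodes, key=lambda v: (-score[v], v))


def attack(
    graph: nx.Graph,
    strategy: str = "betweenness",
    k: int = 10,
    adaptive: bool = False,
    seed: int = 0,
) -> AttackTrajectory:
    """Remove ``k`` top-ranked nodes and track fragmentation after each.

    ``adaptive=False`` ranks once on the intact network; ``adaptive=True``
    re-ranks after every removal.  Removed nodes stay out of the graph but
    nodes isolated by the removals remain, so f can reach 1.
    """
    n = graph.number_of_nodes()
    if k < 0 or k > n - 2:
        raise ValueError("k must leave at least 2 nodes in the network")
    rng = np.random.default_rng(seed)
    work = graph.copy()
    removed: list[str] = []
    f_values = [fragmentation(work)]
    n_remaining = [work.number_of_nodes()]
    n_components = [nx.number_connected_components(work)]
    order = None if adaptive else _rank_nodes(work, strategy, rng)
    for step in range(k):
        target = _rank_nodes(work, strategy, rng)[0] if adaptive else order[step]
        work.remove_node(target)
        removed.append(target)
        f_values.append(fragmentation(work))
        n_remaining.append(work.number_of_nodes())
        n_components.append(nx.number_connected_components(work))
    return AttackTrajectory(strategy, removed, f_values, n_remaining, n_components)


def gatekeeper_table(graph: nx.Graph, top_k: int = 20) -> dict:
    """Top-k node rankings by betweenness centrality, degree and abundance,
    plus pairwise overlap of the rankings.

    High-betweenness "gatekeepers" bridge compartments; the overlap block
    quantifies how far they coincide with high-degree or abundant taxa.
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("empty graph")
    betweenness = nx.betweenness_centrality(graph, normalized=True)
    frame = pd.DataFrame(
        {
            "taxon_id": list(graph.nodes),
            "betweenness": [betweenness[v] for v in graph.nodes],
            "degree": [graph.degree[v] for v in graph.nodes],
            "abundance": [graph.nodes[v].get("abundance", 0.0) for v in graph.nodes],
            "domain": [graph.nodes[v].get("domain", "") for v in graph.nodes],
        }
    )
    rankings = {
        key: frame.sort_values([key, "taxon_id"], ascending=[False, True], ignore_index=True).head(top_k)
        for key in ("betweenness", "degree", "abundance")
    }
    overlap = {}
    keys = list(rankings)
    for i, k1 in enumerate(keys):
        for k2 in keys[i + 1 :]:
            s1 = set(rankings[k1]["taxon_id"])
            s2 = set(rankings[k2]["taxon_id"])
            overlap[f"{k1}__{k2}"] = {
                "shared": len(s1 & s2),
                "jaccard": len(s1 & s2) / len(s1 | s2),
            }
    return {"rankings": rankings, "overlap": overlap, "top_k": top_k}


def write_edge_list(graph: nx.Graph, path) -> None:
    rows = [
        {"source": u, "target": v, **{k: d[k] for k in ("r", "p", "sign")}}
        for u, v, d in graph.edges(data=True)
    ]
    pd.DataFrame(rows, columns=["source", "target", "r", "p", "sign"]).to_csv(
        path, sep="\t", index=False
    )


def write_graphml(graph: nx.Graph, path) -> None:
    nx.write_graphml(graph, path)
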