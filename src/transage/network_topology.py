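"""Protein-interaction network centralities and gene-set path statistics.

Works on an undirected simple graph (gene symbols as nodes). Distances and
centralities are defined on the largest connected component. Per-node
statistics are degree, betweenness (normalized by (N-1)(N-2)/2, endpoints
excluded), closeness ((N-1) / sum of distances — the reciprocal form, so a
compact network scores near 1), and the local clustering coefficient.
Gene-set statistics are the characteristic path length within one set
(mean distance over unordered distinct pairs) or between two sets (mean
over cross pairs, identical-node pairs excluded).

Significance is assessed by permutation: random node sets of the same size
are drawn uniformly from the network and the observed statistic is
standardized against that null (z = (obs - mean) / sd).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class PPINetwork:
    """Undirected simple interaction graph; ``restricted`` marks a graph
    already reduced to its largest connected component."""

    graph: nx.Graph
    restricted: bool = False

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def nodes(self) -> list[str]:
        return list(self.graph.nodes)


def load_network(path) -> PPINetwork:
    """Read a two-column tab-delimited edge list. Lines starting with ``#``
    are comments; self-loops are dropped and duplicate/reversed edges
    merged (counts logged)."""
    g = nx.Graph()
    self_loops = 0
    dupes = 0
    opener = open
    if str(path).endswith(".gz"):
        import gzip

        opener = gzip.open
    with opener(path, "rt") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2 or not parts[0] or not parts[1]:
                raise ValueError(f"malformed edge at line {lineno}: {line!r}")
            u, v = parts[0].strip(), parts[1].strip()
            if u == v:
                self_loops += 1
                continue
            if g.has_edge(u, v):
                dupes += 1
                continue
            g.add_edge(u, v)
    logger.info(
        "load_network: %d nodes, %d edges (%d self-loops dropped, "
        "%d duplicates merged)",
        g.number_of_nodes(), g.number_of_edges(), self_loops, dupes,
    )
    return PPINetwork(graph=g)


def write_network(net: PPINetwork, path) -> None:
    with open(path, "w") as fh:
        for u, v in sorted(map(sorted, net.graph.edges())):
            fh.write(f"{u}\t{v}\n")


def largest_component(net: PPINetwork) -> PPINetwork:
    """Node-maximal connected subgraph; size ties go to the component with
    the lexicographically smallest member node."""
    if net.n_nodes == 0:
        raise ValueError("empty graph has no components")
    comps = sorted(
        nx.connected_components(net.graph),
        key=lambda c: (-len(c), min(str(x) for x in c)),
    )
    sub = net.graph.subgraph(comps[0]).copy()
    return PPINetwork(graph=sub, restricted=True)


def centralities(net: PPINetwork) -> pd.DataFrame:
    """Per-node degree, betweenness, closeness, clustering coefficient on a
    connected graph (run :func:`largest_component` first)."""
    g = net.graph
    if g.number_of_nodes() == 0:
        raise ValueError("empty graph")
    if not nx.is_connected(g):
        raise ValueError("graph is disconnected; restrict to largest_component first")
    nodes = list(g.nodes)
    deg = dict(g.degree())
    btw = nx.betweenness_centrality(g, normalized=True)
    clo = nx.closeness_centrality(g)
    clu = nx.clustering(g)
    return pd.DataFrame(
        {
            "degree": [deg[v] for v in nodes],
            "betweenness": [btw[v] for v in nodes],
            "closeness": [clo[v] for v in nodes],
            "clustering": [clu[v] for v in nodes],
        },
        index=pd.Index(nodes, name="node"),
    )


def _mapped(net: PPINetwork, genes) -> list:
    genes = list(dict.fromkeys(genes))  # dedupe, keep order
    mapped = [g for g in genes if net.graph.has_node(g)]
    dropped = len(genes) - len(mapped)
    if dropped:
        logger.info("dropped %d genes not present in the network", dropped)
    return mapped


def cpl_within(net: PPINetwork, genes) -> float:
    """Characteristic path length within a gene set: mean shortest-path
    distance over unordered distinct pairs of mapped genes."""
    mapped = _mapped(net, genes)
    if len(mapped) < 2:
        raise ValueError("need >= 2 genes mapped to the network")
    total = 0.0
    count = 0
    member = set(mapped)
    for i, src in enumerate(mapped):
        dist = nx.single_source_shortest_path_length(net.graph, src)
        for tgt in mapped[i + 1 :]:
            if tgt not in dist:
                raise ValueError(
                    "gene set spans disconnected parts; restrict to the "
                    "largest component"
                )
            total += dist[tgt]
            count += 1
    return total / count


def cpl_between(net: PPINetwork, genes_a, genes_b) -> float:
    """Characteristic path length between two gene sets: mean distance over
    all cross pairs, excluding pairs where both sides are the same node.
    Symmetric in its arguments."""
    a = _mapped(net, genes_a)
    b = set(_mapped(net, genes_b))
    if not a or not b:
        raise ValueError("both gene sets must map to the network")
    total = 0.0
    count = 0
    for src in a:
        dist = nx.single_source_shortest_path_length(net.graph, src)
        for tgt in b:
            if tgt == src:
                continue
            if tgt not in dist:
                raise ValueError(
                    "gene sets span disconnected parts; restrict to the "
                    "largest component"
                )
            total += dist[tgt]
            count += 1
    if count == 0:
        raise ValueError("no valid cross pairs after excluding self-pairs")
    return total / count


_SET_STATS = (
    "mean_degree",
    "mean_betweenness",
    "mean_closeness",
    "mean_clustering",
    "cpl_within",
    "cpl_between",
)


@dataclass
class GroupTopologyReport:
    statistic: str
    observed: float
    perm_mean: float
    perm_sd: float
    z: float  # NaN when perm_sd == 0
    permuted: np.ndarray
    n_perm: int
    seed: int
    set_sizes: tuple[int, ...]


def permutation_z(
    net: PPINetwork,
    statistic: str,
    genes,
    genes2=None,
    n_perm: int = 1000,
    seed: int = 0,
    background=None,
) -> GroupTopologyReport:
    """Standardize a gene-set statistic against random same-size node sets.

    Random sets are drawn uniformly without replacement from all network
    nodes (or from ``background`` when given). ``cpl_between`` requires
    ``genes2``; all other statistics use ``genes`` alone. A zero permutation
    SD yields z = NaN with a warning.
    """
    if statistic not in _SET_STATS:
        raise ValueError(f"unknown statistic {statistic!r}; choose from {_SET_STATS}")
    if n_perm < 2:
        raise ValueError("n_perm must be >= 2")
    pool = list(background) if background is not None else net.nodes()
    pool = [v for v in pool if net.graph.has_node(v)]

    cent = None
    if statistic.startswith("mean_"):
        cent = centralities(net)[statistic.removeprefix("mean_")]

    def evaluate(set_a, set_b):
        if statistic == "cpl_within":
            return cpl_within(net, set_a)
        if statistic == "cpl_between":
            return cpl_between(net, set_a, set_b)
        mapped = _mapped(net, set_a)
        if not mapped:
            raise ValueError("no genes mapped to the network")
        return float(cent.loc[mapped].mean())

    mapped_a = _mapped(net, genes)
    mapped_b = _mapped(net, genes2) if genes2 is not None else None
    if statistic == "cpl_between" and mapped_b is None:
        raise ValueError("cpl_between needs a second gene set")
    observed = evaluate(mapped_a, mapped_b)

    rng = np.random.default_rng(seed)
    permuted = np.empty(n_perm)
    for r in range(n_perm):
        ra = list(rng.choice(pool, size=len(mapped_a), replace=False))
        rb = (
            list(rng.choice(pool, size=len(mapped_b), replace=False))
            if mapped_b is not None
            else None
        )
        permuted[r] = evaluate(ra, rb)
    perm_mean = float(permuted.mean())
    perm_sd = float(permuted.std(ddof=1))
    if perm_sd == 0.0:
        warnings.warn(
            "permutation distribution has zero variance; z is undefined",
            stacklevel=2,
        )
        z = float("nan")
    else:
        z = (observed - perm_mean) / perm_sd
    sizes = (len(mapped_a),) if mapped_b is None else (len(mapped_a), len(mapped_b))
    return GroupTopologyReport(
        statistic=statistic,
        observed=observed,
        perm_mean=perm_mean,
        perm_sd=perm_sd,
        z=z,
        permuted=permuted,
        n_perm=n_perm,
        seed=seed,
        set_sizes=sizes,
    )
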