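"""The mutation co-occurrence network and its 8 graph features per allele.

Every mutation observed in a cohort is a node; two mutations are linked
when at least one patient carries them as an allelic pair, with the edge
weight counting those patients and a per-phenotype breakdown of the same
count.  Homozygous genotypes are recorded as self-loops: they contribute
to edge-weight totals and to hub scoring but are excluded from paths and
centralities (a mutation is not its own network neighbour).

Per mutation the feature vector is::

    [dist to cPKU hub, dist to mPKU hub, dist to MHP hub,
     degree, betweenness, PageRank, closeness, eccentricity]

Distances are unweighted shortest-path hop counts; an unreachable hub is
replaced by a finite sentinel one hop beyond the largest finite
eccentricity in the network, so no feature vector ever carries an
undefined value.  Genotype vectors concatenate the two allele vectors in
canonical order (8 + 8 = 16).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .cases import CaseDatabase, Genotype, Zygosity
from .hgvs import Mutation
from .phenotype import Phenotype

__all__ = ["MutationNetwork", "HubSet", "NodeNotInNetworkError", "build_network",
           "node_attributes", "find_hub_nodes", "hub_distances",
           "encode_genotype_graph", "connectivity_report", "ComponentReport",
           "write_graphml", "write_edge_list",
           "GRAPH_DIMS_PER_MUTATION", "NODE_ATTRIBUTE_NAMES"]

GRAPH_DIMS_PER_MUTATION = 8
NODE_ATTRIBUTE_NAMES = ("degree", "betweenness", "pagerank", "closeness", "eccentricity")

PAGERANK_DAMPING = 0.85
# Converge well past the 1e-9 agreement guaranteed against power iteration
# (the solver's stopping rule is on the summed error over nodes).
PAGERANK_TOL = 1e-12


class NodeNotInNetworkError(KeyError):
    """A mutation absent from the co-occurrence network."""


@dataclass(frozen=True)
class HubSet:
    """The classification-centre mutation for each phenotype class."""

    hub_cpku: Mutation
    hub_mpku: Mutation
    hub_mhp: Mutation

    def as_dict(self) -> dict[Phenotype, Mutation]:
        return {Phenotype.CPKU: self.hub_cpku,
                Phenotype.MPKU: self.hub_mpku,
                Phenotype.MHP: self.hub_mhp}


@dataclass
class MutationNetwork:
    """Weighted co-occurrence graph plus homozygous self-loop bookkeeping.

    ``graph`` is a simple undirected graph (no self-loops); each edge has
    a ``weight`` (patient count) and ``counts`` (per-phenotype patient
    counts).  ``self_loops`` holds the same bookkeeping for homozygous
    genotypes, keyed by mutation.
    """

    graph: nx.Graph
    self_loops: dict[Mutation, dict] = field(default_factory=dict)
    _cache: dict = field(default_factory=dict, repr=False)

    @property
    def nodes(self) -> list[Mutation]:
        return sorted(self.graph.nodes, key=Mutation.sort_key)

    def __contains__(self, m: Mutation) -> bool:
        return m in self.graph

    def total_edge_weight(self) -> int:
        """Sum of all co-occurrence counts; equals the patient count."""
        w = sum(d["weight"] for _, _, d in self.graph.edges(data=True))
        return w + sum(d["weight"] for d in self.self_loops.values())

    def phenotype_weighted_degree(self, m: Mutation, phen: Phenotype) -> int:
        """Patients of class ``phen`` whose genotype involves ``m``."""
        total = sum(d["counts"][phen] for _, _, d in self.graph.edges(m, data=True))
        if m in self.self_loops:
            total += self.self_loops[m]["counts"][phen]
        return total

    # -- cached whole-graph centralities ------------------------------------

    def _centrality(self, name: str) -> dict[Mutation, float]:
        if name not in self._cache:
            g = self.graph
            if name == "degree":
                self._cache[name] = {n: float(g.degree(n)) for n in g}
            elif name == "betweenness":
                self._cache[name] = nx.betweenness_centrality(g, normalized=True)
            elif name == "pagerank":
                self._cache[name] = nx.pagerank(
                    g, alpha=PAGERANK_DAMPING, tol=PAGERANK_TOL, max_iter=1000,
                    weight="weight",
                )
            elif name == "closeness":
                self._cache[name] = nx.closeness_centrality(g, wf_improved=False)
            elif name == "eccentricity":
                ecc: dict[Mutation, float] = {}
                for comp in nx.connected_components(g):
                    sub = g.subgraph(comp)
                    ecc.update({n: float(e) for n, e in nx.eccentricity(sub).items()})
                self._cache[name] = ecc
            else:  # pragma: no cover
                raise KeyError(name)
        return self._cache[name]

    def disconnection_sentinel(self) -> float:
        """One hop farther than the largest finite eccentricity."""
        ecc = self._centrality("eccentricity")
        return (max(ecc.values()) if ecc else 0.0) + 1.0


def build_network(db: CaseDatabase) -> MutationNetwork:
    """Build the co-occurrence network from a case database.

    One edge per distinct compound-heterozygous genotype with weight equal
    to its patient count; homozygous genotypes become self-loop entries.
    The node set equals the database's mutation index, and the build is
    invariant to the order of the records.
    """
    if len(db) == 0:
        raise ValueError("cannot build a network from an empty case database")
    g = nx.Graph()
    g.add_nodes_from(db.mutation_index)
    loops: dict[Mutation, dict] = {}
    for rec in db.records:
        a, b = rec.genotype.mutations
        if rec.genotype.zygosity is Zygosity.HOMOZYGOUS:
            entry = loops.setdefault(
                a, {"weight": 0, "counts": {p: 0 for p in Phenotype}})
            entry["weight"] += 1
            entry["counts"][rec.phenotype] += 1
        else:
            if not g.has_edge(a, b):
                g.add_edge(a, b, weight=0, counts={p: 0 for p in Phenotype})
            g[a][b]["weight"] += 1
            g[a][b]["counts"][rec.phenotype] += 1
    return MutationNetwork(graph=g, self_loops=loops)


def node_attributes(net: MutationNetwork, m: Mutation) -> np.ndarray:
    """The 5 node attributes of a mutation: degree, betweenness, PageRank,
    closeness and eccentricity.

    Degree counts distinct neighbours (unweighted, self-loops excluded);
    betweenness is normalised node betweenness over the whole graph;
    PageRank uses damping 0.85 on the weighted simple graph; closeness
    and eccentricity are computed within the node's connected component.
    """
    if m not in net:
        raise NodeNotInNetworkError(m.label if isinstance(m, Mutation) else m)
    return np.array([net._centrality(name)[m] for name in NODE_ATTRIBUTE_NAMES])


def find_hub_nodes(net: MutationNetwork,
                   override: HubSet | None = None) -> HubSet:
    """Identify one hub mutation per phenotype class.

    The hub for class c maximises the phenotype-weighted degree: the
    number of class-c patients whose genotype involves the mutation.
    Ties break by total degree, then by canonical mutation order.  An
    ``override`` pins the hubs explicitly (after checking membership).
    """
    if override is not None:
        for hub in override.as_dict().values():
            if hub not in net:
                raise NodeNotInNetworkError(hub.label)
        return override

    chosen: dict[Phenotype, Mutation] = {}
    nodes = net.nodes
    for phen in Phenotype:
        scored = [
            (net.phenotype_weighted_degree(m, phen), net.graph.degree(m), m)
            for m in nodes
        ]
        best_score = max(s for s, _, _ in scored)
        if best_score == 0:
            raise ValueError(f"no cases of class {phen.value}: cannot place a hub")
        candidates = [t for t in scored if t[0] == best_score]
        best_degree = max(d for _, d, _ in candidates)
        candidates = [m for _, d, m in candidates if d == best_degree]
        chosen[phen] = min(candidates, key=Mutation.sort_key)
    return HubSet(hub_cpku=chosen[Phenotype.CPKU],
                  hub_mpku=chosen[Phenotype.MPKU],
                  hub_mhp=chosen[Phenotype.MHP])


def hub_distances(net: MutationNetwork, m: Mutation, hubs: HubSet) -> np.ndarray:
    """Unweighted shortest-path hop counts from ``m`` to the three hubs.

    Hubs unreachable from ``m`` get the disconnection sentinel (largest
    finite eccentricity + 1); a hub's distance to itself is 0.
    """
    if m not in net:
        raise NodeNotInNetworkError(m.label)
    sentinel = net.disconnection_sentinel()
    lengths = nx.single_source_shortest_path_length(net.graph, m)
    return np.array([
        float(lengths.get(hub, sentinel))
        for hub in (hubs.hub_cpku, hubs.hub_mpku, hubs.hub_mhp)
    ])


def _mutation_graph_vector(net: MutationNetwork, m: Mutation, hubs: HubSet,
                           strict: bool) -> np.ndarray:
    if m not in net:
        if strict:
            raise NodeNotInNetworkError(
                f"{m.label} not in the co-occurrence network; add cases or "
                "use lenient mode"
            )
        sentinel = net.disconnection_sentinel()
        return np.array([sentinel, sentinel, sentinel, 0.0, 0.0, 0.0, 0.0, 0.0])
    vec = np.concatenate([hub_distances(net, m, hubs), node_attributes(net, m)])
    assert vec.shape == (GRAPH_DIMS_PER_MUTATION,) and np.all(np.isfinite(vec))
    return vec


def encode_genotype_graph(g: Genotype, net: MutationNetwork, hubs: HubSet,
                          strict: bool = True) -> np.ndarray:
    """Concatenate the two allele 8-vectors in canonical order (16 dims).

    In lenient mode an unseen mutation yields disconnection sentinels for
    the hub distances and zero centralities rather than an error.
    """
    return np.concatenate([
        _mutation_graph_vector(net, g.mut_a, hubs, strict),
        _mutation_graph_vector(net, g.mut_b, hubs, strict),
    ])


def incident_edge_betweenness(net: MutationNetwork) -> dict[Mutation, float]:
    """Alternative per-mutation centrality: the sum of edge betweenness
    over a node's incident edges.

    Provided for comparison with the default (node betweenness); both
    read on how often a mutation participates in shortest paths.
    """
    edge_bet = nx.edge_betweenness_centrality(net.graph, normalized=True)
    out: dict[Mutation, float] = {m: 0.0 for m in net.graph.nodes}
    for (u, v), b in edge_bet.items():
        out[u] += b
        out[v] += b
    return out


@dataclass
class ComponentReport:
    """Connected components of the network, largest first."""

    components: list[list[Mutation]]

    @property
    def sizes(self) -> list[int]:
        return [len(c) for c in self.components]

    @property
    def isolated(self) -> list[Mutation]:
        return [c[0] for c in self.components if len(c) == 1]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"component": i, "size": len(comp), "mutation": m.label}
            for i, comp in enumerate(self.components, start=1)
            for m in comp
        ]
        return pd.DataFrame(rows, columns=["component", "size", "mutation"])


def connectivity_report(net: MutationNetwork) -> ComponentReport:
    comps = [sorted(c, key=Mutation.sort_key)
             for c in nx.connected_components(net.graph)]
    comps.sort(key=lambda c: (-len(c), c[0].sort_key()))
    return ComponentReport(components=comps)


def write_graphml(net: MutationNetwork, path: str | Path) -> None:
    """Export the network with HGVS string node labels (GraphML)."""
    out = nx.Graph()
    for m in net.graph.nodes:
        out.add_node(m.label)
    for a, b, d in net.graph.edges(data=True):
        attrs = {"weight": d["weight"]}
        attrs.update({f"n_{p.value}": d["counts"][p] for p in Phenotype})
        out.add_edge(a.label, b.label, **attrs)
    for m, d in net.self_loops.items():
        attrs = {"weight": d["weight"]}
        attrs.update({f"n_{p.value}": d["counts"][p] for p in Phenotype})
        out.add_edge(m.label, m.label, **attrs)
    nx.write_graphml(out, path)


def write_edge_list(net: MutationNetwork, path: str | Path) -> None:
    """Export a weighted edge list TSV including self-loops."""
    rows = []
    for a, b, d in sorted(
        net.graph.edges(data=True),
        key=lambda e: (e[0].sort_key(), e[1].sort_key()),
    ):
        x, y = sorted((a, b), key=Mutation.sort_key)
        rows.append({
            "mutation_1": x.label, "mutation_2": y.label, "weight": d["weight"],
            **{f"n_{p.value}": d["counts"][p] for p in Phenotype},
        })
    for m in sorted(net.self_loops, key=Mutation.sort_key):
        d = net.self_loops[m]
        rows.append({
            "mutation_1": m.label, "mutation_2": m.label, "weight": d["weight"],
            **{f"n_{p.value}": d["counts"][p] for p in Phenotype},
        })
    cols = ["mutation_1", "mutation_2", "weight",
            *[f"n_{p.value}" for p in Phenotype]]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)
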