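"""Community-wide KO-metabolite network and betweenness centrality.

The bipartite graph links every prevalence-filtered gene family (KO) to
the non-cofactor reactants and products of its reactions. Two one-mode
projections are analyzed: KOs as nodes connected through shared
compounds, and the "inverted" view with compounds as nodes connected
through shared KOs. Shortest-path betweenness centrality on the
unweighted projections ranks genes and metabolites by their importance
to community-wide metabolism.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .metabolites import half_min_positive
from .tables import OmicsTable, ReactionUniverse, ValidationError

__all__ = [
    "CommunityNetwork",
    "CentralityReport",
    "build_network",
    "attach_activity",
    "project_ko",
    "project_compound",
    "betweenness",
    "subnetwork_report",
    "SubnetworkSummary",
    "write_graphml",
]


@dataclass
class CommunityNetwork:
    """Bipartite KO/compound graph plus provenance.

    ``graph`` nodes carry ``kind`` ("ko" or "compound"); edges carry
    ``roles`` (sorted "product"/"reactant" string) and ``reactions``.
    KO nodes gain an ``activity`` attribute (mean MT / mean MG ratio of
    normalized abundances) after :func:`attach_activity`.
    """

    graph: nx.Graph
    prevalence: float
    cofactors: frozenset[str]
    provenance: dict = field(default_factory=dict)

    @property
    def ko_nodes(self) -> list[str]:
        return sorted(n for n, d in self.graph.nodes(data=True) if d["kind"] == "ko")

    @property
    def compound_nodes(self) -> list[str]:
        return sorted(n for n, d in self.graph.nodes(data=True) if d["kind"] == "compound")


def build_network(
    u: ReactionUniverse,
    funMG: OmicsTable,
    prevalence: float = 0.5,
    cofactors: frozenset[str] | None = None,
) -> CommunityNetwork:
    """Build the bipartite KO-compound graph.

    A KO is kept iff it is nonzero in at least ``prevalence`` of the
    funMG samples (>= semantics: exactly 50% passes a 0.5 threshold).
    Edges go from each kept KO to the non-cofactor reactants and
    products of its reactions; compounds left without edges are dropped.
    funMG features absent from the universe are warned about and
    ignored.
    """
    if not (0.0 < prevalence <= 1.0):
        raise ValidationError(f"prevalence must be in (0, 1], got {prevalence}")
    if cofactors is None:
        cofactors = frozenset(u.cofactors)
    else:
        cofactors = frozenset(cofactors)

    known = set(u.ko_reactions)
    extra = sorted(set(funMG.features) - known)
    if extra:
        warnings.warn(
            f"{len(extra)} funMG feature(s) absent from reaction universe "
            f"(e.g. {extra[:3]}); dropped", stacklevel=2,
        )
    n_samples = funMG.data.shape[1]
    frac = (funMG.data > 0).sum(axis=1) / n_samples
    kept = sorted(k for k in funMG.features if k in known and frac[k] >= prevalence)

    g = nx.Graph()
    for ko in kept:
        compounds_touched = False
        for rxn in sorted(u.ko_reactions[ko]):
            lhs, rhs = u.reaction_sides[rxn]
            for cid, role in itertools.chain(
                ((c, "reactant") for c in sorted(lhs)),
                ((c, "product") for c in sorted(rhs)),
            ):
                if cid in cofactors:
                    continue
                compounds_touched = True
                if not g.has_node(ko):
                    g.add_node(ko, kind="ko")
                if not g.has_node(cid):
                    g.add_node(cid, kind="compound", cofactor=False)
                if g.has_edge(ko, cid):
                    roles = set(g[ko][cid]["roles"].split("|"))
                    roles.add(role)
                    g[ko][cid]["roles"] = "|".join(sorted(roles))
                    rxns = set(g[ko][cid]["reactions"].split("|"))
                    rxns.add(rxn)
                    g[ko][cid]["reactions"] = "|".join(sorted(rxns))
                else:
                    g.add_edge(ko, cid, roles=role, reactions=rxn)
        if not compounds_touched and not g.has_node(ko):
            # KO whose reactions touch only cofactors: keep as isolated KO node
            g.add_node(ko, kind="ko")
    return CommunityNetwork(
        graph=g, prevalence=prevalence, cofactors=cofactors,
        provenance={"n_ko_kept": len(kept), "n_samples": n_samples},
    )


def attach_activity(
    net: CommunityNetwork, funMT: OmicsTable, funMG: OmicsTable
) -> CommunityNetwork:
    """Annotate KO nodes with the transcription-to-gene-abundance ratio
    (mean normalized MT + eps) / (mean normalized MG + eps), the per-KO
    activity proxy. eps is half the smallest positive value across both
    layers, keeping ratios positive and finite."""
    for name, t in (("funMT", funMT), ("funMG", funMG)):
        if not t.normalized:
            raise ValidationError(f"{name} must be sum-normalized")
    eps = half_min_positive(funMT.data.to_numpy(), funMG.data.to_numpy())
    for ko in net.ko_nodes:
        if ko in funMT.data.index and ko in funMG.data.index:
            mt = float(funMT.data.loc[ko].mean())
            mg = float(funMG.data.loc[ko].mean())
            net.graph.nodes[ko]["activity"] = (mt + eps) / (mg + eps)
        else:
            net.graph.nodes[ko]["activity_missing"] = True
    net.provenance["activity_eps"] = eps
    return net


def _project(net: CommunityNetwork, node_kind: str, via_kind: str) -> nx.Graph:
    g = nx.Graph()
    nodes = [n for n, d in net.graph.nodes(data=True) if d["kind"] == node_kind]
    g.add_nodes_from(sorted(nodes))
    for via in sorted(n for n, d in net.graph.nodes(data=True) if d["kind"] == via_kind):
        neighbors = sorted(net.graph.neighbors(via))
        for a, b in itertools.combinations(neighbors, 2):
            if g.has_edge(a, b):
                labels = set(g[a][b]["shared"].split("|"))
                labels.add(via)
                g[a][b]["shared"] = "|".join(sorted(labels))
            else:
                g.add_edge(a, b, shared=via)
    return g


def project_ko(net: CommunityNetwork) -> nx.Graph:
    """One-mode projection onto KOs: edge iff two KOs share >= 1
    non-cofactor compound; edge attribute ``shared`` lists the shared
    compound ids."""
    return _project(net, "ko", "compound")


def project_compound(net: CommunityNetwork) -> nx.Graph:
    """Inverted projection: compounds as nodes, connected when >= 1 KO
    links both; edge attribute lists the shared KO ids. Cofactors never
    appear (they were removed at construction)."""
    return _project(net, "compound", "ko")


@dataclass
class CentralityReport:
    """Per-node betweenness, normalized (pair-fraction, in [0, 1]) and raw
    (path-pair count scale)."""

    table: pd.DataFrame  # index: node; columns: bc_norm, bc_raw

    def mean(self, nodes: list[str] | None = None, scale: str = "bc_norm") -> float:
        t = self.table if nodes is None else self.table.loc[nodes]
        return float(t[scale].mean())

    def ranked(self, scale: str = "bc_norm") -> pd.DataFrame:
        return self.table.sort_values(scale, ascending=False, kind="mergesort")


def _raw_betweenness(g: nx.Graph, nodes: list[str]) -> np.ndarray:
    """Unordered-pair shortest-path betweenness counts (Brandes scale).

    Uses igraph's C implementation when available; falls back to
    networkx. Both count each unordered source-target pair once on
    undirected graphs.
    """
    try:
        import igraph
    except ImportError:  # pragma: no cover - igraph present in practice
        raw = nx.betweenness_centrality(g, normalized=False)
        return np.array([raw[n] for n in nodes])
    idx = {n: i for i, n in enumerate(nodes)}
    ig = igraph.Graph(
        n=len(nodes),
        edges=[(idx[a], idx[b]) for a, b in sorted(tuple(sorted(e)) for e in g.edges)],
        directed=False,
    )
    return np.asarray(ig.betweenness(), dtype=float)


def betweenness(g: nx.Graph) -> CentralityReport:
    """Shortest-path betweenness on the unweighted simple graph.

    Raw values count unordered node pairs weighted by the fraction of
    their shortest paths through the node; normalized values divide by
    (n-1)(n-2)/2. Graphs with < 3 nodes have all-zero centrality.
    Disconnected graphs are handled per component with global
    normalization (the standard convention).
    """
    nodes = sorted(g.nodes)
    if len(nodes) < 3:
        table = pd.DataFrame({"bc_norm": 0.0, "bc_raw": 0.0}, index=nodes)
        return CentralityReport(table=table)
    raw = _raw_betweenness(g, nodes)
    n = len(nodes)
    norm = raw / ((n - 1) * (n - 2) / 2.0)
    table = pd.DataFrame(
        {"bc_norm": norm, "bc_raw": raw}, index=pd.Index(nodes, name="node")
    )
    return CentralityReport(table=table)


@dataclass
class SubnetworkSummary:
    label: str
    n_nodes: int
    n_missing: int
    mean_bc_norm: float
    mean_bc_raw: float
    community_mean_bc_norm: float
    community_mean_bc_raw: float
    induced_edges: int
    n_components: int

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def subnetwork_report(
    g: nx.Graph, report: CentralityReport, nodes: set[str] | list[str], label: str
) -> SubnetworkSummary:
    """Compare a node subset's whole-graph centrality with the community.

    The subset mean uses whole-graph betweenness restricted to the
    subset (not recomputed on the induced subgraph), matching the
    community-vs-subnetwork framing; the induced subgraph is summarized
    by its edge count and number of connected components.
    """
    nodes = sorted(set(nodes))
    if not nodes:
        raise ValidationError("empty subnetwork node set")
    present = [n for n in nodes if n in g]
    missing = len(nodes) - len(present)
    if missing:
        warnings.warn(f"{missing} subnetwork node(s) absent from graph", stacklevel=2)
    if not present:
        raise ValidationError("no subnetwork node present in graph")
    sub = g.subgraph(present)
    return SubnetworkSummary(
        label=label,
        n_nodes=len(present),
        n_missing=missing,
        mean_bc_norm=report.mean(present, "bc_norm"),
        mean_bc_raw=report.mean(present, "bc_raw"),
        community_mean_bc_norm=report.mean(scale="bc_norm"),
        community_mean_bc_raw=report.mean(scale="bc_raw"),
        induced_edges=sub.number_of_edges(),
        n_components=nx.number_connected_components(sub),
    )


def write_graphml(g: nx.Graph, path: str | Path) -> None:
    """Deterministic GraphML output: nodes and edges rewritten in sorted
    order so identical graphs give identical bytes."""
    ordered = nx.Graph()
    for n in sorted(g.nodes):
        ordered.add_node(n, **{k: g.nodes[n][k] for k in sorted(g.nodes[n])})
    for a, b in sorted(tuple(sorted(e)) for e in g.edges):
        ordered.add_edge(a, b, **{k: g[a][b][k] for k in sorted(g[a][b])})
    nx.write_graphml(ordered, str(path))
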