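"""Split-graph assembly, maximal-clique extraction, ranking, GraphML export.

A split graph partitions its vertices into a clique side and an independent
set.  Here the correlated taxa occupy the (potential) clique side and the
KEGG modules the independent side: clique edges carry the Spearman rho of a
taxon pair, cross edges the KO density of a taxon-module association, and
no edge ever joins two modules.  Because the module side is independent, a
maximal clique of the mixed graph contains at most one module node — each
extracted clique is one group of mutually correlated taxa plus, at most,
one pathway module associated with every member.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import networkx as nx

from microsplit.association import DensityAssociation
from microsplit.correlation import CorrNetwork
from microsplit.errors import ValidationError


@dataclass
class SplitGraphModel:
    """Two disjoint node sets with clique edges (rho) and cross edges (density)."""

    taxon_nodes: frozenset[str]
    module_nodes: frozenset[str]
    clique_edges: list[tuple[str, str, float]]
    cross_edges: list[tuple[str, str, float]]

    def __post_init__(self) -> None:
        overlap = self.taxon_nodes & self.module_nodes
        if overlap:
            raise ValidationError(f"taxon/module node sets overlap: {sorted(overlap)}")
        for a, b, _ in self.clique_edges:
            if a not in self.taxon_nodes or b not in self.taxon_nodes:
                raise ValidationError(f"clique edge ({a!r}, {b!r}) leaves the taxon side")
        for t, m, _ in self.cross_edges:
            if t not in self.taxon_nodes:
                raise ValidationError(f"cross edge taxon {t!r} not a taxon node")
            if m not in self.module_nodes:
                raise ValidationError(f"cross edge module {m!r} not a module node")

    @property
    def n_nodes(self) -> int:
        return len(self.taxon_nodes) + len(self.module_nodes)

    @property
    def n_edges(self) -> int:
        return len(self.clique_edges) + len(self.cross_edges)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for t in sorted(self.taxon_nodes):
            g.add_node(t, node_class="taxon", label=t)
        for m in sorted(self.module_nodes):
            g.add_node(m, node_class="module", label=m)
        for a, b, rho in self.clique_edges:
            g.add_edge(a, b, edge_class="clique", weight=abs(rho),
                       rho_sign=1 if rho >= 0 else -1)
        for t, m, dens in self.cross_edges:
            g.add_edge(t, m, edge_class="cross", weight=dens, rho_sign=0)
        return g


@dataclass(frozen=True)
class CliqueModule:
    """A maximal clique: correlated taxa plus at most one attached module.

    ``edge_weights`` holds |rho| for each internal taxon-taxon edge followed
    by the density of each taxon-module cross edge; ``weight`` aggregates
    them under ``weight_scheme``.  ``kind`` records whether maximality was
    taken on the mixed graph (default) or the taxa-only subgraph.
    """

    taxa: frozenset[str]
    module: Optional[str]
    weight: float
    weight_scheme: str = "sum"
    edge_weights: tuple[float, ...] = field(default=())
    kind: str = "mixed"

    @property
    def size(self) -> int:
        return len(self.taxa) + (1 if self.module else 0)

    @property
    def members(self) -> frozenset[str]:
        return self.taxa | ({self.module} if self.module else set())


def build_split_graph(
    net: CorrNetwork,
    dens: Sequence[DensityAssociation],
    *,
    taxa_universe: Optional[set[str]] = None,
) -> SplitGraphModel:
    """Assemble the split graph from a correlation network and density list.

    Taxa named only by density associations are retained as isolated taxon
    nodes (they carry cross edges but no clique edge).  If ``taxa_universe``
    is supplied, a density association naming a taxon outside both the
    network and that universe raises :class:`ValidationError`.
    """
    net_taxa = net.features
    if taxa_universe is not None:
        unknown = sorted(
            {d.taxon for d in dens} - net_taxa - set(taxa_universe)
        )
        if unknown:
            raise ValidationError(
                f"density associations name unknown taxa: {unknown}"
            )
    taxon_nodes = frozenset(net_taxa | {d.taxon for d in dens})
    module_nodes = frozenset(d.module_id for d in dens)
    overlap = taxon_nodes & module_nodes
    if overlap:
        raise ValidationError(f"labels used as both taxon and module: {sorted(overlap)}")
    clique_edges = [(e.feature_a, e.feature_b, e.rho) for e in net.edges]
    cross_edges = [(d.taxon, d.module_id, d.density) for d in dens]
    return SplitGraphModel(taxon_nodes, module_nodes, clique_edges, cross_edges)


def _aggregate(weights: Sequence[float], scheme: str) -> float:
    if scheme == "sum":
        return float(sum(weights))
    if scheme == "mean":
        return float(sum(weights) / len(weights)) if weights else 0.0
    raise ValueError(f"unknown weight scheme {scheme!r}")


def _clique_record(
    g: nx.Graph, members: frozenset[str], scheme: str, kind: str
) -> CliqueModule:
    modules = [m for m in members if g.nodes[m]["node_class"] == "module"]
    taxa = frozenset(m for m in members if g.nodes[m]["node_class"] == "taxon")
    module = modules[0] if modules else None
    weights: list[float] = []
    taxa_sorted = sorted(taxa)
    for i, a in enumerate(taxa_sorted):
        for b in taxa_sorted[i + 1:]:
            weights.append(g.edges[a, b]["weight"])
    if module is not None:
        for t in taxa_sorted:
            weights.append(g.edges[t, module]["weight"])
    return CliqueModule(
        taxa=taxa,
        module=module,
        weight=_aggregate(weights, scheme),
        weight_scheme=scheme,
        edge_weights=tuple(weights),
        kind=kind,
    )


def enumerate_maximal_cliques(
    g: SplitGraphModel,
    *,
    scheme: str = "sum",
    min_size: int = 2,
    include_taxa_only: bool = False,
    module_attachment: str = "strict",
) -> list[CliqueModule]:
    """All maximal cliques of the mixed graph, with their module attachment.

    Enumeration is pivoting Bron-Kerbosch on the full graph; the independent
    module side guarantees at most one module node per clique without special
    casing.  Cliques smaller than ``min_size`` nodes (singletons by default)
    are suppressed.  ``include_taxa_only=True`` additionally reports maximal
    cliques of the taxa-only subgraph (``kind="taxa_only"``) that are not
    already mixed-maximal — a taxa clique can be maximal among taxa yet
    extendable by a module node.

    ``module_attachment="any"`` relaxes completeness for the module node: the
    taxa-only maximal cliques are reported with every module adjacent to at
    least one member (one record per such module), instead of requiring the
    module to be adjacent to all members.
    """
    _aggregate([], scheme)  # validate scheme early
    if module_attachment not in ("strict", "any"):
        raise ValueError(f"unknown module_attachment {module_attachment!r}")
    nxg = g.to_networkx()
    out: list[CliqueModule] = []

    if module_attachment == "any":
        taxa_sub = nxg.subgraph(sorted(g.taxon_nodes))
        for members in nx.find_cliques(taxa_sub):
            taxa = frozenset(members)
            adjacent_modules = sorted(
                {m for t in taxa for m in nxg.neighbors(t)
                 if nxg.nodes[m]["node_class"] == "module"}
            )
            if not adjacent_modules:
                if len(taxa) >= min_size:
                    out.append(_clique_record(nxg, taxa, scheme, "relaxed"))
                continue
            for mod in adjacent_modules:
                weights = []
                taxa_sorted = sorted(taxa)
                for i, a in enumerate(taxa_sorted):
                    for b in taxa_sorted[i + 1:]:
                        weights.append(nxg.edges[a, b]["weight"])
                for t in taxa_sorted:
                    if nxg.has_edge(t, mod):
                        weights.append(nxg.edges[t, mod]["weight"])
                if len(taxa) + 1 >= min_size:
                    out.append(
                        CliqueModule(taxa=taxa, module=mod,
                                     weight=_aggregate(weights, scheme),
                                     weight_scheme=scheme,
                                     edge_weights=tuple(weights),
                                     kind="relaxed")
                    )
        return sorted(out, key=lambda c: (sorted(c.taxa), c.module or ""))

    mixed: list[CliqueModule] = []
    for members in nx.find_cliques(nxg):
        fs = frozenset(members)
        if len(fs) < min_size:
            continue
        mixed.append(_clique_record(nxg, fs, scheme, "mixed"))
    out.extend(mixed)

    if include_taxa_only:
        mixed_member_sets = {c.members for c in mixed}
        taxa_sub = nxg.subgraph(sorted(g.taxon_nodes))
        for members in nx.find_cliques(taxa_sub):
            fs = frozenset(members)
            if len(fs) < min_size or fs in mixed_member_sets:
                continue
            out.append(_clique_record(nxg, fs, scheme, "taxa_only"))

    return sorted(out, key=lambda c: (sorted(c.taxa), c.module or ""))


def rank_cliques(
    cliques: Sequence[CliqueModule],
    scheme: str = "sum",
    top_k: Optional[int] = None,
) -> list[CliqueModule]:
    """Re-score cliques under ``scheme`` and sort by descending weight.

    Ties break by clique size (larger first) then lexicographic taxa, so the
    ordering is deterministic across runs.
    """
    _aggregate([], scheme)  # validate scheme even on an empty clique list
    rescored = [
        CliqueModule(
            taxa=c.taxa,
            module=c.module,
            weight=_aggregate(c.edge_weights, scheme),
            weight_scheme=scheme,
            edge_weights=c.edge_weights,
            kind=c.kind,
        )
        for c in cliques
    ]
    rescored.sort(key=lambda c: (-c.weight, -c.size, sorted(c.taxa), c.module or ""))
    return rescored[:top_k] if top_k is not None else rescored


def export_graphml(
    g: SplitGraphModel,
    cliques: Optional[Sequence[CliqueModule]] = None,
    path: str | Path = "splitgraph.graphml",
) -> None:
    """Write Cytoscape-importable GraphML.

    Nodes carry ``node_class`` (taxon/module) and ``label``; edges carry
    ``edge_class`` (clique/cross), ``weight`` (|rho| or density) and
    ``rho_sign`` (+1/-1 for clique edges, 0 for cross edges).  When ranked
    cliques are supplied, each node lists its clique memberships as a
    semicolon-joined attribute of clique ids (``C1`` = top ranked).
    """
    nxg = g.to_networkx()
    if cliques:
        membership: dict[str, list[str]] = {n: [] for n in nxg.nodes}
        for i, c in enumerate(cliques, start=1):
            for n in c.members:
                if n in membership:
                    membership[n].append(f"C{i}")
        nx.set_node_attributes(
            nxg, {n: ";".join(ids) for n, ids in membership.items()}, "cliques"
        )
    nx.write_graphml(nxg, str(path))


def write_cliques_tsv(cliques: Sequence[CliqueModule], path: str | Path) -> None:
    """TSV report: clique_id, taxa (semicolon-joined), module, weight, scheme."""
    with open(path, "w") as fh:
        fh.write("clique_id\ttaxa\tmodule\tweight\tscheme\tkind\n")
        for i, c in enumerate(cliques, start=1):
            fh.write(
                f"C{i}\t{';'.join(sorted(c.taxa))}\t{c.module or ''}"
                f"\t{c.weight:.6g}\t{c.weight_scheme}\t{c.kind}\n"
            )
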