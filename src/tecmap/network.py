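"""Bipartite network of tissue-enriched and group-enriched genes.

Genes classified as tissue enriched or group enriched are grouped by their
exact combination of elevated tissues; each distinct combination becomes a
gene node (carrying the gene count) connected to each member tissue node.
Display filtering keeps a gene node if it (1) contains tissue-enriched
genes, (2) contains at least 5 genes, or (3) ranks among the top 2 largest
nodes of any connected tissue while containing at least 2 genes.  Rule-3
ranking is competition ranking, so equal-count nodes share a rank.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from . import io as tio

ENRICHED_CATEGORIES = ("tissue_enriched", "group_enriched")


@dataclass
class GeneNode:
    node_id: str
    tissues: tuple[str, ...]
    gene_ids: list[str] = field(default_factory=list)
    contains_tissue_enriched: bool = False
    displayed: bool | None = None

    @property
    def gene_count(self) -> int:
        return len(self.gene_ids)


@dataclass
class GeneNetwork:
    """Tissue nodes + gene-combination nodes with display flags."""

    gene_nodes: dict[str, GeneNode]
    tissues: list[str]
    organ_system_of: dict[str, str] = field(default_factory=dict)

    @property
    def n_genes(self) -> int:
        return sum(n.gene_count for n in self.gene_nodes.values())

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for t in self.tissues:
            g.add_node(
                f"tissue:{t}",
                kind="tissue",
                tissue=t,
                organ_system=self.organ_system_of.get(t, ""),
            )
        for node in self.gene_nodes.values():
            g.add_node(
                f"genes:{node.node_id}",
                kind="gene_combination",
                tissues=";".join(node.tissues),
                gene_count=node.gene_count,
                contains_tissue_enriched=bool(node.contains_tissue_enriched),
                displayed=bool(node.displayed) if node.displayed is not None else False,
                genes=";".join(node.gene_ids),
            )
            for t in node.tissues:
                g.add_edge(f"genes:{node.node_id}", f"tissue:{t}")
        return g


def build_network(
    spec_calls: pd.DataFrame, organ_system_of: dict[str, str] | None = None
) -> GeneNetwork:
    """Group enriched/group-enriched genes by elevated-tissue combination."""
    enriched = spec_calls[spec_calls["category"].isin(ENRICHED_CATEGORIES)]
    gene_nodes: dict[str, GeneNode] = {}
    tissues: list[str] = []
    for _, row in enriched.iterrows():
        combo = tuple(sorted(row["elevated_tissues"]))
        if not combo:
            raise ValueError(
                f"enriched gene {row['gene_id']!r} has an empty elevated tissue set"
            )
        node_id = "|".join(combo)
        node = gene_nodes.setdefault(node_id, GeneNode(node_id, combo))
        node.gene_ids.append(str(row["gene_id"]))
        if row["category"] == "tissue_enriched":
            node.contains_tissue_enriched = True
        for t in combo:
            if t not in tissues:
                tissues.append(t)
    return GeneNetwork(gene_nodes, sorted(tissues), organ_system_of or {})


def apply_display_rules(net: GeneNetwork) -> GeneNetwork:
    """Set per-node display flags from the three filtering rules."""
    # per tissue: competition rank of connected gene nodes by gene count
    top2: dict[str, set[str]] = {}
    for t in net.tissues:
        connected = [n for n in net.gene_nodes.values() if t in n.tissues]
        counts = sorted({n.gene_count for n in connected}, reverse=True)
        qualifying = set(counts[:2])
        top2[t] = {n.node_id for n in connected if n.gene_count in qualifying}
    for node in net.gene_nodes.values():
        rule1 = node.contains_tissue_enriched
        rule2 = node.gene_count >= 5
        rule3 = node.gene_count >= 2 and any(node.node_id in top2[t] for t in node.tissues)
        node.displayed = rule1 or rule2 or rule3
    return net


def export_network(net: GeneNetwork, path, fmt: str = "graphml") -> None:
    """Write the network as GraphML, SIF, or a TSV edge list."""
    if any(n.displayed is None for n in net.gene_nodes.values()):
        apply_display_rules(net)
    if fmt == "graphml":
        tio.write_graphml(net.to_networkx(), path)
    elif fmt == "sif":
        with open(path, "w") as fh:
            for node in net.gene_nodes.values():
                for t in node.tissues:
                    fh.write(f"genes:{node.node_id}\televated_in\ttissue:{t}\n")
    elif fmt == "tsv":
        rows = [
            {
                "gene_node": node.node_id,
                "tissue": t,
                "gene_count": node.gene_count,
                "contains_tissue_enriched": node.contains_tissue_enriched,
                "displayed": node.displayed,
            }
            for node in net.gene_nodes.values()
            for t in node.tissues
        ]
        tio.write_table(pd.DataFrame(rows), path)
    else:
        raise ValueError(f"unknown format {fmt!r}; use graphml, sif, or tsv")
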