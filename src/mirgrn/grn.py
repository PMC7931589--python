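"""Per-group regulatory-network assembly under the study's filters.

Order of operations: map species targets into the reference (human-like)
gene namespace via an ortholog table; keep protein-interaction edges with
experimental score > 0 and combined score strictly greater than the
experimental score; keep genes with at least one such interaction to a
kernel gene of heart development (kernel genes themselves are always
retained — they anchor the network); keep genes whose expression is
conserved among the group's samples (TPM >= 1 in at least half of the
species, rounded up); and keep miRNA-target interactions supported by at
least ceil(n/2) of the group's n species — which reproduces the stated
2-of-3 (fishes) and 4-of-8 (mammals) instances.  The resulting per-group
graph has typed nodes (kernel gene, peripheral gene, miRNA family) and
typed undirected edges (ppi, mir_target) carrying species-support counts
and validation flags.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class GroupGRN:
    group: str
    graph: nx.Graph

    @property
    def ppi_edges(self) -> set[tuple[str, str]]:
        return {
            tuple(sorted((a, b)))
            for a, b, d in self.graph.edges(data=True)
            if d["kind"] == "ppi"
        }

    @property
    def mir_target_edges(self) -> set[tuple[str, str]]:
        """(family, reference gene) pairs — the shared comparison namespace."""
        out = set()
        for a, b, d in self.graph.edges(data=True):
            if d["kind"] != "mir_target":
                continue
            fam, gene = (a, b) if self.graph.nodes[a]["kind"] == "mirna" else (b, a)
            out.add((fam, gene))
        return out


def conservation_threshold(n_species: int) -> int:
    """Support required for an interaction in an n-species group: ceil(n/2)."""
    return math.ceil(n_species / 2)


def map_orthologs(interactions: pd.DataFrame, omap: pd.DataFrame) -> pd.DataFrame:
    """Replace species gene ids by reference gene ids.

    ``interactions`` needs columns species, family, gene (species gene id);
    ``omap`` columns species, species_gene, ref_gene, confidence.  Unmapped
    genes are dropped with a logged count.  Many-to-one collisions in the
    map are resolved by highest confidence, then lexicographically smallest
    reference id.
    """
    resolved = (
        omap.sort_values(["species", "species_gene", "confidence", "ref_gene"],
                         ascending=[True, True, False, True])
        .drop_duplicates(["species", "species_gene"], keep="first")
    )
    lookup = {
        (r.species, r.species_gene): r.ref_gene for r in resolved.itertuples(index=False)
    }
    refs = [
        lookup.get((row.species, row.gene)) for row in interactions.itertuples(index=False)
    ]
    out = interactions.copy()
    out["ref_gene"] = refs
    dropped = out["ref_gene"].isna().sum()
    if dropped:
        logger.warning("%d interactions dropped: no ortholog mapping", dropped)
    return out[out["ref_gene"].notna()].reset_index(drop=True)


def filter_ppi(edges: pd.DataFrame) -> pd.DataFrame:
    """Score rule: experimental > 0 AND combined > experimental (both strict)."""
    for col in ("experimental", "combined"):
        bad = edges[(edges[col] < 0) | (edges[col] > 1000)]
        if len(bad):
            raise ValueError(f"{col} score outside [0, 1000] on row {bad.index[0]}")
    keep = (edges["experimental"] > 0) & (edges["combined"] > edges["experimental"])
    return edges[keep].reset_index(drop=True)


def kernel_filter(
    genes: set[str], filtered_edges: pd.DataFrame, kernel: set[str]
) -> set[str]:
    """Kernel genes plus genes with >= 1 filtered interaction to the kernel.

    Adjacency only — genes two hops from the kernel are dropped.  Kernel
    genes are retained even when isolated.
    """
    if not kernel:
        raise ValueError("kernel gene list is empty")
    adjacent = set()
    for row in filtered_edges.itertuples(index=False):
        if row.gene_a in kernel:
            adjacent.add(row.gene_b)
        if row.gene_b in kernel:
            adjacent.add(row.gene_a)
    if genes:
        adjacent &= set(genes)
    return set(kernel) | adjacent


def conservation_filter(
    interactions: pd.DataFrame, group_species: list[str]
) -> pd.DataFrame:
    """Per-group support filter on (family, ref_gene) interactions.

    ``interactions`` has columns species, family, ref_gene (one row per
    supporting species).  Keeps interactions supported by >= ceil(n/2) of
    the group's n species and returns one row per interaction with the
    supporting species set and count.
    """
    if not group_species:
        raise ValueError("group has no species")
    threshold = conservation_threshold(len(group_species))
    sub = interactions[interactions["species"].isin(group_species)]
    rows = []
    for (fam, gene), grp in sub.groupby(["family", "ref_gene"], sort=True):
        support = sorted(set(grp["species"]))
        if len(support) >= threshold:
            rows.append({
                "family": fam,
                "ref_gene": gene,
                "support": ",".join(support),
                "n_support": len(support),
            })
    return pd.DataFrame(rows, columns=["family", "ref_gene", "support", "n_support"])


def assemble_grn(
    group: str,
    conserved_interactions: pd.DataFrame,
    expressed_genes: set[str],
    filtered_ppi: pd.DataFrame,
    kernel: set[str],
    validated: pd.DataFrame | None = None,
) -> GroupGRN:
    """Build one group's network from the filter outputs.

    Nodes: kernel genes (always), peripheral genes passing the kernel and
    expression filters, and miRNA families with >= 1 surviving target.
    Edges: ppi edges between kept genes; mir_target edges for conserved
    interactions whose target gene is kept, annotated as validated when
    present in the user-supplied validated-interaction table.
    """
    kept_genes = kernel_filter(expressed_genes, filtered_ppi, kernel)

    vmap = {}
    if validated is not None and len(validated):
        for row in validated.itertuples(index=False):
            vmap[(row.mirna_family, row.gene)] = getattr(row, "source", "")

    g = nx.Graph(group=group)
    for gene in sorted(kept_genes):
        g.add_node(gene, kind="kernel" if gene in kernel else "gene")
    for row in filtered_ppi.itertuples(index=False):
        if row.gene_a in kept_genes and row.gene_b in kept_genes:
            g.add_edge(row.gene_a, row.gene_b, kind="ppi",
                       experimental=int(row.experimental), combined=int(row.combined))
    for row in conserved_interactions.itertuples(index=False):
        if row.ref_gene not in kept_genes:
            continue
        fam = row.family
        if fam not in g:
            g.add_node(fam, kind="mirna")
        src = vmap.get((fam, row.ref_gene))
        g.add_edge(fam, row.ref_gene, kind="mir_target",
                   support=row.support, n_support=int(row.n_support),
                   validated=src is not None, validated_source=src or "")
    # miRNA families with zero surviving targets never entered; prune any
    # empty miRNA nodes defensively
    for node in [n for n, d in g.nodes(data=True) if d["kind"] == "mirna" and g.degree(n) == 0]:
        g.remove_node(node)
    return GroupGRN(group, g)


def grn_edge_table(grn: GroupGRN) -> pd.DataFrame:
    rows = []
    for a, b, d in grn.graph.edges(data=True):
        a2, b2 = sorted((a, b))
        rows.append({
            "group": grn.group, "node_a": a2, "node_b": b2, "kind": d["kind"],
            "support": d.get("support", ""), "validated": d.get("validated", False),
        })
    return pd.DataFrame(rows, columns=["group", "node_a", "node_b", "kind", "support", "validated"]) \
        .sort_values(["kind", "node_a", "node_b"]).reset_index(drop=True)
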