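"""P450 membership in secondary-metabolite biosynthetic gene clusters.

A P450 gene belongs to a BGC when both lie on the same contig of the same
species and their 1-based inclusive intervals overlap by at least one base
(full containment is available as a stricter mode). Strand is ignored. A
P450 inside two overlapping clusters yields two memberships; hybrid clusters
contribute one count per type label to the family-by-type linkage table.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Sequence

from intervaltree import IntervalTree

from .classify import Assignment
from .io import ClusterRecord, GeneFeature

__all__ = [
    "ClusterMembership",
    "gene_in_cluster",
    "link_p450s",
    "family_bgc_linkage",
    "bgc_type_tally",
]


@dataclass(frozen=True)
class ClusterMembership:
    species_id: str
    protein_id: str
    cluster_id: str
    type_labels: tuple[str, ...]
    family_label: str


def gene_in_cluster(gene: GeneFeature, cluster: ClusterRecord, overlap: str = "any") -> bool:
    """True iff the gene lies in the cluster under the chosen overlap rule.

    ``overlap="any"`` requires >= 1 shared base; ``overlap="contained"``
    requires the gene interval to lie entirely within the cluster.
    """
    if overlap not in ("any", "contained"):
        raise ValueError(f"unknown overlap rule {overlap!r}")
    if gene.species_id != cluster.species_id or gene.contig != cluster.contig:
        return False
    if overlap == "contained":
        return cluster.start <= gene.start and gene.end <= cluster.end
    return gene.start <= cluster.end and cluster.start <= gene.end


def link_p450s(
    assignments: Sequence[Assignment],
    genes: Sequence[GeneFeature],
    clusters: Sequence[ClusterRecord],
    overlap: str = "any",
) -> list[ClusterMembership]:
    """All (P450, cluster) membership pairs.

    Every classified P450 must have a gene coordinate (gene_id == protein_id);
    otherwise an error lists the unmatched ids. Output order follows the
    assignment order, then cluster_id.
    """
    gene_by_id: dict[tuple[str, str], GeneFeature] = {
        (g.species_id, g.gene_id): g for g in genes
    }
    missing = [
        a.protein_id
        for a in assignments
        if (a.species_id, a.protein_id) not in gene_by_id
    ]
    if missing:
        raise ValueError(f"assignments with no gene coordinates: {sorted(missing)}")

    # interval index per (species, contig); intervaltree uses half-open ends
    trees: dict[tuple[str, str], IntervalTree] = {}
    for c in clusters:
        trees.setdefault((c.species_id, c.contig), IntervalTree()).addi(
            c.start, c.end + 1, c
        )

    memberships: list[ClusterMembership] = []
    for a in assignments:
        gene = gene_by_id[(a.species_id, a.protein_id)]
        tree = trees.get((gene.species_id, gene.contig))
        if tree is None:
            continue
        hits = [iv.data for iv in tree.overlap(gene.start, gene.end + 1)]
        for cluster in sorted(hits, key=lambda c: c.cluster_id):
            if not gene_in_cluster(gene, cluster, overlap):
                continue
            memberships.append(
                ClusterMembership(
                    species_id=a.species_id,
                    protein_id=a.protein_id,
                    cluster_id=cluster.cluster_id,
                    type_labels=cluster.type_labels,
                    family_label=a.family_label or "",
                )
            )
    return memberships


def family_bgc_linkage(memberships: Sequence[ClusterMembership]) -> Counter:
    """Counts keyed by (family_label, type_label).

    A membership in a hybrid cluster with k type labels contributes one count
    to each of its k cells, preserving per-type tallies.
    """
    table: Counter = Counter()
    for m in memberships:
        for t in m.type_labels:
            table[(m.family_label, t)] += 1
    return table


def bgc_type_tally(
    clusters: Sequence[ClusterRecord],
    memberships: Sequence[ClusterMembership],
) -> list[tuple[str, int]]:
    """Per-type counts of P450-containing clusters, descending (ties by name).

    Only clusters with at least one membership are counted; a hybrid cluster
    counts once under each of its type labels.
    """
    with_p450 = {(m.species_id, m.cluster_id) for m in memberships}
    tally: Counter = Counter()
    for c in clusters:
        if (c.species_id, c.cluster_id) in with_p450:
            for t in c.type_labels:
                tally[t] += 1
    return sorted(tally.items(), key=lambda kv: (-kv[1], kv[0]))
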