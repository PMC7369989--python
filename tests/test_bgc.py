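import dataclasses

import numpy as np
import pytest

from cypminer.bgc import bgc_type_tally, family_bgc_linkage, gene_in_cluster, link_p450s
from cypminer.classify import SUBFAMILY, Assignment
from cypminer.io import ClusterRecord, GeneFeature, parse_cyp_name

from oracles import brute_memberships


def _gene(gene_id, start, end, sp="sp1", contig="c1"):
    return GeneFeature(sp, gene_id, contig, start, end, "+")


def _cluster(cluster_id, start, end, sp="sp1", contig="c1", types=("terpene",)):
    return ClusterRecord(sp, cluster_id, contig, start, end, tuple(types))


def _assignment(pid, sp="sp1", family="CYP107"):
    return Assignment(sp, pid, parse_cyp_name("CYP107W1"), 90.0, SUBFAMILY, family, family + "W")


class TestGeneInCluster:
    @pytest.mark.parametrize(
        "gene_iv,cluster_iv,expected",
        [
            ((200, 800), (100, 5000), True),
            ((6000, 6500), (100, 5000), False),
            ((4900, 5200), (100, 5000), True),  # boundary-spanning, >=1 shared base
            ((5000, 5200), (100, 5000), True),  # single shared base
            ((5001, 5200), (100, 5000), False),
        ],
    )
    def test_any_overlap_rule(self, gene_iv, cluster_iv, expected):
        assert gene_in_cluster(_gene("g", *gene_iv), _cluster("b", *cluster_iv)) is expected

    def test_containment_mode_is_stricter(self):
        gene, cluster = _gene("g", 4900, 5200), _cluster("b", 100, 5000)
        assert gene_in_cluster(gene, cluster, "any")
        assert not gene_in_cluster(gene, cluster, "contained")
        assert gene_in_cluster(_gene("g", 200, 800), cluster, "contained")

    def test_contig_and_species_must_match(self):
        assert not gene_in_cluster(_gene("g", 200, 800, contig="c2"), _cluster("b", 100, 5000))
        assert not gene_in_cluster(_gene("g", 200, 800, sp="sp2"), _cluster("b", 100, 5000))

    def test_unknown_rule_rejected(self):
        with pytest.raises(ValueError):
            gene_in_cluster(_gene("g", 1, 2), _cluster("b", 1, 2), "touching")


class TestLinkP450s:
    def test_cluster_containing_two_of_three_genes(self):
        genes = [_gene("p1", 200, 800), _gene("p2", 2000, 2600), _gene("p3", 9000, 9600)]
        assignments = [_assignment(p) for p in ("p1", "p2", "p3")]
        clusters = [_cluster("b1", 100, 5000)]
        members = link_p450s(assignments, genes, clusters)
        assert [(m.protein_id, m.cluster_id) for m in members] == [("p1", "b1"), ("p2", "b1")]

    def test_no_clusters_gives_empty(self):
        assert link_p450s([_assignment("p1")], [_gene("p1", 1, 9)], []) == []

    def test_p450_in_two_overlapping_clusters_counts_twice(self):
        members = link_p450s(
            [_assignment("p1")],
            [_gene("p1", 1000, 1500)],
            [_cluster("b1", 1, 2000), _cluster("b2", 1200, 3000)],
        )
        assert [(m.protein_id, m.cluster_id) for m in members] == [("p1", "b1"), ("p1", "b2")]

    def test_missing_gene_coordinates_listed(self):
        with pytest.raises(ValueError, match="p2"):
            link_p450s([_assignment("p1"), _assignment("p2")], [_gene("p1", 1, 9)], [])

    def _random_layout(self, seed, n_genes=200, n_clusters=40):
        rng = np.random.default_rng(seed)
        genes, assignments = [], []
        for i in range(n_genes):
            sp = f"sp{rng.integers(1, 4)}"
            contig = f"c{rng.integers(1, 3)}"
            start = int(rng.integers(1, 200_000))
            genes.append(_gene(f"g{i}", start, start + int(rng.integers(300, 2000)), sp, contig))
            assignments.append(_assignment(f"g{i}", sp))
        # one gene id per (species, protein) pair is required by the linker
        seen, uniq_genes, uniq_asn = set(), [], []
        for g, a in zip(genes, assignments):
            if (g.species_id, g.gene_id) not in seen:
                seen.add((g.species_id, g.gene_id))
                uniq_genes.append(g)
                uniq_asn.append(a)
        clusters = []
        for j in range(n_clusters):
            sp = f"sp{rng.integers(1, 4)}"
            contig = f"c{rng.integers(1, 3)}"
            start = int(rng.integers(1, 200_000))
            clusters.append(_cluster(f"b{j}", start, start + int(rng.integers(1000, 40_000)), sp, contig))
        return uniq_asn, uniq_genes, clusters

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_matches_quadratic_oracle_on_random_layouts(self, seed):
        assignments, genes, clusters = self._random_layout(seed)
        got = {
            (m.species_id, m.protein_id, m.cluster_id)
            for m in link_p450s(assignments, genes, clusters)
        }
        assert got == brute_memberships(genes, clusters)

    def test_translation_invariance(self):
        assignments, genes, clusters = self._random_layout(99, 50, 10)
        before = [(m.protein_id, m.cluster_id) for m in link_p450s(assignments, genes, clusters)]
        offset = 10_000
        genes2 = [dataclasses.replace(g, start=g.start + offset, end=g.end + offset) for g in genes]
        clusters2 = [dataclasses.replace(c, start=c.start + offset, end=c.end + offset) for c in clusters]
        after = [(m.protein_id, m.cluster_id) for m in link_p450s(assignments, genes2, clusters2)]
        assert before == after


class TestTabulations:
    def test_hybrid_cluster_contributes_one_count_per_type(self):
        members = link_p450s(
            [_assignment("p1")],
            [_gene("p1", 1000, 1500)],
            [_cluster("b1", 1, 2000, types=("bacteriocin", "NRPS"))],
        )
        table = family_bgc_linkage(members)
        assert table == {("CYP107", "bacteriocin"): 1, ("CYP107", "NRPS"): 1}

    def test_linkage_total_equals_sum_of_type_label_counts(self):
        assignments, genes, clusters = [], [], []
        rng = np.random.default_rng(5)
        for i in range(30):
            start = 1 + i * 5000
            genes.append(_gene(f"p{i}", start, start + 1000))
            assignments.append(_assignment(f"p{i}", family=f"CYP{100 + i % 3}"))
            if i % 2 == 0:
                n = int(rng.integers(1, 4))
                types = tuple(f"t{k}" for k in range(n))
                clusters.append(_cluster(f"b{i}", start - 10, start + 1500, types=types))
        members = link_p450s(assignments, genes, clusters)
        table = family_bgc_linkage(members)
        assert sum(table.values()) == sum(len(m.type_labels) for m in members)

    def test_type_tally_counts_p450_containing_clusters(self):
        genes = [_gene("p1", 100, 200), _gene("p2", 5000, 5100)]
        assignments = [_assignment("p1"), _assignment("p2")]
        clusters = [
            _cluster("b1", 50, 300, types=("terpene",)),
            _cluster("b2", 4900, 5200, types=("terpene",)),
            _cluster("b3", 9000, 9500, types=("NRPS",)),  # no P450 inside
            _cluster("b4", 90, 210, types=("NRPS", "terpene")),  # hybrid with P450
        ]
        members = link_p450s(assignments, genes, clusters)
        assert bgc_type_tally(clusters, members) == [("terpene", 3), ("NRPS", 1)]

    def test_empty_tallies(self):
        assert family_bgc_linkage([]) == {}
        assert bgc_type_tally([_cluster("b", 1, 2)], []) == []
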