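"""End-to-end orchestration: triage -> classify -> BGC linkage -> cohort stats."""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .bgc import ClusterMembership, bgc_type_tally, family_bgc_linkage, link_p450s
from .classify import Assignment, NearestHomologClassifier, ReferenceDB
from .io import ClusterRecord, GeneFeature, read_cluster_table, read_fasta, read_gff_genes
from .simulate import SimBundle
from .stats import (
    CohortSummary,
    SpeciesProfile,
    build_species_profiles,
    cohort_summary,
    presence_matrix,
)
from .triage import COMPLETE, DEFAULT_FRAGMENT_MAX_LEN, TriageCall, TriageSummary, triage_proteome

__all__ = ["PipelineResult", "run_cohort", "run_cohort_bundle", "run_cohort_dir"]


@dataclass
class PipelineResult:
    triage_calls: dict[str, list[TriageCall]]
    triage_summaries: dict[str, TriageSummary]
    assignments: list[Assignment]
    memberships: list[ClusterMembership]
    linkage: Counter
    type_tally: list[tuple[str, int]]
    profiles: list[SpeciesProfile]
    summary: CohortSummary
    presence: pd.DataFrame

    def assignments_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "species_id": a.species_id,
                    "protein_id": a.protein_id,
                    "best_ref": str(a.best_ref),
                    "identity": a.best_identity,
                    "level": a.level,
                    "family": a.family_label,
                    "subfamily": a.subfamily_label,
                }
                for a in self.assignments
            ]
        )


def run_cohort(
    proteomes: dict[str, list],
    genes: dict[str, list[GeneFeature]],
    clusters: list[ClusterRecord],
    refdb: ReferenceDB,
    classifier: NearestHomologClassifier | None = None,
    fragment_max_len: int = DEFAULT_FRAGMENT_MAX_LEN,
) -> PipelineResult:
    """Run the full analysis over in-memory per-species inputs."""
    classifier = classifier or NearestHomologClassifier()
    classifier.fit(refdb)
    calls: dict[str, list[TriageCall]] = {}
    summaries: dict[str, TriageSummary] = {}
    complete = []
    for sp in sorted(proteomes):
        sp_calls, sp_summary = triage_proteome(proteomes[sp], fragment_max_len)
        calls[sp] = sp_calls
        summaries[sp] = sp_summary
        keep = {c.protein_id for c in sp_calls if c.category == COMPLETE}
        complete.extend(r for r in proteomes[sp] if r.protein_id in keep)
    assignments = classifier.predict(complete)
    all_genes = [g for sp in sorted(genes) for g in genes[sp]]
    memberships = link_p450s(assignments, all_genes, clusters)
    profiles = build_species_profiles(
        assignments, memberships, clusters, species_ids=sorted(proteomes)
    )
    summary = cohort_summary(profiles, assignments, memberships)
    families = sorted(set().union(*(p.family_labels for p in profiles)))
    return PipelineResult(
        triage_calls=calls,
        triage_summaries=summaries,
        assignments=assignments,
        memberships=memberships,
        linkage=family_bgc_linkage(memberships),
        type_tally=bgc_type_tally(clusters, memberships),
        profiles=profiles,
        summary=summary,
        presence=presence_matrix(profiles, families),
    )


def run_cohort_bundle(bundle: SimBundle, **kwargs) -> PipelineResult:
    """Run the pipeline directly on a synthetic bundle."""
    return run_cohort(
        bundle.proteomes, bundle.genes, bundle.clusters, bundle.refdb, **kwargs
    )


def run_cohort_dir(path: str | Path, **kwargs) -> PipelineResult:
    """Run the pipeline on a bundle directory (refs.fasta, <sp>.fasta/.gff3, clusters.tsv).

    Species are discovered from the ``*.gff3`` files; each must have a
    matching FASTA. Gene ids are matched to protein ids one-to-one.
    """
    path = Path(path)
    species = sorted(p.stem for p in path.glob("*.gff3"))
    if not species:
        raise ValueError(f"no *.gff3 species files under {path}")
    proteomes = {sp: read_fasta(path / f"{sp}.fasta") for sp in species}
    genes = {sp: read_gff_genes(path / f"{sp}.gff3") for sp in species}
    clusters = read_cluster_table(path / "clusters.tsv")
    refdb = ReferenceDB.from_fasta(path / "refs.fasta")
    return run_cohort(proteomes, genes, clusters, refdb, **kwargs)
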