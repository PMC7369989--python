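"""Synthetic cohorts with known truth for exercising the whole pipeline.

Real inputs for this kind of survey are proteomes pulled from genome
portals plus a curated named-P450 reference set; neither can be bundled, so
the generator manufactures the same shapes with controlled structure:

* reference databases whose families sit mutually below the 40% family
  threshold and whose subfamily representatives sit between the 40% and 55%
  thresholds of their family seed;
* proteomes containing complete P450s derived from planted references at
  planted identities, pseudo-P450s (one motif), fragments (short, no
  motifs) and non-candidates (long, no motifs);
* one-contig gene layouts and antiSMASH-style cluster tables with a known
  fraction of P450 genes inside clusters.

Planted identities avoid the bands [37, 43] and [52, 58] around the two
thresholds so that +-2-point targeting noise can never flip an assignment;
a threshold-stress mode exists for deliberately in-band boundary cases.
Everything is deterministic given the seed, down to the output bytes.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .align import ScoringScheme, identity_between
from .classify import FAMILY, NEW_FAMILY, SUBFAMILY, ReferenceDB
from .io import ClusterRecord, CypName, GeneFeature, ProteinRecord, write_cluster_table, write_fasta
from .stats import CohortSummary, rounded_mean, truncated_percent
from .triage import COMPLETE, FRAGMENT, NON_CANDIDATE, PSEUDO, scan_cxg, scan_exxr

__all__ = [
    "SimSpec",
    "SimBundle",
    "random_p450_like",
    "mutate_to_identity",
    "make_reference_db",
    "make_proteome",
    "make_cohort",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA = np.frombuffer(AMINO_ACIDS.encode(), dtype=np.uint8)

# synthetic CYP family numbers start high to avoid clashing with real names
_SYNTHETIC_FAMILY_BASE = 9001

_CLUSTER_TYPES = ("terpene", "T1PKS", "NRPS", "T3PKS", "bacteriocin", "lanthipeptide")
_KNOWN_CLUSTERS = ("", "filipin", "oligomycin", "bottromycin", "geldanamycin")


@dataclass(frozen=True)
class SimSpec:
    """Study conditions for one synthetic cohort.

    Per-species protein counts plant two subfamily-level, one family-level
    and one novel P450 (four complete), one pseudo-P450, one fragment and
    one non-candidate, over a reference set of four families with two
    subfamilies each; a fifth of P450 genes sit inside clusters, echoing the
    roughly one-in-five proportion seen in actinomycete surveys.
    """

    seed: int = 42
    n_species: int = 5
    n_subfamily_level: int = 2
    n_family_level: int = 1
    n_new_family: int = 1
    n_pseudo: int = 1
    n_fragment: int = 1
    n_non_candidate: int = 1
    n_ref_families: int = 4
    subfamilies_per_family: int = 2
    in_bgc_fraction: float = 0.2
    n_decoy_clusters: int = 2
    seq_length: int = 420
    fragment_max_len: int = 300
    threshold_stress: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimSpec":
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


def _random_seq(rng: np.random.Generator, length: int) -> np.ndarray:
    return _AA[rng.integers(0, len(_AA), size=length)]


def _scrub(arr: np.ndarray, rng: np.random.Generator, motifs: Sequence[str],
           protected: frozenset[int]) -> None:
    """Mutate anchors in place until none of the named motifs occur."""
    for _ in range(200):
        seq = arr.tobytes().decode()
        hits: list[tuple[int, int]] = []
        if "exxr" in motifs:
            hits += [(i, i + 3) for i in scan_exxr(seq)]
        if "cxg" in motifs:
            hits += [(i, i + 2) for i in scan_cxg(seq)]
        hits = [h for h in hits if not (h[0] in protected and h[1] in protected)]
        if not hits:
            return
        for a, b in hits:
            pos = a if a not in protected else b
            old = arr[pos]
            choices = _AA[(_AA != old) & (_AA != ord("E")) & (_AA != ord("C"))]
            arr[pos] = choices[rng.integers(0, len(choices))]
    raise RuntimeError("could not scrub motifs in a bounded number of passes")


def random_p450_like(
    rng: np.random.Generator,
    length: int,
    motifs: Sequence[str] = ("exxr", "cxg"),
) -> tuple[str, frozenset[int]]:
    """A random sequence carrying exactly the requested motif set.

    Requested motifs are planted at canonical relative positions (ExxR around
    two-thirds of the length, CxG near the C-terminus); non-requested motifs
    are scrubbed everywhere. Returns the sequence and the planted anchor
    positions (which mutation must leave untouched).
    """
    if length < 20:
        raise ValueError("length too short to place motifs")
    arr = _random_seq(rng, length)
    protected: set[int] = set()
    if "exxr" in motifs:
        i = int(length * 0.68)
        arr[i], arr[i + 3] = ord("E"), ord("R")
        protected |= {i, i + 3}
    if "cxg" in motifs:
        i = int(length * 0.85)
        arr[i], arr[i + 2] = ord("C"), ord("G")
        protected |= {i, i + 2}
    absent = tuple(m for m in ("exxr", "cxg") if m not in motifs)
    if absent:
        _scrub(arr, rng, absent, frozenset(protected))
    return arr.tobytes().decode(), frozenset(protected)


def mutate_to_identity(
    seed_sequence: str,
    target_identity: float,
    rng: np.random.Generator,
    scheme: ScoringScheme | None = None,
    protected: frozenset[int] = frozenset(),
    tolerance: float = 2.0,
    max_attempts: int = 50,
) -> str:
    """A mutant of ``seed_sequence`` at ``target_identity`` +- ``tolerance`` percent.

    Identity is targeted by iterative random substitution with re-verification
    against the package's own global aligner (accept/reject, adjusting the
    substitution count), because gapped global identity is not a closed-form
    function of the substitution count. ``protected`` positions (motif
    anchors) are never touched, so planted motifs survive.
    """
    scheme = scheme or ScoringScheme()
    if len(seed_sequence) < 100:
        raise ValueError("seed sequence must be at least 100 residues")
    if not (10 <= target_identity <= 100):
        raise ValueError("target identity must be in [10, 100]")
    if target_identity == 100:
        return seed_sequence
    length = len(seed_sequence)
    mutable = np.array([i for i in range(length) if i not in protected])
    k = int(round(length * (1 - target_identity / 100)))
    for _ in range(max_attempts):
        k = int(np.clip(k, 1, len(mutable)))
        arr = np.frombuffer(seed_sequence.encode(), dtype=np.uint8).copy()
        positions = rng.choice(mutable, size=k, replace=False)
        for pos in positions:
            choices = _AA[_AA != arr[pos]]
            arr[pos] = choices[rng.integers(0, len(choices))]
        mutant = arr.tobytes().decode()
        measured = identity_between(mutant, seed_sequence, scheme)
        if abs(measured - target_identity) <= tolerance:
            return mutant
        k += int(round(length * (measured - target_identity) / 100)) or (
            1 if measured > target_identity else -1
        )
    raise RuntimeError(
        f"could not reach {target_identity}% identity within {max_attempts} attempts"
    )


def make_reference_db(
    n_families: int,
    subfamilies_per_family: int,
    rng: np.random.Generator | int,
    scheme: ScoringScheme | None = None,
    length: int = 420,
    max_attempts: int = 30,
) -> tuple[ReferenceDB, pd.DataFrame]:
    """A synthetic named-P450 reference set plus its pairwise identity certificate.

    Family seeds are mutually below 35% identity (regenerated until so);
    additional subfamily representatives sit at ~45-51% identity to their
    family seed, i.e. inside the family but outside the subfamily. All
    entries carry high-numbered synthetic CYP names and pass COMPLETE triage
    by construction.
    """
    if n_families < 1 or subfamilies_per_family < 1:
        raise ValueError("need at least one family and one subfamily per family")
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    scheme = scheme or ScoringScheme()
    seeds: list[tuple[str, frozenset[int]]] = []
    for _ in range(n_families):
        for _attempt in range(max_attempts):
            seq, anchors = random_p450_like(rng, length)
            if all(identity_between(seq, other, scheme) < 35 for other, _ in seeds):
                seeds.append((seq, anchors))
                break
        else:
            raise RuntimeError("could not generate mutually distant family seeds")
    entries: list[tuple[CypName, str]] = []
    for fam_idx, (seed_seq, anchors) in enumerate(seeds):
        fam_no = _SYNTHETIC_FAMILY_BASE + fam_idx
        entries.append((CypName(fam_no, "A", 1), seed_seq))
        for sub_idx in range(1, subfamilies_per_family):
            target = float(rng.integers(46, 50))
            rep = mutate_to_identity(seed_seq, target, rng, scheme, protected=anchors)
            entries.append((CypName(fam_no, chr(ord("A") + sub_idx), 1), rep))
    names = [str(n) for n, _ in entries]
    cert = pd.DataFrame(100.0, index=names, columns=names)
    for i, (_, a) in enumerate(entries):
        for j in range(i + 1, len(entries)):
            ident = identity_between(a, entries[j][1], scheme)
            cert.iloc[i, j] = cert.iloc[j, i] = ident
    # inter-family identities must stay clear of the 40% threshold band
    for i, (ni, _) in enumerate(entries):
        for j in range(i + 1, len(entries)):
            nj = entries[j][0]
            if ni.family_number != nj.family_number and cert.iloc[i, j] >= 37:
                raise RuntimeError(
                    f"inter-family identity {cert.iloc[i, j]:.1f}% between "
                    f"{ni} and {nj} is inside the threshold band"
                )
    return ReferenceDB(entries), cert


@dataclass(frozen=True)
class SpeciesSpec:
    species_id: str
    n_subfamily_level: int
    n_family_level: int
    n_new_family: int
    n_pseudo: int
    n_fragment: int
    n_non_candidate: int


def _identity_targets(rng: np.random.Generator, stress: bool) -> tuple[float, float]:
    """(subfamily-level, family-level) identity targets for one species."""
    if stress:
        return 55.0, 40.0
    return float(rng.integers(72, 84)), float(rng.integers(46, 50))


def make_proteome(
    species: SpeciesSpec,
    refdb: ReferenceDB,
    rng: np.random.Generator,
    scheme: ScoringScheme | None = None,
    seq_length: int = 420,
    fragment_max_len: int = 300,
    ref_offset: int = 0,
    threshold_stress: bool = False,
) -> tuple[list[ProteinRecord], list[GeneFeature], pd.DataFrame]:
    """One species' records, gene layout and truth rows.

    Complete P450s derive from references (cycling through the database from
    ``ref_offset``, except that the first always derives from the first
    reference so one family is cohort-dominant). Genes are laid end to end
    on a single contig, 2 kb apart, never overlapping.
    """
    scheme = scheme or ScoringScheme()
    anchors_by_name = {}
    records: list[ProteinRecord] = []
    truth_rows: list[dict] = []
    entries = refdb.entries
    idx = 0

    def add(seq: str, category: str, level: str = "", family: str = "",
            subfamily: str = "", ref: str = "", target: float = np.nan) -> None:
        nonlocal idx
        pid = f"{species.species_id}_p{idx:03d}"
        idx += 1
        records.append(ProteinRecord(pid, species.species_id, seq))
        truth_rows.append(
            dict(species_id=species.species_id, protein_id=pid, category=category,
                 level=level, family=family, subfamily=subfamily, ref=ref,
                 target_identity=target, in_bgc=False)
        )

    # complete, subfamily-level
    for k in range(species.n_subfamily_level):
        ref_i = 0 if k == 0 else (ref_offset + k) % len(entries)
        name, seq = entries[ref_i]
        if name not in anchors_by_name:
            exxr = scan_exxr(seq)[0]
            cxg = scan_cxg(seq)[0]
            anchors_by_name[name] = frozenset({exxr, exxr + 3, cxg, cxg + 2})
        target, _ = _identity_targets(rng, threshold_stress)
        mutant = mutate_to_identity(seq, target, rng, scheme, anchors_by_name[name])
        add(mutant, COMPLETE, SUBFAMILY, name.family_label, name.subfamily_label,
            str(name), target)
    # complete, family-level: derive from a family seed (subfamily "A" entry)
    seeds = [e for e in entries if e[0].subfamily_letters == "A"]
    for k in range(species.n_family_level):
        name, seq = seeds[(ref_offset + k) % len(seeds)]
        exxr = scan_exxr(seq)[0]
        cxg = scan_cxg(seq)[0]
        _, target = _identity_targets(rng, threshold_stress)
        mutant = mutate_to_identity(
            seq, target, rng, scheme, frozenset({exxr, exxr + 3, cxg, cxg + 2})
        )
        add(mutant, COMPLETE, FAMILY, name.family_label, "", str(name), target)
    # complete, novel: random P450-like, far from every reference
    for _k in range(species.n_new_family):
        for _attempt in range(30):
            seq, _ = random_p450_like(rng, seq_length)
            if all(identity_between(seq, s, scheme) < 37 for _, s in entries):
                break
        else:
            raise RuntimeError("could not generate a novel P450 far from references")
        add(seq, COMPLETE, NEW_FAMILY)
    for _k in range(species.n_pseudo):
        seq, _ = random_p450_like(rng, seq_length, motifs=("exxr",))
        add(seq, PSEUDO)
    for _k in range(species.n_fragment):
        length = int(rng.integers(80, min(180, fragment_max_len)))
        seq, _ = random_p450_like(rng, length, motifs=())
        add(seq, FRAGMENT)
    for _k in range(species.n_non_candidate):
        seq, _ = random_p450_like(rng, seq_length, motifs=())
        add(seq, NON_CANDIDATE)

    contig = f"{species.species_id}_c1"
    genes = [
        GeneFeature(
            species_id=species.species_id,
            gene_id=rec.protein_id,
            contig=contig,
            start=1000 + i * 2000,
            end=1000 + i * 2000 + 1199,
            strand="+" if i % 2 == 0 else "-",
        )
        for i, rec in enumerate(records)
    ]
    return records, genes, pd.DataFrame(truth_rows)


@dataclass
class SimBundle:
    """A full synthetic input bundle plus its truth table and truth summary."""

    spec: SimSpec
    refdb: ReferenceDB
    certificate: pd.DataFrame
    proteomes: dict[str, list[ProteinRecord]]
    genes: dict[str, list[GeneFeature]]
    clusters: list[ClusterRecord]
    truth: pd.DataFrame
    truth_summary: CohortSummary

    @property
    def species_ids(self) -> list[str]:
        return sorted(self.proteomes)

    def write(self, out_dir: str | Path) -> Path:
        """Write the bundle as the plain-text files the pipeline consumes."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.refdb.write_fasta(out / "refs.fasta")
        for sp in self.species_ids:
            write_fasta(self.proteomes[sp], out / f"{sp}.fasta")
            with open(out / f"{sp}.gff3", "w") as fh:
                fh.write("##gff-version 3\n")
                for g in self.genes[sp]:
                    fh.write(
                        f"{g.contig}\tcypminer\tgene\t{g.start}\t{g.end}\t.\t"
                        f"{g.strand}\t.\tID={g.gene_id}\n"
                    )
        write_cluster_table(self.clusters, out / "clusters.tsv")
        self.truth.to_csv(out / "truth.tsv", sep="\t", index=False)
        self.certificate.to_csv(out / "identity_certificate.tsv", sep="\t")
        self.spec.to_yaml(out / "simspec.yaml")
        return out


def make_cohort(spec: SimSpec, scheme: ScoringScheme | None = None) -> SimBundle:
    """Generate a deterministic synthetic cohort from a :class:`SimSpec`.

    Independent RNG streams are spawned per stage and species so that the
    bundle is byte-reproducible for a given spec. Novel P450s are verified
    mutually below the family threshold (and family-level mutants mutually
    below the subfamily threshold), so the truth summary follows from the
    planted design by counting alone.
    """
    scheme = scheme or ScoringScheme()
    root = np.random.SeedSequence(spec.seed)
    ref_ss, *species_ss = root.spawn(1 + spec.n_species)
    refdb, cert = make_reference_db(
        spec.n_ref_families,
        spec.subfamilies_per_family,
        np.random.default_rng(ref_ss),
        scheme,
        length=spec.seq_length,
    )
    proteomes: dict[str, list[ProteinRecord]] = {}
    genes: dict[str, list[GeneFeature]] = {}
    truths: list[pd.DataFrame] = []
    clusters: list[ClusterRecord] = []
    for s_idx in range(spec.n_species):
        sp_id = f"sp{s_idx + 1:02d}"
        rng = np.random.default_rng(species_ss[s_idx])
        sp_spec = SpeciesSpec(
            sp_id,
            spec.n_subfamily_level,
            spec.n_family_level,
            spec.n_new_family,
            spec.n_pseudo,
            spec.n_fragment,
            spec.n_non_candidate,
        )
        records, sp_genes, truth = make_proteome(
            sp_spec,
            refdb,
            rng,
            scheme,
            seq_length=spec.seq_length,
            fragment_max_len=spec.fragment_max_len,
            ref_offset=s_idx,
            threshold_stress=spec.threshold_stress,
        )
        # lay clusters over a known fraction of complete-P450 genes
        complete_ids = truth.loc[truth.category == COMPLETE, "protein_id"].tolist()
        n_in = int(round(spec.in_bgc_fraction * len(complete_ids)))
        chosen = sorted(
            rng.choice(len(complete_ids), size=n_in, replace=False).tolist()
        )
        gene_by_id = {g.gene_id: g for g in sp_genes}
        for j, ci in enumerate(chosen):
            pid = complete_ids[ci]
            g = gene_by_id[pid]
            n_types = int(rng.integers(1, 3))
            types = tuple(
                _CLUSTER_TYPES[t]
                for t in rng.choice(len(_CLUSTER_TYPES), size=n_types, replace=False)
            )
            known = _KNOWN_CLUSTERS[rng.integers(0, len(_KNOWN_CLUSTERS))]
            clusters.append(
                ClusterRecord(
                    species_id=sp_id,
                    cluster_id=f"{sp_id}_bgc{j + 1:02d}",
                    contig=g.contig,
                    start=g.start - 300,
                    end=g.end + 300,
                    type_labels=types,
                    known_cluster=known,
                    similarity_pct=float(rng.integers(40, 100)) if known else None,
                )
            )
            truth.loc[truth.protein_id == pid, "in_bgc"] = True
        tail = 1000 + (len(sp_genes) + 2) * 2000
        for j in range(spec.n_decoy_clusters):
            t = _CLUSTER_TYPES[rng.integers(0, len(_CLUSTER_TYPES))]
            clusters.append(
                ClusterRecord(
                    species_id=sp_id,
                    cluster_id=f"{sp_id}_decoy{j + 1:02d}",
                    contig=f"{sp_id}_c1",
                    start=tail + j * 5000,
                    end=tail + j * 5000 + 2999,
                    type_labels=(t,),
                )
            )
        proteomes[sp_id] = records
        genes[sp_id] = sp_genes
        truths.append(truth)
    truth = pd.concat(truths, ignore_index=True)
    _verify_novel_separation(truth, proteomes, scheme)
    return SimBundle(
        spec=spec,
        refdb=refdb,
        certificate=cert,
        proteomes=proteomes,
        genes=genes,
        clusters=clusters,
        truth=truth,
        truth_summary=_truth_summary(spec, truth),
    )


def _verify_novel_separation(
    truth: pd.DataFrame,
    proteomes: dict[str, list[ProteinRecord]],
    scheme: ScoringScheme,
) -> None:
    """Check cross-species identity structure the planted design assumes.

    Novel P450s must be mutually below the family threshold band (each
    founds its own new family) and family-level mutants of the same
    reference must be mutually below the subfamily band (each founds its own
    subfamily). Random 400-mers sit near 10% mutual identity, so failures
    mean a generator bug rather than bad luck.
    """
    seq = {
        r.protein_id: r.sequence for recs in proteomes.values() for r in recs
    }
    novel = truth.loc[truth.level == NEW_FAMILY, "protein_id"].tolist()
    for i in range(len(novel)):
        for j in range(i + 1, len(novel)):
            ident = identity_between(seq[novel[i]], seq[novel[j]], scheme)
            if ident >= 37:
                raise RuntimeError(
                    f"novel P450s {novel[i]} and {novel[j]} share {ident:.1f}% identity"
                )
    fam_level = truth.loc[truth.level == FAMILY]
    for ref, group in fam_level.groupby("ref"):
        ids = group.protein_id.tolist()
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                ident = identity_between(seq[ids[i]], seq[ids[j]], scheme)
                if ident >= 52:
                    raise RuntimeError(
                        f"family-level mutants {ids[i]} and {ids[j]} share "
                        f"{ident:.1f}% identity"
                    )


def _truth_summary(spec: SimSpec, truth: pd.DataFrame) -> CohortSummary:
    """The cohort summary implied by the planted design, by counting alone."""
    complete = truth[truth.category == COMPLETE]
    named = complete[complete.family != ""]
    n_novel = int((complete.level == NEW_FAMILY).sum())
    n_family_level = int((complete.level == FAMILY).sum())
    families = set(named.family)
    named_subfams = set(
        complete.loc[complete.level == SUBFAMILY, "subfamily"]
    )
    # dominance: member counts per named family; each novel founds a family of one
    fam_counts = named.family.value_counts()
    dominant = sorted(
        fam_counts.items(), key=lambda kv: (-kv[1], kv[0])
    )[0][0] if len(fam_counts) else ""
    total = len(complete)
    n_in_bgc = int(complete.in_bgc.sum())
    n_species = spec.n_species
    n_bgc = n_species * spec.n_decoy_clusters + n_in_bgc  # one cluster per in-BGC P450
    return CohortSummary(
        n_species=n_species,
        total_p450s=total,
        n_families=len(families) + n_novel,
        n_subfamilies=len(named_subfams) + n_family_level + n_novel,
        dominant_family=dominant,
        avg_p450s=rounded_mean(total, n_species),
        n_bgc_species=n_species,
        total_bgcs=n_bgc,
        avg_bgcs=rounded_mean(n_bgc, n_species),
        total_p450s_in_bgcs=n_in_bgc,
        pct_p450s_in_bgcs=truncated_percent(n_in_bgc, total),
    )
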