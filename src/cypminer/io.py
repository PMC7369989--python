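"""Readers/writers for the formats the pipeline touches, and the CYP name grammar.

All genomic coordinates are 1-based inclusive (GFF3 convention) throughout the
package; any half-open/0-based input must be converted at the boundary.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio.SeqIO.FastaIO import SimpleFastaParser

__all__ = [
    "ProteinRecord",
    "CypName",
    "GeneFeature",
    "ClusterRecord",
    "read_fasta",
    "write_fasta",
    "parse_cyp_name",
    "read_gff_genes",
    "read_cluster_table",
    "write_cluster_table",
]

_VALID_SEQ = re.compile(r"^[A-Z]+$")


@dataclass(frozen=True)
class ProteinRecord:
    """One amino-acid sequence with its species and identifier."""

    protein_id: str
    species_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"empty sequence for protein {self.protein_id!r}")
        if not _VALID_SEQ.match(self.sequence):
            bad = sorted(set(re.sub(r"[A-Z]", "", self.sequence)))
            raise ValueError(
                f"protein {self.protein_id!r}: sequence contains invalid "
                f"characters {bad} (uppercase A-Z required)"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True, order=True)
class CypName:
    """A committee-style cytochrome P450 name: CYP + family [+ subfamily [+ member]].

    ``CYP105D6`` is family 105, subfamily D, member 6. Family and subfamily
    labels (``CYP105``, ``CYP105D``) are derived, not stored.
    """

    family_number: int
    subfamily_letters: str = ""
    member: int | None = None

    def __post_init__(self) -> None:
        if self.family_number <= 0:
            raise ValueError("family_number must be positive")
        letters = self.subfamily_letters
        if len(letters) > 2 or (letters and not (letters.isalpha() and letters.isupper())):
            raise ValueError(f"bad subfamily letters {letters!r}")
        if self.member is not None and self.member <= 0:
            raise ValueError("member number must be positive")

    @property
    def family_label(self) -> str:
        return f"CYP{self.family_number}"

    @property
    def subfamily_label(self) -> str:
        return f"CYP{self.family_number}{self.subfamily_letters}"

    def __str__(self) -> str:
        member = "" if self.member is None else str(self.member)
        return f"CYP{self.family_number}{self.subfamily_letters}{member}"


_CYP_RE = re.compile(r"^CYP(\d+)([A-Z]*)(\d*)$", re.IGNORECASE)


def parse_cyp_name(token: str) -> CypName:
    """Parse a CYP nomenclature token into its family / subfamily / member parts.

    The split is greedy: digits after "CYP" are the family number, the
    following run of 1-2 uppercase letters the subfamily, trailing digits the
    member number. Family-only ("CYP154") and family+subfamily tokens are
    accepted; anything else is rejected.
    """
    m = _CYP_RE.match(token.strip())
    if m is None:
        if not token.upper().startswith("CYP"):
            raise ValueError(f"{token!r} does not start with 'CYP'")
        raise ValueError(f"cannot parse CYP name {token!r}")
    fam, letters, member = m.groups()
    if not fam:
        raise ValueError(f"no family number in {token!r}")
    if len(letters) > 2:
        raise ValueError(
            f"{token!r}: {len(letters)} subfamily letters (at most 2 supported)"
        )
    if member and not letters:
        # greedy digits consume everything, so this cannot occur; guard anyway
        raise ValueError(f"{token!r}: member number without subfamily letters")
    return CypName(
        family_number=int(fam),
        subfamily_letters=letters.upper(),
        member=int(member) if member else None,
    )


@dataclass(frozen=True)
class GeneFeature:
    """A gene interval on a contig, 1-based inclusive coordinates."""

    species_id: str
    gene_id: str
    contig: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(
                f"gene {self.gene_id!r}: invalid interval [{self.start}, {self.end}]"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"gene {self.gene_id!r}: invalid strand {self.strand!r}")


@dataclass(frozen=True)
class ClusterRecord:
    """One secondary-metabolite BGC interval with its type labels.

    Mirrors an antiSMASH-style per-cluster summary row: coordinates, one or
    more type labels (terpene, T1PKS, NRPS, ...), the most similar known
    cluster, and percent similarity to it (both optional).
    """

    species_id: str
    cluster_id: str
    contig: str
    start: int
    end: int
    type_labels: tuple[str, ...]
    known_cluster: str = ""
    similarity_pct: float | None = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"cluster {self.cluster_id!r}: start {self.start} > end {self.end}"
            )
        if not self.type_labels or any(not t for t in self.type_labels):
            raise ValueError(f"cluster {self.cluster_id!r}: empty type label list")
        if self.similarity_pct is not None and not (0 <= self.similarity_pct <= 100):
            raise ValueError(
                f"cluster {self.cluster_id!r}: similarity {self.similarity_pct} "
                "outside [0, 100]"
            )


def read_fasta(path: str | Path, species_id: str | None = None) -> list[ProteinRecord]:
    """Read a protein FASTA into ProteinRecords.

    Multi-line sequences are concatenated, whitespace inside sequence lines is
    stripped, and residues are uppercased. ``species_id`` defaults to the file
    stem (one proteome file per species).
    """
    path = Path(path)
    if species_id is None:
        species_id = path.stem
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    with open(path) as handle:
        for title, seq in SimpleFastaParser(handle):
            pid = title.split()[0] if title.split() else title
            if pid in seen:
                raise ValueError(f"{path}: duplicate protein id {pid!r}")
            seen.add(pid)
            seq = re.sub(r"\s+", "", seq).upper()
            records.append(ProteinRecord(pid, species_id, seq))
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path, width: int = 60) -> None:
    """Write ProteinRecords as FASTA, wrapping sequence lines at ``width``."""
    with open(path, "w") as out:
        for rec in records:
            out.write(f">{rec.protein_id}\n")
            for i in range(0, len(rec.sequence), width):
                out.write(rec.sequence[i : i + width] + "\n")


_DEFAULT_FEATURE_KINDS = frozenset({"gene", "CDS"})
_ID_RE = re.compile(r"(?:^|;)\s*ID=([^;]+)")


def read_gff_genes(
    path: str | Path,
    feature_kinds: Iterable[str] = _DEFAULT_FEATURE_KINDS,
    species_id: str | None = None,
) -> list[GeneFeature]:
    """Read gene features from a GFF3 file (9 tab-separated columns).

    Only rows whose feature type (column 3) is in ``feature_kinds`` are
    returned. ``gene_id`` is taken from the ``ID=`` attribute. Coordinates are
    kept 1-based inclusive exactly as in the file.
    """
    path = Path(path)
    kinds = set(feature_kinds)
    if species_id is None:
        species_id = path.stem
    genes: list[GeneFeature] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 9:
                raise ValueError(
                    f"{path}:{lineno}: expected 9 tab-separated columns, got {len(cols)}"
                )
            contig, _source, kind, start, end, _score, strand, _frame, attrs = cols[:9]
            if kind not in kinds:
                continue
            start_i, end_i = int(start), int(end)
            if end_i < start_i:
                raise ValueError(f"{path}:{lineno}: end {end_i} < start {start_i}")
            m = _ID_RE.search(attrs)
            if m is None:
                raise ValueError(f"{path}:{lineno}: no ID= attribute")
            genes.append(
                GeneFeature(
                    species_id=species_id,
                    gene_id=m.group(1).strip(),
                    contig=contig,
                    start=start_i,
                    end=end_i,
                    strand=strand if strand in ("+", "-", ".") else ".",
                )
            )
    return genes


_CLUSTER_COLUMNS = [
    "species_id",
    "cluster_id",
    "contig",
    "start",
    "end",
    "types",
    "known_cluster",
    "similarity_pct",
]


def read_cluster_table(path: str | Path) -> list[ClusterRecord]:
    """Read an antiSMASH-style BGC summary TSV into ClusterRecords.

    Required columns: species_id, cluster_id, contig, start, end, types
    (semicolon-separated labels), known_cluster, similarity_pct. The last two
    may be empty.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _CLUSTER_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    clusters: list[ClusterRecord] = []
    for row in df.itertuples(index=False):
        try:
            start, end = int(row.start), int(row.end)
        except ValueError as exc:
            raise ValueError(
                f"{path}: non-numeric coordinates for cluster {row.cluster_id!r}"
            ) from exc
        sim = row.similarity_pct.strip()
        clusters.append(
            ClusterRecord(
                species_id=row.species_id,
                cluster_id=row.cluster_id,
                contig=row.contig,
                start=start,
                end=end,
                type_labels=tuple(t.strip() for t in row.types.split(";") if t.strip()),
                known_cluster=row.known_cluster.strip(),
                similarity_pct=float(sim) if sim else None,
            )
        )
    return clusters


def write_cluster_table(clusters: Sequence[ClusterRecord], path: str | Path) -> None:
    rows = [
        {
            "species_id": c.species_id,
            "cluster_id": c.cluster_id,
            "contig": c.contig,
            "start": c.start,
            "end": c.end,
            "types": ";".join(c.type_labels),
            "known_cluster": c.known_cluster,
            "similarity_pct": "" if c.similarity_pct is None else f"{c.similarity_pct:g}",
        }
        for c in clusters
    ]
    pd.DataFrame(rows, columns=_CLUSTER_COLUMNS).to_csv(path, sep="\t", index=False)
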