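"""CYP family/subfamily assignment by nearest named homolog.

The nomenclature rule: a P450 sharing more than 40% identity with a named
homolog belongs to the same family, more than 55% to the same subfamily, and
at 40% or below it founds a new family. Both inequalities are strict:
exactly 55% identity is a family-level call, exactly 40% a new family.

Queries falling below the family threshold receive placeholder family labels
(NEWF001, NEWF002, ...) instead of committee-issued CYP numbers, which only
the nomenclature committee can mint. Novel queries that share more than 40%
identity with each other are merged into one placeholder family by
single-linkage; family-level queries likewise share a placeholder subfamily
when linked above 55%.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from sklearn.base import BaseEstimator

from .align import ScoringScheme, identity_between
from .io import CypName, ProteinRecord, parse_cyp_name, read_fasta
from .triage import COMPLETE, triage

__all__ = [
    "ReferenceDB",
    "Assignment",
    "SUBFAMILY",
    "FAMILY",
    "NEW_FAMILY",
    "DEFAULT_THRESHOLDS",
    "assign",
    "allocate_placeholders",
    "classify_proteome",
    "NearestHomologClassifier",
]

SUBFAMILY = "SUBFAMILY"
FAMILY = "FAMILY"
NEW_FAMILY = "NEW_FAMILY"

#: (family threshold, subfamily threshold) in percent identity
DEFAULT_THRESHOLDS = (40.0, 55.0)


class ReferenceDB:
    """A database of named P450 reference sequences, indexed by name.

    Every entry must parse as a CYP name and pass motif triage as a COMPLETE
    P450; names must be unique.
    """

    def __init__(self, entries: Iterable[tuple[CypName, str]]):
        self.entries: list[tuple[CypName, str]] = sorted(
            entries, key=lambda e: str(e[0])
        )
        if not self.entries:
            raise ValueError("reference database is empty")
        names = [str(n) for n, _ in self.entries]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise ValueError(f"duplicate reference names: {sorted(dupes)}")
        bad = [
            str(name)
            for name, seq in self.entries
            if triage(ProteinRecord(str(name), "ref", seq)).category != COMPLETE
        ]
        if bad:
            raise ValueError(
                f"reference sequences failing COMPLETE triage: {bad}"
            )
        self.by_family: dict[str, list[CypName]] = {}
        self.by_subfamily: dict[str, list[CypName]] = {}
        for name, _ in self.entries:
            self.by_family.setdefault(name.family_label, []).append(name)
            self.by_subfamily.setdefault(name.subfamily_label, []).append(name)

    def __len__(self) -> int:
        return len(self.entries)

    @classmethod
    def from_fasta(cls, path: str | Path) -> "ReferenceDB":
        """Load references from FASTA; the first header token must be a CYP name."""
        records = read_fasta(path, species_id="reference")
        return cls((parse_cyp_name(r.protein_id), r.sequence) for r in records)

    def write_fasta(self, path: str | Path) -> None:
        from .io import write_fasta

        write_fasta(
            [ProteinRecord(str(n), "reference", s) for n, s in self.entries], path
        )


@dataclass(frozen=True)
class Assignment:
    """Best named homolog and the resulting family/subfamily call for one query.

    ``family_label`` / ``subfamily_label`` are None until placeholder
    allocation for NEW_FAMILY calls and for the subfamily of FAMILY-level
    calls (see :func:`allocate_placeholders`).
    """

    species_id: str
    protein_id: str
    best_ref: CypName
    best_identity: float
    level: str
    family_label: str | None
    subfamily_label: str | None


def assign(
    query: ProteinRecord,
    refdb: ReferenceDB,
    scheme: ScoringScheme | None = None,
    thresholds: tuple[float, float] = DEFAULT_THRESHOLDS,
) -> Assignment:
    """Assign one query against every reference; keep the best identity.

    Ties on identity are broken by lexicographically smallest reference name
    for reproducibility. Threshold comparisons are strict (identity must
    exceed the threshold to qualify).
    """
    scheme = scheme or ScoringScheme()
    fam_thr, subfam_thr = thresholds
    if fam_thr >= subfam_thr:
        raise ValueError("family threshold must be below subfamily threshold")
    best_name: CypName | None = None
    best_ident = -1.0
    # entries are pre-sorted by name, so strict > keeps the smallest name on ties
    for name, seq in refdb.entries:
        ident = identity_between(query.sequence, seq, scheme)
        if ident > best_ident:
            best_ident = ident
            best_name = name
    assert best_name is not None
    if best_ident > subfam_thr:
        level = SUBFAMILY
        family = best_name.family_label
        subfamily = best_name.subfamily_label
    elif best_ident > fam_thr:
        level = FAMILY
        family = best_name.family_label
        subfamily = None  # placeholder pending
    else:
        level = NEW_FAMILY
        family = None
        subfamily = None
    return Assignment(
        species_id=query.species_id,
        protein_id=query.protein_id,
        best_ref=best_name,
        best_identity=best_ident,
        level=level,
        family_label=family,
        subfamily_label=subfamily,
    )


def _single_linkage(
    ids: Sequence[str],
    seqs: Mapping[str, str],
    threshold: float,
    scheme: ScoringScheme,
) -> list[int]:
    """Union-find single-linkage clustering over the >threshold identity relation.

    Returns, for each id, the index of its cluster; clusters are numbered by
    first appearance in ``ids``.
    """
    parent = list(range(len(ids)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            if find(i) == find(j):
                continue
            ident = identity_between(seqs[ids[i]], seqs[ids[j]], scheme)
            if ident > threshold:
                ri, rj = find(i), find(j)
                # keep the smaller root so cluster numbering follows first appearance
                if ri < rj:
                    parent[rj] = ri
                else:
                    parent[ri] = rj
    roots: list[int] = []
    labels = []
    for i in range(len(ids)):
        r = find(i)
        if r not in roots:
            roots.append(r)
        labels.append(roots.index(r))
    return labels


def allocate_placeholders(
    assignments: Sequence[Assignment],
    sequences: Mapping[str, str],
    scheme: ScoringScheme | None = None,
    thresholds: tuple[float, float] = DEFAULT_THRESHOLDS,
) -> list[Assignment]:
    """Fill placeholder family/subfamily labels, deterministically.

    ``assignments`` must be sorted by (species_id, protein_id). NEW_FAMILY
    queries get NEWF001, NEWF002, ... in order of first appearance, merging
    queries linked above the family threshold into one placeholder family;
    within such a family, queries linked above the subfamily threshold share
    a subfamily placeholder (``NEWF001-newSF1``). FAMILY-level queries get
    per-family subfamily placeholders (``CYP105-newSF1``) grouped the same
    way.
    """
    scheme = scheme or ScoringScheme()
    fam_thr, subfam_thr = thresholds
    keys = [(a.species_id, a.protein_id) for a in assignments]
    if keys != sorted(keys):
        raise ValueError("assignments must be sorted by (species_id, protein_id)")
    out = list(assignments)
    index = {a.protein_id: i for i, a in enumerate(assignments)}

    # new families: single-linkage over the >40% relation
    new_ids = [a.protein_id for a in assignments if a.level == NEW_FAMILY]
    fam_of = _single_linkage(new_ids, sequences, fam_thr, scheme)
    for cluster in range(max(fam_of, default=-1) + 1):
        members = [pid for pid, c in zip(new_ids, fam_of) if c == cluster]
        fam_label = f"NEWF{cluster + 1:03d}"
        sub_of = _single_linkage(members, sequences, subfam_thr, scheme)
        for pid, sc in zip(members, sub_of):
            i = index[pid]
            out[i] = replace(
                out[i],
                family_label=fam_label,
                subfamily_label=f"{fam_label}-newSF{sc + 1}",
            )

    # family-level queries: per-family subfamily placeholders
    fam_groups: dict[str, list[str]] = {}
    for a in assignments:
        if a.level == FAMILY:
            fam_groups.setdefault(a.family_label, []).append(a.protein_id)
    for fam_label in sorted(fam_groups):
        members = fam_groups[fam_label]
        sub_of = _single_linkage(members, sequences, subfam_thr, scheme)
        for pid, sc in zip(members, sub_of):
            i = index[pid]
            out[i] = replace(out[i], subfamily_label=f"{fam_label}-newSF{sc + 1}")
    return out


def classify_proteome(
    records: Sequence[ProteinRecord],
    refdb: ReferenceDB,
    scheme: ScoringScheme | None = None,
    thresholds: tuple[float, float] = DEFAULT_THRESHOLDS,
) -> list[Assignment]:
    """Classify COMPLETE-triaged records and finalise placeholder labels.

    Records may span several species (placeholder numbering is then
    cohort-wide); output is sorted by (species_id, protein_id) and is
    deterministic given its inputs.
    """
    scheme = scheme or ScoringScheme()
    ordered = sorted(records, key=lambda r: (r.species_id, r.protein_id))
    ids = [(r.species_id, r.protein_id) for r in ordered]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate (species_id, protein_id) among records")
    assignments = [assign(r, refdb, scheme, thresholds) for r in ordered]
    sequences = {r.protein_id: r.sequence for r in ordered}
    return allocate_placeholders(assignments, sequences, scheme, thresholds)


class NearestHomologClassifier(BaseEstimator):
    """Nearest-named-homolog CYP classifier (sklearn-style estimator).

    Fit on a reference database of named P450s; predict yields one
    :class:`Assignment` per query protein, with family/subfamily resolved by
    the >40% / >55% identity rules and placeholder labels allocated for novel
    queries.

    Parameters
    ----------
    matrix_name, gap_open, gap_extend, mode :
        Alignment scoring (see :class:`~cypminer.align.ScoringScheme`).
    family_threshold, subfamily_threshold :
        Percent-identity cutoffs; strict inequalities apply.
    """

    def __init__(
        self,
        matrix_name: str = "BLOSUM62",
        gap_open: float = 10.0,
        gap_extend: float = 1.0,
        mode: str = "global",
        family_threshold: float = DEFAULT_THRESHOLDS[0],
        subfamily_threshold: float = DEFAULT_THRESHOLDS[1],
    ):
        self.matrix_name = matrix_name
        self.gap_open = gap_open
        self.gap_extend = gap_extend
        self.mode = mode
        self.family_threshold = family_threshold
        self.subfamily_threshold = subfamily_threshold

    def _scheme(self) -> ScoringScheme:
        return ScoringScheme(self.matrix_name, self.gap_open, self.gap_extend, self.mode)

    def fit(self, X, y=None) -> "NearestHomologClassifier":
        """Fit from a ReferenceDB, a FASTA path, or (CypName|str, sequence) pairs."""
        if isinstance(X, ReferenceDB):
            refdb = X
        elif isinstance(X, (str, Path)):
            refdb = ReferenceDB.from_fasta(X)
        else:
            refdb = ReferenceDB(
                (n if isinstance(n, CypName) else parse_cyp_name(n), s) for n, s in X
            )
        self._scheme()  # validates parameters
        self.refdb_ = refdb
        self.n_references_ = len(refdb)
        return self

    def predict(self, X: Sequence[ProteinRecord]) -> list[Assignment]:
        if not hasattr(self, "refdb_"):
            raise ValueError("classifier is not fitted; call fit() first")
        return classify_proteome(
            X,
            self.refdb_,
            self._scheme(),
            (self.family_threshold, self.subfamily_threshold),
        )
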