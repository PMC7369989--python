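"""Motif-based triage of candidate P450 proteins.

Bacterial cytochrome P450s carry two highly conserved sequence signatures:
the K-helix ExxR salt-bridge motif and the CxG motif around the heme-binding
cysteine. A candidate carrying both motifs is a complete P450; one motif only
marks a pseudo-P450; neither motif plus short length marks a P450 fragment;
neither motif at full length is a non-candidate (false-positive hit). Only
complete P450s proceed to family/subfamily classification.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

from sklearn.base import BaseEstimator

from .io import ProteinRecord

__all__ = [
    "TriageCategory",
    "TriageCall",
    "TriageSummary",
    "scan_exxr",
    "scan_cxg",
    "triage",
    "triage_proteome",
    "MotifTriager",
    "DEFAULT_FRAGMENT_MAX_LEN",
]

# "Short" is undefined for fragments; a typical bacterial P450 is ~400
# residues, so anything under 300 without motifs is treated as a truncation.
DEFAULT_FRAGMENT_MAX_LEN = 300

COMPLETE = "COMPLETE"
PSEUDO = "PSEUDO"
FRAGMENT = "FRAGMENT"
NON_CANDIDATE = "NON_CANDIDATE"
CATEGORIES = (COMPLETE, PSEUDO, FRAGMENT, NON_CANDIDATE)
TriageCategory = str

_EXXR = re.compile(r"(?=E..R)")
_CXG = re.compile(r"(?=C.G)")


@dataclass(frozen=True)
class TriageCall:
    protein_id: str
    category: TriageCategory
    exxr_positions: tuple[int, ...]
    cxg_positions: tuple[int, ...]
    length: int


@dataclass(frozen=True)
class TriageSummary:
    species_id: str
    counts: dict[TriageCategory, int]

    @property
    def n_total(self) -> int:
        return sum(self.counts.values())


def scan_exxr(sequence: str) -> list[int]:
    """All 0-based start positions of the ExxR motif (E, any two, R).

    Overlapping matches are all reported, in ascending order. Wildcard
    positions match any residue letter, including X; the E and R anchors must
    match exactly.
    """
    return [m.start() for m in _EXXR.finditer(sequence)]


def scan_cxg(sequence: str) -> list[int]:
    """All 0-based start positions of the CxG heme-loop motif (C, any, G)."""
    return [m.start() for m in _CXG.finditer(sequence)]


def triage(record: ProteinRecord, fragment_max_len: int = DEFAULT_FRAGMENT_MAX_LEN) -> TriageCall:
    """Categorise one candidate protein from its motif content and length.

    Both motifs -> COMPLETE; exactly one -> PSEUDO; neither and shorter than
    ``fragment_max_len`` -> FRAGMENT; neither at or above that length ->
    NON_CANDIDATE.
    """
    if fragment_max_len <= 0:
        raise ValueError("fragment_max_len must be positive")
    exxr = tuple(scan_exxr(record.sequence))
    cxg = tuple(scan_cxg(record.sequence))
    if exxr and cxg:
        category = COMPLETE
    elif exxr or cxg:
        category = PSEUDO
    elif len(record.sequence) < fragment_max_len:
        category = FRAGMENT
    else:
        category = NON_CANDIDATE
    return TriageCall(record.protein_id, category, exxr, cxg, len(record.sequence))


def triage_proteome(
    records: Sequence[ProteinRecord],
    fragment_max_len: int = DEFAULT_FRAGMENT_MAX_LEN,
) -> tuple[list[TriageCall], TriageSummary]:
    """Triage a whole single-species proteome; returns calls plus a tally."""
    species = {r.species_id for r in records}
    if len(species) > 1:
        raise ValueError(f"records span multiple species: {sorted(species)}")
    calls = [triage(r, fragment_max_len) for r in records]
    tally = Counter(c.category for c in calls)
    counts = {cat: tally.get(cat, 0) for cat in CATEGORIES}
    species_id = next(iter(species)) if species else ""
    return calls, TriageSummary(species_id, counts)


class MotifTriager(BaseEstimator):
    """Stateless estimator wrapper around motif triage.

    Parameters
    ----------
    fragment_max_len : int
        Length below which a motif-free protein is called a FRAGMENT rather
        than a NON_CANDIDATE (residues; default 300).
    """

    def __init__(self, fragment_max_len: int = DEFAULT_FRAGMENT_MAX_LEN):
        self.fragment_max_len = fragment_max_len

    def fit(self, X: Iterable[ProteinRecord] | None = None, y=None) -> "MotifTriager":
        if self.fragment_max_len <= 0:
            raise ValueError("fragment_max_len must be positive")
        self.n_features_in_ = 1
        return self

    def predict(self, X: Iterable[ProteinRecord]) -> list[TriageCall]:
        return [triage(rec, self.fragment_max_len) for rec in X]
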