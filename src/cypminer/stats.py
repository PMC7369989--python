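"""Cohort-level comparative statistics and roll-ups.

Conventions match the published comparative tables these roll-ups emulate:
per-genus averages are integer-rounded half away from zero, percentages are
truncated (floored), and the species-by-family presence matrix is encoded 3
for presence and -3 for absence (the heat-map export convention). "Number of
P450s" always means complete P450s only; pseudo-P450s and fragments are
excluded upstream by triage. A P450 sitting in two clusters counts once
toward the percentage of P450s in BGCs.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .bgc import ClusterMembership
from .classify import Assignment
from .io import ClusterRecord

__all__ = [
    "SpeciesProfile",
    "CohortSummary",
    "rounded_mean",
    "truncated_percent",
    "modal_count",
    "count_range",
    "presence_matrix",
    "family_tally",
    "conserved_families",
    "subfamily_diversity",
    "build_species_profiles",
    "cohort_summary",
]


def rounded_mean(total: int, n: int) -> int:
    """total / n rounded half away from zero to an integer."""
    if n < 1:
        raise ValueError("n must be >= 1")
    q = total / n
    return int(math.floor(q + 0.5)) if q >= 0 else int(math.ceil(q - 0.5))


def truncated_percent(part: int, total: int) -> int:
    """floor(100 * part / total)."""
    if total < 1:
        raise ValueError("total must be >= 1")
    if part > total:
        raise ValueError("part exceeds total")
    return (100 * part) // total


def modal_count(values: Sequence[int]) -> int:
    """Most frequent value; ties broken by the smallest value."""
    if not values:
        raise ValueError("empty value list")
    counts = Counter(values)
    return min(counts, key=lambda v: (-counts[v], v))


def count_range(values: Sequence[int]) -> tuple[int, int]:
    if not values:
        raise ValueError("empty value list")
    return min(values), max(values)


@dataclass(frozen=True)
class SpeciesProfile:
    """Per-species roll-up: P450 count, family/subfamily sets, BGC counts.

    ``n_bgc`` is None for species without cluster data (they are excluded
    from BGC totals and averages, mirroring surveys where only a subset of
    genomes passes cluster detection).
    """

    species_id: str
    n_p450: int
    family_labels: frozenset[str]
    subfamily_labels: frozenset[str]
    n_in_bgc: int
    n_bgc: int | None

    def __post_init__(self) -> None:
        if len(self.subfamily_labels) < len(self.family_labels):
            raise ValueError(
                f"{self.species_id}: fewer subfamilies than families"
            )
        if self.n_in_bgc > self.n_p450:
            raise ValueError(f"{self.species_id}: n_in_bgc exceeds n_p450")


@dataclass(frozen=True)
class CohortSummary:
    """The per-genus comparative roll-up (totals, averages, percentages)."""

    n_species: int
    total_p450s: int
    n_families: int
    n_subfamilies: int
    dominant_family: str
    avg_p450s: int
    n_bgc_species: int
    total_bgcs: int
    avg_bgcs: int
    total_p450s_in_bgcs: int
    pct_p450s_in_bgcs: int


def presence_matrix(
    profiles: Sequence[SpeciesProfile], family_order: Sequence[str]
) -> pd.DataFrame:
    """Species-by-family incidence matrix encoded 3 (present) / -3 (absent)."""
    used = set().union(*(p.family_labels for p in profiles)) if profiles else set()
    missing = used - set(family_order)
    if missing:
        raise ValueError(f"family order is missing families: {sorted(missing)}")
    data = [
        [3 if fam in p.family_labels else -3 for fam in family_order]
        for p in profiles
    ]
    return pd.DataFrame(
        data,
        index=[p.species_id for p in profiles],
        columns=list(family_order),
        dtype=int,
    )


def family_tally(assignments: Sequence[Assignment]) -> list[tuple[str, int]]:
    """Members per family across the cohort, count descending then name ascending."""
    counts = Counter(a.family_label for a in assignments)
    return sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))


def conserved_families(profiles: Sequence[SpeciesProfile]) -> set[str]:
    """Families present in every species of the cohort."""
    if not profiles:
        raise ValueError("no profiles")
    out = set(profiles[0].family_labels)
    for p in profiles[1:]:
        out &= p.family_labels
    return out


def subfamily_diversity(
    assignments: Sequence[Assignment],
) -> dict[str, dict[str, int]]:
    """Per family: member counts per subfamily (diversity = number of keys)."""
    out: dict[str, dict[str, int]] = {}
    for a in assignments:
        fam = out.setdefault(a.family_label, {})
        fam[a.subfamily_label] = fam.get(a.subfamily_label, 0) + 1
    return out


def build_species_profiles(
    assignments: Sequence[Assignment],
    memberships: Sequence[ClusterMembership],
    clusters: Sequence[ClusterRecord],
    species_ids: Iterable[str] | None = None,
    bgc_species: Iterable[str] | None = None,
) -> list[SpeciesProfile]:
    """Assemble per-species profiles from classification and BGC results.

    ``species_ids`` fixes the species set and order (default: species seen in
    assignments, sorted). ``bgc_species`` restricts which species count as
    having cluster data (default: all).
    """
    if species_ids is None:
        species_ids = sorted({a.species_id for a in assignments})
    species_ids = list(species_ids)
    bgc_set = set(species_ids) if bgc_species is None else set(bgc_species)
    by_species: dict[str, list[Assignment]] = {s: [] for s in species_ids}
    for a in assignments:
        if a.species_id not in by_species:
            raise ValueError(f"assignment for unknown species {a.species_id!r}")
        by_species[a.species_id].append(a)
    in_bgc: dict[str, set[str]] = {s: set() for s in species_ids}
    for m in memberships:
        in_bgc[m.species_id].add(m.protein_id)
    n_bgc: dict[str, int] = {s: 0 for s in species_ids}
    for c in clusters:
        if c.species_id in n_bgc:
            n_bgc[c.species_id] += 1
    profiles = []
    for s in species_ids:
        asn = by_species[s]
        profiles.append(
            SpeciesProfile(
                species_id=s,
                n_p450=len(asn),
                family_labels=frozenset(a.family_label for a in asn),
                subfamily_labels=frozenset(a.subfamily_label for a in asn),
                n_in_bgc=len(in_bgc[s]),
                n_bgc=n_bgc[s] if s in bgc_set else None,
            )
        )
    return profiles


def cohort_summary(
    profiles: Sequence[SpeciesProfile],
    assignments: Sequence[Assignment],
    memberships: Sequence[ClusterMembership],
) -> CohortSummary:
    """Roll a cohort up into the comparative-table summary.

    The percentage of P450s in BGCs uses the same species set for numerator
    and denominator: only species with cluster data contribute to either.
    """
    if not profiles:
        raise ValueError("no profiles")
    known = {p.species_id for p in profiles}
    stray = {a.species_id for a in assignments} - known
    stray |= {m.species_id for m in memberships} - known
    if stray:
        raise ValueError(f"ids outside the profiled species set: {sorted(stray)}")
    total_p450s = sum(p.n_p450 for p in profiles)
    families = set().union(*(p.family_labels for p in profiles))
    subfamilies = set().union(*(p.subfamily_labels for p in profiles))
    tally = family_tally(assignments)
    dominant = tally[0][0] if tally else ""
    bgc_profiles = [p for p in profiles if p.n_bgc is not None]
    total_bgcs = sum(p.n_bgc for p in bgc_profiles)
    total_in_bgc = sum(p.n_in_bgc for p in bgc_profiles)
    denom_p450 = sum(p.n_p450 for p in bgc_profiles)
    return CohortSummary(
        n_species=len(profiles),
        total_p450s=total_p450s,
        n_families=len(families),
        n_subfamilies=len(subfamilies),
        dominant_family=dominant,
        avg_p450s=rounded_mean(total_p450s, len(profiles)),
        n_bgc_species=len(bgc_profiles),
        total_bgcs=total_bgcs,
        avg_bgcs=rounded_mean(total_bgcs, len(bgc_profiles)) if bgc_profiles else 0,
        total_p450s_in_bgcs=total_in_bgc,
        pct_p450s_in_bgcs=(
            truncated_percent(total_in_bgc, denom_p450) if denom_p450 else 0
        ),
    )
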