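"""Bundled reference tables from published comparative P450 surveys.

Three small plain-text tables ship with the package:

* per-species P450 / family / subfamily counts for 203 Streptomyces
  proteomes, transcribed from a published comparative genome-mining survey;
* per-genus roll-up totals (species, P450s, families, subfamilies, BGCs,
  P450s inside BGCs) for Streptomyces, Mycobacterium, Bacillus and
  Cyanobacteria from the same body of surveys;
* the 38 novel CYP family names reported for the newly mined Streptomyces
  genomes.

They serve as worked inputs for the cohort statistics: the roll-up
averages/percentages and the per-species aggregate statistics (modal count,
range, family/subfamily maxima) are recomputed from these tables, not stored.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = [
    "load_streptomyces_counts",
    "load_comparative_totals",
    "load_new_family_names",
]


def _data(name: str):
    return resources.files("cypminer").joinpath("data", name)


def load_streptomyces_counts() -> pd.DataFrame:
    """Per-species counts: species, n_p450, n_families, n_subfamilies (203 rows)."""
    with resources.as_file(_data("streptomyces_p450_counts.tsv")) as p:
        return pd.read_csv(p, sep="\t")


def load_comparative_totals() -> pd.DataFrame:
    """Per-genus totals used by the comparative roll-up, indexed by genus."""
    with resources.as_file(_data("comparative_totals.tsv")) as p:
        return pd.read_csv(p, sep="\t", index_col="genus")


def load_new_family_names() -> list[str]:
    """The 38 novel CYP family member names, one token per line."""
    return _data("new_p450_family_names.txt").read_text().split()
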