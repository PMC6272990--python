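"""Published summary tables from the Dactylis glomerata SSR/IT-ISJ survey.

The original study genotyped 196 plants from 20 germplasm accessions of
nine *D. glomerata* subspecies with 21 SSR and 15 IT-ISJ primer pairs but
deposited only summary tables, not the raw band scores.  The tables shipped
here — per-primer band counts and PIC values, per-subspecies diversity
statistics, AMOVA variance components, and the accession panel layout —
serve two purposes: arithmetic consistency checks (system-level averages
must be recoverable from the printed per-primer rows) and a realistic
template for the synthetic-data generator's population layout.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = [
    "primer_panel",
    "subspecies_diversity",
    "amova_components",
    "accession_panel",
]


def _load(name: str) -> pd.DataFrame:
    with resources.files("bandpop.data").joinpath(name).open("r") as fh:
        return pd.read_csv(fh, sep="\t")


def primer_panel() -> pd.DataFrame:
    """Per-primer TNB, NPB and PIC for the 21 SSR and 15 IT-ISJ primers."""
    return _load("primer_panel.tsv")


def subspecies_diversity() -> pd.DataFrame:
    """Per-subspecies Na, Ne, He and Shannon I reported for the nine subspecies."""
    return _load("subspecies_diversity.tsv")


def amova_components() -> pd.DataFrame:
    """Reported AMOVA sums of squares, variance components and df per analysis."""
    return _load("amova_components.tsv")


def accession_panel() -> pd.DataFrame:
    """The 20-accession collection: subspecies, country, range and climate."""
    return _load("accessions.tsv")
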