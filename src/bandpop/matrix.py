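"""Band-matrix data model and delimited-text input/output.

The unit of analysis throughout the package is the scored electrophoretic
band: a 0/1 matrix of individuals (rows) by band loci (columns), where 1
records presence of a band and 0 its absence.  Every band belongs to exactly
one primer (pair), and every primer to exactly one marker system (e.g. SSR
or IT-ISJ).  Sample metadata maps each individual to a germplasm accession
and the accession to its subspecies, country, distribution range and
climate type.

File formats
------------
Band matrix (.csv or .tsv, sniffed from the extension):
    two header rows — band ids, then the primer of each band — followed by
    one row per sample, first field the sample id.
Primer-system table: two columns ``primer``, ``system``.
Sample metadata: columns ``sample_id``, ``accession``, ``subspecies``,
    ``country``, ``range``, ``climate``.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BandMatrixError",
    "BandMatrix",
    "SampleMetadata",
    "PrimerSummary",
    "read_band_matrix",
    "write_band_matrix",
    "read_metadata",
    "write_metadata",
    "read_primer_systems",
    "write_primer_systems",
    "polymorphism_summary",
]


class BandMatrixError(ValueError):
    """Raised when a band matrix or its companion tables fail validation."""


def _delimiter_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


@dataclass(frozen=True)
class BandMatrix:
    """Presence/absence scores for a panel of dominant-marker bands.

    Parameters
    ----------
    sample_ids : sequence of str
        Unique individual identifiers, one per row.
    band_ids : sequence of str
        Unique band-locus identifiers, one per column.
    values : ndarray of shape (n_samples, n_bands)
        0/1 integer scores.
    band_to_primer : mapping band id -> primer name
        Every band must be assigned to exactly one primer.
    primer_system : mapping primer name -> marker-system label
        Every primer must carry a system tag (e.g. ``"SSR"``).
    """

    sample_ids: tuple[str, ...]
    band_ids: tuple[str, ...]
    values: np.ndarray
    band_to_primer: Mapping[str, str]
    primer_system: Mapping[str, str]

    def __init__(self, sample_ids, band_ids, values, band_to_primer, primer_system):
        sample_ids = tuple(str(s) for s in sample_ids)
        band_ids = tuple(str(b) for b in band_ids)
        values = np.asarray(values)
        if values.shape != (len(sample_ids), len(band_ids)):
            raise BandMatrixError(
                f"matrix shape {values.shape} does not match "
                f"{len(sample_ids)} samples x {len(band_ids)} bands"
            )
        if not sample_ids or not band_ids:
            raise BandMatrixError("sample and band id lists must be non-empty")
        for name, ids in (("sample", sample_ids), ("band", band_ids)):
            if len(set(ids)) != len(ids):
                dup = sorted({i for i in ids if ids.count(i) > 1})
                raise BandMatrixError(f"duplicate {name} ids: {dup}")
        bad = np.argwhere(~np.isin(values, (0, 1)))
        if bad.size:
            r, c = bad[0]
            raise BandMatrixError(
                f"non-binary cell {values[r, c]!r} at sample "
                f"{sample_ids[r]!r} (row {r}), band {band_ids[c]!r} (column {c})"
            )
        band_to_primer = dict(band_to_primer)
        primer_system = dict(primer_system)
        missing = [b for b in band_ids if b not in band_to_primer]
        if missing:
            raise BandMatrixError(f"bands with no primer assignment: {missing}")
        untagged = sorted(
            {band_to_primer[b] for b in band_ids} - set(primer_system)
        )
        if untagged:
            raise BandMatrixError(f"primers with no marker-system tag: {untagged}")
        object.__setattr__(self, "sample_ids", sample_ids)
        object.__setattr__(self, "band_ids", band_ids)
        object.__setattr__(self, "values", values.astype(np.int8))
        object.__setattr__(self, "band_to_primer", band_to_primer)
        object.__setattr__(self, "primer_system", primer_system)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_bands(self) -> int:
        return len(self.band_ids)

    @property
    def primers(self) -> tuple[str, ...]:
        """Primer names in order of first appearance along the band axis."""
        seen: dict[str, None] = {}
        for b in self.band_ids:
            seen.setdefault(self.band_to_primer[b], None)
        return tuple(seen)

    @property
    def systems(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for p in self.primers:
            seen.setdefault(self.primer_system[p], None)
        return tuple(seen)

    def primer_columns(self, primer: str) -> np.ndarray:
        """Column indices of the bands amplified by ``primer``."""
        idx = [
            j for j, b in enumerate(self.band_ids) if self.band_to_primer[b] == primer
        ]
        if not idx:
            raise BandMatrixError(f"unknown primer: {primer!r}")
        return np.asarray(idx)

    def system_columns(self, system: str) -> np.ndarray:
        idx = [
            j
            for j, b in enumerate(self.band_ids)
            if self.primer_system[self.band_to_primer[b]] == system
        ]
        if not idx:
            raise BandMatrixError(f"unknown marker system: {system!r}")
        return np.asarray(idx)

    def presence_freq(self) -> np.ndarray:
        """Per-band presence proportion over all samples."""
        return self.values.mean(axis=0)

    def subset_samples(self, keep: Sequence[str]) -> "BandMatrix":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in keep if s not in pos]
        if missing:
            raise BandMatrixError(f"samples not in matrix: {missing}")
        rows = [pos[s] for s in keep]
        return BandMatrix(
            tuple(keep),
            self.band_ids,
            self.values[rows],
            self.band_to_primer,
            self.primer_system,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.sample_ids), columns=list(self.band_ids)
        )


@dataclass(frozen=True)
class SampleMetadata:
    """Individual -> accession -> subspecies/country/range/climate groupings."""

    table: pd.DataFrame = field(repr=False)

    REQUIRED = ("sample_id", "accession", "subspecies", "country", "range", "climate")

    def __post_init__(self):
        t = self.table
        missing = [c for c in self.REQUIRED if c not in t.columns]
        if missing:
            raise BandMatrixError(f"metadata missing columns: {missing}")
        if t["sample_id"].duplicated().any():
            dup = sorted(t.loc[t["sample_id"].duplicated(), "sample_id"])
            raise BandMatrixError(f"duplicate sample ids in metadata: {dup}")
        amb = (
            t.groupby("accession")["subspecies"].nunique(dropna=False).loc[lambda s: s > 1]
        )
        if len(amb):
            raise BandMatrixError(
                f"accessions mapped to more than one subspecies: {list(amb.index)}"
            )
        object.__setattr__(self, "table", t.reset_index(drop=True))

    def group_map(self, level: str) -> dict[str, str]:
        """Map sample id -> group label at ``level`` (a metadata column)."""
        if level not in self.table.columns:
            raise BandMatrixError(f"unknown grouping level: {level!r}")
        return dict(zip(self.table["sample_id"], self.table[level].astype(str)))

    def check_covers(self, m: BandMatrix) -> None:
        missing = sorted(set(m.sample_ids) - set(self.table["sample_id"]))
        if missing:
            raise BandMatrixError(f"samples without metadata: {missing}")


@dataclass(frozen=True)
class PrimerSummary:
    """Per-primer band counts and, optionally, average information content.

    TNB is the total number of bands assigned to the primer, NPB the number
    that are polymorphic (presence frequency strictly between 0 and 1), and
    PPB the percentage 100*NPB/TNB.
    """

    primer: str
    system: str
    tnb: int
    npb: int
    pic: float | None = None

    def __post_init__(self):
        if self.npb > self.tnb:
            raise BandMatrixError(
                f"{self.primer}: NPB {self.npb} exceeds TNB {self.tnb}"
            )
        if self.pic is not None and not (0.0 <= self.pic < 1.0):
            raise BandMatrixError(f"{self.primer}: PIC {self.pic} outside [0, 1)")

    @property
    def ppb(self) -> float:
        return 100.0 * self.npb / self.tnb


# ---------------------------------------------------------------------------
# readers / writers


def read_band_matrix(
    path: str | Path,
    primer_systems: str | Path | Mapping[str, str],
) -> BandMatrix:
    """Read a band matrix from delimited text.

    The file carries two header rows (band ids, then each band's primer);
    every following row is one sample.  ``primer_systems`` is either a
    mapping primer->system or the path of a two-column table.
    """
    path = Path(path)
    delim = _delimiter_for(path)
    with open(path, newline="", encoding="utf-8") as fh:
        rows = list(csv.reader(fh, delimiter=delim))
    if len(rows) < 3:
        raise BandMatrixError(f"{path}: expected 2 header rows plus >=1 sample row")
    band_ids = rows[0][1:]
    primer_row = rows[1][1:]
    if len(primer_row) != len(band_ids):
        raise BandMatrixError(f"{path}: primer header length mismatch")
    band_to_primer = dict(zip(band_ids, primer_row))
    sample_ids, data = [], []
    for r, row in enumerate(rows[2:], start=3):
        if not row:
            continue
        sample_ids.append(row[0])
        cells = row[1:]
        if len(cells) != len(band_ids):
            raise BandMatrixError(
                f"{path} line {r}: expected {len(band_ids)} cells, got {len(cells)}"
            )
        parsed = []
        for c, cell in enumerate(cells):
            if cell not in ("0", "1"):
                raise BandMatrixError(
                    f"{path} line {r}: non-binary cell {cell!r} for sample "
                    f"{row[0]!r}, band {band_ids[c]!r}"
                )
            parsed.append(int(cell))
        data.append(parsed)
    if not isinstance(primer_systems, Mapping):
        primer_systems = read_primer_systems(primer_systems)
    return BandMatrix(sample_ids, band_ids, np.array(data), band_to_primer, primer_systems)


def write_band_matrix(m: BandMatrix, path: str | Path) -> None:
    path = Path(path)
    delim = _delimiter_for(path)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, delimiter=delim)
        w.writerow(["sample_id", *m.band_ids])
        w.writerow(["primer", *(m.band_to_primer[b] for b in m.band_ids)])
        for i, s in enumerate(m.sample_ids):
            w.writerow([s, *map(int, m.values[i])])


def read_primer_systems(path: str | Path) -> dict[str, str]:
    t = pd.read_csv(path, sep=_delimiter_for(Path(path)), dtype=str)
    if not {"primer", "system"} <= set(t.columns):
        raise BandMatrixError(f"{path}: expected columns 'primer' and 'system'")
    if t["primer"].duplicated().any():
        raise BandMatrixError(f"{path}: duplicate primer rows")
    return dict(zip(t["primer"], t["system"]))


def write_primer_systems(primer_system: Mapping[str, str], path: str | Path) -> None:
    pd.DataFrame(
        {"primer": list(primer_system), "system": list(primer_system.values())}
    ).to_csv(path, sep=_delimiter_for(Path(path)), index=False)


def read_metadata(path: str | Path) -> SampleMetadata:
    t = pd.read_csv(path, sep=_delimiter_for(Path(path)), dtype=str)
    return SampleMetadata(t)


def write_metadata(md: SampleMetadata, path: str | Path) -> None:
    md.table.to_csv(path, sep=_delimiter_for(Path(path)), index=False)


# ---------------------------------------------------------------------------
# polymorphism summary


def polymorphism_summary(m: BandMatrix) -> list[PrimerSummary]:
    """TNB/NPB/PPB per primer, in primer order of first appearance.

    A band is polymorphic when both presence and absence are observed
    across the samples; bands fixed in either state are monomorphic.
    """
    if m.n_samples < 2:
        raise BandMatrixError("polymorphism summary needs at least 2 samples")
    freqs = m.presence_freq()
    out = []
    for primer in m.primers:
        cols = m.primer_columns(primer)
        f = freqs[cols]
        npb = int(np.sum((f > 0.0) & (f < 1.0)))
        out.append(
            PrimerSummary(primer, m.primer_system[primer], tnb=len(cols), npb=npb)
        )
    return out
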