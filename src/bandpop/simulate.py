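"""Synthetic band matrices with known allele frequencies and divergence.

Populations diverge from a common ancestor under the Balding–Nichols model:
for a band with ancestral dominant-allele frequency p0, each population's
frequency p is Beta-distributed with mean p0 and variance F*p0*(1-p0),
i.e. shape parameters p0*(1-F)/F and (1-p0)*(1-F)/F.  F plays the role of
Fst and is the single divergence dial.  Individuals are diploid and the
marker is dominant, so under Hardy–Weinberg equilibrium a band is present
with probability 1 - (1-p)^2.

The default configuration emulates the study design the package targets:
20 accessions of 6–10 diploid plants each (nine subspecies), 21 + 15
primer panels of 3–13 bands.  Every statistic downstream therefore has a
parameter-recovery test against the recorded truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .matrix import BandMatrix, SampleMetadata
from .published import accession_panel

__all__ = ["SimulationConfig", "SimulationTruth", "simulate_band_matrix"]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the band-matrix generator.

    ``samples_per_pop`` may be a single int (all populations equal) or a
    list with one entry per population.  ``primers`` maps marker-system
    label to primer count; ``bands_per_primer`` is an inclusive integer
    range sampled uniformly per primer.  ``divergence`` is the
    Balding–Nichols F in (0, 1); ``ancestral_freq_range`` bounds the
    uniform draw of p0 away from fixation so panels stay polymorphic.
    """

    n_pops: int = 20
    samples_per_pop: int | tuple[int, ...] = (6, 10)
    primers: dict[str, int] = field(
        default_factory=lambda: {"SSR": 21, "IT-ISJ": 15}
    )
    bands_per_primer: tuple[int, int] = (3, 13)
    divergence: float = 0.2
    ancestral_freq_range: tuple[float, float] = (0.05, 0.95)
    seed: int = 0

    def __post_init__(self):
        if self.n_pops < 1:
            raise ValueError("n_pops must be positive")
        if not 0.0 < self.divergence < 1.0:
            raise ValueError(f"divergence F must be in (0,1), got {self.divergence}")
        lo, hi = self.ancestral_freq_range
        if not (0.0 < lo <= hi < 1.0):
            raise ValueError("ancestral_freq_range must lie within (0,1)")
        if any(n < 1 for n in self.primers.values()) or not self.primers:
            raise ValueError("each marker system needs at least one primer")
        b_lo, b_hi = self.bands_per_primer
        if not 1 <= b_lo <= b_hi:
            raise ValueError("bands_per_primer range invalid")

    def pop_sizes(self, rng: np.random.Generator) -> np.ndarray:
        sp = self.samples_per_pop
        if isinstance(sp, int):
            return np.full(self.n_pops, sp)
        sp = tuple(sp)
        if len(sp) == self.n_pops:
            sizes = np.asarray(sp)
        elif len(sp) == 2:  # inclusive range, drawn per population
            sizes = rng.integers(sp[0], sp[1] + 1, size=self.n_pops)
        else:
            raise ValueError(
                "samples_per_pop must be an int, a (lo, hi) range, or one size per population"
            )
        if (sizes < 1).any():
            raise ValueError("population sizes must be positive")
        return sizes


@dataclass(frozen=True)
class SimulationTruth:
    """True frequencies behind a simulated matrix.

    ``pop_freqs`` is bands x populations (dominant-allele frequency p),
    ``ancestral_freqs`` per band, plus the configured F.
    """

    band_ids: tuple[str, ...]
    pop_ids: tuple[str, ...]
    pop_freqs: np.ndarray
    ancestral_freqs: np.ndarray
    divergence: float

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.pop_freqs, index=list(self.band_ids), columns=list(self.pop_ids)
        )
        df.insert(0, "p0", self.ancestral_freqs)
        df.insert(0, "band", list(self.band_ids))
        return df

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _pop_labels(cfg: SimulationConfig) -> pd.DataFrame:
    """Accession/subspecies/country labels per population.

    A 20-population simulation reuses the real accession panel layout so
    subspecies- and country-level analyses have the study's structure;
    other sizes get generic one-accession-per-subspecies labels.
    """
    if cfg.n_pops == 20:
        return accession_panel()
    return pd.DataFrame(
        {
            "accession": [f"ACC{i + 1:02d}" for i in range(cfg.n_pops)],
            "subspecies": [f"pop{i + 1:02d}" for i in range(cfg.n_pops)],
            "country": [f"country{i + 1:02d}" for i in range(cfg.n_pops)],
            "range": "Unknown",
            "climate": "Unknown",
        }
    )


def simulate_band_matrix(
    cfg: SimulationConfig,
) -> tuple[BandMatrix, SampleMetadata, SimulationTruth]:
    """Draw a band matrix, its metadata and the generating truth.

    Deterministic given ``cfg.seed``: the same config yields bit-identical
    outputs.
    """
    rng = np.random.default_rng(cfg.seed)
    sizes = cfg.pop_sizes(rng)
    labels = _pop_labels(cfg)

    band_ids: list[str] = []
    band_to_primer: dict[str, str] = {}
    primer_system: dict[str, str] = {}
    for system, n_primers in cfg.primers.items():
        for k in range(n_primers):
            primer = f"{system}-P{k + 1:02d}"
            primer_system[primer] = system
            n_bands = int(rng.integers(cfg.bands_per_primer[0], cfg.bands_per_primer[1] + 1))
            for b in range(n_bands):
                band = f"{primer}.b{b + 1:02d}"
                band_ids.append(band)
                band_to_primer[band] = primer

    n_bands = len(band_ids)
    lo, hi = cfg.ancestral_freq_range
    p0 = rng.uniform(lo, hi, size=n_bands)
    f = cfg.divergence
    # Balding-Nichols: Beta(p0(1-F)/F, (1-p0)(1-F)/F) per population
    a = p0 * (1.0 - f) / f
    b = (1.0 - p0) * (1.0 - f) / f
    pop_p = rng.beta(
        np.repeat(a[:, None], cfg.n_pops, axis=1),
        np.repeat(b[:, None], cfg.n_pops, axis=1),
    )

    sample_ids: list[str] = []
    meta_rows: list[dict] = []
    blocks: list[np.ndarray] = []
    for j in range(cfg.n_pops):
        acc = labels.iloc[j]
        present_prob = 1.0 - (1.0 - pop_p[:, j]) ** 2  # dominant phenotype, HWE
        block = rng.random((int(sizes[j]), n_bands)) < present_prob[None, :]
        blocks.append(block.astype(np.int8))
        for i in range(int(sizes[j])):
            sid = f"{acc['accession']}_{i + 1:02d}"
            sample_ids.append(sid)
            meta_rows.append(
                {
                    "sample_id": sid,
                    "accession": acc["accession"],
                    "subspecies": acc["subspecies"],
                    "country": acc["country"],
                    "range": acc["range"],
                    "climate": acc["climate"],
                }
            )

    matrix = BandMatrix(
        sample_ids, band_ids, np.vstack(blocks), band_to_primer, primer_system
    )
    metadata = SampleMetadata(pd.DataFrame(meta_rows))
    truth = SimulationTruth(
        band_ids=tuple(band_ids),
        pop_ids=tuple(labels["accession"]),
        pop_freqs=pop_p,
        ancestral_freqs=p0,
        divergence=f,
    )
    return matrix, metadata, truth
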