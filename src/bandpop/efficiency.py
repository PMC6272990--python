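"""Marker-efficiency statistics: PIC, Ibav, EMR and the marker index.

PIC of a locus is 1 - sum(P_j^2) over allele frequencies P_j.  For a
dominant fingerprint there are two readings of "allele": per-primer PIC is
computed by default over the distinct multiband phenotypes of the primer
("pattern" mode, each fingerprint one allele), with a per-band biallelic
alternative ("band" mode) averaging PIC over the primer's polymorphic
bands.  Pattern mode is the default because it is the only reading whose
range is compatible with per-primer PIC values above the 1 - 1/k ceiling
a k-band allele spectrum permits.

System-level efficiency combines average band informativeness
Ibav = mean(1 - 2|0.5 - p_i|) over band presence proportions p_i (pooled
over all samples), the effective multiplex ratio EMR = mean polymorphic
bands per primer, and the marker index MI = Ibav * EMR.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrix import BandMatrix, BandMatrixError, PrimerSummary, polymorphism_summary

__all__ = [
    "pic_locus",
    "pic_primer",
    "ibav",
    "emr",
    "marker_index",
    "EfficiencyReport",
    "efficiency_report",
    "summarize_primer_table",
]

_FREQ_TOL = 1e-9


def pic_locus(freqs) -> float:
    """Polymorphic information content 1 - sum(f^2) of an allele spectrum."""
    f = np.asarray(freqs, dtype=float)
    if (f < 0).any():
        raise ValueError("allele frequencies must be nonnegative")
    total = f.sum()
    if abs(total - 1.0) > _FREQ_TOL:
        raise ValueError(f"allele frequencies sum to {total}, expected 1")
    return float(1.0 - np.sum(f**2))


def pic_primer(m: BandMatrix, primer: str, mode: str = "pattern") -> float:
    """Average PIC of one primer.

    mode="pattern": each distinct multiband phenotype across samples is one
    allele; frequencies are pattern counts / n_samples.
    mode="band": each band is a dominant biallelic locus with phenotype
    frequencies {p, 1-p}; returns the mean PIC over the primer's
    polymorphic bands (0.0 if none are polymorphic).
    """
    if m.n_samples < 2:
        raise BandMatrixError("PIC needs at least 2 samples")
    cols = m.primer_columns(primer)
    sub = m.values[:, cols]
    if mode == "pattern":
        _, counts = np.unique(sub, axis=0, return_counts=True)
        return pic_locus(counts / m.n_samples)
    if mode == "band":
        p = sub.mean(axis=0)
        poly = (p > 0) & (p < 1)
        if not poly.any():
            return 0.0
        per_band = 1.0 - (p[poly] ** 2 + (1.0 - p[poly]) ** 2)
        return float(per_band.mean())
    raise ValueError(f"unknown PIC mode: {mode!r}")


def ibav(m: BandMatrix, system: str) -> float:
    """Average band informativeness of a marker system.

    p_i is each band's presence proportion pooled over all samples; a band
    is maximally informative at p_i = 0.5 and uninformative when fixed.
    """
    cols = m.system_columns(system)
    p = m.values[:, cols].mean(axis=0)
    return float(np.mean(1.0 - 2.0 * np.abs(0.5 - p)))


def emr(m: BandMatrix, system: str) -> float:
    """Effective multiplex ratio: mean polymorphic bands per primer."""
    summaries = [s for s in polymorphism_summary(m) if s.system == system]
    if not summaries:
        raise BandMatrixError(f"unknown marker system: {system!r}")
    return float(np.mean([s.npb for s in summaries]))


def marker_index(ibav_value: float, emr_value: float) -> float:
    """Marker index MI = Ibav * EMR."""
    return float(ibav_value) * float(emr_value)


@dataclass(frozen=True)
class EfficiencyReport:
    """Per-primer summaries plus per-system efficiency parameters."""

    primer_summaries: tuple[PrimerSummary, ...]
    per_system: pd.DataFrame  # indexed by system
    pic_mode: str

    def primer_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "primer": [s.primer for s in self.primer_summaries],
                "system": [s.system for s in self.primer_summaries],
                "tnb": [s.tnb for s in self.primer_summaries],
                "npb": [s.npb for s in self.primer_summaries],
                "ppb": [s.ppb for s in self.primer_summaries],
                "pic": [s.pic for s in self.primer_summaries],
            }
        )


def efficiency_report(m: BandMatrix, pic_mode: str = "pattern") -> EfficiencyReport:
    """All per-primer and per-system efficiency statistics of a matrix."""
    base = polymorphism_summary(m)
    summaries = tuple(
        PrimerSummary(s.primer, s.system, s.tnb, s.npb, pic_primer(m, s.primer, pic_mode))
        for s in base
    )
    rows = {}
    for system in m.systems:
        sys_sum = [s for s in summaries if s.system == system]
        tnb = sum(s.tnb for s in sys_sum)
        npb = sum(s.npb for s in sys_sum)
        ib = ibav(m, system)
        em = emr(m, system)
        rows[system] = {
            "n_primers": len(sys_sum),
            "total_loci": tnb,
            "mean_loci_per_primer": tnb / len(sys_sum),
            "ppb": 100.0 * npb / tnb,
            "mean_pic": float(np.mean([s.pic for s in sys_sum])),
            "ibav": ib,
            "emr": em,
            "mi": marker_index(ib, em),
        }
    per_system = pd.DataFrame.from_dict(rows, orient="index")
    per_system.index.name = "system"
    return EfficiencyReport(summaries, per_system, pic_mode)


def summarize_primer_table(table: pd.DataFrame) -> pd.DataFrame:
    """System-level aggregates from a per-primer summary table.

    ``table`` needs columns ``system``, ``tnb``, ``npb`` and optionally
    ``pic``.  Returns, per system: primer count, band totals, EMR
    (= mean NPB per primer) and the mean per-primer PIC.  This is the
    aggregation used to cross-check a published per-primer table against
    its printed totals, and is also what ties a freshly computed
    per-primer frame to its system rows.
    """
    req = {"system", "tnb", "npb"}
    if not req <= set(table.columns):
        raise ValueError(f"primer table needs columns {sorted(req)}")
    g = table.groupby("system", sort=False)
    out = pd.DataFrame(
        {
            "n_primers": g.size(),
            "total_bands": g["tnb"].sum(),
            "total_polymorphic": g["npb"].sum(),
            "emr": g["npb"].mean(),
            "ppb": 100.0 * g["npb"].sum() / g["tnb"].sum(),
        }
    )
    if "pic" in table.columns:
        out["mean_pic"] = g["pic"].mean()
    out.index.name = "system"
    return out
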