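"""Dominant-marker diversity statistics in the POPGENE style.

Each band is a biallelic dominant locus.  The null-allele frequency q is
estimated from the band-absence proportion x under Hardy–Weinberg
equilibrium, by default as q = sqrt(x) (with p = 1 - q); a Lynch–Milligan
style small-sample correction is available.  Per locus the statistics are

    Na = number of allele states observed (2 if both presence and absence
         occur in the group, else 1)
    Ne = 1 / (p^2 + q^2)          effective number of alleles
    He = 1 - p^2 - q^2            Nei's gene diversity
    I  = -(p ln p + q ln q)       Shannon's index, 0 ln 0 := 0

Group rows are locus means over all bands of the matrix.  The pooled-total
row treats the full sample set as one population.  Shannon diversity is
partitioned into the pooled total It, the mean within-group Is, their
ratio Is/It (intra-group share) and S' = (It - Is)/It (inter-group share).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .matrix import BandMatrix, BandMatrixError

__all__ = [
    "dominant_allele_freq",
    "locus_stats",
    "group_diversity",
    "DiversityReport",
]


def dominant_allele_freq(
    presence_freq, method: str = "sqrt", n: int | None = None
):
    """Estimate (p, q) of a dominant locus from its band-presence proportion.

    ``sqrt``: q = sqrt(1 - presence_freq), the HWE moment estimator.
    ``lynch_milligan``: sampling-bias corrected q = sqrt(x) / (1 - s/(8x))
    with x the absence proportion and s = x(1-x)/n its sampling variance;
    requires ``n`` (the sample count) and clamps q to [0, 1].

    Accepts scalars or arrays; returns (p, q) of the same shape.
    """
    x = 1.0 - np.asarray(presence_freq, dtype=float)
    if (x < -1e-12).any() or (x > 1 + 1e-12).any():
        raise ValueError("presence_freq must lie in [0, 1]")
    x = np.clip(x, 0.0, 1.0)
    if method == "sqrt":
        q = np.sqrt(x)
    elif method == "lynch_milligan":
        if n is None or n < 1:
            raise ValueError("lynch_milligan requires the sample count n >= 1")
        s = x * (1.0 - x) / n
        with np.errstate(divide="ignore", invalid="ignore"):
            q = np.where(x > 0, np.sqrt(x) / (1.0 - s / (8.0 * x)), 0.0)
        q = np.clip(q, 0.0, 1.0)
    else:
        raise ValueError(f"unknown allele-frequency method: {method!r}")
    p = 1.0 - q
    if np.isscalar(presence_freq):
        return float(p), float(q)
    return p, q


def locus_stats(
    presence_freq, method: str = "sqrt", n: int | None = None
) -> pd.DataFrame:
    """Per-locus p, q, Na, Ne, He and Shannon I from presence proportions."""
    pf = np.atleast_1d(np.asarray(presence_freq, dtype=float))
    p, q = dominant_allele_freq(pf, method=method, n=n)
    hom = p**2 + q**2
    he = 1.0 - hom
    ne = 1.0 / hom
    with np.errstate(divide="ignore", invalid="ignore"):
        shannon = -(
            np.where(p > 0, p * np.log(p), 0.0) + np.where(q > 0, q * np.log(q), 0.0)
        )
    na = np.where((pf > 0) & (pf < 1), 2, 1)
    return pd.DataFrame(
        {"presence_freq": pf, "p": p, "q": q, "na": na, "ne": ne, "he": he, "shannon": shannon}
    )


@dataclass(frozen=True)
class DiversityReport:
    """Per-group locus-mean diversity plus the Shannon partition.

    ``per_group`` has one row per group and a ``Total`` row (all samples
    pooled) with columns n, na, ne, he, shannon.  ``it_total`` is the
    pooled Shannon diversity, ``is_within`` the (by default unweighted)
    mean of group Shannon values, and ``s_prime`` the inter-group share
    (It - Is)/It, so that Is/It + S' = 1.
    """

    per_group: pd.DataFrame
    it_total: float
    is_within: float
    method: str
    weighted: bool

    @property
    def is_over_it(self) -> float:
        return self.is_within / self.it_total

    @property
    def s_prime(self) -> float:
        return (self.it_total - self.is_within) / self.it_total

    def to_frame(self) -> pd.DataFrame:
        return self.per_group


def group_diversity(
    m: BandMatrix,
    groups: Mapping[str, str],
    method: str = "sqrt",
    weighted: bool = False,
) -> DiversityReport:
    """Diversity statistics per group and pooled, with the It/Is partition.

    ``groups`` maps every sample id to its group label.  Group rows are
    locus means over all bands.  With ``weighted=True`` Is weights the
    group Shannon means by group sample size instead of averaging them
    equally.
    """
    missing = [s for s in m.sample_ids if s not in groups]
    if missing:
        raise BandMatrixError(f"samples without a group: {missing}")
    labels = np.array([groups[s] for s in m.sample_ids])
    order = list(dict.fromkeys(labels))  # first-appearance order

    rows = {}
    sizes = {}
    for g in order:
        sel = labels == g
        n_g = int(sel.sum())
        if n_g < 2:
            raise BandMatrixError(f"group {g!r} has fewer than 2 samples")
        stats = locus_stats(m.values[sel].mean(axis=0), method=method, n=n_g)
        rows[g] = stats[["na", "ne", "he", "shannon"]].mean()
        sizes[g] = n_g

    pooled = locus_stats(m.presence_freq(), method=method, n=m.n_samples)

    per_group = pd.DataFrame.from_dict(rows, orient="index")
    per_group.insert(0, "n", pd.Series(sizes))
    mean_row = per_group.drop(columns="n").mean()
    mean_row["n"] = per_group["n"].mean()
    total_row = pooled[["na", "ne", "he", "shannon"]].mean()
    total_row["n"] = m.n_samples
    per_group.loc["Mean"] = mean_row
    per_group.loc["Total"] = total_row
    per_group.index.name = "group"

    it_total = float(total_row["shannon"])
    group_i = np.array([rows[g]["shannon"] for g in order])
    if weighted:
        w = np.array([sizes[g] for g in order], dtype=float)
        is_within = float(np.average(group_i, weights=w))
    else:
        is_within = float(group_i.mean())
    return DiversityReport(per_group, it_total, is_within, method, weighted)
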