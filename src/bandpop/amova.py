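"""One-way distance-based analysis of molecular variance (AMOVA).

Variation among and within groups is partitioned from squared Euclidean
distances between band profiles — for 0/1 data the squared Euclidean
distance is simply the number of mismatching bands.  With N samples in G
groups of sizes n_g:

    SS_total  = (1/N)  * sum over all pairs i<j of d2(i, j)
    SS_within = sum_g (1/n_g) * sum over within-group pairs of d2
    SS_among  = SS_total - SS_within
    df_among = G - 1,  df_within = N - G,  MS = SS/df
    sigma2_within = MS_within
    sigma2_among  = (MS_among - MS_within) / n0,
                    n0 = (N - sum_g n_g^2 / N) / (G - 1)

Phi_ST is the among-group share of the summed variance components.
Significance comes from permuting the sample-to-group assignment and
recomputing sigma2_among; the p-value uses the +1 correction so it is
never exactly zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from skbio import DistanceMatrix

from .matrix import BandMatrix, BandMatrixError, SampleMetadata

__all__ = ["squared_euclidean", "AmovaResult", "amova_oneway", "amova_by_country"]


def squared_euclidean(m: BandMatrix) -> DistanceMatrix:
    """Pairwise squared Euclidean distance (= Hamming count for 0/1 data)."""
    v = m.values.astype(float)
    sq = (v**2).sum(axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * (v @ v.T)
    d2 = np.maximum((d2 + d2.T) / 2.0, 0.0)
    np.fill_diagonal(d2, 0.0)
    return DistanceMatrix(d2, ids=list(m.sample_ids))


@dataclass(frozen=True)
class AmovaResult:
    """df, sums of squares, variance components and the permutation test.

    ``proportions`` floors a negative among-group component at zero (the
    ``negative_among`` flag records when that happened); ``phi`` is the
    among-group proportion (Phi_ST).  ``p_value`` is None when no
    permutations were requested.
    """

    df_among: int
    df_within: int
    ss_among: float
    ss_within: float
    ms_among: float
    ms_within: float
    sigma2_among: float
    sigma2_within: float
    n0: float
    n_permutations: int
    p_value: float | None
    group_sizes: dict[str, int]

    @property
    def ss_total(self) -> float:
        return self.ss_among + self.ss_within

    @property
    def negative_among(self) -> bool:
        return self.sigma2_among < 0

    @property
    def proportions(self) -> tuple[float, float]:
        among = max(self.sigma2_among, 0.0)
        total = among + self.sigma2_within
        if total == 0:
            return 0.0, 0.0
        return among / total, self.sigma2_within / total

    @property
    def phi(self) -> float:
        return self.proportions[0]

    def to_frame(self) -> pd.DataFrame:
        among, within = self.proportions
        return pd.DataFrame(
            {
                "source": ["among", "within"],
                "df": [self.df_among, self.df_within],
                "sum_sq": [self.ss_among, self.ss_within],
                "mean_sq": [self.ms_among, self.ms_within],
                "variance_component": [self.sigma2_among, self.sigma2_within],
                "proportion": [among, within],
                "p_value": [self.p_value, None],
            }
        )


def _sums_of_squares(d2: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    n = len(labels)
    iu = np.triu_indices(n, k=1)
    ss_total = d2[iu].sum() / n
    ss_within = 0.0
    for g in np.unique(labels):
        idx = np.flatnonzero(labels == g)
        sub = d2[np.ix_(idx, idx)]
        ss_within += sub[np.triu_indices(len(idx), k=1)].sum() / len(idx)
    return float(ss_total - ss_within), float(ss_within)


def _sigma2_among(d2: np.ndarray, labels: np.ndarray, n0: float, df_a: int, df_w: int) -> float:
    ss_a, ss_w = _sums_of_squares(d2, labels)
    return (ss_a / df_a - ss_w / df_w) / n0


def amova_oneway(
    d2: DistanceMatrix,
    groups: Mapping[str, str],
    n_perm: int = 999,
    seed: int = 0,
) -> AmovaResult:
    """One-way AMOVA of a squared-distance matrix over a group assignment.

    ``groups`` maps every id of ``d2`` to a group label; every group needs
    at least 2 members and there must be at least 2 groups.  The
    permutation test permutes sample-to-group assignment ``n_perm`` times
    (0 disables it) and is deterministic given ``seed``.
    """
    ids = list(d2.ids)
    missing = [s for s in ids if s not in groups]
    if missing:
        raise BandMatrixError(f"samples without a group: {missing}")
    labels = np.array([groups[s] for s in ids])
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise BandMatrixError("AMOVA needs at least 2 groups")
    small = [g for g, c in zip(uniq, counts) if c < 2]
    if small:
        raise BandMatrixError(f"groups with fewer than 2 members: {small}")

    n = len(ids)
    g = len(uniq)
    df_a, df_w = g - 1, n - g
    n0 = (n - float((counts**2).sum()) / n) / df_a

    mat = d2.data
    ss_a, ss_w = _sums_of_squares(mat, labels)
    ms_a, ms_w = ss_a / df_a, ss_w / df_w
    sigma_w = ms_w
    sigma_a = (ms_a - ms_w) / n0

    p_value = None
    if n_perm > 0:
        rng = np.random.default_rng(seed)
        hits = 0
        for _ in range(n_perm):
            perm = rng.permutation(labels)
            if _sigma2_among(mat, perm, n0, df_a, df_w) >= sigma_a:
                hits += 1
        p_value = (1 + hits) / (n_perm + 1)

    return AmovaResult(
        df_among=df_a,
        df_within=df_w,
        ss_among=ss_a,
        ss_within=ss_w,
        ms_among=ms_a,
        ms_within=ms_w,
        sigma2_among=sigma_a,
        sigma2_within=sigma_w,
        n0=n0,
        n_permutations=n_perm,
        p_value=p_value,
        group_sizes={str(k): int(v) for k, v in zip(uniq, counts)},
    )


def amova_by_country(
    m: BandMatrix,
    metadata: SampleMetadata,
    subspecies: str,
    n_perm: int = 999,
    seed: int = 0,
) -> AmovaResult:
    """AMOVA among countries within one subspecies.

    Restricts the matrix to the subspecies' samples, groups them by
    country, and runs the one-way analysis; a subspecies sampled from a
    single country is an error.
    """
    t = metadata.table
    sel = t[t["subspecies"].astype(str) == str(subspecies)]
    if sel.empty:
        raise BandMatrixError(f"unknown subspecies: {subspecies!r}")
    countries = sorted(sel["country"].astype(str).unique())
    if len(countries) < 2:
        raise BandMatrixError(
            f"subspecies {subspecies!r} sampled from a single country "
            f"(countries found: {countries})"
        )
    keep = [s for s in m.sample_ids if s in set(sel["sample_id"])]
    sub = m.subset_samples(keep)
    groups = dict(zip(sel["sample_id"], sel["country"].astype(str)))
    return amova_oneway(squared_euclidean(sub), groups, n_perm=n_perm, seed=seed)
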