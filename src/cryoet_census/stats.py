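"""Rank-based group comparison and the size-landscape regression.

Percent-imaged distributions across domains of life are heavily skewed and
unbalanced (hundreds of bacteria versus a handful of archaea), so the
omnibus comparison is a Kruskal–Wallis test followed by pairwise Dunn
tests, both implemented directly from their rank formulas with midrank tie
handling and tie correction.

Kruskal–Wallis, with N total observations in k groups, group rank sums
R_i over pooled midranks::

    H = [12 / (N (N+1))] * sum_i R_i^2 / n_i  -  3 (N+1)
    H_corrected = H / (1 - sum_ties (t^3 - t) / (N^3 - N))

compared to chi-square with k-1 degrees of freedom.

Dunn's z for groups i, j with mean ranks Rbar::

    z = (Rbar_i - Rbar_j) /
        sqrt([N(N+1)/12 - sum(t^3 - t)/(12 (N-1))] * (1/n_i + 1/n_j))

two-sided p from the standard normal, optionally Holm- or
Bonferroni-adjusted (no adjustment by default, matching common
scikit-posthocs usage and the magnitudes of published pairwise p-values).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import stats as sps

from .conventions import floor_p
from .entries import CellEntry
from .geometry import max_dimension
from .lamella import LAMELLA_WIDTH_UM, percent_imaged

__all__ = [
    "GroupedSamples",
    "TestResult",
    "RegressionFit",
    "kruskal_wallis",
    "dunn_pairwise",
    "size_landscape_regression",
    "median_percent_by_domain",
]


@dataclass
class GroupedSamples:
    """Named groups of real-valued observations."""

    labels: list[str]
    values: list[list[float]]

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, Sequence[float]]) -> "GroupedSamples":
        return cls(labels=list(mapping), values=[list(v) for v in mapping.values()])

    def check(self, min_groups: int = 2) -> None:
        if len(self.labels) != len(self.values):
            raise ValueError("labels and values lengths differ")
        if len(self.labels) < min_groups:
            raise ValueError(f"need at least {min_groups} groups")
        if any(len(v) == 0 for v in self.values):
            raise ValueError("every group must be non-empty")


@dataclass
class TestResult:
    statistic: float
    p_value: float
    method: str
    pairwise: Optional[dict[tuple[str, str], float]] = None
    pairwise_z: Optional[dict[tuple[str, str], float]] = None


@dataclass
class RegressionFit:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int
    log_transformed: bool


def _pooled_midranks(groups: GroupedSamples):
    pooled = np.concatenate([np.asarray(v, dtype=float) for v in groups.values])
    ranks = sps.rankdata(pooled, method="average")
    sizes = [len(v) for v in groups.values]
    split = np.split(ranks, np.cumsum(sizes)[:-1])
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts.astype(float) ** 3 - counts))
    return split, sizes, len(pooled), tie_term


def kruskal_wallis(groups: GroupedSamples) -> TestResult:
    """Kruskal–Wallis H test across the groups (chi-square reference).

    Degenerate data with every observation identical yields H = 0, p = 1.
    """
    groups.check()
    rank_groups, sizes, n_total, tie_term = _pooled_midranks(groups)
    if n_total < 3:
        raise ValueError("need at least 3 observations in total")
    h = (
        12.0 / (n_total * (n_total + 1))
        * sum(float(r.sum()) ** 2 / n for r, n in zip(rank_groups, sizes))
        - 3.0 * (n_total + 1)
    )
    correction = 1.0 - tie_term / (n_total**3 - n_total)
    if correction <= 0:  # all observations tied
        return TestResult(0.0, 1.0, "Kruskal-Wallis")
    h /= correction
    df = len(sizes) - 1
    p = floor_p(sps.chi2.sf(h, df))
    return TestResult(float(h), p, "Kruskal-Wallis")


def _holm(pvals: list[float]) -> list[float]:
    m = len(pvals)
    order = np.argsort(pvals)
    adjusted = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * pvals[idx])
        adjusted[idx] = min(1.0, running)
    return adjusted.tolist()


def dunn_pairwise(groups: GroupedSamples, adjust: str = "none") -> TestResult:
    """Dunn's post-hoc z tests for every group pair.

    The omnibus Kruskal–Wallis H and p are carried in ``statistic`` /
    ``p_value``; per-pair two-sided p-values (optionally holm- or
    bonferroni-adjusted) and z-scores are in ``pairwise`` /
    ``pairwise_z``.  All-tied data gives z = 0, p = 1 per pair.
    """
    if adjust not in ("none", "holm", "bonferroni"):
        raise ValueError("adjust must be one of none|holm|bonferroni")
    omnibus = kruskal_wallis(groups)
    rank_groups, sizes, n_total, tie_term = _pooled_midranks(groups)
    mean_ranks = [float(r.mean()) for r in rank_groups]
    variance = n_total * (n_total + 1) / 12.0
    if n_total > 1:
        variance -= tie_term / (12.0 * (n_total - 1))

    pairs: dict[tuple[str, str], float] = {}
    zscores: dict[tuple[str, str], float] = {}
    labels = groups.labels
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            se = np.sqrt(variance * (1.0 / sizes[i] + 1.0 / sizes[j]))
            if se == 0:  # all observations tied
                z = 0.0
            else:
                z = (mean_ranks[i] - mean_ranks[j]) / se
            zscores[(labels[i], labels[j])] = float(z)
            pairs[(labels[i], labels[j])] = floor_p(2.0 * sps.norm.sf(abs(z)))

    keys = list(pairs)
    raw = [pairs[k] for k in keys]
    if adjust == "bonferroni":
        adj = [min(1.0, p * len(raw)) for p in raw]
    elif adjust == "holm":
        adj = _holm(raw)
    else:
        adj = raw
    return TestResult(
        statistic=omnibus.statistic,
        p_value=omnibus.p_value,
        method=f"Dunn's test ({adjust} adjustment)",
        pairwise=dict(zip(keys, (floor_p(p) for p in adj))),
        pairwise_z=zscores,
    )


def size_landscape_regression(
    entries: Sequence[CellEntry], log10_transform: bool = True
) -> RegressionFit:
    """OLS of cell width/thickness on cell length across the dataset.

    Dimensions span four orders of magnitude (0.1 to ~2,000 um), so both
    axes are log10-transformed by default; ``log10_transform=False`` fits
    on the raw micrometre scale.
    """
    if len(entries) < 3:
        raise ValueError("need at least 3 entries")
    x = np.array([e.length_um for e in entries], dtype=float)
    y = np.array([e.width_um for e in entries], dtype=float)
    if log10_transform:
        x, y = np.log10(x), np.log10(y)
    if np.ptp(x) == 0:
        raise ValueError("zero variance in predictor")
    fit = sps.linregress(x, y)
    return RegressionFit(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        p_value=floor_p(fit.pvalue),
        n=len(entries),
        log_transformed=log10_transform,
    )


def median_percent_by_domain(
    entries: Sequence[CellEntry],
    lamella_width_um: float = LAMELLA_WIDTH_UM,
) -> dict[str, float]:
    """Median percent-of-cell-imaged per domain, single-lamella convention.

    Each entry contributes P = 100 * l / L for one standard-width lamella
    over its maximal dimension L; empty domains are omitted.
    """
    if not entries:
        raise ValueError("no entries")
    per_domain: dict[str, list[float]] = {}
    for e in entries:
        p = percent_imaged(lamella_width_um, 1, max_dimension(e))
        per_domain.setdefault(e.domain.value, []).append(p)
    return {d: float(np.median(v)) for d, v in per_domain.items()}
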