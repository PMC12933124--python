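"""Seeded generator of literature-table-like datasets.

Emulates the structure of the curated cryo-ET census so every analysis
stage is testable without the deposited table: log-normal per-domain size
distributions spanning ~0.1 to 2,000 um, domain-typical shape classes,
and freezing/sectioning assignments that follow the planner's size rules
up to a configurable noise rate (real studies deviate from the "typical"
method choice; the census shows plunge freezing well above 100 um when
cryoprotectant is used).

Default conditions mirror the curated census: 366 entries in a
164 : 14 : 188 bacteria : archaea : eukaryote mix, with per-domain size
medians chosen so a standard 0.18 um lamella captures a median of ~9% of
a bacterium, ~14% of an archaeon and ~1% of a eukaryote — the observed
domain medians.  Taxon names are drawn from fixed wordlists so distinct
genus/species counting is exercised; everything is deterministic for a
fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .biodiversity import RichnessRow, RichnessTable
from .entries import CellEntry, Domain, Freezing, Kingdom, Sectioning, Shape
from .geometry import ShapeDims
from .lamella import PlannerThresholds, recommend_workflow

__all__ = [
    "GeneratorConfig",
    "generate_entries",
    "generate_richness_table",
    "empirical_freezing_transition",
]

#: Median maximal dimension (um) and log10 dispersion per domain.  Medians
#: are set so the single-lamella percent-imaged medians land at 9% (18/2),
#: 14% (18/1.2857) and 1% (18/18) for bacteria, archaea and eukaryotes.
DEFAULT_SIZE_PARAMS: dict[Domain, tuple[float, float]] = {
    Domain.BACTERIA: (2.0, 0.25),
    Domain.ARCHAEA: (18.0 / 14.0, 0.3),
    Domain.EUKARYOTA: (18.0, 0.8),
}

#: Census domain mix (bacteria : archaea : eukaryotes = 164 : 14 : 188).
DEFAULT_DOMAIN_MIX: dict[Domain, float] = {
    Domain.BACTERIA: 164 / 366,
    Domain.ARCHAEA: 14 / 366,
    Domain.EUKARYOTA: 188 / 366,
}

_BACTERIA_GENERA = [
    "Escherichia", "Caulobacter", "Borrelia", "Bacillus", "Vibrio",
    "Pseudomonas", "Mycoplasma", "Helicobacter", "Myxococcus", "Prochlorococcus",
    "Treponema", "Shewanella",
]
_ARCHAEA_GENERA = [
    "Sulfolobus", "Methanococcus", "Haloferax", "Thermococcus",
    "Nitrosopumilus", "Pyrococcus",
]
_EUKARYOTE_GENERA: dict[Kingdom, list[str]] = {
    Kingdom.ANIMALIA: ["Caenorhabditis", "Drosophila", "Mus", "Danio", "Macaca"],
    Kingdom.PLANTAE: ["Ostreococcus", "Physcomitrium", "Arabidopsis", "Spinacia"],
    Kingdom.FUNGI: ["Saccharomyces", "Schizosaccharomyces", "Anncaliia",
                    "Encephalitozoon"],
    Kingdom.PROTISTA: ["Chlamydomonas", "Toxoplasma", "Trypanosoma",
                       "Plasmodium", "Gephyrocapsa", "Dictyostelium"],
}
#: Kingdom draw weights loosely following the census species shares.
_KINGDOM_WEIGHTS = {
    Kingdom.ANIMALIA: 0.37,
    Kingdom.PLANTAE: 0.07,
    Kingdom.FUNGI: 0.15,
    Kingdom.PROTISTA: 0.41,
}
_EPITHETS = ["primus", "secundus", "tertius", "quartus", "quintus",
             "sextus", "septimus", "octavus"]
_CELL_LINES = ["HeLa", "HEK293", "U2OS", "COS-7", "NIH3T3", "MDCK", "CHO", "A549"]


@dataclass
class GeneratorConfig:
    """Conditions for one synthetic census."""

    seed: int = 0
    n_entries: int = 366
    domain_mix: dict[Domain, float] = field(
        default_factory=lambda: dict(DEFAULT_DOMAIN_MIX)
    )
    domain_size_params: dict[Domain, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_SIZE_PARAMS)
    )
    size_log10_range_um: tuple[float, float] = (-1.0, 3.3)
    #: Probability that an entry's freezing/sectioning deviates from the
    #: planner's recommendation.
    rule_noise: float = 0.1
    #: Probability that a eukaryotic entry is an immortalised cell line.
    cell_line_fraction: float = 0.35
    thresholds: PlannerThresholds = field(default_factory=PlannerThresholds)

    def __post_init__(self):
        if self.n_entries < 1:
            raise ValueError("n_entries must be >= 1")
        total = sum(self.domain_mix.values())
        if not math.isclose(total, 1.0, rel_tol=1e-6):
            raise ValueError(f"domain_mix must sum to 1, got {total}")
        if any(p < 0 for p in self.domain_mix.values()):
            raise ValueError("domain_mix proportions must be >= 0")
        if not 0.0 <= self.rule_noise <= 1.0:
            raise ValueError("rule_noise must be in [0, 1]")
        if not 0.0 <= self.cell_line_fraction <= 1.0:
            raise ValueError("cell_line_fraction must be in [0, 1]")


def _allocate_counts(mix: dict[Domain, float], n: int) -> dict[Domain, int]:
    """Largest-remainder allocation so domain counts are exact for the
    default mix (164/14/188 at n = 366), not multinomial draws."""
    quotas = {d: p * n for d, p in mix.items()}
    counts = {d: math.floor(q) for d, q in quotas.items()}
    short = n - sum(counts.values())
    by_remainder = sorted(
        mix, key=lambda d: (quotas[d] - counts[d]), reverse=True
    )
    for d in by_remainder[:short]:
        counts[d] += 1
    return counts


def _draw_size(rng, config, domain, cell_line):
    if cell_line:
        median, sigma = 17.0, 0.15  # cultured mammalian-scale cells
    else:
        median, sigma = config.domain_size_params[domain]
    lo, hi = config.size_log10_range_um
    val = rng.normal(math.log10(median), sigma)
    return 10.0 ** min(max(val, lo), hi)


def _draw_dims(rng, domain, max_dim, cell_line):
    """Shape class and dimension tuple with max(dimensions) == max_dim."""
    if domain in (Domain.BACTERIA, Domain.ARCHAEA):
        if rng.random() < 0.7:
            return Shape.CAPSULE, max_dim, max_dim * rng.uniform(0.3, 0.7), None
        return Shape.SPHERE, max_dim, max_dim, None
    if max_dim >= 100.0 and not cell_line:  # multicellular tissue slab
        thickness = max(1.01, max_dim * rng.uniform(0.05, 0.2))
        return (
            Shape.RECTANGLE,
            max_dim * rng.uniform(0.3, 0.9),
            thickness,
            max_dim,
        )
    u = rng.random()
    if u < 0.75:
        return Shape.SPHERE, max_dim, max_dim, None
    if u < 0.9:
        return Shape.CAPSULE, max_dim, max_dim * rng.uniform(0.4, 0.8), None
    return Shape.SQUARE, max_dim, max_dim, None


def _draw_taxon(rng, domain, cell_line):
    if cell_line:
        return str(rng.choice(_CELL_LINES)), Kingdom.ANIMALIA
    if domain is Domain.BACTERIA:
        genus = str(rng.choice(_BACTERIA_GENERA))
        return f"{genus} {rng.choice(_EPITHETS)}", None
    if domain is Domain.ARCHAEA:
        genus = str(rng.choice(_ARCHAEA_GENERA))
        return f"{genus} {rng.choice(_EPITHETS)}", None
    kingdoms = list(_KINGDOM_WEIGHTS)
    weights = np.array([_KINGDOM_WEIGHTS[k] for k in kingdoms])
    kingdom = kingdoms[rng.choice(len(kingdoms), p=weights / weights.sum())]
    genus = str(rng.choice(_EUKARYOTE_GENERA[kingdom]))
    return f"{genus} {rng.choice(_EPITHETS)}", kingdom


def generate_entries(config: GeneratorConfig | None = None) -> list[CellEntry]:
    """Generate a deterministic synthetic census under the configuration."""
    config = config or GeneratorConfig()
    rng = np.random.default_rng(config.seed)
    counts = _allocate_counts(config.domain_mix, config.n_entries)
    entries: list[CellEntry] = []
    i = 0
    for domain in (Domain.BACTERIA, Domain.ARCHAEA, Domain.EUKARYOTA):
        for _ in range(counts.get(domain, 0)):
            cell_line = (
                domain is Domain.EUKARYOTA
                and rng.random() < config.cell_line_fraction
            )
            max_dim = _draw_size(rng, config, domain, cell_line)
            shape, length, width, extra = _draw_dims(rng, domain, max_dim, cell_line)
            taxon, kingdom = _draw_taxon(rng, domain, cell_line)
            dims = ShapeDims(shape=shape, length_um=length, width_um=width,
                             extra_length_um=extra)
            rec = recommend_workflow(dims, cryoprotectant_available=True,
                                     thresholds=config.thresholds)
            if rng.random() < config.rule_noise:
                freezing = list(Freezing)[rng.integers(len(Freezing))]
                sectioning = list(Sectioning)[rng.integers(len(Sectioning))]
            else:
                freezing, sectioning = rec.freezing, rec.sectioning
            needs_cpa = max_dim > config.thresholds.cryoprotectant_min_dimension_um
            entries.append(CellEntry(
                taxon_name=taxon,
                domain=domain,
                kingdom=kingdom,
                is_cell_line=cell_line,
                shape=shape,
                length_um=length,
                width_um=width,
                extra_length_um=extra,
                freezing=freezing,
                sectioning=sectioning,
                cryoprotectant=needs_cpa,
                cryoprotectant_chemistry="glycerol" if needs_cpa else None,
                year=int(rng.integers(2003, 2025)),
                source_ref=f"synthetic-{i:04d}",
            ))
            i += 1
    order = rng.permutation(len(entries))
    return [entries[j] for j in order]


def generate_richness_table(config: GeneratorConfig | None = None) -> RichnessTable:
    """Synthetic richness constants with self-consistent ordering
    (imaged <= sequenced <= predicted) and order-of-magnitude gaps between
    2 and 5, the regime the coverage analysis operates in."""
    config = config or GeneratorConfig()
    rng = np.random.default_rng(config.seed)
    rows = []
    for category in ("bacterial genera", "eukaryotic genera", "human cell lines"):
        n_imaged = int(rng.integers(30, 100))
        gap_seq = rng.uniform(2.05, 2.95)
        gap_pred = rng.uniform(gap_seq + 0.05, 4.95)
        rows.append(RichnessRow(
            category=category,
            n_imaged=n_imaged,
            n_sequenced=int(round(n_imaged * 10.0 ** gap_seq)),
            n_predicted=int(round(n_imaged * 10.0 ** gap_pred)),
            source="synthetic",
        ))
    return RichnessTable(rows=rows)


def empirical_freezing_transition(
    entries: Sequence[CellEntry],
    bin_width_dex: float = 0.1,
    min_count: int = 5,
) -> Optional[float]:
    """Smallest size (um) at which HPF becomes the majority freezing method.

    Bins entries by log10 maximal dimension and returns the left edge of
    the first bin (ascending size, >= ``min_count`` entries) where the HPF
    fraction exceeds 50%; None when HPF never reaches a majority.  Used to
    recover the plunge-to-HPF transition from a dataset.
    """
    from .geometry import max_dimension

    sizes = np.array([max_dimension(e) for e in entries])
    is_hpf = np.array([e.freezing is Freezing.HPF for e in entries])
    logs = np.log10(sizes)
    lo = math.floor(logs.min() / bin_width_dex) * bin_width_dex
    hi = math.ceil(logs.max() / bin_width_dex) * bin_width_dex
    edges = np.arange(lo, hi + bin_width_dex, bin_width_dex)
    for left in edges[:-1]:
        mask = (logs >= left - 1e-12) & (logs < left + bin_width_dex - 1e-12)
        if mask.sum() < min_count:
            continue
        if is_hpf[mask].mean() > 0.5:
            return float(10.0 ** left)
    return None
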