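"""Biodiversity coverage: cryo-ET taxa versus sequence databases and Earth.

Counts distinct taxa imaged by cryo-ET (genus or species/cell-line rank)
and compares them against rRNA-database richness and predicted planetary
richness supplied as a configuration table.  Gaps are expressed in orders
of magnitude, log10(n_database / n_imaged), matching how the field frames
the disparity (imaged diversity is orders of magnitude below sequenced
diversity, which is itself far below predicted richness).

Genus extraction from free-text organism names takes the first
whitespace-delimited token; cell lines (HeLa, HEK293, ...) never
contribute genera.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import yaml

from .conventions import round_half_away
from .entries import CellEntry, Domain, filter_entries

log = logging.getLogger("cryoet_census")

__all__ = [
    "RichnessRow",
    "RichnessTable",
    "CoverageRow",
    "CoverageReport",
    "taxa_imaged",
    "coverage_gaps",
    "kingdom_proportions",
]


@dataclass(frozen=True)
class RichnessRow:
    """Richness of one taxonomic category across imaging and databases."""

    category: str
    n_imaged: int
    n_sequenced: Optional[int] = None
    n_predicted: Optional[int] = None
    source: str = ""

    def __post_init__(self):
        for name in ("n_imaged", "n_sequenced", "n_predicted"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class RichnessTable:
    rows: list[RichnessRow]

    def validate(self) -> list[str]:
        """Warnings (not errors) where imaged counts exceed database counts;
        databases are incomplete, so this is suspicious rather than illegal."""
        warnings = []
        for row in self.rows:
            for name in ("n_sequenced", "n_predicted"):
                v = getattr(row, name)
                if v is not None and row.n_imaged > v:
                    warnings.append(
                        f"{row.category}: n_imaged ({row.n_imaged}) exceeds "
                        f"{name} ({v})"
                    )
        for w in warnings:
            log.warning("richness table: %s", w)
        return warnings

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RichnessTable":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        rows = [
            RichnessRow(
                category=r["category"],
                n_imaged=int(r["n_imaged"]),
                n_sequenced=(None if r.get("n_sequenced") is None
                             else int(r["n_sequenced"])),
                n_predicted=(None if r.get("n_predicted") is None
                             else int(r["n_predicted"])),
                source=str(r.get("source", "")),
            )
            for r in payload["rows"]
        ]
        table = cls(rows=rows)
        table.validate()
        return table


@dataclass(frozen=True)
class CoverageRow:
    """Coverage of one category: order-of-magnitude gaps and percent of
    predicted richness actually imaged.  Fields are None when the table
    lacks the corresponding denominator."""

    gap_sequenced_orders: Optional[float]
    gap_predicted_orders: Optional[float]
    percent_of_predicted: Optional[float]


CoverageReport = dict[str, CoverageRow]


def taxa_imaged(
    entries: Sequence[CellEntry],
    rank: str = "species_or_line",
    domain: Domain | None = None,
    exclude_cell_lines: bool = False,
) -> int:
    """Count distinct taxa at the requested rank after filtering.

    ``rank='genus'`` counts first-token genera (cell lines always
    excluded); ``rank='species_or_line'`` counts distinct full names,
    including cell lines unless ``exclude_cell_lines``.
    """
    if rank not in ("genus", "species_or_line"):
        raise ValueError("rank must be 'genus' or 'species_or_line'")
    selected = filter_entries(
        entries,
        domain=domain,
        exclude_cell_lines=exclude_cell_lines or rank == "genus",
    )
    if rank == "genus":
        return len({e.taxon_name.split()[0] for e in selected})
    return len({e.taxon_name for e in selected})


def coverage_gaps(richness: RichnessTable) -> CoverageReport:
    """Order-of-magnitude gaps between imaged and database richness.

    gap = log10(n_database / n_imaged); percent_of_predicted =
    100 * n_imaged / n_predicted.  Rows with n_imaged = 0 are skipped
    (gap undefined); missing denominators leave fields None.
    """
    report: CoverageReport = {}
    for row in richness.rows:
        if row.n_imaged < 1:
            log.warning("coverage: skipping %r (n_imaged = 0)", row.category)
            continue
        gap_seq = (
            math.log10(row.n_sequenced / row.n_imaged)
            if row.n_sequenced else None
        )
        gap_pred = (
            math.log10(row.n_predicted / row.n_imaged)
            if row.n_predicted else None
        )
        pct = (
            100.0 * row.n_imaged / row.n_predicted
            if row.n_predicted else None
        )
        report[row.category] = CoverageRow(gap_seq, gap_pred, pct)
    return report


def kingdom_proportions(entries: Sequence[CellEntry]) -> dict[str, int]:
    """Percent of distinct eukaryotic species per kingdom, cell lines
    excluded, rounded to the nearest integer (sums to 100 +- rounding)."""
    eligible = filter_entries(
        entries, domain=Domain.EUKARYOTA, exclude_cell_lines=True
    )
    species: dict[str, set] = {}
    for e in eligible:
        if e.kingdom is None:
            continue
        species.setdefault(e.kingdom.value, set()).add(e.taxon_name)
    total = sum(len(s) for s in species.values())
    if total == 0:
        raise ValueError("no eukaryotic, kingdom-annotated, non-cell-line entries")
    return {
        k: round_half_away(100.0 * len(s) / total) for k, s in species.items()
    }
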