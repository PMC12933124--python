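"""The curated literature table: one row per cellular cryo-ET imaging event.

Each entry records the organism (or cell line) imaged, its domain of life,
an idealised shape class with measured dimensions in micrometres, and the
freezing/sectioning workflow used to prepare it.  Studies imaging several
cell or tissue types contribute one entry per type, so the table counts
*imaging events*, not publications.

The module defines the schema (:class:`CellEntry`), a total validator that
returns human-readable violations instead of raising, CSV (de)serialisation
with optional column aliasing, predicate filtering, and categorical
summaries of the kind used to report method distributions.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, fields
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .conventions import round_half_away

log = logging.getLogger("cryoet_census")

__all__ = [
    "Domain",
    "Kingdom",
    "Shape",
    "Freezing",
    "Sectioning",
    "CellEntry",
    "DatasetSummary",
    "validate_entry",
    "read_entries",
    "write_entries",
    "filter_entries",
    "summarize",
    "CURATED_YEAR_RANGE",
]


class Domain(str, Enum):
    BACTERIA = "Bacteria"
    ARCHAEA = "Archaea"
    EUKARYOTA = "Eukaryota"


class Kingdom(str, Enum):
    ANIMALIA = "Animalia"
    PLANTAE = "Plantae"
    FUNGI = "Fungi"
    PROTISTA = "Protista"


class Shape(str, Enum):
    CAPSULE = "capsule"
    SPHERE = "sphere"
    SQUARE = "square"
    RECTANGLE = "rectangle"
    CONE = "cone"
    RECTANGULAR_PYRAMID = "rectangular_pyramid"


#: Shapes that carry a third recorded dimension (an additional length).
EXTRA_DIM_SHAPES = frozenset({Shape.RECTANGLE, Shape.RECTANGULAR_PYRAMID})


class Freezing(str, Enum):
    PLUNGE = "plunge"
    HPF = "HPF"


class Sectioning(str, Enum):
    NONE = "none"
    FIB_SEM = "FIB_SEM"
    PLASMA_FIB = "plasma_FIB"
    ULTRAMICROTOME = "ultramicrotome"
    LIFT_OUT = "lift_out"
    SERIAL_LIFT_OUT = "serial_lift_out"


#: Publication-year span of the curated literature (validator warns outside).
CURATED_YEAR_RANGE = (2003, 2024)


@dataclass
class CellEntry:
    """One cryo-ET imaging event of a cell or tissue.

    Dimensions are in micrometres.  ``width_um`` holds the width or
    thickness; ``extra_length_um`` is the additional length recorded for
    rectangular and rectangular-pyramid shapes only.  Where a source gave a
    dimension range the mean is stored.
    """

    taxon_name: str
    domain: Domain
    shape: Shape
    length_um: float
    width_um: float
    freezing: Freezing
    sectioning: Sectioning
    kingdom: Optional[Kingdom] = None
    is_cell_line: bool = False
    extra_length_um: Optional[float] = None
    cryoprotectant: bool = False
    cryoprotectant_chemistry: Optional[str] = None
    year: int = 2024
    source_ref: str = ""


def validate_entry(entry: CellEntry) -> list[str]:
    """Return a list of invariant violations (empty iff the entry is valid).

    Total function: never raises.  Publication years outside the curated
    2003-2024 span are logged as warnings, not violations, since they are
    legal for datasets extending the census.
    """
    violations: list[str] = []
    if not entry.taxon_name or not str(entry.taxon_name).strip():
        violations.append("taxon_name must be non-empty")
    if not isinstance(entry.domain, Domain):
        violations.append(f"domain: unknown token {entry.domain!r}")
    if not isinstance(entry.shape, Shape):
        violations.append(f"shape: unknown token {entry.shape!r}")
    if not isinstance(entry.freezing, Freezing):
        violations.append(f"freezing: unknown token {entry.freezing!r}")
    if not isinstance(entry.sectioning, Sectioning):
        violations.append(f"sectioning: unknown token {entry.sectioning!r}")
    if not (isinstance(entry.length_um, (int, float)) and entry.length_um > 0):
        violations.append("length_um must be > 0")
    if not (isinstance(entry.width_um, (int, float)) and entry.width_um > 0):
        violations.append("width_um must be > 0")
    if isinstance(entry.shape, Shape):
        if entry.shape in EXTRA_DIM_SHAPES:
            if entry.extra_length_um is None:
                violations.append(
                    f"extra_length_um required for shape={entry.shape.value}"
                )
            elif entry.extra_length_um <= 0:
                violations.append("extra_length_um must be > 0")
        elif entry.extra_length_um is not None:
            violations.append(
                f"extra_length_um only allowed for rectangle/rectangular_pyramid "
                f"shapes, not {entry.shape.value}"
            )
    if entry.kingdom is not None:
        if not isinstance(entry.kingdom, Kingdom):
            violations.append(f"kingdom: unknown token {entry.kingdom!r}")
        elif entry.domain != Domain.EUKARYOTA:
            violations.append("kingdom only allowed when domain=Eukaryota")
    lo, hi = CURATED_YEAR_RANGE
    if not lo <= entry.year <= hi:
        log.warning(
            "entry %r: year %s outside curated range %s-%s",
            entry.taxon_name, entry.year, lo, hi,
        )
    return violations


# ---------------------------------------------------------------------------
# CSV serialisation
# ---------------------------------------------------------------------------

_COLUMNS = [f.name for f in fields(CellEntry)]
_REQUIRED = {
    "taxon_name", "domain", "shape", "length_um", "width_um",
    "freezing", "sectioning",
}

#: Common header spellings mapped onto canonical column names; callers may
#: extend this with their own alias mapping (e.g. for a deposited table).
DEFAULT_ALIASES: Mapping[str, str] = {
    "species": "taxon_name",
    "organism": "taxon_name",
    "cell_line": "taxon_name",
    "length": "length_um",
    "width": "width_um",
    "thickness": "width_um",
    "width_or_thickness_um": "width_um",
    "extra_length": "extra_length_um",
    "freezing_method": "freezing",
    "sectioning_method": "sectioning",
    "publication_year": "year",
    "reference": "source_ref",
}

_TRUE_TOKENS = {"true", "1", "yes", "y", "t"}
_FALSE_TOKENS = {"false", "0", "no", "n", "f", ""}


def _parse_bool(token: str, column: str) -> bool:
    t = str(token).strip().lower()
    if t in _TRUE_TOKENS:
        return True
    if t in _FALSE_TOKENS:
        return False
    raise ValueError(f"{column}: cannot parse boolean from {token!r}")


def _parse_enum(enum_cls, token: str, column: str):
    t = str(token).strip()
    for member in enum_cls:
        if member.value.lower() == t.lower():
            return member
    raise ValueError(f"{column}: unknown token {token!r}")


def _parse_row(row: Mapping[str, str]) -> CellEntry:
    def opt(name):
        v = row.get(name, "")
        return None if v is None or str(v).strip() == "" else str(v).strip()

    extra = opt("extra_length_um")
    kingdom = opt("kingdom")
    entry = CellEntry(
        taxon_name=str(row["taxon_name"]).strip(),
        domain=_parse_enum(Domain, row["domain"], "domain"),
        shape=_parse_enum(Shape, row["shape"], "shape"),
        length_um=float(row["length_um"]),
        width_um=float(row["width_um"]),
        freezing=_parse_enum(Freezing, row["freezing"], "freezing"),
        sectioning=_parse_enum(Sectioning, row["sectioning"], "sectioning"),
        kingdom=_parse_enum(Kingdom, kingdom, "kingdom") if kingdom else None,
        is_cell_line=_parse_bool(row.get("is_cell_line", ""), "is_cell_line"),
        extra_length_um=float(extra) if extra else None,
        cryoprotectant=_parse_bool(row.get("cryoprotectant", ""), "cryoprotectant"),
        cryoprotectant_chemistry=opt("cryoprotectant_chemistry"),
        year=int(row["year"]) if opt("year") else CURATED_YEAR_RANGE[1],
        source_ref=str(row.get("source_ref", "")).strip(),
    )
    return entry


def read_entries(
    path: str | Path,
    strict: bool = False,
    column_aliases: Mapping[str, str] | None = None,
) -> list[CellEntry]:
    """Read a CSV literature table into validated :class:`CellEntry` rows.

    Header matching is case-insensitive and order-free; ``column_aliases``
    maps non-canonical headers onto schema names (merged over
    :data:`DEFAULT_ALIASES`).  In strict mode any invalid row aborts the
    read; otherwise invalid rows are logged and skipped, and the reject
    count is reported in the log.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    aliases = dict(DEFAULT_ALIASES)
    if column_aliases:
        aliases.update({k.lower(): v for k, v in column_aliases.items()})
    renamed = {}
    for col in frame.columns:
        key = col.strip().lower()
        renamed[col] = aliases.get(key, key)
    frame = frame.rename(columns=renamed)
    missing = _REQUIRED - set(frame.columns)
    if missing:
        raise ValueError(f"missing required column(s): {sorted(missing)}")

    entries: list[CellEntry] = []
    n_rejected = 0
    for i, row in enumerate(frame.to_dict(orient="records")):
        try:
            entry = _parse_row(row)
            violations = validate_entry(entry)
            if violations:
                raise ValueError("; ".join(violations))
        except (ValueError, KeyError) as exc:
            if strict:
                raise ValueError(f"row {i + 2}: {exc}") from exc
            log.warning("skipping row %d: %s", i + 2, exc)
            n_rejected += 1
            continue
        entries.append(entry)
    if n_rejected:
        log.info("read %d entries, rejected %d invalid rows", len(entries), n_rejected)
    return entries


def write_entries(entries: Iterable[CellEntry], path: str | Path) -> None:
    """Write entries to CSV with canonical headers (round-trips losslessly)."""
    rows = []
    for e in entries:
        row = {}
        for f in fields(CellEntry):
            v = getattr(e, f.name)
            row[f.name] = v.value if isinstance(v, Enum) else v
        rows.append(row)
    pd.DataFrame(rows, columns=_COLUMNS).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Filtering and summaries
# ---------------------------------------------------------------------------


def filter_entries(
    entries: Sequence[CellEntry],
    domain: Domain | None = None,
    sectioning: Sectioning | None = None,
    freezing: Freezing | None = None,
    exclude_cell_lines: bool = False,
) -> list[CellEntry]:
    """Select entries matching every provided predicate, preserving order."""
    out = []
    for e in entries:
        if domain is not None and e.domain != domain:
            continue
        if sectioning is not None and e.sectioning != sectioning:
            continue
        if freezing is not None and e.freezing != freezing:
            continue
        if exclude_cell_lines and e.is_cell_line:
            continue
        out.append(e)
    return out


@dataclass
class DatasetSummary:
    """Categorical census of a literature table.

    ``fraction_by_sectioning`` is in percent of total entries, rounded to
    the nearest integer with ties away from zero (the convention that
    yields the familiar 65/26/8/1 split for the curated table).
    """

    n_entries: int
    n_by_domain: dict[str, int]
    n_unique_taxa_by_domain: dict[str, int]
    n_by_sectioning: dict[str, int]
    n_by_freezing: dict[str, int]
    fraction_by_sectioning: dict[str, int]

    def to_dict(self) -> dict:
        return {
            "n_entries": self.n_entries,
            "n_by_domain": self.n_by_domain,
            "n_unique_taxa_by_domain": self.n_unique_taxa_by_domain,
            "n_by_sectioning": self.n_by_sectioning,
            "n_by_freezing": self.n_by_freezing,
            "fraction_by_sectioning_percent": self.fraction_by_sectioning,
        }


def summarize(entries: Sequence[CellEntry]) -> DatasetSummary:
    """Census counts by domain, sectioning and freezing method."""
    if not entries:
        raise ValueError("cannot summarize an empty entry list")
    n = len(entries)
    by_domain = Counter(e.domain.value for e in entries)
    by_sectioning = Counter(e.sectioning.value for e in entries)
    by_freezing = Counter(e.freezing.value for e in entries)
    taxa: dict[str, set] = {}
    for e in entries:
        taxa.setdefault(e.domain.value, set()).add(e.taxon_name)
    return DatasetSummary(
        n_entries=n,
        n_by_domain=dict(by_domain),
        n_unique_taxa_by_domain={d: len(s) for d, s in taxa.items()},
        n_by_sectioning=dict(by_sectioning),
        n_by_freezing=dict(by_freezing),
        fraction_by_sectioning={
            k: round_half_away(100.0 * v / n) for k, v in by_sectioning.items()
        },
    )
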