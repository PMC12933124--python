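"""Lamella yield mathematics and the sample-preparation planner.

A lamella is a thin (~0.18 um) slab of vitrified cellular material — the
unit actually imaged in cellular cryo-ET.  Three quantities summarise how
much cellular insight a freezing + sectioning workflow buys:

* **P**, the percent of a cell's maximal dimension L captured in lamellae::

      P = 100 * l * Nl / L          (capped at 100)

  where l is the lamella width and Nl the maximum number of lamellae one
  pass of the workflow can produce.  On-grid FIB-SEM, plasma-FIB and
  single lift-out give Nl = 1; serial lift-out and the cryo-ultramicrotome
  stack sections along L at a method-specific separation (about 4 um for
  serial lift-out, 0.18 um — contiguous slices — for the ultramicrotome),
  so Nl = max(1, floor(L / separation)).

* **Nc**, the cells captured per lamella: Nc = Al / Ac, the lamella
  cross-sectional area over the cell cross-sectional area.

* **T100c**, the milling time to expose 100 cells: T100c = Tl * 100 / Nc,
  with Tl the per-lamella milling time (trenching and lift-out included).

A fourth throughput number, tomograms per lamella, divides Al by a typical
illumination area of 4*pi ~ 12.6 um^2 (a 1.8 x 1.8 um tomogram at 4.4
A/pixel).

The planner (:func:`recommend_workflow`) encodes the empirical transition
rules observed across the literature: thin samples are plunge frozen and
imaged intact, cells under ~100 um are plunge frozen and FIB milled,
high-pressure freezing (HPF) takes over above ~100 um, and beyond ~200 um
vitrification additionally requires cryoprotectant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

from .conventions import round_half_away, round_to_half
from .entries import CellEntry, Domain, Freezing, Sectioning
from .geometry import ShapeDims, cross_section_area_sphere, dims_of, max_dimension

__all__ = [
    "LAMELLA_WIDTH_UM",
    "SERIAL_LIFT_OUT_SEPARATION_UM",
    "ULTRAMICROTOME_SEPARATION_UM",
    "NlRule",
    "SectioningModel",
    "default_sectioning_model",
    "WorkflowSpec",
    "default_workflow",
    "DEFAULT_WORKFLOW_NAMES",
    "ImagingGeometry",
    "YieldReport",
    "n_lamellae",
    "percent_imaged",
    "cells_per_lamella",
    "display_cells_per_lamella",
    "time_for_n_cells",
    "tomograms_per_lamella",
    "PlannerThresholds",
    "Recommendation",
    "recommend_workflow",
    "yield_report",
]

#: Standard lamella width l (um) for FIB-milled and ultramicrotome sections.
LAMELLA_WIDTH_UM = 0.18
#: Minimum separation between serial lift-out sections (um); sub-4-um
#: sections are possible but 4 um is the standard block subdivision.
SERIAL_LIFT_OUT_SEPARATION_UM = 4.0
#: Ultramicrotome slices are contiguous: separation equals the slice width.
ULTRAMICROTOME_SEPARATION_UM = 0.18


class NlRule(str, Enum):
    """How a sectioning method converts cell length into lamella count."""

    SINGLE_LAMELLA = "single_lamella"
    LENGTH_OVER_SEPARATION = "length_over_separation"


_METHOD_RULES = {
    Sectioning.FIB_SEM: NlRule.SINGLE_LAMELLA,
    Sectioning.PLASMA_FIB: NlRule.SINGLE_LAMELLA,
    Sectioning.LIFT_OUT: NlRule.SINGLE_LAMELLA,
    Sectioning.SERIAL_LIFT_OUT: NlRule.LENGTH_OVER_SEPARATION,
    Sectioning.ULTRAMICROTOME: NlRule.LENGTH_OVER_SEPARATION,
}


@dataclass(frozen=True)
class SectioningModel:
    """Per-method lamella production rule."""

    method: Sectioning
    lamella_width_l: float = LAMELLA_WIDTH_UM
    separation_um: Optional[float] = None
    nl_rule: NlRule = NlRule.SINGLE_LAMELLA

    def __post_init__(self):
        if self.lamella_width_l <= 0:
            raise ValueError("lamella_width_l must be > 0")
        if self.nl_rule is NlRule.LENGTH_OVER_SEPARATION:
            if self.separation_um is None:
                raise ValueError("length_over_separation requires separation_um")
            if self.separation_um < self.lamella_width_l:
                raise ValueError("separation_um must be >= lamella_width_l")
        expected = _METHOD_RULES.get(self.method)
        if expected is not None and self.nl_rule is not expected:
            raise ValueError(
                f"{self.method.value} uses the {expected.value} rule"
            )


def default_sectioning_model(method: Sectioning) -> SectioningModel:
    """Standard lamella-count model for a sectioning method."""
    if method is Sectioning.NONE:
        raise ValueError("unsectioned samples have no lamella model")
    rule = _METHOD_RULES[method]
    sep = None
    if method is Sectioning.SERIAL_LIFT_OUT:
        sep = SERIAL_LIFT_OUT_SEPARATION_UM
    elif method is Sectioning.ULTRAMICROTOME:
        sep = ULTRAMICROTOME_SEPARATION_UM
    return SectioningModel(method=method, separation_um=sep, nl_rule=rule)


@dataclass(frozen=True)
class WorkflowSpec:
    """A combined freezing + sectioning strategy with its lamella geometry.

    ``lamella_area_al_um2`` (Al) is the lamella cross-sectional area and
    ``mill_time_tl_min`` (Tl) the time to produce one lamella including
    trenching/lift-out steps.
    """

    name: str
    freezing: Freezing
    sectioning: Sectioning
    lamella_area_al_um2: float
    mill_time_tl_min: float

    def __post_init__(self):
        if self.lamella_area_al_um2 <= 0:
            raise ValueError("lamella area Al must be > 0")
        if self.mill_time_tl_min <= 0:
            raise ValueError("mill time Tl must be > 0")


DEFAULT_WORKFLOW_NAMES = ("plunge_fib", "hpf_waffle", "hpf_serial")


def default_workflow(name: str, bacterial_biofilm: bool = False) -> WorkflowSpec:
    """Benchmark workflows with literature lamella areas and mill times.

    * ``plunge_fib`` — plunge freezing + on-grid FIB-SEM: Al = 10x10 =
      100 um^2 for eukaryotic cells, or 5x10 = 50 um^2 when milling a
      bacterial biofilm; Tl = 60 min.
    * ``hpf_waffle`` — HPF + Waffle milling: Al = 20x20 = 400 um^2,
      Tl = 150 min.
    * ``hpf_serial`` — HPF + serial lift-out: Al = 10x25 = 250 um^2,
      Tl = 75 min.
    """
    if name == "plunge_fib":
        return WorkflowSpec(
            name=name,
            freezing=Freezing.PLUNGE,
            sectioning=Sectioning.FIB_SEM,
            lamella_area_al_um2=50.0 if bacterial_biofilm else 100.0,
            mill_time_tl_min=60.0,
        )
    if name == "hpf_waffle":
        return WorkflowSpec(
            name=name,
            freezing=Freezing.HPF,
            sectioning=Sectioning.FIB_SEM,
            lamella_area_al_um2=400.0,
            mill_time_tl_min=150.0,
        )
    if name == "hpf_serial":
        return WorkflowSpec(
            name=name,
            freezing=Freezing.HPF,
            sectioning=Sectioning.SERIAL_LIFT_OUT,
            lamella_area_al_um2=250.0,
            mill_time_tl_min=75.0,
        )
    raise ValueError(f"unknown workflow {name!r}; choose from {DEFAULT_WORKFLOW_NAMES}")


@dataclass(frozen=True)
class ImagingGeometry:
    """Tomogram acquisition geometry used for throughput estimates."""

    tomogram_side_um: float = 1.8
    pixel_size_a: float = 4.4
    illumination_radius_um: float = 2.0

    def __post_init__(self):
        if min(self.tomogram_side_um, self.pixel_size_a,
               self.illumination_radius_um) <= 0:
            raise ValueError("imaging geometry values must be > 0")
        if self.illumination_area_um2 < self.tomogram_side_um ** 2:
            raise ValueError("illumination area must cover the tomogram area")

    @property
    def illumination_area_um2(self) -> float:
        """pi*r^2; 12.6 um^2 at the default 2 um radius."""
        return math.pi * self.illumination_radius_um ** 2


# ---------------------------------------------------------------------------
# Yield equations
# ---------------------------------------------------------------------------


def n_lamellae(model: SectioningModel, length_um: float) -> int:
    """Maximum lamellae one pass of the sectioning workflow yields.

    Single-lamella methods return 1.  Serial methods pack sections of
    width ``separation_um`` along the cell length: floor(L / separation),
    never below 1 (a cell the method can reach yields at least one
    lamella).
    """
    if length_um <= 0:
        raise ValueError("length must be > 0")
    if model.nl_rule is NlRule.SINGLE_LAMELLA:
        return 1
    return max(1, math.floor(length_um / model.separation_um))


def percent_imaged(
    lamella_width_um: float, n_lamellae: int, length_um: float
) -> float:
    """Percent of the maximal cell dimension captured in lamellae.

    P = 100 * l * Nl / L, capped at 100 (contiguous ultramicrotome slices
    on a short cell would otherwise exceed full coverage).
    """
    if lamella_width_um <= 0 or length_um <= 0:
        raise ValueError("lamella width and cell length must be > 0")
    if n_lamellae < 1:
        raise ValueError("n_lamellae must be >= 1")
    return min(100.0, 100.0 * lamella_width_um * n_lamellae / length_um)


def cells_per_lamella(al_um2: float, ac_um2: float) -> float:
    """Nc = Al / Ac: how many cells one lamella cross-section captures."""
    if al_um2 <= 0 or ac_um2 <= 0:
        raise ValueError("areas must be > 0")
    return al_um2 / ac_um2


def display_cells_per_lamella(nc: float) -> float:
    """Report Nc to the nearest integer, or the nearest 0.5 below one cell
    (a lamella holding less than a full cell is a meaningful fraction)."""
    if nc >= 1.0:
        return float(round_half_away(nc))
    return round_to_half(nc)


def time_for_n_cells(tl_min: float, nc: float, n_cells: int = 100) -> float:
    """Minutes of milling to expose ``n_cells`` cells: Tl * n / Nc."""
    if tl_min <= 0 or nc <= 0:
        raise ValueError("Tl and Nc must be > 0")
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    return tl_min * n_cells / nc


def tomograms_per_lamella(
    al_um2: float, geom: ImagingGeometry | None = None
) -> int:
    """Maximum tomograms one lamella supports at a typical illumination
    area (nearest integer)."""
    if al_um2 <= 0:
        raise ValueError("lamella area must be > 0")
    geom = geom or ImagingGeometry()
    return round_half_away(al_um2 / geom.illumination_area_um2)


# ---------------------------------------------------------------------------
# Sample-preparation planner
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PlannerThresholds:
    """Size thresholds (um) at which preparation methods hand over.

    Intervals are half-open [low, high).  Defaults follow the empirical
    transitions in the cryo-ET literature: plunge-frozen ice supports
    unsectioned imaging of samples about a micrometre thick or less;
    gallium FIB handles up to ~10 um thickness with plasma-FIB or Waffle
    milling beyond; plunge freezing itself gives way to high-pressure
    freezing once one dimension surpasses ~100 um; and above ~200 um
    vitrification requires cryoprotectant.
    """

    no_section_max_thickness_um: float = 1.0
    gallium_max_thickness_um: float = 10.0
    hpf_min_dimension_um: float = 100.0
    cryoprotectant_min_dimension_um: float = 200.0

    def __post_init__(self):
        if not (0 < self.no_section_max_thickness_um
                <= self.gallium_max_thickness_um
                <= self.hpf_min_dimension_um
                <= self.cryoprotectant_min_dimension_um):
            raise ValueError("thresholds must be positive and ordered")


@dataclass(frozen=True)
class Recommendation:
    """Planner output: a preparation route plus the rules that fired."""

    freezing: Freezing
    sectioning: Sectioning
    cryoprotectant: bool
    rationale: tuple[str, ...]
    warnings: tuple[str, ...] = ()


def recommend_workflow(
    dims: ShapeDims | CellEntry,
    cryoprotectant_available: bool = True,
    thresholds: PlannerThresholds | None = None,
) -> Recommendation:
    """Recommend a freezing + sectioning route from cell/tissue dimensions.

    Deterministic size rules (thickness = smallest recorded dimension,
    L = largest):

    * thickness <= ~1 um — plunge freeze and image intact (typical of
      bacteria and archaea, which need minimal to no sectioning);
    * L < 100 um — plunge freeze + FIB milling (gallium below ~10 um
      thickness, plasma-FIB/Waffle beyond);
    * 100 um <= L < 200 um — HPF + FIB milling via lift-out;
    * L >= 200 um — HPF + serial lift-out with cryoprotectant (required;
      a warning is emitted when none is available).
    """
    if isinstance(dims, CellEntry):
        dims = dims_of(dims)
    t = thresholds or PlannerThresholds()
    thickness = min(dims.dimensions)
    length = max(dims.dimensions)
    warnings: tuple[str, ...] = ()

    if thickness <= t.no_section_max_thickness_um:
        return Recommendation(
            freezing=Freezing.PLUNGE,
            sectioning=Sectioning.NONE,
            cryoprotectant=False,
            rationale=(
                f"thickness {thickness:g} um <= {t.no_section_max_thickness_um:g} um: "
                "electron-transparent enough to plunge freeze and image intact",
            ),
        )
    if length < t.hpf_min_dimension_um:
        if thickness < t.gallium_max_thickness_um:
            sectioning = Sectioning.FIB_SEM
            why = (
                f"thickness {thickness:g} um < {t.gallium_max_thickness_um:g} um: "
                "on-grid gallium FIB-SEM milling"
            )
        else:
            sectioning = Sectioning.PLASMA_FIB
            why = (
                f"thickness {thickness:g} um >= {t.gallium_max_thickness_um:g} um: "
                "plasma-FIB (or Waffle) milling for faster ablation"
            )
        return Recommendation(
            freezing=Freezing.PLUNGE,
            sectioning=sectioning,
            cryoprotectant=False,
            rationale=(
                f"max dimension {length:g} um < {t.hpf_min_dimension_um:g} um: "
                "within the plunge-freezing vitrification range",
                why,
            ),
        )
    if length < t.cryoprotectant_min_dimension_um:
        return Recommendation(
            freezing=Freezing.HPF,
            sectioning=Sectioning.LIFT_OUT,
            cryoprotectant=False,
            rationale=(
                f"max dimension {length:g} um >= {t.hpf_min_dimension_um:g} um: "
                "high-pressure freezing required for vitrification",
                "cryo-FIB lift-out reaches material deep inside the frozen block",
            ),
        )
    if not cryoprotectant_available:
        warnings = (
            f"max dimension {length:g} um >= "
            f"{t.cryoprotectant_min_dimension_um:g} um requires cryoprotectant; "
            "vitrification without it is unlikely to succeed",
        )
    return Recommendation(
        freezing=Freezing.HPF,
        sectioning=Sectioning.SERIAL_LIFT_OUT,
        cryoprotectant=True,
        rationale=(
            f"max dimension {length:g} um >= "
            f"{t.cryoprotectant_min_dimension_um:g} um: HPF with cryoprotectant "
            "extends the vitrifiable thickness",
            "serial lift-out sections the block into many lamellae along its length",
        ),
        warnings=warnings,
    )


# ---------------------------------------------------------------------------
# Composite report
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class YieldReport:
    """All yield quantities for one cell under one workflow.

    Full-precision values; ``display`` applies the reporting conventions
    (Nc to the nearest integer, or nearest 0.5 below one cell).
    ``sub_single_cell`` flags lamellae smaller than the cell cross-section
    (Nc < 1), where one lamella samples only part of a single cell.
    """

    workflow: str
    max_dimension_um: float
    cell_area_ac_um2: float
    n_lamellae: int
    percent_imaged_p: float
    cells_per_lamella_nc: float
    time_100_cells_min: float
    tomograms_per_lamella: int

    @property
    def sub_single_cell(self) -> bool:
        return self.cells_per_lamella_nc < 1.0

    def display(self) -> dict:
        return {
            "workflow": self.workflow,
            "max_dimension_um": round(self.max_dimension_um, 2),
            "cell_area_ac_um2": round(self.cell_area_ac_um2, 1),
            "n_lamellae": self.n_lamellae,
            "percent_imaged": round(self.percent_imaged_p, 3),
            "cells_per_lamella": display_cells_per_lamella(
                self.cells_per_lamella_nc
            ),
            "time_100_cells_min": round(self.time_100_cells_min, 1),
            "tomograms_per_lamella": self.tomograms_per_lamella,
            "sub_single_cell": self.sub_single_cell,
        }


def yield_report(
    entry: CellEntry | ShapeDims,
    workflow: WorkflowSpec,
    geom: ImagingGeometry | None = None,
    sectioning_model: SectioningModel | None = None,
) -> YieldReport:
    """Compose the yield equations into one report for a cell + workflow."""
    geom = geom or ImagingGeometry()
    model = sectioning_model or default_sectioning_model(workflow.sectioning)
    length = max_dimension(entry)
    ac = cross_section_area_sphere(length)
    nl = n_lamellae(model, length)
    return YieldReport(
        workflow=workflow.name,
        max_dimension_um=length,
        cell_area_ac_um2=ac,
        n_lamellae=nl,
        percent_imaged_p=percent_imaged(model.lamella_width_l, nl, length),
        cells_per_lamella_nc=cells_per_lamella(workflow.lamella_area_al_um2, ac),
        time_100_cells_min=time_for_n_cells(
            workflow.mill_time_tl_min,
            cells_per_lamella(workflow.lamella_area_al_um2, ac),
            100,
        ),
        tomograms_per_lamella=tomograms_per_lamella(
            workflow.lamella_area_al_um2, geom
        ),
    )
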