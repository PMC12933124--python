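"""Shape-based cell dimension handling.

Two quantities drive the yield mathematics: the maximal recorded dimension
L (the axis along which lamellae are stacked) and a spherical
cross-sectional-area approximation Ac = pi*(L/2)^2 used when counting how
many cells fit inside one lamella.  The sphere approximation uses the
maximal dimension because that reproduces the benchmark areas quoted for
E. coli (2 um^2), S. cerevisiae (19.6 um^2), C. reinhardtii (50.3 um^2)
and HeLa (227.0 um^2) from their recorded lengths.

Shape-specific volume models are deliberately not implemented: lamella
volumes often exceed whole prokaryotic cell volumes, which makes
volume-fraction comparisons across domains unstable.  Shape is retained as
metadata only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

from .entries import CellEntry, EXTRA_DIM_SHAPES, Shape

__all__ = ["ShapeDims", "dims_of", "max_dimension", "cross_section_area_sphere"]


@dataclass(frozen=True)
class ShapeDims:
    """Recorded dimensions (um) of a cell or tissue under a shape class."""

    shape: Shape
    length_um: float
    width_um: float
    extra_length_um: Optional[float] = None

    def __post_init__(self):
        if self.length_um <= 0 or self.width_um <= 0:
            raise ValueError("dimensions must be > 0")
        if self.shape in EXTRA_DIM_SHAPES:
            if self.extra_length_um is None or self.extra_length_um <= 0:
                raise ValueError(
                    f"shape {self.shape.value} requires a positive extra_length_um"
                )
        elif self.extra_length_um is not None:
            raise ValueError(
                f"extra_length_um not allowed for shape {self.shape.value}"
            )

    @property
    def dimensions(self) -> tuple[float, ...]:
        if self.extra_length_um is not None:
            return (self.length_um, self.width_um, self.extra_length_um)
        return (self.length_um, self.width_um)


def dims_of(entry: CellEntry) -> ShapeDims:
    """Extract the dimension record from a literature entry."""
    return ShapeDims(
        shape=entry.shape,
        length_um=entry.length_um,
        width_um=entry.width_um,
        extra_length_um=entry.extra_length_um,
    )


def max_dimension(dims: ShapeDims | CellEntry) -> float:
    """Largest recorded dimension L (um), the denominator of the
    percent-imaged calculation and the axis divided into serial sections."""
    if isinstance(dims, CellEntry):
        dims = dims_of(dims)
    return max(dims.dimensions)


def cross_section_area_sphere(diameter_um: float) -> float:
    """Cross-sectional area (um^2) of a sphere of the given diameter.

    Cells are approximated as spheres of diameter equal to their maximal
    recorded dimension when estimating how many pack into a lamella.
    """
    if diameter_um <= 0:
        raise ValueError("diameter must be > 0")
    return math.pi * (diameter_um / 2.0) ** 2
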