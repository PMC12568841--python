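"""Stimulus design for the 3x3 conjunctive-rule categorization space.

The stimulus set crosses three levels of a "lips" dimension (lip-to-nose
height, ``x``) with three levels of an "eyes" dimension (eye separation,
``y``).  The target category is the conjunction ``x in {x1, x2} AND
y in {y1, y2}`` (four members); the remaining five stimuli form the
disjunctive contrast category.  Target items are labelled by their
discriminability relative to the two category bounds (LL, LH, HL, HH) and
contrast items by their position relative to the bounds (redundant R,
interior Ix/Iy, exterior Ex/Ey).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

__all__ = [
    "StimulusRole",
    "StimulusDesign",
    "assign_role",
    "default_design",
    "TARGET_ROLES",
    "CONTRAST_ROLES",
]


class StimulusRole(str, enum.Enum):
    """Role of a stimulus in the 3x3 factorial category space."""

    HH = "HH"  # x2 y2: high discriminability on both dimensions
    HL = "HL"  # x2 y1
    LH = "LH"  # x1 y2
    LL = "LL"  # x1 y1
    R = "R"    # x0 y0: redundant (satisfies the disjunction on both dims)
    Ix = "Ix"  # x1 y0: interior on the lips dimension
    Ex = "Ex"  # x2 y0: exterior on the lips dimension
    Iy = "Iy"  # x0 y1: interior on the eyes dimension
    Ey = "Ey"  # x0 y2: exterior on the eyes dimension


_ROLE_BY_CELL: dict[tuple[int, int], StimulusRole] = {
    (2, 2): StimulusRole.HH,
    (2, 1): StimulusRole.HL,
    (1, 2): StimulusRole.LH,
    (1, 1): StimulusRole.LL,
    (0, 0): StimulusRole.R,
    (1, 0): StimulusRole.Ix,
    (2, 0): StimulusRole.Ex,
    (0, 1): StimulusRole.Iy,
    (0, 2): StimulusRole.Ey,
}

CELL_BY_ROLE: dict[StimulusRole, tuple[int, int]] = {
    v: k for k, v in _ROLE_BY_CELL.items()
}

TARGET_ROLES = (StimulusRole.HH, StimulusRole.HL, StimulusRole.LH, StimulusRole.LL)
CONTRAST_ROLES = (
    StimulusRole.R,
    StimulusRole.Ix,
    StimulusRole.Ex,
    StimulusRole.Iy,
    StimulusRole.Ey,
)


def assign_role(x_level: int, y_level: int) -> StimulusRole:
    """Map a (x_level, y_level) cell to its stimulus role.

    The mapping is a bijection between the nine grid cells and the nine
    roles: HH = x2y2, HL = x2y1, LH = x1y2, LL = x1y1, R = x0y0,
    Ix = x1y0, Ex = x2y0, Iy = x0y1, Ey = x0y2.
    """
    key = (int(x_level), int(y_level))
    if key not in _ROLE_BY_CELL:
        raise ValueError(f"stimulus levels must be in 0..2, got {key}")
    return _ROLE_BY_CELL[key]


@dataclass(frozen=True)
class StimulusDesign:
    """The 3x3 grid, its psychological coordinates and the category rule.

    Parameters
    ----------
    x_coords, y_coords
        Psychological positions of the three levels of each dimension
        (arbitrary units; typically an MDS solution).  Must be strictly
        increasing.
    x_name, y_name
        Human-readable dimension names.
    """

    x_coords: tuple[float, float, float]
    y_coords: tuple[float, float, float]
    x_name: str = "lips"
    y_name: str = "eyes"

    def __post_init__(self) -> None:
        for coords, name in ((self.x_coords, "x"), (self.y_coords, "y")):
            if len(coords) != 3:
                raise ValueError(f"{name}_coords must have 3 levels")
            if not np.all(np.diff(coords) > 0):
                raise ValueError(f"{name}_coords must be strictly increasing")

    def is_target(self, x_level: int, y_level: int) -> bool:
        """Conjunctive target rule: x in {x1, x2} AND y in {y1, y2}."""
        if not (0 <= x_level <= 2 and 0 <= y_level <= 2):
            raise ValueError(f"levels must be in 0..2, got {(x_level, y_level)}")
        return x_level >= 1 and y_level >= 1

    @property
    def cells(self) -> list[tuple[int, int]]:
        return [(x, y) for x in range(3) for y in range(3)]

    @property
    def target_cells(self) -> list[tuple[int, int]]:
        return [c for c in self.cells if self.is_target(*c)]

    @property
    def contrast_cells(self) -> list[tuple[int, int]]:
        return [c for c in self.cells if not self.is_target(*c)]

    def coordinates(self, x_level: int, y_level: int) -> tuple[float, float]:
        return (self.x_coords[x_level], self.y_coords[y_level])

    def grid_coordinates(self) -> np.ndarray:
        """(9, 2) array of stimulus coordinates in cell order."""
        return np.array([self.coordinates(x, y) for x, y in self.cells])


def default_design() -> StimulusDesign:
    """Canonical design used throughout the synthetic studies.

    Level spacings are chosen so that, with unit perceptual noise and the
    decision bounds midway between levels 0 and 1 (see
    :func:`facesft.rule_models.default_grt`), target-side standardized
    distances are 0.75 for the low-discriminability levels and 2.0 for the
    high-discriminability levels.
    """
    return StimulusDesign(x_coords=(0.0, 1.25, 2.5), y_coords=(0.0, 1.25, 2.5))
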