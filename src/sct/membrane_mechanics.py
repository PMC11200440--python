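"""Membrane tension of a cell aspirated at the capillary tip.

Micropipette-aspiration mechanics: a cell of radius ``R_OUT`` held at a tip
of inner radius ``R_CH`` by suction ``dP`` develops a cap tension

    tau = (dP / 2) / (1/R_CH - 1/R_OUT)

(law-of-Laplace force balance on the aspirated cap).  Tension grows with tip
size and shrinks with cell size; the flat-cell limit ``R_OUT -> inf`` gives
``dP * R_CH / 2``.  Computed tensions are compared against rupture-tension
thresholds from micropipette deformability studies of clinical tumor cells:
800 to 5000 with a median of 3700.  The computed quantity has dimensions
Pa*um (= uN/m = mN/m * 1e-3); the thresholds are printed in the source
literature with the label "Pa/um", which we carry as-is in display metadata
while comparing magnitudes directly (see docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import GeometryError, GridError

__all__ = [
    "CellModel",
    "TensionAssessment",
    "DesignGrid",
    "membrane_tension",
    "assess_safety",
    "design_grid",
    "DEFAULT_TIP_IDS_UM",
    "DEFAULT_CELL_DIAMETERS_UM",
]

#: Unit note attached to reports: dimensional analysis of tau gives Pa*um,
#: while the literature prints the rupture thresholds as "Pa/um".
TENSION_UNIT_NOTE = (
    "computed tension has dimensions Pa*um (uN/m); literature thresholds "
    "are printed as 'Pa/um' and are compared by magnitude"
)

#: Default design-space axes (um): tip I.D. 0.5-5.0 step 0.25,
#: cell diameter 8-20 step 2.
DEFAULT_TIP_IDS_UM = tuple(np.arange(0.5, 5.0 + 1e-9, 0.25).round(2))
DEFAULT_CELL_DIAMETERS_UM = tuple(range(8, 22, 2))


@dataclass(frozen=True)
class CellModel:
    """Tumor-cell geometry and rupture-tension thresholds.

    Default thresholds (800 / 3700 / 5000) are the reported range and median
    of maximum pre-rupture membrane tension for clinical tumor cells.
    """

    cell_radius: float  #: R_OUT, m
    rupture_tension_min: float = 800.0
    rupture_tension_median: float = 3700.0
    rupture_tension_max: float = 5000.0

    def __post_init__(self) -> None:
        if self.cell_radius <= 0:
            raise GeometryError("cell_radius must be positive")
        if not (0 < self.rupture_tension_min <= self.rupture_tension_median
                <= self.rupture_tension_max):
            raise GeometryError(
                "rupture thresholds must satisfy 0 < min <= median <= max")


@dataclass(frozen=True)
class TensionAssessment:
    """A tension value classified against the rupture-tension band."""

    tension: float  #: tau, Pa*um
    tip_inner_radius: float  #: R_CH, m
    cell_radius: float  #: R_OUT, m
    driving_pressure: float  #: dP, Pa
    classification: str  #: safe | within-rupture-range | above-rupture-range
    margin_to_min: float
    margin_to_median: float
    margin_to_max: float


@dataclass(frozen=True)
class DesignGrid:
    """Tension over a tip-I.D. x cell-diameter grid.

    ``tension`` is NaN where the tip is at least as wide as the cell (the
    cell would be swallowed whole; the cap model does not apply) and
    ``safe_mask`` is False there.
    """

    tip_inner_diameters_um: tuple  #: grid axis, um
    cell_diameters_um: tuple  #: grid axis, um
    tension: np.ndarray = field(repr=False)  #: (n_tip, n_cell), Pa*um
    safe_mask: np.ndarray = field(repr=False)  #: tension < rupture min
    driving_pressure: float  #: dP, Pa
    rupture_tension_min: float

    @property
    def max_tension(self) -> float:
        """Largest tension over the admissible part of the grid."""
        return float(np.nanmax(self.tension))

    @property
    def fraction_safe(self) -> float:
        """Fraction of admissible grid points below the rupture minimum."""
        valid = ~np.isnan(self.tension)
        return float(self.safe_mask[valid].mean())


def membrane_tension(dp: float, tip_radius: float, cell_radius: float) -> float:
    """Aspiration-cap membrane tension, returned in Pa*um.

    Parameters are SI (Pa, m, m); requires ``0 < tip_radius < cell_radius``
    and ``dp > 0``.
    """
    if dp <= 0:
        raise GeometryError("driving pressure must be positive")
    if tip_radius <= 0:
        raise GeometryError("tip_radius must be positive")
    if tip_radius >= cell_radius:
        raise GeometryError(
            "tip_radius must be smaller than cell_radius: a cell no larger "
            "than the tip would be aspirated whole and the cap-tension "
            "model does not apply")
    tau_pa_m = (dp / 2.0) / (1.0 / tip_radius - 1.0 / cell_radius)
    return tau_pa_m * 1e6  # Pa*m -> Pa*um


def assess_safety(tension: float, cell: CellModel, dp: float = float("nan"),
                  tip_radius: float = float("nan")) -> TensionAssessment:
    """Classify a tension value against the cell's rupture band.

    The boundary ``tension == rupture_tension_min`` is classified as
    within-rupture-range (conservative: ties count against safety).
    """
    if tension < cell.rupture_tension_min:
        cls = "safe"
    elif tension > cell.rupture_tension_max:
        cls = "above-rupture-range"
    else:
        cls = "within-rupture-range"
    return TensionAssessment(
        tension=tension,
        tip_inner_radius=tip_radius,
        cell_radius=cell.cell_radius,
        driving_pressure=dp,
        classification=cls,
        margin_to_min=cell.rupture_tension_min - tension,
        margin_to_median=cell.rupture_tension_median - tension,
        margin_to_max=cell.rupture_tension_max - tension,
    )


def design_grid(dp: float,
                tip_ids_um: Sequence[float] = DEFAULT_TIP_IDS_UM,
                cell_diameters_um: Sequence[float] = DEFAULT_CELL_DIAMETERS_UM,
                rupture_tension_min: float = 800.0) -> DesignGrid:
    """Sweep membrane tension over tip I.D. x cell diameter (both in um).

    Pairs where the tip is at least as wide as the cell are masked (NaN),
    not errored; an empty axis raises :class:`GridError`.
    """
    tip_ids = tuple(float(t) for t in tip_ids_um)
    cells = tuple(float(c) for c in cell_diameters_um)
    if not tip_ids or not cells:
        raise GridError("design grid axes must be non-empty")
    tension = np.full((len(tip_ids), len(cells)), np.nan)
    for i, tid in enumerate(tip_ids):
        for j, cd in enumerate(cells):
            r_ch = tid / 2.0 * 1e-6
            r_out = cd / 2.0 * 1e-6
            if r_ch < r_out:
                tension[i, j] = membrane_tension(dp, r_ch, r_out)
    safe = np.where(np.isnan(tension), False, tension < rupture_tension_min)
    return DesignGrid(
        tip_inner_diameters_um=tip_ids,
        cell_diameters_um=cells,
        tension=tension,
        safe_mask=safe,
        driving_pressure=dp,
        rupture_tension_min=rupture_tension_min,
    )
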