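"""Closed-form capillary statics of the single-cell-transfer (SCT) pipette.

The SCT instrument is a tapered glass capillary whose rear end is sealed to a
syringe, so the gas column ("headspace") trapped behind the meniscus is
compressed as fluid rises.  The model combines three pieces of classical
physics:

* the Young–Laplace pressure jump across the meniscus in the un-tapered
  barrel, ``dP = 2*gamma*cos(beta)/R``, which acts as the capillary driving
  pressure;
* Jurin's law, ``h = dP/(rho*g)``, the open-reservoir equilibrium rise;
* Boyle's law for the sealed headspace, ``P1*V1 = P2*V2``, which limits the
  pre-sampling rise ``h2`` to well below the Jurin height.

Eliminating the headspace pressure and volume from the hydrostatic balance
``P2 + rho*g*h2 - dP = P1`` yields a quadratic in the single unknown ``h2``::

    h2**2 - [dP/(rho*g) + V1*sin(theta)/(n*pi*R**2) + P1/(rho*g)] * h2
          +  dP * V1*sin(theta) / (rho*g * n*pi*R**2)  =  0

whose smaller root is the physical rise (the larger root, tens of metres,
violates ``h2 < dP/(rho*g)``).  The overpressure stored in the compressed
headspace, ``P2 - P1``, is released as a gentle suction when the syringe is
disconnected — this "on/off pressure difference" is what actually picks up a
cell.

All quantities are SI (m, Pa, m^3); display-unit conversion lives in
:mod:`sct.config`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

from .errors import (
    EquilibriumError,
    GeometryError,
    HeadspaceExhaustedError,
    ModelViolationError,
    SamplingError,
)

__all__ = [
    "FluidProperties",
    "CapillarySystem",
    "AspirationState",
    "effective_pressure",
    "jurin_height",
    "fluid_length",
    "solve_presample_rise",
    "presample_state",
    "aspirated_volume",
]

#: Relative tolerance to which every solved state must satisfy Boyle's law.
BOYLE_RTOL = 1e-9


@dataclass(frozen=True)
class FluidProperties:
    """Working-fluid constants.

    Parameters
    ----------
    surface_tension : float
        gamma, N/m (J/m^2).
    density : float
        rho, kg/m^3.
    contact_angle_deg : float
        beta, degrees; wetting for beta < 90.
    gravity : float
        g, m/s^2.
    """

    surface_tension: float
    density: float
    contact_angle_deg: float
    gravity: float = 9.81

    def __post_init__(self) -> None:
        if self.surface_tension <= 0:
            raise GeometryError("surface_tension must be positive")
        if self.density <= 0:
            raise GeometryError("density must be positive")
        if self.gravity <= 0:
            raise GeometryError("gravity must be positive")
        if not 0 <= self.contact_angle_deg < 180:
            raise GeometryError("contact_angle_deg must lie in [0, 180)")

    @classmethod
    def water(cls) -> "FluidProperties":
        """Water against borosilicate glass at room temperature:
        gamma = 0.0728 N/m, beta = 32.3 deg, rho = 997 kg/m^3."""
        return cls(surface_tension=0.0728, density=997.0,
                   contact_angle_deg=32.3)


@dataclass(frozen=True)
class CapillarySystem:
    """Geometry and sealed-gas state of the transfer capillary.

    ``tip_volume_coefficient`` (n) corrects the displaced-gas volume for the
    tapered tip: only a fraction n of the nominal barrel cross-section times
    fluid length is actually displaced.
    """

    barrel_inner_radius: float  #: R, m (un-tapered section)
    tip_inner_radius: float  #: R_ch, m
    insertion_angle_deg: float  #: theta, degrees from horizontal
    headspace_volume: float  #: V1, m^3 (sealed gas before sampling)
    ambient_pressure: float  #: P1, Pa
    tip_volume_coefficient: float = 1.0 / 3.0  #: n, dimensionless

    def __post_init__(self) -> None:
        if self.barrel_inner_radius <= 0:
            raise GeometryError("barrel_inner_radius must be positive")
        if not 0 < self.tip_inner_radius <= self.barrel_inner_radius:
            raise GeometryError(
                "tip_inner_radius must lie in (0, barrel_inner_radius]")
        if not 0 < self.insertion_angle_deg <= 90:
            raise GeometryError("insertion_angle_deg must lie in (0, 90]")
        if not 0 < self.tip_volume_coefficient <= 1:
            raise GeometryError("tip_volume_coefficient must lie in (0, 1]")
        if self.headspace_volume <= 0:
            raise GeometryError("headspace_volume must be positive")
        if self.ambient_pressure <= 0:
            raise GeometryError("ambient_pressure must be positive")

    @classmethod
    def default(cls) -> "CapillarySystem":
        """As-operated instrument: 0.56 mm barrel radius, 1.0 um tip radius
        (2.0 um I.D.), 45 deg insertion, 3.1 mL headspace at 1.01e5 Pa,
        n = 1/3."""
        return cls(
            barrel_inner_radius=0.56e-3,
            tip_inner_radius=1.0e-6,
            insertion_angle_deg=45.0,
            headspace_volume=3.1e-6,
            ambient_pressure=1.01e5,
        )


@dataclass(frozen=True)
class AspirationState:
    """Fully solved pre-sampling equilibrium of the sealed capillary."""

    effective_pressure: float  #: dP, Pa
    jurin_height: float  #: h = dP/(rho*g), m
    equilibrium_length: float  #: L = h/sin(theta), m
    presample_height: float  #: h2, m
    presample_length: float  #: L2 = h2/sin(theta), m
    headspace_pressure: float  #: P2, Pa
    headspace_volume: float  #: V2, m^3
    on_off_pressure: float  #: P2 - P1, Pa
    presample_reference_length: float  #: L1, m (convention: L1 = L2)
    aspirated_volume: float  #: dV = (L - L1)*pi*R^2, m^3


def effective_pressure(fluid: FluidProperties, barrel_radius: float) -> float:
    """Young–Laplace capillary driving pressure ``2*gamma*cos(beta)/R``.

    Positive for a wetting fluid (beta < 90 deg), zero at 90 deg, negative
    beyond.
    """
    if barrel_radius <= 0:
        raise GeometryError("barrel_radius must be positive")
    if fluid.contact_angle_deg == 90.0:
        return 0.0  # cos(pi/2) is not exactly zero in floating point
    beta = math.radians(fluid.contact_angle_deg)
    return 2.0 * fluid.surface_tension * math.cos(beta) / barrel_radius


def jurin_height(fluid: FluidProperties, barrel_radius: float) -> float:
    """Open-reservoir equilibrium rise ``2*gamma*cos(beta)/(rho*g*R)``."""
    dp = effective_pressure(fluid, barrel_radius)
    return dp / (fluid.density * fluid.gravity)


def fluid_length(height: float, insertion_angle_deg: float) -> float:
    """Fluid column length along a capillary inclined at ``theta`` degrees
    whose meniscus sits ``height`` above the reservoir: ``L = h/sin(theta)``.
    """
    if insertion_angle_deg <= 0:
        raise GeometryError("insertion_angle_deg must be positive")
    return height / math.sin(math.radians(insertion_angle_deg))


def _quadratic_coefficients(fluid: FluidProperties, sys: CapillarySystem,
                            dp: float) -> tuple[float, float]:
    """(b, c) of ``h2**2 - b*h2 + c = 0`` for the sealed-headspace balance."""
    rg = fluid.density * fluid.gravity
    sin_t = math.sin(math.radians(sys.insertion_angle_deg))
    area_term = (sys.headspace_volume * sin_t
                 / (sys.tip_volume_coefficient * math.pi
                    * sys.barrel_inner_radius ** 2))
    b = dp / rg + area_term + sys.ambient_pressure / rg
    c = dp * area_term / rg
    return b, c


def solve_presample_rise(fluid: FluidProperties, sys: CapillarySystem,
                         dp: float) -> float:
    """Solve the sealed-headspace quadratic for the pre-sampling rise h2.

    Returns the smaller (physical) root, guaranteed to satisfy
    ``0 < h2 < dP/(rho*g)``; the larger root corresponds to a rise above the
    Jurin height, which the stored gas pressure cannot sustain.

    Raises
    ------
    EquilibriumError
        Negative discriminant: no real equilibrium.
    ModelViolationError
        Neither root lies in the admissible band.
    """
    if dp <= 0:
        raise ModelViolationError("driving pressure must be positive")
    b, c = _quadratic_coefficients(fluid, sys, dp)
    disc = b * b - 4.0 * c
    if disc < 0:
        raise EquilibriumError(
            "sealed-headspace balance has no real solution")
    # Smaller root via the numerically stable co-root form: avoids the
    # catastrophic cancellation of (b - sqrt(disc))/2 when c << b**2.
    h2 = 2.0 * c / (b + math.sqrt(disc))
    h_jurin = dp / (fluid.density * fluid.gravity)
    if not 0.0 < h2 < h_jurin:
        raise ModelViolationError(
            f"no admissible root: h2={h2:.6g} m outside (0, {h_jurin:.6g})")
    return h2


def presample_state(fluid: FluidProperties, sys: CapillarySystem,
                    dp_override: Optional[float] = None) -> AspirationState:
    """Solve the complete pre-sampling equilibrium.

    Parameters
    ----------
    dp_override : float, optional
        Replaces the Young–Laplace driving pressure.  Useful to carry a
        rounded upstream value through the chain, or to model an externally
        imposed pressure.  ``dp_override = 0`` short-circuits to the trivial
        no-drive state (h2 = 0, P2 = P1), as does beta = 90 deg.

    Notes
    -----
    By construction the returned state satisfies Boyle's law
    ``P1*V1 = P2*V2`` to relative 1e-9; this is asserted, not assumed.
    """
    dp = (dp_override if dp_override is not None
          else effective_pressure(fluid, sys.barrel_inner_radius))
    rg = fluid.density * fluid.gravity
    sin_t = math.sin(math.radians(sys.insertion_angle_deg))
    barrel_area = math.pi * sys.barrel_inner_radius ** 2

    if dp < 0:
        raise ModelViolationError(
            "non-wetting fluid (negative driving pressure) is outside the "
            "aspiration model")
    if dp == 0:
        return AspirationState(
            effective_pressure=0.0, jurin_height=0.0, equilibrium_length=0.0,
            presample_height=0.0, presample_length=0.0,
            headspace_pressure=sys.ambient_pressure,
            headspace_volume=sys.headspace_volume,
            on_off_pressure=0.0, presample_reference_length=0.0,
            aspirated_volume=0.0)

    h2 = solve_presample_rise(fluid, sys, dp)
    h = dp / rg
    length = h / sin_t
    l2 = h2 / sin_t
    v2 = sys.headspace_volume - sys.tip_volume_coefficient * barrel_area * l2
    if v2 <= 0:
        raise HeadspaceExhaustedError(
            "aspirated column would exhaust the sealed headspace")
    p2 = sys.ambient_pressure + dp - rg * h2

    boyle_gap = abs(sys.ambient_pressure * sys.headspace_volume - p2 * v2)
    if boyle_gap > BOYLE_RTOL * sys.ambient_pressure * sys.headspace_volume:
        raise ModelViolationError(
            f"Boyle consistency violated (relative gap "
            f"{boyle_gap / (sys.ambient_pressure * sys.headspace_volume):.3g})")

    l1 = l2  # reference length convention: pre-sampling column
    return AspirationState(
        effective_pressure=dp,
        jurin_height=h,
        equilibrium_length=length,
        presample_height=h2,
        presample_length=l2,
        headspace_pressure=p2,
        headspace_volume=v2,
        on_off_pressure=p2 - sys.ambient_pressure,
        presample_reference_length=l1,
        aspirated_volume=aspirated_volume(length, l1,
                                          sys.barrel_inner_radius),
    )


def aspirated_volume(length: float, reference_length: float,
                     barrel_radius: float) -> float:
    """Sampled fluid volume ``dV = (L - L1) * pi * R**2``.

    ``L`` is the final fluid length (default convention: the open-reservoir
    Jurin length ``h/sin(theta)`` reached once the syringe is disconnected)
    and ``L1`` the pre-sampling column length.
    """
    if barrel_radius <= 0:
        raise GeometryError("barrel_radius must be positive")
    if reference_length < 0:
        raise SamplingError("reference_length must be non-negative")
    if length < reference_length:
        raise SamplingError(
            "final length shorter than reference length: negative sampling")
    return (length - reference_length) * math.pi * barrel_radius ** 2
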