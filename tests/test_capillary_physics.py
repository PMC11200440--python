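"""Capillary statics: Young–Laplace pressure, Jurin rise, sealed-headspace
equilibrium, and the aspirated-volume formula."""

import math

import pytest
from hypothesis import assume, given, settings
from hypothesis import strategies as st

from sct import (
    CapillarySystem,
    FluidProperties,
    aspirated_volume,
    effective_pressure,
    fluid_length,
    jurin_height,
    presample_state,
    solve_presample_rise,
)
from sct.errors import GeometryError, ModelViolationError, SamplingError


def bisect_unexpanded_balance(fluid, sys, dp, tol=1e-12):
    """Independent oracle: bisection on the un-expanded pressure balance.

    Eliminating nothing, equilibrium requires
    P1*V1 / (V1 - n*pi*R^2*h2/sin(theta)) + rho*g*h2 - dP = P1
    on h2 in (0, dP/(rho*g)).
    """
    rg = fluid.density * fluid.gravity
    sin_t = math.sin(math.radians(sys.insertion_angle_deg))
    area = sys.tip_volume_coefficient * math.pi * sys.barrel_inner_radius ** 2

    def f(h2):
        v2 = sys.headspace_volume - area * h2 / sin_t
        return (sys.ambient_pressure * sys.headspace_volume / v2
                + rg * h2 - dp - sys.ambient_pressure)

    lo, hi = 0.0, dp / rg
    assert f(lo) < 0 < f(hi)
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if f(mid) < 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


# ---------------------------------------------------------------- scalars


@pytest.mark.parametrize("fluid_kw, radius, expected, rtol", [
    # documented operating point: printed value 220.5 Pa (exact 219.8)
    (dict(surface_tension=0.0728, density=997, contact_angle_deg=32.3),
     0.56e-3, 220.5, 0.005),
    # neutral wetting: zero capillary pressure
    (dict(surface_tension=0.05, density=1000, contact_angle_deg=90),
     1e-3, 0.0, None),
    # perfectly wetting: 2*0.05/0.001
    (dict(surface_tension=0.05, density=1000, contact_angle_deg=0),
     1e-3, 100.0, 1e-12),
])
def test_effective_pressure_worked_values(fluid_kw, radius, expected, rtol):
    dp = effective_pressure(FluidProperties(**fluid_kw), radius)
    if expected == 0.0:
        assert dp == pytest.approx(0.0, abs=1e-12)
    else:
        assert dp == pytest.approx(expected, rel=rtol)


def test_jurin_height_operating_point(water):
    assert jurin_height(water, 0.56e-3) * 1e3 == pytest.approx(22.5,
                                                               rel=0.005)


def test_jurin_height_zero_at_neutral_wetting():
    f = FluidProperties(surface_tension=0.0728, density=997,
                        contact_angle_deg=90)
    assert jurin_height(f, 0.56e-3) == pytest.approx(0.0, abs=1e-15)


def test_jurin_height_inverse_in_radius(water):
    assert jurin_height(water, 0.28e-3) == pytest.approx(
        2 * jurin_height(water, 0.56e-3), rel=1e-12)


@given(gamma=st.floats(1e-3, 0.2), beta=st.floats(0, 179),
       rho=st.floats(500, 2000), radius=st.floats(1e-5, 1e-2))
@settings(max_examples=200, deadline=None, derandomize=True)
def test_jurin_pressure_identity(gamma, beta, rho, radius):
    """h * rho * g == dP to relative 1e-12 for all valid inputs."""
    f = FluidProperties(surface_tension=gamma, density=rho,
                        contact_angle_deg=beta)
    h = jurin_height(f, radius)
    dp = effective_pressure(f, radius)
    assert h * rho * f.gravity == pytest.approx(dp, rel=1e-12, abs=1e-12)


@pytest.mark.parametrize("h_mm, theta, expected_mm", [
    (8.9, 45.0, 12.6),   # documented operating point (printed rounding)
    (10.0, 90.0, 10.0),  # vertical capillary
    (10.0, 30.0, 20.0),  # 1/sin(30) = 2
])
def test_fluid_length(h_mm, theta, expected_mm):
    assert fluid_length(h_mm * 1e-3, theta) * 1e3 == pytest.approx(
        expected_mm, rel=0.005)


def test_invalid_geometry_errors(water):
    with pytest.raises(GeometryError):
        effective_pressure(water, 0.0)
    with pytest.raises(GeometryError):
        jurin_height(water, -1e-3)
    with pytest.raises(GeometryError):
        fluid_length(0.01, 0.0)


# ------------------------------------------------- sealed-headspace solve


def test_presample_rise_operating_point(water, system):
    """With the driving pressure carried at its printed 220.5 Pa, the
    quadratic's physical root is the documented 8.9 mm within 1%."""
    h2 = solve_presample_rise(water, system, 220.5)
    assert h2 * 1e3 == pytest.approx(8.9, rel=0.01)


def test_presample_rise_vanishes_with_headspace(water, system):
    from dataclasses import replace
    tiny = replace(system, headspace_volume=1e-12)
    assert solve_presample_rise(water, tiny, 220.5) < 1e-7


def test_presample_rise_matches_bisection_oracle(water, system):
    h2 = solve_presample_rise(water, system, 220.5)
    assert h2 == pytest.approx(
        bisect_unexpanded_balance(water, system, 220.5), abs=1e-9)


@st.composite
def valid_draws(draw):
    gamma = draw(st.floats(0.01, 0.1))
    beta = draw(st.floats(0, 80))
    rho = draw(st.floats(700, 1300))
    radius = draw(st.floats(1e-4, 2e-3))
    theta = draw(st.floats(5, 90))
    v1 = draw(st.floats(1e-7, 1e-5))
    p1 = draw(st.floats(5e4, 2e5))
    n = draw(st.floats(0.05, 1.0))
    fluid = FluidProperties(surface_tension=gamma, density=rho,
                            contact_angle_deg=beta)
    sys = CapillarySystem(barrel_inner_radius=radius, tip_inner_radius=radius,
                          insertion_angle_deg=theta, headspace_volume=v1,
                          ambient_pressure=p1, tip_volume_coefficient=n)
    dp = effective_pressure(fluid, radius)
    assume(dp > 1e-3)
    # keep the Jurin-height column from exhausting the headspace
    rg = rho * fluid.gravity
    col = n * math.pi * radius ** 2 * (dp / rg) / math.sin(math.radians(theta))
    assume(col < 0.5 * v1)
    return fluid, sys, dp


@given(valid_draws())
@settings(max_examples=200, deadline=None, derandomize=True)
def test_quadratic_root_equals_bisection(params):
    fluid, sys, dp = params
    h2 = solve_presample_rise(fluid, sys, dp)
    assert h2 == pytest.approx(
        bisect_unexpanded_balance(fluid, sys, dp), abs=1e-9)
    assert 0 < h2 < dp / (fluid.density * fluid.gravity)


def test_rise_monotone_in_headspace(water, system):
    from dataclasses import replace
    rises = [solve_presample_rise(
        water, replace(system, headspace_volume=v), 220.5)
        for v in (1e-6, 3.1e-6, 1e-5, 1e-4)]
    assert all(a < b for a, b in zip(rises, rises[1:]))


def test_large_headspace_limit(water, system):
    """As V1 -> inf the sealed rise approaches the open Jurin height."""
    from dataclasses import replace
    big = replace(system, headspace_volume=1.0)
    dp = 220.5
    h2 = solve_presample_rise(water, big, dp)
    jurin = dp / (water.density * water.gravity)
    assert abs(h2 - jurin) / jurin < 1e-3


def test_nonpositive_drive_rejected(water, system):
    with pytest.raises(ModelViolationError):
        solve_presample_rise(water, system, -10.0)


# ------------------------------------------------------- presample state


def test_presample_state_consistency(water, system):
    s = presample_state(water, system, dp_override=220.5)
    p1, v1 = system.ambient_pressure, system.headspace_volume
    assert abs(p1 * v1 - s.headspace_pressure * s.headspace_volume) \
        < 1e-9 * p1 * v1
    assert s.headspace_pressure > p1
    assert s.headspace_volume < v1
    assert s.on_off_pressure == pytest.approx(
        s.headspace_pressure - p1, rel=1e-12)
    assert s.presample_length == pytest.approx(
        s.presample_height / math.sin(math.radians(45)), rel=1e-12)
    assert 0 < s.presample_height < s.jurin_height


def test_presample_state_on_off_regime(water, system):
    """Self-consistent on/off pressure lands near the documented 133.3 Pa
    in both driving-pressure modes."""
    carried = presample_state(water, system, dp_override=220.5)
    exact = presample_state(water, system)
    assert carried.on_off_pressure == pytest.approx(133.3, rel=0.006)
    assert exact.on_off_pressure == pytest.approx(133.3, rel=0.006)


def test_presample_state_no_drive(water, system):
    s = presample_state(water, system, dp_override=0.0)
    assert s.presample_height == 0.0
    assert s.headspace_pressure == system.ambient_pressure
    assert s.on_off_pressure == 0.0
    assert s.aspirated_volume == 0.0


def test_presample_state_neutral_wetting(system):
    neutral = FluidProperties(surface_tension=0.0728, density=997,
                              contact_angle_deg=90)
    s = presample_state(neutral, system)
    assert s.presample_height == 0.0 and s.on_off_pressure == 0.0


@given(valid_draws())
@settings(max_examples=100, deadline=None, derandomize=True)
def test_boyle_consistency_property(params):
    fluid, sys, dp = params
    s = presample_state(fluid, sys, dp_override=dp)
    lhs = sys.ambient_pressure * sys.headspace_volume
    assert abs(lhs - s.headspace_pressure * s.headspace_volume) < 1e-9 * lhs


# ------------------------------------------------------ aspirated volume


@pytest.mark.parametrize("l_mm, l1_mm, expected_ul", [
    (31.8, 12.6, 18.9),  # theoretical-Jurin convention
    (33.4, 12.6, 20.5),  # measured-Jurin (23.6 mm) alternative
])
def test_aspirated_volume_values(l_mm, l1_mm, expected_ul):
    dv = aspirated_volume(l_mm * 1e-3, l1_mm * 1e-3, 0.56e-3)
    assert dv * 1e9 == pytest.approx(expected_ul, rel=0.005)


def test_aspirated_volume_edges():
    assert aspirated_volume(0.01, 0.01, 0.56e-3) == 0.0
    with pytest.raises(SamplingError):
        aspirated_volume(0.01, 0.02, 0.56e-3)
    with pytest.raises(GeometryError):
        aspirated_volume(0.02, 0.01, 0.0)
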