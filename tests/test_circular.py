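"""Circular-statistics unit and property tests.

The independent oracle used throughout represents each angle as a unit
complex number; means, deviations and spreads are computed with complex
arithmetic only, never through the implementation under test.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from circaphase import circular as c
from circaphase.exceptions import (
    ConfigError,
    DegenerateDirectionError,
    InvalidAngleError,
    ShapeError,
    UndefinedStatisticError,
)

deg = np.deg2rad


# ---------------------------------------------------------------- oracles
def oracle_mean(angles):
    return float(np.angle(np.mean(np.exp(1j * np.asarray(angles)))) % (2 * np.pi))


def oracle_diff(a, b):
    return np.angle(np.exp(1j * (np.asarray(a) - np.asarray(b))))


def oracle_mae(pred, obs):
    return float(np.mean(np.abs(oracle_diff(pred, obs))) * 12 / np.pi)


def oracle_sd(angles):
    r = np.abs(np.mean(np.exp(1j * np.asarray(angles))))
    return float(np.sqrt(-2 * np.log(min(r, 1.0))))


# ------------------------------------------------------------- conversions
def test_unit_roundtrips_are_identity():
    theta = np.linspace(0, 2 * np.pi, 97, endpoint=False)
    h = c.radians_to_hours(theta)
    d = c.radians_to_degrees(theta)
    assert np.allclose(c.hours_to_radians(h), theta, atol=1e-12)
    assert np.allclose(c.degrees_to_radians(d), theta, atol=1e-12)


def test_canonicalization_maps_into_cycle():
    assert c.canonical(-0.25) == pytest.approx(2 * np.pi - 0.25)
    assert 0 <= c.canonical(1e8) < 2 * np.pi
    with pytest.raises(InvalidAngleError):
        c.canonical(np.nan)


@pytest.mark.parametrize(
    "theta_deg, xy",
    [(0, (1, 0)), (90, (0, 1)), (180, (-1, 0))],
)
def test_to_cartesian_axis_cases(theta_deg, xy):
    x, y = c.to_cartesian(deg(theta_deg))
    assert (x, y) == pytest.approx(xy, abs=1e-12)
    assert x**2 + y**2 == pytest.approx(1.0, abs=1e-12)


def test_from_cartesian_ignores_magnitude():
    assert c.from_cartesian(0.5, 0.5) == pytest.approx(deg(45))
    assert c.from_cartesian(-2.0, 0.0) == pytest.approx(np.pi)
    with pytest.raises(DegenerateDirectionError):
        c.from_cartesian(1e-15, 1e-15)


# ------------------------------------------------------------- differences
@pytest.mark.parametrize(
    "a_deg, b_deg, expect_deg",
    [(350, 10, -20), (10, 350, 20), (180, 0, 180)],
)
def test_signed_diff_wraps_and_boundary(a_deg, b_deg, expect_deg):
    assert c.signed_diff(deg(a_deg), deg(b_deg)) == pytest.approx(
        deg(expect_deg) if expect_deg != 180 else np.pi
    )


def test_signed_diff_antipodal_convention_is_positive_pi():
    # both orders of an exactly antipodal pair report +pi
    assert c.signed_diff(np.pi, 0.0) == pytest.approx(np.pi)
    assert c.signed_diff(0.0, np.pi) == pytest.approx(np.pi)


# ------------------------------------------------------------------- means
def test_circular_mean_examples():
    assert c.circular_mean(deg([0, 90])) == pytest.approx(deg(45))
    assert c.circular_mean(deg([350, 10])) == pytest.approx(0.0, abs=1e-12)
    with pytest.raises(UndefinedStatisticError):
        c.circular_mean(deg([0, 180]))
    with pytest.raises(UndefinedStatisticError):
        c.circular_mean([])


def test_circular_sd_examples():
    assert c.circular_sd(deg([37, 37, 37])) == pytest.approx(0.0, abs=1e-12)
    expected = np.sqrt(-2 * np.log(np.sqrt(2) / 2))
    assert c.circular_sd(deg([0, 90])) == pytest.approx(expected)
    with pytest.raises(UndefinedStatisticError):
        c.circular_sd([])


# ----------------------------------------------------------------- metrics
def test_mae_examples():
    assert c.mae(deg([10, 350]), [0.0, 0.0]) == pytest.approx(2 / 3)
    obs = deg([5, 100, 200])
    assert c.mae(obs, obs) == 0.0
    assert c.mae(deg([180]), [0.0]) == pytest.approx(12.0)
    with pytest.raises(ShapeError):
        c.mae([0.0], [0.0, 1.0])


def test_mean_error_examples():
    bias, _ = c.mean_error(deg([10, 350]), [0.0, 0.0])
    assert bias == pytest.approx(0.0, abs=1e-12)
    bias, sd = c.mean_error(deg([15] * 5), [0.0] * 5)
    assert bias == pytest.approx(1.0)
    assert sd == pytest.approx(0.0, abs=1e-9)


def test_mean_error_matches_complex_oracle_on_random_angles(rng):
    pred = rng.uniform(0, 2 * np.pi, 200)
    obs = rng.uniform(0, 2 * np.pi, 200)
    bias, sd = c.mean_error(pred, obs)
    errs = oracle_diff(pred, obs)
    assert bias == pytest.approx(oracle_mean(errs) * 12 / np.pi
                                 if oracle_mean(errs) <= np.pi
                                 else (oracle_mean(errs) - 2 * np.pi) * 12 / np.pi,
                                 abs=1e-9)
    assert sd == pytest.approx(oracle_sd(errs) * 12 / np.pi, abs=1e-9)


def test_r_squared_examples(rng):
    obs = deg(rng.uniform(0, 60, 30))
    assert c.r_squared(obs, obs) == pytest.approx(1.0)
    mu = c.circular_mean(obs)
    assert c.r_squared([mu] * 30, obs) == pytest.approx(0.0, abs=1e-12)
    spread = c.canonical(c.circular_mean(obs) + deg(rng.uniform(-30, 30, 30)))
    antipodal = c.canonical(spread + np.pi)
    assert c.r_squared(antipodal, spread) < 0
    with pytest.raises(UndefinedStatisticError):
        c.r_squared([0.1, 0.2], [0.3, 0.3])


# ------------------------------------------------------------ binned MAE
def test_phase_binned_mae_hand_assignment():
    tab = c.phase_binned_mae(deg([15, 45]), deg([0, 45]), 30)
    b0 = tab[tab["bin"] == 0].iloc[0]
    b1 = tab[tab["bin"] == 1].iloc[0]
    assert b0["n"] == 1 and b0["mae_hours"] == pytest.approx(1.0)
    assert b1["n"] == 1 and b1["mae_hours"] == pytest.approx(0.0)
    assert tab["n"].sum() == 2


def test_phase_binned_mae_perfect_predictions_give_zero_bins():
    obs = deg(np.arange(12) * 30 + 15.0)
    tab = c.phase_binned_mae(obs, obs, 30)
    assert (tab["n"] == 1).all()
    assert np.allclose(tab["mae_hours"], 0.0)


def test_phase_binned_mae_recombines_to_global(rng):
    pred = rng.uniform(0, 2 * np.pi, 500)
    obs = rng.uniform(0, 2 * np.pi, 500)
    tab = c.phase_binned_mae(pred, obs, 30)
    assert tab["n"].sum() == 500
    pooled = np.nansum(tab["n"] * tab["mae_hours"]) / tab["n"].sum()
    assert pooled == pytest.approx(c.mae(pred, obs), abs=1e-12)


def test_phase_binned_mae_rejects_nondivisor_width():
    with pytest.raises(ConfigError):
        c.phase_binned_mae([0.0], [0.0], bin_width_deg=50)


# ---------------------------------------------------------------- property
angles = st.floats(0, 2 * np.pi - 1e-9)
angle_lists = st.lists(angles, min_size=2, max_size=30)


@settings(max_examples=100, deadline=None, derandomize=True)
@given(angle_lists, angle_lists, angles)
def test_mae_symmetry_and_rotation_invariance(a, b, phi):
    n = min(len(a), len(b))
    pred, obs = np.array(a[:n]), np.array(b[:n])
    assert c.mae(pred, obs) == pytest.approx(c.mae(obs, pred), abs=1e-9)
    rotated = c.mae(c.canonical(pred + phi), c.canonical(obs + phi))
    assert rotated == pytest.approx(c.mae(pred, obs), abs=1e-9)


@settings(max_examples=100, deadline=None, derandomize=True)
@given(angle_lists, angle_lists)
def test_bias_changes_sign_on_swap(a, b):
    n = min(len(a), len(b))
    pred, obs = np.array(a[:n]), np.array(b[:n])
    try:
        bias_ab, _ = c.mean_error(pred, obs)
        bias_ba, _ = c.mean_error(obs, pred)
    except UndefinedStatisticError:
        return
    if abs(abs(bias_ab) - 12.0) < 1e-6:
        return  # +12h boundary maps to itself
    assert bias_ab == pytest.approx(-bias_ba, abs=1e-9)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(angle_lists, angle_lists, angles)
def test_r_squared_rotation_invariance(a, b, phi):
    n = min(len(a), len(b))
    pred, obs = np.array(a[:n]), np.array(b[:n])
    try:
        base = c.r_squared(pred, obs)
        rot = c.r_squared(c.canonical(pred + phi), c.canonical(obs + phi))
    except UndefinedStatisticError:
        return
    assert rot == pytest.approx(base, rel=1e-6, abs=1e-8)
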