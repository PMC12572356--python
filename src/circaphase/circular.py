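"""Circular (angular) arithmetic and performance metrics.

Circadian phase is an angle on the 24-hour cycle, referenced to DLMO
(dim-light melatonin onset = phase 0). Internally every angle is a float in
radians, canonicalized to ``[0, 2*pi)``; reporting interfaces convert to
hours (24 h per cycle) or degrees. All metrics treat errors as wrapped
differences on the circle, so a prediction of 23.5 h against an observation
of 0.5 h is a 1-hour error, not a 23-hour one.

The module is the single source of angle arithmetic for the rest of the
package: predictors return radians from :func:`from_cartesian`, and the
experiment layer evaluates them with :func:`mae`, :func:`mean_error`,
:func:`r_squared` and :func:`phase_binned_mae`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import (
    ConfigError,
    DegenerateDirectionError,
    InvalidAngleError,
    ShapeError,
    UndefinedStatisticError,
)

TWO_PI = 2.0 * np.pi
HOURS_PER_CYCLE = 24.0

#: Resultant-length / direction tolerance below which angular quantities are
#: treated as undefined. Far below the scale of any real data.
EPS_RESULTANT = 1e-9

__all__ = [
    "TWO_PI",
    "HOURS_PER_CYCLE",
    "EPS_RESULTANT",
    "canonical",
    "hours_to_radians",
    "radians_to_hours",
    "degrees_to_radians",
    "radians_to_degrees",
    "to_cartesian",
    "from_cartesian",
    "signed_diff",
    "circular_mean",
    "circular_sd",
    "mae",
    "mean_error",
    "r_squared",
    "phase_binned_mae",
    "MetricsRecord",
    "evaluate",
]


def _validate_finite(theta, name: str = "angle"):
    arr = np.asarray(theta, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise InvalidAngleError(f"non-finite {name} value(s) supplied")
    return arr


def canonical(theta):
    """Map any finite angle (radians) into the canonical interval [0, 2*pi)."""
    arr = _validate_finite(theta)
    out = np.mod(arr, TWO_PI)
    # np.mod can return TWO_PI for inputs like -1e-18 due to rounding
    out = np.where(out >= TWO_PI, 0.0, out)
    return out if out.ndim else float(out)


def hours_to_radians(hours):
    """Convert clock hours (24 h = full cycle) to canonical radians."""
    return canonical(np.asarray(hours, dtype=float) * TWO_PI / HOURS_PER_CYCLE)


def radians_to_hours(theta):
    """Convert radians to hours in [0, 24)."""
    out = canonical(theta) * HOURS_PER_CYCLE / TWO_PI
    return out


def degrees_to_radians(deg):
    """Convert degrees to canonical radians."""
    return canonical(np.deg2rad(np.asarray(deg, dtype=float)))


def radians_to_degrees(theta):
    """Convert radians to degrees in [0, 360)."""
    return np.rad2deg(canonical(theta))


def to_cartesian(theta):
    """Return (cos(theta), sin(theta)), the unit-circle embedding of a phase."""
    arr = _validate_finite(theta)
    return np.cos(arr), np.sin(arr)


def from_cartesian(x, y, eps: float = EPS_RESULTANT):
    """Angle of the vector ``(x, y)``, canonicalized to [0, 2*pi).

    The magnitude is ignored, but a vector shorter than ``eps`` carries no
    usable direction and raises :class:`DegenerateDirectionError`.
    """
    x = _validate_finite(x, "x")
    y = _validate_finite(y, "y")
    norm = np.hypot(x, y)
    if np.any(norm < eps):
        raise DegenerateDirectionError(
            f"vector norm below {eps:g}: direction undefined"
        )
    out = canonical(np.arctan2(y, x))
    return out


def signed_diff(a, b):
    """Wrapped difference ``a - b`` in radians, in the interval (-pi, pi].

    Antisymmetric except at the antipodal boundary, where the convention is
    that an exactly 12-hour difference is reported as +pi (never -pi).
    """
    a = _validate_finite(a, "a")
    b = _validate_finite(b, "b")
    d = np.mod(np.asarray(a, dtype=float) - b, TWO_PI)  # [0, 2pi)
    out = np.where(d > np.pi, d - TWO_PI, d)
    return out if out.ndim else float(out)


def _resultant(angles):
    arr = _validate_finite(angles)
    if arr.size == 0:
        raise UndefinedStatisticError("empty angle list")
    c = np.mean(np.cos(arr))
    s = np.mean(np.sin(arr))
    return c, s, float(np.hypot(c, s))


def circular_mean(angles):
    """Directional mean: atan2 of the mean sine and mean cosine.

    Undefined (raises) when the mean resultant length is ~0, e.g. for two
    antipodal angles.
    """
    c, s, r = _resultant(angles)
    if r <= EPS_RESULTANT:
        raise UndefinedStatisticError(
            "circular mean undefined: zero resultant length"
        )
    return float(canonical(np.arctan2(s, c)))


def circular_sd(angles):
    """Circular standard deviation sqrt(-2 ln R) in radians, R the mean
    resultant length. Zero for identical angles, -> infinity as R -> 0."""
    _, _, r = _resultant(angles)
    if r <= EPS_RESULTANT:
        raise UndefinedStatisticError(
            "circular SD undefined: zero resultant length"
        )
    r = min(r, 1.0)  # guard rounding above 1 for identical angles
    return float(np.sqrt(-2.0 * np.log(r)))


def _paired(pred, obs):
    pred = _validate_finite(pred, "pred")
    obs = _validate_finite(obs, "obs")
    pred = np.atleast_1d(pred)
    obs = np.atleast_1d(obs)
    if pred.shape != obs.shape:
        raise ShapeError(
            f"pred and obs lengths differ: {pred.shape} vs {obs.shape}"
        )
    if pred.size == 0:
        raise ShapeError("empty prediction/observation arrays")
    return pred, obs


def mae(pred, obs):
    """Mean absolute circular error between predicted and observed phases,
    in hours. Bounded by [0, 12]; 12 h is the antipodal maximum."""
    pred, obs = _paired(pred, obs)
    err = np.abs(signed_diff(pred, obs))
    return float(np.mean(err) * HOURS_PER_CYCLE / TWO_PI)


def mean_error(pred, obs):
    """Directional mean of the signed errors (the bias) and their circular SD.

    Returns ``(bias_hours, sd_hours)`` with bias in (-12, 12]. The bias is
    the circular mean of the per-sample error angles, so cancelling errors
    of +e and -e give zero bias even though the MAE is e.
    """
    pred, obs = _paired(pred, obs)
    err = signed_diff(pred, obs)
    bias_angle = circular_mean(err)  # raises on zero resultant
    bias = signed_diff(bias_angle, 0.0) * HOURS_PER_CYCLE / TWO_PI
    sd = circular_sd(err) * HOURS_PER_CYCLE / TWO_PI
    return float(bias), float(sd)


def r_squared(pred, obs):
    """Circular coefficient of determination.

    ``1 - sum d(pred_i, obs_i)^2 / sum d(obs_i, mean(obs))^2`` with d the
    wrapped signed difference in radians. At most 1; zero for a constant
    predictor at the observed circular mean; negative when the model is
    worse than that horizontal-line fit.
    """
    pred, obs = _paired(pred, obs)
    if obs.size < 2:
        raise UndefinedStatisticError("r_squared requires n >= 2")
    mu = circular_mean(obs)
    denom = float(np.sum(signed_diff(obs, mu) ** 2))
    if denom <= 0.0:
        raise UndefinedStatisticError(
            "r_squared undefined: all observed phases identical"
        )
    num = float(np.sum(signed_diff(pred, obs) ** 2))
    return 1.0 - num / denom


def phase_binned_mae(pred, obs, bin_width_deg: float = 30.0) -> pd.DataFrame:
    """MAE per phase bin of the observed phase.

    Bins are half-open ``[k*w, (k+1)*w)`` degrees starting at phase 0
    (= DLMO), so they partition the cycle with no double counting.
    ``bin_width_deg`` must divide 360. Returns a DataFrame with columns
    ``bin`` (index), ``bin_start_deg``, ``n``, ``mae_hours`` (NaN and
    ``empty=True`` for unoccupied bins). The sample-weighted mean of the
    per-bin MAEs equals the global MAE.
    """
    n_bins = 360.0 / bin_width_deg
    if abs(n_bins - round(n_bins)) > 1e-9 or bin_width_deg <= 0:
        raise ConfigError(
            f"bin width {bin_width_deg} deg does not divide 360"
        )
    n_bins = int(round(n_bins))
    pred, obs = _paired(pred, obs)
    obs_deg = radians_to_degrees(obs)
    idx = np.floor(obs_deg / bin_width_deg).astype(int)
    idx = np.clip(idx, 0, n_bins - 1)  # guard 360-epsilon rounding
    rows = []
    for b in range(n_bins):
        mask = idx == b
        n = int(mask.sum())
        rows.append(
            {
                "bin": b,
                "bin_start_deg": b * bin_width_deg,
                "n": n,
                "mae_hours": mae(pred[mask], obs[mask]) if n else np.nan,
                "empty": n == 0,
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class MetricsRecord:
    """Evaluation result for one prediction set.

    mae_hours in [0, 12]; bias_hours in (-12, 12]; circ_sd_hours >= 0;
    r_squared <= 1 (may be negative, NaN when undefined); n >= 1.
    """

    mae_hours: float
    bias_hours: float
    circ_sd_hours: float
    r_squared: float
    n: int


def evaluate(pred, obs) -> MetricsRecord:
    """Compute the full metric set for one (pred, obs) pair of phase arrays."""
    pred, obs = _paired(pred, obs)
    m = mae(pred, obs)
    try:
        bias, sd = mean_error(pred, obs)
    except UndefinedStatisticError:
        bias, sd = np.nan, np.nan
    try:
        r2 = r_squared(pred, obs)
    except UndefinedStatisticError:
        r2 = np.nan
    return MetricsRecord(
        mae_hours=m,
        bias_hours=bias,
        circ_sd_hours=sd,
        r_squared=r2,
        n=int(obs.size),
    )
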