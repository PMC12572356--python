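"""ZeitZeiger-style sparse-component phase prediction.

The pipeline estimates, from a training set of (expression, phase) pairs:

1. a periodic smoothing spline per feature — the feature's mean expression
   as a function of circadian phase;
2. a discretized mean matrix M (``n_time`` phases x features), each column
   scaled by its residual-based noise level and centered, so features with
   high signal-to-noise dominate;
3. sparse principal components (SPCs) of M by penalized matrix
   decomposition (PMD): rank-one factors maximizing u'Mv under unit l2
   norms and an l1 budget ``sumabsv`` on the feature loadings v, solved by
   alternating soft-thresholded updates with deflation;
4. a periodic spline per SPC describing the SPC score's time course, with
   a homoscedastic Gaussian residual SD.

Prediction projects a new sample onto the loadings and maximizes the
Gaussian log-likelihood of the SPC scores over a uniform grid of candidate
phases.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline
from sklearn.base import BaseEstimator, RegressorMixin

from .circular import TWO_PI, canonical
from .exceptions import (
    AlignmentError,
    ConfigError,
    ConvergenceError,
    FitError,
    ShapeError,
)

__all__ = [
    "periodic_spline_basis",
    "PeriodicSpline",
    "fit_periodic_spline",
    "fit_periodic_splines_batch",
    "zz_discretize",
    "penalized_matrix_decomposition",
    "ZeitZeigerPhaseRegressor",
    "zz_fit",
    "zz_predict",
]

#: Floor for residual-based scales and SPC standard deviations, preventing
#: division blow-ups on noiseless fixtures.
SCALE_FLOOR = 1e-6

_DEFAULT_LAMBDAS = np.logspace(-8, 3, 16)


def periodic_spline_basis(theta, n_knots: int) -> np.ndarray:
    """Design matrix of a periodic cubic B-spline basis with ``n_knots``
    evenly spaced knots on the cycle. Rows sum to 1; every basis function
    has period 2*pi."""
    if n_knots < 4:
        raise ConfigError("periodic cubic basis needs n_knots >= 4")
    x = canonical(np.atleast_1d(np.asarray(theta, dtype=float)))
    h = TWO_PI / n_knots
    knots = h * np.arange(-3, n_knots + 4)
    dm = BSpline.design_matrix(x, knots, 3).toarray()  # n x (n_knots + 3)
    out = dm[:, :n_knots].copy()
    out[:, :3] += dm[:, n_knots:]  # fold wrapped basis functions
    return out


def _circular_penalty(n_knots: int) -> np.ndarray:
    """D'D for the cyclic second-difference operator on the coefficients."""
    D = np.zeros((n_knots, n_knots))
    for i in range(n_knots):
        D[i, (i - 1) % n_knots] = 1.0
        D[i, i] = -2.0
        D[i, (i + 1) % n_knots] = 1.0
    return D.T @ D


class PeriodicSpline:
    """A fitted periodic cubic spline: callable on any angle (radians)."""

    def __init__(self, coef: np.ndarray, n_knots: int):
        self.coef = np.asarray(coef, dtype=float)
        self.n_knots = int(n_knots)

    def __call__(self, theta):
        b = periodic_spline_basis(theta, self.n_knots)
        out = b @ self.coef
        return out if np.ndim(theta) else float(out[0])


def fit_periodic_splines_batch(
    phases, Y, n_knots: int = 10, lambdas=None
):
    """Fit periodic smoothing splines to many features at once.

    ``Y`` is n_samples x n_features. All features share the basis and the
    roughness-penalty grid; the penalty is chosen per feature by
    generalized cross-validation (GCV), which is cheap here because the
    effective degrees of freedom depend only on the shared design.

    Returns ``(coefs, residuals, chosen_lambdas)`` with ``coefs`` of shape
    n_knots x n_features.
    """
    phases = np.asarray(phases, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n = phases.size
    if Y.shape[0] != n:
        raise ShapeError("phases and values sample counts differ")
    if np.unique(np.round(canonical(phases), 12)).size < n_knots:
        raise FitError(
            f"need at least n_knots={n_knots} distinct phases for a "
            "periodic spline fit"
        )
    if lambdas is None:
        lambdas = _DEFAULT_LAMBDAS
    B = periodic_spline_basis(phases, n_knots)
    P = _circular_penalty(n_knots)
    BtB = B.T @ B
    BtY = B.T @ Y
    ridge = 1e-10 * np.eye(n_knots)  # numerical guard only
    best_gcv = np.full(Y.shape[1], np.inf)
    best_lam = np.zeros(Y.shape[1])
    coefs = np.zeros((n_knots, Y.shape[1]))
    for lam in lambdas:
        A = BtB + lam * P + ridge
        C = np.linalg.solve(A, BtY)
        df = float(np.trace(np.linalg.solve(A, BtB)))
        if df >= n:
            continue
        rss = ((Y - B @ C) ** 2).sum(axis=0)
        gcv = n * rss / (n - df) ** 2
        better = gcv < best_gcv
        best_gcv[better] = gcv[better]
        best_lam[better] = lam
        coefs[:, better] = C[:, better]
    residuals = Y - B @ coefs
    return coefs, residuals, best_lam


def fit_periodic_spline(phases, values, n_knots: int = 10, lambdas=None):
    """Fit one periodic smoothing spline; returns (PeriodicSpline, residuals)."""
    coefs, resid, _ = fit_periodic_splines_batch(
        phases, np.asarray(values, dtype=float), n_knots, lambdas
    )
    return PeriodicSpline(coefs[:, 0], n_knots), resid[:, 0]


def zz_discretize(coefs: np.ndarray, residuals: np.ndarray, n_time: int = 10):
    """Discretized, scaled, centered mean matrix from per-feature splines.

    Row t holds the fitted means at phase ``2*pi*t/n_time``. Each column is
    divided by its residual scale sqrt(mean squared spline residual),
    floored at ``SCALE_FLOOR``, then centered — so the decomposition sees
    signal-to-noise-weighted, zero-mean time courses.

    Returns ``(M, scales, centers)``.
    """
    n_knots = coefs.shape[0]
    times = TWO_PI * np.arange(n_time) / n_time
    raw = periodic_spline_basis(times, n_knots) @ coefs  # n_time x F
    scales = np.sqrt((residuals**2).mean(axis=0))
    scales = np.maximum(scales, SCALE_FLOOR)
    M = raw / scales
    centers = M.mean(axis=0)
    return M - centers, scales, centers


def _soft(a: np.ndarray, d: float) -> np.ndarray:
    return np.sign(a) * np.maximum(np.abs(a) - d, 0.0)


def _l1_unit(a: np.ndarray, c: float) -> np.ndarray:
    """l2-unit vector proportional to a soft-thresholding of ``a`` with the
    smallest threshold making its l1 norm <= c (Witten-style update)."""
    na = np.linalg.norm(a)
    if na == 0.0:
        raise FitError("zero gradient in PMD update")
    v = a / na
    if np.abs(v).sum() <= c:
        return v
    lo, hi = 0.0, float(np.abs(a).max())
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        sv = _soft(a, mid)
        n2 = np.linalg.norm(sv)
        if n2 == 0.0 or np.abs(sv).sum() / n2 > c:
            lo = mid
        else:
            hi = mid
    sv = _soft(a, hi)
    # entries the threshold shaved to rounding-level residue are exact zeros
    sv[np.abs(sv) < 1e-12 * np.abs(sv).max(initial=0.0)] = 0.0
    n2 = np.linalg.norm(sv)
    if n2 == 0.0:
        # tie at the maximum: fall back to the (first) best single column
        j = int(np.argmax(np.abs(a)))
        sv = np.zeros_like(a)
        sv[j] = np.sign(a[j])
        return sv
    return sv / n2


def penalized_matrix_decomposition(
    M: np.ndarray,
    sumabsv: float,
    n_spc: int,
    tol: float = 1e-8,
    max_iter: int = 1000,
):
    """Rank-``n_spc`` PMD of a column-centered matrix.

    Each factor maximizes ``u' M v`` subject to ``||u||_2 <= 1``,
    ``||v||_2 <= 1`` and ``||v||_1 <= sumabsv``, by alternating updates
    (v soft-thresholded) from a leading-singular-vector start, then
    deflating ``M <- M - d u v'``. With ``sumabsv >= sqrt(n_features)``
    the l1 constraint is inactive and the v's are the leading right
    singular vectors.

    Returns ``(V, d, U)`` with V of shape features x n_spc.
    """
    M = np.asarray(M, dtype=float)
    if sumabsv < 1.0:
        raise ConfigError("sumabsv must be >= 1")
    if n_spc < 1:
        raise ConfigError("n_spc must be >= 1")
    n_time, p = M.shape
    V = np.zeros((p, n_spc))
    U = np.zeros((n_time, n_spc))
    d = np.zeros(n_spc)
    Mk = M.copy()
    for k in range(n_spc):
        _, svals, vt = np.linalg.svd(Mk, full_matrices=False)
        v = vt[0]
        if svals[0] <= 1e-14:
            break  # remaining matrix is (numerically) zero
        d_prev = np.inf
        for _ in range(max_iter):
            mv = Mk @ v
            nu = np.linalg.norm(mv)
            if nu == 0.0:
                break
            u = mv / nu
            v_new = _l1_unit(Mk.T @ u, sumabsv)
            delta = float(np.max(np.abs(v_new - v)))
            v = v_new
            d_cur = float(u @ (Mk @ v))
            # accept either stabilized loadings or a stationary objective
            # (near-degenerate supports can make v drift geometrically
            # while the maximized value has long converged)
            if delta < tol or abs(d_cur - d_prev) <= 1e-11 * max(1.0, abs(d_cur)):
                break
            d_prev = d_cur
        else:
            raise ConvergenceError(
                f"PMD factor {k + 1} did not converge in {max_iter} "
                "iterations",
                n_iter=max_iter,
            )
        # deterministic sign: largest-|.| loading positive
        j = int(np.argmax(np.abs(v)))
        if v[j] < 0:
            v = -v
            u = -u
        dk = float(u @ Mk @ v)
        Mk = Mk - dk * np.outer(u, v)
        V[:, k] = v
        U[:, k] = u
        d[k] = dk
    return V, d, U


class ZeitZeigerPhaseRegressor(RegressorMixin, BaseEstimator):
    """Sparse-principal-component circadian phase predictor.

    Parameters
    ----------
    sumabsv : float, default 4
        l1 budget on each SPC's feature loadings; smaller = sparser.
    n_spc : int, default 3
        Number of sparse components (must be <= n_time - 1).
    n_time : int, default 10
        Number of grid phases used to discretize the fitted time courses.
    n_knots : int, default 10
        Periodic spline basis size for both feature and SPC time courses.
    predict_grid : int, default 360
        Candidate phases in the maximum-likelihood search; the grid step
        (1 degree at 360) bounds the quantization error.
    """

    method = "zeitzeiger"

    def __init__(
        self,
        sumabsv: float = 4.0,
        n_spc: int = 3,
        n_time: int = 10,
        n_knots: int = 10,
        predict_grid: int = 360,
    ):
        self.sumabsv = sumabsv
        self.n_spc = n_spc
        self.n_time = n_time
        self.n_knots = n_knots
        self.predict_grid = predict_grid

    def _validate(self):
        if self.n_spc > self.n_time - 1:
            raise ConfigError("n_spc must be <= n_time - 1")
        if self.sumabsv < 1.0:
            raise ConfigError("sumabsv must be >= 1")
        if self.predict_grid < 2:
            raise ConfigError("predict_grid must be >= 2")

    def fit(self, X, y):
        self._validate()
        if isinstance(X, pd.DataFrame):
            values = X.to_numpy(dtype=float)
            names = [str(c) for c in X.columns]
        else:
            values = np.asarray(X, dtype=float)
            names = [f"f{i:06d}" for i in range(values.shape[1])]
        phases = np.asarray(y, dtype=float)
        coefs, resid, _ = fit_periodic_splines_batch(
            phases, values, self.n_knots
        )
        M, scales, centers = zz_discretize(coefs, resid, self.n_time)
        V, d, _ = penalized_matrix_decomposition(M, self.sumabsv, self.n_spc)
        self.feature_names_ = names
        self.n_features_in_ = values.shape[1]
        self.loadings_ = V
        self.singular_values_ = d
        self.scales_ = scales
        self.centers_ = centers
        scores = (values / scales - centers) @ V
        spc_coefs, spc_resid, _ = fit_periodic_splines_batch(
            phases, scores, self.n_knots
        )
        self.spc_coefs_ = spc_coefs
        self.spc_sd_ = np.maximum(
            np.sqrt((spc_resid**2).mean(axis=0)), SCALE_FLOOR
        )
        return self

    def _scores(self, X) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            cols = set(X.columns.astype(str))
            missing = [f for f in self.feature_names_ if f not in cols]
            if missing:
                raise AlignmentError(
                    f"input is missing {len(missing)} model feature(s): "
                    f"{missing[:5]}"
                )
            values = X.loc[:, self.feature_names_].to_numpy(dtype=float)
        else:
            values = np.atleast_2d(np.asarray(X, dtype=float))
            if values.shape[1] != self.n_features_in_:
                raise AlignmentError(
                    f"expected {self.n_features_in_} features, "
                    f"got {values.shape[1]}"
                )
        return (values / self.scales_ - self.centers_) @ self.loadings_

    def spc_curves(self, phi) -> np.ndarray:
        """SPC mean time courses evaluated at phases ``phi`` (radians)."""
        return periodic_spline_basis(phi, self.n_knots) @ self.spc_coefs_

    def log_likelihood(self, X, phi) -> np.ndarray:
        """Gaussian log-likelihood of each sample's SPC scores at each
        candidate phase (n_samples x n_phases), up to a constant."""
        scores = self._scores(X)
        curves = self.spc_curves(np.asarray(phi, dtype=float))
        ll = np.zeros((scores.shape[0], curves.shape[0]))
        for k in range(self.loadings_.shape[1]):
            resid = scores[:, k][:, None] - curves[:, k][None, :]
            ll -= 0.5 * (resid / self.spc_sd_[k]) ** 2
        return ll

    def predict(self, X) -> np.ndarray:
        phi = TWO_PI * np.arange(self.predict_grid) / self.predict_grid
        ll = self.log_likelihood(X, phi)
        flat = np.ptp(ll, axis=1) < 1e-12
        if np.any(flat):
            warnings.warn(
                f"{int(flat.sum())} sample(s) have a flat likelihood; "
                "returning the smallest candidate phase",
                stacklevel=2,
            )
        # argmax returns the first (= smallest phase) among ties
        return phi[np.argmax(ll, axis=1)]

    def feature_weights(self) -> dict:
        """Per-feature weight sqrt(sum_k loading_k^2); zero loadings absent."""
        w = np.sqrt((self.loadings_**2).sum(axis=1))
        return {
            f: float(wi)
            for f, wi in zip(self.feature_names_, w)
            if wi > 0.0
        }

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        nz = np.flatnonzero((self.loadings_ != 0).any(axis=1))
        return {
            "method": self.method,
            "config": self.get_params(),
            "feature_ids": list(self.feature_names_),
            "loadings": {
                "index": [int(i) for i in nz],
                "values": self.loadings_[nz].tolist(),
            },
            "singular_values": self.singular_values_.tolist(),
            "scales": self.scales_.tolist(),
            "centers": self.centers_.tolist(),
            "spc_coefs": self.spc_coefs_.tolist(),
            "spc_sd": self.spc_sd_.tolist(),
            "normalization_ref": getattr(self, "normalization_ref_", None),
        }

    def _restore(self, d: dict):
        self.feature_names_ = list(d["feature_ids"])
        self.n_features_in_ = len(self.feature_names_)
        n_spc = self.n_spc
        V = np.zeros((self.n_features_in_, n_spc))
        idx = d["loadings"]["index"]
        if idx:
            V[np.asarray(idx, dtype=int)] = np.asarray(
                d["loadings"]["values"], dtype=float
            )
        self.loadings_ = V
        self.singular_values_ = np.asarray(d["singular_values"], dtype=float)
        self.scales_ = np.asarray(d["scales"], dtype=float)
        self.centers_ = np.asarray(d["centers"], dtype=float)
        self.spc_coefs_ = np.asarray(d["spc_coefs"], dtype=float)
        self.spc_sd_ = np.asarray(d["spc_sd"], dtype=float)
        self.normalization_ref_ = d.get("normalization_ref")
        return self


def zz_fit(X, phases, **params) -> ZeitZeigerPhaseRegressor:
    return ZeitZeigerPhaseRegressor(**params).fit(X, phases)


def zz_predict(model: ZeitZeigerPhaseRegressor, x) -> np.ndarray:
    arr = x
    if isinstance(x, pd.Series):
        arr = x.to_frame().T
    elif not isinstance(x, pd.DataFrame):
        arr = np.atleast_2d(np.asarray(x, dtype=float))
    return model.predict(arr)
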