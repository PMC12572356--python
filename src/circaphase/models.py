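"""Phase predictors that regress the Cartesian encoding of circadian phase.

A circadian phase theta cannot be regressed directly (it wraps), so each
training phase is decomposed into its cosine and sine components and two
linear models are fitted, one per component. A prediction is the angle of
the predicted vector ``(c_hat, s_hat)`` — its magnitude is discarded.

Three predictors share this encoding:

* :class:`PlsrPhaseRegressor` — two-stage partial least squares (SIMPLS):
  a PLS fit on all features ranks them by the sum of absolute projection
  weights across the latent factors, the top ``n_predictors`` are kept, and
  the model is refitted on that submatrix.
* :class:`ElasticNetPhaseRegressor` — independent elastic-net fits per
  component with a shared mixing parameter and penalty strength; features
  with a nonzero coefficient in either component are the selected set.
* :class:`FixedPanelPhaseRegressor` — PLSR restricted to a predefined
  feature panel (e.g. probes of classic clock genes); no selection stage.

Inputs are expected to be preprocessed (quantile-normalized, z-scored);
the elastic net deliberately does not re-standardize.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.linear_model import ElasticNet, enet_path
from sklearn.model_selection import KFold

from . import circular
from .exceptions import AlignmentError, ConfigError, FitError, ShapeError

__all__ = [
    "simpls",
    "PlsrPhaseRegressor",
    "ElasticNetPhaseRegressor",
    "FixedPanelPhaseRegressor",
    "phase_to_targets",
    "plsr_core_fit",
    "plsr_select",
    "plsr_fit",
    "en_fit",
    "en_cv_lambda",
    "fixed_panel_fit",
    "cartesian_predict",
    "model_from_dict",
]

#: Reference glmnet penalty strength used by the study this package rebuilds.
DEFAULT_EN_LAMBDA = 0.03280596


def phase_to_targets(theta) -> np.ndarray:
    """Stack (cos theta, sin theta) as an n x 2 target matrix."""
    c, s = circular.to_cartesian(np.atleast_1d(theta))
    return np.column_stack([c, s])


def simpls(X, Y, n_components, rank_tol: float = 1e-12):
    """SIMPLS partial least squares (de Jong 1993) for multi-response Y.

    Latent scores are linear combinations of the centered predictors that
    maximize covariance with the (centered) responses; successive loadings
    are deflated to keep scores orthogonal. With ``n_components`` equal to
    the design rank the regression coefficients reproduce ordinary least
    squares.

    Returns a dict with ``weights`` (p x a projection weights R, applied to
    centered X), ``coef`` (p x m), ``intercept`` (m,), ``n_components``
    (the achieved number), plus the centering vectors.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.ndim != 2 or Y.ndim != 2 or X.shape[0] != Y.shape[0]:
        raise ShapeError("X and Y must be 2D with matching sample counts")
    n, p = X.shape
    m = Y.shape[1]
    if n < 2:
        raise FitError("SIMPLS requires at least 2 samples")
    if n_components <= 0:
        raise ConfigError("n_components must be positive")
    x_mean = X.mean(axis=0)
    y_mean = Y.mean(axis=0)
    X0 = X - x_mean
    Y0 = Y - y_mean
    if not np.any(X0):
        raise FitError("design matrix has rank 0 after centering")
    a_max = min(n - 1, p, n_components)
    if a_max < n_components:
        warnings.warn(
            f"n_components capped from {n_components} to {a_max} "
            "(achievable rank bound)",
            stacklevel=2,
        )
    S = X0.T @ Y0
    R = np.zeros((p, a_max))
    Q = np.zeros((m, a_max))
    V = np.zeros((p, a_max))
    scale0 = max(np.linalg.norm(S), 1.0)
    achieved = 0
    for a in range(a_max):
        # dominant right singular direction of S via the small m x m problem
        StS = S.T @ S
        evals, evecs = np.linalg.eigh(StS)
        q = evecs[:, -1]
        r = S @ q
        t = X0 @ r
        t = t - t.mean()
        normt = np.linalg.norm(t)
        if normt < rank_tol * scale0 or np.linalg.norm(S) < rank_tol * scale0:
            warnings.warn(
                f"n_components capped from {a_max} to {a} (design rank)",
                stacklevel=2,
            )
            break
        t /= normt
        r = r / normt
        p_load = X0.T @ t
        q_load = Y0.T @ t
        v = p_load.copy()
        if a > 0:
            v -= V[:, :a] @ (V[:, :a].T @ p_load)
        nv = np.linalg.norm(v)
        if nv < rank_tol * scale0:
            break
        v /= nv
        S = S - np.outer(v, v @ S)
        R[:, a] = r
        Q[:, a] = q_load
        V[:, a] = v
        achieved = a + 1
    if achieved == 0:
        raise FitError("SIMPLS could not extract any latent factor")
    R = R[:, :achieved]
    Q = Q[:, :achieved]
    coef = R @ Q.T
    intercept = y_mean - x_mean @ coef
    return {
        "weights": R,
        "coef": coef,
        "intercept": intercept,
        "n_components": achieved,
        "x_mean": x_mean,
        "y_mean": y_mean,
    }


def _feature_names(X) -> np.ndarray:
    if isinstance(X, pd.DataFrame):
        return np.asarray(X.columns.astype(str))
    p = np.asarray(X).shape[1]
    return np.array([f"f{i:06d}" for i in range(p)])


def _values(X) -> np.ndarray:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float)
    arr = np.asarray(X, dtype=float)
    if arr.ndim != 2:
        raise ShapeError(f"expected 2D input, got shape {arr.shape}")
    return arr


class CartesianPhaseRegressor(RegressorMixin, BaseEstimator):
    """Shared prediction/serialization for linear Cartesian phase models.

    Fitted subclasses expose ``selected_features_``, ``coef_cos_``,
    ``coef_sin_``, ``intercept_cos_``, ``intercept_sin_``.
    """

    method: str = "cartesian"

    def _align(self, X) -> np.ndarray:
        """Extract the selected-feature columns of X, by id for DataFrames,
        by training column position for plain arrays."""
        if isinstance(X, pd.DataFrame):
            cols = X.columns.astype(str)
            missing = [f for f in self.selected_features_ if f not in set(cols)]
            if missing:
                raise AlignmentError(
                    f"input is missing {len(missing)} model feature(s): "
                    f"{missing[:5]}"
                )
            return X.loc[:, list(self.selected_features_)].to_numpy(dtype=float)
        arr = _values(X)
        if arr.shape[1] == len(self.selected_features_):
            return arr
        if arr.shape[1] != self.n_features_in_:
            raise AlignmentError(
                f"array input must have {self.n_features_in_} (training) or "
                f"{len(self.selected_features_)} (selected) columns, "
                f"got {arr.shape[1]}"
            )
        return arr[:, self.selected_idx_]

    def decision_function(self, X) -> np.ndarray:
        """Predicted Cartesian coordinates (c_hat, s_hat), n x 2."""
        sub = self._align(X)
        c = self.intercept_cos_ + sub @ self.coef_cos_
        s = self.intercept_sin_ + sub @ self.coef_sin_
        return np.column_stack([c, s])

    def predict(self, X) -> np.ndarray:
        """Predicted circadian phase in canonical radians [0, 2*pi)."""
        cs = self.decision_function(X)
        return np.atleast_1d(circular.from_cartesian(cs[:, 0], cs[:, 1]))

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "config": self.get_params(),
            "selected_features": list(map(str, self.selected_features_)),
            "coef_cos": [float(v) for v in self.coef_cos_],
            "coef_sin": [float(v) for v in self.coef_sin_],
            "intercept_cos": float(self.intercept_cos_),
            "intercept_sin": float(self.intercept_sin_),
            "normalization_ref": getattr(self, "normalization_ref_", None),
        }

    def _restore(self, d: dict):
        self.selected_features_ = list(d["selected_features"])
        self.coef_cos_ = np.asarray(d["coef_cos"], dtype=float)
        self.coef_sin_ = np.asarray(d["coef_sin"], dtype=float)
        self.intercept_cos_ = float(d["intercept_cos"])
        self.intercept_sin_ = float(d["intercept_sin"])
        self.normalization_ref_ = d.get("normalization_ref")
        self.n_features_in_ = len(self.selected_features_)
        self.selected_idx_ = np.arange(self.n_features_in_)
        return self

    def feature_weights(self) -> dict:
        """Per-feature weight sqrt(c_cos^2 + c_sin^2), selected features only."""
        w = np.hypot(self.coef_cos_, self.coef_sin_)
        return {
            f: float(wi)
            for f, wi in zip(self.selected_features_, w)
            if wi > 0.0
        }


def _select_top(names: np.ndarray, scores: np.ndarray, k: int) -> np.ndarray:
    """Indices of the k largest scores; ties broken by lexicographically
    smaller feature id."""
    if k > scores.size:
        raise ConfigError(
            f"cannot select {k} predictors from {scores.size} features"
        )
    order = np.lexsort((names, -scores))
    return np.sort(order[:k])  # original column order for stable alignment


class PlsrPhaseRegressor(CartesianPhaseRegressor):
    """Two-stage PLSR phase predictor.

    Stage 1 fits SIMPLS on all features and ranks them by the sum of
    absolute projection weights across the ``n_latent`` latent factors;
    stage 2 refits SIMPLS on the top ``n_predictors`` features (set
    ``refit=False`` to instead slice the full-fit coefficients — kept for
    sensitivity analysis).

    Parameters
    ----------
    n_latent : int, default 5
        Number of latent factors (capped at the achievable rank, with a
        warning, on small designs).
    n_predictors : int, default 100
        Number of features retained after ranking.
    refit : bool, default True
        Refit on the selected submatrix (canonical) or reuse the full fit.
    """

    method = "plsr"

    def __init__(self, n_latent: int = 5, n_predictors: int = 100,
                 refit: bool = True):
        self.n_latent = n_latent
        self.n_predictors = n_predictors
        self.refit = refit

    def fit(self, X, y):
        if self.n_latent <= 0 or self.n_predictors <= 0:
            raise ConfigError("n_latent and n_predictors must be positive")
        values = _values(X)
        names = _feature_names(X)
        theta = np.asarray(y, dtype=float)
        if theta.shape[0] != values.shape[0]:
            raise ShapeError("X and y sample counts differ")
        targets = phase_to_targets(theta)
        full = simpls(values, targets, self.n_latent)
        self.weights_ = full["weights"]
        scores = np.abs(self.weights_).sum(axis=1)
        idx = _select_top(names, scores, min(self.n_predictors, names.size))
        self.n_features_in_ = values.shape[1]
        self.selected_idx_ = idx
        self.selected_features_ = [str(n) for n in names[idx]]
        if self.refit:
            sub = simpls(values[:, idx], targets, self.n_latent)
            coef, intercept = sub["coef"], sub["intercept"]
        else:
            coef = full["coef"][idx]
            intercept = full["y_mean"] - full["x_mean"][idx] @ coef
        self.coef_cos_ = coef[:, 0]
        self.coef_sin_ = coef[:, 1]
        self.intercept_cos_ = float(intercept[0])
        self.intercept_sin_ = float(intercept[1])
        return self


def _lambda_path(X, targets, l1_ratio, n_lambdas, lambda_min_ratio):
    n = X.shape[0]
    Xc = X - X.mean(axis=0)
    yc = targets - targets.mean(axis=0)
    l1 = max(l1_ratio, 1e-3)  # pure-ridge limit has no finite lambda_max
    lam_max = np.max(np.abs(Xc.T @ yc)) / (n * l1)
    lam_max = max(lam_max, 1e-12)
    return np.logspace(
        np.log10(lam_max), np.log10(lam_max * lambda_min_ratio), n_lambdas
    )


def en_cv_lambda(
    X,
    phases,
    alpha: float = 0.5,
    k_folds: int = 10,
    n_lambdas: int = 100,
    lambda_min_ratio: float = 1e-4,
    random_state=None,
):
    """Penalty strength minimizing mean cross-validated squared error.

    The error is summed over the cosine and sine components. The path is
    log-spaced from the smallest all-zero-slope lambda down
    ``lambda_min_ratio`` (4 decades by default); among ties the largest
    lambda (strongest penalty) wins. Fold assignment is seeded.
    """
    values = _values(X)
    targets = phase_to_targets(np.asarray(phases, dtype=float))
    n = values.shape[0]
    if k_folds < 2 or k_folds > n:
        raise ConfigError(f"k_folds={k_folds} invalid for n={n}")
    path = _lambda_path(values, targets, alpha, n_lambdas, lambda_min_ratio)
    kf = KFold(n_splits=k_folds, shuffle=True, random_state=random_state)
    cv_err = np.zeros(path.size)
    for train, test in kf.split(values):
        Xtr = values[train]
        xm = Xtr.mean(axis=0)
        Xtr = Xtr - xm
        Xte = values[test] - xm
        for comp in range(2):
            ytr = targets[train, comp]
            ym = ytr.mean()
            with warnings.catch_warnings():
                # near-unpenalized path tail converges slowly; harmless here
                warnings.simplefilter("ignore")
                _, coefs, _ = enet_path(
                    Xtr, ytr - ym, l1_ratio=max(alpha, 1e-3), alphas=path
                )
            pred = Xte @ coefs + ym  # n_test x n_lambdas
            cv_err += ((targets[test, comp][:, None] - pred) ** 2).sum(axis=0)
    cv_err /= n
    return float(path[int(np.argmin(cv_err))])


class ElasticNetPhaseRegressor(CartesianPhaseRegressor):
    """Elastic-net phase predictor in Cartesian coordinates.

    Two independent penalized least-squares fits, one for the cosine and
    one for the sine component, share the mixing parameter ``alpha``
    (1 = pure lasso, 0 = pure ridge) and penalty strength ``lam`` — the
    same parameterization as glmnet, so published glmnet lambdas transfer
    directly. Intercepts are never penalized. Features nonzero in either
    component form the selected set.

    ``lambda_mode='cv'`` replaces the fixed ``lam`` with the k-fold
    cross-validated optimum along a regularization path.
    """

    method = "elasticnet"

    def __init__(
        self,
        alpha: float = 0.5,
        lam: float = DEFAULT_EN_LAMBDA,
        lambda_mode: str = "fixed",
        cv_folds: int = 10,
        n_lambdas: int = 100,
        lambda_min_ratio: float = 1e-4,
        max_iter: int = 20000,
        random_state=None,
    ):
        self.alpha = alpha
        self.lam = lam
        self.lambda_mode = lambda_mode
        self.cv_folds = cv_folds
        self.n_lambdas = n_lambdas
        self.lambda_min_ratio = lambda_min_ratio
        self.max_iter = max_iter
        self.random_state = random_state

    def fit(self, X, y):
        if not 0.0 <= self.alpha <= 1.0:
            raise ConfigError("alpha (mixing) must be in [0, 1]")
        if self.lambda_mode not in ("fixed", "cv"):
            raise ConfigError("lambda_mode must be 'fixed' or 'cv'")
        if self.lambda_mode == "fixed" and not self.lam > 0:
            raise ConfigError("lam must be positive")
        values = _values(X)
        names = _feature_names(X)
        theta = np.asarray(y, dtype=float)
        targets = phase_to_targets(theta)
        if self.lambda_mode == "cv":
            lam = en_cv_lambda(
                values,
                theta,
                alpha=self.alpha,
                k_folds=self.cv_folds,
                n_lambdas=self.n_lambdas,
                lambda_min_ratio=self.lambda_min_ratio,
                random_state=self.random_state,
            )
        else:
            lam = self.lam
        self.lambda_ = float(lam)
        coefs = []
        intercepts = []
        for comp in range(2):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # l1_ratio=0 advisory
                est = ElasticNet(
                    alpha=lam,
                    l1_ratio=self.alpha,
                    fit_intercept=True,
                    max_iter=self.max_iter,
                )
                est.fit(values, targets[:, comp])
            coefs.append(est.coef_)
            intercepts.append(float(est.intercept_))
        coef_cos, coef_sin = coefs
        nz = (coef_cos != 0.0) | (coef_sin != 0.0)
        self.n_features_in_ = values.shape[1]
        self.selected_idx_ = np.flatnonzero(nz)
        self.selected_features_ = [str(n) for n in names[nz]]
        self.coef_cos_ = coef_cos[nz]
        self.coef_sin_ = coef_sin[nz]
        self.intercept_cos_, self.intercept_sin_ = intercepts
        return self


class FixedPanelPhaseRegressor(CartesianPhaseRegressor):
    """PLSR restricted to a predefined feature panel (e.g. clock genes).

    The selected features are always the panel, in panel order; only the
    coefficients vary with the training set. Input must carry feature ids
    (a DataFrame) so panel members can be resolved.
    """

    method = "fixed_panel"

    def __init__(self, panel=(), n_latent: int = 5):
        self.panel = panel
        self.n_latent = n_latent

    def fit(self, X, y):
        panel = [str(p) for p in self.panel]
        if len(panel) == 0:
            raise ConfigError("panel must be non-empty")
        if not isinstance(X, pd.DataFrame):
            raise AlignmentError(
                "fixed-panel fitting requires a DataFrame with feature ids"
            )
        missing = [p for p in panel if p not in set(X.columns.astype(str))]
        if missing:
            raise AlignmentError(
                f"panel feature(s) absent from training matrix: {missing}"
            )
        sub = X.loc[:, panel].to_numpy(dtype=float)
        targets = phase_to_targets(np.asarray(y, dtype=float))
        res = simpls(sub, targets, self.n_latent)
        self.n_features_in_ = X.shape[1]
        all_names = np.asarray(X.columns.astype(str))
        name_pos = {n: i for i, n in enumerate(all_names)}
        self.selected_idx_ = np.array([name_pos[p] for p in panel])
        self.selected_features_ = panel
        self.coef_cos_ = res["coef"][:, 0]
        self.coef_sin_ = res["coef"][:, 1]
        self.intercept_cos_ = float(res["intercept"][0])
        self.intercept_sin_ = float(res["intercept"][1])
        return self


# ---------------------------------------------------------------------------
# functional wrappers

def plsr_core_fit(X, phases, n_latent: int = 5):
    """SIMPLS on the Cartesian targets; returns the raw fit dict."""
    return simpls(_values(X), phase_to_targets(np.asarray(phases, float)),
                  n_latent)


def plsr_select(weights, feature_ids, n_predictors: int):
    """Top features by sum of absolute weights across latent factors."""
    names = np.asarray([str(f) for f in feature_ids])
    scores = np.abs(np.asarray(weights, dtype=float)).sum(axis=1)
    idx = _select_top(names, scores, n_predictors)
    return [str(n) for n in names[idx]]


def plsr_fit(X, phases, n_latent: int = 5, n_predictors: int = 100,
             refit: bool = True) -> PlsrPhaseRegressor:
    return PlsrPhaseRegressor(
        n_latent=n_latent, n_predictors=n_predictors, refit=refit
    ).fit(X, phases)


def en_fit(X, phases, alpha: float = 0.5, lam: float = DEFAULT_EN_LAMBDA,
           **kwargs) -> ElasticNetPhaseRegressor:
    return ElasticNetPhaseRegressor(alpha=alpha, lam=lam, **kwargs).fit(
        X, phases
    )


def fixed_panel_fit(X, phases, panel, n_latent: int = 5
                    ) -> FixedPanelPhaseRegressor:
    return FixedPanelPhaseRegressor(panel=panel, n_latent=n_latent).fit(
        X, phases
    )


def cartesian_predict(model: CartesianPhaseRegressor, x) -> np.ndarray:
    """Predict phase (radians) for one feature vector or a matrix."""
    arr = x
    if isinstance(x, pd.Series):
        arr = x.to_frame().T
    elif not isinstance(x, pd.DataFrame):
        arr = np.atleast_2d(np.asarray(x, dtype=float))
    return model.predict(arr)


def model_from_dict(d: dict):
    """Rebuild a fitted Cartesian model from its serialized form."""
    classes = {
        "plsr": PlsrPhaseRegressor,
        "elasticnet": ElasticNetPhaseRegressor,
        "fixed_panel": FixedPanelPhaseRegressor,
    }
    try:
        cls = classes[d["method"]]
    except KeyError as exc:
        raise ConfigError(f"unknown model method {d.get('method')!r}") from exc
    est = cls(**d.get("config", {}))
    est._restore(d)
    return est
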