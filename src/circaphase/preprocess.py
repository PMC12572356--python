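"""Training-locked expression preprocessing.

Microarray (or any log2-abundance) data are normalized in three fixed
stages: quantile normalization, technical-replicate collapsing, and
per-feature z-scoring. The defining constraint is that validation data are
always transformed with references *recorded from the training set* — the
reference array of empirical quantiles, and the per-feature means and
standard deviations — so no information leaks from validation samples into
the transform applied to them, and each validation sample is transformed
independently of the others.

The transformers follow the scikit-learn convention: ``X`` is samples x
features, ``fit`` learns the training references, ``transform`` applies
them. :func:`make_preprocessing_pipeline` chains them in the fixed order.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.pipeline import Pipeline

from .exceptions import AlignmentError, FitError, ShapeError

__all__ = [
    "QuantileNormalizer",
    "FeatureZScorer",
    "collapse_replicates",
    "make_preprocessing_pipeline",
    "quantile_normalize_fit",
    "quantile_normalize_apply",
    "zscore_fit",
    "zscore_apply",
]


def _as_2d(X):
    """Return (values, feature_names or None, index or None)."""
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), X.columns, X.index
    arr = np.asarray(X, dtype=float)
    if arr.ndim != 2:
        raise ShapeError(f"expected 2D input, got shape {arr.shape}")
    return arr, None, None


def _check_finite(values):
    if not np.all(np.isfinite(values)):
        raise ShapeError(
            "non-finite expression values; missing data are not supported"
        )


def _map_to_reference(row: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Replace a sample's values by the reference quantiles at their ranks.

    Tied values receive the mean of the reference quantiles at the tied rank
    positions (the tie rule of standard quantile-normalization routines).
    """
    order = np.argsort(row, kind="stable")
    sorted_vals = row[order]
    out_sorted = ref.astype(float).copy()
    # group ties: boundaries where the sorted value changes
    change = np.flatnonzero(np.diff(sorted_vals) != 0) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [row.size]])
    for s, e in zip(starts, ends):
        if e - s > 1:
            out_sorted[s:e] = ref[s:e].mean()
    out = np.empty_like(out_sorted)
    out[order] = out_sorted
    return out


class QuantileNormalizer(TransformerMixin, BaseEstimator):
    """Quantile normalization against a training-derived reference.

    ``fit`` records ``ref_quantiles_``: the mean, over training samples, of
    each sample's r-th order statistic. ``transform`` replaces every
    sample's values by the reference quantiles at that sample's within-
    sample ranks, so each output sample has exactly the reference empirical
    distribution. Applying the fitted transformer to the training matrix
    reproduces the fit-time output.
    """

    def fit(self, X, y=None):
        values, features, _ = _as_2d(X)
        _check_finite(values)
        if values.shape[0] < 2:
            raise FitError(
                "quantile normalization requires at least 2 samples"
            )
        self.n_features_in_ = values.shape[1]
        if features is not None:
            self.feature_names_in_ = np.asarray(features)
        self.ref_quantiles_ = np.sort(values, axis=1).mean(axis=0)
        return self

    def transform(self, X):
        values, features, index = _as_2d(X)
        _check_finite(values)
        if values.shape[1] != self.ref_quantiles_.size:
            raise ShapeError(
                f"reference has {self.ref_quantiles_.size} quantiles but "
                f"input has {values.shape[1]} features"
            )
        out = np.vstack(
            [_map_to_reference(row, self.ref_quantiles_) for row in values]
        )
        if features is not None:
            return pd.DataFrame(out, index=index, columns=features)
        return out


class FeatureZScorer(TransformerMixin, BaseEstimator):
    """Per-feature z-scoring with training-set mean and SD.

    SD uses the n-1 (sample) denominator. Features with zero training SD
    carry no information at fit time; their z-scores are set to 0 and the
    feature is flagged in ``uninformative_`` rather than dropped, keeping
    feature indices aligned between training and validation matrices.
    """

    def fit(self, X, y=None):
        values, features, _ = _as_2d(X)
        _check_finite(values)
        if values.shape[0] < 2:
            raise FitError("z-scoring requires at least 2 samples")
        self.n_features_in_ = values.shape[1]
        if features is not None:
            self.feature_names_in_ = np.asarray(features)
        self.feature_means_ = values.mean(axis=0)
        self.feature_sds_ = values.std(axis=0, ddof=1)
        self.uninformative_ = self.feature_sds_ == 0.0
        return self

    def transform(self, X):
        values, features, index = _as_2d(X)
        _check_finite(values)
        if values.shape[1] != self.feature_means_.size:
            raise ShapeError(
                f"z-score reference covers {self.feature_means_.size} "
                f"features but input has {values.shape[1]}"
            )
        if features is not None and hasattr(self, "feature_names_in_"):
            if not np.array_equal(np.asarray(features), self.feature_names_in_):
                raise AlignmentError(
                    "feature ids do not match the fitted z-score reference"
                )
        sds = np.where(self.uninformative_, 1.0, self.feature_sds_)
        out = (values - self.feature_means_) / sds
        out[:, self.uninformative_] = 0.0
        if features is not None:
            return pd.DataFrame(out, index=index, columns=features)
        return out


def collapse_replicates(
    matrix: pd.DataFrame,
    replicate_map: pd.Series | dict,
    control_flags: pd.Series | dict | None = None,
) -> pd.DataFrame:
    """Average technically replicated probes and drop control probes.

    ``matrix`` is features x samples (the on-disk orientation).
    ``replicate_map`` assigns each feature id a replicate-group id;
    features sharing a group are replaced by their per-sample arithmetic
    mean, under the group id. ``control_flags`` marks features to remove
    before collapsing. Output rows are sorted by group id (deterministic).
    """
    if not isinstance(replicate_map, pd.Series):
        replicate_map = pd.Series(replicate_map)
    missing = matrix.index.difference(replicate_map.index)
    if len(missing):
        raise AlignmentError(
            f"replicate map missing {len(missing)} feature(s), "
            f"e.g. {list(missing[:3])}"
        )
    keep = matrix.index
    if control_flags is not None:
        if not isinstance(control_flags, pd.Series):
            control_flags = pd.Series(control_flags)
        flags = (
            control_flags.reindex(matrix.index)
            .apply(lambda v: bool(v) if pd.notna(v) else False)
            .astype(bool)
        )
        keep = matrix.index[~flags.to_numpy()]
    if len(keep) == 0:
        raise FitError("all features are control probes; empty output")
    sub = matrix.loc[keep]
    groups = replicate_map.loc[keep]
    out = sub.groupby(groups.to_numpy()).mean()
    out = out.sort_index()
    out.index.name = matrix.index.name
    return out


def make_preprocessing_pipeline() -> Pipeline:
    """Quantile normalization followed by z-scoring, both training-locked.

    Replicate collapsing sits between them in the full pipeline but needs a
    probe map, so it is applied separately via :func:`collapse_replicates`
    when a map is available.
    """
    return Pipeline(
        [("quantile", QuantileNormalizer()), ("zscore", FeatureZScorer())]
    )


# ---------------------------------------------------------------------------
# functional wrappers over the transformers (features x samples orientation)

def quantile_normalize_fit(matrix: pd.DataFrame):
    """Fit on a features x samples matrix; return (normalized, ref_quantiles)."""
    qn = QuantileNormalizer().fit(matrix.T)
    return qn.transform(matrix.T).T, qn.ref_quantiles_


def quantile_normalize_apply(matrix: pd.DataFrame, ref_quantiles) -> pd.DataFrame:
    """Apply a recorded reference to a features x samples matrix."""
    qn = QuantileNormalizer()
    qn.ref_quantiles_ = np.asarray(ref_quantiles, dtype=float)
    qn.n_features_in_ = qn.ref_quantiles_.size
    return qn.transform(matrix.T).T


def zscore_fit(matrix: pd.DataFrame):
    """Fit z-scoring on features x samples; return (z, means, sds)."""
    zs = FeatureZScorer().fit(matrix.T)
    return zs.transform(matrix.T).T, zs.feature_means_, zs.feature_sds_


def zscore_apply(matrix: pd.DataFrame, means, sds) -> pd.DataFrame:
    """Apply recorded means/sds to a features x samples matrix."""
    zs = FeatureZScorer()
    zs.feature_means_ = np.asarray(means, dtype=float)
    zs.feature_sds_ = np.asarray(sds, dtype=float)
    zs.uninformative_ = zs.feature_sds_ == 0.0
    return zs.transform(matrix.T).T
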