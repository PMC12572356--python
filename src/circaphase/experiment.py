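"""Factorial training/validation experiment orchestration.

The study design this module reproduces: for each training condition
(IP, OP, SS, IS, or "all" — an equal mix of the four), draw ``n_s``
training samples at random, 20 times (replicates). Each replicate trains a
predictor with training-locked preprocessing, predicts every validation
sample, and is scored separately per validation condition, plus once on
its own training samples. Two sample-selection strategies exist:

* ``A`` — samples drawn freely; a participant may appear in both training
  and validation sets;
* ``B`` — participants are first partitioned, so training and validation
  sets share no participant.

Replicate randomness comes from a counter-based seed derivation
``(seed, replicate, condition, n_s, strategy)``, so every replicate is
individually reproducible and independent of execution order. One failing
replicate is recorded and skipped, never aborting the factorial.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import circular
from .exceptions import ConfigError, SamplingError, ShapeError
from .models import (
    ElasticNetPhaseRegressor,
    FixedPanelPhaseRegressor,
    PlsrPhaseRegressor,
)
from .preprocess import make_preprocessing_pipeline
from .zeitzeiger import ZeitZeigerPhaseRegressor

__all__ = [
    "ExperimentConfig",
    "TrainValSplit",
    "make_estimator",
    "build_split",
    "run_experiment",
    "aggregate",
    "compare_strategies",
    "lopo_cv",
    "METRICS_COLUMNS",
]

METRICS_COLUMNS = [
    "train_condition",
    "replicate",
    "validation_condition",
    "n",
    "mae_h",
    "bias_h",
    "circ_sd_h",
    "r2",
]

_METHODS = {
    "plsr": PlsrPhaseRegressor,
    "zeitzeiger": ZeitZeigerPhaseRegressor,
    "elasticnet": ElasticNetPhaseRegressor,
    "fixed_panel": FixedPanelPhaseRegressor,
}


def make_estimator(method: str, method_params: dict | None = None,
                   random_state=None):
    """Instantiate a phase predictor by method name."""
    if method not in _METHODS:
        raise ConfigError(
            f"unknown method {method!r}; known: {sorted(_METHODS)}"
        )
    params = dict(method_params or {})
    if method == "elasticnet" and "random_state" not in params:
        params["random_state"] = random_state
    return _METHODS[method](**params)


@dataclass(frozen=True)
class ExperimentConfig:
    train_conditions: tuple = ("IP", "OP", "SS", "IS", "all")
    n_s: int = 100
    n_repeats: int = 20
    strategy: str = "A"
    method: str = "plsr"
    method_params: dict = field(default_factory=dict)
    seed: int = 0
    keep_models: bool = True

    def validate(self):
        if self.n_s < 2:
            raise ConfigError("n_s must be >= 2")
        if self.n_repeats < 1:
            raise ConfigError("n_repeats must be >= 1")
        if self.strategy not in ("A", "B"):
            raise ConfigError("strategy must be 'A' or 'B'")
        if self.method not in _METHODS:
            raise ConfigError(f"unknown method {self.method!r}")


@dataclass(frozen=True)
class TrainValSplit:
    train_sample_ids: tuple
    validation: dict  # condition -> tuple of sample ids
    replicate: int
    condition: str
    n_s: int
    strategy: str
    seed: int


def _replicate_rng(seed, replicate, condition, n_s, strategy):
    cond_key = sum(ord(c) for c in condition)  # stable, order-free
    strat_key = 0 if strategy == "A" else 1
    return np.random.default_rng(
        [int(seed), int(replicate), cond_key, int(n_s), strat_key]
    )


def build_split(
    table: pd.DataFrame,
    condition: str,
    n_s: int,
    strategy: str = "A",
    seed: int = 0,
    replicate: int = 0,
) -> TrainValSplit:
    """Construct one training/validation split.

    Training: ``n_s`` samples drawn without replacement from ``condition``
    (for ``"all"``: ``n_s / k`` from each of the k base conditions, which
    must divide evenly). Validation: the remaining samples of the trained
    condition plus all samples of every other condition, grouped by
    condition. Strategy ``B`` first shuffles participants into a training
    pool (accumulated until the draw is feasible) and removes those
    participants from every validation group.
    """
    if strategy not in ("A", "B"):
        raise ConfigError("strategy must be 'A' or 'B'")
    base_conditions = sorted(c for c in table["condition"].unique())
    if condition == "all":
        if n_s % len(base_conditions):
            raise SamplingError(
                f"n_s={n_s} not divisible by the {len(base_conditions)} "
                "base conditions for 'all' training"
            )
        draw_from = base_conditions
        quota = n_s // len(base_conditions)
    elif condition in base_conditions:
        draw_from = [condition]
        quota = n_s
    else:
        raise SamplingError(f"unknown condition {condition!r}")

    rng = _replicate_rng(seed, replicate, condition, n_s, strategy)

    if strategy == "A":
        pool = table
    else:
        participants = pd.unique(table["participant_id"])
        order = rng.permutation(len(participants))
        chosen: list = []
        for i in order:
            chosen.append(participants[i])
            pool = table[table["participant_id"].isin(chosen)]
            if all(
                (pool["condition"] == c).sum() >= quota for c in draw_from
            ):
                break
        else:
            raise SamplingError(
                f"cannot assemble {n_s} training samples for condition "
                f"{condition!r} even using all participants"
            )

    train_ids: list = []
    for c in draw_from:
        ids = pool.loc[pool["condition"] == c, "sample_id"].to_numpy()
        if len(ids) < quota:
            raise SamplingError(
                f"condition {c!r} has only {len(ids)} available samples, "
                f"need {quota}"
            )
        train_ids.extend(rng.choice(ids, size=quota, replace=False))
    train_set = set(train_ids)

    if strategy == "B":
        train_participants = set(
            table.loc[table["sample_id"].isin(train_set), "participant_id"]
        )
        eligible = table[~table["participant_id"].isin(train_participants)]
    else:
        eligible = table
    validation = {}
    for c in base_conditions:
        ids = eligible.loc[
            (eligible["condition"] == c)
            & ~eligible["sample_id"].isin(train_set),
            "sample_id",
        ]
        validation[c] = tuple(ids)
    return TrainValSplit(
        train_sample_ids=tuple(train_ids),
        validation=validation,
        replicate=replicate,
        condition=condition,
        n_s=n_s,
        strategy=strategy,
        seed=seed,
    )


def _record(train_condition, replicate, validation_condition, pred, obs):
    rec = circular.evaluate(pred, obs)
    return {
        "train_condition": train_condition,
        "replicate": replicate,
        "validation_condition": validation_condition,
        "n": rec.n,
        "mae_h": rec.mae_hours,
        "bias_h": rec.bias_hours,
        "circ_sd_h": rec.circ_sd_hours,
        "r2": rec.r_squared,
    }


def run_experiment(matrix: pd.DataFrame, table: pd.DataFrame,
                   config: ExperimentConfig):
    """Run the full factorial; returns (records, models, failures).

    ``matrix`` is features x samples; ``table`` carries ``sample_id``,
    ``participant_id``, ``condition`` and ``phase_rad``. ``records`` is a
    DataFrame with one row per (train condition, replicate, validation
    condition) plus a ``'train'`` row per replicate scoring the model on
    its own training samples. ``models`` maps (train_condition, replicate)
    to the fitted estimator (when ``keep_models``); ``failures`` lists
    dicts describing replicates that errored (the run continues).
    """
    config.validate()
    if not set(table["sample_id"]).issubset(matrix.columns):
        raise ShapeError("sample table references samples absent from matrix")
    phase_of = table.set_index("sample_id")["phase_rad"]
    records = []
    models = {}
    failures = []
    for tc in config.train_conditions:
        for rep in range(config.n_repeats):
            try:
                split = build_split(
                    table, tc, config.n_s, config.strategy, config.seed, rep
                )
                train_ids = list(split.train_sample_ids)
                X_train = matrix[train_ids].T
                y_train = phase_of.loc[train_ids].to_numpy()
                pipe = make_preprocessing_pipeline()
                X_train_p = pipe.fit_transform(X_train)
                est = make_estimator(
                    config.method,
                    config.method_params,
                    random_state=int(
                        _replicate_rng(
                            config.seed, rep, tc, config.n_s, config.strategy
                        ).integers(2**31)
                    ),
                )
                est.fit(X_train_p, y_train)
                pred_tr = est.predict(X_train_p)
                records.append(_record(tc, rep, "train", pred_tr, y_train))
                for vc, ids in split.validation.items():
                    ids = list(ids)
                    if not ids:
                        continue
                    X_val = pipe.transform(matrix[ids].T)
                    pred = est.predict(X_val)
                    obs = phase_of.loc[ids].to_numpy()
                    records.append(_record(tc, rep, vc, pred, obs))
                if config.keep_models:
                    models[(tc, rep)] = est
            except Exception as exc:  # noqa: BLE001 - record-and-continue
                failures.append(
                    {
                        "train_condition": tc,
                        "replicate": rep,
                        "error": f"{type(exc).__name__}: {exc}",
                    }
                )
    return pd.DataFrame(records, columns=METRICS_COLUMNS), models, failures


def aggregate(records: pd.DataFrame) -> pd.DataFrame:
    """Mean +/- SD of the metrics per (train condition, validation
    condition), plus an ``'overall'`` row per train condition pooling all
    validation conditions (the 'train' self-scoring rows are kept as their
    own group and excluded from 'overall')."""
    if records is None or len(records) == 0:
        raise ShapeError("no records to aggregate")

    def _summarize(df, tc, vc):
        return {
            "train_condition": tc,
            "validation_condition": vc,
            "n_records": len(df),
            "mean_mae_h": df["mae_h"].mean(),
            "sd_mae_h": df["mae_h"].std(ddof=1) if len(df) > 1 else 0.0,
            "mean_bias_h": df["bias_h"].mean(),
            "mean_r2": df["r2"].mean(),
        }

    rows = []
    for (tc, vc), df in records.groupby(
        ["train_condition", "validation_condition"], sort=True
    ):
        rows.append(_summarize(df, tc, vc))
    for tc, df in records.groupby("train_condition", sort=True):
        pooled = df[df["validation_condition"] != "train"]
        if len(pooled):
            rows.append(_summarize(pooled, tc, "overall"))
    return pd.DataFrame(rows)


def compare_strategies(records_a: pd.DataFrame, records_b: pd.DataFrame):
    """Pearson correlation and paired differences of matched MAE cells.

    Cells are matched on (train_condition, replicate, validation_condition);
    a mismatch in the cell sets is an error. Returns ``(r, diffs)`` with
    ``diffs`` the merged frame carrying ``mae_h_a``, ``mae_h_b`` and
    ``mae_diff = a - b``.
    """
    keys = ["train_condition", "replicate", "validation_condition"]
    a = records_a[keys + ["mae_h"]].rename(columns={"mae_h": "mae_h_a"})
    b = records_b[keys + ["mae_h"]].rename(columns={"mae_h": "mae_h_b"})
    merged = a.merge(b, on=keys, how="outer", indicator=True)
    if (merged["_merge"] != "both").any():
        n_bad = int((merged["_merge"] != "both").sum())
        raise ShapeError(
            f"{n_bad} cell(s) present in only one strategy's records"
        )
    merged = merged.drop(columns="_merge")
    merged["mae_diff"] = merged["mae_h_a"] - merged["mae_h_b"]
    r = float(stats.pearsonr(merged["mae_h_a"], merged["mae_h_b"])[0])
    return r, merged


def lopo_cv(matrix: pd.DataFrame, table: pd.DataFrame, method: str,
            grid: list):
    """Leave-one-participant-out hyperparameter search.

    Folds are the distinct participants (sorted, deterministic). For each
    parameter combination the model is refitted once per fold with
    training-locked preprocessing and scored on the held-out participant's
    samples; the CV MAE pools all held-out errors. Returns
    ``(best_params, cv_table)``; ties go to the first grid entry.
    """
    participants = sorted(table["participant_id"].unique())
    if len(participants) < 2:
        raise ConfigError("LOPO-CV requires at least 2 participants")
    if not grid:
        raise ConfigError("empty hyperparameter grid")
    phase_of = table.set_index("sample_id")["phase_rad"]
    rows = []
    for params in grid:
        abs_errors = []
        for part in participants:
            held = table.loc[table["participant_id"] == part, "sample_id"]
            train = table.loc[table["participant_id"] != part, "sample_id"]
            X_train = matrix[list(train)].T
            pipe = make_preprocessing_pipeline()
            X_train_p = pipe.fit_transform(X_train)
            est = make_estimator(method, params, random_state=0)
            est.fit(X_train_p, phase_of.loc[train].to_numpy())
            X_held = pipe.transform(matrix[list(held)].T)
            pred = est.predict(X_held)
            obs = phase_of.loc[held].to_numpy()
            abs_errors.extend(np.abs(circular.signed_diff(pred, obs)))
        cv_mae = float(
            np.mean(abs_errors) * circular.HOURS_PER_CYCLE / circular.TWO_PI
        )
        rows.append({**params, "cv_mae_h": cv_mae, "n_folds": len(participants)})
    cv_table = pd.DataFrame(rows)
    best = grid[int(np.argmin(cv_table["cv_mae_h"].to_numpy()))]
    return best, cv_table
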