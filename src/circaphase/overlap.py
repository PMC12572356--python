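"""Predictor-composition analysis across replicate models.

Each fitted model defines a set of selected features with non-negative
weights: for the Cartesian models the weight is the norm of the (cosine,
sine) coefficient pair; for ZeitZeiger it is the norm of the SPC loading
vector. Across the replicate models of one training condition, the
*overlapping predictors* are the features selected in at least half of the
models (>= 10 of 20 at the default threshold), with weights averaged over
the models containing them. Gene-level summaries average the weights of a
gene's probes. The coefficient of variation of overlap counts across
conditions and sample sizes measures a method's feature-selection
consistency, and upset-style exclusive intersection counts describe how
condition-specific the overlapping predictors are.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import (
    ConfigError,
    ProvenanceError,
    ShapeError,
    UndefinedStatisticError,
)

__all__ = [
    "PredictorSet",
    "model_weights",
    "overlapping_predictors",
    "gene_level_weights",
    "overlap_consistency_cv",
    "intersection_table",
]


@dataclass(frozen=True)
class PredictorSet:
    """A feature -> weight map with its provenance (method, condition, n_s)."""

    weights: dict
    provenance: tuple = ()
    n_models: int = 1
    n_models_present: dict = field(default_factory=dict)

    def __post_init__(self):
        if any(w < 0 for w in self.weights.values()):
            raise ConfigError("predictor weights must be non-negative")

    def __len__(self):
        return len(self.weights)

    @property
    def features(self):
        return set(self.weights)


def model_weights(model) -> dict:
    """Per-feature weight of a fitted model.

    sqrt(c_cos^2 + c_sin^2) for Cartesian models, sqrt(sum of squared SPC
    loadings) for ZeitZeiger; features with zero weight are absent.
    """
    if not hasattr(model, "feature_weights"):
        raise ConfigError(
            f"{type(model).__name__} does not expose feature weights"
        )
    try:
        return model.feature_weights()
    except AttributeError as exc:  # missing fitted attributes
        raise ShapeError(
            f"model appears unfitted: {exc}"
        ) from exc


def overlapping_predictors(
    models_or_weights: list,
    min_fraction: float = 0.5,
    provenance: tuple = (),
) -> PredictorSet:
    """Features present in at least ``ceil(min_fraction * n_models)``
    of the replicate models, with weights averaged over the models each
    feature appears in.

    Accepts fitted models or precomputed feature->weight dicts; mixing
    provenances (pass ``PredictorSet``-style (model, provenance) handling
    upstream) is the caller's responsibility, but an explicit provenance
    mismatch among PredictorSet inputs raises.
    """
    if not models_or_weights:
        raise ShapeError("need at least one model")
    weight_maps = []
    for m in models_or_weights:
        if isinstance(m, PredictorSet):
            if m.provenance != () and provenance != () and \
                    m.provenance != provenance:
                raise ProvenanceError(
                    f"mixed provenance: {m.provenance} vs {provenance}"
                )
            weight_maps.append(m.weights)
        elif isinstance(m, dict):
            weight_maps.append(m)
        else:
            weight_maps.append(model_weights(m))
    n_models = len(weight_maps)
    threshold = math.ceil(min_fraction * n_models)
    counts: dict = {}
    sums: dict = {}
    for wm in weight_maps:
        for f, w in wm.items():
            if w > 0.0:
                counts[f] = counts.get(f, 0) + 1
                sums[f] = sums.get(f, 0.0) + w
    kept = {
        f: sums[f] / counts[f] for f in counts if counts[f] >= threshold
    }
    return PredictorSet(
        weights=kept,
        provenance=provenance,
        n_models=n_models,
        n_models_present={f: counts[f] for f in kept},
    )


def gene_level_weights(pset: PredictorSet, probe_to_gene: dict):
    """Average probe weights per gene.

    Probes missing from the map are retained under their own id and
    reported in the returned ``unmapped`` list. Returns
    ``(gene_weights, unmapped)``.
    """
    sums: dict = {}
    counts: dict = {}
    unmapped = []
    for probe, w in pset.weights.items():
        gene = probe_to_gene.get(probe)
        if gene is None:
            gene = probe
            unmapped.append(probe)
        sums[gene] = sums.get(gene, 0.0) + w
        counts[gene] = counts.get(gene, 0) + 1
    return {g: sums[g] / counts[g] for g in sums}, sorted(unmapped)


def overlap_consistency_cv(counts) -> float:
    """Coefficient of variation (sample SD / mean) of overlap counts."""
    arr = np.asarray(list(counts), dtype=float)
    if arr.size == 0:
        raise ShapeError("empty count list")
    mean = arr.mean()
    if mean == 0:
        raise UndefinedStatisticError("CV undefined: zero mean count")
    sd = arr.std(ddof=1) if arr.size > 1 else 0.0
    return float(sd / mean)


def intersection_table(named_sets: dict):
    """Exclusive (upset-style) intersection counts of named predictor sets.

    Every feature of the union is assigned to exactly one region — the
    combination of sets containing it — so region counts sum to the union
    size. Returns ``(table, unique_fractions)``: the table has one row per
    non-empty-membership region with a membership flag column per set; the
    unique fraction of a set is its exclusive-own count over its size.
    """
    names = list(named_sets)
    if len(names) < 2:
        raise ConfigError("need at least 2 sets")
    if len(set(names)) != len(names):
        raise ConfigError("duplicate set names")
    feats = {
        name: (s.features if isinstance(s, PredictorSet) else set(s))
        for name, s in named_sets.items()
    }
    union = set().union(*feats.values())
    regions: dict = {}
    for f in union:
        key = tuple(f in feats[name] for name in names)
        regions[key] = regions.get(key, 0) + 1
    rows = []
    n_sets = len(names)
    for mask in range(1, 2**n_sets):
        key = tuple(bool(mask & (1 << i)) for i in range(n_sets))
        row = {name: key[i] for i, name in enumerate(names)}
        row["count"] = regions.get(key, 0)
        rows.append(row)
    table = pd.DataFrame(rows)
    unique_fractions = {}
    for i, name in enumerate(names):
        own_key = tuple(j == i for j in range(n_sets))
        size = len(feats[name])
        unique_fractions[name] = (
            regions.get(own_key, 0) / size if size else np.nan
        )
    return table, unique_fractions
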