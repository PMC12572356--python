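"""Synthetic rhythmic-transcriptome generator.

Emulates time-stamped blood transcriptome samples from multiple
participants under four sleep-wake conditions:

* ``IP`` — sleeping in phase with the circadian clock (behavioral offset
  delta = 0);
* ``OP`` — sleeping out of phase, during the day (delta = 12 h): the
  sleep-wake cycle is displaced half a cycle from the melatonin rhythm;
* ``SS`` — constant wake after a week of sufficient sleep;
* ``IS`` — constant wake after a week of insufficient sleep, modeled as a
  damped rhythm amplitude (kappa < 1) for both rhythmic feature classes —
  an approximation of the reduced rhythmicity seen after sleep restriction.

Three feature classes are generated on a z-score-like scale:

* *circadian* features track melatonin-referenced phase theta:
  ``b_p + kappa * A * cos(theta - psi) + eps``;
* *behavioral* features track the sleep-wake (behavioral) phase
  ``phi = theta + delta`` instead, so they mislead a melatonin-referenced
  predictor exactly when sleep is mistimed;
* *null* features are participant baseline plus noise.

``b_p ~ N(0, sigma_p)`` is a per-participant, per-feature baseline offset
shared across that participant's samples; ``eps ~ N(0, sigma_e)`` is i.i.d.
measurement noise. Amplitudes are log-normal; peak phases uniform. Sample
phases are evenly spaced over the cycle with uniform jitter of half the
spacing, echoing around-the-clock time-series sampling. Everything is
determined by the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .circular import TWO_PI, canonical, hours_to_radians
from .exceptions import ConfigError

__all__ = [
    "ConditionSpec",
    "SyntheticConfig",
    "SyntheticDataset",
    "simulate",
    "preset",
    "PRESETS",
]


@dataclass(frozen=True)
class ConditionSpec:
    """Per-condition protocol parameters.

    delta_hours: behavioral offset of the sleep-wake cycle from the
    circadian (melatonin) phase, in [0, 24). kappa: rhythm amplitude
    modifier in (0, 1]."""

    delta_hours: float = 0.0
    kappa: float = 1.0


@dataclass(frozen=True)
class SyntheticConfig:
    n_participants: int = 30
    samples_per_participant_per_condition: int = 10
    conditions: dict = field(
        default_factory=lambda: {
            "IP": ConditionSpec(0.0, 1.0),
            "OP": ConditionSpec(12.0, 1.0),
            "SS": ConditionSpec(0.0, 1.0),
            "IS": ConditionSpec(0.0, 0.6),
        }
    )
    n_circadian: int = 100
    n_behavioral: int = 100
    n_null: int = 1800
    amplitude_median: float = 0.5
    amplitude_sigma_log: float = 0.5
    noise_sd: float = 0.5
    participant_sd: float = 0.3
    duplicate_consecutive_day: bool = False
    seed: int = 0

    def validate(self):
        bad = []
        if self.n_participants < 1:
            bad.append("n_participants")
        if self.samples_per_participant_per_condition < 1:
            bad.append("samples_per_participant_per_condition")
        if min(self.n_circadian, self.n_behavioral, self.n_null) < 0:
            bad.append("feature counts")
        if self.n_circadian + self.n_behavioral + self.n_null < 1:
            bad.append("total features")
        if self.noise_sd < 0 or self.participant_sd < 0:
            bad.append("noise/participant sd")
        if self.amplitude_median <= 0:
            bad.append("amplitude_median")
        for name, spec in self.conditions.items():
            if not 0.0 <= spec.delta_hours < 24.0:
                bad.append(f"conditions[{name}].delta_hours")
            if not 0.0 < spec.kappa <= 1.0:
                bad.append(f"conditions[{name}].kappa")
        if bad:
            raise ConfigError(f"invalid config field(s): {', '.join(bad)}")


@dataclass
class SyntheticDataset:
    """Generated expression + annotation + ground truth.

    matrix: features x samples DataFrame (z-score scale log2 abundance
    analogue). table: one row per sample (sample_id, participant_id,
    condition, phase_hours, phase_rad). truth: per-feature class,
    amplitude and peak phase.
    """

    matrix: pd.DataFrame
    table: pd.DataFrame
    truth: pd.DataFrame
    participant_offsets: np.ndarray  # participants x features
    config: SyntheticConfig


def simulate(config: SyntheticConfig) -> SyntheticDataset:
    """Generate a dataset; bit-identical for identical configs."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_c, n_b, n_0 = config.n_circadian, config.n_behavioral, config.n_null
    n_feat = n_c + n_b + n_0
    feature_ids = (
        [f"circ{i:05d}" for i in range(n_c)]
        + [f"behv{i:05d}" for i in range(n_b)]
        + [f"null{i:05d}" for i in range(n_0)]
    )
    classes = ["circadian"] * n_c + ["behavioral"] * n_b + ["null"] * n_0

    amplitudes = rng.lognormal(
        mean=np.log(config.amplitude_median),
        sigma=config.amplitude_sigma_log,
        size=n_feat,
    )
    amplitudes[n_c + n_b:] = 0.0
    peak_phases = rng.uniform(0.0, TWO_PI, size=n_feat)
    peak_phases[n_c + n_b:] = np.nan

    offsets = rng.normal(
        0.0, config.participant_sd, size=(config.n_participants, n_feat)
    )

    m = config.samples_per_participant_per_condition
    cond_names = list(config.conditions)
    rows = []
    columns = {}
    spacing = TWO_PI / m
    for cond in cond_names:
        spec = config.conditions[cond]
        delta = hours_to_radians(spec.delta_hours)
        for p in range(config.n_participants):
            base = spacing * np.arange(m)
            jitter = rng.uniform(-spacing / 2, spacing / 2, size=m)
            theta = canonical(base + jitter)
            if config.duplicate_consecutive_day and m >= 2:
                # second half re-sampled at the first half's clock times
                # (24 h apart => same phase), as in consecutive-day series
                half = m // 2
                theta[half: 2 * half] = theta[:half]
            phi = canonical(theta + delta)
            kappa = spec.kappa
            signal = np.zeros((n_feat, m))
            if n_c:
                signal[:n_c] = kappa * amplitudes[:n_c, None] * np.cos(
                    theta[None, :] - peak_phases[:n_c, None]
                )
            if n_b:
                signal[n_c:n_c + n_b] = (
                    kappa
                    * amplitudes[n_c:n_c + n_b, None]
                    * np.cos(phi[None, :] - peak_phases[n_c:n_c + n_b, None])
                )
            noise = rng.normal(0.0, config.noise_sd, size=(n_feat, m))
            vals = offsets[p][:, None] + signal + noise
            for i in range(m):
                sid = f"{cond}_p{p:03d}_s{i:02d}"
                columns[sid] = vals[:, i]
                rows.append(
                    {
                        "sample_id": sid,
                        "participant_id": f"p{p:03d}",
                        "condition": cond,
                        "phase_hours": float(theta[i] * 24.0 / TWO_PI),
                        "phase_rad": float(theta[i]),
                    }
                )

    matrix = pd.DataFrame(columns, index=pd.Index(feature_ids, name="feature_id"))
    table = pd.DataFrame(rows)
    truth = pd.DataFrame(
        {
            "feature_id": feature_ids,
            "class": classes,
            "amplitude": amplitudes,
            "peak_phase_rad": peak_phases,
        }
    )
    return SyntheticDataset(
        matrix=matrix,
        table=table,
        truth=truth,
        participant_offsets=offsets,
        config=config,
    )


def _paper_default(seed: int) -> SyntheticConfig:
    return SyntheticConfig(seed=seed)


def _noiseless(seed: int) -> SyntheticConfig:
    return SyntheticConfig(noise_sd=0.0, participant_sd=0.0, seed=seed)


def _overfit_regime(seed: int) -> SyntheticConfig:
    # weak signal in a sea of nulls, modest cohort: the regime where
    # feature selection latches onto noise and training error flatters
    return SyntheticConfig(
        n_participants=20,
        samples_per_participant_per_condition=10,
        conditions={"IP": ConditionSpec(0.0, 1.0)},
        n_circadian=20,
        n_behavioral=0,
        n_null=5000,
        noise_sd=1.0,
        participant_sd=0.3,
        seed=seed,
    )


PRESETS = {
    "paper_default": _paper_default,
    "noiseless": _noiseless,
    "overfit_regime": _overfit_regime,
}


def preset(name: str, seed: int = 0) -> SyntheticConfig:
    """Named study-condition presets.

    ``paper_default``: 30 participants x 4 conditions x 10 samples
    (1,200 samples), 100 circadian + 100 behavioral + 1,800 null features.
    ``noiseless``: same design with sigma_e = sigma_p = 0.
    ``overfit_regime``: one condition, 200 samples, 20 weak circadian
    features among 5,000 nulls, high noise.
    """
    try:
        return PRESETS[name](seed)
    except KeyError as exc:
        raise ConfigError(
            f"unknown preset {name!r}; known: {sorted(PRESETS)}"
        ) from exc


def config_to_dict(config: SyntheticConfig) -> dict:
    d = asdict(config)
    d["conditions"] = {
        k: {"delta_hours": v["delta_hours"], "kappa": v["kappa"]}
        for k, v in d["conditions"].items()
    }
    return d
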