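import numpy as np
import pandas as pd
import pytest

from circaphase.synthetic import ConditionSpec, SyntheticConfig, preset, simulate


def sinusoid_matrix(rng, n_samples=80, n_signal=20, n_null=30,
                    noise_sd=0.0, amp=0.5):
    """Noisy sinusoidal features plus nulls; returns (DataFrame, phases)."""
    theta = rng.uniform(0, 2 * np.pi, n_samples)
    psi = rng.uniform(0, 2 * np.pi, n_signal)
    signal = amp * np.cos(theta[:, None] - psi[None, :])
    null = rng.normal(0, max(noise_sd, 1e-12), (n_samples, n_null))
    X = np.column_stack([signal + rng.normal(0, noise_sd, signal.shape),
                         null])
    cols = [f"sig{i:03d}" for i in range(n_signal)] + [
        f"nul{i:03d}" for i in range(n_null)
    ]
    return pd.DataFrame(X, columns=cols), theta


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def noiseless_ds():
    return simulate(preset("noiseless", seed=11))


@pytest.fixture(scope="session")
def default_ds():
    return simulate(preset("paper_default", seed=7))


@pytest.fixture(scope="session")
def tiny_ds():
    """A small noisy dataset for fast pipeline-level tests."""
    cfg = SyntheticConfig(
        n_participants=6,
        samples_per_participant_per_condition=8,
        conditions={
            "IP": ConditionSpec(0.0, 1.0),
            "OP": ConditionSpec(12.0, 1.0),
        },
        n_circadian=30,
        n_behavioral=20,
        n_null=150,
        noise_sd=0.3,
        participant_sd=0.2,
        seed=42,
    )
    return simulate(cfg)
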