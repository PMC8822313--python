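import numpy as np
import pandas as pd
import pytest

from rteha import BinningScheme, HazardModelSpec, inverse_link_fn
from rteha.datasets import (
    masked_priming_counts,
    masked_priming_lifetable,
    masked_priming_scheme,
    masked_priming_trials,
)


@pytest.fixture(scope="session")
def scheme15() -> BinningScheme:
    return masked_priming_scheme()


@pytest.fixture(scope="session")
def example_counts() -> pd.DataFrame:
    return masked_priming_counts()


@pytest.fixture(scope="session")
def example_lifetable():
    return masked_priming_lifetable()


@pytest.fixture(scope="session")
def example_trials():
    return masked_priming_trials()


# True coefficients used throughout the parameter-recovery simulations:
# cubic baseline in (TIME-1) plus a binary covariate x1, a continuous
# covariate x2 and an x2-by-time interaction, on the cloglog scale.
RECOVERY_TRUTH = {
    "alpha_0": -4.0,
    "alpha_1": 0.8,
    "alpha_2": -0.05,
    "alpha_3": 0.001,
    "x1": 0.5,
    "x2": 0.3,
    "x2:time": -0.02,
}

RECOVERY_SPEC = HazardModelSpec(
    link="cloglog",
    time_degree=3,
    covariates=("x1", "x2"),
    time_interactions=("x2",),
)


def simulate_model_dataset(n_trials: int, seed: int, n_bins: int = 15,
                           truth: dict = RECOVERY_TRUTH) -> pd.DataFrame:
    """Person-trial-bin data drawn from the cloglog hazard model itself."""
    from rteha.simulate import sample_event_bins

    rng = np.random.default_rng(seed)
    x1 = rng.integers(0, 2, size=n_trials).astype(float)
    x2 = rng.normal(size=n_trials)
    u = np.arange(n_bins, dtype=float)  # TIME - 1
    eta = (
        truth["alpha_0"]
        + truth["alpha_1"] * u
        + truth["alpha_2"] * u**2
        + truth["alpha_3"] * u**3
    )[None, :]
    eta = eta + truth["x1"] * x1[:, None] + truth["x2"] * x2[:, None]
    eta = eta + truth["x2:time"] * x2[:, None] * u[None, :]
    h = inverse_link_fn(eta, "cloglog")
    bins = sample_event_bins(h, seed=rng)

    last = np.where(bins == 0, n_bins, bins)
    idx = np.repeat(np.arange(n_trials), last)
    t = np.concatenate([np.arange(1, l + 1) for l in last])
    event = np.concatenate(
        [np.eye(1, l, l - 1).ravel() if b else np.zeros(l)
         for l, b in zip(last, bins)]
    ).astype(int)
    return pd.DataFrame(
        {"participant": "sim", "trial": idx, "t": t, "event": event,
         "x1": x1[idx], "x2": x2[idx]}
    )
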