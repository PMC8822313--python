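"""Synthetic trial generation with known ground truth.

Two routes:

* :func:`sample_discrete` draws trials directly from a user-specified
  discrete hazard profile h_true(t) (with an optional conditional-accuracy
  profile ca_true(t)), bin by bin: given survival to bin t, the event occurs
  there with probability h_true(t); trials surviving all K bins are
  right-censored at the deadline.
* :func:`sample_continuous` draws exact event times from a parametric
  family — exponential, Weibull, gamma or log-normal — and censors draws
  beyond a fixed response deadline, mimicking the recommended fixed-deadline
  design. :func:`discretize_true_hazard` gives the implied true discrete
  hazard for any binning scheme, h(t) = [S(a) - S(b)] / S(a) for bin (a, b],
  so estimator output can be checked against closed forms.

All sampling is driven by a single seedable NumPy generator per call.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .lifetable import BinningScheme, TrialRecord

__all__ = [
    "DiscreteProfile",
    "ParametricFamily",
    "exponential",
    "weibull",
    "gamma_family",
    "lognormal",
    "sample_discrete",
    "sample_event_bins",
    "sample_continuous",
    "hazard_curve",
    "discretize_true_hazard",
]


@dataclass(frozen=True)
class DiscreteProfile:
    """True discrete hazard and conditional-accuracy profile over K bins.

    ``h_true`` may contain a 1 (every surviving trial responds there);
    values after the first 1 are unused. ``ca_true`` may be NaN in bins
    where ``h_true`` is 0 (no responses can land there).
    """

    h_true: tuple[float, ...]
    ca_true: tuple[float, ...] | None = None
    scheme: BinningScheme | None = None

    def __post_init__(self) -> None:
        h = np.asarray(self.h_true, dtype=float)
        if np.any((h < 0) | (h > 1)):
            raise ValueError("h_true values must lie in [0, 1]")
        object.__setattr__(self, "h_true", tuple(h.tolist()))
        if self.ca_true is not None:
            ca = np.asarray(self.ca_true, dtype=float)
            if len(ca) != len(h):
                raise ValueError("ca_true must match h_true in length")
            ok = np.isnan(ca) | ((ca >= 0) & (ca <= 1))
            if not ok.all():
                raise ValueError("ca_true values must lie in [0, 1] or be NaN")
            object.__setattr__(self, "ca_true", tuple(ca.tolist()))
        if self.scheme is not None and self.scheme.n_bins != len(h):
            raise ValueError("scheme bin count must match h_true length")

    @property
    def n_bins(self) -> int:
        return len(self.h_true)

    def survivor(self) -> np.ndarray:
        """Implied true S(t), the running product of 1 - h."""
        return np.cumprod(1.0 - np.asarray(self.h_true))


def sample_discrete(
    profile: DiscreteProfile,
    n: int,
    seed: int | np.random.Generator | None = None,
    participant: str = "sim",
    condition: tuple = (),
) -> list[TrialRecord]:
    """Draw n trials from a discrete hazard (+ conditional accuracy) profile.

    Each trial walks bins 1..K; given survival to bin t the response occurs
    there with probability h_true(t) and is correct with probability
    ca_true(t). Event times are placed uniformly inside their bin so records
    re-bin exactly under the profile's scheme. Trials with no response by
    bin K are right-censored. Deterministic given a seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    scheme = profile.scheme or BinningScheme.from_width(1.0, float(profile.n_bins))
    h = np.asarray(profile.h_true)
    K = profile.n_bins

    # reachable bins: those before (and including) the first h == 1
    survive = np.concatenate([[1.0], np.cumprod(1.0 - h)[:-1]])
    reachable = survive > 0
    if profile.ca_true is None:
        ca = np.ones(K)
    else:
        ca = np.asarray(profile.ca_true)
    bad = reachable & (h > 0) & np.isnan(ca)
    if bad.any():
        raise ValueError(
            f"ca_true is NaN in reachable bins with positive hazard: {np.flatnonzero(bad) + 1}"
        )

    u = rng.uniform(size=(n, K))
    event_mat = u < h[None, :]
    any_event = event_mat.any(axis=1)
    first = np.where(any_event, event_mat.argmax(axis=1), -1)

    edges = np.asarray(scheme.edges)
    frac = rng.uniform(size=n)
    ucorr = rng.uniform(size=n)
    trials: list[TrialRecord] = []
    for i in range(n):
        if first[i] < 0:
            trials.append(TrialRecord(participant, condition, None, None))
        else:
            t = int(first[i])
            lo, hi = edges[t], edges[t + 1]
            # strictly inside (lo, hi]: draw in the open interval, keep hi reachable in spirit
            rt = lo + (hi - lo) * (1.0 - frac[i] * (1.0 - 1e-12))
            correct = int(ucorr[i] < ca[t])
            trials.append(TrialRecord(participant, condition, float(rt), correct))
    return trials


def sample_event_bins(
    h_matrix: np.ndarray, seed: int | np.random.Generator | None = None
) -> np.ndarray:
    """Draw event bins from per-trial discrete hazards.

    ``h_matrix`` is (n trials × K bins) of conditional event probabilities —
    rows may differ, e.g. when each trial has its own covariate-dependent
    hazard under a regression model. Returns the 1-based event bin per
    trial, with 0 for trials surviving all K bins (right-censored).
    """
    h_matrix = np.asarray(h_matrix, dtype=float)
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    u = rng.uniform(size=h_matrix.shape)
    event = u < h_matrix
    any_event = event.any(axis=1)
    return np.where(any_event, event.argmax(axis=1) + 1, 0)


_FAMILIES = ("exponential", "weibull", "gamma", "lognormal")


@dataclass(frozen=True)
class ParametricFamily:
    """A continuous waiting-time family with closed-form hazard.

    Wraps a frozen scipy distribution; use the module-level constructors
    (:func:`exponential`, :func:`weibull`, :func:`gamma_family`,
    :func:`lognormal`) which validate parameters. The hazard rate is
    lambda(t) = f(t)/S(t), evaluated on the log scale for stability far in
    the tail.
    """

    family: str
    params: dict

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if any(v <= 0 for k, v in self.params.items() if k != "meanlog"):
            raise ValueError(f"invalid parameters for {self.family}: {self.params}")

    @property
    def dist(self):
        p = self.params
        if self.family == "exponential":
            return stats.expon(scale=1.0 / p["rate"])
        if self.family == "weibull":
            return stats.weibull_min(c=p["shape"], scale=p["scale"])
        if self.family == "gamma":
            return stats.gamma(a=p["shape"], scale=1.0 / p["rate"])
        return stats.lognorm(s=p["sdlog"], scale=np.exp(p["meanlog"]))

    def hazard(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        if np.any(t <= 0):
            raise ValueError("hazard is evaluated at t > 0")
        return np.exp(self.dist.logpdf(t) - self.dist.logsf(t))

    def survivor(self, t) -> np.ndarray:
        return self.dist.sf(t)


def exponential(rate: float) -> ParametricFamily:
    """Constant-hazard family: lambda(t) = rate."""
    return ParametricFamily("exponential", {"rate": rate})


def weibull(shape: float, scale: float) -> ParametricFamily:
    """Monotone hazard; shape 1 reduces to exponential(1/scale)."""
    return ParametricFamily("weibull", {"shape": shape, "scale": scale})


def gamma_family(shape: float, rate: float) -> ParametricFamily:
    """Hazard rises (shape > 1) to the asymptote ``rate``."""
    return ParametricFamily("gamma", {"shape": shape, "rate": rate})


def lognormal(meanlog: float, sdlog: float) -> ParametricFamily:
    """Hazard rises to a peak then decays toward an asymptote."""
    return ParametricFamily("lognormal", {"meanlog": meanlog, "sdlog": sdlog})


def hazard_curve(fam: ParametricFamily, t) -> np.ndarray:
    """Hazard rate lambda(t) = f(t)/S(t) on a time grid (t > 0)."""
    return fam.hazard(t)


def sample_continuous(
    fam: ParametricFamily,
    n: int,
    deadline: float,
    seed: int | np.random.Generator | None = None,
    p_correct: float = 1.0,
    participant: str = "sim",
    condition: tuple = (),
) -> list[TrialRecord]:
    """Draw n i.i.d. event times; censor those beyond the fixed deadline.

    Responses are correct with constant probability ``p_correct`` (1 by
    default — the family describes response occurrence, not accuracy).
    Deterministic given a seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if deadline <= 0:
        raise ValueError("deadline must be positive")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    times = fam.dist.rvs(size=n, random_state=rng)
    correct = (rng.uniform(size=n) < p_correct).astype(int)
    out: list[TrialRecord] = []
    for rt, c in zip(times, correct):
        if rt > deadline or rt <= 0:
            out.append(TrialRecord(participant, condition, None, None))
        else:
            out.append(TrialRecord(participant, condition, float(rt), int(c)))
    return out


def discretize_true_hazard(fam: ParametricFamily, scheme: BinningScheme) -> np.ndarray:
    """True discrete hazard of a continuous family under interval censoring.

    For bin t = (a, b]: h(t) = [S(a) - S(b)] / S(a) = 1 - S(b)/S(a),
    computed from log-survivor differences for numerical stability. Bins
    whose start the distribution cannot survive to (S(a) = 0) are NaN.
    """
    edges = np.asarray(scheme.edges, dtype=float)
    logsf = np.empty_like(edges)
    logsf[0] = 0.0  # S(0) = 1
    with np.errstate(over="ignore", invalid="ignore"):
        logsf[1:] = fam.dist.logsf(edges[1:])
        h = -np.expm1(logsf[1:] - logsf[:-1])
    h[np.isinf(logsf[:-1])] = np.nan
    return h
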