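"""Discrete-time hazard regression on person-trial-bin data.

A trial that responds in bin ``t`` contributes ``t`` Bernoulli observations
(one per bin at risk), the last with event = 1; a trial censored in bin ``c``
contributes ``c`` observations, all zero. Fitting a binomial GLM with a
complementary log-log link to the event indicator then yields maximum-
likelihood estimates of the discrete-time hazard model

    cloglog[h(t)] = ln(-ln[1 - h(t)])
                  = alpha_0 + alpha_1 (TIME-c) + ... + alpha_d (TIME-c)^d
                    + sum_i beta_i X_i  [+ interactions X_i * (TIME-c)]

where TIME is the 1-based bin rank and c a centering constant (default 1).
The cloglog link is preferred for events that occur in continuous time but
are recorded in intervals; exponentiated coefficients are hazard ratios. A
logit link is also supported.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .lifetable import BinningScheme, TrialRecord, assign_bin

__all__ = [
    "HazardModelSpec",
    "HazardModelFit",
    "FitError",
    "expand_person_trial_bin",
    "link_fn",
    "inverse_link_fn",
    "fit_hazard_model",
]


class FitError(RuntimeError):
    """Estimation failed (rank deficiency, separation, non-convergence)."""


def link_fn(p, link: str = "cloglog"):
    """Apply the cloglog or logit link to a probability in (0, 1)."""
    p = np.asarray(p, dtype=float)
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("link is defined for probabilities strictly in (0, 1)")
    if link == "cloglog":
        return np.log(-np.log1p(-p))
    if link == "logit":
        return np.log(p) - np.log1p(-p)
    raise ValueError(f"unknown link {link!r}")


def inverse_link_fn(x, link: str = "cloglog"):
    """Inverse link: map a linear predictor back to a probability."""
    x = np.asarray(x, dtype=float)
    if link == "cloglog":
        return -np.expm1(-np.exp(x))
    if link == "logit":
        return 1.0 / (1.0 + np.exp(-x))
    raise ValueError(f"unknown link {link!r}")


def expand_person_trial_bin(
    trials: Iterable[TrialRecord],
    scheme: BinningScheme,
    covariates: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Expand trial-level records into the long person-trial-bin format.

    Returns one row per (trial, bin-at-risk): columns ``participant``,
    ``trial`` (position in the input), ``t`` and ``event``, followed by any
    trial-level covariate columns replicated across that trial's rows. A
    covariate entry that is a length-K sequence is treated as time-varying
    and indexed by bin.
    """
    trials = list(trials)
    if covariates is not None:
        if len(covariates) != len(trials):
            raise ValueError("covariates must have one row per trial")
        if covariates.isna().to_numpy().any():
            bad = covariates.index[covariates.isna().any(axis=1)].tolist()
            raise ValueError(f"missing covariate values for trials {bad}")

    K = scheme.n_bins
    frames = []
    for i, tr in enumerate(trials):
        last = assign_bin(tr.rt, scheme) if not tr.is_censored else assign_bin(
            tr.censor_time, scheme
        )
        event = np.zeros(last, dtype=int)
        if not tr.is_censored:
            event[-1] = 1
        rows = pd.DataFrame(
            {
                "participant": tr.participant,
                "trial": i,
                "t": np.arange(1, last + 1),
                "event": event,
            }
        )
        if covariates is not None:
            for col in covariates.columns:
                val = covariates.iloc[i][col]
                if isinstance(val, (list, tuple, np.ndarray)):
                    if len(val) != K:
                        raise ValueError(
                            f"time-varying covariate {col!r} must have {K} values"
                        )
                    rows[col] = np.asarray(val)[:last]
                else:
                    rows[col] = val
        frames.append(rows)
    return pd.concat(frames, ignore_index=True)


@dataclass(frozen=True)
class HazardModelSpec:
    """Model structure for a discrete-time hazard regression.

    ``time_degree`` is the degree of the polynomial in (TIME - time_center)
    forming the baseline, or the string ``"saturated"`` for one indicator per
    bin (no intercept). ``covariates`` are column names entering as vertical
    shifts; names listed in ``time_interactions`` additionally enter
    multiplied by (TIME - time_center).
    """

    link: str = "cloglog"
    time_degree: int | str = 3
    time_center: float = 1.0
    covariates: tuple[str, ...] = ()
    time_interactions: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.link not in ("cloglog", "logit"):
            raise ValueError(f"unknown link {self.link!r}")
        if self.time_degree != "saturated" and int(self.time_degree) < 0:
            raise ValueError("time_degree must be >= 0 or 'saturated'")
        missing = set(self.time_interactions) - set(self.covariates)
        if missing:
            raise ValueError(f"interaction terms not among covariates: {missing}")

    def design_matrix(self, data: pd.DataFrame) -> pd.DataFrame:
        t = data["t"].to_numpy(dtype=float)
        cols: dict[str, np.ndarray] = {}
        if self.time_degree == "saturated":
            for tb in np.unique(data["t"]):
                cols[f"bin_{int(tb)}"] = (data["t"] == tb).to_numpy(dtype=float)
        else:
            u = t - self.time_center
            cols["alpha_0"] = np.ones_like(t)
            for d in range(1, int(self.time_degree) + 1):
                cols[f"alpha_{d}"] = u**d
        for name in self.covariates:
            cols[name] = data[name].to_numpy(dtype=float)
        for name in self.time_interactions:
            cols[f"{name}:time"] = data[name].to_numpy(dtype=float) * (
                t - self.time_center
            )
        return pd.DataFrame(cols, index=data.index)


@dataclass
class HazardModelFit:
    """Fitted discrete-time hazard model."""

    spec: HazardModelSpec
    params: pd.Series
    bse: pd.Series
    llf: float
    converged: bool
    n_bins: int
    result: object = field(repr=False, default=None)

    def hazard_ratios(self, alpha: float = 0.05) -> pd.DataFrame:
        """Exponentiated covariate effects with Wald intervals.

        ``HR = exp(beta)``; the interval is ``exp(beta ± z * se)``. Under the
        cloglog link these are hazard ratios; under logit, odds ratios on the
        per-bin event odds.
        """
        names = [
            n
            for n in self.params.index
            if n in self.spec.covariates or n.endswith(":time")
        ]
        z = stats.norm.ppf(1 - alpha / 2)
        beta = self.params[names]
        se = self.bse[names]
        return pd.DataFrame(
            {
                "hr": np.exp(beta),
                "lo": np.exp(beta - z * se),
                "hi": np.exp(beta + z * se),
            }
        )

    def predict_hazard(
        self, profile: Mapping[str, float] | None = None, bins: Sequence[int] | None = None
    ) -> np.ndarray:
        """Predicted h(t) over bins for a covariate profile.

        ``profile`` must supply every covariate in the spec (use 0 for the
        baseline); omit entirely for the all-zero baseline curve. Honors
        covariate × time interactions per bin.
        """
        spec = self.spec
        profile = dict(profile or {})
        missing = [c for c in spec.covariates if c not in profile]
        if profile and missing:
            raise ValueError(f"profile missing covariates: {missing}")
        if bins is None:
            bins = np.arange(1, self.n_bins + 1)
        t = np.asarray(bins, dtype=float)
        if spec.time_degree == "saturated":
            eta = np.array(
                [self.params.get(f"bin_{int(tb)}", np.nan) for tb in t]
            )
        else:
            u = t - spec.time_center
            eta = np.full_like(t, self.params["alpha_0"])
            for d in range(1, int(spec.time_degree) + 1):
                eta = eta + self.params[f"alpha_{d}"] * u**d
        for name in spec.covariates:
            eta = eta + self.params[name] * profile.get(name, 0.0)
        for name in spec.time_interactions:
            eta = eta + self.params[f"{name}:time"] * profile.get(name, 0.0) * (
                t - spec.time_center
            )
        return inverse_link_fn(eta, spec.link)

    def baseline_hazard(self) -> np.ndarray:
        """Fitted h(t) with all covariates at zero."""
        return self.predict_hazard()


def fit_hazard_model(
    data: pd.DataFrame, spec: HazardModelSpec, n_bins: int | None = None
) -> HazardModelFit:
    """Maximum-likelihood fit of a discrete-time hazard model.

    ``data`` is a person-trial-bin table (see :func:`expand_person_trial_bin`)
    with an ``event`` column. Raises :class:`FitError` on a rank-deficient
    design, perfect separation or non-convergence rather than returning a
    silently unusable fit.
    """
    if data["event"].sum() < 1:
        raise FitError("no events in the data")
    X = spec.design_matrix(data)
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        raise FitError(
            f"design matrix is rank deficient (rank {rank} < {X.shape[1]} columns)"
        )
    y = data["event"].to_numpy(dtype=float)
    link = (
        sm.families.links.CLogLog() if spec.link == "cloglog" else sm.families.links.Logit()
    )
    model = sm.GLM(y, X, family=sm.families.Binomial(link=link))
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", sm.tools.sm_exceptions.PerfectSeparationWarning)
            res = model.fit(maxiter=200)
    except (sm.tools.sm_exceptions.PerfectSeparationError,
            sm.tools.sm_exceptions.PerfectSeparationWarning) as exc:
        raise FitError(f"perfect separation detected: {exc}") from exc
    if not res.converged:
        raise FitError("IRLS did not converge")
    if n_bins is None:
        n_bins = int(data["t"].max())
    return HazardModelFit(
        spec=spec,
        params=pd.Series(res.params, index=X.columns),
        bse=pd.Series(res.bse, index=X.columns),
        llf=float(res.llf),
        converged=bool(res.converged),
        n_bins=n_bins,
        result=res,
    )
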