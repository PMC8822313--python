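"""Leave-one-participant-out (jackknife) curve inference.

Individual hazard or conditional-accuracy curves are often too noisy to
locate features such as the bottom of a dip or an onset threshold crossing.
The jackknife sidesteps this: form N subsample curves, each the average of
all participants except one, extract the feature of interest from each
smooth subsample curve, and run a standard ANOVA on the N extracted values.
Because every participant enters N-1 subsamples, the between-subsample
variance is (N-1)^2 times too small, so the resulting F statistics must be
divided by (N-1)^2 (and p recomputed at unchanged degrees of freedom).

For a statistic that is linear in the participant curves this correction is
exact: the corrected subsample F equals the F from an ANOVA on the
individual participants' values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "RegionOfInterest",
    "loo_subsamples",
    "extract_parameter",
    "corrected_anova",
    "AnovaResult",
]


@dataclass(frozen=True)
class RegionOfInterest:
    """Inclusive 1-based bin range [t_lo, t_hi] to search for a feature."""

    t_lo: int
    t_hi: int

    def __post_init__(self) -> None:
        if not 1 <= self.t_lo <= self.t_hi:
            raise ValueError(f"invalid ROI [{self.t_lo}, {self.t_hi}]")

    def slice(self) -> slice:
        return slice(self.t_lo - 1, self.t_hi)


def loo_subsamples(curves: np.ndarray) -> np.ndarray:
    """Leave-one-out averaged curves.

    ``curves`` is an (N participants × K bins) array; row i of the result is
    the bin-wise mean over all participants except i. NaNs propagate: a bin
    is NaN in subsample i whenever any retained participant is NaN there.
    The mean of the subsample curves equals the mean of the individual
    curves.
    """
    curves = np.asarray(curves, dtype=float)
    if curves.ndim != 2:
        raise ValueError("curves must be a 2-D (participants x bins) array")
    n = curves.shape[0]
    if n < 2:
        raise ValueError("need at least 2 participants for leave-one-out")
    nan_mask = np.isnan(curves)
    filled = np.where(nan_mask, 0.0, curves)
    total = filled.sum(axis=0)
    subs = (total[None, :] - filled) / (n - 1)
    # NaN wherever any *retained* participant is NaN
    n_nan = nan_mask.sum(axis=0)
    retained_nan = n_nan[None, :] - nan_mask.astype(int)
    subs[retained_nan > 0] = np.nan
    return subs


def extract_parameter(
    curve: np.ndarray,
    roi: RegionOfInterest,
    kind: str = "min",
    threshold: float | None = None,
    direction: str = "up",
    bin_times: np.ndarray | None = None,
) -> tuple[float, float]:
    """Extract a feature (time, amplitude) from one curve within a ROI.

    ``kind`` is ``"min"``, ``"max"`` or ``"threshold"``. For extrema the
    earliest bin wins ties; for ``"threshold"`` the first bin in the ROI at
    or beyond ``threshold`` is returned (``direction="up"`` for >=, ``"down"``
    for <=), with NaN amplitude time if never crossed. ``bin_times`` maps bin
    index to a time value (e.g. bin midpoints in ms); defaults to the bin
    index itself.
    """
    curve = np.asarray(curve, dtype=float)
    if roi.t_hi > curve.size:
        raise ValueError("ROI extends past the end of the curve")
    window = curve[roi.slice()]
    if np.all(np.isnan(window)):
        raise ValueError("all values in the ROI are NaN")
    times = (
        np.asarray(bin_times, dtype=float)[roi.slice()]
        if bin_times is not None
        else np.arange(roi.t_lo, roi.t_hi + 1, dtype=float)
    )
    if kind in ("min", "max"):
        op = np.nanargmin if kind == "min" else np.nanargmax
        i = int(op(window))  # nanarg* returns the first index on ties
        return float(times[i]), float(window[i])
    if kind == "threshold":
        if threshold is None:
            raise ValueError("threshold kind requires a threshold value")
        mask = window >= threshold if direction == "up" else window <= threshold
        mask &= ~np.isnan(window)
        idx = np.flatnonzero(mask)
        if idx.size == 0:
            return float("nan"), float("nan")
        return float(times[idx[0]]), float(window[idx[0]])
    raise ValueError(f"unknown kind {kind!r}")


@dataclass(frozen=True)
class AnovaResult:
    F: float
    df1: int
    df2: int
    p: float
    corrected: bool
    n_subsamples: int


def corrected_anova(
    values: np.ndarray, design: str = "within", correct: bool = True
) -> AnovaResult:
    """One-way ANOVA on jackknife subsample values with the (N-1)^2 correction.

    ``values`` is a (conditions × N subsamples) table of extracted
    parameters. For ``design="within"`` (the default, matching a repeated-
    measures small-N experiment) the condition effect is tested against the
    condition × subsample interaction; ``design="between"`` runs an ordinary
    one-way ANOVA. The F statistic is divided by (N-1)^2 (identity at N=2)
    and p recomputed from the F distribution at unchanged degrees of
    freedom. ``correct=False`` gives the uncorrected ANOVA, e.g. for
    individual-participant values.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 2:
        raise ValueError("values must be a 2-D (conditions x subsamples) array")
    n_cond, n = values.shape
    if n_cond < 2:
        raise ValueError("need at least 2 conditions")
    if n < 2:
        raise ValueError("need at least 2 subsamples")
    if np.isnan(values).any():
        raise ValueError("incomplete table: NaN values present")

    grand = values.mean()
    cond_means = values.mean(axis=1)
    ss_cond = n * np.sum((cond_means - grand) ** 2)
    df1 = n_cond - 1
    if design == "within":
        subj_means = values.mean(axis=0)
        resid = values - cond_means[:, None] - subj_means[None, :] + grand
        ss_err = np.sum(resid**2)
        df2 = (n_cond - 1) * (n - 1)
    elif design == "between":
        ss_err = np.sum((values - cond_means[:, None]) ** 2)
        df2 = n_cond * (n - 1)
    else:
        raise ValueError("design must be 'within' or 'between'")

    if ss_cond == 0:
        F = 0.0
    elif ss_err == 0:
        F = float("inf")
    else:
        F = (ss_cond / df1) / (ss_err / df2)
    if correct:
        F = F / (n - 1) ** 2
    p = float(stats.f.sf(F, df1, df2)) if np.isfinite(F) else 0.0
    if F == 0.0:
        p = 1.0
    return AnovaResult(F=float(F), df1=df1, df2=df2, p=p,
                       corrected=correct, n_subsamples=n)
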