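"""Life-table estimation of discrete-time hazard, survivor, probability-mass
and conditional-accuracy functions.

The central object is the :class:`LifeTable`, built from trial-level
time-to-event records for one participant in one experimental condition.
Time is partitioned into contiguous half-open bins ``(a, b]`` covering
``(0, censoring_time]``; trials without an observed response by the deadline
are right-censored and remain in the risk set of every bin.

Estimators (per bin ``t``, with ``E`` the event count and ``RS`` the risk set):

* hazard ``h(t) = P(T = t | T >= t)``, estimated as ``E(t)/RS(t)``
* survivor ``S(t) = P(T > t) = prod_{i<=t} (1 - h(i))``
* probability mass ``P(t) = P(T = t) = h(t) * S(t-1)``
* conditional accuracy ``ca(t) = P(correct | T = t)``, estimated as
  ``n_correct(t)/E(t)``

Standard errors for ``h``, ``P`` and ``ca`` use the binomial formula
``sqrt(p(1-p)/N)`` with ``N`` equal to ``RS(t)``, ``RS(1)`` and ``E(t)``
respectively; ``se_S`` uses Greenwood's formula.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CENSORED",
    "TrialRecord",
    "BinningScheme",
    "LifeTable",
    "assign_bin",
    "tabulate",
    "estimate_lifetable",
    "diff_curves",
]

#: Sentinel for a right-censored response time (no response by the deadline).
CENSORED = None


@dataclass(frozen=True)
class TrialRecord:
    """One experimental trial.

    Parameters
    ----------
    participant
        Participant identifier.
    condition
        Tuple of condition labels, one entry per experimental factor.
    rt
        Response time in milliseconds, or ``None`` (:data:`CENSORED`) when no
        response occurred during the data-collection period.
    correct
        Response correctness, 0 or 1; ``None`` exactly when ``rt`` is censored.
    censor_time
        Optional explicit censoring time in ms for interior censoring (e.g.
        equipment failure before the deadline). Only meaningful when ``rt``
        is censored; ``None`` means censored at the scheme's deadline.
    """

    participant: str
    condition: tuple = ()
    rt: float | None = None
    correct: int | None = None
    censor_time: float | None = None

    def __post_init__(self) -> None:
        if self.rt is None:
            if self.correct is not None:
                raise ValueError("censored trial must have missing correctness")
        else:
            if not self.rt > 0:
                raise ValueError(f"rt must be positive, got {self.rt}")
            if self.correct not in (0, 1):
                raise ValueError("observed trial needs correct in {0, 1}")
            if self.censor_time is not None:
                raise ValueError("censor_time only applies to censored trials")

    @property
    def is_censored(self) -> bool:
        return self.rt is None

    @property
    def stratum(self) -> tuple:
        return (self.participant, self.condition)


@dataclass(frozen=True)
class BinningScheme:
    """Contiguous half-open time bins ``(edges[t-1], edges[t]]`` for t = 1..K.

    ``edges`` starts at 0 and ends at the censoring time (the fixed response
    deadline). Bin indices are 1-based.
    """

    edges: tuple[float, ...]

    def __post_init__(self) -> None:
        edges = np.asarray(self.edges, dtype=float)
        if edges.size < 2:
            raise ValueError("need at least two edges (one bin)")
        if edges[0] != 0:
            raise ValueError("first edge must be 0")
        if not np.all(np.diff(edges) > 0):
            raise ValueError("edges must be strictly increasing")
        object.__setattr__(self, "edges", tuple(edges.tolist()))

    @classmethod
    def from_width(cls, width: float, censoring_time: float) -> "BinningScheme":
        """Equal-width bins; ``width`` must divide ``censoring_time``."""
        n, rem = divmod(censoring_time, width)
        if rem:
            raise ValueError(
                f"bin width {width} does not divide censoring time {censoring_time}"
            )
        return cls(tuple(width * i for i in range(int(n) + 1)))

    @property
    def n_bins(self) -> int:
        return len(self.edges) - 1

    @property
    def censoring_time(self) -> float:
        return self.edges[-1]

    @property
    def midpoints(self) -> np.ndarray:
        e = np.asarray(self.edges)
        return (e[:-1] + e[1:]) / 2.0

    @property
    def labels(self) -> list[str]:
        def fmt(x: float) -> str:
            return f"{x:g}"

        return [
            f"({fmt(self.edges[i])},{fmt(self.edges[i + 1])}]"
            for i in range(self.n_bins)
        ]


def assign_bin(rt: float | None, scheme: BinningScheme) -> int:
    """Map a response time to its 1-based bin index.

    Bins are right-closed: an rt equal to an edge belongs to the bin ending
    at that edge. A censored rt (``None``) maps to the final bin K, where
    deadline-censored trials leave the risk set. Response times recorded
    after the deadline are rejected — convert them to :data:`CENSORED`
    explicitly at ingestion.
    """
    if rt is None:
        return scheme.n_bins
    if not rt > 0:
        raise ValueError(f"rt must be positive, got {rt}")
    if rt > scheme.censoring_time:
        raise ValueError(
            f"rt {rt} exceeds the censoring time {scheme.censoring_time}; "
            "convert late responses to CENSORED before binning"
        )
    # right-closed: first edge >= rt
    return int(np.searchsorted(scheme.edges, rt, side="left"))


def tabulate(trials: Iterable[TrialRecord], scheme: BinningScheme) -> pd.DataFrame:
    """Count events, censorings and risk sets per bin for one stratum.

    Returns a DataFrame indexed by t = 1..K with integer columns
    ``E, rc, n_correct, n_error, RS``. All trials must share one
    participant × condition stratum; censored trials count toward ``rc`` in
    the bin containing their censoring time (bin K under the standard fixed
    deadline) and stay at risk through that bin.
    """
    trials = list(trials)
    if not trials:
        raise ValueError("empty trial collection")
    strata = {tr.stratum for tr in trials}
    if len(strata) > 1:
        raise ValueError(f"trials span multiple strata: {sorted(strata)}")

    K = scheme.n_bins
    E = np.zeros(K, dtype=int)
    rc = np.zeros(K, dtype=int)
    n_correct = np.zeros(K, dtype=int)
    for tr in trials:
        if tr.is_censored:
            t = assign_bin(tr.censor_time, scheme)
            rc[t - 1] += 1
        else:
            t = assign_bin(tr.rt, scheme)
            E[t - 1] += 1
            n_correct[t - 1] += tr.correct
    n_error = E - n_correct

    RS = np.empty(K, dtype=int)
    RS[0] = len(trials)
    for t in range(1, K):
        RS[t] = RS[t - 1] - E[t - 1] - rc[t - 1]
    return pd.DataFrame(
        {"E": E, "rc": rc, "n_correct": n_correct, "n_error": n_error, "RS": RS},
        index=pd.RangeIndex(1, K + 1, name="t"),
    )


@dataclass
class LifeTable:
    """Per-bin descriptive statistics for one participant × condition stratum.

    Attributes
    ----------
    scheme
        The binning scheme the table was built on.
    table
        DataFrame indexed by bin rank t = 1..K with the counts
        (``E, rc, n_correct, n_error, RS``) and the estimates with standard
        errors (``h, se_h, S, se_S, P, se_P, ca, se_ca``). ``ca`` is NaN in
        bins without responses; ``h`` is NaN once the risk set is empty.
    participant, condition
        Optional stratum labels, carried through from the trials.
    """

    scheme: BinningScheme
    table: pd.DataFrame
    participant: str | None = None
    condition: tuple = field(default_factory=tuple)

    # -- constructors ------------------------------------------------------

    @classmethod
    def from_trials(
        cls, trials: Iterable[TrialRecord], scheme: BinningScheme
    ) -> "LifeTable":
        trials = list(trials)
        counts = tabulate(trials, scheme)
        lt = cls.from_counts(counts, scheme)
        lt.participant = trials[0].participant
        lt.condition = trials[0].condition
        return lt

    @classmethod
    def from_counts(cls, counts: pd.DataFrame, scheme: BinningScheme) -> "LifeTable":
        """Estimate all functions from tabulated per-bin counts.

        ``counts`` needs columns ``E, rc, n_correct, n_error`` (``RS`` is
        recomputed from the recursion if absent) and must satisfy the count
        invariants (see :func:`tabulate`).
        """
        counts = counts.copy()
        K = scheme.n_bins
        if len(counts) != K:
            raise ValueError(f"counts have {len(counts)} rows, scheme has {K} bins")
        E = counts["E"].to_numpy(dtype=float)
        rc = counts["rc"].to_numpy(dtype=float)
        if "RS" in counts:
            RS = counts["RS"].to_numpy(dtype=float)
        else:
            RS = np.empty(K)
            RS[0] = E.sum() + rc.sum()
            RS[1:] = RS[0] - np.cumsum(E + rc)[:-1]
            counts["RS"] = RS.astype(int)
        if np.any(RS < 0) or np.any(E < 0) or np.any(rc < 0):
            raise ValueError("negative counts")
        if not np.allclose(RS[1:], RS[:-1] - E[:-1] - rc[:-1]):
            raise ValueError("risk-set recursion violated: RS(t+1) != RS(t)-E(t)-rc(t)")
        n_correct = counts["n_correct"].to_numpy(dtype=float)
        n_error = counts["n_error"].to_numpy(dtype=float)
        if np.any(n_correct + n_error != E):
            raise ValueError("n_correct + n_error must equal E per bin")

        with np.errstate(divide="ignore", invalid="ignore"):
            h = np.where(RS > 0, E / np.where(RS > 0, RS, 1.0), np.nan)
            se_h = np.sqrt(h * (1 - h) / np.where(RS > 0, RS, np.nan))
            S = np.cumprod(1.0 - h)  # NaN propagates once the risk set empties
            S_prev = np.concatenate([[1.0], S[:-1]])
            P = h * S_prev
            se_P = np.sqrt(P * (1 - P) / RS[0])
            ca = np.where(E > 0, n_correct / np.where(E > 0, E, 1.0), np.nan)
            se_ca = np.sqrt(ca * (1 - ca) / np.where(E > 0, E, np.nan))
            # Greenwood: se_S(t) = S(t) * sqrt(sum_{i<=t} E/(RS*(RS-E)))
            denom = RS * (RS - E)
            term = np.where(denom > 0, E / np.where(denom > 0, denom, 1.0), np.nan)
            term = np.where((RS > 0) & (RS == E), np.inf, term)
            se_S = S * np.sqrt(np.cumsum(term))
            se_S = np.where(S == 0, 0.0, se_S)

        table = counts[["E", "rc", "n_correct", "n_error", "RS"]].copy()
        table.index = pd.RangeIndex(1, K + 1, name="t")
        for name, vals in [
            ("h", h), ("se_h", se_h), ("S", S), ("se_S", se_S),
            ("P", P), ("se_P", se_P), ("ca", ca), ("se_ca", se_ca),
        ]:
            table[name] = vals
        return cls(scheme=scheme, table=table)

    # -- accessors ---------------------------------------------------------

    def __len__(self) -> int:
        return self.scheme.n_bins

    def _col(self, name: str) -> np.ndarray:
        return self.table[name].to_numpy(dtype=float)

    @property
    def h(self) -> np.ndarray:
        return self._col("h")

    @property
    def S(self) -> np.ndarray:
        return self._col("S")

    @property
    def F(self) -> np.ndarray:
        """Cumulative distribution F(t) = 1 - S(t)."""
        return 1.0 - self.S

    @property
    def P(self) -> np.ndarray:
        return self._col("P")

    @property
    def ca(self) -> np.ndarray:
        return self._col("ca")

    @property
    def se_h(self) -> np.ndarray:
        return self._col("se_h")

    @property
    def se_S(self) -> np.ndarray:
        return self._col("se_S")

    @property
    def se_P(self) -> np.ndarray:
        return self._col("se_P")

    @property
    def se_ca(self) -> np.ndarray:
        return self._col("se_ca")

    @property
    def n_trials(self) -> int:
        return int(self.table["RS"].iloc[0])

    def to_frame(self, formatted: bool = False, decimals: int = 3,
                 ca_decimals: int = 2) -> pd.DataFrame:
        """Export with the standard life-table column order.

        With ``formatted=True`` probabilities and standard errors are rounded
        for display (``decimals`` places; conditional accuracy to
        ``ca_decimals``); otherwise values are kept at full precision.
        """
        out = self.table.reset_index()
        out.insert(0, "bin", self.scheme.labels)
        cols = ["bin", "t", "rc", "E", "RS", "h", "se_h", "S", "se_S",
                "P", "se_P", "n_correct", "n_error", "ca", "se_ca"]
        out = out[cols]
        if formatted:
            for c in ("h", "se_h", "S", "se_S", "P", "se_P", "se_ca"):
                out[c] = out[c].round(decimals)
            out["ca"] = out["ca"].round(ca_decimals)
        return out


def estimate_lifetable(counts: pd.DataFrame, scheme: BinningScheme) -> LifeTable:
    """Functional alias for :meth:`LifeTable.from_counts`."""
    return LifeTable.from_counts(counts, scheme)


def diff_curves(a: LifeTable, b: LifeTable, which: str = "h") -> pd.DataFrame:
    """Per-bin difference curve ``a - b`` for hazard or conditional accuracy.

    The two tables must share a binning scheme. Standard errors combine in
    quadrature: ``se_diff = sqrt(se_a^2 + se_b^2)``. Bins where either input
    is NaN are NaN.
    """
    if which not in ("h", "ca"):
        raise ValueError("which must be 'h' or 'ca'")
    if a.scheme != b.scheme:
        raise ValueError("life tables use different binning schemes")
    va, vb = getattr(a, which), getattr(b, which)
    sa, sb = getattr(a, f"se_{which}"), getattr(b, f"se_{which}")
    return pd.DataFrame(
        {
            "diff": va - vb,
            "se_diff": np.sqrt(sa**2 + sb**2),
        },
        index=pd.RangeIndex(1, a.scheme.n_bins + 1, name="t"),
    )
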