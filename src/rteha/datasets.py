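"""Bundled example data.

A per-bin count table from a masked-priming experiment: 220 trials of one
participant in the no-prime, no-mask condition of a speeded two-choice
arrow-discrimination task with a 600 ms response deadline, binned into
15 bins of 40 ms. Four trials had no response by the deadline and are
right-censored. This is the canonical worked example for life-table
arithmetic: every descriptive function and its standard error can be checked
by hand from these counts.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .lifetable import BinningScheme, LifeTable, TrialRecord

__all__ = [
    "masked_priming_scheme",
    "masked_priming_counts",
    "masked_priming_trials",
    "masked_priming_lifetable",
]

# per-bin counts, t = 1..15: events, right-censored, correct responses
_E = [0, 0, 0, 0, 0, 0, 7, 13, 26, 40, 48, 37, 32, 9, 4]
_RC = [0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 4]
_N_CORRECT = [0, 0, 0, 0, 0, 0, 2, 10, 24, 40, 47, 37, 32, 9, 4]


def masked_priming_scheme() -> BinningScheme:
    """15 bins of 40 ms covering the (0, 600] ms response window."""
    return BinningScheme.from_width(40.0, 600.0)


def masked_priming_counts() -> pd.DataFrame:
    """Per-bin counts (E, rc, n_correct, n_error) for the 220-trial example."""
    E = np.array(_E)
    nc = np.array(_N_CORRECT)
    return pd.DataFrame(
        {"E": E, "rc": np.array(_RC), "n_correct": nc, "n_error": E - nc},
        index=pd.RangeIndex(1, 16, name="t"),
    )


def masked_priming_trials() -> list[TrialRecord]:
    """The 220 example trials reconstructed at bin midpoints.

    Exact within-bin response times are not part of the example; placing
    each response at its bin midpoint reproduces the count table exactly
    under the 40 ms scheme.
    """
    scheme = masked_priming_scheme()
    mids = scheme.midpoints
    trials: list[TrialRecord] = []
    for t in range(15):
        for _ in range(_N_CORRECT[t]):
            trials.append(TrialRecord("P6", ("NP", "NM"), float(mids[t]), 1))
        for _ in range(_E[t] - _N_CORRECT[t]):
            trials.append(TrialRecord("P6", ("NP", "NM"), float(mids[t]), 0))
    for _ in range(sum(_RC)):
        trials.append(TrialRecord("P6", ("NP", "NM"), None, None))
    return trials


def masked_priming_lifetable() -> LifeTable:
    """The fully estimated life table for the example counts."""
    return LifeTable.from_counts(masked_priming_counts(), masked_priming_scheme())
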