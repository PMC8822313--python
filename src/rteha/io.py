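"""Trial CSV ingestion and life-table export.

Trial files are delimited text with one row per trial: a ``participant``
column, zero or more factor columns naming the experimental condition, an
``rt_ms`` column (empty = right-censored at the deadline) and a ``correct``
column (0/1, empty exactly when rt is empty). Response times recorded after
the deadline are converted to censored at ingestion, with a logged count —
under a fixed-deadline design they carry the same information.

Life tables are exported with the standard column set
``bin, t, rc, E, RS, h, se_h, S, se_S, P, se_P, n_correct, n_error, ca,
se_ca``; full precision by default so a write/read round trip is lossless,
with optional display rounding.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .lifetable import BinningScheme, LifeTable, TrialRecord

__all__ = ["RunConfig", "read_trials", "write_lifetable", "read_lifetable"]

log = logging.getLogger("rteha")

REQUIRED_COLUMNS = ("participant", "rt_ms", "correct")


@dataclass
class RunConfig:
    """Ingestion and analysis settings shared by the CLI commands."""

    censor_at: float = 600.0
    bin_width: float | None = 40.0
    edges: tuple[float, ...] | None = None
    factors: tuple[str, ...] = ()
    pooled: bool = False
    link: str = "cloglog"
    time_degree: int = 3
    roi: tuple[int, int] | None = None
    seed: int | None = None
    fail_fast: bool = True

    def scheme(self) -> BinningScheme:
        if self.edges is not None:
            return BinningScheme(tuple(self.edges))
        if self.bin_width is None:
            raise ValueError("either bin_width or explicit edges is required")
        return BinningScheme.from_width(self.bin_width, self.censor_at)


def read_trials(
    path: str | Path, config: RunConfig
) -> dict[tuple, list[TrialRecord]]:
    """Read a trial CSV, validate rows, and group by participant × condition.

    Returns a dict keyed by ``(participant, condition_tuple)``. Rows with an
    rt above the deadline are converted to censored (count logged). Invalid
    rows (rt <= 0, correctness missing for an observed response or present
    for a censored one) raise with per-row diagnostics when
    ``config.fail_fast``; otherwise they are dropped with a warning.
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    missing += [c for c in config.factors if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")

    groups: dict[tuple, list[TrialRecord]] = {}
    n_late = 0
    problems: list[str] = []
    for idx, row in df.iterrows():
        rt = row["rt_ms"]
        correct = row["correct"]
        cond = tuple(str(row[f]) for f in config.factors)
        rt_missing = pd.isna(rt)
        c_missing = pd.isna(correct)
        if not rt_missing and float(rt) > config.censor_at:
            n_late += 1
            rt_missing = c_missing = True  # late response -> censored
        try:
            if rt_missing:
                if not c_missing:
                    raise ValueError("correct present but rt censored")
                rec = TrialRecord(str(row["participant"]), cond, None, None)
            else:
                if c_missing:
                    raise ValueError("correct missing for an observed response")
                rec = TrialRecord(
                    str(row["participant"]), cond, float(rt), int(correct)
                )
        except (ValueError, TypeError) as exc:
            problems.append(f"row {idx}: {exc}")
            continue
        groups.setdefault(rec.stratum, []).append(rec)

    if n_late:
        log.warning("%s: %d responses after the %g ms deadline converted to censored",
                    path.name, n_late, config.censor_at)
    if problems:
        msg = f"{path}: {len(problems)} invalid rows: " + "; ".join(problems[:10])
        if config.fail_fast:
            raise ValueError(msg)
        log.warning(msg)
    if not groups:
        raise ValueError(f"{path}: no valid trials")
    return groups


def write_lifetable(
    lt: LifeTable,
    path: str | Path,
    formatted: bool = False,
    decimals: int = 3,
    ca_decimals: int = 2,
) -> None:
    """Write a life table as CSV (full precision unless ``formatted``)."""
    frame = lt.to_frame(formatted=formatted, decimals=decimals,
                        ca_decimals=ca_decimals)
    # %.17g round-trips IEEE doubles exactly; formatting happens only on request
    frame.to_csv(path, index=False,
                 float_format=None if formatted else "%.17g")


def read_lifetable(path: str | Path) -> LifeTable:
    """Read back a life-table CSV written at full precision."""
    df = pd.read_csv(path, float_precision="round_trip")
    edges = [0.0]
    for label in df["bin"]:
        edges.append(float(label.strip("(]").split(",")[1]))
    scheme = BinningScheme(tuple(edges))
    table = df.drop(columns=["bin"]).set_index("t")
    return LifeTable(scheme=scheme, table=table)
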