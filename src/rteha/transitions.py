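"""Conditional-accuracy state-transition coding.

Compares two conditions (A = congruent, B = incongruent in a priming design)
bin by bin on their conditional-accuracy values and assigns one of eleven
state codes describing the momentary speed-accuracy pattern — e.g. an early
phase where every emitted response is driven by the prime (all-correct on
congruent / all-error on incongruent → positive congruency evidence), a
reversed phase, or a late all-correct state. The per-participant × per-bin
code matrix makes the onset and duration of such states visible across
participants without averaging their curves.

Codes (both conditions have responses in the bin):
  ``P``   ca_A = 1 and ca_B = 0 (extreme positive effect)
  ``N``   ca_A = 0 and ca_B = 1 (extreme negative effect)
  ``p``   ca_A - ca_B >= diff_threshold
  ``n``   ca_A - ca_B <= -diff_threshold
  ``all`` both ca > all_threshold
Responses in only one condition:
  ``cc`` / ``ic``  only A responds, all correct / all error
  ``ci`` / ``ii``  only B responds, all correct / all error
``x`` no responses in either condition; ``?`` anything else.

Exact-extreme codes take precedence over threshold codes, which take
precedence over ``all``; the rules are applied in that order so each cell
gets exactly one, most specific, label.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CODES",
    "DEFAULT_COLOR_CLASSES",
    "code_bin",
    "code_matrix",
    "TransitionCodeMatrix",
]

CODES = ("P", "p", "N", "n", "all", "cc", "ii", "ic", "ci", "x", "?")

#: Evidence class per code: positive-effect codes, negative-effect codes,
#: the no-evidence "all correct" state, and everything else. The mapping for
#: the single-condition codes follows the sign of the implied effect
#: (cc/ii favor a positive congruency effect, ic/ci a negative one) and can
#: be overridden via ``color_classes``.
DEFAULT_COLOR_CLASSES: dict[str, str] = {
    "P": "PCE-evidence",
    "p": "PCE-evidence",
    "cc": "PCE-evidence",
    "ii": "PCE-evidence",
    "N": "NCE-evidence",
    "n": "NCE-evidence",
    "ic": "NCE-evidence",
    "ci": "NCE-evidence",
    "all": "no-evidence",
    "x": "other",
    "?": "other",
}


def _is_na(x) -> bool:
    return x is None or (isinstance(x, float) and math.isnan(x))


def code_bin(
    ca_a: float | None,
    ca_b: float | None,
    has_a: bool | None = None,
    has_b: bool | None = None,
    diff_threshold: float = 0.2,
    all_threshold: float = 0.8,
) -> str:
    """Code one bin's conditional-accuracy comparison.

    ``ca_a``/``ca_b`` are the conditional accuracies (NaN/None when the
    condition has no responses in the bin); ``has_a``/``has_b`` may be given
    explicitly and must agree with the NA pattern. Total: every input maps to
    exactly one code.
    """
    if not (0 < diff_threshold < 1 and 0 < all_threshold < 1):
        raise ValueError("thresholds must lie in (0, 1)")
    if has_a is None:
        has_a = not _is_na(ca_a)
    if has_b is None:
        has_b = not _is_na(ca_b)
    if has_a != (not _is_na(ca_a)) or has_b != (not _is_na(ca_b)):
        raise ValueError("presence flags disagree with NA pattern of ca values")

    if has_a and has_b:
        if ca_a == 1 and ca_b == 0:
            return "P"
        if ca_a == 0 and ca_b == 1:
            return "N"
        d = ca_a - ca_b
        if d >= diff_threshold:
            return "p"
        if d <= -diff_threshold:
            return "n"
        if ca_a > all_threshold and ca_b > all_threshold:
            return "all"
        return "?"
    if has_a:
        if ca_a == 1:
            return "cc"
        if ca_a == 0:
            return "ic"
        return "?"
    if has_b:
        if ca_b == 1:
            return "ci"
        if ca_b == 0:
            return "ii"
        return "?"
    return "x"


@dataclass
class TransitionCodeMatrix:
    """Participants × bins grid of transition codes with evidence classes."""

    codes: pd.DataFrame
    color_classes: dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_COLOR_CLASSES)
    )

    @property
    def colors(self) -> pd.DataFrame:
        return self.codes.apply(lambda col: col.map(self.color_classes))

    def to_long(self) -> pd.DataFrame:
        long = (
            self.codes.stack()
            .rename("code")
            .reset_index()
            .rename(columns={"level_0": "participant", "level_1": "t"})
        )
        long.columns = ["participant", "t", "code"]
        long["color_class"] = long["code"].map(self.color_classes)
        return long


def code_matrix(
    profiles: Mapping[str, tuple[Sequence[float], Sequence[float]]],
    diff_threshold: float = 0.2,
    all_threshold: float = 0.8,
    color_classes: Mapping[str, str] | None = None,
) -> TransitionCodeMatrix:
    """Code every participant × bin cell.

    ``profiles`` maps participant id to a pair ``(ca_A, ca_B)`` of per-bin
    conditional-accuracy sequences (NaN = no responses). All participants
    must share the bin count.
    """
    lengths = {pid: len(a) for pid, (a, b) in profiles.items()}
    for pid, (a, b) in profiles.items():
        if len(a) != len(b):
            raise ValueError(f"participant {pid}: ca_A and ca_B lengths differ")
    if len(set(lengths.values())) > 1:
        raise ValueError(f"participants have mismatched bin counts: {lengths}")

    rows = {}
    for pid, (a, b) in profiles.items():
        rows[pid] = [
            code_bin(
                float(x) if x is not None else math.nan,
                float(y) if y is not None else math.nan,
                diff_threshold=diff_threshold,
                all_threshold=all_threshold,
            )
            for x, y in zip(a, b)
        ]
    K = next(iter(lengths.values())) if lengths else 0
    codes = pd.DataFrame.from_dict(
        rows, orient="index", columns=pd.RangeIndex(1, K + 1, name="t")
    )
    codes.index.name = "participant"
    cc = dict(DEFAULT_COLOR_CLASSES)
    if color_classes:
        cc.update(color_classes)
    return TransitionCodeMatrix(codes=codes, color_classes=cc)
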