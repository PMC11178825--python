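"""Editing-window aggregation across target sites.

Per-position efficiencies from many target sites are averaged — at each
protospacer position, over only those sites whose reference base admits
the conversion — and the editing window of a conversion type is inferred
as the maximal contiguous run of positions whose mean efficiency reaches
a fraction (default one half) of the peak position's mean.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .amplicon import TRACKED_CONVERSIONS, PositionProfile
from .sites import PROTOSPACER_LEN

DEFAULT_THRESHOLD_FRACTION = 0.5


class NoWindowError(ValueError):
    """All position means are zero (or undefined); no window can be inferred."""


@dataclass
class WindowSummary:
    """Mean editing efficiency per position and conversion across sites.

    ``table`` columns: position, conversion, mean, sem, n.  The SEM uses
    the sample standard deviation (n-1 denominator) and is NaN for n < 2;
    mean is NaN where no site is eligible.
    """

    table: pd.DataFrame

    def means(self, conversion: str) -> pd.Series:
        sub = self.table[self.table.conversion == conversion]
        return sub.set_index("position")["mean"].reindex(range(1, PROTOSPACER_LEN + 1))


def aggregate_positions(profiles: Sequence[PositionProfile]) -> WindowSummary:
    """Average per-position efficiencies across sites, per conversion.

    A site contributes to (position, conversion) only when its reference
    base at that position admits the conversion (so its PositionProfile
    carries a row there).  Order of sites is irrelevant.
    """
    if not profiles:
        raise ValueError("need at least one position profile")
    rows = []
    for conv in TRACKED_CONVERSIONS:
        for pos in range(1, PROTOSPACER_LEN + 1):
            vals = []
            for prof in profiles:
                sub = prof.table[(prof.table.position == pos)
                                 & (prof.table.conversion == conv)]
                if not sub.empty and not math.isnan(sub.efficiency.iloc[0]):
                    vals.append(float(sub.efficiency.iloc[0]))
            n = len(vals)
            mean = float(np.mean(vals)) if n else float("nan")
            sem = float(np.std(vals, ddof=1) / math.sqrt(n)) if n >= 2 else float("nan")
            rows.append({"position": pos, "conversion": conv,
                         "mean": mean, "sem": sem, "n": n})
    return WindowSummary(table=pd.DataFrame(rows))


def infer_window(summary: WindowSummary, conversion: str,
                 threshold_fraction: float = DEFAULT_THRESHOLD_FRACTION,
                 ) -> tuple[int, int]:
    """Infer the editing window of one conversion type.

    The window is the maximal contiguous run of positions whose mean
    efficiency is at least ``threshold_fraction`` times the maximum
    position mean; among runs tying in length, the one containing the
    argmax wins.  Positions with no eligible site break contiguity.
    """
    if not 0 < threshold_fraction <= 1:
        raise ValueError("threshold_fraction must lie in (0, 1]")
    means = summary.means(conversion)
    defined = means.dropna()
    if defined.empty or float(defined.max()) <= 0:
        raise NoWindowError(f"no nonzero {conversion} mean at any position")
    peak = float(defined.max())
    argmax = int(defined.idxmax())
    cutoff = threshold_fraction * peak
    qualifying = [int(p) for p, m in means.items()
                  if not math.isnan(m) and m >= cutoff]

    runs: list[tuple[int, int]] = []
    for pos in qualifying:
        if runs and pos == runs[-1][1] + 1:
            runs[-1] = (runs[-1][0], pos)
        else:
            runs.append((pos, pos))
    best_len = max(hi - lo for lo, hi in runs)
    longest = [(lo, hi) for lo, hi in runs if hi - lo == best_len]
    for lo, hi in longest:
        if lo <= argmax <= hi:
            return (lo, hi)
    return longest[0]


def infer_all_windows(summary: WindowSummary,
                      threshold_fraction: float = DEFAULT_THRESHOLD_FRACTION,
                      ) -> dict[str, tuple[int, int] | None]:
    """Windows for every tracked conversion; None where no window exists."""
    out: dict[str, tuple[int, int] | None] = {}
    for conv in TRACKED_CONVERSIONS:
        try:
            out[conv] = infer_window(summary, conv, threshold_fraction)
        except NoWindowError:
            out[conv] = None
    return out
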