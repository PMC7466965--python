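"""Growth-rate extraction from plate-reader curves.

The rate statistic is the 98th percentile of OLS slopes fitted in
five-timepoint overlapping sliding windows, keeping only windows whose
Pearson correlation exceeds 0.8. Slopes are fitted on raw OD (no log
transform) in OD-per-hour units.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from brewtrace.errors import BrewtraceError
from brewtrace.types import GrowthCurve

DEFAULT_CONCENTRATIONS = (0, 2, 4, 6, 8, 10)  # mM CoCl2


@dataclass
class GrowthRate:
    rate: float
    n_windows_kept: int
    flagged: bool  # True when no window passed the correlation filter


def growth_rate(
    curve: GrowthCurve,
    window: int = 5,
    r_min: float = 0.8,
    percentile: float = 98.0,
) -> GrowthRate:
    """Sliding-window percentile growth rate.

    Every run of ``window`` consecutive timepoints contributes an OLS slope
    and a Pearson r; windows with zero OD variance get r := 0. The rate is
    the linear-interpolated ``percentile`` of slopes from windows with
    r > ``r_min`` (signed, so declining windows never pass). If no window
    passes, the rate is 0 and the result is flagged.
    """
    t, od = curve.times, curve.od
    n = len(t)
    if n < window:
        raise BrewtraceError(f"need at least {window} timepoints, got {n}")
    slopes = []
    for i in range(n - window + 1):
        tw, yw = t[i : i + window], od[i : i + window]
        tc = tw - tw.mean()
        yc = yw - yw.mean()
        sxx = float(tc @ tc)
        syy = float(yc @ yc)
        sxy = float(tc @ yc)
        slope = sxy / sxx
        r = sxy / np.sqrt(sxx * syy) if syy > 0 else 0.0
        if r > r_min:
            slopes.append(slope)
    if not slopes:
        return GrowthRate(0.0, 0, True)
    rate = float(np.percentile(slopes, percentile, method="linear"))
    return GrowthRate(rate, len(slopes), False)


def dose_response(
    curves: Iterable[GrowthCurve],
    window: int = 5,
    r_min: float = 0.8,
    percentile: float = 98.0,
) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Aggregate replicate growth rates per strain x condition.

    Returns a table with mean rate, sd and replicate count per cell, and a
    per-condition ranking of strains by mean rate (best first).
    """
    rows = []
    for curve in curves:
        res = growth_rate(curve, window=window, r_min=r_min, percentile=percentile)
        rows.append(
            {"strain": curve.strain, "condition": curve.condition, "rate": res.rate}
        )
    if not rows:
        raise BrewtraceError("no growth curves supplied")
    df = pd.DataFrame(rows)
    table = (
        df.groupby(["strain", "condition"])["rate"]
        .agg(mean="mean", sd="std", n="count")
        .reset_index()
    )
    table["sd"] = table["sd"].fillna(0.0)
    ranking = {
        cond: list(sub.sort_values("mean", ascending=False)["strain"])
        for cond, sub in table.groupby("condition")
    }
    return table, ranking
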