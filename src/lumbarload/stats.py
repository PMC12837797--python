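"""Model comparison: percent-error factor grids and impulse statistics.

The factor grid tabulates percent error per muscle over three experimental
factors — specificity (general vs. specific), linearity (linear vs.
logarithmic) and contraction speed — with marginal means per factor level.
The grid is exported in long format so any standard statistical environment
can run the omnibus repeated-measures analysis; this module itself provides
the paired t-test and Shapiro-Wilk normality check used for impulse
comparisons, plus alignment of normalized load curves for plotting.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from ._exceptions import InputError
from .anthropometrics import CHANNELS

ALPHA = 0.05

_FACTORS = {
    "specificity": ("general", "specific"),
    "linearity": ("linear", "logarithmic"),
}


@dataclass
class FactorGrid:
    """Percent-error cell means and factor-level marginals.

    ``cells`` is indexed by (muscle, specificity, linearity, speed);
    ``marginals`` is long-format (muscle, factor, level, percent_error)
    where each marginal is the mean of its cells.
    """

    cells: pd.Series
    marginals: pd.DataFrame
    grand_mean: float


def build_factor_grid(records) -> FactorGrid:
    """Aggregate long-format percent-error records into the factor grid.

    ``records`` is a DataFrame (or list of dicts) with columns
    subject, muscle, specificity, linearity, speed, percent_error.
    Every muscle x specificity x linearity x speed cell must contain at
    least one record.
    """
    df = pd.DataFrame(records)
    required = {"muscle", "specificity", "linearity", "speed", "percent_error"}
    missing_cols = required - set(df.columns)
    if missing_cols:
        raise InputError(f"records missing columns: {sorted(missing_cols)}")
    speeds = sorted(df["speed"].unique())
    cells = df.groupby(["muscle", "specificity", "linearity", "speed"])["percent_error"].mean()
    expected = [
        (m, sp, lin, v)
        for m in CHANNELS
        for sp in _FACTORS["specificity"]
        for lin in _FACTORS["linearity"]
        for v in speeds
    ]
    missing = [combo for combo in expected if combo not in cells.index]
    if missing:
        raise InputError(f"factor grid incomplete; missing cells: {missing}")
    cells = cells.loc[expected]

    rows = []
    for muscle in CHANNELS:
        sub = cells.xs(muscle, level="muscle")
        for factor, level_name in (
            ("specificity", "specificity"),
            ("linearity", "linearity"),
            ("speed", "speed"),
        ):
            for level, group in sub.groupby(level=level_name):
                rows.append(
                    {
                        "muscle": muscle,
                        "factor": factor,
                        "level": level,
                        "percent_error": float(group.mean()),
                    }
                )
    return FactorGrid(
        cells=cells,
        marginals=pd.DataFrame(rows),
        grand_mean=float(cells.mean()),
    )


def paired_t_test(x, y) -> tuple[float, float]:
    """Two-tailed paired t-test on per-subject pairs; returns (t, p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise InputError("paired samples must have equal length")
    if x.size < 2:
        raise InputError("paired t-test needs at least 2 pairs")
    if np.std(x - y, ddof=1) == 0:
        raise InputError("zero variance of paired differences; t statistic undefined")
    result = sps.ttest_rel(x, y)
    return float(result.statistic), float(result.pvalue)


def normality_check(x) -> tuple[float, float]:
    """Shapiro-Wilk normality test; returns (W, p). Valid for 3 <= n <= 5000."""
    x = np.asarray(x, dtype=float)
    if not 3 <= x.size <= 5000:
        raise InputError(f"Shapiro-Wilk requires 3 <= n <= 5000, got n={x.size}")
    if np.ptp(x) == 0:
        raise InputError("constant sample; normality test undefined")
    w, p = sps.shapiro(x)
    return float(w), float(p)


def compare_load_curves(
    curves: Mapping[str, Sequence[float]], n_points: int = 101
) -> pd.DataFrame:
    """Align normalized load curves on a common percent-of-task grid.

    Each curve (any length >= 2, in %BW) is linearly resampled onto
    ``n_points`` spanning 0-100 %task; the result is a table ready for
    plotting or export, one column per model label.
    """
    grid = np.linspace(0.0, 100.0, n_points)
    out = pd.DataFrame({"percent_task": grid})
    for label, curve in curves.items():
        arr = np.asarray(curve, dtype=float)
        if arr.size < 2:
            raise InputError(f"curve {label!r} needs at least 2 points")
        src = np.linspace(0.0, 100.0, arr.size)
        resampled = np.interp(grid, src, arr)
        if resampled.size != n_points:
            raise InputError("internal resampling length mismatch")
        out[label] = resampled
    return out
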