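"""Rank-correlation decay curves and the robustness slope.

The question a removal simulation answers is not whether index values change
(they must), but whether plots keep their relative order: a study's biological
conclusions rest on which plots are more functionally diverse than which.
Accordingly, each reduction step is summarised by the Spearman rank
correlation between the per-plot index values computed from full data and
those computed at that step.  The decay of these correlations with remaining
relative abundance ``a`` is modelled as

    log(rho_s) = beta * (a_s - 1)

a through-origin regression whose fitted curve passes through rho = 1 at
a = 1 (no data removed).  The slope ``beta`` is the robustness: the less
negative, the slower rank information is lost.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateInputError, ValidationError


def spearman(x, y) -> float:
    """Spearman rank correlation: Pearson correlation of average ranks."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("spearman needs two equal-length 1-D vectors")
    if x.size < 2:
        raise ValidationError("spearman needs at least 2 observations")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        raise DegenerateInputError("rank correlation undefined: zero rank variance")
    return float(stats.spearmanr(x, y).statistic)


@dataclass
class RobustnessCurve:
    """Per-step remaining abundance, rank correlation, and usable plot count."""

    label: str
    remaining: np.ndarray  # a_s, step 0 first (a_0 = 1)
    rho: np.ndarray        # NaN where undefined or < 3 usable plots
    n_plots: np.ndarray

    def usable(self) -> np.ndarray:
        return ~np.isnan(self.rho)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"label": self.label, "remaining": self.remaining,
             "rho": self.rho, "n_plots": self.n_plots}
        )


@dataclass
class RobustnessSlope:
    """Through-origin slope of log(rho) on (remaining - 1)."""

    label: str
    slope: float
    n_steps: int
    n_excluded_nonpositive: int = 0
    n_excluded_undefined: int = 0
    log_base: str = field(default="natural", repr=False)


def robustness_curve(
    full_values,
    stepped_values: pd.DataFrame,
    remaining,
    label: str = "",
    min_plots: int = 3,
) -> RobustnessCurve:
    """Correlate each step's plot ranking with the full-data ranking.

    Parameters
    ----------
    full_values:
        Per-plot index values from the complete data (Series or mapping).
    stepped_values:
        DataFrame with one row per step (ordered, step 0 first) and one
        column per plot; NaN marks a plot whose index was not computable at
        that step.  Such plots are excluded pairwise from that step's
        correlation, with the usable count recorded.
    remaining:
        Remaining relative abundance per step, aligned with the rows.
    """
    full = pd.Series(full_values).astype(float)
    remaining = np.asarray(remaining, dtype=float)
    if stepped_values.shape[0] != remaining.size:
        raise ValidationError("stepped_values rows and remaining steps differ")
    missing = [p for p in stepped_values.columns if p not in full.index]
    if missing:
        raise ValidationError(f"plots without full-data values: {missing}")

    rho = np.full(remaining.size, np.nan)
    n_plots = np.zeros(remaining.size, dtype=int)
    for s in range(remaining.size):
        row = stepped_values.iloc[s]
        mask = row.notna() & full.reindex(row.index).notna()
        n = int(mask.sum())
        n_plots[s] = n
        if n < min_plots:
            continue
        try:
            rho[s] = spearman(full.reindex(row.index)[mask].to_numpy(),
                              row[mask].to_numpy())
        except DegenerateInputError:
            continue
    if not np.isfinite(rho).any():
        raise DegenerateInputError(
            f"curve {label!r} unusable: fewer than {min_plots} computable plots at every step"
        )
    return RobustnessCurve(label, remaining, rho, n_plots)


def fit_slope(curve: RobustnessCurve) -> RobustnessSlope:
    """Least-squares slope of log(rho_s) = beta * (a_s - 1), no intercept.

    Forcing the fit through (a = 1, rho = 1) encodes the theoretical starting
    point — nothing removed, ranking intact — and makes slopes comparable
    across configurations.  Steps with rho <= 0 (log undefined) or an
    undefined rho are excluded and counted, never clamped.
    """
    a = curve.remaining
    rho = curve.rho
    undefined = np.isnan(rho)
    nonpositive = ~undefined & (rho <= 0)
    use = ~undefined & ~nonpositive
    x = a[use] - 1.0
    y = np.log(rho[use])
    informative = int((x != 0).sum())
    if informative < 1 or use.sum() < 2:
        raise DegenerateInputError("fit_slope needs at least 2 usable steps with rho > 0")
    denom = float(np.dot(x, x))
    if denom == 0:
        raise DegenerateInputError("all usable steps are at remaining = 1; slope undefined")
    beta = float(np.dot(x, y) / denom)
    return RobustnessSlope(
        curve.label, beta, int(use.sum()),
        n_excluded_nonpositive=int(nonpositive.sum()),
        n_excluded_undefined=int(undefined.sum()),
    )
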