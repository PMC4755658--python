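"""Trait-coverage assessment and sampling prioritisation.

Before a field or database campaign, one wants to know how much of each
community's relative abundance is already represented by species with
measured traits, and — if below a target such as the common 80% rule of
thumb — which species to measure next.  Coverage can be judged pool-wise
(across all plots) or plot-wise (each plot separately); neither is
universally better, so both are offered.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .community import AvailabilityMask, CommunityMatrix, relative_abundances
from .errors import ValidationError

DEFAULT_THRESHOLD = 0.8


def _species_flags(cm: CommunityMatrix, mask: AvailabilityMask, mode: str) -> np.ndarray:
    flags = mask.species_available(mode)
    missing = [s for s in cm.species_ids if s not in flags.index]
    if missing:
        # species absent from the mask are unavailable by definition
        flags = pd.concat([flags, pd.Series(False, index=missing)])
    return flags.reindex(cm.species_ids).to_numpy(dtype=bool)


def coverage(
    cm: CommunityMatrix,
    mask: AvailabilityMask,
    scenario: str = "plotwise",
    mode: str = "all",
) -> pd.Series:
    """Share of relative abundance covered by trait-available species.

    ``mode`` decides when a species counts as available: ``"all"`` (strict,
    default) requires every masked trait, ``"any"`` at least one.  Returns a
    per-plot Series for ``plotwise`` or a single-entry Series (``"pool"``)
    for ``poolwise``.
    """
    avail = _species_flags(cm, mask, mode)
    if scenario == "plotwise":
        values = [
            float(relative_abundances(cm.data.iloc[pi].to_numpy())[avail].sum())
            for pi in range(cm.n_plots)
        ]
        return pd.Series(values, index=cm.plot_ids, name="coverage")
    if scenario == "poolwise":
        pool = relative_abundances(cm.pool_abundances().to_numpy())
        return pd.Series([float(pool[avail].sum())], index=["pool"], name="coverage")
    raise ValidationError(f"scenario must be plotwise|poolwise, got {scenario!r}")


@dataclass
class PriorityList:
    """Greedy sampling plan for one unit (plot or pool)."""

    unit: object
    coverage_before: float
    species: list            # descending-abundance additions
    coverage_after: list     # cumulative coverage after each addition

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"unit": self.unit, "species": self.species,
             "cumulative_coverage": self.coverage_after,
             "coverage_before": self.coverage_before}
        )


def _greedy(p: np.ndarray, avail: np.ndarray, species_ids: list,
            threshold: float, unit) -> PriorityList:
    before = float(p[avail].sum())
    order = sorted(
        (i for i in range(len(p)) if not avail[i] and p[i] > 0),
        key=lambda i: (-p[i], str(species_ids[i])),
    )
    chosen, cumulative = [], []
    cov = before
    for i in order:
        if cov >= threshold - 1e-12:
            break
        cov += float(p[i])
        chosen.append(species_ids[i])
        cumulative.append(cov)
    return PriorityList(unit, before, chosen, cumulative)


def priority_species(
    cm: CommunityMatrix,
    mask: AvailabilityMask,
    scenario: str = "plotwise",
    threshold: float = DEFAULT_THRESHOLD,
    mode: str = "all",
) -> list[PriorityList]:
    """Species to measure next, most abundant first, until coverage >= threshold.

    ``poolwise`` returns a single list over the pooled abundances.
    ``plotwise`` returns one list per plot plus a union list (unit
    ``"union"``) of every species needed anywhere, ordered by how many plots
    each helps and then by pooled abundance — a convenient overall campaign
    order.  The union list's coverage fields refer to the pool.
    """
    if not (0 < threshold <= 1):
        raise ValidationError(f"threshold must be in (0, 1], got {threshold}")
    avail = _species_flags(cm, mask, mode)
    pool = relative_abundances(cm.pool_abundances().to_numpy())
    if scenario == "poolwise":
        return [_greedy(pool, avail, cm.species_ids, threshold, "pool")]
    if scenario != "plotwise":
        raise ValidationError(f"scenario must be plotwise|poolwise, got {scenario!r}")
    lists = [
        _greedy(relative_abundances(cm.data.iloc[pi].to_numpy()), avail,
                cm.species_ids, threshold, plot)
        for pi, plot in enumerate(cm.plot_ids)
    ]
    counts: dict = {}
    for pl in lists:
        for sp in pl.species:
            counts[sp] = counts.get(sp, 0) + 1
    union_order = sorted(
        counts,
        key=lambda sp: (-counts[sp], -pool[cm.species_ids.index(sp)], str(sp)),
    )
    cov = float(pool[avail].sum())
    cumulative = []
    for sp in union_order:
        cov += float(pool[cm.species_ids.index(sp)])
        cumulative.append(cov)
    lists.append(PriorityList("union", float(pool[avail].sum()), union_order, cumulative))
    return lists
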