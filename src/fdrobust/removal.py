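"""Progressive trait-data-loss simulation by fractional relative-abundance steps.

Missing trait data is emulated by deleting species trait information
rarest-first, in steps that each consume a fixed slice (default 0.5%) of
relative abundance, until only a floor share (default 50%) remains.  Removing
a fixed slice of abundance — rather than one species at a time — makes the
remaining abundance a comparable continuous variable across communities with
very different dominance-diversity structure.  A species whose relative
abundance exceeds what is left of a step's budget is split across steps, so a
step can end mid-species.

Two scenarios are supported: ``plotwise`` ranks and removes species within
each plot independently; ``poolwise`` ranks species by their pooled relative
abundance over all plots and projects each species' removed fraction into
every plot containing it (so plots lacking the removed species are
unaffected at that step).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .community import (
    CommunityMatrix,
    relative_abundances,
    round_relative,
    transform_abundance,
)
from .errors import DegenerateInputError, ValidationError

_TOL = 1e-12


@dataclass
class RemovalSchedule:
    """Cumulative removal state for every step, plot and species.

    Attributes
    ----------
    scenario:
        ``"plotwise"`` or ``"poolwise"``.
    step_size, floor:
        Share of relative abundance removed per step, and the share at which
        removal stops (remaining <= floor).
    relative:
        (n_plots, n_species) base relative abundances per plot (after any
        abundance transform and optional display rounding).
    fractions:
        (n_steps + 1, n_plots, n_species) cumulative fraction of each
        species' relative abundance removed; step 0 is all zeros.
    """

    scenario: str
    step_size: float
    floor: float
    plot_ids: list
    species_ids: list
    relative: np.ndarray
    fractions: np.ndarray
    abundance_transform: str = "none"

    @property
    def n_steps(self) -> int:
        """Number of reduction steps (excluding the untouched step 0)."""
        return self.fractions.shape[0] - 1

    def removed_amount(self, step: int) -> np.ndarray:
        """(n_plots, n_species) relative abundance removed up to ``step``."""
        return self.relative * self.fractions[step]

    def remaining_total(self, step: int) -> np.ndarray:
        """Per-plot remaining relative abundance (absolute units) at ``step``."""
        return self.relative.sum(axis=1) - self.removed_amount(step).sum(axis=1)

    def remaining_share(self, step: int) -> np.ndarray:
        """Per-plot share of the plot's total relative abundance remaining."""
        return self.remaining_total(step) / self.relative.sum(axis=1)

    def n_fully_removed(self, step: int) -> np.ndarray:
        """Per-plot count of species whose abundance is entirely consumed."""
        full = (self.fractions[step] >= 1.0 - 1e-9) & (self.relative > 0)
        return full.sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        """Long format: step, plot, species, cumulative_removed_fraction,
        remaining_total (share of plot total)."""
        rows = []
        for s in range(self.n_steps + 1):
            share = self.remaining_share(s)
            for pi, plot in enumerate(self.plot_ids):
                for si, sp in enumerate(self.species_ids):
                    if self.relative[pi, si] > 0:
                        rows.append(
                            (s, plot, sp, self.fractions[s, pi, si], share[pi])
                        )
        return pd.DataFrame(
            rows,
            columns=["step", "plot", "species",
                     "cumulative_removed_fraction", "remaining_total"],
        )


# ---------------------------------------------------------------------------
# the step walker
# ---------------------------------------------------------------------------

def _removal_order(p: np.ndarray, species_ids: list) -> list[int]:
    """Ascending abundance, ties broken by lexicographic species id."""
    return sorted(range(len(p)), key=lambda i: (p[i], str(species_ids[i])))


def _walk(p: np.ndarray, species_ids: list, step_size: float, floor: float) -> list[np.ndarray]:
    """Cumulative removed amounts after each step for one ranking unit.

    Each step consumes ``step_size`` of relative abundance walking the
    ascending-ordered species, splitting a species when it exceeds the budget
    remainder; a final partial step lands exactly on the floor.
    """
    total = p.sum()
    if total <= 0:
        raise DegenerateInputError("cannot build a removal schedule on zero abundance")
    order = _removal_order(p, species_ids)
    target = total * (1.0 - floor)
    removed = np.zeros_like(p)
    removed_total = 0.0
    steps: list[np.ndarray] = []
    while removed_total < target - _TOL:
        budget = min(step_size, target - removed_total)
        for idx in order:
            avail = p[idx] - removed[idx]
            if avail <= _TOL:
                continue
            take = min(avail, budget)
            removed[idx] += take
            budget -= take
            if budget <= _TOL:
                break
        removed_total = float(removed.sum())
        steps.append(removed.copy())
    return steps


def _fractions(p: np.ndarray, removed_steps: list[np.ndarray]) -> np.ndarray:
    out = np.zeros((len(removed_steps) + 1, p.size))
    safe = np.where(p > 0, p, 1.0)
    for s, removed in enumerate(removed_steps, start=1):
        out[s] = np.where(p > 0, np.minimum(removed / safe, 1.0), 0.0)
    return out


def _plot_relatives(
    cm: CommunityMatrix, abundance_transform: str, round_digits: int | None
) -> np.ndarray:
    rel = np.zeros_like(cm.data.to_numpy(dtype=float))
    for pi in range(cm.n_plots):
        x = transform_abundance(cm.data.iloc[pi].to_numpy(dtype=float), abundance_transform)
        p = relative_abundances(x)
        if round_digits is not None:
            p = round_relative(p, round_digits)
        rel[pi] = p
    return rel


def _validate_steps(step_size: float, floor: float) -> None:
    if not (0 < step_size < 1):
        raise ValidationError(f"step_size must be in (0, 1), got {step_size}")
    if not (0 <= floor < 1):
        raise ValidationError(f"floor must be in [0, 1), got {floor}")


def removal_schedule_plotwise(
    cm: CommunityMatrix,
    step_size: float = 0.005,
    floor: float = 0.5,
    abundance_transform: str = "none",
    round_digits: int | None = None,
) -> RemovalSchedule:
    """Rank species within each plot and remove rarest-first per plot.

    ``round_digits`` rounds the relative abundances before scheduling; it
    exists to reproduce printed low-precision walkthroughs and should stay
    ``None`` for analysis.
    """
    _validate_steps(step_size, floor)
    rel = _plot_relatives(cm, abundance_transform, round_digits)
    per_plot: list[np.ndarray] = []
    for pi, plot in enumerate(cm.plot_ids):
        p = rel[pi]
        if p.sum() <= 0:
            warnings.warn(f"plot {plot!r} has no abundance after rounding; skipped")
            per_plot.append(np.zeros((1, p.size)))
            continue
        per_plot.append(_fractions(p, _walk(p, cm.species_ids, step_size, floor)))
    n_steps = max(f.shape[0] for f in per_plot)
    fractions = np.zeros((n_steps, cm.n_plots, cm.n_species))
    for pi, f in enumerate(per_plot):
        fractions[: f.shape[0], pi] = f
        fractions[f.shape[0]:, pi] = f[-1]  # plots that finished early hold state
    return RemovalSchedule(
        "plotwise", step_size, floor, cm.plot_ids, cm.species_ids, rel, fractions,
        abundance_transform,
    )


def removal_schedule_poolwise(
    cm: CommunityMatrix,
    step_size: float = 0.005,
    floor: float = 0.5,
    abundance_transform: str = "none",
    round_digits: int | None = None,
) -> RemovalSchedule:
    """Rank species by pooled relative abundance and project removal to plots.

    Pool relative abundance is each species' summed (transformed) abundance
    over the grand total.  A species fractionally removed at pool level is
    removed at the same fraction of its local relative abundance in every plot
    containing it; plots not containing it are unaffected at that step.
    On a single-plot dataset the schedule coincides exactly with the
    plot-wise one.
    """
    _validate_steps(step_size, floor)
    rel = _plot_relatives(cm, abundance_transform, round_digits)
    transformed = np.stack([
        transform_abundance(cm.data.iloc[pi].to_numpy(dtype=float), abundance_transform)
        for pi in range(cm.n_plots)
    ])
    pool_p = relative_abundances(transformed.sum(axis=0))
    if round_digits is not None:
        pool_p = round_relative(pool_p, round_digits)
    pool_fractions = _fractions(pool_p, _walk(pool_p, cm.species_ids, step_size, floor))
    fractions = np.repeat(pool_fractions[:, None, :], cm.n_plots, axis=1)
    return RemovalSchedule(
        "poolwise", step_size, floor, cm.plot_ids, cm.species_ids, rel, fractions,
        abundance_transform,
    )


# ---------------------------------------------------------------------------
# applying a step
# ---------------------------------------------------------------------------

def apply_step(
    schedule: RemovalSchedule,
    step: int,
    plot_id,
    partial: str = "weight",
) -> tuple[list, np.ndarray]:
    """Surviving species and renormalised proportions of one plot at ``step``.

    ``partial="weight"`` (default) keeps a partially removed species with its
    relative abundance scaled by the unremoved fraction; ``partial="drop"``
    excludes any species whose removal has begun.  Surviving proportions are
    renormalised to sum to 1; an emptied plot returns empty arrays (callers
    flag the indices as not computable).
    """
    if not (0 <= step <= schedule.n_steps):
        raise ValidationError(f"step {step} outside schedule (0..{schedule.n_steps})")
    if partial not in ("weight", "drop"):
        raise ValidationError("partial must be 'weight' or 'drop'")
    pi = schedule.plot_ids.index(plot_id)
    p = schedule.relative[pi]
    f = schedule.fractions[step, pi]
    if partial == "weight":
        w = p * (1.0 - f)
    else:
        w = np.where(f > _TOL, 0.0, p)
    keep = w > _TOL
    ids = [s for s, k in zip(schedule.species_ids, keep) if k]
    if not ids:
        return [], np.array([])
    return ids, w[keep] / w[keep].sum()
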