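"""End-to-end driver: indices per reduction step, curves, and slopes.

This realises the whole simulation loop — compute FD indices on full data,
remove trait data step by step (re-deriving Gower distances from the surviving
species each time), re-rank plots, correlate, and fit one robustness slope per
(scenario x index x trait set x transform) configuration.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .community import CommunityMatrix, TraitTable
from .errors import DegenerateInputError, ValidationError
from .indices import INDEX_NAMES, compute_all, results_to_frame
from .removal import RemovalSchedule, apply_step, removal_schedule_plotwise, removal_schedule_poolwise
from .robustness import RobustnessCurve, fit_slope, robustness_curve

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of one robustness run; every field has a safe default."""

    scenarios: list[str] = field(default_factory=lambda: ["plotwise"])
    step_size: float = 0.005
    floor: float = 0.5
    abundance_transforms: list[str] = field(default_factory=lambda: ["none"])
    trait_transforms: list[str] = field(default_factory=lambda: ["none"])
    trait_shift: float | None = None
    trait_sets: dict[str, list[str]] | None = None
    partial: str = "weight"
    max_axes: int = 6
    round_digits: int | None = None
    min_plots: int = 3
    seed: int = 0

    @classmethod
    def from_mapping(cls, mapping: dict) -> "RunConfig":
        valid = {f.name for f in dataclasses.fields(cls)}
        unknown = set(mapping) - valid
        if unknown:
            raise ValidationError(
                f"invalid config keys {sorted(unknown)}; valid keys: {sorted(valid)}"
            )
        return cls(**mapping)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


@dataclass
class RobustnessResults:
    """All tables produced by :func:`run_robustness`."""

    indices: pd.DataFrame   # per step x plot x index x trait set
    curves: pd.DataFrame    # per step rank correlations
    slopes: pd.DataFrame    # one row per configuration
    manifest: dict

    def write(self, outdir) -> None:
        from pathlib import Path

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.indices.to_csv(out / "indices.csv", index=False)
        self.curves.to_csv(out / "curves.csv", index=False)
        self.slopes.to_csv(out / "slopes.csv", index=False)
        (out / "manifest.json").write_text(json.dumps(self.manifest, indent=2, default=str))


def _unit_remaining(schedule: RemovalSchedule, step: int) -> float:
    """Remaining share used as the explanatory variable at this step."""
    return float(np.mean(schedule.remaining_share(step)))


def _default_trait_sets(traits: TraitTable) -> dict[str, list[str]]:
    sets = {t: [t] for t in traits.trait_names}
    if len(traits.trait_names) > 1:
        sets["all"] = list(traits.trait_names)
    return sets


def run_robustness(
    cm: CommunityMatrix,
    traits: TraitTable,
    config: RunConfig | None = None,
) -> RobustnessResults:
    """Run the full missing-trait-data simulation and fit robustness slopes.

    For every scenario and transform combination a removal schedule is built,
    all four indices are recomputed for every plot at every step (step 0 =
    full data), plots are ranked per step, and a through-origin slope of
    log rank-correlation on remaining abundance is fitted per index and trait
    set.  Curves with fewer than ``min_plots`` computable plots at every step,
    or slopes with fewer than 2 usable steps, are reported with NaN and a
    flag rather than dropped.
    """
    config = config or RunConfig()
    trait_sets = config.trait_sets or _default_trait_sets(traits)
    index_rows: list[pd.DataFrame] = []
    curve_rows: list[pd.DataFrame] = []
    slope_rows: list[dict] = []

    for scenario in config.scenarios:
        builder = {
            "plotwise": removal_schedule_plotwise,
            "poolwise": removal_schedule_poolwise,
        }.get(scenario)
        if builder is None:
            raise ValidationError(f"unknown scenario {scenario!r}")
        for ab_t in config.abundance_transforms:
            schedule = builder(cm, config.step_size, config.floor,
                               abundance_transform=ab_t,
                               round_digits=config.round_digits)
            for tr_t in config.trait_transforms:
                tagged = _run_one(cm, traits, schedule, trait_sets, ab_t, tr_t, config)
                index_rows.append(tagged["indices"])
                curve_rows.append(tagged["curves"])
                slope_rows.extend(tagged["slopes"])

    indices = pd.concat(index_rows, ignore_index=True)
    curves = pd.concat(curve_rows, ignore_index=True)
    slopes = pd.DataFrame(slope_rows)
    manifest = {
        "package": "fdrobust",
        "version": __version__,
        "config": config.to_dict(),
        "config_hash": config.digest(),
        "seed": config.seed,
        "log_base": "natural",
        "n_plots": cm.n_plots,
        "n_species": cm.n_species,
        "n_flagged_index_values": int(indices["flag"].notna().sum()),
    }
    return RobustnessResults(indices, curves, slopes, manifest)


def _run_one(cm, traits, schedule, trait_sets, ab_t, tr_t, config) -> dict:
    steps = range(schedule.n_steps + 1)
    frames = []
    for step in steps:
        remaining = _unit_remaining(schedule, step)
        for plot in cm.plot_ids:
            ids, weights = apply_step(schedule, step, plot, partial=config.partial)
            if ids:
                results = compute_all(
                    weights, traits, species_ids=ids, trait_sets=trait_sets,
                    abundance_transform="none",  # schedule weights are already transformed
                    trait_transform=tr_t, trait_shift=config.trait_shift,
                    max_axes=config.max_axes, plot_id=plot,
                )
                frame = results_to_frame(results)
            else:
                frame = pd.DataFrame(
                    [{"plot_id": plot, "index": name, "trait_set": label,
                      "value": np.nan, "flag": "plot emptied"}
                     for label in trait_sets for name in INDEX_NAMES]
                )
            frame.insert(0, "step", step)
            frame.insert(1, "remaining", remaining)
            frames.append(frame)
    indices = pd.concat(frames, ignore_index=True)
    indices["value"] = indices["value"].where(indices["flag"].isna(), np.nan)

    curve_frames = []
    slope_records = []
    remaining_by_step = np.array([_unit_remaining(schedule, s) for s in steps])
    for label in trait_sets:
        for name in INDEX_NAMES:
            sub = indices[(indices["index"] == name) & (indices["trait_set"] == label)]
            wide = sub.pivot_table(index="step", columns="plot_id", values="value",
                                   dropna=False)
            wide = wide.reindex(list(steps))
            tag = f"{schedule.scenario}|{name}|{label}|abun={ab_t}|trait={tr_t}"
            base = {
                "scenario": schedule.scenario, "index": name, "trait_set": label,
                "abundance_transform": ab_t, "trait_transform": tr_t,
            }
            try:
                full = wide.iloc[0]
                curve = robustness_curve(full, wide, remaining_by_step,
                                         label=tag, min_plots=config.min_plots)
                cf = curve.to_frame()
                cf.insert(0, "step", list(steps))
                for key, value in base.items():
                    cf[key] = value
                curve_frames.append(cf.drop(columns="label"))
                slope = fit_slope(curve)
                slope_records.append({
                    **base, "slope": slope.slope, "n_steps": slope.n_steps,
                    "n_excluded_nonpositive": slope.n_excluded_nonpositive,
                    "n_excluded_undefined": slope.n_excluded_undefined,
                    "flag": None,
                })
            except DegenerateInputError as exc:
                logger.info("configuration %s not usable: %s", tag, exc)
                slope_records.append({
                    **base, "slope": np.nan, "n_steps": 0,
                    "n_excluded_nonpositive": 0, "n_excluded_undefined": 0,
                    "flag": str(exc),
                })
    for frame in (indices,):
        frame["scenario"] = schedule.scenario
        frame["abundance_transform"] = ab_t
        frame["trait_transform"] = tr_t
    curves = (pd.concat(curve_frames, ignore_index=True) if curve_frames
              else pd.DataFrame(columns=["step", "remaining", "rho", "n_plots",
                                         "scenario", "index", "trait_set",
                                         "abundance_transform", "trait_transform"]))
    return {"indices": indices, "curves": curves, "slopes": slope_records}
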