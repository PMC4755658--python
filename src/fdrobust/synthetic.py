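"""Seeded generator of synthetic communities and traits.

Real community data of the kind the removal simulation targets share a few
statistical signatures: strongly right-skewed dominance-diversity curves
spanning orders of magnitude, moderate numbers of plots with species turnover
between them, positively skewed continuous traits (sometimes with a rare
species carrying an extreme trait value), and categorical traits with few
levels.  This module draws datasets with exactly those signatures so every
analysis in the package can be exercised and tested without any downloads.

Abundance models
----------------
``lognormal``
    Per-species pool abundances ``exp(N(meanlog, sdlog))``; sdlog around
    1.5–2 yields abundances spanning several orders of magnitude.
``geometric``
    Niche-preemption series: expected proportions p_i proportional to
    k (1-k)^(i-1).

Per plot, species occur with an occupancy probability (turnover) and their
abundance is jittered by a lognormal factor; count-type measures are drawn
Poisson around the expectation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .community import AvailabilityMask, CATEGORICAL, CONTINUOUS, CommunityMatrix, TraitTable
from .errors import ValidationError

_MAX_RETRIES = 100


@dataclass
class SynthConfig:
    """Everything the generator needs; the seed fully determines the output."""

    n_plots: int = 10
    n_species: int = 80
    abundance_model: str = "lognormal"   # or "geometric"
    meanlog: float = 2.0                 # lognormal pool abundance, natural log
    sdlog: float = 1.5
    k: float = 0.2                       # geometric preemption share
    occupancy: float = 0.5               # probability a species occurs in a plot
    plot_noise_sdlog: float = 0.5        # per-plot lognormal jitter
    measure: str = "biomass"             # "count" draws Poisson abundances
    continuous_traits: dict[str, float] = field(
        default_factory=lambda: {"size": 1.0}
    )                                    # name -> sdlog of the trait's lognormal
    categorical_traits: dict[str, int] = field(default_factory=dict)  # name -> levels
    rare_outlier: bool = False
    completeness: float = 1.0            # fraction of species with available traits
    seed: int = 0

    def __post_init__(self) -> None:
        for name, value in (("occupancy", self.occupancy), ("k", self.k),
                            ("completeness", self.completeness)):
            if not (0 <= value <= 1):
                raise ValidationError(f"{name} must be in [0, 1], got {value}")
        if self.n_plots < 1 or self.n_species < 2:
            raise ValidationError("need at least 1 plot and 2 species")
        if self.abundance_model not in ("lognormal", "geometric"):
            raise ValidationError(f"unknown abundance model {self.abundance_model!r}")


PRESETS: dict[str, SynthConfig] = {
    # herbaceous vegetation: few plots, biomass spanning orders of magnitude,
    # seed-mass-like highly skewed trait plus two categorical traits
    "plantlike": SynthConfig(
        n_plots=12, n_species=62, sdlog=1.8, occupancy=0.55, measure="biomass",
        continuous_traits={"height": 0.6, "sla": 0.3, "seed_mass": 1.5},
        categorical_traits={"growth_form": 4, "leaf_position": 3},
        rare_outlier=True,
    ),
    # many plots, many rare species, individual counts
    "antlike": SynthConfig(
        n_plots=59, n_species=297, sdlog=2.0, occupancy=0.15, measure="count",
        continuous_traits={"head_length": 0.5, "leg_ratio": 0.3},
        categorical_traits={"pilosity": 4, "sculpturing": 3},
        rare_outlier=True,
    ),
    # few sites along a gradient, counts, weight-like skewed trait
    "birdlike": SynthConfig(
        n_plots=8, n_species=238, sdlog=1.8, occupancy=0.35, measure="count",
        continuous_traits={"body_length": 0.5, "weight": 1.2},
        categorical_traits={"trophic_guild": 5},
        rare_outlier=True,
    ),
}


def preset(name: str, **overrides) -> SynthConfig:
    if name not in PRESETS:
        raise ValidationError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    return replace(PRESETS[name], **overrides)


def geometric_proportions(k: float, n_species: int) -> np.ndarray:
    """Normalised niche-preemption series p_i ∝ k(1-k)^(i-1)."""
    raw = k * (1 - k) ** np.arange(n_species)
    return raw / raw.sum()


def _pool_expectations(config: SynthConfig, rng: np.random.Generator) -> np.ndarray:
    if config.abundance_model == "geometric":
        return geometric_proportions(config.k, config.n_species) * 1000.0
    return rng.lognormal(config.meanlog, config.sdlog, config.n_species)


def synth_abundances(config: SynthConfig) -> CommunityMatrix:
    """Draw a plots x species abundance matrix under ``config``.

    Plots that come out empty (possible at low occupancy) are redrawn up to a
    bounded number of times, then an error is raised.
    """
    rng = np.random.default_rng(config.seed)
    pool = _pool_expectations(config, rng)
    plots = []
    for _ in range(config.n_plots):
        for _attempt in range(_MAX_RETRIES):
            occupied = rng.random(config.n_species) < config.occupancy
            jitter = rng.lognormal(0.0, config.plot_noise_sdlog, config.n_species)
            expected = np.where(occupied, pool * jitter, 0.0)
            if config.measure == "count":
                row = rng.poisson(expected).astype(float)
            else:
                row = expected
            if row.sum() > 0:
                break
        else:
            raise ValidationError("could not draw a non-empty plot; raise occupancy")
        plots.append(row)
    species = [f"sp{i + 1:03d}" for i in range(config.n_species)]
    plot_ids = [f"plot{i + 1:02d}" for i in range(config.n_plots)]
    data = pd.DataFrame(np.vstack(plots), index=plot_ids, columns=species)
    return CommunityMatrix(data, measure=config.measure)


def synth_dataset(config: SynthConfig) -> tuple[CommunityMatrix, TraitTable, AvailabilityMask]:
    """Community, traits and an availability mask from one seed.

    Continuous traits are lognormal (positively skewed; sdlog per trait);
    categorical traits are uniform over their levels.  With ``rare_outlier``
    the species rarest in the pool gets, on its most skewed continuous trait,
    a value several generator standard deviations above the generator mean —
    the "rare species with the most extreme trait" situation that makes FD
    indices fragile.  The mask marks a ``completeness`` fraction of species
    as trait-available.
    """
    cm = synth_abundances(config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    data: dict[str, np.ndarray | list] = {}
    types: dict[str, str] = {}
    for name, sdlog in config.continuous_traits.items():
        data[name] = rng.lognormal(0.0, sdlog, config.n_species)
        types[name] = CONTINUOUS
    for name, levels in config.categorical_traits.items():
        labels = [chr(ord("A") + i) for i in range(levels)]
        data[name] = [labels[i] for i in rng.integers(0, levels, config.n_species)]
        types[name] = CATEGORICAL
    traits = pd.DataFrame(data, index=cm.species_ids)

    if config.rare_outlier and config.continuous_traits:
        trait_name = max(config.continuous_traits, key=config.continuous_traits.get)
        sd = config.continuous_traits[trait_name]
        mean = float(np.exp(sd ** 2 / 2))
        spread = float(mean * np.sqrt(np.exp(sd ** 2) - 1.0))
        rarest = int(np.argmin(np.where(cm.pool_abundances().to_numpy() > 0,
                                        cm.pool_abundances().to_numpy(), np.inf)))
        outlier_value = mean + 6.0 * spread
        current_max = float(traits[trait_name].max())
        traits.iloc[rarest, traits.columns.get_loc(trait_name)] = max(
            outlier_value, current_max * 1.5
        )

    available = rng.random(config.n_species) < config.completeness
    if config.completeness >= 1.0:
        available[:] = True
    mask = AvailabilityMask.from_species(cm.species_ids, available, list(traits.columns))
    return cm, TraitTable(traits, types), mask
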