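"""Community and trait data containers, file I/O, and elementary transforms.

The package works on two aligned tables: a plots x species abundance matrix
(any non-negative abundance measure: counts, biomass, cover, frequency) and a
species x traits table in which each trait is declared continuous or
categorical.  Missing trait values are permitted and propagate into the
pairwise weights of the Gower dissimilarity rather than being imputed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateInputError, ParseError, ValidationError

CONTINUOUS = "continuous"
CATEGORICAL = "categorical"

_ABUNDANCE_TRANSFORMS = ("none", "log_plus_one", "log_over_min_plus_one")
_TRAIT_TRANSFORMS = ("none", "sqrt", "log10")


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class CommunityMatrix:
    """Plots x species abundance matrix.

    Parameters
    ----------
    data:
        DataFrame indexed by plot id with one column per species id.  Values
        are non-negative reals in whatever abundance measure the survey used.
    measure:
        Free-text label for the abundance measure (``"count"``, ``"biomass"``,
        ``"cover"``, ``"frequency"``); informational only.
    """

    data: pd.DataFrame
    measure: str = "count"

    def __post_init__(self) -> None:
        df = self.data
        if df.index.has_duplicates:
            raise ValidationError(f"duplicate plot ids: {sorted(df.index[df.index.duplicated()])}")
        if df.columns.has_duplicates:
            raise ValidationError(
                f"duplicate species ids: {sorted(df.columns[df.columns.duplicated()])}"
            )
        values = df.to_numpy(dtype=float)
        if not np.isfinite(values).all():
            bad = np.argwhere(~np.isfinite(values))[0]
            raise ValidationError(
                f"non-finite abundance at plot {df.index[bad[0]]!r}, "
                f"species {df.columns[bad[1]]!r}"
            )
        if (values < 0).any():
            bad = np.argwhere(values < 0)[0]
            raise ValidationError(
                f"negative abundance at plot {df.index[bad[0]]!r}, "
                f"species {df.columns[bad[1]]!r}"
            )
        empty = values.sum(axis=1) == 0
        if empty.any():
            raise ValidationError(
                f"plots with no positive abundance: {list(df.index[empty])}"
            )
        self.data = df.astype(float)

    @property
    def plot_ids(self) -> list:
        return list(self.data.index)

    @property
    def species_ids(self) -> list:
        return list(self.data.columns)

    @property
    def n_plots(self) -> int:
        return len(self.data.index)

    @property
    def n_species(self) -> int:
        return len(self.data.columns)

    def plot(self, plot_id) -> pd.Series:
        """Abundance vector of one plot."""
        return self.data.loc[plot_id]

    def pool_abundances(self) -> pd.Series:
        """Species abundances summed over all plots."""
        return self.data.sum(axis=0)

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index_label="plot")


@dataclass
class TraitTable:
    """Species x traits table with a per-trait type declaration.

    ``data`` is indexed by species id; continuous trait columns are floats
    (NaN marks a missing value), categorical columns hold labels (NaN/None
    missing).  ``types`` maps each trait name to ``"continuous"`` or
    ``"categorical"``.
    """

    data: pd.DataFrame
    types: dict[str, str]

    def __post_init__(self) -> None:
        df = self.data
        if df.index.has_duplicates:
            raise ValidationError(
                f"duplicate species ids in trait table: {sorted(df.index[df.index.duplicated()])}"
            )
        unknown = set(df.columns) - set(self.types)
        if unknown:
            raise ValidationError(f"traits without a type declaration: {sorted(unknown)}")
        extra = set(self.types) - set(df.columns)
        if extra:
            raise ValidationError(f"type declared for absent traits: {sorted(extra)}")
        bad = {t: k for t, k in self.types.items() if k not in (CONTINUOUS, CATEGORICAL)}
        if bad:
            raise ValidationError(f"trait types must be continuous|categorical, got {bad}")
        for trait, kind in self.types.items():
            if kind == CONTINUOUS:
                col = pd.to_numeric(df[trait], errors="coerce")
                original_missing = df[trait].isna()
                if (col.isna() & ~original_missing).any():
                    offender = df.index[col.isna() & ~original_missing][0]
                    raise ParseError(
                        f"non-numeric value for continuous trait {trait!r}, species {offender!r}"
                    )
                if np.isinf(col.to_numpy(dtype=float)).any():
                    raise ValidationError(f"infinite value in continuous trait {trait!r}")
                df[trait] = col.astype(float)
        self.data = df

    @property
    def species_ids(self) -> list:
        return list(self.data.index)

    @property
    def trait_names(self) -> list[str]:
        return list(self.data.columns)

    def continuous_traits(self) -> list[str]:
        return [t for t in self.data.columns if self.types[t] == CONTINUOUS]

    def categorical_traits(self) -> list[str]:
        return [t for t in self.data.columns if self.types[t] == CATEGORICAL]

    def subset(self, species: Sequence, traits: Sequence[str] | None = None) -> "TraitTable":
        traits = list(traits) if traits is not None else list(self.data.columns)
        missing = [s for s in species if s not in self.data.index]
        if missing:
            raise ValidationError(f"species absent from trait table: {missing}")
        return TraitTable(
            self.data.loc[list(species), traits].copy(),
            {t: self.types[t] for t in traits},
        )

    def transformed(self, method: str, shift: float | None = None) -> "TraitTable":
        """Apply a transform to every continuous trait; categoricals untouched."""
        df = self.data.copy()
        for trait in self.continuous_traits():
            df[trait] = transform_trait(df[trait].to_numpy(), method, shift=shift)
        return TraitTable(df, dict(self.types))

    def to_csv(self, path) -> None:
        header_types = pd.DataFrame(
            [[self.types[t] for t in self.data.columns]],
            index=["type:"], columns=self.data.columns,
        )
        pd.concat([header_types, self.data.astype(object)]).to_csv(path, index_label="species")


@dataclass
class AvailabilityMask:
    """Boolean trait availability per species (optionally per species x trait).

    A species marked unavailable is treated as trait-missing by the coverage
    planners regardless of what the trait table contains.
    """

    available: pd.DataFrame  # species x traits, bool

    def __post_init__(self) -> None:
        if self.available.index.has_duplicates:
            raise ValidationError("duplicate species ids in availability mask")
        self.available = self.available.astype(bool)

    @classmethod
    def from_species(cls, species_ids: Sequence, available: Iterable[bool],
                     traits: Sequence[str] = ("trait",)) -> "AvailabilityMask":
        """Species-level mask broadcast across ``traits`` columns."""
        col = pd.Series(list(available), index=list(species_ids), dtype=bool)
        return cls(pd.DataFrame({t: col for t in traits}))

    @classmethod
    def complete(cls, species_ids: Sequence, traits: Sequence[str] = ("trait",)) -> "AvailabilityMask":
        return cls.from_species(species_ids, [True] * len(list(species_ids)), traits)

    def species_available(self, mode: str = "all") -> pd.Series:
        """Collapse to a per-species flag: 'all' traits present or 'any'."""
        if mode == "all":
            return self.available.all(axis=1)
        if mode == "any":
            return self.available.any(axis=1)
        raise ValidationError(f"mode must be 'all' or 'any', got {mode!r}")


@dataclass
class AlignmentReport:
    """What :func:`load_dataset` found when matching the two tables."""

    trait_missing_species: list = field(default_factory=list)
    community_missing_species: list = field(default_factory=list)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"{len(self.trait_missing_species)} community species lack trait rows; "
            f"{len(self.community_missing_species)} trait-table species absent from community"
        )


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def _read_delimited(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    return pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False,
                       na_values=["", "NA"])


def load_community(path, measure: str = "count") -> CommunityMatrix:
    """Read a community matrix from CSV/TSV.

    Wide format (first column = plot id, remaining columns = species) and long
    format (columns plot, species, abundance) are auto-detected by header.
    """
    raw = _read_delimited(path)
    cols = [c.strip().lower() for c in raw.columns]
    if len(raw.columns) == 3 and set(cols) == {"plot", "species", "abundance"}:
        raw.columns = cols
        long = raw.copy()
        long["abundance"] = _numeric_column(long, "abundance", path)
        wide = long.pivot_table(index="plot", columns="species", values="abundance",
                                aggfunc="sum", fill_value=0.0)
        wide.index.name = None
        wide.columns.name = None
        return CommunityMatrix(wide, measure=measure)
    df = raw.set_index(raw.columns[0])
    df.index.name = None
    for col in df.columns:
        df[col] = _numeric_column(df, col, path)
    return CommunityMatrix(df, measure=measure)


def _numeric_column(df: pd.DataFrame, col: str, path) -> pd.Series:
    converted = pd.to_numeric(df[col], errors="coerce")
    bad = converted.isna() & df[col].notna()
    if bad.any():
        row = df.index[bad][0]
        raise ParseError(f"{path}: cannot parse {df[col][bad].iloc[0]!r} at row {row!r}, column {col!r}")
    return converted.fillna(0.0)


def load_traits(path, trait_types: Mapping[str, str] | None = None) -> TraitTable:
    """Read a trait table from CSV/TSV (first column = species id).

    Trait types come from ``trait_types`` or from a second header row whose
    first cell is ``type:``; without either, numeric columns are taken as
    continuous and the rest as categorical.
    """
    raw = _read_delimited(path)
    df = raw.set_index(raw.columns[0])
    df.index.name = None
    types: dict[str, str] = dict(trait_types) if trait_types else {}
    if len(df) and str(df.index[0]).strip().lower() == "type:":
        declared = df.iloc[0]
        df = df.iloc[1:]
        if not types:
            types = {t: str(declared[t]).strip().lower() for t in df.columns}
    if not types:
        for col in df.columns:
            converted = pd.to_numeric(df[col], errors="coerce")
            numeric = (converted.notna() | df[col].isna()).all()
            types[col] = CONTINUOUS if numeric else CATEGORICAL
    for col in df.columns:
        if types.get(col) == CATEGORICAL:
            df[col] = df[col].where(df[col].notna(), other=pd.NA)
    return TraitTable(df, types)


def load_dataset(
    community_path,
    traits_path,
    trait_types: Mapping[str, str] | None = None,
    measure: str = "count",
) -> tuple[CommunityMatrix, TraitTable, AlignmentReport]:
    """Load and align a community matrix and a trait table.

    Species present in the community but absent from the trait table are kept
    and flagged trait-missing in the returned report (a NaN row is appended so
    downstream coverage logic can see them); this is a normal field situation,
    not an error.
    """
    cm = load_community(community_path, measure=measure)
    traits = load_traits(traits_path, trait_types=trait_types)
    report = AlignmentReport(
        trait_missing_species=[s for s in cm.species_ids if s not in traits.data.index],
        community_missing_species=[s for s in traits.species_ids if s not in cm.data.columns],
    )
    if report.trait_missing_species:
        filler = pd.DataFrame(
            np.nan, index=report.trait_missing_species, columns=traits.data.columns
        )
        traits = TraitTable(pd.concat([traits.data, filler]), dict(traits.types))
    return cm, traits, report


# ---------------------------------------------------------------------------
# elementary numeric operations
# ---------------------------------------------------------------------------

def relative_abundances(abundance) -> np.ndarray:
    """Proportions ``x / sum(x)`` of a non-negative abundance vector."""
    x = np.asarray(abundance, dtype=float)
    if (x < 0).any():
        raise ValidationError("abundances must be non-negative")
    total = x.sum()
    if total <= 0:
        raise DegenerateInputError("cannot relativize an all-zero abundance vector")
    return x / total


def round_relative(p, digits: int = 2) -> np.ndarray:
    """Display-style rounding of a proportion vector (half away from zero).

    Exists to reproduce printed two-decimal examples; analysis code should use
    full precision.
    """
    p = np.asarray(p, dtype=float)
    factor = 10.0 ** digits
    return np.floor(p * factor + 0.5) / factor


def transform_abundance(abundance, method: str = "none", base: float = 10.0) -> np.ndarray:
    """Abundance transform: ``log(x + 1)`` or ``log(x / min(x) + 1)``.

    Both map zero to zero and preserve the rank order of positive values; the
    second divides by the minimum *positive* abundance so that low values keep
    a logarithmic (rather than near-linear) response.  ``base`` defaults to 10.
    """
    x = np.asarray(abundance, dtype=float)
    if (x < 0).any():
        raise ValidationError("abundances must be non-negative")
    if method == "none":
        return x.copy()
    log = np.log(base)
    if method == "log_plus_one":
        return np.log1p(x) / log
    if method == "log_over_min_plus_one":
        positive = x[x > 0]
        if positive.size == 0:
            raise DegenerateInputError("log_over_min_plus_one needs at least one positive value")
        return np.log1p(x / positive.min()) / log
    raise ValidationError(f"unknown abundance transform {method!r}; choose from {_ABUNDANCE_TRANSFORMS}")


def transform_trait(values, method: str = "none", shift: float | None = None) -> np.ndarray:
    """Continuous-trait transform: identity, square root, or log10.

    NaNs pass through untouched.  ``log10`` of non-positive values is an error
    unless an explicit ``shift`` is supplied (added before taking logs); the
    package never shifts silently.
    """
    x = np.asarray(values, dtype=float)
    present = ~np.isnan(x)
    out = x.copy()
    if method == "none":
        return out
    if method == "sqrt":
        if (x[present] < 0).any():
            raise ValidationError("sqrt transform requires non-negative trait values")
        out[present] = np.sqrt(x[present])
        return out
    if method == "log10":
        shifted = x[present] + (shift or 0.0)
        if (shifted <= 0).any():
            raise ValidationError(
                "log10 of a non-positive trait value; supply an explicit shift"
            )
        out[present] = np.log10(shifted)
        return out
    raise ValidationError(f"unknown trait transform {method!r}; choose from {_TRAIT_TRANSFORMS}")


def skewness(values) -> float:
    """Population skewness g1 = m3 / m2^(3/2) (third standardized moment).

    The biased/population version is used throughout; transforms are judged by
    how much they reduce this quantity for right-skewed traits.
    """
    x = np.asarray(values, dtype=float)
    x = x[~np.isnan(x)]
    if x.size < 3:
        raise DegenerateInputError("skewness needs at least 3 non-missing values")
    if np.var(x) == 0:
        raise DegenerateInputError("skewness undefined for a constant vector")
    return float(stats.skew(x, bias=True))
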