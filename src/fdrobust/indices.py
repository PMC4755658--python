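"""Plot-level functional diversity indices: CWM, FRic, FEve and Rao's Q.

All indices operate on relative abundances (proportions) of the species
present in one plot, and — except CWM — on a trait dissimilarity matrix.
Low-level index functions raise :class:`NotComputableError` when an index is
undefined for the input (too few species, zero dissimilarity, ...);
:func:`compute_all` converts those into flagged :class:`IndexResult` records
so a pipeline over many plots and reduction steps never silently drops cases.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError

from .community import CONTINUOUS, TraitTable, relative_abundances, transform_abundance
from .dissimilarity import DistanceMatrix, gower, pcoa
from .errors import DegenerateInputError, ValidationError

logger = logging.getLogger(__name__)

INDEX_NAMES = ("CWM", "FRic", "FEve", "RaoQ")


class NotComputableError(DegenerateInputError):
    """The index is undefined for this input; the message is the reason code."""


@dataclass
class IndexResult:
    """One index value for one plot and trait set (or the reason it is absent)."""

    plot_id: object
    index: str
    trait_set: str
    value: float
    flag: str | None = None

    @property
    def computable(self) -> bool:
        return self.flag is None


def results_to_frame(results: Sequence[IndexResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"plot_id": r.plot_id, "index": r.index, "trait_set": r.trait_set,
             "value": r.value, "flag": r.flag}
            for r in results
        ]
    )


# ---------------------------------------------------------------------------
# individual indices
# ---------------------------------------------------------------------------

def _check_proportions(p) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if (p < 0).any():
        raise ValidationError("proportions must be non-negative")
    if not np.isclose(p.sum(), 1.0, atol=1e-8):
        raise ValidationError(f"proportions must sum to 1, got {p.sum():.6f}")
    return p


def cwm(p, x) -> float:
    """Community weighted mean: sum p_i x_i over species with a trait value.

    Species missing the trait are excluded and the remaining proportions
    renormalised, mirroring how species without trait data are omitted from
    every other index.
    """
    p = _check_proportions(p)
    x = np.asarray(x, dtype=float)
    if x.shape != p.shape:
        raise ValidationError("trait vector and proportions differ in length")
    present = ~np.isnan(x)
    weight = p[present].sum()
    if weight <= 0:
        raise NotComputableError("no abundance carried by species with trait values")
    return float(np.dot(p[present], x[present]) / weight)


def fric(
    d_or_values,
    max_axes: int = 6,
) -> float:
    """Functional richness.

    For a single continuous trait (1-D array input) FRic is the occupied trait
    range max - min.  For a :class:`DistanceMatrix` the species are embedded
    by PCoA and FRic is the convex hull volume over
    m = min(max_axes, S - 1, positive axes) coordinates; degenerate hulls
    (coplanar point sets) retry with one axis fewer, down to the 1-D range.
    """
    if isinstance(d_or_values, DistanceMatrix):
        return _fric_multivariate(d_or_values, max_axes)
    x = np.asarray(d_or_values, dtype=float)
    x = x[~np.isnan(x)]
    if x.size < 2:
        raise NotComputableError("FRic needs at least 2 species with trait values")
    return float(x.max() - x.min())


def _fric_multivariate(d: DistanceMatrix, max_axes: int) -> float:
    s = d.n
    if s < 2:
        raise NotComputableError("FRic needs at least 2 species")
    coords, eigval = pcoa(d)
    if coords.shape[1] == 0:
        raise NotComputableError("no positive PCoA axes (all species identical)")
    m = min(max_axes, s - 1, coords.shape[1])
    while m > s - 1:  # pragma: no cover - guarded by min above
        m -= 1
    while m >= 2:
        try:
            return float(ConvexHull(coords[:, :m]).volume)
        except QhullError:
            logger.info("degenerate hull in %d axes for %d species; retrying with %d",
                        m, s, m - 1)
            m -= 1
    axis = coords[:, 0]
    return float(axis.max() - axis.min())


def _mst_edges(d: np.ndarray, species_ids: Sequence) -> list[tuple[int, int, float]]:
    """Kruskal MST with deterministic ties: edges sorted by
    (weight, lexicographic species-id pair)."""
    n = len(species_ids)
    order = sorted(
        ((d[i, j], str(species_ids[i]), str(species_ids[j]), i, j)
         for i in range(n) for j in range(i + 1, n)),
        key=lambda e: (e[0], min(e[1], e[2]), max(e[1], e[2])),
    )
    parent = list(range(n))

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    edges: list[tuple[int, int, float]] = []
    for w, _, _, i, j in order:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj
            edges.append((i, j, w))
            if len(edges) == n - 1:
                break
    return edges


def feve(p, d: DistanceMatrix) -> float:
    """Functional evenness on the minimum spanning tree of the species.

    For each of the S - 1 MST branches joining species i and j the weighted
    evenness is EW = d_ij / (p_i + p_j); partial weighted evennesses
    PEW = EW / sum(EW) are compared with the perfectly even value 1/(S-1):

        FEve = (sum min(PEW, 1/(S-1)) - 1/(S-1)) / (1 - 1/(S-1))

    FEve is 1 when abundance is spread perfectly regularly along the tree and
    decreases towards 0 as it concentrates.
    """
    p = _check_proportions(p)
    s = d.n
    if p.size != s:
        raise ValidationError("proportions and distance matrix differ in size")
    if s < 3:
        raise NotComputableError("FEve needs at least 3 species")
    edges = _mst_edges(d.values, d.species_ids)
    ew = []
    for i, j, w in edges:
        pij = p[i] + p[j]
        if pij == 0:
            raise NotComputableError("MST branch between two zero-abundance species")
        ew.append(w / pij)
    ew = np.asarray(ew)
    total = ew.sum()
    if total == 0:
        raise NotComputableError("all MST branch lengths are zero")
    pew = ew / total
    even = 1.0 / (s - 1)
    return float((np.minimum(pew, even).sum() - even) / (1.0 - even))


def rao_q(p, d: DistanceMatrix) -> float:
    """Rao's quadratic entropy: expected dissimilarity between two random
    individuals, sum_ij p_i p_j d_ij."""
    p = _check_proportions(p)
    if p.size != d.n:
        raise ValidationError("proportions and distance matrix differ in size")
    return float(p @ d.values @ p)


# ---------------------------------------------------------------------------
# per-plot driver
# ---------------------------------------------------------------------------

def compute_all(
    abundance,
    traits: TraitTable,
    species_ids: Sequence | None = None,
    trait_sets: dict[str, list[str]] | None = None,
    abundance_transform: str = "none",
    trait_transform: str = "none",
    trait_shift: float | None = None,
    max_axes: int = 6,
    plot_id: object = "plot",
) -> list[IndexResult]:
    """All four indices for one plot, per trait set.

    ``abundance`` is the plot's abundance (or already-reduced relative
    abundance) vector aligned with ``species_ids`` (default: the trait table's
    species order).  ``trait_sets`` maps a label to a list of trait names;
    by default each trait is used separately plus all traits combined under
    the label ``"all"``.  Species with zero abundance are dropped; species
    lacking every trait of a set are omitted with proportions renormalised —
    the same semantics as removing their trait data.  Results that cannot be
    computed are returned flagged, never silently dropped.
    """
    species_ids = list(species_ids) if species_ids is not None else list(traits.species_ids)
    x = np.asarray(abundance, dtype=float)
    if x.size != len(species_ids):
        raise ValidationError("abundance vector and species ids differ in length")
    x = transform_abundance(x, abundance_transform)
    work_traits = traits.transformed(trait_transform, shift=trait_shift)

    if trait_sets is None:
        trait_sets = {t: [t] for t in work_traits.trait_names}
        if len(work_traits.trait_names) > 1:
            trait_sets["all"] = list(work_traits.trait_names)

    present = x > 0
    results: list[IndexResult] = []
    for label, names in trait_sets.items():
        results.extend(
            _indices_for_set(x, present, species_ids, work_traits, label, names,
                             max_axes, plot_id)
        )
    return results


def _indices_for_set(
    x: np.ndarray,
    present: np.ndarray,
    species_ids: list,
    traits: TraitTable,
    label: str,
    names: list[str],
    max_axes: int,
    plot_id: object,
) -> list[IndexResult]:
    results: list[IndexResult] = []
    sub = traits.subset([s for s in species_ids], names)
    has_any = sub.data.notna().any(axis=1).to_numpy()
    keep = present & has_any
    kept_ids = [s for s, k in zip(species_ids, keep) if k]

    def flagged(index: str, reason: str) -> IndexResult:
        return IndexResult(plot_id, index, label, float("nan"), reason)

    if not keep.any():
        return [flagged(name, "no species with abundance and trait data") for name in INDEX_NAMES]
    p = relative_abundances(x[keep])

    # CWM: single continuous traits only
    if len(names) == 1 and traits.types[names[0]] == CONTINUOUS:
        vals = sub.data.loc[kept_ids, names[0]].to_numpy(dtype=float)
        try:
            results.append(IndexResult(plot_id, "CWM", label, cwm(p, vals)))
        except NotComputableError as exc:
            results.append(flagged("CWM", str(exc)))
    elif len(names) == 1:
        results.append(flagged("CWM", "categorical trait"))
    else:
        results.append(flagged("CWM", "multivariate trait set"))

    if len(kept_ids) < 2:
        results.append(flagged("FRic", "fewer than 2 species"))
        results.append(flagged("FEve", "fewer than 3 species"))
        results.append(IndexResult(plot_id, "RaoQ", label, 0.0))
        return results

    try:
        d = gower(traits, species=kept_ids, trait_subset=names)
    except DegenerateInputError as exc:
        results.extend(flagged(name, str(exc)) for name in ("FRic", "FEve", "RaoQ"))
        return results

    if len(names) == 1 and traits.types[names[0]] == CONTINUOUS:
        fric_input = sub.data.loc[kept_ids, names[0]].to_numpy(dtype=float)
    else:
        fric_input = d
    for name, fn in (
        ("FRic", lambda: fric(fric_input, max_axes=max_axes)),
        ("FEve", lambda: feve(p, d)),
        ("RaoQ", lambda: rao_q(p, d)),
    ):
        try:
            results.append(IndexResult(plot_id, name, label, fn()))
        except NotComputableError as exc:
            results.append(flagged(name, str(exc)))
    return results
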