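"""Gower dissimilarity for mixed trait types and principal coordinates analysis.

Gower's coefficient averages range-normalised absolute differences (continuous
traits) and simple mismatches (categorical traits), down-weighting any trait
that is missing for either member of a pair.  Ranges are taken over the
species actually included, so removing species can change the dissimilarity of
the remaining pairs — the behaviour required when dissimilarities are
recomputed at every trait-removal step.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .community import CATEGORICAL, CONTINUOUS, TraitTable
from .errors import DegenerateInputError, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class DistanceMatrix:
    """Symmetric dissimilarity matrix with a zero diagonal."""

    species_ids: list
    values: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.values, dtype=float)
        n = len(self.species_ids)
        if d.shape != (n, n):
            raise ValidationError(f"distance matrix shape {d.shape} does not match {n} species")
        if not np.allclose(d, d.T, atol=1e-12):
            raise ValidationError("distance matrix must be symmetric")
        if not np.allclose(np.diag(d), 0.0, atol=1e-12):
            raise ValidationError("distance matrix diagonal must be zero")
        if (d < -1e-12).any():
            raise ValidationError("distances must be non-negative")
        self.values = np.clip(d, 0.0, None)
        self.species_ids = list(self.species_ids)

    @property
    def n(self) -> int:
        return len(self.species_ids)

    def submatrix(self, species: Sequence) -> "DistanceMatrix":
        idx = [self.species_ids.index(s) for s in species]
        return DistanceMatrix(list(species), self.values[np.ix_(idx, idx)])

    def to_csv(self, path) -> None:
        pd.DataFrame(self.values, index=self.species_ids, columns=self.species_ids).to_csv(
            path, index_label="species"
        )

    @classmethod
    def from_csv(cls, path) -> "DistanceMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(list(df.index), df.to_numpy(dtype=float))


def gower(
    traits: TraitTable,
    species: Sequence | None = None,
    trait_subset: Sequence[str] | None = None,
) -> DistanceMatrix:
    """Gower dissimilarity over the given species and traits.

    d_ij = sum_k w_ijk * delta_ijk / sum_k w_ijk with

    * continuous trait k: delta = |x_ik - x_jk| / range_k, range over the
      included species; a zero-range trait gets weight 0 everywhere,
    * categorical trait k: delta = 0 if equal else 1,
    * w_ijk = 0 whenever either value is missing, else 1.

    Raises when fewer than 2 species are included, when a pair shares no
    non-missing trait, or when every trait is uninformative (zero range).
    """
    species = list(species) if species is not None else list(traits.species_ids)
    if len(species) < 2:
        raise DegenerateInputError("Gower needs at least 2 species")
    sub = traits.subset(species, trait_subset)

    n = len(species)
    num = np.zeros((n, n))
    den = np.zeros((n, n))
    informative = 0
    for trait in sub.trait_names:
        col = sub.data[trait]
        if sub.types[trait] == CONTINUOUS:
            x = col.to_numpy(dtype=float)
            present = ~np.isnan(x)
            if present.sum() == 0:
                continue
            rng = np.nanmax(x) - np.nanmin(x)
            if rng == 0:
                continue  # zero-range trait carries no information: weight 0
            delta = np.abs(x[:, None] - x[None, :]) / rng
        else:
            labels = col.to_numpy(dtype=object)
            present = pd.notna(col).to_numpy()
            if present.sum() == 0:
                continue
            delta = (labels[:, None] != labels[None, :]).astype(float)
        informative += 1
        w = (present[:, None] & present[None, :]).astype(float)
        num += w * np.nan_to_num(delta)
        den += w
    if informative == 0:
        raise DegenerateInputError("all traits are missing or zero-range; Gower undefined")
    np.fill_diagonal(den, 1.0)  # diagonal is 0 by definition
    np.fill_diagonal(num, 0.0)
    bad = np.argwhere(den == 0)
    if bad.size:
        i, j = bad[0]
        raise DegenerateInputError(
            f"species pair ({species[i]!r}, {species[j]!r}) shares no non-missing trait"
        )
    d = num / den
    d = (d + d.T) / 2.0
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(species, d)


def pcoa(
    d: DistanceMatrix,
    max_axes: int | None = None,
    tol: float = 1e-9,
) -> tuple[np.ndarray, np.ndarray]:
    """Classical scaling (principal coordinates) of a dissimilarity matrix.

    Eigendecomposes the double-centred matrix of -d^2/2 and returns
    coordinates scaled by sqrt(eigenvalue) for the positive axes only
    (eigenvalues with |lambda| <= tol * max(lambda) are treated as zero;
    negative axes — possible for non-Euclidean Gower matrices — are dropped
    and their inertia share logged).  Axis signs are fixed so the
    largest-magnitude loading on each axis is positive, making the embedding
    deterministic.

    Returns ``(coords, eigenvalues)`` with coords of shape (n, m).
    """
    dm = np.asarray(d.values, dtype=float)
    n = dm.shape[0]
    b = dm ** 2
    b = -0.5 * b
    b = b - b.mean(axis=0, keepdims=True) - b.mean(axis=1, keepdims=True) + b.mean()
    eigval, eigvec = np.linalg.eigh(b)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]

    if n == 1 or eigval.size == 0 or eigval[0] <= 0:
        return np.zeros((n, 0)), np.array([])
    cutoff = tol * eigval[0]
    keep = eigval > cutoff
    negative = eigval[eigval < -cutoff]
    if negative.size:
        share = -negative.sum() / np.abs(eigval).sum()
        logger.info("PCoA dropped %d negative axes (%.1f%% of total inertia)",
                    negative.size, 100 * share)
    eigval = eigval[keep]
    eigvec = eigvec[:, keep]
    if max_axes is not None:
        eigval = eigval[:max_axes]
        eigvec = eigvec[:, : len(eigval)]
    coords = eigvec * np.sqrt(eigval)[None, :]
    # deterministic sign convention: largest-|loading| entry positive per axis
    for j in range(coords.shape[1]):
        pivot = np.argmax(np.abs(coords[:, j]))
        if coords[pivot, j] < 0:
            coords[:, j] = -coords[:, j]
    return coords, eigval
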