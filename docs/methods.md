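# Methods

This note records the model, the numerical choices, and the boundaries of
what the package's tests demonstrate.

## The removal model

Trait-data incompleteness is modelled as an ordered deletion process:
species lose their trait information rarest-first, because in practice rare
species are the ones left unmeasured. Deletion proceeds in steps that each
consume a fixed slice of **relative abundance** (default `step_size = 0.005`,
i.e. 0.5%) rather than one species at a time; with a fixed slice the amount
remaining is a continuous, comparable variable across communities whose
dominance-diversity curves differ wildly. A species larger than the remainder
of a step's budget is split across steps. Removal stops when the remaining
share reaches `floor` (default 0.5); a final partial step lands exactly on
the floor, so with `step_size = 0.05` and `floor = 0.5` there are exactly
ten steps.

Ranking units:

* **plot-wise** — species ranked by relative abundance within each plot;
  every plot declines by `step_size` per step.
* **pool-wise** — species ranked by pooled relative abundance (summed
  abundance over the grand total). A species removed, wholly or fractionally,
  at pool level loses the same fraction of its local relative abundance in
  every plot containing it, so plots decline unevenly and plots lacking the
  removed species are untouched at that step. On a single-plot dataset the
  two scenarios produce bit-identical schedules.

Ties in abundance are broken by lexicographic species id, making schedules
platform-stable. Two readings exist for a species only partially removed at
a step: keep it with its abundance scaled by the unremoved fraction
(`partial="weight"`, the default — the only reading under which remaining
abundance varies continuously), or exclude it outright (`partial="drop"`).
Both are implemented. Surviving proportions are renormalised to sum to 1
before any index is computed, since all four indices are defined on
proportions.

A `round_digits` option rounds relative abundances before scheduling. It
exists solely to reproduce printed low-precision walkthroughs (whose vectors
need not sum to 1 — the scheduler therefore never renormalises internally);
analysis should leave it `None`.

## Indices

* **Gower dissimilarity** handles mixed trait types:
  `d_ij = Σ_k w_ijk δ_ijk / Σ_k w_ijk`, continuous
  `δ = |x_i − x_j| / range_k`, categorical `δ = 1[x_i ≠ x_j]`, `w_ijk = 0`
  when either value is missing and for zero-range continuous traits. Ranges
  are recomputed over the species included at each reduction step — indices
  at different steps are therefore not nested, which is deliberate: each step
  represents the analysis one would run on that incomplete dataset.
* **PCoA** (for FRic): eigendecomposition of the double-centred `−d²/2`.
  Eigenvalues with `|λ| ≤ 1e−9 · λ_max` are treated as zero; negative axes
  (possible for non-Euclidean Gower matrices) are dropped, with the negative
  inertia share logged. No Cailliez/Lingoes correction is applied — dropping
  is the simplest defensible default and the correction would only add a
  constant to all distances. Axis signs are fixed (largest-magnitude loading
  positive) for determinism.
* **FRic**: range for a single continuous trait; otherwise the convex hull
  volume over `m = min(max_axes, S − 1, positive axes)` PCoA coordinates,
  with `max_axes` defaulting to 6. Degenerate (coplanar) hulls retry with one
  axis fewer down to the 1-D range, each retry logged. This keeps small plots
  computable instead of imposing a hard `S ≥ 2^m` rule.
* **FEve**: minimum spanning tree built by Kruskal's algorithm with
  deterministic tie-breaking (edge weight, then lexicographic species-id
  pair) so equal-distance configurations give reproducible trees.
* **CWM** is defined for single continuous traits; categorical or combined
  trait sets yield a flagged, not-computable record rather than an error or a
  silent omission. Species with positive abundance but a missing focal trait
  are excluded with proportions renormalised — exactly the semantics the
  removal simulation applies to deleted trait data.

Flags propagate: every (plot, step, index, trait set) cell in the pipeline
output is either a number or a reason code.

## Transformations

Abundance: `log(x + 1)` and `log(x / min⁺(x) + 1)` (minimum over positive
values), both base 10 by default (configurable); both fix zero and preserve
rank order. The second keeps a logarithmic response when abundances are
small, which matters for measures like biomass where the minimum can be
orders of magnitude below 1. When a transform is configured it applies to
ranking, step accounting, and index weights alike — transformed and
untransformed runs are different study designs, not different displays.
For pool-wise schedules the pooled abundance is the sum of the transformed
plot abundances, which preserves exact plot-/pool-wise equivalence on
single-plot data.

Traits: `sqrt` and `log10` for continuous traits. `log10` of a non-positive
value is an error unless an explicit shift is supplied — the package never
shifts silently. Skewness is the population third standardised moment
`g1 = m₃ / m₂^{3/2}` (the uncorrected variant; the bias correction is a
monotone factor that would not change any before/after comparison).

## Robustness slope

Per configuration, the Spearman correlation `ρₛ` between full-data and
step-`s` plot rankings is computed with average ranks; plots whose index is
not computable at a step are excluded pairwise from that step (counts
recorded), and a step needs at least `min_plots = 3` usable plots. The decay
is fitted as `log ρₛ = β (aₛ − 1)` with no free intercept, so the fitted
curve passes through `ρ = 1` at `a = 1`. The closed form is
`β̂ = Σ log(ρₛ)(aₛ − 1) / Σ (aₛ − 1)²`. Natural log is used (any base rescales
β uniformly; the base is recorded in the run manifest). Steps with `ρ ≤ 0`
are excluded and counted, never clamped — the log is undefined there and a
clamp would inject an arbitrary constant.

Sign convention: with `a ≤ 1` and decaying `ρ`, `β̂` is **positive** and
equals the exponential decay rate per unit abundance removed
(`ρ = exp(−β(1 − a))`); larger `β` = faster rank-information loss = less
robust. Presentations that regress against the removed share instead report
the same magnitude with a negative sign.

## Synthetic data

The generator emulates the statistical structure the method is sensitive to:
lognormal (or geometric-series) pool abundances whose dominance-diversity
curves span orders of magnitude, Bernoulli occupancy for between-plot
turnover, per-plot lognormal jitter, Poisson sampling for count-type
measures, lognormal (right-skewed) continuous traits, few-level categorical
traits, an optional rare species carrying an extreme trait value (six
generator standard deviations above the generator mean), and an availability
mask at a configured completeness. Presets `plantlike` (12 × 62, biomass),
`antlike` (59 × 297, counts) and `birdlike` (8 × 238, counts) echo typical
survey designs for those groups. All draws come from a single
`numpy.random.default_rng` seed; identical seeds give identical datasets.

What it does **not** emulate: spatial or environmental gradients, phylogenetic
trait structure, correlated traits, observation error in traits, and real
species-abundance covariance. Passing tests therefore demonstrate that the
machinery behaves correctly under realistic marginal structure, not that any
particular empirical community will show a particular robustness ordering.

## Problem sizes and tolerances

The test suite and examples run on communities of roughly 8–10 plots and
20–150 species with 5–10% steps — large enough for the directional effects
(log-transforming abundances spares rare species; de-skewing traits improves
index stability) to hold with fixed seeds, small enough to re-run constantly.
Oracle comparisons are exact to 1e−12 (Rao's Q double sum, Spearman average
ranks) or 1e−9 (PCoA reconstruction of Euclidean-embeddable distances); the
end-to-end rate-recovery check constructs rankings with a prescribed
squared-rank-displacement sum, achieving target correlations to within the
swap granularity, and recovers the decay rate to well within 5%.

## Known limitations

* No trait imputation and no name-matching beyond exact identifiers.
* No alternative dissimilarities (standardised Euclidean, dendrogram-based
  FD) and no functional dispersion index.
* The downstream mixed-effects inference over slope ensembles is out of
  scope; slopes are exported as tidy CSV for external statistical analysis.
* Pool-wise fractional removal applies the pool-level fraction uniformly in
  every plot; removing plot-local abundance instead would be a different,
  also defensible, reading.
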