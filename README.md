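# fdrobust

**Robustness of functional diversity indices to missing trait data.**

Functional diversity (FD) studies summarise communities with indices computed
from species abundances and functional traits — but trait data are almost
never complete, and the rare species are usually the ones missing. `fdrobust`
is for community ecologists who want to know, *before* trusting an FD
analysis or planning a trait campaign:

* how quickly each index degrades as trait data disappear from a dataset,
* whether transforming abundances or traits makes the indices more robust,
* how much of the community's abundance is already covered by measured
  traits, and which species to measure next.

## What it computes

For each plot, on a Gower dissimilarity matrix `d` over mixed continuous and
categorical traits (pairwise-missing values down-weighted, continuous traits
range-normalised over the species currently included):

* **CWM** — community weighted mean, `Σᵢ pᵢ xᵢ`;
* **FRic** — functional richness: trait range for one continuous trait, or
  the convex hull volume of the species in PCoA space for combined traits;
* **FEve** — functional evenness on the minimum spanning tree of the species:
  with branch values `EWₗ = d_ij / (pᵢ + pⱼ)` and `PEWₗ = EWₗ / Σ EW`,
  `FEve = (Σ min(PEWₗ, 1/(S−1)) − 1/(S−1)) / (1 − 1/(S−1)) ∈ [0, 1]`;
* **RaoQ** — Rao's quadratic entropy `Σᵢⱼ pᵢ pⱼ d_ij`.

Missing trait data are simulated by deleting species trait information
**rarest-first**, each step consuming a fixed slice (default 0.5%) of
relative abundance — splitting a species across steps when it exceeds the
budget — until only 50% remains. Species can be ranked within each plot
(*plot-wise*) or over the pooled dataset (*pool-wise*). At every step all
indices are recomputed from scratch, including the Gower distances, plots are
re-ranked, and the Spearman correlation `ρₛ` with the full-data ranking is
recorded. The decay is summarised by a through-origin regression

```
log ρₛ = β (aₛ − 1)
```

where `aₛ` is the remaining relative abundance; the fitted `β` is the
**robustness slope** — the exponential rate at which rank information is lost
per unit of abundance removed (smaller = more robust).

Abundance transforms `log(x+1)` and `log(x/min(x)+1)` and trait transforms
`sqrt`/`log10` are built in, so the effect of flattening the
dominance-diversity curve or de-skewing a trait can be measured directly.
A seeded synthetic-community generator (lognormal or geometric-series
abundances, turnover between plots, skewed traits, optional rare
extreme-trait outlier species) makes every part testable without any data
downloads.

## Worked example

A ten-species plot with abundances `{1, 2, 3, 4, 4, 7, 9, 14, 33, 89}` has
two-decimal relative abundances `{0.01, 0.01, 0.02, 0.02, 0.02, 0.04, 0.05,
0.08, 0.20, 0.54}`. Removing 5% of relative abundance per step, rarest first
(`examples/02_removal_walkthrough.py`):

```
step 1: removes {'s01': 0.01, 's02': 0.01, 's03': 0.02, 's04': 0.01}
  fully removed so far: 3 species, remaining share 0.949
step 2: removes {'s04': 0.01, 's05': 0.02, 's06': 0.02}
  fully removed so far: 5 species, remaining share 0.899
```

The first step consumes the three rarest species entirely plus 0.01 of the
fourth; the second finishes the fourth, takes the whole fifth, and 0.02 of
the sixth. `examples/03_robustness_pipeline.py` runs the full pipeline on a
synthetic community and prints one slope per configuration, e.g.

```
scenario index trait_set abundance_transform     slope  n_steps
plotwise   CWM      size                none  0.343626       11
plotwise  FRic      size                none  3.647494        9
plotwise  FEve      size                none  7.009603        7
plotwise  RaoQ      size                none  1.211103       11
```

Here CWM loses rank information an order of magnitude more slowly than FEve —
CWM is dominated by the abundant species that are removed last, while FEve is
sensitive to the rare species that disappear first.

The other examples show index computation on a small mixed-trait plot
(`01_fd_indices.py`) and coverage planning against the 80% rule of thumb
(`04_coverage_planning.py`). A thin CLI wraps the same functions:

```bash
fdrobust synth --preset plantlike --seed 7 --outdir data/
fdrobust robustness data/community.csv data/traits.csv --outdir run/
fdrobust coverage data/community.csv --availability data/availability.csv \
    --threshold 0.8 --out priorities.csv
```

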