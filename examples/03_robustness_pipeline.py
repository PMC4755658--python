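"""Full pipeline: simulate trait loss on a synthetic community and fit
robustness slopes.

Generates a small right-skewed community, removes trait data rarest-first in
5% steps down to half the abundance, recomputes every index at every step,
correlates the plot rankings with the full-data ranking, and fits one
through-origin slope of log rank-correlation per index and trait set.  The
slope is the exponential rate at which rank information is lost per unit of
relative abundance removed: smaller = more robust to missing trait data.
"""

import fdrobust as fr

config = fr.SynthConfig(
    n_plots=10, n_species=40, sdlog=1.5, occupancy=0.6,
    continuous_traits={"size": 0.6, "mass": 1.4},
    categorical_traits={"form": 3},
    rare_outlier=True, seed=7,
)
cm, traits, _ = fr.synth_dataset(config)

run = fr.RunConfig(
    scenarios=["plotwise", "poolwise"],
    step_size=0.05, floor=0.5,
    abundance_transforms=["none", "log_plus_one"],
    max_axes=3,
)
results = fr.run_robustness(cm, traits, run)

slopes = results.slopes[results.slopes.flag.isna()]
print(slopes[["scenario", "index", "trait_set", "abundance_transform",
              "slope", "n_steps"]].to_string(index=False))
print()
print("Each row is one configuration; 'slope' is the fitted decay rate of the")
print("Spearman correlation between full-data and reduced-data plot rankings.")
print("Comparing rows with and without the log abundance transform shows how")
print("flattening the dominance structure changes robustness per index.")
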