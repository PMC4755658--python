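"""Compute the four functional diversity indices for one small plot.

Builds a five-species plot with two continuous traits and one categorical
trait, then prints CWM, FRic, FEve and RaoQ per trait set.  CWM is the
abundance-weighted mean trait value; FRic the occupied trait range (or hull
volume for combined traits); FEve the regularity of abundance along the trait
minimum spanning tree (in [0, 1]); RaoQ the expected Gower dissimilarity
between two randomly drawn individuals.
"""

import numpy as np
import pandas as pd

import fdrobust as fr

traits = fr.TraitTable(
    pd.DataFrame(
        {
            "height_cm": [12.0, 85.0, 40.0, 8.0, 120.0],
            "seed_mass_mg": [0.2, 4.1, 1.0, 0.4, 15.0],
            "growth_form": ["herb", "shrub", "herb", "herb", "tree"],
        },
        index=["sp1", "sp2", "sp3", "sp4", "sp5"],
    ),
    {"height_cm": "continuous", "seed_mass_mg": "continuous",
     "growth_form": "categorical"},
)
abundance = np.array([50.0, 10.0, 25.0, 12.0, 3.0])

results = fr.compute_all(abundance, traits, plot_id="meadow-plot")
print(fr.results_to_frame(results).to_string(index=False))
print()
print("CWM rows give the abundance-weighted mean of each continuous trait;")
print("'all' combines every trait through a Gower distance matrix, so CWM is")
print("flagged there (it is a single-trait statistic) while FRic/FEve/RaoQ use")
print("the multivariate trait space.")
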