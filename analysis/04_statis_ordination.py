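#!/usr/bin/env python
"""STATIS ordination: subject weights, compromise time-point scores,
per-subject trajectories and metabolite loadings.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from dexmet.cohort import read_cohort
from dexmet.preprocess import preprocess
from dexmet.statis import fit_statis, metabolite_loadings, project_tables

ap = argparse.ArgumentParser()
ap.add_argument("--cohort", type=Path, default=Path("results/cohort"))
ap.add_argument("--out", type=Path, default=Path("results"))
ap.add_argument("--axes", type=int, default=2)
args = ap.parse_args()

proc = preprocess(read_cohort(args.cohort))
model = fit_statis(proc)
args.out.mkdir(parents=True, exist_ok=True)
model.weights_frame().to_csv(args.out / "statis_weights.csv")
model.scores_frame(args.axes).to_csv(args.out / "statis_scores.csv")
project_tables(model, args.axes).to_csv(args.out / "statis_trajectories.csv", index=False)
metabolite_loadings(proc, model, args.axes).to_csv(args.out / "statis_loadings.csv")
pd.DataFrame({
    "axis": [f"axis{a + 1}" for a in range(len(model.eigenvalues))],
    "eigenvalue": model.eigenvalues,
    "explained_variance": model.explained_variance,
}).to_csv(args.out / "statis_explained_variance.csv", index=False)

w = model.weights_frame()["weight"]
print(f"subject weights: {w.min():.3f} (most dissimilar: {w.idxmin()}) to "
      f"{w.max():.3f} (most similar: {w.idxmax()}); equal-weight value "
      f"1/sqrt(20) = {1 / np.sqrt(20):.3f}")
ev = model.explained_variance
print(f"compromise axes 1+2 explain {100 * ev[:2].sum():.1f}% "
      f"({100 * ev[0]:.1f}% + {100 * ev[1]:.1f}%)")
scores = model.scores_frame(2)
treated = ["d3_evening", "d4_morning", "d4_midday", "d4_evening"]
sep = scores.loc[treated, "axis2"].mean() - scores.drop(treated)["axis2"].mean()
print(f"treated-vs-untreated separation on axis 2: {sep:+.2f} score units")
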