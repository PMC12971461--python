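#!/usr/bin/env python
"""Per-layer structure-function regression on a synthetic cohort.

Builds a small per-animal cohort in which GLAST density predicts seizure
frequency strongly in layer III, weakly in layer I and not at all in layer
II (the laminar gradient the pipeline is designed to resolve), fits simple
linear regressions per layer and serializes the R^2 grid.
"""

from pathlib import Path

import pandas as pd

import ictalkit as ik
from ictalkit.synthetic import SyntheticCohortSpec, gen_cohort

ROOT = Path(__file__).resolve().parents[1]

# (layer, slope, noise_sd): deepening structure-function coupling
LAYER_PLAN = [("I", 0.8, 0.6), ("II", 0.0, 0.8), ("III", 2.0, 0.15)]


def main() -> None:
    frames = []
    for i, (layer, slope, noise) in enumerate(LAYER_PLAN):
        cohort = gen_cohort(SyntheticCohortSpec(
            n_animals=6, slope=slope, intercept=1.0, noise_sd=noise,
            predictor_range=(0.0, 1.0), seed=40 + i))
        cohort = cohort.rename(columns={"predictor": "glast_density",
                                        "response": "seizure_freq"})
        cohort["layer"] = layer
        frames.append(cohort)
    cohort = pd.concat(frames, ignore_index=True)
    cohort.to_csv(ROOT / "results" / "cohort.csv", index=False)

    grid = ik.r2_matrix(cohort, ["glast_density"], ["seizure_freq"],
                        layers=["I", "II", "III"])
    grid.to_csv(ROOT / "results" / "r2_grid.csv", index=False)
    print(grid.to_string(index=False))
    best = grid.loc[grid.r_squared.idxmax()]
    print(f"\nstrongest coupling in layer {best.layer} "
          f"(R^2 = {best.r_squared:.3f}, slope = {best.slope:.2f}), "
          "consistent with a depth-dependent structure-function gradient")
    print("wrote results/cohort.csv and results/r2_grid.csv")


if __name__ == "__main__":
    main()
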