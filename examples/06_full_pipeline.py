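"""The full pipeline: simulate → intensity → exposure → mvpa → fit → report.

Runs a small demo city end to end and prints the measure × distance
pattern table — exp(β), p and AIC for the exposure term of each gamma
log-link model — which is the analysis's headline output.
"""

import pandas as pd

import moveability as mv
from moveability.pipeline import PipelineConfig, run_pipeline

config = PipelineConfig(
    out_dir="scratch/example_run",
    seed=11,
    city=mv.CityConfig(window_width_m=1600.0, window_height_m=1250.0,
                       points_per_1000_residents={"transit": 12.0,
                                                  "open_space": 10.0}),
    cohort=mv.CohortConfig(n_children=60),
    exposure=mv.ExposureConfig(distances_m=[500.0, 1000.0, 1500.0],
                               cell_size_m=50.0),
    n_days=4,
    layers=["transit", "open_space"],
    strata=[("school", "all")],
)

manifest = run_pipeline(config)
print("stages:", {k: v["status"] for k, v in manifest["stages"].items()})

pattern = pd.read_csv("scratch/example_run/pattern.csv")
print("\npattern table (open space, school children):")
sub = pattern[pattern.kind == "open_space"]
print(sub.pivot(index="measure", columns="distance_m",
                values="exp_beta").round(3).to_string())

# Rows are the seven intensity measures, columns the network-distances;
# each cell is the multiplicative MVPA effect of one unit (1 point/km²)
# of open-space intensity. Re-running with the same seed reproduces the
# manifest checksums exactly.
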