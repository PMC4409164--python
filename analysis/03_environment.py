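#!/usr/bin/env python
"""Granulometry summaries and salinity-range models.

Builds cumulative grain-size curves for each station of the simulated
survey (sand-mud mixture distributions), reduces them to D50, D10 and
the six size-class percentages, fits the two estuary-specific
salinity-range models (range vs mean salinity; range vs distance from
the tidal head) and assembles the 14-driver environmental matrix.
Requires 01_simulate.py to have run. Writes results/granulometry_*.csv
and results/env_assembled_*.csv.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from estmeio import envfeat
from estmeio.envfeat import GrainSizeDistribution
from estmeio.io import read_env_matrix

ROOT = Path(__file__).resolve().parents[1]


def curves_from_env(env: pd.DataFrame, rng) -> dict:
    """Per-station cumulative curves consistent with the env matrix's
    class fractions (log-linear within classes, jittered edges)."""
    edges = np.array([0.24, 4.0, 63.0, 250.0, 500.0, 2000.0, 8000.0])
    frac_cols = ["pct_clay", "pct_silt", "pct_fine_sand",
                 "pct_medium_sand", "pct_coarse_sand", "pct_gravel"]
    out = {}
    for station, row in env.iterrows():
        cum = np.concatenate([[0.0], np.cumsum(row[frac_cols].values)])
        cum[-1] = 100.0
        # refine each class with interior points on the same curve
        log2e = np.log2(edges)
        fine_x = np.unique(np.concatenate(
            [log2e, log2e[:-1] + np.diff(log2e) * rng.uniform(0.3, 0.7)]
        ))
        fine_c = np.interp(fine_x, log2e, cum)
        out[station] = GrainSizeDistribution(2.0 ** fine_x, fine_c)
    return out


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--data", type=Path,
                    default=ROOT / "results" / "data")
    ap.add_argument("--out", type=Path, default=ROOT / "results")
    args = ap.parse_args()
    rng = np.random.default_rng(args.seed)
    args.out.mkdir(parents=True, exist_ok=True)

    for name in ("thames", "mersey"):
        env = read_env_matrix(args.data / f"{name}_env.csv")
        gran_rows = {}
        for station, dist in curves_from_env(env, rng).items():
            summ = envfeat.summarize_granulometry(dist)
            gran_rows[station] = vars(summ)
        gran = pd.DataFrame(gran_rows).T.rename_axis("station")
        gran.to_csv(args.out / f"granulometry_{name}.csv")

        # the range-predictor relation is monotone only seaward of the
        # mid-estuary range maximum, so the linear model is fitted on
        # the outer-estuary stations (as gauge-anchored relations are)
        outer = env["distance_km"] >= env["distance_km"].median()
        if name == "thames":
            # spot-sampled estuary: range inferred from mean salinity
            model = envfeat.fit_salinity_range_model(
                env.loc[outer, "mean_salinity"],
                env.loc[outer, "salinity_range"],
                kind="mean-salinity-regression",
            )
            pred = env["salinity_range"].copy()
            pred[outer] = model.predict(
                env.loc[outer, "mean_salinity"]
            )
        else:
            # gauged estuary: range against distance from the head
            model = envfeat.fit_salinity_range_model(
                env.loc[outer, "distance_km"],
                env.loc[outer, "salinity_range"],
                kind="distance-regression",
            )
            pred = env["salinity_range"].copy()
            pred[outer] = model.predict(env.loc[outer, "distance_km"])
        print(
            f"{name}: salinity-range model ({model.kind}, outer "
            f"estuary, n={model.n_obs}) slope={model.slope:.3f}, "
            f"R2={model.r_squared:.2f}; D50 span "
            f"{gran['d50_um'].min():.0f}-"
            f"{gran['d50_um'].max():.0f} um"
        )

        assembled = envfeat.assemble_env_matrix(
            env[["spring_tidal_range", "mean_velocity", "max_velocity",
                 "mean_bed_shear_stress", "max_bed_shear_stress"]],
            gran,
            pd.Series(pred, index=env.index, name="salinity_range"),
        )
        assembled["core"].to_csv(
            args.out / f"env_assembled_{name}.csv"
        )
    print(f"outputs written to {args.out}")


if __name__ == "__main__":
    main()
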