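#!/usr/bin/env python
"""Community structure along the two salinity gradients.

Reduces each estuary's OTU table to presence/absence over the eleven
metazoan target phyla, computes Sørensen dissimilarities, group-average
dendrograms with SIMPROF group tests, NMDS ordinations and richness
tables, and compares station richness between estuaries with
Levene-gated t-tests. Requires 01_simulate.py. Writes dendrograms
(newick), NMDS coordinates, SIMPROF groups and the t-test table under
results/.
"""

import argparse
from pathlib import Path

import pandas as pd

from estmeio import commstats
from estmeio.io import read_otu_table

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--data", type=Path,
                    default=ROOT / "results" / "data")
    ap.add_argument("--out", type=Path, default=ROOT / "results")
    ap.add_argument("--profile-perms", type=int, default=100)
    ap.add_argument("--test-perms", type=int, default=199)
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    station_rich = {}
    for name in ("thames", "mersey"):
        table = read_otu_table(args.data / f"{name}_otu_table.tsv",
                               args.data / f"{name}_samples.tsv")
        P = commstats.to_presence(table)
        D = commstats.sorensen_dissimilarity(P)
        dend = commstats.upgma(D)
        (args.out / f"{name}_dendrogram.nwk").write_text(
            dend.to_newick() + "\n"
        )
        sp = commstats.simprof(
            P, n_profile_perms=args.profile_perms,
            n_test_perms=args.test_perms, seed=args.seed,
        )
        groups = pd.DataFrame(
            [(g + 1, s) for g, grp in enumerate(sp.groups)
             for s in grp],
            columns=["group", "sample"],
        )
        groups.to_csv(args.out / f"{name}_simprof_groups.csv",
                      index=False)
        ordn = commstats.nmds(D, seed=args.seed)
        ordn.coords.to_csv(args.out / f"{name}_nmds.csv")
        rich = commstats.station_richness(table)
        rich.to_csv(args.out / f"{name}_richness_station.csv")
        station_rich[name] = rich
        n25 = len(dend.cut(0.75))
        print(
            f"{name}: {P.shape[0]} samples, {P.shape[1]} metazoan "
            f"OTUs; SIMPROF {sp.n_groups} groups; {n25} groups at "
            f"25% similarity; NMDS stress {ordn.stress:.3f}"
        )

    rows = []
    ra, rb = station_rich["thames"], station_rich["mersey"]
    shared = [c for c in ra.columns if c in rb.columns]
    for target in ["total"] + shared:
        xa = ra.sum(axis=1) if target == "total" else ra[target]
        xb = rb.sum(axis=1) if target == "total" else rb[target]
        if xa.std(ddof=1) == 0 and xb.std(ddof=1) == 0:
            continue
        tt = commstats.welch_levene_ttest(xa.values, xb.values)
        rows.append({"response": target, "t": tt.t, "df": tt.df,
                     "p": tt.p, "levene_p": tt.levene_p,
                     "pooled": tt.pooled})
    ttests = pd.DataFrame(rows)
    ttests.to_csv(args.out / "richness_ttests.csv", index=False)
    total = ttests[ttests["response"] == "total"].iloc[0]
    print(
        f"total richness t-test: t_{total['df']:.0f}="
        f"{total['t']:.3f}, P={total['p']:.3f}"
    )


if __name__ == "__main__":
    main()
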