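"""End-to-end orchestration of the two-estuary analysis.

``run_full`` drives the whole chain on a synthetic scenario pair:
simulate → community statistics (richness, Sørensen/UPGMA/SIMPROF,
NMDS) → driver inference (BIOENV, Mantel isolation-by-distance, CCA
with collinearity filter + stepwise AIC, PLS-VIP per phylum) → report.
One master seed derives every stage seed, so re-runs with the same
configuration are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from skbio import DistanceMatrix

from . import commstats, drivers, synthio
from .io import ENV_DRIVERS, write_env_matrix, write_otu_table

__all__ = ["AnalysisConfig", "Report", "run_full", "write_report"]


class ConfigError(ValueError):
    pass


@dataclass
class AnalysisConfig:
    """Validated configuration for a full run."""

    master_seed: int = 0
    scenarios: dict = field(default_factory=dict)  # per-estuary overrides
    taxon_filter: list[str] = field(
        default_factory=lambda: list(commstats.METAZOAN_PHYLA)
    )
    n_profile_perms: int = 100
    n_test_perms: int = 199
    simprof_alpha: float = 0.05
    nmds_restarts: int = 4
    bioenv_max_subset_size: int = 4
    bioenv_top_k: int = 10
    cca_n_perm: int = 199
    mantel_n_perm: int = 499
    pls_n_components: int = 2
    pls_min_otus: int = 10
    collinearity_threshold: float = 0.7
    collinearity_prefer: list[str] = field(
        default_factory=lambda: ["mean_velocity", "d50",
                                 "salinity_range"]
    )
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if self.master_seed < 0:
            raise ConfigError("master_seed must be non-negative")
        for name in ("n_profile_perms", "n_test_perms", "cca_n_perm",
                     "mantel_n_perm"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1")
        if not self.taxon_filter:
            raise ConfigError("taxon_filter must not be empty")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage seed below 2^31."""
        digest = hashlib.sha256(
            f"{self.master_seed}:{stage}".encode()
        ).digest()
        return int.from_bytes(digest[:4], "big") % (2 ** 31)


@dataclass
class Report:
    """Assembled outputs of one full run."""

    datasets: dict
    richness: dict
    ttests: pd.DataFrame
    community: dict
    bioenv: dict
    mantel: dict
    cca: dict
    pls: dict
    provenance: dict


def _scenario_configs(config: AnalysisConfig,
                      ) -> list[synthio.ScenarioConfig]:
    base = {
        "thames": synthio.thames_scenario,
        "mersey": synthio.mersey_scenario,
    }
    out = []
    for name, factory in base.items():
        overrides = dict(config.scenarios.get(name, {}))
        overrides["seed"] = config.stage_seed(f"simulate:{name}")
        out.append(factory(**overrides))
    return out


def _station_distance_matrix(env: pd.DataFrame) -> DistanceMatrix:
    x = env["distance_km"].values
    d = np.abs(x[:, None] - x[None, :])
    return DistanceMatrix(d, ids=list(env.index.astype(str)))


def run_full(config: AnalysisConfig) -> Report:
    """Execute every stage on the synthetic two-estuary scenario."""
    datasets = {}
    for scen in _scenario_configs(config):
        try:
            datasets[scen.name] = synthio.make_dataset(scen)
        except Exception as exc:
            raise RuntimeError(
                f"stage 'simulate' failed for scenario "
                f"{scen.name!r}: {exc}"
            ) from exc

    richness, community, bioenv_res, mantel_res = {}, {}, {}, {}
    cca_res, pls_res = {}, {}
    station_total_richness = {}

    for name, ds in datasets.items():
        table, env = ds.table, ds.env
        sample_rich = commstats.richness_by_group(table, "phylum")
        station_rich = commstats.station_richness(table, "phylum")
        richness[name] = {
            "per_sample": sample_rich,
            "per_station": station_rich,
        }
        station_total_richness[name] = station_rich.sum(axis=1)

        # sample-level community structure
        P = commstats.to_presence(table, config.taxon_filter)
        D = commstats.sorensen_dissimilarity(P)
        dend = commstats.upgma(D)
        simprof = commstats.simprof(
            P,
            n_profile_perms=config.n_profile_perms,
            n_test_perms=config.n_test_perms,
            alpha=config.simprof_alpha,
            seed=config.stage_seed(f"simprof:{name}"),
        )
        ord_ = commstats.nmds(
            D, restarts=config.nmds_restarts,
            seed=config.stage_seed(f"nmds:{name}"),
        )
        community[name] = {
            "presence": P,
            "distance": D,
            "dendrogram": dend,
            "simprof": simprof,
            "nmds": ord_,
        }

        # station-level driver inference
        P_station = commstats.pool_replicates(P, table.samples)
        D_station = commstats.sorensen_dissimilarity(P_station)
        E = env.loc[list(P_station.index), ENV_DRIVERS]
        bioenv_res[name] = drivers.bioenv(
            D_station, E,
            max_subset_size=config.bioenv_max_subset_size,
            top_k=config.bioenv_top_k,
        )
        mantel_res[name] = drivers.mantel(
            D_station,
            _station_distance_matrix(env.loc[P_station.index]),
            n_perm=config.mantel_n_perm,
            seed=config.stage_seed(f"mantel:{name}"),
        )
        E_reduced, removed = drivers.filter_collinear(
            E, threshold=config.collinearity_threshold,
            prefer=config.collinearity_prefer,
        )
        step = drivers.cca_stepwise_aic(
            P_station.astype(float), E_reduced,
            n_perm=config.cca_n_perm,
            seed=config.stage_seed(f"cca:{name}"),
        )
        cca_res[name] = {"result": step, "removed": removed,
                         "candidates": list(E_reduced.columns)}
        # CCA on the full retained (post-filter) variable set, the
        # basis for the first-two-axes inertia share of the biplot
        if E_reduced.shape[1] >= 2:
            cca_res[name]["retained_model"] = drivers.cca(
                P_station.astype(float), E_reduced
            )

        # PLS-VIP per response: total + phyla with enough OTUs
        phylum_counts = table.taxonomy["phylum"].value_counts()
        responses = {"total": station_rich.sum(axis=1)}
        for ph in config.taxon_filter:
            if phylum_counts.get(ph, 0) >= config.pls_min_otus:
                if ph in station_rich.columns:
                    responses[ph] = station_rich[ph]
        pls_res[name] = {}
        for resp_name, y in responses.items():
            y = y.loc[E.index]
            if y.std(ddof=1) == 0:
                warnings.warn(
                    f"constant richness for {resp_name} in {name}; "
                    "PLS skipped", stacklevel=2,
                )
                continue
            pls_res[name][resp_name] = drivers.pls_vip(
                E, y, n_components=config.pls_n_components,
                n_perm=199,
                seed=config.stage_seed(f"pls:{name}:{resp_name}"),
            )

    # cross-estuary richness t-tests per phylum (station level)
    names = list(datasets)
    trows = []
    if len(names) == 2:
        a, b = names
        ra = richness[a]["per_station"]
        rb = richness[b]["per_station"]
        targets = ["total"] + [
            ph for ph in config.taxon_filter
            if ph in ra.columns and ph in rb.columns
        ]
        for target in targets:
            xa = (station_total_richness[a] if target == "total"
                  else ra[target])
            xb = (station_total_richness[b] if target == "total"
                  else rb[target])
            if xa.std(ddof=1) == 0 and xb.std(ddof=1) == 0:
                continue
            tt = commstats.welch_levene_ttest(xa.values, xb.values)
            trows.append(
                {"response": target, "t": tt.t, "df": tt.df,
                 "p": tt.p, "levene_p": tt.levene_p,
                 "pooled": tt.pooled}
            )
    ttests = pd.DataFrame(trows)

    provenance = {
        "master_seed": config.master_seed,
        "config": {
            k: v for k, v in asdict(config).items()
            if not isinstance(v, (pd.DataFrame,))
        },
        "stage_seeds": {
            s: config.stage_seed(s)
            for s in [f"simulate:{n}" for n in names]
        },
    }
    return Report(
        datasets=datasets,
        richness=richness,
        ttests=ttests,
        community=community,
        bioenv=bioenv_res,
        mantel=mantel_res,
        cca=cca_res,
        pls=pls_res,
        provenance=provenance,
    )


def write_report(report: Report, out_dir: str | Path) -> list[Path]:
    """Write every numeric table of the report as text files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def save(df: pd.DataFrame, name: str, **kw) -> None:
        path = out / name
        df.to_csv(path, **kw)
        written.append(path)

    for name, ds in report.datasets.items():
        write_otu_table(
            ds.table, out / f"{name}_otu_table.tsv",
            out / f"{name}_samples.tsv",
        )
        write_env_matrix(ds.env, out / f"{name}_env.csv")
        ds.truth.to_json(out / f"{name}_truth.json")
        written += [
            out / f"{name}_otu_table.tsv", out / f"{name}_samples.tsv",
            out / f"{name}_env.csv", out / f"{name}_truth.json",
        ]
    for name in report.richness:
        save(report.richness[name]["per_station"],
             f"{name}_richness_station.csv")
    if len(report.ttests):
        save(report.ttests, "richness_ttests.csv", index=False)
    for name, comm in report.community.items():
        save(comm["nmds"].coords, f"{name}_nmds.csv")
        (out / f"{name}_dendrogram.nwk").write_text(
            comm["dendrogram"].to_newick() + "\n"
        )
        groups = pd.DataFrame(
            [
                {"group": g + 1, "sample": s}
                for g, grp in enumerate(comm["simprof"].groups)
                for s in grp
            ]
        )
        save(groups, f"{name}_simprof_groups.csv", index=False)
    for name, res in report.bioenv.items():
        tbl = res.table.copy()
        tbl["variables"] = tbl["variables"].map(lambda v: ", ".join(v))
        save(tbl, f"{name}_bioenv_top{res.top_k}.csv", index=False)
    summary = {
        name: {
            "mantel_rho": report.mantel[name].rho,
            "mantel_p": report.mantel[name].p_value,
            "cca_selected": report.cca[name]["result"].variables,
            "cca_total_inertia":
                report.cca[name]["result"].total_inertia,
            "cca_constrained_inertia":
                report.cca[name]["result"].constrained_inertia,
            "cca_first_two_axes_fraction":
                report.cca[name]["result"].first_two_axes_fraction,
            "cca_variable_p": report.cca[name]["result"].variable_p,
            "simprof_n_groups":
                report.community[name]["simprof"].n_groups,
            "nmds_stress": report.community[name]["nmds"].stress,
        }
        for name in report.datasets
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(
            {"estuaries": summary, "provenance": report.provenance},
            fh, indent=1, default=str,
        )
    written.append(out / "summary.json")
    for name, per_resp in report.pls.items():
        frames = {}
        for resp, res in per_resp.items():
            frames[resp] = res.table["vip1"]
        if frames:
            save(pd.DataFrame(frames), f"{name}_pls_vip1.csv")
    return written
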