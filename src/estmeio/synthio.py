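"""Synthetic estuary scenarios with known ground truth.

Emulates the sampling design of a paired-estuary meiofaunal
metabarcoding survey: two contrasting estuaries (20 and 15 intertidal
stations, 3 replicate sediment cores each), a seaward-increasing
salinity gradient with a mid-estuary peak in tidal salinity *range*,
station-level granulometry and hydrodynamic metrics, and estuary-specific
taxon pools whose occupancy responds to assigned environmental drivers
on the logit scale.

The generator is the ground-truth oracle for the driver-inference
suite: every OTU's logistic occupancy coefficients are stored in a
:class:`TruthRecord`, so downstream methods (BIOENV, CCA, PLS-VIP) can
be scored on whether they recover the planted drivers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .io import ENV_DRIVERS, OtuTable

__all__ = [
    "ScenarioConfig",
    "TruthRecord",
    "SyntheticDataset",
    "thames_scenario",
    "mersey_scenario",
    "generate_env_gradient",
    "generate_community",
    "generate_reads",
    "make_dataset",
    "salinity_zone",
]


class ConfigError(ValueError):
    """Raised for invalid scenario configurations."""


#: Venice-system salinity zone bounds (p.p.t.).
VENICE_ZONES = [
    ("freshwater", 0.0, 0.5),
    ("oligohaline", 0.5, 5.0),
    ("mesohaline", 5.0, 18.0),
    ("polyhaline", 18.0, 30.0),
    ("euhaline", 30.0, 40.0),
]


def salinity_zone(salinity_ppt: float) -> str:
    """Venice-system zone label for a mean salinity in p.p.t."""
    for name, lo, hi in VENICE_ZONES:
        if lo <= salinity_ppt < hi:
            return name
    return "hyperhaline"


@dataclass(frozen=True)
class ScenarioConfig:
    """Parameters of one synthetic estuary.

    ``driver_effects`` maps a phylum to a list of ``(driver, beta)``
    or ``(driver, beta, sd)`` entries; each OTU of the phylum draws
    its slope from ``Normal(beta, sd)`` (default sd = 0.25·|beta|),
    the occupancy log-odds change per standard deviation of the
    driver across stations. A directional ``beta`` plants a richness
    trend along the driver; a zero-mean ``beta`` with a large ``sd``
    plants pure turnover (taxon replacement with no net richness
    change), the structure a salinity ecocline produces.
    """

    name: str = "estuary"
    n_stations: int = 20
    n_replicates: int = 3
    channel_length_km: float = 106.0
    mouth_salinity: float = 34.0
    salinity_range_max: float = 14.16
    taxon_pool: dict[str, int] = field(default_factory=dict)
    driver_effects: dict[str, list[tuple[str, float]]] = field(
        default_factory=dict
    )
    occupancy_intercept: float = -0.8
    replicate_noise_sd: float = 0.35
    reads_per_sample: tuple[int, int] = (1044, 30786)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_stations < 2:
            raise ConfigError("n_stations must be >= 2")
        if self.n_replicates < 1:
            raise ConfigError("n_replicates must be >= 1")
        if self.channel_length_km <= 0:
            raise ConfigError("channel_length_km must be positive")
        if any(n < 0 for n in self.taxon_pool.values()):
            raise ConfigError("taxon pool sizes must be >= 0")
        lo, hi = self.reads_per_sample
        if lo > hi:
            raise ConfigError("reads_per_sample range has min > max")
        unknown = set(self.driver_effects) - set(self.taxon_pool)
        if unknown:
            raise ConfigError(
                f"driver_effects for phyla absent from taxon_pool: "
                f"{sorted(unknown)}"
            )
        for effects in self.driver_effects.values():
            for entry in effects:
                if len(entry) not in (2, 3):
                    raise ConfigError(
                        "driver effect entries are (driver, beta) or "
                        "(driver, beta, sd)"
                    )
                if entry[0] not in ENV_DRIVERS:
                    raise ConfigError(f"unknown driver {entry[0]!r}")


#: Per-phylum OTU pool sizes emulating a nematode-dominated meiofaunal
#: community (Nematoda richest by a wide margin, then Arthropoda and
#: Platyhelminthes, with a tail of rarer metazoan phyla).
_THAMES_POOL = {
    "Nematoda": 260,
    "Arthropoda": 72,
    "Platyhelminthes": 46,
    "Annelida": 34,
    "Mollusca": 24,
    "Gastrotricha": 16,
    "Tardigrada": 11,
    "Kinorhyncha": 9,
    "Rotifera": 9,
    "Cnidaria": 7,
    "Bryozoa": 5,
}

_MERSEY_POOL = {
    "Nematoda": 233,
    "Arthropoda": 60,
    "Platyhelminthes": 40,
    "Annelida": 26,
    "Mollusca": 19,
    "Gastrotricha": 13,
    "Tardigrada": 9,
    "Kinorhyncha": 7,
    "Rotifera": 8,
    "Cnidaria": 6,
    "Bryozoa": 4,
}

# Default planted effects: wide-spread salinity-range slopes on the
# dominant phyla give ecocline turnover along the gradient, while the
# directional terms plant phylum-specific richness trends (Mollusca
# declining with salinity range, Annelida tracking grain size,
# flow effects of opposite sign in the two estuaries).
_THAMES_EFFECTS = {
    "Nematoda": [("salinity_range", 0.3, 1.0), ("max_velocity", -0.7)],
    "Arthropoda": [("salinity_range", 0.2, 0.9),
                   ("spring_tidal_range", -0.6)],
    "Platyhelminthes": [("d10", 0.8)],
    "Annelida": [("d50", 0.8)],
    "Mollusca": [("salinity_range", -1.2)],
    "Gastrotricha": [("salinity_range", 0.6)],
    "Tardigrada": [("d50", 0.5)],
    "Kinorhyncha": [("salinity_range", 0.5)],
    "Rotifera": [("salinity_range", -0.5)],
    "Cnidaria": [("mean_velocity", 0.4)],
    "Bryozoa": [("spring_tidal_range", 0.4)],
}

_MERSEY_EFFECTS = {
    "Nematoda": [("salinity_range", 0.2, 0.9),
                 ("mean_bed_shear_stress", 0.8), ("mean_velocity", 0.6)],
    "Arthropoda": [("salinity_range", 0.6, 0.8)],
    "Platyhelminthes": [("d10", 0.8)],
    "Annelida": [("mean_bed_shear_stress", 0.6)],
    "Mollusca": [("salinity_range", -0.8)],
    "Gastrotricha": [("salinity_range", 0.5)],
    "Tardigrada": [("d50", 0.5)],
    "Kinorhyncha": [("salinity_range", 0.5)],
    "Rotifera": [("mean_velocity", 0.5)],
    "Cnidaria": [("spring_tidal_range", 0.4)],
    "Bryozoa": [("spring_tidal_range", 0.4)],
}


def thames_scenario(seed: int = 0, **overrides) -> ScenarioConfig:
    """Thames-like scenario: 20 stations over ~106 km."""
    cfg = ScenarioConfig(
        name="thames",
        n_stations=20,
        channel_length_km=106.0,
        salinity_range_max=14.16,
        taxon_pool=dict(_THAMES_POOL),
        driver_effects={k: list(v) for k, v in _THAMES_EFFECTS.items()},
        seed=seed,
    )
    return replace(cfg, **overrides) if overrides else cfg


def mersey_scenario(seed: int = 1, **overrides) -> ScenarioConfig:
    """Mersey-like scenario: 15 stations over ~46 km."""
    cfg = ScenarioConfig(
        name="mersey",
        n_stations=15,
        channel_length_km=46.0,
        salinity_range_max=18.97,
        taxon_pool=dict(_MERSEY_POOL),
        driver_effects={k: list(v) for k, v in _MERSEY_EFFECTS.items()},
        seed=seed,
    )
    return replace(cfg, **overrides) if overrides else cfg


@dataclass
class TruthRecord:
    """Ground truth behind one synthetic dataset."""

    beta0: pd.Series                      # per-OTU intercept (logit)
    beta: pd.DataFrame                    # OTU × driver coefficients (logit)
    env: pd.DataFrame                     # per-station true environment
    zones: pd.Series                      # Venice zone label per station

    def to_json(self, path) -> None:
        import json

        payload = {
            "beta0": self.beta0.to_dict(),
            "beta": {o: row.to_dict() for o, row in self.beta.iterrows()},
            "env": {s: row.to_dict() for s, row in self.env.iterrows()},
            "zones": self.zones.to_dict(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


@dataclass
class SyntheticDataset:
    """One simulated estuary: counts table, environment, ground truth."""

    table: OtuTable
    env: pd.DataFrame
    truth: TruthRecord
    config: ScenarioConfig

    def __post_init__(self) -> None:
        stations = set(self.table.samples["station"])
        if not stations <= set(self.env.index):
            raise ConfigError("sample stations missing from env matrix")


def _station_ids(config: ScenarioConfig) -> list[str]:
    width = len(str(config.n_stations))
    return [
        f"{config.name[:2].upper()}{i + 1:0{width}d}"
        for i in range(config.n_stations)
    ]


def generate_env_gradient(config: ScenarioConfig,
                          rng: np.random.Generator | None = None,
                          ) -> pd.DataFrame:
    """Per-station environmental matrix along the channel.

    Construction (distance ``x`` measured seaward from the tidal head,
    ``s = x/L`` the normalised position):

    * mean salinity: logistic in ``s``, ~0 at the head and approaching
      the mouth value seaward (monotone seaward-increasing);
    * salinity range: scaled beta-shaped curve ``4·s·(1−s)`` peaking
      mid-estuary, bounded by ``salinity_range_max``;
    * granulometry: a log-normal grain-size distribution per station
      whose median coarsens seaward with station-level noise; D50, D10
      and the six Wentworth-class percentages are derived from it and
      therefore internally consistent (fractions sum to 100);
    * hydrodynamics: parametric spring tidal range amplifying seaward,
      a mid-estuary velocity maximum, and quadratic-law bed shear
      stress, each with independent station noise so the 14 drivers are
      correlated but not collinear.
    """
    if config.channel_length_km <= 0:  # pragma: no cover - caught in config
        raise ConfigError("channel length must be positive")
    rng = np.random.default_rng(config.seed) if rng is None else rng
    n = config.n_stations
    stations = _station_ids(config)
    x = np.linspace(0.0, config.channel_length_km, n)
    s = x / config.channel_length_km

    # mean salinity: logistic from head (fresh) to mouth
    mean_sal = config.mouth_salinity / (1.0 + np.exp(-(s - 0.45) / 0.12))
    mean_sal = np.clip(mean_sal + rng.normal(0.0, 0.3, n), 0.0, 40.0)

    # salinity range: unimodal along the channel (largest where the
    # tidal excursion sweeps the steepest part of the salt intrusion),
    # bounded by the config max; local bathymetric control adds
    # station-level scatter
    sal_range = config.salinity_range_max * 4.0 * s * (1.0 - s)
    sal_range *= 1.0 - np.abs(rng.normal(0.0, 0.15, n))
    sal_range = np.clip(sal_range, 0.0, config.salinity_range_max)

    # granulometry: each station's sediment is a sand-mud mixture (the
    # classic estuarine bimodal distribution). The mud fraction
    # declines seaward and the sand mode coarsens seaward, both with
    # independent station-level patchiness; D50, D10 and the six
    # class percentages all derive from the same mixture CDF, so they
    # are internally consistent while no single summary determines
    # the others
    mud_w = np.clip(0.65 - 0.55 * s + rng.normal(0.0, 0.18, n),
                    0.02, 0.95)
    mu_mud = 4.0 + rng.normal(0.0, 0.4, n)          # ~16 um mode
    sg_mud = np.clip(1.5 + rng.normal(0.0, 0.3, n), 0.8, 2.2)
    mu_sand = np.log2(150.0 + 380.0 * s) + rng.normal(0.0, 0.35, n)
    sg_sand = np.clip(0.9 + rng.normal(0.0, 0.25, n), 0.5, 1.6)

    grid = np.linspace(-2.0, 13.0, 601)             # log2 um
    cdf = (
        mud_w[:, None]
        * stats.norm.cdf((grid[None, :] - mu_mud[:, None])
                         / sg_mud[:, None])
        + (1.0 - mud_w[:, None])
        * stats.norm.cdf((grid[None, :] - mu_sand[:, None])
                         / sg_sand[:, None])
    )

    def _quantile(q: float) -> np.ndarray:
        idx = (cdf >= q).argmax(axis=1)
        lo, hi = grid[idx - 1], grid[idx]
        c_lo = cdf[np.arange(n), idx - 1]
        c_hi = cdf[np.arange(n), idx]
        frac = (q - c_lo) / np.maximum(c_hi - c_lo, 1e-12)
        return 2.0 ** (lo + frac * (hi - lo))

    d50 = _quantile(0.5)
    d10 = _quantile(0.1)
    bounds = np.array([4.0, 63.0, 250.0, 500.0, 2000.0])
    cum_b = (
        mud_w[:, None]
        * stats.norm.cdf((np.log2(bounds)[None, :] - mu_mud[:, None])
                         / sg_mud[:, None])
        + (1.0 - mud_w[:, None])
        * stats.norm.cdf((np.log2(bounds)[None, :] - mu_sand[:, None])
                         / sg_sand[:, None])
    ) * 100.0
    cum_full = np.concatenate(
        [np.zeros((n, 1)), cum_b, np.full((n, 1), 100.0)], axis=1
    )
    fracs = np.diff(cum_full, axis=1)   # clay silt fine medium coarse gravel

    # hydrodynamics: tidal range amplifies seaward; velocity peaks
    # mid-estuary; stress follows the quadratic friction law
    spring_range = (1.2 + 5.5 * s ** 1.3) * (
        1.0 + rng.normal(0.0, 0.06, n)
    )
    spring_range = np.clip(spring_range, 0.0, None)
    # velocity maximum sits seaward of mid-estuary (funnel convergence)
    mean_vel = (
        0.25 + 0.9 * np.sin(np.pi * np.clip(s, 0, 1) ** 0.6) ** 1.2
    ) * (1.0 + rng.normal(0.0, 0.12, n))
    mean_vel = np.clip(mean_vel, 0.0, None)
    max_vel = mean_vel * (1.5 + np.abs(rng.normal(0.0, 0.12, n)))
    rho_cd = 1025.0 * 2.5e-3
    mean_tau = rho_cd * mean_vel ** 2
    max_tau = rho_cd * max_vel ** 2

    env = pd.DataFrame(
        {
            "spring_tidal_range": spring_range,
            "mean_velocity": mean_vel,
            "max_velocity": max_vel,
            "mean_bed_shear_stress": mean_tau,
            "max_bed_shear_stress": max_tau,
            "d50": d50,
            "d10": d10,
            "pct_clay": fracs[:, 0],
            "pct_silt": fracs[:, 1],
            "pct_fine_sand": fracs[:, 2],
            "pct_medium_sand": fracs[:, 3],
            "pct_coarse_sand": fracs[:, 4],
            "pct_gravel": fracs[:, 5],
            "salinity_range": sal_range,
            "distance_km": x,
            "mean_salinity": mean_sal,
        },
        index=pd.Index(stations, name="station"),
    )
    return env


def generate_community(config: ScenarioConfig, env: pd.DataFrame,
                       rng: np.random.Generator | None = None,
                       ) -> tuple[OtuTable, TruthRecord]:
    """Presence/absence community from logistic occupancy.

    Occupancy of OTU *j* in sample *i* is Bernoulli with
    ``logit p = beta0_j + sum_k beta_kj * z_k(station_i) + delta_ir``
    where ``z_k`` are station-level driver z-scores, ``beta_kj`` is
    nonzero only for the drivers assigned to *j*'s phylum, and
    ``delta_ir`` is a per-replicate Normal(0, replicate_noise_sd)
    logit offset shared across OTUs of the replicate.
    """
    if len(env) < 2:
        raise ConfigError("environmental matrix needs >= 2 stations")
    rng = (
        np.random.default_rng(config.seed + 1_000_003)
        if rng is None
        else rng
    )
    stations = list(env.index)

    def _z(c: pd.Series) -> pd.Series:
        sd = c.std(ddof=1)
        # a driver constant across stations carries no signal
        return (c - c.mean()) / sd if sd > 0 else c * 0.0

    z = env[ENV_DRIVERS].apply(_z, axis=0)

    otu_ids, phyla, families = [], [], []
    rows_beta0, rows_beta = [], []
    for phylum, pool in config.taxon_pool.items():
        effects = config.driver_effects.get(phylum, [])
        n_families = max(1, pool // 8)
        for j in range(pool):
            otu_ids.append(f"{config.name}_{phylum}_{j + 1:04d}")
            phyla.append(phylum)
            families.append(f"{phylum}_fam{(j % n_families) + 1:02d}")
            rows_beta0.append(
                config.occupancy_intercept + rng.normal(0.0, 0.5)
            )
            beta = dict.fromkeys(ENV_DRIVERS, 0.0)
            for entry in effects:
                drv, eff = entry[0], entry[1]
                sd = entry[2] if len(entry) == 3 else 0.25 * abs(eff)
                # per-OTU slope around the phylum-level effect
                beta[drv] = rng.normal(eff, sd)
            rows_beta.append(beta)

    beta0 = pd.Series(rows_beta0, index=pd.Index(otu_ids, name="otu_id"))
    beta = pd.DataFrame(rows_beta, index=beta0.index)

    sample_ids, sample_station, sample_rep = [], [], []
    logits = []
    for st in stations:
        zvec = z.loc[st].values
        eta_station = beta0.values + beta.values @ zvec
        for r in range(1, config.n_replicates + 1):
            sample_ids.append(f"{st}_r{r}")
            sample_station.append(st)
            sample_rep.append(r)
            delta = rng.normal(0.0, config.replicate_noise_sd)
            logits.append(eta_station + delta)

    p = 1.0 / (1.0 + np.exp(-np.asarray(logits)))     # samples × OTUs
    presence = (rng.random(p.shape) < p).astype(np.int64)

    counts = pd.DataFrame(
        presence.T, index=beta0.index, columns=sample_ids
    )
    taxonomy = pd.DataFrame(
        {"phylum": phyla, "family": families}, index=beta0.index
    )
    samples = pd.DataFrame(
        {
            "station": sample_station,
            "replicate": sample_rep,
            "estuary": config.name,
        },
        index=pd.Index(sample_ids, name="sample"),
    )
    table = OtuTable(counts=counts, taxonomy=taxonomy, samples=samples)
    truth = TruthRecord(
        beta0=beta0,
        beta=beta,
        env=env.copy(),
        zones=env["mean_salinity"].map(salinity_zone).rename("zone"),
    )
    return table, truth


def generate_reads(presence: OtuTable, config: ScenarioConfig,
                   rng: np.random.Generator | None = None) -> OtuTable:
    """Multinomial read counts over present OTUs.

    Present OTUs in a sample receive multinomial reads with log-normal
    relative abundances (sdlog 1); the per-sample total is uniform on
    ``config.reads_per_sample``. Absent OTUs receive 0 reads. Samples
    with no present OTU stay all-zero and are flagged with a warning.
    """
    vals = presence.counts.values
    if not np.isin(vals, (0, 1)).all():
        raise ConfigError("generate_reads expects a 0/1 presence table")
    rng = (
        np.random.default_rng(config.seed + 2_000_003)
        if rng is None
        else rng
    )
    lo, hi = config.reads_per_sample
    if lo > hi:
        raise ConfigError("reads_per_sample range has min > max")
    counts = np.zeros_like(vals)
    empty = []
    for k, sample in enumerate(presence.counts.columns):
        present = np.flatnonzero(vals[:, k])
        if present.size == 0:
            empty.append(sample)
            continue
        total = int(rng.integers(lo, hi + 1))
        w = rng.lognormal(0.0, 1.0, present.size)
        counts[present, k] = rng.multinomial(total, w / w.sum())
    if empty:
        warnings.warn(
            f"samples with no present OTUs left all-zero: {empty}",
            stacklevel=2,
        )
    return OtuTable(
        counts=pd.DataFrame(
            counts, index=presence.counts.index,
            columns=presence.counts.columns,
        ),
        taxonomy=presence.taxonomy.copy(),
        samples=presence.samples.copy(),
    )


def make_dataset(config: ScenarioConfig) -> SyntheticDataset:
    """Environment → presence community → read counts, one seed."""
    rng = np.random.default_rng(config.seed)
    env = generate_env_gradient(config, rng=rng)
    presence, truth = generate_community(config, env, rng=rng)
    table = generate_reads(presence, config, rng=rng)
    return SyntheticDataset(table=table, env=env, truth=truth,
                            config=config)
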