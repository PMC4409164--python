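"""Non-hydrodynamic environmental drivers.

Granulometry summaries (D50, D10 and six Wentworth-style size-class
percentages) are read off cumulative grain-size distributions by
linear interpolation on the log2 (phi) size scale, the sedimentological
convention. Salinity range is inferred per estuary from a simple
linear model — either against mean salinity (spot-sample estuaries) or
against distance from the tidal head (gauged estuaries) — with
predictions clipped at zero. The assembled environmental matrix holds
the 14 candidate drivers in canonical order, with optional macrofauna
metrics appended for the stations that have them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import ENV_DRIVERS, MACROFAUNA_COLUMNS

__all__ = [
    "GrainSizeDistribution",
    "GranulometrySummary",
    "SalinityRangeModel",
    "percentile_diameter",
    "size_fractions",
    "summarize_granulometry",
    "fit_salinity_range_model",
    "assemble_env_matrix",
    "SIZE_CLASS_BOUNDS_UM",
    "SIZE_CLASS_NAMES",
]

#: Wentworth-style class bounds (μm): clay <4, silt 4–63, fine sand
#: 63–250 (absorbing very-fine sand), medium 250–500, coarse 500–2000,
#: gravel >2000.
SIZE_CLASS_BOUNDS_UM = np.array([4.0, 63.0, 250.0, 500.0, 2000.0])
SIZE_CLASS_NAMES = [
    "pct_clay",
    "pct_silt",
    "pct_fine_sand",
    "pct_medium_sand",
    "pct_coarse_sand",
    "pct_gravel",
]


class DistributionError(ValueError):
    """Raised for invalid cumulative grain-size distributions."""


@dataclass
class GrainSizeDistribution:
    """Cumulative percent-finer curve over increasing sizes (μm)."""

    sizes_um: np.ndarray
    cum_pct: np.ndarray

    def __post_init__(self) -> None:
        self.sizes_um = np.asarray(self.sizes_um, dtype=float)
        self.cum_pct = np.asarray(self.cum_pct, dtype=float)
        if self.sizes_um.size != self.cum_pct.size:
            raise DistributionError("sizes and cumulative arrays differ")
        if self.sizes_um.size < 2:
            raise DistributionError("need at least two bin edges")
        if (np.diff(self.sizes_um) <= 0).any():
            raise DistributionError("sizes must be strictly increasing")
        if (self.sizes_um <= 0).any():
            raise DistributionError("sizes must be positive")
        if (np.diff(self.cum_pct) < -1e-9).any():
            raise DistributionError("cumulative percent must be "
                                    "non-decreasing")
        if abs(self.cum_pct[-1] - 100.0) > 0.5:
            raise DistributionError(
                f"cumulative curve ends at {self.cum_pct[-1]:.2f}%, "
                "expected 100 ± 0.5"
            )


@dataclass
class GranulometrySummary:
    d50_um: float
    d10_um: float
    pct_clay: float
    pct_silt: float
    pct_fine_sand: float
    pct_medium_sand: float
    pct_coarse_sand: float
    pct_gravel: float


def percentile_diameter(dist: GrainSizeDistribution, q: float) -> float:
    """Diameter (μm) at cumulative percent *q*, log2-interpolated.

    Returns the exact bin edge when the cumulative curve hits *q*
    there; raises if *q* lies outside the observed cumulative span
    (no extrapolation).
    """
    if not 0.0 < q < 100.0:
        raise ValueError("q must be strictly between 0 and 100")
    c = dist.cum_pct
    exact = np.flatnonzero(np.isclose(c, q))
    if exact.size:
        return float(dist.sizes_um[exact[0]])
    if q < c[0] or q > c[-1]:
        raise DistributionError(
            f"q={q}% outside the observed cumulative span "
            f"[{c[0]:.2f}, {c[-1]:.2f}]%"
        )
    # piecewise-linear in log2(size); interp handles flat segments by
    # taking the first crossing
    log2_d = np.interp(q, c, np.log2(dist.sizes_um))
    return float(2.0 ** log2_d)


def size_fractions(dist: GrainSizeDistribution) -> dict[str, float]:
    """Percent of material in each of the six size classes.

    The cumulative curve is interpolated (log2 scale) at the class
    bounds; mass below the smallest recorded size is assigned to the
    lowest class, above the largest to the highest. Fractions sum to
    100 exactly up to round-off.
    """
    log2_sizes = np.log2(dist.sizes_um)
    log2_bounds = np.log2(SIZE_CLASS_BOUNDS_UM)
    cum_at_bounds = np.interp(
        log2_bounds, log2_sizes, dist.cum_pct,
        left=0.0, right=dist.cum_pct[-1],
    )
    # mass below the first recorded size counts as finer than it
    cum_at_bounds[log2_bounds < log2_sizes[0]] = 0.0
    cum_full = np.concatenate([[0.0], cum_at_bounds, [100.0]])
    cum_full = np.maximum.accumulate(cum_full)
    fracs = np.diff(cum_full)
    return dict(zip(SIZE_CLASS_NAMES, fracs))


def summarize_granulometry(dist: GrainSizeDistribution,
                           ) -> GranulometrySummary:
    return GranulometrySummary(
        d50_um=percentile_diameter(dist, 50.0),
        d10_um=percentile_diameter(dist, 10.0),
        **{k.replace("pct_", "pct_"): v
           for k, v in size_fractions(dist).items()},
    )


class FitError(ValueError):
    pass


@dataclass
class SalinityRangeModel:
    """Linear salinity-range model, kind-tagged by its predictor.

    ``kind`` is ``"mean-salinity-regression"`` (range inferred from
    mean salinity, as for spot-sampled estuaries) or
    ``"distance-regression"`` (range against distance from the tidal
    head in km). Coefficients are pluggable so an externally published
    equation can be substituted directly.
    """

    kind: str
    intercept: float
    slope: float
    r_squared: float | None = None
    n_obs: int | None = None

    def predict(self, x) -> np.ndarray | float:
        """Predicted salinity range (p.p.t.), clipped at 0."""
        raw = self.intercept + self.slope * np.asarray(x, dtype=float)
        if np.any(raw < 0):
            warnings.warn(
                "negative predicted salinity range clipped to 0",
                stacklevel=2,
            )
        out = np.clip(raw, 0.0, None)
        return float(out) if out.ndim == 0 else out


def fit_salinity_range_model(predictor, salinity_range,
                             kind: str = "distance-regression",
                             ) -> SalinityRangeModel:
    """Ordinary least-squares salinity-range model."""
    x = np.asarray(predictor, dtype=float)
    y = np.asarray(salinity_range, dtype=float)
    if x.size < 3:
        raise FitError("need at least 3 observation pairs")
    if np.ptp(x) == 0:
        raise FitError("zero predictor variance")
    res = stats.linregress(x, y)
    return SalinityRangeModel(
        kind=kind,
        intercept=float(res.intercept),
        slope=float(res.slope),
        r_squared=float(res.rvalue ** 2),
        n_obs=int(x.size),
    )


def predict_salinity_range(model: SalinityRangeModel, x):
    """Module-level alias of :meth:`SalinityRangeModel.predict`."""
    return model.predict(x)


class JoinError(ValueError):
    pass


def assemble_env_matrix(hydro: pd.DataFrame,
                        granulometry: pd.DataFrame,
                        salinity_range: pd.Series,
                        macrofauna: pd.DataFrame | None = None,
                        ) -> dict[str, pd.DataFrame]:
    """Join per-station inputs into the 14-column driver matrix.

    Parameters are all keyed by station. ``hydro`` must carry the five
    hydrodynamic statistics, ``granulometry`` D50/D10 and the six size
    classes, ``salinity_range`` one value per station. Returns a dict
    with the full-station ``"core"`` matrix and, when macrofauna data
    are supplied for a subset of stations, a ``"with_macrofauna"``
    view restricted to those stations (mirroring the exclusion of
    un-coreable sites).
    """
    stations = hydro.index
    for name, df in (("granulometry", granulometry),
                     ("salinity_range", salinity_range.to_frame())):
        missing = stations.difference(df.index)
        if len(missing):
            raise JoinError(
                f"{name} missing stations: {list(missing)}"
            )
        bad = df.loc[stations].isna().any(axis=1)
        if bad.any():
            raise JoinError(
                f"{name} has missing values for stations: "
                f"{list(df.loc[stations].index[bad])}"
            )

    gran = granulometry.rename(
        columns={"d50_um": "d50", "d10_um": "d10"}
    )
    core = pd.concat(
        [
            hydro[
                [
                    "spring_tidal_range",
                    "mean_velocity",
                    "max_velocity",
                    "mean_bed_shear_stress",
                    "max_bed_shear_stress",
                ]
            ],
            gran.loc[stations, ["d50", "d10"] + SIZE_CLASS_NAMES[:]],
            salinity_range.loc[stations].rename("salinity_range"),
        ],
        axis=1,
    )[ENV_DRIVERS]
    out = {"core": core}
    if macrofauna is not None:
        have = core.index.intersection(macrofauna.index)
        mac = macrofauna.loc[have, MACROFAUNA_COLUMNS]
        out["with_macrofauna"] = pd.concat(
            [core.loc[have], mac], axis=1
        )
        out["macrofauna_excluded"] = list(
            core.index.difference(macrofauna.index)
        )
    return out
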