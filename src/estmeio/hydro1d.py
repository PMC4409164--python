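"""One-dimensional sectional-averaged tidal model.

Solves the along-channel shallow-water balances

.. math::

    B \\frac{\\partial \\eta}{\\partial t}
        + \\frac{\\partial (A U)}{\\partial x} = 0

    \\frac{\\partial U}{\\partial t} + U \\frac{\\partial U}{\\partial x}
        = -g \\frac{\\partial \\eta}{\\partial x}
          - \\frac{C_D\\, U |U|}{h + \\eta}

on a staggered grid (free surface ``eta`` at cell centres, velocity
``U`` at faces) with a forward-backward time step: the momentum update
uses the current surface slope with semi-implicit quadratic friction
and first-order upwind advection, then the finite-volume continuity
update uses the new face fluxes, which makes the interior mass budget
telescope exactly to the boundary flux.

The seaward boundary (cell 0) carries a prescribed tidal elevation —
a sum of harmonic constituents, ramped over the spin-up interval —
and the landward boundary is a closed weir (zero face flux). Station
statistics (spring tidal range, mean/max velocity and bed shear
stress) are reduced from the post-ramp series at each sampling
position.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ChannelGeometry",
    "TidalConstituent",
    "TidalForcing",
    "HydroParams",
    "HydroSeries",
    "solve_tides",
    "bed_shear_stress",
    "station_statistics",
    "validate_against_gauge",
    "CFLError",
    "DryingError",
]

#: Periods of common constituents (hours).
CONSTITUENT_PERIODS_H = {
    "M2": 12.4206012,
    "S2": 12.0,
    "N2": 12.65834751,
    "K1": 23.93447213,
    "O1": 25.81933871,
}

M2_PERIOD_S = CONSTITUENT_PERIODS_H["M2"] * 3600.0
SPRING_NEAP_DAYS = 14.77


class CFLError(ValueError):
    """Time step violates the explicit-gravity-wave stability bound."""


class DryingError(RuntimeError):
    """Total water depth dropped to zero and drying is set to error."""


class GeometryError(ValueError):
    pass


@dataclass
class ChannelGeometry:
    """Along-channel geometry at uniformly spaced cell centres.

    ``x`` are cell-centre positions (m) with uniform spacing ``dx``;
    the seaward open boundary is the face at ``x[0] - dx/2`` and the
    landward closed weir is the face at ``x[-1] + dx/2``.
    """

    x: np.ndarray
    width: np.ndarray
    depth: np.ndarray
    area: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.width = np.asarray(self.width, dtype=float)
        self.depth = np.asarray(self.depth, dtype=float)
        if self.x.size < 3:
            raise GeometryError("need at least 3 nodes")
        dx = np.diff(self.x)
        if dx.size and not np.allclose(dx, dx[0]):
            raise GeometryError("grid spacing must be uniform")
        if dx.size and dx[0] <= 0:
            raise GeometryError("grid spacing must be positive")
        if (self.width <= 0).any() or (self.depth <= 0).any():
            raise GeometryError("width and depth must be positive")
        if self.area is None:
            self.area = self.width * self.depth
        else:
            self.area = np.asarray(self.area, dtype=float)
            if not np.allclose(self.area, self.width * self.depth,
                               rtol=0.5):
                raise GeometryError(
                    "supplied areas inconsistent with width*depth"
                )

    @property
    def dx(self) -> float:
        return float(self.x[1] - self.x[0])

    @property
    def n(self) -> int:
        return self.x.size

    @classmethod
    def uniform(cls, length_m: float, n_nodes: int, width_m: float,
                depth_m: float) -> "ChannelGeometry":
        """Rectangular prismatic channel of given length."""
        dx = length_m / n_nodes
        x = (np.arange(n_nodes) + 0.5) * dx
        return cls(
            x=x,
            width=np.full(n_nodes, float(width_m)),
            depth=np.full(n_nodes, float(depth_m)),
        )

    @classmethod
    def from_csv(cls, path: str | Path) -> "ChannelGeometry":
        df = pd.read_csv(path)
        return cls(
            x=df["x_m"].values,
            width=df["width_m"].values,
            depth=df["depth_m"].values,
            area=df["area_m2"].values if "area_m2" in df else None,
        )


@dataclass(frozen=True)
class TidalConstituent:
    name: str
    amplitude: float          # m
    phase: float              # rad
    omega: float              # rad/s

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("constituent amplitude must be >= 0")


@dataclass
class TidalForcing:
    """Harmonic boundary elevation: sum of a_i cos(w_i t - phi_i)."""

    constituents: list[TidalConstituent]

    def eta(self, t: np.ndarray | float) -> np.ndarray | float:
        t = np.asarray(t, dtype=float)
        out = np.zeros_like(t)
        for c in self.constituents:
            out = out + c.amplitude * np.cos(c.omega * t - c.phase)
        return out

    @property
    def max_amplitude(self) -> float:
        return sum(c.amplitude for c in self.constituents)

    @classmethod
    def from_amplitudes(cls, **amps: float) -> "TidalForcing":
        """Forcing from named constituents, e.g. ``M2=2.0, S2=0.5``."""
        cons = []
        for name, a in amps.items():
            period_h = CONSTITUENT_PERIODS_H[name]
            cons.append(
                TidalConstituent(
                    name, a, 0.0, 2.0 * np.pi / (period_h * 3600.0)
                )
            )
        return cls(cons)

    @classmethod
    def from_csv(cls, path: str | Path) -> "TidalForcing":
        df = pd.read_csv(path)
        cons = [
            TidalConstituent(
                r["name"], r["amplitude_m"], np.deg2rad(r["phase_deg"]),
                2.0 * np.pi / (r["period_h"] * 3600.0),
            )
            for _, r in df.iterrows()
        ]
        return cls(cons)


def default_forcing(m2: float = 2.0, s2: float = 0.6, n2: float = 0.4,
                    k1: float = 0.1) -> TidalForcing:
    """Four-constituent forcing dominated by the semidiurnal species."""
    return TidalForcing.from_amplitudes(M2=m2, S2=s2, N2=n2, K1=k1)


@dataclass
class HydroParams:
    """Solver parameters (standard coastal defaults, all overridable)."""

    cd: float = 2.5e-3            # bottom friction coefficient
    rho: float = 1025.0           # water density, kg/m3
    g: float = 9.81               # gravitational acceleration, m/s2
    dt: float | None = None       # time step (s); None = 0.5 * CFL limit
    ramp_days: float = 2.0        # spin-up excluded from outputs
    run_days: float = SPRING_NEAP_DAYS   # analysis window
    min_depth: float = 0.1        # wet/dry clamp (m)
    dry: str = "clamp"            # "clamp" | "error"
    store_every: int = 10         # output thinning (steps per sample)

    def __post_init__(self) -> None:
        if self.cd < 0:
            raise ValueError("C_D must be >= 0")
        if self.dry not in ("clamp", "error"):
            raise ValueError("dry must be 'clamp' or 'error'")


@dataclass
class HydroSeries:
    """Post-ramp model output.

    ``eta`` is (time, cell) free-surface elevation, ``u`` is (time,
    interior face) velocity at the ``n-1`` interior faces. ``volume``
    and ``boundary_flux`` are full-rate (every step) mass-budget
    diagnostics over the interior cells: the budget closes as
    ``V[k+1] - V[k] == dt * boundary_flux[k]`` to round-off.
    """

    times: np.ndarray
    x: np.ndarray
    eta: np.ndarray
    u: np.ndarray
    budget_times: np.ndarray
    volume: np.ndarray
    boundary_flux: np.ndarray
    dt: float
    meta: dict = field(default_factory=dict)

    def mass_residuals(self, period_s: float = M2_PERIOD_S) -> np.ndarray:
        """Per-cycle relative mass-budget residual.

        For each full tidal cycle in the analysis window:
        ``|dV - integral(Q dt)| / mean(V)``.
        """
        t = self.budget_times
        dtb = t[1] - t[0]
        steps = int(round(period_s / dtb))
        ncyc = (len(t) - 1) // steps
        res = []
        for c in range(ncyc):
            i0, i1 = c * steps, (c + 1) * steps
            dv = self.volume[i1] - self.volume[i0]
            influx = dtb * self.boundary_flux[i0:i1].sum()
            res.append(abs(dv - influx) / self.volume.mean())
        return np.asarray(res)


def _cfl_limit(geom: ChannelGeometry, forcing: TidalForcing,
               params: HydroParams) -> float:
    hmax = geom.depth.max() + forcing.max_amplitude
    return geom.dx / np.sqrt(params.g * hmax)


def solve_tides(geom: ChannelGeometry, forcing: TidalForcing,
                params: HydroParams | None = None) -> HydroSeries:
    """Integrate the sectional-averaged tidal equations.

    Returns the post-ramp series only; the spin-up (``ramp_days``,
    during which the boundary amplitude is ramped with a sin² factor)
    is excluded from all outputs.
    """
    params = HydroParams() if params is None else params
    n = geom.n
    dx = geom.dx
    g, cd = params.g, params.cd

    dt_lim = _cfl_limit(geom, forcing, params)
    dt = 0.5 * dt_lim if params.dt is None else float(params.dt)
    if dt > dt_lim:
        raise CFLError(
            f"dt={dt:.3f}s violates the gravity-wave CFL bound; "
            f"largest stable dt is {dt_lim:.3f}s for dx={dx:.0f}m"
        )

    ramp_s = params.ramp_days * 86400.0
    total_s = ramp_s + params.run_days * 86400.0
    nsteps = int(np.ceil(total_s / dt))
    ramp_steps = int(np.ceil(ramp_s / dt))

    eta = np.zeros(n)
    u = np.zeros(n - 1)          # interior faces between cells i-1, i
    b = geom.width
    h = geom.depth
    b_face = 0.5 * (b[:-1] + b[1:])
    h_face = 0.5 * (h[:-1] + h[1:])

    store_every = max(1, int(params.store_every))
    out_idx = []
    out_eta, out_u, out_t = [], [], []
    budget_t = np.empty(nsteps - ramp_steps + 1)
    budget_v = np.empty(nsteps - ramp_steps + 1)
    budget_q = np.empty(nsteps - ramp_steps)

    cell_vol_coeff = b[1:] * dx  # interior cells 1..n-1
    k_out = 0

    for step in range(nsteps):
        t = step * dt
        tn = t + dt
        # ramped boundary elevation at the new time level
        if tn < ramp_s:
            ramp = np.sin(0.5 * np.pi * tn / ramp_s) ** 2
        else:
            ramp = 1.0
        if step == ramp_steps:
            # volume over interior cells before the first budget step
            budget_t[0] = t
            budget_v[0] = (cell_vol_coeff * (h[1:] + eta[1:])).sum()
        # momentum on interior faces (uses eta at time t)
        depth_f = h_face + 0.5 * (eta[:-1] + eta[1:])
        if (depth_f <= 0).any():
            if params.dry == "error":
                raise DryingError(
                    f"total depth <= 0 at t={t:.0f}s "
                    f"(face {int(np.argmin(depth_f))})"
                )
            depth_f = np.maximum(depth_f, params.min_depth)
        else:
            depth_f = np.maximum(depth_f, params.min_depth)
        grad = (eta[1:] - eta[:-1]) / dx
        # first-order upwind advection, zero-gradient at both ends
        upad = np.empty_like(u)
        du_up = np.diff(u, prepend=u[0])       # u_i - u_{i-1}
        du_dn = np.diff(u, append=u[-1])       # u_{i+1} - u_i
        upad = np.where(u > 0, u * du_up / dx, u * du_dn / dx)
        rhs = u + dt * (-g * grad - upad)
        u = rhs / (1.0 + dt * cd * np.abs(u) / depth_f)

        # continuity: finite-volume update of interior cells
        q = b_face * depth_f * u              # face fluxes (positive landward)
        eta_new = eta.copy()
        eta_new[1:-1] -= dt * (q[1:] - q[:-1]) / (b[1:-1] * dx)
        eta_new[-1] -= dt * (0.0 - q[-1]) / (b[-1] * dx)   # closed weir
        eta_new[0] = ramp * forcing.eta(tn)
        eta = eta_new

        if step >= ramp_steps:
            k = step - ramp_steps
            budget_q[k] = q[0]
            budget_t[k + 1] = tn
            budget_v[k + 1] = (cell_vol_coeff * (h[1:] + eta[1:])).sum()
            if (step - ramp_steps) % store_every == 0:
                out_t.append(tn)
                out_eta.append(eta.copy())
                out_u.append(u.copy())
                k_out += 1

    return HydroSeries(
        times=np.asarray(out_t),
        x=geom.x.copy(),
        eta=np.asarray(out_eta),
        u=np.asarray(out_u),
        budget_times=budget_t,
        volume=budget_v,
        boundary_flux=budget_q,
        dt=dt,
        meta={
            "dt": dt,
            "ramp_days": params.ramp_days,
            "run_days": params.run_days,
            "cd": params.cd,
            "velocity_statistic": "absolute",
        },
    )


def bed_shear_stress(u: np.ndarray, params: HydroParams) -> np.ndarray:
    """Quadratic-law bed shear stress tau = rho * C_D * U|U| (Pa).

    The sign of tau carries the flow direction; summary statistics are
    taken on |tau|.
    """
    if params.cd < 0:
        raise ValueError("C_D must be >= 0")
    u = np.asarray(u, dtype=float)
    return params.rho * params.cd * u * np.abs(u)


def _interp_series(series: HydroSeries, positions: np.ndarray,
                   what: str) -> np.ndarray:
    """Time series at arbitrary along-channel positions (linear in x)."""
    if what == "eta":
        grid_x, values = series.x, series.eta
    else:
        grid_x = 0.5 * (series.x[:-1] + series.x[1:])
        values = series.u
    idx = np.searchsorted(grid_x, positions).clip(1, grid_x.size - 1)
    x0, x1 = grid_x[idx - 1], grid_x[idx]
    w = np.clip((positions - x0) / (x1 - x0), 0.0, 1.0)
    return values[:, idx - 1] * (1.0 - w) + values[:, idx] * w


def station_statistics(series: HydroSeries, stations: np.ndarray,
                       params: HydroParams | None = None,
                       cycle_period_s: float = M2_PERIOD_S,
                       ) -> pd.DataFrame:
    """Per-station hydrodynamic statistics over the analysis window.

    Tidal range per cycle is high water minus low water within
    successive windows of one dominant-constituent period; the spring
    tidal range is the largest cycle range. Velocity and stress
    statistics are taken on |U| and |tau| (the direction-free
    convention is recorded in the output metadata).
    """
    params = HydroParams() if params is None else params
    stations = np.asarray(stations, dtype=float)
    lo = series.x[0] - 0.51 * (series.x[1] - series.x[0])
    hi = series.x[-1] + 0.51 * (series.x[1] - series.x[0])
    if ((stations < lo) | (stations > hi)).any():
        bad = stations[(stations < lo) | (stations > hi)]
        raise ValueError(f"stations outside channel extent: {bad}")

    eta_s = _interp_series(series, stations, "eta")
    u_s = np.abs(_interp_series(series, stations, "u"))
    tau_s = np.abs(bed_shear_stress(u_s, params))

    t = series.times
    dt_out = t[1] - t[0]
    steps = max(2, int(round(cycle_period_s / dt_out)))
    ncyc = len(t) // steps
    if ncyc < 1:
        raise ValueError("series shorter than one tidal cycle")
    rows = []
    for j, xp in enumerate(stations):
        ranges = [
            eta_s[c * steps:(c + 1) * steps, j].max()
            - eta_s[c * steps:(c + 1) * steps, j].min()
            for c in range(ncyc)
        ]
        rows.append(
            {
                "x_m": xp,
                "spring_tidal_range": max(ranges),
                "mean_velocity": u_s[:, j].mean(),
                "max_velocity": u_s[:, j].max(),
                "mean_bed_shear_stress": tau_s[:, j].mean(),
                "max_bed_shear_stress": tau_s[:, j].max(),
            }
        )
    df = pd.DataFrame(rows)
    df.attrs["velocity_statistic"] = "absolute"
    return df


def validate_against_gauge(series: HydroSeries, position_m: float,
                           gauge_times: np.ndarray,
                           gauge_eta: np.ndarray,
                           ) -> dict[str, float]:
    """RMSE and bias (model minus gauge) of surface elevation."""
    gauge_times = np.asarray(gauge_times, dtype=float)
    gauge_eta = np.asarray(gauge_eta, dtype=float)
    t0, t1 = series.times[0], series.times[-1]
    mask = (gauge_times >= t0) & (gauge_times <= t1)
    if not mask.any():
        raise ValueError("gauge record does not overlap the model window")
    model_at_station = _interp_series(
        series, np.array([position_m]), "eta"
    )[:, 0]
    model = np.interp(gauge_times[mask], series.times, model_at_station)
    diff = model - gauge_eta[mask]
    return {
        "rmse_m": float(np.sqrt(np.mean(diff ** 2))),
        "bias_m": float(diff.mean()),
        "n": int(mask.sum()),
    }


def harmonic_amplitude(times: np.ndarray, eta: np.ndarray,
                       omega: float) -> float:
    """Least-squares amplitude of a single harmonic in a series."""
    A = np.column_stack(
        [np.cos(omega * times), np.sin(omega * times),
         np.ones_like(times)]
    )
    coef, *_ = np.linalg.lstsq(A, eta, rcond=None)
    return float(np.hypot(coef[0], coef[1]))
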