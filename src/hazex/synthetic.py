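"""Synthetic gridded forcing with the statistical structure of climate-impact
model output.

Everything downstream (threshold calibration, event detection, exposure
statistics) is exercised against runs produced here: long stationary
"pre-industrial control" series, historical+scenario runs with injected
trends, a pseudo-ensemble of climate-model x impact-model combinations,
and synthetic species ranges / ecoregion partitions.

Statistical structure per variable (365-day no-leap calendar throughout):

* daily maximum temperature: latitude-dependent mean + seasonal sine
  (hemisphere-phased) + AR(1) noise (default lag-1 autocorrelation 0.7),
  so exceedance days cluster into multi-day runs;
* monthly root-zone soil moisture: bounded logistic transform of a
  seasonal AR(1) latent process (lag-1 0.5), values in (0, 1);
* daily river outflow: lognormal — exp(cell level + seasonal + AR(1));
* annual burned area: Beta-distributed fraction of the cell, i.i.d.
  across years;
* annual-mean discharge: static lognormal wet/dry map (mm/day), used for
  the dryness mask;
* annual flooded fraction: saturating transform of the annual maximum
  outflow (flooded fraction is an input to flood classification, not a
  routed quantity here).

Scenario runs add deterministic trend components (warming in deg C per
decade, fractional soil-moisture decline per decade, multiplicative
outflow / burned-area scaling per decade) on top of the stationary
process from a configurable start year; a zero trend reproduces control
statistics exactly under the same seed.

Random streams are seeded per (variable, cell block, run kind,
combination) from a single base seed, so regenerating one variable never
shifts another.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import signal

from .grid import Grid, RangeMask, TAXA

DAYS_PER_YEAR = 365
MONTHS_PER_YEAR = 12

#: All gridded variables a run can carry, with their time resolution.
VARIABLES = {
    "tasmax": "daily",
    "soil_moisture": "monthly",
    "outflow": "daily",
    "burned_area": "annual",
    "discharge": "annual",
    "flooded_fraction": "annual",
}

_KIND_CODE = {"control": 0, "historical": 1, "scenario": 2}
_VAR_CODE = {v: i for i, v in enumerate(VARIABLES)}
_CELL_BLOCK = 128  # cells per independent noise substream


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class TrendSpec:
    """Deterministic trend components added to a scenario run.

    Rates are per decade, applied from ``start_year`` onwards:
    ``warming_rate`` in deg C/decade on tasmax; ``drying_rate`` as a
    fractional decline on soil moisture; ``flow_scale_rate`` and
    ``burn_scale_rate`` as multiplicative growth on outflow and burned
    area.  All-zero rates reproduce the control process.
    """

    warming_rate: float = 0.0
    drying_rate: float = 0.0
    flow_scale_rate: float = 0.0
    burn_scale_rate: float = 0.0
    start_year: int = 2015

    def __post_init__(self) -> None:
        for r in (self.warming_rate, self.drying_rate, self.flow_scale_rate, self.burn_scale_rate):
            if not np.isfinite(r):
                raise ConfigurationError("trend rates must be finite")


#: Trend presets emulating low / medium-high / high emission pathways.
SCENARIO_TRENDS: dict[str, TrendSpec] = {
    "ssp126": TrendSpec(0.15, 0.010, 0.02, 0.03),
    "ssp370": TrendSpec(0.45, 0.025, 0.05, 0.08),
    "ssp585": TrendSpec(0.70, 0.040, 0.08, 0.12),
}


@dataclass(frozen=True)
class ControlParams:
    """Noise/seasonality settings of the stationary control process."""

    # tasmax (deg C)
    t_equator: float = 28.0          # mean at the equator
    t_pole_drop: float = 35.0        # mean decrease towards |lat| = 90
    t_seasonal_base: float = 3.0     # seasonal amplitude at the equator
    t_seasonal_polar: float = 12.0   # extra amplitude at |lat| = 90
    t_rho: float = 0.7               # daily lag-1 autocorrelation
    t_sigma: float = 3.0             # stationary noise s.d.
    # soil moisture (volumetric fraction, logistic latent space)
    sm_rho: float = 0.5              # monthly lag-1 autocorrelation
    sm_sigma: float = 0.6
    sm_seasonal_amp: float = 0.8
    # outflow (log space)
    q_rho: float = 0.6
    q_sigma: float = 0.5
    q_seasonal_amp: float = 0.8
    # burned area: per-cell Beta mean drawn in [burn_mean_lo, burn_mean_hi]
    burn_mean_lo: float = 0.002
    burn_mean_hi: float = 0.08
    burn_concentration: float = 8.0
    # discharge map (lognormal, mm/day)
    discharge_log_mean: float = 0.0
    discharge_log_sd: float = 1.5
    # flooded-fraction cap per cell drawn in [ff_lo, ff_hi]
    ff_lo: float = 0.005
    ff_hi: float = 0.6
    # seed for the static per-cell maps (discharge, burn means, phases)
    map_seed: int = 0


@dataclass
class SimulationRun:
    """One model-combination's gridded fields for one run kind."""

    run_kind: str                    # control | historical | scenario
    scenario_tag: str                # e.g. picontrol, ssp370
    climate_model_id: str
    impact_model_id: str
    years: np.ndarray                # calendar years, 365-day no-leap
    fields: dict[str, np.ndarray]    # name -> array, leading axis = year

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        n = len(self.years)
        for name, arr in self.fields.items():
            if name not in VARIABLES:
                raise ConfigurationError(f"unknown field {name!r}")
            if arr.shape[0] != n:
                raise ConfigurationError(
                    f"field {name!r} has {arr.shape[0]} years, calendar has {n}"
                )

    @property
    def n_years(self) -> int:
        return len(self.years)

    @property
    def combination_id(self) -> str:
        return f"{self.climate_model_id}_{self.impact_model_id}"


def _substream(base_seed: int, combo: tuple[int, int], kind: str, var: str, block: int) -> np.random.Generator:
    ss = np.random.SeedSequence(
        entropy=int(base_seed) & 0x7FFFFFFF,
        spawn_key=(combo[0], combo[1], _KIND_CODE[kind], _VAR_CODE[var], block),
    )
    return np.random.default_rng(ss)


def _ar1(rng: np.random.Generator, n_steps: int, n_cells: int, rho: float, sigma: float) -> np.ndarray:
    """Stationary AR(1) noise, shape (n_steps, n_cells), marginal s.d. sigma."""
    innov_sd = sigma * np.sqrt(1.0 - rho**2)
    eps = rng.normal(0.0, innov_sd, size=(n_steps, n_cells)).astype(np.float32)
    out = signal.lfilter([1.0], [1.0, -rho], eps, axis=0).astype(np.float32)
    # replace the transient start with a stationary draw propagated forward
    out += (rho ** np.arange(1, n_steps + 1, dtype=np.float32))[:, None] * rng.normal(
        0.0, sigma, size=(1, n_cells)
    ).astype(np.float32)
    return out


def _static_maps(grid: Grid, params: ControlParams) -> dict[str, np.ndarray]:
    """Per-cell static maps (means, phases, caps) shared by all runs."""
    rng = np.random.default_rng(np.random.SeedSequence(params.map_seed))
    nlat, nlon = grid.shape
    lat = grid.lat_centers[:, None] * np.ones((1, nlon))
    t_mean = params.t_equator - params.t_pole_drop * (np.abs(lat) / 90.0) ** 1.5
    t_amp = params.t_seasonal_base + params.t_seasonal_polar * np.abs(lat) / 90.0
    # seasonal phase: boreal summer in the north, austral in the south
    t_phase = np.where(lat >= 0, 196.0, 196.0 - DAYS_PER_YEAR / 2)
    sm_mu = rng.uniform(-0.5, 1.0, size=grid.shape)
    q_mu = rng.normal(1.0, 0.8, size=grid.shape)
    burn_mean = rng.uniform(params.burn_mean_lo, params.burn_mean_hi, size=grid.shape)
    discharge = np.exp(
        rng.normal(params.discharge_log_mean, params.discharge_log_sd, size=grid.shape)
    )
    ff_cap = rng.uniform(params.ff_lo, params.ff_hi, size=grid.shape)
    return {
        "t_mean": t_mean,
        "t_amp": t_amp,
        "t_phase": t_phase,
        "sm_mu": sm_mu,
        "q_mu": q_mu,
        "burn_mean": burn_mean,
        "discharge": discharge,
        "ff_cap": ff_cap,
    }


def _decades(years: np.ndarray, start_year: int) -> np.ndarray:
    return np.maximum(0.0, years.astype(float) - start_year) / 10.0


def _gen_field(
    var: str,
    grid: Grid,
    years: np.ndarray,
    params: ControlParams,
    maps: dict[str, np.ndarray],
    trend: TrendSpec,
    base_seed: int,
    combo: tuple[int, int],
    kind: str,
) -> np.ndarray:
    nlat, nlon = grid.shape
    n_cells = nlat * nlon
    n_years = len(years)
    dec = _decades(years, trend.start_year)

    def noise(n_steps: int, rho: float, sigma: float) -> np.ndarray:
        parts = []
        for b0 in range(0, n_cells, _CELL_BLOCK):
            nb = min(_CELL_BLOCK, n_cells - b0)
            rng = _substream(base_seed, combo, kind, var, b0 // _CELL_BLOCK)
            parts.append(_ar1(rng, n_steps, nb, rho, sigma))
        return np.concatenate(parts, axis=1)  # (n_steps, n_cells)

    if var == "tasmax":
        doy = np.arange(1, DAYS_PER_YEAR + 1, dtype=np.float32)
        seas = np.sin(
            2 * np.pi * (doy[None, :, None] - maps["t_phase"].reshape(-1)[None, None, :]) / DAYS_PER_YEAR
        )  # (1, 365, cells)
        x = noise(n_years * DAYS_PER_YEAR, params.t_rho, params.t_sigma)
        x = x.reshape(n_years, DAYS_PER_YEAR, n_cells)
        x += maps["t_mean"].reshape(-1)[None, None, :].astype(np.float32)
        x += (maps["t_amp"].reshape(-1)[None, None, :] * seas).astype(np.float32)
        x += (trend.warming_rate * dec)[:, None, None].astype(np.float32)
        return x.reshape(n_years, DAYS_PER_YEAR, nlat, nlon)

    if var == "soil_moisture":
        month = np.arange(MONTHS_PER_YEAR, dtype=np.float32)
        seas = params.sm_seasonal_amp * np.sin(2 * np.pi * (month[None, :, None] + 0.5) / MONTHS_PER_YEAR)
        x = noise(n_years * MONTHS_PER_YEAR, params.sm_rho, params.sm_sigma)
        x = x.reshape(n_years, MONTHS_PER_YEAR, n_cells)
        x += maps["sm_mu"].reshape(-1)[None, None, :].astype(np.float32) + seas.astype(np.float32)
        sm = 1.0 / (1.0 + np.exp(-x))
        # fractional decline per decade, multiplicative so bounds are kept
        sm *= ((1.0 - trend.drying_rate) ** dec)[:, None, None].astype(np.float32)
        np.clip(sm, 0.0, 1.0, out=sm)
        return sm.reshape(n_years, MONTHS_PER_YEAR, nlat, nlon)

    if var == "outflow":
        doy = np.arange(1, DAYS_PER_YEAR + 1, dtype=np.float32)
        seas = params.q_seasonal_amp * np.sin(
            2 * np.pi * (doy[None, :, None] - maps["t_phase"].reshape(-1)[None, None, :]) / DAYS_PER_YEAR
        )
        x = noise(n_years * DAYS_PER_YEAR, params.q_rho, params.q_sigma)
        x = x.reshape(n_years, DAYS_PER_YEAR, n_cells)
        x += maps["q_mu"].reshape(-1)[None, None, :].astype(np.float32) + seas.astype(np.float32)
        q = np.exp(x)
        q *= ((1.0 + trend.flow_scale_rate) ** dec)[:, None, None].astype(np.float32)
        return q.reshape(n_years, DAYS_PER_YEAR, nlat, nlon)

    if var == "burned_area":
        m = maps["burn_mean"].reshape(-1)
        k = params.burn_concentration
        rng = _substream(base_seed, combo, kind, var, 0)
        ba = rng.beta(m * k, (1 - m) * k, size=(n_years, n_cells)).astype(np.float32)
        ba *= ((1.0 + trend.burn_scale_rate) ** dec)[:, None].astype(np.float32)
        np.clip(ba, 0.0, 1.0, out=ba)
        return ba.reshape(n_years, nlat, nlon)

    if var == "discharge":
        d = maps["discharge"].astype(np.float32)
        return np.broadcast_to(d, (n_years, nlat, nlon)).copy()

    if var == "flooded_fraction":
        # saturating response to that year's flow anomaly, capped per cell
        q = _gen_field("outflow", grid, years, params, maps, trend, base_seed, combo, kind)
        amax = q.max(axis=1).reshape(n_years, -1)  # (years, cells)
        ref = np.median(amax, axis=0, keepdims=True)
        ff = maps["ff_cap"].reshape(-1)[None, :] * (
            1.0 - np.exp(-np.maximum(amax / np.maximum(ref, 1e-12) - 0.5, 0.0))
        )
        return np.clip(ff, 0.0, 1.0).astype(np.float32).reshape(n_years, nlat, nlon)

    raise ConfigurationError(f"unknown variable {var!r}")


def generate_control(
    grid: Grid,
    n_years: int,
    seed: int,
    params: ControlParams | None = None,
    variables: Sequence[str] | None = None,
    start_year: int = 1850,
    combo: tuple[int, int] = (0, 0),
    climate_model_id: str = "clim00",
    impact_model_id: str = "imp00",
) -> SimulationRun:
    """Stationary pre-industrial-control-style run.

    ``n_years`` must be at least 30 (threshold calibration needs a
    climatology); the same (grid, n_years, seed) always yields
    bit-identical output.
    """
    if n_years < 30:
        raise ConfigurationError("control runs need n_years >= 30")
    params = params or ControlParams()
    variables = tuple(variables) if variables is not None else tuple(VARIABLES)
    years = start_year + np.arange(n_years)
    maps = _static_maps(grid, params)
    zero = TrendSpec()
    fields = {
        v: _gen_field(v, grid, years, params, maps, zero, seed, combo, "control")
        for v in variables
    }
    return SimulationRun("control", "picontrol", climate_model_id, impact_model_id, years, fields)


def generate_scenario(
    grid: Grid,
    trend: TrendSpec,
    n_years: int,
    seed: int,
    params: ControlParams | None = None,
    variables: Sequence[str] | None = None,
    start_year: int = 1985,
    scenario_tag: str = "scenario",
    combo: tuple[int, int] = (0, 0),
    climate_model_id: str = "clim00",
    impact_model_id: str = "imp00",
) -> SimulationRun:
    """Historical+scenario run: control process plus deterministic trends."""
    params = params or ControlParams()
    variables = tuple(variables) if variables is not None else tuple(VARIABLES)
    years = start_year + np.arange(n_years)
    maps = _static_maps(grid, params)
    fields = {
        v: _gen_field(v, grid, years, params, maps, trend, seed, combo, "scenario")
        for v in variables
    }
    return SimulationRun("scenario", scenario_tag, climate_model_id, impact_model_id, years, fields)


@dataclass(frozen=True)
class ModelCombination:
    """One climate-model x impact-model member of the pseudo-ensemble.

    Holds its perturbed control parameters and seed; runs are generated
    on demand so an ensemble can be processed one member at a time.
    """

    climate_model_id: str
    impact_model_id: str
    index: tuple[int, int]
    params: ControlParams
    base_seed: int

    @property
    def combination_id(self) -> str:
        return f"{self.climate_model_id}_{self.impact_model_id}"

    def control(self, grid: Grid, n_years: int, variables: Sequence[str] | None = None,
                start_year: int = 1850) -> SimulationRun:
        return generate_control(
            grid, n_years, self.base_seed, self.params, variables, start_year,
            combo=self.index, climate_model_id=self.climate_model_id,
            impact_model_id=self.impact_model_id,
        )

    def scenario(self, grid: Grid, trend: TrendSpec, n_years: int,
                 variables: Sequence[str] | None = None, start_year: int = 1985,
                 scenario_tag: str = "scenario") -> SimulationRun:
        return generate_scenario(
            grid, trend, n_years, self.base_seed, self.params, variables, start_year,
            scenario_tag, combo=self.index, climate_model_id=self.climate_model_id,
            impact_model_id=self.impact_model_id,
        )


def generate_model_ensemble(
    n_climate: int,
    n_impact: int,
    base_seed: int,
    params: ControlParams | None = None,
) -> list[ModelCombination]:
    """Pseudo-ensemble: each combination gets perturbed noise/seasonality
    parameters and an independent seed stream."""
    if n_climate < 1 or n_impact < 1:
        raise ConfigurationError("ensemble dimensions must be >= 1")
    base = params or ControlParams()
    combos = []
    for ci in range(n_climate):
        for mi in range(n_impact):
            rng = np.random.default_rng(
                np.random.SeedSequence(int(base_seed) & 0x7FFFFFFF, spawn_key=(99, ci, mi))
            )
            p = replace(
                base,
                t_rho=float(np.clip(base.t_rho * rng.uniform(0.92, 1.08), 0.0, 0.95)),
                t_sigma=float(base.t_sigma * rng.uniform(0.85, 1.15)),
                t_seasonal_base=float(base.t_seasonal_base * rng.uniform(0.9, 1.1)),
                t_equator=float(base.t_equator + rng.normal(0.0, 0.5)),
                sm_sigma=float(base.sm_sigma * rng.uniform(0.85, 1.15)),
                q_sigma=float(base.q_sigma * rng.uniform(0.85, 1.15)),
                burn_concentration=float(base.burn_concentration * rng.uniform(0.8, 1.2)),
                map_seed=base.map_seed,  # same world, different weather
            )
            combos.append(
                ModelCombination(f"clim{ci:02d}", f"imp{mi:02d}", (ci, mi), p, int(base_seed))
            )
    return combos


def generate_land_mask(
    nlat: int, nlon: int, seed: int, land_fraction: float = 0.6, smooth: int = 3
) -> np.ndarray:
    """Blobby continent mask: thresholded smoothed Gaussian noise."""
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(7,)))
    z = rng.normal(size=(nlat, nlon))
    for _ in range(smooth):
        z = (
            z
            + np.roll(z, 1, 0) + np.roll(z, -1, 0)
            + np.roll(z, 1, 1) + np.roll(z, -1, 1)
        ) / 5.0
    thr = np.quantile(z, 1.0 - land_fraction)
    return z > thr


def generate_ranges(
    grid: Grid,
    n_species: int,
    seed: int,
    size_lo: int = 1,
    size_hi: int = 40,
    n_offland: int = 0,
    taxa: Sequence[str] = TAXA,
) -> list[RangeMask]:
    """Contiguous random-blob species ranges with fractional cell overlap.

    ``n_offland`` of the ``n_species`` ranges are grown entirely on
    non-land cells (small-island stand-ins), so downstream filtering
    excludes exactly that many.  Requires at least one land and, if
    ``n_offland > 0``, one ocean cell.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(11,)))
    land_cells = np.argwhere(grid.land_mask)
    sea_cells = np.argwhere(~grid.land_mask)
    if len(land_cells) == 0:
        raise ConfigurationError("grid has no land cells")
    if n_offland > 0 and len(sea_cells) == 0:
        raise ConfigurationError("grid has no off-land cells for island species")
    nlat, nlon = grid.shape
    out: list[RangeMask] = []
    offland_flags = np.zeros(n_species, dtype=bool)
    if n_offland:
        offland_flags[rng.choice(n_species, size=n_offland, replace=False)] = True
    for s in range(n_species):
        on_land = not offland_flags[s]
        domain = grid.land_mask if on_land else ~grid.land_mask
        pool = land_cells if on_land else sea_cells
        size = int(rng.integers(size_lo, size_hi + 1))
        start = tuple(pool[rng.integers(len(pool))])
        cells = {start}
        frontier = [start]
        while len(cells) < size and frontier:
            i, j = frontier[rng.integers(len(frontier))]
            nbrs = [
                (i + di, j + dj)
                for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1))
                if 0 <= i + di < nlat and 0 <= j + dj < nlon
                and domain[i + di, j + dj] and (i + di, j + dj) not in cells
            ]
            if not nbrs:
                frontier.remove((i, j))
                continue
            nxt = nbrs[rng.integers(len(nbrs))]
            cells.add(nxt)
            frontier.append(nxt)
        overlap = np.zeros(grid.shape)
        for (i, j) in cells:
            overlap[i, j] = rng.uniform(0.2, 1.0)
        out.append(
            RangeMask(
                f"sp{s:04d}", overlap, entity_kind="species",
                taxon=taxa[s % len(taxa)],
            )
        )
    return out


def generate_ecoregions(grid: Grid, n_regions: int, seed: int) -> list[RangeMask]:
    """Voronoi-like seeded partition of the land cells into ecoregions.

    Every land cell is assigned to exactly one region (overlap 1), so
    per-cell overlaps across regions sum to 1 on land.
    """
    land = np.argwhere(grid.land_mask)
    if n_regions > len(land):
        raise ConfigurationError(
            f"cannot partition {len(land)} land cells into {n_regions} ecoregions"
        )
    if n_regions < 1:
        raise ConfigurationError("need at least one ecoregion")
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(13,)))
    centroids = land[rng.choice(len(land), size=n_regions, replace=False)]
    d2 = ((land[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
    assign = d2.argmin(axis=1)
    out = []
    for r in range(n_regions):
        overlap = np.zeros(grid.shape)
        mine = land[assign == r]
        overlap[mine[:, 0], mine[:, 1]] = 1.0
        out.append(RangeMask(f"eco{r:03d}", overlap, entity_kind="ecoregion", taxon="none"))
    return out
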