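"""Per-cell extreme-event calibration and classification.

Thresholds for all four event types are calibrated from a long
stationary pre-industrial control run, cell by cell, then any run
(control, historical or scenario) is classified year by year:

* **heatwave** — two steps: heatwave periods are runs of >= 3 consecutive
  days above the day-of-year 90th-percentile temperature (31-day pooled
  window, wrapping the year boundary); the annual heatwave magnitude
  index (HWMId) sums, over the days of a period, the daily excess over
  the control annual-maximum 25th percentile normalized by the control
  annual-maximum interquartile range, and takes the maximum over
  periods.  A year is an extreme-heatwave year when its HWMId strictly
  exceeds the configured control percentile (default 97.5th).
* **drought** — a year with >= 3 consecutive calendar months of soil
  moisture strictly below the low-tail control percentile (default
  2.5th, pooled over all control months); restricted to cells whose
  annual-mean discharge is at least 0.1 mm/day.
* **river flood** — a year whose annual maximum daily outflow strictly
  exceeds the return level of a GEV fitted to control annual maxima
  (default 40-yr return period, i.e. the 97.5th percentile), provided at
  least 1% of the cell is flooded that year and the cell passes the
  dryness mask.
* **wildfire** — a year whose burned-area fraction strictly exceeds the
  configured control percentile of annual burned area.

Ties never flag (strict inequalities both tails).  Percentile
sensitivity uses upper-tail q in {95, 97.5, 99} paired with low-tail
100 - q for droughts and the matching return period 1/(1 - q/100) for
floods.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .grid import Grid
from .synthetic import DAYS_PER_YEAR, MONTHS_PER_YEAR, SimulationRun

EVENT_TYPES = ("heatwave", "drought", "flood", "wildfire")

DEFAULT_PERCENTILE = 97.5
SENSITIVITY_PERCENTILES = (95.0, 97.5, 99.0)
DRYNESS_CUTOFF_MM_DAY = 0.1
MIN_FLOODED_FRACTION_PCT = 1.0
HEATWAVE_MIN_RUN_DAYS = 3
DROUGHT_MIN_RUN_MONTHS = 3
DOY_WINDOW_DAYS = 31
DOY_PERCENTILE = 90.0


class CalibrationError(ValueError):
    pass


class DegenerateReferenceError(CalibrationError):
    """Reference distribution has no spread (e.g. Q75 == Q25)."""


def return_period_for_percentile(q: float) -> float:
    """Return period (years) whose exceedance threshold is the q-th
    percentile of the annual-maximum distribution: T = 1/(1 - q/100)."""
    if not 0 < q < 100:
        raise CalibrationError("percentile must lie in (0, 100)")
    return 1.0 / (1.0 - q / 100.0)


# ---------------------------------------------------------------- runs

def _run_segments(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True in a 1-D boolean array as (start, length)."""
    m = np.asarray(mask, dtype=bool)
    if m.ndim != 1:
        raise ValueError("expected a 1-D mask")
    padded = np.concatenate([[False], m, [False]]).astype(np.int8)
    d = np.diff(padded)
    starts = np.nonzero(d == 1)[0]
    ends = np.nonzero(d == -1)[0]
    return [(int(s), int(e - s)) for s, e in zip(starts, ends)]


def _batch_max_run_sums(
    values: np.ndarray, mask: np.ndarray, min_run: int
) -> np.ndarray:
    """Per row: max over runs of True (length >= min_run) of the summed
    values inside the run; 0.0 where no qualifying run exists.

    ``values``/``mask`` have shape (n_series, n_steps).
    """
    n_series, n_steps = mask.shape
    padded = np.zeros((n_series, n_steps + 2), dtype=np.int8)
    padded[:, 1:-1] = mask
    d = np.diff(padded, axis=1)
    rows, starts = np.nonzero(d == 1)
    rows_e, ends = np.nonzero(d == -1)
    # np.nonzero is row-major, so starts/ends pair up within each row
    lengths = ends - starts
    csum = np.concatenate(
        [np.zeros((n_series, 1)), np.cumsum(values, axis=1, dtype=float)], axis=1
    )
    sums = csum[rows, ends] - csum[rows, starts]
    ok = lengths >= min_run
    out = np.zeros(n_series)
    np.maximum.at(out, rows[ok], sums[ok])
    return out


def _batch_has_run(mask: np.ndarray, min_run: int) -> np.ndarray:
    """Per row: does any run of True reach min_run consecutive steps?"""
    m = np.asarray(mask, dtype=np.int32)
    c = np.cumsum(m, axis=-1)
    win = c[..., min_run - 1 :].copy()
    win[..., 1:] -= c[..., : -min_run]
    return (win == min_run).any(axis=-1)


# ------------------------------------------------- heatwave machinery

def calibrate_doy_percentile(
    control_tasmax: np.ndarray, q: float = DOY_PERCENTILE, window: int = DOY_WINDOW_DAYS
) -> np.ndarray:
    """Day-of-year percentile climatology from control daily tasmax.

    ``control_tasmax`` has shape (n_years, 365, ...).  The threshold for
    day d is the empirical q-th percentile of all control values within
    the centred window [d - w/2, d + w/2], wrapping across the year
    boundary, pooled over every control year.  Returns shape (365, ...).
    """
    if not 0 < q < 100:
        raise CalibrationError("percentile must lie in (0, 100)")
    if window % 2 != 1 or window < 1:
        raise CalibrationError("window must be a positive odd number of days")
    x = np.asarray(control_tasmax)
    if x.ndim < 2 or x.shape[1] != DAYS_PER_YEAR:
        raise CalibrationError("expected shape (n_years, 365, ...)")
    half = window // 2
    space = x.shape[2:]
    n_years = x.shape[0]
    n_cells = int(np.prod(space)) if space else 1
    # cells-major layout padded with wrap columns so each window is a slice,
    # and the pool axis is contiguous for the in-place selection below
    cm = np.ascontiguousarray(
        x.reshape(n_years, DAYS_PER_YEAR, n_cells).transpose(2, 1, 0)
    )
    if half > 0:
        padded = np.concatenate([cm[:, -half:], cm, cm[:, :half]], axis=1)
    else:
        padded = cm
    del cm
    n_pool = window * n_years
    k = q / 100.0 * (n_pool - 1)
    kf = int(np.floor(k))
    kc = min(kf + 1, n_pool - 1)
    out = np.empty((DAYS_PER_YEAR, n_cells), dtype=float)
    for d in range(DAYS_PER_YEAR):
        # explicit copy: the in-place selection must never touch `padded`
        pool = padded[:, d : d + window].copy().reshape(n_cells, n_pool)
        pool.partition((kf, kc), axis=1)
        # linear interpolation between the bracketing order statistics
        out[d] = pool[:, kf] + (k - kf) * (pool[:, kc] - pool[:, kf])
    return out.reshape((DAYS_PER_YEAR,) + space)


def detect_heatwave_periods(
    tasmax_year: np.ndarray,
    threshold_curve: np.ndarray,
    min_run: int = HEATWAVE_MIN_RUN_DAYS,
) -> list[tuple[int, int]]:
    """Maximal runs of >= min_run consecutive exceedance days in one year.

    Returns (start_day, length) pairs, start_day 0-based; periods are
    not stitched across year boundaries.
    """
    t = np.asarray(tasmax_year, dtype=float)
    if t.shape != (DAYS_PER_YEAR,):
        raise ValueError(f"expected {DAYS_PER_YEAR} daily values, got {t.shape}")
    exceed = t > np.asarray(threshold_curve, dtype=float)
    return [(s, ln) for s, ln in _run_segments(exceed) if ln >= min_run]


def hwmid_annual(
    tasmax_year: np.ndarray,
    threshold_curve: np.ndarray,
    q25: float,
    q75: float,
    min_run: int = HEATWAVE_MIN_RUN_DAYS,
) -> float:
    """Annual heatwave magnitude index for a single cell-year.

    Daily magnitude within a heatwave period is
    ``(T_d - Q25) / (Q75 - Q25)`` when T_d > Q25, else 0, where Q25/Q75
    are quartiles of the control annual-maximum temperature series.  The
    period magnitude is the daily sum; the annual index is the maximum
    over periods (0.0 for a year without heatwave periods).
    """
    if not q75 > q25:
        raise DegenerateReferenceError(
            f"degenerate magnitude reference: Q25={q25}, Q75={q75}"
        )
    t = np.asarray(tasmax_year, dtype=float)
    best = 0.0
    for start, length in detect_heatwave_periods(t, threshold_curve, min_run):
        seg = t[start : start + length]
        mag = np.where(seg > q25, (seg - q25) / (q75 - q25), 0.0).sum()
        best = max(best, float(mag))
    return best


def hwmid_annual_batch(
    tasmax: np.ndarray,
    threshold_curve: np.ndarray,
    q25: np.ndarray,
    q75: np.ndarray,
    min_run: int = HEATWAVE_MIN_RUN_DAYS,
) -> np.ndarray:
    """Vectorized HWMId: tasmax (n_years, 365, nlat, nlon) -> (n_years, nlat, nlon).

    Cells with a degenerate magnitude reference (Q75 <= Q25) return NaN
    so callers can flag them rather than abort a whole grid.
    """
    n_years = tasmax.shape[0]
    space = tasmax.shape[2:]
    n_cells = int(np.prod(space))
    curve = np.asarray(threshold_curve, dtype=np.float32).reshape(DAYS_PER_YEAR, n_cells)
    lo = np.asarray(q25, dtype=float).reshape(n_cells)
    iqr = np.asarray(q75, dtype=float).reshape(n_cells) - lo
    bad = ~(iqr > 0)
    iqr_safe = np.where(bad, 1.0, iqr)
    out = np.empty((n_years, n_cells))
    for y in range(n_years):
        day_cell = tasmax[y].reshape(DAYS_PER_YEAR, n_cells)
        exceed = (day_cell > curve).T  # (cells, days)
        mag = np.maximum(day_cell.T - lo[:, None], 0.0) / iqr_safe[:, None]
        out[y] = _batch_max_run_sums(mag, exceed, min_run)
    out[:, bad] = np.nan
    return out.reshape((n_years,) + space)


# --------------------------------------------------- simple classifiers

def classify_extreme_years(
    annual_metric: np.ndarray,
    control_metric: np.ndarray,
    q: float = DEFAULT_PERCENTILE,
    tail: str = "upper",
) -> np.ndarray:
    """Flag years whose metric lies strictly beyond the control q-th
    percentile (upper tail: >; lower tail: <).  NaNs never flag."""
    if tail not in ("upper", "lower"):
        raise ValueError("tail must be 'upper' or 'lower'")
    ctrl = np.asarray(control_metric, dtype=float)
    if ctrl.shape[0] == 0:
        raise CalibrationError("empty control series")
    thr = np.nanpercentile(ctrl, q, axis=0)
    x = np.asarray(annual_metric, dtype=float)
    with np.errstate(invalid="ignore"):
        return x > thr if tail == "upper" else x < thr


def detect_drought_years(
    soil_moisture: np.ndarray,
    drought_level: np.ndarray | float,
    min_run: int = DROUGHT_MIN_RUN_MONTHS,
) -> np.ndarray:
    """Flag years with >= min_run consecutive below-level months.

    ``soil_moisture`` has shape (n_years, 12, ...); runs are evaluated
    within each calendar year only.  Returns (n_years, ...) booleans.
    """
    sm = np.asarray(soil_moisture, dtype=float)
    if sm.ndim < 2 or sm.shape[1] != MONTHS_PER_YEAR:
        raise ValueError("expected shape (n_years, 12, ...)")
    below = sm < np.asarray(drought_level, dtype=float)
    # month axis to the end for the run scan
    below_m = np.moveaxis(below, 1, -1)
    return _batch_has_run(below_m, min_run)


def compute_dryness_mask(
    mean_discharge: np.ndarray, cutoff: float = DRYNESS_CUTOFF_MM_DAY
) -> np.ndarray:
    """True where the cell is retained (annual-mean discharge >= cutoff).

    Cells strictly below the cutoff (default 0.1 mm/day) are excluded
    from drought and flood classification; a value exactly at the cutoff
    is retained.
    """
    d = np.asarray(mean_discharge, dtype=float)
    if np.any(d < 0):
        raise ValueError("discharge must be non-negative")
    return ~(d < cutoff)


# ------------------------------------------------------------- floods

@dataclass(frozen=True)
class GEVParams:
    """GEV parameters, Coles convention: shape xi > 0 is heavy-tailed.

    (scipy's genextreme uses c = -xi.)
    """

    loc: float
    scale: float
    shape: float

    def quantile(self, p: float) -> float:
        return float(stats.genextreme.ppf(p, c=-self.shape, loc=self.loc, scale=self.scale))


def _lmoment_gev(x: np.ndarray) -> GEVParams:
    """Hosking's L-moment GEV estimator (used as MLE start and fallback)."""
    xs = np.sort(x)
    n = len(xs)
    i = np.arange(1, n + 1)
    b0 = xs.mean()
    b1 = np.sum((i - 1) / (n - 1) * xs) / n
    b2 = np.sum((i - 1) * (i - 2) / ((n - 1) * (n - 2)) * xs) / n
    l1, l2, l3 = b0, 2 * b1 - b0, 6 * b2 - 6 * b1 + b0
    if l2 <= 0:
        raise DegenerateReferenceError("degenerate annual-maximum series")
    t3 = l3 / l2
    c = 2.0 / (3.0 + t3) - np.log(2) / np.log(3)
    k = 7.8590 * c + 2.9554 * c**2  # Hosking's k = -xi
    if abs(k) < 1e-9:
        scale = l2 / np.log(2)
        loc = l1 - scale * np.euler_gamma
        return GEVParams(loc, scale, 0.0)
    from scipy.special import gamma as gamma_fn

    g = gamma_fn(1.0 + k)
    scale = l2 * k / ((1.0 - 2.0**-k) * g)
    loc = l1 - scale * (1.0 - g) / k
    return GEVParams(float(loc), float(scale), float(-k))


def fit_gev_annual_maxima(
    annual_maxima: np.ndarray,
    return_period: float = 40.0,
    shape_bound: float = 0.5,
) -> tuple[GEVParams, float]:
    """Fit a GEV to control annual maxima and give the return level.

    Maximum likelihood with L-moment starting values; if the MLE fails
    to converge or leaves |shape| >= ``shape_bound`` the (clamped)
    L-moment estimate is used instead.  The return level is the GEV
    quantile at non-exceedance probability 1 - 1/return_period (40 yr ->
    0.975, i.e. the 97.5th percentile).  A constant series raises
    :class:`DegenerateReferenceError`.
    """
    x = np.asarray(annual_maxima, dtype=float)
    if x.ndim != 1 or len(x) < 10:
        raise CalibrationError("need a 1-D series of >= 10 annual maxima")
    if not np.all(np.isfinite(x)):
        raise CalibrationError("annual maxima must be finite")
    if np.ptp(x) == 0:
        raise DegenerateReferenceError("constant annual-maximum series")
    start = _lmoment_gev(x)
    params = None
    try:
        c_hat, loc_hat, scale_hat = stats.genextreme.fit(
            x, -start.shape, loc=start.loc, scale=start.scale
        )
        if np.isfinite([c_hat, loc_hat, scale_hat]).all() and scale_hat > 0 and abs(c_hat) < shape_bound:
            params = GEVParams(float(loc_hat), float(scale_hat), float(-c_hat))
    except Exception:
        params = None
    if params is None:
        xi = float(np.clip(start.shape, -shape_bound + 1e-6, shape_bound - 1e-6))
        params = GEVParams(start.loc, start.scale, xi)
    p = 1.0 - 1.0 / return_period
    return params, params.quantile(p)


def classify_flood_years(
    annual_max_outflow: np.ndarray,
    flood_return_level: np.ndarray | float,
    flooded_fraction: np.ndarray,
    dryness_mask: np.ndarray | bool = True,
    min_fraction_pct: float = MIN_FLOODED_FRACTION_PCT,
) -> np.ndarray:
    """Binary flood classification per year.

    A year floods iff the annual maximum outflow strictly exceeds the
    return level AND at least ``min_fraction_pct``% of the cell is
    flooded that year AND the cell passes the dryness mask.
    """
    q = np.asarray(annual_max_outflow, dtype=float)
    ff = np.asarray(flooded_fraction, dtype=float)
    with np.errstate(invalid="ignore"):
        flags = (q > np.asarray(flood_return_level, dtype=float)) & (
            ff >= min_fraction_pct / 100.0
        )
    return flags & np.asarray(dryness_mask, dtype=bool)


# ------------------------------------------------- whole-grid pipeline

@dataclass
class ControlSummaries:
    """Percentile-free control statistics, reusable across sensitivity q.

    Components are ``None`` when the control run lacks the variables an
    event type needs (e.g. a heatwave-only calibration).
    """

    hw_doy_p90: np.ndarray | None = None       # (365, nlat, nlon)
    hw_q25: np.ndarray | None = None           # (nlat, nlon)
    hw_q75: np.ndarray | None = None
    hwmid_control: np.ndarray | None = None    # (n_ctrl_years, nlat, nlon)
    soil_moisture_control: np.ndarray | None = None  # (n_ctrl_years, 12, ...)
    annmax_outflow_control: np.ndarray | None = None
    burned_control: np.ndarray | None = None
    dryness_mask: np.ndarray | None = None     # (nlat, nlon) True = retained
    gev_params: np.ndarray | None = None       # (3, nlat, nlon): loc, scale, xi
    gev_usable: np.ndarray | None = None


@dataclass
class ThresholdSet:
    """Per-cell calibrated thresholds and masks for all four event types.

    Components for event types the control run could not calibrate are
    ``None``.
    """

    q: float
    hw_doy_p90: np.ndarray | None = None
    hw_q25: np.ndarray | None = None
    hw_q75: np.ndarray | None = None
    hwmid_extreme_level: np.ndarray | None = None   # (nlat, nlon)
    drought_monthly_level: np.ndarray | None = None  # (nlat, nlon)
    gev_params: np.ndarray | None = None            # (3, nlat, nlon)
    flood_return_level: np.ndarray | None = None    # (nlat, nlon)
    flood_return_period: float = 40.0
    wildfire_level: np.ndarray | None = None        # (nlat, nlon)
    dryness_mask: np.ndarray | None = None          # (nlat, nlon)
    gev_usable: np.ndarray | None = None            # (nlat, nlon)


@dataclass
class EventMatrix:
    """Boolean (year, cell) classification per event type for one run."""

    years: np.ndarray
    flags: dict[str, np.ndarray]        # event -> (n_years, nlat, nlon) bool
    valid: dict[str, np.ndarray]        # event -> (nlat, nlon) bool
    combination_id: str = ""
    scenario_tag: str = ""

    def counts_in(self, year_lo: int, year_hi: int, event: str) -> np.ndarray:
        """Flagged-year counts over the inclusive year range."""
        sel = (self.years >= year_lo) & (self.years <= year_hi)
        return self.flags[event][sel].sum(axis=0)


def summarize_control(
    control: SimulationRun,
    grid: Grid | None = None,
    return_period: float | None = None,
    doy_q: float = DOY_PERCENTILE,
    doy_window: int = DOY_WINDOW_DAYS,
) -> ControlSummaries:
    """One-pass control calibration of everything percentile-independent.

    Only the components whose input variables are present in the control
    run are computed; the rest stay ``None``.
    """
    s = ControlSummaries()
    if "tasmax" in control.fields:
        tas = control.fields["tasmax"]
        s.hw_doy_p90 = calibrate_doy_percentile(tas, doy_q, doy_window)
        ann_max_tas = tas.max(axis=1)
        s.hw_q25 = np.percentile(ann_max_tas, 25, axis=0)
        s.hw_q75 = np.percentile(ann_max_tas, 75, axis=0)
        s.hwmid_control = hwmid_annual_batch(tas, s.hw_doy_p90, s.hw_q25, s.hw_q75)
    if "soil_moisture" in control.fields:
        s.soil_moisture_control = control.fields["soil_moisture"]
    if "discharge" in control.fields:
        s.dryness_mask = compute_dryness_mask(control.fields["discharge"].mean(axis=0))
    if "burned_area" in control.fields:
        s.burned_control = control.fields["burned_area"]
    if "outflow" in control.fields:
        annmax_q = control.fields["outflow"].max(axis=1)
        s.annmax_outflow_control = annmax_q
        space = annmax_q.shape[1:]
        gev = np.full((3,) + space, np.nan)
        usable = np.zeros(space, dtype=bool)
        flat = annmax_q.reshape(annmax_q.shape[0], -1)
        gev_flat = gev.reshape(3, -1)
        usable_flat = usable.reshape(-1)
        for c in range(flat.shape[1]):
            try:
                params, _ = fit_gev_annual_maxima(flat[:, c], return_period or 40.0)
            except CalibrationError:
                continue
            gev_flat[:, c] = (params.loc, params.scale, params.shape)
            usable_flat[c] = True
        s.gev_params = gev
        s.gev_usable = usable
    return s


def thresholds_for_percentile(
    summaries: ControlSummaries, q: float = DEFAULT_PERCENTILE
) -> ThresholdSet:
    """Derive the q-dependent thresholds from control summaries.

    The drought level uses the low-tail mirror 100 - q pooled over all
    control months; the flood return period is 1/(1 - q/100) so the
    return level tracks the same percentile as the other event types.
    """
    if not 50 < q < 100:
        raise CalibrationError("upper-tail percentile must lie in (50, 100)")
    thr = ThresholdSet(
        q=q,
        hw_doy_p90=summaries.hw_doy_p90,
        hw_q25=summaries.hw_q25,
        hw_q75=summaries.hw_q75,
        gev_params=summaries.gev_params,
        flood_return_period=return_period_for_percentile(q),
        dryness_mask=summaries.dryness_mask,
        gev_usable=summaries.gev_usable,
    )
    if summaries.hwmid_control is not None:
        with np.errstate(invalid="ignore"):
            thr.hwmid_extreme_level = np.nanpercentile(summaries.hwmid_control, q, axis=0)
    if summaries.soil_moisture_control is not None:
        sm = summaries.soil_moisture_control
        pooled = sm.reshape(-1, *sm.shape[2:])
        thr.drought_monthly_level = np.percentile(pooled, 100.0 - q, axis=0)
    if summaries.gev_params is not None:
        loc, scale, xi = summaries.gev_params
        with np.errstate(invalid="ignore"):
            thr.flood_return_level = stats.genextreme.ppf(
                q / 100.0, c=-xi, loc=loc, scale=scale
            )
    if summaries.burned_control is not None:
        thr.wildfire_level = np.percentile(summaries.burned_control, q, axis=0)
    return thr


def calibrate_thresholds(
    control: SimulationRun, q: float = DEFAULT_PERCENTILE
) -> ThresholdSet:
    """Full control calibration at one percentile (convenience wrapper)."""
    return thresholds_for_percentile(summarize_control(control), q)


def detect_events(
    run: SimulationRun, thresholds: ThresholdSet, grid: Grid,
    hwmid_control: np.ndarray | None = None,
) -> EventMatrix:
    """Classify every (cell, year) of a run for all four event types.

    The heatwave classifier needs the control HWMId series to set its
    percentile threshold; that threshold is already baked into
    ``thresholds.hwmid_extreme_level``.  Validity masks: all events need
    land; drought and flood additionally need the dryness mask; flood
    needs a usable GEV fit.
    """
    land = grid.land_mask
    flags: dict[str, np.ndarray] = {}
    valid: dict[str, np.ndarray] = {}

    if "tasmax" in run.fields and thresholds.hwmid_extreme_level is not None:
        hw = hwmid_annual_batch(
            run.fields["tasmax"], thresholds.hw_doy_p90, thresholds.hw_q25, thresholds.hw_q75
        )
        with np.errstate(invalid="ignore"):
            f = hw > thresholds.hwmid_extreme_level
        valid["heatwave"] = land & (thresholds.hw_q75 > thresholds.hw_q25)
        flags["heatwave"] = f & valid["heatwave"]

    if "soil_moisture" in run.fields and thresholds.drought_monthly_level is not None:
        f = detect_drought_years(run.fields["soil_moisture"], thresholds.drought_monthly_level)
        valid["drought"] = land & thresholds.dryness_mask
        flags["drought"] = f & valid["drought"]

    if (
        "outflow" in run.fields
        and "flooded_fraction" in run.fields
        and thresholds.flood_return_level is not None
    ):
        annmax = run.fields["outflow"].max(axis=1)
        f = classify_flood_years(
            annmax, thresholds.flood_return_level, run.fields["flooded_fraction"],
            thresholds.dryness_mask,
        )
        valid["flood"] = land & thresholds.dryness_mask & thresholds.gev_usable
        flags["flood"] = f & valid["flood"]

    if "burned_area" in run.fields and thresholds.wildfire_level is not None:
        # threshold already calibrated; strict exceedance, ties never flag
        f = run.fields["burned_area"] > thresholds.wildfire_level
        valid["wildfire"] = land
        flags["wildfire"] = f & valid["wildfire"]

    return EventMatrix(
        years=run.years, flags=flags, valid=valid,
        combination_id=run.combination_id, scenario_tag=run.scenario_tag,
    )


def run_sensitivity(
    summaries: ControlSummaries,
    run: SimulationRun,
    grid: Grid,
    percentiles: Sequence[float] = SENSITIVITY_PERCENTILES,
) -> dict[float, EventMatrix]:
    """Event matrices at each sensitivity percentile (95, 97.5, 99 by
    default), recalibrating thresholds per q from shared summaries."""
    return {
        q: detect_events(run, thresholds_for_percentile(summaries, q), grid)
        for q in percentiles
    }
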