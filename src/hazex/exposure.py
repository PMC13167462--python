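"""30-year-window frequencies, ensemble statistics, multi-hazard counts,
and species/ecoregion exposure summaries.

Event frequency is the proportion of years within a 30-year window in
which a cell is classified as experiencing an event (stored as integer
flagged-year counts so threshold comparisons like 10/30 >= 0.33 are
exact).  Entity exposure is the frequency-, area- and overlap-weighted
mean over the cells of a species range or ecoregion:

    exposure = sum_i f_i a_i o_i / sum_i a_i o_i

with f_i the window frequency, a_i the spherical cell area and o_i the
overlap fraction.  Multi-hazard counts tally how many event types reach
a qualification frequency (default >= 0.33 / yr) in a cell.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .events import EventMatrix
from .grid import AreaWeights, Grid, RangeMask

DEFAULT_WINDOW_WIDTH = 30
BASELINE_CENTER = 2000
MULTI_HAZARD_THRESHOLD = 0.33
_EXACT_EPS = 1e-9  # conservative rounding: 10/30 qualifies at 0.33


class ExposureError(ValueError):
    pass


def window_years(center: int, width: int = DEFAULT_WINDOW_WIDTH) -> tuple[int, int]:
    """Inclusive year span of a window centred on ``center``.

    A 30-year window centred on 2000 spans 1985-2014.
    """
    lo = center - width // 2
    return lo, lo + width - 1


@dataclass
class FrequencyField:
    """Per-cell flagged-year counts for one window / event / combination."""

    event_type: str
    window_center: int
    counts: np.ndarray           # (nlat, nlon) int
    width: int = DEFAULT_WINDOW_WIDTH
    valid: np.ndarray | None = None
    combination_id: str = ""
    scenario_tag: str = ""

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if np.any(self.counts < 0) or np.any(self.counts > self.width):
            raise ExposureError("counts must lie in [0, window width]")
        if self.valid is None:
            self.valid = np.ones(self.counts.shape, dtype=bool)

    @property
    def frequency(self) -> np.ndarray:
        """Float frequency in [0, 1]; invalid cells are 0."""
        return np.where(self.valid, self.counts / self.width, 0.0)

    def qualifies(self, threshold: float = MULTI_HAZARD_THRESHOLD) -> np.ndarray:
        """Exact-fraction test counts/width >= threshold (10/30 passes 0.33)."""
        return self.valid & (self.counts >= threshold * self.width - _EXACT_EPS)


def window_frequency(
    events: EventMatrix,
    center: int,
    event_type: str,
    width: int = DEFAULT_WINDOW_WIDTH,
) -> FrequencyField:
    """Flagged-year count over the window centred on ``center`` / width."""
    lo, hi = window_years(center, width)
    if lo < events.years.min() or hi > events.years.max():
        raise ExposureError(
            f"window {lo}-{hi} extends outside available years "
            f"{events.years.min()}-{events.years.max()}"
        )
    return FrequencyField(
        event_type=event_type,
        window_center=center,
        counts=events.counts_in(lo, hi, event_type),
        width=width,
        valid=events.valid[event_type],
        combination_id=events.combination_id,
        scenario_tag=events.scenario_tag,
    )


def frequency_change(future: FrequencyField, baseline: FrequencyField) -> np.ndarray:
    """future - baseline frequency per cell, in [-1, 1]."""
    if future.counts.shape != baseline.counts.shape:
        raise ExposureError("frequency fields are on different grids")
    if future.event_type != baseline.event_type:
        raise ExposureError("frequency fields are for different event types")
    return future.frequency - baseline.frequency


def ensemble_stats(values: Sequence[np.ndarray | float]) -> tuple:
    """Elementwise (mean, min, max) across ensemble members."""
    if len(values) == 0:
        raise ExposureError("empty ensemble")
    arr = np.stack([np.asarray(v, dtype=float) for v in values])
    return arr.mean(axis=0), arr.min(axis=0), arr.max(axis=0)


def multi_hazard_count(
    freqs: Mapping[str, FrequencyField],
    threshold: float = MULTI_HAZARD_THRESHOLD,
) -> np.ndarray:
    """Number of event types (0-4) qualifying per cell at ``threshold``."""
    shapes = {f.counts.shape for f in freqs.values()}
    if len(shapes) != 1:
        raise ExposureError("frequency fields are on different grids")
    count = np.zeros(shapes.pop(), dtype=int)
    for f in freqs.values():
        count += f.qualifies(threshold)
    return count


def _weighted_mean(
    cell_values: np.ndarray, mask: RangeMask, areas: AreaWeights
) -> float:
    w = areas.area * mask.overlap
    denom = float(w.sum())
    if denom <= 0:
        raise ExposureError(
            f"entity {mask.entity_id!r} has zero overlap-weighted area"
        )
    return float((cell_values * w).sum() / denom)


def entity_exposure(
    freq: FrequencyField | np.ndarray, mask: RangeMask, areas: AreaWeights
) -> float:
    """Frequency-, area- and overlap-weighted exposure of one entity.

    Cells where the event is undefined (ocean, dryness-masked, unusable
    GEV) contribute frequency 0: the entity's area there is counted as
    unexposed, not dropped.
    """
    f = freq.frequency if isinstance(freq, FrequencyField) else np.asarray(freq, dtype=float)
    return _weighted_mean(f, mask, areas)


def entity_multi_exposure(
    freqs: Mapping[str, FrequencyField],
    mask: RangeMask,
    areas: AreaWeights,
    min_types: int = 2,
    threshold: float = MULTI_HAZARD_THRESHOLD,
) -> float:
    """Proportion of an entity exposed to >= min_types qualifying event
    types, weighted by area and overlap."""
    indicator = (multi_hazard_count(freqs, threshold) >= min_types).astype(float)
    return _weighted_mean(indicator, mask, areas)


def count_entities_above(
    exposures: pd.DataFrame,
    cutoff: float,
    by: str = "taxon",
    value_col: str = "exposure",
) -> pd.Series:
    """Entities with exposure >= cutoff, grouped by ``by`` (e.g. taxon)."""
    above = exposures[exposures[value_col] >= cutoff]
    counts = above.groupby(by)["entity_id"].nunique()
    return counts.reindex(sorted(exposures[by].unique()), fill_value=0)


def richness_map(masks: Iterable[RangeMask]) -> np.ndarray:
    """Per-cell count of entities with any overlap."""
    out: np.ndarray | None = None
    for rm in masks:
        ind = (rm.overlap > 0).astype(int)
        out = ind if out is None else out + ind
    if out is None:
        raise ExposureError("no range masks supplied")
    return out


def exposure_table(
    freq_by_event: Mapping[str, FrequencyField],
    baseline_by_event: Mapping[str, FrequencyField],
    masks: Sequence[RangeMask],
    areas: AreaWeights,
    multi_orders: Sequence[int] = (2,),
    threshold: float = MULTI_HAZARD_THRESHOLD,
) -> pd.DataFrame:
    """Per-entity exposure rows for one combination and window.

    One row per (entity, event type) plus one per multi-hazard order k
    (event_type ``multi>=k``); columns: entity_id, entity_kind, taxon,
    scenario, window_center, event_type, exposure, change.
    """
    rows = []
    some = next(iter(freq_by_event.values()))
    for mask in masks:
        for ev, f in freq_by_event.items():
            exp_now = entity_exposure(f, mask, areas)
            exp_base = entity_exposure(baseline_by_event[ev], mask, areas)
            rows.append(
                {
                    "entity_id": mask.entity_id,
                    "entity_kind": mask.entity_kind,
                    "taxon": mask.taxon,
                    "scenario": f.scenario_tag,
                    "combination_id": f.combination_id,
                    "window_center": f.window_center,
                    "event_type": ev,
                    "exposure": exp_now,
                    "change": exp_now - exp_base,
                }
            )
        for k in multi_orders:
            exp_now = entity_multi_exposure(freq_by_event, mask, areas, k, threshold)
            exp_base = entity_multi_exposure(baseline_by_event, mask, areas, k, threshold)
            rows.append(
                {
                    "entity_id": mask.entity_id,
                    "entity_kind": mask.entity_kind,
                    "taxon": mask.taxon,
                    "scenario": some.scenario_tag,
                    "combination_id": some.combination_id,
                    "window_center": some.window_center,
                    "event_type": f"multi>={k}",
                    "exposure": exp_now,
                    "change": exp_now - exp_base,
                }
            )
    return pd.DataFrame(rows)


def summarize_ensemble(exposures: pd.DataFrame) -> pd.DataFrame:
    """Collapse per-combination exposure rows to ensemble mean/min/max.

    Exposure is computed per combination first, then summarized, so the
    reported min-max genuinely spans model combinations.
    """
    keys = ["entity_id", "entity_kind", "taxon", "scenario", "window_center", "event_type"]
    g = exposures.groupby(keys, sort=False)
    out = g.agg(
        exposure=("exposure", "mean"),
        ens_min=("exposure", "min"),
        ens_max=("exposure", "max"),
        change=("change", "mean"),
        change_min=("change", "min"),
        change_max=("change", "max"),
        n_combinations=("combination_id", "nunique"),
    ).reset_index()
    return out
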