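"""End-to-end pipeline: synthesis -> calibration -> detection -> exposure.

The pipeline streams the pseudo-ensemble one model combination at a
time (raw daily forcing is never held for more than one member), so the
default desk-scale configuration — 20x20 grid, 100-year control, 5x3
ensemble, 200 species, 12 ecoregions — runs in a few minutes on one CPU.

Every run is deterministic given the configured seed; a provenance
record (config hash, seed, library versions) is written next to the
outputs.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, field_validator

from . import events as ev
from . import exposure as ex
from . import io as hio
from . import synthetic as syn
from .grid import AreaWeights, Grid, filter_unrepresented, ranges_to_table, tally_by_taxon

log = logging.getLogger("hazex")

_EVENT_VARIABLES = {
    "heatwave": ("tasmax",),
    "drought": ("soil_moisture", "discharge"),
    "flood": ("outflow", "flooded_fraction", "discharge"),
    "wildfire": ("burned_area",),
}


class TrendConfig(BaseModel):
    warming_rate: float = 0.0
    drying_rate: float = 0.0
    flow_scale_rate: float = 0.0
    burn_scale_rate: float = 0.0
    start_year: int = 2015

    def to_spec(self) -> syn.TrendSpec:
        return syn.TrendSpec(
            self.warming_rate, self.drying_rate, self.flow_scale_rate,
            self.burn_scale_rate, self.start_year,
        )


class PipelineConfig(BaseModel):
    """Validated pipeline configuration (YAML-serializable)."""

    # grid
    nlat: int = 20
    nlon: int = 20
    resolution: float = 0.5
    land_fraction: float = Field(0.6, gt=0.0, le=1.0)
    # randomness
    seed: int = Field(42, ge=0, lt=2**31)
    # runs
    n_control_years: int = Field(100, ge=30)
    scenario_start: int = 1985
    scenario_end: int = 2100
    scenarios: list[str] = ["ssp126", "ssp370", "ssp585"]
    trends: dict[str, TrendConfig] = {}
    # ensemble
    n_climate: int = Field(5, ge=1)
    n_impact: int = Field(3, ge=1)
    # entities
    n_species: int = 200
    n_offland: int = 5
    n_ecoregions: int = 12
    # classification
    percentile: float = 97.5
    event_types: list[str] = list(ev.EVENT_TYPES)
    # exposure
    window_width: int = 30
    baseline_center: int = 2000
    centers: list[int] = [2030, 2050, 2085]
    mh_threshold: float = 0.33
    multi_orders: list[int] = [2]
    cutoffs: list[float] = [0.5]
    # output
    outdir: str = "results/pipeline"
    write_frequency_maps: bool = True

    @field_validator("percentile")
    @classmethod
    def _check_q(cls, v: float) -> float:
        if not 50 < v < 100:
            raise ValueError("percentile must lie in (50, 100)")
        return v

    @field_validator("event_types")
    @classmethod
    def _check_events(cls, v: list[str]) -> list[str]:
        bad = set(v) - set(ev.EVENT_TYPES)
        if bad:
            raise ValueError(f"unknown event types: {sorted(bad)}")
        return v

    def trend_for(self, tag: str) -> syn.TrendSpec:
        if tag in self.trends:
            return TrendConfig.model_validate(self.trends[tag]).to_spec()
        if tag in syn.SCENARIO_TRENDS:
            return syn.SCENARIO_TRENDS[tag]
        raise ValueError(f"no trend specification for scenario {tag!r}")

    @property
    def variables(self) -> tuple[str, ...]:
        out: list[str] = []
        for e in self.event_types:
            for v in _EVENT_VARIABLES[e]:
                if v not in out:
                    out.append(v)
        return tuple(out)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.model_validate(yaml.safe_load(Path(path).read_text()) or {})

    def to_yaml(self) -> str:
        return yaml.safe_dump(json.loads(self.model_dump_json()), sort_keys=True)


@dataclass
class PipelineResult:
    grid: Grid
    areas: AreaWeights
    species: list
    ecoregions: list
    tally: pd.DataFrame
    exposures: pd.DataFrame          # per combination
    summary: pd.DataFrame            # ensemble mean/min/max
    counts: pd.DataFrame             # entities above cutoffs
    provenance: dict = field(default_factory=dict)


def build_world(config: PipelineConfig) -> tuple[Grid, AreaWeights, list, list, pd.DataFrame]:
    """Grid, areas, filtered species ranges, ecoregions, filter tally."""
    land = syn.generate_land_mask(config.nlat, config.nlon, config.seed, config.land_fraction)
    grid = Grid.regular(config.nlat, config.nlon, config.resolution, land_mask=land)
    areas = AreaWeights.for_grid(grid)
    ranges = syn.generate_ranges(
        grid, config.n_species, config.seed, n_offland=config.n_offland
    )
    kept, excluded = filter_unrepresented(ranges, grid)
    tally = tally_by_taxon(kept, excluded)
    ecoregions = syn.generate_ecoregions(grid, config.n_ecoregions, config.seed)
    log.info(
        "world: %d/%d land cells, %d species kept (%d excluded), %d ecoregions",
        grid.n_land, grid.n_cells, len(kept), len(excluded), len(ecoregions),
    )
    return grid, areas, kept, ecoregions, tally


def _frequency_fields(
    matrix: ev.EventMatrix, centers: Sequence[int], width: int
) -> dict[int, dict[str, ex.FrequencyField]]:
    return {
        c: {
            e: ex.window_frequency(matrix, c, e, width)
            for e in matrix.flags
        }
        for c in centers
    }


def combination_exposures(
    combo: syn.ModelCombination,
    config: PipelineConfig,
    grid: Grid,
    areas: AreaWeights,
    entities: Sequence,
) -> tuple[pd.DataFrame, dict]:
    """Exposure rows for one model combination across scenarios/windows.

    Also returns the per-(scenario, center, event) frequency-count maps
    for optional ensemble-map output.
    """
    t0 = time.perf_counter()
    control = combo.control(grid, config.n_control_years, config.variables)
    summaries = ev.summarize_control(control)
    thresholds = ev.thresholds_for_percentile(summaries, config.percentile)
    del control
    n_years = config.scenario_end - config.scenario_start + 1
    frames = []
    freq_maps: dict = {}
    for tag in config.scenarios:
        run = combo.scenario(
            grid, config.trend_for(tag), n_years,
            config.variables, config.scenario_start, tag,
        )
        matrix = ev.detect_events(run, thresholds, grid)
        del run
        fields = _frequency_fields(
            matrix, [config.baseline_center, *config.centers], config.window_width
        )
        baseline = fields[config.baseline_center]
        for c in config.centers:
            frames.append(
                ex.exposure_table(
                    fields[c], baseline, entities, areas,
                    config.multi_orders, config.mh_threshold,
                )
            )
            freq_maps[(tag, c)] = fields[c]
        freq_maps[(tag, config.baseline_center)] = baseline
    log.info(
        "combination %s: %d scenarios in %.1f s",
        combo.combination_id, len(config.scenarios), time.perf_counter() - t0,
    )
    return pd.concat(frames, ignore_index=True), freq_maps


def run_pipeline(config: PipelineConfig, outdir: str | Path | None = None) -> PipelineResult:
    """Execute the full chain and write all artifacts under ``outdir``."""
    outdir = Path(outdir if outdir is not None else config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config_text = config.to_yaml()
    (outdir / "config.yaml").write_text(config_text)
    provenance = hio.write_provenance(outdir / "provenance.json", config_text, config.seed)

    grid, areas, species, ecoregions, tally = build_world(config)
    tally.to_csv(outdir / "species_tally.csv")
    ranges_to_table(species + ecoregions).to_csv(outdir / "ranges.csv", index=False)

    combos = syn.generate_model_ensemble(config.n_climate, config.n_impact, config.seed)
    entities = list(species) + list(ecoregions)
    frames = []
    count_sums: dict = {}
    count_n = 0
    for combo in combos:
        df, freq_maps = combination_exposures(combo, config, grid, areas, entities)
        frames.append(df)
        for key, fields in freq_maps.items():
            for e, f in fields.items():
                k = key + (e,)
                count_sums.setdefault(k, np.zeros(grid.shape))
                count_sums[k] += f.frequency
        count_n += 1

    exposures = pd.concat(frames, ignore_index=True)
    exposures.to_csv(outdir / "exposure_by_combination.csv", index=False)
    summary = ex.summarize_ensemble(exposures)
    summary.to_csv(outdir / "exposure_summary.csv", index=False)

    if config.write_frequency_maps:
        import xarray as xr

        maps = {}
        for (tag, center, e), s in count_sums.items():
            maps[f"{tag}_{center}_{e}"] = xr.DataArray(
                s / count_n, dims=("lat", "lon"),
                attrs={"long_name": f"ensemble-mean {e} frequency, {tag} window {center}"},
            )
        hio.write_gridded(
            outdir / "frequency_ensemble_mean.nc",
            xr.Dataset(maps, coords=hio.grid_coords(grid)),
        )

    counts = _entity_counts(summary, exposures, config.cutoffs)
    counts.to_csv(outdir / "entities_above_cutoff.csv", index=False)

    _write_report(outdir / "summary_report.json", config, tally, summary, counts)
    return PipelineResult(
        grid, areas, species, ecoregions, tally, exposures, summary, counts, provenance
    )


def _entity_counts(
    summary: pd.DataFrame, exposures: pd.DataFrame, cutoffs: Sequence[float]
) -> pd.DataFrame:
    """Entities above each cutoff, from ensemble-mean exposure and as the
    per-combination min-max range."""
    rows = []
    keys = ["scenario", "window_center", "event_type", "entity_kind"]
    for cutoff in cutoffs:
        for grp, sub in summary.groupby(keys, sort=False):
            per_combo = exposures.merge(
                pd.DataFrame([dict(zip(keys, grp))]), on=keys, how="inner"
            )
            combo_counts = per_combo[per_combo["exposure"] >= cutoff].groupby(
                "combination_id"
            )["entity_id"].nunique()
            combo_counts = combo_counts.reindex(
                per_combo["combination_id"].unique(), fill_value=0
            )
            rows.append(
                {
                    **dict(zip(keys, grp)),
                    "cutoff": cutoff,
                    "n_above_mean": int((sub["exposure"] >= cutoff).sum()),
                    "n_above_combo_min": int(combo_counts.min()) if len(combo_counts) else 0,
                    "n_above_combo_max": int(combo_counts.max()) if len(combo_counts) else 0,
                    "n_entities": int(sub["entity_id"].nunique()),
                }
            )
    return pd.DataFrame(rows)


def _write_report(
    path: Path, config: PipelineConfig, tally: pd.DataFrame,
    summary: pd.DataFrame, counts: pd.DataFrame,
) -> None:
    keys = ["scenario", "window_center", "event_type", "entity_kind"]
    mean_block = (
        summary.groupby(keys)[["exposure", "ens_min", "ens_max", "change"]]
        .mean()
        .reset_index()
        .to_dict(orient="records")
    )
    report = {
        "percentile": config.percentile,
        "mh_threshold": config.mh_threshold,
        "species_tally": tally.to_dict(orient="index"),
        "mean_exposure": mean_block,
        "entities_above_cutoff": counts.to_dict(orient="records"),
    }
    path.write_text(json.dumps(report, indent=2, default=float))
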