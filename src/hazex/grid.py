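"""Regular lat/lon grid, spherical area weights, and range rasterization.

The analysis grid is a regular cell-centre-registered latitude/longitude
grid (default 0.5 deg).  A cell centred on (lat, lon) spans
``[lat - res/2, lat + res/2)`` x ``[lon - res/2, lon + res/2)`` (half-open
in both axes).  Geometries crossing the antimeridian are not supported.

Species ranges and ecoregions are represented as per-cell overlap
fractions (:class:`RangeMask`): the fraction of each grid cell's area
covered by the entity's geometry.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

EARTH_RADIUS_KM = 6371.0

TAXA = ("amphibian", "bird", "mammal", "reptile")


class GridError(ValueError):
    """Invalid grid definition or out-of-domain coordinate."""


@dataclass(frozen=True)
class Grid:
    """Regular cell-centre-registered lat/lon grid with a land mask.

    Parameters
    ----------
    lat_centers, lon_centers
        Strictly monotone cell-centre coordinates in degrees.
    resolution
        Cell size in degrees (same in both axes).
    land_mask
        Boolean array of shape ``(nlat, nlon)``; True marks land cells.
    """

    lat_centers: np.ndarray
    lon_centers: np.ndarray
    resolution: float = 0.5
    land_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        lat = np.asarray(self.lat_centers, dtype=float)
        lon = np.asarray(self.lon_centers, dtype=float)
        object.__setattr__(self, "lat_centers", lat)
        object.__setattr__(self, "lon_centers", lon)
        if self.resolution <= 0:
            raise GridError("resolution must be positive")
        if lat.ndim != 1 or lon.ndim != 1:
            raise GridError("coordinate arrays must be 1-D")
        if np.any(np.abs(lat) > 90) or np.any(lon < -180) or np.any(lon >= 180):
            raise GridError("centres must lie in [-90, 90] x [-180, 180)")
        for arr in (lat, lon):
            d = np.diff(arr)
            if len(arr) > 1 and not (np.all(d > 0) or np.all(d < 0)):
                raise GridError("centres must be strictly monotone")
        if self.land_mask is None:
            object.__setattr__(
                self, "land_mask", np.ones(self.shape, dtype=bool)
            )
        else:
            mask = np.asarray(self.land_mask, dtype=bool)
            if mask.shape != self.shape:
                raise GridError(
                    f"land_mask shape {mask.shape} != grid shape {self.shape}"
                )
            object.__setattr__(self, "land_mask", mask)

    @property
    def shape(self) -> tuple[int, int]:
        return (len(self.lat_centers), len(self.lon_centers))

    @property
    def n_cells(self) -> int:
        return self.shape[0] * self.shape[1]

    @property
    def n_land(self) -> int:
        return int(self.land_mask.sum())

    @classmethod
    def regular(
        cls,
        nlat: int,
        nlon: int,
        resolution: float = 0.5,
        lat0: float | None = None,
        lon0: float | None = None,
        land_mask: np.ndarray | None = None,
    ) -> "Grid":
        """Build a regular grid from a corner cell centre.

        ``lat0``/``lon0`` are the first cell centres; defaults centre the
        grid block on (0, 0).
        """
        if lat0 is None:
            lat0 = -resolution * (nlat - 1) / 2
        if lon0 is None:
            lon0 = -resolution * (nlon - 1) / 2
        lats = lat0 + resolution * np.arange(nlat)
        lons = lon0 + resolution * np.arange(nlon)
        return cls(lats, lons, resolution, land_mask)

    def cell_bounds(self, i: int, j: int) -> tuple[float, float, float, float]:
        """(lon_min, lat_min, lon_max, lat_max) of cell (i, j)."""
        h = self.resolution / 2
        return (
            self.lon_centers[j] - h,
            self.lat_centers[i] - h,
            self.lon_centers[j] + h,
            self.lat_centers[i] + h,
        )


def cell_area(
    latitude: float | np.ndarray,
    resolution: float = 0.5,
    radius_km: float = EARTH_RADIUS_KM,
) -> float | np.ndarray:
    """Exact spherical-band area (km^2) of a cell centred at ``latitude``.

    Uses A = R^2 * dlambda * (sin(phi2) - sin(phi1)) with the cell spanning
    ``latitude +/- resolution/2``; depends on latitude only.  To first
    order this is proportional to cos(latitude) * resolution^2.
    """
    lat = np.asarray(latitude, dtype=float)
    if np.any(np.abs(lat) > 90 - resolution / 2 + 1e-12):
        raise GridError(
            f"cell centre latitude must satisfy |lat| <= 90 - res/2; got {latitude}"
        )
    phi1 = np.deg2rad(lat - resolution / 2)
    phi2 = np.deg2rad(lat + resolution / 2)
    dlam = np.deg2rad(resolution)
    area = radius_km**2 * dlam * (np.sin(phi2) - np.sin(phi1))
    return float(area) if np.isscalar(latitude) else area


@dataclass(frozen=True)
class AreaWeights:
    """Per-cell areas (km^2) for a grid; latitude-only for a regular grid."""

    area: np.ndarray  # (nlat, nlon)

    @classmethod
    def for_grid(cls, grid: Grid) -> "AreaWeights":
        col = cell_area(grid.lat_centers, grid.resolution)
        return cls(np.broadcast_to(col[:, None], grid.shape).copy())


@dataclass
class RangeMask:
    """Per-cell overlap fractions of one entity (species or ecoregion)."""

    entity_id: str
    overlap: np.ndarray  # (nlat, nlon) in [0, 1]
    entity_kind: str = "species"  # "species" | "ecoregion"
    taxon: str = "none"

    def __post_init__(self) -> None:
        self.overlap = np.asarray(self.overlap, dtype=float)
        if self.overlap.min(initial=0.0) < -1e-12 or self.overlap.max(initial=0.0) > 1 + 1e-12:
            raise ValueError("overlap fractions must lie in [0, 1]")
        np.clip(self.overlap, 0.0, 1.0, out=self.overlap)

    @property
    def total_overlap(self) -> float:
        return float(self.overlap.sum())

    def land_overlap(self, grid: Grid) -> float:
        return float(self.overlap[grid.land_mask].sum())


def rasterize_range(
    geometry,
    grid: Grid,
    entity_id: str = "entity",
    entity_kind: str = "species",
    taxon: str = "none",
) -> RangeMask:
    """Rasterize a polygon to per-cell overlap fractions.

    Overlap of cell c is area(geometry & c) / area(c), computed in planar
    lon/lat degrees (both areas share the cos-latitude factor, so the
    ratio is exact for a lat/lon cell).  Empty geometry yields an all-zero
    mask; an invalid geometry raises ``ValueError``.
    """
    import shapely

    if geometry is None:
        raise ValueError("geometry is None")
    if geometry.is_empty:
        return RangeMask(entity_id, np.zeros(grid.shape), entity_kind, taxon)
    if not geometry.is_valid:
        raise ValueError(f"invalid geometry for entity {entity_id!r}")

    overlap = np.zeros(grid.shape)
    h = grid.resolution / 2
    minx, miny, maxx, maxy = geometry.bounds
    jj = np.nonzero(
        (grid.lon_centers + h > minx) & (grid.lon_centers - h < maxx)
    )[0]
    ii = np.nonzero(
        (grid.lat_centers + h > miny) & (grid.lat_centers - h < maxy)
    )[0]
    if len(ii) == 0 or len(jj) == 0:
        return RangeMask(entity_id, overlap, entity_kind, taxon)
    cell_a = float(grid.resolution**2)
    lon_min = grid.lon_centers[jj][None, :] - h
    lat_min = grid.lat_centers[ii][:, None] - h
    boxes = shapely.box(
        lon_min, lat_min, lon_min + grid.resolution, lat_min + grid.resolution
    )  # broadcasts to shape (len(ii), len(jj))
    inter = shapely.area(shapely.intersection(boxes, geometry))
    overlap[np.ix_(ii, jj)] = np.clip(inter / cell_a, 0.0, 1.0)
    return RangeMask(entity_id, overlap, entity_kind, taxon)


def filter_unrepresented(
    ranges: Iterable[RangeMask], grid: Grid
) -> tuple[list[RangeMask], list[RangeMask]]:
    """Split ranges into (kept, excluded) by overlap with land cells.

    A range is excluded iff its total overlap with land cells is zero —
    the fate of species restricted to small islands absent from a coarse
    grid.  Re-filtering the kept list is a no-op.
    """
    kept: list[RangeMask] = []
    excluded: list[RangeMask] = []
    for rm in ranges:
        if rm.overlap.shape != grid.shape:
            raise GridError("range mask built against a different grid")
        (kept if rm.land_overlap(grid) > 0 else excluded).append(rm)
    return kept, excluded


def tally_by_taxon(
    kept: Sequence[RangeMask], excluded: Sequence[RangeMask]
) -> pd.DataFrame:
    """Bookkeeping table: initial / excluded / final counts per taxon.

    Returns a DataFrame indexed by taxon with columns ``initial``,
    ``excluded`` and ``final`` plus a ``total`` row; ``final`` is always
    ``initial - excluded``.
    """
    taxa = sorted(
        {rm.taxon for rm in kept} | {rm.taxon for rm in excluded},
        key=lambda t: (TAXA.index(t) if t in TAXA else len(TAXA), t),
    )
    rows = []
    for t in taxa:
        n_k = sum(1 for rm in kept if rm.taxon == t)
        n_e = sum(1 for rm in excluded if rm.taxon == t)
        rows.append({"taxon": t, "initial": n_k + n_e, "excluded": n_e, "final": n_k})
    df = pd.DataFrame(rows).set_index("taxon")
    df.loc["total"] = df.sum()
    return df


def tally_from_counts(initial: dict[str, int], excluded: dict[str, int]) -> pd.DataFrame:
    """Same bookkeeping table from pre-tabulated per-taxon counts."""
    rows = []
    for t in initial:
        e = int(excluded.get(t, 0))
        rows.append(
            {"taxon": t, "initial": int(initial[t]), "excluded": e, "final": int(initial[t]) - e}
        )
    df = pd.DataFrame(rows).set_index("taxon")
    df.loc["total"] = df.sum()
    return df


def ranges_to_table(ranges: Sequence[RangeMask]) -> pd.DataFrame:
    """Long-format table (entity_id, entity_kind, taxon, cell_row, cell_col, overlap)."""
    recs = []
    for rm in ranges:
        ii, jj = np.nonzero(rm.overlap)
        for i, j in zip(ii, jj):
            recs.append(
                (rm.entity_id, rm.entity_kind, rm.taxon, int(i), int(j), float(rm.overlap[i, j]))
            )
    return pd.DataFrame(
        recs,
        columns=["entity_id", "entity_kind", "taxon", "cell_row", "cell_col", "overlap"],
    )


def ranges_from_table(df: pd.DataFrame, grid: Grid) -> list[RangeMask]:
    """Rebuild RangeMask objects from the long-format overlap table."""
    out = []
    for eid, sub in df.groupby("entity_id", sort=False):
        overlap = np.zeros(grid.shape)
        overlap[sub["cell_row"].to_numpy(), sub["cell_col"].to_numpy()] = sub[
            "overlap"
        ].to_numpy()
        out.append(
            RangeMask(
                str(eid),
                overlap,
                entity_kind=str(sub["entity_kind"].iloc[0]),
                taxon=str(sub["taxon"].iloc[0]),
            )
        )
    return out
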