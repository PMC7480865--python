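"""From suitability surfaces to programmatic outputs.

Binary occurrence maps (suitability >= threshold), population at risk per
zone with an uncertainty interval from the ensemble replicates, co-suitability
overlap with a second disease layer (lymphatic filariasis), classification of
WHO implementation units (IUs), and the share percentages used in reporting.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
import shapely

from .grid import GridError, GridRaster, GridSpec

logger = logging.getLogger("podomap")


class RiskError(ValueError):
    pass


@dataclass
class BinaryMap:
    """Spec-aligned {0,1} raster: 1 iff suitability >= threshold at a valid cell."""

    raster: GridRaster
    threshold: float


def binarize(suitability: GridRaster, threshold: float) -> BinaryMap:
    """Classify a suitability surface into an occurrence map (>= rule,
    presence-inclusive at the cut-off); masked cells stay masked."""
    if not 0 <= threshold <= 1:
        raise RiskError(f"threshold must be in [0, 1], got {threshold}")
    vals = (suitability.values >= threshold).astype(float)
    vals[suitability.nodata_mask] = np.nan
    return BinaryMap(GridRaster(suitability.spec, vals, suitability.nodata_mask.copy()),
                     float(threshold))


@dataclass
class RiskSummary:
    """Population at risk per zone and overall, with uncertainty intervals."""

    per_zone: dict[str, tuple[float, float, float]]  # zone -> (point, lower, upper)
    total: tuple[float, float, float]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"zone": z, "population_at_risk": p, "lower": lo, "upper": hi}
            for z, (p, lo, hi) in self.per_zone.items()
        ]
        rows.append(
            {"zone": "Total", "population_at_risk": self.total[0],
             "lower": self.total[1], "upper": self.total[2]}
        )
        return pd.DataFrame(rows)


def _check_aligned(spec: GridSpec, *rasters: GridRaster) -> None:
    for r in rasters:
        if not r.spec.aligned(spec):
            raise RiskError("rasters are not aligned to a common grid")


def _zone_sum(binary: BinaryMap, population: GridRaster, zone_ids: np.ndarray,
              zone_values: np.ndarray) -> dict:
    valid = binary.raster.valid_mask & population.valid_mask
    at_risk = valid & (binary.raster.values == 1)
    out = {}
    for z in zone_ids:
        cells = at_risk & (zone_values == z)
        out[z] = float(population.values[cells].sum())
    return out


def population_at_risk(
    binary: BinaryMap,
    population: GridRaster,
    member_binaries: list[BinaryMap],
    zones: GridRaster,
    zone_lookup: dict[int, str] | None = None,
) -> RiskSummary:
    """Population in suitable cells per zone, with a 2.5/97.5% interval taken
    over the same sums computed on each ensemble-member binary map."""
    _check_aligned(binary.raster.spec, population, zones,
                   *[m.raster for m in member_binaries])
    zone_vals = zones.values
    zone_ids = np.unique(zone_vals[zones.valid_mask]).astype(int)
    point = _zone_sum(binary, population, zone_ids, zone_vals)
    member_sums = {z: [] for z in zone_ids}
    for m in member_binaries:
        s = _zone_sum(m, population, zone_ids, zone_vals)
        for z in zone_ids:
            member_sums[z].append(s[z])
    per_zone = {}
    for z in zone_ids:
        name = zone_lookup.get(int(z), str(z)) if zone_lookup else str(z)
        if member_sums[z]:
            lo, hi = np.quantile(member_sums[z], [0.025, 0.975])
        else:
            lo = hi = point[z]
        per_zone[name] = (point[z], float(lo), float(hi))
    total_point = float(sum(point.values()))
    if member_binaries:
        totals = [sum(_zone_sum(m, population, zone_ids, zone_vals).values())
                  for m in member_binaries]
        t_lo, t_hi = (float(q) for q in np.quantile(totals, [0.025, 0.975]))
    else:
        t_lo = t_hi = total_point
    return RiskSummary(per_zone=per_zone, total=(total_point, t_lo, t_hi))


OVERLAP_CLASSES = ("neither", "a_only", "b_only", "both")


def overlap_binary(
    a: BinaryMap, b: BinaryMap, population: GridRaster
) -> tuple[GridRaster, dict[str, float]]:
    """Combine two occurrence maps into a 4-class map (0 neither, 1 a-only,
    2 b-only, 3 both) and the population living in each class."""
    _check_aligned(a.raster.spec, b.raster, population)
    valid = a.raster.valid_mask & b.raster.valid_mask & population.valid_mask
    av = a.raster.values == 1
    bv = b.raster.values == 1
    classes = np.where(av & bv, 3, np.where(bv, 2, np.where(av, 1, 0))).astype(float)
    classes[~valid] = np.nan
    pops = {
        "neither": float(population.values[valid & ~av & ~bv].sum()),
        "a_only": float(population.values[valid & av & ~bv].sum()),
        "b_only": float(population.values[valid & ~av & bv].sum()),
        "both": float(population.values[valid & av & bv].sum()),
    }
    return GridRaster(a.raster.spec, classes, ~valid), pops


@dataclass
class IUTable:
    """Per implementation-unit suitability and mapping-need classification."""

    table: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def n_suitable(self) -> int:
        return int(self.table["suitable"].sum())

    @property
    def n_needs_mapping(self) -> int:
        return int(self.table["needs_mapping"].sum())


def classify_ius(
    binary: BinaryMap,
    iu_zones: GridRaster,
    mapped_flags: dict[int, bool],
    min_fraction: float = 0.0,
) -> IUTable:
    """Classify each IU as environmentally suitable and flag those needing
    community-level mapping (suitable but not yet mapped).

    An IU is suitable iff the fraction of its valid cells classified suitable
    exceeds ``min_fraction`` (default: any suitable cell). IUs without valid
    cells are flagged indeterminate and excluded.
    """
    _check_aligned(binary.raster.spec, iu_zones)
    rows = []
    iu_ids = np.unique(iu_zones.values[iu_zones.valid_mask]).astype(int)
    for iu in iu_ids:
        cells = (iu_zones.values == iu) & iu_zones.valid_mask & binary.raster.valid_mask
        n_valid = int(cells.sum())
        if n_valid == 0:
            logger.warning("IU %d has no valid cells; excluded as indeterminate", iu)
            continue
        frac = float((binary.raster.values[cells] == 1).sum()) / n_valid
        suitable = frac > min_fraction
        mapped = bool(mapped_flags.get(int(iu), False))
        rows.append(
            {
                "iu_id": int(iu),
                "suitable": suitable,
                "suitable_cell_fraction": frac,
                "mapped": mapped,
                "needs_mapping": suitable and not mapped,
            }
        )
    return IUTable(pd.DataFrame(rows))


def share_percentage(numerator: float, denominator: float) -> float:
    """100 * numerator / denominator, half-up rounded to one decimal."""
    if denominator <= 0:
        raise RiskError("denominator must be positive")
    pct = Decimal(100 * float(numerator)) / Decimal(float(denominator))
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def share_percentages(numerators, denominator: float) -> list[float]:
    return [share_percentage(n, denominator) for n in np.atleast_1d(numerators)]


def rasterize_zones(geojson: dict, spec: GridSpec, id_property: str = "zone_id") -> GridRaster:
    """Rasterise GeoJSON polygon zones by the cell-centre rule: a cell belongs
    to the zone whose polygon contains its centre."""
    xs = spec.x_centres()
    ys = spec.y_centres()
    gx, gy = np.meshgrid(xs, ys)
    out = np.full(spec.shape, np.nan)
    for feat in geojson.get("features", []):
        geom = shapely.geometry.shape(feat["geometry"])
        zid = feat["properties"][id_property]
        inside = shapely.contains_xy(geom, gx.ravel(), gy.ravel()).reshape(spec.shape)
        out[inside] = zid
    return GridRaster(spec, out, ~np.isfinite(out))


def load_zones_geojson(path, spec: GridSpec, id_property: str = "zone_id") -> GridRaster:
    with open(path) as fh:
        gj = json.load(fh)
    return rasterize_zones(gj, spec, id_property)
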