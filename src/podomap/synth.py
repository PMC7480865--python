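"""Self-consistent desk-scale scenarios for the whole pipeline.

A scenario is a 600 x 600 km planar landscape on a 5-km grid (120 x 120
cells) carrying: smooth spatially autocorrelated covariate fields whose
ranges span the bands that matter for the disease (precipitation 0-3000 mm,
elevation 0-3000 masl, soil pH 4-9, ...), a known true suitability surface
built from documented marginal-effect shapes, survey points drawn Bernoulli
from that truth, country and implementation-unit partitions, country
evidence scores, a log-normal population surface, and a binary lymphatic
filariasis layer. The generating parameters are recorded so recovery tests
can compare fitted models against the truth.

Marginal-effect shapes encoded in the truth: occurrence probability rises
with annual precipitation to a peak inside 1,000-1,800 mm then declines;
elevation risk is elevated between 1,000 and 2,500 masl; acid soils
(pH < 7) and soils richer in clay and silt increase risk.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import ndimage
from scipy.special import expit

from .grid import CovariateStack, GridRaster, GridSpec, distance_to_features, write_raster

logger = logging.getLogger("podomap")

COVARIATE_NAMES = [
    "precipitation",
    "elevation",
    "lst",
    "evi",
    "soil_ph",
    "clay_fraction",
    "silt_fraction",
    "distance_to_water",
]

# field value ranges: (low, high) of the rescaled smooth fields
_RANGES = {
    "precipitation": (0.0, 3000.0),
    "elevation": (0.0, 3000.0),
    "lst": (10.0, 40.0),
    "evi": (0.0, 1.0),
    "soil_ph": (4.0, 9.0),
    "clay_fraction": (5.0, 60.0),
    "silt_fraction": (5.0, 60.0),
}


@dataclass
class ScenarioSpec:
    """Generator settings; the seed fully determines the scenario."""

    grid: GridSpec = field(
        default_factory=lambda: GridSpec(120, 120, 0.0, 0.0, 5.0, "planar-km")
    )
    n_survey_sites: int = 400
    prevalence_target: float = 0.45
    rng_seed: int = 0
    n_countries: int = 6
    n_ius: int = 36
    sampling_bias: float = 0.0  # 0 = uniform site placement
    smooth_sigma: float = 8.0  # Gaussian-filter radius (cells) of the fields


@dataclass
class TrueSuitability:
    probability: GridRaster
    parameters: dict


def _smooth_field(shape, rng, sigma) -> np.ndarray:
    """Spatially autocorrelated standard field: filtered white noise, z-scored."""
    noise = rng.normal(size=shape)
    f = ndimage.gaussian_filter(noise, sigma=sigma, mode="reflect")
    return (f - f.mean()) / f.std()


def make_covariates(spec: ScenarioSpec) -> CovariateStack:
    """Smooth covariate fields plus a distance-to-water surface derived from
    a synthetic river mask."""
    rng = np.random.default_rng(spec.rng_seed)
    layers, names = [], []
    for name in COVARIATE_NAMES:
        if name == "distance_to_water":
            continue
        z = _smooth_field(spec.grid.shape, rng, spec.smooth_sigma)
        lo, hi = _RANGES[name]
        # map z in ~[-3, 3] onto the range, clipped
        vals = lo + (hi - lo) * np.clip((z + 3) / 6, 0, 1)
        layers.append(GridRaster(spec.grid, vals, np.zeros(spec.grid.shape, bool)))
        names.append(name)
    # rivers: level set of one more smooth field -> thin curvilinear features
    river_field = _smooth_field(spec.grid.shape, rng, spec.smooth_sigma)
    rivers = (np.abs(river_field) < 0.05).astype(float)
    if not rivers.any():
        rivers.flat[rng.integers(0, rivers.size)] = 1.0
    dist = distance_to_features(GridRaster(spec.grid, rivers))
    layers.append(dist)
    names.append("distance_to_water")
    return CovariateStack(names=names, layers=layers)


# marginal-effect shape functions (each returns values roughly in [0, 1])


def _precip_effect(p):
    """Rises to a peak at 1,400 mm (inside the 1,000-1,800 band), then declines."""
    return np.exp(-0.5 * ((p - 1400.0) / 300.0) ** 2)


def _elev_effect(e):
    """Window: elevated risk between 1,000 and 2,500 masl."""
    return expit((e - 1000.0) / 60.0) * expit((2500.0 - e) / 60.0)


def _ph_effect(ph):
    """Decreasing, crossing one half at pH 7 (acid soils riskier)."""
    return expit((7.0 - ph) / 0.25)


def _fraction_effect(f):
    """Increasing in clay/silt fraction."""
    return expit((f - 30.0) / 4.0)


# strong effect weights give a sharply delimited niche: occurrence is close
# to deterministic well inside / outside the suitable envelope, as in the
# exhaustively surveyed communities the pipeline is designed for
DEFAULT_RESPONSE = {
    "precipitation": 20.0,
    "elevation": 20.0,
    "soil_ph": 15.0,
    "clay_fraction": 10.0,
    "silt_fraction": 10.0,
}


def true_suitability(
    stack: CovariateStack,
    response: dict[str, float] | None = None,
    prevalence_target: float = 0.45,
) -> TrueSuitability:
    """Logistic combination of the marginal-effect shapes, with the intercept
    calibrated by bisection so the mean probability over valid cells matches
    the prevalence target."""
    response = dict(DEFAULT_RESPONSE if response is None else response)
    effects = {
        "precipitation": _precip_effect,
        "elevation": _elev_effect,
        "soil_ph": _ph_effect,
        "clay_fraction": _fraction_effect,
        "silt_fraction": _fraction_effect,
    }
    missing = [c for c in response if c not in stack.names]
    if missing:
        raise KeyError(f"stack lacks covariates: {missing}")
    eta = np.zeros(stack.spec.shape)
    for cov, weight in response.items():
        eta += weight * effects[cov](stack.layer(cov).values)
    mask = stack.valid_mask()

    def mean_prob(b0):
        return float(expit(b0 + eta[mask]).mean())

    lo, hi = -float(eta[mask].max()) - 20.0, -float(eta[mask].min()) + 20.0
    for _ in range(80):
        mid = (lo + hi) / 2
        if mean_prob(mid) < prevalence_target:
            lo = mid
        else:
            hi = mid
    b0 = (lo + hi) / 2
    prob = expit(b0 + eta)
    prob[~mask] = np.nan
    params = {"intercept": b0, "weights": response, "prevalence_target": prevalence_target,
              "precip_peak_mm": 1400.0, "elev_window_masl": (1000.0, 2500.0),
              "ph_crossing": 7.0}
    return TrueSuitability(GridRaster(stack.spec, prob, ~mask), params)


def simulate_surveys(
    truth: TrueSuitability,
    n_sites: int,
    rng_seed: int,
    country_raster: GridRaster | None = None,
    country_lookup: dict[int, str] | None = None,
    sampling_bias: float = 0.0,
) -> pd.DataFrame:
    """Survey sites over valid cells; endemicity drawn Bernoulli(truth).

    ``sampling_bias > 0`` tilts site placement toward suitable cells
    (probability proportional to ``exp(bias * truth)``), mimicking the
    preferential surveying of high-prevalence areas; default is uniform.
    """
    if n_sites < 2:
        raise ValueError("need at least 2 survey sites")
    rng = np.random.default_rng(rng_seed)
    mask = truth.probability.valid_mask
    rows, cols = np.nonzero(mask)
    p = np.exp(sampling_bias * truth.probability.values[rows, cols])
    p /= p.sum()
    pick = rng.choice(len(rows), size=n_sites, replace=True, p=p)
    spec = truth.probability.spec
    xs = spec.x_centres()[cols[pick]]
    ys = spec.y_centres()[rows[pick]]
    probs = truth.probability.values[rows[pick], cols[pick]]
    presence = rng.random(n_sites) < probs
    cases = np.where(presence, rng.poisson(3, n_sites) + 1, 0)
    if country_raster is not None:
        codes = country_raster.values[rows[pick], cols[pick]].astype(int)
        countries = [country_lookup.get(int(c), str(c)) if country_lookup else str(c)
                     for c in codes]
    else:
        countries = ["C0"] * n_sites
    return pd.DataFrame(
        {
            "site_id": [f"site_{i}" for i in range(n_sites)],
            "x": xs,
            "y": ys,
            "cases": cases.astype(int),
            "country": countries,
            "source": "synthetic_survey",
        }
    )


@dataclass
class ZoneLayers:
    countries: GridRaster
    country_lookup: dict[int, str]
    ius: GridRaster
    iu_lookup: dict[int, str]
    mapped_flags: dict[int, bool]
    evidence: dict[str, float]
    population: GridRaster
    lf_binary: GridRaster


def _rectangular_partition(spec: GridSpec, n_parts: int) -> np.ndarray:
    """Partition the grid into n_parts rectangles (grid of near-square tiles)."""
    n_rows_tiles = int(np.floor(np.sqrt(n_parts)))
    while n_parts % n_rows_tiles:
        n_rows_tiles -= 1
    n_cols_tiles = n_parts // n_rows_tiles
    row_edges = np.linspace(0, spec.n_rows, n_rows_tiles + 1).astype(int)
    col_edges = np.linspace(0, spec.n_cols, n_cols_tiles + 1).astype(int)
    out = np.zeros(spec.shape, dtype=int)
    zid = 0
    for i in range(n_rows_tiles):
        for j in range(n_cols_tiles):
            out[row_edges[i]:row_edges[i + 1], col_edges[j]:col_edges[j + 1]] = zid
            zid += 1
    return out


def make_zones_population_evidence(
    spec: ScenarioSpec, truth: TrueSuitability | None = None
) -> ZoneLayers:
    """Country/IU partitions, evidence scores, population, and an LF layer.

    Countries are a rectangular partition subdivided into IUs. Evidence
    scores reflect each country's mean true suitability (clearly unsuitable
    countries score negative, so pseudo-absences land where the disease is
    genuinely unlikely). Population is a log-normal smooth surface; the LF
    binary layer thresholds a shifted suitability surface so that all four
    overlap classes occur.
    """
    rng = np.random.default_rng(spec.rng_seed + 1)
    grid = spec.grid
    countries = _rectangular_partition(grid, spec.n_countries)
    ius = _rectangular_partition(grid, spec.n_ius)
    country_lookup = {i: f"C{i}" for i in range(spec.n_countries)}
    iu_lookup = {i: f"IU{i}" for i in range(spec.n_ius)}

    # evidence: negative where the country is mostly unsuitable
    evidence = {}
    for i, code in country_lookup.items():
        if truth is not None:
            cells = countries == i
            mean_suit = float(np.nanmean(truth.probability.values[cells]))
            # evidence of absence (score < 0) where the country is mostly unsuitable
            score = round((mean_suit - 0.2) * 10, 2)
        else:
            score = float(rng.normal())
        evidence[code] = score
    if not any(s < 0 for s in evidence.values()):
        worst = min(evidence, key=evidence.get)
        evidence[worst] = -1.0

    pop_field = _smooth_field(grid.shape, rng, spec.smooth_sigma)
    population = np.round(np.exp(np.log(200.0) + 1.0 * pop_field)).astype(float)
    pop_raster = GridRaster(grid, population, np.zeros(grid.shape, bool))

    if truth is not None:
        # LF suitability: same landscape, different optimum -> partial overlap
        shifted = np.roll(truth.probability.values, grid.n_cols // 3, axis=1)
        lf = (shifted >= 0.5).astype(float)
    else:
        lf = (_smooth_field(grid.shape, rng, spec.smooth_sigma) > 0).astype(float)
    lf_raster = GridRaster(grid, lf, np.zeros(grid.shape, bool))

    # roughly half of the IUs have already been mapped
    mapped = {i: bool(rng.random() < 0.5) for i in range(spec.n_ius)}

    return ZoneLayers(
        countries=GridRaster(grid, countries.astype(float), np.zeros(grid.shape, bool)),
        country_lookup=country_lookup,
        ius=GridRaster(grid, ius.astype(float), np.zeros(grid.shape, bool)),
        iu_lookup=iu_lookup,
        mapped_flags=mapped,
        evidence=evidence,
        population=pop_raster,
        lf_binary=lf_raster,
    )


@dataclass
class Scenario:
    spec: ScenarioSpec
    stack: CovariateStack
    truth: TrueSuitability
    surveys: pd.DataFrame
    zones: ZoneLayers


def make_scenario(spec: ScenarioSpec | None = None) -> Scenario:
    """Generate a complete scenario; bit-reproducible given the spec."""
    spec = spec or ScenarioSpec()
    stack = make_covariates(spec)
    truth = true_suitability(stack, prevalence_target=spec.prevalence_target)
    zones = make_zones_population_evidence(spec, truth)
    surveys = simulate_surveys(
        truth,
        spec.n_survey_sites,
        rng_seed=spec.rng_seed + 2,
        country_raster=zones.countries,
        country_lookup=zones.country_lookup,
        sampling_bias=spec.sampling_bias,
    )
    return Scenario(spec=spec, stack=stack, truth=truth, surveys=surveys, zones=zones)


def write_scenario(scenario: Scenario, out_dir) -> Path:
    """Write a scenario directory: covariate GeoTIFFs + manifest, truth,
    surveys, evidence, zone rasters with lookups, population and LF layers."""
    out = Path(out_dir)
    (out / "covariates").mkdir(parents=True, exist_ok=True)
    manifest = {}
    for name, layer in zip(scenario.stack.names, scenario.stack.layers):
        p = out / "covariates" / f"{name}.tif"
        write_raster(p, layer)
        manifest[name] = str(p.relative_to(out))
    with open(out / "covariates.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh)
    write_raster(out / "truth.tif", scenario.truth.probability)
    scenario.surveys.to_csv(out / "surveys.csv", index=False)
    z = scenario.zones
    pd.DataFrame(
        {"country": list(z.evidence), "score": list(z.evidence.values())}
    ).to_csv(out / "evidence.csv", index=False)
    write_raster(out / "countries.tif", z.countries)
    pd.DataFrame(
        {"index": list(z.country_lookup), "country": list(z.country_lookup.values())}
    ).to_csv(out / "countries_lookup.csv", index=False)
    write_raster(out / "ius.tif", z.ius)
    pd.DataFrame(
        {"index": list(z.iu_lookup), "iu": list(z.iu_lookup.values())}
    ).to_csv(out / "ius_lookup.csv", index=False)
    pd.DataFrame(
        {"iu_index": list(z.mapped_flags), "mapped": list(z.mapped_flags.values())}
    ).to_csv(out / "mapped_flags.csv", index=False)
    write_raster(out / "population.tif", z.population)
    write_raster(out / "lf_binary.tif", z.lf_binary)
    with open(out / "scenario.yaml", "w") as fh:
        yaml.safe_dump(
            {
                "n_rows": scenario.spec.grid.n_rows,
                "n_cols": scenario.spec.grid.n_cols,
                "cell_size": scenario.spec.grid.cell_size,
                "x_min": scenario.spec.grid.x_min,
                "y_min": scenario.spec.grid.y_min,
                "n_survey_sites": scenario.spec.n_survey_sites,
                "prevalence_target": scenario.spec.prevalence_target,
                "rng_seed": scenario.spec.rng_seed,
                "n_countries": scenario.spec.n_countries,
                "n_ius": scenario.spec.n_ius,
            },
            fh,
        )
    return out
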