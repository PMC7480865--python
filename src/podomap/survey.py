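"""Weighted training data: surveys, evidence scores, pseudo-absences.

Survey communities are labelled endemic (1) where confirmed cases were
reported and non-endemic (0) otherwise; both carry weight 1 because the
compiled surveys were exhaustive community censuses, so reported absences are
treated as true absences. Outside surveyed regions, pseudo-absence points are
drawn uniformly over the cells of countries whose evidence score is below
zero (evidence of absence), weighted by a 0-1 rescaling of that score so that
countries with stronger evidence of absence count more.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grid import CovariateStack, GridRaster, extract_at_points

logger = logging.getLogger("podomap")


class SurveyError(ValueError):
    pass


SURVEY_COLUMNS = ["site_id", "x", "y", "cases", "country", "source"]


def load_and_dedupe(path) -> pd.DataFrame:
    """Load a survey CSV and collapse spatially duplicated records.

    Records with identical coordinates (exact match, no tolerance) collapse to
    one; if duplicates conflict on endemicity, presence wins — a confirmed
    case cannot be negated by a second survey at the same site.
    """
    df = pd.read_csv(path)
    missing = [c for c in SURVEY_COLUMNS if c not in df.columns]
    if missing:
        raise SurveyError(f"survey file missing columns: {missing}")
    for c in ("x", "y"):
        if not np.issubdtype(df[c].dtype, np.number):
            raise SurveyError(f"non-numeric coordinates in column {c!r}")
    if df[["x", "y"]].isna().any().any():
        raise SurveyError("missing coordinates in survey file")
    n_before = len(df)
    # presence wins on conflict: keep the max-cases record per exact location
    df = (
        df.sort_values("cases", ascending=False, kind="stable")
        .drop_duplicates(subset=["x", "y"], keep="first")
        .sort_index()
        .reset_index(drop=True)
    )
    n_dropped = n_before - len(df)
    if n_dropped:
        logger.info("load_and_dedupe: collapsed %d duplicated records", n_dropped)
    return df


def label_endemicity(records: pd.DataFrame) -> pd.DataFrame:
    """Attach endemicity labels: 1 iff cases were reported, else 0; weight 1."""
    out = records.copy()
    out["label"] = (out["cases"].to_numpy() > 0).astype(int) if len(out) else pd.Series(dtype=int)
    out["weight"] = 1.0
    out["origin"] = "survey"
    return out


def rescale_evidence(evidence: dict[str, float], floor: float = 0.25) -> dict[str, float]:
    """Pseudo-absence weights from country evidence scores.

    Only countries with score < 0 (evidence of absence) are eligible. The
    absolute scores of eligible countries are min-max rescaled onto
    [floor, 1], the most negative score mapping to 1; a single eligible
    country gets weight 1.
    """
    if not 0 < floor <= 1:
        raise SurveyError("floor must be in (0, 1]")
    eligible = {c: abs(s) for c, s in evidence.items() if s < 0}
    if not eligible:
        raise SurveyError("no country has an evidence score below 0")
    lo, hi = min(eligible.values()), max(eligible.values())
    if hi == lo:
        return {c: 1.0 for c in eligible}
    return {c: floor + (1 - floor) * (m - lo) / (hi - lo) for c, m in eligible.items()}


def sample_pseudo_absences(
    country_raster: GridRaster,
    country_lookup: dict[int, str],
    weights_by_country: dict[str, float],
    n: int,
    rng_seed: int = 0,
    stack_valid: np.ndarray | None = None,
) -> pd.DataFrame:
    """Draw n pseudo-absence points uniformly over eligible cells.

    Eligible cells are valid cells of countries that have a pseudo-absence
    weight (negative evidence score); cells are drawn with replacement and
    points placed at cell centres. Each point carries label 0 and its
    country's rescaled weight.
    """
    if n < 1:
        raise SurveyError("n must be >= 1")
    eligible_codes = {idx for idx, c in country_lookup.items() if c in weights_by_country}
    mask = country_raster.valid_mask & np.isin(country_raster.values, list(eligible_codes))
    if stack_valid is not None:
        mask &= stack_valid
    rows, cols = np.nonzero(mask)
    if len(rows) == 0:
        raise SurveyError("no eligible cells for pseudo-absence sampling")
    rng = np.random.default_rng(rng_seed)
    pick = rng.integers(0, len(rows), size=n)
    spec = country_raster.spec
    xs = spec.x_centres()[cols[pick]]
    ys = spec.y_centres()[rows[pick]]
    countries = [country_lookup[int(country_raster.values[r, c])]
                 for r, c in zip(rows[pick], cols[pick])]
    return pd.DataFrame(
        {
            "site_id": [f"pseudo_{i}" for i in range(n)],
            "x": xs,
            "y": ys,
            "cases": 0,
            "country": countries,
            "source": "pseudo_absence",
            "label": 0,
            "weight": [weights_by_country[c] for c in countries],
            "origin": "pseudo_absence",
        }
    )


@dataclass
class ModelFrame:
    """Weighted, labelled training table feeding every learner.

    ``X`` holds one column per covariate; presence and true-absence rows have
    weight 1, pseudo-absence rows weight in (0, 1].
    """

    X: pd.DataFrame
    labels: np.ndarray
    weights: np.ndarray
    coords: np.ndarray  # n x 2 (x, y)
    origin: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.X)
        self.labels = np.asarray(self.labels, dtype=int)
        self.weights = np.asarray(self.weights, dtype=float)
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 2)
        self.origin = np.asarray(self.origin)
        if not (len(self.labels) == len(self.weights) == len(self.coords) == n):
            raise SurveyError("model frame columns have unequal length")
        if np.any(self.weights <= 0) or np.any(self.weights > 1):
            raise SurveyError("weights must lie in (0, 1]")
        if self.X.isna().any().any():
            raise SurveyError("model frame contains missing covariates")

    @property
    def covariate_names(self) -> list[str]:
        return list(self.X.columns)

    def __len__(self) -> int:
        return len(self.X)

    def subset(self, idx) -> "ModelFrame":
        idx = np.asarray(idx)
        return ModelFrame(
            X=self.X.iloc[idx].reset_index(drop=True) if idx.dtype != bool
            else self.X.loc[idx].reset_index(drop=True),
            labels=self.labels[idx],
            weights=self.weights[idx],
            coords=self.coords[idx],
            origin=self.origin[idx],
        )


def build_model_frame(
    labelled: pd.DataFrame, pseudo: pd.DataFrame | None, stack: CovariateStack
) -> ModelFrame:
    """Extract covariates for survey and pseudo-absence points and assemble
    the training frame, dropping (and logging) rows without full covariates."""
    parts = [labelled] if pseudo is None else [labelled, pseudo]
    pts = pd.concat(parts, ignore_index=True)
    if len(pts) == 0:
        raise SurveyError("no points to build a model frame from")
    extracted = extract_at_points(stack, pts[["x", "y"]].to_numpy())
    keep = extracted["valid"].to_numpy()
    n_drop = int((~keep).sum())
    if n_drop:
        logger.info("build_model_frame: dropped %d points without valid covariates", n_drop)
    if not keep.any():
        raise SurveyError("all points fall outside the covariate stack")
    frame = ModelFrame(
        X=extracted.loc[keep, stack.names].reset_index(drop=True),
        labels=pts.loc[keep, "label"].to_numpy(),
        weights=pts.loc[keep, "weight"].to_numpy(),
        coords=pts.loc[keep, ["x", "y"]].to_numpy(),
        origin=pts.loc[keep, "origin"].to_numpy(),
    )
    if len(np.unique(frame.labels)) < 2:
        raise SurveyError("model frame contains a single class; models are untrainable")
    return frame
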