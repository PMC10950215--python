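"""Photoquadrat point-intercept sampling and percent-cover estimation.

The survey design: one 0.25 m^2 (0.5 m x 0.5 m) quadrat at every meter mark
along each 50 m transect, each overlaid with 50 nonaligned systematically
sampled points (one uniform random point per cell of a 10 x 5 grid).  Five
transects x 50 quadrats x 50 points = 12,500 identification points per
survey.  Cover is estimated either from point counts (method "PQ") or from a
classified per-pixel map (method "DR"); fine categories aggregate onto the
10 broad groups.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .categories import CategoryScheme
from .scene import PLATE_CODE, LabelMap

__all__ = [
    "Quadrat",
    "PointSample",
    "place_quadrats",
    "sample_points",
    "identify_points",
    "cover_from_points",
    "cover_from_map",
    "aggregate_cover",
    "tally_attribute",
    "survey_plan",
    "photoquadrat_survey",
    "validate_cover_table",
]

COVER_COLUMNS = ("survey", "transect", "method", "category", "cover_pct")


@dataclass(frozen=True)
class Quadrat:
    """A 0.5 m x 0.5 m quadrat footprint at an integer meter mark.

    The footprint is centered within its meter interval and on the transect
    line: along-track extent [position_m + 0.25, position_m + 0.75) m,
    cross-track extent centered on swath_width / 2.
    """

    position_m: int
    size_m: float = 0.5
    swath_width_m: float = 1.0

    @property
    def extent_m(self) -> tuple[float, float, float, float]:
        """(row0, row1, col0, col1) in meters, half-open intervals."""
        r0 = self.position_m + (1.0 - self.size_m) / 2.0
        c0 = (self.swath_width_m - self.size_m) / 2.0
        return r0, r0 + self.size_m, c0, c0 + self.size_m


@dataclass(frozen=True)
class PointSample:
    """The identification points of one quadrat: map pixel coordinates."""

    quadrat: Quadrat
    rows: np.ndarray  # float map coordinates, meters
    cols: np.ndarray

    def __post_init__(self) -> None:
        r0, r1, c0, c1 = self.quadrat.extent_m
        if not ((self.rows >= r0).all() and (self.rows < r1).all()
                and (self.cols >= c0).all() and (self.cols < c1).all()):
            raise ValueError("points outside the quadrat footprint")

    @property
    def n_points(self) -> int:
        return len(self.rows)


def place_quadrats(transect_length_m: int = 50, size_m: float = 0.5,
                   swath_width_m: float = 1.0) -> list[Quadrat]:
    """One quadrat per meter mark: 50 quadrats on a 50 m transect."""
    if transect_length_m < 1:
        raise ValueError("transect length must be a positive integer")
    return [Quadrat(m, size_m, swath_width_m) for m in range(int(transect_length_m))]


def sample_points(
    quadrat: Quadrat,
    n: int = 50,
    seed: int = 0,
    grid: tuple[int, int] = (10, 5),
    resolution_m: float = 0.01,
) -> PointSample:
    """Nonaligned systematic sampling: one uniform point per grid cell.

    The footprint is partitioned into ``grid`` = (along, across) cells
    (default 10 x 5 = 50) and one uniformly random point is drawn in each,
    the standard stratified reading of "nonaligned, systematically sampled".
    Deterministic per seed.
    """
    ga, gc = grid
    if n != ga * gc:
        raise ValueError(f"n={n} must equal the grid cell count {ga * gc}")
    r0, r1, c0, c1 = quadrat.extent_m
    cell_r = (r1 - r0) / ga
    cell_c = (c1 - c0) / gc
    if cell_r < resolution_m or cell_c < resolution_m:
        raise ValueError("quadrat footprint smaller than the sampling grid")
    rng = np.random.default_rng(seed)
    ai, ci = np.meshgrid(np.arange(ga), np.arange(gc), indexing="ij")
    u = rng.random((2, ga, gc))
    rows = r0 + (ai + u[0]) * cell_r
    cols = c0 + (ci + u[1]) * cell_c
    return PointSample(quadrat, rows.ravel(), cols.ravel())


def identify_points(points: PointSample, truth: LabelMap) -> pd.Series:
    """Label each point by the fine category of its containing pixel.

    Returns per-fine-category tallies (index = fine names of the scheme);
    tallies sum to the number of points.  Raises on out-of-bounds points.
    """
    res = truth.resolution_m
    i = np.floor(points.rows / res).astype(int)
    j = np.floor(points.cols / res).astype(int)
    if (i < 0).any() or (j < 0).any() or (i >= truth.shape[0]).any() or (j >= truth.shape[1]).any():
        raise ValueError("point outside the map bounds")
    labels = truth.grid[i, j]
    if (labels == PLATE_CODE).any():
        labels = labels[labels != PLATE_CODE]
    counts = np.bincount(labels, minlength=truth.scheme.n_fine)
    return pd.Series(counts, index=list(truth.scheme.fine_names), name="n_points")


def cover_from_points(
    tallies: pd.Series | Mapping[str, int],
    survey: str,
    transect: int | str,
) -> pd.DataFrame:
    """Point-intercept percent cover for one transect (method "PQ").

    cover_pct(category) = 100 * points in category / total points.
    """
    s = pd.Series(tallies, dtype=float)
    total = s.sum()
    if total <= 0:
        raise ValueError("no identification points")
    return pd.DataFrame({
        "survey": survey, "transect": transect, "method": "PQ",
        "category": s.index, "cover_pct": 100.0 * s.to_numpy() / total,
    })


def cover_from_map(
    label_map: LabelMap,
    survey: str,
    transect: int | str,
    method: str = "DR",
) -> pd.DataFrame:
    """Percent cover as the pixel fraction per category (plate excluded)."""
    mask = label_map.grid != PLATE_CODE
    if not mask.any():
        raise ValueError("map empty after excluding plate pixels")
    names = (label_map.scheme.fine_names if label_map.level == "fine"
             else label_map.scheme.group_names)
    counts = np.bincount(label_map.grid[mask], minlength=len(names))
    return pd.DataFrame({
        "survey": survey, "transect": transect, "method": method,
        "category": list(names), "cover_pct": 100.0 * counts / counts.sum(),
    })


def aggregate_cover(
    table: pd.DataFrame,
    scheme: CategoryScheme | Mapping[str, str],
) -> pd.DataFrame:
    """Aggregate a fine-category cover table onto groups (sums preserved).

    ``scheme`` may be a :class:`CategoryScheme` (fine -> the 10 groups) or
    any explicit mapping of category -> aggregate name; categories already
    named as their aggregate pass through, so aggregating an
    already-grouped table is the identity.
    """
    if isinstance(scheme, CategoryScheme):
        mapping = dict(scheme.mapping)
        passthrough = set(scheme.group_names)
    else:
        mapping = dict(scheme)
        passthrough = set(mapping.values())
    validate_cover_table(table)

    def target(cat: str) -> str:
        if cat in mapping:
            return mapping[cat]
        if cat in passthrough:
            return cat
        raise KeyError(f"unmapped category: {cat!r}")

    out = table.assign(category=[target(c) for c in table["category"]])
    grouped = (out.groupby(["survey", "transect", "method", "category"],
                           sort=False, as_index=False)["cover_pct"].sum())
    return grouped


def tally_attribute(
    points: pd.DataFrame,
    category: str | Sequence[str],
    attribute: str,
) -> tuple[int, int, float]:
    """Tally a per-point boolean attribute within a category filter.

    Returns ``(count, total, percent)`` with percent = 100 * count / total
    rounded to one decimal (0.0 when the filter matches no points).  E.g.
    47 juvenile flags among 135 points of a coral category -> 34.8%.
    """
    if attribute not in points.columns:
        raise ValueError(f"attribute {attribute!r} not recorded per point")
    cats = [category] if isinstance(category, str) else list(category)
    sel = points[points["fine_label"].isin(cats)]
    total = len(sel)
    count = int(sel[attribute].astype(bool).sum())
    pct = round(100.0 * count / total, 1) if total else 0.0
    return count, total, pct


def survey_plan(
    n_transects: int = 5,
    transect_length_m: int = 50,
    points_per_quadrat: int = 50,
) -> dict[str, int]:
    """Design arithmetic for a survey: quadrat and point totals."""
    quadrats = n_transects * transect_length_m
    plan = {
        "n_transects": n_transects,
        "quadrats_per_transect": transect_length_m,
        "n_quadrats": quadrats,
        "points_per_quadrat": points_per_quadrat,
        "n_points": quadrats * points_per_quadrat,
    }
    return plan


def photoquadrat_survey(
    truth: LabelMap,
    survey: str,
    transect: int | str,
    seed: int = 0,
    points_per_quadrat: int = 50,
    grid: tuple[int, int] = (10, 5),
) -> pd.DataFrame:
    """Run the full point-intercept protocol on one transect map.

    Places quadrats along the mapped transect length, samples the points of
    each quadrat (seeded deterministically per quadrat), identifies them on
    the truth map, and pools the tallies into PQ cover rows (pooling points
    across quadrats, which equals averaging quadrat covers at equal point
    counts).
    """
    length_m = int(truth.shape[0] * truth.resolution_m)
    width_m = truth.shape[1] * truth.resolution_m
    quadrats = place_quadrats(length_m, swath_width_m=width_m)
    tallies = pd.Series(0, index=list(truth.scheme.fine_names), dtype=int)
    for q in quadrats:
        ps = sample_points(q, n=points_per_quadrat, seed=seed + 7919 * q.position_m,
                           grid=grid, resolution_m=truth.resolution_m)
        tallies = tallies.add(identify_points(ps, truth), fill_value=0)
    return cover_from_points(tallies.astype(int), survey, transect)


def validate_cover_table(table: pd.DataFrame, tol: float = 0.5) -> None:
    """Check CoverTable invariants: columns, nonnegative covers, ~100 sums."""
    missing = [c for c in COVER_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"cover table missing columns: {missing}")
    if (table["cover_pct"] < 0).any():
        raise ValueError("negative cover_pct")
    sums = table.groupby(["survey", "transect", "method"])["cover_pct"].sum()
    bad = sums[(sums - 100.0).abs() > tol]
    if len(bad):
        raise ValueError(f"cover sums deviate from 100: {bad.to_dict()}")
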