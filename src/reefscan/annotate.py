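"""Region-of-interest annotation: building and splitting the labeled-pixel library.

Expert annotation of hyperspectral scans happens through polygonal regions of
interest (ROIs), each containing a single fine benthic category.  Rasterizing
the ROIs yields the labeled-pixel library used to train and validate the
classifier; the library is split 90/10 (stratified by group) by default.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import shapely

from .categories import CategoryScheme
from .scene import LabelMap, SpectralCube

__all__ = [
    "ROI",
    "AnnotationLibrary",
    "rasterize_rois",
    "split_library",
    "propose_rois",
    "save_rois",
    "load_rois",
]


@dataclass(frozen=True)
class ROI:
    """A labeled polygon in cube pixel coordinates.

    ``polygon`` lists (row, col) vertices (floats); a pixel belongs to the
    ROI when its center (i + 0.5, j + 0.5) lies strictly inside the polygon
    (even-odd rule with strict interiority, so boundary pixels are excluded).
    """

    polygon: tuple[tuple[float, float], ...]
    fine_label: str
    transect_id: str

    def __post_init__(self) -> None:
        if len(self.polygon) < 3:
            raise ValueError("ROI polygon needs >= 3 vertices")

    def as_shapely(self) -> shapely.Polygon:
        # shapely uses (x, y); map col -> x, row -> y
        return shapely.Polygon([(c, r) for r, c in self.polygon])


@dataclass
class AnnotationLibrary:
    """Labeled pixels extracted from ROIs.

    ``entries`` columns: transect_id, row, col, fine_label, group_label,
    roi_id (provenance), and — after :func:`split_library` — split.
    """

    entries: pd.DataFrame
    scheme: CategoryScheme

    REQUIRED = ("transect_id", "row", "col", "fine_label", "group_label", "roi_id")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.entries.columns]
        if missing:
            raise ValueError(f"library missing columns: {missing}")
        dup = self.entries.duplicated(subset=["transect_id", "row", "col"])
        if dup.any():
            raise ValueError(f"{int(dup.sum())} duplicate pixels within a transect")
        bad = [
            (f, g) for f, g in zip(self.entries["fine_label"], self.entries["group_label"])
            if self.scheme.group_of(f) != g
        ]
        if bad:
            raise ValueError(f"group labels inconsistent with scheme: {bad[:3]}")

    def __len__(self) -> int:
        return len(self.entries)

    def group_counts(self) -> pd.Series:
        return self.entries["group_label"].value_counts()

    def to_csv(self, path: str | Path) -> None:
        self.entries.to_csv(path, index=False)


def rasterize_rois(
    rois: Sequence[ROI],
    cube: SpectralCube | LabelMap,
    scheme: CategoryScheme,
) -> AnnotationLibrary:
    """Label every pixel whose center falls inside an ROI polygon.

    ROIs must lie within cube bounds and must not overlap within a transect
    (two ROIs claiming the same pixel is an error).
    """
    shape = cube.shape if isinstance(cube, LabelMap) else cube.data.shape[:2]
    rows_out: list[pd.DataFrame] = []
    claimed: dict[str, set[tuple[int, int]]] = {}
    for roi_id, roi in enumerate(rois):
        scheme.group_of(roi.fine_label)  # raises on unknown label
        poly = roi.as_shapely()
        minx, miny, maxx, maxy = poly.bounds
        if miny < 0 or minx < 0 or maxy > shape[0] or maxx > shape[1]:
            raise ValueError(f"ROI {roi_id} polygon out of cube bounds {shape}")
        i0, i1 = int(np.floor(miny)), int(np.ceil(maxy))
        j0, j1 = int(np.floor(minx)), int(np.ceil(maxx))
        ii, jj = np.meshgrid(np.arange(i0, i1), np.arange(j0, j1), indexing="ij")
        ii, jj = ii.ravel(), jj.ravel()
        inside = shapely.contains_xy(poly, jj + 0.5, ii + 0.5)
        ii, jj = ii[inside], jj[inside]
        seen = claimed.setdefault(roi.transect_id, set())
        pix = set(zip(ii.tolist(), jj.tolist()))
        clash = seen & pix
        if clash:
            raise ValueError(
                f"ROI {roi_id} overlaps a previous ROI on transect "
                f"{roi.transect_id!r} at pixels {sorted(clash)[:3]}..."
            )
        seen |= pix
        rows_out.append(pd.DataFrame({
            "transect_id": roi.transect_id,
            "row": ii, "col": jj,
            "fine_label": roi.fine_label,
            "group_label": scheme.group_of(roi.fine_label),
            "roi_id": roi_id,
        }))
    entries = (pd.concat(rows_out, ignore_index=True) if rows_out
               else pd.DataFrame(columns=list(AnnotationLibrary.REQUIRED)))
    return AnnotationLibrary(entries, scheme)


def split_library(
    lib: AnnotationLibrary,
    train_fraction: float = 0.9,
    seed: int = 0,
    unit: str = "pixel",
) -> tuple[AnnotationLibrary, AnnotationLibrary]:
    """Stratified train/validation split of the labeled library.

    Stratification is by group label; within each group the train share is
    within one entry of ``train_fraction``.  ``unit="pixel"`` splits pixels
    independently; ``unit="roi"`` keeps whole ROIs together (the safer
    variant under spatial autocorrelation).  Deterministic per seed; the
    partition is disjoint and exhaustive.
    """
    if not (0 < train_fraction <= 1):
        raise ValueError("train_fraction must be in (0, 1]")
    if unit not in ("pixel", "roi"):
        raise ValueError("unit must be 'pixel' or 'roi'")
    small = lib.group_counts()[lambda s: s < 2]
    if len(small):
        raise ValueError(f"groups with < 2 entries cannot be split: {list(small.index)}")
    if train_fraction == 1.0:
        warnings.warn("train_fraction=1.0: validation set is empty", stacklevel=2)

    rng = np.random.default_rng(seed)
    df = lib.entries.reset_index(drop=True)
    train_idx: list[np.ndarray] = []
    for _, grp in df.groupby("group_label", sort=True):
        if unit == "pixel":
            order = grp.index.to_numpy()[rng.permutation(len(grp))]
            n_train = int(round(train_fraction * len(order)))
            train_idx.append(order[:n_train])
        else:
            roi_ids = np.sort(grp["roi_id"].unique())
            roi_ids = roi_ids[rng.permutation(len(roi_ids))]
            n_train_rois = max(1, int(round(train_fraction * len(roi_ids))))
            keep = set(roi_ids[:n_train_rois].tolist())
            train_idx.append(grp.index[grp["roi_id"].isin(keep)].to_numpy())
    tr = np.sort(np.concatenate(train_idx)) if train_idx else np.array([], dtype=int)
    mask = np.zeros(len(df), dtype=bool)
    mask[tr] = True
    train = df[mask].assign(split="train").reset_index(drop=True)
    val = df[~mask].assign(split="validation").reset_index(drop=True)
    return (AnnotationLibrary(train, lib.scheme),
            AnnotationLibrary(val, lib.scheme))


def propose_rois(
    truth: LabelMap,
    transect_id: str,
    *,
    per_group: int = 4,
    size: int = 4,
    seed: int = 0,
    max_tries: int = 4000,
) -> list[ROI]:
    """Propose pure square ROIs from a ground-truth map (simulation helper).

    Emulates expert annotation: for each group present in the map, up to
    ``per_group`` non-overlapping ``size`` x ``size`` squares whose pixels all
    share one fine category are selected by rejection sampling.  Groups too
    rare to yield a pure square may end with fewer (possibly smaller) ROIs.
    """
    rng = np.random.default_rng(seed)
    gg = truth.group_grid()
    taken = np.zeros(truth.shape, dtype=bool)
    rois: list[ROI] = []
    for gi, gname in enumerate(truth.scheme.group_names):
        locs = np.flatnonzero(gg.ravel() == gi)
        if locs.size == 0:
            continue
        found = 0
        for sz in (size, max(2, size // 2)):
            tries = 0
            while found < per_group and tries < max_tries:
                tries += 1
                flat = int(locs[rng.integers(locs.size)])
                i, j = divmod(flat, truth.shape[1])
                i0, j0 = i - sz // 2, j - sz // 2
                i1, j1 = i0 + sz, j0 + sz
                if i0 < 0 or j0 < 0 or i1 > truth.shape[0] or j1 > truth.shape[1]:
                    continue
                block = truth.grid[i0:i1, j0:j1]
                if taken[i0:i1, j0:j1].any() or len(np.unique(block)) != 1:
                    continue
                taken[i0:i1, j0:j1] = True
                fine = truth.scheme.fine_names[int(block[0, 0])]
                # polygon strictly containing the size x size pixel centers
                eps = 0.01
                poly = ((i0 + eps, j0 + eps), (i0 + eps, j1 - eps),
                        (i1 - eps, j1 - eps), (i1 - eps, j0 + eps))
                rois.append(ROI(poly, fine, transect_id))
                found += 1
            if found >= per_group:
                break
    return rois


def save_rois(rois: Iterable[ROI], path: str | Path) -> None:
    """Write ROIs as a JSON array of {transect_id, label, vertices}."""
    payload = [
        {"transect_id": r.transect_id, "label": r.fine_label,
         "vertices": [[float(a), float(b)] for a, b in r.polygon]}
        for r in rois
    ]
    Path(path).write_text(json.dumps(payload, indent=1))


def load_rois(path: str | Path) -> list[ROI]:
    payload = json.loads(Path(path).read_text())
    return [
        ROI(tuple((float(a), float(b)) for a, b in item["vertices"]),
            item["label"], item["transect_id"])
        for item in payload
    ]
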