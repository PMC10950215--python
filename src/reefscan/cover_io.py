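"""Cover-table CSV readers and writers.

The canonical long format has columns ``survey, transect, method, category,
cover_pct``.  Survey labels with a ``-PQ``/``-DR`` suffix (the convention of
published cover tables, where 2019 was surveyed with both methods) are split
into survey and method on read and re-joined on write when requested.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .survey import COVER_COLUMNS, validate_cover_table

__all__ = ["read_cover_csv", "write_cover_csv", "split_survey_label"]

_METHODS = ("PQ", "DR")


def split_survey_label(label: str) -> tuple[str, str]:
    """``"2019-DR"`` -> ``("2019", "DR")``; unsuffixed labels default to PQ."""
    label = str(label)
    for m in _METHODS:
        if label.upper().endswith("-" + m):
            return label[: -(len(m) + 1)], m
    return label, "PQ"


def read_cover_csv(path: str | Path, validate: bool = True) -> pd.DataFrame:
    """Read a cover table (long canonical, or wide with category rows).

    Wide tables have a ``category`` column and one column per survey label
    (e.g. ``2015``, ``2019-DR`` or ``2019-T3-DR``); they are melted to long
    form, with any ``-T<i>-`` infix parsed as the transect.  Long tables may
    carry the method as a survey-label suffix instead of a column.
    """
    df = pd.read_csv(path)
    cols = {c.lower(): c for c in df.columns}
    if "category" not in cols:
        raise ValueError("cover CSV needs a 'category' column")
    df = df.rename(columns={cols["category"]: "category"})
    if "cover_pct" in cols:  # long form
        for want in ("survey", "cover_pct"):
            if want not in cols:
                raise ValueError(f"cover CSV missing column {want!r}")
        df = df.rename(columns={cols[k]: k for k in
                                ("survey", "transect", "method", "cover_pct")
                                if k in cols})
        if "method" not in df.columns:
            parsed = [split_survey_label(s) for s in df["survey"]]
            df["survey"] = [s for s, _ in parsed]
            df["method"] = [m for _, m in parsed]
        if "transect" not in df.columns:
            df["transect"] = 0
    else:  # wide form: melt survey columns
        value_cols = [c for c in df.columns if c != "category"]
        long = df.melt("category", value_cols, var_name="label",
                       value_name="cover_pct")
        surveys, transects, methods = [], [], []
        for label in long["label"]:
            parts = str(label).split("-")
            transect = 0
            if len(parts) >= 2 and parts[-2].upper().startswith("T"):
                try:
                    transect = int(parts[-2][1:])
                    parts = parts[:-2] + parts[-1:]
                except ValueError:
                    pass
            survey, method = split_survey_label("-".join(parts))
            surveys.append(survey)
            transects.append(transect)
            methods.append(method)
        long["survey"], long["transect"], long["method"] = surveys, transects, methods
        df = long.drop(columns="label")
    df = df[list(COVER_COLUMNS)].copy()
    df["survey"] = df["survey"].astype(str)
    df["category"] = df["category"].astype(str)
    if (df["cover_pct"] < 0).any():
        raise ValueError("negative covers in cover CSV")
    if validate:
        validate_cover_table(df)
    return df


def write_cover_csv(table: pd.DataFrame, path: str | Path,
                    suffix_method: bool = False) -> None:
    """Write the canonical long format; ``suffix_method=True`` folds the
    method into the survey label (``2019-DR``) as in published tables."""
    validate_cover_table(table)
    out = table[list(COVER_COLUMNS)].copy()
    if suffix_method:
        out["survey"] = out["survey"].astype(str) + "-" + out["method"].astype(str)
        out = out.drop(columns="method")
    out.to_csv(path, index=False)
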