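"""Bundled reference survey data.

Mean percent covers (± SD across the five permanent transects) of the 10
benthic groups from repeated monitoring of a Guam fore-reef: photoquadrat
surveys in 2015, 2017 and 2019 ("PQ") and a diver-operated hyperspectral
survey in 2019 ("DR").  Values are rounded to the nearest tenth of a percent,
as published.  These means are the package's canonical worked example for the
diversity, aggregation and simulation defaults; per-transect replicates were
not published and are not bundled.
"""

from __future__ import annotations

import pandas as pd

from .categories import GROUP_NAMES

__all__ = ["reference_mean_covers", "reference_cover_sd", "SURVEYS"]

#: Survey labels in chronological order; 2019 was surveyed with both methods.
SURVEYS: tuple[str, ...] = ("2015", "2017", "2019-PQ", "2019-DR")

_MEANS = {
    #                     2015   2017   2019-PQ 2019-DR
    "Acropora abrotanoides":                    (7.5, 10.1, 0.2, 0.6),
    "Scleractinia":                             (24.3, 28.7, 6.9, 7.0),
    "Green macroalgae":                         (0.4, 1.0, 2.9, 1.1),
    "Turf algae/Cyanobacteria/Bare substrate":  (60.9, 52.1, 81.1, 84.6),
    "Corallinophycidae":                        (2.9, 4.0, 2.8, 2.3),
    "Porifera":                                 (1.1, 0.1, 1.9, 0.1),
    "Peyssonneliales":                          (2.2, 2.9, 2.6, 1.0),
    "Red macroalgae":                           (0.0, 0.1, 0.9, 3.4),
    "Octocorals/Hydrozoans":                    (0.6, 0.4, 0.4, 0.1),
    "Brown macroalgae":                         (0.2, 0.4, 0.2, 0.0),
}

_SDS = {
    "Acropora abrotanoides":                    (1.2, 3.7, 0.3, 0.3),
    "Scleractinia":                             (2.5, 6.5, 2.6, 2.7),
    "Green macroalgae":                         (0.2, 0.4, 1.1, 0.8),
    "Turf algae/Cyanobacteria/Bare substrate":  (1.1, 3.8, 2.4, 4.5),
    "Corallinophycidae":                        (0.5, 0.8, 0.9, 1.1),
    "Porifera":                                 (0.6, 0.1, 0.9, 0.0),
    "Peyssonneliales":                          (0.6, 1.5, 0.6, 0.5),
    "Red macroalgae":                           (0.0, 0.2, 1.6, 4.0),
    "Octocorals/Hydrozoans":                    (0.7, 0.4, 0.6, 0.1),
    "Brown macroalgae":                         (0.1, 0.2, 0.2, 0.0),
}


def _frame(source: dict[str, tuple[float, ...]]) -> pd.DataFrame:
    df = pd.DataFrame(source, index=list(SURVEYS)).T
    return df.reindex(list(GROUP_NAMES))


def reference_mean_covers() -> pd.DataFrame:
    """Mean percent cover per group (rows, reporting order) and survey (cols)."""
    return _frame(_MEANS)


def reference_cover_sd() -> pd.DataFrame:
    """Between-transect SD of percent cover, same shape as the means."""
    return _frame(_SDS)
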