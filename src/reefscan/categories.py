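"""Benthic category schemes: fine identification categories and broad groups.

Photoquadrat and hyperspectral annotations use a fine taxonomic resolution
(typically genus or species level, plus abiotic substrates).  For community
analysis these are aggregated into 10 broad taxonomic or functional groups.
The staghorn coral *Acropora abrotanoides* gets its own group, separate from
other Scleractinia, because it is the habitat-defining coral at exposed
fore-reef sites like the one this package models.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "GROUP_NAMES",
    "CategoryScheme",
    "build_category_scheme",
    "default_scheme",
    "default_category_table",
]

#: The 10 broad taxonomic / functional benthic groups, in reporting order.
GROUP_NAMES: tuple[str, ...] = (
    "Acropora abrotanoides",
    "Scleractinia",
    "Green macroalgae",
    "Turf algae/Cyanobacteria/Bare substrate",
    "Corallinophycidae",
    "Porifera",
    "Peyssonneliales",
    "Red macroalgae",
    "Octocorals/Hydrozoans",
    "Brown macroalgae",
)


@dataclass(frozen=True)
class CategoryScheme:
    """A total mapping from fine identification categories onto broad groups.

    Attributes
    ----------
    fine_names
        Fine-category labels, in index order (these indices are what a
        :class:`~reefscan.scene.LabelMap` stores).
    group_names
        The broad groups, in index order.  Always exactly 10 for the default
        survey design.
    mapping
        ``fine name -> group name``; total on ``fine_names``.
    """

    fine_names: tuple[str, ...]
    group_names: tuple[str, ...]
    mapping: Mapping[str, str] = field(repr=False)

    def __post_init__(self) -> None:
        if len(set(self.fine_names)) != len(self.fine_names):
            dupes = {n for n in self.fine_names if list(self.fine_names).count(n) > 1}
            raise ValueError(f"duplicate fine category names: {sorted(dupes)}")
        missing = [n for n in self.fine_names if n not in self.mapping]
        if missing:
            raise ValueError(f"fine categories without a group: {missing}")
        used_groups = {self.mapping[n] for n in self.fine_names}
        unknown = used_groups - set(self.group_names)
        if unknown:
            raise ValueError(f"mapping targets unknown groups: {sorted(unknown)}")

    @property
    def n_fine(self) -> int:
        return len(self.fine_names)

    @property
    def n_groups(self) -> int:
        return len(self.group_names)

    def group_of(self, fine_name: str) -> str:
        """Group label for a fine category; raises ``KeyError`` if unmapped."""
        try:
            return self.mapping[fine_name]
        except KeyError:
            raise KeyError(f"unknown fine category: {fine_name!r}") from None

    def fine_index(self, fine_name: str) -> int:
        return self.fine_names.index(fine_name)

    def group_index(self, group_name: str) -> int:
        return self.group_names.index(group_name)

    def group_index_of_fine(self, fine_idx: int) -> int:
        return self.group_names.index(self.mapping[self.fine_names[fine_idx]])

    def fine_to_group_index(self) -> list[int]:
        """Vector mapping fine index -> group index (for vectorised lookups)."""
        return [self.group_index_of_fine(i) for i in range(self.n_fine)]

    def fines_in_group(self, group_name: str) -> list[str]:
        return [n for n in self.fine_names if self.mapping[n] == group_name]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"fine": self.fine_names,
             "group": [self.mapping[n] for n in self.fine_names]}
        )


def build_category_scheme(
    table: Iterable[tuple[str, str]] | pd.DataFrame,
    n_groups: int = 10,
) -> CategoryScheme:
    """Build a :class:`CategoryScheme` from ``(fine, group)`` rows.

    Parameters
    ----------
    table
        Rows of ``(fine_name, group_name)``, or a DataFrame with columns
        ``fine`` and ``group``.
    n_groups
        Required number of distinct groups (default 10, the survey design).

    Raises
    ------
    ValueError
        On an empty table, duplicate fine names, or a group count different
        from ``n_groups``.
    """
    if isinstance(table, pd.DataFrame):
        rows = list(zip(table["fine"].astype(str), table["group"].astype(str)))
    else:
        rows = [(str(f), str(g)) for f, g in table]
    if not rows:
        raise ValueError("empty category table")
    fine_names = tuple(f for f, _ in rows)
    if len(set(fine_names)) != len(fine_names):
        raise ValueError("duplicate fine category names in table")
    mapping = dict(rows)
    # preserve first-appearance order of groups
    group_names: list[str] = []
    for _, g in rows:
        if g not in group_names:
            group_names.append(g)
    if len(group_names) != n_groups:
        raise ValueError(
            f"expected exactly {n_groups} groups, table defines {len(group_names)}"
        )
    return CategoryScheme(fine_names, tuple(group_names), mapping)


# ---------------------------------------------------------------------------
# Bundled default table
# ---------------------------------------------------------------------------
# 58 fine categories -> 10 groups.  The group structure (including the
# separate Acropora abrotanoides group) matches the survey design this
# package models.  The fine-category names themselves are a SYNTHETIC,
# representative checklist of common Guam fore-reef taxa and substrates —
# they are stand-ins, not a transcription of any particular survey's list.
_A = "Acropora abrotanoides"
_S = "Scleractinia"
_G = "Green macroalgae"
_T = "Turf algae/Cyanobacteria/Bare substrate"
_C = "Corallinophycidae"
_P = "Porifera"
_Y = "Peyssonneliales"
_R = "Red macroalgae"
_O = "Octocorals/Hydrozoans"
_B = "Brown macroalgae"

_DEFAULT_TABLE: tuple[tuple[str, str], ...] = (
    ("Acropora abrotanoides", _A),
    # other scleractinian corals (17)
    ("Acropora spp. (digitate)", _S),
    ("Acropora spp. (tabulate)", _S),
    ("Acropora spp. (corymbose)", _S),
    ("Pocillopora spp.", _S),
    ("Porites rus", _S),
    ("Porites spp. (massive)", _S),
    ("Montipora spp. (encrusting)", _S),
    ("Montipora spp. (foliose)", _S),
    ("Leptoria phrygia", _S),
    ("Goniastrea spp.", _S),
    ("Favites spp.", _S),
    ("Astreopora spp.", _S),
    ("Pavona spp.", _S),
    ("Cyphastrea spp.", _S),
    ("Galaxea spp.", _S),
    ("Leptastrea spp.", _S),
    ("Psammocora spp.", _S),
    # green macroalgae (6)
    ("Halimeda opuntia", _G),
    ("Halimeda macroloba", _G),
    ("Caulerpa spp.", _G),
    ("Chlorodesmis spp.", _G),
    ("Dictyosphaeria spp.", _G),
    ("Ventricaria spp.", _G),
    # turf / cyanobacteria / bare substrate (8)
    ("Turf algae", _T),
    ("Turf on pavement", _T),
    ("Cyanobacteria (mats)", _T),
    ("Bare substrate", _T),
    ("Pavement", _T),
    ("Rubble", _T),
    ("Sediment", _T),
    ("Dead coral skeleton", _T),
    # crustose calcifying red algae (4)
    ("Porolithon onkodes", _C),
    ("Lithophyllum spp.", _C),
    ("Neogoniolithon spp.", _C),
    ("Crustose coralline algae (other)", _C),
    # sponges (4)
    ("Encrusting sponge (orange)", _P),
    ("Encrusting sponge (blue)", _P),
    ("Massive sponge", _P),
    ("Boring sponge", _P),
    # peyssonnelioid algae (3)
    ("Peyssonnelia spp. (encrusting)", _Y),
    ("Peyssonnelia spp. (foliose)", _Y),
    ("Ramicrusta spp.", _Y),
    # non-crustose red macroalgae (6)
    ("Galaxaura spp.", _R),
    ("Actinotrichia spp.", _R),
    ("Asparagopsis spp.", _R),
    ("Hypnea spp.", _R),
    ("Laurencia spp.", _R),
    ("Portieria spp.", _R),
    # octocorals and hydrozoans (4)
    ("Sinularia spp.", _O),
    ("Sarcophyton spp.", _O),
    ("Millepora spp.", _O),
    ("Hydroid colonies", _O),
    # brown macroalgae (5)
    ("Lobophora spp.", _B),
    ("Padina spp.", _B),
    ("Dictyota spp.", _B),
    ("Turbinaria ornata", _B),
    ("Sargassum spp.", _B),
)

assert len(_DEFAULT_TABLE) == 58


def default_category_table() -> pd.DataFrame:
    """The bundled 58-row fine-to-group table as a DataFrame."""
    return pd.DataFrame(_DEFAULT_TABLE, columns=["fine", "group"])


def default_scheme() -> CategoryScheme:
    """The bundled default scheme: 58 fine categories onto the 10 groups."""
    return build_category_scheme(_DEFAULT_TABLE)
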