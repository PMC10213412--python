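"""Nematode trait reference: genus -> trophic guild, c-p value, body mass.

The colonizer-persister (c-p) value places a taxon on the r-to-K
life-history continuum (1 = enrichment opportunist, 5 = persister).
Trophic guilds follow feeding morphology: bacterivores (Ba), fungivores
(Fu), plant parasites (Pp) and omnivores-predators (OP).  For faunal
analysis the OP guild is split into omnivores (Om) and carnivores/
predators (Ca), because their structural components differ (Om3-Om5 vs
Ca2-Ca5); a plain ``OP`` label defaults to ``Om``.

A curated default reference ships with the package
(``data/trait_reference.csv``) and can be overridden from file.
"""

from __future__ import annotations

import importlib.resources
from typing import Iterable

import pandas as pd

#: Fine guild codes used internally.
FINE_GUILDS = ("Ba", "Fu", "Pp", "Om", "Ca")

#: The four trophic guilds of classical faunal analysis.
TROPHIC_GUILDS = ("Ba", "Fu", "Pp", "OP")

#: Free-living guilds (everything except plant parasites).
FREE_LIVING = ("Ba", "Fu", "Om", "Ca")


class TraitLookupError(KeyError):
    """A genus in the count table is missing from the trait reference."""


class TraitReference:
    """Mapping of nematode genera to guild, c-p value and body mass.

    Parameters
    ----------
    table:
        DataFrame with columns ``genus``, ``guild``, ``cp`` and
        optionally ``body_mass`` (ug fresh weight per individual).
        ``guild`` entries may use the coarse code ``OP``, which is
        normalized to ``Om``.
    """

    def __init__(self, table: pd.DataFrame):
        required = {"genus", "guild", "cp"}
        missing = required - set(table.columns)
        if missing:
            raise ValueError(f"trait table missing columns: {sorted(missing)}")
        table = table.copy()
        table["guild"] = table["guild"].replace({"OP": "Om"})
        bad_guild = set(table["guild"]) - set(FINE_GUILDS)
        if bad_guild:
            raise ValueError(f"unknown guild codes: {sorted(bad_guild)}")
        table["cp"] = table["cp"].astype(int)
        if not table["cp"].isin([1, 2, 3, 4, 5]).all():
            raise ValueError("c-p values must be integers in 1-5")
        if table["genus"].duplicated().any():
            dups = table.loc[table["genus"].duplicated(), "genus"].tolist()
            raise ValueError(f"duplicate genera in trait table: {dups}")
        if "body_mass" not in table.columns:
            table["body_mass"] = float("nan")
        self.table = table.set_index("genus")

    def __len__(self) -> int:
        return len(self.table)

    def __contains__(self, genus: str) -> bool:
        return genus in self.table.index

    @property
    def genera(self) -> pd.Index:
        return self.table.index

    def require(self, genera: Iterable[str]) -> None:
        """Raise :class:`TraitLookupError` naming any unknown genus."""
        unknown = [g for g in genera if g not in self.table.index]
        if unknown:
            raise TraitLookupError(
                f"genera absent from trait reference: {unknown}"
            )

    def guild(self, genus: str) -> str:
        """Fine guild code (Ba/Fu/Pp/Om/Ca) of ``genus``."""
        self.require([genus])
        return self.table.at[genus, "guild"]

    def trophic_guild(self, genus: str) -> str:
        """Coarse trophic guild (Ba/Fu/Pp/OP) of ``genus``."""
        g = self.guild(genus)
        return "OP" if g in ("Om", "Ca") else g

    def cp(self, genus: str) -> int:
        self.require([genus])
        return int(self.table.at[genus, "cp"])

    def body_mass(self, genus: str) -> float:
        self.require([genus])
        return float(self.table.at[genus, "body_mass"])

    def functional_guild(self, genus: str) -> str:
        """Functional-guild label: guild code + c-p digit (e.g. Ba1, Om4)."""
        return f"{self.guild(genus)}{self.cp(genus)}"

    def subset(self, genera: Iterable[str]) -> "TraitReference":
        genera = list(genera)
        self.require(genera)
        return TraitReference(self.table.loc[genera].reset_index())

    @classmethod
    def from_csv(cls, path) -> "TraitReference":
        return cls(pd.read_csv(path))

    def to_csv(self, path) -> None:
        self.table.reset_index().to_csv(path, index=False)


def load_default_traits() -> TraitReference:
    """The curated trait reference shipped with the package."""
    ref = importlib.resources.files("soilfoodweb.data") / "trait_reference.csv"
    with importlib.resources.as_file(ref) as path:
        return TraitReference.from_csv(path)
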