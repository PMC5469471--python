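"""Covariate registry: the fixed set of remotely sensed meadow covariates.

Meadow matching uses 27 geospatial, hydro-climatic and vegetation covariates.
A 14-covariate subset of these feeds the CART explanatory variables
(within-pair differences and between-pairs means).  Most covariates are
stored as within-park ranks rather than raw values; one accessibility
covariate (estimated travel time from trailhead) is only available in
Yosemite and is masked out when matching Sequoia meadows.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import pandas as pd

__all__ = ["CovariateEntry", "CovariateRegistry", "default_registry"]


@dataclass(frozen=True)
class CovariateEntry:
    """One covariate: machine name, display label, and role flags."""

    name: str
    label: str
    category: str  # climate | hydrologic | accessibility
    ranked: bool  # value is a within-park rank
    use_in_cart: bool  # member of the 14-covariate CART subset
    yose_only: bool = False  # available only for Yosemite meadows


@dataclass(frozen=True)
class CovariateRegistry:
    """Ordered collection of covariate definitions.

    The registry order is authoritative: correlation filtering keeps the
    earlier entry, and output tables list covariates in registry order.
    """

    entries: tuple[CovariateEntry, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        names = [e.name for e in self.entries]
        if len(set(names)) != len(names):
            raise ValueError("covariate names must be unique")
        for e in self.entries:
            if e.category not in ("climate", "hydrologic", "accessibility"):
                raise ValueError(f"unknown covariate category: {e.category!r}")

    @property
    def names(self) -> list[str]:
        return [e.name for e in self.entries]

    @property
    def cart_names(self) -> list[str]:
        return [e.name for e in self.entries if e.use_in_cart]

    def names_for_park(self, park: str) -> list[str]:
        """Covariates available for matching in a given park."""
        if park == "YOSE":
            return self.names
        return [e.name for e in self.entries if not e.yose_only]

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, name: str) -> bool:
        return any(e.name == name for e in self.entries)

    def __getitem__(self, name: str) -> CovariateEntry:
        for e in self.entries:
            if e.name == name:
                return e
        raise KeyError(name)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CovariateRegistry":
        entries = tuple(
            CovariateEntry(
                name=row["name"],
                label=row["label"],
                category=row["category"],
                ranked=bool(int(row["ranked"])),
                use_in_cart=bool(int(row["use_in_cart"])),
                yose_only=bool(int(row["yose_only"])),
            )
            for _, row in df.iterrows()
        )
        return cls(entries=entries)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "name": [e.name for e in self.entries],
                "label": [e.label for e in self.entries],
                "category": [e.category for e in self.entries],
                "ranked": [int(e.ranked) for e in self.entries],
                "use_in_cart": [int(e.use_in_cart) for e in self.entries],
                "yose_only": [int(e.yose_only) for e in self.entries],
            }
        )


def default_registry() -> CovariateRegistry:
    """Load the packaged registry (27 covariates, 14 CART-flagged)."""
    ref = importlib.resources.files("meadowpack.data") / "covariate_registry.csv"
    with importlib.resources.as_file(ref) as path:
        df = pd.read_csv(path)
    return CovariateRegistry.from_frame(df)
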