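"""Genetic map: ordered markers with chromosome and centimorgan position.

The map is the coordinate system for everything downstream — simulation,
IBD decoding, kinship and scanning all address loci through it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["GeneticMap", "uniform_map"]


class MapError(ValueError):
    """Raised for malformed genetic maps."""


@dataclass(frozen=True)
class GeneticMap:
    """Ordered list of markers with chromosome membership and cM positions.

    Parameters
    ----------
    table : pandas.DataFrame
        Columns ``marker`` (unique ids), ``chrom`` (opaque string ids) and
        ``pos_cm`` (floats, non-decreasing within a chromosome). Markers of
        one chromosome must be contiguous rows.
    """

    table: pd.DataFrame
    _index: dict = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        t = self.table.reset_index(drop=True)
        required = {"marker", "chrom", "pos_cm"}
        if not required.issubset(t.columns):
            raise MapError(f"map table needs columns {sorted(required)}")
        t = t[["marker", "chrom", "pos_cm"]].copy()
        t["marker"] = t["marker"].astype(str)
        t["chrom"] = t["chrom"].astype(str)
        t["pos_cm"] = t["pos_cm"].astype(float)
        if t["marker"].duplicated().any():
            dup = t.loc[t["marker"].duplicated(), "marker"].iloc[0]
            raise MapError(f"duplicate marker id {dup!r}")
        if len(t) == 0:
            raise MapError("empty map")
        # chromosomes must be contiguous blocks with sorted positions
        seen: list[str] = []
        for c, grp in t.groupby("chrom", sort=False):
            if not np.all(np.diff(grp.index.values) == 1):
                raise MapError(f"markers of chromosome {c!r} are not contiguous")
            pos = grp["pos_cm"].to_numpy()
            if np.any(np.diff(pos) < 0):
                raise MapError(f"positions decrease within chromosome {c!r}")
            if np.any(pos < 0):
                raise MapError(f"negative position on chromosome {c!r}")
            seen.append(c)
        object.__setattr__(self, "table", t)
        object.__setattr__(
            self, "_index", {m: i for i, m in enumerate(t["marker"])}
        )

    # -- basic accessors -------------------------------------------------
    @property
    def n_markers(self) -> int:
        return len(self.table)

    @property
    def markers(self) -> np.ndarray:
        return self.table["marker"].to_numpy()

    @property
    def chromosomes(self) -> list[str]:
        return list(dict.fromkeys(self.table["chrom"]))

    def marker_index(self, marker: str) -> int:
        try:
            return self._index[marker]
        except KeyError:
            raise MapError(f"unknown marker {marker!r}") from None

    def chrom_of(self, marker: str) -> str:
        return self.table["chrom"].iloc[self.marker_index(marker)]

    def pos_of(self, marker: str) -> float:
        return float(self.table["pos_cm"].iloc[self.marker_index(marker)])

    def chrom_slice(self, chrom: str) -> slice:
        idx = np.flatnonzero(self.table["chrom"].to_numpy() == str(chrom))
        if idx.size == 0:
            raise MapError(f"unknown chromosome {chrom!r}")
        return slice(int(idx[0]), int(idx[-1]) + 1)

    def positions(self, chrom: str) -> np.ndarray:
        return self.table["pos_cm"].to_numpy()[self.chrom_slice(chrom)]

    def chrom_length(self, chrom: str) -> float:
        return float(self.positions(chrom)[-1])

    def total_length_morgan(self) -> float:
        return sum(self.chrom_length(c) for c in self.chromosomes) / 100.0


def uniform_map(
    chrom_lengths: dict[str, float],
    spacing_cm: float = 1.0,
    prefix: str = "m",
) -> GeneticMap:
    """Build a map with markers evenly spaced at ``spacing_cm`` per chromosome.

    Each chromosome gets markers at 0, spacing, 2*spacing, ... up to its
    length (inclusive when the length is a multiple of the spacing).
    """
    rows = []
    for chrom, length in chrom_lengths.items():
        n = int(np.floor(length / spacing_cm + 1e-9)) + 1
        for i in range(n):
            rows.append(
                {
                    "marker": f"{prefix}{chrom}_{i}",
                    "chrom": str(chrom),
                    "pos_cm": i * spacing_cm,
                }
            )
    return GeneticMap(pd.DataFrame(rows))
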