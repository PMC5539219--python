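"""Longitudinal table of absolute dominance ranks.

The central data container for every mobility and stratification
computation: one row per (individual, year) giving that individual's
absolute rank within its sex-specific hierarchy.  Rank 1 is the alpha
(top) position and rank N the omega (bottom) position, so an *upward*
move is a *decrease* in rank number.

Within each (sex, year) cell the ranks must form the permutation
1..N — no gaps, no ties.  Sexes are always kept as two separate
hierarchies; pooled ("combined") statistics pool individual-year
transitions, never ranks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

REQUIRED_COLUMNS = ("individual_id", "sex", "year", "rank")


class RankTableError(ValueError):
    """Raised when a rank table violates its structural invariants."""


@dataclass(frozen=True)
class RankTable:
    """Validated individual x year table of absolute ranks.

    Parameters
    ----------
    df : pandas.DataFrame
        Must contain columns ``individual_id``, ``sex``, ``year`` and
        ``rank``.  Extra columns are preserved but ignored.
    """

    df: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        missing = [c for c in REQUIRED_COLUMNS if c not in self.df.columns]
        if missing:
            raise RankTableError(f"rank table missing columns: {missing}")
        df = self.df
        if df.duplicated(["individual_id", "year"]).any():
            raise RankTableError("an individual has more than one rank in a year")
        for (sex, year), grp in df.groupby(["sex", "year"], sort=False):
            ranks = np.sort(grp["rank"].to_numpy())
            if not np.array_equal(ranks, np.arange(1, len(ranks) + 1)):
                raise RankTableError(
                    f"ranks for sex={sex!r}, year={year} are not a permutation "
                    f"of 1..{len(ranks)}"
                )
        sex_per_ind = df.groupby("individual_id")["sex"].nunique()
        if (sex_per_ind > 1).any():
            bad = sex_per_ind[sex_per_ind > 1].index.tolist()
            raise RankTableError(f"individuals listed under two sexes: {bad}")

    # ------------------------------------------------------------------
    # constructors
    # ------------------------------------------------------------------
    @classmethod
    def from_records(cls, rows: list[tuple]) -> "RankTable":
        """Build from ``(individual_id, sex, year, rank)`` tuples."""
        return cls(pd.DataFrame(rows, columns=list(REQUIRED_COLUMNS)))

    @classmethod
    def from_csv(cls, path) -> "RankTable":
        df = pd.read_csv(path, dtype={"individual_id": str, "sex": str})
        return cls(df)

    # ------------------------------------------------------------------
    # accessors
    # ------------------------------------------------------------------
    @property
    def sexes(self) -> list[str]:
        return sorted(self.df["sex"].unique())

    @property
    def years(self) -> list[int]:
        return sorted(self.df["year"].unique())

    def sex_view(self, sex: str) -> pd.DataFrame:
        """Rows for one sex-hierarchy, sorted by (year, rank)."""
        out = self.df[self.df["sex"] == sex]
        return out.sort_values(["year", "rank"]).reset_index(drop=True)

    def group_size(self, sex: str, year: int) -> int:
        df = self.df
        return int(((df["sex"] == sex) & (df["year"] == year)).sum())

    def presence_spans(self, sex: str | None = None) -> pd.DataFrame:
        """Per-individual first/last observed year and tenure in years.

        Tenure counts observed years (an individual present from entry
        to exit inclusive has tenure ``exit - entry + 1``).
        """
        df = self.df if sex is None else self.df[self.df["sex"] == sex]
        if df.empty:
            return pd.DataFrame(
                columns=["individual_id", "sex", "entry_year", "exit_year", "tenure"]
            )
        spans = (
            df.groupby(["individual_id", "sex"])["year"]
            .agg(entry_year="min", exit_year="max", tenure="count")
            .reset_index()
        )
        return spans

    def to_csv(self, path) -> None:
        cols = [c for c in self.df.columns]
        self.df.sort_values(["year", "sex", "rank"]).to_csv(
            path, index=False, columns=cols
        )
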