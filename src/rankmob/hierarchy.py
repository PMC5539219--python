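"""Dominance hierarchy inference from decided agonistic interactions.

A decided agonistic interaction is an aggressive act (threat, chase,
slap, grab, bite) answered by a submissive response (fear grin, cower,
flee), yielding an unambiguous winner and loser.  Per year and per
sex-hierarchy the interactions are tallied into a win:loss matrix, and
a linear rank order is derived by rearranging the matrix so that the
number of *reversals* — wins by a lower-ranked individual over a
higher-ranked one, counted as interactions, not dyads — is minimal.

For small groups (N <= 9) the search is exact, via dynamic programming
over subsets (the minimal-reversal ordering is a linear ordering
problem, so the optimal cost decomposes over prefix sets).  Larger
groups fall back to a seeded pairwise-swap hill climb with random
restarts, flagged ``method="heuristic"``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

EXHAUSTIVE_LIMIT = 9  # largest N searched exactly


@dataclass(frozen=True)
class AgonisticRecord:
    """One decided dyadic contest: aggression met by submission."""

    year: int
    actor_id: str
    recipient_id: str
    winner_id: str

    def __post_init__(self) -> None:
        if self.actor_id == self.recipient_id:
            raise ValueError("actor and recipient must differ")
        if self.winner_id not in (self.actor_id, self.recipient_id):
            raise ValueError("winner must be actor or recipient")

    @property
    def loser_id(self) -> str:
        return self.recipient_id if self.winner_id == self.actor_id else self.actor_id


@dataclass(frozen=True)
class WinLossMatrix:
    """Square tally of decided wins: cell (i, j) = wins of i over j."""

    individuals: tuple[str, ...]
    counts: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        n = len(self.individuals)
        counts = np.asarray(self.counts)
        if counts.shape != (n, n):
            raise ValueError(f"counts must be {n}x{n}, got {counts.shape}")
        if np.any(np.diag(counts) != 0):
            raise ValueError("diagonal of a win:loss matrix must be zero")
        if np.any(counts < 0):
            raise ValueError("win counts must be nonnegative")
        object.__setattr__(self, "counts", counts.astype(np.int64))

    @property
    def n(self) -> int:
        return len(self.individuals)

    def index_of(self, individual: str) -> int:
        return self.individuals.index(individual)

    def total_wins(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class RankOrder:
    """A rank order from alpha (index 0) to omega, with its reversal count.

    ``inactive`` lists individuals that appeared in no interaction;
    they are appended after all active individuals, in lexicographic
    order, rather than silently dropped.
    """

    order: tuple[str, ...]
    reversals: int
    method: str  # "exhaustive" | "heuristic"
    inactive: tuple[str, ...] = ()

    def rank_of(self, individual: str) -> int:
        """1-based rank (1 = alpha)."""
        return self.order.index(individual) + 1


def build_win_loss_matrix(
    records, individuals
) -> WinLossMatrix:
    """Tally decided wins per ordered dyad.

    Parameters
    ----------
    records : iterable of AgonisticRecord
    individuals : iterable of str
        The full set of group members to index the matrix by (members
        with no interactions get all-zero rows and columns).
    """
    ids = tuple(sorted(set(individuals)))
    index = {ind: k for k, ind in enumerate(ids)}
    counts = np.zeros((len(ids), len(ids)), dtype=np.int64)
    for k, rec in enumerate(records):
        try:
            i = index[rec.winner_id]
            j = index[rec.loser_id]
        except KeyError as exc:
            raise ValueError(
                f"record {k} names unknown individual {exc.args[0]!r}"
            ) from None
        counts[i, j] += 1
    return WinLossMatrix(ids, counts)


def count_reversals(matrix: WinLossMatrix, order) -> int:
    """Total wins by lower-ranked over higher-ranked individuals.

    Equivalently the below-diagonal sum after rearranging the matrix
    rows and columns into ``order``.
    """
    order = tuple(order)
    if sorted(order) != sorted(matrix.individuals):
        raise ValueError("order must be a permutation of the matrix individuals")
    perm = [matrix.index_of(ind) for ind in order]
    rearranged = matrix.counts[np.ix_(perm, perm)]
    return int(np.tril(rearranged, k=-1).sum())


# ----------------------------------------------------------------------
# exact search: DP over subsets
# ----------------------------------------------------------------------

def _exact_min_order(counts: np.ndarray, ids: tuple[str, ...]) -> tuple[list[int], int]:
    """Minimal-reversal ordering by subset DP with deterministic tie-breaks.

    f(S) = minimal internal reversals of the set S ordered among
    themselves; placing i at the top of S costs the wins of the
    remaining members over i (those pairs are then fixed).  Ties among
    optimal choices at each rank are broken by the larger total win
    count, then by the lexicographically smaller identifier.
    """
    n = counts.shape[0]
    full = (1 << n) - 1
    f = np.zeros(1 << n, dtype=np.int64)
    # cost_top[i][S] = wins over i by members of S; computed on the fly
    col = counts.T.copy()  # col[i, j] = wins of j over i
    for subset in range(1, full + 1):
        best = None
        rest = subset
        while rest:
            i = (rest & -rest).bit_length() - 1
            rest &= rest - 1
            others = subset & ~(1 << i)
            cost = f[others]
            mask = others
            while mask:
                j = (mask & -mask).bit_length() - 1
                mask &= mask - 1
                cost += col[i, j]
            if best is None or cost < best:
                best = cost
        f[subset] = best
    row_sums = counts.sum(axis=1)
    order: list[int] = []
    remaining = full
    while remaining:
        candidates = []
        rest = remaining
        while rest:
            i = (rest & -rest).bit_length() - 1
            rest &= rest - 1
            others = remaining & ~(1 << i)
            cost = f[others]
            mask = others
            while mask:
                j = (mask & -mask).bit_length() - 1
                mask &= mask - 1
                cost += col[i, j]
            if cost == f[remaining]:
                candidates.append(i)
        # tie-break: most total wins first, then smaller identifier
        candidates.sort(key=lambda i: (-row_sums[i], ids[i]))
        pick = candidates[0]
        order.append(pick)
        remaining &= ~(1 << pick)
    return order, int(f[full])


# ----------------------------------------------------------------------
# heuristic search: pairwise-swap hill climbing with restarts
# ----------------------------------------------------------------------

def _hill_climb(counts: np.ndarray, perm: np.ndarray) -> tuple[np.ndarray, int]:
    def cost(p):
        return int(np.tril(counts[np.ix_(p, p)], k=-1).sum())

    best = cost(perm)
    improved = True
    n = len(perm)
    while improved:
        improved = False
        for a in range(n - 1):
            for b in range(a + 1, n):
                perm[a], perm[b] = perm[b], perm[a]
                c = cost(perm)
                if c < best:
                    best = c
                    improved = True
                else:
                    perm[a], perm[b] = perm[b], perm[a]
    return perm, best


def _heuristic_min_order(
    counts: np.ndarray, ids: tuple[str, ...], seed: int, restarts: int
) -> tuple[list[int], int]:
    rng = np.random.default_rng(seed)
    n = counts.shape[0]
    best_perm, best_cost = None, None
    for _ in range(restarts):
        perm, c = _hill_climb(counts, rng.permutation(n))
        if best_cost is None or c < best_cost:
            best_perm, best_cost = perm.copy(), c
    return list(best_perm), int(best_cost)


def find_rank_order(
    matrix: WinLossMatrix,
    *,
    seed: int = 0,
    restarts: int = 20,
    force_heuristic: bool = False,
) -> RankOrder:
    """Rank order minimizing the reversal count.

    Exact (``method="exhaustive"``) for N <= 9 active individuals;
    seeded pairwise-swap hill climbing with ``restarts`` random
    restarts (``method="heuristic"``) above that.  Individuals with no
    interactions at all are placed after all active individuals in
    lexicographic order and listed in ``inactive``; they contribute no
    reversals wherever placed.
    """
    if matrix.n == 0:
        return RankOrder((), 0, "exhaustive")
    activity = matrix.counts.sum(axis=0) + matrix.counts.sum(axis=1)
    active_idx = [k for k in range(matrix.n) if activity[k] > 0]
    inactive = tuple(sorted(matrix.individuals[k] for k in range(matrix.n) if activity[k] == 0))
    if not active_idx:
        order = tuple(sorted(matrix.individuals))
        return RankOrder(order, 0, "exhaustive", inactive)
    sub_ids = tuple(matrix.individuals[k] for k in active_idx)
    sub = matrix.counts[np.ix_(active_idx, active_idx)]
    if len(active_idx) <= EXHAUSTIVE_LIMIT and not force_heuristic:
        local, cost = _exact_min_order(sub, sub_ids)
        method = "exhaustive"
    else:
        local, cost = _heuristic_min_order(sub, sub_ids, seed, restarts)
        method = "heuristic"
    order = tuple(sub_ids[k] for k in local) + inactive
    return RankOrder(order, cost, method, inactive)


# ----------------------------------------------------------------------
# annual pipeline: interactions -> rank table rows
# ----------------------------------------------------------------------

def records_from_frame(df: pd.DataFrame) -> list[AgonisticRecord]:
    """Parse an interactions frame (year, actor_id, recipient_id, winner_id)."""
    needed = {"year", "actor_id", "recipient_id", "winner_id"}
    missing = needed - set(df.columns)
    if missing:
        raise ValueError(f"interactions table missing columns: {sorted(missing)}")
    return [
        AgonisticRecord(int(r.year), str(r.actor_id), str(r.recipient_id), str(r.winner_id))
        for r in df.itertuples(index=False)
    ]


def infer_annual_ranks(
    records, roster: pd.DataFrame, *, seed: int = 0, restarts: int = 20
) -> pd.DataFrame:
    """Derive per-year, per-sex rank orders from interaction records.

    Parameters
    ----------
    records : iterable of AgonisticRecord
    roster : DataFrame with columns ``individual_id`` and ``sex``
        assigns each interacting individual to its sex-hierarchy.

    Returns
    -------
    DataFrame with columns (individual_id, sex, year, rank).  Only
    individuals that interacted in a given year are ranked for that
    year (presence is evidenced by interaction).
    """
    sex_of = dict(
        zip(roster["individual_id"].astype(str), roster["sex"].astype(str))
    )
    by_cell: dict[tuple[int, str], list[AgonisticRecord]] = {}
    for rec in records:
        s1, s2 = sex_of.get(rec.actor_id), sex_of.get(rec.recipient_id)
        if s1 is None or s2 is None:
            missing = rec.actor_id if s1 is None else rec.recipient_id
            raise ValueError(f"individual {missing!r} missing from roster")
        if s1 != s2:
            raise ValueError(
                f"record pairs individuals of different sexes: "
                f"{rec.actor_id!r} ({s1}) vs {rec.recipient_id!r} ({s2})"
            )
        by_cell.setdefault((rec.year, s1), []).append(rec)
    rows = []
    for (year, sex), recs in sorted(by_cell.items()):
        present = sorted({r.actor_id for r in recs} | {r.recipient_id for r in recs})
        matrix = build_win_loss_matrix(recs, present)
        order = find_rank_order(matrix, seed=seed, restarts=restarts)
        for rank, ind in enumerate(order.order, start=1):
            rows.append((ind, sex, year, rank))
    return pd.DataFrame(rows, columns=["individual_id", "sex", "year", "rank"])
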