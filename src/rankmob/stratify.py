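"""Two-stratum Markov model of social stratification.

Each sex-hierarchy is split into an upper (H) and a lower (L) stratum
of equal size; with an odd number of adults the middle-ranking
individual contributes a half-score to each stratum.  Annual
transitions between strata are tallied with fractional weights
(product of the origin-year and destination-year stratum weights),
row-normalized into a 2x2 transition matrix P, and the long-run
stratification process is read off the matrix powers P^n over doubling
horizons.

For a two-state chain everything is available in closed form: with
second eigenvalue lambda2 = p_HH + p_LL - 1 and stationary
distribution pi,

    P^n_HH = pi_H + (1 - pi_H) * lambda2**n
    P^n_LL = pi_L + (1 - pi_L) * lambda2**n

which serves as the module's analytic oracle for the repeated-squaring
power computation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ranktable import RankTable

STRATA = ("H", "L")
DEFAULT_HORIZONS = (2, 4, 8, 16, 32)
_ROW_TOL = 1e-9


@dataclass(frozen=True)
class TransitionMatrix:
    """2x2 row-stochastic matrix over strata {H, L}.

    ``probs[0] = (p_HH, p_HL)`` and ``probs[1] = (p_LH, p_LL)``.
    ``counts`` holds the raw fractional transition weights when the
    matrix was estimated from data (None for directly entered
    matrices).
    """

    probs: np.ndarray = field(repr=False)
    counts: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        probs = np.asarray(self.probs, dtype=float)
        if probs.shape != (2, 2):
            raise ValueError(f"transition matrix must be 2x2, got {probs.shape}")
        if np.any(probs < 0) or np.any(probs > 1):
            raise ValueError("transition probabilities must lie in [0, 1]")
        rowsums = probs.sum(axis=1)
        if np.any(np.abs(rowsums - 1.0) > _ROW_TOL):
            raise ValueError(f"rows must sum to 1, got sums {rowsums}")
        object.__setattr__(self, "probs", probs)
        if self.counts is not None:
            counts = np.asarray(self.counts, dtype=float)
            if counts.shape != (2, 2) or np.any(counts < 0):
                raise ValueError("counts must be a nonnegative 2x2 array")
            object.__setattr__(self, "counts", counts)

    @property
    def p_HH(self) -> float:
        return float(self.probs[0, 0])

    @property
    def p_HL(self) -> float:
        return float(self.probs[0, 1])

    @property
    def p_LH(self) -> float:
        return float(self.probs[1, 0])

    @property
    def p_LL(self) -> float:
        return float(self.probs[1, 1])

    @property
    def second_eigenvalue(self) -> float:
        """lambda2 = p_HH + p_LL - 1 (the non-unit eigenvalue)."""
        return self.p_HH + self.p_LL - 1.0

    @classmethod
    def from_rows(cls, upper: tuple[float, float], lower: tuple[float, float]) -> "TransitionMatrix":
        return cls(np.array([upper, lower], dtype=float))

    @classmethod
    def from_counts(cls, counts: np.ndarray) -> "TransitionMatrix":
        counts = np.asarray(counts, dtype=float)
        rowsums = counts.sum(axis=1)
        if np.any(rowsums <= 0):
            raise ValueError("each stratum needs at least one observed transition")
        return cls(counts / rowsums[:, None], counts=counts)


def assign_strata(table: RankTable, sex: str) -> pd.DataFrame:
    """Half-score assignment of each individual-year to strata H and L.

    Even N: ranks 1..N/2 carry weight 1 in H, the rest weight 1 in L.
    Odd N: the middle rank (N+1)/2 carries weight 0.5 in each stratum,
    so the stratum totals are both N/2 exactly.  N = 1 is the limiting
    odd case: the sole individual sits half in each stratum.

    Returns a DataFrame (individual_id, year, rank, weight_H, weight_L).
    """
    view = table.sex_view(sex)
    rows = []
    for year, grp in view.groupby("year", sort=True):
        n = len(grp)
        for r in grp.itertuples(index=False):
            rank = int(r.rank)
            if 2 * rank <= n:
                w_h, w_l = 1.0, 0.0
            elif n % 2 == 1 and rank == (n + 1) // 2:
                w_h, w_l = 0.5, 0.5
            else:
                w_h, w_l = 0.0, 1.0
            rows.append((r.individual_id, int(year), rank, w_h, w_l))
    return pd.DataFrame(
        rows, columns=["individual_id", "year", "rank", "weight_H", "weight_L"]
    )


def transition_counts(assignment: pd.DataFrame) -> np.ndarray:
    """Fractional stratum-transition weights across consecutive years.

    For every individual present in years t and t+1 the outer product
    of its origin-year weights (w_H, w_L) with its destination-year
    weights is added to the 2x2 count matrix, so a middle-ranking
    individual that stays middle contributes 0.25 to every cell and
    total transition mass is conserved (one unit per individual-year
    pair).  Individuals that exit contribute nothing.
    """
    counts = np.zeros((2, 2))
    merged = assignment.merge(
        assignment.assign(year=assignment["year"] - 1),
        on=["individual_id", "year"],
        suffixes=("_t0", "_t1"),
    )
    for r in merged.itertuples(index=False):
        origin = np.array([r.weight_H_t0, r.weight_L_t0])
        dest = np.array([r.weight_H_t1, r.weight_L_t1])
        counts += np.outer(origin, dest)
    return counts


def estimate_transition_matrix(assignment: pd.DataFrame) -> TransitionMatrix:
    """Row-normalized stratum-transition matrix from an assignment table."""
    counts = transition_counts(assignment)
    if counts.sum() == 0:
        raise ValueError("no consecutive-year transitions observed")
    return TransitionMatrix.from_counts(counts)


def pool_matrices(matrices) -> TransitionMatrix:
    """Pool fractional counts across cohorts before normalizing.

    This is the maximum-likelihood combination of per-sex estimates
    (never an average of the probability matrices).
    """
    total = np.zeros((2, 2))
    for m in matrices:
        if m.counts is None:
            raise ValueError("pooling requires matrices estimated from counts")
        total += m.counts
    return TransitionMatrix.from_counts(total)


def matrix_power(P: TransitionMatrix, n: int) -> TransitionMatrix:
    """Exact n-step matrix via binary (repeated-squaring) powering."""
    if n < 1:
        raise ValueError("power must be >= 1")
    powered = np.linalg.matrix_power(P.probs, n)
    # guard against drift; re-normalize within the stochasticity tolerance
    rowsums = powered.sum(axis=1)
    if np.any(np.abs(rowsums - 1.0) > _ROW_TOL):
        raise ValueError("powering lost row-stochasticity beyond tolerance")
    return TransitionMatrix(powered / rowsums[:, None])


def stationary_distribution(P: TransitionMatrix) -> tuple[float, float]:
    """Limiting probabilities (pi_H, pi_L) of an irreducible aperiodic chain.

    Closed form for two states: pi_H = p_LH / (p_HL + p_LH).  Chains
    with a zero off-diagonal entry are absorbing (or, with both
    diagonals zero, periodic) and have no unique limiting behaviour of
    this form; they are rejected with the violated condition named.
    """
    if P.p_HL == 0 and P.p_LH == 0:
        raise ValueError("chain is reducible: both off-diagonal entries are zero")
    if P.p_HL == 0:
        raise ValueError("stratum H is absorbing (p_HL = 0); no mixing limit")
    if P.p_LH == 0:
        raise ValueError("stratum L is absorbing (p_LH = 0); no mixing limit")
    pi_h = P.p_LH / (P.p_HL + P.p_LH)
    return pi_h, 1.0 - pi_h


def diagonal_closed_form(P: TransitionMatrix, n: int) -> tuple[float, float]:
    """Analytic (H-H, L-L) diagonal of P^n: pi + (1 - pi) * lambda2**n."""
    pi_h, pi_l = stationary_distribution(P)
    lam = P.second_eigenvalue
    return pi_h + (1 - pi_h) * lam**n, pi_l + (1 - pi_l) * lam**n


def convergence_horizon(
    P: TransitionMatrix,
    tol: float = 0.001,
    max_horizon: int = 4096,
) -> tuple[int, float]:
    """First doubling horizon at which P^n has stabilized.

    Returns the smallest n in 2, 4, 8, ... with
    max(|P^n_HH - pi_H|, |P^n_LL - pi_L|) < tol, together with the
    deviation achieved there.
    """
    pi_h, pi_l = stationary_distribution(P)
    n = 2
    while n <= max_horizon:
        powered = matrix_power(P, n)
        dev = max(abs(powered.p_HH - pi_h), abs(powered.p_LL - pi_l))
        if dev < tol:
            return n, dev
        n *= 2
    raise ValueError(f"no convergence below tol={tol} up to horizon {max_horizon}")


def stratification_table(
    matrices: dict[str, TransitionMatrix],
    horizons=DEFAULT_HORIZONS,
) -> pd.DataFrame:
    """Diagonals of P^n per cohort over the doubling horizons.

    Returns a tidy frame (horizon, cohort, HH, LL) with full-precision
    values; round to 4 decimals for display.
    """
    rows = []
    for n in horizons:
        for cohort, P in matrices.items():
            powered = matrix_power(P, n)
            rows.append((n, cohort, powered.p_HH, powered.p_LL))
    return pd.DataFrame(rows, columns=["horizon", "cohort", "HH", "LL"])
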