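import numpy as np
import pandas as pd
import pytest

from rankmob.hierarchy import AgonisticRecord, WinLossMatrix, build_win_loss_matrix
from rankmob.ranktable import RankTable


@pytest.fixture
def worked_matrix() -> WinLossMatrix:
    """Three-individual win:loss example: A>B x5, B>C x4, C>A x3, A>C x1.

    The reversal-minimal order is [A, B, C] with 3 reversals (the wins
    of C over A), verified by brute force over all 6 permutations.
    """
    records = (
        [AgonisticRecord(1, "A", "B", "A")] * 5
        + [AgonisticRecord(1, "B", "C", "B")] * 4
        + [AgonisticRecord(1, "C", "A", "C")] * 3
        + [AgonisticRecord(1, "A", "C", "A")] * 1
    )
    return build_win_loss_matrix(records, ["A", "B", "C"])


def make_rank_table(rows) -> RankTable:
    """rows: (individual_id, sex, year, rank) tuples."""
    return RankTable(
        pd.DataFrame(rows, columns=["individual_id", "sex", "year", "rank"])
    )


@pytest.fixture
def staggered_table() -> RankTable:
    """Three same-sex adults with staggered tenures.

    A: years 1-6, rank 3 -> 1 (net upward, tenure 6)
    B: years 1-2, rank 1 -> 2 (net downward, tenure 2)
    C: year 1 only, rank 2 (no net change, tenure 1)
    """
    rows = [
        ("A", "F", 1, 3), ("B", "F", 1, 1), ("C", "F", 1, 2),
        ("A", "F", 2, 1), ("B", "F", 2, 2),
        ("A", "F", 3, 1),
        ("A", "F", 4, 1),
        ("A", "F", 5, 1),
        ("A", "F", 6, 1),
    ]
    return make_rank_table(rows)


def random_win_loss(rng: np.random.Generator, n: int, max_count: int = 6) -> WinLossMatrix:
    counts = rng.integers(0, max_count + 1, size=(n, n))
    np.fill_diagonal(counts, 0)
    ids = tuple(chr(ord("A") + k) for k in range(n))
    return WinLossMatrix(ids, counts)
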