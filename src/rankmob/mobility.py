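"""Intragenerational social-mobility statistics for rank hierarchies.

The annual rate of mobility is 1 - b, where b is the OLS slope of rank
in year t+1 regressed on rank in year t over all individual-years of a
sex-hierarchy (b = 1 means perfect persistence, b = 0 complete
reshuffling).  Around that core the module provides the transition
classification (up / down / no change, with the magnitude spectrum),
chi-square tests against a 50/50 null, tenure tables of net lifetime
rank direction, tenure-versus-improvement correlations, alpha/omega
spell summaries, Mann-Whitney comparisons, and a Kaplan-Meier analysis
of time to first upward move with right-censoring at exit.

Rank 1 is the alpha position throughout, so an upward move is a
decrease in rank number and the signed *improvement* over a tenure is
initial rank minus final rank.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.diagnostic import normal_ad
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test

from .ranktable import RankTable


@dataclass(frozen=True)
class MobilityFit:
    """OLS fit of R(t+1) on R(t) and the mobility rate 1 - b."""

    slope: float
    intercept: float
    rate: float
    r: float
    n: int
    p: float
    residuals: np.ndarray = field(repr=False)
    sxx: float = 0.0  # sum of squares of the regressor, for slope comparison

    def __post_init__(self) -> None:
        assert abs(self.rate - (1.0 - self.slope)) < 1e-12


@dataclass(frozen=True)
class TransitionCounts:
    """Individual-year transitions classified by annual rank change."""

    n_up: int
    n_down: int
    n_same: int
    magnitudes: Counter = field(default_factory=Counter)

    @property
    def n_pairs(self) -> int:
        return self.n_up + self.n_down + self.n_same

    @property
    def n_change(self) -> int:
        return self.n_up + self.n_down

    @property
    def up_fraction(self) -> float:
        """Share of changes that are upward, n_up / (n_up + n_down)."""
        if self.n_change == 0:
            return float("nan")
        return self.n_up / self.n_change

    @property
    def fraction_within_two(self) -> float:
        """Share of changes with magnitude <= 2 ranks."""
        if self.n_change == 0:
            return float("nan")
        small = sum(c for mag, c in self.magnitudes.items() if mag <= 2)
        return small / self.n_change

    def probabilities(self) -> tuple[float, float, float]:
        """(P(up), P(down), P(same)) over all pairs."""
        n = self.n_pairs
        return self.n_up / n, self.n_down / n, self.n_same / n


def rank_pairs(table: RankTable, sex: str) -> np.ndarray:
    """(R_t, R_t1) pairs for individuals present in consecutive years.

    One pair per individual per consecutive-year presence; individuals
    absent in year t+1 are censored and contribute nothing.  Returned
    as an (n, 2) integer array.
    """
    view = table.sex_view(sex)
    merged = view.merge(
        view.assign(year=view["year"] - 1),
        on=["individual_id", "year"],
        suffixes=("_t0", "_t1"),
    )
    return merged[["rank_t0", "rank_t1"]].to_numpy(dtype=int)


def fit_mobility(pairs: np.ndarray, *, df_offset: int = 2) -> MobilityFit:
    """OLS of R(t+1) on R(t); mobility rate = 1 - slope.

    Significance is the two-tailed p of Pearson's r with
    ``n - df_offset`` degrees of freedom (offset 2 is the standard for
    a fitted mean and slope; it is configurable because some published
    analyses report n - 1).
    """
    pairs = np.asarray(pairs, dtype=float)
    if pairs.ndim != 2 or pairs.shape[1] != 2 or pairs.shape[0] < 3:
        raise ValueError("need at least 3 (R_t, R_t1) pairs")
    x, y = pairs[:, 0], pairs[:, 1]
    if np.ptp(x) == 0:
        raise ValueError("R_t is constant; the regression slope is undefined")
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (intercept + slope * x)
    if np.ptp(y) == 0:
        r = 1.0 if slope >= 0 else -1.0  # degenerate: all mass on the line
        p = 0.0
    else:
        r = float(np.corrcoef(x, y)[0, 1])
        df = len(x) - df_offset
        if abs(r) >= 1.0:
            p = 0.0
        else:
            t = r * np.sqrt(df / (1.0 - r * r))
            p = float(2 * stats.t.sf(abs(t), df))
    return MobilityFit(
        slope=float(slope),
        intercept=float(intercept),
        rate=float(1.0 - slope),
        r=r,
        n=len(x),
        p=p,
        residuals=resid,
        sxx=float(np.sum((x - x.mean()) ** 2)),
    )


def compare_slopes(fit_a: MobilityFit, fit_b: MobilityFit) -> tuple[float, int, float]:
    """Two-sample t-test for equality of regression slopes.

    Pools the residual variance of the two fits:
    t = (b_a - b_b) / sqrt(s2 * (1/Sxx_a + 1/Sxx_b)) with
    df = n_a + n_b - 4.
    """
    sxx_a, sse_a = fit_a.sxx, float(np.sum(fit_a.residuals**2))
    sxx_b, sse_b = fit_b.sxx, float(np.sum(fit_b.residuals**2))
    df = fit_a.n + fit_b.n - 4
    if df <= 0 or sxx_a == 0 or sxx_b == 0:
        raise ValueError("degenerate fits: not enough data to compare slopes")
    s2 = (sse_a + sse_b) / df
    if s2 == 0:
        if fit_a.slope == fit_b.slope:
            return 0.0, df, 1.0
        return float("inf"), df, 0.0
    t = (fit_a.slope - fit_b.slope) / np.sqrt(s2 * (1 / sxx_a + 1 / sxx_b))
    p = float(2 * stats.t.sf(abs(t), df))
    return float(t), df, p


def residual_normality(fit: MobilityFit) -> tuple[float, float]:
    """Anderson-Darling normality test on the regression residuals.

    Uses the case-3 variant (mean and variance estimated from the
    sample) with the standard p-value approximation.
    """
    resid = np.asarray(fit.residuals, dtype=float)
    if len(resid) < 8:
        raise ValueError("need at least 8 residuals for the Anderson-Darling test")
    if np.ptp(resid) < 1e-10:  # exact fits leave only rounding noise
        raise ValueError("residuals are constant; normality test is degenerate")
    ad, p = normal_ad(resid)
    return float(ad), float(p)


def classify_transitions(pairs: np.ndarray) -> TransitionCounts:
    """Classify consecutive-year pairs as up / down / no change.

    Upward means the rank number fell (R_t1 < R_t).  The magnitude
    spectrum counts |R_t1 - R_t| over changes only.
    """
    pairs = np.asarray(pairs, dtype=int).reshape(-1, 2)
    delta = pairs[:, 1] - pairs[:, 0]
    mags = Counter(int(m) for m in np.abs(delta[delta != 0]))
    return TransitionCounts(
        n_up=int(np.sum(delta < 0)),
        n_down=int(np.sum(delta > 0)),
        n_same=int(np.sum(delta == 0)),
        magnitudes=mags,
    )


def chi_square_equal(count_a: int, count_b: int) -> tuple[float, int, float]:
    """Goodness-of-fit of two category counts against a 50/50 null."""
    if count_a < 0 or count_b < 0:
        raise ValueError("counts must be nonnegative")
    total = count_a + count_b
    if total == 0:
        raise ValueError("cannot test with zero total count")
    chi2, p = stats.chisquare([count_a, count_b])
    return float(chi2), 1, float(p)


def _net_directions(table: RankTable, sex: str) -> pd.DataFrame:
    """Per adult: tenure and the sign of its net lifetime rank change."""
    view = table.sex_view(sex)
    if view.empty:
        return pd.DataFrame(columns=["individual_id", "tenure", "direction", "improvement"])
    rows = []
    for ind, grp in view.groupby("individual_id", sort=True):
        grp = grp.sort_values("year")
        first, last = int(grp["rank"].iloc[0]), int(grp["rank"].iloc[-1])
        tenure = int(grp["year"].iloc[-1] - grp["year"].iloc[0] + 1)
        improvement = first - last  # positive = net upward
        if improvement > 0:
            direction = "up"
        elif improvement < 0:
            direction = "down"
        else:
            direction = "same"
        rows.append((ind, tenure, direction, improvement))
    return pd.DataFrame(rows, columns=["individual_id", "tenure", "direction", "improvement"])


def tenure_table(table: RankTable, sex: str, thresholds=(1, 2, 3, 4, 5, 6)) -> pd.DataFrame:
    """Net lifetime mobility direction by minimum tenure.

    Each adult is classified once by the sign of its net rank change
    over its whole tenure; row k gives the class proportions among
    adults with tenure >= k.  Rows whose adult subset is empty are
    flagged (``n = 0`` with NaN proportions).
    """
    thresholds = list(thresholds)
    if any(t <= 0 for t in thresholds) or sorted(thresholds) != thresholds:
        raise ValueError("thresholds must be positive and increasing")
    net = _net_directions(table, sex)
    rows = []
    for k in thresholds:
        sub = net[net["tenure"] >= k]
        n = len(sub)
        if n == 0:
            rows.append((k, 0, np.nan, np.nan, np.nan))
        else:
            rows.append(
                (
                    k,
                    n,
                    (sub["direction"] == "up").mean(),
                    (sub["direction"] == "down").mean(),
                    (sub["direction"] == "same").mean(),
                )
            )
    return pd.DataFrame(
        rows, columns=["min_tenure", "n", "p_upward", "p_downward", "p_no_change"]
    )


def tenure_change_correlation(table: RankTable, sex: str) -> tuple[float, int, float]:
    """Pearson correlation of tenure with net rank improvement.

    Improvement is initial rank minus final rank (positive = ended
    higher than it started).  Returns (r, df, two-tailed p) with
    df = n - 2.
    """
    net = _net_directions(table, sex)
    if len(net) < 4:
        raise ValueError("need at least 4 adults with completed tenures")
    if net["improvement"].nunique() == 1 or net["tenure"].nunique() == 1:
        raise ValueError("zero variance in tenure or improvement; correlation undefined")
    r, p = stats.pearsonr(net["tenure"], net["improvement"])
    return float(r), len(net) - 2, float(p)


@dataclass(frozen=True)
class SpellSummary:
    """Unbroken yearly spells at one extreme of the hierarchy."""

    position: str  # "alpha" | "omega"
    spells: tuple[int, ...]

    @property
    def count(self) -> int:
        return len(self.spells)

    @property
    def mean(self) -> float:
        return float(np.mean(self.spells)) if self.spells else float("nan")

    @property
    def sd(self) -> float:
        if len(self.spells) < 2:
            return float("nan")
        return float(np.std(self.spells, ddof=1))


def extreme_rank_tenure(table: RankTable, sex: str) -> dict[str, SpellSummary]:
    """Spell lengths at the alpha (rank 1) and omega (bottom) positions.

    A spell is a maximal run of consecutive years in which the same
    individual holds rank 1 (alpha) or the bottom rank of that year's
    hierarchy (omega; the bottom rank may move with group size).  Each
    spell is one observation.
    """
    view = table.sex_view(sex)
    out: dict[str, SpellSummary] = {}
    for position in ("alpha", "omega"):
        holders: list[tuple[int, str]] = []
        for year, grp in view.groupby("year", sort=True):
            target = 1 if position == "alpha" else int(grp["rank"].max())
            holder = grp.loc[grp["rank"] == target, "individual_id"].iloc[0]
            holders.append((int(year), holder))
        spells: list[int] = []
        for k, (year, holder) in enumerate(holders):
            prev = holders[k - 1] if k else None
            if prev is not None and prev[1] == holder and prev[0] == year - 1:
                spells[-1] += 1
            else:
                spells.append(1)
        out[position] = SpellSummary(position, tuple(spells))
    return out


def mann_whitney(sample_a, sample_b) -> tuple[float, float]:
    """Two-tailed Mann-Whitney U with midrank tie handling.

    Exact enumeration when both samples have <= 20 observations and no
    ties straddle the samples; otherwise the normal approximation with
    the tie correction.  Returns (U for sample_a, p).
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    has_ties = len(np.unique(np.concatenate([a, b]))) < a.size + b.size
    if max(a.size, b.size) <= 20 and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


@dataclass(frozen=True)
class UpwardTimeResult:
    """Kaplan-Meier analysis of years from adulthood to first upward move."""

    fitters: dict[str, KaplanMeierFitter]
    durations: dict[str, np.ndarray]
    events: dict[str, np.ndarray]
    logrank_statistic: float | None
    logrank_p: float | None


def upward_move_times(table: RankTable, sex: str) -> tuple[np.ndarray, np.ndarray]:
    """Per adult: years until first upward move, and whether it occurred.

    The clock starts at the first observed adult year.  An individual
    whose rank number first falls between years t and t+1 has an event
    at duration t+1 - entry; one that leaves (or the record ends)
    without moving up is right-censored at its last observed year.
    Individuals observed a single year carry a censored duration of 0.
    """
    view = table.sex_view(sex)
    durations, events = [], []
    for _, grp in view.groupby("individual_id", sort=True):
        grp = grp.sort_values("year")
        years = grp["year"].to_numpy()
        ranks = grp["rank"].to_numpy()
        entry = years[0]
        event_time = None
        for t in range(len(years) - 1):
            if years[t + 1] == years[t] + 1 and ranks[t + 1] < ranks[t]:
                event_time = years[t + 1] - entry
                break
        if event_time is not None:
            durations.append(event_time)
            events.append(1)
        else:
            durations.append(years[-1] - entry)
            events.append(0)
    return np.asarray(durations, dtype=float), np.asarray(events, dtype=int)


def km_upward_time(table: RankTable, sexes=None) -> UpwardTimeResult:
    """Product-limit curves of time to first upward move, by sex.

    When exactly two sexes are present (or requested) the curves are
    compared with a log-rank test.
    """
    sexes = list(sexes) if sexes is not None else table.sexes
    if not sexes:
        raise ValueError("need at least one sex-hierarchy")
    fitters, durations, events = {}, {}, {}
    for sex in sexes:
        d, e = upward_move_times(table, sex)
        if d.size == 0:
            raise ValueError(f"no adults for sex {sex!r}")
        kmf = KaplanMeierFitter(label=str(sex))
        kmf.fit(d, event_observed=e)
        fitters[sex], durations[sex], events[sex] = kmf, d, e
    stat = p = None
    if len(sexes) == 2:
        s1, s2 = sexes
        res = logrank_test(
            durations[s1], durations[s2], event_observed_A=events[s1], event_observed_B=events[s2]
        )
        stat, p = float(res.test_statistic), float(res.p_value)
    return UpwardTimeResult(fitters, durations, events, stat, p)
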