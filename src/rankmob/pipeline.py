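"""End-to-end orchestration: simulate -> rank -> mobility -> stratify.

One ``run`` call executes the enabled stages in order and returns a
JSON-serializable report.  Three input modes enter the pipeline at
successive stages:

* ``simulate`` — generate a synthetic group history, infer annual
  rank orders from the simulated contests, then analyse them;
* ``files`` — read ``interactions.csv`` (ranks are inferred) and/or
  ``ranks.csv`` (ranks are taken as given);
* ``matrices`` — read three 2x2 stratum-transition matrices directly
  and run only the stratification stage.

Identical config + seed yields an identical report (the provenance
block records a hash of the resolved configuration).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .hierarchy import infer_annual_ranks, records_from_frame
from .mobility import (
    chi_square_equal,
    classify_transitions,
    compare_slopes,
    extreme_rank_tenure,
    fit_mobility,
    km_upward_time,
    mann_whitney,
    rank_pairs,
    residual_normality,
    tenure_change_correlation,
    tenure_table,
)
from .ranktable import RankTable
from .simulate import GroupSimConfig, simulate_group
from .stratify import (
    DEFAULT_HORIZONS,
    TransitionMatrix,
    assign_strata,
    convergence_horizon,
    estimate_transition_matrix,
    matrix_power,
    pool_matrices,
    stationary_distribution,
)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass(frozen=True)
class RunConfig:
    """Resolved configuration of one pipeline run.

    Exactly one input source must be set: ``sim`` (simulation),
    ``interactions_path``/``ranks_path`` (files), or ``matrices``
    (direct 2x2 matrices keyed male/female/combined).
    """

    sim: GroupSimConfig | None = None
    interactions_path: str | None = None
    ranks_path: str | None = None
    matrices: dict[str, TransitionMatrix] | None = None
    tenure_thresholds: tuple[int, ...] = (1, 2, 3, 4, 5, 6)
    convergence_tol: float = 0.001
    horizons: tuple[int, ...] = DEFAULT_HORIZONS
    seed: int = 0
    output_dir: str | None = None

    def __post_init__(self) -> None:
        sources = [
            self.sim is not None,
            self.interactions_path is not None or self.ranks_path is not None,
            self.matrices is not None,
        ]
        if sum(sources) != 1:
            raise ValueError("exactly one input source (sim, files, matrices) required")

    def mode(self) -> str:
        if self.sim is not None:
            return "simulate"
        if self.matrices is not None:
            return "matrices"
        return "files"


def _round6(x):
    if isinstance(x, float):
        if math.isnan(x):
            return None
        return float(f"{x:.6g}")
    return x


def _config_hash(config: RunConfig) -> str:
    payload = {
        "mode": config.mode(),
        "sim": dataclasses.asdict(config.sim) if config.sim else None,
        "interactions_path": config.interactions_path,
        "ranks_path": config.ranks_path,
        "matrices": {
            k: m.probs.tolist() for k, m in (config.matrices or {}).items()
        } or None,
        "tenure_thresholds": list(config.tenure_thresholds),
        "convergence_tol": config.convergence_tol,
        "horizons": list(config.horizons),
        "seed": config.seed,
    }
    blob = json.dumps(payload, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


# ----------------------------------------------------------------------
# validation
# ----------------------------------------------------------------------

def validate_inputs(
    interactions_path: str | None = None, ranks_path: str | None = None
) -> list[str]:
    """Schema and consistency checks; returns *all* violations found."""
    violations: list[str] = []
    inter = ranks = None
    if interactions_path is not None:
        p = Path(interactions_path)
        if not p.exists():
            return [f"unreadable file: {p}"]
        inter = pd.read_csv(p, dtype=str)
        needed = {"year", "actor_id", "recipient_id", "winner_id"}
        missing = needed - set(inter.columns)
        if missing:
            violations.append(f"interactions missing columns: {sorted(missing)}")
            inter = None
    if ranks_path is not None:
        p = Path(ranks_path)
        if not p.exists():
            return violations + [f"unreadable file: {p}"]
        ranks = pd.read_csv(p, dtype={"individual_id": str, "sex": str})
        needed = {"year", "individual_id", "sex", "rank"}
        missing = needed - set(ranks.columns)
        if missing:
            violations.append(f"ranks missing columns: {sorted(missing)}")
            ranks = None
    if ranks is not None:
        if ranks.duplicated(["individual_id", "year"]).any():
            dup = ranks[ranks.duplicated(["individual_id", "year"], keep=False)]
            for (ind, year), _ in dup.groupby(["individual_id", "year"]):
                violations.append(f"duplicate rank entry for individual {ind} in year {year}")
        for (sex, year), grp in ranks.groupby(["sex", "year"]):
            got = sorted(grp["rank"].astype(int))
            want = list(range(1, len(got) + 1))
            if got != want:
                bad = sorted(set(got) ^ set(want))
                violations.append(
                    f"ranks for sex={sex}, year={year} are not a permutation of "
                    f"1..{len(got)} (offending ranks: {bad})"
                )
    if inter is not None:
        same = inter["actor_id"] == inter["recipient_id"]
        for idx in inter.index[same]:
            violations.append(f"interaction row {idx}: actor equals recipient")
        badwin = ~(
            (inter["winner_id"] == inter["actor_id"])
            | (inter["winner_id"] == inter["recipient_id"])
        )
        for idx in inter.index[badwin]:
            violations.append(f"interaction row {idx}: winner is neither participant")
    if inter is not None and ranks is not None:
        present = {
            (str(r.individual_id), int(r.year)) for r in ranks.itertuples(index=False)
        }
        for idx, row in inter.iterrows():
            year = int(row["year"])
            for col in ("actor_id", "recipient_id"):
                if (str(row[col]), year) not in present:
                    violations.append(
                        f"interaction row {idx}: individual {row[col]} absent from "
                        f"ranks in year {year}"
                    )
    return violations


# ----------------------------------------------------------------------
# stage implementations
# ----------------------------------------------------------------------

def _mobility_section(table: RankTable, config: RunConfig) -> dict:
    section: dict = {"per_sex": {}}
    fits = {}
    pooled_pairs = []
    for sex in table.sexes:
        pairs = rank_pairs(table, sex)
        entry: dict = {"n_pairs": int(len(pairs))}
        if len(pairs) >= 3 and np.ptp(pairs[:, 0]) > 0:
            fit = fit_mobility(pairs)
            fits[sex] = fit
            entry["fit"] = {
                "slope": _round6(fit.slope),
                "intercept": _round6(fit.intercept),
                "rate": _round6(fit.rate),
                "r": _round6(fit.r),
                "n": fit.n,
                "p": _round6(fit.p),
            }
            if fit.n >= 8 and np.ptp(fit.residuals) > 0:
                ad, p = residual_normality(fit)
                entry["residual_normality"] = {"AD": _round6(ad), "p": _round6(p)}
        counts = classify_transitions(pairs)
        entry["transitions"] = {
            "n_up": counts.n_up,
            "n_down": counts.n_down,
            "n_same": counts.n_same,
            "up_fraction": _round6(counts.up_fraction),
            "fraction_within_two": _round6(counts.fraction_within_two),
            "magnitudes": {str(k): v for k, v in sorted(counts.magnitudes.items())},
        }
        tt = tenure_table(table, sex, config.tenure_thresholds)
        entry["tenure_table"] = [
            {k: _round6(v) for k, v in row.items()} for row in tt.to_dict("records")
        ]
        try:
            r, df, p = tenure_change_correlation(table, sex)
            entry["tenure_change_correlation"] = {
                "r": _round6(r), "df": df, "p": _round6(p)
            }
        except ValueError as exc:
            entry["tenure_change_correlation"] = {"error": str(exc)}
        spells = extreme_rank_tenure(table, sex)
        entry["extreme_rank_tenure"] = {
            pos: {
                "spells": list(s.spells),
                "count": s.count,
                "mean": _round6(s.mean),
                "sd": _round6(s.sd),
            }
            for pos, s in spells.items()
        }
        section["per_sex"][sex] = entry

    pooled = np.vstack([rank_pairs(table, sex) for sex in table.sexes])
    counts = classify_transitions(pooled)
    chi_change = chi_square_equal(counts.n_change, counts.n_same)
    section["pooled_transitions"] = {
        "n_up": counts.n_up,
        "n_down": counts.n_down,
        "n_same": counts.n_same,
        "p_up": _round6(counts.n_up / counts.n_pairs),
        "p_down": _round6(counts.n_down / counts.n_pairs),
        "p_same": _round6(counts.n_same / counts.n_pairs),
        "chi2_change_vs_same": {
            "chi2": _round6(chi_change[0]), "df": 1, "p": _round6(chi_change[2])
        },
    }
    if counts.n_change > 0:
        chi_ud = chi_square_equal(counts.n_up, counts.n_down)
        section["pooled_transitions"]["chi2_up_vs_down"] = {
            "chi2": _round6(chi_ud[0]), "df": 1, "p": _round6(chi_ud[2])
        }
    if len(fits) == 2:
        (sa, fa), (sb, fb) = sorted(fits.items())
        t, df, p = compare_slopes(fa, fb)
        section["slope_comparison"] = {
            "sexes": [sa, sb], "t": _round6(t), "df": df, "p": _round6(p)
        }
    sexes = table.sexes
    if len(sexes) == 2:
        spells_a = extreme_rank_tenure(table, sexes[0])
        spells_b = extreme_rank_tenure(table, sexes[1])
        mw = {}
        for pos in ("alpha", "omega"):
            a, b = spells_a[pos].spells, spells_b[pos].spells
            if a and b:
                u, p = mann_whitney(a, b)
                mw[pos] = {"U": _round6(u), "p": _round6(p)}
        if mw:
            section["extreme_tenure_sex_comparison"] = mw
        try:
            km = km_upward_time(table, sexes)
            section["km_upward"] = {
                "logrank_statistic": _round6(km.logrank_statistic),
                "logrank_p": _round6(km.logrank_p),
                "n_events": {s: int(km.events[s].sum()) for s in sexes},
                "n_adults": {s: int(len(km.events[s])) for s in sexes},
            }
        except ValueError as exc:
            section["km_upward"] = {"error": str(exc)}
    return section


def _stratification_section(
    matrices: dict[str, TransitionMatrix], config: RunConfig
) -> dict:
    section: dict = {"matrices": {}, "table": {}, "stationary": {}, "convergence": {}}
    for cohort, P in matrices.items():
        section["matrices"][cohort] = {
            "HH": _round6(P.p_HH),
            "HL": _round6(P.p_HL),
            "LH": _round6(P.p_LH),
            "LL": _round6(P.p_LL),
        }
        rows = {}
        for n in config.horizons:
            powered = matrix_power(P, n)
            rows[str(n)] = {
                "HH": _round6(powered.p_HH),
                "LL": _round6(powered.p_LL),
                "HH_4dp": f"{powered.p_HH:.4f}",
                "LL_4dp": f"{powered.p_LL:.4f}",
            }
        section["table"][cohort] = rows
        try:
            pi_h, pi_l = stationary_distribution(P)
            horizon, dev = convergence_horizon(P, tol=config.convergence_tol)
            section["stationary"][cohort] = {
                "pi_H": _round6(pi_h),
                "pi_L": _round6(pi_l),
                "odds_H_over_L": _round6(pi_h / pi_l),
            }
            section["convergence"][cohort] = {
                "horizon": horizon,
                "max_deviation": _round6(dev),
                "tol": config.convergence_tol,
            }
        except ValueError as exc:
            section["stationary"][cohort] = {"error": str(exc)}
    return section


def estimate_strat_matrices(table: RankTable) -> dict[str, TransitionMatrix]:
    """Per-sex and pooled stratum-transition matrices from a rank table."""
    matrices: dict[str, TransitionMatrix] = {}
    per_sex = []
    names = {"M": "male", "F": "female"}
    for sex in table.sexes:
        assignment = assign_strata(table, sex)
        m = estimate_transition_matrix(assignment)
        matrices[names.get(sex, str(sex))] = m
        per_sex.append(m)
    if len(per_sex) > 1:
        matrices["combined"] = pool_matrices(per_sex)
    return matrices


def run(config: RunConfig) -> dict:
    """Execute all applicable stages and return the analysis report."""
    report: dict = {
        "provenance": {
            "version": __version__,
            "mode": config.mode(),
            "seed": config.seed,
            "config_hash": _config_hash(config),
        }
    }
    table = None
    mode = config.mode()
    if mode == "simulate":
        try:
            history = simulate_group(config.sim)
        except Exception as exc:
            raise StageError("simulate", str(exc)) from exc
        try:
            inferred = infer_annual_ranks(
                history.records,
                history.rank_table().df[["individual_id", "sex"]].drop_duplicates(),
                seed=config.seed,
            )
            table = RankTable(inferred)
        except Exception as exc:
            raise StageError("rank", str(exc)) from exc
        true_table = history.rank_table()
        merged = true_table.df.merge(
            table.df, on=["individual_id", "sex", "year"], suffixes=("_true", "_inferred")
        )
        agreement = float((merged["rank_true"] == merged["rank_inferred"]).mean())
        report["rank_inference"] = {
            "n_individual_years": int(len(merged)),
            "agreement_with_true_ranks": _round6(agreement),
        }
        if config.output_dir:
            history.write_csv(config.output_dir)
    elif mode == "files":
        try:
            if config.ranks_path is not None:
                table = RankTable.from_csv(config.ranks_path)
                roster = table.df[["individual_id", "sex"]].drop_duplicates()
            else:
                roster = None
            if config.interactions_path is not None:
                inter = pd.read_csv(config.interactions_path, dtype=str)
                records = records_from_frame(inter)
                if roster is None:
                    raise ValueError(
                        "ranking from interactions requires a ranks/roster file for sexes"
                    )
                table = RankTable(infer_annual_ranks(records, roster, seed=config.seed))
        except StageError:
            raise
        except Exception as exc:
            raise StageError("load", str(exc)) from exc

    if table is not None:
        try:
            report["mobility"] = _mobility_section(table, config)
        except Exception as exc:
            raise StageError("mobility", str(exc)) from exc
        try:
            matrices = estimate_strat_matrices(table)
        except Exception as exc:
            raise StageError("stratify", str(exc)) from exc
    else:
        matrices = config.matrices

    try:
        report["stratification"] = _stratification_section(matrices, config)
    except Exception as exc:
        raise StageError("stratify", str(exc)) from exc

    if config.output_dir:
        outdir = Path(config.output_dir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "report.json").write_text(json.dumps(report, indent=2) + "\n")
    return report


def read_matrices_file(path) -> dict[str, TransitionMatrix]:
    """Read cohort matrices from JSON or flat key=value text.

    JSON form: ``{"male": [[pHH, pHL], [pLH, pLL]], ...}``.
    Flat form: lines ``male.HH=0.9570`` etc.
    """
    text = Path(path).read_text()
    try:
        payload = json.loads(text)
    except json.JSONDecodeError:
        payload = {}
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, value = line.split("=", 1)
            cohort, cell = key.strip().rsplit(".", 1)
            payload.setdefault(cohort, {})[cell.upper()] = float(value)
        payload = {
            cohort: [[c["HH"], c["HL"]], [c["LH"], c["LL"]]]
            for cohort, c in payload.items()
        }
    return {
        cohort: TransitionMatrix(np.array(rows, dtype=float))
        for cohort, rows in payload.items()
    }
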