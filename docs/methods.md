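# Methods

## Scope and data model

The package analyses annual snapshots of strictly linear dominance
hierarchies kept separately for each sex. The core container
(`RankTable`) stores one absolute rank per (individual, year), with
rank 1 = alpha; within every (sex, year) the ranks must form the
permutation 1..N. Sex-specific hierarchies are never pooled at the rank
level — "combined" statistics pool individual-year *transitions* (or
stratum-transition counts), never ranks, because absolute rank numbers
are not comparable across hierarchies of different size. Absolute rank
(not percentile) is used throughout: with fluctuating group size a
percentile can fall while the absolute rank rises, which makes
percentile mobility ill-defined for groups of this size.

## Rank inference from agonistic records

A decided contest is an aggressive act answered by submission. Contests
are tallied into a win:loss matrix per (year, sex); the rank order is
the permutation minimizing the number of *reversals*, defined as the
total count of interactions won by the lower-ranked member of a dyad
(the below-diagonal sum of the rearranged matrix), not the number of
inconsistent dyads. Minimizing reversal interactions weights strong
inconsistencies more than incidental single wins, which suits
high-volume ad-libitum scoring.

This is a linear-ordering problem, so the optimal cost decomposes over
prefix sets and is solved exactly by dynamic programming over subsets
for up to 9 active individuals (well above the per-sex group sizes the
package targets). Larger groups use pairwise-swap hill climbing with 20
seeded random restarts and are flagged `method="heuristic"`; the
reported reversal count is exact for the returned order in both modes.
Ties among equally minimal orders are broken rank by rank: the
candidate with the larger total win count is preferred, then the
lexicographically smaller identifier. Individuals never observed
interacting are appended after all active ones in lexicographic order
and listed in the result rather than dropped (dropping them would
silently change group size).

## Mobility statistics

* **Rate.** OLS of `R(t+1)` on `R(t)` over individual-years; rate
  `= 1 − slope` (an exact identity in the fitted object). Significance
  is the two-tailed p of Pearson's r with `n − 2` df; the offset is
  configurable because some published analyses use `n − 1`.
* **Slope comparison.** Pooled-residual-variance t-test,
  `df = n_a + n_b − 4`.
* **Residual normality.** Anderson–Darling with estimated mean and
  variance (statsmodels `normal_ad`); residual spreads below 1e-10 are
  treated as degenerate (exact fits leave only rounding noise).
* **Transition classification.** Per consecutive-year pair: up if the
  rank number fell, down if it rose, else no change; the magnitude
  spectrum is |ΔR| over changes. Individuals absent the next year are
  censored, not transitions.
* **Tenure table.** Each adult is classified once by the sign of its
  net rank change over its whole tenure; the row for threshold k
  reports class proportions among adults with tenure ≥ k, so rows are
  nested subsets. (The alternative reading — per-year transition
  probabilities conditioned on current tenure — is coherent too, but
  the whole-tenure reading is the one under which high-tenure rows can
  reach a probability of 1 for upward movement.)
* **Alpha/omega spells.** A spell is a maximal run of consecutive years
  in which one individual holds rank 1 (or the bottom rank, which moves
  with group size); each spell is one observation for the mean/SD and
  for the between-sex Mann–Whitney comparison (exact enumeration when
  both samples are ≤ 20 without ties, otherwise normal approximation
  with tie correction).
* **Time to first upward move.** Kaplan–Meier product-limit estimator
  on years from the first observed adult year to the first annual rank
  improvement, right-censored at exit; two sexes are compared by
  log-rank.

## Two-stratum Markov model

Each (sex, year) is split at the median: ranks 1..N/2 form the upper
stratum H, the rest L; with odd N the middle rank carries weight 0.5 in
each stratum, so both stratum totals are exactly N/2 (N = 1 puts the
sole animal half in each). Transition mass for an individual present in
consecutive years is the outer product of its origin and destination
weights — the only symmetric reading of the half-score rule that
conserves one unit of mass per individual-year pair (a middle animal
staying middle contributes 0.25 to all four cells). Rows of the count
matrix are normalized to probabilities; the combined-sex matrix pools
male and female counts *before* normalizing (the maximum-likelihood
combination), never averages the per-sex probability matrices.

Powers `P^n` are computed by repeated squaring and checked against the
two-state closed form `P^n_HH = π_H + (1 − π_H)·λ2^n` with
`λ2 = p_HH + p_LL − 1` — the module's analytic oracle, accurate to
1e-9. Convergence is declared at the first doubling horizon
(2, 4, 8, ...) where both diagonals are within `tol = 0.001` of the
stationary values π (computed in closed form; chains with a zero
off-diagonal are rejected as absorbing/reducible). Comparing against π
rather than against the previous power is the implemented reading of
"stabilized at the 0.001 level"; it reproduces the published
16-to-32-year convergence window for the bundled combined matrix.
Published table values beyond the 2-year row can differ from
full-precision recomputation by ±0.0001 (they were evidently powered
from unrounded matrices), so table comparisons use ±0.001.

## Synthetic-group generator

The generator emulates the study conditions the analysis assumes: two
sex-hierarchies of initially 8 adults each, observed for 30 annual
snapshots, with turnover and rank dynamics tuned to the empirical
regime (≈2:1 stay/change and ≈3:1 up/down odds per individual-year,
upward drift driven mainly by departures of high-ranking animals).

Annual update order (fixed, documented, seed-deterministic from a
single NumPy stream): (1) departures — Binomial(N, departure_rate)
leavers chosen with weight `(N − rank + 1)^bias`, survivors close the
gaps; (2) immigration — Poisson(immigration_rate) entrants, each at a
uniform rank in the lower half ⌈N/2⌉..N+1 (newcomers rarely enter at
the top; for the female hierarchy "immigration" stands in for
maturation into adulthood); (3) endogenous moves — in random order,
each animal moves with `move_probability`, upward with
`up_given_move = 0.75`, magnitude 1–2 unless `large_jump_probability =
0.2` fires (then 3..max_jump), implemented as remove-and-reinsert so
the year always ends in a permutation; (4) contests — per dyad a
Poisson(20) number of decided contests won by the higher-ranked with
`p_dominant_win = 0.9`.

**Calibration.** The realized annual profile is emergent: every
departure promotes all lower-ranked animals by one, every immigrant
demotes those below its entry, and every endogenous up-move displaces
intermediates downward. The defaults (`departure_rate = 0.065`,
`departure_rank_bias = 2.5`, `immigration_rate = 0.32`,
`move_probability = 0.02`) were calibrated once, by a coarse grid
search against the target profile, to a realized pooled
(up, down, stay) ≈ (0.250, 0.080, 0.670) and a realized up-fraction of
≈ 0.76 — after which they were frozen. The mean steady group size is
≈ 13 adults across both sexes.

**What the generator does not reproduce.** Because displacement makes
nearly all realized changes magnitude 1–2, the simulated magnitude
spectrum is narrower than real field data (≈97% of changes within two
ranks versus ≈80% empirically); matching the broad spectrum and the
3:1/2:1 odds simultaneously would need a different move mechanism.
There is no kinship, coalition, seasonality or within-year dynamics,
and departures are memoryless, so tenure distributions are geometric
rather than senescent. Passing recovery tests therefore demonstrates
the *estimators* are correct in the regime the data occupy, not that
the mechanism generating real histories is this one.

A note on forced-move edge cases: with `move_probability = 1` and
`up_given_move = 1` it is tempting to expect that no rank number ever
rises, but rank sums are conserved within a closed year, so any strict
upward move must push someone else down; the guaranteed invariant is
that each mover's *own* reinsertion never targets a lower rank, and
that the permutation structure survives every year.

## Numerical conventions

Row-stochasticity is enforced to 1e-9 at construction and after every
power. Report floats are rounded to 6 significant digits with 4-dp
"as-printed" renderings alongside table analogues. All randomness in
simulation, heuristic search and tests flows from explicit integer
seeds; identical (config, seed) gives byte-identical CSV output and
hash-identical reports.
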