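# Methods

## Growth-dilution dynamics

The core model treats the bedding of one cage as a well-mixed batch
culture that is periodically diluted. Between events each taxon follows
logistic growth `dN/dt = r N (1 − N/K)` with `r` in 1/day and `K` in
CFU/g; at `t = kT` every abundance is multiplied by the carry-over
fraction `d ∈ (0, 1]`. Because the logistic equation has a closed-form
solution, the per-cycle (pre-event) dynamics reduce to the one-dimensional
map `N ↦ logistic(dN, r, K, T)`, and everything of scientific interest is
algebra on that map:

- per-cycle low-density multiplier `μ = d·e^{rT}`;
- persistence iff `μ > 1`, with pre-event fixed point
  `N* = K(μ − 1)/(d(e^{rT} − 1))`, which is globally attracting on
  `(0, ∞)` (the map is increasing and concave);
- critical growth rate `r_crit = ln(1/d)/T`.

Multi-taxon communities use Lotka–Volterra competition
`dN_i/dt = r_i N_i (1 − Σ_j a_ij N_j / K_i)` with `a_ii = 1`. This is an
extension beyond the single-taxon theory (needed for the cocktail
scenario); single-taxon results never depend on it, and with one taxon it
reduces exactly to the logistic model.

**Assumptions.** Deterministic, well-mixed, no spatial structure within
the cage, no temperature dependence, no stochastic birth–death at low
density. Extinction is imposed by a threshold rather than demographic
noise.

**Numerics.** Integration uses LSODA with relative tolerance 1e-8 and an
essentially zero absolute tolerance: subcritical populations decay through
many decades of abundance and must keep *relative* accuracy all the way
down for trajectories to match the closed-form cycle map (the oracle used
in tests, which they match to better than 1e-6 relative). Event times are
known in advance, so integration simply restarts at each event; no event
detection is needed. Both the pre-event and post-event states are recorded
at the event timestamp, ordered pre then post.

**Default schedule.** `T = 10` days is the routine replacement interval
for static cages. The carry-over fraction is not a measured quantity; the
default `d = 0.01` (1% residual transfer via the mice's gut and coat and
handling) puts `r_crit ≈ 0.46`/day, which produces the observed
persistence/extinction dichotomy at plausible bacterial growth rates.
`N_min = 1` CFU/g is applied only immediately after dilution: a
deterministic model otherwise never reaches zero, and densities below one
organism per gram are unphysical. Both are configurable everywhere.

## Bedding soiledness

Soiling is linear in mouse-days: with clean-substrate mass normalized to
`B0 = 1`, feces mass is `φ·m·t` and spilled-diet mass `δ·m·t` after `t`
days with `m` mice; fractions are taken over the grand total. The shipped
rates are calibrated by exact algebraic inversion of the single quantified
composition (6.9% feces, 43.6% diet at `m = 5`, `t = 10`), giving
`φ ≈ 0.0027879` and `δ ≈ 0.0176162` per mouse-day. Water/moisture is
carried in the data model but defaults to rate 0, since the calibration
datum covers feces and diet only. The calibrate/accumulate pair is an
algebraic identity (tested to 1e-12), so any other single composition
datum can be substituted.

Mixtures of clean bedding with 10% and 50% soiled bedding act as
surrogates for 1-day- and 5-day-soiled bedding, which is how the
soiledness state `s` connects the accumulation model to the in-vitro
scenarios.

## Substrate response and the three-taxon cocktail

No CFU time series is published for the cocktail experiment, so the
response curves are constrained only by the reported *orderings*, and the
package treats them as its own default parameterization:

- piecewise-linear multipliers on `r` in the soiled fraction `s`, with a
  separate plain-diet point (the simplest form able to encode the
  non-monotone *L. murinus* optimum at `s = 0.5`);
- a shared capacity curve rising from 10% of `K` on clean sterile
  substrate to 100% on fully soiled bedding (nutrient availability);
- base rates `r = 0.9, 1.2, 0.7`/day and `K = 1e8` CFU/g for
  *E. faecalis*, *E. coli*, *L. murinus*;
- competition `a = 0.5` between all pairs except the observed
  *E. faecalis* → *L. murinus* inhibition, `a = 2.0` — strong enough to
  suppress *L. murinus* once *E. faecalis* is abundant while keeping
  low-density coexistence possible.

With these defaults the simulated 9-day, 1:1:1 cocktail reproduces the
qualitative outcomes: *E. faecalis* ranks first on fully soiled substrate,
*E. coli* is the least adapted (and declines, `r_eff < 0`, on plain
diet), and *L. murinus*'s effective growth peaks at the 50% scenario.
These are property checks, not numeric reproductions.

## Husbandry accounting

Ledger identities: `cage_days = n_cages × days`,
`mouse_days = (adults + pups) × days`, `mouse_days_per_cage =
mouse_days / n_cages`, `openings = cage_days / interval`. The packaged
census fixture stores the printed values alongside the raw inputs; because
the source table mixes truncation and rounding when printing
mouse-days/cage, `summarize` returns the exact value plus both integer
conventions and flags rows where they differ. Two printed opening counts
(and the totals that propagate them) contradict the identities themselves;
those cells carry a `consistent_* = 0` flag in the fixture and are not
reproduced. The daily-risk figure is reported as 1-in-817
(= round(40,830/50)); an alternative figure of 867 circulates for the same
data but is not supported by the underlying counts.

The Fisher test computes hypergeometric probabilities over the full
margin-preserving support. The two-sided p-value is the probability-mass
convention — the sum over tables whose probability does not exceed the
observed table's, with ties tolerated to a relative 1e-7 — which is also
scipy's convention; tests cross-check against both scipy and an exact
rational-arithmetic enumeration oracle. The one-sided variant
(`one_sided_row2_low`) is the tail probability that the second row's
event count is at or below its observed value. Degenerate tables (an
empty margin) return p = 1 with a warning rather than an exception, since
they arise naturally from event-free ledgers.

## Screening statistics

Cohen's kappa is computed from the 2×2 cell proportions with *both*
standard errors: the null-hypothesis SE (kappa = 0), which underlies the
`Z` statistic, and the unconditional asymptotic (Fleiss–Cohen–Everitt)
SE, the one appropriate for a ±CI on the estimate. The two conventions
differ substantially on small tables — e.g. for the table
`[[8, 1], [1, 9]]`, kappa = 0.789 with null SE 0.229 (Z = 3.44) but
asymptotic SE 0.141 — which is why both are returned explicitly.
Implementations are cross-checked against statsmodels in the test suite.

Replicate combination: "in series" sums reads (a taxon is present if
detected in any replicate), "in parallel" requires positivity in every
replicate; parallel presence is provably a subset of series presence, and
the tests assert this containment on arbitrary inputs.

## Synthetic co-streaking generator

The generator emulates the cyclical convergence/divergence of cage-mates'
cultivable fecal profiles. Each mouse `i` carries a composition `x_i` over
abstract colony types (morphotypes, not sequenced taxa) relaxing toward a
host-specific attractor `h_i` (drawn once per mouse from a Dirichlet(0.5),
encoding individuality) at rate ρ. The cage bedding hosts its own
composition `b` in which type `k` grows exponentially at rate `r_k`
(types span 0.1–1.0/day), so the bedding is progressively dominated by
fast growers as the cycle ages; fresh fecal deposits mix into `b` at
2.0/day. Mouse–bedding exchange acts at rate `κ0 × s(t)` where `s(t)` is
the current feces fraction from the accumulation model — negligible in a
fresh cage, dominant late in the cycle. A cage change resets the bedding.

Defaults (3 cages × 3 mice, 3 cycles of `T = 10` d, observations on days
3 and 10, `κ0 = 60`, `ρ = 0.5`, signature = ranked top-3 types above a 1%
detection fraction, Euler step 0.25 d) were fixed from this mechanism
analysis: cumulative coupling must stay below the host-relaxation scale by
day 3 and exceed it well before day 10. In this regime pooled
distinct-signature counts fall from ≈8 (day 3) to ≈6 (day 10) out of 9
mice and recover after each cage change — the oscillation is asserted as a
sign test across seeds, not as exact profile counts, because the emulated
counts depend on unprinted latent parameters.

What the generator does *not* emulate: real morphotype ambiguity on
plates, anaerobic/aerobic incubation differences, hemolysis phenotypes,
coprophagy network structure, or read-level sequencing noise. Passing
tests therefore show the analysis pipeline behaves correctly on data with
the assumed structure, not that real cages have these parameter values.

All randomness descends from one top-level seed through named CRC32-keyed
substreams, so outputs are bit-reproducible and adding a new generator
never perturbs existing ones. Plate counts are Poisson around
`CFU × 10^{-dilution} × volume`, with a helper choosing the dilution whose
expectation lands in the countable 30–300 range. The agreement-table
generator samples two conditionally independent tests given a latent
contamination status; its analytic kappa (from the cell probabilities) is
the recovery target in tests.

## Problem sizes

Defaults were chosen so the full suite exercises every claim at desk
scale: cycle-map/ODE agreement on a 16-point `(r, T, d)` grid over 12
cycles; persistence scans over 10–12 rates for 30–40 cycles; 50-seed sign
test for the diversity oscillation; 500 tables × 200 cages for kappa
recovery; Fisher enumeration on 150 random tables with totals ≤ 200.

## Known limitations

- The carry-over fraction `d` and the cocktail response curves are design
  defaults constrained by qualitative observations, not fitted to data.
- The deterministic extinction threshold makes `cycles_to_extinction`
  exact but ignores demographic stochasticity near extinction.
- The linear soiling model is calibrated from a single composition datum;
  saturation or grinding-behaviour nonlinearity would need refitting.
- Multi-taxon outcomes report the *single-taxon* μ and N* per taxon for
  interpretability; with strong interactions the simulated fate (which is
  what `status` reports) can differ from the single-taxon prediction.
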