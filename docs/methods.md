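# Methods

## The decision problem

The package models the choice between four surgical strategies for a
massive, irreparable rotator cuff tear without glenohumeral arthropathy:
superior capsular reconstruction (SCR), lower trapezius tendon transfer
(LTTT), subacromial balloon spacer implantation (SABS) and reverse shoulder
arthroplasty (RSA).  Each strategy is characterised by an upfront procedure
cost (payer perspective, US$), an annual probability of arthroscopic
revision, an annual probability of conversion to RSA (zero for RSA, whose
single failure mode is revision RSA), and a per-year health utility for
surgical success obtained by dividing the Constant-Murley shoulder score by
100.  A single complication-year utility (0.35) is shared by all
strategies.

## State structure and accrual rules

Patients move through annual Markov cycles over a 10-year horizon across
four states:

* `INDEX_SUCCESS` — post-index-surgery success; at risk of the strategy's
  two competing events (arthroscopic revision, conversion to RSA);
* `POST_REVISION_SUCCESS` — absorbing success after arthroscopic revision;
* `POST_CONVERSION_RSA` — success after conversion; at risk of revision
  RSA (the conversion target's revision hazard);
* `POST_RSA_REVISION_SUCCESS` — absorbing success after revision RSA.

Accrual rules, applied identically in the stochastic engine, the
deterministic cohort expectation and the exhaustive enumeration:

* the index cost is booked at t = 0 undiscounted; all cycle-t accruals are
  discounted by (1 + d)^-t with d = 0.03/year;
* an arthroscopic revision costs (1 + 0.05) x the strategy's upfront cost;
  a conversion costs the conversion target's upfront cost; a revision RSA
  costs (1 + 0.05) x the target's upfront cost (the revision surcharge for
  RSA can be overridden separately via `rsa_revision_cost_uplift`);
* the cycle in which an event occurs accrues the failure utility; every
  other cycle accrues the utility of the current state — the strategy's
  success utility before conversion, the target's after;
* there is no background mortality, no death state and no half-cycle
  correction over the 10-year horizon.

Table probabilities are interpreted as *annual per-cycle hazards while at
risk*, with at most one event of each kind per pathway (post-event states
are absorbing).  Among the candidate readings — one-time risks, perpetual
hazards, annual hazards with absorption — this one comes closest to the
published cost accumulation; the alternatives are far off in opposite
directions.  A `allow_repeat_events` flag switches to a variant in which
revision returns the patient to the at-risk state; it is off by default
and the enumeration oracle refuses it.

A genuine non-monotonicity is worth noting: with two competing risks,
raising the revision hazard can *increase* expected QALYs, because an early
revision locks in the strategy's success utility and diverts patients from
the costlier, lower-utility conversion pathway.  Monotonicity of cost and
QALY in the event hazard holds only in the single-risk regime, and that is
what the test suite asserts.

## Uncertainty model (PSA)

Each PSA iteration draws one full parameter set, all draws mutually
independent, by method-of-moments matching:

| input class  | family | SD rule              | shape parameters            |
|--------------|--------|----------------------|-----------------------------|
| costs        | gamma  | 20% of the mean      | shape (m/s)^2, scale s^2/m  |
| probabilities| beta   | 20% of the mean      | a = m nu, b = (1-m) nu, nu = m(1-m)/s^2 - 1 |
| utilities    | normal | 0.05 absolute        | (m, s)                      |

A probability with base value exactly 0 becomes a point mass (a beta
distribution has no mean-0 member).  Sampled utilities are clipped into
[0, 1] (clip probability < 1e-10 at these SDs) and a sampled failure
utility is additionally capped at the sampled success utility — a ~3.4
sigma joint event (~3 x 10^-4 per draw) — so that every sampled parameter
set satisfies the configuration invariants.  A sampled hazard pair whose
sum exceeds 1 is rescaled proportionally; this cannot trigger at base-case
magnitudes.  No rank correlation is induced between inputs.

Quantile reporting: `quantile_range` returns *analytic* 10–90% quantiles.
Published ranges of this kind are often finite-sample percentiles of the
software's own draws; with ~1000 draws the empirical 90th percentile of a
cost input has a standard error of a few hundred dollars, so analytic and
printed ranges can disagree by more than a rounding unit without either
being wrong.

## Simulation sizes and random numbers

Defaults are 1000 PSA iterations x 1000 patients per arm — the full run
takes a few seconds — with scaled runs (e.g. 200 x 500) used in the test
suite to keep it fast.  Random streams come from a spawned
`numpy.random.SeedSequence` tree: master seed -> one branch per iteration
-> one branch for parameter sampling plus one per strategy arm.  Results
are therefore reproducible bit-for-bit from (configuration, seed) and
independent of evaluation order; patient draws are vectorised with one
uniform variate per patient per cycle regardless of state, so the stream
consumption is pathway-independent.

## Oracles

Two independent deterministic references pin down the engine's semantics:

* `cohort_expectation` — forward propagation of the state-occupancy
  distribution with expected per-cycle accrual (exact expectation, no
  sampling); occupancy is conserved to 1e-12 per cycle;
* `enumerate_trajectories` — exhaustive enumeration of every distinguishable
  pathway (event-free; revision at cycle i; conversion at i with or without
  revision RSA at j > i), with exact probabilities summing to 1 within
  1e-12.  Over T cycles there are 1 + T + T(T+1)/2 + ... outcomes — 121
  for T = 10 — so enumeration is cheap and exact.

The two agree to 1e-9 on random configurations, and microsimulation means
agree with them within Monte Carlo error (3 SE).

## Synthetic scenarios

`generate_random_config` draws structurally valid decision problems (2–6
strategies, costs $5,000–$30,000, hazards bounded so their sum stays below
0.5, success utilities 0.5–0.9 above a shared failure utility 0.2–0.45, one
strategy designated the conversion target with zero conversion hazard).
These scenarios exercise every pipeline stage without the built-in base
case, but they deliberately share the base case's *structure*: passing
tests demonstrate correctness of the simulation and statistics machinery,
not the clinical realism of any particular input set.

## Cost-effectiveness statistics

* Per-strategy means and sample SDs are computed across iterations of the
  per-iteration arm means.
* Absolute dominance: another strategy costs no more and yields no fewer
  QALYs (one strict).  Extended dominance: iterative removal of
  cost-sorted frontier points whose pairwise ICER chain is non-monotone.
  Incremental cost/effect and the per-row ICER are reported relative to
  the cheapest strategy (so dominated rows can show negative ICERs), and
  the ICER chain between successive undominated strategies is reported
  separately.  Ties break to lower cost, then name.
* NMB = QALYs x WTP − cost; the results table uses WTP = $50,000/QALY.
* CEAC: share of iterations in which each strategy attains maximal NMB,
  on a WTP grid ($0–$100,000 in $1,000 steps by default); shares sum to 1
  at every grid point.  The "% iterations optimal" column is the CEAC value
  at the configured WTP — an iteration-level quantity, the standard CEAC
  convention.
* CEAC crossovers are located on the grid and linearly interpolated
  between the bracketing grid points.
* Confidence ellipses on the incremental plane: centre = sample mean,
  semi-axes = sqrt(covariance eigenvalues) x sqrt(chi2(0.95, 2 df)) ≈
  2.4477 x sqrt(eigenvalue), orientation from the eigenvectors; a
  near-singular covariance is flagged degenerate.

## Known limitations

* The deterministic base-case expectations are SCR $32,250 / 6.179 QALYs,
  LTTT $29,840 / 5.380, SABS $18,675 / 5.515, RSA $26,104 / 4.915 (the
  `base-case` command prints these).  Published figures for this decision
  problem were produced with closed-source modelling software whose event
  mechanics are not fully derivable from its stated inputs: most tellingly,
  a mean RSA QALY of 3.78 is below the 0.59 x 8.5302 = 5.03 floor that an
  event-free 10-year arm at utility 0.59 already attains, so the original
  model must contain additional structure (e.g. persistent failure-state
  occupancy or perioperative disutility) that its input table does not
  state.  The same unreported structure plausibly explains why published
  SABS/LTTT mean costs sit ~14–16% below, and the headline ICER ~16% above,
  any expectation consistent with the stated annual hazards.  This package
  implements exactly the stated inputs and documents the residual gap
  rather than guessing at hidden mechanics.
* Single-event pathways, no mortality, and a fixed 10-year horizon are
  structural assumptions, not estimates; sensitivity to them is outside
  the scope of the uncertainty analysis.
* Costs are single per-procedure payer amounts; follow-up and
  rehabilitation costs are not modelled separately.
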