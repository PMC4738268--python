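# Methods

## The two-compartment interconversion model

The population is split into stem-like, biomarker-positive cells `S` and
differentiated, biomarker-negative cells `D`. Six first-order channels act on
the pair: division and death in each compartment (`α_S, δ_S, α_D, δ_D`),
differentiation `S → D` at rate `k_SD`, and dedifferentiation `D → S` at rate
`k_DS(t)`. All rates are per day; time is in days, matching the cadence of the
FACS and sphere experiments the model is built for. The deterministic
dynamics are the linear system

    dS/dt = (α_S − δ_S) S − k_SD S + k_DS(t) D
    dD/dt = (α_D − δ_D) D − k_DS(t) D + k_SD S

and the stochastic dynamics are the continuous-time Markov jump process with
the same six channels and propensities `rate × source-compartment count`.
Oxygen tension enters only through parameter values: a hypoxic culture is a
different parameter set, not a different model. `k_DS` is a piecewise-constant
schedule (a list of `(start_day, rate)` segments) because the central
biological claim under test is a step change in plasticity at a fixed day;
the default switch day is 3.0.

Assumptions worth keeping in view: first-order (density-independent) rates,
so no crowding or feedback; exactly two phenotypic states, so the
epithelial–mesenchymal continuum is collapsed to its endpoints; no
asymmetric-division channel (`S → S + D`), which would be statistically
confounded with the six channels at the resolution of fraction data anyway.

### Positive fraction and equilibrium

The biomarker-positive fraction `f = S/(S+D)` obeys the Riccati equation
`f' = k_DS (1−f) − k_SD f + Δg f(1−f)` with `Δg = (α_S−δ_S) − (α_D−δ_D)`.
For constant `k_DS` the equilibrium `f*` is the stable root in [0, 1] of
`Δg f² + (k_SD + k_DS − Δg) f − k_DS = 0` (when `Δg = 0`,
`f* = k_DS/(k_SD+k_DS)`). Stability is decided by the sign of the quadratic's
derivative at the root, which matters only in degenerate corners such as
`k_SD = k_DS = 0`.

### Numerics

Deterministic trajectories are integrated with DOP853 with hard breakpoints
at every switch time of `k_DS`, so no step straddles a rate discontinuity.
The system is linear with eigenvalues on the order of the rates themselves
(≤ a few per day), hence never stiff; a high-order explicit method is the
right tool. Default tolerances are `rtol = 3e-14`, `atol = 1e-30`, which keep
the solution within ~1e-11 relative error of the exact segment-wise
matrix-exponential solution even after 20 days of exponential growth (values
up to ~e⁴⁰); lower-order stiff solvers lose four or more digits on the same
span. The grid-search loop integrates at `rtol = 1e-10` instead, since its
residuals are compared at tolerances of order 1e-2 and the sweep dominates
runtime. Integrator undershoots more negative than −1e-12 raise an error;
smaller ones are clamped to zero.

## Stochastic simulation

Sample paths use the direct-method Gillespie algorithm: two uniforms per
event, one for the exponential waiting time, one for the channel. The
piecewise `k_DS` is handled exactly by capping each waiting time at the next
*effective* boundary — a switch time where the rate actually changes — and
redrawing there, which is exact for piecewise-constant propensities. Only
effective boundaries interrupt the draw, so a schedule with a no-op switch
reproduces the constant-rate sample path variate for variate. The state
`(0,0)` is absorbing; frozen states consume no randomness.

States are recorded on a fixed grid (default 0.1 day) by last-event
carry-forward, so ensembles are comparable across runs. Ensembles derive the
seed of run *i* from the master seed via `SeedSequence(master, spawn_key=(i,))`,
making every ensemble reproducible from one integer and every run
independently reseedable.

## The in-silico mammosphere assay

Each well is one clonal stochastic run started from biomarker-negative cells
(default a single cell: a sphere is a clonal outgrowth, and a per-run cell
count criterion is only meaningful clonally). A run is positive when the
total count strictly exceeds 20 cells ("exceeded" read strictly: ≥ 21) at the
10-day end point — the in-silico stand-in for counting spheres above 60 µm.
The formation rate over the runs (default 100) carries an exact
Clopper–Pearson 95% interval, and two conditions are compared with the
two-sided Fisher exact test on the positives/negatives table.

One approximation keeps fast-growth regimes tractable: a run that reaches a
ceiling (default 1000 cells, 50× the threshold) is scored positive and
stopped. Returning from 1000 cells to ≤ 20 by day 10 requires an essentially
impossible downward excursion in any regime able to reach the ceiling, and
without the cutoff a pure-birth run at 2/day would need ~e²⁰ events. The
ceiling is configurable, and the event cap aborts loudly rather than
truncating silently.

## Grid-search parameter estimation

Estimation is deliberately exhaustive: a Cartesian grid over the chosen axes
is fully evaluated, every point whose loss is within the tolerance is
accepted, and the estimate is the per-parameter mean with SD over the
accepted set. No best point is selected — the spread *is* the result, and
with weakly identifying data (small pre-switch fractions, for instance) it is
honest about which rates the data pin down and which they do not.

The loss is the Chebyshev (max-abs) residual over the fraction observations:
a tolerance band on "the closest solutions within a given tolerance" reads
naturally as a sup-norm; a sum-of-squares alternative is available via
`norm="sse"`. When sphere counts are part of the data, the absolute
mammosphere-rate residual joins the max, simulated with one fixed seed for
every grid point (common random numbers) so the search is deterministic and
points are comparable. Model fractions are computed from `S0 = 0`; fractions
rather than raw counts are fitted because FACS reports proportions and
absolute growth is confounded by the hypoxic growth suppression. Tolerance
choice: the packaged default 0.05 suits noisy wet-lab fractions; the
synthetic-recovery analyses in the tests and the acceptance script use 0.01,
about three binomial standard errors at 10,000 FACS events for the largest
fractions in play — chosen from the noise model, not from any recovery
outcome. Acceptance is monotone in the tolerance and invariant to enumeration
order by construction.

The two-phase fit searches `k_DS_early` and `k_DS_late` jointly (switch day
fixed, default 3.0) and reports `mean(k_DS_late)/mean(k_DS_early)`. On the
packaged hypoxia scenario the recovered ratio lands at 10–13 across seeds:
the late rate is pinned to its grid value exactly while the early rate's
accepted set spreads toward small values, biasing the ratio slightly high —
within one two-fold grid step of the generating ten-fold jump, which is the
resolution the method claims.

## Signature overlap statistics

Signatures are defined on probes, not collapsed genes: the up-signature of a
condition is every probe whose normalised intensity is ≥ 2× the reference
condition's, the down-signature ≤ 0.5× — both boundaries inclusive, the
reciprocal threshold mirroring the inclusive two-fold rule. Two signatures
from the same universe feed a 2×2 confusion matrix (overlap, the two
exclusive sets, neither) whose universe size is always an explicit input —
all probes measured, never inferred from the signatures. The two-sided
Fisher exact p sums hypergeometric probabilities, at fixed margins, of every
table with point probability not exceeding the observed table's (the
point-probability convention; the doubling convention exists but is not
used). Implementation is `scipy.stats.fisher_exact`, validated in the test
suite against a full-enumeration oracle in exact rational arithmetic over
every table with total ≤ 30 (agreement to 1e-12) — the oracle shares no code
with the implementation. No multiplicity adjustment is applied by default;
each pair is reported at its own alpha.

## Synthetic data: what it emulates, what it does not

The generators emulate the *statistical structure* of the study's readouts:

* **Time courses**: true fractions from the deterministic model with a pure
  negative start (`S0 = 0`, so day 0 observes exactly zero), observed
  fractions as `Binomial(n, f_true)/n` per day with `n = 10,000` FACS events
  (typical cytometry scale; days 0–8).
* **Sphere counts**: `Binomial(wells, rate)` around the simulated formation
  rate.
* **Expression tables**: log-normal reference intensities around a baseline
  of 100, planted up/down probe sets multiplied/divided by a fold ≥ 2 before
  multiplicative log-normal noise, with an exactly controlled shared fraction
  between consecutive conditions' planted sets.

The packaged scenario rates (normoxia `α_S=0.8, δ_S=0.1, α_D=0.9, δ_D=0.1,
k_SD=0.1, k_DS=0.002`; hypoxia with division rates halved and `k_DS`
stepping 0.002 → 0.02 at day 3) are fixtures: only the day-3 switch and the
ten-fold late/early ratio are anchored in the modelled biology, the rest are
plausible daily rates chosen to produce a slow normoxic rise to a small
(~1%) equilibrium and a post-switch hypoxic acceleration toward a larger
(~12%) one. What passing tests on these data show is that the *methods* are
sound — the estimator recovers planted rates at the stated resolution, the
simulator is exact, the test is calibrated. They do not show that real FACS
noise is purely binomial (gating drift and compensation error are not
modelled), that microarray noise is log-normal and independent across probes,
or that real sphere assays are clonal and well-independent.

One known limitation follows directly from the fixture structure and is
worth stating plainly: with stem cells no fitter than differentiated cells
(`α_S < α_D`, equal death rates) and hypoxia halving division rates, the
simulated sphere formation rate under full hypoxic parameters is *lower*
than the normoxic one — threshold crossing is dominated by net clonal
growth, and the raised `k_DS` routes cells into the slower compartment. The
wet-lab observation that hypoxia-pretreated cells form more spheres (assayed
back in normoxia) reflects a CSC self-renewal advantage under sphere
conditions that this parameterisation deliberately does not encode; the
corresponding ordering check in the acceptance tests documents the
discrepancy rather than papering over it.

## Sizes and defaults used in the shipped analyses

Ensembles default to 100 runs; the truncated-master-equation comparison uses
2000 runs against a state space capped at 60 total cells; Yule closed-form
checks use 1000 runs per division rate; the type-I-error calibration uses
2000 null signature pairs; recovery fits use a 75-point grid (3 × 5 × 5,
two-fold-spaced dedifferentiation axes bracketing the generating values
asymmetrically). These sizes give standard errors comfortably inside every
asserted tolerance while keeping any single analysis in the seconds-to-a-
minute range.
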