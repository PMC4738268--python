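# cscplasticity

Modelling the plasticity of cancer-cell populations: how fast do
differentiated, biomarker-negative tumour cells dedifferentiate back into
stem-like, biomarker-positive ones, and how does an oxygen-poor
microenvironment change that rate?

The package is aimed at quantitative cancer biologists who have (or can
simulate) two kinds of readout for a mammary carcinoma line such as GD2-sorted
HMLER cells: FACS time courses of the biomarker-positive fraction after
sorting to a pure negative population, and mammosphere formation efficiencies.
It provides the full computational chain from raw readouts to interconversion
rate estimates, plus fold-change gene-signature overlap statistics.

## The model

Two compartments — stem-like cells `S` (biomarker-positive) and differentiated
cells `D` — interconvert through six first-order channels (division, death,
and switching in both directions, all rates per day):

```
dS/dt = (α_S − δ_S) S − k_SD S + k_DS(t) D
dD/dt = (α_D − δ_D) D − k_DS(t) D + k_SD S
```

The dedifferentiation rate `k_DS(t)` may be piecewise constant, so a
hypoxia-induced jump in plasticity at a fixed switch day is a first-class
model object. The positive fraction `f = S/(S+D)` obeys a Riccati equation
whose stable root in [0, 1] gives the equilibrium fraction in closed form.

Around this core the package provides:

* **`model`** — deterministic trajectories (adaptive high-order integration
  with hard breakpoints at rate switches), positive fraction, equilibrium
  fraction.
* **`ssa`** — exact Gillespie sampling of the same six-channel network
  (direct method; piecewise rates handled exactly), with seeded ensembles.
* **`mammosphere`** — the in-silico sphere assay: clonal stochastic runs from
  a single negative cell; a run exceeding 20 cells at day 10 scores as a
  mammosphere; rates come with exact binomial confidence intervals and
  Fisher-exact condition comparisons.
* **`gridfit`** — brute-force grid search: every parameter combination within
  a tolerance of the data is accepted, and estimates are means ± SD over the
  accepted set, including a two-phase (early/late `k_DS`) fit that reports
  the late/early ratio.
* **`signatures`** — two-fold up/down probe signatures, 2×2 confusion
  matrices, and the two-sided Fisher exact test.
* **`synth`** — seeded generators for all of the above inputs, with packaged
  `normoxia` and `hypoxia` scenarios.
* **`cscplast`** CLI — `synth`, `simulate`, `mammosphere`, `fit`, `overlap`,
  `run-all`, with a manifest (path, stage, seed, checksum) per run.

## Worked example

Generate a hypoxic FACS time course (10,000 events per day, pure negative
start) and recover the dedifferentiation switch by grid search:

```python
from cscplasticity import (GridSpec, MammosphereProtocol, load_scenario,
                           generate_timecourse, fit_two_phase_dedifferentiation,
                           simulate_mammosphere_rate)

hypoxia = load_scenario("hypoxia")
data = generate_timecourse(hypoxia, seed=11)
print(data.fractions.to_string(index=False))
```
```
 time  fraction       n
  0.0    0.0000 10000.0
  1.0    0.0024 10000.0
  2.0    0.0024 10000.0
  3.0    0.0046 10000.0
  4.0    0.0236 10000.0
  5.0    0.0326 10000.0
  6.0    0.0485 10000.0
  7.0    0.0598 10000.0
  8.0    0.0672 10000.0
```

The fraction creeps up slowly for three days, then accelerates — the
signature of a plasticity switch. Fitting early and late dedifferentiation
rates jointly with the differentiation rate:

```python
grid = GridSpec(
    axes={"k_SD": [0.05, 0.1, 0.2],
          "k_DS_early": [0.0005, 0.001, 0.002, 0.004, 0.008],
          "k_DS_late": [0.005, 0.01, 0.02, 0.04, 0.08]},
    fixed={"alpha_S": 0.4, "delta_S": 0.1, "alpha_D": 0.45, "delta_D": 0.1},
    switch_day=3.0)
res = fit_two_phase_dedifferentiation(grid, data, tolerance=0.01)
print(res.summary())
print(f"late/early ratio: {res.ratio_late_early:.2f}")
```
```
accepted 7/75 grid points at tolerance 0.01
  k_SD: 0.1 +/- 0.0463
  k_DS_early: 0.00185714 +/- 0.00143
  k_DS_late: 0.02 +/- 0
late/early ratio: 10.77
```

The late rate is pinned exactly (0.02/day, zero spread); the early rate is
only weakly constrained by the small pre-switch fractions, so its accepted
set spreads — exactly why the estimate is reported as mean ± SD over all
accepted sets rather than a single best point. The recovered ratio (~10)
says the dedifferentiation rate jumps an order of magnitude at day 3.

The in-silico sphere assay works the same way from the other readout:

```python
normoxia = load_scenario("normoxia")
print(simulate_mammosphere_rate(normoxia.params,
                                MammosphereProtocol(n_runs=200, seed=5)).summary())
```
```
mammosphere rate 0.925 [95% CI 0.879, 0.957] (185/200 positive)
```

Or end to end from a shell:

```bash
cscplast run-all --outdir results --seed 1 -v
```

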