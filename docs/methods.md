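# Methods

## The cell-kinetic model

`oncokin` models a clinically developed non-small-cell lung cancer (NSCLC)
tumor as a well-mixed population of five cell categories arranged in a
cancer-stem-cell hierarchy:

* **Stem cells** have unlimited mitotic potential. At mitosis a stem cell
  divides symmetrically (two stem daughters) with probability `P_sym`, else
  asymmetrically (one stem, one LIMP daughter).
* **LIMP cells** (LImited Mitotic Potential progenitors) double per
  generation; after `N_LIMP` generations their divisions produce terminally
  differentiated cells.
* **DIFF cells** cannot divide and are lost to apoptosis (rate `R_ADiff`)
  or necrosis (rate `R_NDiff`).
* **Apoptotic** and **necrotic** dead cells remain part of the tumor bulk
  until cleared, with mean residence times `T_A` and `T_N`.

Stem and LIMP cells are either cycling (G1/S/G2/M, total duration `T_C`) or
dormant in G0. Newborn cells with proliferative capacity enter G0 with
probability `P_sleep`; dormancy (hypoxia or absent growth stimuli) lasts
`T_G0` on average, after which a cell re-enters G1 with probability
`P_G0toG1` or dies through necrosis. Cycling and dormant cells undergo
spontaneous apoptosis at rate `R_A`.

Durations are in hours, rates in 1/h. Volume is cell count divided by a
constant cell density (default 10^6 cells/mm^3); every quantity the
estimator uses is a *relative* volume, so results are density-invariant.

### Balanced exponential growth

A fully developed tumor with time-invariant kinetics settles into balanced
exponential growth: all compartments grow as `e^{a t}` with constant
fractions. The intrinsic rate `a` solves the discounted stem-cell renewal
equation

    (1 + P_sym) · [(1 − P_sleep) + P_sleep · P_G0toG1 · κ] · e^{−(a+R_A) T_C} = 1,
    κ = (1/T_G0) / (a + R_A + 1/T_G0),

and the volume doubling time is `T_d = ln 2 / a`. The steady-state
composition follows in closed form from flux bookkeeping: per unit stem
mitosis flux, `1+P_sym` stem and `1−P_sym` first-generation LIMP newborns
are produced; each LIMP generation's newborn flux is amplified by
`2·[(1−P_sleep)+P_sleep·P_G0toG1·κ]·e^{−(a+R_A)T_C}`; terminal mitoses feed
the DIFF pool, whose steady-state size is inflow/(a+R_ADiff+R_NDiff); the
dead-cell pools are inflow/(a+1/T_A) and inflow/(a+1/T_N). The memoryless
(exponential) treatment of G0 residence and dead-cell clearance is not an
approximation bolted onto the model — it is what makes these closed forms
exact, and the simulator uses the same semantics so that the two routes
agree (tested to 0.5% relative).

### Calibration

The macroscopic proliferation profile of a tumor — doubling time `T_d`,
growth fraction `GF` (cycling/living), apoptotic and necrotic fractions
`AF`, `NF` (of total cells) and stem fraction `SF` (of living cells) — is
what pathology and imaging can constrain. Calibration inverts the
balanced-growth relations for the dependent parameters in sequence:

1. `P_sleep` from `T_d` (renewal equation, solved in closed form);
2. `R_NDiff` from `GF` (living-cell balance);
3. `T_A` from `AF` and 4. `T_N` from `NF` (pool balances);
5. `N_LIMP` from `SF`, by minimising the residual of the integer geometric
   sum `Σ_{n<N} 2^n/(1+P_sym)^{n+1} = 1/[(1−P_sym)·N_S/N_L]`.

A profile that demands a negative rate, a fraction outside [0, 1] or a
non-positive clearance time is *unreachable*; `calibrate_full` reports this
as a structured result (with reason codes) because the sampling workflow
uses reachability as a filter, not as an error.

Two calibration modes exist: the baseline mode solves all five dependents;
the sampling mode takes `N_LIMP` (and the stem-cell kill factor) from the
Latin hypercube and solves only the four continuous dependents.

The built-in subtype profiles are: adenocarcinoma `T_d` 225 d, `GF` 0.18,
`AF` 0.01, `NF` 0.02, `SF` 5·10⁻⁵; squamous-cell carcinoma `T_d` 109 d,
`GF` 0.36, `AF` 0.01, `NF` 0.20, `SF` 2·10⁻⁴ — literature-survey averages
for the two histologies. Stem and LIMP kinetics are assumed identical
during calibration; the simulator supports distinct values.

**Reporting convention.** Calibration is carried at full precision
(round-trip invariants hold to 10⁻⁴ on fractions); only *reports* round.
Clearance durations `T_A`/`T_N` are reported rounded **up** to the whole
hour — the simulator's tick — so a report never understates the residence
of death products. `N_LIMP` is inherently an integer (residual minimiser).

## The simulator

Time advances in 1 h ticks (configurable). Cycling cells carry an
intra-cycle age; `T_C` is split into G1/S/G2/M as 0.40/0.39/0.19/0.02
(typical mammalian proportions; configurable). Per tick, in order:
spontaneous losses, mitoses and newborn routing, dormancy and DIFF
turnover, hit-cohort progression, dead-cell clearance. Per-tick
probabilities are `1 − e^{−rate·dt}` for exponential attrition across the
fixed-duration cycle and `dt/T` for the memoryless compartments, so that
survival across the cycle and mean residences are exact, not O(dt)-biased.

Initialization constructs the exact stationary profile of the discrete
update (intra-phase age density proportional to `(e^{−R_A dt}/λ)^{age}`,
with `λ` the per-tick growth factor from the discrete renewal equation), so
free growth is exponential from the first tick; compartment fractions are
stationary to machine precision in expectation mode.

Two modes: **expectation** (deterministic mean propagation; used for all
reported numbers) and **stochastic** (per-transition binomial/multinomial
draws from a seeded generator, with randomised rounding of the initial
state so small compartments are not biased away).

### Chemotherapy

A drug administration is instantaneous. In every proliferative phase the
fraction `min(1, Σ CKR)` of LIMP cells — and `min(1, CKF_stem · Σ CKR)` of
stem cells, modelling stem-cell chemoresistance — is lethally hit,
allocated among the drugs of a doublet proportionally to their kill rates.
Hit cells stop dividing, traverse a rudimentary cycle and join the
apoptotic pool at the drug's death phase: end of S (gemcitabine), end of G2
(cisplatin), end of M (vinorelbine, docetaxel). A cell already past its
death phase completes the current cycle (without dividing) and dies in the
next one. Only cell-cycle non-specific drugs (cisplatin) hit dormant cells;
a hit G0 cell must re-enter the cycle to die, and one that instead exits to
necrosis dies necrotically. Pharmacokinetic delays are neglected: the weeks
between the last administration and the volume endpoint clear the hit
cohorts entirely, so delays of hours to days would not move the estimates.

## Cell-kill-rate estimation

For a clinical case (volumes `V0`, `V1` at two CTs, the administrations in
between, histology), the cisplatin kill rate is the root of

    simulated reduction(CKR_cis) − 100·(V0 − V1)/V0 = 0

on [0, 1] (Brent bracketed root finding, tolerance 10⁻⁶ on the rate;
residual below 10⁻⁴ percentage points), with the partner drug's rate fixed
at `CKR_B` (default 0.2; 0.1 for the one case whose tumor grew, so that a
root exists across the whole parameter sample). The simulated reduction is
strictly increasing in the kill rate, so the root is unique; targets
outside the achievable range yield a classified no-solution result
(`shrinks_without_drug` / `cannot_shrink_enough`). The two drugs of a
doublet cannot be separated from a single reduction — only `CKR_cis` given
`CKR_B`, and hence `CKR_sum`, is identified.

The simulation starts at the first CT. When treatment began before the
first CT (one bundled case, by one day) the clock starts at onset and the
start volume is back-extrapolated along the free-growth exponential. Only
administrations between the two CTs enter the estimation; administrations
between the second CT and surgery enter only the validation simulations.

Patient-specific kinetics are unknown, so the estimate is a distribution:
a Latin hypercube over the independent parameters (shared `T_C` ∈ [18, 134] h,
`T_G0` ∈ [90, 1200] h, `R_A` ∈ [0, 0.001]/h, `R_ADiff` ∈ [0.0001, 0.02]/h,
`P_G0toG1` ∈ [0, 1], `P_sym` ∈ [0, 0.4], `N_LIMP` ∈ {8..24}, `CKF_stem` ∈ [0, 1])
is calibrated per set to the subtype profile; sets are kept only if the
calibration is reachable, `SF` ≤ 10⁻³, `T_A` ≤ 24 h, `T_N` ≤ 200 h,
`R_NDiff` ≤ 0.02/h and the tick-quantized doubling time is within ±10% of
the subtype target. Per case, `CKR_sum` over the surviving sets is
summarised by its median, 10th/90th percentiles and extremes.

Validation extends each surviving simulation to the date of surgery and
compares the distribution of predicted equivalent diameters
(`d = 2·(3V/4π)^{1/3}`; quartiles and 1.5·IQR whiskers) with the resected
specimen, whose volume is approximated by a triaxial ellipsoid
(`V = π/6·a·b·c`) — clinicians size tumors by maximum dimensions, hence
the diameter scale.

## Sensitivity analysis

The output under study is the `CKR_sum` required to shrink a 925 mm³
virtual tumor (12 mm sphere; one week of free growth; three 3-week
cisplatin+gemcitabine cycles with gemcitabine repeated on day 8;
gemcitabine rate fixed at 0.2) by 72% on day 49.

**OFAT**: each parameter is perturbed ±10% (±5% for `P_sym` and `P_sleep`,
whose larger elasticities would otherwise push the tumor outside the
biologically sustainable regime) around a subtype baseline; elasticities
`SM±%` divide the relative output change by the magnitude of the input
change *actually applied* (integer rounding can distort the nominal ±10%),
so a positive input–output correlation shows as `SM₊ > 0 > SM₋`. The
score `SC = |(SM₊ − SM₋)/2| · range/mean` weights the elasticity by the
parameter's variability under a uniform distribution over its range.

**LHS/PRCC**: a Latin hypercube over all 15 free-growth parameters
(uniform marginals, one point per stratum, integers rounded after
rescaling) is filtered to growing, NSCLC-like tumors (`a > 0`,
`T_d` ≥ 26 d, `SF` ≤ 10⁻³); per survivor the scenario `CKR_sum` is
estimated and the partial rank correlation computed: all columns replaced
by average ranks, each input's partial correlation with the output
controlling for all remaining inputs, significance from the t distribution
with `N − 2 − (P − 1)` degrees of freedom at P < .01. A second study uses
the proliferation features at diagnosis (`T_d`, `SF`, `LF`, `GF`, `QF`,
`AF`, `NF`) as inputs; variants replace `SF` by the stem-to-LIMP (`SLF`)
or stem-to-DIFF (`SDF`) ratio, which are near-deterministic functions of
`SF`. Survivor counts are realisations of the sampler's RNG and are
reported, never asserted.

## Synthetic data

`generate_synthetic_case` simulates a subtype-calibrated tumor under a
known `CKR_cis` and packages the volumes as a clinical case, optionally
corrupting both readings with multiplicative lognormal noise (log-sd
`noise_sd`; 0.10 emulates the 10–20% error of CT volumetry). It emulates
the measurement structure of the cohort — two volumes, a schedule, a
histology — but **not** real-data features such as Gompertzian
deceleration, spatially heterogeneous kinetics, time-varying parameters or
segmentation bias; passing recovery tests therefore demonstrates the
estimator's internal consistency and noise behaviour, not clinical
accuracy.

## Numerical choices and problem sizes

* Growth-rate roots are bracketed in a ∈ [−0.1, 0.1]/h (doubling times of
  26–700 d sit well inside) right of the pole at `a = −(R_A + 1/T_G0)`;
  Brent with relative tolerance 10⁻¹⁴.
* Time step 1 h; phase tick allocation by largest remainder with at least
  one tick per phase.
* Expectation mode is bit-reproducible; every CLI run writes a manifest
  (config, seed, version) sufficient to replay it.
* Test and acceptance runs use deliberately scaled problem sizes chosen as
  the smallest that leave conclusions stable: LHS size 8000 for the PRCC
  study (~70 survivors per 1000 sampled; standard error ≈ 0.02 on the
  leading coefficient; the test suite uses 4000, and sizes from 2000 to
  8000 move the coefficient by less than 0.05), 150–300 for subtype
  samples in tests, 30 stochastic replicates for the mean-field comparison.

## Known limitations

* Well-mixed tumor: no voxel grid, shape evolution or distinct metabolic
  regions; relative-volume quantities are unaffected, spatial readouts are
  out of scope.
* Kinetic parameters are constant over the simulated window (months); the
  model addresses neither tumor initiation nor long-horizon Gompertzian
  slowing.
* The phase split of `T_C` shifts only the timing of hit-cell death by
  less than one cycle; CKR estimates are insensitive to it at the
  week-scale endpoints used here.
* Identical baseline profiles within a histological subtype ignore
  inter-patient variability in grade — the dominant caveat for the
  per-case validation.
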