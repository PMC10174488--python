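# Methods

## Population model

The engine propagates expected (real-valued) cell counts through a
three-state cell-cycle network at a fixed 1-hour step, default horizon
72 h (both configurable; the horizon must be an integer number of steps).
Although the underlying biology is a stochastic jump process, the core
engine is deterministic mean-field: the hourly update is linear,
`x(t+1) = A x(t)`, with

```
A = [[1−M1−φ1,   0,      2·M3   ],
     [M1,        1−M2−φ2, 0     ],
     [0,         M2,      1−M3−φ3]]
```

States are indexed 1 = G0/G1, 2 = lateG1/S, 3 = G2/M throughout. The
division factor 2 on the G2/M→G0/G1 edge is a module constant. Death
(`φ_i`) removes cells permanently; the core engine does not track a
dead-cell compartment (the synthetic plate generator accumulates dead
counts separately, since dead nuclei are what the dead-cell stain sees).
Linearity has two useful consequences exploited everywhere: relative cell
counts are independent of the seeding number, and 72-step propagation can
be computed as a matrix power (the vectorized path used in fitting stacks
per-dose update matrices and exponentiates by squaring).

Balanced exponential growth corresponds to the dominant eigenpair of `A`:
the growth factor λ gives the doubling time ln2/lnλ (reported as infinite
when λ ≤ 1, e.g. when a zero transition probability breaks the cycle) and
the normalized dominant right eigenvector is the stationary phase
composition. The eigensystem is the closed-form cross-check for what the
calibration obtains by simulation.

## Growth calibration

Inputs per cell line: doubling time τ_d (hours) and steady-state phase
fractions (renormalized on input; rejected if they miss 1 by more than
1%). The three transition probabilities are fitted by bounded
least squares (`scipy.optimize.least_squares`, bounds [0,1], ftol/xtol/
gtol 1e-12) so that a 72-h simulation from 100 cells split by the phase
fractions reproduces the target `100·e^(72·ln2/τ_d)` cells split the same
way. Residuals are scaled by the target counts so the three states weigh
comparably (the unscaled SSE is reported); the unweighted choice matters
little because the system is exactly identified (three constraints, three
parameters) and the optimum has SSE ≈ 0. Five uniform random starts
(seeded) guard against local minima; a result is flagged unique when the
across-start parameter spread is below 1e-4. Built-in reference
constraints: U87 31.13 h, 0.602:0.235:0.163 (literature extremes
37.1/25.5 h and 0.668:0.263:0.069 / 0.54:0.23:0.23); U251 24.93 h,
0.581:0.225:0.194 (extremes 27.8/23.0 h and 0.716:0.204:0.08 /
0.482:0.237:0.281). `sensitivity_sweep` recalibrates under any set of
constraint variants and re-scores downstream predictions, recording
per-variant failures without aborting.

## Pharmacodynamics

Each drug maps to exactly one state (PD0325901→1, Abemaciclib→2,
TAK-960→3 by default; configurable). Transition inhibition is a Hill
function of dose with parameters EC50 (µM) and n; drug-induced death is a
saturating hyperbola (Hill coefficient fixed at 1) with parameters
E_max,φ (hr⁻¹) and EC50,φ (µM). Doses are handled internally in µM; the
CSV readers convert nM. `effective_rates` enforces `M_i + φ_i ≤ 1`
(cannot trigger for the built-in parameters; guards user input). The
relative cell count divides the treated 72-h total by the untreated
control total, both simulated from the no-drug stationary composition —
the cells settle overnight before dosing, so the population is in
balanced growth when the drug arrives, and by linearity the initial total
cancels. Normalization is to the vehicle control (not the seeded count),
matching saturating single-drug curves that plateau above zero.

One deliberate consequence of per-state death: predicted combination
surfaces are *not* exactly monotone in each dose. Inhibiting an upstream
transition can hold cells out of the partner drug's death state, so at a
high dose of one drug a small dose of the other can raise the predicted
count by up to ~2×10⁻³ in relative-count units for the built-in
parameters. Without death terms the surfaces are strictly nonincreasing;
the tests document both facts.

## Single-drug fitting and model selection

Per drug, (EC50, n) and optionally (E_max,φ, EC50,φ) are estimated by
multi-start bounded least squares against the mean relative count per
dose (replicate-level fitting is available through the data container).
EC50s are bounded to [1e-5, 1e3] µM and optimized in log10 space for
conditioning; n ∈ (0, 10]; E_max,φ is capped so every state's retained
fraction stays nonnegative. Default 20 starts: EC50 starts log-uniform
over the nonzero dose range, n uniform in [0.3, 3], E_max,φ uniform over
its range. Plain (unweighted) SSE is the fit objective; sd-normalized
residuals enter only the likelihood, with each dose's sd floored at 1% of
its mean count to avoid infinite weights. AIC = 2k − 2logL; the pooled
death-vs-no-death comparison counts 24 vs 12 free parameters over the six
cell-line/drug fits, and ΔAIC = AIC(death) − AIC(no death) is negative
when death terms are warranted. Fits are bit-for-bit reproducible given
the seed.

Identifiability caveat, established with the synthetic generator: with
noise-free data all four parameters are recovered to well under 1%, but
at realistic plate noise the EC50 of a shallow-Hill drug (n ≈ 0.5) is
poorly identified — the 4-parameter likelihood is nearly flat along
correlated EC50↔n↔death-term directions — and even for a steep drug
(n ≈ 2.9) the 3.16-fold dose spacing limits EC50 resolution to roughly
half a dilution step. Single-plate EC50 estimates should be treated as
order-of-magnitude for shallow curves.

## Combination prediction and excess over Bliss

Combination surfaces are predicted cell-by-cell with no refitting; the
default 8×8 dose grids are 4-fold series (0, 1.22 … 5000 nM for
PD0325901 and Abemaciclib; 0, 0.012 … 50 nM for TAK-960). Measured grids
are replicate-averaged before comparison (per-replicate comparison is
available); agreement is summarized by Pearson r over the 64 paired
cells.

EOB uses the inhibition effect y = 1 − relative count. A 4PL
`Emin + Emax·(D/EC50)^n / (1+(D/EC50)^n)` is fitted to each of the 8 rows
and 8 columns (16 fits, multi-start, seeded); each cell's fitted
inhibition is the mean of its row- and column-fit values. Parameter
bounds keep fits physically meaningful while tolerating noise: Emin ∈
[−0.5, 1], Emax ∈ [0, 1.5], EC50 within [min nonzero dose/10, max
dose·10], n ∈ (0, 10]. A constant series short-circuits to a flat fit
flagged degenerate. Single-agent inhibitions y_A, y_B are read off the
averaged surface at the zero-dose column/row by default; they can be
supplied explicitly (needed, e.g., to verify that a surface constructed
exactly 0.1 above the Bliss null scores mean EOB = 0.1 — reading
marginals off the shifted surface would shift the null too). The summary
score is the mean EOB over all 64 cells with a between-cell standard
error; because zero-dose cells contribute ≈ 0 and dilute the mean, the
interior mean over the 49 both-nonzero cells is always reported
alongside.

## Synthetic plate generator

The generator emulates the experimental workflow that produced the
reference data: 500 cells seeded per well (multinomially split at the
stationary composition), 72-h endpoint, live count = total-stain count
minus dead-stain count. Single-drug layout: ten doses (nine 3.16-fold
dilutions from 10 µM plus vehicle) × biological duplicate × technical
triplicate. Combination layout: 8×8 grid × biological triplicate.
Cell fate is sampled exactly — each hour every state's cells are
partitioned multinomially among stay/transition/die — so the expectation
equals the deterministic engine (verified to 3 SE over 1000 wells) and
small-well branching noise is present with the correct variance.
Measurement noise, chosen to resemble realistic viability-assay error
bars (the reference experiments report SE bars of a few percent): each
nucleus is detected with probability 0.95, modulated per well by a
lognormal factor with 10% CV (mean 1); dead nuclei are stained only if
still attached, retained with probability 0.5. Relative counts are
normalized to the mean vehicle-control live count within the same
biological replicate. All randomness derives from the single plate seed
via `SeedSequence` spawning in layout order, so identical seeds give
byte-identical plates.

What the generator does not emulate: image segmentation errors with
density-dependent bias, plate-edge and position effects, pipetting
serial-dilution error (dose errors), day-to-day biological drift beyond
the per-well factor, and any model-misspecification — the ground truth
*is* the Markov model. Passing recovery tests therefore demonstrates
estimator correctness and statistical identifiability under the stated
noise, not robustness to real-data systematics.

## Pipeline, formats, reproducibility

Tidy long-form CSV is the interchange format (replicates representable);
an 8×8 matrix CSV export exists for human inspection. Dose 0 is stored as
literal 0; plots place it at a configurable offset on log axes. The
`run-all` pipeline executes calibrate → fit singles → predict combos →
compare → EOB and writes a versioned JSON report plus CSV tables; every
seed and solver tolerance used is recorded in the report, reruns are
byte-identical, and all figures regenerate from the report alone.
Stage-internal seeds are derived from the run seed via CRC32-keyed
`SeedSequence` entropy (stable across processes).

## Problem sizes used in the tests

The suite favors exact small cases: oracle comparisons use single 72-step
trajectories; the stochastic/deterministic agreement test uses 400–1000
wells; the EC50 recovery study uses 50 plates of 60 wells. These sizes
were chosen to make the statistical assertions sharp (3-SE bands, 50
Bernoulli trials) while keeping the default test run fast.

## Known limitations

Fixed three-state cycle (no arbitrary networks), at most one drug per
transition and one transition per drug, simultaneous constant dosing only
(no schedules or pharmacokinetics), no spatial structure or co-culture,
no resistance evolution. EOB is the only synergy metric (no Loewe, HSA,
ZIP, or Chou–Talalay). Calibration provides multi-start spread, not
uncertainty intervals.
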