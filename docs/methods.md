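# Methods

`navclamp` regenerates, as tested software, the functional-genetics arm of a
case-control study of the skeletal-muscle sodium channel NaV1.4 (gene
*SCN4A*): whole-cell voltage-clamp recordings of wild-type and rare-variant
channels in a heterologous expression system, extraction of seven gating
parameters per cell, variant-vs-wild-type statistics under a family-wise
Bonferroni threshold, functional classification, and the rare-variant
carrier burden tests in 278 cases vs 729 controls.  No raw recordings were
deposited for the study, so the package's synthetic-data generator defines
the study conditions: it simulates cohorts whose measured parameters match
the published per-variant means, standard errors and sample sizes.

## Channel model

The simulator uses the minimal Hodgkin–Huxley scheme that reproduces the
measured quantities: whole-cell current

    I(t) = gmax · C · m(t)^p · h(t) · (V − E_rev),        p = 3 by default,

with activation gates `m` and one fast-inactivation gate `h` relaxing
exponentially toward voltage-dependent steady states,
`dm/dt = (m∞ − m)/τ_m`, `dh/dt = (h∞ − h)/τ_h`.  Within each
constant-voltage epoch these have exact solutions, so sweeps are integrated
in closed form; the only discretisation is the sampling grid itself, and the
simulator refuses a sample interval coarser than one fifth of the fastest
time constant it would need to represent.

Steady states are Boltzmann curves.  Because the experimentally fitted
object is the *open-probability* voltage dependence, the single-gate steady
state is defined as the p-th root of the activation Boltzmann,
`m∞(V) = B_act(V)^(1/p)`; the availability gate uses the decreasing
Boltzmann directly.  In the instantaneous-gating limit the peak-conductance
curve then equals `B_act` and the availability curve equals `B_inact`
exactly, which is what the oracle tests assert.

Time constants: `τ_h(V)` is pinned at the two voltages the study measures —
the open-state decay at 0 mV and recovery at −80 mV — and log-linearly
interpolated in voltage between them, clamped outside.  `τ_m(V)` is 0.2 ms
at 0 mV with a mild bell-shaped voltage dependence around the activation
midpoint (floor 55% of the peak value); it is deliberately fast so that the
peak current approximates a conductance readout.  Defaults: `E_rev` +65 mV
(physiological Na⁺ reversal; the recording solutions were not published),
sampling 0.02 ms (50 kHz), additive white Gaussian current noise of 10 pA,
no leak or capacitive transients (published traces are shown subtracted).

## Protocols

Three epoch-based protocols, holding −80 mV throughout:

* **activation** — 20 ms steps from −100 to +50 mV in 10 mV increments
  (16 sweeps);
* **availability ("inactivation")** — 150 ms prepulses from −150 to 0 mV
  followed by a 10 ms tail step to −10 mV; tail peaks are measured in the
  first 5 ms;
* **recovery** — paired 10 ms pulses to 0 mV separated by a variable
  −80 mV interval of 0, 1, 2, 5, 10, 20 ms plus 30 and 50 ms (the published
  ladder shows six durations; the two longer points anchor the fit
  asymptote).  Sweeps are padded at the tail so the sweep matrix stays
  rectangular; the zero-length interval makes the second pulse follow the
  first immediately.

## Measurement pipeline

Mirrors standard patch-clamp practice: baseline (pre-step mean) subtracted
signed peaks; current density = peak at 0 mV / capacitance; reversal voltage
from a linear fit of the I–V limb at V ≥ +20 mV extrapolated to zero current
(falling back to the configured +65 mV when the limb is unusable); chord
conductance `G = I/(V − E_rev)` excluding points within 5 mV of reversal;
four-parameter Boltzmann fits (plain least squares, data-driven
initialisation, honest convergence flags); normalisation to fitted
asymptotes for cohort averaging.

Exponential fits use variable projection: time constants are searched on a
log grid and polished from the best few starts while offset and signed
amplitudes are solved linearly at every step.  This is immune to the
amplitude blow-up that degenerate fully-nonlinear biexponential fits suffer,
and it recovers exact parameters on noiseless data to 1e−6.  The onset of
fast inactivation is fitted with two components on the decay starting
0.2 ms after the 0 mV peak; the reported constant is the fastest component
whose amplitude has the decaying sign — the opposite-signed fast residual of
activation is thereby excluded, matching what an experimenter calls "the
fast component".  Recovery is fitted as `P2/P1 = 1 − a·exp(−Δt/τ)` with the
asymptote fixed at full recovery and `a` free.

Quality control follows the study's two tiers: cells enter the density tier
above 0.1 nA peak current, and the biophysics tier above 0.5 nA with a
series-resistance error (`|I_peak|·R_s`) below 5 mV.  Series resistance is
modelled as a QC quantity only, not as a command-voltage distortion — the
published analysis treats it the same way, and keeping the simulator linear
preserves the exact-peak oracles.  Summaries report mean and SE = SD/√N per
parameter over the appropriate tier.

## Calibration: parameters live in measurement space

Peak-based measurements are biased relative to the underlying steady-state
curves because activation and inactivation overlap in time (with the default
kinetics the raw bias on the activation midpoint is several mV — the same
bias real recordings carry).  The study specifies variant effects only as
measured values, so cohort means are defined in measurement space: for each
cohort the generator solves a small inverse problem, adjusting the latent
Hodgkin–Huxley parameters (quasi-Newton root solve with a damped fixed-point
polish) until the standard analysis of one noiseless simulated cell
reproduces the seven target values exactly (≤0.02 mV on midpoints and
slopes, ≤0.5% on time constants and density).  Per-cell draws are made
around the calibrated latent means — normal for voltages, mean-preserving
log-normal for positive quantities — with coefficients of variation set so
that the cell-to-cell SD equals `SE·√N` at the published N; the published
standard errors are then reproduced at the published sample sizes.  Wild-type
SEs printed as 0.0 (availability slope, onset τ) are below printed precision
and are taken as half the rounding unit (0.04 mV, 0.004 ms).  Capacitance is
15 ± 4.5 pF and effective (compensated) series resistance 0.8 ± 0.25 MΩ,
typical for HEK293 recordings; with the wild-type density this reproduces
the study's small attrition between the density and biophysics QC tiers.
Cohorts simulate the density-column N cells, with the recovery protocol
recorded only in the first N_recovery cells, matching the per-parameter N.

## Statistics

Every variant × parameter cell is compared against wild type with one of the
two post-hoc schemes the study names, against a fixed Bonferroni threshold
`α/(n_variants · n_parameters)` = 0.05/98 ≈ 0.00051 (applied as a threshold
on raw p-values, not as p-value multiplication):

* **Kruskal–Wallis + Dunn** — pooled-rank z against the control group with
  tie correction, two-sided normal p.  Default for the right-skewed positive
  parameters: peak current density and the two time constants (generated
  log-normally; rank-based comparison is the field's standard for such
  quantities).
* **ANOVA + Games-Howell** — Welch-type statistic with Welch–Satterthwaite
  degrees of freedom referred to the studentized-range distribution with
  k = 15 groups (`q = |t|·√2`; the CDF is scipy's numerical quadrature).
  Default for voltages and slope factors, which are generated normally.

The study used both schemes without stating the assignment; the default
mapping above is the package's distribution-based choice and a single-scheme
override is a config field.  With two groups Games-Howell reduces exactly to
Welch's t-test, which the tests assert.

Classification applies the study's logic in precedence order: no significant
parameter → wild-type-like; any significant inactivation-impairing change
(depolarised availability midpoint, faster recovery, slower onset, increased
availability slope) → gain of function, winning over coexisting
loss-of-function evidence (recorded as a conflict); otherwise significant
density reduction, hyperpolarised availability or slower recovery → loss of
function.  A significant change fitting neither pattern (e.g. an isolated
activation-slope change) does not alter the call.

## Burden tests

Variants qualify when novel or with ExAC allele frequency strictly below
5·10⁻⁵.  Carrier-level tests tally carriers per cohort (each study variant
had exactly one carrier; multi-variant carriers would be collapsed to one)
and compute the one-tailed Fisher exact p — the hypergeometric upper tail
P(X ≥ a) with fixed margins, enrichment direction = cases.  Selectors: all
rare variants; functionally disruptive only; and a sensitivity mode counting
the control intronic variant as deleterious.  The variant-level test counts
disruptive variants among the rare variants per cohort; the control
denominator includes the intronic variant (nine control variants), the only
reading that reproduces the published p = 0.011, which the enumeration
oracle confirms.

## What the synthetic data does and does not emulate

Emulated: cohort sizes and per-parameter N, cell-to-cell biological spread
matching the published SEs, capacitance/series-resistance variability,
recording noise, peak-measurement kinetic bias, and the QC attrition
structure.  Not emulated: leak and capacitive transients, P/N subtraction,
voltage-command errors from series resistance, transfection-batch effects,
temperature, slow inactivation, and any Markov-scheme gating beyond m³h.
Passing tests therefore show that the measurement and inference pipeline
recovers known ground truth under realistic variability — not that the
simple gating model captures every feature of real NaV1.4 recordings.

A note on reproducing the published significance pattern: when cohorts are
generated from the printed means and SEs alone, one published significant
cell (the Ser682Trp activation-slope change: Δ = 0.8 mV against summed SEs
of ~0.22) cannot reach p < 0.00051 under either scheme — its star must
reflect features of the original raw data beyond the printed summary.
Several further cells are intrinsically borderline at these effect sizes:
the Val1442Met and Arg1463Ser availability midpoints under Games-Howell
(small Welch df against k = 15), and the Glu1520Lys onset constant and
Met1493Val density under the rank test, which cross the threshold in a
minority-to-half of replicates.  An exact whole-pattern match across all 98
cells in a single replicate is therefore essentially unattainable from the
printed summaries.  The validation routines report per-cell majority
agreement across replicates alongside the exact-pattern match rate, and the
acceptance suite records this limit honestly rather than relaxing the
comparison.

## Problem sizes and numerics

Validation runs use 20 full-pipeline replicates of all 15 cohorts at the
published sample sizes (~376 cells each) for the significance pattern, and
1000 parameter-level replicates for the family-wise error rate (measurement
noise is negligible beside the cell-to-cell spread there, so traces are not
re-simulated; Games-Howell significance is decided against critical values
precomputed on a degrees-of-freedom grid).  Fit tolerances: Boltzmann and
exponential parameter recovery on noiseless data to 1e−6; calibrated
cv=0/noise=0 round trips to ≤0.2 mV on midpoints and ≤2% on time constants.
Degenerate inputs (constant traces, zero-conductance cells, all-zero I–V
limbs, sub-threshold P1 amplitudes) are flagged and propagated as notes
rather than silently dropped.
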