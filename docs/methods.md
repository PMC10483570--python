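# Methods

## Scope and model family

`spikebench` implements nine classical single-neuron spiking models — leaky
integrate-and-fire (LIF), non-linear IF (NLIF), adaptive exponential IF
(AdEx), IF with spike-frequency adaptation (IF-SFA), theta neuron,
Hodgkin–Huxley (HH), quadratic IF (QIF), Izhikevich, and the spike response
model (SRM) — as one-step update kernels, and three experiments over them:

1. a **pulse-response trace experiment** (membrane potential and spike raster
   under an input-current pulse),
2. a **two-class spike-classification benchmark** on a synthetic Gaussian
   dataset, with accuracy, error rate and a pairwise performance-loss matrix,
3. **arithmetic-operation accounting** of each model's update rule.

There are no networks, no synaptic connectivity beyond the SRM's own kernel,
and no learning rule of any kind: the benchmark probes the *intrinsic*
input-to-spike transfer of each model under fixed parameters.

## Integration scheme and spike convention

All models advance by **explicit forward Euler** at the regime's fixed time
step; there is no adaptive or event-driven stepping, so spike times are
quantized to the grid. A membrane potential **at or above** threshold emits a
spike (ties spike), after which the stated reset rule of the model applies.
Models with a refractory period hold the membrane at the reset value for
`round(tau_ref / dt)` steps, decremented before each update; no spike can be
emitted while the counter is positive. Each emitted spike carries a per-model
plotting amplitude (e.g. 0.7 for NLIF, 0.9 for AdEx); it is cosmetic metadata
only and never enters any computation.

Every kernel is written elementwise, so a state may hold scalars (one neuron)
or equal-shaped arrays (a batch of independent neurons stepped in lockstep).
The batch path is the same arithmetic as the scalar path — a test asserts
their equality — and is what makes the 1.8-million-neuron-windows benchmark
run in about two seconds.

## The two parameter regimes

Each model exists in two printed formulations with different parameter sets,
kept as explicit variants:

* **Benchmark regime** (`table3`, variant A; dimensionless units, thresholds
  near 1, `dt = 0.1`): the simpler single-equation forms, used by the
  classification benchmark.
* **Trace regime** (`table2`, variant B; time in ms, potentials in mV): the
  forms with membrane resistance/leak conductance, adaptation currents and
  refractory periods, used by the pulse experiment.

The regimes ship as YAML documents whose keys mirror the source parameter
tables row-for-row; "not applicable" cells are absent keys and are never
required. QIF is special: its benchmark column (`tau`, `beta`) parameterizes
the genuinely quadratic rule `dV/dt = (-V + beta*V^2 + I)/tau` (variant C),
which the benchmark therefore uses; its trace column parameterizes the linear
drive `dV/dt = (-V + C_m*I)/tau_ref` with a refractory hold (variant B).
The conductance-driven QIF form (variant A) is implemented but not
parameterized by either regime.

### Filled gaps in the regimes

A few cells the regime tables leave open had to be fixed once; they are
package defaults, documented here:

* **HH spike-detection threshold (benchmark regime).** The benchmark column
  prints none; the only printed HH threshold anywhere is **−66 mV** (trace
  regime), *below* the −65 mV reset/initial potential. We adopt it for the
  benchmark as well. Consequence: the benchmark HH emits a "spike" every
  step, i.e. it is a degenerate constant predictor — which is exactly the
  behaviour consistent with its chance-level benchmark accuracy. Had we
  instead used the field-standard 0 mV detection criterion, the benchmark HH
  would fire single spikes for step currents above ≈ 2.3 (we measured this)
  and become a ≈ 87 % classifier, a qualitatively different unit. Tests of
  HH *membrane dynamics* (resting stability, gating bounds) construct the
  model with an explicit 0 mV detection level, since those properties
  presuppose a suprathreshold detection criterion.
* **Izhikevich initial recovery value (trace regime):** not printed; we start
  `u` on its nullcline, `u0 = b * V_init`, so the recovery variable begins in
  equilibrium with the membrane.
* **Theta-neuron sinusoid (benchmark regime):** no amplitude/frequency/phase
  are printed, so the theta-rhythm current defaults to zero and the benchmark
  theta neuron degenerates to a plain leaky integrator.
* **SRM time constants (benchmark regime):** the column prints a single
  `tau = 0.3`, which is taken as the synaptic/membrane constant `tau_s`
  appearing in both the `s` and `V` updates, and an explicit `tau_r = 10`
  for the refractory-response variable.

## Hodgkin–Huxley details

The gating rates are the canonical squid-axon forms (resting at −65 mV); the
benchmark regime's printed initial gating values (n = 0.3177, m = 0.0529,
h = 0.5961) are exactly that system's resting equilibrium, which is what
justifies this choice — no rate functions are printed anywhere. The removable
singularities of the `x / (1 − exp(−x/10))` terms at V = −55 and −40 mV are
evaluated by their limit values. Gating variables are clamped to [0, 1] after
every update.

The membrane equation is integrated in the standard current-balance sign
convention, `C_m dV/dt = I − I_Na − I_K − I_L` with `I_x = g_x·(gates)·(V −
E_x)`. Summing the `(V − E)` currents with a *plus* sign (as one printed
variant of the equation does) makes the resting state an unstable fixed point
and the integrator diverges from rest; the package uses the stable, physical
convention, under which the benchmark-regime HH sits within 0.002 mV of
−65 mV over 1,000 steps.

A caveat for the trace regime: its HH column specifies `dt = 1.5 ms`, far
beyond the forward-Euler stability limit for HH (~0.01–0.1 ms). The trace is
reproduced as configured — the constant resets at the −66 mV detection level
keep the state bounded — but it is a numerical artifact, not squid-axon
physiology; we keep it because the trace experiment's purpose is to reproduce
the configured behaviour, not to solve HH accurately.

## Numerical edge cases

* **Exponential overflow (AdEx).** For strongly suprathreshold states the
  exponential term overflows double precision; a non-finite candidate
  potential is treated as a spike (in exponential IF models the divergence
  *is* the spike) and the reset keeps the state finite.
* **Non-finite inputs.** A kernel receiving a non-finite membrane potential
  or input current raises a numeric-overflow error; the trace runner converts
  this into an abort that reports the offending step index.
* **Determinism.** Every stochastic element (dataset draws, population
  weights, QIF noise) comes from an explicitly passed seeded generator;
  identical configuration and seeds give bit-identical spike records.

## Synthetic dataset

The benchmark's sole data source is a balanced scalar two-class problem:
`n_per_class` features from Normal(0, 1) labelled 0 and `n_per_class` from
Normal(3, 1) labelled 1, shuffled by a single seeded permutation applied
jointly to features and labels. With three standard deviations between the
means, the optimal single-threshold classifier (threshold 1.5) attains
`Φ(1.5) ≈ 93.32 %` accuracy — the ceiling against which the spiking
classifiers are read. (A printed two-column feature layout exists in the
source description but is inconsistent with its own label-vector length; the
scalar reading is the only self-consistent one and is what the benchmark
uses. The two-column matrix is exposed as `LabeledDataset.feature_matrix()`
for completeness and used nowhere.)

The generator emulates *none* of the structure of real sensory data: no
temporal structure, no correlations between features, no class imbalance, no
label noise. Passing the benchmark therefore says how a model's
constant-current input-to-spike threshold relates to the class separation —
nothing more.

## Benchmark protocol

The source experiments state inputs and spike outputs but not the drive
protocol or the spike-to-label rule; the package fixes both, once:

* **Drive (unit mapping, default):** each sample's feature is applied as a
  constant current to a freshly initialized neuron for **100 steps** at the
  regime `dt`; the prediction is class 1 iff the neuron spikes at least once.
  State never carries over between samples. This is the simplest protocol
  consistent with "same inputs to every model".
* **Population mapping (optional):** 1,000 neurons per sample with input
  weights drawn from Normal(0, 1) under a stated seed; prediction is class 1
  iff more than half the population spikes.
* **Seeds:** accuracies are means over 10 dataset seeds; the variance of the
  mean shrinks at the usual 1/√10 rate (tested).

Accuracy is `100 · mean(predictions == labels)`; the error rate is defined as
its complement `100 − accuracy` (a single consistent scale). The performance
loss of model A against reference B is the relative accuracy difference
`L(A,B) = 100 · (acc_A − acc_B) / acc_B`, with an inapplicable diagonal;
`L(A,B)` and `L(B,A)` always carry opposite signs.

### What the benchmark shows

Under this protocol a model's accuracy is essentially determined by its
*effective input threshold* — the smallest constant current that elicits a
spike within the window — relative to the optimal 1.5:

| behaviour | models | mean accuracy |
|---|---|---|
| effective threshold ≈ 1.1 | IF-SFA, theta (≡ LIF here), LIF | ≈ 92 % |
| effective threshold ≈ 0.55 | QIF | ≈ 89 % |
| effective threshold ≈ 0.2 (the `tau·I` drive term) | AdEx | ≈ 79 % |
| constant predictors (always fire: Izhikevich, HH; never fire: NLIF) | — | 50 % |
| spikes only on strongly negative inputs | SRM | ≈ 42 % |

Two of these deserve a note. The AdEx benchmark form multiplies the input by
the membrane time constant (`tau·I` with `tau = 4`), making it four times
more input-sensitive than LIF — under a constant-current drive this
*necessarily* places AdEx below the LIF family, whatever the window. And the
SRM membrane equation integrates the input current with a **negative** sign
(printed twice in its source formulation, and implemented as printed), so
only class-0 samples with feature ≤ −1 make it fire; on balanced classes
that yields below-chance accuracy, ≈ 42 %. Neither behaviour can be changed
without rewriting the printed equations, and the package does not.

## Operation accounting

Per-step costs are tabulated from the source's itemized English descriptions
(LIF: 1 multiplication, 1 subtraction, 1 comparison; HH: 18 additions, 15
multiplications, 3 divisions; and so on) in a single table,
`spikebench.ops.PER_STEP_COSTS`. `counted_step` performs the ordinary update
and returns the tabulated delta; `count_run` accumulates it over a run and is
exactly linear in the step count, since every tabulated cost is
state-independent (spike-reset branch costs are not itemized in the source
and are not counted). The source also prints per-model run *totals* whose
generating convention (per neuron? per population? per run?) is internally
inconsistent — its cheapest-model and most-expensive-model claims contradict
each other — so those totals are recorded nowhere as expectations: the
package reports its own tallies and leaves cross-convention comparisons
alone. Wall-clock and memory profiling are deliberately out of scope
(hardware-dependent).

## Problem sizes

Default experiment sizes, chosen to match the stated study conditions:
benchmark 1,000 samples per class × 10 seeds × 100-step windows (about 1.8 M
neuron-steps per model, ~2 s for all nine, vectorized); trace runs 1,000
steps; dataset property checks use 10,000 samples per class and the
Monte-Carlo reference check uses 10⁶ samples.

## Known limitations

* Forward Euler at the configured `dt` is first-order; spike times are
  accurate only to O(dt) (the LIF interspike-interval test quantifies this
  against the closed form `tau·ln(RI/(RI − V_th))`).
* The trace-regime HH configuration is integrated far beyond Euler's
  stability limit (see above) and is a configured reproduction, not a
  reference HH solution.
* The benchmark's spike-to-label mapping is a protocol choice; accuracies of
  the mid-table models move substantially under other defensible drive
  protocols (e.g. shorter windows raise every effective threshold), so only
  the degenerate (chance-level) behaviours and the threshold-ordering logic
  are robust conclusions.
* Single neurons only; nothing here measures network effects, temporal
  coding, or learning.
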