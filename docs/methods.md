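# Methods

## Setting

Acceleromyographic train-of-four monitoring produces one TOFR reading every
15 s while a patient recovers from a nondepolarising neuromuscular blocker
(here cisatracurium, whose organ-independent Hofmann elimination makes the
recovery profile comparatively stereotyped). A reading of 90 (on the 0–100 %
scale used throughout) marks adequate recovery. The package forecasts the
next reading from the four most recent ones, and — because a model cannot be
trained for a patient who is already on the table — transfers pre-trained
models between demographically similar patients.

## Synthetic cohort model

Clinical recordings are not redistributable, so cohorts are simulated. Each
virtual patient has a latent noiseless recovery curve

    TOFR(t) = t_max / (1 + exp(−(t − t50)/s)),

a logistic sigmoid chosen as the minimal monotone block-to-recovery shape
with a closed-form inverse. Parameters per patient:

* `n` ~ UniformInteger(119, 228) samples on the 15-s grid (30–57 min).
* `age` ~ Uniform(18, 75) years, `bmi` ~ Uniform(18, 35) kg/m² — the
  inclusion ranges of the emulated cohort; uniform because no demographic
  table is available to fit.
* `s = slope_base · exp(ε)`, ε ~ N(0, slope_sd²); `slope_base = 9` min,
  `slope_sd = 0.1`. Nine minutes places the recovery transition across the
  recording so that both the first (training) and second (test) halves
  contain curve structure, matching recordings in which recovery occupies
  most of the monitored window; a much faster sigmoid would confine the
  entire rise to the test half and make first-half training vacuous.
* The end value `e` ~ Uniform(90, 100); `t50` is solved in closed form so
  the noiseless curve equals `e` at the final sample time `(n−1)·15 s`, then
  shifted by the demographic terms
  `β_age·(age − 50) + β_bmi·(bmi − 25) + N(0, patient_sd²)`
  (defaults 0.15 min/y, 0.25 min·m²/kg, 2 min). Positive shifts prolong
  recovery, the direction reported for elderly patients. The shifted `t50`
  is finally capped at the value for which the noiseless end equals 90, so
  the clinical exclusion rule (end-of-surgery TOFR ≥ 90) holds by
  construction. The demographic shift is applied *before* the cap: similar
  (age, BMI) must give similar dynamics, which is exactly the structure the
  transfer experiments probe. The cap saturates rather than erases the
  shift, so the demographics→dynamics map stays monotone.
* Observations add N(0, noise_sd²) noise (default 1.5 TOFR points,
  acceleromyography-scale jitter), clipped at 0 only (devices can read
  slightly above 100). Each sample is missing independently with
  `missing_rate` (default 0.05) except the final sample, kept observed so
  the end-value rule is checkable.

With noise, patient effects and β terms all zero, demographics and length
fully determine the series — the limit in which similarity transfer is
exact.

The "strong covariate" configuration used by the transfer direction-of-
effect experiments sets β_age = 0.8, β_bmi = 1.2, patient_sd = 0.5,
slope_sd = 0.05, noise_sd = 0.5, missing_rate = 0.02: demographics dominate
the dynamics, noise is small, and the question reduces to whether the donor
selection rule finds the right donors.

What the generator does **not** emulate: pharmacokinetic compartments or
top-up dosing (curves are single monotone recoveries), device recalibration
artefacts, non-stationary noise, or any empirical joint distribution of age
and BMI. Passing tests therefore demonstrate that the pipeline recovers the
structure this generator puts in — demographic similarity implying curve
similarity — not that the effect exists, or has this magnitude, in clinical
data.

## Preprocessing

Each series is split into a first half of ⌈n/2⌉ samples for training (the
ceiling favours training data on the shortest sequences; configurable) and a
raw second half for testing. Missing values in the training half are filled
by linear interpolation on the index grid, with constant extension at the
edges; the operation is idempotent and exact on affine segments. Missing
values in the *test* half are never interpolated: interpolation would use
future samples. Instead, missing test targets are excluded from RMSE, and
missing lag values are causally filled with the most recent observed value.
Supervised patterns use 4 lags → 1 target (so a series of length m yields
m − 4 patterns), and all values are scaled by the constant 100 — a common
scale across patients is required for cross-patient transfer to be
meaningful, unlike per-patient min–max scaling. RMSE is always reported
unscaled.

## Sequence models

Three one-step predictors share the same skeleton: a single recurrent layer
(32 units) over the 4-step window, followed by a **bounded residual head**

    x̂_{t+1} = x_t + 0.05 · tanh(w·h_T + b)      (scaled units),

i.e. the network predicts an increment of at most ±5 TOFR points per 15-s
step — above the steepest physiological recovery rate. Anchoring the
prediction at the last lag means an uninformative hidden state degrades the
model toward the persistence baseline rather than toward an arbitrary level,
which matters because the training half of a recovery curve covers only the
lower part of the TOFR range the test half visits. Each time step feeds the
cell two features: the scaled level and its within-window first difference
(the local trend, which generalises along the curve; the level keeps the
model sensitive to where on the curve it operates, preserving the transfer
signal).

Cells are the standard formulations (simple tanh RNN; GRU with update/reset
gates; LSTM with forget-gate bias initialised at 1). Training minimises MSE
with Adam (lr 1e-3, batch 16, 200 epochs), with the global gradient norm
clipped at 1.0. There is no validation split or early stopping: with ≤ 110
training windows a further split is noise, and a fixed epoch count keeps
runs deterministic. Cells, backpropagation through time and Adam are
implemented directly in numpy in float64; the analytic gradients are checked
against central finite differences in the test suite, and training is a pure
function of (windows, spec incl. seed). Weight initialisation is Glorot
uniform (input and output maps) and orthogonal (recurrent maps).

Forecasting is strictly walk-forward: the prediction at test index t uses
the four causally filled observed values ending at t − 1 (spanning the
train/test boundary for the first test points) and never the model's own
previous predictions. A recursive multi-step mode is deliberately absent
from every evaluation path. The persistence baseline (predict the previous
observed value) is the internal sanity floor; on smooth synthetic recoveries
every model kind must undercut it.

## Transfer

Donor selection: among candidates within |Δage| ≤ 2 years, take the one
minimising |ΔBMI|; ties break by smaller |Δage|, then lexicographically
smallest patient id (the tie-break is an implementation convention — any
deterministic rule would do). When no candidate falls inside the age window
the nearest-age candidate is used and a warning is logged; a hard failure
would leave age-isolated patients undefined under leave-one-out evaluation.
Thresholds are inclusive ("within 2 years" read as ≤ 2) with an `inclusive`
flag. Transferred models are used exactly as trained — no fine-tuning of any
parameter. The random-donor baseline draws uniformly from the pool,
deterministic per seed.

## Evaluation

RMSE over the observed test-half targets is the sole metric. Group summaries
report mean ± sample standard deviation (ddof = 1; a singleton group reports
std 0). The pairwise experiment scores every *ordered* (target, donor) pair
(an `ordered=False` flag de-duplicates), partitions pairs by
|Δage| ≤ 2 y AND |ΔBMI| ≤ 3 kg/m², and compares the groups with Welch's
two-sided t-test (the safe default under unequal group sizes and variances;
Student's variant by flag; two zero-variance groups with equal means define
t = 0, p = 1). The leave-one-out experiment holds out each patient, selects
the similarity donor and `n_random_draws` random donors (default 10,
averaged), and compares the two arms. Donor predictors are always the ones
trained on the donor's own first half and are shared across experiments, so
the similarity arm of the leave-one-out run reproduces the corresponding
pairwise entries exactly — an internal-consistency invariant the tests
assert. Per-patient failures are logged and skipped, not fatal; skip counts
appear in every report.

Seeds: a master seed is hashed (BLAKE2) with stage names and patient ids
into per-stage 31-bit seeds, so no stream is reused across patients and
every report is a deterministic function of the master seed. Reports carry
the full configuration echo and all seeds, and exclude timestamps so that
repeated runs are byte-identical.

## Problem sizes

The bundled acceptance script runs the per-patient experiment on an
83-patient cohort (all three kinds), the transfer experiments on 40-patient
strong-covariate cohorts, and the direction-of-effect comparison across 10
replicate cohorts with 10 random draws per held-out patient — sizes chosen
to exercise the full pipeline at cohort scale while completing in minutes on
a single CPU.

## Known limitations

* The logistic curve is a stand-in, not a pharmacodynamic model; no
  compartments, no Hofmann-elimination kinetics, no re-dosing.
* Network hyperparameters are fixed, stability-oriented defaults for
  ~60–114-window training sets, not tuned optima; no architecture search.
* Demographics influence predictions only through donor selection, never as
  model inputs.
* Bitwise reproducibility holds for a fixed numpy/BLAS build; across
  builds, forecasts agree only to floating-point tolerance.
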