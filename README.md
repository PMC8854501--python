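# tofcast

Real-time, patient-specific forecasting of the **train-of-four ratio (TOFR)**
during recovery from cisatracurium-induced neuromuscular block.

## The problem

During general anaesthesia, acceleromyographic TOF monitoring delivers a new
TOFR reading every 15 s, but each reading only describes the *current* depth
of block. Anaesthesiologists would rather know where the recovery curve is
heading — whether the patient will reach adequate recovery (TOFR ≥ 90 on the
0–100 % scale) in time, or whether a top-up dose or a reversal agent is
needed. `tofcast` treats the per-patient TOFR recording
`X = {x₁, x₂, …, xₙ}` as a temporal sequence and provides:

* **One-step-ahead recurrent predictors.** Small recurrent networks (simple
  RNN, GRU, LSTM; one 32-unit recurrent layer and a bounded residual output
  head, trained with Adam on MSE) map the four most recent samples to the
  next one. Forecasting is walk-forward: every prediction re-anchors on the
  latest observation, never on the model's own previous output.
* **Transfer learning by patient similarity.** A patient under anaesthesia
  cannot wait for their own model to be trained, so a pre-trained model is
  borrowed from the most similar previous patient — first restricting donors
  to within a 2-year age difference, then choosing the minimum |ΔBMI| — and
  applied *without retraining*.
* **A synthetic cohort generator.** Real recordings are not redistributable,
  so the package ships a generator of virtual patients whose logistic
  recovery curves are modulated by age and BMI, sampled on the 15-s grid
  with lengths 119–228, observation noise, sporadic missing values, and a
  noiseless end value ≥ 90 (mirroring the clinical exclusion rule).
* **Three evaluation experiments.** (1) per-patient self-forecasting of the
  second half of each series after training on the first half, scored by
  RMSE = √((1/n)Σ(xᵢ−x̂ᵢ)²); (2) all ordered donor→target pairs, grouped
  into demographically similar (|Δage| ≤ 2 y and |ΔBMI| ≤ 3 kg/m²) vs
  dissimilar pairs and compared with a Welch t-test; (3) leave-one-out
  transfer comparing the similarity-selected donor against randomly chosen
  donors.

## Worked example

```python
from tofcast import GeneratorConfig, ModelSpec, generate_cohort
from tofcast.evaluation import run_per_patient, run_persistence

cohort = generate_cohort(GeneratorConfig(n_patients=10, noise_sd=0.0,
                                         missing_rate=0.0, seed=11))
gru = run_per_patient(cohort, ModelSpec(kind="GRU", seed=7))
naive = run_persistence(cohort)
mean, std, n = gru.group_stats["all"]
print(f"GRU   one-step RMSE: {mean:.3f} ± {std:.3f}  (n={n})")
print(f"naive one-step RMSE: {naive.group_stats['all'][0]:.3f}")
```

prints

```
GRU   one-step RMSE: 0.314 ± 0.201  (n=10)
naive one-step RMSE: 0.400
```

i.e. on a noiseless 10-patient cohort the GRU's mean one-step error over the
unseen second halves is 0.31 TOFR percentage points, below the 0.40 of the
persistence baseline (predicting the previous value) — the model has learned
the recovery dynamics rather than merely echoing the last reading.

The same pipeline runs from the shell:

```bash
tofcast generate --n-patients 83 --seed 1 --outdir data/
tofcast run-all --demographics data/demographics.csv --series data/series.csv \
        --kind GRU --kind LSTM --seed 1 --outdir reports/
```

Each experiment writes a JSON report with per-patient RMSEs, group
mean ± SD, and (for the pairwise experiment) the Welch t-test comparing
similar with dissimilar donor pairs. Reports carry the full configuration
and all seeds, and identical invocations produce byte-identical files.

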