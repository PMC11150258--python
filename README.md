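# softsensor

Adaptive soft sensing for fed-batch bioprocesses. The package combines:

- **`softsensor.fermsim`** — a fed-batch penicillin fermentation simulator
  (Monod-type growth with substrate/oxygen limitation, substrate-inhibited
  product formation, proportional pH/temperature control). Each batch yields
  15 hourly process variables (actuator flows, concentrations, pH,
  temperature, heat) plus the product-concentration target; multi-batch
  campaigns vary initial conditions and can add measurement noise.
- **`softsensor.features_kernel`** — grouped random feature layers, random
  Fourier feature (RFF) maps whose inner products approximate an RBF kernel,
  exact RBF Gram matrices, and ridge "autoencoder" weights linking feature
  nodes to the kernel block.
- **`softsensor.models`** — three flat, closed-form-trained regressors
  sharing one pipeline (standardize → random feature layer → hidden block →
  ridge/pseudo-inverse output weights): `bls` (random enhancement nodes),
  `kbls` (exact kernel block) and `akbls` (RFF-approximated kernel block).
- **`softsensor.adaptive_ensemble`** — a stacking ensemble of three base
  models with out-of-fold meta-features and a Gaussian-process meta-learner,
  plus a moving-window driver that re-fits the stack along a time-ordered
  test stream with configurable feedback (self-labeled predictions, delayed
  true labels, or none).
- **`softsensor.evalcli`** — R²/RMSE metrics, exhaustive 5-fold CV
  hyperparameter search, experiment presets, and the command-line interface.

## Command line

```bash
# simulate a 2-batch campaign (800 hourly samples) to CSV
fermsim simulate --batches 2 --hours 400 --seed 0 --out data.csv
fermsim simulate --preset table3_1 --seed 0 --out data.csv

# train / predict a single model
softsensor train --model akbls --train train.csv --target-col target \
    --seed 0 --save model.npz
softsensor predict --load model.npz --in test.csv --out pred.csv

# moving-window stacking over a test stream
softsensor mw-run --train train.csv --test test.csv --window 1200 --step 200 \
    --feedback predicted --out pred.csv --report report.json

# named experiment presets
softsensor experiment --preset framework_ablation --seed 0 --outdir results/
```

Exit codes: 0 success, 2 usage error, 3 data error, 4 numerical failure.

## Notes

- All randomness flows through explicit integer seeds; identical
  (config, seed) inputs reproduce outputs bit-for-bit, including saved-model
  round-trips.
- Kernel-mode models map test points through the direct cross-Gram by
  default; `test_kernel="ae"` switches to the ridge-autoencoder
  reconstruction for ablation.
- Reported RMSE values are on the standardized-target scale unless labelled
  otherwise.
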