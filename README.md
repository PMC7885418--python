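# emgdecode

Simultaneous and proportional decoding of wrist/hand kinematics from
multichannel surface EMG, calibrated with categorical movement cues only,
plus the two pieces needed to evaluate it end to end without any recorded
data:

* a **pattern-recognition benchmark** (Hudgins time-domain features, a
  9-class linear discriminant classifier, and motion-normalized
  proportional speed scalars), and
* a **virtual Fitts's-law test environment** (40-target cursor task with
  dwell/timeout logic and a scripted simulated user closing the
  sensor-to-cursor loop).

Everything runs on synthetic sEMG produced by the built-in generator, so
the whole pipeline — signal synthesis, preprocessing, network
calibration, benchmark calibration, closed-loop evaluation, and metric
aggregation — is exercisable offline on one CPU.

## Layout

| Module | Role |
| --- | --- |
| `emgdecode.synth` | Synthetic multichannel sEMG + ternary stimulus encodings emulating the cued acquisition protocol |
| `emgdecode.envelope` | Rectified moving-average envelopes, percentile normalization, exact streaming replica of the batch pipeline |
| `emgdecode.network` | Shared-encoder / per-DoF-decoder feed-forward net (leaky ReLU, parameter-free layer norm), analytic Jacobians |
| `emgdecode.calibration` | L1 inference loss + contractive (squared-Jacobian) penalty, Gaussian input corruption, AdamW, validation early stopping |
| `emgdecode.lda` | TD features, windowing with majority-vote labels, LDA classifier, proportionality tables |
| `emgdecode.fitts` | Target layout, velocity mappings, dwell/timeout trial state machine, simulated user |
| `emgdecode.metrics` | CR/CT/PE/O/T session metrics, index of difficulty, difficulty-vs-time regression, Cohen's d |
| `emgdecode.study` | End-to-end per-subject calibration and controller comparison |
| `emgdecode.autodiff` | Minimal numpy reverse-mode autodiff with double-backward (needed to train through the Jacobian penalty) |

The network and its training loop are implemented on a small
self-contained autodiff engine rather than a deep-learning framework, so
the package has no heavyweight dependencies: just numpy, scipy, h5py and
click.

## CLI

```bash
emgdecode simulate --seed 1 --out session/
emgdecode calibrate-regressor --emg session/emg.csv --stimulus session/stimulus.csv \
    --config cfg.json --out model.h5
emgdecode calibrate-lda --emg session/emg.csv --stimulus session/stimulus.csv --out lda.json
emgdecode fitts-run --controller regressor --model model.h5 --seed 1 --out trials/
emgdecode report --sessions trials_root/ --out report.json
```

`calibrate-regressor` accepts a JSON file overriding any
`TrainingConfig` field (e.g. `{"max_iterations": 700, "batch_size": 256,
"learning_rate": 3e-3}`); without a config it uses the full published
hyperparameter set, which is slow on CPU.

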