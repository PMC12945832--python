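# glioscope

A resource-aware CNN pipeline for classifying low-contrast grayscale
slices, with hyperparameter search driven by a two-phase single-candidate
metaheuristic.  Because the clinical MRI cohort that motivated this tool
is not publicly distributable, the package ships a seeded synthetic
phantom generator so that every stage — contrast enhancement, training,
evaluation, and hyperparameter search — is testable end to end.

Everything is pure numpy/scipy (no deep-learning framework required):
the small mobile-inverted-bottleneck network, its analytic backward pass,
and the SGD trainer are implemented directly.

## Components

| Module | What it does |
| --- | --- |
| `glioscope.sco` | Single-candidate two-phase optimizer: global phase, local phase, decaying step weight, stagnation escape, reset-to-best boundary rule |
| `glioscope.asco` | Opposition-based initialization + Chebyshev iterate stream layered on the same loop |
| `glioscope.benchmarks` | sphere / rastrigin / rosenbrock test objectives |
| `glioscope.nn` | MBConv blocks (expansion, depthwise, squeeze-and-excitation, projection, residual), losses, deterministic size/latency proxies |
| `glioscope.trainer` | SGD with momentum, L2 weight decay, per-epoch exponential LR decay, Xavier/He init, dropout |
| `glioscope.preprocess` | CLAHE (tile 8, clip 2.0 defaults), augmentation catalogue, leakage-guarded normalization |
| `glioscope.phantom` | Seeded T2-like phantom slices with two texture-surrogate classes |
| `glioscope.evaluation` | Confusion-matrix metrics (incl. MCC), patient-level stratified 80/10/10 split, stratified k-fold |
| `glioscope.hpo` | Unit-cube encoding of the hyperparameter space, training-based objective, SCO/ASCO search, ablation harness |
| `glioscope.pipeline` | Split -> CLAHE -> augment(train) -> normalize(train stats) -> train -> evaluate, as hold-out or k-fold CV |

## CLI

```bash
# optimizer benchmarks
glioscope bench --objective sphere --dim 10 --budget 5000 --seed 1 --algo asco

# synthetic cohort (PNGs + manifest.csv with path,patient_id,label,split)
glioscope simulate --n 600 --seed 42 --out data/

# standalone contrast enhancement
glioscope preprocess --data data/ --out enhanced/ --clahe-tile 8 --clahe-clip 2.0

# hold-out training run (writes checkpoint, report, split-filled manifest)
glioscope train --data data/ --out run/ --epochs 18 --lr 0.005 --batch 16 --seed 0

# evaluate a checkpoint on the stored test partition
glioscope eval --model run/model --data run/ --split test

# 10-fold cross-validation of the full pipeline
glioscope cv --data data/ --k 10 --seed 0

# hyperparameter search (desk scale: epochs capped per candidate)
glioscope hpo --data data/ --algo asco --budget 60 --runs 3 --seed 7 --out hpo/

# architecture cost summary
glioscope model summarize
```

## Notes

- All randomness flows through integer seeds (`numpy.random.default_rng`);
  fixed seeds give bit-identical optimizer runs, datasets, and training
  reports.
- The latency term of the resource-aware loss is a deterministic
  multiply-accumulate count (MMACs), not wall-clock time, so results do
  not depend on the host machine.
- Normalization statistics must originate from the training partition and
  evaluation refuses partitions overlapping the training patients; both
  violations raise `LeakageError`.
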