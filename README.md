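# blockdecode

Decoding block-design fMRI sessions with multi-voxel pattern analysis
(MVPA), and mapping where the decodable information lives.

The package targets a block paradigm in which 15-s stimulus epochs
(1–6 characters on screen) alternate with 15-s no-character "travel"
epochs in 6-minute runs at TR = 2.5 s; the decoding target is the
character count, a balanced six-class problem with chance accuracy
1/6 ≈ 16.7%. It provides:

- a **synthetic-session generator** with planted, known ground truth
  (which voxels are informative, and how), writing standard 4-D NIfTI
  plus BIDS-style events TSV;
- **temporal preprocessing**: initial-frame discard and Wiener
  deconvolution with a difference-of-gamma hemodynamic response function,
  `X(f) = conj(H(f))·Y(f) / (|H(f)|² + nsr)`;
- **fold-nested ANOVA voxel selection** (task-activated or
  classification-target grouping);
- a **one-hidden-layer feed-forward network decoder** (tanh hidden,
  logistic outputs, MSE training, hidden-size grid search plus 20-restart
  selection on a held-out validation split) with SVM / Gaussian naive
  Bayes / k-NN baselines;
- **block-integration rules** that pool per-frame decisions over a block:
  input averaging, block voting, confidence voting
  (`c_block = argmax_c Σᵢ wᵢ·1_c(cᵢ)`), and output averaging
  (`c_block = argmax_c Σᵢ O_{c,i}`);
- **temporal-unit cross-validation** (frame / block / half-run / run
  splits), label-permutation p-values, and percentile bootstrap CIs;
- **network sensitivity mapping**: per-voxel relevance from the Jacobian
  `S(x) = O′·W·Y′·V` averaged over a 100-net ensemble and RMS-averaged
  over inputs, `φᵢ = max_k S_RMS[k,i]`; **recursive feature elimination**
  ranked by φ with a bootstrapped stopping rule; and **searchlight** and
  **GLM t-map** baselines with percent-coverage comparison over an
  anatomical partition.

It is aimed at methods work on block-design decoding — bias of CV split
choices, block-level decision rules, and classifier-based brain mapping —
where a ground-truth generator and calibrated inference are worth more
than raw scale.

## Worked example

```python
from blockdecode import PipelineConfig, run_pipeline

cfg = PipelineConfig(
    seed=3, n_runs=2, n_voxels=40, n_informative=8,
    effect_scale=1.2, white_sd=1.2,
    classifier={"name": "nn", "hidden_grid": [6], "n_restarts": 1,
                "max_epochs": 120},
    selection_k=20, split_unit="block", aggregate="output_average",
    out_dir="out")
report = run_pipeline(cfg)
print(report["mean_accuracy"], report["ci68"], report["chance_level"])
```

prints

```
0.7 [0.583333, 0.75] 0.166667
```

i.e. the pipeline simulated a 2-run session with 8 informative voxels
among 40, discarded the first 15 s of each run, deconvolved the
hemodynamic response, selected 20 voxels by ANOVA inside each of 10
block-split folds, trained the network decoder, pooled frame posteriors
over each 15-s block by output averaging, and decoded 70% of blocks
correctly (68% CI 58–75%) against a 16.7% chance level. The same config
and seed reproduce the report byte-for-byte.

The same pipeline is scriptable from the shell:

```bash
blockdecode simulate --runs 2 --voxels 40 --informative 8 --effect 2 --seed 3 --out sess/
blockdecode evaluate --data sess/ --classifier svm_linear --selection-k 20 --out res.json
blockdecode rfe --data sess/ --out rfe.csv
```

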