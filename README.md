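# copdfusion

Multi-modal classification of COPD severity stage (early, GOLD 1–2, vs
advanced, GOLD 3–4) from two routinely collected modalities:

* a table of **physiological and biochemical (PB) indicators** — age, sex,
  height, weight, smoking status, BMI, plus routine blood, liver-function,
  CRP and coagulation panels (24 indicators);
* a **3-D chest CT volume** in Hounsfield units.

The package implements the full method as a tested, reusable library plus a
CLI, together with a synthetic paired-modality generator so every stage is
runnable and testable at desk scale on one CPU — the clinical cohort this
kind of model is built for is hospital-held and not redistributable.

## The model

Each modality has its own encoder producing a 64-d vector:

* **PB branch** — indicators become nodes of a feature graph with an edge
  wherever the absolute Pearson correlation across training samples exceeds
  0.3. Four propagation layers update node states
  `h_i ← normalize(ReLU(W [h_i ‖ mean_{j∈N(i)} h_j]))` (states re-normalised
  to unit L2 after every layer). A TopK pooling layer scores nodes by the
  projection `z = Xp/‖p‖` and keeps the top ⌈kN⌉ nodes (gated by `tanh z`);
  the readout sums, over layers, the concatenation of mean- and max-pooled
  surviving states, and a linear layer emits `z_a`.
* **CT branch** — HU values are windowed to [0, 1] via
  `I = (H − HU_min)/(HU_max − HU_min)`, volumes are rotation-augmented
  (±15° about z), crop/resized, and encoded by a 3-D residual CNN
  (ResNet50-3D, or a lite 3-stage variant for desk scale) into `z_v`.
* **Fusion** — low-rank multi-modal fusion (LMF) computes the tensor-fusion
  product `h_k = Σ_{i≤r} Π_m ⟨w_{m,k}^{(i)}, z_m⟩` without materialising the
  outer-product tensor; `z_a` and `z_v` each pass a cross-modal transformer
  block attending to `h` (queries from the modality, keys/values from `h`),
  then one self-attention layer; mean-pooled tokens are concatenated and
  classified by an MLP. The whole network trains end-to-end under a single
  cross-entropy loss, with the CT branch initialised from image-only
  pretraining.
* **Indicator identification** — pooling scores select candidate
  indicators; each is then "removed" (mean-substituted) and the accuracy
  drop ranks them; two-sample *t*-tests on z-scored values describe the
  group differences of the shortlisted indicators.

All differentiable components run on a compact numpy reverse-mode autodiff
core included in the package (`copdfusion.autodiff`), so there is no deep
learning framework dependency.

## Worked example

```python
import numpy as np
from copdfusion.synthetic import default_spec, generate_paired_dataset
from copdfusion.train import SplitSpec, make_splits, train_joint

spec = default_spec(300, seed=1000, modality_signal="complementary")
dataset = generate_paired_dataset(spec)          # 300 paired samples
split = make_splits(dataset.labels, SplitSpec(seed=0))[0]
result = train_joint(dataset, split)
print({k: round(v, 3) for k, v in result.metrics["test"].as_dict().items()})
```

which prints (single seed, 60 test samples):

```
{'acc': 0.783, 'pre': 0.828, 'sen': 0.75, 'spe': 0.821, 'f1': 0.787, 'auc': 0.923}
```

Here `acc/pre/sen/spe/f1` are the confusion-count metrics with the advanced
stage as the positive class and `auc` the rank statistic. In the
`complementary` generator mode each single modality carries only part of
the label signal (its Bayes accuracy is capped near 0.75), so a fused
accuracy above that cap is direct evidence that the model combines the
modalities rather than leaning on one.

The same pipeline is scriptable from the shell:

```bash
copdfusion simulate --config examples/config.yaml
copdfusion train-fusion --config examples/config.yaml
copdfusion select-indicators --config examples/config.yaml
```

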