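# Methods

## Problem setting

The package classifies COPD severity stage (early vs advanced) from two
modalities collected per patient — a 24-indicator physiological/biochemical
(PB) table and a 3-D chest CT volume — and identifies which PB indicators
drive the classification. The cohorts such models are built on are
hospital-held; everything here therefore runs against a synthetic paired
generator whose structure mirrors the clinical setting, at sizes where the
full pipeline trains in minutes on one CPU.

## PB branch: correlation graph + GNN

Indicators are nodes; an undirected, unweighted edge joins indicators whose
absolute Pearson correlation across *training* samples exceeds 0.3. Edges
carry no weight because the aggregation is a plain neighbour mean. Each
sample is classified on this shared topology: node *i*'s initial state is
the sample's value of indicator *i* lifted to the hidden width by a
per-indicator linear embedding (weight and bias per node). Per-node rather
than shared embeddings are what give nodes an identity under per-sample
inference — with one shared scalar embedding the readout cannot tell
indicators apart and the branch plateaus well below its achievable
accuracy.

Each of the 4 propagation layers computes, per node,
`h ← ReLU(W [h ‖ mean of neighbour states]) `, applies dropout, and
re-normalises rows to unit L2 (zero rows stay zero; the normalisation has a
bounded-gradient guard at ‖h‖ ≤ 1e−6). The node's own state enters through
the concatenation, not the neighbour mean; isolated nodes aggregate a zero
vector.

A single TopK pooling layer after the last propagation layer scores nodes
with `z = Xp/‖p‖` and keeps the ⌈kN⌉ best (default k = 0.5; ties break
toward the lower node index). Kept states are gated by `tanh z` so the
projection vector receives gradient; the gate applies to every layer's
surviving states so all readout scales see one consistent survival mask.
The readout sums over layers the concatenation of mean- and max-pooled
surviving states; a linear layer maps it to the 64-d modality vector `z_a`
and a second linear layer provides the branch's own classification logits
(used only when the branch trains alone).

Training: Adam, lr 3e−3, weight decay 1e−4, batch 32, 120 epochs, dropout
0.05, keeping the epoch with the best validation negative log-likelihood.
NLL rather than accuracy is used for selection because a 60-sample
validation fold quantises accuracy in 1.7-point steps. Dropout above ~0.1
interacts badly with the per-layer re-normalisation at these small widths
(the noise is re-amplified to unit norm every layer) and measurably
underfits, hence the small default.

## CT branch

HU windowing defaults to a fixed (−1000, 400) clinical window;
dataset-level min/max computed on training volumes is available but is
outlier-sensitive and leaks scale when computed globally, so the fixed
window is the default. Augmentation is an in-plane rotation of ±15° about
z applied identically to all slices, plus random in-plane flips. Rotation
corners are filled with the volume's *median* intensity (the parenchyma
level): filling with 0 — which after windowing equals air — would paint
emphysema-like low-attenuation wedges into every rotated volume and
destroys the class signal. Crop/resize is a centre crop followed by
trilinear resampling to the configured shape, which also standardises the
slice count.

Two backbones share one interface: `resnet50_3d` (stem + 3/4/6/3
bottleneck stages, trailing linear layer to the 64-d `z_v`) and
`resnet_lite_3d` (stride-2 stem + two basic blocks, channels 8/16/32,
~70k parameters) for desk-scale volumes. Batch normalisation keeps running
statistics; because training batches are augmented while evaluation is
not, the running statistics are re-calibrated each epoch by a few forward
passes over un-augmented training volumes, and checkpoints snapshot the
statistics together with the weights (restoring weights without their
matching statistics silently destroys eval-mode accuracy).

The clinical-scale recipe (Adam lr 2e−5, betas (0.9, 0.999), eps 1e−8, weight
decay 1e−3, ×0.1 every 10 epochs, batch 10, 30×224×224 input) is the
`resnet50_3d` default and presumes a pretrained backbone; the lite preset
trains from scratch and uses lr 1e−3, 16×32×32 input, 25 epochs, same
schedule otherwise.

## Fusion

LMF parameterises the (d_h × d_1 × … × d_M) weight tensor by rank-r
per-modality factors and computes
`h_k = Σ_{i≤r} Π_m ⟨w_{m,k}^{(i)}, z_m⟩` — rank-wise products across
modalities summed over ranks. This order of operations is forced by the
requirement that the factorised path equal the dense contraction of the
reconstructed weight tensor (`reconstruct_weight_tensor` +
`tensor_fusion_oracle`, which double as the full tensor-fusion baseline);
the common shorthand "product over modalities of factor-projected vectors"
elides the rank index and is not equivalent. Rank defaults to 4; the
constant-1 augmentation of the modality vectors found in some LMF variants
is available behind `append_one` but off by default. The module accepts
M ≥ 2 modalities; the fusion head wires two.

Attention over length-1 sequences is degenerate, so each 64-d vector is
reshaped to 8 tokens of 8 dims and embedded to d_model = 32 with learned
positional embeddings. Each modality passes one pre-norm cross-modal block
(queries from the modality tokens, keys/values from the fused-vector
tokens; `swap_query` flips this) and one self-attention block, all 4-head;
token means are concatenated (64-d) and a 2-layer MLP classifies. A single
cross-entropy on the fused head is the joint loss.

Joint training proceeds in three stages: branch pretraining (CT per the
recipe above, PB as its own branch run), a fusion-head warm-up on cached
frozen branch features (60 epochs — cheap, since the CNN never runs), and
a short end-to-end fine-tune of everything (6 epochs, lr 1e−4, batch 10)
with best-validation-epoch selection. Warm-starting the head is what makes
a short joint fine-tune sufficient; fine-tuning longer at higher rates
erodes the pretrained branches faster than the head improves.

## Preprocessing

* Repeated measurements (several values of one indicator in one visit) are
  resolved by an ordinary least-squares line in time evaluated at the
  reference day (mean when all timestamps coincide, the value itself when
  single). Whether the intended regression is in time or across
  co-measured indicators is ambiguous; value~time is implemented.
* The 3σ rule flags cells strictly more than three *population* standard
  deviations from the column mean, pooled over classes; σ = 0 columns flag
  nothing.
* Flagged or missing cells are imputed by the mean of the K = 10 nearest
  neighbours *of the same class*; distance is the RMS difference over
  z-scored columns observed and unflagged in both samples (RMS rather than
  a raw sum so pairs sharing fewer columns are not favoured). The
  z-scoring for distances excludes flagged cells, which also makes
  re-imputation under a frozen mask idempotent. Fewer than K eligible
  neighbours → all are used; none → an error naming sample and indicator.
* Fold safety: screening statistics, the imputation pool, z-scoring, graph
  edges and the HU window are fitted on training samples only
  (`Preprocessor`), and held-out samples are processed against them.

## Splits and evaluation

A stratified 3:1:1 train/validation/test split is the default; stratified
k-fold (default 5) is available, each training portion internally split
3:1 so the overall proportions match. Metrics are the confusion-count
formulas with advanced stage as positive, AUC is the Mann–Whitney rank
statistic (ties count ½), and any zero-denominator metric is reported as
undefined (`None`/null), never as 0. Decision threshold is 0.5 on the
positive-class softmax probability.

## Indicator ranking

Candidates are the nodes surviving TopK pooling (by eval-mode pooled score
averaged over samples). Each candidate is mean-substituted (its z-scored
column set to the training mean) and the model re-evaluated; candidates
rank by accuracy drop, ties toward larger pooled score, and the top 4 form
the shortlist. Ablation is at inference time — re-training per indicator
is available conceptually but non-deterministic and ambiguous, so the
default probes the trained model. Drops are measured on the full dataset:
an 80-sample test fold quantises accuracy in 1.25-point steps, which would
swamp the sub-2-point effects of ablating noise indicators; the ablation
probes the model, it does not claim generalisation. Group statistics are
two-sample Student *t*-tests (Welch behind a flag) on z-scored values with
a 95% CI on the mean difference, early minus advanced.

## Synthetic data

The generator emulates the study conditions: 24 standardised indicators
(named after the clinical panel) with equicorrelated blocks (Gaussian
copula; liver enzymes at ρ = 0.6, routine blood at ρ = 0.5), four
informative indicators planted at the BMI / weight / albumin / APTT
positions with a standardised between-class shift of δ = 1.5 each, 1.67%
gross outliers (uniform cells pushed 5–8σ, guaranteed detectable by the 3σ
screen), and 3% of cells carrying 2–4 timestamped values around a latent
linear visit trend. Volumes are lung-like fields (parenchyma ≈ −800 HU
with noise) whose class signal is the *density of low-attenuation
spherical blobs* (≈ −990 HU, emphysema-like), not global brightness, so
the CNN must read texture; blob count is λ = 10 + 8·effect·signal.

Modality coupling: `pb_only` / `ct_only` silence the other modality;
`redundant` drives both from the label; `complementary` draws two
independent N(0, 1) latents, labels by `1{(u_pb+u_ct)/√2 > Φ⁻¹(1−balance)}`
and couples each modality to its own latent (feature shifts rescaled so the
between-class standardised shift is still ≈ δ). This caps each unimodal
Bayes accuracy near 0.75 at balance 0.5 while the two latents jointly
determine the label — the structural reason fusion must help, with a
closed-form Bayes-rule oracle (`bayes_accuracies`).

What the generator does **not** model: anatomy (airways, vasculature,
lobes), acquisition effects (kernels, slice-thickness mixtures, DICOM
metadata), indicator-specific units and skew, informative missingness.
Passing tests therefore demonstrate that the pipeline's machinery is
correct and that it recovers planted structure under controlled
conditions — not clinical performance.

## Study-scale experiments

* *Fusion gain*: five seeds; per seed a fresh complementary dataset
  (n = 300, 24 indicators, 16×32×32 volumes), 3:1:1 split, three models
  (PB alone, CT alone, joint fusion with the lite backbone). The seed-mean
  fused test accuracy is compared with each unimodal mean; the expected
  regime is unimodal ≈ 0.70–0.73 (near the 0.75 cap) and fused ≈ 0.80.
* *Indicator recovery*: five seeds of pb_only data (n = 400, 4 planted
  among 24); the pooling + ablation shortlist of 4 is scored against the
  planted set, and the largest |accuracy drop| over selected noise
  indicators is recorded.

Problem sizes (n = 300/400, 16×32×32 volumes, lite backbone) are the
package's desk-scale study conditions: large enough for the effects to be
resolvable, small enough that the whole suite trains on one CPU in
minutes.

## Numerical choices and degenerate inputs

* float64 throughout the graph/fusion stacks; float32 in the CNN.
* Xavier-uniform initialisation everywhere (per-branch seeded generators).
* Ties: TopK selection → lower node index; neighbour distances → lower
  sample index; ranking → larger pooled score; best-epoch → later epoch.
* Zero rows after ReLU stay zero through L2 normalisation with a bounded
  gradient; `‖p‖ = 0` in pooling, single-class AUC, all-missing columns,
  zero-variance groups and degenerate HU windows raise (or are flagged as
  undefined) rather than returning silent zeros.

## Known limitations

* The transductive reading of the GNN's initial node states (feature
  vectors spanning all samples) is incompatible with held-out inference
  and a 3:1:1 split; the per-sample reading implemented here is the
  standard inductive resolution.
* The lite CNN's accuracy on complementary-mode data is intrinsically
  noisy: each branch trains against labels that are 25% noise with respect
  to its own latent. Validation-based selection and augmentation contain
  but do not eliminate seed variance.
* `resnet50_3d` is exercised structurally (shape propagation, interface)
  at desk scale; training it at 30×224×224 is out of scope on one CPU.
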