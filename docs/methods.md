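# Methods

## Generative model

`perturbdiff` models the post-perturbation bulk transcriptome **x**₀ (a
log-normalized vector over a fixed gene panel) with a denoising diffusion
probabilistic model conditioned on the paired pre-perturbation profile
**c**_pre and a perturbation embedding **c**_pert.  The forward chain
corrupts data with Gaussian noise under a strictly increasing variance
schedule β₁ < … < β_T; the closed-form marginal is
x_t = √ᾱ_t·x₀ + √(1−ᾱ_t)·ε with ᾱ_t = ∏(1−βᵢ).  A noise predictor
ε_θ(x_t, t | c_pre, c_pert) is trained on the squared noise residual
(summed over genes per sample, averaged over the batch) with t drawn
uniformly from [1, T] per sample.  Sampling runs the standard ancestral
reverse chain from x_T ~ N(0, I) with posterior noise scale
σ_t = √((1−ᾱ_{t−1})/(1−ᾱ_t)·β_t); we adopt the convention ᾱ₀ := 1 so σ₁ = 0
and the final step is deterministic.  Timesteps are 1-based at every public
interface; the 0-based array indexing is confined to the schedule lookup.

Intermediate states and final samples are not clipped: log-normalized
expression is bounded below but not above, and desk-scale experiments showed
no divergence.  No accelerated samplers (DDIM/EDM/consistency) are provided;
prediction always uses the full T-step chain.

### Schedule choices

`make_schedule` defaults to the common 1000-step linear schedule
(β ∈ [1e-4, 0.02]).  Training runs configured through `RunConfig` default to
a desk-scale chain of T = 50 steps with β ∈ [2e-3, 0.4] — the β range is
scaled up by 1000/T so that ᾱ_T ≈ 10⁻⁵ and the reverse chain genuinely
starts from noise.  A 50-step chain with the 1000-step β range would retain
ᾱ_T ≈ 0.6 of the signal, and a model trained that way samples from the wrong
prior; this is the single most consequential schedule parameter.

## Noise-predictor architecture

All four variants share: three linear adapters (transcriptome per-gene
values → d_model tokens; perturbation token matrix → d_model; sinusoidal
timestep encoding → two-layer MLP → d_model), a learnable gene positional
table Pos ∈ R^{n_gene×d_model} added to transcriptome tokens, the timestep
embedding added to every stream, pre-norm residual transformer layers, and a
per-token linear head (after a final layer norm) mapping tokens back to an
n_gene vector.

- **crossdit** — x_t and c_pre are adapted by separate linear layers into two
  token streams (both receive Pos and the timestep embedding); each layer
  applies cross-attention of the x_t stream over the c_pre stream, then over
  the perturbation tokens, then a feed-forward block.  The condition streams
  are adapted once and reused by every layer.
- **catcrossdit** — x_t and c_pre are concatenated per gene (R^{n_gene×2} →
  d_model by one linear layer); layers run self-attention, cross-attention
  over perturbation tokens, feed-forward.
- **catonlycrossdit** — catcrossdit without the self-attention block.
- **adadit** — catcrossdit with the perturbation entering as a pooled vector
  through adaptive layer norm instead of cross-attention: each layer derives
  two (γ, β, α) sets from the perturbation vector via an MLP, applies
  γ⊙x + β before the self-attention and feed-forward blocks and the gate α⊙x
  after them.  The modulation heads are zero-initialized with γ biased at 1,
  so gates start closed and open during training.

Numerical/initialization choices that matter:

- **Pos initialization scale = 1.0.**  Gene-specific routing of the drug
  signature happens through attention queries, and Pos is the only
  gene-identity signal.  With the tiny init scales customary for positional
  embeddings (~0.02) the conditional (drug-effect) part of the model learns
  an order of magnitude more slowly on desk-scale data; unit-scale init
  removed a long plateau in every variant we trained.
- GELU uses the tanh approximation; attention is standard multi-head
  scaled-dot-product (the algebra is layout-equivalent to formulations that
  write the projections transposed); padding masks from the text encoder are
  applied additively before the softmax, and a fully masked context row is an
  error.
- Weights are float32 by default (configurable); gradient-correctness tests
  run in float64.  The output head and all adapters initialize at
  N(0, 1/√fan_in); the training optimizer is AdamW with cosine learning-rate
  decay to 10% of the peak (2e-3 at desk scale).
- Optional per-gene standardization of expression before diffusion exists in
  `RunConfig` but is off by default: log-normalized profiles are already
  near unit scale, and dividing by each gene's cross-cell-line spread shrinks
  the drug effect relative to the chain noise, demonstrably slowing
  conditional learning.

The engine beneath the network is a small reverse-mode autodiff tape over
numpy with fused softmax/layer-norm/GELU primitives; every primitive and the
full denoiser are checked against central finite differences.

## Perturbation representation

A perturbation is text: a molecule description plus the dose prompt
"The dosage is &lt;d&gt; micromoles" (dose printed as a plain decimal with
trailing zeros stripped).  The description backend is pluggable; the built-in
describer derives a short deterministic sentence from the canonical SMILES
(formula, heavy-atom count, ring count, molecular weight).  It is kept
deliberately short: tokens shared across all drugs dilute the
drug-identifying signal that cross-attention must extract, and longer
boilerplate measurably slows conditional learning.  The built-in text
encoder maps each whitespace token to a fixed pseudo-random vector via a
keyed BLAKE2 hash (d_text = 64, max 16–32 tokens, padded with a mask) — a
deterministic, download-free stand-in exercising the same contracts as an
external language-model encoder.  Real encoders are supported through an
HDF5 + JSON-manifest cache keyed by (canonical SMILES, dose).  Average
pooling over unmasked tokens yields the vector form used by AdaLN
conditioning.

The baseline chemistry representation is an FCFP4 fingerprint (feature-based
Morgan, radius 2) multiplied by log₁₀(dose in µM).  At exactly 1 µM this
weight is zero and the embedding vanishes; the behaviour is preserved
as-specified for the baseline and flagged with a warning.

Canonical SMILES (RDKit) defines drug identity everywhere: record
`drug_id`s, compound filtering, DEG grouping, and drug-level split units, so
one compound at several doses is held out as a unit.

## Data model and preprocessing

Datasets are paired: each record holds a control profile, a perturbed
profile, SMILES, dose (µM), cell line, and optional organ, over one shared
gene panel fixed at load time.  Log-normalization scales each sample to a
common total (default 1e4) then applies log(1+x), matching the scanpy
convention (cross-checked in tests).  Control pairing assigns each treated
sample one control drawn (seeded) from the controls matching on cell line
(plus any further keys such as batch).  Compound filtering first removes
records whose SMILES fails canonicalization, then compounds with fewer than
5 observations — the convention of the large public perturbation corpus this
package targets.

Differentially expressed genes are ranked within drug (or drug × cell)
groups by the mean log fold change of perturbed vs. paired control (a
Wilcoxon rank-sum alternative is provided); ties break by gene-panel order
via stable sorting, making DEG sets independent of record order.  Down-genes
exclude genes already taken by the up set so the two lists are disjoint even
in degenerate null cases.  Defaults: 25 up + 25 down.

## Evaluation

Two metrics × five groupings (drug, drug_dose, cov_drug, cov_drug_dose,
per_sample).  Within a group, true, predicted and control profiles are
averaged before computing the metric; the reported value is the unweighted
mean over groups, and groups where a metric is undefined (constant truth or
zero-variance fold change) are excluded with their counts surfaced in the
report.  R² uses the standard definition centered on mean(y_true); a
`center="pred"` switch reproduces a variant that centers the total sum of
squares on the prediction mean, which is not a true coefficient of
determination and is off by default.  Doses are grouped after rounding to 6
significant digits.  The DEG-restricted analysis computes, per drug and DEG,
the Pearson correlation of true vs. predicted single-gene lnFC across that
drug's samples, then averages over the drug's DEGs (≥3 samples required;
zero-variance genes skipped with a warning).

## Splits

The five-way benchmark split samples held-out drugs and held-out cell lines
independently (default 20% of each) and routes records by the
cross-classification: both held out → Both_unseen, drug only → Drug_unseen,
cell only → Cell_line_unseen; the remainder is split at record level into
train/val (default 25% val).  Cross-validation partitions records (random
mode) or drug/cell units into k folds; fold i tests on chunk i, validates on
chunk i+1 (random mode) or on a 1/(k−1) record fraction of the training side
(unit modes — validation on unseen units would conflate model selection with
the OOD test), giving ≈6:2:2 at k = 5.

## Synthetic data generator

The generator emulates the structure of a large drug-perturbation compendium
at desk scale.  For cell line c, drug d, dose v:

    control_obs = B[c] + η_c,   perturbed_obs = B[c] + r(v)·(S[d] ⊙ M[c]) + η_p

with per-cell baselines B ~ U(0.5, 5) per gene (log-normalized scale), drug
signatures S ~ N(0, effect_scale²), cell modulators M ~ 1 + N(0,
cell_modulation_scale²), saturating dose response r(v) = log10(1+v) /
log10(1+v_max) over doses log-spaced in [1, 10] µM, and independent
measurement noise η ~ N(0, noise_sd²) on **both** the stored control and the
perturbed profile around the shared latent state.  Consequently the observed
log fold change is effect + η_p − η_c, and the best possible per-sample
PCC(lnFC) — attained by the oracle predictor control + effect — is
s/√(s² + 2·noise_sd²) for per-record effect spread s (`analytic_oracle_pcc`
computes this ceiling; the oracle's observed score matches it in tests).

Defaults are the package's study conditions: 50 genes, 12 drugs (small valid
molecules from a fixed SMILES pool, so the cheminformatics path runs for
real), 6 cell lines, 3 dose levels, 4 samples per condition (864 records),
effect_scale 0.5, cell_modulation_scale 0.3, noise_sd 0.05.  Cell lines
carry a cyclic organ label (lung/kidney/pancreas) to exercise organ-based
holdouts.  What the generator does **not** emulate: plate/batch structure,
count saturation, heavy-tailed noise, correlated gene modules, or any
biological plausibility of the signatures — passing tests show that the
machinery recovers a planted, well-specified signal near its noise ceiling,
not that the model is accurate on real perturbation corpora.

## Problem sizes and training settings

The recovery experiments train on the default synthetic conditions with the
desk-scale network (d_model 64, 2 layers, 4 heads, feed-forward multiplier
2, max 16 perturbation tokens), T = 50, batch 96, AdamW at 2e-3 with cosine
decay, 200 epochs for CatCrossDiT and 60 for CrossDiT, evaluated on the
random-split test fold (~173 records) by full reverse-chain sampling.  These
sizes were chosen as the package's reference configuration; all of them are
plain `RunConfig`/`SyntheticSpec` fields.

## Known limitations

- The built-in describer/encoder carry no chemical semantics: two similar
  molecules get unrelated embeddings, so generalization to *unseen* drugs
  with the hash encoder is not meaningful — use cached embeddings from a
  real captioning/text model for that question.  The OOD split machinery is
  exercised structurally regardless.
- One-CPU numpy training limits practical scale to panels of a few hundred
  genes; the architecture itself has no such limit.
- The forward/reverse chain assumes homoscedastic Gaussian corruption in
  log space; raw counts must be log-normalized first.
- The fingerprint baseline's dose weighting is identically zero at 1 µM by
  construction.
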