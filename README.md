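# perturbdiff

Conditional diffusion-transformer modelling of drug-perturbed bulk
transcriptomes.

## The problem

Given a cell population's expression profile *before* treatment, which
transcriptome will it show *after* exposure to a particular small molecule at
a particular dose?  Answering this in silico — for drugs or cell lines never
measured — supports compound triage in drug discovery and response prediction
in personalized medicine.  `perturbdiff` is for computational biologists who
want a trainable, fully seeded, desk-scale implementation of this modelling
problem: data model, chemistry-aware perturbation encoding, the generative
model, evaluation metrics, out-of-distribution splits, and a synthetic data
generator with known ground truth.

## The model

The perturbed transcriptome **x**₀ (log-normalized, fixed gene panel) is
generated by a denoising diffusion probabilistic model conditioned on two
inputs: the paired pre-perturbation profile **c**_pre and a perturbation
embedding **c**_pert.  The forward process corrupts data with a variance
schedule β₁ < … < β_T:

    x_t = √ᾱ_t·x₀ + √(1−ᾱ_t)·ε,   ε ~ N(0, I),   ᾱ_t = ∏ᵢ(1−βᵢ)

A noise predictor ε_θ(x_t, t | c_pre, c_pert) is trained by minimising
E‖ε − ε_θ‖², and prediction runs the reverse chain from x_T ~ N(0, I):

    x_{t−1} = (x_t − β_t/√(1−ᾱ_t)·ε_θ) / √α_t + σ_t·z,
    σ_t = √((1−ᾱ_{t−1})/(1−ᾱ_t)·β_t),  σ₁ = 0

ε_θ is a transformer over per-gene tokens with learnable gene positional
embeddings.  Four fusion variants are provided — how **c**_pre enters
(cross-attention vs. per-gene concatenation, with or without self-attention)
and how **c**_pert enters (cross-attention over text tokens vs. adaptive
layer norm on a pooled vector):

| variant           | perturbation fusion | transcriptome fusion             |
|-------------------|---------------------|----------------------------------|
| `crossdit`        | cross-attention     | cross-attention (separate streams)|
| `catcrossdit`     | cross-attention     | concatenation + self-attention   |
| `adadit`          | AdaLN (γ,β scale/shift + α gate) | concatenation + self-attention |
| `catonlycrossdit` | cross-attention     | concatenation only               |

Perturbations are text: a deterministic molecule description derived from the
canonical SMILES, followed by the prompt `The dosage is <d> micromoles`,
tokenised to an embedding matrix (a seeded hash encoder ships for offline
use; precomputed embeddings from external captioning/text models plug in via
an HDF5 cache).  An FCFP4-fingerprint × log₁₀(dose) baseline representation
is also included.

Predictions are scored with two metrics × five grouping granularities
(drug, drug_dose, cov_drug, cov_drug_dose, per_sample): the coefficient of
determination R² of the predicted vs. true profile, and the Pearson
correlation of log fold changes PCC(lnFC) relative to the paired control,
averaging profiles within groups before scoring.  Benchmark splits hold out
drugs and cell lines independently (train / val / Drug_unseen /
Cell_line_unseen / Both_unseen) alongside classic 5-fold random/drug/cell
cross-validation.

## Worked example

```python
from perturbdiff import (
    SyntheticSpec, generate_dataset, analytic_oracle_pcc,
    DenoiserConfig, RunConfig, run_train, run_predict, evaluate_all,
    split_prnet_cv,
)

dataset, truth = generate_dataset(SyntheticSpec())      # 864 paired records, 50 genes
fold = split_prnet_cv(dataset, mode="random", n_folds=5, seed=1)[0]
train, test = dataset.subset(fold.indices("train")), dataset.subset(fold.indices("test"))

config = RunConfig(
    denoiser=DenoiserConfig(variant="catcrossdit", n_gene=50, d_model=64,
                            n_layers=2, n_heads=4, max_tokens=16, ffn_mult=2),
    schedule_T=50, epochs=200, batch_size=96, lr=2e-3,
    data_seed=0, model_seed=1, sampling_seed=2,
)
model, schedule, history = run_train(train, config)
preds = run_predict(model, schedule, test, sampling_seed=2)
report = evaluate_all(test, preds)
print(round(report[("PCC_lnFC", "per_sample")], 3),
      round(report[("R2", "per_sample")], 3),
      round(analytic_oracle_pcc(test, truth), 3))
```

```
0.84 0.987 0.946
```

The trained model's per-sample PCC(lnFC) of 0.84 approaches 0.946 — the
analytic ceiling for *any* predictor on this data, set by the measurement
noise on both sides of each control/perturbed pair
(s/√(s² + 2·noise_sd²) for per-record effect spread s).  R² near 1 means the
predicted absolute profiles match record by record, far above the ~0.2 of a
mean-perturbed-profile baseline.

The same pipeline is scriptable from the shell:

```bash
perturbdiff synth --seed 1 --out data.h5ad
perturbdiff split --data data.h5ad --mode benchmark --out splits/
perturbdiff train --data data.h5ad --seed 1 --out ckpt.npz
perturbdiff predict --ckpt ckpt.npz --data data.h5ad --seed 2 --out preds.csv
perturbdiff evaluate --data data.h5ad --pred preds.csv --out reports/
```

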