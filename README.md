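# contrastive-ehr

Contrastive pre-training and fine-tuning for predicting post-discharge
depression and anxiety in hospitalized type-2-diabetes patients, built as a
fully testable desk-scale pipeline on synthetic discharge records.

Hospital discharge records are heterogeneous: structured demographics and
laboratory panels sit next to free-text-like history, diagnosis codes and
medication codes. The package implements a two-stage framework for this
setting:

1. **Contrastive pre-training.** Each hospitalization yields three views —
   the patient state `x` (demographics + labs encoded by a transformer ψ_E,
   fused with the embedded history by gated single-head linear-attention
   blocks), the discharge diagnoses `d`, and the medications `m` (each
   encoded by a transformer and a projection head). Training minimizes the
   paired contrastive loss

   L_CP = L(x, m) + L(m, x) + L(x, d) + L(d, x),

   where each term is a temperature-scaled InfoNCE,
   L(q, k) = −log [ exp(q·k⁺/τ) / Σᵢ exp(q·kᵢ/τ) ],
   over in-batch negatives (τ = 0.07).
2. **Fine-tuning.** The concatenated triple [x‖m‖d] feeds one affine layer;
   the sigmoid of its logit is the probability that a depression/anxiety
   event — an ICD-10 diagnosis in F31–F34, F39, F06.3, F40–F43, F06.4 or a
   medication in ATC N06A/N05B — occurs within 30/180/365 days of
   discharge. The loss is summed binary cross-entropy,
   L_FT = Σᵢ −[yᵢ log uᵢ + (1−yᵢ) log(1−uᵢ)].

Around the model, the package provides the full study machinery: a seeded
synthetic EHR generator with a planted latent patient state (and a
ground-truth sidecar for oracle tests), isolation-forest outlier screening
and quantile discretization, case–control cohort construction with a
6-month prior-event exclusion, 7-day record merging and 1:3
propensity-score matching, patient-disjoint 10-fold cross-validation
against logistic-regression / random-forest / XGBoost baselines, decision
curve analysis (net benefit NB(t) = TP/n − (FP/n)·t/(1−t)), and
integrated-gradients attribution with per-feature aggregation. Everything
neural runs on a small, finite-difference-verified numpy autodiff engine —
no GPU or deep-learning framework required.

Intended users: methods researchers and students who want a transparent,
CPU-scale reimplementation of contrastive EHR pre-training whose every
stage is testable against planted ground truth.

## Worked example

```python
import numpy as np
from contrastive_ehr import (
    assemble_record, build_cohort, fit_schema, generate_timelines,
)
from contrastive_ehr.synthetic_ehr import strong_signal_config
from contrastive_ehr.pretraining import EncoderConfig, pretrain, retrieval_accuracy
from contrastive_ehr.finetuning import FineTuneConfig, finetune
from contrastive_ehr.evaluation import auc_roc

# 1. a synthetic world with a strongly learnable latent state
timelines, truth = generate_timelines(strong_signal_config(n_patients=1000, seed=7))
records = [r for t in timelines for r in t.admissions]
y = np.array([g.event_within_365 for g in truth])
print(f"{len(records)} records, event rate {y.mean():.3f}, "
      f"Bayes AUC {auc_roc(y, [g.risk_score for g in truth]):.3f}")

# 2. preprocess and pre-train contrastively
schema = fit_schema(records, n_bins=10, embed_dim=32)
encoded = {r.record_id: assemble_record(r, schema) for r in records}
pre = pretrain(list(encoded.values()), EncoderConfig(seed=0), schema)
x, _, d = pre.encoder.encode_numpy(list(encoded.values()))
print(f"x->d retrieval in batches of 8: {retrieval_accuracy(x, d, 8):.3f} (chance 0.125)")

# 3. build the 365-day matched cohort and fine-tune
cohort = build_cohort(timelines, 365)
print(f"cohort: {cohort.provenance['n_cases']} cases, "
      f"{cohort.provenance['n_controls_matched']} matched controls")
X = [encoded[c.record_id] for c, _, _ in cohort.entries]
labels = cohort.labels
order = np.random.default_rng(0).permutation(len(X)); cut = int(0.75 * len(X))
res = finetune(pre.encoder, schema, [X[i] for i in order[:cut]], labels[order[:cut]],
               FineTuneConfig(epochs=2, seed=0),
               val_records=[X[i] for i in order[cut:]], val_labels=labels[order[cut:]])
print(f"held-out ROC-AUC after 2 epochs: {res.val_roc_auc[-1]:.3f}")
```

prints

```
1998 records, event rate 0.182, Bayes AUC 0.932
x->d retrieval in batches of 8: 0.875 (chance 0.125)
cohort: 357 cases, 1071 matched controls
held-out ROC-AUC after 2 epochs: 0.893
```

Reading the numbers: the planted latent risk score separates realized
one-year outcomes with AUC 0.93 (the ceiling any model can reach); after
pre-training, a record's patient-state vector retrieves its own diagnosis
vector among 8 candidates 87% of the time (chance 12.5%), i.e. the three
views are aligned; matching yields exactly 3 controls per case; and the
fine-tuned model ranks held-out records close to the planted ceiling.

The same pipeline runs end to end from the command line:

```bash
cehr run-all --config config.yaml --out run/
```

writing `timelines.jsonl`, `schema.json`, `cohort.csv` (+ provenance),
`pretrained.npz`, `evaluation.json`, `decision_curve.csv`,
`top_features.csv` and a `manifest.json` with per-stage seeds and artifact
hashes.

## Layout

| Module | Contents |
| --- | --- |
| `synthetic_ehr` | seeded generator, JSONL timeline I/O, ground-truth sidecar |
| `preprocessing` | outlier screening, quantile discretizer, hash embeddings, record assembly |
| `cohorts` | outcome code sets, window labelling, record merging, propensity matching |
| `pretraining` | encoders, FLASH-style fusion, InfoNCE / paired loss, training loop |
| `finetuning` | risk head, BCE, fine-tuning with validation traces |
| `evaluation` | ROC/PR-AUC, fold t-tests, k-fold CV with baselines, decision curves |
| `interpretation` | integrated gradients, per-feature aggregation, top-k table |
| `pipeline` / `cli` | YAML-configured orchestration, manifest, `cehr` command |
| `nn` | the numpy autodiff engine (tensors, layers, Adam) |

See `docs/methods.md` for modelling assumptions, parameter defaults and
known limitations.
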