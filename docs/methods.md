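# Methods

## Problem and design

The package models post-discharge depression/anxiety risk for hospitalized
type-2-diabetes patients from heterogeneous discharge records, in two
stages. A self-supervised **contrastive pre-training** stage learns, from
unlabeled records, to align three views of one hospitalization — the
patient state (demographics + labs + medical history), the discharge
diagnoses, and the prescribed medications. A supervised **fine-tuning**
stage then attaches a single affine head to the aligned representations and
trains end-to-end to predict whether a depression/anxiety event occurs
within 30/180/365 days of discharge.

## Synthetic data generator

Real regional EHR data of this kind is not publicly available, so the
package is driven by a seeded generator with a planted latent structure
that gives every downstream stage learnable signal and an exact oracle:

* each patient draws a latent state `z ~ N(0, I_k)` (default `k = 4`);
* lab values are `μ_f + s·(L_f·z) + ε` with `ε ~ N(0,1)`, plus planted
  outliers (rate 0.01, 6–12 σ) and missingness (rate 0.05);
* history tokens, diagnosis codes and medication codes are drawn from
  categorical distributions with logits `s·(W·z)`;
* a record has a depression/anxiety event within 365 days with probability
  `σ(logit(h₀) + s·(w·z))`, placed uniformly in `(discharge,
  discharge+365]` and coded from the ICD-10 (F31–F34, F39, F06.3;
  F40–F43, F06.4) / ATC (N06A, N05B) outcome sets.

`s` is the *signal strength*: it couples every observable (and the hazard)
to the latent state, so `s = 0` removes all signal and the event rate
collapses to the base hazard `h₀`. Defaults: 500 patients, 1–3 admissions
each, 12 labs, history vocabulary 200, 40 diagnosis / 25 medication codes,
`h₀ = 0.05`, `w = 0.5·𝟙₄`. At the default `s = 1` the one-year record-level
event rate is ≈ 7%, near the 5–6% reported for comparable hospital
populations; the *strong-signal* study condition (`s = 3`, 1000 patients,
≈ 2000 records) has an event rate ≈ 20% and a Bayes AUC of the true latent
risk score ≈ 0.93, so trained models can be compared against a known
ceiling. Ground truth (`z`, event probability, realized event) lives in a
sidecar file the model pipeline never reads.

What the generator deliberately does **not** emulate: clinical
vocabularies, free-text notes (tokens are code-like symbols; the static
embedding makes the distinction irrelevant), realistic lab reference
ranges, calendar structure, or care-seeking behaviour. Passing tests
therefore demonstrate that the machinery recovers a planted latent signal
under controlled conditions — not clinical validity on real records.

## Preprocessing

Numeric labs are screened with scikit-learn's isolation forest
(contamination 0.01) per feature; flagged cells count as missing. Values
are then discretized into quantile bins (`n_bins = 10`, deciles) fitted on
training data only; bin `n_bins` is reserved for missing/unknown. A
constant feature collapses to a single bin; out-of-range values clamp to
the edge bins. Quantile binning makes a separate normalization step
unnecessary.

Text-like fields (feature names, history tokens, code names) are embedded
by a deterministic **hash embedding**: SHA-256 of the token seeds a PRNG
that emits a fixed unit-norm vector, identical across machines. This keeps
the architecture's "static encoding as preprocessing" contract — token
identity is preserved, distinct tokens are nearly orthogonal at dimension
32–64 — while requiring no model download or inference. Non-informative
history tokens (a configurable stop list: "unclear", "unknown", …) are
dropped before embedding.

## Model

All neural components run on a compact reverse-mode autodiff engine over
float64 numpy arrays (`contrastive_ehr.nn`), verified against central
finite differences end to end.

* **Structured encoder ψ_E** — per feature slot, a learned (feature, bin)
  embedding plus a projection of the feature-name hash embedding; slots are
  mixed by pre-norm single-head softmax transformer blocks (no positional
  encoding; the slot set is unordered).
* **Fusion f_X** — the structured slots concatenated with the embedded
  history are fused by gated single-head linear-attention blocks (gated
  attention unit with `relu²` scoring): quadratic attention within chunks
  of `chunk_size` (default 64) plus a running `kᵀv` linear term across
  chunks, so cost stays linear in sequence length. Within-chunk scores are
  normalized by the fixed chunk size, which keeps outputs independent of
  batch padding.
* **Text encoders f_D, f_M** — transformer stacks of the same shape over
  the embedded diagnosis/medication code names; a learned null token is
  prepended so empty fields remain well-defined, and the absence of
  positional encodings plus masked mean pooling makes the diagnosis and
  medication representations order-invariant.
* **Projection heads g_x, g_m, g_d** — two-layer MLPs to dimension 32,
  followed by L2 normalization (the usual cosine-similarity convention for
  contrastive objectives). The risk head reads the same normalized triple;
  normalization also bounds the logit's curvature, which keeps the
  integrated-gradients path integral accurate at moderate step counts.

The paired contrastive loss is `L_CP = L(x,m) + L(m,x) + L(x,d) + L(d,x)`
with each term a temperature-scaled InfoNCE over in-batch negatives
(τ default 0.07). Fine-tuning concatenates `[x‖m‖d]`, applies one affine
layer, and minimizes summed binary cross-entropy with probabilities clipped
to `[10⁻⁷, 1−10⁻⁷]`; the encoder is unfrozen by default (a
`freeze_encoder` flag covers the alternative) and the class imbalance of
the 1:3 matched cohorts is left unweighted, matching the
construction-by-matching design.

Desk-scale defaults — embed dim 32, 2 encoder layers, 2 fusion layers,
batch 64, Adam 3·10⁻³, 10 pre-training epochs, 2–5 fine-tuning epochs —
are chosen so a full study (generate → pre-train → match → fine-tune →
10-fold CV → attribution) runs in minutes on one CPU. At desk scale both
in-batch retrieval and downstream AUC improve with pre-training up to
roughly 10 epochs and degrade by 20 (the views over-align and discard
view-specific information), which fixes the default. The full-scale
reference configuration (24 layers, 2500-token inputs, lr 2·10⁻⁵, batch 6,
10 epochs) is kept as a documented preset that tests do not exercise.

## Cohort construction

A record is a **case** for window `W` if an outcome event falls in
`(discharge, discharge + W]` (half-open; integer day indices), **excluded**
if any outcome event falls in `[discharge − 183 d, discharge]`
(exclusion takes precedence; "six months" is fixed at 183 days for
determinism), otherwise control-eligible. Repeat records whose discharge
dates chain within 7 days are merged by transitive closure, keeping the
latest. Code matching is prefix-based, case-insensitive and dot-tolerant.
Exclusion applies at the record (hospitalization) level, following the
construction of the cohorts being emulated.

Controls are matched 1:3 by propensity score on exactly two covariates:
discharge time, and days from discharge to the event (cases) or to the
window end (controls). A logistic model on standardized covariates supplies
the logit; matching is greedy without replacement, in descending case
propensity, ties broken by record id. Because the control follow-up
covariate is a constant by construction, the propensity model typically
(near-)separates the groups, making logit distances meaningless for ranking
controls; the matcher detects this (propensity AUC ≥ 0.99) and falls back
to standardized euclidean covariate distance with a logged warning — the
direct reading of "similar discharge times and similar event times". No
caliper by default; one can be configured. Standardized mean differences
before/after matching are always reported.

## Evaluation and interpretation

ROC-AUC is the Mann–Whitney rank statistic with averaged ties; PR-AUC is
average precision (step integration). Cross-validation is stratified and
patient-disjoint (grouped by patient id) so repeat admissions never
straddle a split; baselines (logistic regression, random forest, XGBoost)
consume mean-imputed structured features concatenated with TF-IDF of the
token fields, with imputation means and vocabulary fitted per training
fold. Fold metrics are compared with a two-sided Welch t-test (a paired
mode exists since folds are shared); two zero-variance vectors compare as
p = 1 when equal and p = 0 otherwise, documented rather than undefined.
Decision curves report `NB(t) = TP/n − (FP/n)·t/(1−t)` on a 0.01–0.99 grid
with fold-wise mean ± sd and treat-all/treat-none references; threshold 1
is rejected (the harm weight diverges). External-validation style runs
(train on one cohort file, test on another) resample training folds and
keep the external test set fixed.

Integrated gradients use the midpoint Riemann rule (default 50 steps; 200
in the completeness checks) on the embedded input representation — the
differentiable surface of the model. The reference input is a
"no-information" patient: all structured slots at the missing bin with
feature names kept, and all text positions replaced by the learned null
token, so shapes always match. Per-dimension scores are summed within each
clinical feature and averaged over the attributed batch; the null/pad
positions are tracked so the per-feature table plus the null share exactly
conserves the per-dimension total.

## Numerical and design choices

* Dates are integer day indices; all windows are half-open on the left.
* One global seed fans out per stage as `(seed·1009 + stage_index) mod 2³¹`.
* Identical config + seed reproduces generator output byte-for-byte and
  matching/order decisions exactly; training is deterministic given the
  seed because the engine is single-threaded numpy.
* The contrastive loss at random initialization sits near `4·log K` only in
  the uniform-similarity regime (similarities ≪ τ); at the τ = 0.07 default
  the plateau is higher, so the initialization-plateau test pins τ = 1.
* Divergence (non-finite loss) aborts training with diagnostics rather
  than continuing silently.

## Known limitations

The generator's linear-logistic latent structure is easier than real EHR
data; the strong-signal condition is intentionally well-posed. A direct
consequence: because labs are linear in the latent state and tokens/codes
are drawn independently from latent-conditioned categoricals, a TF-IDF +
logistic-regression baseline is essentially the Bayes model family for
this synthetic world and sits at the task ceiling (10-fold mean ROC-AUC
≈ 0.90, with the planted Bayes score at ≈ 0.91–0.93). The fine-tuned
contrastive model tracks it to within about 0.006 AUC but does not
dominate it here; the advantage of contrastive pre-training over shallow
vectorization is expected on data whose text is not linearly sufficient,
which this generator deliberately does not emulate. The contrastive and
supervised stages also share one synthetic population (the real study
pre-trained and fine-tuned on different institutions). The hash embedding
carries no semantics between related codes, so nothing is said about
ontology-aware generalization. Sub-cohort institutional comparisons and
all numbers tied to the original hospital data are out of scope.
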