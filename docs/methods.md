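# Methods

This note documents the models and procedures implemented in `multiscreen`,
the assumptions behind them, the defaults that matter, and what the bundled
synthetic screens do and do not establish.

## Data model

A screen is a long table of viability measurements, one row per
(study, sample, drug, concentration, replicate). Concentrations are stored in
µM and handled internally in log10(µM); viability is fraction-of-control.
Values in (1, 2] are retained — over-control growth is common in raw screens —
while values above 2 are rejected at load time. Replicates are kept as
separate records and never pre-averaged; the observation model treats them as
independent draws. Validation is strict by default (invalid rows abort with
file line numbers) with a lenient drop-and-log mode behind a flag.

Per-drug dose grids place K points (default **K = 10**) uniformly in
log10(µM) over the drug's observed range pooled across studies. Drugs
observed at a single concentration c get a grid over
[log10 c − s, log10 c + s] with **s = 1.0** log10 units. These choices are
config-exposed: nothing downstream depends on a specific K beyond resolution,
and the single-dose span only needs to cover the plausible informative window
around the tested dose.

## Drug-name harmonization

Raw drug names are normalized (lower-casing, punctuation collapse, trailing
salt/solvate words stripped from an editable resource list) and merged
through an alias graph: nodes are normalized forms, edges come from exact
normalized matches, study aliases and a curated synonym table. Merging
iterates connected components to a fixpoint — each pass can expose newly
shared aliases. Components whose members carry contradictory curated
canonical names are split back along curated edges and reported for review
rather than merged; an irreducible curated contradiction is an error in
strict mode. Every merge decision is logged. The procedure is idempotent and
independent of study input order (both are asserted by tests). Cross-study
integration then keeps only drugs screened in ≥ 3 studies by default.

## Dose-response model

The core model is a constrained tensor factorization over
samples × drugs × concentrations. Each sample i has an embedding
v_i ∈ ℝ^d; each drug j has one embedding per dose-grid point,
u_j^(1..K) ∈ ℝ^d. Latent grid viabilities are cumulative retention products

    m_0 = 1,  m_k = m_{k−1} · σ(u_j^(k) · v_i),   k = 1..K,

so σ(u·v) is the fraction of viability retained between adjacent grid
points. This guarantees every inferred curve is monotone non-increasing and
lies in (0, 1], which is the substantive constraint: dose-response curves
for cytotoxic agents do not go back up. Observed concentrations between grid
points are linearly interpolated in log10 space; queries beyond the grid
ends are clamped flat.

**Likelihood.** Gaussian around the latent curve with a per-study noise
scale, learned log-parameterized. A Gaussian is the simplest likelihood that
accommodates viabilities above the (0, 1] model mean; the per-study scale
absorbs assay-level noise differences.

**Inference.** Mean-field Gaussian variational inference with the
reparameterization trick, one joint Monte-Carlo draw per gradient step,
closed-form KL against the N(0, τ²I) prior (τ = 1), optimized by Adam
(lr 0.05, 800 iterations by default). Posterior means are initialized small
(sd 0.05) and posterior log-sds at −3. Uncertainty is exposed by drawing S
(default 50) joint samples of all embeddings and summarizing the curve
ensemble; each draw's curve is individually monotone, so the 90% band is a
band over valid curves. A divergent step restores the last checkpoint.

**Contrastive regularization.** The training objective is
−ELBO + λ_s·L(samples | primary site) + λ_d·L(drugs | first-listed
mechanism), where L is a supervised contrastive loss on cosine similarities
of posterior means (for drugs, the concatenation of all K grid embeddings):
per anchor, −log(Σ_positives e^{sim/T} / Σ_others e^{sim/T}), averaged over
anchors with at least one positive. Defaults: λ_s = λ_d = 0.1, T = 0.5.
Unlabeled samples/drugs are excluded from the penalty, never from the
likelihood. The penalty injects the prior belief that same-tissue samples
and same-mechanism drugs respond similarly, which both regularizes sparse
entities and counteracts study-level clustering of embeddings.

**Capacity and identifiability notes.** d = 32 by default. Embedding
posteriors of weakly observed coordinates stay near the prior; this is
correct behavior but means raw embedding vectors are only identified up to
the subspace the data constrains — comparisons of embeddings across fits
should use predictions or similarities, not coordinates. Pilot-screen
embedding of a new sample (`embed_new_sample`) optimizes only the new
sample's posterior against the pilot likelihood with drug parameters frozen
at posterior means.

**Model persistence** is a directory with JSON metadata (config, ids, label
maps, format version) plus array blobs; predictions at a fixed seed are
identical after a save/load round trip. Major format-version mismatches
refuse to load; minor ones load with a warning.

## Curve summaries and de-batched z-scores

AUC is the trapezoidal integral of viability over the drug's log10 grid,
normalized by the range width (1 = no effect; lower = more cytotoxic). IC50
is the log-linearly interpolated first 0.5-crossing, with explicit censoring
(`above_max`, `below_min`) carrying the boundary value. AUCs for *all* pairs
— observed and imputed — are computed on the same model grid so they are
commensurable; provenance is recorded per cell.

The fitted model reproduces each study's assay scale, so model AUCs still
carry batch effects. De-batching uses a per-sample empirical null: most
drugs are inert for any given sample, so the bulk of its AUC histogram
estimates the "typical drug" distribution while true hits are outliers. The
null is the median and 1.4826×MAD, refined once by re-estimating (mean/sd)
on values with provisional |z| ≤ 2.5; the trimmed fraction is reported.
Then z = (μ₀ − AUC)/σ₀, so positive z = more cytotoxic than the sample's
typical drug. Because the null is per sample (hence per study — when a
sample appears in several studies it is nulled per (study, sample)), any
study-level affine shift of AUCs cancels exactly. A pooled global z-score is
implemented only as the comparison arm; on affine-batch fixtures its
per-study medians separate while the de-batched medians sit within ±0.2 for
≥95% of samples.

## Differential analyses

All tests run on de-batched z-scores unless stated. Conventions: Welch
(unequal-variance) t-tests wherever an unqualified t-test is called for;
minimum group size 3; Benjamini–Hochberg correction with a default FDR of
0.1. Tissue-vs-rest compares, per (tissue, drug), primary samples of a
tissue against all other tissues pooled (z-scores are already de-batched, so
no study stratification). Metastatic-vs-primary uses (a) per-(disease, drug)
signs of mean AUC differences with a one-sided binomial test for the
resistance direction, plus a standard-of-care-restricted two-sided
Mann-Whitney on within-(disease, drug) AUC ranks, and (b) per-(disease,
drug-group) z differences with percentile bootstrap CIs (1,000 resamples
over samples) and average-linkage clustering on the Pearson-correlation
distance of disease-wise difference vectors. Cell-line-vs-ex-vivo deviations
are permuted within (disease, status, class) strata (two-sided, add-one
floor), BH across strata, and aggregated per class across diseases by
Fisher's method. The paired "cell-cycling vs cell-signaling" comparison uses
normalized rankings: each drug's z is ranked within its sample and divided
by the panel size, averaged within drug group and (disease, modality), with
a two-tailed paired t-test across diseases — the normalization makes panels
of different sizes comparable. k-NN analyses use Euclidean distance;
disease purity uses the majority label among k = 5 neighbors (an any-match
variant is not provided; majority is the committed reading).

## Few-shot transformer

Tokens are the concatenation of three sub-embeddings (drug dictionary, dose,
viability), 3 × 128 = 384-d at paper scale. Continuous scalars (log10 dose,
viability) are embedded by learnable Fourier features: 32 frequencies
initialized log-spaced, sin and cos features, a learned linear map to the
sub-embedding width. Query tokens replace the viability slot with a learned
placeholder. Unknown drugs map to a reserved out-of-vocabulary embedding
with a warning.

The stack is 8 pre-norm transformer blocks (hidden 384, intermediate 512,
8 heads) applied to the concatenated [context ‖ query] sequence with an
attention mask: context positions attend only to context; each query attends
to the context and to itself. There are no positional encodings, so
predictions are invariant (to 1e-6) under permutations of either sequence,
and queries do not influence each other. Query representations pass through
a linear head; outputs are clipped to [0, 2] at the interface. A desk preset
(2 blocks, hidden 96, sub-embedding 32, 4 heads) keeps CPU runs fast; tests
and the acceptance script use it.

Training is episodic MSE: sample a biological sample, draw a context size
from the configured range, predict a random query subset of its remaining
measurements; Adam at lr 3e-3. Fine-tuning (the "++" mode) deep-copies the
model and takes a few epochs at lr 3e-4 on the new few-shot records only;
the original model is untouched. Sample embeddings are the mean-pooled
final-block context representations — pooling over an exchangeable set is
the natural permutation-invariant readout.

Probes are deliberately linear so that they measure the embeddings, not the
probe: logistic regression with stratified 5-fold CV and AUROC for binary
mutation status; ridge regression (inner-CV regularization) and per-fold
Pearson r for pathway activities. Pathway activity is PC1 of the member
genes after library-size normalization, log1p, and per-gene standardization,
signed so the mean gene loading is positive. Cross-modality consistency
combines one-sided Mann–Whitney tests across few-shot repeats with Fisher's
method, with the hypothesized direction declared per readout.

## Synthetic screens

The generator emulates the structure of multi-study ex vivo collections with
a fully known ground truth. True curves are descending Hill functions with
top fixed at 1 and bottom drawn in [0, 0.3]; every effect acts additively on
log10 IC50 (drug base potency, tissue×mechanism planted effects, mutation
effects, a metastatic resistance shift of +0.4, cell-line class shifts, a
rank-4 sample-latent contribution, and idiosyncratic noise of sd 0.25), so
truth curves stay monotone by construction. Class shifts for cell lines are
applied on the IC50 scale (sign-preserving) rather than the viability scale
so the Hill form is preserved. Batch effects are affine on the viability
scale (offset sd 0.05, scale sd 0.08), matching study-level assay
differences, plus Gaussian observation noise (sd 0.05) and clipping to
[0, 2]. The default "paper-shaped small" configuration is 6 studies × 30
samples, 120 drugs across 10 mechanisms, 8 tissues, 5-dose curves with one
single-dose study, 50% drug panels, seed 1. Six tissue×mechanism
sensitivities of −1.2 log10 units are planted as the recoverable ground
truth for the differential analyses; TMB is coupled to the first latent
factor so embedding neighbors share TMB.

What the generator does **not** emulate: real marginal distributions of
potencies or panel designs, plate/well structure, drug-combination effects,
non-monotone responses, censoring by assay floor, or realistic mutation
co-occurrence. Passing tests therefore establish that each method recovers
the structure it targets when that structure is present and calibrates
correctly when it is absent — not that effect sizes on real screens will
match.

## Problem sizes and numerical choices

Tests and the acceptance script run desk-scale problems: the default
synthetic screen (46,800 records), dose-model fits of 400–800 Adam
iterations, S = 20–30 posterior draws, the desk transformer for 300 episodic
steps, bootstrap/permutation counts of a few hundred, and 3–10 seeds for
rate assertions. These sizes are the package's defaults for interactive use;
all are config-exposed upward. Numerical guards: logistic and softplus are
computed in their stable forms; cumulative products go through log space;
contrastive similarities clip norms at 1e-12; degenerate spreads (constant
AUCs), empty groups, single-class probes and unknown ids raise explicit
errors rather than propagating NaNs. Ties in the power analysis's IC50
ranking break by lower AUC then lexicographic drug id; a top hit found in
the pilot itself counts as a success (a strict mode excludes it).

## Known limitations

- Mean-field VI underestimates posterior correlations; bands are pointwise
  and can be conservative for unobserved pairs while slightly narrow for
  well-observed ones. The uncertainty test therefore asserts rank agreement
  (wider band ↔ larger error), not exact coverage.
- The alias-graph conflict-split rule is one committed interpretation of
  iterative identity merging; genuinely ambiguous curation is flagged, not
  resolved.
- The bucketed-mean baseline is very strong at desk scale because synthetic
  per-study dose grids repeat across samples; comparisons against it are
  most informative when sample-level heterogeneity dominates.
- The transformer's in-context accuracy saturates quickly on synthetic
  screens (drug and dose main effects dominate); learning-curve gains beyond
  50 shots are small at desk scale.
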