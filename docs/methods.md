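# Methods

This note records the model, the defaults and the numerical choices made
where the design was genuinely open, and what the synthetic experiments
do and do not establish.

## Problem framing

A ubiquitylation-site predictor scores each lysine of a protein from its
local sequence context. The unit of prediction is a 31-residue window
centred on the lysine (15 residues each side); windows that run past a
protein terminus are padded with the pseudo-residue X. Residues outside
the 20-letter standard alphabet (B, J, O, U, Z, `*`, `-`, …) are also
normalised to X on input. Site annotations are 1-based protein
coordinates; all internal array indices are 0-based.

## Dataset construction

One fragment is extracted per lysine: annotated positions are positives,
all remaining lysines of the same (annotated) proteins are negatives.
Redundancy is removed by greedy incremental clustering at a pairwise
identity threshold (default 30 %): fragments are scanned in input order
and each joins the first cluster whose *founder* it matches at or above
the threshold, else founds a new cluster; founders are returned. For
equal-length ungapped windows, identity is the fraction of identical
columns, and X never counts as a match (two fully padded flanks are not
evidence of homology). This is a self-contained reimplementation of the
greedy-incremental idea behind CD-HIT, not a wrapper around it, and no
parity with CD-HIT's word-filtered definition is claimed. Clustering is
applied to positives and negatives jointly by default (per-class
available in the CLI). Classes are then balanced by uniform subsampling
of negatives, and a stratified test set is held out; both steps are
reproducible from a single seed.

## Feature statistics

* **AAC**: A_r = N_r / N with N = window × fragment count. X stays in
  the denominator (N is defined as total fragment length) but is not
  reported as a residue, so the 20 frequencies sum to 1 only for X-free
  data. This asymmetry is deliberate and documented.
* **AAPC**: dipeptides are the 30 overlapping ordered adjacent pairs per
  window; pairs touching X are excluded from numerator and denominator.
  (Non-adjacent pairs belong to the k-spaced-pair encoding, a different
  feature family, out of scope.)
* **PWM**: 21 × 31 residue-by-position counts; every column sums to the
  fragment count.
* **Log-ratios** (the P_{r,s} and M_PA heatmaps): counts or pooled
  frequencies are compared elementwise as ln((pos + c)/(neg + c)) with a
  Laplace pseudocount c = 1 by default, which keeps empty cells finite.
  Counts are pooled first and normalised once.
* **Two-sample logo**: per (residue, position) two-proportion z test
  using the pooled-variance statistic; the centre column (always K) is
  excluded. Default α = 0.05 without multiple-testing correction, with a
  Bonferroni option over the 20 × 30 tested cells. Whenever a claim is
  about the *exact set* of significant cells (as in the planted-motif
  recovery checks), the Bonferroni option is the right tool: at α = 0.05
  uncorrected, ~30 of 600 null cells are expected to flag by chance.

## Embedding pretraining

Sequences are tokenized into all overlapping bigrams (400 tokens + 1 pad
token for X-containing grams; tokenizing the single stream of overlapping
bigrams is equivalent to tokenizing the two frame-offset non-overlapping
streams). Skip-gram training pairs each token with its neighbours within
±2 positions; pad tokens never act as centre or context. The objective
is negative sampling (k = 5, noise = unigram^0.75), 5 epochs, learning
rate 0.025 with linear decay, mini-batched and deterministic per seed.
These output-side details are standard word2vec practice; embedding
dimension defaults to 20 to match the 30 × 20 classifier input, with the
dimension exposed in the config (a 200-dimensional setting is equally
supported).

**Mean-centring.** The returned matrix is the input-side weight matrix
with its trained rows mean-centred (`SkipGramConfig.center`, default
on). Skip-gram vectors share a large common component that encodes
corpus frequency rather than token identity; on near-uniform corpora
this component is an order of magnitude larger than the informative
residual (measured here: common-mean norm ≈ 1.25 vs residual ≈ 0.11) and,
transferred into a small-initialisation network, it saturates the first
convolution and stalls fine-tuning completely. Removing the common mean
is standard word-vector post-processing and leaves all pairwise geometry
intact.

## Classifier

Embedding lookup → three blocks of [1D convolution (128 filters, width
3, valid padding, ReLU) → max pool (2) → dropout (0.5)] → dense 128 →
dense 64 (ReLU) → sigmoid unit. Valid padding gives the length chain
30 → 28 → 14 → 12 → 6 → 4 → 2 (flatten = 256); padding mode, dense
activation and all sizes are configurable. Loss is mean binary
cross-entropy with scores clipped to [1e-7, 1 − 1e-7]. The optimiser is
RMSprop with learning rate 0.001 and squared-gradient decay β = 0.9;
conv/dense weights start from Gaussian(0, 0.01), biases at 0, and the
embedding from the transferred matrix (fine-tuned unless frozen).
Dropout and shuffling derive from the training seed, so runs are
bit-reproducible; dropout is inference-disabled, and predictions are
invariant to inference batch size.

Numerical choices worth recording:

* **RMSprop ε = 1e-8.** With σ = 0.01 initialisation the early weight
  gradients sit near 1e-9; an ε of 1e-7 dominates the adaptive
  denominator and suppresses learning almost entirely, while 1e-8 (the
  common default in at least one major framework) lets the usual
  RMSprop behaviour emerge. The backward pass is verified against
  central finite differences (worst relative error ~3e-7).
* **Small-initialisation fragility.** In the σ = 0.01 regime the
  network must amplify weights over hundreds of steps before the loss
  moves. During that phase RMSprop steps biases by ~lr per update while
  pre-activations are only ~1e-3, so conv biases can drift negative and
  permanently silence rectifier units (observed: up to ~70 % dead
  filters in the deeper blocks of stalled runs). With strong class
  signal the weights outgrow the drift reliably; with weak signal,
  convergence from σ = 0.01 is intermittent at small problem sizes.
  Defaults are kept at the stated σ = 0.01; experiments whose *purpose*
  is a controlled comparison (below) raise the initialisation to
  σ = 0.05 in **all** arms so that optimisation reliability does not
  masquerade as a treatment effect.

## Evaluation

Accuracy, precision, recall and F-score come from the confusion matrix
at threshold 0.5 (score ≥ threshold predicts positive). Undefined ratios
(no predicted positives / no actual positives) are reported as NaN with
a warning rather than silently as 0. AUC uses the rank (Mann–Whitney)
formulation with ties counted ½, which equals the trapezoidal area under
the empirical ROC curve. Repeated k-fold cross-validation draws a fresh
partition per repeat (one seed per repeat) and aggregates mean ± sample
standard deviation over all k × repeats fold results; folds are
stratified by default so every fold preserves the designed 1:1 class
balance (plain random partitioning is available).

## Synthetic data: what it emulates and what it does not

Background proteins draw residues i.i.d. from a stated composition
(uniform by default) with shifted-geometric lengths (min 31). Positive
fragments draw each flank position independently from the background
multiplied by per-(residue, offset) enrichment factors and renormalised;
negatives are pure background; both are K-centred. The corpus generator
implants positive windows into background proteins at annotated lysines,
so the FASTA + site-table round-trips through the full dataset pipeline
and doubles as a pretraining corpus carrying the motif structure. A
dipeptide-repeat corpus (pure a-b-a-b proteins, the synthetic analogue
of low-complexity regions) provides planted token co-occurrence for
embedding checks: in such a protein the bigram token *ab* co-occurs
exclusively with its reversal *ba*, its designated nearest-neighbour
partner.

The plant-like preset enriches arginine at flank offsets −9…−5 and
+1…+8, mirroring the qualitative pattern reported around plant
ubiquitylation sites. Because flank positions are independent, the
Bayes-optimal discriminant for this single-residue motif is the R count
over the enriched offsets, and the exact attainable AUC ceiling follows
by binomial enumeration (`bayes_auc_ceiling`). The presets were fixed
from that calculation: ×3 ("moderate", consistent with the roughly
doubled arginine composition of real plant positives; ceiling 0.769) and
×8 ("strong"; ceiling 0.960, chosen so that recovery above AUC 0.9 is
information-theoretically possible with margin — no classifier can reach
0.9 under the ×3 motif). The generator does *not* attempt real
ubiquitylation biology: no E3-ligase specificity, no domain structure,
no compositional heterogeneity between proteins, and no correlated flank
positions. Passing the synthetic experiments therefore demonstrates that
the pipeline recovers planted positional signal up to near its
information-theoretic ceiling — not that any particular accuracy will be
reached on curated plant data.

## Synthetic experiments and their problem sizes

* **End-to-end recovery**: per seed, a 150-protein pretraining corpus
  (mean length 300), 2,000 + 2,000 labelled fragments, embedding
  dimension 20, 20 training epochs at batch 100, 3-fold stratified CV.
  Strong-effect mean CV AUC lands near the 0.96 ceiling (≈ 0.94); the
  null preset stays at chance. Batch 100 (rather than the 500 default)
  keeps the optimiser step count adequate at this reduced sample size,
  and 3 folds estimate the same mean as more folds at a third of the
  cost.
* **Transfer comparison**: per seed, both arms share data and every
  hyperparameter; only the embedding initialisation differs (pretrained
  + fine-tuned vs Gaussian(0, 0.01)). Moderate effect, 1,000 + 1,000
  train, 500 + 500 test, 20 epochs, batch 100, init σ = 0.05 in both
  arms (see above), 5 seeds. The expected ordering (pretrained ≥ random)
  is asserted non-strictly with a 0.03 tolerance on mean accuracy: at
  this scale the margin between arms is small and seed-dependent, and
  the claim defended is "pretraining does not hurt and tends to help",
  not a specific margin.

## Known limitations

* The greedy clustering is O(fragments × clusters) and single-threaded;
  adequate for ~10⁵ windows, not for proteome-scale redundancy removal.
* The CNN is CPU NumPy; a full 120-epoch, batch-500 run on a 5,500
  fragment dataset takes minutes, not seconds, and there is no GPU path.
* Undefined precision/recall propagates NaN into F-scores on degenerate
  folds rather than imputing 0; summary means over folds use
  NaN-ignoring aggregation.
* The two-sample logo z test is asymptotic; at very small per-class
  counts an exact test would be preferable.
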