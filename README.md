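# ubisite

Sequence-based prediction of lysine ubiquitylation sites in plant
proteins, with the comparative sequence statistics used to characterise
ubiquitylation motifs and a repeated cross-validation harness.

Ubiquitylation — the covalent attachment of ubiquitin to a substrate
lysine via the E1/E2/E3 enzyme cascade — regulates protein degradation
and signalling throughout plant physiology. Experimentally mapping which
lysines are modified is slow and expensive, so classifiers that score
candidate sites from sequence alone are widely used. Plant sites carry a
distinctive local sequence pattern (notably arginine enrichment around
the modified lysine) that differs from animals and fungi, which motivates
a plant-specific model. `ubisite` is aimed at computational biologists who
want a transparent, dependency-light, fully reproducible implementation
of such a predictor, together with the statistics used to describe the
motifs.

## Model

A candidate site is the 31-residue window centred on a lysine (flanks
beyond the protein termini padded with the pseudo-residue X). The window
is read as its 30 overlapping bigrams over the 20-letter alphabet
(20² = 400 bigram tokens plus one pad token).

1. **Unsupervised pretraining.** A skip-gram model with negative
   sampling is trained on the bigram streams of whole protein sequences:
   each token predicts its neighbours within ±2 positions. The trained
   input-side weight matrix assigns every bigram a d-dimensional vector
   (d = 20 by default); rows are mean-centred before use.
2. **Supervised fine-tuning.** The vectors initialise the embedding
   layer of a 1D CNN — three blocks of [convolution (128 filters, width
   3, ReLU) → max-pool (2) → dropout (0.5)], then dense 128 → dense 64
   (ReLU) → one sigmoid unit giving P(site is ubiquitylated). With valid
   convolutions the token axis runs 30 → 28 → 14 → 12 → 6 → 4 → 2, so the
   flattened feature vector has 256 entries. Training minimises mean
   binary cross-entropy with RMSprop (lr 0.001, decay β = 0.9, batch 500,
   120 epochs by default); the embedding is fine-tuned with the rest.

Alongside the classifier:

- **AAC** A_r = N_r / N — per-residue composition;
- **AAPC** D_{r,s} = N_{r,s} / N — adjacent-dipeptide composition, and
  its positive/negative log-ratio heatmap P_{r,s} = ln(ΣD⁺ / ΣD⁻);
- **PWM** — residue × position counts, and the positional log-ratio
  M_PA = ln(ΣM⁺ / ΣM⁻);
- **two-sample logo** — per (residue, position) two-proportion z tests
  flagging significantly enriched/depleted cells;
- **evaluation** — confusion-matrix metrics, rank-based (Mann–Whitney)
  AUC, and repeated stratified k-fold cross-validation;
- **synthetic data** — background proteins and motif-planted fragment
  sets with controllable effect size, so the whole pipeline runs and is
  tested without any external database.

Everything numerical (skip-gram, CNN forward/backward, RMSprop) is
vectorised NumPy; no deep-learning framework is required.

## Worked example

The synthetic generator stands in for a curated FASTA + site table; every
command below also accepts real data in the same formats (FASTA;
TSV `protein_id<TAB>position`, 1-based).

```sh
ubisite simulate --n-proteins 40 --mean-length 250 --effect 8.0 --seed 7 \
    --out-fasta plant.fasta --out-sites sites.tsv
# wrote 40 proteins to plant.fasta; 72 sites to sites.tsv

ubisite build-dataset --fasta plant.fasta --sites sites.tsv \
    --identity 0.30 --seed 7 --out dataset.tsv
# train: 142 fragments (71 positive) -> dataset.tsv

ubisite pretrain --fasta plant.fasta --epochs 5 --seed 7 --out embedding.tsv
# trained 401 x 20 embedding on 31604 pairs -> embedding.tsv

ubisite train --dataset dataset.tsv --embedding embedding.tsv \
    --epochs 20 --batch 32 --seed 7 --out model/
# final training loss 0.1989; model saved to model/

ubisite predict --model model/ --fasta plant.fasta --threshold 0.5 \
    --out predictions.tsv
# 239 sites predicted at threshold 0.5 -> predictions.tsv
head -5 predictions.tsv
# protein_id    position  score     label
# synth8_00000  9         0.027137  0
# synth8_00000  11        0.044650  0
# synth8_00000  24        0.194965  0
# synth8_00000  52        0.999697  1
```

`build-dataset` extracts one fragment per lysine (annotated ones
positive), removes redundancy by greedy 30 %-identity clustering, and
balances classes by subsampling negatives; here 72 planted sites yield 71
positives after clustering plus 71 matched negatives. The prediction
table scores **every** lysine of each input protein: position 52 of the
first protein is a planted site and scores 0.9997, while unmodified
lysines score low. `ubisite features --dataset dataset.tsv --out-dir
features/` writes the AAC/AAPC/PWM/logo tables for the same dataset, and
`ubisite evaluate` runs repeated stratified k-fold cross-validation.

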