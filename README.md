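# pirnadetect

Sequence-based detection of Piwi-interacting RNAs (piRNAs) using n-gram
Markov model features and a support vector machine.

piRNAs are 26–36 nt small non-coding RNAs that guard germline genomes
against transposons. They lack conserved structure and cross-species
sequence homology, so classifying a short sequence as piRNA or not is
hard. This package implements a detector for that problem, aimed at
computational biologists who have a set of known piRNAs (e.g. a piRBase
export) and a pool of background ncRNAs (e.g. Rfam sequences) in FASTA,
and want calibrated piRNA/non-piRNA calls for new sequences — plus a
k-mer baseline and an evaluation harness to measure how well that works.

## Method

**1. Motif-family clustering.** An n-gram model (NGM) is an
(n−1)th-order Markov chain over {A,C,G,T}; the tetragram (n = 4) is the
default. The homology likelihood of the length-L window of sequence b̲
at offset k is

    R(b̲, k) = log P(b_{k+1..k+n−1}) + Σ_{i=k+n..k+L} log P(b_i | b_{i−n+1..i−1})

with state and transition probabilities estimated from counts plus a
pseudo-count α (mutation tolerance). The similarity S(b̲) is the
maximum of R(b̲, k) over all offsets, computed with a constant-work
sliding update; L is the minimum sequence length in the dataset. Raw
similarities are standardized against a Monte-Carlo null of
mononucleotide-shuffled sequences:

    Z(b̲) = (S(b̲) − μ) / σ.

Training piRNAs are partitioned into homologous families by repeatedly
taking the sequence containing the most frequent (n−1)-gram as a seed,
fitting an NGM on it, and collecting every sequence with Z ≥ Z_th; a
group of at least N_th sequences becomes a family (defaults
(N_th, Z_th) = (200, 1.5)).

**2. Z-score features and SVM.** Each family's NGM is refitted on its
members and calibrated with shuffled ensembles (18,000 sequences by
default) at anchor lengths 21, 26, 31, 36; μ(length) and σ(length) are
interpolated by ε-SVR regression (RBF kernel). A sequence's feature
vector is its Z-score against every family — typically well under 50
features — and a C-support-vector classifier with RBF kernel maps it to
a piRNA confidence probability.

**3. Baseline and evaluation.** The k-mer baseline counts all 1,364
k-mers (k = 1..5) and scores sequences by class-conditional log-odds
with a decision cutoff t (default 1.2), or feeds the counts to the same
SVM. The evaluation module builds length-matched shuffled negative
controls, runs stratified 5-fold cross-validation, and reports
ACC = (TP+TN)/(TP+TN+FP+FN), TPR = TP/(TP+FN), FPR = FP/(TN+FP), ROC
curves and AUC.

Because real piRNA/ncRNA corpora are external downloads, the package
ships a synthetic-fixture generator (`pirnadetect.simulate`) producing
ground-truth-labeled motif families — short sequences sharing a planted
12-nt motif with 10% per-base mutation noise, embedded in random flanks
— plus background pools, so the whole pipeline is testable offline.

## Worked example

Simulate a labeled dataset, train a detector, and score sequences:

```
$ pirnadetect simulate --out demo/data --num-families 2 --family-size 150 \
      --background-size 300 --seed 1
wrote 300 positives, 300 background sequences to demo/data

$ pirnadetect train --positives demo/data/positives.fasta \
      --negatives demo/data/background.fasta --out demo/model \
      --n-th 80 --ensemble-size 1000 --detection-ensemble-size 2000 --seed 2
trained 2-family detector -> demo/model

$ pirnadetect predict --model demo/model --input demo/data/positives.fasta \
      --out demo/pred
252/300 sequences called piRNA

$ head -4 demo/pred/predictions.tsv
id      label   confidence
fam0_m0 piRNA   0.986009
fam0_m1 piRNA   0.993133
fam0_m2 piRNA   0.988083
```

The trainer recovered both planted families and built one Z-score
feature per family; 252 of the 300 true family members clear the 0.5
confidence threshold. Cross-validated evaluation against shuffled
negatives prints the standard metrics (AUC on the ×100 scale):

```
$ pirnadetect evaluate --positives demo/data/positives.fasta \
      --background demo/data/background.fasta --out demo/eval \
      --n-th 60 --ensemble-size 1000 --detection-ensemble-size 1000 --seed 3
ACC=0.8617 TPR=0.7733 FPR=0.0500 AUC=91.31
```

So on this fixture the detector accepts 77% of true piRNAs while
flagging only 5% of shuffled controls. `pirnadetect sweep` grids
dataset size × N_th × Z_th (the family-count/accuracy trend harness)
and `pirnadetect kmer-baseline` runs the 1,364-feature comparison.

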