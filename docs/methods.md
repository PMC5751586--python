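# Methods

## Model

A sequence b̲ = (b_1, …, b_|b̲|) over {A,C,G,T} (U mapped to T on
input) is scored against an n-gram model (NGM): an (n−1)th-order Markov
chain with state probabilities P(g) for every (n−1)-gram g and
transition probabilities P(x | c) for each base x given its (n−1)-gram
context c. Probabilities are estimated from windowed counts over the
training sequences — every (n−1)-gram window contributes to the state
counts, every n-gram to the transition counts — with an additive
pseudo-count α in each cell, so all probabilities are strictly positive
and point mutations are penalized rather than annihilated.

The log-likelihood of the length-L window at 0-based offset k is

    R(b̲, k) = ln P(b_{k+1..k+n−1}) + Σ_{i=k+n}^{k+L} ln P(b_i | b_{i−n+1..i−1})

(1-based indices in the formula; the code uses 0-based offsets). The
homologous similarity S(b̲) = max_k R(b̲, k) is computed for all
offsets at once from a prefix sum of the transition log-terms —
algebraically identical to the O(1)-per-shift sliding update (drop the
leading state and transition terms, add the trailing term, re-add the
new leading state term) — and ties go to the smallest offset. The
window length L is the minimum sequence length in the dataset, so every
sequence offers at least one window.

Because S depends on sequence length and model composition, scores are
standardized: Z(b̲) = (S(b̲) − μ)/σ, where μ and σ are the mean and
standard deviation of S over a null ensemble of shuffled sequences.

## Clustering into motif families

Training piRNAs are partitioned greedily. The pool-wide occurrence
count of every (n−1)-gram is tallied; the sequence containing the most
frequent gram is the seed (ties: more own copies of that gram, then
input order — this targets repeat-derived piRNAs, which share motifs
with repeat subsequences). An NGM is fitted on the seed alone, a
clustering-stage null is built by shuffling random length-L windows of
the pool, and every pool sequence with Z ≥ Z_th joins the candidate
family. If at least N_th sequences are collected, the family is
accepted: its NGM is refitted on all members, its calibration rebuilt,
and the members are removed from the pool. Otherwise the seed is
retired — ineligible as a future seed but still collectible by later
families. The loop ends when every remaining sequence has been tried as
a seed; each iteration removes ≥ N_th sequences or retires one seed, so
termination is guaranteed (asserted with a 2·|dataset| iteration bound).
L is fixed once from the full dataset (not recomputed as the pool
shrinks) so all families score on one scale.

## Detection features and classifier

For detection, each family's refitted NGM gets a length-resolved
calibration: ensembles of shuffled training-set windows (default
18,000 sequences) at anchor lengths 21, 26, 31, 36 nt give empirical
μ(ℓ) and σ(ℓ), and an ε-SVR with RBF kernel interpolates between
anchors; outside the anchor range predictions clamp to the nearest
anchor. A sequence's feature vector holds its Z-score against every
family (family discovery order); scan windows are capped at the
sequence length. An RBF-kernel C-SVC on these features produces the
final call, with a Platt-style sigmoid mapping of the decision value to
a confidence probability (label piRNA iff confidence ≥ 0.5; the
evaluation module sweeps the threshold for ROC curves). Z-scores are
already standardized, so no additional feature scaling is applied.

## Parameters

| parameter | default | meaning / rationale |
|---|---|---|
| n | 4 | gram size; the tetragram balances motif specificity against robustness to variation for 26–36 nt sequences |
| α (pseudo-count) | 1 | Laplace smoothing; collection quality is insensitive to α over 0.02–16 on synthetic families |
| Z_th | 1.5 | family-membership Z threshold |
| N_th | 200 | minimum family size; smaller values find more (smaller) families |
| L | dataset min length | scan window (nt) |
| clustering ensemble | 2,000 | null size per seed attempt (runs once per seed; a smaller ensemble keeps clustering fast) |
| detection ensemble | 18,000 | null size per anchor length for μ/σ estimation |
| anchor lengths | 21, 26, 31, 36 | calibration lengths spanning the piRNA size range (step 5) |
| SVR (μ, σ regression) | C=100, ε=0.01, RBF, standardized x and y | with four anchor points the regression must near-interpolate; small C shrinks predictions toward the anchor mean and mis-centers Z far from zero, so C is set high. Any smooth interpolator reproducing the anchors would do |
| SVM (detector) | C=1, γ='scale' | standard defaults; optional 3-fold-CV grid search over C ∈ {0.1,1,10}, γ ∈ {0.01,0.1,1} |
| k-mer cutoff t | 1.2 | decision threshold of the baseline score |

## Null ensembles and shuffling

Shuffles preserve mononucleotide composition (a dinucleotide-preserving
shuffle is a possible extension; any shuffle destroys the n-gram
structure the models key on, and the mono shuffle matches the
negative-control construction). Ensemble members are random
length-matched windows of randomly drawn source sequences, shuffled;
the source is the positive training set itself, so calibration needs no
negatives. Negative controls for training/evaluation are built the same
way from a user-supplied background pool, one length-matched shuffled
window per positive. Sample standard deviations use ddof=1; a null with
σ < 1e−12 (e.g. under the uniform model, whose score is a deterministic
function of length) is rejected as degenerate.

## Synthetic fixtures

`pirnadetect.simulate` draws families of sequences sharing a planted
motif: a random 12-nt template, copied with i.i.d. per-base
substitutions at rate 0.10 into each member, embedded at a random
offset in i.i.d. random flanks; lengths are uniform on [26, 36] nt
(the piRNA size range) and the background pool is i.i.d. from a
(default uniform) base-composition model. Motifs are embedded rather
than whole-sequence homologous so the max-over-windows scan is
genuinely exercised. Everything is reproducible from one seed, and a
ground-truth map accompanies each draw.

What the fixtures do not emulate: real piRNA base-composition bias
(e.g. 5′-U preference), families related by more than one short motif,
length-composition correlations, and structured (Rfam-like) background
sequences. Passing on fixtures therefore demonstrates the mechanics
and the statistical calibration of the pipeline, not field performance
on real piRNA corpora — the harness accepts any user-supplied FASTA
for that.

A note on difficulty: at the default 10% mutation rate the planted
motif retains large recoverable signal (a matched filter on the true
motif separates members from background almost perfectly), but a
single-seed tetragram model is a much blunter instrument — family
collection recovers roughly two thirds of planted members, and
background sequences, being distributed like the shuffled null, exceed
Z = 1.5 at the null tail rate (~8% under a length-matched null, higher
under the fixed-length clustering null, which inflates the Z of
sequences longer than L). Both effects are properties of the method,
not bugs: at mutation rate 0 recovery and held-out AUC are perfect,
and `scripts/acceptance.py` recomputes the operating figures at the
default settings on every run.

## Numerical and design choices

- Natural logarithms throughout; the base cancels in Z-scores but is
  fixed for serialized scores.
- State probabilities count all (n−1)-gram windows (not only
  window-initial grams): short sequences give few counts, and the
  choice only shifts R by a near-constant.
- Scan tie-break: smallest offset, for determinism.
- The clustering stage uses a single fixed-length null (scalar μ, σ) at
  L; the detection stage uses the per-length anchored regression. One
  calibration per family (each family has its own score scale).
- Model documents are JSON (probabilities round-trip exactly via
  shortest-repr floats); calibrations store anchors and refit their
  regressors deterministically on load; the SVM state is serialized
  with joblib inside the model bundle.
- The k-mer baseline's published scoring internals are not public; the
  implementation here scores by length-normalized log-odds of
  class-conditional k-mer frequencies (per-k additive smoothing),
  thresholded at t, and also offers the SVM back-end on raw counts for
  an apples-to-apples feature comparison.
- ROC curves pool held-out confidences across CV folds (per-fold counts
  are also reported); folds are stratified by class; AUC uses the
  trapezoidal rule and is reported ×100.

## Limitations

- Genome-scale scanning (sliding windows over chromosomes) and
  locus/cluster-based detection are out of scope; inputs are short
  extracted sequences.
- No backoff/interpolated smoothing beyond the single pseudo-count.
- Family collection is single-pass per seed; iterative re-collection
  after refitting would recover more members but is a different
  procedure.
- With very small positive sets (fewer than N_th usable sequences) no
  family can form and training fails with an explanatory error.
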