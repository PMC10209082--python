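# Methods

## Problem and model

Plastids carry proteins from two genomes. Nuclear-encoded proteins are
imported through the envelope using a cleavable N-terminal transit peptide;
plastid-encoded proteins are synthesised in the stroma. Within the
organelle a protein resides in the envelope (inner or outer membrane), the
stroma, the thylakoid membrane, or the thylakoid lumen, which is reached
through the Sec or the Tat translocon (Tat substrates carry the
twin-arginine RR motif and travel folded). `subplastid` predicts one of
eight classes combining origin and compartment — N_E, N_TM, N_S, N_TL_SEC,
N_TL_TAT, P_IM, P_TM, P_S — and derives from the prediction the origin, the
generalized localization, the lumenal import pathway, and optionally an
inner/outer envelope membrane call for N_E proteins.

The predictor is a stacked ensemble (S, G): a set of lower-level models
S = {S1..Sn}, each answering one labelling question, and a higher-level
predictive model G trained on their outputs, so that
ŷ = G(S1(x), ..., Sn(x)). The default registry has eight lower-level
models: six random forests on gapped n-gram presence features (origin,
membrane association, P_IM vs P_TM, N_E vs N_TM, N_S vs other nuclear,
nuclear membrane vs other nuclear) and two profile HMMs scoring the Sec and
Tat lumenal targeting signals. The higher-level model is a 500-tree
probability forest by default; a multinomial log-linear model (penalized
maximum likelihood with a tiny ridge, 1e-6, purely against separability) is
available. An optional *conditional* mode implements expert routing: a
guard model's decision (e.g. "plastid-encoded") masks the models that are
meaningless for that record (the nuclear-only models); masked meta-feature
cells are set to 0 and flagged through companion binary mask columns, so G
can distinguish "masked" from "genuinely zero". Guards decide at
probability 0.5; an exact tie leaves every model active.

By default the higher-level model is trained on the lower-level models'
in-sample outputs on the same training records. An out-of-fold mode
(`EnsembleConfig.out_of_fold`) is available for users worried about
stacking leakage; it is off by default to match the protocol this package
reimplements.

## Features and selection

Sequences are represented by binary presence/absence of gapped amino-acid
n-grams: 20 unigrams; bigrams with a gap of 0–3 wildcard positions
(4 x 400 = 1,600); trigrams with two gaps of 0 or 1 wildcards each
(4 x 8,000 = 32,000); 33,620 patterns in total. The stated gap rule for
trigrams ("gaps of length 1") is ambiguous between {1}x{1} and {0,1}x{0,1};
we take the maximal reading, isolated behind the `TRIGRAM_GAPS` constant.
Presence matrices are stored sparse; patterns never observed in the data
are pruned before testing (an all-zero column has p = 1 by definition).

Per-model feature selection uses QuiPT, the quick permutation test: with a
binary feature and binary target the permutation distribution of any
contingency statistic depends only on the 2x2 table overlap, which follows
a hypergeometric law at fixed margins — so the exact permutation p-value is
a hypergeometric tail sum over the overlaps whose statistic reaches the
observed one. The statistic is the mutual information of the table in
bits. The selection cutoff is p < 0.01 (note the strict inequality: a
non-constant feature whose overlap sits at the hypergeometric mode has
exactly p = 1 and is never selected, even at alpha = 1).

Class imbalance on designated tasks (the membrane model by default) is
handled by SMOTE oversampling written for binary features: a synthetic
minority row interpolates a random minority row toward one of its k = 5
nearest minority neighbours under Hamming distance and rounds at 0.5 (ties
to 1), keeping the feature space binary. Majority rows are never altered.

## Profile HMMs

Sec/Tat signal models are profile HMMs estimated from input alignments of
signal regions (the alignments are inputs; this package does not align).
Columns with gap fraction < 0.5 become match states. Match emissions are
(count + 1) / (column residue count + 20); insert emissions are tied to the
background (uniform 1/20 by default); transitions are estimated from
observed state paths with the same +1 pseudocount over each state's allowed
successors; rows are weighted equally (no effective-sequence-number
weighting — the estimation formulas are pinned by a brute-force path
enumeration oracle in the tests rather than by compatibility with any
external profile builder). The architecture is glocal: begin-to-end
traversal of all match columns with flanking insert states absorbing the
rest of the query's N-terminal window (first 100 residues by default, where
targeting signals live). Scores are forward log-odds in bits against an
i.i.d. background null; Viterbi scoring exists for diagnostics and is
bounded above by the forward score. Inside an ensemble, HMM scores are
z-standardized with the training-set mean and standard deviation, since
raw bit scores are not commensurate with the forests' probabilities.

## Homology handling

Pairwise identity is computed from a Needleman–Wunsch global alignment
under BLOSUM62 with gap open 10 / extend 0.5 and free end gaps (the classic
`needle` convention; a gap of length L costs open + L·extend), as
100 x identical columns / alignment length (a shorter-sequence denominator
is available to mimic k-mer clustering tools). The pair is sorted before
aligning so tie-breaking among co-optimal alignments cannot break symmetry.

Homology *reduction* (default 90% within each class) is greedy incremental
clustering, longest sequence first, each sequence joining the first
representative it matches at or above threshold. Exact all-pairs alignment
replaces k-mer prefilter heuristics — the datasets targeted here are a few
thousand sequences at most, and the contract (no retained pair at or above
threshold within a class) is unchanged. Reduction is idempotent because
every representative was checked against all earlier representatives.

Homology *partitioning* (default 40% threshold, 15% independent fraction)
forms single-linkage clusters over the at-or-above-threshold identity graph
and assigns clusters whole, largest first, taking a cluster into the
independent set only when that moves the achieved fraction closer to the
target; records are never relocated out of their cluster. This guarantees
every cross-set pair is below threshold, and the achieved fraction is
within one cluster of the target. The exact cluster-assignment heuristic
of the originally cited partitioning procedure is not restated in our
source protocol; largest-first greedy is this package's documented choice
honouring the stated constraints. A dataset collapsing into one cluster
cannot be split and is an explicit error.

## Evaluation

Stratified k-fold cross-validation (default 5 folds) repeated (default 5
times, fresh fold assignments per repetition) with all models retrained
inside each fold; metrics are computed per fold x repetition cell and
pooled over all 25 cells (whether to average folds first is immaterial for
balanced folds; pooling is the documented choice). Metrics: Cohen's kappa
((p_o − p_e)/(1 − p_e); the degenerate p_e = 1 case is defined as 0 with a
warning), the Hand–Till average one-vs-one multiclass AUC (AU1U; ties
credited 0.5, pairs with an absent class skipped — it equals the ordinary
AUC for two classes), and per-class accuracy interpreted as the recall of
each true class (the convention under which a single class has a
well-defined accuracy); absent classes are reported missing, never 0.
Model selection over a configuration space takes the argmax of mean CV
kappa, breaking exact ties toward fewer lower-level models. The candidate
space is generated by a slot grammar (Cartesian product of per-slot model
options, deduplicated) crossed with {plain, conditional} x {random forest,
multinomial log-linear}, a factor of 4.

## Synthetic data generator

The generator emulates the *signal structure* the method exploits, one
seeded generator driving all randomness:

- mature regions: i.i.d. draws, uniform 1/20 for nuclear-encoded classes;
  plastid-encoded classes add delta = 0.02 to each of {F, I, L} and
  renormalize (the recoverable per-residue difference is therefore
  (0.05 + delta)/(1 + 3 delta) − 0.05 ≈ 0.016, the quantity the
  compositional-shift test checks); mature length uniform on 60–140;
- transit peptides on nuclear-encoded classes: length uniform on 30–80,
  S/T probability 0.30 total, D/E probability 0.02 total (qualitative
  literature consensus; free generator parameters);
- lumenal classes: a shorter transit peptide (uniform 20–32, so the
  twin-arginine motif always falls within the first 40 residues) followed
  by a bipartite signal of fixed 24-column layout — polar n-region
  (ending in RR for Tat, arginine-free for Sec), 12-residue hydrophobic
  h-region, polar c-region;
- membrane classes: 1–3 transmembrane-like runs of 18–24 residues from
  {A, I, L, V, F, M} (N_E-OM 1, N_E-IM and N_TM and P_IM 2, P_TM 3),
  spliced at cut points of the base sequence so runs and motifs never
  interrupt each other;
- signature motifs with probability 0.9 where compartments are otherwise
  compositionally alike: DPLG for N_TM (the real cpSRP43-interaction motif
  of light-harvesting proteins) and synthetic stand-in signatures for
  P_IM, P_TM and the N_E outer-membrane side.

`generate_signal_msa` draws rows from the same fixed-layout signal model,
so the "alignment" is gapless and equal-length by construction, and a Tat
alignment has two conserved arginine columns.

What this does **not** emulate: natural amino-acid composition, length
distributions, phylogenetic correlation between sequences, homologous
families (every record is independent), annotation noise, or the severe
class imbalance of curated plastid datasets (per-class counts are
configurable but balanced by default). Passing tests therefore demonstrate
that the machinery recovers the planted signal structure under controlled
conditions — not field performance on real proteins.

## Numerical choices

- QuiPT statistic comparisons use "statistic ≥ observed − 1e-12";
  probability bookkeeping is float64 and pinned to the exhaustive oracle at
  1e-12.
- Forward/Viterbi run in log2 space (bits everywhere) with
  `logaddexp2`/`maximum`; emissions of probability 0 map to −inf safely.
- Forests are 500 trees, sqrt(p) features per split, no tuning, seeded; all
  per-model seeds derive deterministically from the run seed.
- Argmax ties (class probabilities) resolve by the fixed class order
  N_E, N_TM, N_S, N_TL_SEC, N_TL_TAT, P_IM, P_TM, P_S.
- Empty feature selections fall back to a single constant design column
  (the forest then predicts the class prior) rather than failing.
- Problem sizes for the shipped experiments: 60 records per class, 5x5 CV,
  50-row signal alignments — chosen as the package's standard synthetic
  study conditions.

## Known limitations

- Exact all-pairs alignment makes reduction/partitioning quadratic; beyond
  a few thousand sequences a k-mer prefilter tool is the right choice.
- The glocal HMM cannot reward signals beyond the N-terminal window, and
  no E-value calibration is attempted; scores are only meaningful relative
  to other scores from the same profile (hence the z-standardization).
- The printed sizes of the historical configuration search (336 base
  variants, 18,600 model sets) are not recoverable from a stated grammar;
  `enumerate_model_sets` is fully configurable instead, and only the
  x4 crossing arithmetic is treated as fixed.
- Multi-compartment (multi-label) proteins are out of scope by design; the
  model predicts exactly one class.
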