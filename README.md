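# subplastid

Prediction of plastid protein **origin** (nuclear- vs plastid-encoded) and
**subplastid localization** (envelope, stroma, thylakoid membrane, thylakoid
lumen — with the Sec/Tat import pathway for the lumen, and an optional
inner/outer envelope membrane call), for researchers annotating chloroplast
and other plastid proteomes who need more than a generic subcellular
localization predictor.

Protein location in the plastid is tightly coupled to function, and the
route a protein travels — cytosolic import with a transit peptide versus
stromal synthesis, Sec versus Tat translocation into the lumen — leaves
characteristic sequence signals. `subplastid` classifies a protein into one
of eight classes combining origin and compartment:

    N_E  N_TM  N_S  N_TL_SEC  N_TL_TAT  P_IM  P_TM  P_S

## The model

The predictor is a **stacked ensemble**: a set of lower-level models
𝒮 = {S₁, …, Sₙ} and a higher-level predictive model G, with

    ŷ = G(S₁(x), S₂(x), …, Sₙ(x))

The default registry holds eight lower-level models — six random forests
(500 trees, untuned) over **gapped n-gram** presence/absence features
(n-grams of length 1–3; gaps of 0–3 wildcards for bigrams, 0–1 per slot for
trigrams; 33,620 patterns) selected per task by **QuiPT**, the exact
permutation test whose p-values come from the hypergeometric distribution
of the 2×2 contingency overlap; plus two **profile HMMs** that score the
N-terminal window for Sec- and Tat-style lumenal targeting signals (the Tat
signal carries the twin-arginine RR motif). The higher-level model is a
probability forest (or a multinomial log-linear model), optionally with
expert *conditional routing* (e.g. proteins called plastid-encoded skip the
nuclear-only models).

The package also ships the surrounding machinery such a predictor needs:
Needleman–Wunsch percent identity (needle convention), homology
**reduction** (90%) and homology **partitioning** (40%, whole-cluster
assignment at an 85/15 split), repeated stratified cross-validation with
Cohen's κ, the Hand–Till multiclass AUC (AU1U) and per-class accuracy, and
a synthetic-data generator that plants the class-specific signals (transit
peptides, RR/h-region signals, transmembrane runs, compositional shift
between origins) so every stage is testable without downloads. See
`docs/methods.md` for the full model description and its limitations.

## Worked example

```sh
subplastid generate --n 20 --seed 1 --out demo
subplastid train demo/dataset.fasta --labels demo/dataset.tsv \
    --sec-msa demo/sec_signals.fasta --tat-msa demo/tat_signals.fasta \
    --seed 1 --envelope-submodel --out demo/model
subplastid predict demo/model demo/dataset.fasta --out demo/predictions.tsv
subplastid evaluate demo/predictions.tsv --labels demo/dataset.tsv \
    --out demo/metrics.json
```

`generate` writes 160 labeled synthetic records (20 per class) plus Sec/Tat
signal alignments; `train` fits the 8-model stacked ensemble; `predict`
reports, per record, the fine class with its probability, the derived
origin and localization, the import pathway for lumenal calls, and the
IM/OM side for proteins called N_E:

    id        fine_class  probability  origin   localization  pathway  envelope_side
    N_E_0000  N_E         0.92         nuclear  envelope               IM
    N_E_0001  N_E         0.978        nuclear  envelope               OM

Re-predicting the training set is a sanity check, not an evaluation — here
`evaluate` prints kappa 1.0 and AU1U 1.0, i.e. the ensemble fits its own
training data perfectly. An honest estimate comes from cross-validation:

```sh
subplastid cv demo/dataset.fasta --labels demo/dataset.tsv \
    --sec-msa demo/sec_signals.fasta --tat-msa demo/tat_signals.fasta \
    --folds 5 --reps 5 --seed 1 --out demo/cv
```

which retrains every model inside each fold and pools κ, AU1U and
per-class accuracies over the 25 fold×repetition cells.

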