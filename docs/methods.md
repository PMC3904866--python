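# Methods

`notesignal` re-implements, as a tested pipeline on synthetic data, a
linguistics-driven approach to three-way risk stratification from
clinical-note text: free text is reduced to per-patient bag-of-words (or
bag-of-word-pairs) counts, features are ranked by mutual information
with the cohort label, ensembles of evolutionary Boolean-program
classifiers are trained on two binary tasks, and the two tasks are
composed into a cascaded 1 vs 2 vs 3 classifier.  Cohort 1 is a
non-mental-health control group, cohort 2 the suicide group, cohort 3 a
psychiatric-inpatient non-suicide group, each of 70 patients.

The real corpora such a study uses are protected medical records and
cannot be distributed, so the package ships a calibrated synthetic
generator; every empirical claim made by the test suite is a claim
about that generator's corpora, not about clinical text.

## Synthetic corpus generator

Each cohort profile fixes a patient count, a note-volume law and a set
of enriched signature terms.

* **Note counts** per patient are zero-truncated negative binomial.
  Defaults: means 27 / 61 / 77 notes for cohorts 1/2/3 and dispersion
  1.5, giving the strong overdispersion characteristic of service-use
  counts (many patients with a handful of notes, inpatients with
  hundreds).  Poisson was rejected because its variance is far too
  small for visit-count data.
* **Tokens** are drawn i.i.d. from a Zipf(1.1) distribution over a
  5,000-term background vocabulary (real note corpora run 30,000–40,000
  distinct words; 5,000 keeps desk-scale runtime and is configurable).
  Note lengths are Poisson with mean 100 tokens.
* **Signature terms** replace background terms at ranks 2,500–4,500 (the
  moderately rare tail).  Within its cohort a term's token probability
  is multiplied by an enrichment factor `6 + hint/2`, where `hint` is a
  per-term frequency weight (range ≈ 7–18).  Cohort 2's terms are
  clinical keywords from the risk-factor domains associated with
  suicide decedents (agitation, frightened, delusional, analgesia,
  demerol, terminal, nebulizer, ...); cohorts 1 and 3 get disjoint
  invented sets (primary-care resp. inpatient-psychiatry language).
  At these settings the weakest cohort's terms reach patient-level
  presence of roughly 55% in their own cohort versus ~15% elsewhere:
  individually non-separating, informative in combination.
* **Realism features**: pipe-delimited medication-table blocks are
  appended to 5% of notes; 0.2% of tokens receive a single-character
  typo; text is rendered as capitalized sentences.  Dates are uniform
  over one calendar year and carry no downstream meaning.
* **Exclusion emulation**: a profile can mark patients as having zero
  notes; they appear in the ground truth but never in feature matrices,
  mirroring cohort-2 subjects with no service use in the observation
  window.
* **Bigram-only signal** (`bigram_signal_config`): word pairs are
  injected into every cohort's notes at the same rate, but placed
  *adjacently* only in the signal cohort.  Unigram marginals are
  matched across cohorts by construction, so any classifier advantage
  must come from word-pair features.

What the generator does **not** emulate: real clinical language and its
template structure, negation and context, visit-level temporal
patterns, inter-patient vocabulary drift, and correlated term
co-occurrence beyond the planted pairs.  Passing tests therefore show
that the pipeline recovers planted signal of a plausible shape and
strength — not that any particular accuracy is attainable on real
records.

## Featurization

Tokens are lowercased maximal alphanumeric runs; punctuation and markup
are discarded and no stemming or spell-correction is applied, so typos
and abbreviations remain distinct features.  All of a patient's notes
are pooled into one document.  Word-pair features are within-note
adjacent bigrams by default (an unordered once-per-note co-occurrence
mode is available); pairs never span note boundaries.  Matrices are
stored sparse with a deterministic lexicographic vocabulary order.
Patients whose notes are all empty are reported; patients with no notes
at all never enter a matrix.

## Feature selection

Mutual information is the plug-in estimate on the empirical
(presence × label) contingency table, in bits; presence means count ≥ 1
(an optional quantile-binned variant on raw counts exists).  Ties are
broken lexicographically.  The default cut keeps the top 2,000
features.  Word pairs pass a staged exclusion process, applied in
order: (a) one member word must sit in the top-500 unigrams by MI,
(b) pair document frequency ≥ 3, (c) pair MI above a floor (default 0),
(d) per-pair chi-squared p < 0.05 (Yates-corrected for 2×2; an optional
Benjamini–Hochberg correction is off by default, since the staged
filter is a screening device, not an inference).

## The GP learner

The classifier unit is a Boolean expression tree over AND/OR/NOT with
literals (feature, polarity) on binarized features.  A generational GP
evolves programs with tournament selection (size 4), subtree crossover
(rate 0.8), mutation (rate 0.2), elitism of one, and fitness = training
accuracy − λ·(node count) with λ = 0.002.  Population 200, 50
generations, depth cap 5 (enforced by truncating overflow subtrees to
literals).  Initialization is ramped half-and-half plus one
single-literal program per selected feature (capped at the population
size).  Search stops early only when the elite is provably optimal
(accuracy 1 with a single node).  Defaults are sized so one model
trains in well under two seconds on a 210 × 2,000 presence matrix;
training internally bit-packs feature columns into Python integers so a
program evaluation is a handful of machine-word bitwise operations.

Two search-quality choices deserve emphasis, because the vanilla
operator set demonstrably under-searched (it stalled on single-literal
programs while four-literal conjunctions with ~10 points higher held-out
accuracy existed):

* a fifth mutation kind, **extend**, wraps the current program in a
  fresh AND/OR with one new literal — the shortest path from a good
  literal to a feature combination;
* new literals are sampled from a power-law over column order
  (`feature_bias`, default exponent 1.0).  The trainer feeds columns in
  MI order, so exploration leans toward informative features while
  keeping a heavy tail over the rest.  Setting `feature_bias = 0`
  restores uniform sampling.

This learner is a deliberately transparent stand-in for the large
meta-optimizing evolutionary program-learning systems used for this
problem class; their deme/representation-building machinery is out of
scope, and no hyperparameter fidelity to any such system is claimed.

## Ensembles and the cascade

An ensemble is `n` independently seeded models (model *i* uses seed
`base_seed + i`); the prediction is the majority vote, with the vote
fraction exposed.  A tie at exactly 0.5 predicts the positive class —
in a screening application the differentiated (riskier) call is
preferred; the tie-break is configurable.  Two binary tasks are formed
by group combination: task A (cohort 1 vs {2,3}) and task B (cohort 2
vs {1,3}); each task runs its own feature selection on its own
relabeled training data.  The cascade applies A first (a patient
recognized as group 1 is labeled 1), then B (group 2), and otherwise
labels 3; the decision table is exhaustive over {1,2,3}.

## Evaluation

Stratified patient-level 5-fold cross-validation (cohort balance
survives splitting by design; plain k-fold is available).  Feature
selection is re-run on each training fold; handing the harness a
vocabulary selected on the full dataset is a hard `LeakageError`,
because it leaks held-out labels.  Reported numbers: per-fold and mean
cascade accuracy (plain proportion correct; the balanced version is
reported alongside and coincides in expectation under the 70/70/70
design), per-model held-out accuracies (histogrammable by model type)
and per-task ensemble accuracies.  A dry-run mode records the
experiment bookkeeping — folds and the k × n_models model count per
task — without training.

Informative terms are extracted by taking the high-MI features,
assigning each to the cohort whose patients carry it most often (ties
dropped with a log entry) and ranking by that frequency — the data
behind per-cohort word-cloud-style lists.

## Numerical and design choices

* MI on binary presence rather than raw counts: standard for short-text
  class association, and it matches the Boolean literals the learner
  consumes.  MI is computed against the labels of the task being
  trained.
* Chi-squared with Yates correction for 2×2 pair-association tables;
  degenerate margins return (statistic 0, p 1).
* Vote ties to the positive class; fold sizes differ by ≤ 1; MI ties
  lexicographic; all randomness flows from explicit integer seeds (no
  global RNG), and identical configs reproduce byte-identical corpora,
  models and reports.
* Test-scale choices: distributional generator properties use 20 seeds
  at full scale; permutation-null and pair-vs-unigram suites run on
  reduced corpora (20–30 patients per cohort, shorter notes) with small
  GP budgets, sized to keep the whole suite at desk scale while leaving
  the tested property intact.

## Known limitations

* Synthetic text is a bag-of-words process; nothing in it tests
  negation handling, template boilerplate or concept normalization —
  all explicitly out of scope.
* The GP is not a reconstruction of any production evolutionary
  learner; accuracy comparisons to published numbers for such systems
  are not meaningful beyond the simulation surrogate reported here.
* Accuracy on the default corpus depends on the planted-signal
  calibration; the reported cross-validated numbers characterize the
  pipeline under those defaults, not clinical performance.
* The co-occurrence pair mode is quadratic in per-note distinct tokens
  and is intended for short notes.
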