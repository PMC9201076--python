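# Methods

## Problem and scope

`tnmstage` extracts clinical and pathological TNM stage of prostate cancer
from free-text clinical notes at the **patient** level, and uses the
extracted values to fill missing stage fields in a registry table. Five
binary tasks are exposed, following the dichotomization used when T-stage
category counts are too unbalanced for multi-class work:

| task | categories | note types eligible |
|------|------------|---------------------|
| cT   | T1-2 vs T3-4 | operative, history & physical, discharge/transfer, progress |
| cN   | N0 vs N1     | same as cT |
| cM   | M0 vs M1     | same as cT |
| pT   | T2 vs T3-4   | pathology, history & physical, progress |
| pN   | N0 vs N1     | same as pT |

Pathological M is not a task: pM1 is assigned only after radical
prostatectomy and is vanishingly rare in such cohorts, so `dichotomize`
rejects it. Radiology reports and unknown note types pass neither
note-type filter; a conservative choice mirroring how manual abstraction
restricts its sources.

## Rule engine

Mentions come from two detectors run on **raw** sentence text (punctuation
and short alphanumerics are stage-bearing, so the ML normalization chain is
deliberately not applied here):

1. **Compact grammar.** `[c|p|yp] T<d>[a-c] N<d> M<d>` with any non-empty,
   in-order subset of components, contiguous or whitespace-separated; the
   prefix distributes over all components of one pattern. A bare single
   component with no prefix ("t3a" alone) is instead reported by the
   narrative detector and flagged *ambiguous*, because nothing marks it as
   clinical or pathological. Out-of-range numerals (T>4, N>3, M>1) yield no
   mention.
2. **Narrative terms.** The bundled lexicon maps AJCC 7th-edition criteria
   phrases to axis/value (e.g. "extracapsular extension" → T3, "seminal
   vesicle invasion" → T3, "lymph node involvement" → N1, "organ confined"
   → T2); matching is case-insensitive, longest-match-wins at word
   boundaries, spans never overlap. Overall-stage phrases ("stage 1
   prostate cancer") are recorded as `overall` mentions but never converted
   to TNM values — they are an ambiguity signal, not staging evidence.

**Contextual scoping** follows the ConText scheme: negation, historical,
hypothetical and other-experiencer triggers open directional scopes bounded
by the sentence end, a termination term ("but", "however", ...) or another
trigger of the same type; pseudo-triggers ("no increase") shadow the
embedded trigger via longest-match and open no scope. A trigger that lies
inside a mention's own span never flags that mention — this is what lets a
term like "lymph nodes negative for tumor" carry an N0 value without
negating itself.

**Patient-level resolution**, per axis and stage kind:

1. drop mentions flagged negated, hypothetical or other-experiencer
   (historical mentions are *kept*: a stage assigned in the past is still
   the stage at diagnosis);
2. keep mentions whose prefix matches the requested stage kind; mentions
   with no prefix are routed by note type (pathology report → pathological,
   anything else → clinical);
3. choose the modal numeral among survivors; ties break by the most recent
   mention (note date, then note id, then position in text), making the
   result independent of mention order;
4. if no positive survivor exists but a negated N≥1 / M1 mention does, the
   complementary benign value (N0 / M0) is asserted and marked
   `from_negation` in provenance. This complementary assertion applies only
   to the binary axes, never to T;
5. dichotomize.

The resolution policy (filter → route → mode → recency) is a design choice:
the mode resists isolated transcription noise, recency reflects staging
refinement over time. Clinical mentions are taken from the full
longitudinal record without a pre-treatment time window.

## ML arm

* **Embeddings**: skip-gram with negative sampling, vector length 100,
  window 5, minimum count 2, 5 epochs, k = 5 negatives with a
  unigram^0.75 noise distribution, linearly decaying learning rate from
  0.025. Implemented in numpy, single-threaded and seeded, so identical
  corpora give identical vectors. One embedding model per stage kind,
  trained on the normalized sentences of the kind-eligible notes.
* **Normalization** (ML path only): rule-based sentence splitting with a
  clinical abbreviation list; lowercase; punctuation-only tokens and
  single-letter alphabetic tokens dropped; integers 0–20 become single
  number words, larger integers and decimals are spelled digit-by-digit
  ("4.5" → "four point five"); mixed alphanumerics ("t2a", "pt3an0") are
  kept intact because they carry the staging signal.
* **Patient vectors**: a sentence is *context* for a task if it contains an
  axis-matching lexicon term, a compact TNM component of that axis, or a
  bare stage token of that axis; each context sentence is the mean of its
  in-vocabulary token vectors and the patient vector is the mean over
  context sentences. Patients with no context are *degenerate*: zero
  vector, excluded from training, abstaining at prediction time so the
  imputation accounting can distinguish "no evidence" from "predicted".
* **Classifier**: one binary SVM per task on standardized features
  (StandardScaler → SVC; embedding coordinates are small-scale, and
  standardization keeps the RBF bandwidth search range meaningful).
  Random search over kernel ∈ {linear, RBF}, C log-uniform [1e-2, 1e2],
  RBF γ log-uniform [1e-3, 1e1], class weight ∈ {none, balanced}; 50
  draws scored by mean macro-F1 over 5-fold stratified CV on the training
  side of a stratified 80/20 split; the winner is refit and evaluated on
  the held-out 20%.

## Synthetic corpus generator

The generator replaces PHI-restricted institutional data and defines the
study conditions under which the package is validated:

* **Stage marginals** (registry-observed): clinical T1/T2/T3/T4 =
  44/19/3/1% with 33% missing; N0/N1 = 61/3% (36% missing); M0/M1 = 62/5%
  (33% missing); 33% of patients undergo prostatectomy, with pT2 51%,
  pT3/pT4 27/3% (19% missing) and pN0/pN1 75/3% (22% missing). The pT3-4
  block is split 27/3 as a generator choice; only the combined 30% is
  pinned by the emulated cohort.
* Every patient draws a **true** stage from the normalized non-missing
  mass; the registry cell is blanked *independently* with the missing
  mass. Registry marginals therefore converge to the configured numbers,
  and registry missingness is independent of note documentation — some
  missing cells are recoverable from text, some are not, which keeps
  imputation non-trivial.
* **Pathological stage is sampled conditionally on clinical stage** through
  a concordance kernel calibrated by iterative proportional fitting, so
  both configured marginals are preserved exactly while cT and pT remain
  correlated (they measure the same tumor; independent sampling would make
  clinical-stage context pure noise for the pathological tasks, which no
  real cohort exhibits). The discordance penalty (0.1 per step) yields
  roughly 31% upstaging from cT1-2 to pT3, in line with real prostatectomy
  series.
* **Rendering**: each documented axis is rendered exactly once — as a
  compact pattern (probability `p_compact_pattern` = 0.6, merged across
  axes of one stage kind into patterns like "cT1cN0M0"), a narrative
  template, or (probability `p_ambiguous_prefix` = 0.2) a prefix-less
  ambiguous phrasing. Pathological sentences are placed in pathology
  notes; clinical sentences in clinically eligible notes, so unprefixed
  mentions route correctly by note type. Noise sentences — negated
  benign-consistent assertions (rate 0.15), historical restatements
  (0.05), hypothetical discussion (0.05) — are always consistent with the
  truth, as real notes are; distractor sentences exercise matching against
  negatives.
* **Gold labels** cover only documented axes: chart-review ground truth is
  abstracted from the notes, so an axis no note documents has no gold
  label (the underlying truth remains on `PatientTruth` for auditing).
* Fully seeded: identical config gives byte-identical corpora.

What the generator does **not** emulate: real clinical language variety,
section structure, typos, copy-forward, cross-sentence coreference,
synoptic pathology blocks, or adversarial ambiguity (e.g. MRI "T2-weighted"
collisions). Passing tests therefore demonstrate the pipeline's internal
correctness and its behavior under the modeled noise channels, not
real-world accuracy.

## Evaluation and imputation

Per-task, per-category one-vs-rest TP/FP/FN/TN with precision, recall and
F1; zero-denominator metrics are marked undefined rather than reported as
0. Abstentions and missing gold labels are excluded pairwise and counted,
keeping denominators visible. Cohen's kappa is computed per task on the
dichotomized categories (scikit-learn), undefined when fewer than two
distinct categories appear.

Imputation writes predictions into empty registry cells only; populated
cells are never overwritten and disagreements are counted as conflicts;
the operation is idempotent and marks imputed cells in provenance columns.
One caveat: the registry schema cannot distinguish "missing pathological
stage" from "patient never had surgery", so pathological missing counts are
computed over all patients; restrict the table to surgery patients for
paper-style denominators.

## Validation sizes and numerical choices

The shipped checks use: noise-free oracle equivalence at n = 200 (the rule
engine must reproduce ground truth on 100% of documented axes); ML
parameter recovery at n = 1,000 on a noise-free corpus (majority-class
held-out F1 ≥ 0.9); the rule-vs-ML minority comparison on the clinical N
task at n = 600 × 3 seeds (N1 prevalence 3%, ambiguity noise 0.2);
simulator fidelity at n = 10,000 (±2 points). These sizes give stable
statistics while keeping the whole suite in a few minutes on one CPU.

Ties in random search resolve to the first-drawn configuration; stratified
splitting keeps scarce categories in both partitions; CV fold count drops
below 5 only when a training class has fewer members. All randomness flows
from explicit integer seeds.

## Known limitations

* The lexicon is a curated equivalent of an expert list, not a validated
  clinical artifact; swap in a site-specific file via `load_lexicon`.
* ConText scoping is sentence-bounded; negation spanning sentences is
  missed.
* The complementary-assertion rule can emit N0/M0 from purely negated
  evidence; such fields are flagged `from_negation` so consumers can
  exclude them.
* Overall-stage phrases are surfaced but unused; mapping stage groups I–IV
  back to TNM would require grade and PSA, which are out of scope.
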