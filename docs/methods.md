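# Methods

## Problem and model

The package classifies whether a psychiatrically hospitalized adolescent
reported a suicide attempt in the past year, using only the free text of
clinical notes written in the year before the index admission. Supervision
is a single binary label per patient (a confidential self-report survey
item, dichotomized as zero vs. at least one attempt), while the classifier
operates note by note — a multiple-instance structure. The procedure:

1. **Concept extraction.** Each note is split into sentences, tokenized,
   and matched against a CUI lexicon (Concept Unique Identifier → surface
   variants) by greedy leftmost-longest dictionary matching. A NegEx-style
   rule flags negated mentions: a trigger ("no", "not", "denies",
   "denied", "without", "negative for") within the 6 tokens preceding the
   mention, in the same sentence, with no intervening contrast conjunction
   ("but", "however"). A negated mention of `Cxxxxxxx` becomes the separate
   feature code `Cxxxxxxx_neg`.
2. **Dummy matrix.** One binary row per note, one column per feature code
   observed anywhere in the corpus; cell = presence. Note labels are
   inherited from the patient. Codes occurring in notes of fewer than 4
   distinct patients are dropped (an overfitting guard — distinct
   *patients*, not notes).
3. **Patient-level 80/20 split** (random, unstratified by default), then
   **5 folds** over the training patients with sizes differing by at most
   one.
4. **Per-fold feature selection.** On the fold's training notes, restricted
   to codes present in those notes, a 300-tree random forest ranks codes by
   mean decrease in Gini impurity; the top 50 are kept and unioned with
   curated-list codes present in those notes. Importance ties break
   lexicographically so selection is reproducible.
5. **Note classification and patient aggregation.** A 300-tree random
   forest (Gini splits, √p features per split, unlimited depth — the
   canonical defaults) classifies each test-fold note; a patient is called
   positive at cutoff c when the fraction of their notes classified
   positive strictly exceeds c, swept over 0%, 10%, …, 100%. The strict
   inequality makes the 100% cutoff classify everyone negative and the 0%
   cutoff classify exactly the patients with ≥1 positive note.
6. **Cutoff selection and holdout.** Fold metrics are averaged per cutoff;
   the operating cutoff is the one with the highest mean specificity among
   cutoffs whose mean sensitivity is ≥ 0.70. Specificity ties break toward
   the higher mean sensitivity and then the smaller cutoff — the policy is
   sensitivity-first, so an equal-specificity tie must never cost recall
   (with proportion thresholding, several cutoffs often share a specificity
   of exactly 1.0 and the tie is common, not an edge case). If no cutoff
   clears the floor, Youden's J is maximized instead; a manual override is
   supported. The
   final forest is fitted on the full training set with features re-selected
   by the same procedure, and evaluated once on the untouched holdout:
   per-cutoff confusion counts, sensitivity/specificity/PPV/NPV/accuracy,
   and the grid AUC.

## Key parameters

| parameter | default | meaning |
|---|---|---|
| `train_fraction` | 0.8 | patient-level training share (58/15 at n=73) |
| `k_folds` | 5 | CV folds over training patients |
| `min_patients` | 4 | distinct-patient floor for a code to enter the model |
| `top_k` | 50 | Gini-ranked codes kept per fold |
| `n_trees` | 300 | trees in both the ranking and the final forest |
| `sens_floor` | 0.70 | mean-sensitivity floor for cutoff selection |
| `negation window` | 6 tokens | NegEx-style scope preceding a mention |

All are exposed in `PipelineSettings` / the YAML config; defaults are the
procedure's fixed constants.

## Numerical and design choices

- **0/0 metric convention = 0.0.** At degenerate cutoffs a denominator can
  be empty (no positive calls → PPV, no negative calls → NPV); reporting
  0.0 keeps every cell of the cutoff sweep defined and matches the
  direction of the boundary rows (sensitivity 0.00 at high cutoffs).
- **Grid AUC.** FPR/TPR are computed per cutoff, anchors (0,0) and (1,1)
  appended, and the trapezoid rule applied to the per-FPR upper envelope:
  operating points sharing an FPR contribute zero width, so only the best
  TPR at each FPR shapes the curve. With note-proportion thresholding,
  several high cutoffs typically collapse onto the same operating point;
  the envelope treats them as one.
- **Ranking forest = final forest settings.** The importance-ranking forest
  uses the same 300-tree configuration as the classifier; nothing suggests
  they should differ, and sharing settings removes a free parameter.
- **Final-model features.** Each fold selects its own features, so "the
  features of the best model" is ambiguous for the final fit. Default:
  re-run the identical selection procedure on the full training set
  (consistent with the fold procedure); pooling the union of fold features
  is available via `final_feature_mode="union"`.
- **Curated-term resolution** maps a curated surface term to every lexicon
  CUI containing it as a contiguous, case-insensitive token subsequence,
  restricted to CUIs actually observed in the corpus. Resolution is
  computed on the full corpus (it uses no labels); per-fold inclusion is
  then restricted to codes present in that fold's training notes.
  Unmatched curated terms are reported, never errors.
- **Determinism.** Every stochastic step (split, folds, each fold's ranking
  and fitting forest, the final selection and fit) receives a child seed
  derived from the master seed via `numpy.random.SeedSequence`. Trained
  models carry a SHA-256 fingerprint of exactly the training-side inputs
  (training rows, labels, codes, seed, tree count), which is how the
  no-leakage test verifies that holdout labels cannot influence any fitted
  artifact.
- **Strict timestamps.** Dates are ISO calendar dates; time of day is
  ignored. A 1-year window filter is not applied by default (synthetic
  corpora are generated pre-windowed).

## Synthetic cohort generator

The generator emulates the statistical structure the analysis assumes, not
clinical prose:

- **Prevalence** 0.37 (Bernoulli per patient).
- **Notes per patient** ~ round(clip(LogNormal(μ=4.25, σ=1.15), 1, 876)).
  The clipped distribution has mean ≈128 and median ≈70, reproducing a
  strongly right-skewed documentation profile (mean ≫ median).
- **Note text** is assembled from sentence templates. For each note, each
  configured signal CUI is mentioned with a label-conditional per-note rate
  (defaults 0.15 vs 0.05 on the 10 suicide-related concepts), each noise
  CUI at a flat 0.04. A mention renders inside a negation template with
  probability 0.15, tripled (capped at 0.95) for signal mentions in
  label-0 patients — mirroring "no suicide attempts"-style charting. The
  `null_config` preset equalizes mention rates *and* negation behavior so
  that no feature, affirmed or negated, carries label information.
- **Demographics** (age, sex, race/ethnicity, insurance) are generated to
  exercise corpus I/O; the model never reads them.

What the generator does **not** emulate: realistic clinical narrative,
misspellings, abbreviation ambiguity, section structure, co-occurrence
correlation between concepts, temporal trends within the year, or
documentation-frequency differences by outcome. Passing tests therefore
demonstrate that the pipeline recovers label-conditional lexical signal
through extraction, filtering, selection and aggregation — not that any
particular performance level would be attained on real EHR data.

## Problem sizes used in tests and the acceptance script

Multi-seed full-pipeline checks run on 400-patient cohorts with the
strong-separation rates (0.30 vs 0.02 on 10 signal CUIs) and a reduced
notes-per-patient profile, LogNormal(μ=2.0, σ=0.6) clipped to [1, 40]
(≈9 notes per patient). The signal-recovery and null-behavior properties
concern the label structure of the corpus, not its bulk, and this size
keeps 20 independent end-to-end runs practical; single-run tests use
smaller cohorts still. The generator's defaults remain the full-scale
profile above.

## Limitations

- The dictionary matcher has no word-sense disambiguation, POS filtering,
  or spelling correction; lexicon coverage bounds extraction recall.
- Negation is a single-window rule; post-mention triggers ("suicidal
  ideation: none") are not handled by default.
- With ~9 notes per test patient, the proportion-of-notes grid is coarse;
  per-patient proportions are quantized and several cutoffs can coincide.
- The cutoff-selection policy encodes one clinical preference
  (sensitivity-first); other trade-offs require the override or a custom
  policy.
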