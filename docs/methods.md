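# Methods

This note records the models, conventions and parameter choices behind the
package, what the synthetic study emulates, and what it does not.

## Knowledge graph and rule semantics

The graph holds exactly four independent ontologies (suicide, time, space,
wish). Reasoning is limited to reflexive–transitive subclass reachability
over parent links; parent relations must be acyclic and are validated at
load time. Mention finding scans the text for every surface form of every
concept below the queried root, case-insensitively, and suppresses
overlapping shorter matches (longest match wins, earlier start breaks
ties). Spans are 0-based half-open character offsets. Storage is plain
JSON rather than a logic-programming environment: the clause semantics used
here — ordered slots with free-text gaps — are fully captured by ordered,
non-overlapping mention assignment, so a JSON slot list is an equivalent
and far more testable encoding.

A rule is an alternation of `free_text` and `concept` slots (no two
concept slots adjacent). A match assigns non-negated mentions to concept
slots in order with non-overlapping spans; all satisfying assignments are
returned. A comment's level is the **maximum** over matched rules, a
deliberate conservative tie-break for risk triage; no rule match means
level 0 ("no risk"). Levels ≥ 6 binarize to high risk.

Only the level-8 rule pair (plan+future in both orders) follows the
published clause template verbatim. The shipped defaults extrapolate the
same shape to the neighboring level criteria — method+future (9), method
alone (7), plan alone (6), wish+future (5), wish alone (4) — and each such
rule carries `"extrapolated": true`, because those clause bodies were never
published and our reconstructions cannot be validated against a reference.
Every two-slot rule ships in both slot orders, so matching is
order-invariant at the rule-set level.

### Negation

A mention is negated when a cue from a configurable lexicon ends within a
scope window (default 8 characters) before the mention start with no
clause-boundary punctuation in between. Cues with Latin/digit edges match
only at word boundaries. The window, cue list and boundary set live in
`data/negation.json`; the defaults are deliberately simple and auditable
rather than a full clinical negation system.

## Preprocessing

Cleaning removes exact duplicates (after emoji stripping and whitespace
normalization, first occurrence kept), strips a fixed, documented list of
emoji Unicode blocks, and drops comments of five or fewer words. "Word"
means one CJK character, plus one per whitespace-delimited non-CJK token —
a deterministic convention that avoids a word-segmenter dependency; whether
the original length filter counted characters or segmented words is
unknowable, and this choice is flagged here for that reason.

## Psychological features

Ten per-user features are computed from raw activity counts; all rates are
within-user ratios and zero denominators map to 0 so the fusion input is
dense. Three definitions in the source material are ambiguous and were
resolved as follows (flagged, not verifiable against a reference):

- `night_activity_rate` = night posts (22:00–06:00) / total posts. The
  original wording is population-level and unusable per user.
- `social_activity_rate` = mutual follows / followers (dimensionless,
  within-user).
- `social_support_rate` = comments received / posts ("support" read as
  received attention).

Cohort normalization (z-scoring per feature, constants → 0) is applied
before fusion so the 10 features are commensurate with the reduced
sentence vector.

## Encoders and classifier stages

The default encoder hashes character n-grams (n = 1–3) of the first
`max_chars` (128) characters into `embed_dim` (768) signed buckets and
L2-normalizes; it is deterministic given (text, seed) and the empty string
maps to the zero vector. n-gram features share a large common direction
(common vocabulary), so every stage centers sentence vectors on the
training-set mean before its head; the center is stored with the model.
Without centering, a single random weight along the common direction tilts
all predictions one way, which distorts evaluation on no-signal data.

- **Stage 1**: dropout (0.1) → affine(768→1) → sigmoid. With the hashing
  encoder, "the encoder trains too" is a no-op because the hash features
  have no trainable parameters; this is the one deliberate architectural
  deviation of the default backend, and it disappears when a trainable
  transformer encoder is plugged in (optional extra; not required by any
  test).
- **Stage 2**: frozen encoder; head of two affine(768→768) layers, each
  followed by ReLU, dropout and batch normalization, then affine(768→1) →
  sigmoid.
- **Stage 3**: frozen encoder; affine(768→256) → ReLU → affine(256→64) →
  ReLU reduces the sentence vector to `reduce_dim` = 64 (the intermediate
  width 256 is a free choice); concatenation with the 10 features gives a
  74-D fused vector classified by affine(74→1) → sigmoid.

Training is mini-batch Adam on binary cross-entropy, batch size 8
(validation/test batching 16 is irrelevant to vectorized inference but kept
in the config). Epochs default to 5 with best-epoch selection on a 10%
validation split monitored by cross-entropy; loss rather than F1 is the
monitor because F1 selection is positively biased when labels carry no
signal (predicting all-positive yields F1 2/3 on a balanced set). The
learning rate resolves per backend: 0.01 for the hashing backend (a
conventional Adam step size for a freshly initialized shallow head on
fixed features) and 2·10⁻⁵ for the transformer backend (the published
fine-tuning rate). The decision threshold is 0.5 with ties classified
high — conservative for triage. Seeded `numpy` generators drive
initialization, shuffling and dropout, so training is bitwise reproducible.

## Evaluation

The positive class is high risk. Precision or recall with a zero
denominator is reported as 0 with a warning flag instead of NaN, so
aggregate tables stay numeric. Cross-validation uses stratified k-fold
(k = 5 by default) with pooled confusion counts (micro averaging) across
folds; the original fold-aggregation scheme is unknown, and micro averaging
was chosen for robustness to small folds.

## Synthetic study generator

The generator produces the study conditions every behavioral test runs
under. Comments are filler-padded templates over the fixture graph's
surface forms; the concept combination fixes the gold level (method+future
→ 9, plan+future → 8, method → 7, plan → 6, wish+future → 5, wish → 4,
filler → 0), and the class label follows the ≥6 threshold. One synthetic
user backs each comment. Realistic noise enters through three channels:

- `high_fraction` (default 0.05): high-risk comments are a small minority
  of raw traffic, as in live streams where only a handful of comments per
  day are high risk. Tier-level experiments that emulate the curated
  annotation sets use ~0.5, matching the roughly balanced class shares of
  rule-selected and expert-audited sets.
- `negation_rate` (default 0.1 of low-risk comments): denied risk
  statements ("never …"). Half place the cue immediately before the
  concept (in scope, rules label them correctly) and half separate it by
  filler beyond the scope window, where the rules err — so free-tier label
  noise concentrates in negated records.
- `obscure_rate` (default 0.15): comments whose text underdetermines the
  label, emulating context-dependent expressions that only expert
  annotators resolve. High-risk obscure comments read as mild wish
  statements (gold level 7, rule label low); their gold label reflects the
  user's true class, the signal the psychological features carry.

`easy_noise_rate` (default 0.05) flips gold labels independently to
emulate non-expert corrections; the hard tier is gold exactly. User
records draw each informative feature (default: the first 4 of self-focus,
night activity, social support, social activity, …) from class-conditional
normals whose means differ by `psych_effect_size` (δ) pooled standard
deviations — high-risk users self-focus more and post more at night, and
engage and receive less socially. Rates are converted back to counts, so
all count invariants hold by construction; clipping and rounding shrink
the realized δ slightly (verified within ±0.2 at δ = 2).

With `negation_rate = 0` and `obscure_rate = 0` the rule engine recovers
the gold binary label on 100% of generated comments — the construction
guarantee the tests pin down.

### What passing tests do and do not show

The generator preserves the *computational* structure of the task —
hierarchical gazetteer matching, negation scope, ordered slot binding,
class imbalance, tier noise, text/feature complementarity — but none of
the linguistic reality: no Chinese morphology, no segmentation ambiguity,
no discourse context, no contradictory long posts, and intentionally no
real risk vocabulary (the fixture lexicon is invented). Passing tests
therefore demonstrate the correctness and stability of the machinery, not
clinical performance on real social-media text.

## Problem sizes and numerical choices

Behavioral checks use synthetic corpora of 500–2000 comments, a hard tier
of 1458 (matching the published expert-label budget) with class share
813/1458, ten seeded repetitions for the fusion-gain comparison, and a
1200-comment balanced set for the permuted-label null. Under the null,
the held-out F1 of a trained stage fluctuates around 0.5 with a spread of
several points (predictions are correlated through shared feature
directions), so single-seed values in the 0.55–0.62 range are sampling
dispersion, not residual signal. Degenerate inputs are defined rather
than exceptional: empty text encodes to the zero vector, zero training
epochs leave a valid (random-initialization) classifier, and probability
exactly at threshold classifies high.

## Known limitations

- The default rule set beyond level 8 is extrapolated; its agreement with
  any clinically validated rule base is unknown.
- The negation model is a windowed cue match; morphological negation,
  double negation and scope across clause-like boundaries without
  punctuation are out of reach.
- The hashing encoder cannot model word order beyond 3-character n-grams;
  distant-negation distinctions are learned only insofar as cue n-grams
  correlate with labels.
- Multi-class (level-wise) prediction heads are not provided; the
  classifiers are binary, mirroring how the staged system is evaluated.
- Feature ambiguities listed above are resolved by documented convention.
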