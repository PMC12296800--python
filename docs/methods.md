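# Methods

This note documents the statistical model, the preprocessing conventions,
the synthetic-data generators and the numerical choices behind `lexkey`, in
the package's own terms.

## The keyness model

The pipeline compares lemma frequencies between a target corpus *i* and a
reference corpus *j*.  Each corpus is reduced to a frequency table
(normalized lemma → count, plus the total token count), the two tables are
merged over the union of their vocabularies with zero-filling, and each
merged lemma *w* is scored with the log-odds ratio under an informative
Dirichlet prior:

- prior pseudo-counts: `alpha_w = y_w_i + y_w_j` (the pooled count of the
  lemma) and `alpha_0 = n_i + n_j` (the pooled total);
- `delta_w = log[(y_i+a_w)/(n_i+a_0-(y_i+a_w))] -
  log[(y_j+a_w)/(n_j+a_0-(y_j+a_w))]` (natural log);
- `sigma2_w ≈ 1/(y_i+a_w) + 1/(y_j+a_w)`;
- `z_w = delta_w / sqrt(sigma2_w)`.

The prior serves two purposes: it keeps odds finite for lemmas absent from
one corpus (the zero-filled rows), and it shrinks the estimate toward the
pooled distribution, damping the extreme log-odds that rare words would
otherwise produce.

**Shrinkage and calibration.** Because the pseudo-counts are the pooled
*observed* counts, they grow linearly with corpus size.  Two consequences
matter for interpreting results and for testing:

1. `delta_w` is *not* a consistent estimator of the raw population log-odds
   difference; it converges to a shrunken functional of it (for two
   equal-sized corpora, roughly one third of the raw value at small
   probabilities).  The synthetic truth record therefore stores both the
   raw population log-odds shift and the *implied* value of the statistic —
   expected counts substituted into the delta formula — and all recovery
   checks compare against the implied value.
2. Under the null, `z_w` is under-dispersed (variance ≈ 1/3 for equal-sized
   corpora): `sigma2` is computed from the smoothed counts while `delta` is
   shrunk by the same smoothing.  The Bonferroni rule on these z-scores is
   therefore conservative; the observed family-wise error rate in the null
   simulations sits near zero, comfortably below the nominal level.  This
   conservatism is a property of the statistic as defined, not an artifact
   of the implementation.

**Multiplicity.** The threshold is the upper standard-normal quantile at
`alpha/m` (one-sided convention, default) or `alpha/(2m)` (two-sided),
where `m` is the number of merged lemmas.  The one-sided convention is the
default because the published threshold for this family of analyses
(|z| = 5.10 at alpha = 0.01 over m = 59,190) equals the one-sided quantile;
the two-sided quantile at the same level is 5.23.  Selecting by `|z| >=
threshold` with a one-sided quantile is, strictly, a pair of one-sided
tests per lemma; given the under-dispersion above, the procedure still
controls the family-wise rate with a wide margin.  The convention used is
recorded in every run's metadata.

**Selection and ranking.** Target keys are lemmas with `z >= threshold`
sorted by descending z; reference keys have `z <= -threshold` sorted
ascending.  Equal z values are ordered alphabetically by lemma so that runs
are deterministic.  Reports show the top-k (default 50) of each list with
`|z|`.

## Preprocessing conventions

- **Normalization.** All lemma and type counting operates on NFC-normalized,
  case-folded strings with apostrophe variants (`'`, `’`, `ʼ`, `` ` ``, `´`,
  `‘`) unified to U+02BC, so spelling variants of the same Ukrainian lemma
  are never split across rows of the merged table.
- **Stopwords.** A token is dropped iff its POS is PUNCT, or its POS is in
  the closed-class set {ADP, PRON, CCONJ, SCONJ, PART, DET, AUX}, or its
  normalized lemma is on the stopword list.  The bundled
  `data/stopwords_uk.txt` is a small curated reconstruction of Ukrainian
  function lemmas (the list used for the original corpus release is
  unpublished); analyses that need a specific list should supply their own
  file.  By default the lemma list (not the POS rule, which needs tags) is
  also applied to the reference frequency list, so both sides of the merge
  are filtered comparably; this is switchable per run.
- **De-identification** replaces whole-word, case-sensitive alias matches
  with `[NAME]`/`[CITY]` tags, indexed 1..k in order of first appearance
  when more than one entity of a kind occurs in a narrative.  Alias lists
  are supplied by the operator (inflected forms included); there is no
  automatic named-entity recognition, matching how such corpora are
  de-identified in practice (manually, with review).
- **Sample trimming** applies, in order: consent, age parseable and within
  the sanity band [12, 120], age >= 18, narrative not a duplicate.  Each
  excluded record receives exactly one primary reason, so the exclusion log
  partitions the removed records.  Duplicates are exact matches after
  NFC/case-fold/whitespace-collapse; near-duplicates (character-5-gram
  Jaccard >= 0.9 by default) are also excluded, with a shingle-set-size
  prefilter (similarity >= t forces a size ratio >= t) that keeps the scan
  fast on realistic length distributions.  The threshold is configurable
  and the scan can be disabled.
- **Degenerate inputs.** A single-narrative corpus reports SD 0 with an
  explicit degeneracy flag (all other SDs use the n−1 denominator).  A
  token with an empty lemma is counted under its case-folded surface form
  and tallied as a fallback.  Merging requires both frequency tables
  non-empty, and the statistic raises a domain error on a one-lemma
  universe (where a smoothed complement hits zero).  Psychometric summaries
  (PCL-5, 0–80; MISS, 10–100) are computed per instrument over respondents
  with that total present; out-of-range totals quarantine the row at read
  time.

## Synthetic data

The generators exist so that every pipeline stage and statistical claim can
be exercised without the real (sensitive) corpus.  They emulate structure,
not language.

- **Lexicon.** Zipf–Mandelbrot rank-frequency law `p_r ∝ 1/(r+q)^s`,
  defaults `s = 1.1`, `q = 2.7`, vocabulary 10,000 (2,000 for the narrative
  fixtures) — exponents and offsets in the range typically fitted to
  natural-language lemma distributions.
- **Corpus pairs.** Reference counts are multinomial at a fixed total from
  the base distribution; target counts are multinomial from the base tilted
  by `exp(shift)` on effect lemmas and renormalized.  Multinomial sampling
  at fixed totals matches the fixed-size corpora the statistic sees (the
  variance formula is an approximation under either multinomial or Poisson
  sampling).  Default totals are 100,000 tokens per corpus.  The truth
  record stores the exact post-normalization probabilities, the raw
  log-odds shift and the implied (shrunken) delta.
- **Planted-effect design.** The recovery study plants shifts
  {log 1.5, log 2, log 4}, ten lemmas each, round-robin over Zipf ranks
  21–50, so the three groups have nearly identical base frequencies.  An
  a-priori power calculation at these sizes (base probability ≈ 2–8·10⁻³,
  implied deltas ≈ 0.07 / 0.16 / 0.36, per-lemma sd ≈ 0.02–0.03 after
  shrinkage) places shift log 4 essentially always above the Bonferroni
  threshold, log 2 most of the time, and log 1.5 almost never — a design
  that separates the power curve without saturating it.
- **Narrative fixtures.** `generate_narratives` emits both release formats.
  Lengths are log-normal, moment-matched to mean 333 / SD 237 words and
  truncated at one word; metadata marginals follow the emulated sample
  (16/84% men/women, 43% displaced, occupation 703/976/324, education
  439/564/314/686, trauma-history 22/301/1220/470, ~61% questionnaire
  completion with PCL-5 ≈ N(41, 19) clipped to 0–80 and MISS ≈ N(42, 17)
  clipped to 10–100, ages log-normal with median 32 clipped to 18–86,
  submission dates uniform over the collection window).  Fields are sampled
  independently: the generator does not model covariance between, say,
  displacement and region, nor temporal drift.  The "text" is a lemma
  sequence from the lexicon chunked into 6–15-word sentences with sampled
  POS tags and a flat dependency tree — so passing tests demonstrate the
  pipeline's bookkeeping and the statistic's calibration, not anything
  about real language.
- **Determinism.** Every generator is a pure function of its seed;
  replicate seeds derive from the master seed via `SeedSequence` spawning.

## Simulation study sizes

The bundled calibration studies use 500 null replicates (vocabulary 10⁴,
10⁵ tokens per corpus) for the family-wise error rate and 200 replicates
(vocabulary 10³, 10⁵ tokens per corpus) for recovery/power — sizes at which
the Monte-Carlo standard errors (≈0.004 on the FWER, ≈0.001 on group-mean
deltas) are well below the effects being checked, while a full run of the
test suite and the acceptance script stays in the minutes range on a single
CPU.

## Known limitations

- Unigrams only: no bigram/trigram keyness (reference frequency lists of
  the kind consumed here are unigram exports).
- The statistic's shrinkage means reported deltas understate raw population
  log-odds differences; rankings and significance calls are unaffected in
  direction, but effect sizes should be read on the statistic's own scale.
- The bundled stopword list is a reconstruction; results on real Ukrainian
  corpora will depend on the list actually supplied.
- De-identification coverage is only as good as the alias lists provided.
- The synthetic narrative fixtures are structurally faithful but
  linguistically meaningless; they cannot validate tagger- or
  lemmatizer-dependent behaviour (the pipeline consumes, never produces,
  morphosyntactic annotation).
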