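# Methods

`depsym` implements a dual-source analysis of depressive symptoms: a
lexicon-based detector of five PHQ-8 symptom categories in short German
social-media texts, a parallel processing path for questionnaire
self-reports, covariate-adjusted temporal models with contrasts around the
first 2020 German social-contact ban, and a rank-correlation assessment of
how well the two sources agree over calendar weeks 1–31 of 2020. Because
the original data (a restricted national health survey and a
non-redistributable tweet corpus) cannot ship, a first-class synthetic-data
module generates stand-ins with the statistical structure the analysis
assumes; every empirical claim in this note is about what the package
computes on that synthetic data.

## Symptom categories

Five PHQ-8 items are analysed: diminished interest, depressed mood,
insomnia/hypersomnia, fatigue/loss of energy, and worthlessness/
inappropriate guilt. The appetite, concentration and psychomotor items are
not represented: in short social-media text their signal is either too
sparse (fewer than 12 matching tweets a day, the exclusion threshold also
applied per symptom at run time) or too ambiguous to detect lexically.

## Lexicon construction

Each symptom is anchored by a small seed set of German keywords taken from
the wording of the questionnaire item (e.g. *Niedergeschlagenheit*,
*Schwermut*, *Hoffnungslosigkeit* for depressed mood). Seeds are enriched
from a depression-forum-style corpus:

1. tokens are counted in symmetric windows (default width 5), with known
   multi-word phrases merged into single tokens first;
2. the co-occurrence matrix is weighted by positive pointwise mutual
   information (PPMI) and factorized with a dense truncated SVD
   (default dimension 50, minimum token count 2); word vectors are
   `U_k * sqrt(S_k)` with each singular vector's sign fixed by making its
   largest-magnitude component positive, so training is bit-reproducible;
3. for every seed word, up to `k = 25` nearest cosine neighbours scoring at
   least `tau = 0.4` join the lexicon as `expanded` entries, ties breaking
   lexicographically. Manual curation is modelled by optional allow/deny
   lists.

The PPMI+SVD backend replaces a proprietary neural vocabulary-refinement
tool; it is deterministic, desk-scale, and interchangeable behind the
`EmbeddingSpace` contract. `tau` and `k` have no published reference
values; both defaults are surfaced in configuration and the lexicon records
the cosine score of every expanded keyword, so sensitivity analyses are a
config change.

Matching is exact by construction: lowercased token-sequence match with
hashtag markers stripped, no stemming, no compound splitting, multi-word
keywords matched as contiguous token runs. `Energie` never matches
`energielos`. Stemming or lemmatization would silently widen the match
contract and is deliberately excluded.

## Tweet pipeline

Classification order is fixed and every stage's retention count is
reported: (1) records with unparseable timestamps are rejected with a
warning; (2) records outside the study window are dropped; (3) retweets are
dropped (the `is_retweet` flag or a leading `RT @` prefix); (4) texts
without an exact keyword match are dropped; (5) texts without a
first-person marker are dropped. Self-reference is a token-level test for
first-person pronouns (*ich, mir, mich, mein-, wir, uns, unser-*) or
first-person verb forms. Only person-unambiguous verb forms are listed
(*bin, habe, fühle, leide, …*); forms identical in first and third person
singular (*war, kann, muss*) are excluded because they would mark
third-person reports as self-references. Both lists are configurable.

Retained tweets aggregate to per-symptom weekly series of mean tweets per
day, dividing by the number of calendar days of that ISO week inside the
window; edge weeks may be partial and are flagged. A tweet matching m
symptoms counts once in each of the m series (the series are per-symptom,
and their margins are reported per symptom). A symptom averaging strictly
fewer than 12 tweets/day over the whole window is excluded from modelling
and correspondence, and the exclusion is reported, never silent. Weeks are
ISO-8601 ("calendar week" in the German convention).

## Survey path

Item responses on the 0–3 frequency scale are dichotomized to affected
(≥ 1) versus not affected (0), mirroring the binary presence signal
extractable from tweets. Missing or out-of-range responses are excluded
per item (available-case), not listwise, which minimizes data loss and
matches the per-item models. Weekly values are survey-weighted
proportions, invariant to rescaling all weights; weeks without respondents
are flagged missing rather than set to zero so downstream models skip them
explicitly. Without the survey's design variables, design-based variance
estimation is approximated by weighted estimation with robust sandwich
covariances — an approximation stated as such.

## Models

Per symptom and source, one fitting surface covers the six model shapes:

* survey: weighted logistic regression on the binary outcome at respondent
  level (IRLS, convergence tolerance 1e-8, max 100 iterations);
* Twitter: linear regression on tweets/day in week × sex × age-group
  cells, unweighted by default with a tweet-volume weight switch;
* controls: age group, sex and their interaction, treatment-coded against
  male and the youngest age group (interaction switchable);
* time: nothing, calendar week as a centered fourth-degree polynomial
  (centering for conditioning only; predictions are invariant to it, and
  at least five distinct weeks are required), or the three contact-ban
  periods (*before* weeks 1–11, *during* 12–18, *after* 19–31; reference
  *before*; bounds configurable).

Covariances are HC1 sandwiches for both families (weighted data; count
outcomes modelled as gaussian). Non-convergence and separation flag the
result rather than raising; margins refuse to compute from a flagged fit.
Rank-deficient designs raise an error naming the aliased columns.

Predictive margins are observed-covariate averages: the focal time
variable is set to the requested level for every estimation-sample row,
predictions are averaged with the estimation weights, and the standard
error follows by the delta method; 95% CIs are normal-based, clipped to
[0, 1] for probabilities. The period term is tested jointly by a Wald
test — large-sample chi-square by default, or an adjusted F with
denominator df `n_clusters − 1` when a cluster variable is supplied (the
design-based small-sample adjustment; real design variables are not
available to this package). Pairwise period contrasts are margin
differences with delta-method standard errors, unadjusted for multiplicity
(three contrasts, presented as-is).

## Correspondence

Per symptom, the headline statistic is the Spearman rank correlation
between the two sources' quartic-smoothed weekly margins — rank-based
because tweets/day and weighted proportions live on incommensurable
scales, so only monotone co-movement is meaningful. p-values use the t
approximation with n − 2 df (n ≈ 31 weeks); an exact permutation p is
available for n ≤ 10. A raw-weekly-values option exists for sensitivity
analysis. Constant series leave rho undefined and are flagged, not
silently zeroed.

The lag scan is this package's operationalization of the visual
impression that the social-media signal can lead the survey signal; it is
exploratory and labelled as such. For each integer lag ℓ in −4..+4,
survey week w is paired with Twitter week w + ℓ and rho is recomputed on
the overlap (lags with fewer than 3 overlapping weeks are skipped);
`best_lag` maximizes rho with ties broken toward the smallest |ℓ|. A
Twitter series that reacts earlier therefore yields a negative best lag.

## Synthetic data: what it emulates, and what it does not

The generator's defaults are the study conditions: 9011 survey
respondents; 48,549 tweeting users (the user count implied by 96%
single-tweet users numbering 46,607); weeks 1–31 of 2020 with period
bounds 11/18; 1–10 tweets per user-week with P(one tweet) = 0.96; a
female-dominant (83.9%), 18–24-modal Twitter sample versus a near-even,
older survey sample; log-normal survey weights with mean 1.

Symptom base rates default to the pre-ban survey margins (.38/.27/.50/
.54/.14 — worthlessness rarest, fatigue most common) and period log-odds
offsets are back-computed from the during/after margins, giving the
documented dip in sleep problems, fatigue and worthlessness during the ban
and a small rise in low mood. Demographic log-odds offsets encode the
elevated risk of young adult women (sex, age, and sex × age terms).
Survey item responses place P(response ≥ 1) on exactly this logistic
model; conditional on being affected, severities 1/2/3 split 0.55/0.30/
0.15. Tweet texts are minimal carrier sentences holding exactly one
lexicon keyword, first-person with the configured probability and
third-person otherwise — fluency is irrelevant because matching is exact.
Weekly tweet volume is modulated so each symptom's absolute weekly rate is
proportional to `base_rate × exp(period_effect)`, which makes the two
sources share the same underlying temporal structure. The enrichment
corpus places seed and related words among symptom-specific context words
(plus distractor documents), so embedding expansion can discover the
related words through shared contexts.

Deliberately not modelled: realistic Twitter language, emoji, negation,
sentiment, bot or network structure, within-user temporal correlation,
seasonal components, and any real geography (region is an opaque label).
Passing tests therefore demonstrate the pipeline's correctness and
calibration on data whose generating process is known — they do not
demonstrate that the lexicon or the self-reference rules would recall real
depressive tweets at any particular rate.

A consequence worth stating: with the published effect sizes, the survey's
weekly signal amplitude (±0.01–0.04 in probability) is comparable to its
weekly sampling noise at ~290 respondents/week, so the cross-source rho on
synthetic data varies substantially by symptom and seed and sits below the
range reported for the real study, where the sources evidently shared more
week-level structure than the three-period step this generator encodes.
The package reports whatever it computes; no output is calibrated toward
the published correlations.

## Numerical choices and degenerate inputs

* IRLS tolerance 1e-8, 100 iterations; coefficients with |β| > 15 flag
  probable separation.
* SVD sign convention as above; expansion ties break lexicographically;
  lag-scan ties break toward the smallest |lag|, then the smaller lag.
* Weekly aggregation with zero tweets yields explicit zero series
  (tweets) or flagged-missing values (survey) — the two sources' absence
  semantics differ because a week without tweets is an observed zero rate
  while a week without respondents is no observation at all.
* The exclusion rule's mean is total tweets over total window days, so
  partial edge weeks carry their real day counts; the comparison is
  strict (`< threshold` excludes).
* Degree-4 time smoothing refuses to fit on fewer than five distinct
  weeks.
* All generators draw from `numpy` Generator streams spawned from the
  configured seed; identical configuration gives byte-identical outputs,
  including the run report.

## Problem sizes in the test and acceptance suites

Replicated checks use desk-scale sizes chosen for statistical validity of
the check itself: parameter recovery runs 200 cohorts of 5000 respondents
(2-SE coverage per period coefficient ≥ 90%); the Wald test's type-I error
runs 1000 null cohorts of 800 respondents (large enough for the
large-sample chi-square reference to apply); lag recovery adds noise
scaled to 5% of the series' own weekly standard deviation — the only
noise scale a rank statistic can feel, since Spearman rho is invariant to
affine transforms of either series.

## Known limitations

* Exact matching trades recall for precision: inflected or compounded
  keyword forms (common in German) do not match unless present in the
  lexicon.
* The self-reference rules are lists of unambiguous forms, not a parser;
  quoted or reported first-person speech counts as self-reference.
* Demographics are consumed as input fields; nothing is inferred from
  text.
* The Twitter models treat week × sex × age cells as independent
  gaussian observations; no autocorrelation or count-family modelling.
* The survey variance approximation ignores the original complex
  sampling design.
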