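# Methods

`diatrend` implements a diachronic text-mining pipeline for dated article
corpora: corpus filtering with exclusion accounting, token preprocessing,
LDA topic modelling, discretisation of topic probabilities into "aboutness"
calls, incidence time series, lexicon- and topic-based article classifiers,
and binomial trend models on publication date. This note records the models,
the parameters that matter, and the design choices made where the design was
genuinely open.

## Corpus filtering

Filtering runs in four sequential steps, each counted against the corpus as
it stands when the step runs, so the report reconciles as a waterfall:
duplicate titles (exact match after trimming surrounding whitespace and
case-folding — the most conservative reading of "duplicate title"), articles
with fewer than `min_tokens` words (default 50), articles absent from either
of the two upstream datasets, and articles dated inside a parse-error window
(default 1997-01-04 through 1998-02-14, inclusive) whose length triggers an
outlier rule.

The outlier rule is deliberately pluggable because "implausibly long" has no
canonical threshold. The default flags token counts strictly above the
99.5th percentile of the corpus at step-4 time; an explicit numeric
threshold can be passed instead. Note the percentile default cannot isolate
a planted outlier block whose share of the corpus exceeds 0.5% — the cutoff
then falls inside the block — so fixtures with explicitly planted outliers
(e.g. `planted_defect_manifest`) carry their own separating threshold, and
the filter is run with it. Idempotence of filtering holds exactly for
threshold rules; the percentile rule recomputes its cutoff on the filtered
corpus and is idempotent whenever no surviving in-window count straddles the
updated cutoff.

The `window_start`/`window_end` arguments describe the corpus's nominal date
span and are validated, but no removal class exists for them; date-range
subsetting is left to the caller.

## Preprocessing

Tokens are lowercased, split on non-word boundaries with hyphens retained
inside tokens. Cleaning removes stopwords, tokens containing any digit, and
hyphenated tokens with an empty hyphen-delimited part ("less than one
letter" read as an empty part). The packaged stopword list is a plain-text,
one-term-per-line list of common English words written for this package in
the style of the classic SMART information-retrieval list; it is
configurable, and the loader records the term count and sha256 of whatever
list actually ran, so an analysis can state its preprocessing exactly.
Hyphenated tokens are kept as single terms (not split); no stemming,
lemmatisation or n-grams.

## Topic model

LDA is fitted by a collapsed Gibbs sampler (`topic_model.fit_lda`): both
Dirichlet layers are integrated out and token-topic assignments resampled
from their collapsed conditionals. Defaults: `alpha = 1/300`,
`beta = 1/100`, hyperparameters re-estimated every 10 sweeps by Minka's
fixed-point update (asymmetric alpha vector, scalar beta);
`optimize_interval = 0` fixes them. `k` defaults to a desk-scale 20; the
full-scale configuration (k = 400 over ~72k articles) is a config choice,
not a test target. Estimates are smoothed final-state counts — a single
draw, not an average over samples — which is sufficient for the downstream
discretisation and keeps the determinism contract simple: given a seed, the
token visit order and random stream are fixed, so runs are bitwise
reproducible. A `k = 1` fit is permitted as the degenerate normalisation
case (every `p_ia` is exactly 1). Any external fitter can stand behind the
same `TopicModelFit` contract via `from_matrices`; the test suite
cross-checks topic recovery against scikit-learn's variational LDA on a
separable corpus.

## Discretisation and incidence

Topic probabilities are standardised over the set of topics of interest and
an article is "about" a topic when its standardised probability is **>=
0.05** (boundary inclusive). A super-topic call thresholds the *sum* of the
standardised subsidiary probabilities; standardisation happens over the
analysis subset (e.g. all clinical topics) before summation — the
alternative (thresholding raw sums) is not exposed, because downstream
classifiers are defined on standardised mass. Topic incidence divides a
topic's yearly call count by the total number of calls that year (articles
can be about several topics, so the denominator is calls, not papers);
consequently yearly incidences over the topics of interest sum to one.
Word incidence divides variant occurrences by all cleaned tokens; article
incidence is a plain proportion of articles. All series carry Wilson 95%
score intervals (well behaved near 0 and 1; the interval method is our
choice). Display binning is the calendar year, but records keep full dates
and all trend models consume dates.

## Subcorpus classifiers

*Women-specific health*: probabilities over clinical topics are collapsed
into a women-specific bucket W and a remainder O, the pair standardised by
W + O, and the article called women-specific when standardised W >= 0.05.
W + O = 0 yields an explicit unclassifiable outcome rather than a silent
False.

*Gender vocal/silent*: whole-token, case-insensitive match against the
variant groups woman/women, female/females, gender, sex/sexes. Substrings
("sexual") never match; plural/possessive forms beyond the four printed
groups are not matched. The classifier runs on pre-stopword tokens so a
stopword list cannot eat a lexicon term. Corpus records are assumed
table-free; stripping data tables from source documents is out of scope.

A documented arithmetic note: the psychiatry exclusion share 615/6595
computes to 9.33% (9.3% at one decimal); a published rounding gives 9.4%.
Tests assert the quotient.

## Trend models

Dates are encoded as days since 1948-01-01 and regressed on the year scale
(days/365.25) for conditioning; the annual odds factor is
`exp(slope_per_day * 365.25)`, with 365.25 as the annualisation constant.
Plain trends are binomial GLMs fitted by IRLS (statsmodels backend,
convergence tolerance 1e-10, max 100 iterations) with Wald 95% intervals.
Fitting aggregated yearly counts or per-article Bernoulli rows with the same
dates gives identical estimates (binomial sufficiency; tested). Complete
separation and all-zero outcomes are flagged and the CI suppressed.

The segmented model estimates a single breakpoint psi by iterative
linearisation: augment the logistic model with the hinge `(x - psi0)+` and
the gap indicator `I(x > psi0)`, then update psi by the gap-to-slope ratio
`gamma/beta2`, iterating until the update is below 0.01 day (max 50
iterations). Two refinements matter in practice: the step is damped
(halved on every direction reversal) because the raw update two-cycles once
psi sits between adjacent observation dates, and steps that would leave the
data range are halved before declaring failure. The breakpoint standard
error is the delta-method ratio SE(gamma)/|beta2|. Slope standard errors
are taken from the final linearised fit *including* the gap column, which
propagates breakpoint uncertainty into the segment slopes — without this the
post-break CI is materially anti-conservative (observed coverage ~40%
instead of ~95% in the recovery simulations). AIC counts four parameters
for the segmented model (intercept, two slopes, breakpoint) against two for
the no-break null. Initialisation defaults to the midpoint of the date
range; the recovery tests in `tests/` probe sensitivity by comparing against
an exhaustive grid-search maximum-likelihood breakpoint.

Era contrasts are logistic models with a single era indicator; the fitted OR
equals the closed-form cross-ratio of pooled per-era counts. Word-trend
ranking batch-fits one trend per word in a single corpus pass and reports
the focal word's percentile among the *other* words' slopes (strictly
smaller; ties reported separately).

Generalised additive smooths are visualisation aids and are intentionally
not part of this package's tested surface.

## Synthetic corpus generator

The generator emulates the statistical structure the analysis assumes:
per-year article counts (constant by default; real corpora drift in volume,
which is not modelled), publication dates uniform within the year, topic
mixtures drawn from a Dirichlet centred on year-specific prevalences
(softmax of per-topic logit trajectories; concentration 30 by default),
topic-specific word emissions over disjoint per-topic signature
vocabularies, and two independent injection channels: focal words whose
per-token probability follows a logistic trajectory, and a gender-lexicon
channel whose per-article hit probability follows a (possibly two-segment)
logistic trajectory. Trajectories are parameterised on the logit scale so a
planted "annual odds factor" is exactly the quantity the trend module
estimates, making recovery tests sharp. The lexicon channel is independent
of topic content by default (isolating the gender-vocal signal); a coupling
knob ties hit odds to women-specific calls when correlated structure is
wanted.

For super-topic recovery the generator can plant the *article-level call
probability* directly: the about-flag is drawn from the trajectory and the
mixture constructed so the standardised super-topic mass lands on the
correct side of the 0.05 threshold. Planting only prevalences and letting
calls fall out of the Dirichlet draw would attenuate the planted factor and
make calibrated recovery impossible.

What passing tests show — and do not show. The generator produces exactly
the model class the estimators assume (logistic trends, exact lexicon
recovery, clean tokens). Recovery tests therefore validate the estimation
machinery, not robustness to OCR noise, tables, topic drift, volume drift,
or misspecified trend shapes, none of which are modelled.

Default experiment conditions (`diatrend.experiments`), chosen to match the
study-scale quantities the trend estimates describe: focal word pair at
p(1948) = 0.001 rising by 1.023/year (≈1 per 1000 words in 1948 to ≈5 by
2018), 500 articles/year at 200 tokens/article; gender-vocal rate
p(1948) = 0.40 declining at 0.99/year to a break at 2005.2 then rising at
2.18/year, 500 articles/year (60 tokens/article — token count is irrelevant
to an article-level hit channel, so it is kept small); women-specific
super-topic call probability p(1948) = 0.11 rising at 1.004/year, 1 000
articles/year, mixtures only (no token emission). Each recovery experiment
is repeated over 20 seeds and judged by 95% CI coverage (expected >= 18/20).

## Degenerate inputs and numerical conventions

Empty corpora are legal inputs to readers and matrix builders (empty
outputs, no error); all-zero documents are an error for the sampler but are
retained and flagged by the matrix builder. Zero-denominator years are
emitted with undefined incidence rather than dropped. Ties in topic-word
probabilities break lexicographically, making `top_words` stable across
runs. All randomness flows through `numpy.random.default_rng` seeds;
nothing reads global RNG state.
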