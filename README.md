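# diatrend

Diachronic text-mining of a clinical-journal corpus: how the representation
of a theme in a research literature changes over decades, measured as topic,
word and article incidence, and modelled with binomial trend regressions on
publication date.

`diatrend` is aimed at computational researchers studying the history of a
literature from dated full-text article records. It provides the full
pipeline:

- **corpus_io** — read a line-delimited JSON corpus and filter it in four
  accounted steps (duplicate titles, short articles, dataset-intersection,
  implausibly long articles inside a parse-error window), with a
  reconciling `FilterReport`;
- **preprocess** — tokenise, remove stopwords / digit-bearing tokens /
  degenerate hyphenations, and build a sparse document-term matrix
  (MatrixMarket export);
- **topic_model** — latent Dirichlet allocation by collapsed Gibbs sampling
  with Minka fixed-point hyperparameter re-estimation, producing topic-word
  probabilities φ and article-topic probabilities p_ia;
- **incidence** — standardise p_ia over a topic subset, call an article
  "about" topic *i* when p_ia ≥ 0.05, and compute incidence
  I_it = N_it / N_t where N_t counts *topic calls* (not papers) at time *t*;
  word incidence relative to all tokens; Wilson 95% intervals;
- **subcorpora** — classify articles as women-specific-health
  (standardised two-bucket topic mass ≥ 0.05) or gender-vocal (whole-token
  match on woman/women, female/females, gender, sex/sexes);
- **trends** — binomial GLMs of incidence on publication date reported as
  annual odds factors exp(365.25·slope), single-breakpoint segmented
  regression by iterative linearisation (ψ ← ψ + γ̂/β̂ with step damping,
  delta-method CI, AIC against the no-break model), era-contrast odds
  ratios, and batch per-word trend ranking;
- **synthetic_data** — a corpus generator with logit-scale ground-truth
  trajectories (including structural breaks) so every stage is testable
  without any proprietary corpus.

## Worked example

Plant a gender-vocal trajectory that declines by an annual odds factor of
0.99 from a 40% incidence in 1948, breaks in mid-2005, and rises at
2.18/year afterwards; classify articles with the lexicon; refit the break:

```python
import numpy as np
from diatrend import (SyntheticSpec, TopicSpec, Trajectory, generate_corpus,
                      classify_gender_vocal, article_incidence,
                      fit_segmented_trend)

traj = Trajectory(p_ref=0.40, annual_factor=0.99, break_year=2005.2, post_factor=2.18)
spec = SyntheticSpec(
    articles_per_year=200, tokens_per_article=60,
    topics=[TopicSpec("background", Trajectory(0.5), n_words=50)],
    lexicon_trajectory=traj, seed=11,
)
records, truth = generate_corpus(spec)
flags = np.array([classify_gender_vocal(r.tokens) for r in records])
dates = [r.pub_date for r in records]

print(article_incidence(flags, dates).data.head(3).to_string(index=False))
fit = fit_segmented_trend((dates, flags.astype(int), np.ones(len(flags))))
print(f"break {fit.breakpoint_year:.2f} "
      f"(95% CI {fit.psi_ci_low_year:.2f}-{fit.psi_ci_high_year:.2f})")
print(f"pre-break annual factor  {fit.pre_annual_factor:.4f}")
print(f"post-break annual factor {fit.post_annual_factor:.4f} "
      f"(95% CI {fit.post_ci_low:.3f}-{fit.post_ci_high:.3f})")
print(f"AIC {fit.aic:.1f} vs no-break {fit.null_model_aic:.1f}")
```

Output:

```
 year  numerator  denominator  incidence   ci_low  ci_high
 1948         77          200      0.385 0.320333 0.454001
 1949         75          200      0.375 0.310854 0.443857
 1950         81          200      0.405 0.339378 0.474203
break 2005.00 (95% CI 2004.65-2005.34)
pre-break annual factor  0.9914
post-break annual factor 2.0198 (95% CI 1.876-2.175)
AIC 15660.5 vs no-break 18361.3
```

The yearly rows are the incidence of gender-vocal articles with Wilson 95%
intervals. The segmented fit places the structural break at 2005.0 (truth:
2005.2), estimates the pre-break decline at 0.9914/year (truth 0.99) and the
post-break rise at 2.02/year with a CI reaching the generating 2.18 at 200
articles/year; the break model beats the no-break model by ~2700 AIC points.

A thin CLI mirrors the library: `diatrend simulate`, `diatrend filter`,
`diatrend trend fit|segmented|contrast`, `diatrend word-incidence`,
`diatrend vocal-incidence`.

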