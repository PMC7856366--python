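# engage

Measures how much countries talk about the **health impacts of climate
change** in their formal statements to intergovernmental bodies, and ranks
the country-level factors that predict this engagement.

The package is aimed at researchers in global health policy and
text-as-data political science. It implements the two-arm measurement used
in studies of UN engagement:

- **General-debate arm (`gd`).** For each UN general-debate statement
  (one per country-year), engagement is counted with a keyword-in-context
  (KWIC) co-occurrence rule: a *reference* is an occurrence of a health
  term h with at least one climate-change term within the *w* = 25 words
  immediately before or after h. Each qualifying health mention counts
  once, however many climate terms are nearby; per-country totals sum over
  the 2000–2019 statements.
- **Pledge arm (`ndc`).** For each nationally determined contribution
  (one per country), engagement is the plain frequency of health terms.

Matching uses fixed term lexicons (28 health phrases, 31 climate phrases
after normalization), case-insensitive exact matching with longest-match
precedence ("health care" suppresses "health"; "greenhouse gas" suppresses
"greenhouse"), and a tokenizer that folds hyphen/underscore/subscript
variants (CO₂, CO_2, CO2 → `co2`).

Per-country engagement counts *y* are then modelled with a random forest
on a Table-of-predictors feature matrix **X** (log GDP per capita, growth,
trade, electricity access, democracy, log population, |latitude|, life
expectancy, infant mortality, maternal death risk, healthy life years,
health expenditure, CO₂ per capita, fossil/renewable shares, carbon
footprint, oil rents, and eight negotiating-group indicators). Predictor
relevance is scored with **out-of-bag permutation importance**:

    imp(j) = E[ err_OOB(X with column j permuted) − err_OOB(X) ]

averaged over repeats, with err the OOB mean squared error (regression on
counts) or misclassification rate (any-engagement classification).
Negative values — the permuted feature predicting better than the real one
— are reported as-is; only ranks are comparable across runs.

A synthetic-data module generates corpora with *planted* health/climate
co-occurrences at controlled token distances (so true counts are known
exactly) and predictor tables with a known effect vector under a Poisson
log-link, making the whole pipeline testable without any downloads.

## Worked example

```python
from pathlib import Path
from engage import (CorpusSpec, generate_corpus, load_corpus,
                    load_default_lexicon, summarize_engagement)
from engage.feature_table import aggregate_gd_outcome
from engage.reporting import score_documents

root = Path("scratch/demo")
spec = CorpusSpec(n_countries=5, years=(2000, 2004), planted_gd_pairs=2,
                  planted_orphan_health=2, seed=42)
generate_corpus(spec, root)

health = load_default_lexicon("health")
climate = load_default_lexicon("climate")
docs = load_corpus(root / "gd", "gd")
scores = score_documents(docs, health, climate, window=25)
print(summarize_engagement(aggregate_gd_outcome(scores)).to_dict())
```

prints

```
{'mean': 10.0, 'min': 10, 'max': 10, 'n_zero': 0, 'n_countries': 5,
 'pct_any_engagement': 100, 'top_k': [['ABW', 10], ['AFG', 10], ['AGO', 10],
 ['AIA', 10], ['ALA', 10]], 'tie_at_cutoff': False}
```

Each of the 5 countries has 5 statements with 2 planted co-occurrences
each, so every 2000–2004 total is exactly 2 × 5 = 10 — the pipeline
recovers the planted ground truth, and the mean, range, zero-count and
(alphabetically tie-broken) top-k summary follow.

The same flow from the shell:

```sh
engage synth --out scratch/demo --seed 42
engage score-gd scratch/demo/gd --out scratch/scores.csv
engage importance --table scratch/demo/features.csv --out scratch/imp.csv
```

To score real corpora, point `engage score-gd` / `engage score-ndc` at a
directory of UTF-8 `.txt` statements named `{ISO3}_{SESSION}_{YEAR}.txt`
(general debate) or `{ISO3}.txt` (pledges), and `engage features` /
`engage run` at wide CSVs of predictors keyed on `country_iso3`.

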