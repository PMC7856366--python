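# Methods

## Engagement measurement

Documents are statements by countries to intergovernmental bodies: annual
general-debate statements (one per country-year, 2000–2019 by default) and
climate pledges under the Paris Agreement (one per country; the EU's joint
pledge is attributed to the pseudo-entity `EUU`, never fanned out to member
states). Text is tokenized into lowercase word tokens; punctuation, hyphens
and underscores separate tokens, digits are kept, subscript digits map to
ASCII, and the pair ("co", "2") merges to `co2` so CO₂/CO_2/CO2 coincide.
The token is the unit of distance everywhere; sentence boundaries are
ignored.

Two fixed lexicons drive matching: 28 health phrases and 31 climate-change
phrases after normalization (the printed source lists carry one duplicate
health term and several hyphen/space spelling variants that collapse).
Matching is exact and case-insensitive — no stemming, lemmatization or
fuzzy matching, since near-variants ("disease"/"diseases") are listed as
separate phrases deliberately. Within one category, scanning is left to
right with longest-match precedence and no overlap; across categories,
mentions may overlap freely.

The general-debate engagement count is the number of health mentions with
at least one climate-term token within `window` (default 25) tokens before
the health phrase's first token or after its last token. Key conventions,
chosen where the measurement rule is under-specified and fixed throughout:

- the window is inclusive at distance exactly `window` (25 in, 26 out);
- a multi-token climate phrase qualifies if *any* of its tokens is in range;
- one health mention is one reference regardless of how many climate terms
  are nearby, while two health mentions sharing one climate mention are two
  references;
- a health mention matched by several overlapping health phrases is counted
  once (longest-match already enforces this).

The pledge-arm count is simply the number of health mentions.

## Predictor table

Predictors are country-level: economic (log GDP per capita in constant
USD, annual growth %, trade % of GDP, electricity access %), political (a
pre-combined Freedom-House/Polity democracy score, consumed as given),
geographic/demographic (log population, absolute latitude of the capital),
health (life expectancy, infant mortality per 1000 births, lifetime risk
of maternal death, healthy life years, health expenditure % of GDP) and
climate-related (CO₂ tonnes per capita, fossil and renewable shares of
energy consumption, carbon footprint in global hectares per person, oil
rents % of GDP), plus eight binary negotiating-group indicators (G77,
African Group, Arab States, EU, LDC, SIDS, Umbrella, EIG). Log transforms
apply only to GDP per capita and population; non-positive inputs are
flagged missing rather than erroring. Missing data are handled by listwise
deletion with a completeness report (`n_total = n_complete + n_dropped +
n_unmatched`); no imputation.

The bundled group-membership CSV is an editable fixture: the Umbrella and
EIG lists are complete published memberships; the larger groups are
compiled from public UN/UNFCCC lists at their study-window sizes (G77 135,
African Group 54, Arab States 22, EU 28 including the UK, LDC 48 including
Equatorial Guinea before its 2017 graduation, SIDS 41 including Cook
Islands, Niue and the pre-2010 Netherlands Antilles). Users with a
different vintage in mind should edit the CSV.

For the general-debate model the outcome is the country's 20-year total by
default; a per-year panel mode exists but neither mode is claimed to match
any particular published alignment of predictor vintages.

## Random forest and permutation importance

The forest (scikit-learn, 1000 trees by default) models counts by
regression with squared error, or any-engagement-vs-none by
classification; regression is the default because the outcome is a count.
Hyperparameters are chosen by grid search on out-of-bag (OOB) error over
mtry ∈ {p/3, √p, p/2} and minimum node size ∈ {1, 5, 10}; features are
never weighted, and correlated predictors are kept (the method tolerates
multicollinearity, which is the point of using it here).

Permutation importance is computed on OOB predictions, not on resubstituted
training predictions: per-tree OOB sample masks are reconstructed from each
tree's bootstrap random state, OOB predictions are aggregated across trees
(mean for regression, probability votes for classification), and for each
of 50 repeats (default) each feature column is shuffled over all rows and
the OOB error recomputed. The importance is the mean error increase;
repeat-level values are retained, and negative means are passed through
unmodified — for an uninformative feature a random permutation can beat
the real column, and that sign is informative. Ranks break ties
alphabetically and flag them. Importance magnitudes depend on the task and
error metric and are not comparable across tasks or datasets; ranks are.

Degenerate inputs fail loudly: fewer than 10 complete rows, or a constant
outcome. A constant *feature* is fine and gets importance exactly 0.
Everything is deterministic given the config seed (bootstrap, grid fits,
permutation draws). The `ranger` R package computes the same OOB
permutation importance independently and is used as a cross-check in the
test suite, never as the implementation.

## Synthetic data

The corpus generator emulates the *measurement structure* of statement
corpora, not their language: documents are filler-token streams (filler
vocabulary filtered to be disjoint from every lexicon token) with planted
structures — health+climate pairs at a distance drawn uniformly from
[1, window] (or pinned to a boundary distance for window fixtures), and
orphan health terms. Planted structures are separated by more than
`window` filler tokens, so the true counts per document are unambiguous
and the pipeline must recover them *exactly*. Defaults (2 pairs + 2 orphan
health terms per statement, 3 health terms per pledge, 400 filler tokens)
keep per-country totals in the range seen in real 20-year totals.

The feature generator draws predictors from marginals loosely calibrated
to the world-country cross section (log-normal GDP and mortality, bounded
percentages, Bernoulli group flags) and produces counts from a Poisson
log-link on standardized features, `y ~ Poisson(exp(α + β·z))`, with the
default effect β = 1.0 on infant mortality, all other effects 0, and
α = ln 4.5. Standardized features are winsorized at ±3 SD inside the link
so skewed predictors cannot produce absurd counts; this keeps outcomes in
a realistic 0–50 range. Because the planted signal is a single monotone
effect plus Poisson noise, recovering it says the importance machinery
works — it does not say anything about collinear, confounded or
interaction-driven real predictor sets, and the filler corpus says nothing
about real rhetorical language (negation, metaphor, "temperature" in
non-climate senses — all counted by design, as the lexicon implies).

## Problem sizes in the checks

The test suite and the acceptance script run entirely on synthetic data:
oracle-equivalence on 1000 random streams of up to 500 tokens, 100 small
two-arm corpora, and 100 importance runs at n = 200 countries with a
reduced forest (150 trees, single grid point, 5 permutation repeats) —
sizes chosen to exercise every code path at negligible cost while the
library defaults (1000 trees, 50 repeats, full grid) remain the analysis
settings.

## Known limitations

- Corpus acquisition, PDF conversion and translation are out of scope; the
  loader only flags low-ASCII (likely non-English) documents.
- Word counts use this package's tokenizer and will differ slightly from
  counts produced by other tokenizers; published corpus statistics are
  therefore approximated, not reproduced.
- The window/overlap conventions above are this package's documented
  choices among defensible readings of the measurement rule, not claims
  about any original study's unstated implementation.
- Choropleth maps are not rendered; per-country totals CSVs are emitted
  for mapping elsewhere.
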