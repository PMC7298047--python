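# Methods

This note documents the models and procedures implemented by `repurpose`,
the defaults and why they were chosen, what the synthetic generators do and
do not emulate, and the numerical decisions a maintainer should know about.

## Gene-set assembly

`gene_catalog` merges labelled symbol lists into a union with per-symbol
provenance. Normalization is purely lexical (strip whitespace, upper-case).
We deliberately do **no** alias or synonym resolution: symbol nomenclature
mapping requires an external, versioned database, and any such mapping would
make merged set sizes depend on that snapshot. Consequence: two spellings of
the same gene that differ beyond case survive as two records. Iteration is
lexicographic by symbol so downstream outputs are byte-reproducible.

## 2×2 statistics

* **Chi-squared** uses the 2×2 shortcut form
  `X² = n(|ad−bc| − n/2·[yates])² / ((a+b)(c+d)(a+c)(b+d))` with one degree
  of freedom. The Yates term is clamped: when `|ad−bc| ≤ n/2` the statistic
  is exactly 0 and p = 1, which matters for tiny cohorts. Cells may be
  real-valued because the EMR scaling rule (below) produces fractional
  counts. Zero marginal totals raise a "degenerate margin" error rather than
  silently returning p = 1; callers that can use an exact test fall back to
  Fisher. The statistic is computed in-package (the clamped-Yates form on
  real-valued cells is the primitive everything else relies on); only the
  χ²₁ survival function comes from scipy.
* **Fisher exact** (two-sided) sums hypergeometric probabilities, over all
  tables with the observed margins, of outcomes no more probable than the
  observed one, with a 1e-9 relative tolerance when comparing probabilities
  so that ties are not broken by floating-point noise. It requires integer
  cells. Computed from the log-pmf with `logsumexp`, so extreme tables do
  not underflow.
* **BH-FDR** delegates to statsmodels' step-up implementation behind a
  validating wrapper; the test suite checks it against a from-scratch
  step-up oracle.
* p-values are floored at the smallest positive normal double (and the
  flooring logged) instead of ever reporting 0.

## Drug-target overrepresentation

For each drug the table is (in-query ∧ targeted, in-query ∧ not,
not-in-query ∧ targeted, neither) over a gene universe.

* **Universe.** There is no canonical universe for a drug-target table; the
  default is all distinct genes appearing in the interaction table, which is
  self-contained and reproducible. It can be overridden by a gene list.
  P-values depend directly on this choice — documented prominently because
  a larger universe inflates significance.
* **Test.** Default chi-squared with continuity correction; per-drug
  automatic fall-back to the one-sided hypergeometric upper tail
  `P(X ≥ k)` when any expected cell is below 5 (the usual validity rule),
  since real target sets are small and the asymptotic test misbehaves
  there. When the method is `"fisher"` the one-sided tail is used for every
  drug: one-sided is the field convention for overrepresentation, and the
  direction of interest is excess overlap only. (The standalone
  `fisher_exact` primitive remains two-sided; the enrichment context is
  what makes the one-sided tail appropriate.)
* **Consensus.** Sources are weighted equally; survivors of the per-source
  FDR filter are ordered by supporting-source count, then minimum p across
  sources, then drug id. This aggregation is our definition (simple,
  auditable) — rank products or Fisher's method would be alternatives, but
  with two to four heterogeneous sources a count-then-best-p rule is
  transparent and ties are broken deterministically.

## EMR prevalence screen

Per drug, from a long-format exposure table (one row per patient-drug;
patients may repeat): cohort counts overall and in the strictly-over-40
stratum, prevalences, and a comparison of the over-40 cohort against a fixed
background model (prevalence 0.01, pseudo-cohort 1000 — the commonly used
population prevalence of glaucoma in those over 40).

* **Scaling rule.** Cohorts smaller than the background pseudo-cohort are
  scaled up to its size with the event count rescaled proportionally before
  the chi-squared comparison; an empty cohort becomes (1000, 0) and is
  flagged `zero_event`. This keeps the comparison between equal-sized
  groups while preserving the observed prevalence; it produces real-valued
  cells, which is why the chi-squared accepts them and why Fisher is not
  used here.
* **Continuity correction on by default.** Verified directly: with the
  correction the screen reproduces the published nine-cohort values
  (celecoxib P 1.74E-03, zero-event rows 4.30E-03, within 1% relative);
  without it those cells become ≈9.9E-04 and ≈1.5E-03. Two published P
  cells (theophylline 7.60E-06, aspirin 9.80E-04) recompute ≈2–3% higher
  under the same procedure — consistent with intermediate rounding at the
  source — and are treated as near-misses (5% band), not exact targets.
* **Odds ratio from raw counts.** The OR divides the cohort's raw odds
  `g/(n−g)` by the background odds; the scaling rule applies only to the
  chi-squared. This is the only combination consistent with the published
  table (its OR of 0.35 for a 564-patient cohort matches raw 2/562, while
  its P matches only the scaled comparison). OR is 0 when `g = 0` and
  flagged undefined when `g = n`. No confidence interval is computed.
* A patient exposed to several drugs counts in each drug's cohort;
  duplicate (patient, drug) rows collapse; a patient whose disease flag
  differs across rows is an input error, reported by patient id.

## Synthetic data

The generators emulate the shapes and the signal structure of the real
inputs, not their content:

* `simulate_interactions` — universe of `n_genes`, `n_drugs` drugs with
  `targets_per_drug` distinct targets each. Planted drugs draw each target
  from the query set with probability `q·f/(q·f + 1 − q)` (`q` the query
  fraction, `f` the enrichment factor, so `f` is the relative odds of
  hitting the query); background drugs draw uniformly. Defaults — 2000
  genes, 200 drugs, 20 targets/drug, 200-gene query, 10 planted drugs at
  factor 10 — are the study conditions of the recovery checks.
* `simulate_emr` — ages uniform integers on a range (default 41–90, i.e.
  an entirely over-40 population); per-drug independent Bernoulli
  exposures; disease ~ Bernoulli with odds = baseline odds × product of
  the true odds ratios of the patient's exposures (baseline prevalence
  0.01). Default: one drug, exposure 0.5, true OR 0.25 at n = 20,000 — the
  protective-signal recovery condition. Unexposed patients appear under the
  sentinel drug label `NONE` so pooled prevalence stays computable.
* `table7_fixture` — a deterministic EMR table whose per-drug cohort counts
  equal the published nine-row hospital screen exactly; ages and patient
  ids are arbitrary fixed values since only the four counts per drug flow
  downstream.

Each generator draws from its own named random stream derived from the
single seed, so adding a generator never perturbs existing outputs; all
generators are pure functions of their config.

**What passing tests do not show about real data:** the simulators have no
confounding (exposure is independent of age and of other drugs' exposures),
no diagnosis-code noise, no visit structure or time ordering, uniform drug
target degrees, and a query set drawn uniformly from the universe. Recovery
and calibration results therefore validate the statistical machinery, not
robustness to real-EMR biases such as confounding by indication.

## Numerical and design notes

* Enrichment results sort by (p, drug id); ties in rank share the minimum
  rank. Adding a drug to a table never changes another drug's p (only
  q-values move, through the BH multiplicity).
* All file formats are plain TSV/CSV with headers; floats round-trip via
  `%.17g`, and result files re-read with `float_precision="round_trip"`.
* The pipeline runner executes only the stages whose inputs are configured,
  writes a JSON manifest (config echo, per-stage row counts, version,
  timestamps), and aborts with the failing stage named.
* Problem sizes in the validation suite — 5000 null tables at n = 2000 for
  type-I calibration, 20 replicates of the planted-enrichment condition,
  200 replicates of the EMR recovery condition — are chosen so Monte-Carlo
  error is small relative to the acceptance bands while a full run stays in
  the tens of seconds.

## Known limitations

* Lexical-only gene normalization (no HGNC alias handling).
* No covariate adjustment or time-to-event modelling in the EMR screen; the
  background is a fixed external prevalence, not matched controls.
* Consensus ranking ignores effect-size direction; it assumes every source's
  p-values are comparably calibrated.
* The chi-squared on scaled cohorts treats rescaled counts as if observed;
  this mirrors the published procedure but understates sampling variance
  for very small cohorts (the `scaled` flag marks affected rows).
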