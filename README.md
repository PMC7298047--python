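# repurpose

Gene-set driven drug repurposing with an electronic-medical-record (EMR)
prevalence screen.

Given a disease gene set assembled from several evidence sources (Mendelian
databases, GWAS hits, phenotype-ranking tools, differential-expression
studies), the package scores every drug in a drug–gene interaction table for
overrepresentation of its targets in that set, filters by
Benjamini–Hochberg FDR, bridges disease→drug→gene maps into indirect query
sets, aggregates per-source rankings into a consensus candidate list, and —
as an orthogonal line of evidence — screens per-drug disease prevalence in
hospital EMR cohorts against a fixed population background. It was built
around glaucoma drug discovery but every disease-specific quantity
(background prevalence, gene lists, category vocabularies) is input data,
not a constant.

## The statistics

**Per-drug overrepresentation.** For a drug with target set *T* and a query
gene set *Q* over a gene universe of size *N* (default: all genes in the
interaction table), the 2×2 table is

|              | targeted | not targeted |
|--------------|----------|--------------|
| in query     | k        | n − k        |
| not in query | K − k    | N − n − K + k|

with `k = |T∩Q|`, `K = |T|`, `n = |Q|` (all intersected with the universe).
The default test is the chi-squared statistic with Yates continuity
correction,

    X² = N·(max(|ad − bc| − N/2, 0))² / ((a+b)(c+d)(a+c)(b+d)),

falling back per drug to the one-sided hypergeometric (Fisher) upper tail
P(X ≥ k) when any expected cell is below 5. q-values are BH step-up across
all tested drugs; candidates pass `q ≤ α` (α = 0.05 by default).

**EMR screen.** For each drug, the exposed over-40 cohort `(n, g)` (patients,
disease cases) is compared against a fixed background — prevalence 0.01 in a
pseudo-cohort of 1000, i.e. cells (10, 990). Cohorts smaller than 1000 are
scaled up to 1000 participants with the event count rescaled proportionally
(real-valued cells) before the Yates chi-squared test. The odds ratio is
always computed from the **raw** counts:

    OR = (g/(n−g)) / (0.01/0.99),

zero when `g = 0`, undefined when `g = n`.

**Consensus.** Drugs passing the FDR filter in at least one source are
ranked by (number of supporting sources, best p across sources, drug id)
and the top *k* (default 40) are reported.

## Worked example

Simulate an interaction table of 200 drugs over 2000 genes in which 10
planted drugs preferentially target a 200-gene query set (relative odds 10
per target draw), then score every drug:

```python
from repurpose import EnrichmentSimConfig, simulate_interactions, enrich_drugs

table, query, truth = simulate_interactions(EnrichmentSimConfig(seed=1))
results = enrich_drugs(table, query)
for r in results[:6]:
    print(f"{r.drug_id} k={r.k} K={r.K} p={r.p_value:.2e} q={r.q_value:.2e} {r.candidate}")
```

prints

```
D0087 k=11 K=20 p=8.25e-07 q=8.25e-05 True
D0191 k=11 K=20 p=8.25e-07 q=8.25e-05 True
D0086 k=10 K=20 p=8.41e-06 q=2.80e-04 True
D0139 k=10 K=20 p=8.41e-06 q=2.80e-04 True
D0154 k=10 K=20 p=8.41e-06 q=2.80e-04 True
D0173 k=10 K=20 p=8.41e-06 q=2.80e-04 True
```

— each line is a drug whose 20 targets include k query genes; a null drug
expects k ≈ 2, so k ≥ 10 yields vanishing p. In this run 9 of the 10
planted drugs pass `q ≤ 0.05` (all 9 flagged candidates are planted).

The EMR screen on the built-in fixed nine-cohort hospital fixture:

```python
from repurpose import table7_fixture, screen_all
from repurpose.synthetic_data import TABLE7_COHORTS

results = screen_all(table7_fixture(), list(TABLE7_COHORTS))
r = [x for x in results if x.drug == "celecoxib"][0]
print(f"{r.drug}: n>40={r.n_over40} cases={r.g_over40} p={r.p_value:.2e} OR={r.odds_ratio:.3f}")
```

prints

```
celecoxib: n>40=1488 cases=1 p=1.75e-03 OR=0.067
```

meaning 1 glaucoma case among 1488 exposed patients over 40 — significantly
below the 1% background (OR 0.067), flagging celecoxib as potentially
protective.

Everything is also available from the shell:

```sh
repurpose simulate emr --seed 1 --out-dir sim/
repurpose emr-screen --emr sim/emr.csv --out screen.tsv
repurpose run --config run.yaml     # config-driven end-to-end pipeline
```

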