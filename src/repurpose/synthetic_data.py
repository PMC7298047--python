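"""Seeded generators for every input the pipeline consumes.

Real runs of this pipeline depend on proprietary hospital EMR data and
external drug-database exports.  These generators emulate those inputs
with known ground truth, so the statistical machinery can be validated by
parameter recovery:

* :func:`simulate_interactions` builds a drug-gene interaction table in
  which a chosen number of "planted" drugs preferentially target the
  query gene set (relative odds ``enrichment_factor`` per target draw);
  the rest draw targets uniformly from the universe.
* :func:`simulate_emr` builds a patient-level exposure table where the
  disease outcome is Bernoulli with odds equal to the baseline odds
  multiplied by the true odds ratio of every drug the patient is exposed
  to (1% baseline prevalence by default, the over-40 population figure).
* :func:`table7_fixture` emits a deterministic EMR table whose per-drug
  cohort counts equal a published nine-drug hospital screen, used to
  check the screen end to end against printed values.

Each generator draws from its own named pseudo-random stream derived from
the single integer seed, so adding a generator never perturbs the output
of an existing one.  All generators are pure functions of their config.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .drug_mining import Interaction, InteractionTable
from .emr_screen import EMR_COLUMNS
from .gene_catalog import GeneSet

__all__ = [
    "EnrichmentSimConfig",
    "EmrSimConfig",
    "GroundTruth",
    "simulate_interactions",
    "simulate_emr",
    "table7_fixture",
    "TABLE7_COHORTS",
]

# stable per-generator stream ids mixed with the user seed
_STREAMS = {"interactions": 101, "emr": 202}


def _rng(stream: str, seed: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([_STREAMS[stream], int(seed)]))


@dataclass(frozen=True)
class GroundTruth:
    """Planted entities and their true simulation parameters."""

    planted: dict[str, dict[str, float]]


@dataclass(frozen=True)
class EnrichmentSimConfig:
    """Configuration of the interaction-table simulator.

    ``enrichment_factor`` is the relative odds that a planted drug's
    target lies in the query set: each target falls in the query with
    probability ``q*f / (q*f + 1 - q)`` where ``q = query_size/n_genes``.
    """

    n_genes: int = 2000
    n_drugs: int = 200
    targets_per_drug: int = 20
    query_size: int = 200
    planted_drugs: int = 10
    enrichment_factor: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.targets_per_drug > self.n_genes:
            raise ValueError("targets_per_drug exceeds the gene universe")
        if self.query_size > self.n_genes:
            raise ValueError("query_size exceeds the gene universe")
        if self.planted_drugs > self.n_drugs:
            raise ValueError("planted_drugs exceeds n_drugs")
        if self.enrichment_factor < 1.0:
            raise ValueError("enrichment_factor must be >= 1")


def simulate_interactions(
    config: EnrichmentSimConfig,
) -> tuple[InteractionTable, GeneSet, GroundTruth]:
    """Simulate a drug-gene table with planted enriched drugs.

    Returns the interaction table, the query gene set, and the ground
    truth naming the planted drugs.  Deterministic for a fixed config.
    """
    rng = _rng("interactions", config.seed)
    genes = np.array([f"G{i:05d}" for i in range(config.n_genes)])
    query_idx = rng.choice(config.n_genes, size=config.query_size, replace=False)
    in_query = np.zeros(config.n_genes, dtype=bool)
    in_query[query_idx] = True
    query_genes = genes[in_query]
    other_genes = genes[~in_query]

    drug_ids = [f"D{i:04d}" for i in range(config.n_drugs)]
    planted = set(rng.choice(config.n_drugs, size=config.planted_drugs, replace=False).tolist())

    q = config.query_size / config.n_genes
    f = config.enrichment_factor
    p_in_query = q * f / (q * f + (1.0 - q))

    edges: list[Interaction] = []
    for i, drug_id in enumerate(drug_ids):
        t = config.targets_per_drug
        if i in planted:
            n_in = int(rng.binomial(t, p_in_query))
            n_in = min(n_in, len(query_genes))
            n_out = t - n_in
            if n_out > len(other_genes):  # degenerate config; spill back
                n_in, n_out = t - len(other_genes), len(other_genes)
            targets = np.concatenate([
                rng.choice(query_genes, size=n_in, replace=False),
                rng.choice(other_genes, size=n_out, replace=False),
            ])
        else:
            targets = rng.choice(genes, size=t, replace=False)
        name = drug_id.lower()
        edges.extend(Interaction(drug_id, name, g, "SIM") for g in sorted(targets))

    table = InteractionTable(edges)
    query = GeneSet.from_symbols(query_genes, label="sim_query", source="SIM")
    truth = GroundTruth(planted={
        drug_ids[i]: {"enrichment_factor": f} for i in sorted(planted)
    })
    return table, query, truth


@dataclass(frozen=True)
class EmrSimConfig:
    """Configuration of the EMR cohort simulator.

    ``drug_specs`` lists ``(drug, exposure_probability, true_odds_ratio)``
    triples; exposures are independent Bernoulli draws and the outcome
    odds multiply across a patient's exposures.
    """

    n_patients: int = 20000
    age_range: tuple[int, int] = (41, 90)
    baseline_prevalence: float = 0.01
    drug_specs: Sequence[tuple[str, float, float]] = field(
        default_factory=lambda: [("drug_a", 0.5, 0.25)]
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.baseline_prevalence < 1.0:
            raise ValueError("baseline_prevalence must lie in (0, 1)")
        if self.age_range[0] > self.age_range[1] or self.age_range[0] < 0:
            raise ValueError("invalid age range")
        for drug, p_exp, true_or in self.drug_specs:
            if not 0.0 < p_exp < 1.0:
                raise ValueError(f"exposure probability for {drug} must lie in (0, 1)")
            if true_or <= 0:
                raise ValueError(f"true odds ratio for {drug} must be positive")


UNEXPOSED_LABEL = "NONE"


def simulate_emr(config: EmrSimConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate a long-format EMR exposure table with known drug effects.

    Outcome model: ``odds(glaucoma) = baseline_odds * prod(OR_d)`` over
    the drugs ``d`` the patient is exposed to.  Patients with no exposure
    appear once under the sentinel drug label ``"NONE"`` so that pooled
    prevalence remains computable.  Deterministic for a fixed config.
    """
    rng = _rng("emr", config.seed)
    n = config.n_patients
    ages = rng.integers(config.age_range[0], config.age_range[1] + 1, size=n)

    exposures = np.zeros((n, len(config.drug_specs)), dtype=bool)
    log_or = np.zeros(n)
    for j, (_, p_exp, true_or) in enumerate(config.drug_specs):
        exposures[:, j] = rng.random(n) < p_exp
        log_or += exposures[:, j] * np.log(true_or)

    base_odds = config.baseline_prevalence / (1.0 - config.baseline_prevalence)
    odds = base_odds * np.exp(log_or)
    prob = odds / (1.0 + odds)
    if np.any(~np.isfinite(prob)) or np.any(prob >= 1.0):
        raise ValueError("odds model out of range")
    glaucoma = (rng.random(n) < prob).astype(int)

    patient_ids = np.array([f"P{i:06d}" for i in range(n)])
    frames = []
    any_exposed = exposures.any(axis=1)
    for j, (drug, _, _) in enumerate(config.drug_specs):
        mask = exposures[:, j]
        frames.append(pd.DataFrame({
            "patient_id": patient_ids[mask],
            "age": ages[mask],
            "drug": drug,
            "glaucoma": glaucoma[mask],
        }))
    frames.append(pd.DataFrame({
        "patient_id": patient_ids[~any_exposed],
        "age": ages[~any_exposed],
        "drug": UNEXPOSED_LABEL,
        "glaucoma": glaucoma[~any_exposed],
    }))
    records = pd.concat(frames, ignore_index=True)[EMR_COLUMNS]
    truth = GroundTruth(planted={
        drug: {"exposure_probability": p_exp, "true_odds_ratio": true_or}
        for drug, p_exp, true_or in config.drug_specs
    })
    return records, truth


# Published nine-drug hospital screen: per-drug
# (cases, glaucoma cases, cases age > 40, glaucoma cases age > 40).
TABLE7_COHORTS: dict[str, tuple[int, int, int, int]] = {
    "cytarabine": (435, 0, 242, 0),
    "caffeine": (3, 0, 0, 0),
    "dipyridamole": (46, 0, 15, 0),
    "paclitaxel": (634, 0, 573, 0),
    "dasatinib": (6, 0, 2, 0),
    "celecoxib": (1719, 1, 1488, 1),
    "theophylline": (4594, 5, 4397, 5),
    "aspirin": (5358, 16, 5197, 13),
    "nicardipine": (588, 2, 564, 2),
}

_AGE_OVER = 41   # any age strictly above the 40-year cutoff
_AGE_UNDER = 30  # any age at or below the cutoff


def table7_fixture() -> pd.DataFrame:
    """Deterministic EMR table reproducing the published nine cohorts.

    Counts are split into four strata per drug (glaucoma x over-40);
    non-essential attributes (exact ages, patient id text) are arbitrary
    but fixed.  Each synthetic patient appears for exactly one drug.
    """
    rows: list[tuple[str, int, str, int]] = []
    for drug, (n_total, g_total, n_over, g_over) in TABLE7_COHORTS.items():
        strata = [
            (g_over, _AGE_OVER, 1),
            (g_total - g_over, _AGE_UNDER, 1),
            (n_over - g_over, _AGE_OVER, 0),
            ((n_total - g_total) - (n_over - g_over), _AGE_UNDER, 0),
        ]
        i = 0
        for count, age, flag in strata:
            for _ in range(count):
                rows.append((f"P_{drug}_{i:05d}", age, drug, flag))
                i += 1
    return pd.DataFrame(rows, columns=EMR_COLUMNS)
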