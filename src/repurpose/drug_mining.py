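"""Per-drug target overrepresentation, bridge expansion, and consensus ranking.

Each drug in a drug-gene interaction table is scored for overrepresentation
of its target genes in a query (disease) gene set.  The 2x2 table per drug,
formed over a gene universe, is::

    (in-query & targeted, in-query & not targeted,
     not-in-query & targeted, not-in-query & not targeted)

The gene universe defaults to all distinct genes in the interaction table
(overridable), since p-values depend directly on its definition.  The
default test is chi-squared with continuity correction, with an automatic
fall-back to the one-sided (overrepresentation) Fisher exact test when any
expected cell drops below 5 or a margin degenerates — chi-squared is
invalid at the tiny counts real target sets produce.  When the method is
``"fisher"`` the one-sided hypergeometric upper tail is used throughout,
which is the conventional direction for enrichment.

A disease->drug->gene "bridge" expands a disease into the union of the
target genes of its approved drugs, yielding an indirect query set.
Consensus ranking aggregates the FDR-passing drugs of several evidence
sources: drugs are ordered by how many sources support them, then by the
best (smallest) p-value across sources, then lexicographically.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from scipy.stats import rankdata

from .enrichment_stats import ContingencyTable, bh_fdr, chi_squared, hypergeom_sf
from .gene_catalog import GeneRecord, GeneSet, normalize_symbol

__all__ = [
    "Interaction",
    "InteractionTable",
    "DrugEnrichmentResult",
    "BridgeMap",
    "ConsensusEntry",
    "enrich_drugs",
    "bridge_expand",
    "consensus_rank",
]

logger = logging.getLogger(__name__)

METHODS = ("chi2_yates", "chi2", "fisher")


@dataclass(frozen=True)
class Interaction:
    drug_id: str
    drug_name: str
    gene_symbol: str
    source: str


class InteractionTable:
    """Many-to-many drug <-> gene mapping with source labels."""

    def __init__(self, edges: Iterable[Interaction]) -> None:
        seen: set[tuple[str, str, str]] = set()
        self.edges: list[Interaction] = []
        for e in edges:
            symbol = normalize_symbol(e.gene_symbol)
            if not symbol:
                raise ValueError(f"empty gene symbol for drug {e.drug_id!r}")
            key = (e.drug_id, symbol, e.source)
            if key in seen:
                raise ValueError(f"duplicate interaction {key}")
            seen.add(key)
            self.edges.append(replace(e, gene_symbol=symbol))
        if not self.edges:
            raise ValueError("interaction table has no edges")

    def drug_targets(self) -> dict[str, set[str]]:
        """drug_id -> set of target gene symbols."""
        out: dict[str, set[str]] = {}
        for e in self.edges:
            out.setdefault(e.drug_id, set()).add(e.gene_symbol)
        return out

    def drug_names(self) -> dict[str, str]:
        return {e.drug_id: e.drug_name for e in self.edges}

    def genes(self) -> set[str]:
        return {e.gene_symbol for e in self.edges}

    @classmethod
    def from_tsv(cls, path: str | Path) -> "InteractionTable":
        df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
        required = {"drug_id", "drug_name", "gene_symbol", "source"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"interaction TSV missing columns {sorted(missing)}")
        return cls(
            Interaction(r.drug_id, r.drug_name, r.gene_symbol, r.source)
            for r in df.itertuples(index=False)
        )

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(
            [(e.drug_id, e.drug_name, e.gene_symbol, e.source) for e in self.edges],
            columns=["drug_id", "drug_name", "gene_symbol", "source"],
        )
        df.to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class DrugEnrichmentResult:
    """Per-drug overrepresentation outcome.

    k targets fall in the query set, out of K targets in the universe;
    the query contributes n of the N universe genes.
    """

    drug_id: str
    k: int
    K: int
    n: int
    N: int
    statistic: float | None
    p_value: float
    q_value: float
    rank: int
    candidate: bool

    def __post_init__(self) -> None:
        if not (0 <= self.k <= min(self.K, self.n) and self.K <= self.N and self.n <= self.N):
            raise ValueError(f"inconsistent enrichment counts for {self.drug_id}: "
                             f"k={self.k} K={self.K} n={self.n} N={self.N}")


@dataclass
class BridgeMap:
    """disease -> drugs and drug -> target genes maps."""

    disease_to_drugs: dict[str, set[str]]
    drug_to_genes: dict[str, set[str]]

    @classmethod
    def from_tsvs(cls, disease_drugs: str | Path, drug_genes: str | Path) -> "BridgeMap":
        dd = pd.read_csv(disease_drugs, sep="\t", dtype=str)
        dg = pd.read_csv(drug_genes, sep="\t", dtype=str)
        d2d: dict[str, set[str]] = {}
        for r in dd.itertuples(index=False):
            d2d.setdefault(r.disease, set()).add(r.drug_id)
        d2g: dict[str, set[str]] = {}
        for r in dg.itertuples(index=False):
            d2g.setdefault(r.drug_id, set()).add(normalize_symbol(r.gene_symbol))
        return cls(disease_to_drugs=d2d, drug_to_genes=d2g)


@dataclass(frozen=True)
class ConsensusEntry:
    drug_id: str
    sources: tuple[str, ...]
    best_p: float
    best_q: float


def _one_drug_p(k: int, K: int, n: int, N: int, method: str,
                ) -> tuple[float | None, float]:
    """(statistic, p) for a single drug's 2x2 table, with Fisher fall-back."""
    if method == "fisher":
        return None, hypergeom_sf(k, N, K, n)
    cells = (k, n - k, K - k, N - n - K + k)
    # expected cells under independence; chi-squared needs all >= 5
    r = (n, N - n)
    c = (K, N - K)
    expected_min = min(ri * cj / N for ri in r for cj in c)
    if expected_min < 5 or min(r) == 0 or min(c) == 0:
        return None, hypergeom_sf(k, N, K, n)
    return_stat = chi_squared(
        ContingencyTable(*cells), continuity_correction=(method == "chi2_yates")
    )
    return return_stat.statistic, return_stat.p_value


def enrich_drugs(
    interactions: InteractionTable,
    query: GeneSet,
    universe: GeneSet | str = "auto",
    method: str = "chi2_yates",
    alpha: float = 0.05,
) -> list[DrugEnrichmentResult]:
    """Score every drug for target overrepresentation in ``query``.

    Parameters
    ----------
    interactions
        Drug-gene edges to score.
    query
        Disease gene set; intersected with the universe before testing.
    universe
        Background gene set, or ``"auto"`` to use all distinct genes in
        the interaction table.
    method
        ``"chi2_yates"`` (default), ``"chi2"``, or ``"fisher"``
        (one-sided overrepresentation).  The chi-squared variants fall
        back to Fisher per drug when any expected cell is below 5.
    alpha
        FDR threshold for the ``candidate`` flag.

    Returns
    -------
    Results sorted by ascending p-value then drug_id, with BH q-values
    computed across all tested drugs.
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
    if len(query) == 0:
        raise ValueError("query gene set is empty")
    universe_genes = (
        interactions.genes() if isinstance(universe, str) and universe == "auto"
        else set(universe.symbols)  # type: ignore[union-attr]
    )
    N = len(universe_genes)
    query_genes = set(query.symbols) & universe_genes
    n = len(query_genes)
    if n == 0:
        raise ValueError("query disjoint from universe")

    rows: list[tuple[str, int, int, float | None, float]] = []
    for drug_id, targets in sorted(interactions.drug_targets().items()):
        targets_in_universe = targets & universe_genes
        K = len(targets_in_universe)
        if K == 0:
            logger.warning("drug %s has no targets in the universe; skipped", drug_id)
            continue
        k = len(targets_in_universe & query_genes)
        stat, p = _one_drug_p(k, K, n, N, method)
        rows.append((drug_id, k, K, stat, p))

    if not rows:
        return []
    p_values = [r[4] for r in rows]
    q_values = bh_fdr(p_values)
    ranks = rankdata(p_values, method="min").astype(int)
    results = [
        DrugEnrichmentResult(
            drug_id=drug_id, k=k, K=K, n=n, N=N, statistic=stat,
            p_value=p, q_value=float(q), rank=int(rank),
            candidate=bool(q <= alpha),
        )
        for (drug_id, k, K, stat, p), q, rank in zip(rows, q_values, ranks)
    ]
    results.sort(key=lambda r: (r.p_value, r.drug_id))
    return results


def bridge_expand(bridge: BridgeMap, disease: str) -> tuple[set[str], GeneSet]:
    """Expand a disease to its drugs and the union of their target genes.

    The returned :class:`GeneSet` can be used directly as the ``query``
    of :func:`enrich_drugs`.  Drugs missing from the drug->gene map are
    dropped with a warning.
    """
    if disease not in bridge.disease_to_drugs:
        known = ", ".join(sorted(bridge.disease_to_drugs))
        raise KeyError(f"unknown disease {disease!r}; known diseases: {known}")
    drugs = set(bridge.disease_to_drugs[disease])
    genes: dict[str, set[str]] = {}
    for drug in sorted(drugs):
        if drug not in bridge.drug_to_genes:
            logger.warning("bridge: drug %s has no gene map entry; skipped", drug)
            continue
        for g in bridge.drug_to_genes[drug]:
            genes.setdefault(g, set()).add(drug)
    records = [GeneRecord(symbol=g, sources=frozenset(ds)) for g, ds in genes.items()]
    return drugs, GeneSet(records, label=f"bridge:{disease}")


def consensus_rank(
    result_lists: Sequence[tuple[str, Sequence[DrugEnrichmentResult]]],
    alpha: float = 0.05,
    k: int = 40,
) -> list[ConsensusEntry]:
    """Aggregate per-source enrichment results into a consensus top list.

    Drugs that fail ``q <= alpha`` in every source are dropped.  The
    survivors are ordered by (descending number of supporting sources,
    ascending minimum p across sources, drug_id), and the first ``k``
    are returned.
    """
    if not result_lists:
        raise ValueError("at least one result list is required")
    if k < 1:
        raise ValueError("k must be >= 1")
    per_drug: dict[str, dict[str, DrugEnrichmentResult]] = {}
    for label, results in result_lists:
        for res in results:
            if res.q_value <= alpha:
                per_drug.setdefault(res.drug_id, {})[label] = res
    entries = [
        ConsensusEntry(
            drug_id=drug,
            sources=tuple(sorted(by_src)),
            best_p=min(r.p_value for r in by_src.values()),
            best_q=min(r.q_value for r in by_src.values()),
        )
        for drug, by_src in per_drug.items()
    ]
    entries.sort(key=lambda e: (-len(e.sources), e.best_p, e.drug_id))
    return entries[:k]


def results_to_frame(results: Sequence[DrugEnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (r.drug_id, r.k, r.K, r.n, r.N,
             "" if r.statistic is None else r.statistic,
             r.p_value, r.q_value, r.rank, int(r.candidate))
            for r in results
        ],
        columns=["drug_id", "k", "K", "n", "N", "statistic",
                 "p_value", "q_value", "rank", "candidate"],
    )


def write_results(results: Sequence[DrugEnrichmentResult], path: str | Path) -> None:
    # %.17g keeps doubles exact through a TSV round-trip
    results_to_frame(results).to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_results(path: str | Path) -> list[DrugEnrichmentResult]:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    out = []
    for r in df.itertuples(index=False):
        stat = None if pd.isna(r.statistic) or r.statistic == "" else float(r.statistic)
        out.append(DrugEnrichmentResult(
            drug_id=str(r.drug_id), k=int(r.k), K=int(r.K), n=int(r.n), N=int(r.N),
            statistic=stat, p_value=float(r.p_value), q_value=float(r.q_value),
            rank=int(r.rank), candidate=bool(r.candidate),
        ))
    return out


def write_consensus(entries: Sequence[ConsensusEntry], path: str | Path) -> None:
    df = pd.DataFrame(
        [(e.drug_id, ",".join(e.sources), e.best_p, e.best_q) for e in entries],
        columns=["drug_id", "sources", "best_p", "best_q"],
    )
    df.to_csv(path, sep="\t", index=False)
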