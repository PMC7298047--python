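"""Disease-category breakdown for a gene set.

Given a gene -> disease association table (PheWAS-style) and a
disease -> category map, compute which disease categories the diseases
linked to a query gene set fall into.  Diseases are deduplicated (a
disease linked through several query genes counts once) and diseases
without a category entry fall into ``"other"``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .gene_catalog import GeneSet, normalize_symbol

__all__ = ["DiseaseCategoryBreakdown", "disease_breakdown",
           "read_gene_disease_tsv", "read_category_tsv", "write_breakdown"]

OTHER_CATEGORY = "other"


@dataclass(frozen=True)
class DiseaseCategoryBreakdown:
    """Distinct-disease total and per-category (count, proportion)."""

    total_diseases: int
    per_category: dict[str, tuple[int, float]]


def disease_breakdown(
    gene_disease: Iterable[tuple[str, str]] | pd.DataFrame,
    disease_category: Mapping[str, str],
    query: GeneSet,
) -> DiseaseCategoryBreakdown:
    """Category breakdown of diseases linked to at least one query gene."""
    if isinstance(gene_disease, pd.DataFrame):
        pairs = list(gene_disease[["gene_symbol", "disease_id"]].itertuples(index=False))
    else:
        pairs = list(gene_disease)
    if not pairs:
        raise ValueError("gene-disease table is empty")
    if len(query) == 0:
        raise ValueError("query gene set is empty")

    query_symbols = set(query.symbols)
    diseases = {
        disease for gene, disease in pairs
        if normalize_symbol(str(gene)) in query_symbols
    }
    counts: dict[str, int] = {}
    for disease in diseases:
        category = disease_category.get(disease, OTHER_CATEGORY)
        counts[category] = counts.get(category, 0) + 1
    total = len(diseases)
    per_category = {
        cat: (cnt, cnt / total) for cat, cnt in sorted(counts.items())
    }
    return DiseaseCategoryBreakdown(total_diseases=total, per_category=per_category)


def read_gene_disease_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = {"gene_symbol", "disease_id"} - set(df.columns)
    if missing:
        raise ValueError(f"gene-disease TSV missing columns {sorted(missing)}")
    return df


def read_category_tsv(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = {"disease_id", "category"} - set(df.columns)
    if missing:
        raise ValueError(f"category TSV missing columns {sorted(missing)}")
    return dict(zip(df["disease_id"], df["category"]))


def write_breakdown(breakdown: DiseaseCategoryBreakdown, path: str | Path) -> None:
    df = pd.DataFrame(
        [(cat, cnt, prop) for cat, (cnt, prop) in breakdown.per_category.items()],
        columns=["category", "count", "proportion"],
    )
    df.to_csv(path, sep="\t", index=False)
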