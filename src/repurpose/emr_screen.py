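"""Per-drug pharmaco-epidemiology screen over an EMR exposure table.

For each candidate drug, the screen extracts the exposed cohort from a
long-format EMR table (one row per patient-drug exposure), computes
glaucoma prevalence overall and in the over-40 stratum, and compares the
over-40 cohort against a fixed background prevalence (default 1% in a
pseudo-cohort of 1000, the accepted population figure for those over 40).

Two deliberately different count conventions coexist:

* The chi-squared comparison uses an *adjusted* cohort: when fewer than
  ``cohort_size`` exposed patients are available, the cohort is scaled up
  to ``cohort_size`` participants with the event count rescaled
  proportionally (producing real-valued cells).  This stabilises the test
  for small cohorts while preserving the observed prevalence.
* The odds ratio is computed from the RAW over-40 counts:
  ``OR = (g/(n-g)) / (prev/(1-prev))``, zero when no exposed patient has
  glaucoma, undefined when all do.

Age stratification is strict (``age > cutoff``).  A patient exposed to
several drugs is counted in each drug's cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .enrichment_stats import ContingencyTable, chi_squared

__all__ = [
    "EmrRecord",
    "EmrCohort",
    "BackgroundModel",
    "EmrScreenResult",
    "records_to_frame",
    "summarize_cohorts",
    "prevalence",
    "adjust_cohort",
    "screen_drug",
    "screen_all",
    "read_emr_csv",
    "write_screen_results",
]

EMR_COLUMNS = ["patient_id", "age", "drug", "glaucoma"]


@dataclass(frozen=True)
class EmrRecord:
    """One patient-drug exposure row; patients repeat across rows."""

    patient_id: str
    age: int
    drug: str
    glaucoma: int

    def __post_init__(self) -> None:
        if self.age < 0:
            raise ValueError(f"negative age for patient {self.patient_id}")
        if self.glaucoma not in (0, 1):
            raise ValueError(f"glaucoma flag must be 0/1 for patient {self.patient_id}")


@dataclass(frozen=True)
class EmrCohort:
    """Exposure cohort counts for one drug."""

    drug: str
    n_total: int
    g_total: int
    n_over40: int
    g_over40: int

    def __post_init__(self) -> None:
        ok = (0 <= self.g_total <= self.n_total
              and 0 <= self.g_over40 <= self.n_over40 <= self.n_total
              and self.g_over40 <= self.g_total)
        if not ok:
            raise ValueError(f"inconsistent cohort counts for {self.drug}: {self}")


@dataclass(frozen=True)
class BackgroundModel:
    """Fixed background: disease prevalence in a pseudo-cohort."""

    prevalence: float = 0.01
    cohort_size: float = 1000.0

    def __post_init__(self) -> None:
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError("background prevalence must lie in (0, 1)")
        if self.cohort_size <= 0:
            raise ValueError("background cohort_size must be positive")


@dataclass(frozen=True)
class EmrScreenResult:
    drug: str
    n_total: int
    g_total: int
    prevalence_total: float
    n_over40: int
    g_over40: int
    prevalence_over40: float
    adjusted_n: float
    adjusted_g: float
    p_value: float
    odds_ratio: float | None
    flags: tuple[str, ...] = field(default=())


def records_to_frame(records: Iterable[EmrRecord] | pd.DataFrame) -> pd.DataFrame:
    """Coerce EMR records (dataclasses or a DataFrame) into a typed frame."""
    if isinstance(records, pd.DataFrame):
        missing = set(EMR_COLUMNS) - set(records.columns)
        if missing:
            raise ValueError(f"EMR frame missing columns {sorted(missing)}")
        df = records[EMR_COLUMNS].copy()
    else:
        df = pd.DataFrame(
            [(r.patient_id, r.age, r.drug, r.glaucoma) for r in records],
            columns=EMR_COLUMNS,
        )
    df["age"] = df["age"].astype(int)
    df["glaucoma"] = df["glaucoma"].astype(int)
    if (df["age"] < 0).any():
        raise ValueError("negative age in EMR records")
    if not df["glaucoma"].isin((0, 1)).all():
        raise ValueError("glaucoma flag must be 0/1")
    return df


def summarize_cohorts(
    records: Iterable[EmrRecord] | pd.DataFrame,
    drugs: Sequence[str],
    age_cutoff: int = 40,
) -> list[EmrCohort]:
    """Count exposed patients and glaucoma cases per requested drug.

    A patient counts once per drug regardless of row multiplicity; the
    over-``age_cutoff`` stratum is strict.  A patient whose glaucoma flag
    differs across rows is an input error.
    """
    df = records_to_frame(records)
    flags_per_patient = df.groupby("patient_id")["glaucoma"].nunique()
    bad = flags_per_patient[flags_per_patient > 1]
    if len(bad):
        raise ValueError(
            f"inconsistent glaucoma flag for patient(s): {', '.join(bad.index[:5])}"
        )
    dedup = df.drop_duplicates(subset=["patient_id", "drug"])
    cohorts = []
    for drug in drugs:
        sub = dedup[dedup["drug"] == drug]
        over = sub[sub["age"] > age_cutoff]
        cohorts.append(EmrCohort(
            drug=drug,
            n_total=len(sub),
            g_total=int(sub["glaucoma"].sum()),
            n_over40=len(over),
            g_over40=int(over["glaucoma"].sum()),
        ))
    return cohorts


def prevalence(g: float, n: float) -> float:
    """Event proportion g/n; zero for an empty cohort."""
    if g > n:
        raise ValueError(f"event count {g} exceeds cohort size {n}")
    if n == 0:
        return 0.0
    return g / n


def adjust_cohort(
    n_over40: float, g_over40: float, background: BackgroundModel
) -> tuple[float, float, bool]:
    """Apply the assumed-cohort scaling rule for small cohorts.

    Cohorts smaller than ``background.cohort_size`` are scaled up to that
    size with the event count rescaled proportionally (real-valued); an
    empty cohort maps to (cohort_size, 0).  Larger cohorts pass through
    unchanged.  Returns ``(adjusted_n, adjusted_g, scaled)``.
    """
    if g_over40 < 0 or g_over40 > n_over40:
        raise ValueError("invalid cohort counts")
    if n_over40 >= background.cohort_size:
        return float(n_over40), float(g_over40), False
    size = float(background.cohort_size)
    if n_over40 == 0:
        return size, 0.0, True
    return size, g_over40 * size / n_over40, True


def screen_drug(
    cohort: EmrCohort,
    background: BackgroundModel = BackgroundModel(),
    correction: bool = True,
) -> EmrScreenResult:
    """Compare one drug cohort against the fixed background.

    The p-value comes from a chi-squared test (Yates correction on by
    default) of the adjusted over-40 cohort against the background
    pseudo-cohort ``(prevalence*size, (1-prevalence)*size)``.  The odds
    ratio uses raw over-40 counts against the background odds.
    """
    flags: list[str] = []
    adj_n, adj_g, scaled = adjust_cohort(cohort.n_over40, cohort.g_over40, background)
    if scaled:
        flags.append("scaled")
    if cohort.g_over40 == 0:
        flags.append("zero_event")

    bg_g = background.prevalence * background.cohort_size
    bg_ng = (1.0 - background.prevalence) * background.cohort_size
    test = chi_squared(
        ContingencyTable(adj_g, adj_n - adj_g, bg_g, bg_ng),
        continuity_correction=correction,
    )

    odds_ratio: float | None
    if cohort.g_over40 == 0:
        odds_ratio = 0.0
    elif cohort.g_over40 == cohort.n_over40:
        odds_ratio = None
        flags.append("or_undefined")
    else:
        cohort_odds = cohort.g_over40 / (cohort.n_over40 - cohort.g_over40)
        bg_odds = background.prevalence / (1.0 - background.prevalence)
        odds_ratio = cohort_odds / bg_odds

    return EmrScreenResult(
        drug=cohort.drug,
        n_total=cohort.n_total,
        g_total=cohort.g_total,
        prevalence_total=prevalence(cohort.g_total, cohort.n_total),
        n_over40=cohort.n_over40,
        g_over40=cohort.g_over40,
        prevalence_over40=prevalence(cohort.g_over40, cohort.n_over40),
        adjusted_n=adj_n,
        adjusted_g=adj_g,
        p_value=test.p_value,
        odds_ratio=odds_ratio,
        flags=tuple(flags),
    )


def screen_all(
    records: Iterable[EmrRecord] | pd.DataFrame,
    drugs: Sequence[str],
    background: BackgroundModel = BackgroundModel(),
    correction: bool = True,
    age_cutoff: int = 40,
) -> list[EmrScreenResult]:
    """Screen every requested drug; sorted by ascending p then drug."""
    cohorts = summarize_cohorts(records, drugs, age_cutoff=age_cutoff)
    results = [screen_drug(c, background, correction) for c in cohorts]
    results.sort(key=lambda r: (r.p_value, r.drug))
    return results


def read_emr_csv(path: str | Path) -> pd.DataFrame:
    """Read a long-format EMR CSV with header patient_id,age,drug,glaucoma."""
    df = pd.read_csv(path, dtype={"patient_id": str, "drug": str})
    return records_to_frame(df)


def write_screen_results(results: Sequence[EmrScreenResult], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            (r.drug, r.n_total, r.g_total, r.prevalence_total,
             r.n_over40, r.g_over40, r.prevalence_over40,
             r.adjusted_n, r.adjusted_g, r.p_value,
             "" if r.odds_ratio is None else r.odds_ratio,
             ",".join(r.flags))
            for r in results
        ],
        columns=["drug", "n_total", "g_total", "prevalence",
                 "n_over40", "g_over40", "prevalence_over40",
                 "adjusted_n", "adjusted_g", "p_value", "odds_ratio", "flags"],
    )
    df.to_csv(path, sep="\t", index=False)
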