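"""Config-driven end-to-end orchestration.

A run config (YAML) names the inputs of each stage; stages whose inputs
are omitted are skipped.  Stage order follows the data dependencies:

    genes -> enrich (per source) -> consensus
    bridge (independent)
    emr (independent)
    spectrum (needs genes)

Every output is written in the owning module's TSV format and a JSON run
manifest records the config echo, per-stage row counts, version, and
timestamps.  Defaults mirror the screen-reproducing settings: continuity
correction on, alpha 0.05, consensus size 40, background prevalence 0.01
in a pseudo-cohort of 1000, age cutoff 40.
"""

from __future__ import annotations

import datetime
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from . import __version__
from .disease_spectrum import (disease_breakdown, read_category_tsv,
                               read_gene_disease_tsv, write_breakdown)
from .drug_mining import (BridgeMap, InteractionTable, bridge_expand,
                          consensus_rank, enrich_drugs, write_consensus,
                          write_results)
from .emr_screen import BackgroundModel, read_emr_csv, screen_all, write_screen_results
from .gene_catalog import (GeneSet, gene_set_from_files, read_gene_file,
                           write_gene_set)

__all__ = ["RunConfig", "RunManifest", "run_pipeline"]

logger = logging.getLogger("repurpose.pipeline")


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage and input."""


@dataclass
class RunConfig:
    """Validated run configuration."""

    out_dir: Path
    genes: dict[str, str] = field(default_factory=dict)
    enrich: list[dict[str, Any]] = field(default_factory=list)
    bridge: dict[str, Any] = field(default_factory=dict)
    consensus: dict[str, Any] = field(default_factory=dict)
    emr: dict[str, Any] = field(default_factory=dict)
    spectrum: dict[str, Any] = field(default_factory=dict)
    raw: dict[str, Any] = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw, base_dir=Path(path).parent)

    @classmethod
    def from_dict(cls, raw: dict[str, Any], base_dir: Path | None = None) -> "RunConfig":
        base = base_dir or Path(".")
        if "out_dir" not in raw:
            raise ValueError("config requires out_dir")

        def _resolve(p: str) -> str:
            path = Path(p)
            return str(path if path.is_absolute() else base / path)

        cfg = cls(out_dir=Path(_resolve(str(raw["out_dir"]))), raw=raw)
        cfg.genes = {lab: _resolve(p) for lab, p in (raw.get("genes") or {}).items()}
        for spec in raw.get("enrich") or []:
            spec = dict(spec)
            spec["interactions"] = _resolve(spec["interactions"])
            if spec.get("universe") not in (None, "auto"):
                spec["universe"] = _resolve(spec["universe"])
            cfg.enrich.append(spec)
        for key in ("bridge", "consensus", "emr", "spectrum"):
            setattr(cfg, key, dict(raw.get(key) or {}))
        for pkey in ("disease_drugs", "drug_genes"):
            if pkey in cfg.bridge:
                cfg.bridge[pkey] = _resolve(cfg.bridge[pkey])
        if "records" in cfg.emr:
            cfg.emr["records"] = _resolve(cfg.emr["records"])
        if isinstance(cfg.emr.get("drugs"), str):
            cfg.emr["drugs"] = _resolve(cfg.emr["drugs"])
        for pkey in ("gene_disease", "categories"):
            if pkey in cfg.spectrum:
                cfg.spectrum[pkey] = _resolve(cfg.spectrum[pkey])

        alpha = cfg.consensus.get("alpha", 0.05)
        if not 0.0 < float(alpha) < 1.0:
            raise ValueError("consensus alpha must lie in (0, 1)")
        if int(cfg.consensus.get("k", 40)) < 1:
            raise ValueError("consensus k must be >= 1")
        cfg._check_paths()
        return cfg

    def _check_paths(self) -> None:
        paths = list(self.genes.values())
        paths += [s["interactions"] for s in self.enrich]
        paths += [self.bridge[k] for k in ("disease_drugs", "drug_genes") if k in self.bridge]
        if "records" in self.emr:
            paths.append(self.emr["records"])
        paths += [self.spectrum[k] for k in ("gene_disease", "categories") if k in self.spectrum]
        missing = [p for p in paths if not Path(p).exists()]
        if missing:
            raise FileNotFoundError(f"config references missing input(s): {missing}")


@dataclass
class RunManifest:
    config: dict[str, Any]
    stage_counts: dict[str, int]
    version: str
    started: str
    finished: str
    warnings: list[str]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2, sort_keys=True) + "\n")


def _now() -> str:
    return datetime.datetime.now(datetime.timezone.utc).isoformat()


def run_pipeline(config: RunConfig | dict[str, Any]) -> RunManifest:
    """Execute the configured stages in dependency order.

    Returns the manifest (also written to ``out_dir/manifest.json``).
    Any stage failure raises :class:`StageError` naming the stage.
    """
    if isinstance(config, dict):
        config = RunConfig.from_dict(config)
    started = _now()
    out_dir = config.out_dir
    out_dir.mkdir(parents=True, exist_ok=True)
    counts: dict[str, int] = {}
    warnings: list[str] = []

    gene_set: GeneSet | None = None
    if config.genes:
        try:
            logger.info("[genes] merging %d sources", len(config.genes))
            gene_set = gene_set_from_files(config.genes)
            write_gene_set(gene_set, out_dir / "genes.tsv")
            counts["genes"] = len(gene_set)
        except Exception as exc:
            raise StageError(f"stage 'genes' failed on {config.genes}: {exc}") from exc

    results_by_label = []
    for spec in config.enrich:
        label = spec.get("label", Path(spec["interactions"]).stem)
        try:
            logger.info("[enrich:%s] scoring %s", label, spec["interactions"])
            table = InteractionTable.from_tsv(spec["interactions"])
            query = gene_set
            if spec.get("genes"):
                query = gene_set_from_files({label: spec["genes"]})
            if query is None:
                raise ValueError("no query gene set (configure 'genes')")
            universe: GeneSet | str = "auto"
            if spec.get("universe") not in (None, "auto"):
                universe = gene_set_from_files({"universe": spec["universe"]})
            results = enrich_drugs(
                table, query, universe=universe,
                method=spec.get("method", "chi2_yates"),
                alpha=float(spec.get("alpha", 0.05)),
            )
            write_results(results, out_dir / f"enrich_{label}.tsv")
            counts[f"enrich_{label}"] = len(results)
            results_by_label.append((label, results))
        except StageError:
            raise
        except Exception as exc:
            raise StageError(f"stage 'enrich:{label}' failed on "
                             f"{spec['interactions']}: {exc}") from exc

    if config.bridge:
        try:
            disease = config.bridge["disease"]
            logger.info("[bridge] expanding disease %s", disease)
            bmap = BridgeMap.from_tsvs(config.bridge["disease_drugs"],
                                       config.bridge["drug_genes"])
            drugs, genes = bridge_expand(bmap, disease)
            write_gene_set(genes, out_dir / "bridge_genes.tsv")
            (out_dir / "bridge_drugs.txt").write_text("\n".join(sorted(drugs)) + "\n")
            counts["bridge_drugs"] = len(drugs)
            counts["bridge_genes"] = len(genes)
        except Exception as exc:
            raise StageError(f"stage 'bridge' failed: {exc}") from exc

    if config.consensus and results_by_label:
        try:
            logger.info("[consensus] aggregating %d sources", len(results_by_label))
            entries = consensus_rank(
                results_by_label,
                alpha=float(config.consensus.get("alpha", 0.05)),
                k=int(config.consensus.get("k", 40)),
            )
            write_consensus(entries, out_dir / "consensus.tsv")
            counts["consensus"] = len(entries)
        except Exception as exc:
            raise StageError(f"stage 'consensus' failed: {exc}") from exc

    if config.emr:
        try:
            logger.info("[emr] screening %s", config.emr["records"])
            records = read_emr_csv(config.emr["records"])
            drugs_spec = config.emr.get("drugs")
            if drugs_spec is None:
                drug_list = sorted(records["drug"].unique())
            elif isinstance(drugs_spec, str):
                drug_list = [raw for raw, _ in read_gene_file(drugs_spec)]
            else:
                drug_list = list(drugs_spec)
            background = BackgroundModel(
                prevalence=float(config.emr.get("prevalence", 0.01)),
                cohort_size=float(config.emr.get("cohort_size", 1000)),
            )
            screen = screen_all(
                records, drug_list, background=background,
                correction=bool(config.emr.get("correction", True)),
                age_cutoff=int(config.emr.get("age_cutoff", 40)),
            )
            write_screen_results(screen, out_dir / "emr_screen.tsv")
            counts["emr_screen"] = len(screen)
        except Exception as exc:
            raise StageError(f"stage 'emr' failed on "
                             f"{config.emr.get('records')}: {exc}") from exc

    if config.spectrum:
        try:
            logger.info("[spectrum] categorizing diseases")
            if gene_set is None:
                raise ValueError("spectrum stage requires the 'genes' stage")
            gd = read_gene_disease_tsv(config.spectrum["gene_disease"])
            categories = read_category_tsv(config.spectrum["categories"])
            breakdown = disease_breakdown(gd, categories, gene_set)
            write_breakdown(breakdown, out_dir / "spectrum.tsv")
            counts["spectrum"] = len(breakdown.per_category)
        except Exception as exc:
            raise StageError(f"stage 'spectrum' failed: {exc}") from exc

    manifest = RunManifest(
        config=config.raw,
        stage_counts=counts,
        version=__version__,
        started=started,
        finished=_now(),
        warnings=warnings,
    )
    manifest.to_json(out_dir / "manifest.json")
    return manifest
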