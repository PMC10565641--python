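"""End-to-end orchestration: motif → scan → annotate → conserve → enrich.

The pipeline is a thin, deterministic composition of the stage functions;
each stage's output equals calling that stage directly with the same
inputs.  A JSON manifest records package version, parameters, seeds and
SHA-256 checksums of every input, sufficient to re-run bit-identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import yaml

from . import __version__
from .annotate import (annotate_phospho, read_gmt, read_phosphosites,
                       venn_overlap, write_annotated_tsv)
from .catalog import read_degron_table
from .conserve import (HIGH_CONSERVATION_THRESHOLD, read_alignment_fasta,
                       score_conservation, write_conservation_tsv)
from .motif import build_pfm, derive_consensus, parse_pattern, serialize_pattern
from .scan import read_fasta, scan_proteome, write_candidates_tsv
from .stats import ora, write_enrichment_tsv

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Invalid pipeline configuration."""


@dataclass
class PipelineConfig:
    """Flat configuration for one pipeline run.

    Exactly one of ``motif_pattern`` / ``degron_table`` must be given;
    the latter derives the consensus from a validated-degron TSV.
    """

    proteome: str
    out_dir: str
    motif_pattern: Optional[str] = None
    degron_table: Optional[str] = None
    dialect: str = "plain"
    phosphosites: Optional[str] = None
    ortholog_dir: Optional[str] = None
    gmt: List[str] = field(default_factory=list)
    universe: Optional[str] = None          # optional newline-delimited gene list
    venn_set: Optional[str] = None          # GMT set name for the overlap counts
    window_length: int = 7
    zero_column: int = 3
    include_threshold: float = 0.2
    max_class: int = 4
    conservation_threshold: float = HIGH_CONSERVATION_THRESHOLD
    fdr_cut: float = 0.05
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        doc = yaml.safe_load(Path(path).read_text())
        if not isinstance(doc, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        known = set(cls.__dataclass_fields__)
        unknown = set(doc) - known
        if unknown:
            raise ConfigError(f"{path}: unknown key(s) {sorted(unknown)}")
        try:
            return cls(**doc)
        except TypeError as exc:
            raise ConfigError(str(exc)) from None

    def validate(self) -> None:
        if (self.motif_pattern is None) == (self.degron_table is None):
            raise ConfigError(
                "exactly one motif source required: motif_pattern or degron_table"
            )
        for p in filter(None, [self.proteome, self.degron_table,
                               self.phosphosites, self.universe,
                               self.ortholog_dir, *self.gmt]):
            if not Path(p).exists():
                raise ConfigError(f"input path does not exist: {p}")


def _sha256(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> Dict[str, object]:
    """Execute all configured stages; write artifacts and a manifest.

    Returns a result bundle with the motif, candidate table, enrichment
    rows, conservation rows and the manifest dict.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: Dict[str, object] = {
        "degscan_version": __version__,
        "parameters": {k: v for k, v in vars(config).items()},
        "inputs": {},
        "stages": [],
        "complete": False,
    }
    for p in filter(None, [config.proteome, config.degron_table,
                           config.phosphosites, config.universe, *config.gmt]):
        manifest["inputs"][str(p)] = _sha256(p)

    def stage(name):
        logger.info("[%s] starting", name)
        manifest["stages"].append(name)

    try:
        # ---- motif -------------------------------------------------
        stage("motif")
        if config.motif_pattern is not None:
            motif = parse_pattern(config.motif_pattern)
            provenance = "pattern supplied in config"
            pfm = None
        else:
            catalog = read_degron_table(
                config.degron_table, config.window_length, config.zero_column
            )
            pfm = build_pfm(catalog)
            motif = derive_consensus(
                pfm,
                include_threshold=config.include_threshold,
                max_class=config.max_class,
                zero_column=config.zero_column,
            )
            provenance = f"derived from {config.degron_table} ({len(catalog)} instances)"
        motif.save(out / "motif.json", provenance=provenance)

        # ---- scan --------------------------------------------------
        stage("scan")
        records = read_fasta(config.proteome, header_dialect=config.dialect)
        table = scan_proteome(motif, records)
        write_candidates_tsv(table, out / "candidates.tsv")

        # ---- annotate ----------------------------------------------
        annotated = None
        if config.phosphosites:
            stage("annotate")
            sites = read_phosphosites(config.phosphosites)
            annotated = annotate_phospho(table, sites, records)
            write_annotated_tsv(annotated, out / "annotated.tsv")

        # ---- conserve ----------------------------------------------
        conservation = []
        if config.ortholog_dir:
            stage("conserve")
            by_id = {}
            for m in table.matches:
                by_id.setdefault(m.protein_id, []).append(m)
            for fam_path in sorted(Path(config.ortholog_dir).glob("*.fa*")):
                ref_id = fam_path.stem
                if ref_id not in by_id:
                    continue
                family = read_alignment_fasta(fam_path, reference_id=ref_id)
                for m in by_id[ref_id]:
                    conservation.append(score_conservation(motif, family, m.start_pos))
            write_conservation_tsv(conservation, out / "conservation.tsv")

        # ---- enrich ------------------------------------------------
        enrichment = []
        venn = None
        if config.gmt:
            stage("enrich")
            sets: Dict[str, List[str]] = {}
            for g in config.gmt:
                sets.update(read_gmt(g))
            if config.universe:
                universe = [
                    line.strip()
                    for line in Path(config.universe).read_text().splitlines()
                    if line.strip()
                ]
            else:
                universe = [r.gene_symbol for r in records]
            enrichment = ora(table.candidate_genes, sets, universe)
            write_enrichment_tsv(enrichment, out / "enrichment.tsv")
            if config.venn_set:
                if config.venn_set not in sets:
                    raise ConfigError(f"venn_set {config.venn_set!r} not in GMT input")
                venn = venn_overlap(table.candidate_genes, sets[config.venn_set])
                (out / "venn.json").write_text(
                    json.dumps({"set": config.venn_set, **venn}, indent=2) + "\n"
                )

        manifest["complete"] = True
        return {
            "motif": motif,
            "pfm": pfm,
            "candidates": table,
            "annotated": annotated,
            "conservation": conservation,
            "enrichment": enrichment,
            "venn": venn,
            "manifest": manifest,
        }
    except Exception as exc:
        failed = manifest["stages"][-1] if manifest["stages"] else "config"
        logger.error("[%s] failed: %s", failed, exc)
        raise
    finally:
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str) + "\n")
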