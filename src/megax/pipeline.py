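"""End-to-end orchestration: effects → pooling (full + partial) → covariate
regression → networks → enrichment, from a single YAML config.

All outputs are plain TSV/JSON; a manifest records input hashes, package
version and seed so a rerun with identical inputs is byte-identical
(timestamps are deliberately excluded).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .covariate_regression import fit_mlr
from .effect_size import StudyEffect, compute_effect_table
from .enrichment import enrich, enrichment_frame
from .errors import PipelineStageError, ValidationError
from .io import (
    read_expression_study,
    read_gene_sets,
    read_relation_table,
    read_study_table,
)
from .mega_analysis import MegaAnalysis, MegaResult
from .network_builder import build_diagnostic_network, build_prognostic_network

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Pipeline configuration; exactly one of ``expression_dir`` (per-study
    TSVs named ``<study_id>.tsv``) or ``effects_path`` (tidy effect table)."""

    study_table_path: str
    genes: list[str]
    output_dir: str
    expression_dir: str | None = None
    effects_path: str | None = None
    partial_fraction: float = 0.5
    mlr_factors: list[str] = field(default_factory=lambda: ["n_total", "country", "study_age"])
    relation_path: str | None = None
    driver: str = "PPARG"
    disease: str = "LSCC"
    gmt_path: str | None = None
    seed: int = 0

    def __post_init__(self):
        if (self.expression_dir is None) == (self.effects_path is None):
            raise ValidationError("exactly one of expression_dir / effects_path must be set")
        if not 0 < self.partial_fraction <= 1:
            raise ValidationError("partial_fraction must be in (0, 1]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def _sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _stage(name: str, source: object, fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except Exception as exc:  # annotate with stage + input, keep the cause
        raise PipelineStageError(name, source, exc) from exc


def _effects_frame(effects: list[StudyEffect]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "study_id": [e.study_id for e in effects],
            "gene": [e.gene for e in effects],
            "lfc": [e.lfc for e in effects],
            "se": [e.se for e in effects],
            "n_control": [e.n_control for e in effects],
            "n_case": [e.n_case for e in effects],
        }
    )


def read_effect_table(path: str | Path) -> list[StudyEffect]:
    """Read a tidy effects TSV (study_id, gene, lfc, se, n_control, n_case)."""
    df = pd.read_csv(path, sep="\t")
    return [
        StudyEffect(
            study_id=str(r.study_id), gene=str(r.gene), lfc=float(r.lfc),
            se=float(r.se), n_control=int(r.n_control), n_case=int(r.n_case),
        )
        for r in df.itertuples(index=False)
    ]


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and write outputs under ``config.output_dir``.

    Returns the manifest dict (also written as ``manifest.json``).
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    inputs: dict[str, str] = {}

    studies = _stage("read_study_table", config.study_table_path,
                     read_study_table, config.study_table_path)
    inputs["study_table"] = _sha256(config.study_table_path)

    if config.effects_path:
        effects = _stage("read_effects", config.effects_path,
                         read_effect_table, config.effects_path)
        inputs["effects"] = _sha256(config.effects_path)
    else:
        expr_dir = Path(config.expression_dir)
        expr_studies = []
        for s in studies:
            path = expr_dir / f"{s.study_id}.tsv"
            expr_studies.append(_stage("read_expression", path, read_expression_study, path, s))
            inputs[f"expression/{s.study_id}"] = _sha256(path)
        effects = _stage("compute_effects", config.expression_dir,
                         compute_effect_table, expr_studies, config.genes)
    _effects_frame(effects).to_csv(out / "effects.tsv", sep="\t", index=False)

    mega_full: dict[str, MegaResult] = {}
    mega_out: dict[str, dict] = {}
    for gene in config.genes:
        gene_effects = [e for e in effects if e.gene == gene]
        if len(gene_effects) < 2:
            logger.warning("gene %s has %d studies; skipped", gene, len(gene_effects))
            continue
        model = MegaAnalysis(gene_effects)
        full = _stage("mega_analyze", gene, model.fit)
        partial = _stage("partial_mega_analyze", gene, model.fit_partial, config.partial_fraction)
        mega_full[gene] = full
        mega_out[gene] = {"full": full.to_dict(), "partial": partial.to_dict()}
    (out / "mega.json").write_text(json.dumps(mega_out, indent=2, sort_keys=True) + "\n")

    mlr_rows = []
    for gene in mega_full:
        gene_effects = [e for e in effects if e.gene == gene]
        try:
            res = fit_mlr(gene_effects, studies, config.mlr_factors)
        except ValidationError as exc:
            logger.warning("MLR for %s skipped: %s", gene, exc)
            continue
        row = {"gene": gene, "n_studies": res.n_studies, "r2": res.r2}
        row.update({f"p_{f}": p for f, p in res.factor_p.items()})
        mlr_rows.append(row)
    pd.DataFrame(mlr_rows).to_csv(out / "mlr.tsv", sep="\t", index=False)

    diag = prog = None
    if config.relation_path:
        relations = _stage("read_relations", config.relation_path,
                           read_relation_table, config.relation_path)
        inputs["relations"] = _sha256(config.relation_path)
        diag = _stage("diagnostic_network", config.relation_path,
                      build_diagnostic_network, relations, config.driver, config.disease, mega_full)
        prog = _stage("prognostic_network", config.relation_path,
                      build_prognostic_network, relations, config.driver, config.disease, mega_full)
        for name, net in (("diagnostic", diag), ("prognostic", prog)):
            (out / f"network_{name}.json").write_text(
                json.dumps(net.to_dict(), indent=2, sort_keys=True) + "\n"
            )
            pd.DataFrame(
                {
                    "source": [r.source for r in net.edges],
                    "target": [r.target for r in net.edges],
                    "polarity": [r.polarity for r in net.edges],
                    "kind": [r.relation_kind for r in net.edges],
                }
            ).to_csv(out / f"network_{name}.tsv", sep="\t", index=False)

    if config.gmt_path and diag is not None:
        sets = _stage("read_gene_sets", config.gmt_path, read_gene_sets, config.gmt_path)
        inputs["gmt"] = _sha256(config.gmt_path)
        universe = set().union(*(s.members for s in sets))
        for name, net in (("diagnostic", diag), ("prognostic", prog)):
            genes = [g for g in net.genes if g in universe]
            if not genes:
                logger.warning("no %s network genes in GMT universe; enrichment skipped", name)
                continue
            rows = _stage("enrich", name, enrich, genes, sets)
            enrichment_frame(rows).to_csv(out / f"enrich_{name}.tsv", sep="\t", index=False)

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "genes": list(config.genes),
        "partial_fraction": config.partial_fraction,
        "mlr_factors": list(config.mlr_factors),
        "inputs": inputs,
        "outputs": sorted(p.name for p in out.iterdir() if p.name != "manifest.json"),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
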