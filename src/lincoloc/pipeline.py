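"""End-to-end orchestration: simulate → quantify → colocalize → enrich →
compare-expression, with a YAML config, per-stage TSV outputs and a
structured run report.

Stages are pure functions of their inputs; rerunning with the same config
and seed reproduces every output byte-identically. Any stage failure aborts
with the stage name attached.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import colocalization as coloc
from . import contacts as ct
from . import enrichment as enr
from . import expression as expr
from .intervals import Track, genes_to_track, read_bed, read_gtf_genes
from .simulate import SyntheticConfig, write_synthetic_inputs

__all__ = ["PipelineConfig", "StageError", "run_pipeline"]

log = logging.getLogger("lincoloc")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and the cause."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Paths and parameters for a full run.

    When ``simulate`` is set, all input paths are generated under
    ``outdir/inputs`` first and the explicit path fields are ignored.
    """

    outdir: str = "results"
    seed: int = 0
    # inputs (ignored when simulate is set)
    genes_gtf: Optional[str] = None
    lincs_bed: Optional[str] = None
    contacts_rep1: Optional[str] = None
    contacts_rep2: Optional[str] = None
    repeats_bed: Optional[str] = None
    expression_tsv: Optional[str] = None
    library_gmt: Optional[str] = None
    # parameters
    max_pair_size: float = 100_000.0
    alpha: float = 0.05
    contact_threshold: int = 100
    extend_length: int = 5_000
    background_size: int = 20_000
    simulate: Optional[SyntheticConfig] = None

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        sim = d.get("simulate")
        if isinstance(sim, dict):
            d["simulate"] = SyntheticConfig(**sim)
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def _require(path: Optional[str], what: str, stage: str) -> Path:
    if path is None:
        raise StageError(stage, FileNotFoundError(f"no {what} configured"))
    p = Path(path)
    if not p.exists():
        raise StageError(stage, FileNotFoundError(f"{what} not found: {p}"))
    return p


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage in canonical order; returns the run report.

    Writes per-stage TSVs under ``config.outdir``, a colocalization summary
    row in the conventional track-comparison layout, and ``run_report.json``
    with per-stage wall times and record counts.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    report: dict = {"stages": []}

    def _stage(name):
        class _Ctx:
            def __enter__(self_inner):
                self_inner.t0 = time.perf_counter()
                log.info("stage %s: start", name)
                return self_inner

            def __exit__(self_inner, exc_type, exc, tb):
                dt = time.perf_counter() - self_inner.t0
                if exc is not None:
                    log.error("stage %s: failed (%s)", name, exc)
                    if not isinstance(exc, StageError):
                        raise StageError(name, exc) from exc
                    return False
                report["stages"].append({"stage": name, "seconds": round(dt, 3)})
                log.info("stage %s: done in %.2fs", name, dt)
                return False

        return _Ctx()

    try:
        cfg = config
        if cfg.simulate is not None:
            with _stage("simulate"):
                paths = write_synthetic_inputs(cfg.simulate, outdir / "inputs")
                cfg = dataclasses.replace(
                    cfg,
                    genes_gtf=str(paths["genes_gtf"]),
                    lincs_bed=str(paths["lincs_bed"]),
                    contacts_rep1=str(paths["contacts_rep1"]),
                    contacts_rep2=str(paths["contacts_rep2"]),
                    repeats_bed=str(paths["repeats_bed"]),
                    expression_tsv=str(paths["expression_tsv"]),
                    library_gmt=str(paths["library_gmt"]),
                )

        with _stage("quantify"):
            genes = read_gtf_genes(_require(cfg.genes_gtf, "genes GTF", "quantify"))
            rep1 = ct.read_contacts_bed(_require(cfg.contacts_rep1, "replicate 1", "quantify"))
            rep2 = ct.read_contacts_bed(_require(cfg.contacts_rep2, "replicate 2", "quantify"))
            repeats = (
                read_bed(cfg.repeats_bed) if cfg.repeats_bed and Path(cfg.repeats_bed).exists()
                else None
            )
            table = ct.quantify_contacts(
                rep1, rep2, genes,
                exclude_regions=repeats,
                target_length=cfg.extend_length,
                threshold=cfg.contact_threshold,
            )
            table.to_tsv(outdir / "gene_contacts.tsv")
            report["n_genes"] = len(genes)
            report["n_contact_genes_passing"] = int(table.table.passes_filter.sum())

        with _stage("colocalize"):
            lincs = read_bed(_require(cfg.lincs_bed, "lincRNA BED", "colocalize"))
            passing_ids = set(table.passing_gene_ids)
            passing = [g for g in genes if g.gene_id in passing_ids]
            gene_track = genes_to_track(passing if passing else genes)
            params = coloc.ColocalizationParams(
                max_pair_size=cfg.max_pair_size, alpha=cfg.alpha
            )
            result = coloc.colocalize(gene_track, lincs, params)
            row = {"track_a": "rDNA-contacting genes", "track_b": lincs.name, **result.to_row()}
            pd.DataFrame([row]).to_csv(outdir / "colocalization.tsv", sep="\t", index=False)
            report["colocalization"] = {
                "IO": result.io_mean,
                "zeta": result.zeta,
                "p": result.p_two_sided,
                "pairs": result.K,
                "colocalized": result.colocalized,
            }

        with _stage("enrich"):
            library = enr.GeneSetLibrary.from_gmt(
                _require(cfg.library_gmt, "gene-set library", "enrich"),
                background_size=cfg.background_size,
            )
            id_to_name = {g.gene_id: g.gene_name for g in genes}
            query = [id_to_name[g] for g in passing_ids if g in id_to_name]
            rows = enr.fisher_enrichment(query, library)
            enr.enrichment_to_frame(rows).to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
            report["n_terms_tested"] = len(rows)
            report["top_term"] = rows[0].term if rows else None

        with _stage("compare_expression"):
            table_expr = pd.read_csv(
                _require(cfg.expression_tsv, "expression table", "compare_expression"), sep="\t"
            )
            gene_ids = {g.gene_id for g in genes}
            linc_mask = ~table_expr.gene_id.isin(gene_ids)
            groups = {
                "contact_genes": table_expr.tpm[table_expr.gene_id.isin(passing_ids)].to_numpy(),
                "other_genes": table_expr.tpm[
                    table_expr.gene_id.isin(gene_ids - passing_ids)
                ].to_numpy(),
                "lincRNAs": table_expr.tpm[linc_mask].to_numpy(),
            }
            groups = {k: v for k, v in groups.items() if len(v) > 0}
            summary = expr.distribution_summary(groups, reference="contact_genes"
                                                if "contact_genes" in groups else None)
            summary.to_csv(outdir / "expression_summary.tsv", sep="\t", index=False)
            if len(groups) >= 2:
                mat = expr.pairwise_mw_holm(groups)
                mat.to_csv(outdir / "expression_pairwise_p.tsv", sep="\t")
            report["expression_groups"] = {k: int(len(v)) for k, v in groups.items()}

        (outdir / "run_report.json").write_text(json.dumps(report, indent=2, default=float))
        return report
    finally:
        log.removeHandler(handler)
        handler.close()
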