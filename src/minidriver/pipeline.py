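"""End-to-end orchestration: expression -> networks -> modules -> enrichment -> survival.

Mutations are projected onto the NORMAL-condition partition by default: the
normal network represents the tissue before the system-wide expression
reorganisation of oncogenesis and so provides the reference map of cellular
subsystems.  Projection onto the tumour partition is available behind a
config switch for the contrast analysis.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .community import Partition, louvain_partition, normalized_modularity
from .enrichment import (
    cohort_enrichment_summary,
    cohort_overrepresentation,
    e_status,
    union_enrichment_fraction,
)
from .expression import (
    filter_low_expression,
    read_expression_matrix,
    split_by_condition,
)
from .mutations import patient_gene_sets, read_maf
from .network import build_coexpression_network, export_network
from .survival import (
    build_survival_table,
    km_logrank,
    multivariate_stepwise,
    univariate_screen,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "select_candidate_modules"]

#: cBioPortal-style column names mapped onto the canonical clinical schema.
DEFAULT_CLINICAL_ALIASES = {
    "PATIENT_ID": "patient",
    "OS_STATUS": "vital_status",
    "DAYS_TO_DEATH": "days_to_death",
    "DAYS_TO_LAST_FOLLOWUP": "days_to_last_followup",
    "PERSON_NEOPLASM_CANCER_STATUS": "tumour_status",
    "AJCC_PATHOLOGIC_TUMOR_STAGE": "tnm_stage",
    "PATH_T_STAGE": "t_stage",
    "PATH_N_STAGE": "n_stage",
    "PATH_M_STAGE": "m_stage",
    "RESIDUAL_TUMOR": "margin_status",
}


@dataclass
class PipelineConfig:
    """Paths, thresholds and seeds for one pipeline run."""

    expression_path: str
    condition_path: str | None = None
    mutations_path: str | None = None
    clinical_path: str | None = None
    gmt_path: str | None = None
    output_dir: str = "minidriver_run"

    percentile: float = 40.0
    rho_thresholds: list[float] = field(default_factory=lambda: [0.8])
    primary_rho: float = 0.8
    correlation_mode: str = "positive"

    seed: int = 0
    n_null: int = 100
    swaps_per_edge: int = 10
    normalization: str = "shifted"

    alpha: float = 0.05
    bh_family: str = "patient"
    min_module_size: int = 5
    projection_condition: str = "normal"
    top_k: int = 2
    exclude_patients: list[str] = field(default_factory=list)
    barcode_length: int | None = None

    horizon_days: int = 1826
    survival_covariates: list[str] = field(
        default_factory=lambda: ["n_stage", "smoking", "margin_status"]
    )
    clinical_aliases: dict[str, str] = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def select_candidate_modules(summary: pd.DataFrame, top_k: int = 2) -> list[int]:
    """Top modules by fraction of patients enriched.

    Ties are broken by larger module, then lower module id, so the output
    is deterministic.
    """
    if summary.empty:
        raise ValueError("enrichment summary is empty")
    size_col = (
        summary["module_size"]
        if "module_size" in summary.columns
        else pd.Series(0, index=summary.index)
    )
    ranked = summary.assign(_size=size_col).sort_values(
        ["fraction_enriched", "_size", "module"],
        ascending=[False, False, True],
    )
    return ranked["module"].head(top_k).astype(int).tolist()


def read_clinical(path, aliases: dict[str, str] | None = None) -> pd.DataFrame:
    """Read a clinical TSV, renaming columns via the alias table."""
    df = pd.read_csv(path, sep="\t", comment="#")
    mapping = dict(DEFAULT_CLINICAL_ALIASES)
    mapping.update(aliases or {})
    return df.rename(columns=mapping)


def _network_stage(matrix, cfg: PipelineConfig, label: str, outdir: Path) -> dict:
    nets = {}
    for rho in cfg.rho_thresholds:
        nets[rho] = build_coexpression_network(
            matrix, rho, mode=cfg.correlation_mode
        )
    primary = nets.get(cfg.primary_rho) or build_coexpression_network(
        matrix, cfg.primary_rho, mode=cfg.correlation_mode
    )
    export_network(primary, outdir / f"network_{label}.graphml", "graphml")
    export_network(primary, outdir / f"network_{label}.edgelist", "edgelist")
    partition = louvain_partition(primary, seed=cfg.seed)
    partition.to_tsv(outdir / f"partition_{label}.tsv")
    report = normalized_modularity(
        primary,
        n_null=cfg.n_null,
        swaps_per_edge=cfg.swaps_per_edge,
        seed=cfg.seed,
        formula=cfg.normalization,
    )
    with open(outdir / f"modularity_{label}.json", "w") as fh:
        json.dump(report.to_dict(), fh, indent=2)
    return {"network": primary, "partition": partition, "modularity": report}


def run_pipeline(cfg: PipelineConfig) -> Path:
    """Run every stage and write all intermediates to the output directory.

    Returns the artifact directory.  Stage failures abort with a
    stage-tagged message; stages whose inputs are not configured
    (no mutations / no clinical table) are skipped and noted in the
    manifest.
    """
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "seed": cfg.seed, "stages": {}}
    log_lines = [f"minidriver {__version__}", f"seed={cfg.seed}"]

    def stage(name):
        def wrap(fn):
            try:
                result = fn()
            except Exception as exc:
                raise RuntimeError(f"[stage {name}] {exc}") from exc
            manifest["stages"][name] = "ok"
            log_lines.append(f"stage {name}: ok")
            return result
        return wrap

    matrix = stage("expression")(
        lambda: filter_low_expression(
            read_expression_matrix(cfg.expression_path, cfg.condition_path),
            cfg.percentile,
        )
    )

    labels = (
        sorted(matrix.condition.reindex(matrix.data.columns).dropna().unique())
        if matrix.condition is not None
        else []
    )
    condition_results: dict[str, dict] = {}
    for label in labels:
        sub = split_by_condition(matrix, label)
        condition_results[label] = stage(f"network_{label}")(
            lambda sub=sub, label=label: _network_stage(sub, cfg, label, outdir)
        )
    if len(condition_results) < 2:
        log_lines.append(
            "modularity comparison: single condition only "
            f"({', '.join(condition_results) or 'none'})"
        )

    projection = cfg.projection_condition
    if projection not in condition_results:
        if condition_results:
            projection = next(iter(condition_results))
            logger.warning(
                "projection condition %r unavailable; using %r",
                cfg.projection_condition, projection,
            )
        else:
            projection = None

    results = None
    if cfg.mutations_path is not None and projection is not None:
        partition = condition_results[projection]["partition"]

        def enrich():
            maf = read_maf(cfg.mutations_path)
            profiles = patient_gene_sets(
                maf,
                exclude_patients=set(cfg.exclude_patients),
                barcode_length=cfg.barcode_length,
            )
            res = cohort_overrepresentation(
                profiles, partition,
                alpha=cfg.alpha, min_module_size=cfg.min_module_size,
                family=cfg.bh_family,
            )
            res.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
            summary = cohort_enrichment_summary(res)
            summary.to_csv(outdir / "enrichment_summary.tsv", sep="\t",
                           index=False)
            return profiles, res, summary

        profiles, results, summary = stage("enrichment")(enrich)
        candidates = select_candidate_modules(summary, top_k=cfg.top_k)
        log_lines.append(f"candidate modules: {candidates}")
        if len(candidates) >= 2:
            log_lines.append(
                "union enrichment fraction (top 2): "
                f"{union_enrichment_fraction(results, candidates[:2]):.3f}"
            )

    if cfg.clinical_path is not None and results is not None:
        designated = candidates[0]

        def survive():
            clinical = read_clinical(cfg.clinical_path, cfg.clinical_aliases)
            status = e_status(results, designated, alpha=cfg.alpha)
            clinical = clinical.set_index(clinical["patient"].astype(str))
            clinical["e_status"] = (
                status.reindex(clinical.index).fillna(False).astype(int)
            )
            clinical["mutational_load"] = [
                profiles[p].mutational_load if p in profiles else 0
                for p in clinical.index
            ]
            covs = ["e_status", "mutational_load"] + [
                c for c in cfg.survival_covariates if c in clinical.columns
            ]
            table = build_survival_table(
                clinical, horizon_days=cfg.horizon_days, covariates=covs
            )
            screen = univariate_screen(table, covs)
            out = {
                "designated_module": int(designated),
                "horizon_days": cfg.horizon_days,
                "n_patients": int(len(table)),
                "n_events": int(table["event"].sum()),
                "univariate": [
                    {
                        "covariate": r.covariate,
                        "model_p": r.model_p,
                        "n_used": r.n_used,
                        "aic": r.aic,
                        "terms": r.terms.to_dict(orient="records"),
                    }
                    for r in screen
                ],
            }
            try:
                _, logrank_p = km_logrank(table, "e_status")
                out["e_status_logrank_p"] = logrank_p
            except ValueError as exc:
                out["e_status_logrank_p"] = None
                logger.warning("KM by E status unavailable: %s", exc)
            try:
                final = multivariate_stepwise(table, screen)
                out["stepwise"] = {
                    "covariates": final.covariates,
                    "aic": final.aic,
                    "aic_trace": final.aic_trace,
                    "dropped": final.dropped,
                    "n_used": final.n_used,
                    "terms": final.terms.to_dict(orient="records"),
                }
            except ValueError as exc:
                out["stepwise"] = {"error": str(exc)}
            with open(outdir / "survival.json", "w") as fh:
                json.dump(out, fh, indent=2)
            return out

        stage("survival")(survive)

    with open(outdir / "run_log.txt", "w") as fh:
        fh.write("\n".join(log_lines) + "\n")
    manifest["outputs"] = sorted(
        p.name for p in outdir.iterdir() if p.name != "manifest.json"
    )
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return outdir
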