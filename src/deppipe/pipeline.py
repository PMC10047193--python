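"""End-to-end orchestration of the analysis stages.

Fixed stage order — exclusive detection on the raw matrix, then the NA
filter, sample-mean imputation, differential expression, |FC| outliers,
sample clustering/PCA, direction x category association, PPI hub
consensus, and the gene-disease filter — with every stage's parameters
and outputs collected into one machine-readable report. One global seed
fans out to per-stage sub-seeds by fixed offsets so each stochastic
stage is individually reproducible.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import yaml

from . import association, differential, disease, hubs, io, missingness, multivariate
from .datamodel import ONTOLOGIES

logger = logging.getLogger(__name__)

# per-stage seed offsets (stable across runs and versions)
_SEED_OFFSETS = {
    "kmeans": 11,
    "GO-CC": 21,
    "GO-BP": 22,
    "GO-MF": 23,
    "KOG": 24,
}


def _jsonable(obj):
    if isinstance(obj, np.integer):
        return int(obj)
    if isinstance(obj, np.floating):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


class StageError(RuntimeError):
    """An analysis stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception) -> None:
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Input paths plus every stage parameter (defaults as documented)."""

    matrix: str
    metadata: str
    network: str | None = None
    annotations: str | None = None
    disease: str | None = None
    out_dir: str = "deppipe_run"

    exclusive_min_present: int = 3
    min_present_per_group: int = 4
    max_total_na: int = 3
    p_cutoff: float = 0.05
    d_cutoff: float = 2.0
    test: str = "welch"
    outlier_k: float = 2.0
    linkage: str = "complete"
    edge_min_score: float = 0.9
    hub_threshold: float = 2.0
    hub_mode: str = "score"
    disease_min_score: float = 2.0
    doid: str | None = None
    n_sim: int = 2000
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages, write per-stage outputs, return the report.

    Identical config and inputs produce a byte-identical report.json.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": asdict(config), "stages": {}}

    def stage(name: str):
        logger.info("stage: %s", name)
        return name

    name = stage("load")
    try:
        dataset = io.read_abundance_matrix(config.matrix, config.metadata)
    except Exception as e:  # noqa: BLE001 - re-raised with stage context
        raise StageError(name, e) from e
    report["stages"]["load"] = {
        "n_proteins": dataset.n_proteins,
        "n_samples": dataset.n_samples,
        "groups": dataset.groups,
        "input": "raw matrix",
    }

    name = stage("exclusive")
    try:
        exclusive = missingness.detect_exclusive(
            dataset, min_present=config.exclusive_min_present
        )
    except Exception as e:
        raise StageError(name, e) from e
    report["stages"]["exclusive"] = {
        "input": "raw matrix",
        "min_present": config.exclusive_min_present,
        "records": [asdict(r) for r in exclusive],
        "by_group": {
            g: sorted(r.protein_id for r in exclusive if r.present_group == g)
            for g in dataset.groups
        },
    }

    name = stage("filter")
    try:
        filtered, filt_report = missingness.filter_missingness(
            dataset,
            min_present_per_group=config.min_present_per_group,
            max_total_na=config.max_total_na,
        )
    except Exception as e:
        raise StageError(name, e) from e
    report["stages"]["filter"] = {
        "min_present_per_group": config.min_present_per_group,
        "max_total_na": config.max_total_na,
        **filt_report.to_dict(),
    }

    name = stage("impute")
    try:
        imputed, imp_counts = missingness.impute_sample_mean(filtered)
    except Exception as e:
        raise StageError(name, e) from e
    report["stages"]["impute"] = {
        "n_cells_imputed": int(sum(imp_counts.values())),
        "n_proteins_imputed": int(sum(1 for v in imp_counts.values() if v)),
    }

    name = stage("differential")
    try:
        model = differential.DifferentialExpression(
            imputed, imputation_counts=imp_counts, test=config.test
        )
        results = model.fit(p_cutoff=config.p_cutoff, d_cutoff=config.d_cutoff)
    except Exception as e:
        raise StageError(name, e) from e
    results.to_frame().to_csv(out_dir / "dep_records.tsv", sep="\t", index=False)
    results.volcano_table().to_csv(out_dir / "volcano.tsv", sep="\t", index=False)
    report["stages"]["differential"] = {
        "input": "filtered+imputed matrix",
        "test": config.test,
        "p_cutoff": config.p_cutoff,
        "d_cutoff": config.d_cutoff,
        "contrast": f"{model.case_group} - {model.control_group}",
        "n_tested": len(results.records),
        "n_up": len(results.up),
        "n_down": len(results.down),
        "up_ids": sorted(r.protein_id for r in results.up),
        "down_ids": sorted(r.protein_id for r in results.down),
    }

    name = stage("outliers")
    deps = results.deps
    if len(deps) >= 2:
        try:
            out_rep = differential.detect_outliers(deps, k=config.outlier_k)
        except Exception as e:
            raise StageError(name, e) from e
        report["stages"]["outliers"] = {
            "cutoff": out_rep.cutoff,
            "mean_abs_lfc": out_rep.mean_abs_lfc,
            "sd_abs_lfc": out_rep.sd_abs_lfc,
            "up": out_rep.up_outliers,
            "down": out_rep.down_outliers,
        }
    else:
        report["stages"]["outliers"] = {"skipped": "fewer than 2 DEPs"}

    name = stage("multivariate")
    try:
        ordination = multivariate.kmeans_pca(
            imputed,
            seed=config.seed + _SEED_OFFSETS["kmeans"],
            linkage=config.linkage,
        )
    except Exception as e:
        raise StageError(name, e) from e
    report["stages"]["multivariate"] = {
        "explained_variance_fraction": [
            float(v) for v in ordination.explained_variance_fraction
        ],
        "kmeans_labels": {
            s: int(l) for s, l in zip(ordination.sample_ids, ordination.kmeans_labels)
        },
    }

    if config.annotations:
        name = stage("association")
        try:
            ann = io.read_annotation_table(config.annotations)
            assoc_out = {}
            up_ids = [r.protein_id for r in results.up]
            down_ids = [r.protein_id for r in results.down]
            for ont in sorted(ONTOLOGIES):
                present = set(ann.for_ontology(ont)["id"])
                if not present & (set(up_ids) | set(down_ids)):
                    assoc_out[ont] = {"skipped": "no annotated DEPs"}
                    continue
                res = association.CategoryAssociation(
                    up_ids, down_ids, ann, ont
                ).fit(n_sim=config.n_sim, seed=config.seed + _SEED_OFFSETS[ont])
                assoc_out[ont] = res.to_dict()
        except StageError:
            raise
        except Exception as e:
            raise StageError(name, e) from e
        report["stages"]["association"] = assoc_out
    else:
        report["stages"]["association"] = {"skipped": "no annotation table"}

    if config.network:
        name = stage("hubs")
        try:
            net = io.read_edge_list(config.network)
            hub_table = hubs.score_hubs(
                net,
                min_score=config.edge_min_score,
                threshold=config.hub_threshold,
                mode=config.hub_mode,
            )
        except Exception as e:
            raise StageError(name, e) from e
        report["stages"]["hubs"] = {
            "edge_min_score": config.edge_min_score,
            "threshold": config.hub_threshold,
            "mode": config.hub_mode,
            "selected": hub_table.selected,
            "consensus": hub_table.consensus,
        }
    else:
        report["stages"]["hubs"] = {"skipped": "no network"}

    if config.disease:
        name = stage("disease")
        try:
            recs = io.read_disease_table(config.disease)
            summary = disease.filter_associations(
                recs, min_score=config.disease_min_score, doid=config.doid
            )
        except Exception as e:
            raise StageError(name, e) from e
        report["stages"]["disease"] = summary.to_dict()
    else:
        report["stages"]["disease"] = {"skipped": "no disease table"}

    report_path = out_dir / "report.json"
    with open(report_path, "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=_jsonable)
        fh.write("\n")
    logger.info("report written to %s", report_path)
    return report
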