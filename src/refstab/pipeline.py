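"""End-to-end orchestration: screen -> rank -> select -> normalize -> validate.

The in-memory entry points are the primary interface; :class:`PipelineConfig`
and :func:`run_pipeline` wire them to files for the command-line layer,
persisting every stage report as JSON.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import genorm, normfinder
from .data_model import (
    CqTable,
    NormalizedExpression,
    SampleAnnotations,
    StabilityReport,
    read_annotations,
    read_cq_table,
    read_expression_matrix,
    read_probe_map,
)
from .genorm import OptimalSet, V_CUTOFF
from .qc import collapse_replicates, delta_cq, log_quantity_matrix
from .screen import ScreenConfig, run_screen
from .validation import cross_platform_correlation, hypoxia_association

__all__ = [
    "StabilityAnalysis",
    "rank_candidates",
    "PipelineConfig",
    "run_pipeline",
    "MIN_REFERENCE_GENES",
]

logger = logging.getLogger(__name__)

#: Minimum reference-panel size used by pipeline-level selection.  geNorm
#: practice recommends normalizing against at least three reference genes;
#: the V_n/n+1 criterion then only decides whether a fourth (fifth, ...)
#: gene is needed.
MIN_REFERENCE_GENES = 3


@dataclass
class StabilityAnalysis:
    """Joint geNorm/NormFinder ranking of a candidate panel plus the
    V-based choice of the reference set."""

    genorm: StabilityReport
    normfinder: StabilityReport
    optimal_set: OptimalSet
    dropped_qc: list[str]
    subgroups: dict[str, StabilityReport] = field(default_factory=dict)


def rank_candidates(
    cq: CqTable,
    candidates: list[str] | None = None,
    annotations: SampleAnnotations | None = None,
    groupings: list[str] | None = None,
    v_cutoff: float = V_CUTOFF,
    min_genes: int = MIN_REFERENCE_GENES,
    max_mean_cq: float = 37.0,
    max_sd: float = 0.4,
    efficiency: float = 2.0,
) -> StabilityAnalysis:
    """Replicate collapsing + QC, then geNorm and NormFinder stability
    ranking of the candidate genes, and the pairwise-variation choice of
    how many reference genes the normalization factor needs."""
    collapsed = collapse_replicates(cq, max_mean_cq=max_mean_cq, max_sd=max_sd)
    log_m, dropped = log_quantity_matrix(collapsed, efficiency=efficiency, genes=candidates)
    g_report = genorm.stepwise_rank(log_m)
    chosen = genorm.select_optimal_set(
        g_report.pairwise_variation, g_report.ranking, cutoff=v_cutoff, min_genes=min_genes
    )
    nf_report = normfinder.rank(log_m)
    subgroups: dict[str, StabilityReport] = {}
    if annotations is not None and groupings:
        shared = [s for s in log_m.columns if s in annotations.sample_ids]
        subgroups = normfinder.subgroup_scan(log_m[shared], annotations, groupings)
    return StabilityAnalysis(
        genorm=g_report,
        normfinder=nf_report,
        optimal_set=chosen,
        dropped_qc=dropped,
        subgroups=subgroups,
    )


@dataclass
class PipelineConfig:
    """File-level configuration of the full study pipeline."""

    cq_path: str
    out_dir: str
    candidates: list[str] | None = None
    annotations_path: str | None = None
    array_path: str | None = None
    probe_map_path: str | None = None
    celllines_path: str | None = None
    cellline_pairs: dict[str, tuple[str, str]] | None = None
    target_genes: list[str] = field(default_factory=list)
    groupings: list[str] = field(default_factory=list)
    abrix_covariate: str = "a_brix"
    cq_dialect: str = "long"
    v_cutoff: float = V_CUTOFF
    min_reference_genes: int = MIN_REFERENCE_GENES
    fold_threshold: float = 1.5
    alpha: float = 0.05
    min_mean_log2: float = 7.0
    max_mean_cq: float = 37.0
    max_sd: float = 0.4

    def __post_init__(self) -> None:
        for value, name in [
            (self.v_cutoff, "v_cutoff"),
            (self.fold_threshold, "fold_threshold"),
            (self.alpha, "alpha"),
            (self.max_mean_cq, "max_mean_cq"),
            (self.max_sd, "max_sd"),
        ]:
            if value <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = json.load(fh)
        if "cellline_pairs" in raw and raw["cellline_pairs"] is not None:
            raw["cellline_pairs"] = {
                k: tuple(v) for k, v in raw["cellline_pairs"].items()
            }
        return cls(**raw)


def _dump(obj: dict, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=str) + "\n")


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the configured stages and persist one JSON report each.

    Stages with missing optional inputs are skipped; missing *named*
    inputs raise with the offending path.  Returns the report bundle.
    """
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    bundle: dict = {"schema_version": 1}

    for path in [cfg.cq_path, cfg.annotations_path, cfg.array_path, cfg.probe_map_path, cfg.celllines_path]:
        if path is not None and not Path(path).exists():
            raise FileNotFoundError(f"pipeline input not found: {path}")

    cq = read_cq_table(cfg.cq_path, dialect=cfg.cq_dialect)
    annotations = read_annotations(cfg.annotations_path) if cfg.annotations_path else None
    array = read_expression_matrix(cfg.array_path) if cfg.array_path else None
    probe_map = read_probe_map(cfg.probe_map_path) if cfg.probe_map_path else None

    # optional array-based screening
    candidates = cfg.candidates
    if cfg.celllines_path and array is not None and probe_map is not None and annotations is not None:
        from .screen import CellLinePairing

        celllines = read_expression_matrix(cfg.celllines_path)
        pairs = CellLinePairing(cfg.cellline_pairs or {})
        screen_report = run_screen(
            candidates or probe_map.genes,
            array,
            celllines,
            pairs,
            annotations,
            probe_map,
            ScreenConfig(
                fold_threshold=cfg.fold_threshold,
                alpha=cfg.alpha,
                min_mean_log2=cfg.min_mean_log2,
                abrix_covariate=cfg.abrix_covariate,
            ),
        )
        bundle["screen"] = screen_report.to_dict()
        _dump(bundle["screen"], out_dir / "screen.json")
        candidates = screen_report.survivors

    analysis = rank_candidates(
        cq,
        candidates=candidates,
        annotations=annotations,
        groupings=cfg.groupings,
        v_cutoff=cfg.v_cutoff,
        min_genes=cfg.min_reference_genes,
        max_mean_cq=cfg.max_mean_cq,
        max_sd=cfg.max_sd,
    )
    bundle["rank"] = {
        "genorm": analysis.genorm.to_dict(),
        "normfinder": analysis.normfinder.to_dict(),
        "optimal_set": {
            "genes": analysis.optimal_set.genes,
            "n": analysis.optimal_set.n,
            "v": analysis.optimal_set.v,
            "all_above_cutoff": analysis.optimal_set.all_above_cutoff,
        },
        "dropped_qc": analysis.dropped_qc,
        "subgroups": {k: v.to_dict() for k, v in analysis.subgroups.items()},
    }
    _dump(bundle["rank"], out_dir / "rank.json")

    refs = analysis.optimal_set.genes
    collapsed = collapse_replicates(cq, max_mean_cq=cfg.max_mean_cq, max_sd=cfg.max_sd)
    ndcq = delta_cq(collapsed, refs)
    ndcq.values.to_csv(out_dir / "ndcq.csv", index_label="gene")
    bundle["normalize"] = {
        "reference_genes": refs,
        "n_samples": len(ndcq.samples),
        "excluded": [list(e) for e in ndcq.excluded],
    }
    _dump(bundle["normalize"], out_dir / "normalize.json")

    if cfg.target_genes and annotations is not None:
        validation: dict = {}
        targets = [g for g in cfg.target_genes if g in ndcq.values.index]
        abrix = annotations.covariate(cfg.abrix_covariate)
        validation["hypoxia_association"] = [
            asdict(r) for r in hypoxia_association(ndcq, abrix, targets)
        ]
        if array is not None and probe_map is not None:
            gene_level = _gene_level_matrix(array, probe_map)
            present = [g for g in targets if g in gene_level.values.index]
            validation["cross_platform"] = [
                asdict(r) for r in cross_platform_correlation(ndcq, gene_level, present)
            ]
        bundle["validate"] = validation
        _dump(validation, out_dir / "validate.json")

    _dump(
        {k: v for k, v in bundle.items() if k in ("schema_version", "normalize")},
        out_dir / "pipeline.json",
    )
    return bundle


def _gene_level_matrix(array, probe_map):
    """Collapse a probe-level matrix to genes by averaging probes."""
    from .data_model import ExpressionMatrix

    gene_of = probe_map.as_series()
    frame = array.values.copy()
    frame["gene"] = gene_of.reindex(frame.index)
    collapsed = frame.dropna(subset=["gene"]).groupby("gene").mean()
    return ExpressionMatrix(collapsed)
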