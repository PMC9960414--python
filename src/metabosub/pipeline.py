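"""End-to-end pipeline: preprocess -> consensus -> cores -> scores -> subtypes."""

from __future__ import annotations

from dataclasses import dataclass

from metabosub.consensus import ConsensusConfig, ConsensusResult, consensus_cluster
from metabosub.data_io import ClinicalTable, ExpressionMatrix, GeneSet
from metabosub.preprocess import (
    center_scale_genes,
    filter_low_purity,
    tpm_log_transform,
)
from metabosub.subtyping import (
    CoreClusters,
    SubtypeCall,
    assign_subtype,
    compute_pathway_scores,
    select_core_clusters,
)


@dataclass
class PipelineResult:
    expr_centered: ExpressionMatrix
    clinical: ClinicalTable
    consensus: ConsensusResult
    cores: CoreClusters
    calls: list[SubtypeCall]
    purity_report: dict


def run_subtyping_pipeline(
    expr: ExpressionMatrix,
    clinical: ClinicalTable,
    gly_set: GeneSet,
    chol_set: GeneSet,
    purity_min: float = 0.30,
    k: int = 4,
    consensus_config: ConsensusConfig | None = None,
    centering: str = "median",
    scaling: str = "sd",
) -> PipelineResult:
    """Classify every retained sample into one of the four metabolic subtypes.

    Steps: restrict to the two gene sets, log-transform (if raw), purity
    filter, gene-wise center/scale, consensus-cluster the genes at k, select
    the core co-expressed clusters, score samples by core medians, apply the
    quadrant rule.
    """
    genes = [g for g in expr.gene_ids if g in gly_set or g in chol_set]
    expr = expr.subset_genes(genes)
    if expr.scale_tag in ("counts", "tpm"):
        expr = tpm_log_transform(expr)
    expr, clinical, purity_report = filter_low_purity(expr, clinical, purity_min)
    centered = center_scale_genes(expr, centering=centering, scaling=scaling)
    config = consensus_config or ConsensusConfig()
    if k not in config.k_values:
        raise ValueError(f"k={k} not among configured k_values {config.k_values}")
    result = consensus_cluster(centered, config)
    cores = select_core_clusters(result.labels[k], gly_set, chol_set)
    scores = compute_pathway_scores(centered, cores)
    calls = assign_subtype(scores)
    return PipelineResult(centered, clinical, result, cores, calls, purity_report)
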