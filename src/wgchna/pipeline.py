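"""End-to-end pipeline: preprocess -> hypergraph -> Laplacian/TOM -> modules
-> downstream analysis, with a single serializable configuration."""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import analysis, hypergraph, laplacian, modules, softthreshold
from .io import ExpressionMatrix, TraitTable, filter_genes, impute_missing, standardize

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All pipeline knobs, serializable to/from YAML.

    ``beta = None`` triggers an automatic soft-threshold scan over
    ``scan_betas`` with selection at ``r2_cut``.
    """

    tau: float = 1.0
    beta: int | None = None
    scan_betas: list[int] = field(default_factory=lambda: list(range(1, 13)))
    n_bins: int = 10
    r2_cut: float = 0.8
    max_missing_frac: float = 0.2
    min_variance: float = 0.0
    min_cluster_size: int = 50
    deep_split: int = 2
    merge_similarity: float = 0.8
    mi_bins: int = 8
    top_k: int = 10

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


@dataclass
class PipelineResult:
    """Everything the pipeline computes, for programmatic use or export."""

    expression: ExpressionMatrix  # filtered + imputed (analysis scale)
    hypergraph: hypergraph.WeightedHypergraph
    scan: softthreshold.SoftThresholdScan | None
    beta: int
    laplacians: laplacian.LaplacianSet
    tom: laplacian.TOMatrix
    diss: laplacian.DissTOM
    assignment: modules.ModuleAssignment
    module_trait: analysis.ModuleTraitResult | None
    hubs: pd.DataFrame | None
    config: RunConfig


def run_pipeline(
    X: ExpressionMatrix,
    traits: TraitTable | None = None,
    config: RunConfig | None = None,
) -> PipelineResult:
    """Run the full analysis on an expression matrix.

    Steps: quality filter and median-impute genes; standardize; threshold
    standardized expression into sample hyperedges (tau); choose the soft
    threshold beta (fixed or scanned); compute soft-thresholded hyperedge
    weights, the normalized hypergraph Laplacian, affinity and TOM; cluster
    dissTOM, cut, merge and renumber modules; finally compute eigengenes,
    module-trait correlations and hub genes.
    """
    config = config or RunConfig()
    X = filter_genes(X, config.max_missing_frac, config.min_variance)
    X = impute_missing(X)
    Z = standardize(X)

    scan = None
    if config.beta is None:
        scan = softthreshold.scan_beta(X, config.tau, config.scan_betas, config.n_bins)
        beta = softthreshold.pick_beta(scan, config.r2_cut)
    else:
        beta = int(config.beta)
    logger.info("soft threshold beta = %d%s", beta, " (scanned)" if scan else "")

    hg = hypergraph.build_incidence(Z, config.tau)
    # restrict expression to retained hypergraph nodes, preserving order
    keep = [X.gene_ids.index(g) for g in hg.node_ids]
    X = ExpressionMatrix(X.values[keep], list(hg.node_ids), list(X.sample_ids))
    hg = hypergraph.hyperedge_weights_corr(X, hg, beta=beta)

    laps = laplacian.laplacians(hg)
    t = laplacian.tom(laps)
    d = laplacian.diss_tom(t)

    cfg = modules.DetectionConfig(
        min_cluster_size=config.min_cluster_size,
        deep_split=config.deep_split,
        merge_similarity=config.merge_similarity,
    )
    assignment = modules.detect_modules(X, d, cfg)

    module_trait = None
    hubs = None
    if assignment.n_modules > 0:
        if traits is not None:
            module_trait = analysis.module_trait_correlation(assignment.eigengenes, traits)
        hubs = analysis.hub_genes(X, assignment, assignment.eigengenes, config.top_k)

    return PipelineResult(
        expression=X,
        hypergraph=hg,
        scan=scan,
        beta=beta,
        laplacians=laps,
        tom=t,
        diss=d,
        assignment=assignment,
        module_trait=module_trait,
        hubs=hubs,
        config=config,
    )
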