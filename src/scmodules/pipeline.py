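"""End-to-end pipeline: QC -> normalization -> clustering -> DE -> modules ->
prioritization (+ optional TCR classification), with a run manifest.

Every stage writes its artifact under the output directory and the manifest
records the config hash, seed, stage output paths and SHA-256 checksums, so a
rerun with the same inputs, config and seed reproduces byte-identical tables.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import cluster as _cluster
from . import de as _de
from . import io as _io
from . import modules as _modules
from . import priority as _priority
from . import tcr as _tcr
from .qc import (
    CountMatrix,
    QCThresholds,
    compute_qc_metrics,
    filter_cells,
    filter_genes,
    lognormalize,
    recover_counts,
    regress_confounders,
)

__all__ = ["PipelineConfig", "run_pipeline"]

log = logging.getLogger("scmodules")


@dataclass
class PipelineConfig:
    """All stage parameters with the pipeline defaults.

    Defaults follow the full-length scRNA-seq workflow this package
    implements: 43 bp count recovery, QC thresholds 40%/50%/50%/200 and 5
    cells per gene, log-normalization scale 1000, 50 PCs, KNN k=10, SNN
    Jaccard 1/15, Louvain resolution 2.4, marker DE at log2FC>0.25 &
    FDR<0.01, permissive DE at |log2FC|>0.1 & p<0.1, 100 modules with a 5-NN
    module graph, and clone read-count filter > 5.
    """

    read_length: int = 43
    tpm_input: bool = True
    qc: QCThresholds = field(default_factory=QCThresholds)
    scale_factor: float = 1000.0
    covariates: tuple = ("pct_mito", "pct_ribo", "pct_noncoding")
    n_hvg: int = 2000
    n_pcs: int = 50
    knn_k: int = 10
    snn_jaccard_min: float = 1 / 15
    resolution: float = 2.4
    marker_lfc_min: float = 0.25
    marker_fdr_max: float = 0.01
    permissive_lfc_abs_min: float = 0.1
    permissive_p_max: float = 0.1
    n_modules: int = 100
    module_graph_k: int = 5
    clone_min_count_exclusive: int = 5
    top_n_degs: int = 100
    background_min_cells: int = 5
    compare_p_max: float = 0.01
    priority_factors: tuple = ("tissue", "subset", "donor")
    seed: int = 0

    def __post_init__(self):
        positive = {
            "read_length": self.read_length,
            "scale_factor": self.scale_factor,
            "n_hvg": self.n_hvg,
            "n_pcs": self.n_pcs,
            "knn_k": self.knn_k,
            "resolution": self.resolution,
            "n_modules": self.n_modules,
            "module_graph_k": self.module_graph_k,
        }
        for name, v in positive.items():
            if v <= 0:
                raise ValueError(f"{name} must be positive, got {v}")
        if not 0 <= self.snn_jaccard_min <= 1:
            raise ValueError("snn_jaccard_min must lie in [0, 1]")
        if self.clone_min_count_exclusive < 0:
            raise ValueError("clone_min_count_exclusive must be >= 0")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["covariates"] = list(self.covariates)
        d["priority_factors"] = list(self.priority_factors)
        return d


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(
    matrix: CountMatrix,
    metadata: pd.DataFrame,
    outdir,
    config: PipelineConfig | None = None,
    clone_table: pd.DataFrame | None = None,
    exclude_cells=(),
) -> dict:
    """Run every stage in order and return the manifest.

    ``metadata`` must cover all cells; numeric columns named in
    ``config.covariates`` beyond the internally computed fractions are taken
    from it.  ``exclude_cells`` is an optional manual removal list (e.g.
    contaminating populations identified by marker expression).
    Stage artifacts land under ``outdir``.
    """
    config = config or PipelineConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages: dict[str, dict] = {}
    t_start = time.time()

    def record(stage: str, path: Path, shape) -> None:
        stages[stage] = {
            "path": str(path.relative_to(outdir)),
            "sha256": _sha256(path),
            "shape": list(shape),
        }
        log.info("stage %-10s -> %s %s", stage, path.name, tuple(shape))

    # --- qc ---------------------------------------------------------------
    if exclude_cells:
        keep = [c for c in matrix.cells if c not in set(exclude_cells)]
        matrix = matrix.subset(cell_ids=keep)
    counts = recover_counts(matrix, config.read_length) if config.tpm_input else matrix
    qc_table = compute_qc_metrics(counts)
    kept_cells = filter_cells(qc_table, config.qc)
    counts = counts.subset(cell_ids=kept_cells)
    kept_genes = filter_genes(counts, config.qc.min_cells_per_gene)
    counts = counts.subset(gene_ids=kept_genes)
    p = outdir / "qc_table.csv"
    qc_table.assign(kept=qc_table.index.isin(kept_cells)).to_csv(p)
    record("qc", p, counts.shape)

    # --- normalize --------------------------------------------------------
    norm = lognormalize(counts, config.scale_factor)
    _io.write_matrix(norm, outdir / "normalized", fmt="mtx")
    record("normalize", outdir / "normalized.mtx", norm.shape)

    # --- regress ----------------------------------------------------------
    internal = compute_qc_metrics(counts)[["pct_mito", "pct_ribo", "pct_noncoding"]]
    cov_cols = []
    for name in config.covariates:
        if name in internal.columns:
            cov_cols.append(internal[name])
        elif name in metadata.columns:
            cov_cols.append(metadata.loc[norm.cells, name].astype(float))
        else:
            raise ValueError(f"unknown covariate {name!r}")
    cov = pd.concat(cov_cols, axis=1) if cov_cols else None
    scaled = regress_confounders(norm, cov)
    _io.write_matrix(scaled, outdir / "scaled", fmt="mtx")
    record("regress", outdir / "scaled.mtx", scaled.shape)

    # --- cluster ----------------------------------------------------------
    hvgs = _cluster.select_hvgs(norm, min(config.n_hvg, norm.shape[0]))
    emb = _cluster.run_pca(scaled.subset(gene_ids=hvgs), config.n_pcs)
    g, knn_lists = _cluster.build_knn_graph(emb, config.knn_k)
    snn = _cluster.prune_snn(g, knn_lists, config.snn_jaccard_min)
    labels_pos = _cluster.louvain_cluster(snn, config.resolution, config.seed)
    labels = pd.Series(labels_pos.to_numpy(), index=norm.cells, name="cluster")
    p = outdir / "clusters.csv"
    labels.to_csv(p)
    record("cluster", p, (len(labels), int(labels.nunique())))

    # --- de ---------------------------------------------------------------
    de_all = _de.de_all_clusters(norm, labels)
    p = outdir / "de_table.csv"
    de_all.to_csv(p, index=False)
    record("de", p, de_all.shape)
    markers = _de.marker_genes(de_all, config.marker_lfc_min, config.marker_fdr_max)

    # --- permissive gene set ---------------------------------------------
    permissive = _de.permissive_gene_set(
        de_all, config.permissive_lfc_abs_min, config.permissive_p_max
    )
    p = outdir / "permissive_genes.tsv"
    p.write_text("\n".join(map(str, permissive)) + "\n")
    record("permissive", p, (len(permissive),))

    # --- modules ----------------------------------------------------------
    n_modules = min(config.n_modules, max(2, len(permissive)))
    module_input = norm.subset(gene_ids=permissive)
    nonconst = module_input.gene_ids[module_input.values.std(axis=1) > 0]
    module_input = module_input.subset(gene_ids=nonconst)
    adj = _modules.correlation_adjacency(module_input)
    tom = _modules.topological_overlap(adj)
    assignment = _modules.cut_modules(tom, module_input.gene_ids, n_modules)
    scores = _modules.module_scores(module_input, assignment)
    p = outdir / "module_assignment.tsv"
    assignment.to_csv(p, sep="\t")
    scores.to_csv(outdir / "module_scores.tsv", sep="\t")
    if config.module_graph_k < len(scores):
        _modules.module_knn_graph(scores, config.module_graph_k).to_csv(
            outdir / "module_graph.tsv", sep="\t", index=False
        )
    record("modules", p, scores.shape)

    # --- priority ---------------------------------------------------------
    meta = metadata.loc[norm.cells].copy()
    meta["cluster"] = labels
    factors = [f for f in (*config.priority_factors, "cluster") if f in meta.columns]
    hk = _priority.flag_housekeeping_modules(assignment, module_input.genes)
    priority = _priority.prioritize_modules(scores, meta, factors, housekeeping=hk)
    p = outdir / "module_priority.csv"
    priority.to_csv(p, index=False)
    record("priority", p, priority.shape)

    # --- optional tcr -----------------------------------------------------
    if clone_table is not None:
        calls, dominant = _tcr.classify_cells(
            clone_table, all_cells=norm.cells,
            min_count_exclusive=config.clone_min_count_exclusive,
        )
        p = outdir / "tcr_calls.csv"
        calls.to_csv(p)
        # clone frequencies grouped by cluster: only QC-kept cells have labels
        kept_dom = dominant[dominant["cell_id"].isin(labels.index)]
        _tcr.clone_frequency_table(kept_dom, labels.astype(str)).to_csv(
            outdir / "clone_frequencies.csv", index=False
        )
        record("tcr", p, (len(calls),))

    manifest = {
        "config": config.to_dict(),
        "config_sha256": hashlib.sha256(
            json.dumps(config.to_dict(), sort_keys=True).encode()
        ).hexdigest(),
        "seed": config.seed,
        "n_markers": {str(k): len(v) for k, v in markers.items()},
        "stages": stages,
        "runtime_s": round(time.time() - t_start, 3),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
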