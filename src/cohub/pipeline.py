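"""End-to-end orchestration: simulate/load -> preprocess -> network ->
hub selection -> classification -> enrichment, with a JSON run manifest.

One global seed fans out to per-stage seeds by fixed offsets so any stage
can be reproduced in isolation; the manifest echoes every resolved
configuration value plus the headline numbers of each stage (DE gene
count, chosen soft power, module count and sizes, hub count, AUCs).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from cohub import io
from cohub.classify import crossvalidated_roc
from cohub.datatypes import ExpressionMatrix, PhenotypeTable, TRAITS
from cohub.enrichment import enrichment_frame, hypergeometric_enrichment
from cohub.hubs import run_hub_selection
from cohub.network import CoexpressionAnalysis
from cohub.preprocess import (
    intersect_by_gene_id,
    merge_platforms,
    select_network_genes,
    standardize_within_platform,
    t_test_de,
)
from cohub.simulate import SyntheticConfig, generate_synthetic_study

logger = logging.getLogger(__name__)

# fixed per-stage seed offsets from the global seed
_SEED_OFFSETS = {"simulate": 0, "hubs": 1_000, "classify": 2_000}


@dataclass
class RunConfig:
    """Every tunable of the pipeline, validated before any stage runs."""

    # inputs: either explicit files or a synthetic study
    expression_paths: list[str] = field(default_factory=list)
    phenotype_path: str | None = None
    gmt_path: str | None = None
    synthetic: bool = True
    synthetic_config: SyntheticConfig = field(default_factory=SyntheticConfig)

    # preprocess
    deg_fdr: float = 0.01            # FDR for the initial DE gene list
    network_fdr: float = 0.05        # FDR for network-gene selection
    fc_cut: float = 1.5
    target_n: int = 450
    pooled_t: bool = False

    # network
    beta: int | None = None
    r2_threshold: float = 0.8
    signed: bool = False
    cut_height: float = 0.95
    min_size: int = 100
    k_scale: str = "module"
    tom_export_cutoff: float = 0.1

    # hub selection
    B: int = 1000
    alpha: float = 0.5
    lambda_rule: str = "cv"
    lam: float | None = None
    f_cut: int | None = None         # default 0.75 * B
    k_cut: float = 0.25
    gs_cut: float = 0.2
    module_alpha: float = 0.05

    # classifier
    folds: int = 10
    n_perm: int = 199

    seed: int = 0

    def validate(self) -> None:
        if not self.synthetic and not self.expression_paths:
            raise ValueError("need expression_paths when synthetic=False")
        if not (0 < self.deg_fdr <= 1 and 0 < self.network_fdr <= 1):
            raise ValueError("FDR thresholds must lie in (0, 1]")
        if self.fc_cut <= 0:
            raise ValueError("fc_cut must be positive")
        if self.target_n < 1:
            raise ValueError("target_n must be positive")
        if not (0.0 < self.cut_height <= 1.0):
            raise ValueError("cut_height must lie in (0, 1]")
        if self.min_size < 1:
            raise ValueError("min_size must be >= 1")
        if self.B < 1:
            raise ValueError("B must be >= 1")
        if not (0.0 <= self.alpha <= 1.0):
            raise ValueError("alpha must lie in [0, 1]")
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if self.synthetic:
            self.synthetic_config.validate()

    def resolved(self) -> dict:
        d = dataclasses.asdict(self)
        d["f_cut"] = self.f_cut if self.f_cut is not None else int(round(0.75 * self.B))
        return d

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        syn = raw.pop("synthetic_config", None)
        cfg = cls(**raw)
        if syn:
            cfg.synthetic_config = SyntheticConfig(**syn)
        return cfg


def _stage_seed(config: RunConfig, stage: str) -> int:
    return (config.seed + _SEED_OFFSETS[stage]) % (2**31 - 1)


def load_inputs(config: RunConfig) -> tuple[ExpressionMatrix, PhenotypeTable, object | None]:
    """Stage 0: synthetic generation or reading the declared input files."""
    if config.synthetic:
        syn = dataclasses.replace(config.synthetic_config, seed=_stage_seed(config, "simulate"))
        matrix, phenotypes, truth = generate_synthetic_study(syn)
        return matrix, phenotypes, truth
    matrices = [
        io.read_expression(p, platform_label=f"P{i + 1}")
        for i, p in enumerate(config.expression_paths)
    ]
    merged = merge_platforms(
        [standardize_within_platform(m) for m in intersect_by_gene_id(matrices)]
    )
    if config.phenotype_path is None:
        raise ValueError("phenotype_path is required for file inputs")
    phenotypes = io.read_phenotypes(config.phenotype_path).align(merged.sample_ids)
    return merged, phenotypes, None


def run_pipeline(config: RunConfig, out_dir: str | Path) -> dict:
    """Execute every stage in order, writing TSV outputs and a manifest.

    Returns the manifest dictionary (also written to ``manifest.json``).
    """
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": _jsonable(config.resolved()), "stages": {}}

    # ---- inputs ---------------------------------------------------------
    try:
        matrix, phenotypes, truth = load_inputs(config)
    except Exception as exc:
        raise RuntimeError(f"stage 'inputs' failed: {exc}") from exc
    io.write_expression(matrix, out / "expression.tsv")
    io.write_platform_map(matrix, out / "platforms.tsv")
    io.write_phenotypes(phenotypes, out / "phenotypes.tsv")
    if truth is not None:
        import pandas as pd

        pd.DataFrame(
            {
                "gene": truth.gene_ids,
                "module": truth.module_label,
                "hub_flag": truth.hub_flag.astype(int),
            }
        ).to_csv(out / "truth.tsv", sep="\t", index=False)
    manifest["stages"]["inputs"] = {
        "n_genes": matrix.n_genes,
        "n_samples": matrix.n_samples,
        "platforms": matrix.platforms,
        "n_cases": int(phenotypes.status.sum()),
    }

    # ---- preprocess -----------------------------------------------------
    try:
        if config.synthetic:
            per_platform = [
                matrix.subset_samples(np.asarray(matrix.platform) == p)
                for p in matrix.platforms
            ]
            merged = merge_platforms(
                [standardize_within_platform(m) for m in intersect_by_gene_id(per_platform)]
            )
            phenos = phenotypes.align(merged.sample_ids)
        else:
            merged, phenos = matrix, phenotypes
        de = t_test_de(merged, phenos.status, pooled=config.pooled_t)
        n_deg = sum(r.q_value < config.deg_fdr for r in de)
        genes = select_network_genes(
            de, merged,
            fdr_cut=config.network_fdr, fc_cut=config.fc_cut,
            target_n=min(config.target_n, merged.n_genes),
        )
        network_matrix = merged.subset_genes(genes)
    except Exception as exc:
        raise RuntimeError(f"stage 'preprocess' failed: {exc}") from exc
    import pandas as pd

    pd.DataFrame(
        [
            {
                "gene": r.gene, "lfc": r.log_fold_change, "t": r.t_statistic,
                "p": r.p_value, "q": r.q_value,
            }
            for r in de
        ]
    ).to_csv(out / "de.tsv", sep="\t", index=False)
    io.write_expression(network_matrix, out / "network_matrix.tsv")
    manifest["stages"]["preprocess"] = {
        "n_deg": n_deg,
        "n_network_genes": network_matrix.n_genes,
    }

    # ---- network --------------------------------------------------------
    try:
        analysis = CoexpressionAnalysis(
            network_matrix, phenos,
            beta=config.beta, r2_threshold=config.r2_threshold,
            signed=config.signed, cut_height=config.cut_height,
            min_size=config.min_size, k_scale=config.k_scale,
        )
        results = analysis.fit()
    except Exception as exc:
        raise RuntimeError(f"stage 'network' failed: {exc}") from exc
    results.partition.to_frame().to_csv(out / "modules.tsv", sep="\t", index=False)
    pd.DataFrame(results.eigengenes, index=network_matrix.sample_ids).T.to_csv(
        out / "eigengenes.tsv", sep="\t"
    )
    results.module_trait_frame().to_csv(out / "module_trait.tsv", sep="\t", index=False)
    results.gene_scores_frame().to_csv(out / "gene_scores.tsv", sep="\t", index=False)
    results.network.edge_list(config.tom_export_cutoff).to_csv(
        out / "edges.tsv", sep="\t", index=False
    )
    manifest["stages"]["network"] = {
        "beta": results.network.soft_power,
        "n_modules": len(results.partition.modules),
        "module_sizes": results.partition.sizes(),
        "n_unassigned": results.partition.module_label.count("unassigned"),
    }

    # ---- hubs -----------------------------------------------------------
    try:
        hub_result = run_hub_selection(
            results, network_matrix, phenos,
            B=config.B, alpha=config.alpha, lambda_rule=config.lambda_rule,
            lam=config.lam, f_cut=config.f_cut, k_cut=config.k_cut,
            gs_cut=config.gs_cut, module_alpha=config.module_alpha,
            seed=_stage_seed(config, "hubs"),
        )
    except Exception as exc:
        raise RuntimeError(f"stage 'hubs' failed: {exc}") from exc
    io.write_hub_table(hub_result.candidates, out / "hub_candidates.tsv")
    io.write_hub_table(hub_result.hubs, out / "hubs.tsv")
    manifest["stages"]["hubs"] = {
        "B": config.B,
        "relevant_modules": hub_result.relevant_modules,
        "n_hubs": len(hub_result.hubs),
        "hubs": [
            {"gene": r.gene, "trait": r.trait, "module": r.module,
             "f": r.f, "K": round(r.K, 4), "GS": round(r.GS, 4)}
            for r in hub_result.hubs
        ],
    }

    # ---- classify -------------------------------------------------------
    classify_stats = {}
    roc_rows = []
    try:
        for trait in TRAITS:
            hub_genes = sorted({r.gene for r in hub_result.hubs_for(trait)})
            if not hub_genes:
                continue
            y = phenos.trait(trait)
            known = ~np.isnan(y)
            yk = y[known].astype(int)
            if min(yk.sum(), yk.size - yk.sum()) < config.folds:
                raise ValueError(
                    f"trait '{trait}': folds={config.folds} exceeds minority class"
                )
            X = network_matrix.subset_genes(hub_genes).values[:, known].T
            roc = crossvalidated_roc(
                X, yk, k=config.folds, alpha=config.alpha,
                n_perm=config.n_perm, seed=_stage_seed(config, "classify"),
            )
            classify_stats[trait] = {
                "n_signature_genes": len(hub_genes),
                "auc": round(roc.auc, 4),
                "p_value": roc.p_value,
            }
            for thr, fp, tp in zip(roc.thresholds, roc.fpr, roc.tpr):
                roc_rows.append(
                    {"trait": trait, "threshold": thr, "fpr": fp, "tpr": tp}
                )
    except Exception as exc:
        raise RuntimeError(f"stage 'classify' failed: {exc}") from exc
    if roc_rows:
        pd.DataFrame(roc_rows).to_csv(out / "roc.tsv", sep="\t", index=False)
    pd.DataFrame(
        [{"trait": t, **v} for t, v in classify_stats.items()]
    ).to_csv(out / "classifier.tsv", sep="\t", index=False)
    manifest["stages"]["classify"] = classify_stats

    # ---- enrichment -----------------------------------------------------
    if config.gmt_path:
        try:
            sets = io.read_gmt(config.gmt_path)
            enr = hypergeometric_enrichment(results.partition, sets)
        except Exception as exc:
            raise RuntimeError(f"stage 'enrich' failed: {exc}") from exc
        enrichment_frame(enr).to_csv(out / "enrichment.tsv", sep="\t", index=False)
        manifest["stages"]["enrich"] = {"n_tests": len(enr)}

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj
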