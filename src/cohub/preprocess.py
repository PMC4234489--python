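"""Cross-platform merging, standardization, differential expression and
network-gene selection.

Platforms are merged on the intersection of gene identifiers and then
standardized gene-wise within platform (mean 0, SD 1, population
convention).  Per-platform standardization is the package's substitute for
model-based cross-platform normalization: it removes any gene-wise affine
(location/scale) platform distortion exactly, which is precisely the
distortion model the synthetic generator plants, at the price of also
discarding genuine platform-level location/scale biology.

Differential expression uses the two-sample t test (Welch by default,
pooled optional) with Benjamini-Hochberg FDR control; the gene set entering
the network is the union of the DE genes (q and fold-change cuts) and the
highest-variance remainder, up to a target count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from cohub.datatypes import ExpressionMatrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DifferentialExpressionResult:
    """Per-gene two-group comparison on log-scale expression."""

    gene: str
    mean_case: float
    mean_control: float
    log_fold_change: float   # mean(case) - mean(control) on the log scale
    t_statistic: float
    p_value: float
    q_value: float = float("nan")


def intersect_by_gene_id(matrices: list[ExpressionMatrix]) -> list[ExpressionMatrix]:
    """Restrict every matrix to the sorted intersection of gene identifiers.

    All returned matrices share identical row order.
    """
    if not matrices:
        raise ValueError("need at least one expression matrix")
    common = set(matrices[0].gene_ids)
    for m in matrices[1:]:
        common &= set(m.gene_ids)
    if not common:
        raise ValueError("gene identifier intersection across platforms is empty")
    order = sorted(common)
    return [m.subset_genes(order) for m in matrices]


def standardize_within_platform(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Z-score every gene within each platform (population SD, divisor n).

    Constant rows map to all-zero with a warning.  This removes gene-wise
    affine platform effects exactly (see module docstring).
    """
    values = matrix.values.copy()
    platform = np.asarray(matrix.platform)
    n_constant = 0
    for label in matrix.platforms:
        cols = np.flatnonzero(platform == label)
        if cols.size < 2:
            raise ValueError(f"platform '{label}' has a single sample; cannot standardize")
        block = values[:, cols]
        mean = block.mean(axis=1, keepdims=True)
        sd = block.std(axis=1, keepdims=True)  # population convention
        constant = (sd == 0).ravel()
        n_constant += int(constant.sum())
        sd[sd == 0] = 1.0
        values[:, cols] = (block - mean) / sd
    if n_constant:
        logger.warning("standardize: %d constant gene rows mapped to zero", n_constant)
    return ExpressionMatrix(
        gene_ids=list(matrix.gene_ids),
        sample_ids=list(matrix.sample_ids),
        platform=list(matrix.platform),
        values=values,
    )


def merge_platforms(matrices: list[ExpressionMatrix]) -> ExpressionMatrix:
    """Column-concatenate per-platform matrices sharing identical gene order.

    Sample-identifier collisions across platforms are resolved by prefixing
    with the platform label ("P1:s1").
    """
    if not matrices:
        raise ValueError("need at least one expression matrix")
    gene_ids = matrices[0].gene_ids
    for m in matrices[1:]:
        if m.gene_ids != gene_ids:
            raise ValueError("matrices do not share identical gene order; intersect first")
    if len(matrices) == 1:
        return matrices[0].copy()

    seen: dict[str, int] = {}
    for m in matrices:
        for s in m.sample_ids:
            seen[s] = seen.get(s, 0) + 1
    sample_ids: list[str] = []
    platform: list[str] = []
    for m in matrices:
        for s, p in zip(m.sample_ids, m.platform):
            sample_ids.append(f"{p}:{s}" if seen[s] > 1 else s)
            platform.append(p)
    values = np.concatenate([m.values for m in matrices], axis=1)
    return ExpressionMatrix(
        gene_ids=list(gene_ids), sample_ids=sample_ids, platform=platform, values=values
    )


def t_test_de(
    matrix: ExpressionMatrix,
    status: np.ndarray,
    pooled: bool = False,
) -> list[DifferentialExpressionResult]:
    """Two-sample t test per gene, case (status 1) versus control (status 0).

    Welch's unequal-variance statistic by default (``pooled=True`` for the
    classic equal-variance version).  The log fold change is the difference
    of group means on the log scale.  Degenerate all-constant genes with
    equal means give t = 0, p = 1; perfect separation with zero variance
    gives the p -> 0 sentinel.
    """
    status = np.asarray(status)
    case = matrix.values[:, status == 1]
    control = matrix.values[:, status == 0]
    if case.shape[1] < 2 or control.shape[1] < 2:
        raise ValueError("need at least 2 samples per group for the t test")

    t, p = stats.ttest_ind(case, control, axis=1, equal_var=pooled)
    mean_case = case.mean(axis=1)
    mean_control = control.mean(axis=1)
    lfc = mean_case - mean_control

    # zero within-group variance: scipy yields nan; resolve by mean equality
    degenerate = ~np.isfinite(t)
    with np.errstate(invalid="ignore"):
        t = np.where(degenerate & (lfc == 0), 0.0, t)
        p = np.where(degenerate & (lfc == 0), 1.0, p)
        t = np.where(degenerate & (lfc != 0), np.sign(lfc) * np.inf, t)
        p = np.where(degenerate & (lfc != 0), 0.0, p)

    q = bh_fdr(list(p))
    return [
        DifferentialExpressionResult(
            gene=g,
            mean_case=float(mean_case[i]),
            mean_control=float(mean_control[i]),
            log_fold_change=float(lfc[i]),
            t_statistic=float(t[i]),
            p_value=float(p[i]),
            q_value=float(q[i]),
        )
        for i, g in enumerate(matrix.gene_ids)
    ]


def bh_fdr(p_values: list[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values (order-preserving)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)) or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return [float(x) for x in q]


def select_network_genes(
    de: list[DifferentialExpressionResult],
    matrix: ExpressionMatrix,
    fdr_cut: float = 0.05,
    fc_cut: float = 1.5,
    target_n: int = 4500,
    fc_is_log: bool = False,
) -> list[str]:
    """Choose the genes entering network construction.

    All genes with q < ``fdr_cut`` and |fold change| > ``fc_cut`` are kept;
    remaining slots up to ``target_n`` are filled by descending overall
    variance.  ``fc_cut`` is on the natural scale by default and compared
    against log2(fc_cut) on the log-scale fold changes (set ``fc_is_log``
    if the cut is already a log2 difference).  If the DE genes alone exceed
    ``target_n`` they are all kept (logged).
    """
    if target_n > matrix.n_genes:
        raise ValueError("target_n exceeds the number of available genes")
    lfc_cut = fc_cut if fc_is_log else np.log2(fc_cut)
    de_genes = [
        r.gene for r in de if r.q_value < fdr_cut and abs(r.log_fold_change) > lfc_cut
    ]
    de_set = set(de_genes)
    if len(de_genes) >= target_n:
        logger.warning(
            "select_network_genes: %d DE genes exceed target %d; keeping all",
            len(de_genes), target_n,
        )
        return de_genes

    variances = matrix.values.var(axis=1, ddof=1)
    order = np.argsort(-variances, kind="stable")
    fill = [matrix.gene_ids[i] for i in order if matrix.gene_ids[i] not in de_set]
    return de_genes + fill[: target_n - len(de_genes)]
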