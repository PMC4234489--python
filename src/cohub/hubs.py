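"""Bootstrap elastic-net selection frequency and the hub-gene triage rule.

For each trait, the member genes of the trait-associated modules are
offered to an elastic-net logistic model of the trait; the samples are
resampled with replacement B times (default 1000, stratified by class)
and the selection frequency f of a gene is the number of resamples in
which its coefficient is nonzero.  A (gene, trait) pair is called a hub
when, within a trait-relevant module,

    f > f_cut  and  K > k_cut  and  GS > gs_cut      (strict inequalities)

with default cuts f > 750 (of B = 1000), K > 0.25 and GS > 0.2.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from cohub.datatypes import ExpressionMatrix, HubScoreRow, PhenotypeTable, TRAITS
from cohub.elasticnet import ElasticNetLogistic
from cohub.network import CoexpressionResults, GeneNetworkScores

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class BootstrapSelectionResult:
    """Selection count of one gene for one trait over B bootstrap resamples."""

    gene: str
    trait: str
    f: int
    B: int

    def __post_init__(self) -> None:
        if not (0 <= self.f <= self.B):
            raise ValueError(f"f={self.f} outside [0, B={self.B}]")


def bootstrap_selection_frequency(
    X: np.ndarray,
    y: np.ndarray,
    gene_ids: list[str],
    trait: str,
    B: int = 1000,
    alpha: float = 0.5,
    lambda_rule: str = "cv",
    lam: float | None = None,
    seed: int = 0,
    stratified: bool = True,
    n_folds: int = 5,
    n_lambdas: int = 10,
    tol: float = 1e-4,
) -> list[BootstrapSelectionResult]:
    """Selection frequency f per gene over B bootstrap resamples.

    Parameters
    ----------
    X : ndarray, samples x genes
    y : 0/1 labels (no unknowns)
    lambda_rule : {"cv", "fixed"}
        "cv": the penalty is re-chosen on every resample by internal
        stratified cross-validated deviance (the default); "fixed": use
        ``lam`` on every resample (fast mode).
    stratified : bool
        Resample within each class so every replicate is fittable; when
        False, plain resampling is used and degenerate one-class
        replicates are redrawn (counted and logged).

    ``tol`` is the solver tolerance used inside the bootstrap; only the
    active set matters for f, so it is looser than the fitting default.
    Deterministic for a fixed seed.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if lambda_rule not in {"cv", "fixed"}:
        raise ValueError("lambda_rule must be 'cv' or 'fixed'")
    if lambda_rule == "fixed" and lam is None:
        raise ValueError("lambda_rule='fixed' requires lam")
    rng = np.random.default_rng(seed)
    n = y.size
    idx_pos = np.flatnonzero(y == 1)
    idx_neg = np.flatnonzero(y == 0)

    counts = np.zeros(X.shape[1], dtype=int)
    n_redrawn = 0
    for b in range(B):
        while True:
            if stratified:
                take = np.concatenate(
                    [
                        rng.choice(idx_pos, size=idx_pos.size, replace=True),
                        rng.choice(idx_neg, size=idx_neg.size, replace=True),
                    ]
                )
            else:
                take = rng.choice(n, size=n, replace=True)
            yb = y[take]
            if 0 < yb.sum() < yb.size:
                break
            n_redrawn += 1
        model = ElasticNetLogistic(X[take], yb, alpha=alpha, tol=tol)
        if lambda_rule == "fixed":
            fit = model.fit(lam)
        else:
            fit = model.fit_cv(
                n_folds=min(n_folds, int(min(yb.sum(), yb.size - yb.sum()))),
                n_lambdas=n_lambdas,
                seed=int(rng.integers(2**31 - 1)),
            )
        counts[fit.nonzero] += 1
    if n_redrawn:
        logger.info("bootstrap: redrew %d degenerate one-class resamples", n_redrawn)
    return [
        BootstrapSelectionResult(gene=g, trait=trait, f=int(c), B=B)
        for g, c in zip(gene_ids, counts)
    ]


def select_hub_genes(
    scores: list[GeneNetworkScores],
    freqs: list[BootstrapSelectionResult],
    f_cut: int = 750,
    k_cut: float = 0.25,
    gs_cut: float = 0.2,
    relevant_modules: dict[str, list[str]] | None = None,
) -> list[HubScoreRow]:
    """Apply the (f, K, GS) triage rule; returns hubs sorted by descending f.

    ``relevant_modules`` maps each trait to the modules whose eigengene is
    significantly associated with it; (gene, trait) pairs outside those
    modules are never hubs.  When omitted, all modules are eligible.
    """
    if not (0.0 <= k_cut <= 1.0 and 0.0 <= gs_cut <= 1.0):
        raise ValueError("K and GS cuts must lie in [0, 1]")
    by_gene = {s.gene: s for s in scores}
    rows: list[HubScoreRow] = []
    for fr in freqs:
        s = by_gene.get(fr.gene)
        if s is None or s.module == "unassigned":
            continue
        if relevant_modules is not None and s.module not in relevant_modules.get(fr.trait, []):
            continue
        gs = s.GS.get(fr.trait, float("nan"))
        if np.isnan(gs) or np.isnan(s.K):
            continue
        row = HubScoreRow(
            gene=fr.gene, trait=fr.trait, module=s.module,
            f=fr.f, K=s.K, GS=gs, B=fr.B,
        )
        if row.passes(f_cut, k_cut, gs_cut):
            rows.append(row)
    rows.sort(key=lambda r: (-r.f, r.trait, r.gene))
    return rows


def apply_hub_cuts(
    rows: list[HubScoreRow],
    f_cut: int = 750,
    k_cut: float = 0.25,
    gs_cut: float = 0.2,
) -> list[HubScoreRow]:
    """Triage pre-scored (f, K, GS) rows, e.g. a published hub table."""
    kept = [r for r in rows if r.passes(f_cut, k_cut, gs_cut)]
    kept.sort(key=lambda r: (-r.f, r.trait, r.gene))
    return kept


@dataclass
class HubSelectionResult:
    """All scored candidates plus the hub calls for one study."""

    candidates: list[HubScoreRow]
    hubs: list[HubScoreRow]
    relevant_modules: dict[str, list[str]]
    B: int

    def hubs_for(self, trait: str) -> list[HubScoreRow]:
        return [r for r in self.hubs if r.trait == trait]


def run_hub_selection(
    results: CoexpressionResults,
    matrix: ExpressionMatrix,
    phenotypes: PhenotypeTable,
    B: int = 1000,
    alpha: float = 0.5,
    lambda_rule: str = "cv",
    lam: float | None = None,
    f_cut: int | None = None,
    k_cut: float = 0.25,
    gs_cut: float = 0.2,
    module_alpha: float = 0.05,
    seed: int = 0,
) -> HubSelectionResult:
    """Full hub-gene screen over every trait-relevant module.

    For each trait, modules with Bonferroni-adjusted eigengene-trait
    p < ``module_alpha`` are screened: the module's member genes enter a
    bootstrap elastic net against the trait (known-trait samples only),
    and the (f, K, GS) cuts are applied.  ``f_cut`` defaults to the upper
    quartile of B (0.75 * B, i.e. 750 of 1000).
    """
    if f_cut is None:
        f_cut = int(round(0.75 * B))
    pheno = phenotypes.align(matrix.sample_ids)
    relevant = {t: results.trait_relevant_modules(t, alpha=module_alpha) for t in TRAITS}
    rng = np.random.default_rng(seed)

    candidates: list[HubScoreRow] = []
    all_freqs: list[BootstrapSelectionResult] = []
    for trait in TRAITS:
        y = pheno.trait(trait)
        known = ~np.isnan(y)
        for module in relevant[trait]:
            members = results.partition.members(module)
            if int(y[known].sum()) < 2 or int((1 - y[known]).sum()) < 2:
                logger.warning("trait %s: too few labelled samples; skipped", trait)
                continue
            sub = matrix.subset_genes(members)
            freqs = bootstrap_selection_frequency(
                sub.values[:, known].T,
                y[known],
                gene_ids=members,
                trait=trait,
                B=B,
                alpha=alpha,
                lambda_rule=lambda_rule,
                lam=lam,
                seed=int(rng.integers(2**31 - 1)),
            )
            all_freqs.extend(freqs)
            candidates.extend(
                select_hub_genes(
                    results.gene_scores, freqs,
                    f_cut=-1, k_cut=0.0, gs_cut=0.0,   # no cuts: keep all scored pairs
                    relevant_modules={trait: [module]},
                )
            )
    hubs = apply_hub_cuts(candidates, f_cut=f_cut, k_cut=k_cut, gs_cut=gs_cut)
    return HubSelectionResult(candidates=candidates, hubs=hubs, relevant_modules=relevant, B=B)
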