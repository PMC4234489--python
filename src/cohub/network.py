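"""Weighted gene co-expression network construction and module statistics.

The pipeline's network stage follows the standard weighted co-expression
recipe: Pearson correlation across samples; soft-threshold adjacency
a_ij = |cor_ij|^beta (unsigned by default) with beta chosen by the
scale-free-topology fit; the topological overlap measure

    TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij),
    l_ij = sum_u a_iu * a_uj,   k_i = sum_{u != i} a_iu;

average-linkage clustering of the dissimilarity 1 - TOM; a static cut of
the dendrogram at a fixed height (default 0.95) with a minimum module size
(default 100); module eigengenes (first principal component of the
standardized member submatrix); eigengene-trait Pearson correlations with
Bonferroni adjustment across module x trait tests; and per-gene scaled
intramodular connectivity K and gene significance GS.

`CoexpressionAnalysis` wraps the stage as a model object whose ``fit()``
returns a :class:`CoexpressionResults` carrying the network, partition,
eigengenes, module-trait table and gene scores.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from cohub.datatypes import ExpressionMatrix, PhenotypeTable, TRAITS

logger = logging.getLogger(__name__)

#: Display aliases for modules in size order, following the conventional
#: color sequence used in co-expression analyses.
MODULE_COLORS = (
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan", "midnightblue",
)


# ---------------------------------------------------------------------------
# primitive operations

def correlation_matrix(matrix: ExpressionMatrix) -> np.ndarray:
    """Gene-gene Pearson correlation across samples (unit diagonal)."""
    if matrix.n_samples < 3:
        raise ValueError("need at least 3 samples for a correlation network")
    sd = matrix.values.std(axis=1)
    if (sd == 0).any():
        bad = matrix.gene_ids[int(np.argmax(sd == 0))]
        raise ValueError(f"constant expression row for gene '{bad}'")
    cor = np.corrcoef(matrix.values)
    cor = np.clip((cor + cor.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(cor, 1.0)
    return cor


def adjacency_from_correlation(cor: np.ndarray, beta: int, signed: bool = False) -> np.ndarray:
    """Soft-threshold adjacency: |cor|^beta (unsigned) or ((1+cor)/2)^beta."""
    if beta < 1:
        raise ValueError("soft power beta must be >= 1")
    adj = ((1.0 + cor) / 2.0) ** beta if signed else np.abs(cor) ** beta
    np.fill_diagonal(adj, 1.0)
    return adj


def scale_free_fit(adjacency: np.ndarray, n_bins: int = 10) -> float:
    """Signed R^2 of the scale-free-topology fit of the connectivity law.

    Bins the connectivity distribution, regresses log10(frequency) on
    log10(mean bin connectivity) and returns R^2 when the slope is
    negative (0 otherwise, since scale-free topology requires a decreasing
    law).  Returns NaN when fewer than 3 non-empty bins exist.
    """
    k = adjacency.sum(axis=0) - np.diag(adjacency)
    if np.allclose(k.max(), k.min()):
        return float("nan")
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    which = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    mean_k = np.array([k[which == b].mean() if (which == b).any() else np.nan for b in range(n_bins)])
    freq = np.array([(which == b).mean() for b in range(n_bins)])
    ok = ~np.isnan(mean_k) & (freq > 0) & (mean_k > 0)
    if ok.sum() < 3:
        return float("nan")
    x, y = np.log10(mean_k[ok]), np.log10(freq[ok])
    slope, _, r, _, _ = stats.linregress(x, y)
    return float(r**2) if slope < 0 else 0.0


def _fallback_power(n_samples: int | None, signed: bool) -> int:
    """Conventional default soft power by sample size (doubled if signed)."""
    if n_samples is None or n_samples > 40:
        base = 6
    elif n_samples > 30:
        base = 8
    elif n_samples > 20:
        base = 9
    else:
        base = 10
    return 2 * base if signed else base


def pick_soft_power(
    cor: np.ndarray,
    candidates: list[int] | None = None,
    r2_threshold: float = 0.8,
    signed: bool = False,
    n_samples: int | None = None,
    min_mean_connectivity: float = 5.0,
) -> int:
    """Smallest soft power with a *sustained* scale-free fit.

    Two robustness guards temper the raw criterion.  First, candidates
    whose mean connectivity falls below ``min_mean_connectivity`` are
    excluded: as the power grows the network empties, its binned
    connectivity histogram looks spuriously scale-free, and no module of
    meaningful size can survive.  Second, the binned R^2 is a noisy
    statistic, so a single candidate crossing ``r2_threshold`` is not
    trusted: the fit must hold at the candidate and its successor (the
    final candidate needs no successor).  When no candidate qualifies —
    networks dominated by a few planted modules are genuinely not
    scale-free — the conventional sample-size default power is used
    (6 for unsigned networks with > 40 samples) with a warning, rather
    than chasing the noisiest bin regression.
    """
    if candidates is None:
        candidates = list(range(1, 21))
    if not candidates:
        raise ValueError("no candidate powers")
    if not (0.0 < r2_threshold < 1.0):
        raise ValueError("r2_threshold must lie in (0, 1)")
    fits = []
    mean_k = []
    for beta in candidates:
        adj = adjacency_from_correlation(cor, beta, signed=signed)
        fits.append(scale_free_fit(adj))
        mean_k.append(float((adj.sum(axis=0) - np.diag(adj)).mean()))
    good = [
        not np.isnan(r2) and r2 >= r2_threshold and k >= min_mean_connectivity
        for r2, k in zip(fits, mean_k)
    ]
    for i, beta in enumerate(candidates):
        if good[i] and (i + 1 == len(candidates) or good[i + 1]):
            return beta
    fallback = _fallback_power(n_samples, signed)
    logger.warning(
        "pick_soft_power: no sustained scale-free fit at R2 >= %.2f "
        "(best %.3f); using default beta=%d",
        r2_threshold,
        max((r2 for r2 in fits if not np.isnan(r2)), default=float("nan")),
        fallback,
    )
    return fallback


def tom_from_adjacency(adjacency: np.ndarray) -> np.ndarray:
    """Topological overlap of a symmetric adjacency in [0,1] with unit diagonal."""
    A = np.asarray(adjacency, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("adjacency must be square")
    if not np.allclose(A, A.T, atol=1e-12):
        raise ValueError("adjacency must be symmetric")
    A0 = A.copy()
    np.fill_diagonal(A0, 0.0)
    L = A0 @ A0                      # shared-neighbor weight l_ij
    k = A0.sum(axis=0)
    denom = np.minimum.outer(k, k) + 1.0 - A0
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = (L + A0) / denom
    tom[denom == 0] = 0.0
    tom = np.clip((tom + tom.T) / 2.0, 0.0, 1.0)
    np.fill_diagonal(tom, 1.0)
    return tom


def average_linkage_dendrogram(dissimilarity: np.ndarray) -> np.ndarray:
    """Average-linkage (UPGMA) merge tree of a symmetric dissimilarity.

    Returns the standard 4-column linkage matrix (scipy convention).
    """
    D = np.asarray(dissimilarity, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("dissimilarity must be square")
    condensed = squareform(np.clip((D + D.T) / 2.0, 0.0, None), checks=False)
    return linkage(condensed, method="average")


@dataclass
class ModulePartition:
    """Static-cut module assignment with deterministic size-ranked names."""

    gene_ids: list[str]
    module_label: list[str]          # "M1", "M2", ... or "unassigned"
    merge_heights: np.ndarray
    cut_height: float
    min_size: int

    @property
    def modules(self) -> list[str]:
        out = []
        for lab in self.module_label:
            if lab != "unassigned" and lab not in out:
                out.append(lab)
        return sorted(out, key=lambda m: int(m[1:]))

    def members(self, module: str) -> list[str]:
        return [g for g, m in zip(self.gene_ids, self.module_label) if m == module]

    def sizes(self) -> dict[str, int]:
        return {m: len(self.members(m)) for m in self.modules}

    def color_alias(self) -> dict[str, str]:
        """Conventional color names for modules, in size order."""
        mods = self.modules
        return {
            m: (MODULE_COLORS[i] if i < len(MODULE_COLORS) else f"color{i + 1}")
            for i, m in enumerate(mods)
        }

    def to_frame(self) -> pd.DataFrame:
        colors = self.color_alias()
        return pd.DataFrame(
            {
                "gene": self.gene_ids,
                "module": self.module_label,
                "color": [colors.get(m, "grey") for m in self.module_label],
            }
        )


def static_cut_modules(
    dendrogram: np.ndarray,
    gene_ids: list[str],
    cut_height: float,
    min_size: int,
) -> ModulePartition:
    """Cut the merge tree at a fixed height and drop undersized clusters.

    Clusters are the connected components of merges at height <=
    ``cut_height``; those with fewer than ``min_size`` members become
    "unassigned".  Surviving modules are named M1, M2, ... by decreasing
    size (ties broken by smallest member index).
    """
    if not (0.0 < cut_height <= 1.0):
        raise ValueError("cut_height must lie in (0, 1]")
    if min_size < 1:
        raise ValueError("min_size must be >= 1")
    raw = fcluster(dendrogram, t=cut_height, criterion="distance")
    clusters: dict[int, list[int]] = {}
    for i, c in enumerate(raw):
        clusters.setdefault(int(c), []).append(i)
    big = [idx for idx in clusters.values() if len(idx) >= min_size]
    big.sort(key=lambda idx: (-len(idx), min(idx)))
    labels = ["unassigned"] * len(gene_ids)
    for rank, idx in enumerate(big, start=1):
        for i in idx:
            labels[i] = f"M{rank}"
    return ModulePartition(
        gene_ids=list(gene_ids),
        module_label=labels,
        merge_heights=dendrogram[:, 2].copy(),
        cut_height=cut_height,
        min_size=min_size,
    )


def module_eigengene(matrix: ExpressionMatrix, members: list[str]) -> np.ndarray:
    """First principal component of the standardized member submatrix.

    Unit-length per-sample vector, sign-oriented so that its correlation
    with the members' mean standardized profile is non-negative.
    """
    if len(members) < 2:
        raise ValueError("module eigengene needs at least 2 member genes")
    if matrix.n_samples < 3:
        raise ValueError("module eigengene needs at least 3 samples")
    sub = matrix.subset_genes(members).values
    mean = sub.mean(axis=1, keepdims=True)
    sd = sub.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    Z = (sub - mean) / sd
    _, _, vt = np.linalg.svd(Z, full_matrices=False)
    eig = vt[0]
    reference = Z.mean(axis=0)
    if np.dot(eig, reference) < 0:
        eig = -eig
    return eig


@dataclass(frozen=True)
class ModuleTraitResult:
    """Eigengene-trait Pearson correlation with Bonferroni adjustment."""

    module: str
    trait: str
    r: float
    p_raw: float
    p_adjusted: float
    n: int
    computable: bool = True


def module_trait_correlation(
    eigengene: np.ndarray,
    trait: np.ndarray,
    n_tests: int = 1,
    module: str = "",
    trait_name: str = "",
) -> ModuleTraitResult:
    """Pearson correlation of an eigengene with a partially observed trait.

    Unknown (NaN) samples are excluded; the two-sided p-value comes from
    the t transform t = r * sqrt((n-2) / (1-r^2)); Bonferroni adjustment
    multiplies by ``n_tests``.  Fewer than 3 known samples (or a constant
    trait) yields a not-computable result.
    """
    trait = np.asarray(trait, dtype=float)
    known = ~np.isnan(trait)
    n = int(known.sum())
    if n < 3 or len(set(trait[known])) < 2 or np.std(eigengene[known]) == 0:
        return ModuleTraitResult(module, trait_name, float("nan"), float("nan"),
                                 float("nan"), n, computable=False)
    r = float(np.corrcoef(eigengene[known], trait[known])[0, 1])
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
        p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
    return ModuleTraitResult(
        module=module,
        trait=trait_name,
        r=r,
        p_raw=p,
        p_adjusted=min(1.0, p * n_tests),
        n=n,
    )


@dataclass
class CoexpressionNetwork:
    """Adjacency, topological overlap and connectivity of one network."""

    gene_ids: list[str]
    adjacency: np.ndarray
    tom: np.ndarray
    soft_power: int
    signed: bool = False

    @property
    def connectivity(self) -> np.ndarray:
        """Whole-network connectivity k_i = sum_{j != i} a_ij."""
        return self.adjacency.sum(axis=0) - np.diag(self.adjacency)

    def edge_list(self, cutoff: float = 0.0) -> pd.DataFrame:
        """Upper-triangle (gene1, gene2, tom) edges with TOM > ``cutoff``."""
        iu, ju = np.triu_indices(len(self.gene_ids), k=1)
        w = self.tom[iu, ju]
        keep = w > cutoff
        return pd.DataFrame(
            {
                "gene1": [self.gene_ids[i] for i in iu[keep]],
                "gene2": [self.gene_ids[j] for j in ju[keep]],
                "tom": w[keep],
            }
        )


@dataclass(frozen=True)
class GeneNetworkScores:
    """Per-gene scaled connectivity and gene significance."""

    gene: str
    module: str
    K: float                      # scaled (intramodular) connectivity
    GS: dict[str, float]          # trait -> |cor(expression, trait)|


def gene_network_scores(
    matrix: ExpressionMatrix,
    network: CoexpressionNetwork,
    partition: ModulePartition,
    phenotypes: PhenotypeTable,
    scale: str = "module",
) -> list[GeneNetworkScores]:
    """Scaled connectivity K and gene significance GS for every gene.

    K is the gene's connectivity divided by the maximum, computed within
    its module by default (``scale="module"``; hubs are defined by their
    intramodular centrality) or over the whole network
    (``scale="network"``).  GS(trait) is the absolute Pearson correlation
    of the gene's expression with the trait over known-trait samples.
    Unassigned genes carry K = NaN under module scaling.
    """
    if network.gene_ids != partition.gene_ids or network.gene_ids != matrix.gene_ids:
        raise ValueError("matrix, network and partition must cover the same genes in order")
    pheno = phenotypes.align(matrix.sample_ids)

    n = len(network.gene_ids)
    K = np.full(n, np.nan)
    if scale == "network":
        k = network.connectivity
        K = k / k.max() if k.max() > 0 else np.zeros(n)
    elif scale == "module":
        labels = np.asarray(partition.module_label)
        for module in partition.modules:
            idx = np.flatnonzero(labels == module)
            sub = network.adjacency[np.ix_(idx, idx)]
            k = sub.sum(axis=0) - np.diag(sub)
            K[idx] = k / k.max() if k.max() > 0 else 0.0
    else:
        raise ValueError("scale must be 'module' or 'network'")

    gs: dict[str, np.ndarray] = {}
    for trait in TRAITS:
        y = pheno.trait(trait)
        known = ~np.isnan(y)
        col = np.full(n, np.nan)
        if known.sum() >= 3 and len(set(y[known])) == 2:
            X = matrix.values[:, known]
            yk = y[known]
            Xc = X - X.mean(axis=1, keepdims=True)
            yc = yk - yk.mean()
            denom = np.sqrt((Xc**2).sum(axis=1) * (yc**2).sum())
            with np.errstate(invalid="ignore", divide="ignore"):
                col = np.abs(Xc @ yc / denom)
            col[denom == 0] = np.nan
        gs[trait] = np.clip(col, 0.0, 1.0)

    return [
        GeneNetworkScores(
            gene=g,
            module=partition.module_label[i],
            K=float(K[i]),
            GS={t: float(gs[t][i]) for t in TRAITS},
        )
        for i, g in enumerate(network.gene_ids)
    ]


# ---------------------------------------------------------------------------
# model / results facade

class CoexpressionAnalysis:
    """Weighted co-expression network model for one expression study.

    Parameters
    ----------
    matrix : ExpressionMatrix
        Preprocessed (merged, standardized) expression.
    phenotypes : PhenotypeTable, optional
        Sample traits for eigengene-trait statistics and GS.
    beta : int, optional
        Soft power; chosen by the scale-free criterion when omitted.
    signed : bool
        Signed adjacency ((1+cor)/2)^beta instead of |cor|^beta.
    cut_height, min_size
        Static-cut parameters of the 1-TOM dendrogram.
    """

    def __init__(
        self,
        matrix: ExpressionMatrix,
        phenotypes: PhenotypeTable | None = None,
        beta: int | None = None,
        beta_candidates: list[int] | None = None,
        r2_threshold: float = 0.8,
        signed: bool = False,
        cut_height: float = 0.95,
        min_size: int = 100,
        k_scale: str = "module",
    ) -> None:
        self.matrix = matrix
        self.phenotypes = phenotypes
        self.beta = beta
        self.beta_candidates = beta_candidates
        self.r2_threshold = r2_threshold
        self.signed = signed
        self.cut_height = cut_height
        self.min_size = min_size
        self.k_scale = k_scale

    def fit(self) -> "CoexpressionResults":
        cor = correlation_matrix(self.matrix)
        beta = self.beta
        if beta is None:
            beta = pick_soft_power(
                cor, self.beta_candidates, self.r2_threshold,
                signed=self.signed, n_samples=self.matrix.n_samples,
            )
        adjacency = adjacency_from_correlation(cor, beta, signed=self.signed)
        tom = tom_from_adjacency(adjacency)
        network = CoexpressionNetwork(
            gene_ids=list(self.matrix.gene_ids),
            adjacency=adjacency,
            tom=tom,
            soft_power=beta,
            signed=self.signed,
        )
        dendrogram = average_linkage_dendrogram(1.0 - tom)
        partition = static_cut_modules(
            dendrogram, self.matrix.gene_ids, self.cut_height, self.min_size
        )

        eigengenes: dict[str, np.ndarray] = {
            m: module_eigengene(self.matrix, partition.members(m)) for m in partition.modules
        }

        module_trait: list[ModuleTraitResult] = []
        scores: list[GeneNetworkScores] = []
        if self.phenotypes is not None:
            pheno = self.phenotypes.align(self.matrix.sample_ids)
            n_tests = max(1, len(partition.modules) * len(TRAITS))
            for m in partition.modules:
                for trait in TRAITS:
                    module_trait.append(
                        module_trait_correlation(
                            eigengenes[m], pheno.trait(trait), n_tests,
                            module=m, trait_name=trait,
                        )
                    )
            scores = gene_network_scores(
                self.matrix, network, partition, pheno, scale=self.k_scale
            )
        return CoexpressionResults(
            model=self,
            network=network,
            dendrogram=dendrogram,
            partition=partition,
            eigengenes=eigengenes,
            module_trait=module_trait,
            gene_scores=scores,
        )


@dataclass
class CoexpressionResults:
    """Fitted co-expression network: modules, eigengenes and statistics."""

    model: CoexpressionAnalysis
    network: CoexpressionNetwork
    dendrogram: np.ndarray
    partition: ModulePartition
    eigengenes: dict[str, np.ndarray]
    module_trait: list[ModuleTraitResult] = field(default_factory=list)
    gene_scores: list[GeneNetworkScores] = field(default_factory=list)

    def module_trait_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "module": r.module, "trait": r.trait, "r": r.r,
                    "p_raw": r.p_raw, "p_adjusted": r.p_adjusted,
                    "n": r.n, "computable": r.computable,
                }
                for r in self.module_trait
            ]
        )

    def gene_scores_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.gene_scores:
            row = {"gene": s.gene, "module": s.module, "K": s.K}
            row.update({f"GS_{t}": s.GS[t] for t in TRAITS})
            rows.append(row)
        return pd.DataFrame(rows)

    def trait_relevant_modules(self, trait: str, alpha: float = 0.05) -> list[str]:
        """Modules whose eigengene-trait Bonferroni-adjusted p is below alpha."""
        return [
            r.module
            for r in self.module_trait
            if r.trait == trait and r.computable and r.p_adjusted < alpha
        ]

    def summary(self) -> str:
        sizes = self.partition.sizes()
        colors = self.partition.color_alias()
        lines = [
            "Weighted co-expression network analysis",
            "=" * 47,
            f"genes: {len(self.network.gene_ids)}   "
            f"samples: {self.model.matrix.n_samples}   "
            f"soft power beta: {self.network.soft_power} "
            f"({'signed' if self.network.signed else 'unsigned'})",
            f"static cut: height {self.partition.cut_height}, "
            f"min size {self.partition.min_size}",
            f"modules: {len(sizes)} "
            f"(unassigned genes: {self.partition.module_label.count('unassigned')})",
        ]
        for m in self.partition.modules:
            lines.append(f"  {m} ({colors[m]}): {sizes[m]} genes")
        if self.module_trait:
            lines.append("")
            lines.append("module-trait correlations (Pearson r, Bonferroni-adjusted p):")
            for r in self.module_trait:
                if r.computable:
                    lines.append(
                        f"  {r.module:>4} x {r.trait:<6} r={r.r:+.3f}  "
                        f"p_adj={r.p_adjusted:.2e}  (n={r.n})"
                    )
                else:
                    lines.append(f"  {r.module:>4} x {r.trait:<6} not computable (n={r.n})")
        return "\n".join(lines)
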