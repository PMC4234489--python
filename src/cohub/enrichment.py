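"""Hypergeometric gene-set over-representation for network modules.

For a module of size m drawn from a universe of size N, and a gene set
with s members in the universe, the over-representation p-value of an
overlap of x genes is the upper hypergeometric tail

    p = P(X >= x),   X ~ Hypergeometric(N, s, m).

Raw p-values are Bonferroni-adjusted across all module x set tests and
BH-adjusted within each module.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from cohub.datatypes import GeneSetCollection
from cohub.network import ModulePartition
from cohub.preprocess import bh_fdr


@dataclass(frozen=True)
class EnrichmentResult:
    module: str
    set_name: str
    overlap: int
    module_size: int
    set_size: int
    universe_size: int
    p_raw: float
    p_bonferroni: float
    q_bh: float


def hypergeometric_tail(overlap: int, universe: int, set_size: int, module_size: int) -> float:
    """Upper tail P(X >= overlap) of the hypergeometric overlap law."""
    if overlap == 0:
        return 1.0
    return float(stats.hypergeom.sf(overlap - 1, universe, set_size, module_size))


def hypergeometric_enrichment(
    partition: ModulePartition,
    sets: GeneSetCollection,
    universe: list[str] | None = None,
) -> list[EnrichmentResult]:
    """Over-representation of every gene set in every module.

    ``universe`` defaults to all genes in the partition (assigned or not);
    it must cover every module gene.  Sets are intersected with the
    universe before testing; sets with no universe members are dropped.
    """
    if universe is None:
        universe = list(partition.gene_ids)
    universe_set = set(universe)
    if not universe_set:
        raise ValueError("empty gene universe")
    module_genes = {g for g, m in zip(partition.gene_ids, partition.module_label)
                    if m != "unassigned"}
    if not module_genes <= universe_set:
        raise ValueError("universe does not cover all module genes")
    restricted = sets.restrict_to(universe_set)

    records = []
    for module in partition.modules:
        members = set(partition.members(module))
        for name, set_members in sorted(restricted.sets.items()):
            overlap = len(members & set_members)
            records.append(
                {
                    "module": module,
                    "set_name": name,
                    "overlap": overlap,
                    "module_size": len(members),
                    "set_size": len(set_members),
                    "p_raw": hypergeometric_tail(
                        overlap, len(universe_set), len(set_members), len(members)
                    ),
                }
            )
    if not records:
        return []
    n_tests = len(records)
    q_by_module: dict[str, list[float]] = {}
    for module in partition.modules:
        ps = [r["p_raw"] for r in records if r["module"] == module]
        q_by_module[module] = bh_fdr(ps)
    counters = {m: 0 for m in partition.modules}
    out = []
    for r in records:
        m = r["module"]
        q = q_by_module[m][counters[m]]
        counters[m] += 1
        out.append(
            EnrichmentResult(
                module=m,
                set_name=r["set_name"],
                overlap=r["overlap"],
                module_size=r["module_size"],
                set_size=r["set_size"],
                universe_size=len(universe_set),
                p_raw=r["p_raw"],
                p_bonferroni=min(1.0, r["p_raw"] * n_tests),
                q_bh=q,
            )
        )
    return out


def enrichment_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "module": r.module, "set_name": r.set_name, "overlap": r.overlap,
                "module_size": r.module_size, "set_size": r.set_size,
                "universe_size": r.universe_size, "p_raw": r.p_raw,
                "p_bonferroni": r.p_bonferroni, "q_bh": r.q_bh,
            }
            for r in results
        ]
    )
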