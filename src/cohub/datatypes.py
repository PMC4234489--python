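"""Domain containers shared by every pipeline stage.

Expression values are always log-scale and unitless; phenotypes are binary
with NaN marking "unknown" (samples with an unknown trait are excluded from
any computation specific to that trait, never from the study as a whole).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: The three partially observed binary tumor traits, in canonical order.
TRAITS: tuple[str, ...] = ("grade", "type", "stage")

#: Encoding of the 0/1 levels of each trait (0-level first).
TRAIT_LEVELS: dict[str, tuple[str, str]] = {
    "grade": ("low", "high"),
    "type": ("I", "II"),
    "stage": ("early", "late"),
}


@dataclass
class ExpressionMatrix:
    """Genes x samples real-valued expression with platform labels.

    Parameters
    ----------
    gene_ids : list of str
        Unique gene identifiers, one per row.
    sample_ids : list of str
        Unique sample identifiers, one per column.
    platform : list of str
        Platform label per sample (same length as ``sample_ids``).
    values : ndarray, shape (n_genes, n_samples)
        Log-scale expression; no missing entries.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    platform: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = list(map(str, self.gene_ids))
        self.sample_ids = list(map(str, self.sample_ids))
        self.platform = list(map(str, self.platform))
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D genes x samples matrix")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if len(self.platform) != len(self.sample_ids):
            raise ValueError("platform must have one label per sample")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene identifiers")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample identifiers")
        if np.isnan(self.values).any():
            raise ValueError("expression values contain missing entries")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def platforms(self) -> list[str]:
        """Distinct platform labels in order of first appearance."""
        seen: dict[str, None] = {}
        for p in self.platform:
            seen.setdefault(p)
        return list(seen)

    def to_frame(self) -> pd.DataFrame:
        """Return the matrix as a genes x samples DataFrame."""
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    def subset_genes(self, genes: list[str]) -> "ExpressionMatrix":
        """Restrict to ``genes`` (kept in the given order)."""
        index = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in genes if g not in index]
        if missing:
            raise KeyError(f"genes not in matrix: {missing[:5]}")
        rows = [index[g] for g in genes]
        return ExpressionMatrix(
            gene_ids=list(genes),
            sample_ids=list(self.sample_ids),
            platform=list(self.platform),
            values=self.values[rows],
        )

    def subset_samples(self, mask: np.ndarray) -> "ExpressionMatrix":
        mask = np.asarray(mask, dtype=bool)
        keep = np.flatnonzero(mask)
        return ExpressionMatrix(
            gene_ids=list(self.gene_ids),
            sample_ids=[self.sample_ids[i] for i in keep],
            platform=[self.platform[i] for i in keep],
            values=self.values[:, keep],
        )

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(
            list(self.gene_ids), list(self.sample_ids), list(self.platform), self.values.copy()
        )


@dataclass
class PhenotypeTable:
    """Per-sample case/control status plus three partially observed traits.

    ``status`` is 0 (control) / 1 (case). Each trait array is float with
    0.0/1.0 for the two levels and NaN for unknown; controls always carry
    NaN for the tumor traits.
    """

    sample_ids: list[str]
    status: np.ndarray
    grade: np.ndarray
    type: np.ndarray
    stage: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = list(map(str, self.sample_ids))
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample identifiers in phenotype table")
        n = len(self.sample_ids)
        self.status = np.asarray(self.status, dtype=int)
        for name in TRAITS:
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (n,):
                raise ValueError(f"trait '{name}' must have one value per sample")
            known = arr[~np.isnan(arr)]
            if not np.isin(known, [0.0, 1.0]).all():
                raise ValueError(f"trait '{name}' must be coded 0/1/NaN")
            setattr(self, name, arr)
        if self.status.shape != (n,) or not np.isin(self.status, [0, 1]).all():
            raise ValueError("status must be one 0/1 value per sample")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def trait(self, name: str) -> np.ndarray:
        if name not in TRAITS:
            raise KeyError(f"unknown trait '{name}'; expected one of {TRAITS}")
        return getattr(self, name)

    def align(self, sample_ids: list[str]) -> "PhenotypeTable":
        """Reorder/subset to ``sample_ids`` (all must be present)."""
        index = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in index]
        if missing:
            raise KeyError(f"samples not in phenotype table: {missing[:5]}")
        rows = np.array([index[s] for s in sample_ids])
        return PhenotypeTable(
            sample_ids=list(sample_ids),
            status=self.status[rows],
            grade=self.grade[rows],
            type=self.type[rows],
            stage=self.stage[rows],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample": self.sample_ids,
                "status": self.status,
                "grade": self.grade,
                "type": self.type,
                "stage": self.stage,
            }
        )


@dataclass
class GeneSetCollection:
    """Named gene sets (e.g. GO terms or pathways) in the expression-matrix
    gene-identifier namespace."""

    sets: dict[str, set[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"gene set '{name}' is empty")
            self.sets[name] = {str(m) for m in members}
        for name in self.sets:
            self.descriptions.setdefault(name, "")

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> set[str]:
        return self.sets[name]

    def restrict_to(self, universe: set[str]) -> "GeneSetCollection":
        """Intersect every set with ``universe``, dropping emptied sets."""
        kept = {n: m & universe for n, m in self.sets.items()}
        kept = {n: m for n, m in kept.items() if m}
        return GeneSetCollection(
            sets=kept, descriptions={n: self.descriptions[n] for n in kept}
        )


@dataclass(frozen=True)
class HubScoreRow:
    """One (gene, trait, module) triple with its hub-triage scores.

    f is the bootstrap elastic-net selection count (out of B resamples),
    K the scaled intramodular connectivity, GS the absolute gene-trait
    correlation.
    """

    gene: str
    trait: str
    module: str
    f: int
    K: float
    GS: float
    B: int = 1000

    def __post_init__(self) -> None:
        if self.trait not in TRAITS:
            raise ValueError(f"trait must be one of {TRAITS}, got '{self.trait}'")
        if not (0 <= self.f <= self.B):
            raise ValueError(f"f={self.f} outside [0, B={self.B}]")
        if not (0.0 <= self.K <= 1.0):
            raise ValueError(f"K={self.K} outside [0, 1]")
        if not (0.0 <= self.GS <= 1.0):
            raise ValueError(f"GS={self.GS} outside [0, 1]")

    def passes(self, f_cut: int, k_cut: float, gs_cut: float) -> bool:
        """Strict-inequality hub triage: f > f_cut and K > k_cut and GS > gs_cut."""
        return self.f > f_cut and self.K > k_cut and self.GS > gs_cut
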