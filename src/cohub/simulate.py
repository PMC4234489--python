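"""Synthetic multi-platform expression studies with planted structure.

The generator emulates the study design the pipeline assumes: several
co-expression modules, each driven by one latent factor per sample;
designated hub genes loading more strongly on their module's factor than
ordinary members; binary tumor traits (grade, type, stage) drawn from
logistic models on the factors of their configured modules; case/control
status shifting the factors so module genes are also differentially
expressed; and per-platform gene-wise affine distortions (location/scale)
of the kind cross-platform normalization must remove.

Model, per sample s and module m:

    u_m(s) ~ Normal(status_shift * case(s), 1)                (latent factor)
    x_g(s) = lambda_g * u_m(s) + sqrt(1 - lambda_g^2) * noise_sd * eps,
             eps ~ Normal(0, 1)

with lambda_g = ``loading_hub`` for hub genes and ``loading_in_module``
otherwise; background genes are pure noise.  With ``noise_sd = 1`` and no
status shift the within-module gene-gene correlation is exactly
lambda_i * lambda_j in expectation.  Traits exist only for cases
(controls carry unknown), and a configurable fraction of cases has its
traits masked to unknown, mirroring partially annotated clinical tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from cohub.datatypes import ExpressionMatrix, PhenotypeTable, TRAITS


def _default_trait_effects() -> dict[str, tuple[int, float]]:
    # one driving module per trait; log-odds slope 2 on the module factor
    return {"grade": (0, 2.0), "type": (1, 2.0), "stage": (2, 2.0)}


@dataclass
class SyntheticConfig:
    """Study-design parameters for :func:`generate_synthetic_study`.

    Defaults describe the reference recovery setting used throughout the
    test-suite: 3 modules of 150 genes plus 150 background genes, 5 hubs
    per module, 300 samples split over two platforms, member loading 0.7
    and hub loading 0.9, and a log-odds trait effect of 2 on each trait's
    driving module.
    """

    n_genes: int = 600
    module_sizes: list[int] = field(default_factory=lambda: [150, 150, 150])
    n_hubs_per_module: int = 5
    n_samples_per_platform: list[int] = field(default_factory=lambda: [150, 150])
    loading_in_module: float = 0.7
    loading_hub: float = 0.9
    trait_effects: dict[str, tuple[int, float]] = field(default_factory=_default_trait_effects)
    platform_shift_sd: float = 0.5
    platform_scale_sd: float = 0.2
    noise_sd: float = 1.0
    missing_trait_fraction: float = 0.2
    case_fraction: float = 0.5
    status_shift: float = 1.5
    seed: int = 0

    def validate(self) -> None:
        if sum(self.module_sizes) > self.n_genes:
            raise ValueError("module sizes exceed n_genes")
        if any(s <= 0 for s in self.module_sizes):
            raise ValueError("module sizes must be positive")
        if any(s <= 0 for s in self.n_samples_per_platform):
            raise ValueError("per-platform sample counts must be positive")
        if self.n_hubs_per_module > min(self.module_sizes, default=0):
            raise ValueError("more hubs requested than module members")
        if not (0.0 <= self.loading_in_module < 1.0):
            raise ValueError("loading_in_module must lie in [0, 1)")
        if not (self.loading_in_module < self.loading_hub < 1.0) and self.loading_in_module > 0:
            raise ValueError("loading_hub must exceed loading_in_module and lie below 1")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if not (0.0 <= self.missing_trait_fraction < 1.0):
            raise ValueError("missing_trait_fraction must lie in [0, 1)")
        if self.platform_shift_sd < 0 or self.platform_scale_sd < 0:
            raise ValueError("platform effect SDs must be non-negative")
        for trait, (module, _effect) in self.trait_effects.items():
            if trait not in TRAITS:
                raise ValueError(f"unknown trait '{trait}'")
            if not (0 <= module < len(self.module_sizes)):
                raise ValueError(f"trait '{trait}' references missing module {module}")


@dataclass
class SyntheticTruth:
    """Planted ground truth for recovery testing."""

    gene_ids: list[str]
    module_label: list[str]          # "M1", "M2", ... or "unassigned"
    hub_flag: np.ndarray             # bool per gene
    trait_effects: dict[str, tuple[int, float]]
    latent_factors: np.ndarray       # modules x samples

    def module_members(self, module_index: int) -> list[str]:
        label = f"M{module_index + 1}"
        return [g for g, m in zip(self.gene_ids, self.module_label) if m == label]

    def hubs_for_module(self, module_index: int) -> list[str]:
        label = f"M{module_index + 1}"
        return [
            g
            for g, m, h in zip(self.gene_ids, self.module_label, self.hub_flag)
            if m == label and h
        ]


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def generate_synthetic_study(
    config: SyntheticConfig,
) -> tuple[ExpressionMatrix, PhenotypeTable, SyntheticTruth]:
    """Generate one synthetic multi-platform study plus its ground truth.

    Identical configs (including seed) produce byte-identical outputs.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    n_modules = len(config.module_sizes)
    n_background = config.n_genes - sum(config.module_sizes)
    n_samples = sum(config.n_samples_per_platform)

    platform_labels: list[str] = []
    for p, count in enumerate(config.n_samples_per_platform):
        platform_labels.extend([f"P{p + 1}"] * count)
    sample_ids = [f"s{i + 1:04d}" for i in range(n_samples)]

    status = (rng.random(n_samples) < config.case_fraction).astype(int)

    # latent module factors, shifted in cases so module genes are DE
    factors = rng.standard_normal((n_modules, n_samples))
    factors = factors + config.status_shift * status[None, :]

    gene_ids: list[str] = []
    module_label: list[str] = []
    hub_flag = np.zeros(config.n_genes, dtype=bool)
    values = np.empty((config.n_genes, n_samples))

    row = 0
    for m, size in enumerate(config.module_sizes):
        for j in range(size):
            is_hub = j < config.n_hubs_per_module
            lam = config.loading_hub if is_hub else config.loading_in_module
            eps = rng.standard_normal(n_samples)
            values[row] = lam * factors[m] + np.sqrt(1.0 - lam**2) * config.noise_sd * eps
            gene_ids.append(f"M{m + 1}{'H' if is_hub else 'G'}{j + 1:03d}")
            module_label.append(f"M{m + 1}")
            hub_flag[row] = is_hub
            row += 1
    for j in range(n_background):
        values[row] = config.noise_sd * rng.standard_normal(n_samples)
        gene_ids.append(f"BG{j + 1:04d}")
        module_label.append("unassigned")
        row += 1

    # binary traits from logistic models on the configured module factor;
    # controls and a masked fraction of cases carry unknown
    traits: dict[str, np.ndarray] = {}
    for trait in TRAITS:
        y = np.full(n_samples, np.nan)
        if trait in config.trait_effects:
            module, effect = config.trait_effects[trait]
            case_idx = np.flatnonzero(status == 1)
            centered = factors[module, case_idx] - factors[module, case_idx].mean()
            p = _sigmoid(effect * centered)
            y[case_idx] = (rng.random(case_idx.size) < p).astype(float)
            if config.missing_trait_fraction > 0 and case_idx.size:
                n_mask = int(round(config.missing_trait_fraction * case_idx.size))
                masked = rng.choice(case_idx, size=n_mask, replace=False)
                y[masked] = np.nan
        traits[trait] = y

    # per-platform gene-wise affine distortion (location/scale)
    for p, label in enumerate(f"P{i + 1}" for i in range(len(config.n_samples_per_platform))):
        cols = [i for i, pl in enumerate(platform_labels) if pl == label]
        shift = rng.normal(0.0, config.platform_shift_sd, size=config.n_genes)
        scale = np.exp(rng.normal(0.0, config.platform_scale_sd, size=config.n_genes))
        values[:, cols] = values[:, cols] * scale[:, None] + shift[:, None]

    matrix = ExpressionMatrix(
        gene_ids=gene_ids, sample_ids=sample_ids, platform=platform_labels, values=values
    )
    phenotypes = PhenotypeTable(
        sample_ids=sample_ids,
        status=status,
        grade=traits["grade"],
        type=traits["type"],
        stage=traits["stage"],
    )
    truth = SyntheticTruth(
        gene_ids=gene_ids,
        module_label=module_label,
        hub_flag=hub_flag,
        trait_effects=dict(config.trait_effects),
        latent_factors=factors,
    )
    return matrix, phenotypes, truth
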