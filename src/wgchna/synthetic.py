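"""Planted-module synthetic expression data.

A one-factor-per-module Gaussian model: each module k has a latent factor
f_k ~ N(0, 1) over samples, each member gene is

    x_g = loading * f_k + noise_sd * eps_g,        eps_g ~ N(0, 1) iid,

and background genes are pure standard-normal noise.  The expected Pearson
correlation between two genes of the same module is
loading^2 / (loading^2 + noise_sd^2), between modules it is 0 — closed forms
the tests assert against.  Traits are noisy copies of selected factors
(trait = f_map(t) + trait_noise_sd * eta), so module-trait correlation has a
known ground truth.  All draws come from one seeded generator in a fixed,
documented order (factors, then the gene noise matrix, then trait noise),
making every dataset bit-reproducible from (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import ExpressionMatrix, TraitTable


@dataclass
class SyntheticConfig:
    """Generator settings; ``seed`` is mandatory (no unseeded generation)."""

    n_genes: int = 300
    n_samples: int = 60
    module_sizes: tuple[int, ...] = (60, 60, 60, 60)
    loading: float = 0.8
    noise_sd: float = 0.6
    n_traits: int = 2
    trait_module_map: tuple[int, ...] = (1, 3)  # 1-based module index per trait
    trait_noise_sd: float = 0.5
    seed: int = 20250404

    def __post_init__(self) -> None:
        if sum(self.module_sizes) > self.n_genes:
            raise ValueError("module sizes exceed the number of genes")
        if not 0 < self.loading < 1:
            raise ValueError("loading must be in (0, 1)")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if len(self.trait_module_map) != self.n_traits:
            raise ValueError("one mapped module per trait required")
        if any(not 1 <= m <= len(self.module_sizes) for m in self.trait_module_map):
            raise ValueError("trait_module_map entries must index a module (1-based)")
        if self.seed is None:
            raise ValueError("seed is mandatory")

    @property
    def n_modules(self) -> int:
        return len(self.module_sizes)

    @property
    def expected_within_corr(self) -> float:
        """Closed-form expected Pearson correlation within a module."""
        l2 = self.loading**2
        return l2 / (l2 + self.noise_sd**2)


@dataclass
class SyntheticDataset:
    """Generated expression, planted truth labels, traits and latent factors."""

    expression: ExpressionMatrix
    truth: np.ndarray  # gene -> planted module label, 0 = background
    traits: TraitTable
    factors: np.ndarray  # samples x modules
    config: SyntheticConfig = field(repr=False, default=None)


def generate(config: SyntheticConfig) -> SyntheticDataset:
    """Draw one dataset from the factor model (deterministic given config)."""
    rng = np.random.default_rng(config.seed)
    n_mod = config.n_modules
    factors = rng.standard_normal((config.n_samples, n_mod))
    noise = rng.standard_normal((config.n_genes, config.n_samples))
    trait_noise = rng.standard_normal((config.n_samples, config.n_traits))

    truth = np.zeros(config.n_genes, dtype=int)
    start = 0
    for k, size in enumerate(config.module_sizes, start=1):
        truth[start:start + size] = k
        start += size

    values = np.empty((config.n_genes, config.n_samples))
    for g in range(config.n_genes):
        if truth[g] > 0:
            f = factors[:, truth[g] - 1]
            values[g] = config.loading * f + config.noise_sd * noise[g]
        else:
            values[g] = noise[g]

    width = len(str(config.n_genes))
    gene_ids = [f"G{g + 1:0{width}d}" for g in range(config.n_genes)]
    sample_ids = [f"S{s + 1:02d}" for s in range(config.n_samples)]
    expression = ExpressionMatrix(values, gene_ids, sample_ids)

    trait_values = np.empty((config.n_samples, config.n_traits))
    trait_ids = []
    for t, module in enumerate(config.trait_module_map):
        trait_values[:, t] = factors[:, module - 1] + config.trait_noise_sd * trait_noise[:, t]
        trait_ids.append(f"trait_m{module}")
    traits = TraitTable(trait_values, trait_ids, sample_ids)

    return SyntheticDataset(expression, truth, traits, factors, config)


def default_scenario() -> SyntheticConfig:
    """The canonical test scenario: 4 planted modules of 60 genes, 60 noise
    genes, 60 samples, loading 0.8, noise sd 0.6 (expected within-module
    correlation 0.64), two traits driven by factors 1 and 3, fixed seed."""
    return SyntheticConfig()
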