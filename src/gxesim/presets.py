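"""Ready-made configurations for the package's validation experiments.

``gxe_validation_config`` reproduces the reaction-norm parameter-recovery
experiment: heritability 0.1 at c = 0 (Var(a0) = 1, Var(e0) = 9), interaction
variance Var(a1) = 0.25, environment c = eps ~ N(0, 1) with no genetic part
(Var(beta) = 0), all covariances zero, reduced generative model.  The default
scale (1,000 genotyped offspring, 2,000 markers, 300 QTLs) is a desk-scale
stand-in for the original 10,000-individual runs.

``threshold_trait_config`` and ``binary_quantitative_config`` set up the
incidence-recovery experiments (single binary / three-category trait, and a
genetically correlated binary-quantitative pair).
"""

from __future__ import annotations

from .config import (
    CurrentDesign,
    GenomeSettings,
    GxESettings,
    SimulationConfig,
    TraitSpec,
)


def gxe_validation_config(
    n_sires: int = 10,
    n_dams: int = 100,
    offspring_per_dam: int = 10,
    n_markers: int = 2000,
    n_qtl: int = 300,
    seed: int = 1,
) -> SimulationConfig:
    """Reaction-norm G-by-E validation preset (reduced model, h2 = 0.1 at c=0)."""
    cfg = SimulationConfig(
        genome=GenomeSettings(
            n_chromosomes=10,
            chromosome_length=1.0,
            n_candidate_loci=500,
            n_markers=n_markers,
            n_qtl=n_qtl,
        ),
        current=CurrentDesign(
            n_sires=n_sires,
            n_dams=n_dams,
            offspring_per_dam=offspring_per_dam,
            n_generations=1,
        ),
        gxe=GxESettings(),  # var_a0=1, var_a1=0.25, var_e0=9, var_eps=1, reduced
        n_replicates=5,
        seed=seed,
    )
    cfg.validate()
    return cfg


def threshold_trait_config(incidences, seed: int = 1) -> SimulationConfig:
    """One quantitative trait thresholded into categories (10,000 individuals).

    *incidences* is the upper-tail incidence vector, e.g. ``[0.3]`` for a
    binary trait or ``[0.3, 0.4]`` for a three-category trait.
    """
    cfg = SimulationConfig(
        genome=GenomeSettings(
            n_chromosomes=3,
            chromosome_length=1.0,
            n_candidate_loci=200,
            n_markers=100,
            n_qtl=100,
        ),
        current=CurrentDesign(
            n_sires=50, n_dams=500, offspring_per_dam=20, n_generations=1
        ),
        traits=[TraitSpec(heritability=0.3, phenotypic_variance=1.0)],
        thresholds=[list(incidences)],
        n_replicates=20,
        seed=seed,
    )
    cfg.validate()
    return cfg


def binary_quantitative_config(
    incidence: float = 0.3,
    genetic_correlation: float = 0.5,
    seed: int = 1,
) -> SimulationConfig:
    """Genetically correlated pair: trait 1 thresholded binary, trait 2 continuous."""
    cfg = SimulationConfig(
        genome=GenomeSettings(
            n_chromosomes=3,
            chromosome_length=1.0,
            n_candidate_loci=200,
            n_markers=100,
            n_qtl=100,
        ),
        current=CurrentDesign(
            n_sires=50, n_dams=500, offspring_per_dam=20, n_generations=1
        ),
        traits=[
            TraitSpec(heritability=0.3, phenotypic_variance=1.0),
            TraitSpec(heritability=0.3, phenotypic_variance=1.0),
        ],
        genetic_correlations=[
            [1.0, genetic_correlation],
            [genetic_correlation, 1.0],
        ],
        thresholds=[[incidence], []],
        n_replicates=20,
        seed=seed,
    )
    cfg.validate()
    return cfg
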