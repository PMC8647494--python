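"""End-to-end simulation replicates and the REML validation experiment."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import ConfigError, SimulationConfig
from .effects import (
    EffectMatrix,
    compute_tbv,
    rescale_to_targets,
    sample_component_effects,
)
from .genome import LocusPanel, run_historical_population, select_panel
from .phenotype import (
    PhenotypeTable,
    compose_environment,
    compose_phenotype,
    sample_residual_triplets,
)
from .population import Population, founders_population, generate_current_population
from .relmat import build_A, build_G
from .reml import ReactionNormModel, summarize_replicates
from .thresholds import CategoricalPhenotypes, categorize, thresholds_from_incidences


@dataclass
class ReplicateResult:
    """Everything one simulation replicate produced."""

    config: SimulationConfig
    seed: int
    population: Population  # full pedigree, founders included
    phenotyped: Population  # the last generation (records carriers)
    panel: LocusPanel
    effects: EffectMatrix
    realized_vcov: np.ndarray
    tbv: np.ndarray
    phenotypes: pd.DataFrame
    table: PhenotypeTable | None  # reaction-norm component table (G-by-E mode)
    categories: dict  # trait index -> CategoricalPhenotypes


def simulate_replicate(config: SimulationConfig, seed: int) -> ReplicateResult:
    """Run one full replicate: historical burn-in, current population,
    QTL effects, phenotypes and (optionally) threshold categories."""
    config.validate()
    rng = np.random.default_rng(seed)

    hist = run_historical_population(config, rng)
    founders = founders_population(hist)
    panel = select_panel(
        founders.haplotypes,
        config.genome.n_markers,
        config.genome.n_qtl,
        config.genome.maf_min_marker,
        config.genome.maf_min_qtl,
        rng,
    )
    population = generate_current_population(founders, config.current, rng)
    phen_pop = population.last_generation()
    n = phen_pop.n_individuals
    ids = phen_pop.ids

    if config.gxe is not None:
        gvcov = config.gxe.genetic_vcov()
        raw = sample_component_effects(gvcov, config.genome.n_qtl, rng)
        effects, realized = rescale_to_targets(raw, panel, gvcov)
        tbv = compute_tbv(phen_pop, panel, effects)
        residuals = sample_residual_triplets(config.gxe.residual_vcov(), n, rng)
        c = compose_environment(tbv[:, 1], residuals[:, 2])
        table = compose_phenotype(tbv, c, residuals, config.gxe.model, ids=ids)
        phen = table.data.copy()
        y_columns = {0: "y"}
    else:
        names = tuple(f"trait_{t + 1}" for t in range(len(config.traits)))
        gvcov = config.genetic_trait_vcov()
        raw = sample_component_effects(gvcov, config.genome.n_qtl, rng, components=names)
        effects, realized = rescale_to_targets(raw, panel, gvcov)
        tbv = compute_tbv(phen_pop, panel, effects)
        resid_sd = np.sqrt([t.residual_variance for t in config.traits])
        e = rng.standard_normal((n, len(names))) * resid_sd[None, :]
        y = tbv + e
        phen = pd.DataFrame({"id": ids})
        y_columns = {}
        for t, name in enumerate(names):
            phen[f"y_{t + 1}"] = y[:, t]
            y_columns[t] = f"y_{t + 1}"
        for t, name in enumerate(names):
            phen[f"tbv_{t + 1}"] = tbv[:, t]
            phen[f"e_{t + 1}"] = e[:, t]
        table = None

    categories: dict[int, CategoricalPhenotypes] = {}
    for t_idx, spec in enumerate(config.thresholds):
        if not spec:
            continue  # empty spec: trait stays continuous
        thr = thresholds_from_incidences(spec)
        cats = categorize(phen[y_columns[t_idx]].to_numpy(), thr, standardize=True)
        phen[f"cat_{t_idx + 1}"] = cats.category
        categories[t_idx] = cats

    return ReplicateResult(
        config=config,
        seed=seed,
        population=population,
        phenotyped=phen_pop,
        panel=panel,
        effects=effects,
        realized_vcov=realized,
        tbv=tbv,
        phenotypes=phen,
        table=table,
        categories=categories,
    )


def run_replicates(
    config: SimulationConfig,
    base_seed: int | None = None,
    n_replicates: int | None = None,
) -> list[ReplicateResult]:
    """Run the configured replicates; replicate r uses seed base_seed + r."""
    base = config.seed if base_seed is None else base_seed
    reps = config.n_replicates if n_replicates is None else n_replicates
    return [simulate_replicate(config, base + r) for r in range(1, reps + 1)]


def incidence_replicates(
    config: SimulationConfig,
    category_index: int = 0,
    base_seed: int | None = None,
    n_replicates: int | None = None,
    trait_index: int = 0,
) -> np.ndarray:
    """Observed incidence of one category across simulation replicates."""
    from .thresholds import estimate_incidence

    obs = []
    for result in run_replicates(config, base_seed=base_seed, n_replicates=n_replicates):
        inc = estimate_incidence(result.categories[trait_index])
        obs.append(inc[category_index])
    return np.array(obs)


def realized_covariance_replicates(
    config: SimulationConfig,
    base_seed: int | None = None,
    n_replicates: int = 20,
) -> np.ndarray:
    """Realized Cov(a0, a1) = sum 2 p q m n after rescaling, across independent
    effect-sampling replicates on one simulated genome."""
    if config.gxe is None:
        raise ConfigError("realized-covariance replicates require a gxe block")
    base = config.seed if base_seed is None else base_seed
    rng = np.random.default_rng(base)
    hist = run_historical_population(config, rng)
    founders = founders_population(hist)
    panel = select_panel(
        founders.haplotypes,
        config.genome.n_markers,
        config.genome.n_qtl,
        config.genome.maf_min_marker,
        config.genome.maf_min_qtl,
        rng,
    )
    gvcov = config.gxe.genetic_vcov()
    covs = []
    for r in range(1, n_replicates + 1):
        raw = sample_component_effects(gvcov, config.genome.n_qtl, base + r)
        _, realized = rescale_to_targets(raw, panel, gvcov)
        covs.append(realized[0, 2])
    return np.array(covs)


def relationship_matrix(result: ReplicateResult, kind: str = "G") -> np.ndarray:
    """A or G relationship matrix over the phenotyped individuals."""
    if kind == "G":
        dos = result.phenotyped.dosages()[:, result.panel.marker_indices].astype(float)
        p = dos.mean(axis=0) / 2.0
        keep = (p > 0.0) & (p < 1.0)  # drop markers drifted to fixation
        return build_G(dos[:, keep], p[keep])
    if kind == "A":
        ped = result.population.pedigree
        A = build_A(ped)
        rows = ped.index[ped["generation"] == ped["generation"].max()].to_numpy()
        return A[np.ix_(rows, rows)]
    raise ConfigError(f"unknown relationship matrix kind {kind!r}")


def run_validation(
    config: SimulationConfig,
    relmat: str = "G",
    n_replicates: int | None = None,
    base_seed: int | None = None,
) -> tuple[pd.DataFrame, list]:
    """Parameter-recovery experiment: simulate replicates under the G-by-E
    configuration, fit the reaction-norm model by REML with the chosen
    relationship matrix, and summarize estimates across replicates."""
    if config.gxe is None:
        raise ConfigError("validation requires a gxe block in the configuration")
    fits = []
    for result in run_replicates(config, base_seed=base_seed, n_replicates=n_replicates):
        K = relationship_matrix(result, relmat)
        phen = result.phenotypes
        model = ReactionNormModel(phen["y"].to_numpy(), phen["c"].to_numpy(), K)
        fits.append(model.fit())
    assigned = {
        "Var(a0)": config.gxe.var_a0,
        "Cov(a0,a1)": config.gxe.cov_a0_a1,
        "Var(a1)": config.gxe.var_a1,
        "Var(e0)": config.gxe.var_e0,
    }
    summary = summarize_replicates(fits, assigned)
    return summary, fits
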