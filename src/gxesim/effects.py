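"""QTL substitution effects, rescaling to target variances, and breeding values.

For the reaction-norm model the three effects of every QTL -- the intercept
a0, the genetic part beta of the environmental value, and the environmental
slope a1 -- are drawn jointly from a zero-mean multivariate normal with the
configured variance-covariance matrix (every QTL is pleiotropic for all three
components).  The variance contributed by QTL i to one component is

    2 * p_i * (1 - p_i) * m_i**2,

with p_i the counted-allele frequency and m_i the substitution effect, so each
component's effects are multiplied by sqrt(target / sum_i 2 p_i q_i m_i**2) to
hit its target variance exactly.  Cross-component covariances are then
*recalculated* from the scaled effects as sum_i 2 p_i q_i m_i n_i -- they are
reported, never forced back to the pre-scaling settings.

True breeding values are QTL effects times allele dosage, summed over QTLs and
mean-centered per component within the phenotyped population.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import ValidationError, check_psd
from .genome import LocusPanel
from .population import Population

GXE_COMPONENTS = ("a0", "beta", "a1")


@dataclass
class EffectMatrix:
    """Per-QTL substitution effects, one column per component or trait."""

    effects: np.ndarray  # (n_qtl, T)
    components: tuple
    frequencies: np.ndarray | None = None  # filled by rescale_to_targets

    def __post_init__(self):
        self.effects = np.atleast_2d(np.asarray(self.effects, dtype=float))
        if not np.all(np.isfinite(self.effects)):
            raise ValidationError("QTL effects must be finite")
        if self.effects.shape[1] != len(self.components):
            raise ValidationError("effect columns must match component names")

    @property
    def n_qtl(self) -> int:
        return self.effects.shape[0]


def sample_component_effects(
    vcov: np.ndarray,
    n_qtl: int,
    seed: int | np.random.Generator,
    components: tuple = GXE_COMPONENTS,
) -> EffectMatrix:
    """Draw ``n_qtl`` i.i.d. effect vectors from N(0, vcov)."""
    vcov = check_psd(vcov, "effect variance-covariance")
    if n_qtl < 1:
        raise ValidationError("n_qtl must be >= 1")
    if vcov.shape[0] != len(components):
        raise ValidationError("vcov dimension must match the component count")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    draws = rng.multivariate_normal(
        np.zeros(vcov.shape[0]), vcov, size=n_qtl, method="svd"
    )
    return EffectMatrix(draws, tuple(components))


def sample_multitrait_effects(
    trait_vcov: np.ndarray,
    n_qtl: int,
    seed: int | np.random.Generator,
    names: tuple | None = None,
) -> EffectMatrix:
    """Effects for T >= 2 genetically correlated traits (same pipeline)."""
    trait_vcov = np.asarray(trait_vcov, dtype=float)
    if trait_vcov.shape[0] < 2:
        raise ValidationError("multi-trait sampling needs at least two traits")
    if names is None:
        names = tuple(f"trait_{t + 1}" for t in range(trait_vcov.shape[0]))
    return sample_component_effects(trait_vcov, n_qtl, seed, components=names)


def qtl_variance(p, m):
    """Genetic variance contributed by a QTL: 2 p (1-p) m^2 (vectorized)."""
    p = np.asarray(p, dtype=float)
    if np.any((p <= 0.0) | (p >= 1.0)):
        raise ValidationError("QTL allele frequencies must lie strictly in (0, 1)")
    m = np.asarray(m, dtype=float)
    return 2.0 * p * (1.0 - p) * m**2


def realized_vcov(effects: np.ndarray, freqs: np.ndarray) -> np.ndarray:
    """Realized variance-covariance sum_i 2 p_i q_i m_i n_i across components."""
    w = 2.0 * freqs * (1.0 - freqs)
    return (effects * w[:, None]).T @ effects


def rescale_to_targets(
    effects: EffectMatrix,
    panel: LocusPanel,
    targets: np.ndarray,
) -> tuple[EffectMatrix, np.ndarray]:
    """Scale each component's effects so its realized variance hits the target.

    Returns the scaled :class:`EffectMatrix` (with the panel QTL frequencies
    attached) and the realized variance-covariance matrix recomputed from the
    scaled effects.  A component with target variance 0 gets all-zero effects.
    """
    targets = check_psd(targets, "target variance-covariance")
    freqs = panel.frequency[panel.qtl_indices]
    if freqs.size != effects.n_qtl:
        raise ValidationError(
            f"panel has {freqs.size} QTLs but effect matrix has {effects.n_qtl}"
        )
    if np.any((freqs <= 0.0) | (freqs >= 1.0)):
        raise ValidationError("QTL frequencies must lie strictly in (0, 1)")
    w = 2.0 * freqs * (1.0 - freqs)
    scaled = effects.effects.copy()
    for k in range(scaled.shape[1]):
        target = targets[k, k]
        raw = float(w @ scaled[:, k] ** 2)
        if target == 0.0:
            scaled[:, k] = 0.0
            continue
        if raw == 0.0:
            raise ValidationError(
                f"component {effects.components[k]!r} has zero pre-scaling variance "
                "but a positive target"
            )
        scaled[:, k] *= np.sqrt(target / raw)
    realized = realized_vcov(scaled, freqs)
    return EffectMatrix(scaled, effects.components, freqs), realized


def compute_tbv(
    population: Population,
    panel: LocusPanel,
    effects: EffectMatrix,
) -> np.ndarray:
    """Centered true breeding values, one column per component/trait.

    TBV_component(j) = sum_i dosage_{j,i} * effect_i, then each column is
    centered by its mean across the population (the pseudo-TBV means are
    scaled to zero).
    """
    dos = population.dosages()[:, panel.qtl_indices].astype(float)
    tbv = dos @ effects.effects
    return tbv - tbv.mean(axis=0, keepdims=True)
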