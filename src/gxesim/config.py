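"""Run configuration: dataclasses, validation, and the text parameter dialect.

A simulation run is described by a single YAML parameter file.  The dialect is
versioned by a ``format`` key; every section maps onto one of the dataclasses
below.  Unstated keys fall back to documented defaults, and every default that
is filled in is logged at INFO level so a run's effective configuration is
always reconstructable from its log.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

logger = logging.getLogger("gxesim")

FORMAT_VERSION = 1


class ConfigError(ValueError):
    """A parameter file is structurally invalid (missing/unknown keys)."""


class ValidationError(ConfigError):
    """A parameter value violates a model constraint."""


def check_psd(mat: np.ndarray, name: str, tol: float = 1e-10) -> np.ndarray:
    """Validate that *mat* is a symmetric positive semi-definite matrix."""
    a = np.asarray(mat, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValidationError(f"{name} must be a square matrix, got shape {a.shape}")
    if not np.allclose(a, a.T, atol=1e-8):
        raise ValidationError(f"{name} must be symmetric")
    eig = np.linalg.eigvalsh(a)
    if eig.min() < -tol * max(1.0, abs(eig.max())):
        raise ValidationError(
            f"{name} is not positive semi-definite (min eigenvalue {eig.min():.3g})"
        )
    return a


@dataclass
class HistoricalSettings:
    """Historical (burn-in) population driven to mutation-drift equilibrium.

    ``ne_schedule`` is a list of ``[generation_span, population_size]`` stages;
    after the schedule the population is ramped linearly to the founder count
    required by the current design over ``expand_generations`` generations.
    ``mutation_rate`` is the per-locus, per-transmitted-gamete allele flip
    probability; ``initial_frequency`` is the allele frequency used to draw the
    starting haplotypes (0 gives a monomorphic start).
    """

    ne_schedule: list = field(default_factory=lambda: [[1000, 100]])
    expand_generations: int = 10
    mutation_rate: float = 2.5e-3
    initial_frequency: float = 0.5

    def validate(self) -> None:
        if not self.ne_schedule:
            raise ValidationError("historical.ne_schedule must be non-empty")
        for stage in self.ne_schedule:
            if len(stage) != 2:
                raise ValidationError("ne_schedule stages are [span, size] pairs")
            span, size = stage
            if span < 0:
                raise ValidationError("ne_schedule spans must be >= 0")
            if size < 2:
                raise ConfigError("historical population size must be >= 2")
        if self.mutation_rate < 0:
            raise ValidationError("mutation_rate must be >= 0")
        if not 0.0 <= self.initial_frequency <= 1.0:
            raise ValidationError("initial_frequency must be in [0, 1]")
        if self.expand_generations < 1:
            raise ValidationError("expand_generations must be >= 1")


@dataclass
class GenomeSettings:
    """Genome structure: candidate loci are uniformly spaced per chromosome."""

    n_chromosomes: int = 10
    chromosome_length: float = 1.0  # Morgans
    n_candidate_loci: int = 500  # per chromosome
    n_markers: int = 2000
    n_qtl: int = 300
    maf_min_marker: float = 0.05
    maf_min_qtl: float = 0.05

    def validate(self) -> None:
        if self.n_chromosomes < 1 or self.n_candidate_loci < 1:
            raise ValidationError("need at least one chromosome and one candidate locus")
        if self.chromosome_length < 0:
            raise ValidationError("chromosome_length must be >= 0 Morgans")
        for key in ("maf_min_marker", "maf_min_qtl"):
            v = getattr(self, key)
            if not 0.0 < v < 0.5:
                raise ValidationError(f"{key} must lie strictly in (0, 0.5), got {v}")
        total = self.n_chromosomes * self.n_candidate_loci
        if self.n_markers + self.n_qtl > total:
            raise ValidationError(
                f"n_markers + n_qtl = {self.n_markers + self.n_qtl} exceeds the "
                f"{total} candidate loci"
            )
        if self.n_markers < 0 or self.n_qtl < 0:
            raise ValidationError("marker/QTL counts must be >= 0")


@dataclass
class CurrentDesign:
    """Mating design of the pedigreed current population.

    ``mating`` is ``hierarchical`` (dams nested within sires, the common
    livestock design) or ``random`` (each dam paired with a uniformly drawn
    sire). Generations are discrete; parents of generation g come from
    generation g-1 only.
    """

    n_sires: int = 10
    n_dams: int = 100
    offspring_per_dam: int = 10
    n_generations: int = 1
    mating: str = "hierarchical"

    def validate(self) -> None:
        if self.n_sires < 1 or self.n_dams < 1:
            raise ConfigError("n_sires and n_dams must be >= 1")
        if self.offspring_per_dam < 0 or self.n_generations < 0:
            raise ValidationError("offspring_per_dam and n_generations must be >= 0")
        if self.mating not in ("hierarchical", "random"):
            raise ValidationError(f"unknown mating scheme {self.mating!r}")
        if self.mating == "hierarchical" and self.n_dams < self.n_sires:
            raise ConfigError("hierarchical mating needs n_dams >= n_sires")

    @property
    def n_founders(self) -> int:
        # alternating sexes: 2*max guarantees enough males and females
        return 2 * max(self.n_sires, self.n_dams) + 2


@dataclass
class TraitSpec:
    """A quantitative trait defined by heritability and phenotypic variance."""

    heritability: float = 0.3
    phenotypic_variance: float = 1.0

    def validate(self) -> None:
        if not 0.0 < self.heritability <= 1.0:
            raise ValidationError("heritability must lie in (0, 1]")
        if self.phenotypic_variance <= 0:
            raise ValidationError("phenotypic_variance must be > 0")

    @property
    def genetic_variance(self) -> float:
        return self.heritability * self.phenotypic_variance

    @property
    def residual_variance(self) -> float:
        return (1.0 - self.heritability) * self.phenotypic_variance


@dataclass
class GxESettings:
    """Reaction-norm G-by-E settings.

    The genetic side holds the variance-covariance of the per-QTL effects for
    the intercept (a0), the genetic part of the environment (beta) and the
    environmental slope (a1).  The residual side holds the triplet
    (e0, e1, eps): intercept residual, slope residual and the environmental
    residual.  ``model`` selects the generative form: ``full`` is
    y = a0 + a1*c + e0 + e1*c (heterogeneous residual variance), ``reduced``
    drops the e1*c term.
    """

    var_a0: float = 1.0
    var_beta: float = 0.0
    var_a1: float = 0.25
    cov_a0_beta: float = 0.0
    cov_a0_a1: float = 0.0
    cov_beta_a1: float = 0.0
    var_e0: float = 9.0
    var_e1: float = 0.0
    var_eps: float = 1.0
    cov_e0_e1: float = 0.0
    cov_e0_eps: float = 0.0
    cov_e1_eps: float = 0.0
    model: str = "reduced"

    def genetic_vcov(self) -> np.ndarray:
        """3x3 covariance of the (a0, beta, a1) per-QTL effects."""
        return np.array(
            [
                [self.var_a0, self.cov_a0_beta, self.cov_a0_a1],
                [self.cov_a0_beta, self.var_beta, self.cov_beta_a1],
                [self.cov_a0_a1, self.cov_beta_a1, self.var_a1],
            ]
        )

    def residual_vcov(self) -> np.ndarray:
        """3x3 covariance of the (e0, e1, eps) residual triplet."""
        return np.array(
            [
                [self.var_e0, self.cov_e0_e1, self.cov_e0_eps],
                [self.cov_e0_e1, self.var_e1, self.cov_e1_eps],
                [self.cov_e0_eps, self.cov_e1_eps, self.var_eps],
            ]
        )

    def validate(self) -> None:
        for key in ("var_a0", "var_beta", "var_a1", "var_e0", "var_e1", "var_eps"):
            if getattr(self, key) < 0:
                raise ValidationError(f"{key} must be >= 0")
        check_psd(self.genetic_vcov(), "gxe genetic variance-covariance")
        check_psd(self.residual_vcov(), "gxe residual variance-covariance")
        if self.model not in ("full", "reduced"):
            raise ValidationError(f"unknown model form {self.model!r}")


@dataclass
class SimulationConfig:
    """Complete declarative description of one simulation run."""

    genome: GenomeSettings
    current: CurrentDesign
    historical: HistoricalSettings = field(default_factory=HistoricalSettings)
    traits: list = field(default_factory=lambda: [TraitSpec()])
    genetic_correlations: list | None = None
    gxe: GxESettings | None = None
    thresholds: list = field(default_factory=list)
    n_replicates: int = 1
    seed: int = 1
    output_dir: str = "gxesim_out"

    def validate(self) -> None:
        self.historical.validate()
        self.genome.validate()
        self.current.validate()
        if self.gxe is not None:
            self.gxe.validate()
        else:
            if not self.traits:
                raise ConfigError("at least one trait is required without a gxe block")
            for t in self.traits:
                t.validate()
            if self.genetic_correlations is not None:
                corr = check_psd(
                    np.asarray(self.genetic_correlations, float), "genetic_correlations"
                )
                if corr.shape[0] != len(self.traits):
                    raise ValidationError(
                        "genetic_correlations dimension must match the trait count"
                    )
                if not np.allclose(np.diag(corr), 1.0):
                    raise ValidationError("genetic_correlations diagonal must be 1")
        for spec in self.thresholds:
            for inc in spec:
                if not 0.0 < inc < 1.0:
                    raise ValidationError(f"incidence {inc} outside (0, 1)")
            if spec and sum(spec) >= 1.0:
                raise ValidationError(
                    f"cumulative incidence {sum(spec)} must be < 1 "
                    "(the remainder forms the last category)"
                )
        n_traits = 1 if self.gxe is not None else len(self.traits)
        if len(self.thresholds) > n_traits:
            raise ValidationError("more threshold specs than traits")
        if self.n_replicates < 1:
            raise ValidationError("n_replicates must be >= 1")

    @property
    def n_traits(self) -> int:
        return 1 if self.gxe is not None else len(self.traits)

    def genetic_trait_vcov(self) -> np.ndarray:
        """Genetic variance-covariance across traits (multi-trait mode)."""
        if self.gxe is not None:
            raise ConfigError("genetic_trait_vcov applies to multi-trait mode only")
        sd = np.sqrt([t.genetic_variance for t in self.traits])
        if self.genetic_correlations is None:
            corr = np.eye(len(self.traits))
        else:
            corr = np.asarray(self.genetic_correlations, float)
        return corr * np.outer(sd, sd)


_SECTION_TYPES = {
    "historical": HistoricalSettings,
    "genome": GenomeSettings,
    "current": CurrentDesign,
    "gxe": GxESettings,
}

_MANDATORY = ("genome", "current")


def _build_section(cls, data: dict, section: str):
    fields = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - fields
    if unknown:
        raise ConfigError(f"unknown key(s) {sorted(unknown)} in section '{section}'")
    for f in dataclasses.fields(cls):
        if f.name not in data:
            default = (
                f.default if f.default is not dataclasses.MISSING else f.default_factory()
            )
            logger.info("config: %s.%s defaulted to %r", section, f.name, default)
    return cls(**data)


def config_from_dict(raw: dict) -> SimulationConfig:
    """Build and validate a :class:`SimulationConfig` from a plain mapping."""
    if not isinstance(raw, dict):
        raise ConfigError("parameter file must contain a mapping at the top level")
    raw = dict(raw)
    fmt = raw.pop("format", FORMAT_VERSION)
    if fmt != FORMAT_VERSION:
        raise ConfigError(f"unsupported parameter format version {fmt!r}")
    for key in _MANDATORY:
        if key not in raw:
            raise ConfigError(f"missing mandatory section '{key}'")
    kwargs: dict = {}
    for section, cls in _SECTION_TYPES.items():
        if section in raw:
            data = raw.pop(section)
            if data is None:
                continue  # empty optional block: feature off
            kwargs[section] = _build_section(cls, data, section)
    if "traits" in raw:
        traits = raw.pop("traits")
        kwargs["traits"] = [_build_section(TraitSpec, t, "traits[]") for t in traits]
    top_fields = {f.name for f in dataclasses.fields(SimulationConfig)}
    unknown = set(raw) - top_fields
    if unknown:
        raise ConfigError(f"unknown top-level key(s) {sorted(unknown)}")
    kwargs.update(raw)
    cfg = SimulationConfig(**kwargs)
    cfg.validate()
    return cfg


def config_to_dict(cfg: SimulationConfig) -> dict:
    out: dict = {"format": FORMAT_VERSION}
    out["historical"] = dataclasses.asdict(cfg.historical)
    out["genome"] = dataclasses.asdict(cfg.genome)
    out["current"] = dataclasses.asdict(cfg.current)
    out["traits"] = [dataclasses.asdict(t) for t in cfg.traits]
    if cfg.genetic_correlations is not None:
        out["genetic_correlations"] = cfg.genetic_correlations
    if cfg.gxe is not None:
        out["gxe"] = dataclasses.asdict(cfg.gxe)
    out["thresholds"] = cfg.thresholds
    out["n_replicates"] = cfg.n_replicates
    out["seed"] = cfg.seed
    out["output_dir"] = cfg.output_dir
    return out


def parse_parameter_file(path) -> SimulationConfig:
    """Parse a YAML parameter file into a validated :class:`SimulationConfig`."""
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    try:
        return config_from_dict(raw)
    except ConfigError as exc:
        raise type(exc)(f"{path}: {exc}") from None


def write_parameter_file(cfg: SimulationConfig, path) -> Path:
    """Serialize *cfg* to YAML; ``parse_parameter_file`` round-trips exactly."""
    path = Path(path)
    text = "# gxesim parameter file, format v%d\n" % FORMAT_VERSION
    text += yaml.safe_dump(config_to_dict(cfg), sort_keys=False, default_flow_style=None)
    tmp = path.with_suffix(path.suffix + ".tmp")
    tmp.write_text(text)
    tmp.replace(path)
    return path
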