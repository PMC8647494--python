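import numpy as np
import pytest

from gxesim import (
    CurrentDesign,
    GenomeSettings,
    GxESettings,
    HistoricalSettings,
    SimulationConfig,
    simulate_replicate,
)


def small_gxe_config(**overrides) -> SimulationConfig:
    """Desk-scale G-by-E configuration used across unit tests."""
    cfg = SimulationConfig(
        historical=HistoricalSettings(ne_schedule=[[200, 60]], mutation_rate=2.5e-3),
        genome=GenomeSettings(
            n_chromosomes=2,
            chromosome_length=1.0,
            n_candidate_loci=100,
            n_markers=60,
            n_qtl=30,
        ),
        current=CurrentDesign(n_sires=5, n_dams=25, offspring_per_dam=8),
        gxe=GxESettings(),
    )
    for key, value in overrides.items():
        obj = cfg
        parts = key.split(".")
        for part in parts[:-1]:
            obj = getattr(obj, part)
        setattr(obj, parts[-1], value)
    cfg.validate()
    return cfg


@pytest.fixture(scope="session")
def gxe_replicate():
    """One small reduced-model G-by-E replicate shared by read-only tests."""
    return simulate_replicate(small_gxe_config(), seed=42)


@pytest.fixture(scope="session")
def gxe_replicate_full():
    """Same scale under the full (heterogeneous-residual) model."""
    cfg = small_gxe_config(**{"gxe.model": "full", "gxe.var_e1": 0.5})
    return simulate_replicate(cfg, seed=43)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
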