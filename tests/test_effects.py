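import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gxesim import (
    ValidationError,
    compute_tbv,
    qtl_variance,
    realized_vcov,
    rescale_to_targets,
    sample_component_effects,
    sample_multitrait_effects,
)
from gxesim.genome import QTL, GenomeGeometry, HaplotypeSet, LocusPanel
from gxesim.population import Population, founders_population
from tests.oracles import naive_tbv


def _panel(freqs):
    freqs = np.asarray(freqs, dtype=float)
    n = freqs.size
    geom = GenomeGeometry(np.ones(n, dtype=int), np.linspace(0, 0.9, n), np.array([1.0]))
    return LocusPanel(geom, np.full(n, QTL, dtype=np.int8), freqs)


@pytest.mark.parametrize(
    "p,m,expected",
    [(0.5, 1.0, 0.5), (0.1, 2.0, 0.72), (0.3, 0.0, 0.0)],
)
def test_qtl_variance_arithmetic(p, m, expected):
    assert qtl_variance(p, m) == pytest.approx(expected)


@pytest.mark.parametrize("p", [0.0, 1.0, -0.2, 1.3])
def test_qtl_variance_rejects_frequency_outside_unit_interval(p):
    with pytest.raises(ValidationError):
        qtl_variance(p, 1.0)


def test_zero_vcov_gives_zero_effects():
    eff = sample_component_effects(np.zeros((3, 3)), 50, seed=1)
    assert np.all(eff.effects == 0.0)


def test_component_correlations_match_vcov():
    diag = sample_component_effects(np.diag([1.0, 2.0, 0.5]), 100_000, seed=2)
    corr = np.corrcoef(diag.effects, rowvar=False)
    assert np.max(np.abs(corr - np.eye(3))) < 0.02

    vcov = np.array([[1.0, 0.0, 0.5], [0.0, 1.0, 0.0], [0.5, 0.0, 1.0]])
    dep = sample_component_effects(vcov, 100_000, seed=3)
    r = np.corrcoef(dep.effects[:, 0], dep.effects[:, 2])[0, 1]
    assert r == pytest.approx(0.5, abs=0.02)


def test_non_psd_vcov_rejected():
    bad = np.array([[1.0, 2.0, 0.0], [2.0, 1.0, 0.0], [0.0, 0.0, 1.0]])
    with pytest.raises(ValidationError):
        sample_component_effects(bad, 10, seed=1)


@settings(deadline=None, max_examples=25, derandomize=True)
@given(
    seed=st.integers(0, 2**31 - 1),
    n_qtl=st.integers(1, 40),
    va0=st.floats(0.01, 10.0),
    va1=st.floats(0.01, 10.0),
)
def test_rescaling_hits_targets_exactly(seed, n_qtl, va0, va1):
    """Brute-force re-summation of 2p(1-p)m^2 over the returned effects
    equals the target variance to machine precision."""
    rng = np.random.default_rng(seed)
    panel = _panel(rng.uniform(0.05, 0.95, n_qtl))
    targets = np.diag([va0, 0.0, va1])
    raw = sample_component_effects(targets, n_qtl, seed=rng)
    scaled, realized = rescale_to_targets(raw, panel, targets)
    p = scaled.frequencies
    for k, target in [(0, va0), (2, va1)]:
        total = sum(2 * p[i] * (1 - p[i]) * scaled.effects[i, k] ** 2 for i in range(n_qtl))
        assert total == pytest.approx(target, rel=1e-9)
        assert realized[k, k] == pytest.approx(target, rel=1e-9)
    assert np.all(scaled.effects[:, 1] == 0.0)  # zero-target component zeroed


def test_realized_covariance_from_double_loop():
    rng = np.random.default_rng(4)
    n = 10
    panel = _panel(rng.uniform(0.1, 0.9, n))
    targets = np.diag([1.0, 0.2, 0.25])
    scaled, realized = rescale_to_targets(
        sample_component_effects(targets, n, seed=5), panel, targets
    )
    p, eff = scaled.frequencies, scaled.effects
    manual = np.zeros((3, 3))
    for a in range(3):
        for b in range(3):
            manual[a, b] = sum(2 * p[i] * (1 - p[i]) * eff[i, a] * eff[i, b] for i in range(n))
    assert np.allclose(realized, manual, atol=1e-12)


def test_zero_prescaling_variance_with_positive_target_errors():
    panel = _panel([0.5, 0.2])
    raw = sample_component_effects(np.zeros((3, 3)), 2, seed=1)
    with pytest.raises(ValidationError, match="zero pre-scaling"):
        rescale_to_targets(raw, panel, np.diag([1.0, 0.0, 0.0]))


def test_realized_covariance_consistent_with_zero_assignment():
    """With zero assigned covariance, the across-seed mean realized covariance
    is statistically indistinguishable from zero."""
    rng = np.random.default_rng(6)
    panel = _panel(rng.uniform(0.1, 0.9, 100))
    targets = np.diag([1.0, 0.0, 0.25])
    covs = []
    for s in range(20):
        scaled, realized = rescale_to_targets(
            sample_component_effects(targets, 100, seed=1000 + s), panel, targets
        )
        covs.append(realized[0, 2])
    covs = np.array(covs)
    assert abs(covs.mean()) <= 2 * covs.std(ddof=1) / np.sqrt(covs.size)


def _tiny_population(dosage_rows):
    """Population with prescribed genotype dosages (het phased arbitrarily)."""
    dosage_rows = np.asarray(dosage_rows)
    n, L = dosage_rows.shape
    haps = np.zeros((2 * n, L), dtype=np.uint8)
    haps[0::2] = (dosage_rows >= 1).astype(np.uint8)
    haps[1::2] = (dosage_rows == 2).astype(np.uint8)
    geom = GenomeGeometry(np.ones(L, dtype=int), np.linspace(0, 0.5, L), np.array([1.0]))
    return founders_population(HaplotypeSet(haps, geom))


def test_tbv_matches_naive_loop_oracle():
    rng = np.random.default_rng(7)
    dosages = rng.integers(0, 3, size=(10, 5))
    pop = _tiny_population(dosages)
    geom = pop.haplotypes.geometry
    panel = LocusPanel(geom, np.full(5, QTL, dtype=np.int8), np.full(5, 0.4))
    eff = sample_component_effects(np.diag([1.0, 0.5, 0.25]), 5, seed=8)
    tbv = compute_tbv(pop, panel, eff)
    assert np.allclose(tbv, naive_tbv(dosages.astype(float), eff.effects), atol=1e-12)
    assert np.allclose(tbv.mean(axis=0), 0.0, atol=1e-10)


def test_tbv_zero_effects_and_single_qtl():
    pop = _tiny_population(np.array([[0], [1], [2]]))
    geom = pop.haplotypes.geometry
    panel = LocusPanel(geom, np.array([QTL], dtype=np.int8), np.array([0.5]))
    from gxesim.effects import EffectMatrix

    zero = EffectMatrix(np.zeros((1, 3)), ("a0", "beta", "a1"))
    assert np.all(compute_tbv(pop, panel, zero) == 0.0)
    one = EffectMatrix(np.array([[1.0, 0.0, 0.0]]), ("a0", "beta", "a1"))
    tbv = compute_tbv(pop, panel, one)[:, 0]
    assert np.allclose(tbv, np.array([0.0, 1.0, 2.0]) - 1.0)


def test_multitrait_effects_shapes_and_limits():
    with pytest.raises(ValidationError):
        sample_multitrait_effects(np.array([[1.0]]), 10, seed=1)
    vcov = np.array([[1.0, 0.99], [0.99, 1.0]])
    eff = sample_multitrait_effects(vcov, 50_000, seed=2)
    z = (eff.effects - eff.effects.mean(0)) / eff.effects.std(0)
    assert np.corrcoef(z[:, 0], z[:, 1])[0, 1] > 0.985


def test_multitrait_tbv_correlation_tracks_assignment(gxe_replicate):
    """Correlation 0.5 between trait effects yields TBV correlation near 0.5."""
    pop = gxe_replicate.phenotyped
    panel = gxe_replicate.panel
    vcov = np.array([[1.0, 0.5], [0.5, 1.0]])
    rs = []
    for s in range(5):
        raw = sample_multitrait_effects(vcov, panel.n_qtl, seed=200 + s)
        scaled, _ = rescale_to_targets(raw, panel, vcov)
        tbv = compute_tbv(pop, panel, scaled)
        rs.append(np.corrcoef(tbv[:, 0], tbv[:, 1])[0, 1])
    assert np.mean(rs) == pytest.approx(0.5, abs=0.1)
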