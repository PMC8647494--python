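import numpy as np
import pytest
from scipy import stats

from gxesim import (
    GxESettings,
    ValidationError,
    compose_environment,
    compose_phenotype,
    sample_residual_triplets,
    simulate_replicate,
    variance_profile,
)
from tests.conftest import small_gxe_config


def test_zero_residual_vcov_gives_zero_triplets():
    r = sample_residual_triplets(np.zeros((3, 3)), 100, seed=1)
    assert np.all(r == 0.0)


def test_residual_sampling_moments():
    r = sample_residual_triplets(np.diag([9.0, 0.0, 1.0]), 100_000, seed=2)
    assert r[:, 0].var() == pytest.approx(9.0, abs=0.2)
    assert np.allclose(r[:, 1], 0.0, atol=1e-6)  # zero-variance component
    rv = np.array([[9.0, 0.0, 1.5], [0.0, 0.5, 0.0], [1.5, 0.0, 1.0]])
    r2 = sample_residual_triplets(rv, 100_000, seed=3)
    assert np.cov(r2[:, 0], r2[:, 2])[0, 1] == pytest.approx(1.5, abs=0.1)


def test_compose_environment_limits(rng):
    eps = rng.standard_normal(50)
    beta = rng.standard_normal(50)
    assert np.array_equal(compose_environment(np.zeros(50), eps), eps)
    assert np.array_equal(compose_environment(beta, np.zeros(50)), beta)


def test_phenotype_arithmetic_full_model():
    table = compose_phenotype(
        tbv=np.array([[1.0, 0.0, 0.5]]),
        c=np.array([2.0]),
        residuals=np.array([[0.1, 0.05, 0.0]]),
        model="full",
    )
    assert table.data["y"].iloc[0] == pytest.approx(2.2)


def test_models_agree_when_environment_is_zero(rng):
    tbv = rng.standard_normal((200, 3))
    resid = rng.standard_normal((200, 3))
    c = np.zeros(200)
    full = compose_phenotype(tbv, c, resid, "full")
    reduced = compose_phenotype(tbv, c, resid, "reduced")
    assert np.array_equal(full.data["y"], reduced.data["y"])


def test_unknown_model_form_rejected(rng):
    with pytest.raises(ValidationError):
        compose_phenotype(np.zeros((3, 3)), np.zeros(3), np.zeros((3, 3)), "quadratic")


@pytest.mark.parametrize("fixture", ["gxe_replicate", "gxe_replicate_full"])
def test_phenotype_reconstruction_exact(fixture, request):
    """y recomputed from stored components matches stored y to <= 1e-12."""
    res = request.getfixturevalue(fixture)
    table = res.table
    assert np.max(np.abs(table.reconstruct_y() - table.data["y"].to_numpy())) <= 1e-12


def test_environment_decoupled_from_genetics_when_beta_zero():
    """With var(beta)=0 and no residual-environment covariance, c carries no
    genetic signal: |corr(c, TBV_k)| < 3/sqrt(n) on average across seeds."""
    cfg = small_gxe_config()
    cors = []
    for s in range(4):
        res = simulate_replicate(cfg, seed=60 + s)
        d = res.phenotypes
        for col in ("tbv_a0", "tbv_a1"):
            cors.append(abs(np.corrcoef(d["c"], d[col])[0, 1]))
        n = len(d)
    assert np.mean(cors) < 3.0 / np.sqrt(n)


def test_interaction_free_settings_match_plain_spread():
    """With var(a1)=0 and var(e1)=0 the per-genotype spread of phenotypes is
    indistinguishable between the full and reduced model forms."""
    cfg_full = small_gxe_config(**{"gxe.var_a1": 0.0, "gxe.model": "full"})
    cfg_red = small_gxe_config(**{"gxe.var_a1": 0.0})
    y_full = simulate_replicate(cfg_full, seed=77).phenotypes["y"]
    y_red = simulate_replicate(cfg_red, seed=78).phenotypes["y"]
    ks = stats.ks_2samp(y_full, y_red)
    assert ks.pvalue > 0.01


def test_variance_profile_heritability():
    gxe = GxESettings()  # var_a0=1, var_e0=9, reduced
    prof = variance_profile(gxe.genetic_vcov(), gxe.residual_vcov(), [0.0], "reduced")
    assert prof["heritability"].iloc[0] == pytest.approx(0.1)

    flat = GxESettings(var_a1=0.0)
    grid = np.linspace(-3, 3, 7)
    prof2 = variance_profile(flat.genetic_vcov(), flat.residual_vcov(), grid, "reduced")
    assert prof2["genetic_variance"].nunique() == 1  # constant in c

    prof3 = variance_profile(gxe.genetic_vcov(), gxe.residual_vcov(), [1e4], "reduced")
    assert prof3["heritability"].iloc[0] > 0.999  # h2 -> 1 as c grows


def test_phenotype_and_environment_normality():
    """Simulated y and c are approximately normal at n = 10,000."""
    cfg = small_gxe_config()
    cfg.current.n_sires, cfg.current.n_dams = 20, 500
    cfg.current.offspring_per_dam = 20
    res = simulate_replicate(cfg, seed=90)
    d = res.phenotypes
    assert len(d) == 10_000
    for col in ("y", "c"):
        assert abs(stats.skew(d[col])) < 0.1
        assert abs(stats.kurtosis(d[col])) < 0.1
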