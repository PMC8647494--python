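import numpy as np
import pytest
from scipy import stats

from gxesim import (
    HaplotypeSet,
    ValidationError,
    expected_heterozygosity,
    ld_decay_profile,
    run_historical_population,
    select_panel,
)
from gxesim.genome import build_geometry, recombine
from tests.conftest import small_gxe_config


def _geometry(n_chrom=1, length=1.0, n_loci=200):
    cfg = small_gxe_config()
    cfg.genome.n_chromosomes = n_chrom
    cfg.genome.chromosome_length = length
    cfg.genome.n_candidate_loci = n_loci
    return build_geometry(cfg.genome)


def test_geometry_positions_uniform_and_ordered():
    geom = _geometry(n_chrom=3, length=2.0, n_loci=50)
    assert geom.n_loci == 150
    for lo, hi in geom.chrom_bounds:
        pos = geom.position[lo:hi]
        assert np.all(np.diff(pos) > 0)
        assert pos[0] == 0.0 and pos[-1] < 2.0


def test_gamete_from_identical_parents_is_identical(rng):
    geom = _geometry()
    hap = rng.integers(0, 2, size=(20, geom.n_loci), dtype=np.uint8)
    gam = recombine(hap, hap.copy(), geom, rng)
    assert np.array_equal(gam, hap)


def test_zero_length_chromosome_transmits_whole_haplotype(rng):
    geom = _geometry(length=0.0)
    a = np.zeros((500, geom.n_loci), dtype=np.uint8)
    b = np.ones((500, geom.n_loci), dtype=np.uint8)
    gam = recombine(a, b, geom, rng)
    whole = (gam == 0).all(axis=1) | (gam == 1).all(axis=1)
    assert whole.all()
    # the source haplotype is chosen fairly
    frac = (gam == 1).all(axis=1).mean()
    assert abs(frac - 0.5) < 0.07


def test_gamete_alleles_always_parental(rng):
    """Mendelian membership: without mutation every transmitted allele is one
    of the parent's two alleles at that locus."""
    geom = _geometry(n_chrom=2)
    a = rng.integers(0, 2, size=(100, geom.n_loci), dtype=np.uint8)
    b = rng.integers(0, 2, size=(100, geom.n_loci), dtype=np.uint8)
    gam = recombine(a, b, geom, rng)
    assert np.all((gam == a) | (gam == b))


def test_switch_count_distribution_poisson(rng):
    """A fully heterozygous 1-Morgan chromosome shows Poisson(1) switch points."""
    geom = _geometry(length=1.0, n_loci=200)
    n = 10_000
    a = np.zeros((n, 200), dtype=np.uint8)
    b = np.ones((n, 200), dtype=np.uint8)
    gam = recombine(a, b, geom, rng)
    switches = (np.diff(gam.astype(np.int8), axis=1) != 0).sum(axis=1)
    kmax = 5
    observed = np.bincount(np.minimum(switches, kmax), minlength=kmax + 1)
    pmf = stats.poisson.pmf(np.arange(kmax), mu=1.0)
    expected = n * np.append(pmf, 1.0 - pmf.sum())
    chi2 = ((observed - expected) ** 2 / expected).sum()
    p = stats.chi2.sf(chi2, df=kmax)
    assert p > 1e-3


def test_monomorphic_start_without_mutation_stays_monomorphic():
    cfg = small_gxe_config()
    cfg.historical.mutation_rate = 0.0
    cfg.historical.initial_frequency = 0.0
    haps = run_historical_population(cfg, seed=1, n_final=30)
    assert expected_heterozygosity(haps) == 0.0
    assert haps.haplotypes.sum() == 0


def test_zero_generations_returns_initial_state():
    cfg = small_gxe_config()
    cfg.historical.ne_schedule = [[0, 40]]
    cfg.historical.initial_frequency = 0.0
    cfg.historical.mutation_rate = 0.01
    haps = run_historical_population(cfg, seed=1, n_final=40)
    assert haps.n_individuals == 40
    assert haps.haplotypes.sum() == 0  # no meiosis happened, so no mutation


def test_heterozygosity_matches_biallelic_equilibrium():
    """Stationary E[2p(1-p)] under symmetric flip mutation is theta/(2 theta+1),
    theta = 4 Ne u; at Ne=100, u=2.5e-3 that is 1/3."""
    cfg = small_gxe_config()
    cfg.genome.n_chromosomes = 3
    cfg.genome.n_candidate_loci = 100
    cfg.historical.ne_schedule = [[2000, 100]]
    cfg.historical.mutation_rate = 2.5e-3
    hets = [
        expected_heterozygosity(run_historical_population(cfg, seed=s, n_final=100))
        for s in range(5)
    ]
    theta = 4 * 100 * 2.5e-3
    assert abs(np.mean(hets) - theta / (2 * theta + 1)) < 0.05


def test_select_panel_errors_when_no_eligible_loci():
    cfg = small_gxe_config()
    cfg.historical.mutation_rate = 0.0
    cfg.historical.initial_frequency = 0.0
    haps = run_historical_population(cfg, seed=1, n_final=30)
    with pytest.raises(ValidationError, match="0 eligible"):
        select_panel(haps, 5, 5, 0.05, 0.05, seed=1)


def test_select_panel_roles_disjoint_and_maf_respected(gxe_replicate):
    panel = gxe_replicate.panel
    cfg = gxe_replicate.config
    assert panel.n_markers == cfg.genome.n_markers
    assert panel.n_qtl == cfg.genome.n_qtl
    assert not set(panel.marker_indices) & set(panel.qtl_indices)
    maf = np.minimum(panel.frequency, 1 - panel.frequency)
    assert np.all(maf[panel.marker_indices] > cfg.genome.maf_min_marker)
    assert np.all(maf[panel.qtl_indices] > cfg.genome.maf_min_qtl)


def test_select_panel_markers_only(gxe_replicate):
    haps = gxe_replicate.phenotyped.haplotypes
    panel = select_panel(haps, 10, 0, 0.05, 0.05, seed=3)
    assert panel.n_qtl == 0 and panel.n_markers == 10


def test_ld_r2_limits(rng):
    geom = _geometry(n_loci=4)
    n = 4000
    col = rng.integers(0, 2, size=(2 * n, 1), dtype=np.uint8)
    other = rng.integers(0, 2, size=(2 * n, 2), dtype=np.uint8)
    haps = HaplotypeSet(np.hstack([col, col, other]), geom)  # loci 0,1 identical
    panel = select_panel(haps, 4, 0, 0.01, 0.01, seed=1)
    prof = ld_decay_profile(haps, panel, max_distance=1.0, bin_width=1.0)
    # perfect coupling pair dominates nothing; check pairwise r2 directly
    from numpy import corrcoef

    r = corrcoef(haps.haplotypes.astype(float), rowvar=False)
    assert r[0, 1] ** 2 == pytest.approx(1.0)
    assert abs(r[0, 2] ** 2) < 0.01  # independent loci, large n
    assert prof["mean_r2"].notna().all()


def test_ld_decays_with_distance():
    cfg = small_gxe_config()
    cfg.genome.n_chromosomes = 1
    cfg.genome.n_candidate_loci = 120
    cfg.historical.ne_schedule = [[500, 80]]
    haps = run_historical_population(cfg, seed=5, n_final=80)
    panel = select_panel(haps, 60, 0, 0.05, 0.05, seed=5)
    prof = ld_decay_profile(haps, panel, max_distance=1.0, bin_width=0.2)
    assert prof["mean_r2"].iloc[0] > prof["mean_r2"].iloc[-1]
    rho = stats.spearmanr(np.arange(len(prof)), prof["mean_r2"]).statistic
    assert rho < 0
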