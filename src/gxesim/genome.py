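"""Historical-population genome simulation.

The historical phase drives a closed, randomly mating population of biallelic
loci to mutation-drift equilibrium, which both creates polymorphism and builds
linkage disequilibrium among nearby loci.  Meiosis follows the Haldane map
function: the crossover count per chromosome per gamete is Poisson with mean
equal to the map length in Morgans, crossover positions are uniform, and
chromosomes assort independently.  Mutation flips each transmitted allele
independently with the configured per-locus rate.

Under this recurrent two-allele flip model the stationary allele-frequency
distribution at an unlinked locus is Beta(theta, theta) with theta = 4*Ne*u,
so the expected heterozygosity at equilibrium is

    E[2p(1-p)] = theta / (2*theta + 1),

which is the closed form the equilibrium tests check against (it approaches
the familiar infinite-alleles value theta/(1+theta) only as theta -> 0).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import ConfigError, SimulationConfig, ValidationError

MARKER = 1
QTL = 2
UNUSED = 0


@dataclass
class GenomeGeometry:
    """Positions (Morgans, 0-based within chromosome) of all candidate loci."""

    chromosome: np.ndarray  # (L,) int, 1-based
    position: np.ndarray  # (L,) float, within-chromosome Morgans
    lengths: np.ndarray  # (n_chrom,) map length per chromosome

    def __post_init__(self):
        self.chromosome = np.asarray(self.chromosome, dtype=np.int32)
        self.position = np.asarray(self.position, dtype=float)
        self.lengths = np.asarray(self.lengths, dtype=float)

    @property
    def n_loci(self) -> int:
        return self.chromosome.size

    @property
    def chrom_bounds(self) -> list[tuple[int, int]]:
        """Half-open [lo, hi) locus index ranges, one per chromosome."""
        if not hasattr(self, "_bounds"):
            bounds = []
            for c in range(1, self.lengths.size + 1):
                idx = np.flatnonzero(self.chromosome == c)
                if idx.size:
                    bounds.append((int(idx[0]), int(idx[-1]) + 1))
                else:
                    bounds.append((0, 0))
            self._bounds = bounds
        return self._bounds


def build_geometry(genome) -> GenomeGeometry:
    """Uniformly spaced candidate loci from :class:`GenomeSettings`."""
    k = genome.n_candidate_loci
    pos_one = np.linspace(0.0, genome.chromosome_length, k, endpoint=False)
    chrom = np.repeat(np.arange(1, genome.n_chromosomes + 1, dtype=np.int32), k)
    position = np.tile(pos_one, genome.n_chromosomes)
    lengths = np.full(genome.n_chromosomes, float(genome.chromosome_length))
    return GenomeGeometry(chrom, position, lengths)


@dataclass
class HaplotypeSet:
    """Diploid haplotypes: individual i owns rows 2i and 2i+1."""

    haplotypes: np.ndarray  # (2n, L) uint8
    geometry: GenomeGeometry

    def __post_init__(self):
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.uint8)
        if self.haplotypes.shape[0] % 2:
            raise ValueError("haplotype row count must be even (two per individual)")
        if self.haplotypes.shape[1] != self.geometry.n_loci:
            raise ValueError("haplotype length must equal the candidate locus count")

    @property
    def n_individuals(self) -> int:
        return self.haplotypes.shape[0] // 2

    def dosages(self) -> np.ndarray:
        """Allele-count genotypes in {0, 1, 2}, shape (n, L)."""
        h = self.haplotypes
        return (h[0::2].astype(np.int16) + h[1::2]).astype(np.int8)

    def allele_frequencies(self) -> np.ndarray:
        return self.haplotypes.mean(axis=0)


@dataclass
class LocusPanel:
    """Role assignment (marker / QTL / unused) and frequencies of all loci."""

    geometry: GenomeGeometry
    role: np.ndarray  # (L,) int8 in {UNUSED, MARKER, QTL}
    frequency: np.ndarray  # (L,) counted-allele frequency

    def __post_init__(self):
        self.role = np.asarray(self.role, dtype=np.int8)
        self.frequency = np.asarray(self.frequency, dtype=float)

    @property
    def marker_indices(self) -> np.ndarray:
        return np.flatnonzero(self.role == MARKER)

    @property
    def qtl_indices(self) -> np.ndarray:
        return np.flatnonzero(self.role == QTL)

    @property
    def n_markers(self) -> int:
        return int(self.marker_indices.size)

    @property
    def n_qtl(self) -> int:
        return int(self.qtl_indices.size)


def recombine(
    hap_a: np.ndarray,
    hap_b: np.ndarray,
    geometry: GenomeGeometry,
    rng: np.random.Generator,
) -> np.ndarray:
    """Produce one gamete per parental haplotype pair.

    ``hap_a`` and ``hap_b`` are (G, L) arrays holding the two haplotypes of
    each of G parents.  Crossovers per chromosome are Poisson(map length),
    positions uniform, no interference; the starting strand is fair.
    """
    hap_a = np.ascontiguousarray(hap_a)
    hap_b = np.ascontiguousarray(hap_b)
    if hap_a.shape != hap_b.shape:
        raise ValueError("parental haplotypes must have equal shapes")
    n_gam = hap_a.shape[0]
    gam = np.empty_like(hap_a)
    for ci, (lo, hi) in enumerate(geometry.chrom_bounds):
        if hi <= lo:
            continue
        pos = geometry.position[lo:hi]
        n_loc = hi - lo
        clen = geometry.lengths[ci]
        start = rng.integers(0, 2, size=n_gam, dtype=np.uint8)
        total = 0
        if clen > 0 and n_gam:
            k = rng.poisson(clen, size=n_gam)
            total = int(k.sum())
        if total == 0:
            source = np.broadcast_to(start[:, None], (n_gam, n_loc))
        else:
            # scatter each crossover onto the first locus at or beyond it, then
            # an xor-accumulate gives the crossover parity left of every locus;
            # only gametes with at least one crossover need the scan
            rows = np.flatnonzero(k > 0)
            gidx = np.repeat(np.arange(rows.size), k[rows])
            xo = rng.random(total) * clen
            landing = np.searchsorted(pos, xo, side="left")
            switches = np.zeros((rows.size, n_loc + 1), dtype=np.uint8)
            np.add.at(switches, (gidx, landing), 1)
            parity = np.bitwise_xor.accumulate(switches[:, :n_loc] & 1, axis=1)
            source = np.repeat(start[:, None], n_loc, axis=1)
            source[rows] ^= parity
        gam[:, lo:hi] = np.where(source == 0, hap_a[:, lo:hi], hap_b[:, lo:hi])
    return gam


def mutate(
    gametes: np.ndarray,
    rate: float,
    rng: np.random.Generator,
    inplace: bool = False,
) -> np.ndarray:
    """Flip each transmitted allele independently with probability *rate*.

    Equivalent to an i.i.d. Bernoulli(rate) flip field: the flip count is
    binomial over all cells and, given the count, flipped cells are a uniform
    random subset (drawn by rejection until distinct).
    """
    if rate <= 0:
        return gametes
    out = gametes if inplace else gametes.copy()
    flat = out.reshape(-1)
    k = int(rng.binomial(flat.size, rate))
    if k == 0:
        return out
    idx = np.unique(rng.integers(0, flat.size, size=k))
    while idx.size < k:
        extra = rng.integers(0, flat.size, size=k - idx.size)
        idx = np.unique(np.concatenate([idx, extra]))
    flat[idx] ^= 1
    return out


def _next_generation(
    haps: np.ndarray,
    n_offspring: int,
    geometry: GenomeGeometry,
    mutation_rate: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """One generation of random mating with two distinct parents per offspring."""
    n_par = haps.shape[0] // 2
    if n_par < 2:
        raise ConfigError("historical population size fell below 2")
    p1 = rng.integers(0, n_par, size=n_offspring)
    p2 = (p1 + 1 + rng.integers(0, n_par - 1, size=n_offspring)) % n_par
    out = np.empty((2 * n_offspring, haps.shape[1]), dtype=np.uint8)
    for slot, par in ((0, p1), (1, p2)):
        gam = recombine(haps[2 * par], haps[2 * par + 1], geometry, rng)
        out[slot::2] = mutate(gam, mutation_rate, rng, inplace=True)
    return out


def run_historical_population(
    config: SimulationConfig,
    seed: int,
    n_final: int | None = None,
) -> HaplotypeSet:
    """Simulate the historical population and return its final generation.

    The population follows ``historical.ne_schedule`` and is then expanded
    linearly to *n_final* individuals (default: the founder count implied by
    the current design) over ``expand_generations`` generations.
    """
    hist = config.historical
    hist.validate()
    config.genome.validate()
    geometry = build_geometry(config.genome)
    rng = np.random.default_rng(seed)
    if n_final is None:
        n_final = config.current.n_founders

    n0 = int(hist.ne_schedule[0][1])
    f0 = hist.initial_frequency
    if f0 in (0.0, 1.0):
        haps = np.full((2 * n0, geometry.n_loci), int(f0), dtype=np.uint8)
    else:
        haps = (rng.random((2 * n0, geometry.n_loci)) < f0).astype(np.uint8)

    sizes: list[int] = []
    for span, size in hist.ne_schedule:
        sizes.extend([int(size)] * int(span))
    last = sizes[-1] if sizes else n0
    if n_final != last:
        ramp = np.linspace(last, n_final, hist.expand_generations + 1)[1:]
        sizes.extend(int(round(s)) for s in ramp)
    for size in sizes:
        haps = _next_generation(haps, size, geometry, hist.mutation_rate, rng)
    return HaplotypeSet(haps, geometry)


def select_panel(
    haps: HaplotypeSet,
    n_markers: int,
    n_qtl: int,
    maf_min_marker: float,
    maf_min_qtl: float,
    seed: int | np.random.Generator,
) -> LocusPanel:
    """Assign marker and QTL roles to segregating loci.

    QTLs are drawn uniformly at random from loci whose minor allele frequency
    strictly exceeds ``maf_min_qtl``; markers are then drawn from the remaining
    loci passing ``maf_min_marker``.  Frequencies are recorded from *haps*
    (the generation on which effects will be assigned), which makes the QTL
    effect rescaling exact in that generation.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    freq = haps.allele_frequencies()
    maf = np.minimum(freq, 1.0 - freq)
    role = np.zeros(freq.size, dtype=np.int8)

    qtl_eligible = np.flatnonzero(maf > maf_min_qtl)
    if qtl_eligible.size < n_qtl:
        raise ValidationError(
            f"requested {n_qtl} QTLs but only {qtl_eligible.size} eligible loci "
            f"at MAF > {maf_min_qtl}"
        )
    qtl_idx = rng.choice(qtl_eligible, size=n_qtl, replace=False)
    role[qtl_idx] = QTL

    marker_eligible = np.flatnonzero((maf > maf_min_marker) & (role == UNUSED))
    if marker_eligible.size < n_markers:
        raise ValidationError(
            f"requested {n_markers} markers but only {marker_eligible.size} eligible "
            f"loci at MAF > {maf_min_marker} after QTL selection"
        )
    marker_idx = rng.choice(marker_eligible, size=n_markers, replace=False)
    role[marker_idx] = MARKER
    return LocusPanel(haps.geometry, role, freq)


def expected_heterozygosity(haps: HaplotypeSet) -> float:
    """Mean 2p(1-p) across all candidate loci."""
    p = haps.allele_frequencies()
    return float(np.mean(2.0 * p * (1.0 - p)))


def ld_decay_profile(
    haps: HaplotypeSet,
    panel: LocusPanel,
    max_distance: float,
    bin_width: float = 0.05,
) -> pd.DataFrame:
    """Mean marker-pair r-squared by map-distance bin (LD decay diagnostic)."""
    rows = []
    h = haps.haplotypes.astype(float)
    for c, (lo, hi) in enumerate(panel.geometry.chrom_bounds, start=1):
        midx = panel.marker_indices
        midx = midx[(midx >= lo) & (midx < hi)]
        if midx.size < 2:
            continue
        cols = h[:, midx]
        sd = cols.std(axis=0)
        keep = sd > 0
        cols, mpos = cols[:, keep], panel.geometry.position[midx[keep]]
        if cols.shape[1] < 2:
            continue
        r = np.corrcoef(cols, rowvar=False)
        iu, ju = np.triu_indices(cols.shape[1], k=1)
        dist = np.abs(mpos[ju] - mpos[iu])
        sel = dist <= max_distance
        rows.append(pd.DataFrame({"distance": dist[sel], "r2": r[iu[sel], ju[sel]] ** 2}))
    if not rows:
        raise ValidationError("need at least 2 polymorphic markers on some chromosome")
    pairs = pd.concat(rows, ignore_index=True)
    edges = np.arange(0.0, max_distance + bin_width, bin_width)
    pairs["bin"] = pd.cut(pairs["distance"], edges, include_lowest=True)
    prof = (
        pairs.groupby("bin", observed=True)
        .agg(distance=("distance", "mean"), mean_r2=("r2", "mean"), n_pairs=("r2", "size"))
        .reset_index(drop=True)
    )
    return prof
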