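"""Pedigreed current populations generated from historical founders.

Founders are the final historical generation; they form generation 1 with
unknown parents (coded 0).  Sexes alternate with ID parity (odd IDs male),
which keeps replicate runs reproducible from the seed alone.  Each subsequent
generation draws its sires and dams at random (no selection) from the previous
generation and mates them hierarchically (dams nested within sires) or at
random; gametes are produced by the same Haldane/Poisson meiosis model as the
historical phase, with mutation off so that offspring genotypes stay Mendelian
consistent with their parents.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import ConfigError, CurrentDesign
from .genome import HaplotypeSet, recombine

MALE = 1
FEMALE = 2

PEDIGREE_COLUMNS = ["id", "sire", "dam", "sex", "generation"]


@dataclass
class Population:
    """Ordered pedigree records plus the haplotypes of those individuals."""

    pedigree: pd.DataFrame  # columns: id, sire, dam, sex, generation
    haplotypes: HaplotypeSet

    def __post_init__(self):
        if list(self.pedigree.columns) != PEDIGREE_COLUMNS:
            raise ValueError(f"pedigree columns must be {PEDIGREE_COLUMNS}")
        if len(self.pedigree) != self.haplotypes.n_individuals:
            raise ValueError("pedigree rows and haplotype pairs must match 1:1")

    @property
    def n_individuals(self) -> int:
        return len(self.pedigree)

    @property
    def ids(self) -> np.ndarray:
        return self.pedigree["id"].to_numpy()

    def generation(self, g: int) -> "Population":
        """Subset to one generation (keeps pedigree/haplotype alignment)."""
        mask = (self.pedigree["generation"] == g).to_numpy()
        return self.subset(np.flatnonzero(mask))

    def last_generation(self) -> "Population":
        return self.generation(int(self.pedigree["generation"].max()))

    def subset(self, rows: np.ndarray) -> "Population":
        ped = self.pedigree.iloc[rows].reset_index(drop=True)
        hap_rows = np.empty(2 * rows.size, dtype=np.intp)
        hap_rows[0::2] = 2 * rows
        hap_rows[1::2] = 2 * rows + 1
        haps = HaplotypeSet(self.haplotypes.haplotypes[hap_rows], self.haplotypes.geometry)
        return Population(ped, haps)

    def dosages(self) -> np.ndarray:
        return self.haplotypes.dosages()


def _sex_by_parity(ids: np.ndarray) -> np.ndarray:
    return np.where(ids % 2 == 1, MALE, FEMALE).astype(np.int8)


def founders_population(haps: HaplotypeSet) -> Population:
    """Wrap the final historical generation as generation 1 with unknown parents."""
    n = haps.n_individuals
    ids = np.arange(1, n + 1, dtype=np.int64)
    ped = pd.DataFrame(
        {
            "id": ids,
            "sire": np.zeros(n, dtype=np.int64),
            "dam": np.zeros(n, dtype=np.int64),
            "sex": _sex_by_parity(ids),
            "generation": np.ones(n, dtype=np.int32),
        }
    )
    return Population(ped, haps)


def _pick_parents(
    prev: pd.DataFrame,
    design: CurrentDesign,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    males = prev.index[prev["sex"] == MALE].to_numpy()
    females = prev.index[prev["sex"] == FEMALE].to_numpy()
    if males.size < design.n_sires:
        raise ConfigError(
            f"need {design.n_sires} sires but only {males.size} males available"
        )
    if females.size < design.n_dams:
        raise ConfigError(
            f"need {design.n_dams} dams but only {females.size} females available"
        )
    sires = rng.choice(males, size=design.n_sires, replace=False)
    dams = rng.choice(females, size=design.n_dams, replace=False)
    return sires, dams


def generate_current_population(
    founders: Population,
    design: CurrentDesign,
    seed: int | np.random.Generator,
) -> Population:
    """Grow *founders* by ``design.n_generations`` discrete generations.

    Returns the full pedigreed population (founders plus all offspring
    generations).  With ``offspring_per_dam == 0`` or ``n_generations == 0``
    the founders are returned unchanged.
    """
    design.validate()
    if design.offspring_per_dam == 0 or design.n_generations == 0:
        return founders
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    geometry = founders.haplotypes.geometry

    ped = founders.pedigree.copy()
    hap_blocks = [founders.haplotypes.haplotypes]
    next_id = int(ped["id"].max()) + 1
    gen0 = int(ped["generation"].max())

    for g in range(gen0 + 1, gen0 + design.n_generations + 1):
        prev = ped[ped["generation"] == g - 1]
        sire_rows, dam_rows = _pick_parents(prev, design, rng)
        n_off = design.n_dams * design.offspring_per_dam
        if design.mating == "hierarchical":
            # contiguous blocks of dams nested within each sire
            dam_order = rng.permutation(dam_rows)
            sire_of_dam = sire_rows[np.arange(design.n_dams) * design.n_sires // design.n_dams]
        else:
            dam_order = dam_rows
            sire_of_dam = rng.choice(sire_rows, size=design.n_dams, replace=True)
        off_dam = np.repeat(dam_order, design.offspring_per_dam)
        off_sire = np.repeat(sire_of_dam, design.offspring_per_dam)

        all_haps = np.concatenate(hap_blocks, axis=0)
        pat = recombine(all_haps[2 * off_sire], all_haps[2 * off_sire + 1], geometry, rng)
        mat = recombine(all_haps[2 * off_dam], all_haps[2 * off_dam + 1], geometry, rng)
        block = np.empty((2 * n_off, geometry.n_loci), dtype=np.uint8)
        block[0::2] = pat
        block[1::2] = mat
        hap_blocks = [all_haps, block]

        ids = np.arange(next_id, next_id + n_off, dtype=np.int64)
        next_id += n_off
        new = pd.DataFrame(
            {
                "id": ids,
                "sire": ped.loc[off_sire, "id"].to_numpy(),
                "dam": ped.loc[off_dam, "id"].to_numpy(),
                "sex": _sex_by_parity(ids),
                "generation": np.full(n_off, g, dtype=np.int32),
            }
        )
        ped = pd.concat([ped, new], ignore_index=True)

    haps = HaplotypeSet(np.concatenate(hap_blocks, axis=0), geometry)
    return Population(ped, haps)
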