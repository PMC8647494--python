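"""Whitespace-delimited output writers and the PLINK PED/MAP export.

All tables are plain text with a ``# gxesim v1 ...`` header comment line and
are written atomically (temp file + rename).  The genotype file holds marker
allele counts (0/1/2); QTL positions, frequencies and effects go to the QTL
report so downstream analyses can separate observed markers from causal loci.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .effects import EffectMatrix
from .genome import MARKER, QTL, LocusPanel
from .population import Population

HEADER = "# gxesim v1"


@dataclass
class OutputBundle:
    """Paths of one replicate's output files (unset entries were not written)."""

    genotype_file: Path | None = None
    pedigree_file: Path | None = None
    phenotype_file: Path | None = None
    qtl_report_file: Path | None = None
    frequency_file: Path | None = None
    ped_file: Path | None = None
    map_file: Path | None = None


def _atomic_write(path: Path, text: str) -> Path:
    tmp = path.with_suffix(path.suffix + ".tmp")
    tmp.write_text(text)
    tmp.replace(path)
    return path


def _frame_text(df: pd.DataFrame, title: str) -> str:
    return f"{HEADER} {title}\n" + df.to_csv(sep=" ", index=False, float_format="%.10g")


def write_outputs(
    population: Population,
    phenotypes: pd.DataFrame,
    panel: LocusPanel,
    effects: EffectMatrix,
    out_dir,
) -> OutputBundle:
    """Write genotype, pedigree, phenotype, QTL-report and frequency files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    midx = panel.marker_indices
    dos = population.dosages()[:, midx]
    geno = pd.DataFrame(dos, columns=[f"M{j + 1}" for j in range(midx.size)])
    geno.insert(0, "id", population.ids)
    genotype_file = _atomic_write(out / "genotypes.txt", _frame_text(geno, "genotypes"))

    pedigree_file = _atomic_write(
        out / "pedigree.txt", _frame_text(population.pedigree, "pedigree")
    )
    phenotype_file = _atomic_write(
        out / "phenotypes.txt", _frame_text(phenotypes, "phenotypes")
    )

    qidx = panel.qtl_indices
    qtl = pd.DataFrame(
        {
            "locus": qidx + 1,
            "chromosome": panel.geometry.chromosome[qidx],
            "position_morgans": panel.geometry.position[qidx],
            "frequency": panel.frequency[qidx],
        }
    )
    for k, name in enumerate(effects.components):
        qtl[f"effect_{name}"] = effects.effects[:, k]
    qtl_report_file = _atomic_write(out / "qtl_report.txt", _frame_text(qtl, "qtl report"))

    sel = np.flatnonzero(panel.role != 0)
    freq = pd.DataFrame(
        {
            "locus": sel + 1,
            "chromosome": panel.geometry.chromosome[sel],
            "position_morgans": panel.geometry.position[sel],
            "role": np.where(panel.role[sel] == MARKER, "marker", "qtl"),
            "frequency": panel.frequency[sel],
        }
    )
    frequency_file = _atomic_write(out / "frequencies.txt", _frame_text(freq, "frequencies"))

    return OutputBundle(
        genotype_file=genotype_file,
        pedigree_file=pedigree_file,
        phenotype_file=phenotype_file,
        qtl_report_file=qtl_report_file,
        frequency_file=frequency_file,
    )


def export_plink(population: Population, panel: LocusPanel, out_dir) -> OutputBundle:
    """PED/MAP pair: alleles coded 1/2, MAP positions in centimorgans."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    midx = panel.marker_indices
    if midx.size == 0:
        raise ValueError("marker panel is empty")

    geom = panel.geometry
    map_rows = []
    for j, locus in enumerate(midx):
        chrom = geom.chromosome[locus]
        cm = geom.position[locus] * 100.0
        bp = int(round(geom.position[locus] * 1e6)) + 1
        map_rows.append(f"{chrom} M{j + 1} {cm:.6g} {bp}")
    map_file = _atomic_write(out / "gxesim.map", "\n".join(map_rows) + "\n")

    ped = population.pedigree
    haps = population.haplotypes.haplotypes
    lines = []
    for i in range(population.n_individuals):
        rec = ped.iloc[i]
        a = haps[2 * i, midx] + 1  # alleles coded 1/2
        b = haps[2 * i + 1, midx] + 1
        pairs = " ".join(f"{x} {y}" for x, y in zip(a, b))
        lines.append(f"1 {rec['id']} {rec['sire']} {rec['dam']} {rec['sex']} -9 {pairs}")
    ped_file = _atomic_write(out / "gxesim.ped", "\n".join(lines) + "\n")

    return OutputBundle(ped_file=ped_file, map_file=map_file)
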