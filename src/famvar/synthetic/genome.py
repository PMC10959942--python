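"""Synthetic genome model backing the cohort simulator.

A small diploid genome (six autosomes + chrX, 60 Mb each) with regularly
spaced multi-exon genes, fixed recurrent-genomic-disorder (RGD) loci,
segmental duplications, centromeres, a copy-number-stable map, an
excluded-region set for SNV filtering (emulating HLA/mucin/olfactory
clusters) and a pseudo-autosomal region on chrX. Array probes sit on a
regular grid so probe counts are exact functions of an interval.

All coordinates are 0-based half-open internally; BED output keeps that
convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

CHROM_LENGTH = 60_000_000
AUTOSOMES = tuple(f"chr{i}" for i in range(1, 7))
CHROMS = AUTOSOMES + ("chrX",)

GENES_PER_CHROM = 40
FIRST_GENE_START = 2_000_000
GENE_SPACING = 1_400_000
GENE_LENGTH = 60_000
N_EXONS = 10
EXON_LENGTH = 300
EXON_SPACING = 6_000  # start-to-start
UTR = 500  # span trimmed off each end of the gene to form the CDS

#: Fixed recurrent genomic disorder loci (chrom, start, end).
RGD_LOCI = (
    ("chr2", 10_000_000, 10_800_000),
    ("chr3", 20_000_000, 21_200_000),
    ("chr4", 39_700_000, 40_300_000),
    ("chr5", 15_000_000, 16_500_000),
)

#: Windows excluded from the copy-number-stable map besides centromeres.
CN_UNSTABLE = tuple((c, 48_000_000, 49_000_000) for c in CHROMS)

#: Regions excluded from SNV analysis (difficult-to-call gene clusters).
EXCLUDED_REGIONS = (("chr6", 6_000_000, 9_500_000),)

PAR_REGIONS = (("chrX", 0, 2_700_000),)

CENTROMERE_HALF = 500_000


def centromeres() -> list[tuple[str, int, int]]:
    mid = CHROM_LENGTH // 2
    return [(c, mid - CENTROMERE_HALF, mid + CENTROMERE_HALF) for c in CHROMS]


def segdups() -> list[tuple[str, int, int]]:
    """Segmental duplications: flanks of each RGD locus plus fixed windows."""
    out: list[tuple[str, int, int]] = []
    for chrom, start, end in RGD_LOCI:
        out.append((chrom, start - 100_000, start))
        out.append((chrom, end, end + 100_000))
    for c in CHROMS:
        out.append((c, 5_000_000, 5_200_000))
        out.append((c, 45_000_000, 45_150_000))
    return sorted(out)


def cn_stable_map() -> list[tuple[str, int, int]]:
    """Copy-number-stable regions: chromosomes minus centromeres/unstable windows."""
    holes: dict[str, list[tuple[int, int]]] = {c: [] for c in CHROMS}
    for chrom, s, e in list(centromeres()) + list(CN_UNSTABLE):
        holes[chrom].append((s, e))
    out = []
    for chrom in CHROMS:
        pos = 0
        for s, e in sorted(holes[chrom]):
            if s > pos:
                out.append((chrom, pos, s))
            pos = max(pos, e)
        if pos < CHROM_LENGTH:
            out.append((chrom, pos, CHROM_LENGTH))
    return out


def exon_starts(gene_start: int) -> list[int]:
    return [gene_start + i * EXON_SPACING for i in range(N_EXONS)]


def make_gene_table(rng: np.random.Generator) -> pd.DataFrame:
    """Build the per-gene annotation table.

    Columns: gene, chrom, start, end, cds_start, cds_end, exon_starts
    (comma-joined), exon_length, loeuf, phaplo, ptriplo, ndd_list,
    asd_list, moi (monoallelic/biallelic/both).
    """
    rows = []
    idx = 0
    for chrom in CHROMS:
        for g in range(GENES_PER_CHROM):
            start = FIRST_GENE_START + g * GENE_SPACING
            end = start + GENE_LENGTH
            rows.append(
                {
                    "gene": f"G{idx:04d}",
                    "chrom": chrom,
                    "start": start,
                    "end": end,
                    "cds_start": start + UTR,
                    "cds_end": end - UTR,
                    "exon_starts": ",".join(str(s) for s in exon_starts(start)),
                    "exon_length": EXON_LENGTH,
                }
            )
            idx += 1
    table = pd.DataFrame(rows)
    n = len(table)
    table["loeuf"] = np.round(rng.uniform(0.1, 1.5, size=n), 3)
    table["phaplo"] = np.round(rng.uniform(0.0, 1.0, size=n), 3)
    table["ptriplo"] = np.round(rng.uniform(0.0, 1.0, size=n), 3)
    table["ndd_list"] = rng.random(n) < 0.15
    table["asd_list"] = rng.random(n) < 0.08
    table["moi"] = rng.choice(
        ["monoallelic", "biallelic", "both"], size=n, p=[0.6, 0.2, 0.2]
    )
    return table


@dataclass
class SyntheticGenome:
    """Gene table plus all region sets, with probe-grid arithmetic."""

    genes: pd.DataFrame
    probe_spacing: int = 2_000

    @classmethod
    def build(cls, rng: np.random.Generator, probe_spacing: int = 2_000) -> "SyntheticGenome":
        return cls(genes=make_gene_table(rng), probe_spacing=probe_spacing)

    def n_probes(self, start: int, end: int) -> int:
        """Number of grid probes (multiples of the spacing) in [start, end)."""
        if end <= start:
            return 0
        first = -(-start // self.probe_spacing)  # ceil division
        last = (end - 1) // self.probe_spacing
        return max(0, last - first + 1)

    def genes_overlapping(self, chrom: str, start: int, end: int) -> pd.DataFrame:
        g = self.genes
        return g[(g["chrom"] == chrom) & (g["start"] < end) & (g["end"] > start)]

    def exon_intervals(self, gene_row) -> list[tuple[int, int]]:
        starts = [int(s) for s in str(gene_row.exon_starts).split(",")]
        return [(s, s + int(gene_row.exon_length)) for s in starts]

    def random_exonic_position(self, rng: np.random.Generator, gene_row) -> int:
        starts = [int(s) for s in str(gene_row.exon_starts).split(",")]
        s = int(rng.choice(starts))
        return s + int(rng.integers(0, EXON_LENGTH))

    # -- BED export -------------------------------------------------------
    def region_beds(self) -> dict[str, list[tuple[str, int, int]]]:
        exons = []
        for row in self.genes.itertuples(index=False):
            for s, e in self.exon_intervals(row):
                exons.append((row.chrom, s, e))
        return {
            "exons": exons,
            "rgd": list(RGD_LOCI),
            "segdup": segdups(),
            "centromere": centromeres(),
            "cn_stable": cn_stable_map(),
            "excluded": list(EXCLUDED_REGIONS),
            "par": list(PAR_REGIONS),
        }


def write_bed(intervals: list[tuple[str, int, int]], path: str | Path, names: list[str] | None = None) -> None:
    with open(path, "w") as fh:
        for i, (chrom, start, end) in enumerate(intervals):
            name = f"\t{names[i]}" if names else ""
            fh.write(f"{chrom}\t{start}\t{end}{name}\n")


def read_bed(path: str | Path) -> list[tuple[str, int, int]]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.rstrip("\n").split("\t")
            out.append((parts[0], int(parts[1]), int(parts[2])))
    return out
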