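"""One-call cohort simulation and serialization to the on-disk formats.

:func:`simulate` builds the whole synthetic study — genome, pedigrees,
dual-caller SNV call sets, multi-caller CNV call sets, PRS inputs and
fixture term/edge resources for enrichment — from a single seeded
configuration; :func:`write_cohort` lays it out as the file bundle the
pipeline (and any external tool) consumes.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .config import SimulationConfig
from .pedigree import Pedigree
from .synthetic import (
    GroundTruth,
    SyntheticGenome,
    generate_cnv_callsets,
    generate_pedigrees,
    generate_prs_inputs,
    generate_snv_callset,
    substreams,
)
from .synthetic.prs import SUMMARY_COLUMNS


@dataclass
class SyntheticCohort:
    config: SimulationConfig
    genome: SyntheticGenome
    pedigree: Pedigree
    ann: pd.DataFrame
    geno: pd.DataFrame
    cnv_calls: pd.DataFrame
    wgs_fids: set[str]
    summary: pd.DataFrame
    dosages: pd.DataFrame
    terms: list[dict]
    edges: list[tuple[str, str]]
    truth: GroundTruth


def make_term_fixture(genome: SyntheticGenome, rng: np.random.Generator, n_cc: int = 13, n_bp: int = 8) -> list[dict]:
    """Fixture gene-set terms over the synthetic gene universe (standing in
    for an external annotation service's cellular-component and
    biological-process vocabularies)."""
    genes = genome.genes["gene"].tolist()
    terms = []
    for domain, count in (("CC", n_cc), ("BP", n_bp)):
        parent = None
        for i in range(count):
            size = int(rng.integers(8, 30))
            members = sorted(rng.choice(genes, size=size, replace=False))
            term_id = f"{domain}:{i + 1:04d}"
            terms.append(dict(term=term_id, label=f"{domain.lower()}_term_{i + 1}", domain=domain,
                              parent=parent, genes=set(members)))
            if i == 0:
                parent = term_id  # shallow hierarchy rooted at the first term
    return terms


def make_edge_fixture(genome: SyntheticGenome, rng: np.random.Generator, density: float = 0.01) -> list[tuple[str, str]]:
    """Fixture interaction edges: sparse random graph with a denser core
    among the NDD-listed genes (synthetic stand-in for a protein
    interaction network)."""
    genes = genome.genes["gene"].tolist()
    ndd = genome.genes.loc[genome.genes["ndd_list"], "gene"].tolist()
    edges: set[frozenset] = set()
    n = len(genes)
    n_random = int(density * n * (n - 1) / 2)
    for _ in range(n_random):
        a, b = rng.choice(genes, size=2, replace=False)
        edges.add(frozenset((a, b)))
    for _ in range(max(1, len(ndd) * 2)):
        if len(ndd) >= 2:
            a, b = rng.choice(ndd, size=2, replace=False)
            edges.add(frozenset((a, b)))
    return [tuple(sorted(e)) for e in sorted(edges, key=lambda e: tuple(sorted(e)))]


def simulate(config: SimulationConfig) -> SyntheticCohort:
    """Generate the full cohort; identical configs give identical cohorts."""
    rngs = substreams(config.seed)
    genome = SyntheticGenome.build(rngs["genome"], probe_spacing=config.probe_spacing_bp)
    pedigree = generate_pedigrees(config, rngs["pedigree"])
    truth = GroundTruth()
    ann, geno, truth = generate_snv_callset(pedigree, config, genome, rngs["snv"], truth)
    cnv_calls, truth, wgs_fids = generate_cnv_callsets(pedigree, config, genome, rngs["cnv"], truth)
    summary, dosages, truth = generate_prs_inputs(pedigree, config, rngs["prs"], truth)
    terms = make_term_fixture(genome, rngs["genome"])
    edges = make_edge_fixture(genome, rngs["genome"])
    return SyntheticCohort(
        config=config, genome=genome, pedigree=pedigree, ann=ann, geno=geno,
        cnv_calls=cnv_calls, wgs_fids=wgs_fids, summary=summary, dosages=dosages,
        terms=terms, edges=edges, truth=truth,
    )


def write_cohort(cohort: SyntheticCohort, out_dir: str | Path) -> dict[str, Path]:
    """Serialize a cohort to its input-file bundle; returns the path map."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf_caller_a": out / "caller_a.vcf",
        "vcf_caller_b": out / "caller_b.vcf",
        "ped_path": out / "cohort.ped",
        "annotation_path": out / "annotations.tsv",
        "gene_table_path": out / "genes.tsv",
        "cnv_calls_path": out / "cnv_calls.tsv",
        "gwas_path": out / "gwas_summary.tsv",
        "dosage_path": out / "dosages.tsv",
        "truth_path": out / "truth.json",
        "terms_path": out / "terms.gmt",
        "edges_path": out / "edges.tsv",
    }
    io.write_vcf(paths["vcf_caller_a"], cohort.ann, cohort.geno, cohort.pedigree, "a")
    io.write_vcf(paths["vcf_caller_b"], cohort.ann, cohort.geno, cohort.pedigree, "b")
    cohort.pedigree.write(paths["ped_path"])
    io.write_tsv(cohort.ann, paths["annotation_path"])
    io.write_tsv(cohort.genome.genes, paths["gene_table_path"])
    io.write_tsv(cohort.cnv_calls, paths["cnv_calls_path"])
    io.write_tsv(cohort.summary[SUMMARY_COLUMNS], paths["gwas_path"])
    io.write_tsv(cohort.dosages.reset_index(), paths["dosage_path"])
    cohort.truth.to_json(paths["truth_path"])
    io.write_terms(cohort.terms, paths["terms_path"])
    pd.DataFrame(cohort.edges, columns=["gene1", "gene2"]).to_csv(paths["edges_path"], sep="\t", index=False)
    beds = cohort.genome.region_beds()
    from .synthetic.genome import write_bed

    for name, key in (
        ("excluded", "excluded_bed"), ("rgd", "rgd_bed"), ("segdup", "segdup_bed"),
        ("centromere", "centromere_bed"), ("cn_stable", "cn_stable_bed"),
        ("exons", "exon_bed"), ("par", "par_bed"),
    ):
        paths[key] = out / f"{name}.bed"
        write_bed(beds[name], paths[key])
    with open(out / "wgs_families.txt", "w") as fh:
        for fid in sorted(cohort.wgs_fids):
            fh.write(fid + "\n")
    paths["wgs_families_path"] = out / "wgs_families.txt"
    return paths
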