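"""End-to-end pipeline: simulate (optional), then the analysis stages.

Stage order: de novo SNVs -> CNV consensus/prioritization -> recessive and
X-linked scans -> PRS/pTDT -> cohort statistics -> enrichment. Every stage
writes its report into the output directory; a run log records the seed,
thresholds and per-stage counts. Reports contain no timestamps, so two
runs with the same configuration are byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, cnv, denovo, enrich, io, prs, recessive, stats
from .config import PipelineConfig
from .pedigree import Pedigree
from .simulate import simulate, write_cohort
from .synthetic.genome import read_bed

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _require(config: PipelineConfig, *names: str) -> None:
    missing = [n for n in names if getattr(config, n) is None]
    if missing:
        raise FileNotFoundError(f"missing required inputs: {missing}")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns the report bundle as a dict."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    th = config.thresholds
    log: dict = {"famvar_version": __version__, "seed": config.seed,
                 "thresholds": th.model_dump(), "stages": {}}

    if config.simulate:
        try:
            cohort = simulate(config.simulation)
            paths = write_cohort(cohort, out / "inputs")
            for key, path in paths.items():
                if hasattr(config, key):
                    setattr(config, key, path)
            config.terms_path = paths["terms_path"]  # type: ignore[attr-defined]
            config.edges_path = paths["edges_path"]  # type: ignore[attr-defined]
            log["stages"]["simulate"] = {
                "n_families": config.simulation.n_families,
                "n_variants": len(cohort.ann),
                "n_cnv_calls": len(cohort.cnv_calls),
                "n_prs_snps": len(cohort.summary),
            }
        except Exception as e:  # pragma: no cover - defensive
            raise StageError("simulate", e) from e

    # ---- load inputs ------------------------------------------------------
    try:
        _require(config, "vcf_caller_a", "vcf_caller_b", "ped_path", "annotation_path",
                 "gene_table_path", "excluded_bed")
        pedigree = Pedigree.read(config.ped_path)
        ann = io.read_tsv(config.annotation_path)
        gene_table = io.read_tsv(config.gene_table_path)
        excluded = read_bed(config.excluded_bed)
        par = read_bed(config.par_bed) if config.par_bed else []
    except StageError:
        raise
    except Exception as e:
        raise StageError("load_inputs", e) from e

    # ---- de novo SNV stage ------------------------------------------------
    try:
        geno = io.read_dual_caller_geno(config.vcf_caller_a, config.vcf_caller_b, pedigree)
        records = io.build_trio_records(ann, geno, pedigree)
        carriers_mono = denovo.pdsnv_table(ann, records, excluded, th, mode="monoallelic")
        carriers_bi = denovo.pdsnv_table(ann, records, excluded, th, mode="biallelic")
        io.write_tsv(carriers_mono, out / "pdsnv.tsv")
        log["stages"]["denovo"] = {
            "trio_records": len(records),
            "retained_carrier_records": len(carriers_mono),
            "de_novo_calls": int((carriers_mono["origin"] == "de_novo").sum()),
            "pdsnv_records": int(carriers_mono["pdsnv"].sum()),
        }
    except Exception as e:
        raise StageError("denovo", e) from e

    # ---- CNV stage --------------------------------------------------------
    rare_children = pd.DataFrame()
    platform_counts: dict[str, int] = {}
    try:
        if config.cnv_calls_path is None:
            raise FileNotFoundError("cnv_calls_path not set")
        calls = io.read_tsv(config.cnv_calls_path)
        regions = {
            "segdup": read_bed(config.segdup_bed),
            "centromere": read_bed(config.centromere_bed),
            "cn_stable": read_bed(config.cn_stable_bed),
            "rgd": read_bed(config.rgd_bed),
        }
        consensus = cnv.build_array_consensus(calls, th)
        wgs = cnv.wgs_callset(calls)
        merged, platform_counts = cnv.reconcile_array_wgs(consensus, wgs, th)
        founders = {p.iid for p in pedigree.founders}
        parent_calls = merged[merged["sample_id"].isin(founders)]
        annotated = cnv.annotate_consensus(merged, gene_table, regions, parent_calls, len(founders), th)
        # inheritance for children's calls against the parents' call sets
        inheritance = []
        for row in annotated.itertuples(index=False):
            ind = pedigree.individual(row.sample_id) if row.sample_id in pedigree else None
            if ind is None or ind.is_founder:
                inheritance.append("")
                continue
            father, mother = pedigree.parents_of(ind.iid)
            fc = parent_calls[parent_calls["sample_id"] == (father.iid if father else "")]
            mc = parent_calls[parent_calls["sample_id"] == (mother.iid if mother else "")]
            inheritance.append(
                cnv.determine_cnv_inheritance(row, fc, mc, th,
                                              father_present=father is not None,
                                              mother_present=mother is not None)
            )
        annotated["inheritance"] = inheritance
        rare = cnv.filter_rare_exonic(annotated, th)
        children_ids = {c.iid for f in pedigree.families for c in f.children}
        rare_children = rare[rare["sample_id"].isin(children_ids)].reset_index(drop=True)
        rare_children = cnv.prioritize_pdcnv(rare_children, gene_table, th)
        io.write_tsv(rare_children, out / "pdcnv.tsv")
        log["stages"]["cnv"] = {
            "raw_calls": len(calls),
            "array_consensus": len(consensus),
            "platform_counts": platform_counts,
            "rare_exonic_children": len(rare_children),
            "pdcnv": int((rare_children["category"] != "").sum()) if len(rare_children) else 0,
        }
    except Exception as e:
        raise StageError("cnv", e) from e

    # ---- recessive / X-linked / multiple hits ----------------------------
    try:
        biallelic = recessive.find_biallelic_events(carriers_bi, rare_children, gene_table, ann)
        xlinked = recessive.find_xlinked_candidates(carriers_mono, rare_children, pedigree, par, ann)
        bias = {
            s: recessive.transmission_bias_test(carriers_mono, pedigree, ann, subset=s)
            for s in ("all", "novel", "novel_not_shared")
        }
        multihits = recessive.detect_multiple_hits(rare_children, carriers_mono, gene_table, pedigree)
        io.write_tsv(biallelic, out / "biallelic_events.tsv")
        io.write_tsv(xlinked, out / "xlinked_candidates.tsv")
        io.write_tsv(multihits, out / "multiple_hits.tsv")
        log["stages"]["recessive"] = {
            "biallelic_events": len(biallelic),
            "xlinked_candidates": len(xlinked),
            "multiple_hit_probands": int(multihits["proband"].nunique()) if len(multihits) else 0,
            "transmission_bias": {k: {"paternal": v[0], "maternal": v[1], "p": round(v[2], 4)} for k, v in bias.items()},
        }
    except Exception as e:
        raise StageError("recessive", e) from e

    # ---- PRS / pTDT -------------------------------------------------------
    try:
        _require(config, "gwas_path", "dosage_path")
        summary = io.read_tsv(config.gwas_path)
        dosages = io.read_tsv(config.dosage_path).set_index("snp")
        founders = [p.iid for p in pedigree.founders if p.iid in dosages.columns]
        r2 = prs.r2_from_dosages(dosages, founders)
        selected = prs.qc_and_clump(summary, r2, th)
        scores = prs.compute_prs(dosages, selected, th)
        ptdt_results = {}

        def try_ptdt(group: str, trios) -> None:
            if len(trios) < 2:
                return
            try:
                ptdt_results[group] = asdict(prs.ptdt_test(scores, trios, group))
            except ValueError as err:  # degenerate group (e.g. shared parents)
                logger.warning("pTDT skipped for group %s: %s", group, err)

        for group, affected in (("cases", True), ("unaffected_siblings", False)):
            try_ptdt(group, prs.cohort_trios(pedigree, scores, affected))
        spx = {c.iid for f in pedigree.families if f.family_type == "SPX" for c in f.affected_children}
        for group, ids in (("SPX", spx), ("MPX", {c.iid for c in pedigree.affected_children} - spx)):
            try_ptdt(group, [t for t in prs.cohort_trios(pedigree, scores, True) if t[0] in ids])
        scores.rename("prs").to_frame().reset_index(names="individual").to_csv(
            out / "prs_scores.tsv", sep="\t", index=False
        )
        with open(out / "ptdt.json", "w") as fh:
            json.dump(ptdt_results, fh, indent=1, sort_keys=True)
        log["stages"]["prs"] = {"snps_retained": len(selected), "individuals_scored": len(scores)}
    except Exception as e:
        raise StageError("prs", e) from e

    # ---- cohort statistics ------------------------------------------------
    try:
        burden = stats.denovo_rates(carriers_mono, pedigree)
        cases = {c.iid for c in pedigree.affected_children}
        sibs = {c.iid for c in pedigree.unaffected_children}
        dn = carriers_mono[carriers_mono["origin"] == "de_novo"]
        tab = stats.carrier_table(dn, cases, sibs)
        chi2_stat, chi2_p = (np.nan, np.nan)
        if min(tab.a + tab.b, tab.c + tab.d) > 0 and tab.a + tab.c > 0 and tab.b + tab.d > 0:
            chi2_stat, chi2_p = stats.chi2_test(tab)
        gene_lists = {
            "ASD": set(gene_table.loc[gene_table["asd_list"], "gene"]),
            "NDD": set(gene_table.loc[gene_table["ndd_list"], "gene"]),
        }
        novel_ids = set(ann.loc[ann["maf_mono"] == 0.0, "variant_id"])
        classes = {
            "pdsnv": carriers_mono["pdsnv"],
            "de_novo_pdsnv": carriers_mono["pdsnv"] & (carriers_mono["origin"] == "de_novo"),
            "severe_pdsnv": carriers_mono["pdsnv"] & carriers_mono["severe"],
            "novel_pdsnv": carriers_mono["pdsnv"] & carriers_mono["variant_id"].isin(novel_ids),
        }
        burden_table = stats.genelist_burden(carriers_mono, gene_lists, pedigree, classes)
        males = sum(1 for c in pedigree.affected_children if c.is_male)
        females = len(pedigree.affected_children) - males
        stats_report = {
            "burden": {k: asdict(v) for k, v in burden.items()},
            "carrier_chi2": {"table": [[tab.a, tab.b], [tab.c, tab.d]],
                             "stat": None if np.isnan(chi2_stat) else round(chi2_stat, 4),
                             "p": None if np.isnan(chi2_p) else round(chi2_p, 4)},
            "male_female_ratio": round(males / females, 1) if females else None,
            "genelist_burden": burden_table.round(4).to_dict(orient="records"),
        }
        with open(out / "stats.json", "w") as fh:
            json.dump(stats_report, fh, indent=1, sort_keys=True)
        log["stages"]["stats"] = {"groups": list(burden)}
    except Exception as e:
        raise StageError("stats", e) from e

    # ---- enrichment -------------------------------------------------------
    try:
        terms_path = getattr(config, "terms_path", None)
        edges_path = getattr(config, "edges_path", None)
        enrichment_report = pd.DataFrame()
        edge_result = None
        if terms_path and edges_path:
            terms = io.read_terms(terms_path)
            edge_df = io.read_tsv(edges_path)
            edges = list(zip(edge_df["gene1"], edge_df["gene2"]))
            background = set(gene_table["gene"])
            query = set(carriers_mono.loc[carriers_mono["pdsnv"] & carriers_mono["individual"].isin(cases), "gene"])
            query &= background
            enrichment_report = enrich.term_enrichment(query, background, terms, th.fdr_q)
            dn_genes = set(dn.loc[dn["pdsnv"], "gene"]) & background
            edge_result = enrich.edge_enrichment(dn_genes, edges, background)
            io.write_tsv(enrichment_report, out / "term_enrichment.tsv")
            with open(out / "edge_enrichment.json", "w") as fh:
                json.dump(asdict(edge_result), fh, indent=1, sort_keys=True)
        log["stages"]["enrich"] = {
            "terms_tested": len(enrichment_report),
            "significant_terms": int(enrichment_report["significant"].sum()) if len(enrichment_report) else 0,
            "edge_fold": None if edge_result is None else round(edge_result.fold, 3),
        }
    except Exception as e:
        raise StageError("enrich", e) from e

    with open(out / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=1, sort_keys=True, default=str)
    return log
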