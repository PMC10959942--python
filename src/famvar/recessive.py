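"""Family scans for recessive-acting and multi-hit variation.

Covers four analyses: biallelic events (homozygous pdSNVs, per-gene trans
compound heterozygotes, and deletion + pdSNV compounds), X-linked
hemizygous candidates in male probands, the paternal-vs-maternal
transmission balance of inherited pdSNVs, and secondary hits in probands
carrying recurrent-genomic-disorder (RGD) CNVs.

Phase is taken from parental transmission only: two alleles form a trans
pair when their parental origins differ, or when one origin is unknown or
de novo and the other is established. Two same-parent alleles are assumed
cis and never paired.
"""

from __future__ import annotations

import pandas as pd
from scipy import stats

from .pedigree import Pedigree

_ESTABLISHED = ("paternal", "maternal")


def _trans_pair(origin1: str, origin2: str) -> bool:
    if origin1 in _ESTABLISHED and origin2 in _ESTABLISHED:
        return origin1 != origin2
    if origin1 in _ESTABLISHED or origin2 in _ESTABLISHED:
        return origin2 in ("unknown", "de_novo") or origin1 in ("unknown", "de_novo")
    return False


def find_biallelic_events(
    carriers: pd.DataFrame,
    cnvs: pd.DataFrame | None,
    gene_table: pd.DataFrame,
    variants: pd.DataFrame,
) -> pd.DataFrame:
    """Biallelic pdSNV/pdCNV events per proband and gene.

    ``carriers`` is the per-individual carrier table under the biallelic
    rarity model (<= 1% MAF) with pdSNV flags and parental origins;
    ``cnvs`` the rare CNV set with ``inheritance`` labels. ``passes_strict``
    requires zero homozygotes in the reference population for every SNV
    allele and a biallelic (or dual) mode of inheritance for the gene.
    """
    moi = dict(zip(gene_table["gene"], gene_table["moi"]))
    hom_col = variants["gnomad_hom"] if "gnomad_hom" in variants.columns else pd.Series(0, index=variants.index)
    hom_ref = dict(zip(variants["variant_id"], hom_col))
    pds = carriers[carriers["pdsnv"]]
    events = []

    def strict(gene: str, allele_vids: list[str]) -> bool:
        if moi.get(gene) not in ("biallelic", "both"):
            return False
        return all(hom_ref.get(v, 0) == 0 for v in allele_vids if v in hom_ref)

    for (iid, gene), grp in pds.groupby(["individual", "gene"], sort=True):
        rows = grp.sort_values("variant_id").to_dict("records")
        # homozygous pdSNVs
        for r in rows:
            if r["genotype"] == 2:
                events.append(
                    dict(
                        gene=gene, proband=iid, allele1=r["variant_id"], allele2=r["variant_id"],
                        origin1="paternal", origin2="maternal", kind="hom",
                        passes_strict=strict(gene, [r["variant_id"]]),
                    )
                )
        # trans compound hets (canonical order: sorted variant ids)
        for i in range(len(rows)):
            for j in range(i + 1, len(rows)):
                a, b = rows[i], rows[j]
                if a["genotype"] == 2 or b["genotype"] == 2:
                    continue
                if _trans_pair(a["origin"], b["origin"]):
                    events.append(
                        dict(
                            gene=gene, proband=iid,
                            allele1=a["variant_id"], allele2=b["variant_id"],
                            origin1=a["origin"], origin2=b["origin"],
                            kind="comphet_snv_snv",
                            passes_strict=strict(gene, [a["variant_id"], b["variant_id"]]),
                        )
                    )

    # deletion + pdSNV compounds
    if cnvs is not None and len(cnvs):
        dels = cnvs[cnvs["cnv_type"] == "DEL"]
        for d in dels.itertuples(index=False):
            genes = str(d.genes).split(",") if getattr(d, "genes", "") else []
            sub = pds[(pds["individual"] == d.sample_id) & (pds["gene"].isin(genes))]
            for r in sub.itertuples(index=False):
                if r.genotype == 2:
                    continue
                if _trans_pair(d.inheritance, r.origin):
                    events.append(
                        dict(
                            gene=r.gene, proband=d.sample_id,
                            allele1=f"{d.chrom}:{d.start}-{d.end}:DEL", allele2=r.variant_id,
                            origin1=d.inheritance, origin2=r.origin,
                            kind="comphet_cnv_snv",
                            passes_strict=strict(r.gene, [r.variant_id]),
                        )
                    )
    cols = ["gene", "proband", "allele1", "allele2", "origin1", "origin2", "kind", "passes_strict"]
    return pd.DataFrame(events, columns=cols)


def find_xlinked_candidates(
    carriers: pd.DataFrame,
    cnvs: pd.DataFrame | None,
    pedigree: Pedigree,
    par_regions: list[tuple[str, int, int]],
    variants: pd.DataFrame,
) -> pd.DataFrame:
    """Hemizygous chrX pdSNVs/pdCNVs in male probands, absent from every
    unaffected full brother. Adds absence-in-reference-males annotation."""
    hemi_col = (
        variants["gnomad_male_hemi"] if "gnomad_male_hemi" in variants.columns else pd.Series(0, index=variants.index)
    )
    male_hemi_ref = dict(zip(variants["variant_id"], hemi_col))
    par = [(s, e) for c, s, e in par_regions if c == "chrX"]
    x = carriers[(carriers["chrom"] == "chrX") & carriers["pdsnv"]]
    out = []
    for r in x.itertuples(index=False):
        ind = pedigree.individual(r.individual)
        if not (ind.is_male and ind.affected):
            continue
        if any(s <= r.pos < e for s, e in par):
            continue
        brothers = pedigree.unaffected_brothers(ind.iid)
        carrier_ids = set(x.loc[x["variant_id"] == r.variant_id, "individual"])
        if any(b.iid in carrier_ids for b in brothers):
            continue
        out.append(
            dict(
                proband=r.individual, kind="snv", item=r.variant_id, gene=r.gene, bin=r.bin,
                absent_in_unaffected_brothers=True,
                absent_in_reference_males=male_hemi_ref.get(r.variant_id, 0) == 0,
            )
        )
    if cnvs is not None and len(cnvs):
        xc = cnvs[cnvs["chrom"] == "chrX"]
        for d in xc.itertuples(index=False):
            ind = pedigree.individual(d.sample_id) if d.sample_id in pedigree else None
            if ind is None or not (ind.is_male and ind.affected):
                continue
            brothers = {b.iid for b in pedigree.unaffected_brothers(ind.iid)}
            shared = xc[(xc["sample_id"].isin(brothers)) & (xc["start"] < d.end) & (xc["end"] > d.start)]
            if len(shared):
                continue
            out.append(
                dict(
                    proband=d.sample_id, kind="cnv", item=f"{d.chrom}:{d.start}-{d.end}:{d.cnv_type}",
                    gene=getattr(d, "genes", ""), bin="",
                    absent_in_unaffected_brothers=True, absent_in_reference_males=True,
                )
            )
    cols = ["proband", "kind", "item", "gene", "bin", "absent_in_unaffected_brothers", "absent_in_reference_males"]
    return pd.DataFrame(out, columns=cols)


def transmission_bias_test(
    carriers: pd.DataFrame,
    pedigree: Pedigree,
    variants: pd.DataFrame,
    subset: str = "all",
) -> tuple[int, int, float]:
    """Paternal vs maternal counts of inherited pdSNVs in affected
    children, with a two-sided exact binomial test against 1/2.

    subset: "all", "novel" (absent from the reference populations) or
    "novel_not_shared" (additionally not carried by any unaffected
    sibling). Zero informative transmissions return p = 1.
    """
    if subset not in ("all", "novel", "novel_not_shared"):
        raise ValueError(f"unknown subset {subset!r}")
    affected = {c.iid for c in pedigree.affected_children}
    unaffected = {c.iid for c in pedigree.unaffected_children}
    inh = carriers[
        carriers["pdsnv"]
        & carriers["origin"].isin(_ESTABLISHED)
        & carriers["individual"].isin(affected)
    ]
    if subset in ("novel", "novel_not_shared"):
        maf = variants.set_index("variant_id")[["maf_mono"]]
        novel_ids = set(maf.index[maf["maf_mono"] == 0.0])
        inh = inh[inh["variant_id"].isin(novel_ids)]
    if subset == "novel_not_shared":
        shared = set(carriers.loc[carriers["individual"].isin(unaffected), "variant_id"])
        inh = inh[~inh["variant_id"].isin(shared)]
    paternal = int((inh["origin"] == "paternal").sum())
    maternal = int((inh["origin"] == "maternal").sum())
    n = paternal + maternal
    p = 1.0 if n == 0 else float(stats.binomtest(paternal, n, 0.5).pvalue)
    return paternal, maternal, p


def detect_multiple_hits(
    pdcnvs: pd.DataFrame,
    carriers: pd.DataFrame,
    gene_table: pd.DataFrame,
    pedigree: Pedigree,
) -> pd.DataFrame:
    """Secondary hits in probands carrying RGD CNVs.

    Qualifying hits: de novo pdSNVs; protein-truncating variants in
    constrained genes (PTV_LOEUF) within the NDD gene list, any origin;
    and pdCNVs inherited from the parent who did not transmit the
    recurrent CNV.
    """
    ndd_genes = set(gene_table.loc[gene_table["ndd_list"], "gene"])
    affected = {c.iid for c in pedigree.affected_children}
    rgd_rows = pdcnvs[(pdcnvs["category"] == "RGD") & pdcnvs["sample_id"].isin(affected)]
    hits = []
    for rgd in rgd_rows.itertuples(index=False):
        iid = rgd.sample_id
        sub = carriers[carriers["individual"] == iid]
        for r in sub[(sub["origin"] == "de_novo") & sub["pdsnv"]].itertuples(index=False):
            hits.append(
                dict(proband=iid, rgd_cnv=rgd.rgd_hit, hit_class="de_novo_pdsnv",
                     detail=f"{r.variant_id}({r.gene},{r.bin})")
            )
        ptv = sub[(sub["bin"] == "PTV_LOEUF") & sub["gene"].isin(ndd_genes)]
        for r in ptv.itertuples(index=False):
            if r.origin == "de_novo":
                continue  # already counted above when pdSNV
            hits.append(
                dict(proband=iid, rgd_cnv=rgd.rgd_hit, hit_class="ptv_loeuf_ndd",
                     detail=f"{r.variant_id}({r.gene})")
            )
        other_parent = {"paternal": "maternal", "maternal": "paternal"}.get(rgd.inheritance)
        if other_parent:
            others = pdcnvs[
                (pdcnvs["sample_id"] == iid)
                & (pdcnvs["inheritance"] == other_parent)
                & (pdcnvs["category"] != "")
                & ~(
                    (pdcnvs["chrom"] == rgd.chrom)
                    & (pdcnvs["start"] == rgd.start)
                    & (pdcnvs["end"] == rgd.end)
                )
            ]
            for o in others.itertuples(index=False):
                hits.append(
                    dict(proband=iid, rgd_cnv=rgd.rgd_hit, hit_class="pdcnv_other_parent",
                         detail=f"{o.chrom}:{o.start}-{o.end}:{o.cnv_type}")
                )
    cols = ["proband", "rgd_cnv", "hit_class", "detail"]
    return pd.DataFrame(hits, columns=cols)
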