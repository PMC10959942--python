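"""Readers and writers for every on-disk format the pipeline touches.

Minimal VCF v4.2 with ``GT:DP:GQ:AD`` per sample (one file per emulated
caller; reading via cyvcf2), 6-column PED, BED (0-based half-open), TSV
for all tabular data, a GMT-like term file for enrichment, and the ground
truth JSON sidecar. Internal coordinates are 0-based half-open; VCF
positions are 1-based as the format requires.

Male chrX genotypes are written haploid ("0"/"1"); an alt count of 1 on a
haploid call means hemizygous carrier.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .pedigree import Pedigree
from .synthetic.genome import CHROMS, CHROM_LENGTH


class VcfFormatError(ValueError):
    """Raised when a VCF record lacks the required FORMAT fields."""


_CHROM_RANK = {c: i for i, c in enumerate(CHROMS)}


def _sorted_sites(ann: pd.DataFrame) -> pd.DataFrame:
    rank = ann["chrom"].map(_CHROM_RANK).fillna(len(_CHROM_RANK))
    return ann.assign(_rank=rank).sort_values(["_rank", "pos", "variant_id"]).drop(columns="_rank")


def write_vcf(
    path: str | Path,
    ann: pd.DataFrame,
    geno: pd.DataFrame,
    pedigree: Pedigree,
    caller: str,
) -> None:
    """Write one emulated caller's call set as VCF v4.2.

    ``caller`` selects the genotype column (``gt_a`` or ``gt_b``). Samples
    not in the variant's family are emitted as confident reference calls.
    """
    gt_col = f"gt_{caller}"
    if gt_col not in geno.columns:
        raise ValueError(f"unknown caller {caller!r}")
    samples = [ind.iid for ind in pedigree.individuals]
    sex = {ind.iid: ind.sex for ind in pedigree.individuals}
    by_variant: dict[str, dict[str, tuple]] = {}
    for row in geno.itertuples(index=False):
        by_variant.setdefault(row.variant_id, {})[row.iid] = (
            getattr(row, gt_col), row.dp, row.gq, row.ad_ref, row.ad_alt
        )
    sites = _sorted_sites(ann)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##source=famvar-synthetic-{caller}\n")
        for c in CHROMS:
            fh.write(f"##contig=<ID={c},length={CHROM_LENGTH}>\n")
        fh.write('##FILTER=<ID=LowQual,Description="Low quality">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">\n')
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples) + "\n")
        for site in sites.itertuples(index=False):
            calls = by_variant.get(site.variant_id, {})
            haploid_chrom = site.chrom == "chrX"
            fields = []
            for iid in samples:
                male_haploid = haploid_chrom and sex[iid] == 1
                if iid in calls:
                    gt, dp, gq, adr, ada = calls[iid]
                    gt, dp, gq, adr, ada = int(gt), int(dp), int(gq), int(adr), int(ada)
                    if gt < 0:
                        gstr = "." if male_haploid else "./."
                    elif male_haploid:
                        gstr = "1" if gt >= 1 else "0"
                    else:
                        gstr = {0: "0/0", 1: "0/1", 2: "1/1"}[min(gt, 2)]
                    fields.append(f"{gstr}:{dp}:{gq}:{adr},{ada}")
                else:
                    gstr = "0" if male_haploid else "0/0"
                    fields.append(f"{gstr}:30:99:30,0")
            fh.write(
                f"{site.chrom}\t{site.pos + 1}\t{site.variant_id}\t{site.ref}\t{site.alt}\t.\t"
                f"{site.filter_status}\t.\tGT:DP:GQ:AD\t" + "\t".join(fields) + "\n"
            )


def _read_vcf_genotypes(path: str | Path, samples_expected: list[str]):
    """Yield (variant_id, chrom, pos0, filter, alt_counts, dp, gq, ad) per record."""
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=False)
    missing = [s for s in samples_expected if s not in vcf.samples]
    if missing:
        raise ValueError(f"samples in pedigree missing from VCF {path}: {missing}")
    order = [vcf.samples.index(s) for s in samples_expected]
    for i, v in enumerate(vcf, start=1):
        fmt = v.FORMAT
        if not {"GT", "DP", "GQ", "AD"}.issubset(set(fmt)):
            raise VcfFormatError(
                f"record {i} at {v.CHROM}:{v.POS}: FORMAT must contain GT:DP:GQ:AD, got {':'.join(fmt)}"
            )
        alt = np.empty(len(order), dtype=np.int16)
        for k, idx in enumerate(order):
            alleles = v.genotypes[idx][:-1]
            if any(a < 0 for a in alleles):
                alt[k] = -1
            else:
                alt[k] = sum(1 for a in alleles if a > 0)
        dp = v.format("DP")[:, 0].astype(np.int32)[order]
        gq = v.format("GQ")[:, 0].astype(np.int32)[order]
        ad = v.format("AD").astype(np.int32)[order]
        vid = v.ID or f"{v.CHROM}:{v.POS}"
        yield vid, v.CHROM, v.POS - 1, (v.FILTER or "PASS"), alt, dp, gq, ad


def read_dual_caller_geno(
    vcf_a: str | Path, vcf_b: str | Path, pedigree: Pedigree
) -> pd.DataFrame:
    """Reconstruct the long genotype table from the two caller VCFs.

    Rows are restricted to families containing at least one alternate-
    allele carrier in either call set (the rest of the cohort is reference
    at a private variant).
    """
    samples = [ind.iid for ind in pedigree.individuals]
    fid_of = np.array([ind.fid for ind in pedigree.individuals])
    gt_b: dict[str, np.ndarray] = {}
    for vid, *_rest in _read_vcf_genotypes(vcf_b, samples):
        gt_b[vid] = _rest[3]
    rows = []
    for vid, chrom, pos, filt, alt, dp, gq, ad in _read_vcf_genotypes(vcf_a, samples):
        b = gt_b.get(vid, np.zeros(len(samples), dtype=np.int16))
        carrier = (alt > 0) | (b > 0)
        if not carrier.any():
            continue
        fids = set(fid_of[carrier])
        keep = np.isin(fid_of, list(fids))
        for k in np.flatnonzero(keep):
            rows.append(
                dict(
                    variant_id=vid, fid=fid_of[k], iid=samples[k],
                    gt_a=int(alt[k]), gt_b=int(b[k]),
                    dp=int(dp[k]), gq=int(gq[k]),
                    ad_ref=int(ad[k, 0]), ad_alt=int(ad[k, 1]),
                )
            )
    return pd.DataFrame(rows)


def read_trio_vcf(path: str | Path, pedigree: Pedigree) -> pd.DataFrame:
    """Single-caller convenience reader: long genotype table for carriers'
    families, with allele balance derived from AD."""
    samples = [ind.iid for ind in pedigree.individuals]
    fid_of = np.array([ind.fid for ind in pedigree.individuals])
    rows = []
    for vid, chrom, pos, filt, alt, dp, gq, ad in _read_vcf_genotypes(path, samples):
        carrier = alt > 0
        if not carrier.any():
            continue
        fids = set(fid_of[carrier])
        keep = np.isin(fid_of, list(fids))
        for k in np.flatnonzero(keep):
            denom = ad[k, 0] + ad[k, 1]
            rows.append(
                dict(
                    variant_id=vid, chrom=chrom, pos=pos, filter_status=filt,
                    fid=fid_of[k], iid=samples[k], gt=int(alt[k]),
                    dp=int(dp[k]), gq=int(gq[k]),
                    ad_ref=int(ad[k, 0]), ad_alt=int(ad[k, 1]),
                    ab=float(ad[k, 1] / denom) if denom > 0 else np.nan,
                )
            )
    return pd.DataFrame(rows)


def build_trio_records(ann: pd.DataFrame, geno: pd.DataFrame, pedigree: Pedigree) -> pd.DataFrame:
    """Per-(variant, child) dual-caller trio records.

    Missing parents yield NaN genotype columns; allele balance is
    alt_reads / (ref_reads + alt_reads) from the AD field.
    """
    children = pd.DataFrame(
        [
            dict(iid=c.iid, fid=c.fid, father_id=c.father, mother_id=c.mother)
            for c in pedigree.individuals
            if not c.is_founder
        ]
    )
    child_rows = geno.merge(children, on=["iid", "fid"], how="inner")
    parent_side = geno[["variant_id", "iid", "gt_a", "gt_b", "dp", "gq", "ad_alt"]]

    def attach(side: str, key: str) -> pd.DataFrame:
        renamed = parent_side.rename(
            columns={
                "iid": key,
                "gt_a": f"{side}_gt_a", "gt_b": f"{side}_gt_b",
                "dp": f"{side}_dp", "gq": f"{side}_gq", "ad_alt": f"{side}_ao",
            }
        )
        return child_rows.merge(renamed, on=["variant_id", key], how="left")

    child_rows = attach("father", "father_id")
    child_rows = attach("mother", "mother_id")
    denom = child_rows["ad_ref"] + child_rows["ad_alt"]
    child_rows["child_ab"] = np.where(denom > 0, child_rows["ad_alt"] / denom, np.nan)
    out = child_rows.rename(
        columns={
            "iid": "child_id", "gt_a": "child_gt_a", "gt_b": "child_gt_b",
            "dp": "child_dp", "gq": "child_gq",
        }
    )
    site_cols = [c for c in ("chrom", "pos", "gene", "filter_status") if c in ann.columns]
    out = out.merge(ann[["variant_id", *site_cols]], on="variant_id", how="left")
    for c in ("chrom", "pos", "gene", "filter_status"):
        if c not in out.columns:
            out[c] = pd.NA
    cols = [
        "variant_id", "chrom", "pos", "gene", "filter_status", "fid", "child_id",
        "child_gt_a", "child_gt_b", "child_dp", "child_gq", "child_ab",
        "father_gt_a", "father_gt_b", "father_dp", "father_gq", "father_ao",
        "mother_gt_a", "mother_gt_b", "mother_dp", "mother_gq", "mother_ao",
    ]
    return out[cols]


# ---------------------------------------------------------------------------
# TSV helpers (deterministic round-trips)

def write_tsv(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


def read_tsv(path: str | Path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kwargs)


# ---------------------------------------------------------------------------
# GMT-like term file: term <tab> label|domain|parent <tab> gene1 <tab> ...

def write_terms(terms: list[dict], path: str | Path) -> None:
    with open(path, "w") as fh:
        for t in terms:
            meta = f"{t['label']}|{t['domain']}|{t.get('parent') or ''}"
            fh.write("\t".join([t["term"], meta, *sorted(t["genes"])]) + "\n")


def read_terms(path: str | Path) -> list[dict]:
    out = []
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 2:
                continue
            label, domain, parent = (parts[1].split("|") + ["", ""])[:3]
            out.append(
                dict(term=parts[0], label=label, domain=domain, parent=parent or None, genes=set(parts[2:]))
            )
    return out
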