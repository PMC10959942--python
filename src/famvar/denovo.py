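"""Trio SNV filtering, de novo calling and severity tiering.

The analysis proceeds in four steps:

1. ``filter_quality_and_rarity`` — keep coding/splicing variants with
   DP >= 10 and GQ >= 20 in the carrier child, a PASS site filter,
   outside excluded regions, with population MAF <= 0.1% (monoallelic
   model) or <= 1% (biallelic model).
2. ``call_de_novo`` — the dual-caller de novo rule with strict
   inequalities: child heterozygous and both parents reference in both
   callers, DP > 9 in all three members, child GQ > 20, child allele
   balance > 0.25, parental alternate read count 0. A missing parent
   routes the variant to "unknown" origin, never to de novo.
3. ``assign_severity_bin`` — six bins: PTVs split by gene constraint
   (LOEUF < 0.6), missense split by MPC (>= 2 DmisB, [1, 2) DmisA,
   < 1 low), synonymous.
4. ``flag_pdsnv_and_severe`` — pdSNV = PTV_LOEUF or DmisB or DmisA;
   severe = high-confidence LoF PTV_LOEUF or AlphaMissense
   likely-pathogenic DmisB; brain expression tier from the pext score.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .config import PDSNV_BINS, Thresholds
from .pedigree import Pedigree

logger = logging.getLogger(__name__)

SEVERITY_BINS = ("PTV_LOEUF", "PTV_other", "DmisB", "DmisA", "Mis_low", "Synonymous")
CODING_CONSEQUENCES = ("PTV", "missense", "synonymous")


def region_tree(intervals: list[tuple[str, int, int]]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for chrom, start, end in intervals:
        trees.setdefault(chrom, IntervalTree()).addi(start, end)
    return trees


def in_regions(trees: dict[str, IntervalTree], chrom: pd.Series, pos: pd.Series) -> np.ndarray:
    out = np.zeros(len(chrom), dtype=bool)
    for i, (c, p) in enumerate(zip(chrom, pos)):
        t = trees.get(c)
        if t is not None and t.overlaps(p):
            out[i] = True
    return out


def filter_quality_and_rarity(
    variants: pd.DataFrame,
    trio_records: pd.DataFrame,
    mode: str,
    excluded_regions: list[tuple[str, int, int]],
    thresholds: Thresholds = Thresholds(),
) -> pd.DataFrame:
    """Per-(variant, child) records surviving quality + rarity filtering.

    ``mode`` selects the MAF threshold: "monoallelic" (<= 0.1%) for
    dominant/X-linked analyses, "biallelic" (<= 1%) for recessive ones.
    Quality is assessed on the child of each trio record.
    """
    if mode == "monoallelic":
        maf_col, maf_max = "maf_mono", thresholds.maf_monoallelic
    elif mode == "biallelic":
        maf_col, maf_max = "maf_bi", thresholds.maf_biallelic
    else:
        raise ValueError(f"unknown rarity mode {mode!r}")

    ann_cols = ["variant_id", "consequence", maf_col]
    rec = trio_records.merge(variants[ann_cols], on="variant_id", how="inner")
    n0 = len(rec)

    keep = rec["consequence"].isin(CODING_CONSEQUENCES)
    keep &= rec["filter_status"] == "PASS"
    keep &= rec["child_dp"] >= thresholds.min_dp
    keep &= rec["child_gq"] >= thresholds.min_gq
    keep &= rec[maf_col] <= maf_max
    trees = region_tree(excluded_regions)
    if trees:
        keep &= ~in_regions(trees, rec["chrom"], rec["pos"])
    out = rec[keep].drop(columns=[maf_col])
    logger.info("quality/rarity filter (%s): %d -> %d records", mode, n0, len(out))
    return out.reset_index(drop=True)


def call_de_novo(trio_records: pd.DataFrame, thresholds: Thresholds = Thresholds()) -> pd.DataFrame:
    """Apply the dual-caller de novo rule; returns qualifying records.

    Adds an ``origin`` column: "de_novo" for qualifying records. Records
    with a missing parent are excluded here (handled by
    :func:`assign_origin` as "unknown").
    """
    r = trio_records
    parent_known = r["father_gt_a"].notna() & r["mother_gt_a"].notna()
    het_both = (r["child_gt_a"] == 1) & (r["child_gt_b"] == 1)
    parents_ref = (
        (r["father_gt_a"] == 0) & (r["father_gt_b"] == 0)
        & (r["mother_gt_a"] == 0) & (r["mother_gt_b"] == 0)
    )
    dp_ok = (
        (r["child_dp"] > thresholds.denovo_min_dp_exclusive)
        & (r["father_dp"] > thresholds.denovo_min_dp_exclusive)
        & (r["mother_dp"] > thresholds.denovo_min_dp_exclusive)
    )
    gq_ok = r["child_gq"] > thresholds.denovo_min_gq_exclusive
    ab_ok = r["child_ab"] > thresholds.denovo_min_ab_exclusive
    ao_ok = (r["father_ao"] <= thresholds.denovo_max_parent_ao) & (
        r["mother_ao"] <= thresholds.denovo_max_parent_ao
    )
    keep = parent_known & het_both & parents_ref & dp_ok & gq_ok & ab_ok & ao_ok
    out = r[keep].copy()
    out["origin"] = "de_novo"
    return out.reset_index(drop=True)


def assign_origin(trio_records: pd.DataFrame, thresholds: Thresholds = Thresholds()) -> pd.DataFrame:
    """Label every carrier record: de_novo / paternal / maternal / unknown.

    Inherited labels require exactly one carrier parent; carrier records
    with a missing parent or with both parents carrying are "unknown".
    """
    r = trio_records[(trio_records["child_gt_a"] > 0)].copy()
    dn = call_de_novo(trio_records, thresholds)
    dn_keys = set(zip(dn["variant_id"], dn["child_id"]))
    father_carrier = r["father_gt_a"] > 0
    mother_carrier = r["mother_gt_a"] > 0
    parent_missing = r["father_gt_a"].isna() | r["mother_gt_a"].isna()
    origin = np.select(
        [
            father_carrier & ~mother_carrier & ~parent_missing,
            mother_carrier & ~father_carrier & ~parent_missing,
        ],
        ["paternal", "maternal"],
        default="unknown",
    )
    is_dn = [
        (v, c) in dn_keys for v, c in zip(r["variant_id"], r["child_id"])
    ]
    r["origin"] = np.where(is_dn, "de_novo", origin)
    return r.reset_index(drop=True)


def assign_severity_bin(variants: pd.DataFrame, thresholds: Thresholds = Thresholds()) -> pd.Series:
    """Map each annotated coding variant to one of the six severity bins."""
    v = variants
    cons = v["consequence"]
    mpc = v["mpc"]
    missing_mpc = cons.eq("missense") & mpc.isna()
    if missing_mpc.any():
        logger.warning(
            "%d missense variants lack an MPC score; binned as low-MPC missense",
            int(missing_mpc.sum()),
        )
    bins = np.select(
        [
            cons.eq("PTV") & (v["loeuf"] < thresholds.loeuf_constrained),
            cons.eq("PTV"),
            cons.eq("synonymous"),
            cons.eq("missense") & (mpc >= thresholds.mpc_dmisb),
            cons.eq("missense") & (mpc >= thresholds.mpc_dmisa),
            cons.eq("missense"),
        ],
        ["PTV_LOEUF", "PTV_other", "Synonymous", "DmisB", "DmisA", "Mis_low"],
        default="",
    )
    if (bins == "").any():
        raise ValueError("variant with unknown consequence cannot be binned")
    return pd.Series(bins, index=v.index, name="bin")


def flag_pdsnv_and_severe(variants: pd.DataFrame, thresholds: Thresholds = Thresholds()) -> pd.DataFrame:
    """Add ``bin``, ``pdsnv``, ``severe`` and ``brain_expressed`` columns.

    severe: PTV_LOEUF with a high-confidence LoF flag, or DmisB predicted
    likely pathogenic. Brain expression tiers on pext: constitutive
    (> 0.9), intermediate ((0.1, 0.9]), low otherwise.
    """
    v = variants.copy()
    v["bin"] = assign_severity_bin(v, thresholds)
    v["pdsnv"] = v["bin"].isin(PDSNV_BINS)
    v["severe"] = (v["bin"].eq("PTV_LOEUF") & v["loftee"].eq("HC")) | (
        v["bin"].eq("DmisB") & v["alpha_missense"].eq("likely_pathogenic")
    )
    v["brain_expressed"] = np.select(
        [v["pext"] > thresholds.pext_constitutive, v["pext"] > thresholds.pext_low],
        ["constitutive", "intermediate"],
        default="low",
    )
    return v


def pdsnv_table(
    variants: pd.DataFrame,
    trio_records: pd.DataFrame,
    excluded_regions: list[tuple[str, int, int]],
    thresholds: Thresholds = Thresholds(),
    mode: str = "monoallelic",
) -> pd.DataFrame:
    """End-to-end per-individual pdSNV report.

    Columns: individual, variant, gene, bin, origin, severe,
    brain_expressed (plus pdsnv flag and fid). Includes every retained
    carrier record; pdSNVs are rows with ``pdsnv`` True.
    """
    retained = filter_quality_and_rarity(variants, trio_records, mode, excluded_regions, thresholds)
    with_origin = assign_origin(retained, thresholds)
    flags = flag_pdsnv_and_severe(variants, thresholds)
    cols = ["variant_id", "gene", "bin", "pdsnv", "severe", "brain_expressed", "chrom"]
    out = with_origin.merge(flags[cols + ["pos"]], on="variant_id", how="left", suffixes=("", "_ann"))
    out = out.rename(columns={"child_id": "individual", "child_gt_a": "genotype"})
    keep = [
        "individual", "fid", "variant_id", "gene", "chrom", "pos", "genotype", "bin",
        "origin", "pdsnv", "severe", "brain_expressed",
    ]
    return out[keep].sort_values(["individual", "variant_id"]).reset_index(drop=True)
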