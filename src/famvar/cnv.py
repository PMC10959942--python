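"""Rare-CNV consensus building, annotation, inheritance and prioritization.

Array calls from three callers are merged into a stringent consensus
(pairwise reciprocal overlap >= 50%, single-linkage, cluster must contain
the designated primary caller and >= 2 callers; members need confidence
>= 10, size >= 1 kb, >= 3 probes; the consensus interval is the union
extent of its members). Consensus calls are annotated (size, genes,
exonic content, segmental-duplication / centromere / copy-number-stable
overlap, recurrent-genomic-disorder hits, parental cohort frequency) and
filtered to rare exonic CNVs >= 10 kb. Inheritance is read off parental
call sets; array and WGS call sets are reconciled at 50% reciprocal
overlap with WGS coordinates retained. Surviving calls are prioritized
into four potentially-damaging categories with fixed precedence:
LARGE (>= 3 Mb) > RGD > DE_NOVO > DOSAGE_SENSITIVE.

Intervals are 0-based half-open throughout.
"""

from __future__ import annotations

import itertools
import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

from .config import Thresholds

CATEGORY_ORDER = ("LARGE", "RGD", "DE_NOVO", "DOSAGE_SENSITIVE")


# ---------------------------------------------------------------------------
# interval primitives

def reciprocal_overlap(a: tuple[str, int, int], b: tuple[str, int, int]) -> float:
    """min(shared/|a|, shared/|b|); 0 when on different chromosomes."""
    if a[0] != b[0]:
        return 0.0
    shared = min(a[2], b[2]) - max(a[1], b[1])
    if shared <= 0:
        return 0.0
    return min(shared / (a[2] - a[1]), shared / (b[2] - b[1]))


def _overlap_len(start: int, end: int, intervals: list[tuple[int, int]]) -> int:
    """Total bases of [start, end) covered by a set of intervals (assumed
    non-overlapping within a region set)."""
    total = 0
    for s, e in intervals:
        total += max(0, min(end, e) - max(start, s))
    return min(total, end - start)


def _by_chrom(regions: list[tuple[str, int, int]]) -> dict[str, list[tuple[int, int]]]:
    out: dict[str, list[tuple[int, int]]] = {}
    for chrom, s, e in regions:
        out.setdefault(chrom, []).append((s, e))
    return out


def covered_fraction(chrom: str, start: int, end: int, regions: dict[str, list[tuple[int, int]]]) -> float:
    if end <= start:
        return 0.0
    return _overlap_len(start, end, regions.get(chrom, [])) / (end - start)


# ---------------------------------------------------------------------------
# consensus

def _cluster_single_linkage(calls: pd.DataFrame, min_ro: float) -> list[list[int]]:
    """Single-linkage clusters over the >= min_ro reciprocal-overlap
    relation; input must be one (sample, chrom, type) group sorted by
    start so the result is order-independent."""
    idx = list(calls.index)
    parent = {i: i for i in idx}

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    rows = list(calls.itertuples())
    for a, b in itertools.combinations(rows, 2):
        if reciprocal_overlap((a.chrom, a.start, a.end), (b.chrom, b.start, b.end)) >= min_ro:
            ra, rb = find(a.Index), find(b.Index)
            parent[ra] = rb
    clusters: dict[int, list[int]] = {}
    for i in idx:
        clusters.setdefault(find(i), []).append(i)
    return list(clusters.values())


def build_array_consensus(
    calls: pd.DataFrame,
    thresholds: Thresholds = Thresholds(),
    primary_caller: str = "arrayA",
) -> pd.DataFrame:
    """Stringent multi-caller consensus over array calls, per sample.

    Returns one row per consensus CNV: sample_id, fid, chrom, start, end,
    cnv_type, supporting_callers (comma-joined), n_callers, confidence
    (max), n_probes (max), platform="array".
    """
    if len(calls) == 0:
        return _empty_consensus()
    c = calls[calls["platform"] == "array"].copy()
    member_ok = (
        (c["confidence"] >= thresholds.consensus_min_confidence)
        & ((c["end"] - c["start"]) >= thresholds.consensus_min_size)
        & (c["n_probes"] >= thresholds.consensus_min_probes)
    )
    c = c[member_ok].sort_values(["sample_id", "chrom", "cnv_type", "start"])
    out = []
    for (sample, chrom, ctype), grp in c.groupby(["sample_id", "chrom", "cnv_type"], sort=True):
        for cluster in _cluster_single_linkage(grp, thresholds.reciprocal_overlap):
            rows = grp.loc[cluster]
            callers = set(rows["caller"])
            if primary_caller not in callers or len(callers) < thresholds.consensus_min_callers:
                continue
            out.append(
                dict(
                    sample_id=sample, fid=rows["fid"].iloc[0], chrom=chrom,
                    start=int(rows["start"].min()), end=int(rows["end"].max()),
                    cnv_type=ctype, supporting_callers=",".join(sorted(callers)),
                    n_callers=len(callers), confidence=float(rows["confidence"].max()),
                    n_probes=int(rows["n_probes"].max()), platform="array",
                )
            )
    if not out:
        return _empty_consensus()
    return (
        pd.DataFrame(out)
        .sort_values(["sample_id", "chrom", "start"])
        .reset_index(drop=True)
    )


def _empty_consensus() -> pd.DataFrame:
    return pd.DataFrame(
        columns=[
            "sample_id", "fid", "chrom", "start", "end", "cnv_type",
            "supporting_callers", "n_callers", "confidence", "n_probes", "platform",
        ]
    )


def wgs_callset(calls: pd.DataFrame) -> pd.DataFrame:
    """WGS calls reshaped to the consensus schema."""
    w = calls[calls["platform"] == "wgs"].copy()
    if len(w) == 0:
        return _empty_consensus()
    w["supporting_callers"] = w["caller"]
    w["n_callers"] = 1
    return w[
        [
            "sample_id", "fid", "chrom", "start", "end", "cnv_type",
            "supporting_callers", "n_callers", "confidence", "n_probes", "platform",
        ]
    ].reset_index(drop=True)


# ---------------------------------------------------------------------------
# reconciliation and inheritance

def reconcile_array_wgs(
    array_set: pd.DataFrame, wgs_set: pd.DataFrame, thresholds: Thresholds = Thresholds()
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Merge per-sample array and WGS calls.

    Same-sample same-type pairs with reciprocal overlap >= 50% become one
    record with platform "both" and the WGS coordinates; unpaired calls
    keep their platform. Returns (merged set, counts per class).
    """
    merged_rows = []
    used_wgs: set[int] = set()
    wgs_by_sample: dict[tuple, pd.DataFrame] = (
        {k: g for k, g in wgs_set.groupby(["sample_id", "chrom", "cnv_type"])} if len(wgs_set) else {}
    )
    for row in array_set.itertuples(index=False):
        key = (row.sample_id, row.chrom, row.cnv_type)
        match_idx = None
        best = thresholds.reciprocal_overlap
        if key in wgs_by_sample:
            for w in wgs_by_sample[key].itertuples():
                if w.Index in used_wgs:
                    continue
                ro = reciprocal_overlap((row.chrom, row.start, row.end), (w.chrom, w.start, w.end))
                if ro >= best:
                    best, match_idx = ro, w.Index
        rec = row._asdict()
        if match_idx is not None:
            used_wgs.add(match_idx)
            w = wgs_set.loc[match_idx]
            rec.update(start=int(w.start), end=int(w.end), platform="both",
                       supporting_callers=rec["supporting_callers"] + "," + w.supporting_callers)
        merged_rows.append(rec)
    leftovers = wgs_set.loc[[i for i in wgs_set.index if i not in used_wgs]] if len(wgs_set) else wgs_set
    parts = [p for p in (pd.DataFrame(merged_rows), leftovers) if len(p)]
    merged = pd.concat(parts, ignore_index=True) if parts else _empty_consensus()
    counts = {
        "both": int((merged["platform"] == "both").sum()) if len(merged) else 0,
        "array_only": int((merged["platform"] == "array").sum()) if len(merged) else 0,
        "wgs_only": int((merged["platform"] == "wgs").sum()) if len(merged) else 0,
    }
    logger.info("platform reconciliation: %s", counts)
    return merged.reset_index(drop=True), counts


def determine_cnv_inheritance(
    child_cnv, father_calls: pd.DataFrame, mother_calls: pd.DataFrame,
    thresholds: Thresholds = Thresholds(),
    father_present: bool = True, mother_present: bool = True,
) -> str:
    """paternal / maternal / de_novo / unknown for one child CNV.

    A parental same-type call at reciprocal overlap >= 50% assigns the
    parent; no parental overlap at all means potentially de novo; a
    partial or type-mismatched overlap (or a missing parent) yields
    "unknown" (manual-review in the original workflow).
    """
    interval = (child_cnv.chrom, int(child_cnv.start), int(child_cnv.end))
    any_overlap = False
    for label, calls, present in (("paternal", father_calls, father_present), ("maternal", mother_calls, mother_present)):
        if not present or calls is None or len(calls) == 0:
            continue
        for p in calls.itertuples(index=False):
            if p.chrom != child_cnv.chrom:
                continue
            shared = min(p.end, interval[2]) - max(p.start, interval[1])
            if shared <= 0:
                continue
            any_overlap = True
            ro = reciprocal_overlap(interval, (p.chrom, p.start, p.end))
            if ro >= thresholds.reciprocal_overlap and p.cnv_type == child_cnv.cnv_type:
                return label
    if not (father_present and mother_present):
        return "unknown"
    return "unknown" if any_overlap else "de_novo"


# ---------------------------------------------------------------------------
# annotation, rare filter, prioritization

def _gene_exons(gene_row) -> list[tuple[int, int]]:
    starts = [int(s) for s in str(gene_row.exon_starts).split(",")]
    return [(s, s + int(gene_row.exon_length)) for s in starts]


def annotate_consensus(
    consensus: pd.DataFrame,
    gene_table: pd.DataFrame,
    regions: dict[str, list[tuple[str, int, int]]],
    parent_calls: pd.DataFrame,
    n_parents: int,
    thresholds: Thresholds = Thresholds(),
) -> pd.DataFrame:
    """Attach size, gene/exon content, region overlaps, RGD hits and the
    parental cohort frequency to every consensus CNV."""
    segdup = _by_chrom(regions["segdup"])
    centro = _by_chrom(regions["centromere"])
    stable = _by_chrom(regions["cn_stable"])
    rgd = regions["rgd"]
    genes_by_chrom = {c: g for c, g in gene_table.groupby("chrom")}
    parent_groups = (
        {k: g for k, g in parent_calls.groupby(["chrom", "cnv_type"])} if len(parent_calls) else {}
    )

    rows = []
    for row in consensus.itertuples(index=False):
        size = int(row.end - row.start)
        genes = genes_by_chrom.get(row.chrom, gene_table.iloc[0:0])
        hit = genes[(genes["start"] < row.end) & (genes["end"] > row.start)]
        exonic = False
        gene_names = []
        max_phaplo = np.nan
        max_ptriplo = np.nan
        for g in hit.itertuples(index=False):
            gene_names.append(g.gene)
            if any(s < row.end and e > row.start for s, e in _gene_exons(g)):
                exonic = True
            max_phaplo = np.nanmax([max_phaplo, g.phaplo])
            max_ptriplo = np.nanmax([max_ptriplo, g.ptriplo])
        rgd_hit = ""
        for chrom, ls, le in rgd:
            if chrom == row.chrom:
                shared = min(le, row.end) - max(ls, row.start)
                if shared > 0 and shared / (le - ls) >= thresholds.rgd_min_locus_cov:
                    rgd_hit = f"{chrom}:{ls}-{le}"
                    break
        carriers = set()
        key = (row.chrom, row.cnv_type)
        if key in parent_groups:
            for p in parent_groups[key].itertuples(index=False):
                if reciprocal_overlap((row.chrom, row.start, row.end), (p.chrom, p.start, p.end)) >= thresholds.reciprocal_overlap:
                    carriers.add(p.sample_id)
        parent_freq = len(carriers) / n_parents if n_parents else 0.0
        rows.append(
            dict(
                **row._asdict(),
                size=size,
                genes=",".join(gene_names),
                exonic=exonic,
                segdup_frac=covered_fraction(row.chrom, row.start, row.end, segdup),
                centromere_frac=covered_fraction(row.chrom, row.start, row.end, centro),
                cn_stable_frac=covered_fraction(row.chrom, row.start, row.end, stable),
                rgd_hit=rgd_hit,
                parent_freq=parent_freq,
                max_phaplo=max_phaplo,
                max_ptriplo=max_ptriplo,
            )
        )
    return pd.DataFrame(rows) if rows else consensus.iloc[0:0]


def filter_rare_exonic(annotated: pd.DataFrame, thresholds: Thresholds = Thresholds()) -> pd.DataFrame:
    """The stringent rare-CNV filter.

    Keep CNVs >= 10 kb, with >= 5 probes when array-derived, overlapping
    at least one exon, that are either RGD hits (>= 40% of the locus
    covered) or pass all of: segmental-duplication and centromere overlap
    < 50% of the CNV, parental frequency <= 1% at 50% reciprocal overlap,
    copy-number-stable overlap > 75% of the CNV.
    """
    if len(annotated) == 0:
        return annotated
    a = annotated
    keep = a["size"] >= thresholds.cnv_min_size
    array_derived = a["platform"].isin(["array", "both"])
    keep &= ~array_derived | (a["n_probes"] >= thresholds.cnv_min_probes)
    keep &= a["exonic"]
    clean = (
        (a["segdup_frac"] < thresholds.segdup_centromere_max_frac)
        & (a["centromere_frac"] < thresholds.segdup_centromere_max_frac)
        & (a["parent_freq"] <= thresholds.parent_freq_max)
        & (a["cn_stable_frac"] > thresholds.cn_stable_min_frac)
    )
    keep &= (a["rgd_hit"] != "") | clean
    logger.info("rare-CNV filter: %d -> %d calls", len(a), int(keep.sum()))
    return a[keep].reset_index(drop=True)


def _breakpoint_in_cds(start: int, end: int, g) -> bool:
    return (g.cds_start < start < g.cds_end) or (g.cds_start < end < g.cds_end)


def _disrupts_cds(row, g) -> bool:
    """Deletion touching a coding exon, or any breakpoint inside the CDS."""
    if _breakpoint_in_cds(row.start, row.end, g):
        return True
    if row.cnv_type == "DEL":
        for s, e in _gene_exons(g):
            s, e = max(s, g.cds_start), min(e, g.cds_end)
            if s < e and s < row.end and e > row.start:
                return True
    return False


def prioritize_pdcnv(
    annotated: pd.DataFrame,
    gene_table: pd.DataFrame,
    thresholds: Thresholds = Thresholds(),
) -> pd.DataFrame:
    """Assign each CNV its highest potentially-damaging category (or none).

    Precedence LARGE > RGD > DE_NOVO > DOSAGE_SENSITIVE. The dosage-
    sensitive test follows the haploinsufficiency / triplosensitivity
    scores: CDS-disrupting events need a gene with pHaplo >= 0.55;
    duplications containing an entire CDS need pTriplo >= 0.68; a CNV
    with both breakpoints inside two different genes is flagged as a
    fusion candidate. Requires an ``inheritance`` column.
    """
    genes_by_chrom = {c: g for c, g in gene_table.groupby("chrom")}
    categories = []
    dosage_genes_col = []
    fusion_col = []
    for row in annotated.itertuples(index=False):
        genes = genes_by_chrom.get(row.chrom, gene_table.iloc[0:0])
        hit = genes[(genes["start"] < row.end) & (genes["end"] > row.start)]
        dosage_genes = []
        for g in hit.itertuples(index=False):
            full_cds = row.start <= g.cds_start and g.cds_end <= row.end
            if row.cnv_type == "DUP" and full_cds and g.ptriplo >= thresholds.ptriplo_min:
                dosage_genes.append(g.gene)
            elif g.phaplo >= thresholds.phaplo_min and _disrupts_cds(row, g):
                dosage_genes.append(g.gene)
        start_gene = next((g.gene for g in hit.itertuples(index=False) if g.start < row.start < g.end), None)
        end_gene = next((g.gene for g in hit.itertuples(index=False) if g.start < row.end < g.end), None)
        fusion = bool(start_gene and end_gene and start_gene != end_gene)
        if row.size >= thresholds.large_cnv_size:
            cat = "LARGE"
        elif row.rgd_hit:
            cat = "RGD"
        elif getattr(row, "inheritance", "") == "de_novo":
            cat = "DE_NOVO"
        elif dosage_genes or fusion:
            cat = "DOSAGE_SENSITIVE"
        else:
            cat = ""
        categories.append(cat)
        dosage_genes_col.append(",".join(dosage_genes))
        fusion_col.append(fusion)
    out = annotated.copy()
    out["category"] = categories
    out["dosage_genes"] = dosage_genes_col
    out["fusion_candidate"] = fusion_col
    return out
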