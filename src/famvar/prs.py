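"""Polygenic risk scoring and the polygenic transmission disequilibrium test.

The score follows the standard clump-and-threshold recipe: QC (effect-
allele frequency > 1%, imputation INFO > 0.8, strand-ambiguous A/T and
C/G SNPs removed), greedy linkage-disequilibrium clumping (ascending
association p; a SNP is dropped if an already-retained SNP within 250 kb
has r^2 > 0.1), association threshold p <= 0.01, then a weighted dosage
sum. Weights default to ln(OR) — the additive log-odds convention of the
standard scoring tools — with raw odds-ratio weighting available as a
switch.

The pTDT statistic for a group of trios is the one-sample two-sided
t-test of the deviations (child - midparent) / SD(midparent), where the
SD is taken over the group's midparent scores (n-1 denominator).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd
from scipy import stats

from .config import Thresholds
from .pedigree import Pedigree

logger = logging.getLogger(__name__)

_AMBIGUOUS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}

R2Provider = Callable[[str, str], float]


@dataclass
class PtdtResult:
    group: str
    n_trios: int
    mean_deviation: float
    t_statistic: float
    p_value: float


def qc_summary(summary: pd.DataFrame, thresholds: Thresholds = Thresholds()) -> pd.DataFrame:
    """Drop low-frequency, poorly imputed and strand-ambiguous SNPs."""
    s = summary
    ambiguous = [
        (a1, a2) in _AMBIGUOUS for a1, a2 in zip(s["a1"].str.upper(), s["a2"].str.upper())
    ]
    keep = (
        (s["maf"] > thresholds.prs_maf_min)
        & (s["info"] > thresholds.prs_info_min)
        & ~pd.Series(ambiguous, index=s.index)
    )
    logger.info("PRS QC: %d -> %d SNPs", len(s), int(keep.sum()))
    return s[keep].reset_index(drop=True)


def greedy_clump(
    summary: pd.DataFrame,
    r2: R2Provider,
    thresholds: Thresholds = Thresholds(),
) -> pd.DataFrame:
    """Greedy LD clumping by ascending p (ties broken by genomic position).

    A candidate is removed when a retained SNP on the same chromosome
    within the clump radius (centre to centre) has r^2 above the
    threshold.
    """
    order = summary.sort_values(["p", "chrom", "pos"], kind="mergesort")
    retained: list[int] = []
    by_chrom: dict[str, list[tuple[int, str]]] = {}
    for idx, row in zip(order.index, order.itertuples(index=False)):
        ok = True
        for pos, snp in by_chrom.get(row.chrom, []):
            if abs(pos - row.pos) <= thresholds.clump_radius_bp and r2(snp, row.snp) > thresholds.clump_r2:
                ok = False
                break
        if ok:
            retained.append(idx)
            by_chrom.setdefault(row.chrom, []).append((row.pos, row.snp))
    return summary.loc[sorted(retained)].reset_index(drop=True)


def qc_and_clump(
    summary: pd.DataFrame,
    r2: R2Provider,
    thresholds: Thresholds = Thresholds(),
) -> pd.DataFrame:
    """Full SNP selection: QC, clumping, then the p <= 0.01 threshold."""
    cleaned = qc_summary(summary, thresholds)
    clumped = greedy_clump(cleaned, r2, thresholds)
    out = clumped[clumped["p"] <= thresholds.prs_p_threshold].reset_index(drop=True)
    if len(out) == 0:
        logger.warning("no SNPs survived QC/clumping/threshold; empty score basis")
    return out


def r2_from_dosages(dosages: pd.DataFrame, reference_ids: list[str] | None = None) -> R2Provider:
    """r^2 provider computed from a genotype reference matrix
    (SNPs x individuals), e.g. the cohort founders."""
    mat = dosages[reference_ids] if reference_ids else dosages
    arr = mat.to_numpy(dtype=float)
    index = {snp: i for i, snp in enumerate(mat.index)}

    def r2(a: str, b: str) -> float:
        x, y = arr[index[a]], arr[index[b]]
        if x.std() == 0 or y.std() == 0:
            return 0.0
        return float(np.corrcoef(x, y)[0, 1] ** 2)

    return r2


def r2_from_table(pairs: pd.DataFrame) -> R2Provider:
    """r^2 provider from a precomputed pair table (snp1, snp2, r2)."""
    lut = {}
    for row in pairs.itertuples(index=False):
        lut[(row.snp1, row.snp2)] = row.r2
        lut[(row.snp2, row.snp1)] = row.r2
    return lambda a, b: float(lut.get((a, b), 0.0))


def compute_prs(
    dosages: pd.DataFrame,
    retained: pd.DataFrame,
    thresholds: Thresholds = Thresholds(),
) -> pd.Series:
    """Per-individual score: sum over retained SNPs of dosage x weight.

    ``dosages`` is SNPs x individuals in [0, 2]; missing dosages are
    skipped for that individual (logged). Weight is ln(OR) by default,
    raw OR when ``prs_log_or_weights`` is off.
    """
    snps = [s for s in retained["snp"] if s in dosages.index]
    if len(snps) < len(retained):
        logger.warning("%d retained SNPs missing from the dosage matrix", len(retained) - len(snps))
    weights = retained.set_index("snp").loc[snps, "or_value"].astype(float)
    w = np.log(weights.to_numpy()) if thresholds.prs_log_or_weights else weights.to_numpy()
    mat = dosages.loc[snps].to_numpy(dtype=float)
    missing = np.isnan(mat)
    if missing.any():
        logger.warning("%d missing dosage entries skipped", int(missing.sum()))
        mat = np.where(missing, 0.0, mat)
    scores = mat.T @ w
    return pd.Series(scores, index=dosages.columns, name="prs")


def ptdt_deviations(scores: pd.Series, trios: list[tuple[str, str, str]]) -> np.ndarray:
    """(child - midparent) / SD(midparent) for a group of trios."""
    if len(trios) < 2:
        raise ValueError("pTDT needs at least two trios")
    child = np.array([scores[c] for c, _, _ in trios], dtype=float)
    mid = np.array([(scores[f] + scores[m]) / 2 for _, f, m in trios], dtype=float)
    sd = mid.std(ddof=1)
    if sd == 0:
        raise ValueError("midparent scores have zero variance")
    return (child - mid) / sd


def ptdt_test(scores: pd.Series, trios: list[tuple[str, str, str]], group: str = "all") -> PtdtResult:
    """One-sample two-sided t-test that the mean pTDT deviation is zero."""
    dev = ptdt_deviations(scores, trios)
    if np.all(dev == dev[0]) and dev[0] == 0.0:
        t, p = 0.0, 1.0
    else:
        t, p = stats.ttest_1samp(dev, 0.0)
    return PtdtResult(group=group, n_trios=len(dev), mean_deviation=float(dev.mean()),
                      t_statistic=float(t), p_value=float(p))


def cohort_trios(pedigree: Pedigree, scores: pd.Series, affected: bool) -> list[tuple[str, str, str]]:
    """Scored (child, father, mother) triples for the requested group."""
    out = []
    for child, father, mother in pedigree.iter_trios():
        if child.affected != affected or father is None or mother is None:
            continue
        if child.iid in scores and father.iid in scores and mother.iid in scores:
            out.append((child.iid, father.iid, mother.iid))
    return out
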