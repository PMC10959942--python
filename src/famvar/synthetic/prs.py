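"""GWAS summary statistics and trio dosage simulation for PRS / pTDT.

The generator plants a polygenic overtransmission of a chosen effect size
``e`` (in midparent-SD units). At every effect SNP a heterozygous parent
transmits the risk allele with probability 1/2 + delta; with weights
w = ln(OR), allele frequency p and q = 1 - p, the expected child-minus-
midparent score is 4*delta*sum(|w| p q) and the midparent SD is
sqrt(sum(w^2 p q)) (sums over effect SNPs), so

    delta = e * sqrt(sum w^2 p q) / (4 * sum |w| p q)

recovers a mean pTDT deviation of ``e`` in expectation. Effect SNPs are
the clump-surviving SNPs (QC-pass, p <= 0.01, block representatives), so
the planted effect is fully visible to the standard clump-and-threshold
score. Linkage blocks of 2-3 SNPs (near-copies of a representative within
the clumping radius) exercise the clumping step; block members carry
p > 0.01 so they never enter the score.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..config import SimulationConfig
from ..pedigree import Pedigree
from .cohort import GroundTruth
from .genome import AUTOSOMES

AMBIGUOUS_PAIRS = (("A", "T"), ("T", "A"), ("C", "G"), ("G", "C"))
NONAMBIGUOUS_PAIRS = (("A", "G"), ("A", "C"), ("G", "A"), ("C", "A"), ("T", "G"), ("T", "C"), ("G", "T"), ("C", "T"))

SUMMARY_COLUMNS = ["snp", "chrom", "pos", "a1", "a2", "or_value", "p", "info", "maf"]


def make_summary_stats(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Simulated GWAS summary rows plus generator-internal block columns.

    Extra columns (not written to disk): ``block`` (block id), ``is_rep``
    (block representative), used to place genotypes in LD and to define
    the effective effect-SNP set.
    """
    rows = []
    pos = 1_000_000
    chrom_i = 0
    block_id = 0
    i = 0
    while i < config.n_prs_snps:
        block_size = 1
        if rng.random() < 0.2:
            block_size = int(rng.integers(2, 4))
        block_size = min(block_size, config.n_prs_snps - i)
        block_id += 1
        for j in range(block_size):
            is_rep = j == 0
            ambiguous = rng.random() < 0.05
            pair = AMBIGUOUS_PAIRS if ambiguous else NONAMBIGUOUS_PAIRS
            a1, a2 = pair[int(rng.integers(0, len(pair)))]
            low_maf = rng.random() < 0.05
            maf = float(rng.uniform(0.001, 0.01)) if low_maf else float(rng.uniform(0.05, 0.5))
            low_info = rng.random() < 0.05
            info = float(rng.uniform(0.3, 0.8)) if low_info else float(rng.uniform(0.85, 1.0))
            qc_ok = not (ambiguous or low_maf or low_info)
            if is_rep and qc_ok and rng.random() < 0.4:
                p = float(10 ** -rng.uniform(2.5, 8.0))
            else:
                p = float(rng.uniform(0.02, 1.0))
            rows.append(
                dict(
                    snp=f"rs{i + 1:05d}", chrom=AUTOSOMES[chrom_i], pos=pos,
                    a1=a1, a2=a2,
                    or_value=float(np.round(np.exp(rng.normal(0.0, 0.15)), 5)),
                    p=p, info=float(np.round(info, 4)), maf=float(np.round(maf, 4)),
                    block=block_id, is_rep=is_rep, qc_ok=qc_ok,
                )
            )
            i += 1
            pos += int(rng.integers(40_000, 110_000))  # within the clump radius
        pos += 600_000  # next block is outside the radius
        if pos > 55_000_000:
            pos = 1_000_000
            chrom_i = (chrom_i + 1) % len(AUTOSOMES)
    return pd.DataFrame(rows)


def effect_snp_mask(summary: pd.DataFrame, p_threshold: float = 0.01) -> np.ndarray:
    return (summary["qc_ok"] & summary["is_rep"] & (summary["p"] <= p_threshold)).to_numpy()


def planted_delta(summary: pd.DataFrame, effect: np.ndarray, overtransmission: float) -> float:
    """Per-SNP transmission bias achieving the requested pTDT mean."""
    if overtransmission == 0 or not effect.any():
        return 0.0
    w = np.log(summary["or_value"].to_numpy())[effect]
    p = summary["maf"].to_numpy()[effect]
    pq = p * (1 - p)
    denom = 4.0 * np.sum(np.abs(w) * pq)
    if denom == 0:
        return 0.0
    delta = overtransmission * np.sqrt(np.sum(w**2 * pq)) / denom
    return float(np.clip(delta, -0.49, 0.49))


def _apply_blocks(g: np.ndarray, summary: pd.DataFrame, rng: np.random.Generator) -> np.ndarray:
    """Overwrite block members with near-copies of their representative."""
    blocks = summary["block"].to_numpy()
    reps = summary["is_rep"].to_numpy()
    maf = summary["maf"].to_numpy()
    rep_col = np.empty(len(summary), dtype=int)
    for j in range(len(summary)):
        rep_col[j] = j if reps[j] else rep_col[j - 1] if blocks[j] == blocks[j - 1] else j
    for j in range(len(summary)):
        if rep_col[j] == j:
            continue
        keep = rng.random(g.shape[0]) < 0.95
        fresh = rng.binomial(2, maf[j], size=g.shape[0])
        g[:, j] = np.where(keep, g[:, rep_col[j]], fresh)
    return g


def _transmit(parent: np.ndarray, bias: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One transmitted-allele dosage per SNP; het sites are biased toward
    the effect allele with per-SNP probability 1/2 + bias."""
    u = rng.random(parent.shape)
    het_pick = (u < 0.5 + bias).astype(np.int64)
    return np.where(parent == 2, 1, np.where(parent == 1, het_pick, 0))


def simulate_prs_trios(
    summary: pd.DataFrame,
    n_trios: int,
    overtransmission: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized trio dosages (father, mother, child), each (n_trios, n_snps).

    Used both by the cohort generator and for replicate studies of the
    pTDT null and power.
    """
    maf = summary["maf"].to_numpy()
    n_snps = len(summary)
    father = rng.binomial(2, maf, size=(n_trios, n_snps))
    mother = rng.binomial(2, maf, size=(n_trios, n_snps))
    father = _apply_blocks(father, summary, rng)
    mother = _apply_blocks(mother, summary, rng)
    effect = effect_snp_mask(summary)
    delta = planted_delta(summary, effect, overtransmission)
    w_sign = np.sign(np.log(summary["or_value"].to_numpy()))
    bias = np.where(effect, delta * w_sign, 0.0)
    child = _transmit(father, bias, rng) + _transmit(mother, bias, rng)
    return father, mother, child


def generate_prs_inputs(
    pedigree: Pedigree,
    config: SimulationConfig,
    rng: np.random.Generator,
    truth: GroundTruth | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Summary statistics plus a per-individual dosage matrix.

    Affected children receive the planted overtransmission; unaffected
    siblings are transmitted without bias. Optional monozygotic twin pairs
    duplicate the first affected child's genotypes exactly.
    """
    if truth is None:
        truth = GroundTruth()
    summary = make_summary_stats(config, rng)
    maf = summary["maf"].to_numpy()
    n_snps = len(summary)
    effect = effect_snp_mask(summary)
    delta = planted_delta(summary, effect, config.prs_overtransmission)
    w_sign = np.sign(np.log(summary["or_value"].to_numpy()))
    bias_aff = np.where(effect, delta * w_sign, 0.0)
    bias_null = np.zeros(n_snps)

    dosages: dict[str, np.ndarray] = {}
    for fam in pedigree.families:
        father = next((p for p in fam.parents if p.is_male), None)
        mother = next((p for p in fam.parents if not p.is_male), None)
        for parent in (father, mother):
            if parent is not None:
                g = rng.binomial(2, maf, size=(1, n_snps))
                dosages[parent.iid] = _apply_blocks(g, summary, rng)[0]
        for child in fam.children:
            fg = dosages.get(father.iid) if father else rng.binomial(2, maf)
            mg = dosages.get(mother.iid) if mother else rng.binomial(2, maf)
            bias = bias_aff if child.affected else bias_null
            c = _transmit(fg[None, :], bias, rng) + _transmit(mg[None, :], bias, rng)
            dosages[child.iid] = c[0]

    mz_pairs: list[list[str]] = []
    if config.mz_twin_families:
        twin_fams = [f for f in pedigree.families if len(f.affected_children) >= 2]
        for fam in twin_fams[: config.mz_twin_families]:
            a, b = fam.affected_children[0], fam.affected_children[1]
            dosages[b.iid] = dosages[a.iid].copy()
            mz_pairs.append([a.iid, b.iid])

    dosage_df = pd.DataFrame(dosages, index=summary["snp"])
    dosage_df.index.name = "snp"
    truth.prs_meta = {
        "delta": delta,
        "overtransmission": config.prs_overtransmission,
        "effect_snps": summary.loc[effect, "snp"].tolist(),
        "mz_pairs": mz_pairs,
    }
    return summary, dosage_df, truth
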