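"""Dual-caller SNV call-set simulation with planted ground truth.

Emits three things: a per-variant annotation table, a long genotype table
(one row per variant x family member, for both emulated callers A and B)
and :class:`~famvar.synthetic.cohort.GroundTruth` entries. Inherited
variants obey Mendelian transmission from a simulated carrier parent;
de novo variants are heterozygous in one child and absent from both
parents. A configurable fraction of true de novos is planted with failing
quality (DP <= 9, GQ <= 20, allele balance <= 0.25, parental alternate
reads, single-caller support, or a non-PASS site filter) to exercise the
downstream filters.

Autosomal variants only, except explicitly planted X-linked events; male
chrX genotypes are haploid (alt count 1 == hemizygous carrier).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..config import BIN_ORDER, SimulationConfig
from ..pedigree import Family, Individual, Pedigree
from .cohort import GroundTruth
from .genome import AUTOSOMES, EXCLUDED_REGIONS, SyntheticGenome

BASES = np.array(list("ACGT"))

GENO_COLUMNS = [
    "variant_id", "fid", "iid", "gt_a", "gt_b",
    "dp", "gq", "ad_ref", "ad_alt",
]

FAIL_MODES = ("low_dp", "low_gq", "low_ab", "parent_ao", "single_caller", "non_pass")


class _VariantFactory:
    """Draws per-bin annotations consistent with the severity tiers."""

    def __init__(self, genome: SyntheticGenome, rng: np.random.Generator):
        self.genome = genome
        self.rng = rng
        g = genome.genes
        excluded = np.zeros(len(g), dtype=bool)
        for chrom, s, e in EXCLUDED_REGIONS:
            excluded |= ((g["chrom"] == chrom) & (g["start"] < e) & (g["end"] > s)).to_numpy()
        self.excluded_genes = g[excluded]
        auto = g[g["chrom"].isin(AUTOSOMES) & ~excluded]
        self.auto_constrained = auto[auto["loeuf"] < 0.6]
        self.auto_unconstrained = auto[auto["loeuf"] >= 0.6]
        self.auto_all = auto
        self.x_genes = g[(g["chrom"] == "chrX") & ~excluded]
        self.counter = 0

    def relocate_to_excluded(self, ann: dict) -> dict:
        """Move a variant onto an excluded-region gene (difficult-to-call
        cluster); keeps the annotation self-consistent."""
        if len(self.excluded_genes) == 0:
            return ann
        row = self.excluded_genes.iloc[int(self.rng.integers(0, len(self.excluded_genes)))]
        ann.update(chrom=row.chrom, pos=self.genome.random_exonic_position(self.rng, row),
                   gene=row.gene, loeuf=float(row.loeuf))
        return ann

    def _pick_gene(self, bin_name: str, pool: pd.DataFrame | None = None):
        if pool is None:
            if bin_name == "PTV_LOEUF":
                pool = self.auto_constrained
            elif bin_name == "PTV_other":
                pool = self.auto_unconstrained
            else:
                pool = self.auto_all
        idx = int(self.rng.integers(0, len(pool)))
        return pool.iloc[idx]

    def _pext(self) -> float:
        u = self.rng.random()
        if u < 0.6:
            return float(np.round(self.rng.uniform(0.90001, 1.0), 4))
        if u < 0.9:
            return float(np.round(self.rng.uniform(0.10001, 0.9), 4))
        return float(np.round(self.rng.uniform(0.0, 0.1), 4))

    def new_variant(self, bin_name: str, *, maf: float, gene_row=None) -> dict:
        rng = self.rng
        if gene_row is None:
            gene_row = self._pick_gene(bin_name)
        pos = self.genome.random_exonic_position(rng, gene_row)
        ref, alt = rng.choice(BASES, size=2, replace=False)
        self.counter += 1
        row = {
            "variant_id": f"v{self.counter:06d}",
            "chrom": gene_row.chrom,
            "pos": int(pos),
            "ref": str(ref),
            "alt": str(alt),
            "gene": gene_row.gene,
            "loeuf": float(gene_row.loeuf),
            "maf_mono": maf,
            "maf_bi": maf,
            "mpc": np.nan,
            "loftee": "NA",
            "alpha_missense": "NA",
            "pext": self._pext(),
            "gnomad_hom": 0 if maf == 0 else int(rng.random() < 0.1) * int(rng.integers(1, 5)),
            "gnomad_male_hemi": 0,
            "filter_status": "PASS",
        }
        if bin_name in ("PTV_LOEUF", "PTV_other"):
            row["consequence"] = "PTV"
            hc = 0.95 if bin_name == "PTV_LOEUF" else 0.7
            row["loftee"] = "HC" if rng.random() < hc else "LC"
        elif bin_name == "Synonymous":
            row["consequence"] = "synonymous"
        else:
            row["consequence"] = "missense"
            if bin_name == "DmisB":
                row["mpc"] = float(np.round(rng.uniform(2.0, 3.5), 3))
                lp = 0.85
            elif bin_name == "DmisA":
                row["mpc"] = float(np.round(rng.uniform(1.0, 1.999), 3))
                lp = 0.5
            else:
                row["mpc"] = float(np.round(rng.uniform(0.0, 0.999), 3))
                lp = 0.05
            u = rng.random()
            row["alpha_missense"] = (
                "likely_pathogenic" if u < lp else ("ambiguous" if u < lp + 0.15 else "likely_benign")
            )
        return row


def _draw_maf(rng: np.random.Generator) -> float:
    """Inherited-variant frequency mixture; ~30% are novel (absent from
    the reference populations), most pass the 0.1% cut, some only the 1%
    biallelic cut, a few fail both."""
    u = rng.random()
    if u < 0.3:
        return 0.0
    if u < 0.8:
        return float(rng.uniform(1e-6, 1e-3))
    if u < 0.92:
        return float(rng.uniform(1e-3, 1e-2))
    return float(rng.uniform(1e-2, 0.1))


def _qual_passing(rng: np.random.Generator, *, het: bool, hom: bool = False) -> tuple[int, int, int, int]:
    """(dp, gq, ad_ref, ad_alt) comfortably inside all thresholds."""
    dp = int(rng.integers(20, 60))
    gq = int(rng.integers(30, 100))
    if hom:
        alt = dp
    elif het:
        alt = int(rng.binomial(dp, 0.5))
        lo, hi = dp // 4 + 1, dp - 1  # enforce AB > 0.25 for planted carriers
        alt = min(max(alt, lo), hi)
    else:
        alt = 0
    return dp, gq, dp - alt, alt


def _geno_row(variant_id: str, ind: Individual, gt: int, dp: int, gq: int, ad_ref: int, ad_alt: int) -> dict:
    return dict(
        variant_id=variant_id, fid=ind.fid, iid=ind.iid, gt_a=gt, gt_b=gt,
        dp=dp, gq=gq, ad_ref=ad_ref, ad_alt=ad_alt,
    )


def generate_snv_callset(
    pedigree: Pedigree,
    config: SimulationConfig,
    genome: SyntheticGenome,
    rng: np.random.Generator,
    truth: GroundTruth | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Simulate the cohort's SNV call sets for both emulated callers.

    Returns (annotation table, long genotype table, ground truth).
    """
    if truth is None:
        truth = GroundTruth()
    factory = _VariantFactory(genome, rng)
    ann_rows: list[dict] = []
    geno_rows: list[dict] = []
    bin_mix = np.asarray(config.planted_bin_mix)

    families = pedigree.families

    for fam in families:
        father = next((p for p in fam.parents if p.is_male), None)
        mother = next((p for p in fam.parents if not p.is_male), None)
        children = fam.children
        if not children:
            continue

        # ---- inherited background variants -----------------------------
        for _ in range(config.background_variants_per_family):
            bin_name = str(rng.choice(BIN_ORDER, p=bin_mix))
            ann = factory.new_variant(bin_name, maf=_draw_maf(rng))
            if rng.random() < 0.05:  # exercise the excluded-region filter
                ann = factory.relocate_to_excluded(ann)
            vid = ann["variant_id"]
            ann_rows.append(ann)
            carrier = father if rng.random() < 0.5 else mother
            if carrier is None:  # missing parent: fall back to the other
                carrier = father or mother
            origin = "paternal" if carrier.is_male else "maternal"
            for parent in (father, mother):
                if parent is None:
                    continue
                het = parent is carrier
                dp, gq, adr, ada = _qual_passing(rng, het=het)
                geno_rows.append(_geno_row(vid, parent, int(het), dp, gq, adr, ada))
            for child in children:
                transmitted = bool(rng.random() < 0.5)
                dp, gq, adr, ada = _qual_passing(rng, het=transmitted)
                geno_rows.append(_geno_row(vid, child, int(transmitted), dp, gq, adr, ada))
                if transmitted:
                    truth.inherited.append(
                        dict(variant_id=vid, child_id=child.iid, origin=origin)
                    )

        # ---- de novo variants ------------------------------------------
        for child in children:
            n_dn = int(rng.poisson(config.de_novo_rate_per_child))
            for _ in range(n_dn):
                bin_name = str(rng.choice(BIN_ORDER, p=bin_mix))
                ann = factory.new_variant(bin_name, maf=0.0)
                vid = ann["variant_id"]
                fail = bool(rng.random() < config.quality_fail_fraction)
                mode = str(rng.choice(FAIL_MODES)) if fail else ""

                dp, gq, adr, ada = _qual_passing(rng, het=True)
                gt_b = 1
                if mode == "low_dp":
                    dp = int(rng.integers(3, 10))
                    ada = max(1, int(rng.binomial(dp, 0.5)))
                    adr = dp - ada
                elif mode == "low_gq":
                    gq = int(rng.integers(0, 21))
                elif mode == "low_ab":
                    ada = max(1, dp // 4 - int(rng.integers(0, max(1, dp // 8))))
                    ada = min(ada, dp // 4)  # AB <= 0.25
                    adr = dp - ada
                elif mode == "single_caller":
                    gt_b = 0
                elif mode == "non_pass":
                    ann["filter_status"] = "LowQual"
                ann_rows.append(ann)

                row = _geno_row(vid, child, 1, dp, gq, adr, ada)
                row["gt_b"] = gt_b
                geno_rows.append(row)
                ao_parent = rng.random() < 0.5  # which parent shows stray reads
                for j, parent in enumerate((father, mother)):
                    if parent is None:
                        continue
                    pdp, pgq, padr, pada = _qual_passing(rng, het=False)
                    if mode == "parent_ao" and (j == 0) == ao_parent:
                        pada = int(rng.integers(1, 3))
                        padr = pdp - pada
                    geno_rows.append(_geno_row(vid, parent, 0, pdp, pgq, padr, pada))
                # siblings are reference
                for sib in children:
                    if sib.iid == child.iid:
                        continue
                    sdp, sgq, sadr, sada = _qual_passing(rng, het=False)
                    geno_rows.append(_geno_row(vid, sib, 0, sdp, sgq, sadr, sada))
                truth.de_novo.append(
                    dict(
                        variant_id=vid, child_id=child.iid, bin=bin_name,
                        quality_fail=fail, fail_mode=(mode if fail else ""),
                    )
                )

    _plant_biallelic(pedigree, config, factory, rng, truth, ann_rows, geno_rows)
    _plant_xlinked(pedigree, config, factory, rng, truth, ann_rows, geno_rows)

    ann = pd.DataFrame(ann_rows)
    geno = pd.DataFrame(geno_rows, columns=GENO_COLUMNS)
    return ann, geno, truth


def _plant_biallelic(pedigree, config, factory, rng, truth, ann_rows, geno_rows) -> None:
    """Compound-heterozygous DmisA pairs in genes with biallelic MOI."""
    if config.n_biallelic_events == 0:
        return
    pool = factory.auto_all
    biallelic_genes = pool[pool["moi"].isin(["biallelic", "both"])]
    fams = [f for f in pedigree.families if f.affected_children and len(f.parents) == 2]
    k = min(config.n_biallelic_events, len(fams), len(biallelic_genes))
    fam_idx = rng.choice(len(fams), size=k, replace=False)
    gene_idx = rng.choice(len(biallelic_genes), size=k, replace=False)
    for fi, gi in zip(fam_idx, gene_idx):
        fam: Family = fams[int(fi)]
        gene_row = biallelic_genes.iloc[int(gi)]
        proband = fam.affected_children[0]
        father = next(p for p in fam.parents if p.is_male)
        mother = next(p for p in fam.parents if not p.is_male)
        vids = []
        for carrier, non_carrier in ((father, mother), (mother, father)):
            ann = factory.new_variant("DmisA", maf=float(rng.uniform(1e-3, 5e-3)), gene_row=gene_row)
            ann["gnomad_hom"] = 0
            vid = ann["variant_id"]
            ann_rows.append(ann)
            vids.append(vid)
            dp, gq, adr, ada = _qual_passing(rng, het=True)
            geno_rows.append(_geno_row(vid, carrier, 1, dp, gq, adr, ada))
            dp, gq, adr, ada = _qual_passing(rng, het=False)
            geno_rows.append(_geno_row(vid, non_carrier, 0, dp, gq, adr, ada))
            for child in fam.children:
                het = child.iid == proband.iid
                dp, gq, adr, ada = _qual_passing(rng, het=het)
                geno_rows.append(_geno_row(vid, child, int(het), dp, gq, adr, ada))
                if het:
                    origin = "paternal" if carrier.is_male else "maternal"
                    truth.inherited.append(dict(variant_id=vid, child_id=child.iid, origin=origin))
        truth.biallelic.append(
            dict(gene=str(gene_row.gene), child_id=proband.iid, variant_ids=vids, kind="comphet_snv_snv")
        )


def _plant_xlinked(pedigree, config, factory, rng, truth, ann_rows, geno_rows) -> None:
    """Maternally inherited hemizygous DmisB in male probands, absent from
    unaffected brothers and from reference males."""
    if config.n_xlinked_events == 0:
        return
    fams = [
        f
        for f in pedigree.families
        if any(c.is_male for c in f.affected_children) and len(f.parents) == 2
    ]
    x_pool = factory.x_genes
    # keep clear of the pseudo-autosomal region (first 2.7 Mb)
    x_pool = x_pool[x_pool["start"] > 3_000_000]
    k = min(config.n_xlinked_events, len(fams), len(x_pool))
    fam_idx = rng.choice(len(fams), size=k, replace=False)
    gene_idx = rng.choice(len(x_pool), size=k, replace=False)
    for fi, gi in zip(fam_idx, gene_idx):
        fam: Family = fams[int(fi)]
        gene_row = x_pool.iloc[int(gi)]
        proband = next(c for c in fam.affected_children if c.is_male)
        father = next(p for p in fam.parents if p.is_male)
        mother = next(p for p in fam.parents if not p.is_male)
        ann = factory.new_variant("DmisB", maf=float(rng.uniform(1e-4, 1e-3)), gene_row=gene_row)
        ann["gnomad_male_hemi"] = 0
        vid = ann["variant_id"]
        ann_rows.append(ann)
        dp, gq, adr, ada = _qual_passing(rng, het=True)
        geno_rows.append(_geno_row(vid, mother, 1, dp, gq, adr, ada))
        dp, gq, adr, ada = _qual_passing(rng, het=False)
        geno_rows.append(_geno_row(vid, father, 0, dp, gq, adr, ada))
        for child in fam.children:
            carrier = child.iid == proband.iid
            if carrier:
                dp, gq, _, _ = _qual_passing(rng, het=True)
                geno_rows.append(_geno_row(vid, child, 1, dp, gq, 0, dp))  # hemizygous
            else:
                dp, gq, adr, ada = _qual_passing(rng, het=False)
                geno_rows.append(_geno_row(vid, child, 0, dp, gq, adr, ada))
        truth.xlinked.append(dict(gene=str(gene_row.gene), child_id=proband.iid, variant_id=vid))
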