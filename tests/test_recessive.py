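"""Biallelic, X-linked, transmission-bias and multiple-hit scans."""

from __future__ import annotations

import pandas as pd
import pytest

from famvar import denovo, io as fio, recessive
from famvar.config import Thresholds
from famvar.pedigree import PED_COLUMNS, Pedigree
from oracles import binom_two_sided_exact

TH = Thresholds()


def carrier(individual="F1.3", gene="G1", vid="v1", origin="paternal", genotype=1,
            bin_="DmisA", pdsnv=True, chrom="chr1", pos=1000, severe=False, fid="F1"):
    return dict(individual=individual, fid=fid, variant_id=vid, gene=gene, chrom=chrom,
                pos=pos, genotype=genotype, bin=bin_, origin=origin, pdsnv=pdsnv,
                severe=severe, brain_expressed="constitutive")


def genes_df(moi="biallelic", ndd=False):
    return pd.DataFrame([dict(gene="G1", chrom="chr1", start=0, end=10_000, cds_start=100,
                              cds_end=9_900, exon_starts="0", exon_length=300, loeuf=1.0,
                              phaplo=0.1, ptriplo=0.1, ndd_list=ndd, asd_list=False, moi=moi)])


def variants_df(hom=0):
    return pd.DataFrame([
        dict(variant_id="v1", gnomad_hom=hom, gnomad_male_hemi=0, maf_mono=0.0),
        dict(variant_id="v2", gnomad_hom=0, gnomad_male_hemi=0, maf_mono=0.0),
    ])


class TestBiallelic:
    def test_trans_pair_emitted(self):
        carriers = pd.DataFrame([
            carrier(vid="v1", origin="paternal"), carrier(vid="v2", origin="maternal"),
        ])
        out = recessive.find_biallelic_events(carriers, None, genes_df(), variants_df())
        assert len(out) == 1
        row = out.iloc[0]
        assert row.kind == "comphet_snv_snv" and bool(row.passes_strict)

    def test_cis_pair_not_emitted(self):
        carriers = pd.DataFrame([
            carrier(vid="v1", origin="maternal"), carrier(vid="v2", origin="maternal"),
        ])
        out = recessive.find_biallelic_events(carriers, None, genes_df(), variants_df())
        assert len(out) == 0

    def test_unknown_pairs_with_established(self):
        carriers = pd.DataFrame([
            carrier(vid="v1", origin="unknown"), carrier(vid="v2", origin="maternal"),
        ])
        out = recessive.find_biallelic_events(carriers, None, genes_df(), variants_df())
        assert len(out) == 1

    def test_de_novo_pairs_with_inherited(self):
        carriers = pd.DataFrame([
            carrier(vid="v1", origin="maternal", bin_="DmisA"),
            carrier(vid="v2", origin="de_novo", bin_="DmisB"),
        ])
        out = recessive.find_biallelic_events(carriers, None, genes_df(), variants_df())
        assert len(out) == 1

    def test_hom_event(self):
        carriers = pd.DataFrame([carrier(vid="v1", genotype=2, origin="unknown")])
        out = recessive.find_biallelic_events(carriers, None, genes_df(), variants_df())
        assert out.iloc[0].kind == "hom"

    def test_strict_needs_moi_and_no_reference_homs(self):
        carriers = pd.DataFrame([
            carrier(vid="v1", origin="paternal"), carrier(vid="v2", origin="maternal"),
        ])
        not_biallelic = recessive.find_biallelic_events(carriers, None, genes_df(moi="monoallelic"), variants_df())
        assert not not_biallelic.iloc[0].passes_strict
        with_homs = recessive.find_biallelic_events(carriers, None, genes_df(), variants_df(hom=3))
        assert not with_homs.iloc[0].passes_strict

    def test_cnv_snv_compound_with_unknown_cnv_origin(self):
        carriers = pd.DataFrame([carrier(vid="v2", origin="maternal")])
        cnvs = pd.DataFrame([dict(sample_id="F1.3", chrom="chr1", start=0, end=5_000,
                                  cnv_type="DEL", genes="G1", inheritance="unknown")])
        out = recessive.find_biallelic_events(carriers, cnvs, genes_df(), variants_df())
        assert (out["kind"] == "comphet_cnv_snv").any()

    def test_symmetry_under_input_order(self):
        rows = [carrier(vid="v1", origin="paternal"), carrier(vid="v2", origin="maternal")]
        a = recessive.find_biallelic_events(pd.DataFrame(rows), None, genes_df(), variants_df())
        b = recessive.find_biallelic_events(pd.DataFrame(rows[::-1]), None, genes_df(), variants_df())
        pd.testing.assert_frame_equal(a, b)


def _ped(rows):
    return Pedigree(pd.DataFrame(rows, columns=PED_COLUMNS))


class TestXLinked:
    def _family(self, brother_sex=1, brother_affected=1):
        return _ped([
            ("F1", "F1.1", "0", "0", 1, 1), ("F1", "F1.2", "0", "0", 2, 1),
            ("F1", "F1.3", "F1.1", "F1.2", 1, 2),
            ("F1", "F1.4", "F1.1", "F1.2", brother_sex, brother_affected),
        ])

    def test_male_proband_no_brothers_is_candidate(self):
        ped = _ped([
            ("F1", "F1.1", "0", "0", 1, 1), ("F1", "F1.2", "0", "0", 2, 1),
            ("F1", "F1.3", "F1.1", "F1.2", 1, 2),
        ])
        carriers = pd.DataFrame([carrier(chrom="chrX", pos=5_000_000, bin_="DmisB")])
        out = recessive.find_xlinked_candidates(carriers, None, ped, [("chrX", 0, 2_700_000)], variants_df())
        assert len(out) == 1 and out.iloc[0].absent_in_reference_males

    def test_variant_in_unaffected_brother_excluded(self):
        ped = self._family(brother_sex=1, brother_affected=1)
        carriers = pd.DataFrame([
            carrier(individual="F1.3", chrom="chrX", pos=5_000_000),
            carrier(individual="F1.4", chrom="chrX", pos=5_000_000),
        ])
        out = recessive.find_xlinked_candidates(carriers, None, ped, [], variants_df())
        assert len(out) == 0

    def test_par_region_and_female_probands_skipped(self):
        ped = _ped([
            ("F1", "F1.1", "0", "0", 1, 1), ("F1", "F1.2", "0", "0", 2, 1),
            ("F1", "F1.3", "F1.1", "F1.2", 2, 2),
        ])
        carriers = pd.DataFrame([carrier(chrom="chrX", pos=1_000_000)])
        out = recessive.find_xlinked_candidates(carriers, None, ped, [("chrX", 0, 2_700_000)], variants_df())
        assert len(out) == 0

    def test_planted_events_recovered(self, clean_cohort):
        c = clean_cohort
        records = fio.build_trio_records(c.ann, c.geno, c.pedigree)
        carriers = denovo.pdsnv_table(c.ann, records, c.genome.region_beds()["excluded"], TH)
        out = recessive.find_xlinked_candidates(
            carriers, None, c.pedigree, c.genome.region_beds()["par"], c.ann
        )
        planted = {(e["child_id"], e["variant_id"]) for e in c.truth.xlinked}
        found = set(zip(out["proband"], out["item"]))
        assert planted <= found


class TestTransmissionBias:
    def _setup(self, n_pat, n_mat):
        ped = _ped([
            ("F1", "F1.1", "0", "0", 1, 1), ("F1", "F1.2", "0", "0", 2, 1),
            ("F1", "F1.3", "F1.1", "F1.2", 1, 2),
        ])
        rows = [carrier(vid=f"p{i}", origin="paternal") for i in range(n_pat)]
        rows += [carrier(vid=f"m{i}", origin="maternal") for i in range(n_mat)]
        variants = pd.DataFrame(
            [dict(variant_id=r["variant_id"], maf_mono=0.0) for r in rows],
            columns=["variant_id", "maf_mono"],
        )
        return pd.DataFrame(rows, columns=list(carrier().keys())), ped, variants

    def test_balanced_large_counts_not_significant(self):
        carriers, ped, variants = self._setup(1300, 1259)
        pat, mat, p = recessive.transmission_bias_test(carriers, ped, variants)
        assert (pat, mat) == (1300, 1259)
        assert p > 0.05

    def test_symmetric_counts_p_one(self):
        carriers, ped, variants = self._setup(10, 10)
        assert recessive.transmission_bias_test(carriers, ped, variants)[2] == 1.0

    def test_extreme_counts_closed_form(self):
        carriers, ped, variants = self._setup(0, 20)
        _, _, p = recessive.transmission_bias_test(carriers, ped, variants)
        assert p == pytest.approx(2 * 0.5**20)

    def test_zero_counts_p_one(self):
        carriers, ped, variants = self._setup(0, 0)
        assert recessive.transmission_bias_test(carriers, ped, variants) == (0, 0, 1.0)

    @pytest.mark.parametrize("k,n", [(0, 5), (3, 11), (7, 25), (12, 25)])
    def test_matches_exact_enumeration(self, k, n):
        carriers, ped, variants = self._setup(k, n - k)
        _, _, p = recessive.transmission_bias_test(carriers, ped, variants)
        assert p == pytest.approx(float(binom_two_sided_exact(k, n)), rel=1e-12)


class TestMultipleHits:
    def _pdcnv(self, inheritance="paternal", category="RGD"):
        return pd.DataFrame([dict(sample_id="F1.3", chrom="chr2", start=10_000_000,
                                  end=10_800_000, cnv_type="DUP", rgd_hit="chr2:locus",
                                  category=category, inheritance=inheritance)])

    def _ped(self):
        return _ped([
            ("F1", "F1.1", "0", "0", 1, 1), ("F1", "F1.2", "0", "0", 2, 1),
            ("F1", "F1.3", "F1.1", "F1.2", 1, 2),
        ])

    def test_de_novo_pdsnv_is_secondary_hit(self):
        carriers = pd.DataFrame([carrier(origin="de_novo", bin_="DmisB")])
        out = recessive.detect_multiple_hits(self._pdcnv(), carriers, genes_df(ndd=True), self._ped())
        assert len(out) == 1 and out.iloc[0].hit_class == "de_novo_pdsnv"

    def test_inherited_ptv_loeuf_in_ndd_gene(self):
        carriers = pd.DataFrame([carrier(origin="maternal", bin_="PTV_LOEUF")])
        out = recessive.detect_multiple_hits(self._pdcnv(), carriers, genes_df(ndd=True), self._ped())
        assert (out["hit_class"] == "ptv_loeuf_ndd").any()

    def test_pdcnv_from_other_parent(self):
        pdcnvs = pd.concat([
            self._pdcnv(inheritance="paternal"),
            pd.DataFrame([dict(sample_id="F1.3", chrom="chr3", start=1_000_000, end=1_100_000,
                               cnv_type="DEL", rgd_hit="", category="DOSAGE_SENSITIVE",
                               inheritance="maternal")]),
        ], ignore_index=True)
        carriers = pd.DataFrame([], columns=list(carrier().keys()))
        out = recessive.detect_multiple_hits(pdcnvs, carriers, genes_df(), self._ped())
        assert (out["hit_class"] == "pdcnv_other_parent").any()

    def test_rgd_carrier_with_nothing_else(self):
        carriers = pd.DataFrame([], columns=list(carrier().keys()))
        out = recessive.detect_multiple_hits(self._pdcnv(), carriers, genes_df(), self._ped())
        assert len(out) == 0


def test_planted_biallelic_recovered(clean_cohort):
    c = clean_cohort
    records = fio.build_trio_records(c.ann, c.geno, c.pedigree)
    carriers = denovo.pdsnv_table(c.ann, records, c.genome.region_beds()["excluded"], TH, mode="biallelic")
    events = recessive.find_biallelic_events(carriers, None, c.genome.genes, c.ann)
    for planted in c.truth.biallelic:
        match = events[
            (events["gene"] == planted["gene"]) & (events["proband"] == planted["child_id"])
        ]
        assert len(match) >= 1, f"planted biallelic event in {planted['gene']} not recovered"
        assert match["passes_strict"].any()
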