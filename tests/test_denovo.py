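"""De novo SNV filtering, severity binning and pdSNV flagging."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from famvar import denovo, io as fio
from famvar.config import Thresholds

TH = Thresholds()


def make_variant(vid="v1", consequence="missense", maf=0.0001, loeuf=1.0, mpc=1.5,
                 loftee="NA", alpha="NA", pext=0.95, chrom="chr1", pos=1000,
                 filter_status="PASS"):
    return dict(variant_id=vid, chrom=chrom, pos=pos, gene="G1", consequence=consequence,
                maf_mono=maf, maf_bi=maf, loeuf=loeuf, mpc=mpc, loftee=loftee,
                alpha_missense=alpha, pext=pext, filter_status=filter_status)


def make_record(vid="v1", child_gt=(1, 1), father_gt=(0, 0), mother_gt=(0, 0),
                child_dp=30, father_dp=30, mother_dp=30, child_gq=60, child_ab=0.5,
                father_ao=0, mother_ao=0, chrom="chr1", pos=1000, filter_status="PASS"):
    return dict(variant_id=vid, chrom=chrom, pos=pos, gene="G1", filter_status=filter_status,
                fid="F1", child_id="F1.3",
                child_gt_a=child_gt[0], child_gt_b=child_gt[1],
                child_dp=child_dp, child_gq=child_gq, child_ab=child_ab,
                father_gt_a=father_gt[0], father_gt_b=father_gt[1],
                father_dp=father_dp, father_gq=60, father_ao=father_ao,
                mother_gt_a=mother_gt[0], mother_gt_b=mother_gt[1],
                mother_dp=mother_dp, mother_gq=60, mother_ao=mother_ao)


class TestQualityRarityFilter:
    def test_toy_table_each_rule_violated_once(self):
        """10 variants, 3 violating one rule each -> 7 retained."""
        variants, records = [], []
        for i in range(10):
            vid = f"v{i}"
            v = make_variant(vid=vid)
            r = make_record(vid=vid)
            if i == 0:
                r["child_dp"] = 9  # below DP 10
            elif i == 1:
                r["child_gq"] = 19  # below GQ 20
            elif i == 2:
                v["maf_mono"] = 0.002  # above 0.1%
            variants.append(v)
            records.append(r)
        out = denovo.filter_quality_and_rarity(
            pd.DataFrame(variants), pd.DataFrame(records), "monoallelic", [], TH
        )
        assert len(out) == 7
        assert set(out["variant_id"]) == {f"v{i}" for i in range(3, 10)}

    @pytest.mark.parametrize(
        "maf,mode,kept",
        [(0.0009, "monoallelic", True), (0.002, "monoallelic", False),
         (0.009, "biallelic", True), (0.02, "biallelic", False)],
    )
    def test_maf_thresholds(self, maf, mode, kept):
        out = denovo.filter_quality_and_rarity(
            pd.DataFrame([make_variant(maf=maf)]), pd.DataFrame([make_record()]), mode, [], TH
        )
        assert (len(out) == 1) is kept

    def test_excluded_region_and_non_pass_removed(self):
        v1 = make_variant(vid="v1", chrom="chr6", pos=7_000_000)
        v2 = make_variant(vid="v2", filter_status="LowQual")
        r1 = make_record(vid="v1", chrom="chr6", pos=7_000_000)
        r2 = make_record(vid="v2", filter_status="LowQual")
        out = denovo.filter_quality_and_rarity(
            pd.DataFrame([v1, v2]), pd.DataFrame([r1, r2]), "monoallelic",
            [("chr6", 6_000_000, 9_500_000)], TH
        )
        assert len(out) == 0

    def test_unknown_mode_raises(self):
        with pytest.raises(ValueError, match="mode"):
            denovo.filter_quality_and_rarity(
                pd.DataFrame([make_variant()]), pd.DataFrame([make_record()]), "triallelic", [], TH
            )


class TestDeNovoRule:
    def test_boundary_pass(self):
        rec = make_record(child_dp=10, father_dp=10, mother_dp=10, child_gq=21, child_ab=0.26)
        out = denovo.call_de_novo(pd.DataFrame([rec]), TH)
        assert len(out) == 1 and out["origin"].iloc[0] == "de_novo"

    @pytest.mark.parametrize(
        "kwargs",
        [dict(father_ao=1), dict(mother_ao=2), dict(child_ab=0.25), dict(child_dp=9),
         dict(father_dp=9), dict(child_gq=20), dict(child_gt=(1, 0)),
         dict(father_gt=(1, 1)), dict(child_gt=(0, 1))],
    )
    def test_single_violations_rejected(self, kwargs):
        rec = make_record(**kwargs)
        assert len(denovo.call_de_novo(pd.DataFrame([rec]), TH)) == 0

    def test_missing_parent_routes_to_unknown(self):
        rec = make_record()
        rec.update(mother_gt_a=np.nan, mother_gt_b=np.nan, mother_dp=np.nan, mother_ao=np.nan)
        assert len(denovo.call_de_novo(pd.DataFrame([rec]), TH)) == 0
        origin = denovo.assign_origin(pd.DataFrame([rec]), TH)
        assert origin["origin"].iloc[0] == "unknown"

    def test_recovery_matches_planted_truth(self, clean_cohort):
        """With no quality-failing planted events, sensitivity and
        specificity versus ground truth are both exactly 1."""
        c = clean_cohort
        records = fio.build_trio_records(c.ann, c.geno, c.pedigree)
        retained = denovo.filter_quality_and_rarity(
            c.ann, records, "monoallelic", c.genome.region_beds()["excluded"], TH
        )
        found = denovo.call_de_novo(retained, TH)
        found_ids = set(zip(found["variant_id"], found["child_id"]))
        assert found_ids == c.truth.passing_de_novo_ids()

    def test_no_parental_evidence_ever_de_novo(self, sim_small):
        """Exhaustive scan: no call with any parental alternate reads."""
        c = sim_small
        records = fio.build_trio_records(c.ann, c.geno, c.pedigree)
        found = denovo.call_de_novo(records, TH)
        assert (found["father_ao"] == 0).all() and (found["mother_ao"] == 0).all()


class TestSeverityBins:
    @pytest.mark.parametrize(
        "consequence,loeuf,mpc,expected",
        [("PTV", 0.59, np.nan, "PTV_LOEUF"), ("PTV", 0.6, np.nan, "PTV_other"),
         ("missense", 1.0, 2.0, "DmisB"), ("missense", 1.0, 1.0, "DmisA"),
         ("missense", 1.0, 0.99, "Mis_low"), ("synonymous", 1.0, 3.0, "Synonymous")],
    )
    def test_bin_assignment(self, consequence, loeuf, mpc, expected):
        v = pd.DataFrame([make_variant(consequence=consequence, loeuf=loeuf, mpc=mpc)])
        assert denovo.assign_severity_bin(v, TH).iloc[0] == expected

    def test_missing_mpc_binned_low_with_warning(self, caplog):
        v = pd.DataFrame([make_variant(consequence="missense", mpc=np.nan)])
        with caplog.at_level("WARNING"):
            out = denovo.assign_severity_bin(v, TH)
        assert out.iloc[0] == "Mis_low"
        assert "MPC" in caplog.text

    def test_bins_partition_retained_variants(self, sim_small):
        coding = sim_small.ann[sim_small.ann["consequence"].isin(denovo.CODING_CONSEQUENCES)]
        bins = denovo.assign_severity_bin(coding, TH)
        assert bins.isin(denovo.SEVERITY_BINS).all()
        assert bins.value_counts().sum() == len(coding)


class TestPdsnvFlags:
    @pytest.mark.parametrize(
        "kwargs,pdsnv,severe,brain",
        [
            (dict(consequence="PTV", loeuf=0.3, loftee="HC", pext=0.95), True, True, "constitutive"),
            (dict(consequence="PTV", loeuf=0.3, loftee="LC", pext=0.46), True, False, "intermediate"),
            (dict(consequence="missense", mpc=2.5, alpha="likely_benign", pext=0.5), True, False, "intermediate"),
            (dict(consequence="missense", mpc=2.5, alpha="likely_pathogenic", pext=0.05), True, True, "low"),
            (dict(consequence="missense", mpc=1.2, alpha="likely_pathogenic"), True, False, "constitutive"),
            (dict(consequence="missense", mpc=0.5), False, False, "constitutive"),
            (dict(consequence="synonymous"), False, False, "constitutive"),
        ],
    )
    def test_flags(self, kwargs, pdsnv, severe, brain):
        out = denovo.flag_pdsnv_and_severe(pd.DataFrame([make_variant(**kwargs)]), TH)
        row = out.iloc[0]
        assert bool(row["pdsnv"]) is pdsnv
        assert bool(row["severe"]) is severe
        assert row["brain_expressed"] == brain
        if row["severe"]:
            assert row["bin"] in ("PTV_LOEUF", "DmisB")
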