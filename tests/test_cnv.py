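"""CNV consensus, annotation/rare filter, inheritance, reconciliation and
pdCNV prioritization."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from famvar import cnv
from famvar.config import Thresholds
from oracles import reciprocal_overlap_per_base

TH = Thresholds()


def toy_gene(gene="G1", chrom="chr1", start=100_000, end=160_000, phaplo=0.1, ptriplo=0.1,
             ndd=False, moi="monoallelic"):
    exon_starts = ",".join(str(start + i * 6_000) for i in range(10))
    return dict(gene=gene, chrom=chrom, start=start, end=end, cds_start=start + 500,
                cds_end=end - 500, exon_starts=exon_starts, exon_length=300,
                loeuf=1.0, phaplo=phaplo, ptriplo=ptriplo, ndd_list=ndd, asd_list=False, moi=moi)


def call(sample="S1", chrom="chr1", start=100_000, end=150_000, cnv_type="DEL",
         caller="arrayA", confidence=50.0, n_probes=25, platform="array", fid="F1"):
    return dict(sample_id=sample, fid=fid, chrom=chrom, start=start, end=end,
                cnv_type=cnv_type, caller=caller, confidence=confidence,
                n_probes=n_probes, platform=platform)


class TestReciprocalOverlap:
    def test_identity_and_analytic(self):
        assert cnv.reciprocal_overlap(("chr1", 0, 100), ("chr1", 0, 100)) == 1.0
        assert cnv.reciprocal_overlap(("chr1", 0, 100), ("chr1", 50, 200)) == pytest.approx(1 / 3)
        assert cnv.reciprocal_overlap(("chr1", 0, 100), ("chr2", 0, 100)) == 0.0
        assert cnv.reciprocal_overlap(("chr1", 0, 100), ("chr1", 100, 200)) == 0.0

    @settings(max_examples=200, derandomize=True)
    @given(st.lists(st.integers(0, 500), min_size=4, max_size=4))
    def test_properties_hold_for_arbitrary_intervals(self, xs):
        a = ("chr1", min(xs[0], xs[1]), max(xs[0], xs[1]) + 1)
        b = ("chr1", min(xs[2], xs[3]), max(xs[2], xs[3]) + 1)
        ro = cnv.reciprocal_overlap(a, b)
        assert 0.0 <= ro <= 1.0
        assert ro == cnv.reciprocal_overlap(b, a)
        assert (ro == 1.0) == (a == b)

    def test_matches_per_base_oracle_on_random_pairs(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            a = sorted(rng.integers(0, 300, size=2).tolist())
            b = sorted(rng.integers(0, 300, size=2).tolist())
            if a[0] == a[1] or b[0] == b[1]:
                continue
            got = cnv.reciprocal_overlap(("chr1", a[0], a[1]), ("chr1", b[0], b[1]))
            want = reciprocal_overlap_per_base(("chr1", a[0], a[1]), ("chr1", b[0], b[1]))
            assert got == pytest.approx(want)
            # symmetry and bounds
            assert got == cnv.reciprocal_overlap(("chr1", b[0], b[1]), ("chr1", a[0], a[1]))
            assert 0.0 <= got <= 1.0


class TestConsensus:
    def test_primary_plus_secondary_at_60pct(self):
        calls = pd.DataFrame([
            call(caller="arrayA", start=100_000, end=150_000),
            call(caller="arrayB", start=110_000, end=160_000),  # RO = 40/60 ~ 0.67
        ])
        out = cnv.build_array_consensus(calls, TH)
        assert len(out) == 1
        row = out.iloc[0]
        assert (row.start, row.end) == (100_000, 160_000)  # union extent
        assert row.supporting_callers == "arrayA,arrayB"

    def test_two_secondary_callers_rejected(self):
        calls = pd.DataFrame([
            call(caller="arrayB"), call(caller="arrayC"),
        ])
        assert len(cnv.build_array_consensus(calls, TH)) == 0

    def test_exact_duplicates_consensus_equals_call(self):
        calls = pd.DataFrame([call(caller=c) for c in ("arrayA", "arrayB", "arrayC")])
        out = cnv.build_array_consensus(calls, TH)
        assert len(out) == 1
        assert (out.iloc[0].start, out.iloc[0].end) == (100_000, 150_000)
        assert out.iloc[0].n_callers == 3

    def test_member_filters(self):
        low_conf = pd.DataFrame([call(caller="arrayA", confidence=9.0), call(caller="arrayB")])
        assert len(cnv.build_array_consensus(low_conf, TH)) == 0
        few_probes = pd.DataFrame([call(caller="arrayA", n_probes=2), call(caller="arrayB")])
        assert len(cnv.build_array_consensus(few_probes, TH)) == 0
        tiny = pd.DataFrame([
            call(caller="arrayA", start=100_000, end=100_900),
            call(caller="arrayB", start=100_000, end=100_900),
        ])
        assert len(cnv.build_array_consensus(tiny, TH)) == 0

    def test_empty_input(self):
        assert len(cnv.build_array_consensus(pd.DataFrame(), TH)) == 0

    def test_consensus_contains_every_member(self, clean_cohort):
        c = clean_cohort
        consensus = cnv.build_array_consensus(c.cnv_calls, TH)
        calls = c.cnv_calls[c.cnv_calls["platform"] == "array"]
        for row in consensus.itertuples(index=False):
            members = calls[
                (calls["sample_id"] == row.sample_id) & (calls["chrom"] == row.chrom)
                & (calls["cnv_type"] == row.cnv_type)
                & (calls["start"] >= row.start) & (calls["end"] <= row.end)
            ]
            assert len(members) >= 2  # the union extent contains its members


def _toy_regions():
    return {
        "segdup": [("chr1", 480_000, 700_000)],
        "centromere": [("chr1", 5_000_000, 5_500_000)],
        "cn_stable": [("chr1", 0, 4_000_000)],
        "rgd": [("chr1", 2_000_000, 2_600_000)],
    }


class TestRareFilter:
    def test_toy_set_hand_enumerated(self):
        """Eight CNVs, each violating exactly one rule; two survivors
        (the clean one and the RGD hit, enumerated by hand)."""
        genes = pd.DataFrame([
            toy_gene("G1", start=100_000, end=160_000),
            toy_gene("G2", start=2_200_000, end=2_260_000),
            toy_gene("G3", start=300_000, end=360_000),
        ])
        rows = [
            call(sample="S1", start=100_000, end=150_000),                   # clean: survives
            call(sample="S2", start=100_000, end=108_000),                   # too small (<10 kb)
            call(sample="S3", start=100_000, end=150_000, n_probes=4),       # too few probes
            call(sample="S4", start=170_000, end=190_000),                   # no exon overlap
            call(sample="S5", start=500_000, end=600_000),                   # segdup >= 50%
            call(sample="S6", start=4_500_000, end=5_400_000),               # cn-stable <= 75% (and centromere)
            call(sample="S7", start=300_000, end=350_000),                   # common in parents
            call(sample="S8", start=2_050_000, end=2_500_000, n_probes=200), # RGD hit: survives
        ]
        base = pd.DataFrame(rows).assign(supporting_callers="arrayA,arrayB", n_callers=2)
        parents = pd.DataFrame(
            [call(sample=f"P{i}", start=300_000, end=350_000) for i in range(5)]
        )
        annotated = cnv.annotate_consensus(base, genes, _toy_regions(), parents, n_parents=5, thresholds=TH)
        out = cnv.filter_rare_exonic(annotated, TH)
        assert set(out["sample_id"]) == {"S1", "S8"}

    def test_intronic_only_removed(self):
        genes = pd.DataFrame([toy_gene("G1", start=100_000, end=160_000)])
        # between exon 0 (100000-100300) and exon 1 (106000-106300)
        c = pd.DataFrame([call(start=100_500, end=105_900, n_probes=10)])
        annotated = cnv.annotate_consensus(c, genes, _toy_regions(), pd.DataFrame(), 0, TH)
        assert not annotated.iloc[0]["exonic"]


class TestInheritance:
    def _row(self, **kw):
        d = call(**kw)
        return pd.DataFrame([d]).iloc[0]

    def test_identical_call_in_mother(self):
        child = self._row()
        mother = pd.DataFrame([call(sample="M")])
        assert cnv.determine_cnv_inheritance(child, pd.DataFrame(), mother, TH) == "maternal"

    def test_no_parental_calls_is_de_novo(self):
        child = self._row()
        assert cnv.determine_cnv_inheritance(child, pd.DataFrame(), pd.DataFrame(), TH) == "de_novo"

    def test_partial_or_type_mismatch_is_unknown(self):
        child = self._row(cnv_type="DEL", start=100_000, end=200_000)
        father = pd.DataFrame([call(sample="P", cnv_type="DUP", start=100_000, end=200_000)])
        assert cnv.determine_cnv_inheritance(child, father, pd.DataFrame(), TH) == "unknown"
        partial = pd.DataFrame([call(sample="P", cnv_type="DEL", start=180_000, end=400_000)])
        assert cnv.determine_cnv_inheritance(child, partial, pd.DataFrame(), TH) == "unknown"

    def test_missing_parent_is_unknown(self):
        child = self._row()
        assert (
            cnv.determine_cnv_inheritance(child, pd.DataFrame(), pd.DataFrame(), TH, father_present=False)
            == "unknown"
        )


class TestReconcile:
    def test_both_platforms_keep_wgs_coordinates(self):
        arr = pd.DataFrame([call()]).assign(supporting_callers="arrayA,arrayB", n_callers=2)
        wgs = pd.DataFrame([call(start=99_500, end=150_700, caller="wgs", platform="wgs")]).assign(
            supporting_callers="wgs", n_callers=1
        )
        merged, counts = cnv.reconcile_array_wgs(arr, wgs, TH)
        assert counts == {"both": 1, "array_only": 0, "wgs_only": 0}
        assert (merged.iloc[0].start, merged.iloc[0].end) == (99_500, 150_700)

    def test_unpaired_keep_platform(self):
        arr = pd.DataFrame([call()]).assign(supporting_callers="arrayA,arrayB", n_callers=2)
        wgs = pd.DataFrame([call(chrom="chr2", caller="wgs", platform="wgs")]).assign(
            supporting_callers="wgs", n_callers=1
        )
        merged, counts = cnv.reconcile_array_wgs(arr, wgs, TH)
        assert counts == {"both": 0, "array_only": 1, "wgs_only": 1}

    def test_empty_wgs_returns_array(self):
        arr = pd.DataFrame([call()]).assign(supporting_callers="arrayA,arrayB", n_callers=2)
        merged, counts = cnv.reconcile_array_wgs(arr, cnv.wgs_callset(pd.DataFrame(columns=arr.columns.tolist() + ["caller"])), TH)
        assert counts["array_only"] == 1 and len(merged) == 1


class TestPrioritize:
    def _annotated(self, genes, **kw):
        extra = {k: kw.pop(k) for k in ("rgd_hit", "inheritance") if k in kw}
        row = {**call(**kw),
               "size": kw.get("end", 150_000) - kw.get("start", 100_000),
               "rgd_hit": "", "inheritance": "paternal", **extra}
        return pd.DataFrame([row]), genes

    def test_large_beats_everything(self):
        genes = pd.DataFrame([toy_gene()])
        df, g = self._annotated(genes, start=0, end=3_200_000, cnv_type="DUP",
                                inheritance="de_novo", rgd_hit="chr1:0-1")
        out = cnv.prioritize_pdcnv(df, g, TH)
        assert out.iloc[0]["category"] == "LARGE"

    def test_rgd_beats_de_novo(self):
        genes = pd.DataFrame([toy_gene()])
        df, g = self._annotated(genes, start=100_000, end=150_000, inheritance="de_novo",
                                rgd_hit="chr1:x")
        assert cnv.prioritize_pdcnv(df, g, TH).iloc[0]["category"] == "RGD"

    def test_inherited_del_dosage_sensitive_at_boundary(self):
        genes = pd.DataFrame([toy_gene(phaplo=0.55)])
        df, g = self._annotated(genes, start=100_000, end=150_000, cnv_type="DEL")
        assert cnv.prioritize_pdcnv(df, g, TH).iloc[0]["category"] == "DOSAGE_SENSITIVE"

    def test_full_cds_dup_needs_triplo(self):
        genes = pd.DataFrame([toy_gene(phaplo=0.1, ptriplo=0.68)])
        df, g = self._annotated(genes, start=90_000, end=170_000, cnv_type="DUP")
        assert cnv.prioritize_pdcnv(df, g, TH).iloc[0]["category"] == "DOSAGE_SENSITIVE"

    def test_low_scores_no_category(self):
        genes = pd.DataFrame([toy_gene(phaplo=0.54, ptriplo=0.67)])
        df, g = self._annotated(genes, start=100_000, end=150_000, cnv_type="DEL")
        assert cnv.prioritize_pdcnv(df, g, TH).iloc[0]["category"] == ""

    def test_fusion_candidate_flagged(self):
        genes = pd.DataFrame([
            toy_gene("G1", start=100_000, end=160_000, phaplo=0.0, ptriplo=0.0),
            toy_gene("G2", start=200_000, end=260_000, phaplo=0.0, ptriplo=0.0),
        ])
        df, g = self._annotated(genes, start=150_000, end=210_000, cnv_type="DUP")
        out = cnv.prioritize_pdcnv(df, g, TH)
        assert bool(out.iloc[0]["fusion_candidate"])
        assert out.iloc[0]["category"] == "DOSAGE_SENSITIVE"

    def test_single_category_per_cnv(self, clean_cohort):
        """Precedence: a CNV gets exactly one (or no) category."""
        c = clean_cohort
        consensus = cnv.build_array_consensus(c.cnv_calls, TH)
        regions = {k: c.genome.region_beds()[k] for k in ("segdup", "centromere", "cn_stable", "rgd")}
        annotated = cnv.annotate_consensus(consensus, c.genome.genes, regions, pd.DataFrame(), 0, TH)
        annotated["inheritance"] = "de_novo"
        out = cnv.prioritize_pdcnv(annotated, c.genome.genes, TH)
        assert out["category"].isin(["", *cnv.CATEGORY_ORDER]).all()
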