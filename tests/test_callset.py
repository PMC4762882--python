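"""Caller merge, unique-variant rule, exclusion filters, classification."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mutburden.callset import (
    CallerSet,
    DepthVafClass,
    MissingGenotypeError,
    VariantCall,
    VariantKey,
    apply_exclusion_filters,
    classify_calls,
    classify_confidence,
    identify_unique_variants,
    merge_caller_outputs,
    minimal_representation,
)
from mutburden.intervals import GenomicInterval, IntervalIndex


def hc_row(sample, chrom="chr1", pos=100, ref="A", alt="G", depth=50,
           alt_depth=25, tranche=True):
    return {"sample_id": sample, "chrom": chrom, "pos": pos, "ref": ref,
            "alt": alt, "depth": depth, "alt_depth": alt_depth,
            "tranche_pass": tranche}


def mt_row(chrom="chr1", pos=100, ref="A", alt="G", depth=50, alt_depth=25,
           judgment="KEEP"):
    return {"chrom": chrom, "pos": pos, "ref": ref, "alt": alt,
            "depth": depth, "alt_depth": alt_depth, "judgment": judgment}


class TestVariantKey:
    def test_insertion_deletion_typing(self):
        assert VariantKey("chr1", 5, "A", "AT").vtype == "insertion"
        assert VariantKey("chr1", 5, "AT", "A").vtype == "deletion"
        assert VariantKey("chr1", 5, "A", "T").vtype == "SNV"

    @pytest.mark.parametrize("pos,ref,alt", [(0, "A", "T"), (5, "A", "A"),
                                             (5, "", "T"), (5, "N", "T")])
    def test_invalid_keys_raise(self, pos, ref, alt):
        with pytest.raises(ValueError):
            VariantKey("chr1", pos, ref, alt)

    def test_minimal_representation(self):
        # shared trailing bases trimmed first, then shared leading bases
        assert minimal_representation(100, "CAA", "CA") == (100, "CA", "C")
        assert minimal_representation(100, "TAG", "TG") == (100, "TA", "T")
        assert minimal_representation(100, "GCAT", "GAT") == (100, "GC", "G")
        assert minimal_representation(100, "TTACG", "TGACG") == (101, "T", "G")
        assert minimal_representation(100, "A", "T") == (100, "A", "T")


class TestMerge:
    def test_dual_caller_agreement_sets_all_flags(self):
        merged = merge_caller_outputs(
            pd.DataFrame([hc_row("S1")]), {"S1": pd.DataFrame([mt_row()])})
        assert len(merged) == 1
        r = merged.iloc[0]
        assert bool(r.hc_called) and bool(r.mutect_called) and bool(r.mutect_keep)
        assert r.vaf == pytest.approx(0.5)

    def test_reject_judgment_propagates(self):
        merged = merge_caller_outputs(
            pd.DataFrame(columns=pd.DataFrame([hc_row("x")]).columns),
            {"S1": pd.DataFrame([mt_row(judgment="REJECT")])})
        r = merged.iloc[0]
        assert bool(r.mutect_called) and not bool(r.mutect_keep)

    def test_different_alts_stay_distinct(self):
        merged = merge_caller_outputs(
            pd.DataFrame([hc_row("S1", alt="G")]),
            {"S1": pd.DataFrame([mt_row(alt="T")])})
        assert len(merged) == 2
        assert set(merged["alt"]) == {"G", "T"}

    def test_conflicting_duplicates_raise(self):
        with pytest.raises(ValueError, match="conflicting"):
            merge_caller_outputs(
                pd.DataFrame([hc_row("S1", depth=50), hc_row("S1", depth=40)]),
                {})


class TestUniqueVariants:
    samples = ["F", "M1", "M2", "M3", "R1", "R2", "R3", "S1", "S2", "S3"]

    def table(self, rows):
        df = pd.DataFrame(rows)
        df["hc_called"] = True
        df["mutect_called"] = False
        df["mutect_keep"] = False
        return df

    def test_single_sample_key_is_unique(self):
        uniq = identify_unique_variants(
            self.table([hc_row("M1")]), self.samples, "F")
        assert uniq["M1"] == {VariantKey("chr1", 100, "A", "G")}

    def test_two_sample_key_is_unique_to_nobody(self):
        uniq = identify_unique_variants(
            self.table([hc_row("M1"), hc_row("R2")]), self.samples, "F")
        assert all(not keys for keys in uniq.values())

    def test_parental_only_key_is_unique_to_nobody(self):
        uniq = identify_unique_variants(
            self.table([hc_row("F")]), self.samples, "F")
        assert all(not keys for keys in uniq.values())

    def test_parental_sharing_blocks_line_uniqueness(self):
        uniq = identify_unique_variants(
            self.table([hc_row("M1"), hc_row("F")]), self.samples, "F")
        assert not uniq["M1"]

    def test_reference_call_does_not_claim_key(self):
        # an explicit alt_depth 0 record is a reference genotype
        uniq = identify_unique_variants(
            self.table([hc_row("M1"), hc_row("R1", alt_depth=0)]),
            self.samples, "F")
        assert uniq["M1"] == {VariantKey("chr1", 100, "A", "G")}

    def test_strict_mode_requires_full_records(self):
        with pytest.raises(MissingGenotypeError):
            identify_unique_variants(
                self.table([hc_row("M1")]), self.samples, "F", mode="strict")
        rows = [hc_row(s, alt_depth=(25 if s == "M1" else 0))
                for s in self.samples]
        uniq = identify_unique_variants(self.table(rows), self.samples, "F",
                                        mode="strict")
        assert uniq["M1"] == {VariantKey("chr1", 100, "A", "G")}

    def test_empty_sample_list_raises(self):
        with pytest.raises(ValueError):
            identify_unique_variants(self.table([hc_row("M1")]), [], "F")

    def test_partition_property(self):
        rng = np.random.default_rng(5)
        rows = [hc_row(self.samples[rng.integers(0, 10)],
                       pos=int(rng.integers(1, 50)))
                for _ in range(120)]
        df = self.table(rows).drop_duplicates(["sample_id", "chrom", "pos"])
        uniq = identify_unique_variants(df, self.samples, "F")
        all_keys = [k for keys in uniq.values() for k in keys]
        assert len(all_keys) == len(set(all_keys)), "each key owned at most once"
        n_distinct = df.groupby(["chrom", "pos", "ref", "alt"]).ngroups
        assert len(all_keys) <= n_distinct


class TestExclusionFilters:
    def calls(self):
        return pd.DataFrame([
            hc_row("M1", pos=150),                       # in low-complexity
            hc_row("M1", pos=500, ref="C", alt="T"),     # in the known set
            hc_row("M1", pos=700, ref="G", alt="A"),     # clean
            hc_row("M1", pos=800, ref="G", alt="C", tranche=False),
        ])

    def test_filters(self):
        lowc = IntervalIndex([GenomicInterval("chr1", 100, 200)])
        known = {("chr1", 500, "C", "T")}
        out = apply_exclusion_filters(self.calls(), lowc, known,
                                      require_tranche=True)
        assert list(out["pos"]) == [700]

    def test_monotone_and_idempotent(self):
        lowc = IntervalIndex([GenomicInterval("chr1", 100, 200)])
        once = apply_exclusion_filters(self.calls(), lowc)
        twice = apply_exclusion_filters(once, lowc)
        assert list(once["pos"]) == list(twice["pos"]) == [500, 700, 800]

    def test_no_filters_is_identity(self):
        calls = self.calls()
        assert apply_exclusion_filters(calls).equals(calls)


# 12-variant hand-labelled toy table: (depth, vaf, hc, mutect, keep) ->
# expected caller_set / depth_vaf_class, worked out by hand from the
# window definitions
TOY_TABLE = [
    (50, 0.50, True, True, True, "SET1", "HIGH"),
    (30, 0.50, False, True, True, "SET2", "LOW"),
    (45, 0.30, False, True, True, "SET3", "SUBCLONAL"),
    (40, 0.40, True, True, True, "SET1", "HIGH"),        # abutting boundaries
    (39, 0.45, True, True, True, "SET1", "LOW"),
    (60, 0.60, True, True, True, "SET1", "HIGH"),        # inclusive uppers
    (61, 0.50, False, True, True, "UNCLASSIFIED", "UNCLASSIFIED"),
    (45, 0.39, True, False, False, "SET3", "SUBCLONAL"),
    (45, 0.40, False, True, True, "SET2", "HIGH"),       # vaf 0.4 is clonal
    (20, 0.50, False, True, True, "SET2", "LOW"),
    (50, 0.19, False, True, True, "UNCLASSIFIED", "UNCLASSIFIED"),
    (50, 0.50, False, True, False, "UNCLASSIFIED", "HIGH"),  # REJECTed
]


class TestClassification:
    @pytest.mark.parametrize("depth,vaf,hc,mu,keep,cset,dv", TOY_TABLE)
    def test_hand_labelled_examples(self, depth, vaf, hc, mu, keep, cset, dv):
        call = VariantCall(
            key=VariantKey("chr1", 10, "A", "G"), sample_id="M1",
            depth=depth, alt_depth=round(depth * vaf),
            hc_called=hc, mutect_called=mu, mutect_keep=keep)
        df = pd.DataFrame([{"depth": depth, "vaf": vaf, "hc_called": hc,
                            "mutect_called": mu, "mutect_keep": keep}])
        row = classify_calls(df).iloc[0]
        assert (row["caller_set"], row["depth_vaf_class"]) == (cset, dv)

    def test_single_call_api_matches_vectorized(self):
        call = VariantCall(key=VariantKey("chr1", 10, "A", "G"),
                           sample_id="M1", depth=50, alt_depth=25,
                           hc_called=True, mutect_called=True, mutect_keep=True)
        label = classify_confidence(call)
        assert label.caller_set == CallerSet.SET1
        assert label.depth_vaf_class == DepthVafClass.HIGH

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(depth=st.integers(1, 100), vaf_pct=st.integers(0, 100),
           hc=st.booleans(), mu=st.booleans(), keep=st.booleans())
    def test_totality_and_axis_agreement(self, depth, vaf_pct, hc, mu, keep):
        vaf = vaf_pct / 100
        df = pd.DataFrame([{"depth": depth, "vaf": vaf, "hc_called": hc,
                            "mutect_called": mu, "mutect_keep": keep}])
        row = classify_calls(df).iloc[0]
        assert row["caller_set"] in {s.value for s in CallerSet}
        assert row["depth_vaf_class"] in {s.value for s in DepthVafClass}
        # dual-caller KEEP calls in the high-confidence window land in the
        # top class on both axes
        if hc and mu and keep and 40 <= depth <= 60 and 0.4 <= vaf <= 0.6:
            assert row["caller_set"] == "SET1"
            assert row["depth_vaf_class"] == "HIGH"
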