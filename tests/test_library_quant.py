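"""Tests for read parsing, variant annotation, filters and quantification."""

import numpy as np
import pandas as pd
import pytest

from ratchetscan.library_quant import (
    BARCODE_MISMATCH,
    PAIR_DISAGREEMENT,
    PATTERN_MISMATCH,
    BinSpec,
    LibraryDesign,
    annotate_variant,
    build_variant_table,
    combine_replicates,
    filter_variants,
    gfp_intensity,
    group_summary,
    mrna_level,
    parse_read_pair,
    reverse_complement,
)

DESIGN = LibraryDesign.datg()
B2S = {"AACCGT": "bin_1", "CCGATA": "bin_2"}


def make_pair(region, barcode="AACCGT", design=DESIGN):
    construct = ("T" * 12 + barcode + design.flank5 + region + design.flank3
                 + barcode + "T" * 12)
    return construct, reverse_complement(construct)


@pytest.fixture
def region():
    # 6 doped + aATG + 30 doped, single extra ATG at +9
    return "CACCCC" + "ATG" + "CCCCC" + "ATG" + "C" * 22


class TestParseReadPair:
    def test_perfect_pair_yields_variable_region(self, region):
        r1, r2 = make_pair(region)
        assert parse_read_pair(r1, r2, DESIGN, B2S) == (region, "bin_1")

    def test_reads_longer_than_insert_still_parse(self, region):
        # far read runs into the opposite adapter, shifting the construct
        r1, r2 = make_pair(region)
        pad = "ATCTCGTATGCCG"
        assert parse_read_pair(r1 + pad, pad + r2[: len(r2)], DESIGN, B2S)[0] == region

    def test_broken_flank_is_pattern_mismatch(self, region):
        r1, r2 = make_pair(region)
        broken = r1[:20] + ("A" if r1[20] != "A" else "C") + r1[21:]
        assert parse_read_pair(broken, r2, DESIGN, B2S) == PATTERN_MISMATCH

    def test_unknown_barcode_is_barcode_mismatch(self, region):
        r1, r2 = make_pair(region, barcode="GGGGGG")
        assert parse_read_pair(r1, r2, DESIGN, B2S) == BARCODE_MISMATCH

    def test_barcodes_from_two_samples_rejected(self, region):
        # read1 carries bin_1 barcodes, read2 bin_2 barcodes
        r1, _ = make_pair(region, barcode="AACCGT")
        _, r2 = make_pair(region, barcode="CCGATA")
        assert parse_read_pair(r1, r2, DESIGN, B2S) == BARCODE_MISMATCH

    def test_substitution_in_mate_region_is_pair_disagreement(self, region):
        r1, _ = make_pair(region)
        mutated = region[:10] + ("A" if region[10] != "A" else "G") + region[11:]
        _, r2 = make_pair(mutated)
        assert parse_read_pair(r1, r2, DESIGN, B2S) == PAIR_DISAGREEMENT


class TestAnnotation:
    def test_duo_nomenclature_for_datg_at_plus4(self):
        # dATG directly after the aATG: its -3 nt is the aATG's A
        region = "CCCTCC" + "ATG" + "ATG" + "C" * 27
        ann = annotate_variant(region, DESIGN)
        assert ann.variant_class == "Duo"
        assert ann.nomenclature == "Duo(1N, 4A)"
        datg = [s for s in ann.atgs if s.position == 4][0]
        assert datg.context == "A"
        assert datg.frame == 0

    def test_solo_named_by_concrete_context(self):
        region = "CCCTCC" + "ATG" + "C" * 30
        assert annotate_variant(region, DESIGN).nomenclature == "Solo(1T)"

    def test_frames_and_contexts_of_downstream_atgs(self):
        region = "CACCCC" + "ATG" + "CC" + "ATG" + "C" * 25  # dATG at +6
        ann = annotate_variant(region, DESIGN)
        datg = [s for s in ann.atgs if s.position != 1][0]
        assert datg.position == 6
        assert datg.frame == 2
        assert datg.context == "G"  # -3 of +6 is +3, the aATG's G

    def test_inframe_stop_detected(self):
        region = "CCCTCC" + "ATG" + "CCC" + "TAA" + "C" * 24
        assert annotate_variant(region, DESIGN).has_inframe_stop
        clean = "CCCTCC" + "ATG" + "C" * 30
        assert not annotate_variant(clean, DESIGN).has_inframe_stop

    def test_uatg_detected_in_upstream_doped_region(self):
        region = "ATGCCC" + "ATG" + "C" * 30
        ann = annotate_variant(region, DESIGN)
        assert ann.has_uatg
        uatg = [s for s in ann.atgs if s.position < 0][0]
        assert uatg.position == -6
        assert uatg.frame == 0  # in frame with the main ORF

    def test_uorf_stop_in_uatg_library(self):
        design = LibraryDesign.uatg()
        # uATG at -12 followed by an in-frame stop before the aATG
        region = "C" * 18 + "ATG" + "TAA" + "C" * 6 + "ATG"
        ann = annotate_variant(region, design)
        assert ann.has_uorf_stop
        no_stop = "C" * 18 + "ATG" + "CCC" + "C" * 6 + "ATG"
        assert not annotate_variant(no_stop, design).has_uorf_stop

    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError):
            annotate_variant("ATG", DESIGN)


class TestFilters:
    @staticmethod
    def table(rows):
        cols = ["bin_1", "bin_2", "dna_count", "rna_count",
                "has_inframe_stop", "has_uatg", "has_uorf_stop"]
        df = pd.DataFrame(rows, columns=cols)
        df["facs_total"] = df["bin_1"] + df["bin_2"]
        df["class"] = "Solo"
        return df

    def test_each_rule_and_audit_bookkeeping(self):
        rows = [
            [40, 40, 9, 5, False, False, False],   # kept (FACS 80>64, DNA 9>8)
            [40, 40, 9, 0, False, False, False],   # absent from RNA-seq
            [40, 40, 8, 5, False, False, False],   # DNA exactly at threshold: removed
            [32, 32, 9, 5, False, False, False],   # FACS total 64: removed
            [33, 32, 9, 5, False, False, False],   # FACS total 65: kept
            [40, 40, 9, 5, True, False, False],    # in-frame stop
            [40, 40, 9, 5, False, True, False],    # uATG
        ]
        kept, audit = filter_variants(self.table(rows), kind="dATG")
        assert list(kept.index) == [0, 4]
        removed = dict(zip(audit["rule"], audit["removed"]))
        assert removed == {
            "absent_from_a_library": 1, "low_dna_reads": 1, "low_facs_reads": 1,
            "inframe_stop": 1, "uatg": 1,
        }
        assert audit["removed"].sum() == len(rows) - len(kept)

    def test_uatg_library_uses_uorf_stop_rule(self):
        rows = [
            [40, 40, 9, 5, False, True, False],   # uATG allowed in the uATG library
            [40, 40, 9, 5, False, True, True],    # uORF stop removed
        ]
        kept, audit = filter_variants(self.table(rows), kind="uATG")
        assert list(kept.index) == [0]
        assert dict(zip(audit["rule"], audit["removed"]))["uorf_stop"] == 1


class TestGfpIntensity:
    BINS = [BinSpec(1, 1.0, 0.25), BinSpec(2, 5.0, 0.75)]

    def test_all_weight_in_one_bin_returns_its_median(self):
        assert gfp_intensity([10, 0], self.BINS) == pytest.approx(1.0)
        assert gfp_intensity([0, 3], self.BINS) == pytest.approx(5.0)

    def test_hand_computed_weighted_mean(self):
        # n=[3,1], P=[0.25,0.75], G=[1,5] -> (0.75*1 + 0.75*5)/1.5 = 3.0
        assert gfp_intensity([3, 1], self.BINS) == pytest.approx(3.0)

    def test_invariant_to_per_bin_count_rescaling(self):
        v1 = gfp_intensity([3, 1], self.BINS, bin_totals=[30, 10])
        v2 = gfp_intensity([30, 10], self.BINS, bin_totals=[300, 100])
        assert v1 == pytest.approx(v2)

    def test_bounded_by_contributing_bin_medians(self, rng):
        for _ in range(20):
            counts = rng.integers(0, 50, size=2)
            if counts.sum() == 0:
                continue
            v = gfp_intensity(counts, self.BINS)
            assert 1.0 - 1e-12 <= v <= 5.0 + 1e-12

    def test_zero_weight_rejected(self):
        with pytest.raises(ValueError):
            gfp_intensity([0, 0], self.BINS)
        with pytest.raises(ValueError):
            BinSpec(1, 0.0, 0.5)


class TestMrnaLevel:
    def test_fraction_ratio(self):
        assert mrna_level(10, 20, 1000, 1000) == pytest.approx(0.5)
        assert mrna_level(5, 5, 100, 100) == pytest.approx(1.0)

    def test_zero_dna_fraction_rejected(self):
        with pytest.raises(ValueError):
            mrna_level(10, 0, 1000, 1000)


class TestGroupSummary:
    def test_identical_values_zero_width_ci(self):
        df = pd.DataFrame({"context": ["A"] * 5, "gfp": [2.0] * 5})
        out = group_summary(df, "context")
        assert out.loc["A", "ci_low"] == out.loc["A", "ci_high"] == 2.0

    def test_singleton_group_flagged(self):
        df = pd.DataFrame({"context": ["A"], "gfp": [2.0]})
        out = group_summary(df, "context")
        assert not out.loc["A", "ci_defined"]

    def test_known_group_means_within_ci(self, rng):
        df = pd.DataFrame({
            "position": np.repeat([7, 8], 60),
            "gfp": np.concatenate([rng.normal(1.0, 0.1, 60), rng.normal(0.6, 0.1, 60)]),
        })
        out = group_summary(df, "position")
        assert out.loc[7, "ci_low"] < 1.0 < out.loc[7, "ci_high"]
        assert out.loc[8, "ci_low"] < 0.6 < out.loc[8, "ci_high"]
        boot = group_summary(df, "position", method="bootstrap")
        assert boot.loc[7, "ci_low"] < 1.0 < boot.loc[7, "ci_high"]


class TestReplicates:
    def test_shared_variants_averaged_and_correlated(self):
        idx1 = ["AAA", "CCC", "GGG"]
        idx2 = ["CCC", "GGG", "TTT"]
        r1 = pd.DataFrame({"gfp": [1.0, 2.0, 3.0]}, index=idx1)
        r2 = pd.DataFrame({"gfp": [2.4, 3.8, 9.0]}, index=idx2)
        merged, report = combine_replicates(r1, r2, columns=("gfp",))
        assert list(merged.index) == ["CCC", "GGG"]
        assert merged.loc["CCC", "gfp"] == pytest.approx((2.0 + 2.4) / 2)
        assert report["n_shared"] == 2
        assert report["gfp"] == pytest.approx(1.0)  # two points: perfect correlation


class TestVariantTable:
    def test_missing_regions_get_zero_counts(self):
        facs = pd.DataFrame({1: {"CACCCCATG" + "C" * 30: 10}}).fillna(0)
        dna = pd.Series({"CCCTCCATG" + "C" * 30: 12})
        rna = pd.Series(dtype=float)
        table = build_variant_table(facs, dna, rna, DESIGN)
        assert len(table) == 2
        assert (table["rna_count"] == 0).all()
        assert table["facs_total"].sum() == 10
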