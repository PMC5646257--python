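"""Unit and property tests for the variant acceptance rule and classifier."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from straindrift.errors import DataError
from straindrift.variants import (
    CrossSampleClass,
    FilterThresholds,
    VariantObservation,
    apply_filter,
    classify_across_samples,
    estimate_frequency,
    screen_variants,
    strand_bias,
)


def obs(depth, alt, fwd, sample="s1", pos=100, ref="G", alt_allele="C"):
    return VariantObservation(sample, pos, ref, alt_allele, depth, alt, fwd, alt - fwd)


class TestObservationInvariants:
    def test_strand_counts_must_sum_to_alt_depth(self):
        with pytest.raises(DataError, match="alt_fwd"):
            VariantObservation("s", 1, "G", "C", 50, 10, 4, 4)

    def test_alt_depth_bounded_by_depth(self):
        with pytest.raises(DataError, match="exceeds depth"):
            obs(10, 11, 5)

    def test_ref_must_differ_from_alt(self):
        with pytest.raises(DataError, match="ref == alt"):
            VariantObservation("s", 1, "G", "G", 50, 10, 5, 5)


class TestFrequencyAndBias:
    @pytest.mark.parametrize(
        "alt,depth,expected",
        [(0, 50, 0.0), (34, 50, 0.68), (50, 50, 1.0), (15, 64, 15 / 64)],
    )
    def test_frequency_is_alt_over_depth(self, alt, depth, expected):
        assert estimate_frequency(obs(depth, alt, alt // 2)) == pytest.approx(expected)

    def test_uncovered_site_is_an_error(self):
        with pytest.raises(DataError, match="uncovered"):
            estimate_frequency(obs(0, 0, 0))

    @pytest.mark.parametrize(
        "fwd,rev,expected",
        [(7, 7, 0.5), (14, 1, 14 / 15), (0, 9, 1.0), (9, 0, 1.0)],
    )
    def test_strand_bias_is_major_strand_share(self, fwd, rev, expected):
        o = obs(50, fwd + rev, fwd)
        assert strand_bias(o) == pytest.approx(expected)
        assert 0.5 <= strand_bias(o) <= 1.0

    def test_bias_undefined_without_supporting_reads(self):
        with pytest.raises(DataError, match="strand bias"):
            strand_bias(obs(50, 0, 0))


class TestAcceptanceRule:
    def test_below_ten_percent_fails(self):
        call = apply_filter(obs(50, 3, 2))
        assert not call.passed and call.fail_reason == "below_min_frequency"

    def test_subfixation_strand_biased_fails(self):
        call = apply_filter(obs(64, 15, 14))
        assert call.frequency == pytest.approx(15 / 64)
        assert call.strand_bias == pytest.approx(14 / 15)
        assert not call.passed and call.fail_reason == "strand_biased"

    def test_high_frequency_waives_strand_clause(self):
        call = apply_filter(obs(50, 45, 45))
        assert call.passed and call.fail_reason is None

    def test_exact_boundaries(self):
        # "at least 10%" is inclusive; bias "less than 70%" is strict
        assert apply_filter(obs(50, 5, 3)).passed  # freq exactly 0.10, bias 0.6
        assert apply_filter(obs(100, 10, 7)).fail_reason == "strand_biased"  # bias 0.70

    def test_exhaustive_truth_table_small_instances(self):
        """The implementation agrees with a direct evaluation of the
        written rule over every pileup with depth <= 30."""
        t = FilterThresholds()
        for depth in range(1, 31):
            for alt in range(0, depth + 1):
                for fwd in range(0, alt + 1):
                    call = apply_filter(obs(depth, alt, fwd), t)
                    freq = alt / depth
                    if alt:
                        bias = max(fwd, alt - fwd) / alt
                        expected = freq >= 0.10 and (freq >= 0.80 or bias < 0.70)
                    else:
                        expected = False
                    assert call.passed == expected, (depth, alt, fwd)

    @given(
        base_fwd=st.integers(0, 20),
        base_rev=st.integers(0, 20),
        depth=st.integers(1, 200),
        scale=st.integers(2, 5),
    )
    def test_monotone_in_alt_depth_at_fixed_strand_ratio(self, base_fwd, base_rev, depth, scale):
        alt1 = base_fwd + base_rev
        if alt1 == 0 or alt1 * scale > depth:
            return
        call1 = apply_filter(obs(depth, alt1, base_fwd))
        call2 = apply_filter(obs(depth, alt1 * scale, base_fwd * scale))
        if call1.passed:
            assert call2.passed


def _calls(passing_by_sample, strain_map, pos=500):
    calls = []
    for sample, passes in passing_by_sample.items():
        alt = 60 if passes else 0
        o = VariantObservation(sample, pos, "G", "C", 63, alt, alt // 2, alt - alt // 2)
        calls.append(apply_filter(o))
    return calls


STRAINS = {"MT-batch": "MT", "MO-batch": "MO", "MO-biofilm": "MO"}


class TestCrossSampleClassification:
    @pytest.mark.parametrize(
        "passing,expected,strain",
        [
            ({"MT-batch": True, "MO-batch": True, "MO-biofilm": True}, "shared_all", None),
            ({"MT-batch": False, "MO-batch": True, "MO-biofilm": True}, "strain_unique", "MO"),
            ({"MT-batch": False, "MO-batch": False, "MO-biofilm": True}, "emergent", None),
            ({"MT-batch": True, "MO-batch": True, "MO-biofilm": False}, "other", None),
            ({"MT-batch": False, "MO-batch": False, "MO-biofilm": False}, "other", None),
        ],
    )
    def test_label_assignment(self, passing, expected, strain):
        out = classify_across_samples(_calls(passing, STRAINS), STRAINS, ["MO-biofilm"])
        assert len(out) == 1
        assert out[0].label == expected
        assert out[0].strain == strain

    def test_unknown_sample_is_an_error(self):
        calls = _calls({"mystery": True}, {"mystery": "X"})
        with pytest.raises(DataError, match="mystery"):
            classify_across_samples(calls, STRAINS)

    def test_partition_every_key_gets_exactly_one_label(self, rng):
        calls = []
        for pos in range(1, 40):
            for sample in STRAINS:
                alt = int(rng.integers(0, 64))
                calls.append(
                    apply_filter(
                        VariantObservation(sample, pos, "A", "T", 63, alt,
                                           alt // 2, alt - alt // 2)
                    )
                )
        out = classify_across_samples(calls, STRAINS, ["MO-biofilm"])
        keys = [c.key for c in out]
        assert len(keys) == len(set(keys)) == 39
        assert all(c.label in ("shared_all", "strain_unique", "emergent", "other") for c in out)


class TestScreenVariants:
    def test_empty_pileup_gives_empty_report(self):
        df = pd.DataFrame(columns=["sample", "pos", "ref", "alt", "depth",
                                   "alt_depth", "alt_fwd", "alt_rev"])
        report = screen_variants(df, None, STRAINS)
        assert report.empty

    def test_intergenic_variant_has_empty_codon_fields(self):
        rows = [(s, 10, "G", "C", 63, 60, 30, 30) for s in STRAINS]
        df = pd.DataFrame(rows, columns=["sample", "pos", "ref", "alt", "depth",
                                         "alt_depth", "alt_fwd", "alt_rev"])
        report = screen_variants(df, None, STRAINS, cds_records=(), genome={"chr": "A" * 100})
        assert report.loc[0, "label"] == "shared_all"
        assert report.loc[0, "gene_id"] == "" and report.loc[0, "aa_change"] == ""

    def test_report_sorted_by_position(self, rng):
        rows = []
        for pos in (900, 100, 500):
            for s in STRAINS:
                rows.append((s, pos, "G", "A", 63, 63, 31, 32))
        df = pd.DataFrame(rows, columns=["sample", "pos", "ref", "alt", "depth",
                                         "alt_depth", "alt_fwd", "alt_rev"])
        report = screen_variants(df, None, STRAINS)
        assert list(report["position"]) == [100, 500, 900]
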