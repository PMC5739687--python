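"""mtDNA stage: heteroplasmy, origin calls, annotation, prioritization, copy ratio."""

import numpy as np
import pandas as pd
import pytest
from Bio.Seq import Seq
from hypothesis import given, settings, strategies as st

from oncomito import (
    MtVariant,
    MtdnaThresholds,
    annotate_mt,
    classify_origin,
    heteroplasmic_fraction,
    mtdna_copy_ratio,
    prioritize,
)
from oncomito.mtdna import _revcomp


class TestHeteroplasmicFraction:
    @pytest.mark.parametrize(
        "alt,ref,expected",
        [(10, 90, 0.10), (0, 100, 0.0), (57, 43, 0.57)],
    )
    def test_point_estimates(self, alt, ref, expected):
        hf, (lo, hi) = heteroplasmic_fraction(alt, ref)
        assert hf == pytest.approx(expected)
        assert lo <= hf <= hi

    def test_zero_alt_interval_starts_at_zero(self):
        _, (lo, _) = heteroplasmic_fraction(0, 100)
        assert lo == pytest.approx(0.0, abs=1e-12)

    def test_zero_depth_raises(self):
        with pytest.raises(ValueError):
            heteroplasmic_fraction(0, 0)

    @settings(max_examples=200, deadline=None)
    @given(st.integers(0, 5000), st.integers(0, 5000))
    def test_wilson_interval_contains_hf(self, alt, ref):
        if alt + ref == 0:
            return
        hf, (lo, hi) = heteroplasmic_fraction(alt, ref)
        assert 0.0 <= lo <= hf <= hi <= 1.0


class TestClassifyOrigin:
    @staticmethod
    def variant(tumor_hf, normal_hf, depth=1000):
        normal_ad = None
        if normal_hf is not None:
            alt = round(normal_hf * depth)
            normal_ad = (depth - alt, alt)
        alt_t = round(tumor_hf * depth)
        return MtVariant(position=100, ref="A", alt="G",
                         tumor_ad=(depth - alt_t, alt_t), normal_ad=normal_ad)

    def test_concordant_high_hf_is_germline(self):
        assert classify_origin(self.variant(0.98, 0.99)) == "germline"

    def test_low_hf_tumor_only_is_somatic(self):
        assert classify_origin(self.variant(0.05, 0.0)) == "somatic"

    def test_homoplasmic_without_normal_detection_is_somatic(self):
        assert classify_origin(self.variant(1.0, None)) == "somatic"

    def test_discordant_heteroplasmy_is_unclassified(self):
        assert classify_origin(self.variant(0.8, 0.3)) == "unclassified"

    def test_mismatched_loci_raise(self):
        tumor = self.variant(0.5, None)
        normal = MtVariant(position=101, ref="A", alt="G", normal_ad=(500, 500))
        with pytest.raises(ValueError, match="loci"):
            classify_origin(tumor, normal)


def find_substitution(genome, gene, target_class):
    """Scan a gene for a substitution with the requested functional class."""
    iv = next(i for i in genome.intervals if i.gene == gene)
    for pos in range(iv.start, iv.end + 1):
        ref = genome.sequence[pos - 1]
        for alt in "ACGT":
            if alt == ref:
                continue
            v = annotate_mt(MtVariant(position=pos, ref=ref, alt=alt), genome)
            if v.functional_class == target_class:
                return v
    raise AssertionError(f"no {target_class} substitution found in {gene}")


class TestAnnotation:
    def test_stop_gain_in_nd5_frame(self, genome):
        v = find_substitution(genome, "MT-ND5", "stop_gain")
        assert v.gene == "MT-ND5"
        assert v.functional_class == "stop_gain"

    def test_hypervariable_region_position_is_dloop(self, genome):
        v = annotate_mt(
            MtVariant(position=16100, ref=genome.sequence[16099], alt="A"
                      if genome.sequence[16099] != "A" else "C"),
            genome,
        )
        assert v.functional_class == "dloop"

    def test_synonymous_third_position_change_exists(self, genome):
        v = find_substitution(genome, "MT-CO1", "synonymous")
        assert v.functional_class == "synonymous"

    def test_gap_position_is_other_noncoding(self, genome):
        # 5656..5903 lies between mapped features in this gene layout
        pos = 5700
        ref = genome.sequence[pos - 1]
        alt = "A" if ref != "A" else "C"
        v = annotate_mt(MtVariant(position=pos, ref=ref, alt=alt), genome)
        assert v.functional_class == "other_noncoding"
        assert v.gene is None

    def test_mismatched_ref_allele_raises(self, genome):
        pos = 6000
        ref = genome.sequence[pos - 1]
        wrong = "A" if ref != "A" else "C"
        alt = next(b for b in "ACGT" if b not in (ref, wrong))
        with pytest.raises(ValueError, match="does not match"):
            annotate_mt(MtVariant(position=pos, ref=wrong, alt=alt), genome)

    @pytest.mark.parametrize("gene", ["MT-CO2", "MT-ND6"])
    def test_agrees_with_full_cds_translation_oracle(self, genome, gene):
        """Independent oracle: translate the whole mutated CDS with the
        vertebrate mitochondrial table and diff the protein sequences.

        Covers every possible substitution in one plus-strand and the
        minus-strand protein gene.
        """
        iv = next(i for i in genome.intervals if i.gene == gene)
        region = genome.sequence[iv.start - 1 : iv.end]
        for pos in range(iv.start, iv.end + 1):
            ref = genome.sequence[pos - 1]
            for alt in "ACGT":
                if alt == ref:
                    continue
                got = annotate_mt(
                    MtVariant(position=pos, ref=ref, alt=alt), genome
                ).functional_class
                offset = pos - iv.start
                mutated = region[:offset] + alt + region[offset + 1 :]
                cds_ref, cds_alt = region, mutated
                if iv.strand == "-":
                    cds_ref, cds_alt = _revcomp(region), _revcomp(mutated)
                prot_ref = str(Seq(cds_ref).translate(table=2))
                prot_alt = str(Seq(cds_alt).translate(table=2))
                diffs = [
                    (a, b) for a, b in zip(prot_ref, prot_alt) if a != b
                ]
                if not diffs:
                    expected = "synonymous"
                elif any(b == "*" for _, b in diffs):
                    expected = "stop_gain"
                else:
                    expected = "nonsynonymous"
                assert got == expected, (pos, ref, alt, diffs)


class TestPrioritize:
    thresholds = MtdnaThresholds()

    @staticmethod
    def variant(cls, variability, score, haplogroup=False, rna_score=None):
        return MtVariant(
            position=500, ref="A", alt="G", functional_class=cls,
            nucleotide_variability=variability, disease_score=score,
            rna_prediction_score=rna_score, haplogroup_defining=haplogroup,
        )

    def test_trna_variant_above_rna_threshold_prioritized(self):
        v = self.variant("tRNA", 0.001, None, rna_score=0.65)
        result = prioritize(v, self.thresholds)
        assert result.prioritized
        assert any("0.65" in r for r in result.reasons)

    def test_conserved_nonsynonymous_variant_prioritized(self):
        v = self.variant("nonsynonymous", 0.00031, 0.5)
        assert prioritize(v, self.thresholds).prioritized

    def test_haplogroup_defining_excluded_despite_perfect_scores(self):
        v = self.variant("nonsynonymous", 0.0001, 0.99, haplogroup=True)
        result = prioritize(v, self.thresholds)
        assert not result.prioritized
        assert "haplogroup" in result.reasons[0]

    def test_unscored_class_never_prioritized(self):
        v = self.variant("synonymous", 0.0001, 0.99)
        assert not prioritize(v, self.thresholds).prioritized

    def test_missing_score_raises_with_field_name(self):
        v = self.variant("nonsynonymous", 0.001, None)
        with pytest.raises(ValueError, match="disease_score"):
            prioritize(v, self.thresholds)

    @settings(max_examples=200, deadline=None)
    @given(
        st.sampled_from(["nonsynonymous", "tRNA", "rRNA"]),
        st.floats(0.00001, 0.01),
        st.floats(0, 1),
        st.floats(0.00001, 0.01),
        st.floats(0, 1),
    )
    def test_monotone_in_variability_and_score(self, cls, var1, s1, var2, s2):
        """Lowering variability or raising the score never de-prioritizes."""
        lo_var, hi_var = sorted([var1, var2])
        lo_s, hi_s = sorted([s1, s2])
        weaker = prioritize(self.variant(cls, hi_var, lo_s), self.thresholds)
        stronger = prioritize(self.variant(cls, lo_var, hi_s), self.thresholds)
        assert not (weaker.prioritized and not stronger.prioritized)


class TestCopyRatio:
    @staticmethod
    def coverage(rows):
        return pd.DataFrame(rows, columns=["sample", "mt_coverage", "nuclear_coverage"])

    def test_hand_arithmetic(self):
        cov = self.coverage([("P1_T", 400, 100), ("P1_N", 200, 100)])
        table, mean, _ = mtdna_copy_ratio(
            cov, {"P1_T": "tumor", "P1_N": "normal"}, {"P1_T": "P1", "P1_N": "P1"}
        )
        assert table.copy_ratio.iloc[0] == pytest.approx(2.0)

    def test_identical_coverages_give_unit_ratio(self):
        cov = self.coverage([("P1_T", 300, 80), ("P1_N", 300, 80),
                             ("P2_T", 150, 40), ("P2_N", 150, 40)])
        groups = {s: ("tumor" if s.endswith("T") else "normal") for s in cov["sample"]}
        pairs = {s: s[:2] for s in cov["sample"]}
        table, mean, sd = mtdna_copy_ratio(cov, groups, pairs)
        np.testing.assert_allclose(table.copy_ratio, 1.0)
        assert mean == pytest.approx(1.0)

    def test_zero_nuclear_coverage_raises(self):
        cov = self.coverage([("P1_T", 400, 0), ("P1_N", 200, 100)])
        with pytest.raises(ValueError, match="P1_T"):
            mtdna_copy_ratio(
                cov, {"P1_T": "tumor", "P1_N": "normal"}, {"P1_T": "P1", "P1_N": "P1"}
            )
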