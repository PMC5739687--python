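"""Generator determinism, null behavior, truth consistency and calibration."""

import numpy as np
import pandas as pd
import pytest

from oncomito import (
    CohortConfig,
    classify_cohort,
    cnv_dose_test,
    gen_cnv,
    gen_metabolome,
    gen_mt_variants,
    gen_nuclear_variants,
    gen_proteome,
    log2_fold_changes,
    mito_mass_ratio,
    mtdna_copy_ratio,
    oncocytoma_v1,
    spectrum_6class,
    titv,
)
from oncomito.cohort import (
    CnvSim,
    MtdnaSim,
    NuclearSim,
    ProteomeSim,
    write_cohort,
)


def coverage_maps(coverage):
    groups = {s: ("tumor" if s.endswith("_T") else "normal")
              for s in coverage["sample"]}
    pairs = {s: s[:-2] for s in coverage["sample"]}
    return groups, pairs


class TestDeterminism:
    def test_proteome_seed_reproducibility(self, config):
        a, _, _ = gen_proteome(config, 11)
        b, _, _ = gen_proteome(config, 11)
        pd.testing.assert_frame_equal(a.values, b.values)
        c, _, _ = gen_proteome(config, 12)
        assert not a.values.equals(c.values)

    def test_metabolome_seed_reproducibility(self, config):
        a, _ = gen_metabolome(config, 11)
        b, _ = gen_metabolome(config, 11)
        pd.testing.assert_frame_equal(a.raw.values, b.raw.values)
        assert a.tissue_mass == b.tissue_mass

    def test_mt_variants_seed_reproducibility(self, config):
        va, cov_a, _ = gen_mt_variants(config, 11)
        vb, cov_b, _ = gen_mt_variants(config, 11)
        assert [(v.position, v.ref, v.alt, v.tumor_ad) for v in va] == [
            (v.position, v.ref, v.alt, v.tumor_ad) for v in vb
        ]
        pd.testing.assert_frame_equal(cov_a, cov_b)

    def test_nuclear_seed_reproducibility(self, config):
        a, _ = gen_nuclear_variants(config, 11)
        b, _ = gen_nuclear_variants(config, 11)
        assert a == b


class TestProteomeGenerator:
    def test_null_preset_gives_unit_ratios(self):
        config = CohortConfig(proteome=ProteomeSim(
            mito_mass_factor=1.0, mito_mass_sd=0.0,
            nonmito_mass_factor=1.0, nonmito_mass_sd=0.0,
            ci_depletion_factor=1.0, mnar_threshold_quantile=0.0,
            mnar_steepness=50.0,
        ))
        m, ann, _ = gen_proteome(config, 5)
        assert not m.missing_mask().any().any()
        _, summary = mito_mass_ratio(m, ann)
        assert summary["mito"][0] == pytest.approx(1.0, abs=0.05)
        assert summary["non_mito"][0] == pytest.approx(1.0, abs=0.05)

    def test_truth_covers_every_protein_exactly_once(self, config):
        m, ann, truth = gen_proteome(config, 6)
        assert list(truth.protein_log2_effect.index) == m.features
        assert set(truth.mito_proteins) == set(ann.index[ann.is_mito])
        assert set(truth.ci_subunits) <= set(truth.mito_proteins)

    def test_tiny_mito_compartment_rejected(self):
        with pytest.raises(ValueError, match="frac_mito"):
            gen_proteome(
                CohortConfig(proteome=ProteomeSim(n_proteins=100, frac_mito=0.05)),
                1,
            )

    def test_missingness_is_left_censored(self, config):
        m, _, _ = gen_proteome(config, 8)
        observed_mean = m.values.stack().mean()
        # rows with missing cells sit lower than fully observed rows
        has_missing = m.missing_mask().any(axis=1)
        assert (
            m.values[has_missing].stack().mean() < observed_mean
        )


class TestMtGenerator:
    def test_origin_recovery_is_exact_at_these_depths(self, config):
        variants, _, truth = gen_mt_variants(config, 4)
        classify_cohort(variants)
        recovered = {i: v.origin for i, v in enumerate(variants)}
        assert recovered == truth.origin

    def test_haplogroup_fraction_matches_preset(self, config):
        variants, _, truth = gen_mt_variants(config, 4)
        flagged = sum(v.haplogroup_defining for v in variants)
        assert flagged == truth.n_haplogroup == round(0.593 * 54)

    def test_no_haplogroup_flags_when_fraction_zero(self):
        config = CohortConfig(mtdna=MtdnaSim(frac_haplogroup=0.0))
        variants, _, _ = gen_mt_variants(config, 4)
        assert not any(v.haplogroup_defining for v in variants)

    def test_unit_copy_ratio_preset(self):
        config = CohortConfig(mtdna=MtdnaSim(copy_ratio_mean=1.0, copy_ratio_sd=0.0))
        _, coverage, _ = gen_mt_variants(config, 4)
        groups, pairs = coverage_maps(coverage)
        _, mean, _ = mtdna_copy_ratio(coverage, groups, pairs)
        assert mean == pytest.approx(1.0, abs=0.05)

    def test_somatic_hf_within_preset_range(self, config):
        variants, _, truth = gen_mt_variants(config, 9)
        lo, hi = config.mtdna.somatic_hf_range
        homoplasmic = 0
        for i, v in enumerate(variants):
            if truth.origin[i] != "somatic":
                continue
            if truth.true_hf[i] > 0.9:
                homoplasmic += 1
            else:
                assert lo <= truth.true_hf[i] <= hi
        assert homoplasmic == config.mtdna.n_homoplasmic_somatic

    def test_invalid_hf_range_rejected(self):
        with pytest.raises(ValueError, match="somatic_hf_range"):
            CohortConfig(mtdna=MtdnaSim(somatic_hf_range=(0.01, 1.5)))


class TestNuclearGenerator:
    def test_uniform_spectrum_titv_converges_to_half(self):
        config = CohortConfig(nuclear=NuclearSim(
            spectrum_counts={c: 1 for c in ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")},
            burden_median=400, burden_log_sd=0.1,
        ))
        ratios = [titv(spectrum_6class(gen_nuclear_variants(config, s)[0]))
                  for s in range(1, 6)]
        assert np.mean(ratios) == pytest.approx(0.5, abs=0.06)

    def test_reference_spectrum_titv_converges_to_printed_ratio(self, config):
        counts = {c: 0 for c in ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")}
        for s in range(1, 6):
            variants, _ = gen_nuclear_variants(config, s)
            sp = spectrum_6class(variants)
            for c in counts:
                counts[c] += sp.counts[c]
        from oncomito import SpectrumCounts

        pooled = SpectrumCounts(counts)
        # expectation 2924/1359 ~ 2.15; allow multinomial sampling error
        assert titv(pooled) == pytest.approx(2924 / 1359, rel=0.10)

    def test_burden_truth_matches_emitted_nonsilent_counts(self, config):
        from oncomito import burden_stats

        variants, truth = gen_nuclear_variants(config, 2)
        burden, _, _ = burden_stats(variants)
        assert burden.to_dict() == truth.burden


class TestCnvGenerator:
    def test_no_segments_leaves_proteome_untouched(self, config):
        m, ann, _ = gen_proteome(config, 3)
        segments, modified, truth = gen_cnv(
            CohortConfig(cnv=CnvSim(n_segments=0)), 3, m, ann
        )
        assert segments == []
        assert truth.loss_genes == ()
        pd.testing.assert_frame_equal(modified.values, m.values)

    def test_null_dose_effect_gives_calibrated_p(self, config):
        pvals = []
        for seed in range(1, 21):
            # distinct sub-seeds: sharing one stream across generation,
            # segment placement and permutation draws couples them
            m, ann, _ = gen_proteome(config, seed)
            cfg = CohortConfig(cnv=CnvSim(dose_effect_log2=0.0))
            _, modified, truth = gen_cnv(cfg, 1000 + seed, m, ann)
            log2fc = log2_fold_changes(modified)
            result = cnv_dose_test(log2fc, list(truth.loss_genes),
                                   n_perm=300, seed=2000 + seed)
            pvals.append(result.p_value)
        assert 0.2 <= np.mean(pvals) <= 0.8
        assert min(pvals) > 0.001

    def test_strong_dose_effect_is_powerful(self, config):
        hits = 0
        for seed in range(1, 11):
            m, ann, _ = gen_proteome(config, seed)
            cfg = CohortConfig(cnv=CnvSim(dose_effect_log2=-1.0,
                                          genes_per_segment=50, n_segments=2))
            _, modified, truth = gen_cnv(cfg, 1000 + seed, m, ann)
            log2fc = log2_fold_changes(modified)
            result = cnv_dose_test(log2fc, list(truth.loss_genes),
                                   n_perm=500, seed=2000 + seed)
            hits += int(result.p_value <= 0.01)
        assert hits >= 9


class TestWriteCohort:
    def test_materialized_directory_round_trips(self, tmp_path, config):
        from oncomito import read_annotation, read_matrix, read_mt_tsv, read_mt_vcf

        truth = write_cohort(config, 21, tmp_path)
        assert (tmp_path / "truth.json").exists()
        ann = read_annotation(tmp_path / "protein_annotation.tsv")
        groups = {f"P{i}_{s}": ("tumor" if s == "T" else "normal")
                  for i in range(1, 7) for s in "TN"}
        pairs = {f"P{i}_{s}": f"P{i}" for i in range(1, 7) for s in "TN"}
        proteome = read_matrix(tmp_path / "proteome.tsv", groups, pairs)
        assert proteome.values.shape == (2000, 12)
        assert ann.is_mito.sum() == 500
        variants = read_mt_tsv(tmp_path / "mtdna_variants.tsv")
        assert len(variants) == 54 + 195
        p1 = [v for v in variants if v.patient == "P1"]
        vcf = read_mt_vcf(tmp_path / "mtdna_P1.vcf", patient="P1")
        assert {v.position for v in vcf} == {v.position for v in p1}
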