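"""Proteome stage: validity filters, mass ratios, compartment thresholds, OXPHOS."""

import numpy as np
import pandas as pd
import pytest

from oncomito import (
    compartment_stats,
    filter_min_valid,
    gen_proteome,
    log2_fold_changes,
    mito_mass_ratio,
    oncocytoma_v1,
    oxphos_complex_summary,
)

from conftest import make_matrix


def matrix_with_validity(n_tumor_valid: int, n_normal_valid: int):
    """One feature with the given number of observed cells per group of 6."""
    cols = {}
    for i in range(1, 7):
        cols[f"P{i}_T"] = [10.0 if i <= n_tumor_valid else np.nan]
        cols[f"P{i}_N"] = [11.0 if i <= n_normal_valid else np.nan]
    return make_matrix(cols, ["F1"])


class TestFilterMinValid:
    @pytest.mark.parametrize(
        "valid_t,valid_n,kept_each3,kept_full6",
        [
            (6, 6, True, True),   # fully observed survives both filters
            (2, 6, False, True),  # one complete group rescues it in mode B
            (2, 5, False, False), # neither rule satisfied
            (3, 3, True, False),
        ],
    )
    def test_rule_application(self, valid_t, valid_n, kept_each3, kept_full6):
        m = matrix_with_validity(valid_t, valid_n)
        assert (len(filter_min_valid(m, "each_group_min3").features) == 1) is kept_each3
        assert (len(filter_min_valid(m, "one_group_full6").features) == 1) is kept_full6

    def test_unknown_mode_raises(self, paired_matrix_3x4):
        with pytest.raises(ValueError, match="mode"):
            filter_min_valid(paired_matrix_3x4, "bogus")

    def test_stringent_filter_is_subset_of_union(self, config):
        m, _, _ = gen_proteome(config, 5)
        a = set(filter_min_valid(m, "each_group_min3").features)
        b = set(filter_min_valid(m, "one_group_full6").features)
        assert a <= (a | b)
        assert a  # non-degenerate at default missingness


class TestMitoMassRatio:
    @staticmethod
    def annotation_for(features, mito):
        return pd.DataFrame(
            {"is_mito": [f in mito for f in features], "complex": "",
             "is_assembly": False},
            index=pd.Index(features, name="feature_id"),
        )

    def test_identical_tissues_give_unit_ratios(self):
        cols = {"P1_T": [5.0, 6.0, 7.0], "P1_N": [5.0, 6.0, 7.0],
                "P2_T": [5.5, 6.5, 7.5], "P2_N": [5.5, 6.5, 7.5]}
        m = make_matrix(cols, ["A", "B", "C"])
        table, summary = mito_mass_ratio(m, self.annotation_for(["A", "B", "C"], {"A"}))
        np.testing.assert_allclose(table.mito_ratio, 1.0)
        np.testing.assert_allclose(table.non_mito_ratio, 1.0)

    def test_three_protein_hand_arithmetic(self):
        # raw intensities: mito sums 300 vs 100, non-mito 90 vs 100
        cols = {
            "P1_T": np.log2([200.0, 100.0, 90.0]),
            "P1_N": np.log2([60.0, 40.0, 100.0]),
        }
        m = make_matrix(cols, ["M1", "M2", "NM"])
        table, _ = mito_mass_ratio(m, self.annotation_for(["M1", "M2", "NM"], {"M1", "M2"}))
        assert table.mito_ratio.iloc[0] == pytest.approx(3.0)
        assert table.non_mito_ratio.iloc[0] == pytest.approx(0.9)

    def test_scale_invariance_per_pair(self, config):
        m, ann, _ = gen_proteome(config, 9)
        table, _ = mito_mass_ratio(m, ann)
        scaled = m.values.copy()
        scaled[["P1_T", "P1_N"]] = scaled[["P1_T", "P1_N"]] + np.log2(7.0)
        table2, _ = mito_mass_ratio(m.with_values(scaled), ann)
        pd.testing.assert_frame_equal(table, table2)

    def test_zero_compartment_in_normal_raises(self):
        cols = {"P1_T": [5.0, 6.0], "P1_N": [np.nan, 6.0]}
        m = make_matrix(cols, ["M1", "NM"])
        with pytest.raises(ValueError, match="P1_N"):
            mito_mass_ratio(m, self.annotation_for(["M1", "NM"], {"M1"}))


def two_point_sample(mean, sd, n=10):
    """n values with exact sample mean and (ddof=1) SD via a +-d pattern."""
    d = sd * np.sqrt((n - 1) / n)
    return np.array([mean - d, mean + d] * (n // 2))


class TestCompartmentStats:
    def annotation(self, mito_ids, nonmito_ids):
        idx = list(mito_ids) + list(nonmito_ids)
        return pd.DataFrame(
            {"is_mito": [True] * len(mito_ids) + [False] * len(nonmito_ids)},
            index=pd.Index(idx, name="feature_id"),
        )

    def test_cutoffs_are_mean_plus_minus_sd(self):
        # the compartment rule reproduces the published-style cutoffs when the
        # compartment distributions have the corresponding mean and SD
        mito = two_point_sample(0.70715, 1.33385)
        nonmito = two_point_sample(-0.0321, 0.9547)
        ids_m = [f"M{i}" for i in range(10)]
        ids_n = [f"N{i}" for i in range(10)]
        log2fc = pd.Series(np.r_[mito, nonmito], index=ids_m + ids_n)
        thresholds, calls = compartment_stats(log2fc, self.annotation(ids_m, ids_n))
        assert thresholds["mito"].up_cutoff == pytest.approx(2.041, abs=5e-4)
        assert thresholds["mito"].down_cutoff == pytest.approx(-0.6267, abs=5e-4)
        assert thresholds["non_mito"].up_cutoff == pytest.approx(0.9226, abs=5e-4)
        assert thresholds["non_mito"].down_cutoff == pytest.approx(-0.9868, abs=5e-4)
        assert set(calls.unique()) <= {"up", "down", "none"}

    def test_degenerate_equal_values_make_no_calls(self):
        ids_m = [f"M{i}" for i in range(10)]
        ids_n = [f"N{i}" for i in range(10)]
        log2fc = pd.Series([0.5] * 20, index=ids_m + ids_n)
        thresholds, calls = compartment_stats(log2fc, self.annotation(ids_m, ids_n))
        assert thresholds["mito"].sd_log2fc == 0
        assert (calls == "none").all()

    def test_small_compartment_raises(self):
        ids_m = ["M1"]
        ids_n = [f"N{i}" for i in range(10)]
        log2fc = pd.Series(np.arange(11, dtype=float), index=ids_m + ids_n)
        with pytest.raises(ValueError, match="mito"):
            compartment_stats(log2fc, self.annotation(ids_m, ids_n))

    def test_one_sd_rule_calls_about_a_third_on_normal_data(self):
        # under normality, P(|z| > 1) ~ 31.7%
        rng = np.random.default_rng(12)
        ids_m = [f"M{i}" for i in range(2000)]
        ids_n = [f"N{i}" for i in range(2000)]
        log2fc = pd.Series(rng.normal(1.0, 0.8, 4000), index=ids_m + ids_n)
        _, calls = compartment_stats(log2fc, self.annotation(ids_m, ids_n))
        frac = (calls != "none").mean()
        assert frac == pytest.approx(0.317, abs=0.10)


class TestOxphosSummary:
    def test_preset_cohort_shows_ci_down_rest_up(self, config):
        m, ann, _ = gen_proteome(config, 2)
        log2fc = log2_fold_changes(m)
        summaries, verdict = oxphos_complex_summary(log2fc, ann)
        assert verdict == "CI_down_rest_up"
        by_cx = {s.complex: s for s in summaries}
        assert by_cx["CI"].subunit_median < 0
        # assembly factors are boosted with the mitochondrial mass, CI included
        assert by_cx["CI"].assembly_median > 0

    def test_flat_cohort_gives_no_verdict(self):
        rng = np.random.default_rng(3)
        ids = [f"G{i}" for i in range(100)]
        ann = pd.DataFrame(
            {"is_mito": True,
             "complex": ["CI"] * 20 + ["CII"] * 20 + ["CIII"] * 20
                        + ["CIV"] * 20 + ["CV"] * 20,
             "is_assembly": False},
            index=pd.Index(ids, name="feature_id"),
        )
        log2fc = pd.Series(rng.normal(0, 0.01, 100), index=ids)
        summaries, verdict = oxphos_complex_summary(log2fc, ann)
        assert verdict is None
        assert all(abs(s.subunit_median) < 0.05 for s in summaries)

    def test_unquantified_complex_reported_absent(self):
        ids = ["A", "B"]
        ann = pd.DataFrame(
            {"is_mito": True, "complex": ["CI", "CIII"], "is_assembly": False},
            index=pd.Index(ids, name="feature_id"),
        )
        log2fc = pd.Series([-1.0, 0.5], index=ids)
        summaries, _ = oxphos_complex_summary(log2fc, ann)
        assert {s.complex for s in summaries} == {"CI", "CIII"}
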