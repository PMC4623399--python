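"""GC-MS normalization, energy ratios, group tests and ddCt math."""

import numpy as np
import pandas as pd
import pytest

from energyomics.assays import (
    ddct_relative_expression,
    derive_energy_ratios,
    normalize_gcms,
    relative_to_reference_group,
    significance_stars,
    two_sample_t,
)

from _oracles import student_t_cdf_df4


def gcms_frame(rows):
    return pd.DataFrame(
        rows,
        columns=[
            "metabolite",
            "genotype",
            "timepoint",
            "replicate",
            "peak_height",
            "ribitol_height",
            "fresh_weight",
        ],
    )


class TestGcmsNormalization:
    def test_arithmetic_example(self):
        df = gcms_frame([("m", "WT", "0h", 1, 1000.0, 500.0, 0.05)])
        assert normalize_gcms(df)["normalized"].iloc[0] == pytest.approx(40.0)

    def test_zero_peak_gives_zero(self):
        df = gcms_frame([("m", "WT", "0h", 1, 0.0, 500.0, 0.05)])
        assert normalize_gcms(df)["normalized"].iloc[0] == 0.0

    def test_doubling_fresh_weight_halves_value(self):
        df = gcms_frame(
            [
                ("m", "WT", "0h", 1, 1000.0, 500.0, 0.05),
                ("m", "WT", "0h", 2, 1000.0, 500.0, 0.10),
            ]
        )
        v = normalize_gcms(df)["normalized"]
        assert v.iloc[0] == pytest.approx(2 * v.iloc[1])

    def test_nonpositive_fields_rejected_with_ids(self):
        df = gcms_frame([("m", "WT", "0h", 1, 1.0, 0.0, 0.05)])
        with pytest.raises(ValueError):
            normalize_gcms(df)


class TestReferenceScaling:
    def make_table(self, wt0=(2.0, 4.0), oe0=(6.0, 6.0)):
        rows = []
        for i, v in enumerate(wt0):
            rows.append(("m", "WT", "0h", i, v))
        for i, v in enumerate(oe0):
            rows.append(("m", "OE", "0h", i, v))
        return pd.DataFrame(
            rows,
            columns=["metabolite", "genotype", "timepoint", "replicate", "normalized"],
        )

    def test_reference_group_mean_maps_to_one(self):
        out = relative_to_reference_group(self.make_table())
        ref = out[(out["genotype"] == "WT") & (out["timepoint"] == "0h")]
        assert ref["relative"].mean() == pytest.approx(1.0)

    def test_all_equal_data_all_one(self):
        out = relative_to_reference_group(self.make_table(wt0=(3, 3), oe0=(3, 3)))
        assert np.allclose(out["relative"], 1.0)

    def test_doubled_group_mean_maps_to_two(self):
        out = relative_to_reference_group(self.make_table())
        oe = out[out["genotype"] == "OE"]
        assert oe["relative"].mean() == pytest.approx(2.0)

    def test_scale_equivariance(self):
        t1 = self.make_table()
        t2 = t1.assign(normalized=t1["normalized"] * 7.3)
        r1 = relative_to_reference_group(t1)["relative"]
        r2 = relative_to_reference_group(t2)["relative"]
        assert np.allclose(r1, r2)

    def test_zero_reference_mean_flagged(self):
        out = relative_to_reference_group(self.make_table(wt0=(0.0, 0.0)))
        assert (out["reference_flag"] == "zero_reference_mean").all()
        assert out["relative"].isna().all()


class TestEnergyRatios:
    def panel(self, values):
        rows = []
        for (analyte, gt, tp, rep), v in values.items():
            rows.append((analyte, gt, tp, rep, v))
        return pd.DataFrame(
            rows,
            columns=["analyte", "genotype", "timepoint", "replicate", "value_nmol_per_gfw"],
        )

    def test_ratio_and_sum_arithmetic(self):
        panel = self.panel(
            {
                ("ATP", "WT", "0h", 1): 40.0,
                ("ADP", "WT", "0h", 1): 40.0,
                ("NADPH", "WT", "0h", 1): 10.0,
                ("NADP+", "WT", "0h", 1): 5.0,
            }
        )
        per_rep = derive_energy_ratios(panel).set_index("quantity")["value"]
        assert per_rep["ATP/NADPH"] == pytest.approx(4.0)
        assert per_rep["ATP/ADP"] == pytest.approx(1.0)
        assert per_rep["ATP+ADP"] == pytest.approx(80.0)
        assert per_rep["NADPH/NADP+"] == pytest.approx(2.0)
        assert per_rep["NADP++NADPH"] == pytest.approx(15.0)

    def test_sums_match_componentwise_addition_random(self):
        rng = np.random.default_rng(6)
        values = {}
        for rep in (1, 2, 3):
            for analyte in ("ATP", "ADP", "NADP+", "NADPH"):
                values[(analyte, "WT", "0h", rep)] = rng.uniform(5, 50)
        per_rep = derive_energy_ratios(self.panel(values))
        for rep in (1, 2, 3):
            sub = per_rep[per_rep["replicate"] == rep].set_index("quantity")
            assert sub.loc["ATP+ADP", "value"] == pytest.approx(
                values[("ATP", "WT", "0h", rep)] + values[("ADP", "WT", "0h", rep)]
            )

    def test_zero_denominator_left_missing(self):
        panel = self.panel(
            {
                ("ATP", "WT", "0h", 1): 40.0,
                ("ADP", "WT", "0h", 1): 0.0,
                ("NADPH", "WT", "0h", 1): 10.0,
                ("NADP+", "WT", "0h", 1): 5.0,
            }
        )
        per_rep = derive_energy_ratios(panel).set_index("quantity")["value"]
        assert np.isnan(per_rep["ATP/ADP"])


class TestTwoSampleT:
    def test_identical_groups(self):
        t, p, stars = two_sample_t([5.0, 5.0, 5.0], [5.0, 5.0, 5.0])
        assert (t, p, stars) == (0.0, 1.0, "")

    def test_hand_arithmetic_equal_variances(self):
        t, p, stars = two_sample_t([10, 11, 9], [20, 21, 19], equal_var=True)
        assert t == pytest.approx(-12.247, abs=5e-4)
        assert p == pytest.approx(2 * student_t_cdf_df4(t), abs=1e-9)
        assert p == pytest.approx(2.5e-4, abs=5e-5)
        assert stars == "**"

    def test_swap_flips_sign_same_p(self):
        t1, p1, _ = two_sample_t([10, 11, 9], [20, 21, 19])
        t2, p2, _ = two_sample_t([20, 21, 19], [10, 11, 9])
        assert t1 == pytest.approx(-t2)
        assert p1 == pytest.approx(p2)

    def test_welch_matches_hand_formula(self):
        a = np.array([4.0, 6.0, 5.5, 7.0])
        b = np.array([9.0, 12.0, 10.5])
        t, _, _ = two_sample_t(a, b, equal_var=False)
        se = np.sqrt(a.var(ddof=1) / a.size + b.var(ddof=1) / b.size)
        assert t == pytest.approx((a.mean() - b.mean()) / se, rel=1e-9)

    def test_stars_thresholds(self):
        assert significance_stars(0.049) == "*"
        assert significance_stars(0.009) == "**"
        assert significance_stars(0.05) == ""


class TestDdct:
    def qpcr_frame(self, trt_dct, ctl_dct, ct_ref=18.0):
        rows = []
        for i, d in enumerate(trt_dct):
            rows.append(("T1", "treatment", i + 1, ct_ref + d, ct_ref))
        for i, d in enumerate(ctl_dct):
            rows.append(("T1", "control", i + 1, ct_ref + d, ct_ref))
        return pd.DataFrame(
            rows,
            columns=["target", "group", "replicate", "ct_target", "ct_reference"],
        )

    def test_equal_ct_fold_one(self):
        res = ddct_relative_expression(self.qpcr_frame([6, 6, 6], [6, 6, 6]))
        assert res.loc[0, "fold_change"] == pytest.approx(1.0)
        assert res.loc[0, "p_paired"] == pytest.approx(1.0)

    def test_worked_example_fold_four(self):
        res = ddct_relative_expression(self.qpcr_frame([5, 5, 5], [7, 7, 7]))
        assert res.loc[0, "ddct"] == pytest.approx(-2.0)
        assert res.loc[0, "fold_change"] == pytest.approx(4.0)
        # normalized to the maximum: treatment is the max group
        assert res.loc[0, "relative_treatment"] == pytest.approx(1.0)
        assert res.loc[0, "relative_control"] == pytest.approx(0.25)

    def test_paired_test_matches_reference(self):
        from scipy import stats

        trt, ctl = [5.1, 4.8, 5.3], [6.9, 7.2, 7.1]
        res = ddct_relative_expression(self.qpcr_frame(trt, ctl))
        expected = stats.ttest_rel(trt, ctl).pvalue
        assert res.loc[0, "p_paired"] == pytest.approx(expected, rel=1e-9)

    def test_unpaired_replicates_rejected(self):
        frame = self.qpcr_frame([5, 5], [7, 7, 7])
        with pytest.raises(ValueError):
            ddct_relative_expression(frame)
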