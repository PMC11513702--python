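"""Statistical layer: clustered comparisons, Scheffe, ICC, sample size."""

import numpy as np
import pandas as pd
import pytest

from gingimetry.stats import (
    SampleSizeSpec,
    StatsError,
    build_study_table,
    group_compare,
    icc,
    noninferiority_sample_size,
    simulate_study_table,
    summarize_outcomes,
    validate_study_table,
)


class TestSampleSize:
    def test_study_planning_inputs_give_66_teeth(self):
        res = noninferiority_sample_size(SampleSizeSpec())
        assert res.n_teeth == 66

    def test_doubling_margin_shrinks_to_17(self):
        res = noninferiority_sample_size(SampleSizeSpec(noninferiority_margin=20.0))
        assert res.n_teeth == 17

    def test_zero_sd_degenerates_to_minimum(self):
        assert noninferiority_sample_size(SampleSizeSpec(sd=0.0)).n_teeth == 1

    def test_vif_adjustment_reported_alongside(self):
        res = noninferiority_sample_size(SampleSizeSpec())
        assert res.n_vif_adjusted == int(np.ceil(3 * res.n_raw)) == 198

    def test_monotonicity_in_sd_power_margin(self):
        base = noninferiority_sample_size(SampleSizeSpec()).n_teeth
        assert noninferiority_sample_size(SampleSizeSpec(sd=30.0)).n_teeth >= base
        assert noninferiority_sample_size(SampleSizeSpec(power=0.95)).n_teeth >= base
        assert (
            noninferiority_sample_size(SampleSizeSpec(noninferiority_margin=12.0)).n_teeth
            <= base
        )

    def test_invalid_parameters_rejected(self):
        with pytest.raises(StatsError):
            noninferiority_sample_size(SampleSizeSpec(power=1.2))
        with pytest.raises(StatsError):
            noninferiority_sample_size(
                SampleSizeSpec(sd=0.5, noninferiority_margin=10.0)
            )
        with pytest.raises(StatsError):
            noninferiority_sample_size(SampleSizeSpec(power=0.04, alpha=0.05))


class TestGroupCompare:
    def test_identical_groups_all_adjusted_p_one(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(size=40)
        df = pd.DataFrame(
            {
                "patient_id": np.repeat([f"P{i}" for i in range(10)], 8),
                "tooth_id": [f"T{i}" for i in range(80)],
                "recession_type": ["RT1"] * 40 + ["RT2"] * 40,
                "recession_reduction": np.concatenate([vals, vals]),
            }
        )
        gc = group_compare(df, "recession_reduction", "recession_type")
        for c in gc.pairwise:
            assert c.estimate == pytest.approx(0.0, abs=1e-8)
            assert c.p_scheffe == pytest.approx(1.0, abs=1e-6)

    @pytest.mark.parametrize("patient_effect", ["random", "fixed"])
    def test_scheffe_never_below_unadjusted(self, patient_effect):
        tab = simulate_study_table(
            factor="tooth_type",
            levels=("incisor", "canine", "premolar", "molar"),
            effects={"canine": 0.4},
            seed=8,
        )
        gc = group_compare(tab, "recession_reduction", "tooth_type", patient_effect)
        assert gc.df_num == 3
        for c in gc.pairwise:
            assert c.p_scheffe >= c.p_unadjusted - 1e-12

    def test_adjustment_invariant_to_level_ordering(self):
        tab = simulate_study_table(effects={"RT1": 0.3}, seed=5)
        gc1 = group_compare(tab, "recession_reduction", "recession_type")
        relabel = {"RT1": "RT2", "RT2": "RT1"}
        tab2 = tab.assign(recession_type=tab.recession_type.map(relabel))
        gc2 = group_compare(tab2, "recession_reduction", "recession_type")
        # reference-level recoding perturbs the REML optimum path slightly
        assert gc1.overall_p == pytest.approx(gc2.overall_p, rel=1e-3)
        assert gc1.pairwise[0].p_scheffe == pytest.approx(
            gc2.pairwise[0].p_scheffe, rel=1e-3
        )

    def test_true_effect_confidence_interval_coverage(self):
        """RT1-RT2 shift of 0.5 mm: the contrast CI covers the truth in at
        least 93% of seeded simulated studies."""
        from scipy import stats as sps

        covered = 0
        runs = 300
        for s in range(runs):
            tab = simulate_study_table(
                effects={"RT1": 0.5}, residual_sd=0.3, patient_sd=0.3, seed=10_000 + s
            )
            gc = group_compare(tab, "recession_reduction", "recession_type")
            (c,) = gc.pairwise
            tcrit = sps.t.ppf(0.975, gc.df_den)
            lo, hi = c.estimate - tcrit * c.se, c.estimate + tcrit * c.se
            covered += lo <= 0.5 <= hi
        assert covered / runs >= 0.93

    def test_single_level_or_single_patient_rejected(self):
        tab = simulate_study_table(seed=0)
        with pytest.raises(StatsError):
            group_compare(tab.assign(recession_type="RT1"), "recession_reduction", "recession_type")
        with pytest.raises(StatsError):
            group_compare(tab.assign(patient_id="P01"), "recession_reduction", "recession_type")


class TestICC:
    def test_identical_columns_give_one(self):
        rng = np.random.default_rng(0)
        M = np.tile(rng.normal(size=(12, 1)), (1, 3))
        assert icc(M).estimate == pytest.approx(1.0, abs=1e-9)

    def test_pure_noise_near_zero(self):
        rng = np.random.default_rng(1)
        M = rng.normal(size=(500, 3))
        assert abs(icc(M).estimate) < 0.1

    def test_matches_variance_component_ratio(self):
        """sigma_row^2 = 9, sigma_col^2 = 0, sigma_e^2 = 1 -> ICC ~ 0.9."""
        rng = np.random.default_rng(2)
        M = rng.normal(0, 3, (200, 1)) + rng.normal(0, 1, (200, 3))
        est = icc(M).estimate
        assert est == pytest.approx(0.9, abs=0.04)

    def test_agrees_with_independent_implementation(self):
        """Cross-check mean-squares ICC(2,1)/(3,1) against pingouin."""
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(3)
        M = rng.normal(0, 2, (40, 1)) + rng.normal(0, 0.6, (40, 4)) + rng.normal(
            0, 0.3, (1, 4)
        )
        n, k = M.shape
        df = pd.DataFrame(
            {
                "targets": np.repeat(np.arange(n), k),
                "raters": np.tile(np.arange(k), n),
                "score": M.ravel(),
            }
        )
        ref = pingouin.intraclass_corr(
            df, targets="targets", raters="raters", ratings="score"
        ).set_index("Type")
        mine2 = icc(M, form="ICC2")
        mine3 = icc(M, form="ICC3")
        assert mine2.estimate == pytest.approx(ref.loc["ICC(A,1)", "ICC"], abs=1e-9)
        assert mine3.estimate == pytest.approx(ref.loc["ICC(C,1)", "ICC"], abs=1e-9)
        lo, hi = ref.loc["ICC(A,1)", "CI95"]
        assert mine2.ci_lower == pytest.approx(lo, abs=0.01)
        assert mine2.ci_upper == pytest.approx(hi, abs=0.01)

    def test_shift_invariance(self):
        rng = np.random.default_rng(4)
        M = rng.normal(0, 2, (30, 1)) + rng.normal(0, 1, (30, 3))
        assert icc(M).estimate == pytest.approx(icc(M + 100.0).estimate, abs=1e-9)

    def test_degenerate_zero_between_variance(self):
        with pytest.warns(UserWarning):
            res = icc(np.zeros((10, 3)))
        assert res.estimate == 0.0 and res.degenerate

    def test_rows_with_missing_cells_dropped(self):
        rng = np.random.default_rng(5)
        M = rng.normal(0, 2, (20, 1)) + rng.normal(0, 0.5, (20, 3))
        M[3, 1] = np.nan
        res = icc(M)
        assert res.n_dropped == 1 and res.n_rows == 19

    def test_too_few_rows_rejected(self):
        with pytest.raises(StatsError):
            icc(np.random.default_rng(0).normal(size=(4, 3)))


class TestSummaries:
    def test_jaw_counts_reproduced(self):
        rows = [
            {"patient_id": "P1", "tooth_id": f"T{i}", "jaw": "maxilla" if i < 38 else "mandible",
             "recession_depth_pre": 1.3, "complete_coverage": i < 21}
            for i in range(82)
        ]
        summary = summarize_outcomes(pd.DataFrame(rows))
        assert summary["counts"]["jaw"] == {"maxilla": 38, "mandible": 44}
        assert summary["complete_root_coverage_pct"] == 25.61

    def test_empty_table_rejected(self):
        with pytest.raises(StatsError):
            summarize_outcomes(pd.DataFrame())

    def test_study_table_collapses_replicates(self, registered_quiet):
        from gingimetry.measurement import assess_case

        pre, post, anns, _, reg = registered_quiet
        records = assess_case(
            pre, post, anns, reg, raters=("a", "b"), n_replicates=2, landmark_sd=0.01
        )
        table = build_study_table(records, "P01")
        assert len(table) == len(anns)
        validate_study_table(table)

    def test_duplicate_rows_rejected(self):
        tab = simulate_study_table(seed=0)
        dup = pd.concat([tab, tab.iloc[[0]]])
        with pytest.raises(StatsError):
            validate_study_table(dup)
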