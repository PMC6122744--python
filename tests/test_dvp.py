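"""Differential variability: Bartlett test and the two-stage gating caller."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import twinmeth as tm
from twinmeth.dvp import summarize_dvp_directionality
from tests.conftest import make_group_sheet


class TestBartlett:
    def test_equal_variances_near_zero(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        b, p = tm.bartlett_test(x, x)
        assert b == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_sixteen_fold_variance_highly_significant(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, 79)
        y = rng.normal(0, 4, 79)
        _, p = tm.bartlett_test(x, y)
        assert p < 1e-10

    def test_matches_scipy(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            x, y = rng.normal(0, 1, 15), rng.normal(0, 1.5, 25)
            b, p = tm.bartlett_test(x, y)
            ref = stats.bartlett(x, y)
            assert b == pytest.approx(ref.statistic, rel=1e-10)
            assert p == pytest.approx(ref.pvalue, rel=1e-10)

    def test_symmetry_and_input_checks(self):
        rng = np.random.default_rng(2)
        x, y = rng.normal(0, 1, 10), rng.normal(0, 2, 12)
        assert tm.bartlett_test(x, y) == pytest.approx(tm.bartlett_test(y, x))
        with pytest.raises(ValueError):
            tm.bartlett_test([1.0], [1.0, 2.0])

    def test_zero_variance_floored(self):
        b, p = tm.bartlett_test([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        assert np.isfinite(b) and 0 <= p <= 1


def _group_beta(n_probes, n_case, n_control, seed=0):
    rng = np.random.default_rng(seed)
    sheet = make_group_sheet(n_case, n_control)
    base = rng.uniform(0.2, 0.8, n_probes)[:, None]
    beta = np.clip(base + rng.normal(0, 0.04, (n_probes, n_case + n_control)), 0, 1)
    frame = pd.DataFrame(
        beta, index=[f"cg{i:06d}" for i in range(n_probes)], columns=sheet.index
    )
    return frame, sheet


class TestIevora:
    def test_direction_labels(self):
        """Case-hypervariable probe with lower case mean: (case, hypo_in_case)."""
        rng = np.random.default_rng(3)
        beta, sheet = _group_beta(300, 40, 40, seed=3)
        case_cols = (sheet["status"] == "case").values
        # outlier subpopulation dragging cases down
        out_rows = np.flatnonzero(case_cols)[:10]
        beta.iloc[0, out_rows] = beta.iloc[0, out_rows] - 0.25
        table = tm.ievora(beta, sheet, q_thresh=0.05)
        assert beta.index[0] in table.index
        row = table.loc[beta.index[0]]
        assert row["hypervariable_group"] == "case"
        assert row["trend"] == "hypo_in_case"

    def test_q_recomputed_genome_wide(self):
        """Stored Bartlett q equals BH over the full probe set, not the
        retained subset."""
        rng = np.random.default_rng(4)
        beta, sheet = _group_beta(500, 30, 30, seed=4)
        case_cols = np.flatnonzero((sheet["status"] == "case").values)
        for i in range(5):
            beta.iloc[i, case_cols[:8]] += 0.3
        table = tm.ievora(beta, sheet, q_thresh=0.05)
        case = beta.loc[:, (sheet["status"] == "case").values].values
        ctrl = beta.loc[:, (sheet["status"] == "control").values].values
        p_all = np.array(
            [tm.bartlett_test(case[i], ctrl[i])[1] for i in range(len(beta))]
        )
        q_all = pd.Series(tm.bh_adjust(p_all), index=beta.index)
        assert np.allclose(table["q_bartlett"], q_all.loc[table.index], rtol=1e-10)

    def test_gating_matches_brute_force_oracle(self):
        """Independent sequential-threshold reimplementation agrees on which
        probes are called."""
        rng = np.random.default_rng(5)
        beta, sheet = _group_beta(400, 25, 25, seed=5)
        case_cols = np.flatnonzero((sheet["status"] == "case").values)
        for i in range(8):
            beta.iloc[i, case_cols[: 5 + i % 3]] -= 0.2 + 0.02 * i
        q_thresh, p_thresh = 0.05, 0.05
        table = tm.ievora(beta, sheet, q_thresh=q_thresh, p_thresh=p_thresh)

        case = beta.loc[:, (sheet["status"] == "case").values].values
        ctrl = beta.loc[:, (sheet["status"] == "control").values].values
        p_bt = np.array(
            [stats.bartlett(case[i], ctrl[i]).pvalue for i in range(len(beta))]
        )
        from statsmodels.stats.multitest import multipletests

        q = multipletests(p_bt, method="fdr_bh")[1]
        expected = set()
        for i in np.flatnonzero(q < q_thresh):
            p_tt = stats.ttest_ind(case[i], ctrl[i], equal_var=False).pvalue
            if p_tt < p_thresh:
                expected.add(beta.index[i])
        assert set(table.index) == expected

    def test_rank_orders_by_ttest_p(self):
        rng = np.random.default_rng(6)
        beta, sheet = _group_beta(400, 30, 30, seed=6)
        case_cols = np.flatnonzero((sheet["status"] == "case").values)
        for i in range(6):
            beta.iloc[i, case_cols[:9]] -= 0.25
        table = tm.ievora(beta, sheet, q_thresh=0.05)
        assert (table["rank"].values == np.arange(1, len(table) + 1)).all()
        assert (np.diff(table["p_ttest"].values) >= -1e-15).all()

    def test_permutation_of_probe_rows_invariant(self):
        beta, sheet = _group_beta(300, 20, 20, seed=7)
        case_cols = np.flatnonzero((sheet["status"] == "case").values)
        beta.iloc[0, case_cols[:6]] += 0.3
        table1 = tm.ievora(beta, sheet, q_thresh=0.05)
        rng = np.random.default_rng(8)
        shuffled = beta.iloc[rng.permutation(len(beta))]
        table2 = tm.ievora(shuffled, sheet, q_thresh=0.05)
        pd.testing.assert_frame_equal(table1, table2)

    def test_minimum_group_size(self):
        beta, sheet = _group_beta(50, 2, 10, seed=9)
        with pytest.raises(ValueError):
            tm.ievora(beta, sheet)

    def test_recovery_on_synthetic_truth(self, annotation_mid):
        """Injected hypervariability (v = 4) is recovered with high
        sensitivity and controlled empirical FDR."""
        config = tm.SyntheticConfig(seed=77)
        _, beta, sheet, truth = tm.generate_twin_cohort(
            config, annotation_mid, with_intensities=False
        )
        table = tm.ievora(beta, sheet)
        true_set = set(truth.index[truth["is_dvp"]])
        called = set(table.index)
        tp = len(called & true_set)
        assert tp / len(true_set) >= 0.8
        assert (len(called) - tp) / max(1, len(called)) <= 0.05

    def test_hypervariable_group_matches_truth(self, annotation_mid):
        config = tm.SyntheticConfig(seed=78)
        _, beta, sheet, truth = tm.generate_twin_cohort(
            config, annotation_mid, with_intensities=False
        )
        table = tm.ievora(beta, sheet)
        shared = table.index.intersection(truth.index[truth["is_dvp"]])
        agree = (
            table.loc[shared, "hypervariable_group"]
            == truth.loc[shared, "dvp_hypervariable_group"]
        ).mean()
        assert agree >= 0.95


class TestDirectionality:
    def test_empty_table(self):
        counts = summarize_dvp_directionality(pd.DataFrame())
        assert counts == {
            "n_total": 0,
            "n_hyper_case": 0,
            "n_hyper_control": 0,
            "n_hyper_case_hypo_trend": 0,
            "n_hyper_control_hypo_trend": 0,
        }

    def test_constructed_partition(self):
        table = pd.DataFrame(
            {
                "hypervariable_group": ["case"] * 5 + ["control"] * 3,
                "trend": ["hypo_in_case"] * 4 + ["hyper_in_case"] * 4,
            },
            index=[f"cg{i}" for i in range(8)],
        )
        counts = summarize_dvp_directionality(table)
        assert counts["n_total"] == 8
        assert counts["n_hyper_case"] == 5
        assert counts["n_hyper_control"] == 3
        assert counts["n_hyper_case"] + counts["n_hyper_control"] == counts["n_total"]
        assert counts["n_hyper_case_hypo_trend"] == 4
        assert counts["n_hyper_control_hypo_trend"] == 3

    def test_partition_on_synthetic_run(self, default_cohort):
        _, _, beta, sheet, _ = default_cohort
        table = tm.ievora(beta, sheet)
        counts = summarize_dvp_directionality(table)
        assert counts["n_hyper_case"] + counts["n_hyper_control"] == counts["n_total"]
        assert counts["n_total"] == len(table)
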