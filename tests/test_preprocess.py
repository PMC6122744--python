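"""QC filters, transforms, normalization and covariate screening."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import twinmeth as tm
from twinmeth.preprocess import FilterThresholds


def _toy_qc_inputs():
    """10 probes: one per defect class, five clean."""
    probes = [f"cg{i:06d}" for i in range(10)]
    samples = [f"s{i}" for i in range(20)]
    rng = np.random.default_rng(0)
    beta = pd.DataFrame(rng.uniform(0.2, 0.8, (10, 20)), index=probes, columns=samples)
    ann = pd.DataFrame(
        {
            "CHR": ["1"] * 10,
            "SNP_within_2bp": [False] * 10,
            "Cross_reactive": [False] * 10,
        },
        index=pd.Index(probes, name="IlmnID"),
    )
    det = pd.DataFrame(1e-4, index=probes, columns=samples)
    beads = pd.DataFrame(12, index=probes, columns=samples)
    det.iloc[0, 3] = 0.02           # detection failure
    ann.iloc[1, ann.columns.get_loc("CHR")] = "X"
    ann.iloc[2, ann.columns.get_loc("SNP_within_2bp")] = True
    ann.iloc[3, ann.columns.get_loc("Cross_reactive")] = True
    beads.iloc[4, :2] = 2           # 2/20 = 10% of samples below 3 beads
    return beta, ann, det, beads


class TestFilterProbes:
    def test_one_probe_per_defect_class(self):
        beta, ann, det, beads = _toy_qc_inputs()
        filtered, report = tm.filter_probes(beta, ann, det, beads)
        assert report.n_retained == 5
        assert report.removed_counts == {
            "detection_p": 1,
            "sex_chromosome": 1,
            "snp_within_2bp": 1,
            "cross_reactive": 1,
            "low_bead_count": 1,
        }
        assert len(filtered) == 5

    def test_all_clean_is_identity(self):
        beta, ann, det, beads = _toy_qc_inputs()
        det.iloc[0, 3] = 1e-4
        ann["CHR"] = "1"
        ann["SNP_within_2bp"] = False
        ann["Cross_reactive"] = False
        beads.iloc[4, :2] = 12
        filtered, report = tm.filter_probes(beta, ann, det, beads)
        pd.testing.assert_frame_equal(filtered, beta)
        assert report.n_retained == report.n_initial

    @pytest.mark.parametrize("n_low,removed", [(1, True), (0, False)])
    def test_bead_rule_boundary(self, n_low, removed):
        """ceil(0.05 * 20) = 1 low-count sample removes the probe; 0 keeps it."""
        beta, ann, det, beads = _toy_qc_inputs()
        beads.iloc[4, :2] = 12
        beads.iloc[5, :n_low] = 2
        _, report = tm.filter_probes(beta, ann, det, beads)
        assert (report.removed_counts["low_bead_count"] == 1) == removed

    def test_detection_fraction_rule(self):
        beta, ann, det, beads = _toy_qc_inputs()
        thresholds = FilterThresholds(detection_rule="fraction", detection_frac=0.10)
        # single failing sample (5%) survives the 10% fraction rule
        _, report = tm.filter_probes(beta, ann, det, beads, thresholds)
        assert report.removed_counts["detection_p"] == 0

    def test_idempotent(self):
        beta, ann, det, beads = _toy_qc_inputs()
        once, _ = tm.filter_probes(beta, ann, det, beads)
        twice, report = tm.filter_probes(
            once, ann, det.loc[once.index], beads.loc[once.index]
        )
        pd.testing.assert_frame_equal(once, twice)
        assert report.n_retained == len(once)

    def test_misaligned_matrices_rejected(self):
        beta, ann, det, beads = _toy_qc_inputs()
        with pytest.raises(ValueError):
            tm.filter_probes(beta, ann, det.iloc[:, :-1], beads)


class TestTransforms:
    def test_compute_beta_values(self):
        assert tm.compute_beta(np.array([900.0]), np.array([0.0]))[0] == pytest.approx(0.9)
        assert tm.compute_beta(np.array([0.0]), np.array([0.0]))[0] == 0.0
        with pytest.raises(ValueError):
            tm.compute_beta(np.array([-1.0]), np.array([0.0]))

    @pytest.mark.parametrize(
        "beta,expected",
        [(0.5, 0.0), (0.8, 2.0), (0.2, -2.0)],
    )
    def test_beta_to_m_known_values(self, beta, expected):
        assert tm.beta_to_m(np.array([beta]))[0] == pytest.approx(expected)

    def test_beta_to_m_clipping_contract(self):
        eps = 1e-6
        m = tm.beta_to_m(np.array([1.0]), epsilon=eps)[0]
        assert np.isfinite(m)
        assert m == pytest.approx(np.log2((1 - eps) / eps))

    def test_round_trip_monotone(self):
        b = np.linspace(0.01, 0.99, 101)
        m = tm.beta_to_m(b)
        assert (np.diff(m) > 0).all()
        assert np.allclose(tm.m_to_beta(m), b, atol=1e-12)


class TestNormalizeTypeBias:
    def _frame(self, values1, values2):
        n1, n2 = len(values1), len(values2)
        probes = [f"p{i}" for i in range(n1 + n2)]
        ann = pd.DataFrame(
            {"Infinium_Design_Type": ["I"] * n1 + ["II"] * n2},
            index=pd.Index(probes, name="IlmnID"),
        )
        beta = pd.DataFrame(
            {"s1": np.concatenate([values1, values2])}, index=probes
        )
        return beta, ann

    def test_identical_distributions_fixed_point(self):
        vals = np.linspace(0.05, 0.95, 40)
        beta, ann = self._frame(vals, vals)
        out = tm.normalize_type_bias(beta, ann)
        assert np.abs(out.values - beta.values).max() <= 1e-9

    def test_shift_reduces_ks_distance(self):
        rng = np.random.default_rng(1)
        v1 = rng.beta(2, 2, 400)
        v2 = np.clip(rng.beta(2, 2, 400) * 0.8 + 0.1, 0, 1)  # compressed type II
        beta, ann = self._frame(v1, v2)
        out = tm.normalize_type_bias(beta, ann)
        before = stats.ks_2samp(v1, v2).statistic
        n1 = len(v1)
        after = stats.ks_2samp(out.values[:n1, 0], out.values[n1:, 0]).statistic
        assert after < before

    def test_rank_order_preserved(self):
        rng = np.random.default_rng(2)
        v1, v2 = rng.uniform(0, 1, 50), rng.uniform(0, 1, 60)
        beta, ann = self._frame(v1, v2)
        out = tm.normalize_type_bias(beta, ann)
        assert (np.argsort(out.values[:50, 0]) == np.argsort(v1)).all()
        assert (np.argsort(out.values[50:, 0]) == np.argsort(v2)).all()

    def test_small_type_skipped_with_warning(self):
        beta, ann = self._frame(np.linspace(0.1, 0.9, 5), np.linspace(0.1, 0.9, 40))
        with pytest.warns(UserWarning):
            out = tm.normalize_type_bias(beta, ann)
        pd.testing.assert_frame_equal(out, beta)


class TestPCAScreen:
    def _m_and_sheet(self, seed=0, n_probes=400, n_samples=40):
        rng = np.random.default_rng(seed)
        m = pd.DataFrame(
            rng.normal(0, 1, (n_probes, n_samples)),
            index=[f"p{i}" for i in range(n_probes)],
            columns=[f"s{i}" for i in range(n_samples)],
        )
        sheet = pd.DataFrame(index=m.columns)
        return m, sheet

    def test_self_association_selected(self):
        m, sheet = self._m_and_sheet()
        probe = tm.pca_covariate_screen(m, pd.DataFrame({"dummy": 1.0}, index=m.columns))
        sheet["pc1_copy"] = probe.scores["PC1"].values
        screen = tm.pca_covariate_screen(m, sheet)
        assert screen.pvalues.loc["PC1", "pc1_copy"] < 1e-10
        assert "pc1_copy" in screen.selected

    def test_variance_explained_non_increasing(self):
        m, _ = self._m_and_sheet(seed=3)
        screen = tm.pca_covariate_screen(
            m, pd.DataFrame({"x": np.arange(m.shape[1], dtype=float)}, index=m.columns)
        )
        assert (np.diff(screen.variance_explained) <= 1e-12).all()

    def test_noise_factor_selected_at_null_rate(self):
        """A pure-noise factor is screened against 4 PCs, so its null
        selection rate is 1 - (1 - alpha)^4 ~ 0.185."""
        hits = 0
        runs = 120
        m, _ = self._m_and_sheet(seed=1, n_probes=1000, n_samples=30)
        rng = np.random.default_rng(99)
        for _ in range(runs):
            sheet = pd.DataFrame({"noise": rng.normal(size=m.shape[1])}, index=m.columns)
            screen = tm.pca_covariate_screen(m, sheet)
            hits += "noise" in screen.selected
        rate = hits / runs
        assert 0.08 <= rate <= 0.32  # wide band around 0.185 for 120 runs

    def test_constant_factor_noted(self):
        m, _ = self._m_and_sheet()
        sheet = pd.DataFrame({"const": ["a"] * m.shape[1]}, index=m.columns)
        screen = tm.pca_covariate_screen(m, sheet)
        assert any("const" in note for note in screen.notes)
        assert "const" not in screen.selected


class TestMDS:
    def test_separated_clusters_high_score(self):
        rng = np.random.default_rng(4)
        a = rng.normal(0.3, 0.01, (200, 15))
        b = rng.normal(0.7, 0.01, (200, 15))
        beta = pd.DataFrame(
            np.hstack([a, b]),
            index=[f"p{i}" for i in range(200)],
            columns=[f"s{i}" for i in range(30)],
        )
        labels = ["g1"] * 15 + ["g2"] * 15
        _, score = tm.mds_top_variable(beta, k=100, group_labels=labels)
        assert score > 0.5

    def test_random_labels_score_near_zero(self):
        rng = np.random.default_rng(5)
        beta = pd.DataFrame(
            rng.uniform(0, 1, (300, 40)),
            index=[f"p{i}" for i in range(300)],
            columns=[f"s{i}" for i in range(40)],
        )
        labels = rng.permutation(["g1", "g2"] * 20)
        _, score = tm.mds_top_variable(beta, k=200, group_labels=labels)
        assert abs(score) < 0.2

    def test_distances_preserved_for_2d_embeddable_input(self):
        """Exact 2-D data: pairwise distances survive the embedding."""
        rng = np.random.default_rng(6)
        coords_true = rng.normal(0, 1, (12, 2))
        basis = np.linalg.qr(rng.normal(0, 1, (50, 2)))[0]
        x = coords_true @ basis.T + 0.5  # embed in 50-probe space
        beta = pd.DataFrame(
            x.T, index=[f"p{i}" for i in range(50)], columns=[f"s{i}" for i in range(12)]
        )
        coords, _ = tm.mds_top_variable(beta, k=50)
        from scipy.spatial.distance import pdist

        assert np.allclose(pdist(coords.values), pdist(coords_true), atol=1e-8)

    def test_k_bounds(self):
        beta = pd.DataFrame(np.eye(5), columns=[f"s{i}" for i in range(5)])
        with pytest.raises(ValueError):
            tm.mds_top_variable(beta, k=1)
        with pytest.raises(ValueError):
            tm.mds_top_variable(beta, k=6)
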