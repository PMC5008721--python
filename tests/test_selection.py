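import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import metadrift as md


class TestPairedT:
    def test_hand_computed_example(self):
        # differences (1, 2, 3): t = 2 / (1/sqrt(3)) = 3.4641, df = 2
        t, p = md.paired_t([0.0, 0.0, 0.0], [1.0, 2.0, 3.0])
        assert t == pytest.approx(3.4641, abs=1e-4)
        assert p == pytest.approx(0.0742, abs=1e-4)

    def test_identical_vectors_degenerate(self):
        t, p = md.paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert (t, p) == (0.0, 1.0)

    def test_constant_shift_degenerate(self):
        t, p = md.paired_t([1.0, 2.0, 3.0], [2.0, 3.0, 4.0])
        assert np.isinf(t) and t > 0
        assert p == 0.0

    def test_pairs_with_missing_dropped(self):
        t1, p1 = md.paired_t([1, 2, 3, np.nan], [2, 4, 4, 5])
        t2, p2 = md.paired_t([1, 2, 3], [2, 4, 4])
        assert (t1, p1) == (t2, p2)

    @given(st.integers(0, 2**32 - 1))
    def test_antisymmetry(self, seed):
        rng = np.random.default_rng(seed)
        a, b = rng.normal(size=10), rng.normal(size=10)
        t1, p1 = md.paired_t(a, b)
        t2, p2 = md.paired_t(b, a)
        assert t1 == pytest.approx(-t2)
        assert p1 == pytest.approx(p2)

    def test_type_one_error_calibration(self):
        """Null features reject at the nominal 5% rate (n = 44 pairs)."""
        rng = np.random.default_rng(123)
        n_feat = 1000
        pre = rng.normal(size=(44, n_feat))
        post = rng.normal(size=(44, n_feat))
        frac = np.mean(
            [md.paired_t(pre[:, j], post[:, j])[1] < 0.05 for j in range(n_feat)]
        )
        assert frac == pytest.approx(0.05, abs=0.02)


class TestBhAdjust:
    def test_hand_computed_example(self):
        np.testing.assert_allclose(
            md.bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_p_identity(self):
        assert md.bh_adjust([0.03])[0] == pytest.approx(0.03)

    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=40))
    def test_bounds_and_monotonicity(self, p):
        adj = md.bh_adjust(p)
        assert np.all(adj >= np.asarray(p) - 1e-12)
        assert np.all(adj <= 1.0 + 1e-12)

    @given(st.integers(0, 2**32 - 1))
    def test_permutation_invariance(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.uniform(size=15)
        perm = rng.permutation(15)
        np.testing.assert_allclose(md.bh_adjust(p)[perm], md.bh_adjust(p[perm]))

    def test_out_of_range_rejected(self):
        with pytest.raises(md.FeatureTableError):
            md.bh_adjust([0.5, 1.2])


class TestTrainRf:
    def _separable(self, seed, n_noise=100, n=40):
        rng = np.random.default_rng(seed)
        x = pd.DataFrame(rng.normal(size=(n, n_noise + 1)))
        y = np.array(["a"] * (n // 2) + ["b"] * (n // 2))
        x[0] = np.where(y == "a", 0.0, 5.0) + rng.normal(0, 0.3, n)
        return x, y

    def test_informative_feature_has_max_mda_low_oob(self):
        for seed in range(10):
            x, y = self._separable(seed)
            rf = md.train_rf(x, y, n_trees=300, mtry=30, seed=seed)
            assert rf.mda.idxmax() == 0
            assert rf.oob_error <= 0.05

    def test_pure_noise_mda_centered_at_zero(self):
        means = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            x = pd.DataFrame(rng.normal(size=(40, 200)))
            y = np.array(["a", "b"] * 20)
            rf = md.train_rf(x, y, n_trees=150, mtry=30, seed=seed)
            means.append(rf.mda.mean())
        se = np.std(means, ddof=1) / np.sqrt(len(means))
        assert abs(np.mean(means)) < 2 * se + 1e-4

    def test_proximity_symmetric_unit_diagonal(self):
        x, y = self._separable(3, n_noise=20)
        rf = md.train_rf(x, y, n_trees=50, mtry=5, seed=3)
        np.testing.assert_allclose(rf.proximity, rf.proximity.T)
        np.testing.assert_allclose(np.diag(rf.proximity), 1.0)
        assert rf.proximity.min() >= 0.0 and rf.proximity.max() <= 1.0

    def test_deterministic_given_seed(self):
        x, y = self._separable(4, n_noise=30)
        rf1 = md.train_rf(x, y, n_trees=60, mtry=5, seed=9)
        rf2 = md.train_rf(x, y, n_trees=60, mtry=5, seed=9)
        assert rf1.oob_error == rf2.oob_error
        pd.testing.assert_series_equal(rf1.mda, rf2.mda)
        np.testing.assert_array_equal(rf1.proximity, rf2.proximity)

    def test_single_class_rejected(self):
        x = pd.DataFrame(np.random.default_rng(0).normal(size=(10, 4)))
        with pytest.raises(md.FeatureTableError):
            md.train_rf(x, ["a"] * 10)


class TestRfMds:
    def test_equal_off_diagonal_gives_equidistant_points(self):
        """A proximity with all off-diagonal entries equal describes a regular
        simplex: the full MDS configuration keeps every pair equidistant."""
        n = 6
        prox = np.full((n, n), 0.4)
        np.fill_diagonal(prox, 1.0)
        coords = md.rf_mds(prox, k=n - 1)
        dists = [
            np.linalg.norm(coords[i] - coords[j])
            for i in range(n)
            for j in range(i + 1, n)
        ]
        np.testing.assert_allclose(dists, dists[0], rtol=1e-6)

    def test_two_clusters_linearly_separable(self):
        rng = np.random.default_rng(0)
        labels = np.array([0] * 10 + [1] * 10)
        prox = np.where(labels[:, None] == labels[None, :], 0.9, 0.1)
        prox = prox + rng.uniform(0, 0.01, prox.shape)
        prox = (prox + prox.T) / 2
        np.fill_diagonal(prox, 1.0)
        coords = md.rf_mds(prox)
        a, b = coords[labels == 0, 0], coords[labels == 1, 0]
        assert max(a) < min(b) or max(b) < min(a)

    def test_eckart_young_residual_matches_eigenvalue_tail(self):
        rng = np.random.default_rng(1)
        raw = rng.uniform(0.2, 0.9, (12, 12))
        prox = (raw + raw.T) / 2
        np.fill_diagonal(prox, 1.0)
        d = 1.0 - prox
        n = d.shape[0]
        j = np.eye(n) - np.ones((n, n)) / n
        gram = -0.5 * j @ (d**2) @ j
        coords = md.rf_mds(prox, k=2)
        eigval = np.sort(np.linalg.eigvalsh(gram))[::-1]
        resid = np.linalg.norm(gram - coords @ coords.T) ** 2
        expected = float(np.sum(eigval[2:] ** 2))
        assert resid == pytest.approx(expected, abs=1e-8 + 1e-8 * expected)


class TestSelectContrast:
    @pytest.fixture(scope="class")
    def recovery_runs(self):
        """Simulations with 50 differential among 900 features, |log2FC| = 1."""
        runs = []
        for seed in range(10):
            cfg = md.SimulationConfig(
                seed=seed, n_features=900,
                frac_system_peaks=0.0, frac_poorly_detected=0.0,
                differential_spec=(
                    md.DifferentialSpec("increasing", 25, 1.0),
                    md.DifferentialSpec("decreasing", 25, 1.0),
                ),
            )
            table, design, truth = md.simulate(cfg)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                corrected, _, _ = md.correct_table(table, design)
            analysis = md.apply_filters(corrected, md.rsd_filter(corrected, design))
            runs.append((analysis, design, truth))
        return runs

    def test_recovery_of_differential_features(self, recovery_runs):
        """Recall >= 0.8 and false-selection rate among nulls <= 0.02."""
        recalls, fprs = [], []
        for seed, (analysis, design, truth) in enumerate(recovery_runs):
            res = md.select_contrast(analysis, design, "PRE_FU", seed=seed)
            sel = set(res.selected_ids)
            true = set(truth.differential_ids)
            nulls = set(analysis.feature_ids) - true
            recalls.append(len(sel & true) / len(true))
            fprs.append(len(sel - true) / len(nulls))
        assert np.mean(recalls) >= 0.8
        assert np.mean(fprs) <= 0.02

    def test_alpha_zero_selects_nothing(self, recovery_runs):
        analysis, design, _ = recovery_runs[0]
        res = md.select_contrast(analysis, design, "PRE_POST", alpha=0.0, seed=0)
        assert res.selected_ids == []

    def test_lambda_features_not_selected_in_pre_fu(self):
        """A feature differential only at POST has PRE = FU truly, so the
        long-term contrast must not pick it up."""
        cfg = md.SimulationConfig(
            seed=21, n_features=300, frac_system_peaks=0.0, frac_poorly_detected=0.0,
            differential_spec=(md.DifferentialSpec("Lambda", 20, 1.0),),
        )
        table, design, truth = md.simulate(cfg)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            corrected, _, _ = md.correct_table(table, design)
        analysis = md.apply_filters(corrected, md.rsd_filter(corrected, design))
        res = md.select_contrast(analysis, design, "PRE_FU", seed=21)
        lam = set(truth.ids_with_pattern("Lambda"))
        assert len(set(res.selected_ids) & lam) <= 1


class TestIntersectContrasts:
    def _mock(self, contrast, ids, selected):
        stats = pd.DataFrame(
            {"t": 0.0, "p": 1.0, "p_adj": 1.0, "mda": 0.0,
             "selected": [i in selected for i in ids]},
            index=pd.Index(ids, name="feature_id"),
        )
        return md.ContrastResult(contrast, stats, 0.0, np.eye(2), ["s1", "s2"],
                                 np.array(["PRE", "POST"]), 0.01)

    def test_plain_intersection(self):
        a = self._mock("PRE_POST", ["f1", "f2", "f3"], {"f1", "f2"})
        b = self._mock("PRE_FU", ["f1", "f2", "f3"], {"f2", "f3"})
        assert md.intersect_contrasts(a, b) == ["f2"]

    def test_disjoint_selections_warn_but_complete(self):
        a = self._mock("PRE_POST", ["f1", "f2"], {"f1"})
        b = self._mock("PRE_FU", ["f1", "f2"], {"f2"})
        with pytest.warns(UserWarning, match="disjoint"):
            assert md.intersect_contrasts(a, b) == []


class TestUnsupervisedRf:
    def test_proximity_restricted_to_real_samples(self):
        rng = np.random.default_rng(0)
        x = pd.DataFrame(rng.normal(size=(20, 30)))
        rf = md.unsupervised_rf(x, n_trees=50, mtry=5, seed=0)
        assert rf.proximity.shape == (20, 20)
        np.testing.assert_allclose(np.diag(rf.proximity), 1.0)
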