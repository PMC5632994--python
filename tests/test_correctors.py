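import numpy as np
import pandas as pd
import pytest

from twophase.correctors import (METHODS, CorrectionSpec, CostingSampler,
                                 IPBagger, IPOversampler, NoCorrection,
                                 ParametricIPBagger, StochasticIPOversampler,
                                 StratifiedSMOTE, make_corrector,
                                 noise_covariance)
from twophase.strata import assign_strata, build_stratum_table

from conftest import make_four_strata


class TestSizeContracts:
    def test_none_is_identity(self, four_strata_sample, weighted_table):
        out = NoCorrection().resample(four_strata_sample, weighted_table)[0]
        pd.testing.assert_frame_equal(out.data, four_strata_sample.data)
        assert out.provenance == "none"

    def test_ip_oversampling_replication_counts(self, four_strata_sample,
                                                weighted_table):
        out = IPOversampler().resample(four_strata_sample, weighted_table)[0]
        assert out.n == weighted_table.n_prime == 170
        counts = out.stratum_counts()
        assert counts.tolist() == [10, 50, 20, 90]
        # each original row appears exactly w_h times
        key = ["x_e", "y", "x1", "x2"]
        orig = four_strata_sample.data[key].apply(tuple, axis=1).value_counts()
        new = out.data[key].apply(tuple, axis=1).value_counts()
        w_by_row = weighted_table.weight_of(four_strata_sample.stratum_id)
        for row_key, w in zip(four_strata_sample.data[key].apply(tuple, axis=1),
                              w_by_row):
            assert new[row_key] == w * orig[row_key]

    @pytest.mark.parametrize("method,expected_sizes", [
        ("ip_bagging", [40, 40, 40]),
        ("stochastic_ip_oversampling", [170, 170, 170]),
        ("parametric_ip_bagging", [170, 170, 170]),
    ])
    def test_ensemble_sizes(self, four_strata_sample, weighted_table,
                            method, expected_sizes):
        corr = make_corrector(method, m=3)
        out = corr.resample(four_strata_sample, weighted_table, random_state=0)
        assert [s.n for s in out] == expected_sizes

    def test_costing_sizes_vary_and_stay_complete(self, four_strata_sample,
                                                  weighted_table):
        out = CostingSampler(m=10).resample(four_strata_sample, weighted_table,
                                            random_state=0)
        sizes = [s.n for s in out]
        assert all(sz <= 40 for sz in sizes)
        assert len(set(sizes)) > 1
        for s in out:
            assert set(s.stratum_id) == {1, 2, 3, 4}


class TestAllWeightsOneLimit:
    def test_oversample_and_smote_and_stochastic_are_identity(
            self, four_strata_sample, unit_table):
        for corr in (IPOversampler(), StratifiedSMOTE(k=3),
                     StochasticIPOversampler(m=2)):
            for out in corr.resample(four_strata_sample, unit_table,
                                     random_state=5):
                assert out.n == four_strata_sample.n
                np.testing.assert_array_equal(out.feature_matrix(),
                                              four_strata_sample.feature_matrix())

    def test_costing_returns_full_sample(self, four_strata_sample, unit_table):
        for out in CostingSampler(m=3).resample(four_strata_sample, unit_table,
                                                random_state=5):
            assert out.n == four_strata_sample.n

    def test_ip_bagging_is_plain_bootstrap_size(self, four_strata_sample,
                                                unit_table):
        out = IPBagger(m=2).resample(four_strata_sample, unit_table,
                                     random_state=5)
        assert [s.n for s in out] == [40, 40]


class TestLabelConservation:
    @pytest.mark.parametrize("method", METHODS)
    def test_no_corrector_alters_labels_or_drops_strata(
            self, four_strata_sample, weighted_table, method):
        corr = make_corrector(method, m=2, k=3)
        for out in corr.resample(four_strata_sample, weighted_table,
                                 random_state=9):
            cells = set(zip(out.data["x_e"], out.data["y"]))
            assert cells <= set(four_strata_sample.strata)
            assert set(out.stratum_id) == {1, 2, 3, 4}
            # the (x_e, y) pair determines the stratum id exactly as in input
            for sid, (xe, y) in zip(out.stratum_id,
                                    zip(out.data["x_e"], out.data["y"])):
                assert four_strata_sample.strata[sid - 1] == (xe, y)


class TestReproducibility:
    @pytest.mark.parametrize("method", METHODS)
    def test_same_seed_same_output(self, four_strata_sample, weighted_table,
                                   method):
        corr = make_corrector(method, m=3, k=3)
        a = corr.resample(four_strata_sample, weighted_table, random_state=123)
        b = corr.resample(four_strata_sample, weighted_table, random_state=123)
        assert len(a) == len(b)
        for s1, s2 in zip(a, b):
            pd.testing.assert_frame_equal(s1.data, s2.data)

    def test_larger_m_preserves_earlier_repetitions(self, four_strata_sample,
                                                    weighted_table):
        a = IPBagger(m=2).resample(four_strata_sample, weighted_table,
                                   random_state=7)
        b = IPBagger(m=5).resample(four_strata_sample, weighted_table,
                                   random_state=7)
        for s1, s2 in zip(a, b[:2]):
            pd.testing.assert_frame_equal(s1.data, s2.data)


class TestIPBaggingLaw:
    def test_expected_stratum_count_matches_closed_form(
            self, four_strata_sample, weighted_table):
        """Mean stratum-2 count over many bootstrap draws equals n*n_h*w_h/n'."""
        m = 20_000
        out = IPBagger(m=m).resample(four_strata_sample, weighted_table,
                                     random_state=11)
        counts = np.array([(s.stratum_id == 2).sum() for s in out])
        p = 50 / 170  # stratum-2 selection mass: n_h * w_h / n'
        expected = 40 * p
        se = np.sqrt(40 * p * (1 - p) / m)
        assert abs(counts.mean() - expected) < 3 * se


class TestCostingLaw:
    def test_unfiltered_expected_size(self, four_strata_sample, weighted_table):
        """Raw acceptance sampling has expected size sum n_h w_h / max w."""
        m = 20_000
        corr = CostingSampler(m=m, filter_incomplete=False)
        out = corr.resample(four_strata_sample, weighted_table, random_state=13)
        sizes = np.array([s.n for s in out])
        w = np.array([1, 5, 2, 9]) / 9
        expected = (10 * w).sum()  # 170/9
        var = (10 * w * (1 - w)).sum()
        se = np.sqrt(var / m)
        assert abs(sizes.mean() - expected) < 3 * se

    def test_max_weight_stratum_always_fully_present(self, four_strata_sample,
                                                     weighted_table):
        out = CostingSampler(m=20).resample(four_strata_sample, weighted_table,
                                            random_state=17)
        for s in out:
            assert (s.stratum_id == 4).sum() == 10  # w_h = max w -> accept prob 1


class TestSMOTE:
    def test_duplicate_points_produce_the_same_point(self):
        df = pd.DataFrame({"x_e": [0, 0, 1, 1], "y": [0, 0, 0, 0],
                           "x1": [3.0, 3.0, 0.0, 1.0]})
        s = assign_strata(df, "y", "x_e")
        t = build_stratum_table(s, p_select={(0, 0): 1 / 3, (1, 0): 1.0})
        out = StratifiedSMOTE(k=1).resample(s, t, random_state=3)[0]
        assert out.n == 2 * 3 + 2  # stratum (0,0) tripled, (1,0) untouched
        synth = out.data.iloc[4:]
        assert (synth.loc[synth["x_e"] == 0, "x1"] == 3.0).all()

    def test_synthetic_rows_lie_on_segments_between_stratum_members(
            self, four_strata_sample, weighted_table):
        out = StratifiedSMOTE(k=3).resample(four_strata_sample, weighted_table,
                                            random_state=29)[0]
        X_new = out.feature_matrix()[four_strata_sample.n:]
        sid_new = out.stratum_id[four_strata_sample.n:]
        X_orig = four_strata_sample.feature_matrix()
        for x, sid in zip(X_new, sid_new):
            members = X_orig[four_strata_sample.stratum_id == sid]
            ok = False
            for i in range(len(members)):
                for j in range(len(members)):
                    if i == j:
                        continue
                    a, b = members[i], members[j]
                    d = b - a
                    denom = float(d @ d)
                    u = 0.0 if denom == 0 else float((x - a) @ d) / denom
                    if 0 <= u <= 1 and np.allclose(a + u * d, x, atol=1e-9):
                        ok = True
                        break
                if ok:
                    break
            assert ok, "synthetic point not on any segment between stratum members"

    def test_rejects_k_not_below_stratum_size(self, four_strata_sample,
                                              weighted_table):
        with pytest.raises(ValueError, match="stratum"):
            StratifiedSMOTE(k=10).resample(four_strata_sample, weighted_table,
                                           random_state=0)


class TestNoiseCovariance:
    def test_weight_one_gives_zero(self):
        sigma = np.array([[2.0, 0.3], [0.3, 1.0]])
        assert np.all(noise_covariance(sigma, w_h=1, n_h=10) == 0)

    def test_closed_form_factor(self):
        out = noise_covariance(np.eye(2), w_h=2, n_h=3)
        np.testing.assert_allclose(out, np.eye(2) / 5)

    @pytest.mark.parametrize("bad,kwargs", [
        (np.array([[1.0, 0.5], [0.2, 1.0]]), {"w_h": 2, "n_h": 5}),
        (np.eye(2), {"w_h": 2, "n_h": 1}),
    ])
    def test_rejections(self, bad, kwargs):
        with pytest.raises(ValueError):
            noise_covariance(bad, **kwargs)


class TestStochasticIPOversampling:
    def test_noise_preserves_stratum_mean(self):
        """Average noisy stratum mean over many repetitions equals the
        original stratum mean (the added noise has expectation zero)."""
        sample = make_four_strata(n_per_cell=20, p=2, seed=5)
        t = build_stratum_table(
            sample, p_select={(0, 0): 1.0, (0, 1): 0.5, (1, 0): 0.25, (1, 1): 1.0})
        m = 400
        out = StochasticIPOversampler(m=m).resample(sample, t, random_state=31)
        for sid, w in zip(t.table.index, t.w_h):
            if w == 1:
                continue
            orig_mean = sample.feature_matrix()[sample.stratum_id == sid].mean(axis=0)
            rep_means = np.array([
                s.feature_matrix()[s.stratum_id == sid].mean(axis=0) for s in out])
            se = rep_means.std(axis=0, ddof=1) / np.sqrt(m)
            assert np.all(np.abs(rep_means.mean(axis=0) - orig_mean) < 4 * se + 1e-12)

    def test_rejects_singleton_stratum(self):
        df = pd.DataFrame({"x_e": [0, 0, 1], "y": [0, 0, 0],
                           "x1": [1.0, 2.0, 3.0]})
        s = assign_strata(df, "y", "x_e")
        t = build_stratum_table(s, p_select={(0, 0): 1.0, (1, 0): 0.25})
        with pytest.raises(ValueError, match="fewer than 2"):
            StochasticIPOversampler(m=1).resample(s, t, random_state=0)


class TestParametricIPBagging:
    def test_per_stratum_draw_counts(self):
        sample = make_four_strata(n_per_cell=5, p=2, seed=9)
        t = build_stratum_table(
            sample, p_select={(0, 0): 1.0, (0, 1): 0.25, (1, 0): 0.5, (1, 1): 1.0})
        out = ParametricIPBagger(m=2).resample(sample, t, random_state=7)
        for s in out:
            assert s.stratum_counts().tolist() == [5, 20, 10, 5]

    def test_degenerate_stratum_reproduces_constant_point(self):
        df = pd.DataFrame({"x_e": [0] * 4 + [1] * 4, "y": [0] * 8,
                           "x1": [2.5] * 4 + [0.0, 1.0, 2.0, 3.0]})
        s = assign_strata(df, "y", "x_e")
        t = build_stratum_table(s, p_select={(0, 0): 0.5, (1, 0): 1.0})
        out = ParametricIPBagger(m=1).resample(s, t, random_state=0)[0]
        vals = out.data.loc[out.data["x_e"] == 0, "x1"]
        assert np.allclose(vals, 2.5, atol=1e-3)

    def test_gaussian_generator_hits_the_fitted_mean(self):
        """CLT check: the sample mean of n_h*w draws stays within
        4*sigma/sqrt(n_h*w) of the fitted stratum mean, per coordinate."""
        rng = np.random.default_rng(21)
        n_h, w = 200, 2
        df = pd.DataFrame({
            "x_e": [0] * n_h + [1] * 2, "y": [0] * (n_h + 2),
            "x1": np.r_[rng.normal(2, 1, n_h), [0, 0]],
            "x2": np.r_[rng.normal(-1, 1, n_h), [0, 0]],
        })
        s = assign_strata(df, "y", "x_e")
        t = build_stratum_table(s, p_select={(0, 0): 0.5, (1, 0): 1.0})
        mu_hat = s.feature_matrix()[s.stratum_id == 1].mean(axis=0)
        misses = 0
        for seed in range(10):
            out = ParametricIPBagger(m=1).resample(s, t, random_state=seed)[0]
            draws = out.feature_matrix()[out.stratum_id == 1]
            assert len(draws) == n_h * w
            if np.any(np.abs(draws.mean(axis=0) - mu_hat) > 4 / np.sqrt(n_h * w)):
                misses += 1
        assert misses <= 1

    def test_rejects_unknown_family(self, four_strata_sample, weighted_table):
        with pytest.raises(ValueError, match="family"):
            ParametricIPBagger(m=1, family="gamma").resample(
                four_strata_sample, weighted_table, random_state=0)


class TestCorrectionSpec:
    def test_json_roundtrip_and_validation(self):
        spec = CorrectionSpec(method="smote", m=1, k=3, seed=4)
        again = CorrectionSpec.from_json(spec.to_json())
        assert again == spec
        with pytest.raises(ValueError, match="unknown correction"):
            CorrectionSpec(method="oversample_twice")
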