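import numpy as np
import pandas as pd
import pytest
from scipy import stats

from dgi.scoring import compute_differentials, ds_score, s_score


def diffs_frame(deltas_by_pair):
    """deltas_by_pair: {(query, array): [delta, ...]}"""
    rows = []
    for (q, a), deltas in deltas_by_pair.items():
        for i, d in enumerate(deltas, start=1):
            rows.append(dict(query_id=q, array_id=a, replicate=i, delta=d))
    return pd.DataFrame(rows)


def residual_frame(values_by_pair, condition="UT"):
    rows = []
    for (q, a), vals in values_by_pair.items():
        for i, v in enumerate(vals, start=1):
            rows.append(dict(query_id=q, array_id=a, replicate=i,
                             condition=condition, residual=v))
    return pd.DataFrame(rows)


class TestComputeDifferentials:
    def _residuals(self):
        rows = []
        for i, (rt, ru) in enumerate([(2.0, 0.5), (1.0, 1.0), (-1.0, 2.0)], start=1):
            rows.append(dict(query_id="q", array_id="a", replicate=i,
                             condition="MMS", residual=rt))
            rows.append(dict(query_id="q", array_id="a", replicate=i,
                             condition="UT", residual=ru))
        return pd.DataFrame(rows)

    def test_pairwise_subtraction(self):
        d = compute_differentials(self._residuals(), "MMS", "UT")
        assert sorted(d["delta"]) == [-3.0, 0.0, 1.5]

    def test_identical_conditions_give_zero(self):
        res = self._residuals()
        res.loc[res["condition"] == "MMS", "residual"] = (
            res.loc[res["condition"] == "UT", "residual"].to_numpy()
        )
        d = compute_differentials(res, "MMS", "UT")
        assert np.allclose(d["delta"], 0.0)

    def test_swapping_conditions_negates(self):
        res = self._residuals()
        d1 = compute_differentials(res, "MMS", "UT").sort_values("replicate")
        d2 = compute_differentials(res, "UT", "MMS").sort_values("replicate")
        np.testing.assert_allclose(d1["delta"].to_numpy(), -d2["delta"].to_numpy())

    def test_unpaired_measurements_dropped(self):
        res = self._residuals().iloc[:-1]  # drop one UT measurement
        d = compute_differentials(res, "MMS", "UT")
        assert len(d) == 2

    def test_unknown_condition_rejected(self):
        with pytest.raises(ValueError, match="HU"):
            compute_differentials(self._residuals(), "HU", "UT")


class TestDsScoreOneSample:
    def test_zero_mean_scores_zero(self):
        _, s = ds_score(diffs_frame({("q", "a"): [1, -1, 1, -1, 1, -1]}),
                        mode="one_sample")
        assert s[0].score == 0.0

    def test_textbook_t_statistic(self):
        deltas = [2.0, 2.0, 2.0, 4.0, 4.0, 4.0]
        _, s = ds_score(diffs_frame({("q", "a"): deltas}), mode="one_sample")
        oracle = stats.ttest_1samp(deltas, popmean=0.0).statistic
        assert s[0].score == pytest.approx(oracle, abs=1e-12)
        assert s[0].score == pytest.approx(3 / (np.sqrt(1.2) / np.sqrt(6)), abs=1e-4)
        assert s[0].n == 6 and s[0].mean_diff == 3.0

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_reference_on_random_fixtures(self, seed):
        rng = np.random.default_rng(seed)
        deltas = rng.normal(0.3, 1.0, size=rng.integers(3, 12))
        _, s = ds_score(diffs_frame({("q", "a"): list(deltas)}), mode="one_sample")
        oracle = stats.ttest_1samp(deltas, popmean=0.0).statistic
        assert s[0].score == pytest.approx(oracle, abs=1e-12)

    def test_negating_deltas_negates_scores(self):
        d = diffs_frame({("q", "a"): [0.5, 1.5, -0.2, 0.9]})
        _, s1 = ds_score(d, mode="one_sample")
        d["delta"] *= -1
        _, s2 = ds_score(d, mode="one_sample")
        assert s2[0].score == -s1[0].score

    def test_degenerate_zero_spread(self):
        _, s = ds_score(diffs_frame({("q", "a"): [0.0, 0.0, 0.0]}),
                        mode="one_sample")
        assert s[0].score == 0.0 and not s[0].degenerate
        _, s = ds_score(diffs_frame({("q", "a"): [2.0, 2.0, 2.0]}),
                        mode="one_sample")
        assert np.isnan(s[0].score) and s[0].degenerate

    def test_min_reps_skips_single_delta(self):
        mat, s = ds_score(diffs_frame({("q1", "a"): [1.0],
                                       ("q2", "a"): [1.0, 2.0, 3.0]}),
                          mode="one_sample")
        assert [x.query_id for x in s] == ["q2"]


class TestDsScorePooled:
    @pytest.mark.parametrize("seed", range(10))
    def test_matches_two_sample_reference(self, seed):
        """Pooled dS equals the reference equal-variance two-sample t of the
        pair's deltas against the rest of the array's deltas."""
        rng = np.random.default_rng(100 + seed)
        pairs = {(f"q{j}", "a"): list(rng.normal(0, 1, 6)) for j in range(8)}
        d = diffs_frame(pairs)
        _, summaries = ds_score(d, mode="pooled")
        for s in summaries:
            x = np.array(pairs[(s.query_id, "a")])
            y = np.concatenate(
                [v for k, v in pairs.items() if k[0] != s.query_id]
            )
            oracle = stats.ttest_ind(x, y, equal_var=True).statistic
            assert s.score == pytest.approx(oracle, abs=1e-12)

    def test_shared_pipeline_constant_cancels(self, null_residuals, null_screen):
        """Adding any per-(query, replicate) constant to both conditions'
        residuals leaves dS unchanged: shared noise never reaches the
        deltas. This is the cancellation that motivates the paired design."""
        cfg, _, _ = null_screen
        residuals, _ = null_residuals
        rng = np.random.default_rng(0)
        keys = residuals[["query_id", "replicate"]].apply(tuple, axis=1)
        offsets = {k: rng.normal(0, 50.0) for k in keys.unique()}
        perturbed = residuals.copy()
        perturbed["residual"] = perturbed["residual"] + keys.map(offsets)
        d1 = compute_differentials(residuals, cfg.treatment, cfg.reference)
        d2 = compute_differentials(perturbed, cfg.treatment, cfg.reference)
        _, s1 = ds_score(d1, mode="pooled")
        _, s2 = ds_score(d2, mode="pooled")
        np.testing.assert_allclose(
            [x.score for x in s1], [x.score for x in s2], atol=1e-9
        )

    def test_rank_agreement_with_one_sample(self, null_diffs):
        m1, _ = ds_score(null_diffs, mode="one_sample")
        mp, _ = ds_score(null_diffs, mode="pooled")
        a, b = m1.values.stack().align(mp.values.stack(), join="inner")
        rho = stats.spearmanr(a, b).statistic
        assert rho > 0.95

    def test_null_scores_follow_student_t(self, null_screen, null_diffs):
        """Under the simulator null, one-sample dS is t(n-1): two-sided
        exceedance of the 97.5% t quantile is 5% +- 1.5%."""
        cfg, _, _ = null_screen
        _, summaries = ds_score(null_diffs, mode="one_sample")
        scores = np.array([s.score for s in summaries if not s.degenerate])
        assert scores.size >= 2000
        crit = stats.t.ppf(0.975, cfg.n_replicates - 1)
        exceed = np.mean(np.abs(scores) > crit)
        assert exceed == pytest.approx(0.05, abs=0.015)


class TestSScore:
    def _pairs(self, seed=0):
        rng = np.random.default_rng(seed)
        return {(f"q{j}", "a"): list(rng.normal(0, 1, 6)) for j in range(8)}

    def test_floor_is_applied_to_low_variance_pair(self):
        pairs = self._pairs(5)
        pairs[("q0", "a")] = [0.5, 0.5001, 0.4999, 0.5, 0.5001, 0.4999]
        res = residual_frame(pairs)
        _, summaries = s_score(res, "UT")
        by_q = {s.query_id: s for s in summaries}
        sds = [np.std(v, ddof=1) for v in pairs.values()]
        floor = float(np.median(sds))
        x = np.array(pairs[("q0", "a")])
        y = np.concatenate([v for k, v in pairs.items() if k[0] != "q0"])
        n1, n2 = len(x), len(y)
        s1 = max(x.std(ddof=1), floor)
        sp2 = ((n1 - 1) * s1**2 + (n2 - 1) * y.std(ddof=1) ** 2) / (n1 + n2 - 2)
        oracle = (x.mean() - y.mean()) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
        assert by_q["q0"].score == pytest.approx(oracle, abs=1e-12)
        # the floor shrinks the statistic relative to the unbounded version
        unbounded = stats.ttest_ind(x, y, equal_var=True).statistic
        assert abs(by_q["q0"].score) <= abs(unbounded)

    def test_pair_at_population_mean_scores_zero(self):
        pairs = {("q0", "a"): [1.0, 2.0, 3.0],  # mean 2
                 ("q1", "a"): [1.5, 2.5],       # mean 2
                 ("q2", "a"): [2.0, 2.0, 1.0, 3.0]}  # mean 2
        _, summaries = s_score(residual_frame(pairs), "UT")
        by_q = {s.query_id: s for s in summaries}
        assert by_q["q0"].score == pytest.approx(0.0, abs=1e-12)

    def test_matches_reference_with_manual_floor(self):
        pairs = self._pairs(6)
        res = residual_frame(pairs)
        _, summaries = s_score(res, "UT")
        sds = [np.std(v, ddof=1) for v in pairs.values()]
        floor = float(np.median(sds))
        for s in summaries:
            x = np.array(pairs[(s.query_id, "a")])
            y = np.concatenate([v for k, v in pairs.items() if k[0] != s.query_id])
            n1, n2 = len(x), len(y)
            s1 = max(x.std(ddof=1), floor)
            sp2 = ((n1 - 1) * s1**2 + (n2 - 1) * y.std(ddof=1) ** 2) / (n1 + n2 - 2)
            oracle = (x.mean() - y.mean()) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
            assert s.score == pytest.approx(oracle, abs=1e-12)
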