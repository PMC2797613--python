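import math

import numpy as np
import pandas as pd
import pytest

from songvar import (
    FeatureTrajectory,
    ScoreMatrix,
    aggregate_cv,
    aggregate_scores,
    feature_summary,
    identity_score,
    mad_scale,
    stabilize_sample_count,
    trajectory_similarity,
)
from songvar.io import FEATURE_COLUMNS
from songvar.synthetic import DEFAULT_FEATURE_MEANS, sample_feature_renditions


def _table(values_by_feature, bird="b1", syllable="a", condition="NS-UD"):
    n = len(next(iter(values_by_feature.values())))
    base = {f: [1.0] * n for f in FEATURE_COLUMNS}
    base.update(values_by_feature)
    return pd.DataFrame(
        {"bird": bird, "syllable": syllable, "condition": condition,
         "rendition": np.arange(1, n + 1), **base}
    )


class TestFeatureSummary:
    def test_identical_renditions_zero_cv(self):
        tbl = _table({"pitch": [700.0] * 25})
        summ = feature_summary(tbl)
        assert (summ["cv"] == 0).all()
        assert (summ["n_renditions"] == 25).all()

    def test_hand_computed_cv(self):
        tbl = _table({"pitch": [9.0, 10.0, 11.0]})
        row = feature_summary(tbl).set_index("feature").loc["pitch"]
        assert row["mean"] == pytest.approx(10.0)
        assert row["sd"] == pytest.approx(1.0)  # sample SD, n-1 denominator
        assert row["cv"] == pytest.approx(0.1)
        assert row["se"] == pytest.approx(1.0 / math.sqrt(3))

    def test_gaussian_recovery_within_monte_carlo_error(self):
        mu, sigma, n_seeds = 700.0, 700.0 * 0.074, 200
        cvs = []
        for seed in range(n_seeds):
            tbl = sample_feature_renditions(
                DEFAULT_FEATURE_MEANS, {"pitch": 0.074}, n=25, seed=seed
            )
            summ = feature_summary(tbl).set_index("feature")
            cvs.append(summ.loc["pitch", "cv"])
        # CV of n=25 Gaussian draws: SE ~ cv / sqrt(2(n-1))
        se = (sigma / mu) / math.sqrt(2 * 24) / math.sqrt(n_seeds)
        assert abs(np.mean(cvs) - sigma / mu) < 3 * se + 0.001

    def test_cv_invariant_under_feature_rescaling(self):
        vals = [9.0, 10.0, 12.0, 11.0]
        a = feature_summary(_table({"pitch": vals}))
        b = feature_summary(_table({"pitch": [v * 7.5 for v in vals]}))
        ia, ib = a.set_index("feature"), b.set_index("feature")
        assert ia.loc["pitch", "cv"] == pytest.approx(ib.loc["pitch", "cv"])

    def test_single_rendition_rejected(self):
        with pytest.raises(ValueError, match=">= 2"):
            feature_summary(_table({"pitch": [700.0]}))

    def test_zero_mean_cv_missing_with_warning(self):
        tbl = _table({"FM": [-1.0, 1.0]})
        with pytest.warns(UserWarning, match="zero mean"):
            summ = feature_summary(tbl)
        assert math.isnan(summ.set_index("feature").loc["FM", "cv"])


class TestAggregateCV:
    @staticmethod
    def _summary(bird_cvs):
        rows = []
        for bird, cvs in bird_cvs.items():
            for i, cv in enumerate(cvs):
                rows.append(
                    {"bird": bird, "syllable": f"{bird}s{i}", "condition": "NS-UD",
                     "feature": "pitch", "mean": 1.0, "sd": cv, "se": 0.0,
                     "cv": cv, "n_renditions": 25}
                )
        return pd.DataFrame(rows)

    def test_hand_computed_two_bird_example(self):
        summ = self._summary({"b1": [0.1, 0.1], "b2": [0.2, 0.2, 0.2, 0.2]})
        per_bird = aggregate_cv(summ, "per_bird_then_group")
        per_syl = aggregate_cv(summ, "per_syllable")
        assert per_bird["mean_cv"].iloc[0] == pytest.approx(0.15)
        assert per_syl["mean_cv"].iloc[0] == pytest.approx(1.0 / 6)
        assert per_syl["n_units"].iloc[0] == 6

    def test_one_syllable_per_bird_levels_agree(self):
        summ = self._summary({"b1": [0.1], "b2": [0.2], "b3": [0.3]})
        pb = aggregate_cv(summ, "per_bird_then_group")
        ps = aggregate_cv(summ, "per_syllable")
        assert pb["mean_cv"].iloc[0] == pytest.approx(ps["mean_cv"].iloc[0])

    def test_per_syllable_equals_flat_average(self):
        rng = np.random.default_rng(0)
        bird_cvs = {f"b{i}": list(rng.uniform(0.05, 0.2, 3)) for i in range(11)}
        summ = self._summary(bird_cvs)
        ps = aggregate_cv(summ, "per_syllable")
        flat = np.mean([cv for cvs in bird_cvs.values() for cv in cvs])
        assert ps["mean_cv"].iloc[0] == pytest.approx(flat)

    def test_unknown_level_rejected(self):
        with pytest.raises(ValueError, match="level"):
            aggregate_cv(self._summary({"b1": [0.1]}), "per_motif")


class TestAggregateScores:
    @pytest.mark.parametrize("m,expected", [(20, 380), (30, 870)])
    def test_off_diagonal_score_counts(self, m, expected):
        rng = np.random.default_rng(m)
        sim = rng.uniform(50, 90, size=(m, m))
        np.fill_diagonal(sim, 100.0)
        res = aggregate_scores(ScoreMatrix(similarity=sim))
        assert res.n_scores == expected == m * m - m

    def test_constant_matrix_mean_and_zero_se(self):
        sim = np.full((5, 5), 85.0)
        res = aggregate_scores(ScoreMatrix(similarity=sim))
        assert res.similarity_mean == pytest.approx(85.0)
        assert res.similarity_se == pytest.approx(0.0)

    def test_single_item_rejected(self):
        with pytest.raises(ValueError):
            aggregate_scores(ScoreMatrix(similarity=np.array([[100.0]])))


class TestIdentityScore:
    def test_boundary_values(self):
        assert identity_score(100, 100) == 100.0
        assert identity_score(50, 50) == 25.0
        assert identity_score(0, 80) == 0.0

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            identity_score(101, 50)
        with pytest.raises(ValueError):
            identity_score(50, -1)

    def test_bounds_and_zero_condition(self):
        rng = np.random.default_rng(1)
        sim = rng.uniform(0, 100, 50)
        acc = rng.uniform(0, 100, 50)
        ident = identity_score(sim, acc)
        assert np.all(ident <= 100)
        assert np.all(ident == 0) == bool(np.all((sim == 0) | (acc == 0)))

    def test_average_of_identities_differs_from_product_of_means(self):
        # identity is applied per syllable before averaging
        rng = np.random.default_rng(2)
        sim = rng.uniform(40, 100, 30)
        acc = rng.uniform(40, 100, 30)
        mean_ident = identity_score(sim, acc).mean()
        ident_of_means = identity_score(sim.mean(), acc.mean())
        direct = np.mean(sim * acc / 100.0)
        assert mean_ident == pytest.approx(direct)
        assert mean_ident != pytest.approx(ident_of_means, abs=1e-6)


def _trajectory(rng, n=40, shift=0):
    t = np.arange(n + shift) * 0.3
    return FeatureTrajectory(
        pitch=700 + 80 * np.sin(t)[shift:],
        fm=25 + 10 * np.cos(t)[shift:],
        wiener_entropy=-2 + 0.5 * np.sin(2 * t)[shift:],
        pitch_goodness=300 + 50 * np.cos(3 * t)[shift:],
    )


class TestTrajectorySimilarity:
    def test_identical_trajectories_score_100(self):
        rng = np.random.default_rng(0)
        a = _trajectory(rng)
        for mode in ("symmetric", "asymmetric"):
            sim, acc = trajectory_similarity(a, a, mode=mode)
            assert sim == pytest.approx(100.0)
            assert acc == pytest.approx(100.0)

    def test_scores_decrease_with_noise(self):
        rng = np.random.default_rng(1)
        a = _trajectory(rng)
        scale = mad_scale([a])
        sims, accs = [], []
        for noise_sd in (0.0, 0.5, 1.0, 2.0):
            sim_seeds, acc_seeds = [], []
            for seed in range(20):
                r = np.random.default_rng(seed)
                b = FeatureTrajectory(
                    pitch=a.pitch + r.normal(0, noise_sd * scale[0], a.n_frames),
                    fm=a.fm + r.normal(0, noise_sd * scale[1], a.n_frames),
                    wiener_entropy=a.wiener_entropy
                    + r.normal(0, noise_sd * scale[2], a.n_frames),
                    pitch_goodness=a.pitch_goodness
                    + r.normal(0, noise_sd * scale[3], a.n_frames),
                )
                s, ac = trajectory_similarity(a, b, mode="symmetric", scale=scale)
                sim_seeds.append(s)
                acc_seeds.append(ac)
            sims.append(np.mean(sim_seeds))
            accs.append(np.mean(acc_seeds))
        assert all(x > y for x, y in zip(sims, sims[1:]))
        assert all(x > y for x, y in zip(accs, accs[1:]))

    def test_asymmetric_beats_symmetric_on_time_shift(self):
        rng = np.random.default_rng(2)
        a = _trajectory(rng, n=60)
        b = _trajectory(rng, n=60, shift=9)  # time-shifted copy
        scale = mad_scale([a, b])
        s_asym, _ = trajectory_similarity(a, b, mode="asymmetric", scale=scale)
        s_sym, _ = trajectory_similarity(a, b, mode="symmetric", scale=scale)
        assert s_asym > s_sym

    def test_symmetric_mode_is_symmetric(self):
        rng = np.random.default_rng(3)
        a = _trajectory(rng, n=50)
        b = _trajectory(rng, n=37, shift=4)
        scale = mad_scale([a, b])
        s_ab, a_ab = trajectory_similarity(a, b, mode="symmetric", scale=scale)
        s_ba, a_ba = trajectory_similarity(b, a, mode="symmetric", scale=scale)
        assert abs(s_ab - s_ba) < 1e-9
        assert abs(a_ab - a_ba) < 1e-9

    def test_invalid_inputs_rejected(self):
        a = _trajectory(np.random.default_rng(0))
        with pytest.raises(ValueError):
            trajectory_similarity(a, a, mode="diagonal")
        with pytest.raises(ValueError):
            trajectory_similarity(a, a, scale=np.zeros(4))
        with pytest.raises(ValueError):
            FeatureTrajectory(pitch=[], fm=[], wiener_entropy=[], pitch_goodness=[])


class TestStabilizeSampleCount:
    def test_identical_scores_return_start(self):
        items = list(range(30))
        res = stabilize_sample_count(items, lambda i, j: (85.0, 80.0))
        assert res.n == 10
        assert res.stabilized

    def test_converging_means_settle_at_30(self):
        # per-item scores drift over the first 30 items, after which every
        # new item sits at the settled batch mean, so the running
        # off-diagonal mean stops changing exactly at n = 30
        head = np.linspace(40, 80, 30)
        values = np.concatenate([head, np.full(15, head.mean())])

        def score(i, j):
            v = (values[i] + values[j]) / 2
            return v, v

        res = stabilize_sample_count(list(range(45)), score, tol=0.5)
        assert res.stabilized
        assert res.n == 30

    def test_never_stabilizes_warns_and_uses_all(self):
        values = np.arange(40) * 3.0  # mean keeps drifting

        def score(i, j):
            return min(values[i], 100.0), min(values[j], 100.0)

        with pytest.warns(UserWarning, match="did not stabilize"):
            res = stabilize_sample_count(list(range(40)), score, tol=0.5)
        assert res.n == 40
        assert not res.stabilized

    def test_shuffle_changes_trace_but_not_n_by_much(self):
        rng = np.random.default_rng(5)
        base = 75 + rng.normal(0, 0.05, 60)  # low-variance set

        def make_fn(order):
            def score(i, j):
                return base[order[i]], base[order[j]]
            return score

        ns = []
        for k in range(20):
            order = np.random.default_rng(k).permutation(60)
            res = stabilize_sample_count(list(range(60)), make_fn(order), tol=0.5)
            ns.append(res.n)
        assert max(ns) - min(ns) <= 5  # at most one step of spread
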