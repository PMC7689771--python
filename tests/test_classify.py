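"""Labeling schemes, training protocol, chance statistics and LOPOCV."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from mwdecode.classify import (assign_labels, attach_probe_ratings,
                               corrected_chance_level, cross_task_predict,
                               evaluate_vs_chance, prepare_training,
                               run_lopocv, train_svm)
from tests.conftest import make_feature_dataset


class TestProbeWindow:
    def test_probe_labels_exactly_three_preceding_trials(self):
        trials = pd.DataFrame({
            "participant": ["P0"] * 6,
            "task": ["VS"] * 6,
            "onset_sample": [100, 200, 300, 400, 500, 600],
        })
        probes = pd.DataFrame({
            "participant": ["P0"], "task": ["VS"],
            "onset_sample": [650], "rating": [5],
        })
        out = attach_probe_ratings(trials, probes)
        assert out["rating"].tolist()[:3] == [np.nan] * 3 or \
            out["rating"].isna().tolist()[:3] == [True] * 3
        assert out["rating"].tolist()[3:] == [5.0, 5.0, 5.0]

    def test_two_probes_two_windows(self):
        trials = pd.DataFrame({
            "participant": ["P0"] * 8,
            "task": ["VS"] * 8,
            "onset_sample": np.arange(8) * 100,
        })
        probes = pd.DataFrame({
            "participant": ["P0", "P0"], "task": ["VS", "VS"],
            "onset_sample": [350, 750], "rating": [-2, 4],
        })
        out = attach_probe_ratings(trials, probes)
        assert out["rating"].tolist()[1:4] == [-2.0] * 3
        assert out["rating"].tolist()[5:8] == [4.0] * 3
        assert np.isnan(out["rating"].iloc[0])


class TestAssignLabels:
    def _table(self):
        rows = []
        for p in ("P0", "P1"):
            for i in range(420):
                rows.append(dict(
                    participant=p, task="VS",
                    condition="counting" if (i // 21) % 2 == 0
                    else "noncounting",
                    block=i // 21, onset_sample=i * 100, rating=np.nan,
                ))
        df = pd.DataFrame(rows)
        df.loc[0:2, "rating"] = -3.0
        df.loc[21:23, "rating"] = 2.0
        df.loc[42:44, "rating"] = 0.0
        return df

    def test_selfreport_thresholds(self):
        ls = assign_labels(self._table(), "selfreport")
        # -3 -> mind-wandering (1), +2 -> on-task (0), 0 -> excluded
        assert len(ls) == 6
        assert ls.y[:3].tolist() == [1, 1, 1]
        assert ls.y[3:].tolist() == [0, 0, 0]

    def test_demand_polarity(self):
        ls = assign_labels(self._table(), "demand")
        t = self._table().iloc[ls.indices]
        assert np.all(ls.y[(t["condition"] == "counting").to_numpy()] == 0)
        assert np.all(ls.y[(t["condition"] == "noncounting").to_numpy()] == 1)

    def test_vigilance_median_split_is_even(self):
        ls = assign_labels(self._table(), "vigilance")
        for p in ("P0", "P1"):
            y = ls.y[ls.participants == p]
            assert len(y) == 420
            assert y.sum() == 210

    def test_sart_only_selfreport(self):
        df = self._table()
        df["task"] = "SART"
        with pytest.raises(ValueError):
            assign_labels(df, "demand", task="SART")

    def test_unknown_scheme_rejected(self):
        with pytest.raises(ValueError):
            assign_labels(self._table(), "arousal")


class TestPrepareTraining:
    def test_oversampling_to_parity(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(140, 5))
        y = np.array([0] * 100 + [1] * 40)
        prep = prepare_training(X, y, seed=1)
        assert (prep.y == 0).sum() == 100
        assert (prep.y == 1).sum() == 100
        # majority indices preserved exactly, minority only duplicated
        assert np.array_equal(prep.indices[:140], np.arange(140))
        assert np.all(prep.indices[140:] >= 100)

    def test_scaler_zscores_training_sample(self):
        rng = np.random.default_rng(1)
        X = rng.normal(3.0, 2.0, size=(200, 4))
        y = np.array([0, 1] * 100)
        prep = prepare_training(X, y, seed=0)
        Z = prep.scaler.transform(X)
        assert np.allclose(Z.mean(axis=0), 0.0, atol=1e-9)
        assert np.allclose(Z.std(axis=0), 1.0, atol=1e-9)

    def test_balanced_input_is_identity(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(60, 3))
        y = np.array([0, 1] * 30)
        prep = prepare_training(X, y, seed=0)
        assert np.array_equal(prep.indices, np.arange(60))

    def test_reproducible_given_seed(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(50, 3))
        y = np.array([0] * 40 + [1] * 10)
        a = prepare_training(X, y, seed=7)
        b = prepare_training(X, y, seed=7)
        assert np.array_equal(a.indices, b.indices)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            prepare_training(np.zeros((10, 2)), np.zeros(10), seed=0)

    def test_zero_variance_features_dropped(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(40, 3))
        X[:, 1] = 5.0
        y = np.array([0, 1] * 20)
        prep = prepare_training(X, y, seed=0)
        assert prep.scaler.n_dropped == 1
        assert prep.X.shape[1] == 2


class TestCorrectedChance:
    def test_enumeration_oracle_n10(self):
        # Binomial(10, .5): P(X>=9) = 11/1024 < .05 < P(X>=8) = 56/1024,
        # so the inverse-CDF threshold (largest still-compatible count) is 8
        assert corrected_chance_level(10, 0.05) == pytest.approx(0.8)

    def test_printed_study_values(self):
        assert round(100 * corrected_chance_level(11436, 0.05), 2) == 50.77
        assert round(100 * corrected_chance_level(1494, 0.05), 2) == 52.14

    @pytest.mark.parametrize("n", [50, 500, 5000])
    def test_monte_carlo_cross_check(self, n):
        rng = np.random.default_rng(123)
        draws = rng.binomial(n, 0.5, size=100_000) / n
        mc = np.quantile(draws, 0.95)
        assert abs(corrected_chance_level(n, 0.05) - mc) < 0.002

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(st.integers(min_value=1, max_value=20000))
    def test_above_half_and_shrinks_toward_half(self, n):
        c = corrected_chance_level(n, 0.05)
        assert 0.5 <= c <= 1.0
        assert corrected_chance_level(4 * n, 0.05) <= c + 1e-12

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            corrected_chance_level(0, 0.05)
        with pytest.raises(ValueError):
            corrected_chance_level(100, 1.5)


class TestEvaluateVsChance:
    def test_all_at_chance(self):
        r = evaluate_vs_chance(np.array([0.52, 0.52, 0.52]), 0.52)
        assert r.t == 0.0 and r.p == 1.0

    def test_hand_computed_three_values(self):
        acc = np.array([0.6, 0.7, 0.8])
        r = evaluate_vs_chance(acc, 0.5)
        # mean .7, sd .1 -> t = .2 / (.1/sqrt(3)) = 3.4641, df = 2
        assert r.df == 2
        assert r.t == pytest.approx(2.0 * np.sqrt(3.0), rel=1e-6)
        assert r.p == pytest.approx(
            2 * stats.t.sf(2.0 * np.sqrt(3.0), 2), rel=1e-6)

    def test_sensitivity_specificity_from_confusion(self):
        # model always predicts the positive (mind-wandering) class
        r = evaluate_vs_chance(np.array([0.4, 0.5]), 0.5,
                               confusion=(0, 10, 0, 10))
        assert r.sensitivity == 1.0 and r.specificity == 0.0

    def test_zero_variance_off_chance_flagged(self):
        r = evaluate_vs_chance(np.array([0.9, 0.9]), 0.5)
        assert r.degenerate and np.isinf(r.t)


class TestSVM:
    def test_separable_blobs(self):
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(-3, 0.3, (50, 4)),
                       rng.normal(3, 0.3, (50, 4))])
        y = np.array([0] * 50 + [1] * 50)
        model = train_svm(prepare_training(X, y, seed=0))
        assert (model.predict(X) == y).mean() >= 0.99
        assert model.gamma == 0.25

    def test_duplication_invariance(self):
        rng = np.random.default_rng(1)
        X = np.vstack([rng.normal(-2, 0.5, (30, 3)),
                       rng.normal(2, 0.5, (30, 3))])
        y = np.array([0] * 30 + [1] * 30)
        grid = rng.normal(0, 2.5, size=(200, 3))
        m1 = train_svm(prepare_training(X, y, seed=0))
        m2 = train_svm(prepare_training(np.vstack([X, X]),
                                        np.hstack([y, y]), seed=0))
        assert np.array_equal(m1.predict(grid), m2.predict(grid))

    def test_random_labels_score_at_chance(self):
        from mwdecode.classify import _inner_cv_accuracies

        rng = np.random.default_rng(2)
        means = []
        for s in range(20):
            X = rng.normal(size=(60, 5))
            y = rng.integers(0, 2, size=60)
            if y.min() == y.max():
                continue
            accs, _ = _inner_cv_accuracies(X, y, seed=s, n_splits=5)
            means.append(np.mean(accs))
        # 3 binomial sd of the pooled estimate around 0.5
        sd = 0.5 / np.sqrt(len(means) * 60)
        assert abs(np.mean(means) - 0.5) < 3 * sd + 0.02


class TestLOPOCV:
    def test_one_accuracy_per_participant(self, feature_dataset):
        run = run_lopocv(feature_dataset, "demand", seed=0, inner_cv=False,
                         transfer=False)
        n_parts = feature_dataset.trials["participant"].nunique()
        assert len(run.lopocv.accuracies) <= n_parts
        assert len(set(run.lopocv.fold_ids)) == len(run.lopocv.fold_ids)

    def test_injected_effects_are_decodable(self, feature_dataset):
        for scheme in ("demand", "vigilance", "selfreport"):
            run = run_lopocv(feature_dataset, scheme, seed=0, inner_cv=False,
                             transfer=False)
            assert run.lopocv.mean_accuracy > run.lopocv.chance, scheme

    def test_attention_effect_transfers_to_sart(self, feature_dataset):
        run = run_lopocv(feature_dataset, "selfreport", seed=0,
                         inner_cv=False, transfer=True)
        assert run.transfer is not None
        assert run.transfer.mean_accuracy > run.transfer.chance

    def test_no_leakage_from_held_out_participant(self):
        fm = make_feature_dataset(seed=9, demand_effect=1.0)
        run1 = run_lopocv(fm, "demand", seed=3, inner_cv=False,
                          transfer=False)
        # corrupt one participant's features; models fitted without that
        # participant must be bit-identical
        part = run1.lopocv.fold_ids[0]
        fm2 = make_feature_dataset(seed=9, demand_effect=1.0)
        rows = fm2.trials["participant"] == part
        fm2.values[rows.to_numpy()] = 0.0
        run2 = run_lopocv(fm2, "demand", seed=3, inner_cv=False,
                          transfer=False)
        m1 = next(m for m in run1.models if m.manifest["held_out"] == part)
        m2 = next(m for m in run2.models if m.manifest["held_out"] == part)
        assert np.array_equal(m1.svc.dual_coef_, m2.svc.dual_coef_)
        assert np.array_equal(m1.svc.support_, m2.svc.support_)

    def test_label_permutation_sits_at_chance(self):
        fm = make_feature_dataset(seed=5, demand_effect=1.5)
        rng = np.random.default_rng(0)
        t = fm.trials
        for p, grp in t.groupby("participant"):
            vs = grp[grp["task"] == "VS"]
            perm = rng.permutation(vs.index)
            t.loc[vs.index, "condition"] = t.loc[perm, "condition"].to_numpy()
        run = run_lopocv(fm, "demand", seed=0, inner_cv=False, transfer=False)
        # never above the corrected chance; CV on null data is allowed its
        # usual slight pessimistic (below-0.5) bias
        assert 0.35 <= run.lopocv.mean_accuracy <= run.lopocv.chance

    def test_too_few_participants_rejected(self):
        fm = make_feature_dataset(seed=0, n_participants=2)
        with pytest.raises(ValueError):
            run_lopocv(fm, "demand", seed=0)


class TestCrossTask:
    def test_scheme_mismatch_rejected(self, feature_dataset):
        run = run_lopocv(feature_dataset, "demand", seed=0, inner_cv=False,
                         transfer=False)
        sart = assign_labels(feature_dataset.trials, "selfreport",
                             task="SART")
        sart.scheme = "demand"
        with pytest.raises(ValueError):
            cross_task_predict(run.models[0], feature_dataset, sart)

    def test_featureless_data_raises_degenerate_error(self):
        fm = make_feature_dataset(seed=1)
        fm.values[:] = 0.0
        with pytest.raises(ValueError):
            run_lopocv(fm, "demand", seed=0, inner_cv=False, transfer=False)

    def test_per_participant_report(self, feature_dataset):
        run = run_lopocv(feature_dataset, "demand", seed=0, inner_cv=False,
                         transfer=False)
        sart = assign_labels(feature_dataset.trials, "selfreport",
                             task="SART")
        rep = cross_task_predict(run.models[0], feature_dataset, sart)
        assert rep.kind == "transfer"
        assert rep.n_test == len(sart)
        assert len(rep.accuracies) == len(set(sart.participants))
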