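"""mRMR selection and easy-ensemble classification."""

import numpy as np
import pandas as pd
import pytest
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import mutual_info_score
from sklearn.preprocessing import StandardScaler

from radrepeat.modeling import (
    EasyEnsembleClassifier,
    ModelConfig,
    MRMRSelector,
    mrmr_rank,
    train_easy_ensemble,
)
from radrepeat.reliability import auc


def informative_data(rng, n=100, prevalence=0.5, n_noise=3):
    y = (rng.random(n) < prevalence).astype(int)
    f = y + rng.normal(0, 0.8, size=n)       # informative
    g = 0.5 * y + rng.normal(0, 1.0, size=n)  # weaker
    cols = {"f": f, "copy_of_f": f.copy(), "g": g}
    for i in range(n_noise):
        cols[f"noise{i}"] = rng.normal(size=n)
    return pd.DataFrame(cols), y


def exhaustive_mrmr_trace(X, y, n_select):
    """Independent brute-force mRMR (MID): re-evaluates every candidate
    score at every step from scratch."""
    def disc(x):
        mu, sd = x.mean(), x.std()
        return np.digitize(x, [mu - sd, mu + sd])

    names = list(X.columns)
    D = {c: disc(X[c].to_numpy()) for c in names}
    rel = {c: mutual_info_score(y, D[c]) for c in names}
    chosen = []
    while len(chosen) < n_select:
        best, best_score = None, None
        for c in sorted(set(names) - set(chosen)):
            red = (np.mean([mutual_info_score(D[c], D[s]) for s in chosen])
                   if chosen else 0.0)
            score = rel[c] - red
            if best_score is None or score > best_score + 1e-15:
                best, best_score = c, score
        chosen.append(best)
    return chosen


class TestMRMR:
    def test_single_candidate(self):
        rng = np.random.default_rng(0)
        X, y = informative_data(rng)
        assert mrmr_rank(X, y, ["g"], 1) == ["g"]

    def test_duplicate_never_ranked_second(self):
        """A bit-identical copy of the top feature carries maximal
        redundancy, so the weaker independent feature is picked second."""
        rng = np.random.default_rng(1)
        X, y = informative_data(rng)
        ranked = mrmr_rank(X, y, ["f", "copy_of_f", "g"], 3)
        assert ranked[0] in ("f", "copy_of_f")
        assert ranked[1] == "g"

    @pytest.mark.parametrize("seed", [2, 3, 4])
    def test_greedy_trace_matches_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        X, y = informative_data(rng, n_noise=4)  # 7 candidates
        ranked = mrmr_rank(X, y, list(X.columns), 5)
        assert ranked == exhaustive_mrmr_trace(X, y, 5)

    def test_n_select_exceeding_candidates_rejected(self):
        rng = np.random.default_rng(5)
        X, y = informative_data(rng)
        with pytest.raises(ValueError, match="exceeds"):
            mrmr_rank(X, y, ["f", "g"], 3)

    def test_sklearn_estimator_interface(self):
        rng = np.random.default_rng(6)
        X, y = informative_data(rng)
        sel = MRMRSelector(n_selected=2)
        assert sel.get_params()["n_selected"] == 2
        sel.fit(X, y)
        assert sel.get_support().sum() == 2
        assert sel.transform(X).shape == (len(X), 2)


class TestEasyEnsemble:
    def test_balanced_single_round_equals_plain_fit(self):
        """On balanced data with n_ensemble=1 the ensemble is one
        standard fit on all (standardized) samples."""
        rng = np.random.default_rng(0)
        X, y = informative_data(rng, n=60, prevalence=0.5)
        Xa = X.to_numpy()
        while y.sum() * 2 != len(y):  # force exact balance
            flip = rng.integers(len(y))
            y[flip] = 1 - y[flip]
        ens = EasyEnsembleClassifier(n_ensemble=1, random_state=0).fit(Xa, y)
        ref = LogisticRegression(max_iter=2000).fit(StandardScaler().fit_transform(Xa), y)
        np.testing.assert_allclose(
            ens.predict_proba(Xa)[:, 1],
            ref.predict_proba(StandardScaler().fit_transform(Xa))[:, 1],
            atol=1e-6)

    def test_members_see_balanced_subsamples(self):
        """10 majority vs 5 minority: every member trains on 5+5."""
        rng = np.random.default_rng(1)
        X = rng.normal(size=(15, 3))
        y = np.array([0] * 10 + [1] * 5)
        ens = EasyEnsembleClassifier("gaussian_naive_bayes", n_ensemble=7,
                                     random_state=0).fit(X, y)
        for member in ens.estimators_:
            np.testing.assert_array_equal(member.class_count_, [5.0, 5.0])

    def test_probability_bounds_and_averaging(self):
        rng = np.random.default_rng(2)
        X, y = informative_data(rng, n=80, prevalence=0.3)
        cfg = ModelConfig("logistic_regression", n_selected=2, n_ensemble=9, seed=1)
        bundle = train_easy_ensemble(X, y, cfg, selected=["f", "g"])
        p = bundle.predict_proba(X)
        assert np.all((p >= 0) & (p <= 1))
        members = bundle.ensemble.estimators_
        scaler = bundle.ensemble.scaler_
        manual = np.mean([m.predict_proba(scaler.transform(X[["f", "g"]]))[:, 1]
                          for m in members], axis=0)
        np.testing.assert_allclose(p, manual, atol=1e-12)

    def test_missing_descriptor_named_in_error(self):
        rng = np.random.default_rng(3)
        X, y = informative_data(rng)
        cfg = ModelConfig(n_selected=1, n_ensemble=2, seed=0)
        bundle = train_easy_ensemble(X, y, cfg, selected=["f"])
        with pytest.raises(KeyError, match="f"):
            bundle.predict_proba(X.drop(columns=["f"]).rename(columns={"g": "h"}))

    def test_deterministic_replay(self):
        rng = np.random.default_rng(4)
        X, y = informative_data(rng, n=60, prevalence=0.25)
        cfg = ModelConfig("random_forest", n_selected=2, n_ensemble=5, seed=7)
        p1 = train_easy_ensemble(X, y, cfg, ["f", "g"]).predict_proba(X)
        p2 = train_easy_ensemble(X, y, cfg, ["f", "g"]).predict_proba(X)
        np.testing.assert_array_equal(p1, p2)

    def test_single_class_rejected(self):
        X = np.random.default_rng(5).normal(size=(10, 2))
        with pytest.raises(ValueError, match="two classes"):
            EasyEnsembleClassifier(n_ensemble=1).fit(X, np.zeros(10, dtype=int))

    @pytest.mark.parametrize("kind", ["logistic_regression", "svm",
                                      "random_forest", "gaussian_naive_bayes"])
    def test_all_classifier_kinds_fit_and_predict(self, kind):
        rng = np.random.default_rng(8)
        X, y = informative_data(rng, n=50, prevalence=0.3)
        ens = EasyEnsembleClassifier(kind, n_ensemble=3, random_state=0)
        ens.fit(X[["f", "g"]].to_numpy(), y)
        p = ens.predict_proba(X[["f", "g"]].to_numpy())
        assert p.shape == (50, 2)
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-9)

    def test_ensemble_improves_minority_sensitivity(self):
        """On imbalanced data the balanced ensemble beats a single plain
        fit on raw data more often than not over 20 seeds (AUC on an
        independent test set)."""
        wins = 0
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            X, y = informative_data(rng, n=120, prevalence=0.15)
            Xt, yt = informative_data(rng, n=200, prevalence=0.15)
            if yt.sum() < 2 or y.sum() < 2:
                continue
            cols = ["f", "g"]
            ens = EasyEnsembleClassifier("gaussian_naive_bayes", n_ensemble=25,
                                         random_state=seed).fit(X[cols].to_numpy(), y)
            from sklearn.naive_bayes import GaussianNB

            single = GaussianNB().fit(X[cols].to_numpy(), y)
            a_ens = auc(yt, ens.predict_proba(Xt[cols].to_numpy())[:, 1])
            a_single = auc(yt, single.predict_proba(Xt[cols].to_numpy())[:, 1])
            wins += a_ens >= a_single
        assert wins >= 10

    def test_large_ensemble_stabilizes_across_seeds(self):
        """Two 500-member ensembles with different seeds give test AUCs
        within 0.02 of each other."""
        rng = np.random.default_rng(9)
        X, y = informative_data(rng, n=150, prevalence=0.2)
        Xt, yt = informative_data(rng, n=150, prevalence=0.2)
        cols = ["f", "g"]
        aucs = []
        for seed in (1, 2):
            ens = EasyEnsembleClassifier("logistic_regression", n_ensemble=500,
                                         random_state=seed).fit(X[cols].to_numpy(), y)
            aucs.append(auc(yt, ens.predict_proba(Xt[cols].to_numpy())[:, 1]))
        assert abs(aucs[0] - aucs[1]) < 0.02
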