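"""Labeling, scaling, selection, search, LOSO evaluation and attribution."""

import numpy as np
import pandas as pd
import pytest

from nocisense.features import FEATURE_REGISTRY, METADATA_COLUMNS
from nocisense.ml import (
    DEFAULT_GRIDS,
    LabelSpec,
    attribute_features,
    compute_metrics,
    halving_search,
    loso_cv,
    make_labels,
    rfe_select,
    subject_scale,
    train_final,
)


def toy_table(n_subjects=8, n_trials=8, n_features=6, effect=2.0, seed=0):
    """Small feature table with one informative feature tied to level."""
    rng = np.random.default_rng(seed)
    rows = []
    tgi = [0, 2, 1]
    tens = [2, 0, 1, 3, 4]
    for s in range(n_subjects):
        offset = rng.normal(0, 1)
        for trial in range(n_trials):
            modality = "TGI" if trial < 3 else "TENS"
            level = tgi[trial] if trial < 3 else tens[trial - 3]
            pain = min(10, max(0, int(round(2.0 * level + rng.normal(0, 0.5)))))
            anx = min(10, max(0, int(round(1.5 * level + rng.normal(0, 0.5)))))
            for phase in ("anticipation", "stimulation"):
                row = {
                    "subject_id": f"S{s}", "trial_index": trial,
                    "modality": modality, "level": level, "phase": phase,
                    "anxiety_vas": anx, "pain_vas": pain,
                }
                for j in range(n_features):
                    base = rng.normal(offset, 1.0)
                    if j == 0 and phase == "stimulation":
                        base += effect * level
                    row[f"f{j}"] = base
                rows.append(row)
    return pd.DataFrame(rows)


class TestMakeLabels:
    def test_pain_vas_rule(self):
        t = toy_table(n_subjects=3)
        t.loc[t.index[:6], "pain_vas"] = [6, 6, 0, 0, 3, 3]
        out = make_labels(t, LabelSpec(target="pain_vas"))
        assert set(out["phase"]) == {"stimulation"}
        merged = out.merge(t.drop_duplicates(["subject_id", "trial_index"]),
                           on=["subject_id", "trial_index"], suffixes=("", "_y"))
        assert ((merged["pain_vas"] >= 5) == (merged["label"] == 1)).all()
        assert not (set(out["pain_vas"]) & set(range(1, 5)))  # middle excluded

    def test_stim_level_rule(self):
        out = make_labels(toy_table(), LabelSpec.for_target("stim_level"))
        assert set(out.loc[out.label == 0, "level"]) == {0}
        assert set(out.loc[out.label == 1, "level"]) <= {2, 3, 4}
        assert 1 not in set(out["level"])

    def test_prev_pain_uses_previous_trial_in_block(self):
        t = toy_table(n_subjects=2)
        out = make_labels(t, LabelSpec(target="prev_pain_vas"))
        assert set(out["phase"]) == {"anticipation"}
        # first trial of each block has no previous and is dropped
        assert 0 not in set(out["trial_index"])  # first TGI trial
        assert 3 not in set(out["trial_index"])  # first TENS trial
        # every labeled row agrees with the block predecessor's pain score
        pain = t.drop_duplicates(["subject_id", "trial_index"]).set_index(
            ["subject_id", "trial_index"])["pain_vas"]
        for _, row in out.iterrows():
            prev = pain[(row.subject_id, row.trial_index - 1)]
            expected = 1 if prev >= 5 else (0 if prev <= 0 else None)
            assert expected is not None  # middle predecessors were excluded
            assert row.label == expected

    def test_unknown_target_rejected(self):
        with pytest.raises(ValueError):
            LabelSpec(target="nope")


class TestSubjectScale:
    def test_mean_zero_unit_sd(self):
        t = toy_table()
        out = subject_scale(t)
        g = out.groupby("subject_id")["f0"]
        assert np.abs(g.mean()).max() < 1e-9
        assert np.abs(g.std(ddof=0) - 1.0).max() < 1e-9

    def test_subject_constant_feature_zeroed(self):
        t = toy_table(n_subjects=3)
        t["f1"] = 7.0
        out = subject_scale(t)
        assert (out["f1"] == 0.0).all()

    def test_affine_invariance(self):
        t = toy_table(n_subjects=3)
        t2 = t.copy()
        t2["f0"] = 3.5 * t2["f0"] - 11.0
        pd.testing.assert_series_equal(subject_scale(t)["f0"],
                                       subject_scale(t2)["f0"], atol=1e-9)

    def test_single_row_subject_rejected(self):
        t = toy_table(n_subjects=2)
        t = pd.concat([t, t.iloc[[0]].assign(subject_id="LONE")])
        with pytest.raises(ValueError, match="one row"):
            subject_scale(t)


class TestRfeSelect:
    def test_planted_feature_recovered(self):
        t = toy_table(n_subjects=8, effect=3.0)
        lab = make_labels(t, LabelSpec.for_target("stim_level"))
        sc = subject_scale(lab)
        feats = [c for c in sc.columns if c.startswith("f")]
        X = sc[feats].to_numpy()
        y = sc["label"].to_numpy(int)
        g = sc["subject_id"].to_numpy()
        selected = rfe_select("lr", X, y, g, feats, seed=0)
        assert "f0" in selected

    def test_deterministic(self):
        t = toy_table(n_subjects=6, effect=1.0)
        lab = make_labels(t, LabelSpec.for_target("stim_level"))
        sc = subject_scale(lab)
        feats = [c for c in sc.columns if c.startswith("f")]
        args = (sc[feats].to_numpy(), sc["label"].to_numpy(int),
                sc["subject_id"].to_numpy(), feats)
        assert rfe_select("lr", *args, seed=3) == rfe_select("lr", *args, seed=3)

    def test_single_class_rejected(self):
        X = np.random.default_rng(0).normal(size=(20, 4))
        y = np.zeros(20, dtype=int)
        g = np.repeat(np.arange(4), 5)
        with pytest.raises(ValueError):
            rfe_select("lr", X, y, g, [f"f{i}" for i in range(4)])


class TestHalvingSearch:
    @staticmethod
    def _data(seed=0):
        t = toy_table(n_subjects=8, effect=2.0, seed=seed)
        lab = make_labels(t, LabelSpec.for_target("stim_level"))
        sc = subject_scale(lab)
        feats = [c for c in sc.columns if c.startswith("f")]
        return (sc[feats].to_numpy(), sc["label"].to_numpy(int),
                sc["subject_id"].to_numpy())

    def test_single_point_grid_returned(self):
        X, y, g = self._data()
        assert halving_search("lr", X, y, g, grid={"C": [0.5]}) == {"C": 0.5}

    def test_empty_grid_rejected(self):
        X, y, g = self._data()
        with pytest.raises(ValueError, match="empty"):
            halving_search("lr", X, y, g, grid={"C": []})

    def test_near_exhaustive_on_small_grid(self):
        from nocisense.ml import _inner_bac

        X, y, g = self._data()
        grid = {"C": [0.003, 0.03, 0.3, 3.0], "fit_intercept": [True, False],
                "class_weight": [None, "balanced"]}  # 16 combos, sample 12
        best_exhaustive = max(
            _inner_bac("lr", X, y, g, 0, {"C": c, "fit_intercept": fi,
                                          "class_weight": cw})
            for c in grid["C"] for fi in grid["fit_intercept"]
            for cw in grid["class_weight"])
        for seed in (1, 2):
            params = halving_search("lr", X, y, g, seed=seed, grid=grid,
                                    n_candidates=12)
            bac = _inner_bac("lr", X, y, g, 0, params)
            assert bac >= best_exhaustive - 0.05

    def test_deterministic(self):
        X, y, g = self._data()
        a = halving_search("svm", X, y, g, seed=5)
        b = halving_search("svm", X, y, g, seed=5)
        assert a == b


class TestComputeMetrics:
    def test_perfect_separation(self):
        y = np.array([0, 0, 1, 1])
        s = np.array([0.1, 0.2, 0.8, 0.9])
        sens, spec, bac, auc, _ = compute_metrics(y, s)
        assert (sens, spec, bac, auc) == (1.0, 1.0, 1.0, 1.0)

    def test_bac_is_mean_of_sens_spec(self):
        # sensitivity 0.8, specificity 0.6 -> BAC 0.7
        y = np.array([1] * 5 + [0] * 5)
        s = np.array([0.9, 0.9, 0.9, 0.9, 0.1, 0.9, 0.9, 0.1, 0.1, 0.1])
        sens, spec, bac, _, _ = compute_metrics(y, s)
        assert sens == pytest.approx(0.8)
        assert spec == pytest.approx(0.6)
        assert bac == pytest.approx(0.7)

    def test_auc_equals_mann_whitney(self, rng):
        from scipy.stats import mannwhitneyu

        for _ in range(200):
            n1, n0 = rng.integers(3, 20, size=2)
            y = np.concatenate([np.ones(n1, int), np.zeros(n0, int)])
            s = rng.standard_normal(n1 + n0)
            *_, auc, _ = compute_metrics(y, s)
            u = mannwhitneyu(s[:n1], s[n1:], alternative="two-sided").statistic
            assert auc == pytest.approx(u / (n1 * n0), abs=1e-9)

    def test_auc_invariant_to_monotone_transform(self, rng):
        y = rng.integers(0, 2, size=50)
        y[:2] = [0, 1]
        s = rng.standard_normal(50)
        *_, auc1, _ = compute_metrics(y, s)
        *_, auc2, _ = compute_metrics(y, np.exp(3 * s) + 7)
        assert auc1 == pytest.approx(auc2, abs=1e-12)

    def test_roc_endpoints(self, rng):
        y = np.array([0, 1, 0, 1, 1])
        s = rng.standard_normal(5)
        *_, (fpr, tpr) = compute_metrics(y, s)
        assert (fpr[0], tpr[0]) == (0.0, 0.0)
        assert (fpr[-1], tpr[-1]) == (1.0, 1.0)
        assert (np.diff(fpr) >= 0).all() and (np.diff(tpr) >= 0).all()

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            compute_metrics(np.ones(5, int), np.random.rand(5))


class TestLosoCv:
    def test_partition_contract(self):
        t = toy_table(n_subjects=5, effect=2.0)
        cv = loso_cv(t, LabelSpec.for_target("stim_level"), "lr", seed=0,
                     do_search=False)
        subjects = [f.subject for f in cv.folds]
        assert len(subjects) == len(set(subjects)) == 5

    def test_strong_effect_high_auc(self):
        t = toy_table(n_subjects=8, effect=3.0)
        cv = loso_cv(t, LabelSpec.for_target("stim_level"), "lr", seed=0)
        assert cv.auc >= 0.85

    def test_determinism(self):
        t = toy_table(n_subjects=5, effect=2.0)
        a = loso_cv(t, LabelSpec.for_target("stim_level"), "lr", seed=4)
        b = loso_cv(t, LabelSpec.for_target("stim_level"), "lr", seed=4)
        assert a.to_dict() == b.to_dict()

    def test_too_few_subjects_rejected(self):
        t = toy_table(n_subjects=2)
        with pytest.raises(ValueError, match="subjects"):
            loso_cv(t, LabelSpec.for_target("stim_level"), "lr")


class TestTrainFinal:
    def test_features_subset_of_fold_union(self):
        t = toy_table(n_subjects=6, effect=2.0)
        spec = LabelSpec.for_target("stim_level")
        cv = loso_cv(t, spec, "lr", seed=1, do_search=False)
        final = train_final(t, spec, "lr", seed=1, cv=cv, do_search=False)
        union = {f for fold in cv.folds for f in fold.selected_features}
        assert set(final.selected_features) <= union

    def test_training_bac_at_least_loso_bac(self):
        t = toy_table(n_subjects=6, effect=3.0)
        spec = LabelSpec.for_target("stim_level")
        cv = loso_cv(t, spec, "lr", seed=1, do_search=False)
        final = train_final(t, spec, "lr", seed=1, cv=cv, do_search=False)
        sc = subject_scale(make_labels(t, spec))
        proba = final.predict_proba(sc)
        *_, bac, _, _ = compute_metrics(sc["label"].to_numpy(int), proba)
        assert bac >= cv.bac - 1e-9


class TestAttribution:
    @staticmethod
    def _fit(family="lr", effect=3.0):
        t = toy_table(n_subjects=6, effect=effect)
        spec = LabelSpec.for_target("stim_level")
        final = train_final(t, spec, family, seed=0, do_rfe=False,
                            do_search=False)
        sc = subject_scale(make_labels(t, spec))
        return final, sc

    def test_linear_closed_form(self):
        final, sc = self._fit("lr")
        out = attribute_features(final, sc)
        phi = out.attrs["attributions"]
        X = sc[final.selected_features].to_numpy(float)
        w = np.ravel(final.estimator.coef_)
        np.testing.assert_allclose(phi, (X - X.mean(axis=0)) * w, atol=1e-9)

    def test_efficiency_linear(self):
        # attributions live on the linear decision scale for linear models
        final, sc = self._fit("lr")
        out = attribute_features(final, sc)
        phi = out.attrs["attributions"]
        X = sc[final.selected_features].to_numpy(float)
        logits = final.estimator.decision_function(X)
        ref = final.estimator.decision_function(X.mean(axis=0, keepdims=True))[0]
        np.testing.assert_allclose(phi.sum(axis=1), logits - ref, atol=1e-6)

    def test_efficiency_sampled(self):
        final, sc = self._fit("rfc")
        out = attribute_features(final, sc, n_permutations=10, seed=0)
        phi = out.attrs["attributions"]
        X = sc[final.selected_features].to_numpy(float)
        from nocisense.ml import _raw_scores

        ref_score = _raw_scores(final.estimator,
                                X.mean(axis=0, keepdims=True))[0]
        scores = _raw_scores(final.estimator, X)
        np.testing.assert_allclose(phi.sum(axis=1), scores - ref_score,
                                   atol=0.05)

    def test_planted_feature_ranks_first(self):
        final, sc = self._fit("lr", effect=4.0)
        out = attribute_features(final, sc)
        assert out.index[0] == "f0"

    def test_absent_feature_rejected(self):
        final, sc = self._fit("lr")
        with pytest.raises(ValueError, match="absent"):
            attribute_features(final, sc.drop(columns=["f0"]))
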