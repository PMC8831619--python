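import numpy as np
import pandas as pd
import pytest

from metabscreen import (
    CANCER_CLASSES,
    LayeredScreen,
    ValidationError,
    classify_binary,
    predict_layered,
    predict_layered_matrix,
    score_binary,
    score_ovr,
    split_train_test,
    train_binary,
    train_ovr,
)
from metabscreen.models import MulticlassModel, TrainedBinaryModel, score_binary_matrix

from _util import make_matrix


def _manifest(counts):
    rows = [(f"{lbl[:2]}{i:03d}", lbl) for lbl, n in counts.items() for i in range(n)]
    return pd.DataFrame(rows, columns=["sample_id", "label"])


class TestSplit:
    def test_even_split(self):
        man = _manifest({"normal": 10})
        split = split_train_test(man, 0.5, seed=1)
        counts = pd.Series(split.assignment).value_counts()
        assert counts["train"] == 5 and counts["test"] == 5

    def test_study_scale_counts_within_one_of_halves(self):
        man = _manifest(
            {"normal": 250, "endometrial": 304, "breast": 303, "cervical": 250, "ovarian": 262}
        )
        split = split_train_test(man, 0.5, seed=3)
        assign = pd.Series(split.assignment)
        labels = man.set_index("sample_id")["label"]
        for lbl, n in labels.value_counts().items():
            n_train = (assign.loc[labels[labels == lbl].index] == "train").sum()
            assert abs(n_train - n / 2) <= 1

    def test_deterministic_and_seed_sensitive(self):
        man = _manifest({"normal": 30, "breast": 30})
        a = split_train_test(man, 0.5, seed=4).assignment
        b = split_train_test(man, 0.5, seed=4).assignment
        c = split_train_test(man, 0.5, seed=5).assignment
        assert a == b
        assert a != c

    def test_tiny_label_rejected(self):
        man = _manifest({"normal": 1, "breast": 10})
        with pytest.raises(ValidationError, match="normal"):
            split_train_test(man, 0.5, seed=1)


def _separable_training(n_per_class=10, seed=0):
    rng = np.random.default_rng(seed)
    pos = rng.normal(5.0, 0.3, size=(2, n_per_class))
    neg = rng.normal(0.0, 0.3, size=(2, n_per_class))
    vals = np.hstack([pos, neg])
    sids = [f"p{i}" for i in range(n_per_class)] + [f"n{i}" for i in range(n_per_class)]
    m = make_matrix(vals, sample_ids=sids)
    labels = pd.Series(
        ["cancer"] * n_per_class + ["normal"] * n_per_class, index=sids
    )
    return m, labels


class TestBinaryModel:
    def test_separable_training_set_classified_perfectly(self):
        m, labels = _separable_training()
        model = train_binary(m, labels)
        scores = score_binary_matrix(model, m)
        calls = scores.map(lambda s: classify_binary(s, model.threshold))
        assert (calls == labels.map(lambda v: v if v == "normal" else "cancer")).all()

    def test_balanced_weights_match_unweighted_on_balanced_classes(self):
        m, labels = _separable_training()
        a = train_binary(m, labels, weighting="balanced")
        b = train_binary(m, labels, weighting="none")
        np.testing.assert_allclose(a.coefficients, b.coefficients, atol=1e-6)

    def test_single_class_rejected(self):
        m, labels = _separable_training()
        with pytest.raises(ValidationError):
            train_binary(m, pd.Series("cancer", index=labels.index))

    def test_nonfinite_rejected(self):
        m, labels = _separable_training()
        m.values.iloc[0, 0] = np.nan
        with pytest.raises(ValidationError):
            train_binary(m, labels)

    def test_deterministic_coefficients(self):
        m, labels = _separable_training()
        a = train_binary(m, labels)
        b = train_binary(m, labels)
        assert (a.coefficients == b.coefficients).all()
        assert a.intercept == b.intercept and a.threshold == b.threshold

    def test_signature_enrichment_in_top_weights(self, small_cohort, small_fit):
        # planted cancer signatures should dominate the gate's largest weights
        _, _, _, truth = small_cohort
        model = small_fit["results"].binary_model
        planted = set().union(*(set(s) for s in truth.signature_map.values()))
        order = np.argsort(-np.abs(model.coefficients))
        top = [model.feature_ids[i] for i in order[: len(planted)]]
        overlap = len(planted & set(top))
        # hypergeometric expectation when drawing |planted| features blindly
        expected = len(planted) ** 2 / len(model.feature_ids)
        assert overlap > expected  # deeper margin exercised at cohort scale


class TestScoring:
    def test_intercept_only(self):
        model = TrainedBinaryModel(5.0, np.zeros(3), 0.0, "none", ("a", "b", "c"))
        assert score_binary(model, np.array([9.0, -2.0, 7.0])) == 5.0

    def test_linearity_in_one_feature(self):
        model = TrainedBinaryModel(1.0, np.array([2.0, -3.0]), 0.0, "none", ("a", "b"))
        x = np.array([1.0, 1.0])
        x2 = x.copy()
        x2[0] *= 2
        assert score_binary(model, x2) - score_binary(model, x) == pytest.approx(2.0 * 1.0)

    def test_matches_extended_precision_dot_product(self):
        rng = np.random.default_rng(8)
        coef = rng.normal(size=200)
        x = rng.normal(size=200)
        model = TrainedBinaryModel(
            0.37, coef, 0.0, "none", tuple(f"f{i}" for i in range(200))
        )
        import math

        expected = 0.37 + math.fsum(c * v for c, v in zip(coef, x))
        assert score_binary(model, x) == pytest.approx(expected, abs=1e-9)

    def test_length_mismatch_rejected(self):
        model = TrainedBinaryModel(0.0, np.zeros(3), 0.0, "none", ("a", "b", "c"))
        with pytest.raises(ValidationError):
            score_binary(model, np.zeros(4))

    def test_classify_boundary_strict(self):
        assert classify_binary(5.1, 5.0) == "cancer"
        assert classify_binary(5.0, 5.0) == "normal"

    def test_lower_threshold_never_decreases_sensitivity(self):
        rng = np.random.default_rng(1)
        scores = rng.normal(size=50)
        truth = rng.uniform(size=50) < 0.5
        last = -1.0
        for thr in [2.0, 1.0, 0.0, -1.0, -2.0]:
            sens = ((scores > thr) & truth).sum() / truth.sum()
            assert sens >= last
            last = sens


def _four_class_toy():
    # each class has one private marker feature
    n = 6
    vals = []
    labels = []
    for c, cls in enumerate(CANCER_CLASSES):
        block = np.zeros((4, n))
        block[c] = 5.0
        vals.append(block)
        labels += [cls] * n
    vals = np.hstack(vals) + np.random.default_rng(0).normal(0, 0.1, size=(4, 4 * n))
    sids = [f"s{i}" for i in range(4 * n)]
    m = make_matrix(vals, feature_ids=[f"marker_{c}" for c in CANCER_CLASSES], sample_ids=sids)
    return m, pd.Series(labels, index=sids)


class TestOVR:
    def test_components_find_their_markers(self):
        m, labels = _four_class_toy()
        model = train_ovr(m, labels)
        for cls in CANCER_CLASSES:
            comp = model.components[cls]
            best = comp.feature_ids[int(np.argmax(np.abs(comp.coefficients)))]
            assert best == f"marker_{cls}"

    def test_components_equal_independent_binary_fits(self):
        m, labels = _four_class_toy()
        model = train_ovr(m, labels)
        for cls in CANCER_CLASSES:
            relabeled = labels.map(lambda v: cls if v == cls else "rest")
            solo = train_binary(m, relabeled, positive_label=cls)
            np.testing.assert_array_equal(model.components[cls].coefficients, solo.coefficients)
            assert model.components[cls].intercept == solo.intercept

    def test_missing_class_rejected(self):
        m, labels = _four_class_toy()
        labels = labels.replace("ovarian", "breast")
        with pytest.raises(ValidationError, match="ovarian"):
            train_ovr(m, labels)

    def test_intercept_only_scores(self):
        comps = {
            cls: TrainedBinaryModel(float(i + 1), np.zeros(2), 0.0, "none", ("a", "b"))
            for i, cls in enumerate(CANCER_CLASSES)
        }
        model = MulticlassModel(components=comps, feature_ids=("a", "b"))
        scores = score_ovr(model, np.array([3.0, 4.0]))
        assert [scores[c] for c in CANCER_CLASSES] == [1.0, 2.0, 3.0, 4.0]

    def test_scores_match_dot_product_oracle(self):
        m, labels = _four_class_toy()
        model = train_ovr(m, labels)
        x = m.values.iloc[:, 0]
        scores = score_ovr(model, x)
        for cls in CANCER_CLASSES:
            comp = model.components[cls]
            assert scores[cls] == pytest.approx(
                comp.intercept + float(x.to_numpy() @ comp.coefficients), abs=1e-9
            )

    def test_feature_permutation_invariance(self):
        m, labels = _four_class_toy()
        model = train_ovr(m, labels)
        x = m.values.iloc[:, 3]
        perm = [2, 0, 3, 1]
        comps = {}
        for cls, comp in model.components.items():
            comps[cls] = TrainedBinaryModel(
                comp.intercept,
                comp.coefficients[perm],
                comp.threshold,
                comp.class_weighting,
                tuple(comp.feature_ids[i] for i in perm),
            )
        permuted = MulticlassModel(components=comps, feature_ids=comps["breast"].feature_ids)
        sp = score_ovr(permuted, x.iloc[perm])
        so = score_ovr(model, x)
        for cls in CANCER_CLASSES:
            assert sp[cls] == pytest.approx(so[cls], abs=1e-12)


class TestLayered:
    def _models(self):
        gate = TrainedBinaryModel(0.0, np.array([1.0, 0.0, 0.0, 0.0]), 0.5, "none",
                                  ("a", "b", "c", "d"))
        comps = {
            cls: TrainedBinaryModel(s, np.zeros(4), 0.0, "none", ("a", "b", "c", "d"))
            for cls, s in zip(CANCER_CLASSES, (0.2, 0.9, 0.1, 0.3))
        }
        return gate, MulticlassModel(components=comps, feature_ids=("a", "b", "c", "d"))

    def test_gate_negative_is_final(self):
        gate, m2 = self._models()
        pred = predict_layered(gate, m2, np.array([0.4, 0, 0, 0]), "s")
        assert pred.final_label == "normal"
        assert pred.stage2_scores is None

    def test_argmax_selects_breast(self):
        gate, m2 = self._models()
        pred = predict_layered(gate, m2, np.array([0.9, 0, 0, 0]), "s")
        assert pred.stage1_label == "cancer"
        assert pred.final_label == "breast"

    def test_gate_dominance_structural(self):
        with pytest.raises(ValidationError):
            from metabscreen import LayeredPrediction

            LayeredPrediction("s", 0.0, "normal", {"breast": 1.0}, "breast")

    def test_matrix_prediction_equals_manual_composition(self, small_fit):
        res = small_fit["results"]
        test = small_fit["completed"].subset_samples(small_fit["test_ids"][:20])
        frame = predict_layered_matrix(res.binary_model, res.ovr_model, test)
        for sid in test.sample_ids:
            manual = predict_layered(
                res.binary_model, res.ovr_model, test.values[sid], sid
            )
            assert frame.loc[sid, "final_label"] == manual.final_label
            assert frame.loc[sid, "stage1_score"] == pytest.approx(manual.stage1_score)

    def test_class_weighting_protects_minority_specificity(self):
        # 9:1 imbalance: balanced weighting keeps the specificity/sensitivity
        # gap small, unweighted fitting sacrifices the minority class
        # evaluated at the model's natural decision boundary (score > 0),
        # where the fitted class weights, not a re-tuned cutoff, must do
        # the balancing work
        rng = np.random.default_rng(12)
        n_pos, n_neg, p = 270, 30, 25
        X = np.hstack(
            [
                rng.normal(0.6, 1.0, size=(p, n_pos)),
                rng.normal(0.0, 1.0, size=(p, n_neg)),
            ]
        )
        sids = [f"s{i}" for i in range(n_pos + n_neg)]
        m = make_matrix(X, sample_ids=sids)
        labels = pd.Series(["cancer"] * n_pos + ["normal"] * n_neg, index=sids)
        Xt = np.hstack(
            [
                rng.normal(0.6, 1.0, size=(p, 300)),
                rng.normal(0.0, 1.0, size=(p, 300)),
            ]
        )
        mt = make_matrix(Xt, sample_ids=[f"t{i}" for i in range(600)])
        yt = np.array([True] * 300 + [False] * 300)

        def at_natural_threshold(weighting):
            model = train_binary(m, labels, weighting=weighting, threshold=0.0)
            s = score_binary_matrix(model, mt).to_numpy()
            pred = s > 0.0
            sens = (pred & yt).sum() / yt.sum()
            spec = (~pred & ~yt).sum() / (~yt).sum()
            return sens, spec

        sens_b, spec_b = at_natural_threshold("balanced")
        sens_u, spec_u = at_natural_threshold("none")
        assert abs(sens_b - spec_b) <= 0.10
        assert spec_b >= spec_u + 0.05

    def test_layered_screen_summary_reports_fit(self, small_fit):
        text = small_fit["results"].summary()
        assert "stage 1" in text
        assert "sensitivity" in text
        assert "threshold" in text
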