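import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cyanocount.classification import (
    ClassLabel,
    ConfusionMatrix,
    RuleThresholds,
    classify_rule,
    cross_validate,
    load_model,
    macro_average,
    metrics,
    save_model,
    train_svm,
)
from cyanocount.errors import ContractError, UndefinedMetricWarning
from cyanocount.morphology import ComponentFeatures
from cyanocount.synthdata import generate_feature_table


def feat(eccentricity, compactness, area_px=50):
    return ComponentFeatures(
        label=1, area_px=area_px, perimeter_px=10.0,
        eccentricity=eccentricity, compactness=compactness,
        convex_area_px=float(area_px), solidity=1.0, extent=0.8,
        centroid=(0.0, 0.0), area_um2=float(area_px),
    )


DEFAULTS = RuleThresholds()


class TestRuleCascade:
    def test_filamentous_representative_values(self):
        # high eccentricity, low compactness: the filamentous signature
        assert classify_rule(feat(0.8537, 0.6444), DEFAULTS) is (
            ClassLabel.ANABAENA
        )

    def test_unicellular_representative_values(self):
        # low eccentricity, high compactness: the round-unicell signature
        assert classify_rule(feat(0.5205, 0.9834), DEFAULTS) is (
            ClassLabel.MICROCYSTIS
        )

    def test_boundary_inclusivity_favours_filamentous(self):
        # at exactly (omega, tau) the >=/<= conjuncts of the A branch hold
        t = DEFAULTS
        assert classify_rule(feat(t.omega, t.tau), t) is ClassLabel.ANABAENA

    def test_area_window_excludes(self):
        t = RuleThresholds(psi_ml=10, psi_mu=20)
        assert classify_rule(feat(0.2, 1.5, area_px=50), t) is ClassLabel.NONE
        assert classify_rule(feat(0.2, 1.5, area_px=15), t) is (
            ClassLabel.MICROCYSTIS
        )

    def test_from_unit_areas_windows(self):
        t = RuleThresholds.from_unit_areas(60.0, 64.0)
        assert t.psi_ml == pytest.approx(15.0)
        assert t.psi_mu == pytest.approx(240.0)
        assert t.psi_al == pytest.approx(16.0)
        assert t.psi_au == pytest.approx(64 * 64.0)

    @given(
        eccentricity=st.floats(0, 1),
        compactness=st.floats(0.01, 3),
        area=st.integers(1, 10_000),
    )
    @settings(max_examples=200, deadline=None)
    def test_partition_exactly_one_class(self, eccentricity, compactness, area):
        """The cascade maps every feature tuple to exactly one class, and
        the A and M branch conditions are mutually exclusive."""
        t = RuleThresholds(psi_al=20, psi_au=5000, psi_ml=10, psi_mu=300)
        f = feat(eccentricity, compactness, area)
        label = classify_rule(f, t)
        in_a = (
            eccentricity >= t.omega and compactness <= t.tau
            and t.psi_al <= area <= t.psi_au
        )
        in_m = (
            eccentricity < t.omega and compactness > t.tau
            and t.psi_ml <= area <= t.psi_mu
        )
        assert not (in_a and in_m)
        assert label is {
            (True, False): ClassLabel.ANABAENA,
            (False, True): ClassLabel.MICROCYSTIS,
            (False, False): ClassLabel.NONE,
        }[(in_a, in_m)]

    def test_invalid_thresholds_rejected(self):
        with pytest.raises(ContractError):
            RuleThresholds(omega=1.5)
        with pytest.raises(ContractError):
            RuleThresholds(psi_al=10, psi_au=5)


def separable_set(n=60, seed=0):
    rng = np.random.default_rng(seed)
    a = rng.normal(0, 0.3, (n, 7))
    b = rng.normal(0, 0.3, (n, 7))
    b[:, 0] += 10.0  # separated in the first feature only
    X = np.vstack([a, b])
    y = np.array(["A"] * n + ["M"] * n)
    return X, y


class TestSvm:
    def test_separable_training_accuracy(self):
        X, y = separable_set()
        model = train_svm(X, y, seed=0)
        assert (np.array(model.predict(X)) == y).all()

    def test_duplication_invariance(self):
        X, y = separable_set(n=30)
        m1 = train_svm(X, y, seed=0)
        m2 = train_svm(np.vstack([X, X]), np.concatenate([y, y]), seed=0)
        probe = np.random.default_rng(1).normal(5, 3, (50, 7))
        assert m1.predict(probe) == m2.predict(probe)

    def test_contract_errors(self):
        X, y = separable_set(n=10)
        with pytest.raises(ContractError):
            train_svm(X, np.array(["A"] * len(y)))
        with pytest.raises(ContractError):
            train_svm(X[:, :5], y)
        Xbad = X.copy()
        Xbad[0, 0] = np.nan
        with pytest.raises(ContractError):
            train_svm(Xbad, y)

    def test_model_roundtrip(self, tmp_path):
        X, y = separable_set(n=20)
        model = train_svm(X, y, seed=0)
        p = tmp_path / "model.joblib"
        save_model(model, p)
        back = load_model(p)
        probe = np.random.default_rng(2).normal(5, 3, (20, 7))
        assert back.predict(probe) == model.predict(probe)


class TestCrossValidate:
    def test_perfectly_separable(self):
        X, y = separable_set()
        res = cross_validate(X, y, k=5, seed=0)
        assert res.accuracy == 1.0
        assert np.trace(res.matrix.counts) == res.matrix.total

    def test_each_instance_predicted_once(self):
        X, y = separable_set(n=25)
        res = cross_validate(X, y, k=5, seed=3)
        assert res.matrix.total == len(y)

    def test_shuffled_labels_hit_chance_level(self):
        table = generate_feature_table(n_per_class=100, seed=5)
        X = table.drop(columns="label").to_numpy()
        rng = np.random.default_rng(5)
        y = rng.permutation(table["label"].to_numpy())
        res = cross_validate(X, y, k=5, seed=5)
        assert res.accuracy == pytest.approx(1 / 3, abs=0.1)

    def test_benchmark_layout_total(self):
        table = generate_feature_table(n_per_class=272, seed=3)
        X = table.drop(columns="label").to_numpy()
        y = table["label"].to_numpy()
        res = cross_validate(X, y, k=5, seed=3)
        assert res.matrix.total == 816

    def test_small_class_error_names_class(self):
        X, y = separable_set(n=3)
        with pytest.raises(ContractError, match="'A'"):
            cross_validate(X, y, k=5)


class TestMetrics:
    def _matrix(self, tp, fn, fp, tn):
        return ConfusionMatrix(
            counts=np.array([[tp, fn], [fp, tn]]), class_names=["P", "N"]
        )

    def test_hand_arithmetic(self):
        m = metrics(self._matrix(tp=50, fn=0, fp=10, tn=40), "P")
        assert m.precision == pytest.approx(50 / 60, abs=1e-12)
        assert m.recall == 1.0
        assert m.f1 == pytest.approx(2 * (50 / 60) / (50 / 60 + 1), abs=1e-12)
        assert m.accuracy == pytest.approx(0.9, abs=1e-12)
        assert m.specificity == pytest.approx(0.8, abs=1e-12)
        assert m.sensitivity == m.recall

    def test_perfect_classifier_all_ones(self):
        m = metrics(self._matrix(tp=30, fn=0, fp=0, tn=70), "P")
        assert all(v == 1.0 for v in m.as_dict().values())

    def test_zero_denominator_flagged_not_zero(self):
        with pytest.warns(UndefinedMetricWarning):
            m = metrics(self._matrix(tp=0, fn=5, fp=0, tn=10), "P")
        assert np.isnan(m.precision)
        assert np.isnan(m.f1)

    def test_empty_matrix_rejected(self):
        with pytest.raises(ContractError):
            metrics(
                ConfusionMatrix(np.zeros((2, 2), int), ["P", "N"]), "P"
            )

    def test_f1_bounded_by_precision_and_recall(self, rng):
        for _ in range(200):
            counts = rng.integers(1, 50, (3, 3))
            cm = ConfusionMatrix(counts, ["A", "M", "K"])
            for cls in cm.class_names:
                m = metrics(cm, cls)
                if np.isfinite(m.f1):
                    assert min(m.precision, m.recall) - 1e-12 <= m.f1
                    assert m.f1 <= max(m.precision, m.recall) + 1e-12

    def test_accuracy_invariant_under_relabelling(self, rng):
        counts = rng.integers(0, 20, (3, 3))
        cm = ConfusionMatrix(counts, ["A", "M", "K"])
        perm = [2, 0, 1]
        cm2 = ConfusionMatrix(
            counts[np.ix_(perm, perm)], [cm.class_names[i] for i in perm]
        )
        assert cm.accuracy == cm2.accuracy

    def test_macro_average_between_extremes(self):
        cm = ConfusionMatrix(
            np.array([[8, 2], [1, 9]]), ["P", "N"]
        )
        per = [metrics(cm, c).f1 for c in cm.class_names]
        assert min(per) <= macro_average(cm).f1 <= max(per)
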