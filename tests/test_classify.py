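"""Proportion prediction and gamma-score classification."""

import numpy as np
import pytest

from deconfound.classify import (
    ABSTAIN,
    ClassificationStudyConfig,
    GroupModel,
    build_group_models,
    gamma_score,
    permutation_null_correlations,
    predict_proportions,
    run_classification_study,
    train_proportion_predictor,
    ttest_lda_baseline,
)
from deconfound.core import DeconfoundingConfig
from deconfound.matrices import (
    ConcentrationMatrix,
    ExpressionMatrix,
    SignatureMatrix,
    ValidationError,
)
from deconfound.simulate import SimulationConfig, simulate_dataset


def _training_fixture(n_samples=50, seed=0, noise=0.0):
    """Marker expression exactly linear in the target proportion."""
    rng = np.random.default_rng(seed)
    c = rng.uniform(0.2, 0.8, n_samples)
    markers = [f"m{i}" for i in range(4)]
    X = np.vstack([c * (6 + 2 * i) + (1 - c) * 2 for i in range(4)])
    X = np.clip(X + rng.normal(0, noise, X.shape), 0, None)
    Xm = ExpressionMatrix(X, markers, [f"s{j}" for j in range(n_samples)])
    Cm = ConcentrationMatrix(
        np.vstack([c, 1 - c]), ["CD3", "Other"], list(Xm.sample_ids)
    )
    return Xm, Cm, markers


class TestProportionPredictor:
    def test_easy_recovery(self):
        Xm, Cm, markers = _training_fixture()
        pred = train_proportion_predictor(Xm, Cm, markers, n_trees=300, seed=1)
        assert pred.oob_correlation > 0.95

    def test_constant_target_reports_nan(self):
        Xm, Cm, markers = _training_fixture()
        const = ConcentrationMatrix(
            np.full((2, Cm.n_samples), 0.5), ["CD3", "Other"], list(Cm.sample_ids)
        )
        pred = train_proportion_predictor(Xm, const, markers, n_trees=50, seed=2)
        assert np.isnan(pred.oob_correlation)
        p = predict_proportions(pred, Xm)
        np.testing.assert_allclose(p.sum(axis=1), 1.0)

    def test_too_few_samples_rejected(self):
        Xm, Cm, markers = _training_fixture(n_samples=3)
        with pytest.raises(ValidationError):
            train_proportion_predictor(Xm, Cm, markers)

    def test_predictions_are_valid_proportions(self):
        Xm, Cm, markers = _training_fixture(seed=3, noise=0.5)
        pred = train_proportion_predictor(Xm, Cm, markers, n_trees=100, seed=3)
        Xnew, _, _ = _training_fixture(n_samples=100, seed=4, noise=0.5)
        P = predict_proportions(pred, Xnew)
        assert P.shape == (100, 2)
        assert np.all(P >= 0) and np.all(P <= 1)
        np.testing.assert_allclose(P.sum(axis=1), 1.0)

    def test_missing_marker_rejected(self):
        Xm, Cm, markers = _training_fixture()
        pred = train_proportion_predictor(Xm, Cm, markers, n_trees=50, seed=5)
        with pytest.raises(ValidationError, match="m0"):
            predict_proportions(pred, {"m1": 1.0, "m2": 1.0, "m3": 1.0})

    def test_permutation_null_centred_at_zero(self):
        Xm, Cm, markers = _training_fixture(seed=6, noise=0.2)
        nulls = permutation_null_correlations(
            Xm, Cm, markers, n_permutations=40, n_trees=60, seed=7
        )
        assert abs(np.nanmean(nulls)) < 0.15


def _toy_models():
    genes = ["a", "b", "c"]
    S_a = SignatureMatrix(np.array([[2.0, 4.0], [1.0, 1.0], [5.0, 3.0]]), genes, ["CD3", "Other"])
    S_b = SignatureMatrix(np.array([[6.0, 8.0], [1.0, 1.0], [1.0, 1.0]]), genes, ["CD3", "Other"])
    cand = ["a", "c"]
    return GroupModel("A", S_a, cand), GroupModel("B", S_b, cand)


class TestGammaScore:
    def test_exact_match_predicts_that_group(self):
        ma, mb = _toy_models()
        c = np.array([0.5, 0.5])
        x = ma.S_hat.values @ c  # sample equals group A's prediction
        score = gamma_score(x, (ma, mb), c)
        assert score.gamma["A"] == 0.0
        assert score.predicted_group == "A"

    def test_equidistant_sample_abstains(self):
        ma, mb = _toy_models()
        c = np.array([0.5, 0.5])
        x = (ma.S_hat.values @ c + mb.S_hat.values @ c) / 2
        for rule in ("sum_abs", "majority"):
            assert gamma_score(x, (ma, mb), c, rule=rule).predicted_group == ABSTAIN

    def test_invalid_proportions_rejected(self):
        ma, mb = _toy_models()
        with pytest.raises(ValidationError):
            gamma_score(np.ones(3), (ma, mb), np.array([0.7, 0.7]))

    def test_per_group_proportions(self):
        ma, mb = _toy_models()
        x = ma.S_hat.values @ np.array([0.3, 0.7])
        score = gamma_score(
            x, (ma, mb), {"A": np.array([0.3, 0.7]), "B": np.array([0.5, 0.5])}
        )
        assert score.predicted_group == "A"

    def test_majority_counts_loci(self):
        ma, mb = _toy_models()
        c = np.array([0.5, 0.5])
        x = mb.S_hat.values @ c
        score = gamma_score(x, (ma, mb), c, rule="majority")
        assert score.gamma["B"] == 0.0 and score.gamma["A"] == 2.0
        assert score.predicted_group == "B"


class TestGroupModels:
    def test_identical_groups_yield_zero_candidate_stats(self, small_dataset):
        X = small_dataset.X["A"]
        cfg = DeconfoundingConfig(random_seed=8, max_iterations=25)
        ma, mb, (CA, CB) = build_group_models(X, X, small_dataset.markers, cfg, n_cand=5)
        np.testing.assert_allclose(ma.S_hat.values, mb.S_hat.values)
        np.testing.assert_array_equal(CA.values, CB.values)
        assert len(ma.candidate_gene_ids) == 5

    def test_n_cand_bounds(self, small_dataset):
        X = small_dataset.X["A"]
        with pytest.raises(ValidationError):
            build_group_models(X, X, small_dataset.markers, n_cand=X.n_genes + 1)


class TestLdaBaseline:
    def _groups(self, effect, seed=0, n=20, n_genes=50):
        rng = np.random.default_rng(seed)
        base = rng.uniform(4, 10, n_genes)
        A = np.clip(base[:, None] + rng.normal(0, 1, (n_genes, n)), 0, None)
        B = np.clip(base[:, None] + rng.normal(0, 1, (n_genes, n)), 0, None)
        B[:5] += effect
        ids = [f"g{i}" for i in range(n_genes)]
        return (
            ExpressionMatrix(A, ids, [f"a{j}" for j in range(n)]),
            ExpressionMatrix(B, ids, [f"b{j}" for j in range(n)]),
        )

    def test_separable_case_near_zero_error(self):
        A, B = self._groups(effect=8.0, seed=1)
        VA, VB = self._groups(effect=8.0, seed=2)
        X_val = ExpressionMatrix(
            np.concatenate([VA.values, VB.values], axis=1),
            list(VA.gene_ids),
            list(VA.sample_ids) + [f"v{j}" for j in range(VB.n_samples)],
        )
        labels = ["A"] * 20 + ["B"] * 20
        err = ttest_lda_baseline(A, B, 5, X_val, labels)
        assert err < 0.1

    def test_null_labels_near_chance(self):
        A, B = self._groups(effect=0.0, seed=3, n=30, n_genes=200)
        VA, VB = self._groups(effect=0.0, seed=4, n=50, n_genes=200)
        X_val = ExpressionMatrix(
            np.concatenate([VA.values, VB.values], axis=1),
            list(VA.gene_ids),
            [f"v{j}" for j in range(100)],
        )
        labels = ["A"] * 50 + ["B"] * 50
        err = ttest_lda_baseline(A, B, 10, X_val, labels)
        assert 0.3 <= err <= 0.7


def test_classification_study_smoke_and_determinism():
    cfg = ClassificationStudyConfig(
        sim=SimulationConfig(
            n_genes=400, n_diff=24, n_markers=10, delta_diff=2.0,
            de_pattern="reverse", n_samples_per_group=12,
        ),
        n_runs=2, n_validation_cases=10, n_cand=8, n_trees=50, seed=99,
    )
    t1 = run_classification_study(cfg)
    t2 = run_classification_study(cfg)
    assert t1.equals(t2)
    assert set(t1["method"]) == {"deconfounding", "ttest_lda"}
    assert ((t1["error_rate"] >= 0) & (t1["error_rate"] <= 1)).all()
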