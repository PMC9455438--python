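import numpy as np
import pandas as pd
import pytest

from chemotrace.plsda_core import (
    PLSDAModel,
    encode_dummy,
    fit_plsda,
    predict_classes,
    predict_scores,
)
from chemotrace.spectra_io import SpectraSet
from chemotrace.validation import r2_explained

from conftest import make_spectra_set
from oracles import ols_predict


def spectra_from_matrix(X, labels, processed=True):
    n, p = X.shape
    ids = [f"s{i:03d}" for i in range(n)]
    meta = pd.DataFrame(
        {"sample_id": ids, "species": "sp", "origin": labels}
    ).set_index("sample_id")
    return SpectraSet(ids, np.arange(1.0, p + 1.0), X, meta, processed=processed)


def random_problem(seed, n=15, p=8, k=3):
    rng = np.random.default_rng(seed)
    X = rng.normal(0, 1, (n, p))
    labels = [f"class_{i % k + 1}" for i in range(n)]
    return spectra_from_matrix(X, labels)


class TestEncodeDummy:
    def test_basic_coding(self):
        coding = encode_dummy(["north", "south", "north"])
        assert coding.class_labels == ["north", "south"]
        np.testing.assert_array_equal(coding.Y, [[1, 0], [0, 1], [1, 0]])

    def test_balanced_study_column_sums(self):
        labels = [f"class_{c + 1}" for c in range(4) for _ in range(30)]
        coding = encode_dummy(labels)
        np.testing.assert_array_equal(coding.Y.sum(axis=0), [30, 30, 30, 30])
        np.testing.assert_array_equal(coding.Y.sum(axis=1), 1)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            encode_dummy(["a", "a", "a"])

    def test_fixed_label_space(self):
        coding = encode_dummy(["b", "b"], class_labels=["a", "b", "c"])
        assert coding.Y.shape == (2, 3)
        np.testing.assert_array_equal(coding.Y.sum(axis=0), [0, 2, 0])


class TestFitInvariants:
    @pytest.mark.parametrize("seed,n,p,k,A", [(0, 15, 8, 3, 2), (1, 20, 12, 4, 3),
                                              (2, 12, 30, 2, 1), (3, 25, 10, 5, 4)])
    def test_model_identities(self, seed, n, p, k, A):
        s = random_problem(seed, n, p, k)
        m = fit_plsda(s, A=A)
        # unit-norm weights
        np.testing.assert_allclose(np.linalg.norm(m.W, axis=0), 1.0, atol=1e-10)
        # mutually orthogonal scores
        gram = m.T.T @ m.T
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() <= 1e-8 * np.abs(np.diag(gram)).max()
        # B assembly identity
        B = m.W @ np.linalg.solve(m.P.T @ m.W, m.C.T)
        np.testing.assert_allclose(m.B, B, rtol=1e-10, atol=1e-12)
        assert m.A <= min(n - 1, p)

    def test_default_component_count_is_k_minus_1(self):
        s = random_problem(5, n=20, p=10, k=4)
        assert fit_plsda(s).A == 3

    def test_rank_one_separable_problem_is_exact(self):
        # two classes exactly separated along one direction: one component
        # reproduces the dummy response perfectly
        rng = np.random.default_rng(0)
        direction = rng.normal(0, 1, 5)
        signs = np.array([1.0, 1.0, 1.0, -1.0, -1.0, -1.0])
        X = np.outer(signs, direction)
        labels = ["pos"] * 3 + ["neg"] * 3
        s = spectra_from_matrix(X, labels)
        m = fit_plsda(s, A=1)
        assert r2_explained(s, m) == pytest.approx(1.0, abs=1e-8)

    def test_full_rank_pls_equals_ols(self):
        s = random_problem(7, n=14, p=6, k=3)
        A = min(s.n - 1, s.p)
        m = fit_plsda(s, A=A)
        yhat = predict_scores(m, s)
        oracle = ols_predict(s.intensities, encode_dummy(s.origins).Y)
        np.testing.assert_allclose(yhat, oracle, rtol=1e-6, atol=1e-8)

    def test_zero_variance_matrix_rejected(self):
        s = spectra_from_matrix(np.ones((6, 4)), ["a", "b"] * 3)
        with pytest.raises(ValueError, match="zero variance"):
            fit_plsda(s, A=1)


class TestPrediction:
    def test_training_predictions_equal_score_reconstruction(self):
        s = random_problem(11, n=18, p=9, k=3)
        m = fit_plsda(s, A=2)
        yhat = predict_scores(m, s)
        np.testing.assert_allclose(yhat, m.T @ m.C.T + m.y_mean, rtol=1e-10, atol=1e-12)

    def test_mean_spectrum_predicts_class_prevalences(self):
        s = random_problem(12, n=18, p=9, k=3)
        m = fit_plsda(s, A=2)
        row = m.predict_response(s.intensities.mean(axis=0))
        np.testing.assert_allclose(row[0], m.y_mean, atol=1e-10)

    def test_duplicate_row_prediction_matches(self):
        s = random_problem(13)
        m = fit_plsda(s, A=2)
        np.testing.assert_allclose(
            m.predict_response(s.intensities[4]),
            predict_scores(m, s)[4:5],
            rtol=1e-12,
        )

    def test_channel_mismatch_rejected(self):
        s = random_problem(14)
        m = fit_plsda(s, A=2)
        with pytest.raises(ValueError, match="channels"):
            m.predict_response(np.zeros(s.p + 1))

    def test_argmax_assignment_and_lexicographic_ties(self):
        m = PLSDAModel(
            A=1,
            class_labels=["center", "north", "south"],
            x_mean=np.zeros(2),
            x_scale=np.ones(2),
            y_mean=np.array([0.4, 0.3, 0.3]),
            W=np.ones((2, 1)) / np.sqrt(2),
            P=np.ones((2, 1)),
            C=np.zeros((3, 1)),
            T=np.zeros((4, 1)),
            B=np.zeros((2, 3)),
        )
        # B = 0: every prediction equals y_mean -> argmax picks "center"
        assert m.predict_labels(np.zeros((1, 2))) == ["center"]
        m.y_mean = np.array([0.5, 0.5, 0.0])
        assert m.predict_labels(np.zeros((1, 2))) == ["center"]  # tie -> lexicographic

    def test_high_snr_training_assignment_is_perfect(self, signal_set):
        from chemotrace.preprocessing import sg_filter

        proc = sg_filter(signal_set)
        m = fit_plsda(proc)
        assert predict_classes(m, proc) == list(proc.origins)


class TestSerialisation:
    def test_json_round_trip_preserves_predictions(self, tmp_path):
        s = random_problem(21)
        m = fit_plsda(s, A=2)
        m.to_json(tmp_path / "model.json")
        back = PLSDAModel.from_json(tmp_path / "model.json")
        np.testing.assert_array_equal(back.B, m.B)
        assert back.class_labels == m.class_labels
        np.testing.assert_allclose(
            predict_scores(back, s), predict_scores(m, s), rtol=0, atol=0
        )


class TestReferenceImplementation:
    @pytest.mark.parametrize("seed", range(5))
    @pytest.mark.parametrize("A", [1, 2, 3])
    def test_agrees_with_sklearn_pls2(self, seed, A):
        sklearn = pytest.importorskip("sklearn.cross_decomposition")
        s = random_problem(seed, n=20, p=12, k=3)
        m = fit_plsda(s, A=A, tol=1e-14, max_iter=5000)
        Y = encode_dummy(s.origins).Y
        ref = sklearn.PLSRegression(
            n_components=A, scale=False, tol=1e-14, max_iter=5000
        ).fit(s.intensities, Y)
        np.testing.assert_allclose(
            predict_scores(m, s), ref.predict(s.intensities), rtol=1e-6, atol=1e-6
        )

    def test_permuted_label_training_accuracy_approaches_chance(self):
        # random labels can only be memorised through overfitting, whose
        # excess over chance shrinks roughly like p/n as n grows
        def mean_excess(n):
            accs = []
            for seed in range(15):
                rng = np.random.default_rng(seed)
                X = rng.normal(0, 1, (n, 10))
                labels = rng.permutation(["a", "b"] * (n // 2))
                s = spectra_from_matrix(X, list(labels))
                m = fit_plsda(s, A=1)
                accs.append(np.mean(np.array(predict_classes(m, s)) == labels))
            return np.mean(accs) - 0.5

        excess = [mean_excess(n) for n in (100, 400, 1000)]
        assert excess[0] > excess[1] > excess[2]
        assert abs(excess[-1]) < 0.05
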