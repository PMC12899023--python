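import numpy as np
import pytest

from ssvepclean import (
    EpochSet,
    accuracy,
    cca_classify,
    clean_epochs,
    enumerate_aux_subsets,
    fit_window_regression,
    search_best_subset,
    summarize_betas,
)
from ssvepclean.regression_cleaner import BetaTensor, design_matrix
from ssvepclean.synthetic_data import SourceSpec, SynthConfig, generate_dataset

FS = 256.0
N = 256


def sine(freq, phase=0.0):
    t = np.arange(N) / FS
    return np.sin(2 * np.pi * freq * t + phase)


def normal_equations(X, y):
    """Independent brute-force oracle: solve X'X b = X'y directly."""
    return np.linalg.solve(X.T @ X, X.T @ y)


def gradient_descent(X, y, iters=20000, lr=None):
    """Second independent oracle: plain gradient descent on the LS loss."""
    if lr is None:
        lr = 1.0 / np.linalg.norm(X, 2) ** 2
    b = np.zeros(X.shape[1])
    for _ in range(iters):
        b -= lr * (X.T @ (X @ b - y))
    return b


class TestFitWindowRegression:
    def test_exact_construction(self):
        s = sine(8.0)
        X = np.column_stack([np.ones(N), s])
        beta = fit_window_regression(5.0 + 2.0 * s, X)
        np.testing.assert_allclose(beta, [5.0, 2.0], atol=1e-10)

    def test_integer_cycle_orthogonality(self):
        X = np.column_stack([np.ones(N), sine(8.0)])
        beta = fit_window_regression(sine(9.0), X)
        assert abs(beta[1]) <= 1e-9

    def test_exact_mixture_recovery(self, rng):
        X = np.column_stack([np.ones(N), rng.normal(size=(N, 6))])
        b_true = np.array([1.0, 0.7, -0.3, 0.0, 0.2, -1.1, 0.05])
        beta = fit_window_regression(X @ b_true, X)
        np.testing.assert_allclose(beta, b_true, atol=1e-8)

    def test_matches_brute_force_oracles(self, rng):
        X = np.column_stack([np.ones(50), rng.normal(size=(50, 3))])
        y = rng.normal(size=50)
        beta = fit_window_regression(y, X)
        np.testing.assert_allclose(beta, normal_equations(X, y), atol=1e-6)
        np.testing.assert_allclose(beta, gradient_descent(X, y), atol=1e-6)

    def test_dimension_checks(self):
        with pytest.raises(ValueError):
            fit_window_regression(np.zeros(5), np.zeros((4, 2)))
        with pytest.raises(ValueError):
            fit_window_regression(np.zeros(2), np.zeros((2, 3)))


def make_epochs(target_data, aux_data, labels=None):
    """(n_w, n_samples) target + dict of aux name -> (n_w, n_samples)."""
    n_w = target_data.shape[0]
    chans = [target_data[:, None, :]] + [a[:, None, :] for a in aux_data.values()]
    return EpochSet(
        epochs=np.concatenate(chans, axis=1),
        labels=np.full(n_w, 8.0) if labels is None else labels,
        subject_ids=np.array(["S01"] * n_w, dtype=object),
        window_s=1.0,
        fs=FS,
        channel_labels=["Oz"] + list(aux_data),
        channel_roles=["target"] + ["auxiliary"] * len(aux_data),
    )


class TestCleanEpochs:
    def test_recovers_ssvep_under_known_mixing(self, rng):
        n_w = 20
        ssvep = np.stack([sine(8.0, rng.uniform(0, 2 * np.pi)) for _ in range(n_w)])
        aux = rng.normal(size=(n_w, N))
        eps = make_epochs(ssvep + 0.7 * aux, {"Cz": aux})
        res = clean_epochs(eps)
        rs = [
            np.corrcoef(res.cleaned.epochs[w, 0], ssvep[w])[0, 1]
            for w in range(n_w)
        ]
        # chance in-sample correlation of white aux with a 256-sample sine
        # perturbs beta by ~1/sqrt(n), so allow the rare window near 0.97
        assert np.median(rs) >= 0.99
        assert min(rs) >= 0.97

    def test_exact_combination_leaves_nothing(self, rng):
        aux1 = rng.normal(size=(5, N))
        aux2 = rng.normal(size=(5, N))
        y = 2.0 + 0.5 * aux1 - 1.5 * aux2
        res = clean_epochs(make_epochs(y, {"a": aux1, "b": aux2}))
        resid_rms = np.sqrt(np.mean(res.cleaned.epochs**2))
        assert resid_rms <= 1e-8 * np.sqrt(np.mean(y**2))
        np.testing.assert_allclose(res.variance_explained, 1.0)

    def test_chance_fit_level_with_independent_noise(self, rng):
        n_w = 1000
        y = rng.normal(size=(n_w, N))
        aux = {f"a{i}": rng.normal(size=(n_w, N)) for i in range(6)}
        res = clean_epochs(make_epochs(y, aux))
        assert np.median(res.variance_explained) <= 0.05

    def test_duplicated_auxiliary_flags_degenerate(self, rng):
        aux = rng.normal(size=(3, N))
        eps = make_epochs(rng.normal(size=(3, N)), {"a": aux, "b": aux.copy()})
        res = clean_epochs(eps)  # must not raise
        assert res.betas.degenerate.all()
        assert np.all(np.isfinite(res.betas.betas))

    def test_metadata_preserved_and_aux_untouched(self, rng):
        labels = np.array([7.0, 8.0, 9.0])
        eps = make_epochs(
            rng.normal(size=(3, N)), {"Cz": rng.normal(size=(3, N))}, labels
        )
        before = eps.epochs.copy()
        res = clean_epochs(eps)
        np.testing.assert_array_equal(res.cleaned.labels, labels)
        np.testing.assert_array_equal(eps.epochs, before)
        assert res.cleaned.n_epochs == 3

    def test_cleaning_twice_is_idempotent(self, rng):
        eps = make_epochs(
            rng.normal(size=(4, N)), {"Cz": rng.normal(size=(4, N))}
        )
        once = clean_epochs(eps)
        aux_block = eps.epochs[:, 1:, :]
        twice_input = make_epochs(once.cleaned.epochs[:, 0, :], {"Cz": aux_block[:, 0, :]})
        twice = clean_epochs(twice_input)
        # residual already orthogonal to the auxiliary column space
        assert np.max(np.abs(twice.betas.betas[:, :, 1:])) <= 1e-8

    def test_validation_errors(self, rng):
        eps = make_epochs(rng.normal(size=(2, N)), {"Cz": rng.normal(size=(2, N))})
        with pytest.raises(ValueError, match="non-empty"):
            clean_epochs(eps, targets=["Oz"], auxiliaries=[])
        with pytest.raises(ValueError, match="both"):
            clean_epochs(eps, targets=["Oz"], auxiliaries=["Oz"])


class TestSummarizeBetas:
    @staticmethod
    def tensor(values, aux=("Cz",)):
        values = np.asarray(values, dtype=float)
        n_w = values.shape[0]
        betas = np.zeros((n_w, 1, len(aux) + 1))
        betas[:, 0, 1:] = values.reshape(n_w, len(aux))
        return BetaTensor(
            betas, list(aux), ["Oz"], np.zeros((n_w, 1), dtype=bool)
        )

    def test_cv_matches_published_convention(self):
        # mean |beta| 0.416 with SD 0.175 must report CV 0.42 at 2 dp
        rng = np.random.default_rng(3)
        vals = np.abs(rng.normal(0.416, 0.175, size=20000))
        summary = summarize_betas(self.tensor(vals)).table
        cv = summary.loc["Cz", "sd"] / summary.loc["Cz", "mean_abs_beta"]
        assert summary.loc["Cz", "cv"] == pytest.approx(cv)
        assert round(0.175 / 0.416, 2) == 0.42

    def test_hand_arithmetic(self):
        summary = summarize_betas(self.tensor([[0.1], [0.3]])).table
        assert summary.loc["Cz", "mean_abs_beta"] == pytest.approx(0.2)
        assert summary.loc["Cz", "sd"] == pytest.approx(0.1)  # population SD
        assert summary.loc["Cz", "cv"] == pytest.approx(0.5)

    def test_constant_betas_have_zero_cv(self):
        summary = summarize_betas(self.tensor([[0.4], [0.4], [0.4]])).table
        assert summary.loc["Cz", "sd"] == pytest.approx(0.0, abs=1e-12)
        assert summary.loc["Cz", "cv"] == pytest.approx(0.0, abs=1e-12)

    def test_all_degenerate_rejected(self):
        t = self.tensor([[0.1]])
        t.degenerate[:] = True
        with pytest.raises(ValueError, match="degenerate"):
            summarize_betas(t)


class TestEnumerateAuxSubsets:
    @pytest.mark.parametrize(
        "n,expected", [(1, 1), (3, 7), (6, 63)]
    )
    def test_counts(self, n, expected):
        subsets = enumerate_aux_subsets([f"a{i}" for i in range(n)])
        assert len(subsets) == expected
        assert len(set(subsets)) == expected

    def test_deterministic_order_by_size(self):
        subsets = enumerate_aux_subsets(["x", "y", "z"])
        assert subsets[:3] == [("x",), ("y",), ("z",)]
        assert subsets[-1] == ("x", "y", "z")

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            enumerate_aux_subsets([])


class TestSearchBestSubset:
    @staticmethod
    def cca_eval(cleaned, subject):
        mask = cleaned.subject_ids == subject
        labels, _ = cca_classify(cleaned.select_epochs(mask))
        return accuracy(labels, cleaned.labels[mask])

    def test_identifies_true_artifact_channel(self):
        # the only artifact source feeds auxiliary "jaw"
        cfg = SynthConfig(
            sources=[SourceSpec("emg_burst", "jaw", amplitude=120.0, participation=1.0)],
            mixing=[[0.6, 0.6, 0.6]],
            n_subjects=2,
            session_s=20.0,
            seed=21,
        )
        dataset, _ = generate_dataset(cfg)
        best, accs = search_best_subset(
            dataset, "S01", self.cca_eval, auxiliaries=["Cz", "jaw"]
        )
        assert len(accs) == 3
        assert "jaw" in best

    def test_needs_two_subjects(self, rng):
        eps = make_epochs(rng.normal(size=(4, N)), {"Cz": rng.normal(size=(4, N))})
        with pytest.raises(ValueError, match="subjects"):
            search_best_subset(eps, "S01", self.cca_eval, auxiliaries=["Cz"])


def test_design_matrix_layout(rng):
    aux = rng.normal(size=(2, 5))
    X = design_matrix(aux)
    assert X.shape == (5, 3)
    np.testing.assert_array_equal(X[:, 0], 1.0)
    np.testing.assert_array_equal(X[:, 1], aux[0])
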