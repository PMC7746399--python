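"""Latent class model: FIML likelihood, EM behaviour, posteriors, ordering
and model selection."""

import numpy as np
import pandas as pd
import pytest

from conftest import zero_effects
from paitraj.lca import LatentClassModel, em_fit, loglik, order_classes, select_model
from paitraj.simulate import CohortConfig, PAPanel, generate_cohort


def toy_panel(rows, ages=(33, 42)):
    ids = [f"p{i}" for i in range(len(rows))]
    data = pd.DataFrame(np.asarray(rows, dtype=float), index=ids, columns=list(ages))
    return PAPanel(data, pd.Series("male", index=ids))


class TestLoglik:
    def test_one_class_one_wave_hand_value(self):
        y = np.array([[1.0], [1.0], [0.0]])
        ll = loglik([1.0], [[2 / 3]], y)
        assert ll == pytest.approx(2 * np.log(2 / 3) + np.log(1 / 3), abs=1e-12)

    def test_missing_waves_contribute_no_factor(self):
        # observed only at wave 1 with y=1: contribution = ln sum_k pi_k rho[k,1]
        y = np.array([[1.0, np.nan]])
        pi, rho = [0.3, 0.7], [[0.9, 0.5], [0.2, 0.4]]
        expected = np.log(0.3 * 0.9 + 0.7 * 0.2)
        assert loglik(pi, rho, y) == pytest.approx(expected, abs=1e-12)

    def test_duplication_doubles_loglik(self):
        y = np.array([[1.0, 0.0], [0.0, np.nan], [1.0, 1.0]])
        pi, rho = [0.4, 0.6], [[0.8, 0.7], [0.1, 0.3]]
        assert loglik(pi, rho, np.vstack([y, y])) == pytest.approx(2 * loglik(pi, rho, y), rel=1e-12)

    def test_all_missing_person_rejected(self):
        with pytest.raises(ValueError, match="all waves missing"):
            loglik([1.0], [[0.5, 0.5]], np.array([[np.nan, np.nan]]))


class TestEMFit:
    def test_one_class_closed_form(self):
        y = np.array([[1, 1], [1, 0], [0, 0], [1, 1]], dtype=float)
        res = em_fit(y, 1)
        np.testing.assert_allclose(res.class_probs, [1.0])
        np.testing.assert_allclose(res.response_probs, [[0.75, 0.5]], atol=1e-12)

    def test_separable_two_class_panel(self):
        rows = [[1, 1, 1, 1]] * 12 + [[0, 0, 0, 0]] * 8
        res = em_fit(toy_panel(rows, ages=(33, 42, 50, 55)), 2, seed=0)
        np.testing.assert_allclose(sorted(res.class_probs), [0.4, 0.6], atol=1e-6)
        assert res.response_probs[0].min() > 0.999
        assert res.response_probs[1].max() < 0.001

    def test_loglik_monotone_over_iterations(self):
        rng = np.random.default_rng(0)
        y = rng.integers(0, 2, size=(60, 4)).astype(float)
        for seed in range(20):
            res = em_fit(y, 3, n_starts=1, seed=seed, sort_classes=False)
            assert (np.diff(res.loglik_path) >= -1e-9).all()

    def test_reproducible_given_seed(self):
        rng = np.random.default_rng(1)
        y = rng.integers(0, 2, size=(50, 4)).astype(float)
        r1 = em_fit(y, 2, seed=3)
        r2 = em_fit(y, 2, seed=3)
        np.testing.assert_array_equal(r1.class_probs, r2.class_probs)
        np.testing.assert_array_equal(r1.response_probs, r2.response_probs)

    def test_excess_classes_warn(self):
        y = np.array([[1, 1], [0, 0]] * 5, dtype=float)
        with pytest.warns(UserWarning, match="distinct observed response patterns"):
            LatentClassModel(y, 5)

    def test_fiml_handles_missing_waves(self):
        # identified cells only: wave 50 is never observed for the active
        # group, wave 42 never for the inactive group
        rows = [[1, 1, np.nan, 1]] * 10 + [[0, np.nan, 0, 0]] * 10
        res = em_fit(toy_panel(rows, ages=(33, 42, 50, 55)), 2, seed=0)
        assert res.converged
        assert res.response_probs[0][[0, 1, 3]].min() > 0.99
        assert res.response_probs[1][[0, 2, 3]].max() < 0.01


class TestPosterior:
    def test_uninformative_likelihood_returns_prior(self):
        y = np.array([[1, 0], [0, 1]], dtype=float)
        model = LatentClassModel(y, 2)
        from paitraj.lca import LatentClassResults

        res = LatentClassResults(
            model, 2, np.array([0.3, 0.7]), np.array([[0.6, 0.4], [0.6, 0.4]]),
            0.0, True, 1, 1, np.array([0.0]),
        )
        post = res.predict_posterior()
        np.testing.assert_allclose(post[["p_class1", "p_class2"]].to_numpy(), [[0.3, 0.7]] * 2, atol=1e-12)

    def test_deterministic_pattern_pins_posterior(self):
        rows = [[1, 1, 1, 1]] * 10 + [[0, 0, 0, 0]] * 10
        res = em_fit(toy_panel(rows, ages=(33, 42, 50, 55)), 2, seed=0)
        post = res.predict_posterior()
        assert post["p_class1"].iloc[0] > 0.999
        assert post["modal_class"].iloc[0] == 1

    def test_matches_direct_bayes_enumeration(self):
        pi = np.array([0.25, 0.75])
        rho = np.array([[0.9, 0.8], [0.2, 0.3]])
        y = np.array([[1, 0], [0, 0], [1, 1]], dtype=float)
        model = LatentClassModel(y, 2)
        from paitraj.lca import LatentClassResults

        res = LatentClassResults(model, 2, pi, rho, 0.0, True, 1, 1, np.array([0.0]))
        post = res.predict_posterior()[["p_class1", "p_class2"]].to_numpy()
        for i, row in enumerate(y):
            lik = pi * np.prod(rho ** row * (1 - rho) ** (1 - row), axis=1)
            np.testing.assert_allclose(post[i], lik / lik.sum(), atol=1e-12)

    def test_posteriors_sum_to_one(self, default_cohort):
        res = em_fit(default_cohort.pa_panel.subset_ages((33, 42, 50, 55)), 4, n_starts=5, seed=0)
        post = res.predict_posterior()
        sums = post[[f"p_class{k}" for k in range(1, 5)]].sum(axis=1)
        np.testing.assert_allclose(sums, 1.0, atol=1e-10)


class TestOrderClasses:
    def _fit(self):
        rows = [[1, 1, 1, 1]] * 10 + [[0, 0, 0, 0]] * 5 + [[1, 1, 0, 0]] * 5
        return em_fit(toy_panel(rows, ages=(33, 42, 50, 55)), 3, seed=0, sort_classes=False)

    def test_idempotent(self):
        res = order_classes(self._fit())
        again = order_classes(res)
        np.testing.assert_array_equal(res.class_probs, again.class_probs)
        np.testing.assert_array_equal(res.response_probs, again.response_probs)

    def test_descending_mean_activity(self):
        res = order_classes(self._fit())
        means = res.response_probs.mean(axis=1)
        assert (np.diff(means) <= 1e-12).all()

    def test_permutation_invariance(self):
        from paitraj.lca import LatentClassResults

        res = self._fit()
        perm = np.array([2, 0, 1])
        shuffled = LatentClassResults(
            res.model, res.k_classes, res.class_probs[perm], res.response_probs[perm],
            res.llf, res.converged, res.n_iter, res.n_starts, res.loglik_path,
        )
        a, b = order_classes(res), order_classes(shuffled)
        np.testing.assert_allclose(a.class_probs, b.class_probs, atol=1e-12)
        np.testing.assert_allclose(a.response_probs, b.response_probs, atol=1e-12)

    def test_default_cohort_extremes(self, default_cohort):
        res = em_fit(default_cohort.pa_panel.subset_ages((33, 42, 50, 55)), 4, n_starts=10, seed=0)
        means = res.response_probs.mean(axis=1)
        assert means[0] == means.max() and means[-1] == means.min()
        assert means[0] > 0.8 and means[-1] < 0.2


class TestSelectModel:
    def test_fit_indices_recomputable_from_loglik(self, default_cohort):
        panel = default_cohort.pa_panel.subset_ages((33, 42, 50, 55))
        table, chosen, fits = select_model(panel, range(2, 5), n_starts=5, seed=0)
        n = fits[2].nobs
        for K, row in table.iterrows():
            p = (K - 1) + K * 4
            assert row["n_params"] == p
            assert row["AIC"] == pytest.approx(-2 * row["loglik"] + 2 * p, rel=1e-12)
            assert row["BIC"] == pytest.approx(-2 * row["loglik"] + p * np.log(n), rel=1e-12)
        assert chosen == table["BIC"].idxmin()

    def test_three_class_structure_recovered_and_selected(self):
        # identified case: K=3 on four binary waves (14 parameters <= 15 dof)
        cfg = CohortConfig(
            n_persons=5000,
            seed=100,
            pai_class_effects={s: {"active": (0.0,) * 3, "spectator": (0.0,) * 3} for s in ("male", "female")},
            class_names=("always_active", "increasing", "always_inactive"),
            class_probs_by_sex={"male": (0.55, 0.25, 0.20), "female": (0.55, 0.25, 0.20)},
            response_probs=(
                (0.5, 0.94, 0.92, 0.94, 0.93),
                (0.3, 0.25, 0.45, 0.80, 0.90),
                (0.1, 0.06, 0.05, 0.05, 0.04),
            ),
        )
        cohort = generate_cohort(cfg)
        panel = cohort.pa_panel.subset_ages((33, 42, 50, 55))
        table, chosen, fits = select_model(panel, range(2, 6), n_starts=10, seed=0)
        assert chosen == 3
        res = fits[3]
        f = (cohort.covariates["sex"] == "female").mean()
        pi_true = np.asarray(cfg.class_probs_by_sex["male"])  # same for both sexes
        rho_true = np.asarray(cfg.response_probs)[:, 1:]
        assert np.abs(res.class_probs - pi_true).max() < 0.03
        assert np.abs(res.response_probs - rho_true).max() < 0.04
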