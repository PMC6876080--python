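"""Bagging arithmetic, Newton logistic fits, GD refinement and vote tallies."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lrrgd import core
from lrrgd.associations import DiseaseProteinTable, build_feature_matrix


def logit(p):
    return np.log(p / (1 - p))


class TestBaggingArithmetic:
    @pytest.mark.parametrize(
        "n,expected", [(1608, 40), (1, 1), (100, 10), (246, 16)]
    )
    def test_bag_size_is_rounded_sqrt(self, n, expected):
        assert core.feature_subset_size(n) == expected

    def test_expected_selections_published_regime(self):
        assert core.expected_selections(400, 40, 1608) == pytest.approx(9.95, abs=0.005)

    def test_full_pool_bag_selected_every_round(self):
        assert core.expected_selections(37, 12, 12) == 37.0

    def test_expected_selections_matched_by_simulation(self):
        # 2000 seeded draws of 5 from 50: each index ~200 +/- 3 sigma
        n_draws, bag, pool = 2000, 5, 50
        counts = np.zeros(pool)
        for r in range(n_draws):
            rng = np.random.default_rng([7, r])
            counts[core.sample_features(pool, bag, rng)] += 1
        expected = core.expected_selections(n_draws, bag, pool)
        sigma = np.sqrt(n_draws * (bag / pool) * (1 - bag / pool))
        assert np.all(np.abs(counts - expected) <= 3 * sigma)

    def test_sample_determinism_and_validation(self):
        a = core.sample_features(20, 5, np.random.default_rng(3))
        b = core.sample_features(20, 5, np.random.default_rng(3))
        assert np.array_equal(a, b)
        assert len(set(a.tolist())) == 5
        with pytest.raises(ValueError):
            core.sample_features(4, 5, np.random.default_rng(0))

    def test_full_bag_returns_every_index(self):
        idx = core.sample_features(6, 6, np.random.default_rng(0))
        assert sorted(idx.tolist()) == list(range(6))


class TestNewtonFit:
    def test_intercept_only_closed_form(self):
        X = np.zeros((6, 3))
        y = np.full(6, 0.3)
        model = core.fit_logistic_newton(X, y, ridge=1.0)
        assert model.intercept == pytest.approx(logit(0.3), abs=1e-6)
        assert np.allclose(model.weights, 0.0)
        assert model.converged

    def test_informative_feature_beats_intercept_only(self):
        X = np.array([[0.0], [0], [0], [1], [1], [1]])
        y = np.array([0.0, 0, 0, 1, 1, 1])
        with_x = core.fit_logistic_newton(X, y, ridge=0.1)
        without = core.fit_logistic_newton(np.zeros_like(X), y, ridge=0.1)
        assert with_x.final_loss < without.final_loss

    def test_matches_plain_gradient_descent_on_same_objective(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(5, 3))
        y = rng.uniform(0.1, 0.9, 5)
        ridge = 0.3
        model = core.fit_logistic_newton(X, y, ridge=ridge)

        # independent oracle: long-run first-order descent of the identical loss
        m = X.shape[0]
        Xa = np.hstack([np.ones((m, 1)), X])
        mask = np.array([0.0, 1, 1, 1])
        theta = np.zeros(4)
        for _ in range(200_000):
            p = 1 / (1 + np.exp(-(Xa @ theta)))
            grad = Xa.T @ (p - y) / m + (ridge / m) * mask * theta
            theta -= 0.5 * grad
        assert np.allclose(model.theta, theta, atol=1e-4)

    def test_singular_hessian_without_ridge_names_the_cure(self):
        X = np.ones((4, 2))  # duplicated columns: exactly rank-deficient
        y = np.array([0.2, 0.4, 0.6, 0.8])
        with pytest.raises(core.OptimizationError, match="ridge"):
            core.fit_logistic_newton(X, y, ridge=0.0)

    def test_non_finite_input_rejected(self):
        with pytest.raises(ValueError):
            core.fit_logistic_newton(np.array([[np.nan]]), np.array([0.5]))

    def test_loss_never_exceeds_starting_point(self):
        rng = np.random.default_rng(11)
        for _ in range(5):
            X = rng.integers(0, 2, size=(8, 4)).astype(float)
            y = rng.uniform(0, 1, 8)
            model = core.fit_logistic_newton(X, y, ridge=1.0)
            start = core._penalized_loss(
                np.hstack([np.ones((8, 1)), X]), y, np.zeros(5), 1.0
            )
            assert model.final_loss <= start + 1e-12


class TestGDRefine:
    def _model(self, b, w):
        w = np.asarray(w, dtype=float)
        return core.LogisticModel(
            theta=np.concatenate([[b], w]),
            feature_ids=tuple(f"p{i}" for i in range(len(w))),
            converged=True,
            final_loss=0.0,
        )

    def test_all_ones_is_fixed_point_for_positive_weights(self):
        model = self._model(0.2, [0.5, 1.0, 0.7])
        out = core.gd_refine_indicator(model, np.ones(3), core.GDConfig())
        assert np.array_equal(out.values, np.ones(3))

    def test_zero_weights_are_stationary(self):
        model = self._model(0.3, [0.0, 0.0])
        x0 = np.array([1.0, 0.0])
        out = core.gd_refine_indicator(model, x0, core.GDConfig())
        assert np.array_equal(out.values, x0)

    def test_binarized_view_thresholds_at_half(self):
        iv = core.IndicatorVector(values=np.array([0.49, 0.5, 0.51, 0.0, 1.0]))
        assert iv.binarized.tolist() == [0, 1, 1, 0, 1]

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            core.GDConfig(step=0.0)
        with pytest.raises(ValueError):
            core.GDConfig(tol=-1.0)

    def test_objective_nonincreasing_along_trajectory(self):
        # run with a deliberately large step: internal halving must keep
        # f monotone, so the final f cannot exceed the starting f
        rng = np.random.default_rng(2)
        for _ in range(10):
            k = 4
            w = rng.normal(scale=2.0, size=k)
            model = self._model(float(rng.normal()), w)
            x0 = rng.integers(0, 2, k).astype(float)
            f0 = (1 / (1 + np.exp(-(model.intercept + w @ x0))) - 1) ** 2
            out = core.gd_refine_indicator(
                model, x0, core.GDConfig(step=5.0, tol=1e-12, max_iter=2000)
            )
            f1 = (1 / (1 + np.exp(-(model.intercept + w @ out.values))) - 1) ** 2
            assert f1 <= f0 + 1e-15

    @pytest.mark.parametrize("trial", range(20))
    def test_converged_calls_match_weight_signs(self, trial):
        # constrained optimum of the monotone sigmoid objective pushes each
        # coordinate to the bound matching its weight's sign
        rng = np.random.default_rng(100 + trial)
        k = int(rng.integers(2, 7))
        w = rng.uniform(0.8, 1.5, k) * rng.choice([-1, 1], k)
        x0 = rng.integers(0, 2, k).astype(float)
        b = -float(w @ x0) + float(rng.uniform(-1, 1))
        out = core.gd_refine_indicator(
            self._model(b, w), x0, core.GDConfig(step=0.05, tol=1e-18, max_iter=200_000)
        )
        assert np.array_equal(out.binarized, (w > 0).astype(np.int8))


def tiny_matrix():
    rows = [
        ("target", "p1"), ("target", "p2"), ("target", "p3"),
        ("near", "p1"), ("near", "p2"), ("near", "p4"),
        ("mid", "p2"), ("mid", "p4"), ("mid", "p5"),
        ("far", "p4"), ("far", "p5"), ("far", "p6"),
    ]
    table = DiseaseProteinTable.from_rows(rows)
    labels = {"target": 0.9, "near": 0.8, "mid": 0.55, "far": 0.45}
    return build_feature_matrix(table, labels)


class TestEnsemble:
    def test_single_round_full_bag_selects_everything(self):
        fm = tiny_matrix()
        tally = core.run_ensemble(
            fm, "target", set(), core.BagConfig(n_rounds=1, bag_size=6, rng_seed=0)
        )
        assert tally.times_selected.tolist() == [1] * 6
        assert tally.bag_size == 6

    def test_same_seed_reproduces_tally(self):
        fm = tiny_matrix()
        cfg = core.BagConfig(n_rounds=25, bag_size=3, rng_seed=9)
        t1 = core.run_ensemble(fm, "target", {"p1"}, cfg)
        t2 = core.run_ensemble(fm, "target", {"p1"}, cfg)
        assert np.array_equal(t1.times_selected, t2.times_selected)
        assert np.array_equal(t1.times_called_related, t2.times_called_related)

    def test_vote_conservation(self):
        fm = tiny_matrix()
        cfg = core.BagConfig(n_rounds=40, bag_size=3, rng_seed=1)
        tally = core.run_ensemble(fm, "target", set(), cfg)
        assert int(tally.times_selected.sum()) == 40 * 3
        assert np.all(tally.times_called_related <= tally.times_selected)

    def test_failed_fits_count_selections_but_not_calls(self, caplog):
        fm = tiny_matrix()
        # duplicate every protein column by pairing p1..p6 with ridge 0:
        # any bag of >= 2 identical columns has a singular Hessian
        fm.X[:, :] = 1  # all columns identical -> rank-1 design
        with caplog.at_level("WARNING"):
            tally = core.run_ensemble(
                fm, "target", set(),
                core.BagConfig(n_rounds=3, bag_size=2, rng_seed=0), ridge=0.0,
            )
        assert tally.failed_rounds == 3
        assert int(tally.times_selected.sum()) == 6
        assert int(tally.times_called_related.sum()) == 0

    def test_unknown_target_rejected(self):
        with pytest.raises(KeyError):
            core.run_ensemble(tiny_matrix(), "absent", set())

    def test_unknown_seed_proteins_logged_and_ignored(self, caplog):
        fm = tiny_matrix()
        with caplog.at_level("WARNING"):
            core.run_ensemble(
                fm, "target", {"p1", "pX"},
                core.BagConfig(n_rounds=2, bag_size=2, rng_seed=0),
            )
        assert "pX" in caplog.text


class TestSelection:
    def _tally(self, counts, selected=None):
        proteins = tuple(sorted(counts))
        sel = selected or {p: 10 for p in proteins}
        return core.VoteTally(
            protein_index=proteins,
            times_selected=np.array([sel[p] for p in proteins]),
            times_called_related=np.array([counts[p] for p in proteins]),
            n_rounds=10,
            bag_size=3,
        )

    def test_threshold_seven_keeps_top_two(self):
        tally = self._tally({"p1": 10, "p2": 7, "p3": 6})
        assert core.select_related(tally, 7) == ["p1", "p2"]

    def test_threshold_zero_returns_every_selected_protein(self):
        tally = self._tally({"p1": 0, "p2": 3}, selected={"p1": 4, "p2": 4})
        assert core.select_related(tally, 0) == ["p2", "p1"]

    def test_never_selected_protein_is_not_reported(self):
        tally = self._tally({"p1": 0, "p2": 3}, selected={"p1": 0, "p2": 4})
        assert core.select_related(tally, 0) == ["p2"]

    def test_selection_shrinks_as_threshold_grows(self):
        tally = self._tally({"p1": 10, "p2": 7, "p3": 6, "p4": 1})
        prev = set(core.select_related(tally, 0))
        for thr in range(1, 12):
            cur = set(core.select_related(tally, thr))
            assert cur <= prev
            prev = cur

    @settings(derandomize=True, max_examples=50)
    @given(
        counts=st.lists(st.integers(0, 10), min_size=1, max_size=8),
        thr=st.integers(0, 10),
    )
    def test_selection_honours_threshold_exactly(self, counts, thr):
        tally = self._tally({f"p{i}": c for i, c in enumerate(counts)})
        picked = set(core.select_related(tally, thr))
        for i, c in enumerate(counts):
            assert (f"p{i}" in picked) == (c >= thr)


class TestKnownFraction:
    def test_published_scale(self):
        assert round(core.known_fraction(376, 308)) == 18

    def test_no_novel_means_all_known(self):
        assert core.known_fraction(12, 0) == 100.0

    def test_simple_fraction(self):
        assert core.known_fraction(10, 4) == pytest.approx(60.0)

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            core.known_fraction(0, 0)
        with pytest.raises(ValueError):
            core.known_fraction(5, 6)
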