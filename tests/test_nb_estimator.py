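"""Greedy feature assignment and the naive-Bayes posterior."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from transage.data_io import ExpressionDataset
from transage.dichotomize_screen import (
    AgeThresholdSet,
    ScreenResult,
    screen_matrix,
)
from transage.nb_estimator import (
    Classifier,
    NBModel,
    fit_nb,
    greedy_assign,
    posterior_over_thresholds,
    predict_ages,
    select_N,
    smoothed_conditionals,
)


def make_scores(abs_lor, p=None, gene_ids=None):
    """ScreenResult stub from an explicit |log2 OR| matrix."""
    abs_lor = np.asarray(abs_lor, dtype=float)
    G, T = abs_lor.shape
    ages = np.arange(20.0, 20.0 + 10 * (T + 1), 10.0)
    ths = AgeThresholdSet(ages, (ages[:-1] + ages[1:]) / 2)
    return ScreenResult(
        gene_ids=gene_ids or [f"g{i+1}" for i in range(G)],
        thresholds=ths,
        p=np.full((G, T), 0.5) if p is None else np.asarray(p, float),
        theta=np.zeros((G, T)),
        log2_or=abs_lor,
        counts=np.zeros((G, T, 4), dtype=int),
    )


class TestGreedyAssign:
    def test_hand_trace_one_round(self):
        sc = make_scores([[3, 1], [2, 5], [0.5, 0.2]])
        a = greedy_assign(sc, 1)
        assert a.genes_per_threshold == [["g1"], ["g2"]]

    def test_hand_trace_two_rounds_with_shortage(self):
        sc = make_scores([[3, 1], [2, 5], [0.5, 0.2]])
        with pytest.warns(UserWarning, match="ran out"):
            a = greedy_assign(sc, 2)
        assert a.genes_per_threshold == [["g1", "g3"], ["g2"]]
        assert a.exhausted

    def test_single_gene_single_threshold(self):
        sc = make_scores([[1.0]])
        assert greedy_assign(sc, 1).genes_per_threshold == [["g1"]]

    def test_tie_broken_by_smaller_p_then_gene_id(self):
        p = [[0.5, 0.5], [0.1, 0.5], [0.5, 0.5]]
        sc = make_scores([[2, 1], [2, 1], [2, 1]], p=p)
        a = greedy_assign(sc, 1)
        assert a.genes_per_threshold[0] == ["g2"]  # smaller p wins the tie
        assert a.genes_per_threshold[1] == ["g1"]  # then lexicographic

    @given(
        st.integers(2, 40),  # genes
        st.integers(1, 8),  # thresholds
        st.integers(1, 6),  # N
        st.integers(0, 10_000),  # rng seed
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_invariants_random(self, G, T, N, seed):
        """No gene is reused, and each threshold gets exactly
        min(N, feasible) genes, filled round-robin."""
        rng = np.random.default_rng(seed)
        sc = make_scores(rng.exponential(1.0, (G, T)), p=rng.random((G, T)))
        a = greedy_assign(sc, N)
        flat = [g for col in a.genes_per_threshold for g in col]
        assert len(flat) == len(set(flat))  # no reuse
        expected_total = min(N * T, G)
        assert len(flat) == expected_total
        counts = [len(c) for c in a.genes_per_threshold]
        full_rounds = expected_total // T
        assert all(full_rounds <= c <= full_rounds + 1 for c in counts)


class TestSmoothing:
    @pytest.mark.parametrize(
        "table,expected",
        [
            ((4, 0, 0, 2), (3 / 4, 1 / 6)),
            ((0, 0, 0, 0), (1 / 2, 1 / 2)),
            ((2, 2, 2, 2), (1 / 2, 1 / 2)),
        ],
    )
    def test_known_values(self, table, expected):
        assert smoothed_conditionals(*table) == pytest.approx(expected)

    def test_probabilities_strictly_inside_unit_interval(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            p1o, p1y = smoothed_conditionals(*rng.integers(0, 30, 4))
            assert 0.0 < p1o < 1.0 and 0.0 < p1y < 1.0


def two_classifier_model():
    return NBModel(
        deltas=np.array([30.0, 50.0]),
        classifiers=[
            Classifier("c1", 30.0, 0.0, 0.8, 0.2),
            Classifier("c2", 50.0, 0.0, 0.9, 0.3),
        ],
        N=1,
    )


from oracle_utils import brute_posterior


class TestPosterior:
    def test_hand_example(self):
        est = posterior_over_thresholds(two_classifier_model(), {"c1": 1.0, "c2": 1.0})
        np.testing.assert_allclose(est.posterior, [0.2, 0.8], atol=1e-12)
        assert est.predicted_age == 50.0

    def test_uninformative_model_uniform(self):
        m = NBModel(
            deltas=np.array([30.0, 50.0, 70.0]),
            classifiers=[Classifier("c", 50.0, 0.0, 0.5, 0.5)],
            N=1,
        )
        est = posterior_over_thresholds(m, {"c": 5.0})
        np.testing.assert_allclose(est.posterior, [1 / 3] * 3, atol=1e-12)
        assert est.predicted_age == 30.0  # tie -> smallest threshold

    def test_single_threshold_model(self):
        m = NBModel(
            deltas=np.array([40.0]),
            classifiers=[Classifier("c", 40.0, 0.0, 0.7, 0.2)],
            N=1,
        )
        est = posterior_over_thresholds(m, {"c": 10.0})
        np.testing.assert_allclose(est.posterior, [1.0])

    def test_missing_gene_named(self):
        with pytest.raises(KeyError, match="c2"):
            posterior_over_thresholds(two_classifier_model(), {"c1": 1.0})

    @given(st.integers(0, 10_000))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_normalization_and_brute_force_random_models(self, seed):
        rng = np.random.default_rng(seed)
        K = int(rng.integers(2, 8))
        deltas = np.sort(rng.uniform(25, 95, K))
        n_cls = int(rng.integers(1, 12))
        cls = [
            Classifier(
                f"c{i}",
                float(rng.choice(deltas)),
                float(rng.normal()),
                float(rng.uniform(0.05, 0.95)),
                float(rng.uniform(0.05, 0.95)),
            )
            for i in range(n_cls)
        ]
        m = NBModel(deltas=deltas, classifiers=cls, N=1)
        expr = {f"c{i}": float(rng.normal()) for i in range(n_cls)}
        est = posterior_over_thresholds(m, expr)
        assert est.posterior.sum() == pytest.approx(1.0, abs=1e-9)
        b = [expr[c.gene_id] > c.theta for c in cls]
        np.testing.assert_allclose(est.posterior, brute_posterior(m, b), atol=1e-9)

    def test_monotone_in_older_conditional(self):
        """Raising P(b=1|older) of one classifier never moves posterior
        mass away from candidates older than that classifier's delta, for
        a sample with b=1."""
        base = two_classifier_model()
        expr = {"c1": 1.0, "c2": 1.0}
        mass = []
        for p1o in [0.4, 0.6, 0.8, 0.95]:
            m = NBModel(
                deltas=base.deltas,
                classifiers=[
                    Classifier("c1", 30.0, 0.0, p1o, 0.2),
                    base.classifiers[1],
                ],
                N=1,
            )
            post = posterior_over_thresholds(m, expr).posterior
            mass.append(post[1])  # candidates older than delta=30
        assert all(a <= b + 1e-12 for a, b in zip(mass, mass[1:]))


class TestFitAndPredict:
    def test_fit_freezes_theta_and_probabilities(self, noiseless_step_dataset):
        ds = noiseless_step_dataset
        sc = screen_matrix(ds)
        model = fit_nb(ds, sc, N=1)
        # 4 genes cannot fill 11 thresholds; all get used exactly once
        assert len(model.classifiers) == ds.n_genes
        genes = {c.gene_id for c in model.classifiers}
        assert "step" in genes

    def test_noiseless_recovery_bracketing_threshold(self):
        """With one clean step gene per age threshold, each subject's
        predicted age is the threshold just above it (the bracketing one),
        so every prediction is within one age gap of the truth."""
        ages = np.linspace(26, 94, 12)
        mids = (ages[:-1] + ages[1:]) / 2
        values = np.vstack([6.0 + 2.0 * (ages > m) for m in mids])
        ds = ExpressionDataset(
            [f"step{k}" for k in range(len(mids))],
            [f"s{j}" for j in range(12)],
            values,
            ages=ages,
        )
        model = fit_nb(ds, screen_matrix(ds), N=1)
        preds = [e.predicted_age for e in predict_ages(model, ds)]
        expected = list(mids) + [mids[-1]]  # oldest subject has no upper mid
        np.testing.assert_allclose(preds, expected)

    def test_gene_order_irrelevant(self):
        m1 = two_classifier_model()
        m2 = NBModel(
            deltas=m1.deltas, classifiers=list(reversed(m1.classifiers)), N=1
        )
        e1 = posterior_over_thresholds(m1, {"c1": 1.0, "c2": -1.0})
        e2 = posterior_over_thresholds(m2, {"c1": 1.0, "c2": -1.0})
        np.testing.assert_allclose(e1.posterior, e2.posterior, atol=1e-12)

    def test_duplicated_sample_duplicates_estimate(self, noiseless_step_dataset):
        ds = noiseless_step_dataset
        model = fit_nb(ds, screen_matrix(ds), N=1)
        dup = ExpressionDataset(
            list(ds.gene_ids),
            ["a", "b", "c"],
            ds.values[:, [0, 0, 5]],
            ages=ds.ages[[0, 0, 5]],
        )
        est = predict_ages(model, dup)
        np.testing.assert_allclose(est[0].posterior, est[1].posterior)
        assert est[0].predicted_age == est[1].predicted_age

    def test_json_round_trip(self, tmp_path):
        m = two_classifier_model()
        path = tmp_path / "model.json"
        m.to_json(path)
        back = NBModel.from_json(path)
        np.testing.assert_allclose(back.deltas, m.deltas)
        assert back.classifiers == m.classifiers

    def test_invalid_probability_rejected(self):
        with pytest.raises(ValueError):
            NBModel(
                deltas=np.array([30.0]),
                classifiers=[Classifier("c", 30.0, 0.0, 1.0, 0.5)],
                N=1,
            )


class TestSelectN:
    def test_singleton_grid(self, noiseless_step_dataset):
        assert select_N(noiseless_step_dataset, [1], k=3, seed=0) == 1

    def test_flat_data_prefers_smaller_n(self):
        rng = np.random.default_rng(0)
        ds = ExpressionDataset(
            [f"g{i}" for i in range(6)],
            [f"s{j}" for j in range(12)],
            np.tile(rng.normal(6, 1, (6, 1)), (1, 12)),  # constant genes
            ages=np.linspace(25, 95, 12),
        )
        assert select_N(ds, [1, 2], k=3, seed=0) == 1
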