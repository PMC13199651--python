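"""Metrics against brute-force oracles; benchmark harness; LODO protocol."""

import numpy as np
import pytest
from sklearn.metrics import average_precision_score, roc_auc_score

import trscreen as ts
from trscreen.errors import ContractError, DomainError
from trscreen.io import GenePanel, subset_panel
from trscreen.metrics import (
    ConfusionMatrix,
    basic_metrics,
    benchmark_classical,
    brier,
    confusion,
    lodo_evaluate,
    metrics_report,
    pr_auc,
    roc_auc,
)
from trscreen.nn import NetworkSpec, TrainConfig


class TestConfusion:
    def test_perfect(self):
        cm = confusion([1, 1, 0, 0], [1, 1, 0, 0])
        assert (cm.tp, cm.tn, cm.fp, cm.fn) == (2, 2, 0, 0)

    def test_inverted(self):
        cm = confusion([1, 1, 0, 0], [0, 0, 1, 1])
        assert cm.tp == 0 and cm.tn == 0 and cm.fp == 2 and cm.fn == 2

    def test_all_positive_predictions(self):
        cm = confusion([1, 0], [1, 1])
        assert cm.tp == 1 and cm.fp == 1


class TestBasicMetrics:
    def test_perfect_accuracy(self):
        m = basic_metrics(ConfusionMatrix(tp=2, fp=0, tn=2, fn=0))
        assert m["accuracy"] == 1.0 and m["balanced_accuracy"] == 1.0

    def test_coin_flip_counts(self):
        m = basic_metrics(ConfusionMatrix(tp=1, fp=1, tn=1, fn=1))
        assert m["accuracy"] == 0.5 and m["precision"] == 0.5 and m["recall"] == 0.5

    def test_zero_denominator_flagged(self):
        m = basic_metrics(ConfusionMatrix(tp=0, fp=0, tn=4, fn=1))
        assert m["precision"] == 0.0
        assert "precision" in m["zero_denominator"]

    def test_balanced_accuracy_invariant_to_duplication(self):
        rng = np.random.default_rng(0)
        labels = rng.integers(0, 2, 30)
        preds = rng.integers(0, 2, 30)
        once = basic_metrics(confusion(labels, preds))["balanced_accuracy"]
        thrice = basic_metrics(confusion(np.tile(labels, 3), np.tile(preds, 3)))[
            "balanced_accuracy"
        ]
        assert once == pytest.approx(thrice)


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([0.9, 0.8, 0.3, 0.2], [1, 1, 0, 0]) == 1.0

    def test_enumerated_pairs(self):
        # pos-neg pairs: (.9,.8)w (.9,.2)w (.3,.8)l (.3,.2)w -> 3/4
        assert roc_auc([0.9, 0.8, 0.3, 0.2], [1, 0, 1, 0]) == 0.75

    def test_all_ties_give_half(self):
        assert roc_auc([0.5] * 6, [1, 0, 1, 0, 1, 0]) == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(ContractError):
            roc_auc([0.1, 0.9], [1, 1])

    def test_matches_pair_counting_oracle_and_sklearn(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            n = rng.integers(4, 50)
            scores = np.round(rng.random(n), 1)  # heavy ties
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                continue
            pos, neg = scores[labels == 1], scores[labels == 0]
            wins = (pos[:, None] > neg[None, :]).sum()
            ties = (pos[:, None] == neg[None, :]).sum()
            oracle = (wins + 0.5 * ties) / (len(pos) * len(neg))
            assert roc_auc(scores, labels) == pytest.approx(oracle, abs=1e-12)
            assert roc_auc(scores, labels) == pytest.approx(
                roc_auc_score(labels, scores), abs=1e-12
            )

    def test_complement_symmetry(self):
        rng = np.random.default_rng(8)
        scores = rng.random(40)
        labels = rng.integers(0, 2, 40)
        assert roc_auc(scores, labels) + roc_auc(scores, 1 - labels) == pytest.approx(1.0)


class TestPrAuc:
    def test_perfect_ranking(self):
        assert pr_auc([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0]) == 1.0

    def test_single_positive_ranked_last(self):
        n = 8
        scores = np.arange(n, dtype=float)
        labels = np.zeros(n, dtype=int)
        labels[0] = 1  # lowest score
        assert pr_auc(scores, labels) == pytest.approx(1.0 / n)

    def test_random_scores_approach_prevalence(self):
        rng = np.random.default_rng(9)
        labels = (rng.random(5000) < 0.2).astype(int)
        scores = rng.random(5000)
        assert pr_auc(scores, labels) == pytest.approx(0.2, abs=0.03)

    def test_no_positives_rejected(self):
        with pytest.raises(ContractError):
            pr_auc([0.1, 0.2], [0, 0])

    def test_matches_step_sum_oracle_and_sklearn(self):
        rng = np.random.default_rng(10)
        for _ in range(200):
            n = rng.integers(4, 50)
            scores = np.round(rng.random(n), 1)
            labels = rng.integers(0, 2, n)
            if labels.sum() == 0:
                continue
            # brute-force step sum over descending unique thresholds
            area, prev_rec = 0.0, 0.0
            for t in sorted(set(scores), reverse=True):
                pred = scores >= t
                prec = labels[pred].sum() / pred.sum()
                rec = labels[pred].sum() / labels.sum()
                area += (rec - prev_rec) * prec
                prev_rec = rec
            assert pr_auc(scores, labels) == pytest.approx(area, abs=1e-12)
            assert pr_auc(scores, labels) == pytest.approx(
                average_precision_score(labels, scores), abs=1e-12
            )


class TestBrier:
    @pytest.mark.parametrize(
        "scores,labels,expected",
        [([1.0, 0.0], [1, 0], 0.0), ([0.5, 0.5], [1, 0], 0.25), ([1.0, 0.0], [0, 1], 1.0)],
    )
    def test_known_values(self, scores, labels, expected):
        assert brier(scores, labels) == expected

    def test_score_outside_unit_interval_rejected(self):
        with pytest.raises(DomainError):
            brier([1.5], [1])


class TestMetricsReport:
    def test_single_class_auc_undefined_but_brier_reported(self):
        report = metrics_report([0.2, 0.4, 0.1], [0, 0, 0], 0.5)
        assert report["roc_auc"] is None
        assert report["roc_auc_reason"] == "single class in labels"
        assert report["brier"] == pytest.approx(np.mean([0.04, 0.16, 0.01]))

    def test_imbalance_flag(self):
        labels = [1] + [0] * 24
        report = metrics_report(np.linspace(0, 1, 25), labels, 0.5)
        assert report["imbalance_flag"]
        assert report["pr_auc"] is not None and report["balanced_accuracy"] >= 0


class TestBenchmarkClassical:
    @pytest.fixture(scope="class")
    def separable_split(self):
        m, meta, _ = ts.generate_separable_binary(600, 60, 15, 2.5, seed=21)
        X = m.values.T
        y = meta["label"].to_numpy(int)
        tr, te = ts.stratified_split(y, 0.8, seed=21)
        return X[tr], y[tr], X[te], y[te]

    def test_all_ten_models_reported_with_status(self, separable_split):
        report = benchmark_classical(*separable_split, seed=42)
        assert len(report) == 10
        assert set(report["status"]) == {"ok"}
        assert {"lightgbm", "xgboost", "svm_rbf", "gaussian_nb"} <= set(report["model"])

    def test_every_model_separates_strong_signal(self, separable_split):
        report = benchmark_classical(*separable_split, seed=42)
        ok = report[report["status"] == "ok"]
        assert (ok["roc_auc"] >= 0.9).all()

    def test_permuted_labels_fall_to_chance(self, separable_split):
        # permutation null: shuffle the full label vector before splitting so
        # scores are evaluated against labels independent of the features
        xtr, ytr, xte, yte = separable_split
        y_all = np.concatenate([ytr, yte])
        y_perm = y_all[np.random.default_rng(5).permutation(len(y_all))]
        report = benchmark_classical(xtr, y_perm[: len(ytr)], xte, y_perm[len(ytr) :], seed=42)
        ok = report[report["status"] == "ok"]
        assert ok["roc_auc"].between(0.3, 0.7).all()

    def test_unknown_model_rejected(self, separable_split):
        with pytest.raises(ContractError, match="unknown model"):
            benchmark_classical(*separable_split, models=["perceptron_9000"])


class TestLodo:
    @pytest.fixture(scope="class")
    def cohorts(self):
        cfg = ts.GeneratorConfig(
            n_cohorts=3, samples_per_cohort=(60, 60, 60),
            prevalence_per_cohort=(0.4, 0.5, 0.6),
            n_genes=120, n_informative=20, effect_size=2.5,
            batch_shift_sd=1.0, batch_scale_sd=0.1, noise_sd=0.7, seed=19,
        )
        matrix, meta, truth = ts.generate_multicohort(cfg)
        items = []
        for name in truth.cohort_names:
            ids = meta.loc[meta["cohort"] == name, "sample_id"].tolist()
            items.append((name, matrix.subset_samples(ids),
                          meta[meta["cohort"] == name].reset_index(drop=True)))
        return items, truth

    def _fast_setup(self, truth):
        genes = sorted(set(truth.informative_genes) | {f"G{i:03d}" for i in range(1, 13)})
        panel = GenePanel(genes, name="fast")
        spec = NetworkSpec(input_length=len(panel), filters1=4, filters2=6, dense_units=8)
        config = TrainConfig(epochs=10, seed=42)
        return panel, spec, config

    def test_heldout_cohort_excluded_from_training(self, cohorts):
        items, truth = cohorts
        panel, spec, config = self._fast_setup(truth)
        results = lodo_evaluate(items, metabolic=panel, spec=spec, config=config,
                                fixed_panel=panel)
        assert len(results) == 3
        for res in results:
            held_ids = {
                s for name, m, _ in items if name == res.cohort for s in m.sample_ids
            }
            assert held_ids.isdisjoint(res.training_sample_ids)
            assert res.cohort not in res.training_cohorts
            assert len(res.training_matrix_hash) == 64

    def test_strong_signal_generalizes_across_cohorts(self, cohorts):
        items, truth = cohorts
        panel, spec, config = self._fast_setup(truth)
        results = lodo_evaluate(items, metabolic=panel, spec=spec, config=config,
                                fixed_panel=panel)
        aucs = [r.metrics_default["roc_auc"] for r in results]
        assert all(a is not None and a >= 0.8 for a in aucs)

    def test_all_negative_cohort_flagged(self, cohorts):
        items, truth = cohorts
        panel, spec, config = self._fast_setup(truth)
        name, m, meta = items[0]
        meta0 = meta.copy()
        meta0["label"] = 0
        degenerate = [(name, m, meta0)] + list(items[1:])
        results = lodo_evaluate(degenerate, metabolic=panel, spec=spec, config=config,
                                fixed_panel=panel)
        res0 = next(r for r in results if r.cohort == name)
        assert res0.metrics_default["roc_auc"] is None
        assert res0.metrics_default["brier"] is not None
        assert any("single class" in n for n in res0.notes)

    def test_fewer_than_three_cohorts_rejected(self, cohorts):
        items, truth = cohorts
        panel, spec, config = self._fast_setup(truth)
        with pytest.raises(ContractError):
            lodo_evaluate(items[:2], metabolic=panel, spec=spec, config=config)
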