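"""Batch correction: EB adjustment, covariate protection, silhouette scoring."""

import subprocess

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import silhouette_score

import trscreen as ts
from trscreen.errors import ContractError
from trscreen.io import ExpressionMatrix


def _two_batch_shifted(n=30, genes=80, shift=3.0, seed=0):
    """Two equal batches differing only by a constant per-gene shift, covariate balanced."""
    rng = np.random.default_rng(seed)
    base = rng.normal(8, 1, size=(genes, 2 * n))
    offsets = rng.normal(0, shift, size=genes)
    base[:, n:] += offsets[:, None]
    batch = np.array(["b1"] * n + ["b2"] * n, dtype=object)
    cov = np.tile([0, 1], n)  # balanced within each batch
    ids = [f"s{i}" for i in range(2 * n)]
    m = ExpressionMatrix([f"g{i}" for i in range(genes)], ids, base)
    return m, batch, cov


class TestCombatAdjust:
    def test_constant_shift_removed(self):
        m, batch, cov = _two_batch_shifted()
        corrected, dropped = ts.combat_adjust(m, batch, covariate=cov)
        assert not dropped
        before = np.abs(
            m.values[:, batch == "b1"].mean(axis=1) - m.values[:, batch == "b2"].mean(axis=1)
        )
        after = np.abs(
            corrected.values[:, batch == "b1"].mean(axis=1)
            - corrected.values[:, batch == "b2"].mean(axis=1)
        )
        # closed-form oracle: mean-centering each batch removes 100% of a
        # constant shift; EB shrinkage must recover >= 95% of it
        assert after.sum() <= 0.05 * before.sum()

    def test_confounded_class_effect_preserved(self, batched_cohorts):
        m, meta, truth = batched_cohorts
        y = meta["label"].to_numpy(int)
        corrected, _ = ts.combat_adjust(m, meta["cohort"].to_numpy(object), covariate=y)
        idx = [corrected.gene_ids.index(g) for g in truth.informative_genes]
        effect = (
            corrected.values[idx][:, y == 1].mean() - corrected.values[idx][:, y == 0].mean()
        )
        assert abs(effect - 2.0) < 0.2  # within 10% of the simulated 2.0

    def test_single_fitting_batch_is_identity(self):
        m, batch, cov = _two_batch_shifted()
        out, dropped = ts.combat_adjust(m, batch, covariate=cov, holdout_batches=["b2"])
        np.testing.assert_allclose(out.values, m.values, atol=1e-9)

    def test_holdout_batch_untouched_and_excluded(self):
        rng = np.random.default_rng(4)
        genes, ids = [f"g{i}" for i in range(50)], [f"s{i}" for i in range(60)]
        m = ExpressionMatrix(genes, ids, rng.normal(8, 1, size=(50, 60)))
        batch = np.array(["a"] * 20 + ["b"] * 20 + ["ext"] * 20, dtype=object)
        cov = np.tile([0, 1], 30)
        with_holdout, _ = ts.combat_adjust(m, batch, covariate=cov, holdout_batches=["ext"])
        np.testing.assert_array_equal(
            with_holdout.values[:, batch == "ext"], m.values[:, batch == "ext"]
        )
        # fitting must ignore the held-out block entirely
        m2 = m.copy()
        m2.values[:, batch == "ext"] += 100.0
        with_perturbed, _ = ts.combat_adjust(m2, batch, covariate=cov, holdout_batches=["ext"])
        np.testing.assert_array_equal(
            with_holdout.values[:, batch != "ext"], with_perturbed.values[:, batch != "ext"]
        )

    def test_singleton_batch_rejected(self):
        m, batch, cov = _two_batch_shifted(n=3)
        batch = batch.copy()
        batch[0] = "lonely"
        with pytest.raises(ContractError, match="lonely"):
            ts.combat_adjust(m, batch, covariate=cov)

    def test_zero_variance_gene_dropped_and_reported(self):
        m, batch, cov = _two_batch_shifted()
        m.values[3, :] = 7.7  # flat gene
        corrected, dropped = ts.combat_adjust(m, batch, covariate=cov)
        assert dropped == ["g3"]
        assert "g3" not in corrected.gene_ids

    def test_approximately_idempotent(self):
        # EB shrinkage leaves O(1/n) residuals, so idempotence is asymptotic:
        # with 200 samples per batch the second pass moves each gene by well
        # under 1% of its spread on average
        cfg = ts.GeneratorConfig(
            n_cohorts=3, samples_per_cohort=(200,) * 3, prevalence_per_cohort=(0.3, 0.5, 0.7),
            n_genes=400, n_informative=30, effect_size=2.0,
            batch_shift_sd=2.0, batch_scale_sd=0.2, noise_sd=0.5, seed=7,
        )
        m, meta, _ = ts.generate_multicohort(cfg)
        batch = meta["cohort"].to_numpy(object)
        y = meta["label"].to_numpy(int)
        once, _ = ts.combat_adjust(m, batch, covariate=y)
        twice, _ = ts.combat_adjust(once, batch, covariate=y)
        per_gene = np.abs(twice.values - once.values).mean(axis=1) / once.values.std(axis=1)
        assert per_gene.max() < 0.01

    def test_matches_sva_combat_reference(self, tmp_path):
        """Independent oracle: R sva::ComBat with a protected covariate."""
        cfg = ts.GeneratorConfig(
            n_cohorts=2, samples_per_cohort=(20, 20), prevalence_per_cohort=(0.4, 0.6),
            n_genes=120, n_informative=15, effect_size=1.5,
            batch_shift_sd=1.5, batch_scale_sd=0.3, noise_sd=0.6, seed=3,
        )
        m, meta, _ = ts.generate_multicohort(cfg)
        mine, _ = ts.combat_adjust(
            m, meta["cohort"].to_numpy(object), covariate=meta["label"].to_numpy(int)
        )
        m.to_frame().to_csv(tmp_path / "expr.tsv", sep="\t")
        meta.to_csv(tmp_path / "meta.tsv", sep="\t", index=False)
        script = f"""
        suppressMessages(library(sva))
        expr <- as.matrix(read.delim("{tmp_path}/expr.tsv", row.names=1, check.names=FALSE))
        meta <- read.delim("{tmp_path}/meta.tsv")
        out <- ComBat(dat=expr, batch=meta$cohort, mod=model.matrix(~ label, data=meta))
        write.table(out, "{tmp_path}/ref.tsv", sep="\\t", quote=FALSE)
        """
        (tmp_path / "run.R").write_text(script)
        proc = subprocess.run(
            ["Rscript", str(tmp_path / "run.R")], capture_output=True, text=True
        )
        assert proc.returncode == 0, proc.stderr
        ref = pd.read_csv(tmp_path / "ref.tsv", sep="\t", index_col=0)
        np.testing.assert_allclose(mine.to_frame().values, ref.values, atol=1e-8)


class TestMeanSilhouette:
    def test_identical_points_score_zero(self):
        m = ExpressionMatrix(["g1", "g2"], list("abcd"), np.ones((2, 4)))
        assert ts.mean_silhouette(m, ["x", "x", "y", "y"]) == 0.0

    def test_tight_far_clusters_near_one(self):
        # brute-force-checkable 6-point fixture: two clusters 100 apart
        vals = np.array([[0.0, 0.1, 0.2, 100.0, 100.1, 100.2]])
        m = ExpressionMatrix(["g1"], list("abcdef"), vals)
        labels = ["l", "l", "l", "r", "r", "r"]
        assert ts.mean_silhouette(m, labels) > 0.9
        # against the brute-force definition computed by hand for point 'a':
        # a(i) = (0.1+0.2)/2 = 0.15, b(i) = (100+100.1+100.2)/3 = 100.1
        # s(a) = (100.1-0.15)/100.1
        assert ts.mean_silhouette(m, labels) == pytest.approx(
            np.mean([
                (100.1 - 0.15) / 100.1, (100.0 - 0.1) / 100.0, (99.9 - 0.15) / 99.9,
                (99.9 - 0.15) / 99.9, (100.0 - 0.1) / 100.0, (100.1 - 0.15) / 100.1,
            ])
        )

    def test_permuted_labels_near_zero(self):
        vals = np.array([[0.0, 0.1, 0.2, 100.0, 100.1, 100.2]])
        m = ExpressionMatrix(["g1"], list("abcdef"), vals)
        assert abs(ts.mean_silhouette(m, ["l", "r", "l", "r", "l", "r"])) < 0.1

    def test_single_label_rejected(self):
        m = ExpressionMatrix(["g1"], ["a", "b"], np.zeros((1, 2)))
        with pytest.raises(ContractError):
            ts.mean_silhouette(m, ["x", "x"])

    def test_agrees_with_sklearn(self):
        rng = np.random.default_rng(6)
        vals = rng.normal(size=(10, 40))
        labels = rng.choice(["a", "b", "c"], size=40)
        m = ExpressionMatrix([f"g{i}" for i in range(10)], [f"s{i}" for i in range(40)], vals)
        assert ts.mean_silhouette(m, labels) == pytest.approx(
            silhouette_score(vals.T, labels), abs=1e-12
        )


class TestCorrectionReport:
    def test_unchanged_data_equal_silhouettes(self, batched_cohorts):
        m, meta, _ = batched_cohorts
        rep = ts.correction_report(m, m, meta["cohort"].to_numpy(object))
        assert rep.silhouette_before == rep.silhouette_after
        assert rep.n_batches == 3

    def test_correction_lowers_silhouette_below_threshold(self, batched_cohorts):
        m, meta, _ = batched_cohorts
        batch = meta["cohort"].to_numpy(object)
        corrected, _ = ts.combat_adjust(m, batch, covariate=meta["label"].to_numpy(int))
        rep = ts.correction_report(m, corrected, batch)
        assert rep.silhouette_after < rep.silhouette_before
        assert rep.silhouette_after < 0.1

    def test_sample_mismatch_rejected(self, batched_cohorts):
        m, meta, _ = batched_cohorts
        other = m.subset_samples(m.sample_ids[:10])
        with pytest.raises(ContractError):
            ts.correction_report(m, other, meta["cohort"].to_numpy(object))
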