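import logging

import numpy as np
import pytest

from sgatt.fixtures import FixtureSpec, generate
from sgatt.molio import PropertyDataset
from sgatt.train import (
    Checkpoint,
    TrainConfig,
    compute_metrics,
    evaluate,
    export_embeddings,
    split_dataset,
    train,
    train_single_seed,
)


def toy_dataset(smiles, labels):
    records = [(s, np.array([float(y)]), np.array([True])) for s, y in zip(smiles, labels)]
    return PropertyDataset(records=records, task_names=["y"], task_type="classification")


TINY = TrainConfig(
    seeds=[0], max_epochs=2, patience=5, batch_size=16, split="random",
    dim=8, seq_heads=2, seq_layers=1, fusion_heads=2, rounds=1, set2set_steps=1,
    dropout=0.0, fcs_min_freq=3, explicit_h=False, lr=1e-3,
)


class TestSplitDataset:
    def test_random_sizes(self):
        ds = toy_dataset([f"{'C' * (i + 1)}" for i in range(10)], [0, 1] * 5)
        tr, va, te = split_dataset(ds, "random", (0.8, 0.1, 0.1), seed=0)
        assert (len(tr), len(va), len(te)) == (8, 1, 1)

    def test_same_seed_identical(self):
        ds = toy_dataset([f"{'C' * (i + 1)}O" for i in range(10)], [0, 1] * 5)
        a = split_dataset(ds, "random", (0.8, 0.1, 0.1), seed=7)
        b = split_dataset(ds, "random", (0.8, 0.1, 0.1), seed=7)
        for x, y in zip(a, b):
            assert x.smiles == y.smiles

    def test_disjoint_and_exhaustive(self, smiles_pool):
        ds = toy_dataset(smiles_pool[:40], [0, 1] * 20)
        parts = split_dataset(ds, "scaffold", (0.8, 0.1, 0.1), seed=0)
        all_smiles = [s for p in parts for s in p.smiles]
        assert sorted(all_smiles) == sorted(ds.smiles)

    def test_scaffold_groups_not_separated(self, smiles_pool):
        from rdkit import Chem
        from rdkit.Chem.Scaffolds import MurckoScaffold

        pool = smiles_pool[::12][:60]  # spread sample: multiple ring scaffolds
        ds = toy_dataset(pool, [0, 1] * (len(pool) // 2))
        tr, va, te = split_dataset(ds, "scaffold", (0.8, 0.1, 0.1), seed=0)
        scaff = lambda smi: MurckoScaffold.MurckoScaffoldSmiles(mol=Chem.MolFromSmiles(smi))
        sets = [set(map(scaff, p.smiles)) for p in (tr, va, te)]
        assert not (sets[0] & sets[1]) and not (sets[0] & sets[2])

    def test_single_scaffold_falls_back_with_warning(self, caplog):
        ds = toy_dataset(["CC", "CCC", "CCCC", "CCCCC", "CCO", "CCN", "CCCO", "CCCN", "CO", "CN"], [0, 1] * 5)
        with caplog.at_level(logging.WARNING, logger="sgatt.train"):
            parts = split_dataset(ds, "scaffold", (0.8, 0.1, 0.1), seed=0)
        assert any("falling back" in r.message for r in caplog.records)
        assert sum(len(p) for p in parts) == 10

    def test_bad_fractions_rejected(self):
        ds = toy_dataset(["CC"] * 4, [0, 1, 0, 1])
        with pytest.raises(ValueError):
            split_dataset(ds, "random", (0.5, 0.2, 0.2))

    def test_empty_partition_raises(self):
        ds = toy_dataset(["CC", "CCC"], [0, 1])
        with pytest.raises(ValueError, match="empty partition"):
            split_dataset(ds, "random", (1.0, 0.0, 0.0))


class TestMetrics:
    def test_perfect_predictor_auc_one(self):
        y = np.array([[0.0], [0.0], [1.0], [1.0]])
        preds = np.array([[0.1], [0.2], [0.8], [0.9]])
        m = compute_metrics(y, np.ones_like(y, bool), preds, "classification")
        assert m["roc_auc"] == 1.0

    def test_constant_predictor_auc_half(self):
        y = np.array([[0.0], [1.0], [0.0], [1.0]])
        preds = np.full((4, 1), 0.5)
        m = compute_metrics(y, np.ones_like(y, bool), preds, "classification")
        assert m["roc_auc"] == 0.5

    def test_four_point_auc_matches_mann_whitney(self):
        # oracle: AUC = (#concordant + 0.5 #ties) / (n_pos * n_neg)
        y = np.array([[0.0], [1.0], [0.0], [1.0]])
        preds = np.array([[0.3], [0.6], [0.5], [0.4]])
        concordant = ties = 0
        pos = preds[y[:, 0] == 1, 0]
        neg = preds[y[:, 0] == 0, 0]
        for p in pos:
            for q in neg:
                concordant += p > q
                ties += p == q
        expected = (concordant + 0.5 * ties) / (len(pos) * len(neg))
        m = compute_metrics(y, np.ones_like(y, bool), preds, "classification")
        np.testing.assert_allclose(m["roc_auc"], expected)

    def test_single_class_task_excluded_with_warning(self, caplog):
        y = np.array([[1.0, 1.0], [1.0, 0.0]])
        preds = np.random.default_rng(0).random((2, 2))
        with caplog.at_level(logging.WARNING, logger="sgatt.train"):
            m = compute_metrics(y, np.ones_like(y, bool), preds, "classification")
        assert any("single class" in r.message for r in caplog.records)
        assert np.isfinite(m["roc_auc"])  # macro over remaining task

    def test_regression_metrics(self):
        y = np.array([[0.0], [0.0]])
        preds = np.array([[3.0], [4.0]])
        m = compute_metrics(y, np.ones_like(y, bool), preds, "regression")
        np.testing.assert_allclose(m["rmse"], np.sqrt(12.5))
        np.testing.assert_allclose(m["mae"], 3.5)


@pytest.fixture(scope="module")
def small_fixture_ds():
    return generate(FixtureSpec(n_molecules=40, seed=1))


class TestTrainSingleSeed:
    def test_runs_and_reports(self, small_fixture_ds):
        ckpt, summary, history = train_single_seed(TINY, small_fixture_ds, 0)
        assert not summary["failed"]
        assert len(history) == 2
        assert "test_roc_auc" in summary
        assert ckpt is not None

    def test_patience_zero_stops_after_first_non_improvement(self, small_fixture_ds):
        import dataclasses

        cfg = dataclasses.replace(TINY, patience=0, max_epochs=10, lr=0.0)
        _, _, history = train_single_seed(cfg, small_fixture_ds, 0)
        # lr=0: epoch 0 sets the best, epoch 1 cannot improve, then stop
        assert len(history) == 2

    def test_vocab_mined_on_train_split_covers_eval(self, small_fixture_ds):
        ckpt, summary, _ = train_single_seed(TINY, small_fixture_ds, 0)
        assert not summary["failed"]  # would fail on tokenization gaps


class TestTrain:
    def test_report_carries_one_entry_per_seed(self, small_fixture_ds):
        import dataclasses

        cfg = dataclasses.replace(TINY, seeds=list(range(10)), max_epochs=1)
        result = train(cfg, small_fixture_ds)
        assert len(result.report.per_seed) == 10
        assert result.report.metric_name == "roc_auc"
        assert np.isfinite(result.report.mean) and result.report.sd >= 0
        assert result.report.config_hash == cfg.hash()

    def test_checkpoint_round_trip(self, small_fixture_ds, tmp_path):
        result = train(TINY, small_fixture_ds)
        result.checkpoint.save(tmp_path / "ckpt")
        loaded = Checkpoint.load(tmp_path / "ckpt")
        m1, f1 = result.checkpoint.build_model()
        m2, f2 = loaded.build_model()
        smiles = small_fixture_ds.smiles[:4]
        np.testing.assert_allclose(
            m1.predict_smiles(smiles, f1), m2.predict_smiles(smiles, f2), atol=1e-12
        )


class TestExportEmbeddings:
    def test_cosine_properties(self, small_fixture_ds):
        ckpt, _, _ = train_single_seed(TINY, small_fixture_ds, 0)
        model, feat = ckpt.build_model()
        emb, cosine, failures = export_embeddings(model, feat, small_fixture_ds.smiles[:5])
        assert failures == []
        np.testing.assert_allclose(np.diag(cosine), 1.0, atol=1e-9)
        np.testing.assert_allclose(cosine, cosine.T, atol=1e-12)
        assert np.all(cosine <= 1 + 1e-9)

    def test_orthogonal_vectors_zero_similarity(self):
        a = np.array([[1.0, 0.0], [0.0, 1.0]])
        unit = a / np.linalg.norm(a, axis=1, keepdims=True)
        np.testing.assert_allclose((unit @ unit.T)[0, 1], 0.0)

    def test_parse_failures_reported(self, small_fixture_ds):
        ckpt, _, _ = train_single_seed(TINY, small_fixture_ds, 0)
        model, feat = ckpt.build_model()
        emb, cosine, failures = export_embeddings(model, feat, ["CCO", "not_a_smiles("])
        assert len(failures) == 1
        assert failures[0][0] == "not_a_smiles("
        assert emb.shape[0] == 1
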