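import math

import numpy as np
import pandas as pd
import pytest

from duplexgnn.duplex_graph import build_duplex_graph
from duplexgnn.gnn_classifier import ClassifierConfig
from duplexgnn.synthetic_data import DuplexRecord, SimulationConfig, generate_dataset
from duplexgnn.training_eval import (SplitSpec, TrainConfig, Trainer,
                                     build_graphs, compute_metrics,
                                     run_replicates, split_dataset,
                                     summarize_replicates, train_model)
from duplexgnn.word2vec import CbowParams


# ---------------------------------------------------------------------------
# splitting
# ---------------------------------------------------------------------------

class TestSplitDataset:
    @pytest.fixture(scope="class")
    @staticmethod
    def records():
        return generate_dataset(SimulationConfig(n_pairs=1000, rng_seed=4))

    def test_sizes_700_150_150(self, records):
        spec = SplitSpec(base_seed=0)
        train, val, test = split_dataset(records, spec, 0)
        assert (len(train), len(val), len(test)) == (700, 150, 150)

    def test_partition_disjoint_and_exhaustive(self, records):
        train, val, test = split_dataset(records, SplitSpec(), 3)
        keys = lambda part: {(r.mirna_id, r.site_id) for r in part}
        assert keys(train) | keys(val) | keys(test) == keys(records)
        assert not (keys(train) & keys(val))
        assert not (keys(train) & keys(test))
        assert not (keys(val) & keys(test))

    def test_deterministic(self, records):
        a = split_dataset(records, SplitSpec(base_seed=9), 2)
        b = split_dataset(records, SplitSpec(base_seed=9), 2)
        assert a == b

    def test_different_replicates_differ(self, records):
        a = split_dataset(records, SplitSpec(base_seed=9), 0)
        b = split_dataset(records, SplitSpec(base_seed=9), 1)
        assert a != b

    def test_stratification_balanced(self, records):
        train, val, test = split_dataset(records, SplitSpec(stratified=True), 1)
        for part in (train, val, test):
            positives = sum(r.label for r in part)
            assert abs(positives - len(part) / 2) <= 1

    def test_bad_fractions_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            SplitSpec(train_frac=0.7, val_frac=0.2, test_frac=0.2)

    def test_replicate_index_bound(self, records):
        with pytest.raises(ValueError):
            split_dataset(records, SplitSpec(n_replicates=5), 5)

    def test_too_few_records_rejected(self, records):
        with pytest.raises(ValueError):
            split_dataset(records[:5], SplitSpec(), 0)

    def test_many_random_datasets_disjoint(self):
        rng = np.random.default_rng(0)
        for trial in range(100):
            n = int(rng.integers(20, 80))
            recs = [DuplexRecord(f"m{i}", "ACGU" * 5, f"s{i}", "ACGT" * 10,
                                 int(rng.integers(0, 2))) for i in range(n)]
            spec = SplitSpec(stratified=False, base_seed=trial)
            train, val, test = split_dataset(recs, spec, 0)
            assert len(train) + len(val) + len(test) == n
            ids = [r.mirna_id for part in (train, val, test) for r in part]
            assert len(set(ids)) == n


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

class TestComputeMetrics:
    def test_printed_formula_example(self):
        # TP=8, FN=2, TN=9, FP=1
        labels = [1] * 10 + [0] * 10
        preds = [1] * 8 + [0] * 2 + [0] * 9 + [1]
        report = compute_metrics(labels, preds)
        assert (report.tp, report.fn, report.tn, report.fp) == (8, 2, 9, 1)
        assert report.balanced_accuracy == pytest.approx(0.85, abs=1e-12)
        assert report.precision == pytest.approx(8 / 9, abs=1e-12)
        assert report.recall == pytest.approx(0.8, abs=1e-12)

    def test_perfect_classifier(self):
        report = compute_metrics([0, 1, 1, 0], [0, 1, 1, 0])
        assert report.balanced_accuracy == 1.0
        assert report.precision == 1.0
        assert report.recall == 1.0

    def test_no_positive_predictions_undefined_precision(self):
        report = compute_metrics([1, 1, 0], [0, 0, 0])
        assert math.isnan(report.precision)
        assert report.recall == 0.0

    def test_no_positive_labels_undefined_recall_and_bacc(self):
        report = compute_metrics([0, 0], [0, 1])
        assert math.isnan(report.recall)
        assert math.isnan(report.balanced_accuracy)

    def test_count_conservation(self):
        rng = np.random.default_rng(1)
        y, p = rng.integers(0, 2, 57), rng.integers(0, 2, 57)
        report = compute_metrics(y, p)
        assert report.n_records == 57

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            compute_metrics([0, 1], [0])

    def test_non_binary_rejected(self):
        with pytest.raises(ValueError):
            compute_metrics([0, 2], [0, 1])

    def test_agrees_with_independent_recomputation(self):
        rng = np.random.default_rng(8)
        for _ in range(1000):
            n = int(rng.integers(2, 40))
            y = rng.integers(0, 2, n)
            p = rng.integers(0, 2, n)
            report = compute_metrics(y, p)
            # independent confusion-matrix recomputation by explicit loop
            tp = sum(1 for a, b in zip(y, p) if a == 1 and b == 1)
            tn = sum(1 for a, b in zip(y, p) if a == 0 and b == 0)
            fp = sum(1 for a, b in zip(y, p) if a == 0 and b == 1)
            fn = sum(1 for a, b in zip(y, p) if a == 1 and b == 0)
            assert (report.tp, report.tn, report.fp, report.fn) == (tp, tn, fp, fn)
            if tp + fn and tn + fp:
                expected = (tp / (tp + fn) + tn / (tn + fp)) / 2
                assert report.balanced_accuracy == pytest.approx(expected, abs=1e-12)


# ---------------------------------------------------------------------------
# training loop
# ---------------------------------------------------------------------------

def _separable_pairs(n=50, dim=16, seed=0):
    """Graphs whose node features directly encode the label (+1 / -1)."""
    rng = np.random.default_rng(seed)
    pairs = []
    for i in range(n):
        label = i % 2
        base = 1.0 if label else -1.0
        mirna = base + 0.1 * rng.normal(size=(3, dim))
        site = base + 0.1 * rng.normal(size=(5, dim))
        pairs.append((build_duplex_graph(mirna, site), label))
    return pairs


TINY_MODEL = ClassifierConfig(e_gnn="GAT", l_gnn=1, d_gnn=4, l_fc=2, d_fc=4,
                              p_h="MEAN", r_d=0.0, input_dim=16)


class TestTrainModel:
    def test_loss_decreases_on_separable_data(self):
        pairs = _separable_pairs()
        tc = TrainConfig(max_epochs=20, batch_size=16, seed=0)
        params, log = train_model(pairs, pairs[:10], TINY_MODEL, tc)
        df = log.to_dataframe()
        assert df.train_loss.iloc[-1] < df.train_loss.iloc[0]

    def test_identical_seeds_identical_logs(self):
        pairs = _separable_pairs()
        tc = TrainConfig(max_epochs=5, batch_size=16, seed=3)
        _, log1 = train_model(pairs, pairs[:10], TINY_MODEL, tc)
        _, log2 = train_model(pairs, pairs[:10], TINY_MODEL, tc)
        pd.testing.assert_frame_equal(log1.to_dataframe(), log2.to_dataframe())

    def test_early_stopping_at_exact_patience_bound(self, monkeypatch):
        # adversarial stub: validation loss never improves after epoch 1
        monkeypatch.setattr(Trainer, "_validation_metrics",
                            lambda self, params, g, y: (0.7, 0.5))
        pairs = _separable_pairs(20)
        tc = TrainConfig(max_epochs=100, batch_size=8, early_stop_patience=7, seed=0)
        _, log = train_model(pairs, pairs[:5], TINY_MODEL, tc)
        assert log.stopped_early
        assert log.best_epoch == 1
        assert len(log.epochs) == 1 + tc.early_stop_patience

    def test_best_epoch_never_after_last(self):
        pairs = _separable_pairs(30)
        tc = TrainConfig(max_epochs=8, batch_size=8, seed=1)
        _, log = train_model(pairs, pairs[:8], TINY_MODEL, tc)
        assert 1 <= log.best_epoch <= len(log.epochs)

    def test_lr_reduced_on_plateau(self, monkeypatch):
        monkeypatch.setattr(Trainer, "_validation_metrics",
                            lambda self, params, g, y: (0.7, 0.5))
        pairs = _separable_pairs(16)
        tc = TrainConfig(max_epochs=10, batch_size=8, early_stop_patience=50,
                         lr_reduce_patience=3, lr_reduce_factor=0.1, seed=0)
        _, log = train_model(pairs, pairs[:4], TINY_MODEL, tc)
        lrs = log.to_dataframe().lr
        assert lrs.iloc[0] == pytest.approx(0.001)
        assert lrs.min() == pytest.approx(0.001 * 0.1 * 0.1, rel=1e-9)

    def test_empty_sets_rejected(self):
        with pytest.raises(ValueError):
            train_model([], _separable_pairs(4), TINY_MODEL, TrainConfig())
        with pytest.raises(ValueError):
            train_model(_separable_pairs(4), [], TINY_MODEL, TrainConfig())

    def test_returns_best_epoch_parameters(self, monkeypatch):
        # force best at epoch 2 via a scripted validation loss
        losses = iter([0.9, 0.2, 0.8, 0.7, 0.6, 0.5, 0.4, 0.3])
        snapshots = {}
        original = Trainer._validation_metrics

        def scripted(self, params, g, y):
            loss = next(losses)
            snapshots[loss] = params.copy_arrays()
            return loss, 0.5

        monkeypatch.setattr(Trainer, "_validation_metrics", scripted)
        pairs = _separable_pairs(16)
        tc = TrainConfig(max_epochs=8, batch_size=8, early_stop_patience=50, seed=0)
        params, log = train_model(pairs, pairs[:4], TINY_MODEL, tc)
        assert log.best_epoch == 2
        for got, want in zip(params.copy_arrays(), snapshots[0.2]):
            np.testing.assert_array_equal(got, want)


# ---------------------------------------------------------------------------
# replicate orchestration
# ---------------------------------------------------------------------------

class TestSummarize:
    def test_hand_computed_ci(self):
        table = pd.DataFrame({"balanced_accuracy": [0.8, 0.9, 1.0],
                              "precision": [0.8, 0.9, 1.0],
                              "recall": [0.8, 0.9, 1.0]})
        summary = summarize_replicates(table)
        row = summary[summary.metric == "balanced_accuracy"].iloc[0]
        se = 0.1 / math.sqrt(3)
        assert row["mean"] == pytest.approx(0.9, abs=1e-12)
        assert row["ci_low"] == pytest.approx(0.9 - 1.96 * se, abs=1e-9)
        assert row["ci_high"] == pytest.approx(0.9 + 1.96 * se, abs=1e-9)

    def test_zero_variance_ci_width_zero(self):
        table = pd.DataFrame({"balanced_accuracy": [0.9] * 4,
                              "precision": [0.9] * 4, "recall": [0.9] * 4})
        summary = summarize_replicates(table)
        assert (summary.ci_high - summary.ci_low).abs().max() == 0.0

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            summarize_replicates(pd.DataFrame({"balanced_accuracy": []}))


class TestRunReplicates:
    def test_three_replicates_bookkeeping(self, small_dataset):
        config = ClassifierConfig(e_gnn="GCN", l_gnn=1, d_gnn=4, l_fc=1, d_fc=4,
                                  p_h="MEAN", r_d=0.0)
        tc = TrainConfig(max_epochs=2, batch_size=16, seed=0)
        spec = SplitSpec(n_replicates=3, base_seed=0)
        table, summary = run_replicates(small_dataset, config, tc, spec,
                                        cbow=CbowParams(epochs=2))
        assert len(table) == 3
        assert list(table.replicate) == [0, 1, 2]
        assert (table.status == "ok").all()
        assert set(summary.metric) == {"balanced_accuracy", "precision", "recall"}

    def test_failures_are_recorded_not_raised(self, small_dataset, monkeypatch):
        calls = {"n": 0}

        def flaky(self, train, val):
            calls["n"] += 1
            if calls["n"] == 1:
                raise RuntimeError("injected failure")
            return Trainer.fit.__wrapped__(self, train, val) if hasattr(Trainer.fit, "__wrapped__") else original(self, train, val)

        original = Trainer.fit
        monkeypatch.setattr(Trainer, "fit", flaky)
        config = ClassifierConfig(e_gnn="GCN", l_gnn=1, d_gnn=4, l_fc=1, d_fc=4,
                                  p_h="MEAN", r_d=0.0)
        tc = TrainConfig(max_epochs=1, batch_size=16, seed=0)
        spec = SplitSpec(n_replicates=2, base_seed=0)
        table, summary = run_replicates(small_dataset, config, tc, spec,
                                        cbow=CbowParams(epochs=2))
        assert list(table.status) == ["failed", "ok"]
        assert "injected failure" in table.error.iloc[0]
        assert len(summary) == 3  # computed over the single completed replicate


class TestBuildGraphs:
    def test_one_graph_per_record(self, small_dataset, tiny_tables):
        mirna_table, mrna_table = tiny_tables
        graphs = build_graphs(small_dataset[:7], mirna_table, mrna_table)
        assert len(graphs) == 7
        for r, g in zip(small_dataset[:7], graphs):
            n_words = -(-len(r.mirna_seq) // 3) + -(-len(r.site_seq) // 3)
            assert g.n_nodes == n_words
            assert g.node_features.shape == (n_words, 16)
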