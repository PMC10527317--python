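"""Splits, fold-safe pipeline fitting, indicator ranking, and the
degenerate-optimiser contract of joint training."""

import numpy as np
import pytest

from copdfusion.ct import lite_config
from copdfusion.datatypes import FeatureTable
from copdfusion.fusion import FusionConfig
from copdfusion.gnn import GNNConfig
from copdfusion.graph import build_feature_graph
from copdfusion.metrics import MetricsRecord
from copdfusion.synthetic import default_spec, generate_paired_dataset
from copdfusion.train import (SplitSpec, TrainSpec, _mean_metrics,
                              _predict_proba, _prepare_modalities,
                              make_splits, rank_indicators, train_joint,
                              train_pb_branch, _zscored_clean)


class TestSplits:
    def test_ratio_sizes_and_stratification(self):
        labels = np.tile([0, 1], 50)
        part = make_splits(labels, SplitSpec(seed=0))[0]
        assert len(part["train"]) == 60
        assert len(part["val"]) == 20
        assert len(part["test"]) == 20
        for idx in part.values():
            assert 0.4 <= labels[idx].mean() <= 0.6
        merged = np.concatenate(list(part.values()))
        assert np.array_equal(np.sort(merged), np.arange(100))

    def test_kfold_partitions_test_folds(self):
        labels = np.tile([0, 1], 30)
        parts = make_splits(labels, SplitSpec(mode="kfold", folds=5, seed=1))
        tests = np.concatenate([p["test"] for p in parts])
        assert np.array_equal(np.sort(tests), np.arange(60))
        for p in parts:
            assert len(set(p["train"]) & set(p["test"])) == 0
            assert len(set(p["val"]) & set(p["test"])) == 0

    def test_deterministic_under_seed(self):
        labels = np.tile([0, 1], 40)
        a = make_splits(labels, SplitSpec(seed=5))[0]
        b = make_splits(labels, SplitSpec(seed=5))[0]
        for k in a:
            assert np.array_equal(a[k], b[k])

    def test_insufficient_class_counts_rejected(self):
        labels = np.array([0] * 30 + [1] * 3)
        with pytest.raises(ValueError):
            make_splits(labels, SplitSpec(mode="kfold", folds=5, seed=0))


@pytest.fixture(scope="module")
def small_paired():
    return generate_paired_dataset(
        default_spec(60, seed=13, volume_shape=(8, 16, 16)))


class TestPipelinePlumbing:
    def test_graph_and_stats_fitted_on_training_partition_only(
            self, small_paired):
        part = make_splits(small_paired.labels, SplitSpec(seed=0))[0]
        cfg = lite_config(input_shape=(8, 16, 16), epochs=1)
        prep, scaler, x_pb, graph, window, x_ct = _prepare_modalities(
            small_paired, part, cfg)
        tr = part["train"]
        # z-scoring centred on the training rows, not globally
        assert np.allclose(x_pb[tr].mean(0), 0.0, atol=1e-9)
        assert not np.allclose(x_pb.mean(0), 0.0, atol=1e-3)
        # the graph equals one built from the training rows alone
        ref = build_feature_graph(FeatureTable(
            x_pb[tr] * scaler[1] + scaler[0],
            small_paired.table.feature_names, small_paired.labels[tr]))
        assert graph.edges == ref.edges

    def test_joint_with_zero_lr_and_no_training_keeps_init_metrics(
            self, small_paired):
        part = make_splits(small_paired.labels, SplitSpec(seed=0))[0]
        kwargs = dict(
            gnn_config=GNNConfig(hidden_dim=4, out_dim=8, seed=0),
            cnn_config=lite_config(input_shape=(8, 16, 16), epochs=0),
            fusion_config=FusionConfig(d_h=8, n_tokens=2, d_model=4,
                                       heads=2, seed=0),
        )
        tspec = TrainSpec(joint_epochs=1, joint_lr=0.0, weight_decay=0.0,
                          head_epochs=0, ct_pretrain=False,
                          pb_pretrain=False, seed=0)
        res = train_joint(small_paired, part, tspec=tspec, **kwargs)
        # an optimiser no-op must leave every learned parameter at its
        # initial value (batch-norm running statistics are forward-pass
        # state, not parameters, and are exempt)
        tspec0 = TrainSpec(joint_epochs=0, head_epochs=0, ct_pretrain=False,
                           pb_pretrain=False, seed=0)
        res0 = train_joint(small_paired, part, tspec=tspec0, **kwargs)
        sd = dict(res.model.named_parameters())
        sd0 = dict(res0.model.named_parameters())
        assert sd.keys() == sd0.keys()
        for k in sd:
            assert np.allclose(sd[k].data, sd0[k].data), k
        # and the PB branch (stateless in eval) scores identically
        pb_probs = _predict_proba(res.model.pb_net, res.x_pb[part["test"]])
        pb_probs0 = _predict_proba(res0.model.pb_net, res0.x_pb[part["test"]])
        assert np.allclose(pb_probs, pb_probs0)

    def test_mean_metrics_ignores_undefined(self):
        recs = [MetricsRecord(0.8, None, 0.5, 0.5, None, 0.9),
                MetricsRecord(0.6, 0.7, 0.7, 0.5, 0.6, 0.7)]
        mean = _mean_metrics(recs)
        assert mean.acc == pytest.approx(0.7)
        assert mean.pre == pytest.approx(0.7)
        assert mean.auc == pytest.approx(0.8)


class TestIndicatorRanking:
    @pytest.fixture(scope="class")
    def trained_pb(self):
        ds = generate_paired_dataset(default_spec(
            200, seed=31, modality_signal="pb_only", volume_shape=(4, 8, 8)))
        part = make_splits(ds.labels, SplitSpec(seed=0))[0]
        x_pb, _ = _zscored_clean(ds, part["train"])
        graph = build_feature_graph(FeatureTable(
            x_pb[part["train"]], ds.table.feature_names,
            ds.labels[part["train"]]))
        net, _ = train_pb_branch(x_pb[part["train"]],
                                 ds.labels[part["train"]], graph,
                                 GNNConfig(seed=0), epochs=60, seed=0,
                                 x_val=x_pb[part["val"]],
                                 y_val=ds.labels[part["val"]])
        return net, x_pb, ds

    def test_report_is_deterministic(self, trained_pb):
        net, x_pb, ds = trained_pb
        r1 = rank_indicators(net, x_pb, ds.labels, ds.table.feature_names)
        r2 = rank_indicators(net, x_pb, ds.labels, ds.table.feature_names)
        assert r1.shortlist == r2.shortlist
        assert r1.frame.equals(r2.frame)

    def test_ranks_are_a_permutation_and_shortlist_sized(self, trained_pb):
        net, x_pb, ds = trained_pb
        rep = rank_indicators(net, x_pb, ds.labels, ds.table.feature_names,
                              q=4)
        ranks = rep.frame.loc[rep.frame["selected"], "rank"]
        m = int(np.ceil(net.config.pool_ratio * net.graph.n_nodes))
        assert sorted(ranks) == list(range(1, m + 1))
        assert len(rep.shortlist) == 4

    def test_group_stats_columns_present(self, trained_pb):
        net, x_pb, ds = trained_pb
        rep = rank_indicators(net, x_pb, ds.labels, ds.table.feature_names,
                              raw_values=ds.table.values)
        for col in ("difference", "ci_low", "ci_high", "t", "p"):
            assert col in rep.frame.columns
            assert np.isfinite(rep.frame[col]).all()


class TestBranchAccuracyProperties:
    def test_pb_branch_reaches_085_on_planted_signal(self):
        """The GNN branch alone, trained on tables with 4 informative
        indicators among 24 (n=400), reaches seed-mean test accuracy
        >= 0.85 over five seeds."""
        accs = []
        for s in range(5):
            ds = generate_paired_dataset(default_spec(
                400, seed=2000 + s, modality_signal="pb_only",
                volume_shape=(4, 8, 8)))
            part = make_splits(ds.labels, SplitSpec(seed=s))[0]
            x_pb, _ = _zscored_clean(ds, part["train"])
            net, _ = train_pb_branch(
                x_pb[part["train"]], ds.labels[part["train"]],
                build_feature_graph(FeatureTable(
                    x_pb[part["train"]], ds.table.feature_names,
                    ds.labels[part["train"]])),
                GNNConfig(seed=s), seed=s,
                x_val=x_pb[part["val"]], y_val=ds.labels[part["val"]])
            proba = _predict_proba(net, x_pb[part["test"]], batch=256)
            accs.append(float(
                ((proba > 0.5).astype(int) == ds.labels[part["test"]]).mean()))
        assert np.mean(accs) >= 0.85, accs

    def test_ct_branch_reaches_085_on_texture_signal(self):
        """The lite 3-D CNN alone, trained on 16x32x32 volumes whose class
        signal is low-attenuation blob density (n=300), reaches seed-mean
        test accuracy >= 0.85 over five seeds."""
        from copdfusion.ct import prepare_volumes, pretrain_cnn

        accs = []
        for s in range(5):
            ds = generate_paired_dataset(default_spec(
                300, seed=3000 + s, modality_signal="ct_only"))
            part = make_splits(ds.labels, SplitSpec(seed=s))[0]
            cfg = lite_config(epochs=25, seed=s)
            x_ct = prepare_volumes(ds.volumes, cfg)
            model, _ = pretrain_cnn(
                x_ct[part["train"]], ds.labels[part["train"]], cfg,
                x_val=x_ct[part["val"]], y_val=ds.labels[part["val"]])
            proba = _predict_proba(model, x_ct[part["test"]], batch=32)
            accs.append(float(
                ((proba > 0.5).astype(int) == ds.labels[part["test"]]).mean()))
        assert np.mean(accs) >= 0.85, accs
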