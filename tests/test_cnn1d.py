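"""1-D CNN family: depth convention, shape propagation, parameter counts, sweeps."""

import numpy as np
import pytest

from specnet.cnn1d import (
    Cnn1dClassifier,
    Cnn1dConfig,
    build_1d_model,
    fc1_size,
    shape_trace,
    sweep_depth,
    sweep_kernel,
    sweep_maps,
    sweep_pool,
)
from specnet.nn import Conv1d, Dense, Pool1d, TrainSpec


@pytest.mark.parametrize("n_stages,depth", [(1, 5), (2, 7), (3, 9), (4, 11), (5, 13)])
def test_depth_counts_stages_fc_and_output(n_stages, depth):
    cfg = Cnn1dConfig(n_stages=n_stages, conv_width=5, pool_width=2,
                      feature_maps=12, input_length=1609)
    assert cfg.depth == depth


def test_layer_sequence_for_two_stages():
    cfg = Cnn1dConfig(n_stages=2, conv_width=5, pool_width=2, feature_maps=4,
                      input_length=101, n_classes=3)
    net = build_1d_model(cfg)
    kinds = [type(l).__name__ for l in net.layers]
    assert kinds == [
        "Conv1d", "ReLU", "Pool1d", "Conv1d", "ReLU", "Pool1d",
        "Flatten", "Dense", "ReLU", "Dropout", "Dense", "ReLU", "Dropout", "Dense",
    ]


def test_reference_shape_trace_depth_11():
    # hand propagation: conv 1*15 shortens by 14, pool 1*2 halves (floor)
    cfg = Cnn1dConfig(n_stages=4, conv_width=15, pool_width=2, feature_maps=24)
    lengths = [length for _, length in shape_trace(cfg, warn=False)]
    assert lengths[:9] == [1609, 1595, 797, 783, 391, 377, 188, 174, 87]
    assert fc1_size(cfg) == 87 * 24


def test_truncation_rule_shape_example():
    cfg = Cnn1dConfig(n_stages=1, conv_width=5, pool_width=2, feature_maps=3,
                      input_length=1609)
    trace = dict(shape_trace(cfg, warn=False))
    assert trace["conv1"] == 1605
    assert trace["pool1"] == 802  # 1605 // 2, remainder dropped
    assert fc1_size(cfg) == 802 * 3


def test_fc1_scales_linearly_in_feature_maps():
    sizes = [
        fc1_size(Cnn1dConfig(n_stages=2, conv_width=5, pool_width=2,
                             feature_maps=m, input_length=201))
        for m in (4, 8, 12)
    ]
    assert sizes[1] == 2 * sizes[0]
    assert sizes[2] == 3 * sizes[0]


def test_conv_width_equal_to_input_gives_length_one():
    cfg = Cnn1dConfig(n_stages=1, conv_width=101, pool_width=1, feature_maps=2,
                      input_length=101)
    assert dict(shape_trace(cfg, warn=False))["conv1"] == 1


def test_overdeep_config_rejected():
    with pytest.raises(ValueError, match="shorter than"):
        Cnn1dConfig(n_stages=5, conv_width=15, pool_width=5, feature_maps=2,
                    input_length=201)


def test_parameter_count_matches_closed_form():
    cfg = Cnn1dConfig(n_stages=2, conv_width=5, pool_width=2, feature_maps=6,
                      input_length=201, n_classes=3)
    net = build_1d_model(cfg)
    M, m, K = cfg.feature_maps, cfg.conv_width, cfg.n_classes
    F = fc1_size(cfg)
    expected = (
        (1 * m * M + M)          # stage-1 conv weights + biases
        + (M * m * M + M)        # stage-2 conv
        + (F * F + F) * 2        # two fully connected layers
        + (F * K + K)            # output layer
    )
    assert net.n_parameters() == expected


def test_shape_trace_positive_and_decreasing_through_pooling():
    cfg = Cnn1dConfig(n_stages=3, conv_width=7, pool_width=2, feature_maps=4,
                      input_length=301)
    trace = shape_trace(cfg, warn=False)
    lengths = [length for name, length in trace if name.startswith(("conv", "pool"))]
    assert all(length > 0 for length in lengths)
    pools = [length for name, length in trace if name.startswith("pool")]
    assert all(a > b for a, b in zip(pools, pools[1:]))


def test_seeded_build_reproducible():
    cfg = Cnn1dConfig(n_stages=1, conv_width=5, pool_width=2, feature_maps=3,
                      input_length=101, n_classes=3)
    a = build_1d_model(cfg, seed=5)
    b = build_1d_model(cfg, seed=5)
    for pa, pb in zip(a.all_parameters(), b.all_parameters()):
        assert np.array_equal(pa, pb)


def test_eval_forward_probabilities_and_determinism(tiny_prep):
    cfg = Cnn1dConfig(n_stages=1, conv_width=5, pool_width=2, feature_maps=3,
                      input_length=201, n_classes=3)
    net = build_1d_model(cfg)
    x = np.asarray(tiny_prep.absorbance[:4], dtype=np.float32)[:, None, :]
    p1 = net.predict_proba(x)
    p2 = net.predict_proba(x)
    assert p1.shape == (4, 3)
    assert np.allclose(p1.sum(axis=1), 1.0, atol=1e-6)
    assert np.array_equal(p1, p2)  # dropout is inert at evaluation


@pytest.fixture(scope="module")
def quick_spec():
    return TrainSpec(max_epochs=3, batch_size=9, early_stop_patience=3, seed=0)


@pytest.fixture(scope="module")
def small_cfg():
    return Cnn1dConfig(n_stages=1, conv_width=5, pool_width=2, feature_maps=6,
                       input_length=201, n_classes=3)


def test_depth_sweep_table_shape(tiny_prep, quick_spec, small_cfg):
    table = sweep_depth(tiny_prep, depths=(5, 7, 9, 11, 13), base_cfg=small_cfg,
                        spec=quick_spec)
    assert len(table) == 5
    assert list(table["depth"]) == [5, 7, 9, 11, 13]
    assert table["test_accuracy"].between(0, 100).all()
    assert table["train_accuracy"].between(0, 100).all()


def test_kernel_sweep_runs_for_extreme_widths(tiny_prep, quick_spec, small_cfg):
    table = sweep_kernel(tiny_prep, widths=(3, 15), base_cfg=small_cfg, spec=quick_spec)
    assert list(table["conv_width"]) == [3, 15]
    assert table["test_accuracy"].between(0, 100).all()


def test_pool_sweep_includes_identity_pooling(tiny_prep, quick_spec, small_cfg):
    table = sweep_pool(tiny_prep, widths=(1, 2, 3), base_cfg=small_cfg, spec=quick_spec)
    assert list(table["pool_width"]) == [1, 2, 3]
    assert table["test_accuracy"].between(0, 100).all()


def test_maps_sweep_row_count(tiny_prep, quick_spec, small_cfg):
    counts = (6, 12, 18)
    table = sweep_maps(tiny_prep, counts=counts, base_cfg=small_cfg, spec=quick_spec)
    assert len(table) == len(counts)


def test_classifier_rejects_mismatched_config(tiny_prep):
    bad = Cnn1dConfig(n_stages=1, conv_width=5, pool_width=2, feature_maps=3,
                      input_length=999, n_classes=3)
    with pytest.raises(ValueError, match="input_length"):
        Cnn1dClassifier(tiny_prep, bad)


def test_fit_learns_separable_tiny_problem(tiny_prep):
    cfg = Cnn1dConfig(n_stages=1, conv_width=5, pool_width=2, feature_maps=6,
                      input_length=201, n_classes=3)
    res = Cnn1dClassifier(tiny_prep, cfg).fit(
        TrainSpec(learning_rate=0.05, max_epochs=50, batch_size=9, dropout_p=0.0,
                  early_stop_patience=50, seed=1)
    )
    assert res.accuracy("train") == 100.0
    assert res.state.n_epochs <= 50
    assert "test accuracy" in res.summary()
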