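"""Synthetic spectra generator: design counts, determinism, separability."""

import dataclasses

import numpy as np
import pytest

from specnet.datasets import (
    SynthConfig,
    WavenumberGrid,
    class_template,
    default_grid,
    generate_dataset,
)


def test_grid_invariants():
    g = default_grid()
    assert g.n_points == 1609
    assert g.values[0] == 4000.0 and g.values[-1] == 10000.0
    assert np.all(np.diff(g.values) > 0)


@pytest.mark.parametrize("bad", [
    [4000.0], [4000.0, 4000.0, 10000.0], [5000.0, 10000.0], [4000.0, 9000.0],
])
def test_grid_rejects_malformed(bad):
    with pytest.raises(ValueError):
        WavenumberGrid(np.asarray(bad))


def test_design_counts_per_class(tiny_ds, tiny_cfg):
    assert tiny_ds.n_samples == tiny_cfg.n_classes * tiny_cfg.samples_per_class
    for k in range(1, tiny_cfg.n_classes + 1):
        mask = tiny_ds.labels == k
        assert mask.sum() == tiny_cfg.samples_per_class
        assert (tiny_ds.split[mask] == "train").sum() == tiny_cfg.train_per_class
        assert (tiny_ds.split[mask] == "test").sum() == (
            tiny_cfg.samples_per_class - tiny_cfg.train_per_class
        )


def test_fixed_seed_bit_identical(tiny_cfg):
    a = generate_dataset(tiny_cfg)
    b = generate_dataset(dataclasses.replace(tiny_cfg, seed=tiny_cfg.seed))
    assert np.array_equal(a.absorbance, b.absorbance)
    assert np.array_equal(a.labels, b.labels)


def test_different_seeds_differ(tiny_cfg):
    a = generate_dataset(tiny_cfg)
    b = generate_dataset(dataclasses.replace(tiny_cfg, seed=tiny_cfg.seed + 1))
    assert not np.allclose(a.absorbance, b.absorbance)


def test_zero_noise_samples_equal_template():
    cfg = SynthConfig(
        n_classes=3, samples_per_class=4, train_per_class=2, n_points=101,
        n_replicates=1, noise_sd=0.0, baseline_slope_sd=0.0, baseline_offset_sd=0.0,
        seed=3,
    )
    ds = generate_dataset(cfg)
    grid = default_grid(cfg.n_points)
    for k in range(1, 4):
        template = class_template(k, cfg, grid)
        rows = ds.absorbance[ds.labels == k]
        assert np.allclose(rows, template[None, :], atol=1e-14)
        assert np.allclose(rows.var(axis=0), 0.0)


def test_zero_separability_collapses_templates():
    cfg = SynthConfig(n_classes=13, samples_per_class=2, train_per_class=1,
                      n_points=101, separability=0.0, seed=5)
    t1 = class_template(1, cfg)
    t13 = class_template(13, cfg)
    assert np.array_equal(t1, t13)


def test_class_id_range_checked():
    cfg = SynthConfig(n_classes=3, samples_per_class=2, train_per_class=1, n_points=101)
    with pytest.raises(ValueError):
        class_template(0, cfg)
    with pytest.raises(ValueError):
        class_template(4, cfg)


def test_band_peak_height_matches_amplitude():
    # single class band of pinned amplitude: the excess over the shared
    # component must peak at (approximately, up to grid discretisation) it
    cfg = SynthConfig(
        n_classes=2, samples_per_class=2, train_per_class=1, n_points=2001,
        bands_per_class=1, band_amplitude_range=(0.5, 0.5), seed=9,
    )
    base = class_template(1, dataclasses.replace(cfg, separability=0.0))
    peak = np.max(class_template(1, cfg) - base)
    assert peak == pytest.approx(0.5, rel=1e-3)


def test_separability_monotone_in_between_class_distance():
    dists = []
    for sep in (0.5, 1.0, 2.0):
        cfg = SynthConfig(n_classes=4, samples_per_class=2, train_per_class=1,
                          n_points=201, separability=sep, seed=11)
        templates = np.array([class_template(k, cfg) for k in range(1, 5)])
        d = [
            np.linalg.norm(templates[i] - templates[j])
            for i in range(4) for j in range(i + 1, 4)
        ]
        dists.append(np.mean(d))
    assert dists[0] < dists[1] < dists[2]


def test_adding_classes_keeps_earlier_templates():
    small = SynthConfig(n_classes=3, samples_per_class=2, train_per_class=1, n_points=101, seed=2)
    big = dataclasses.replace(small, n_classes=6)
    for k in (1, 2, 3):
        assert np.array_equal(class_template(k, small), class_template(k, big))


def test_sign_flip_balances_class_means():
    cfg = SynthConfig(
        n_classes=3, samples_per_class=40, train_per_class=30, n_points=201,
        separability=3.0, noise_sd=0.0, baseline_slope_sd=0.0,
        baseline_offset_sd=0.0, band_sign_flip=True, seed=13,
    )
    ds = generate_dataset(cfg)
    means = np.array([ds.absorbance[ds.labels == k].mean(axis=0) for k in (1, 2, 3)])
    # exact sign balance: all class means collapse onto the shared component
    assert np.allclose(means[0], means[1], atol=1e-12)
    assert np.allclose(means[0], means[2], atol=1e-12)
    # but within-class spread concentrates at the class bands
    assert ds.absorbance[ds.labels == 1].std(axis=0).max() > 0.1


@pytest.mark.parametrize("kwargs", [
    {"samples_per_class": 0},
    {"train_per_class": 12},  # == samples_per_class
    {"noise_sd": -1.0},
    {"separability": -0.5},
    {"n_replicates": 0},
])
def test_invalid_config_rejected(kwargs):
    base = dict(n_classes=3, samples_per_class=12, train_per_class=9)
    with pytest.raises(ValueError):
        SynthConfig(**{**base, **kwargs})
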