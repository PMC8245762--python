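"""Splitting, prior-weighted sampling, augmentation, losses, training loop."""

import numpy as np
import pytest

from acpcnet.heatmap_targets import HeatmapSpec, make_sampling_prior, make_target_heatmap
from acpcnet.network import NetConfig, build_network
from acpcnet.synthetic_phantom import PhantomParams, default_template, generate_cohort
from acpcnet.training import (
    TrainConfig,
    augment_window,
    compute_loss,
    sample_windows,
    split_dataset,
    train_model,
)
from acpcnet.volumes_io import FiducialSet, Volume


# ---------------------------------------------------------------------- split

def test_split_908_gives_726_91_91():
    tr, va, te = split_dataset(908, (80, 10, 10), seed=0)
    assert (len(tr), len(va), len(te)) == (726, 91, 91)


def test_split_exact_division():
    tr, va, te = split_dataset(10, (80, 10, 10), seed=1)
    assert (len(tr), len(va), len(te)) == (8, 1, 1)


def test_split_disjoint_exhaustive_and_seed_dependent():
    tr, va, te = split_dataset(37, (80, 10, 10), seed=5)
    assert sorted(np.concatenate([tr, va, te])) == list(range(37))
    tr2, va2, te2 = split_dataset(37, (80, 10, 10), seed=6)
    assert (len(tr), len(va), len(te)) == (len(tr2), len(va2), len(te2))
    assert not (set(te) == set(te2) and set(va) == set(va2))


def test_split_bad_ratios_rejected():
    with pytest.raises(ValueError, match="sum"):
        split_dataset(10, (80, 10, 5), seed=0)


# ------------------------------------------------------------------- sampling

@pytest.fixture(scope="module")
def sampling_setup():
    params = PhantomParams(shape=(48, 48, 36), jitter_mm=0, noise_sigma=0, seed=0)
    from acpcnet.synthetic_phantom import generate_phantom

    vol, fids = generate_phantom(params)
    spec = HeatmapSpec()
    target = make_target_heatmap(vol.shape, fids, vol.affine, spec)
    prior = make_sampling_prior(default_template(), vol.shape, vol.affine, spec)
    return vol, fids, target, prior


def test_sampled_windows_fully_inside_bounds(sampling_setup):
    vol, _, target, prior = sampling_setup
    wins = sample_windows(vol, target, prior, (16, 16, 1), n=10000, seed=3)
    assert len(wins) == 10000
    for wi, wt in wins[:100]:
        assert wi.shape == (16, 16, 1) and wt.shape == (16, 16, 1)
    # shapes canonical for all => every slab fit inside the volume
    assert all(w[0].shape == (16, 16, 1) for w in wins)


def test_prior_sampling_hits_landmarks_far_more_than_uniform(sampling_setup):
    vol, _, target, prior = sampling_setup
    uniform = Volume(
        data=np.full(vol.shape, 1.0 / np.prod(vol.shape)), affine=vol.affine
    )
    def hit_fraction(pri):
        wins = sample_windows(vol, target, pri, (16, 16, 1), n=2000, seed=7)
        return np.mean([w[1].max() > 0.6 for w in wins])

    assert hit_fraction(prior) > 5 * max(hit_fraction(uniform), 0.02)


def test_sampled_centers_follow_prior_chi_square(sampling_setup):
    from scipy.stats import chisquare

    vol, _, target, prior = sampling_setup
    n = 5000
    # 1-voxel windows: the returned target value identifies the center's
    # target-heatmap stratum, whose probability under the prior is known
    wins = sample_windows(vol, target, prior, (1, 1, 1), n=n, seed=11, orient=False)
    vals = np.array([w[1][0, 0, 0] for w in wins])
    edges = np.array([0.0, 1e-6, 0.01, 0.1, 0.5, 1.0001])
    obs, _ = np.histogram(vals, bins=edges)
    pv = prior.data.ravel()
    tv = target.data.ravel()
    exp = np.array([pv[(tv >= lo) & (tv < hi)].sum() for lo, hi in zip(edges[:-1], edges[1:])])
    exp = exp / exp.sum() * n
    keep = exp > 5
    res = chisquare(obs[keep], exp[keep] * obs[keep].sum() / exp[keep].sum())
    assert res.pvalue > 0.01


def test_default_window_is_quasi_2d_72():
    assert TrainConfig().window == (72, 72, 1)
    assert TrainConfig().batch_windows == 64
    assert TrainConfig().iterations == 2500
    assert TrainConfig().learning_rate == pytest.approx(0.005)
    assert TrainConfig().weight_decay == pytest.approx(1e-5)


def test_degenerate_prior_rejected(sampling_setup):
    vol, _, target, _ = sampling_setup
    zero = Volume(data=np.zeros(vol.shape), affine=vol.affine)
    with pytest.raises(ValueError, match="prior"):
        sample_windows(vol, target, zero, (8, 8, 1), n=1, seed=0)


# ---------------------------------------------------------------- augmentation

def test_augmentation_applies_identical_geometry_to_pair():
    rng = np.random.default_rng(0)
    wi = rng.normal(size=(16, 16, 1)).astype(np.float32)
    wt = np.zeros((16, 16, 1), dtype=np.float32)
    wt[4, 9, 0] = 1.0
    marker = wi[4, 9, 0]
    for seed in range(20):
        ai, at = augment_window((wi, wt), seed=seed, scale_aug_pct=0.0)
        pos = np.unravel_index(int(np.argmax(at)), at.shape)
        assert ai[pos] == marker  # target peak tracks the same input voxel
        assert sorted(ai.ravel()) == sorted(wi.ravel())  # flips permute values


def test_augmentation_preserves_shape_and_target_bound():
    rng = np.random.default_rng(1)
    wi = rng.normal(size=(24, 24, 1)).astype(np.float32)
    wt = np.clip(rng.normal(0.5, 0.3, size=(24, 24, 1)), 0, 1).astype(np.float32)
    for seed in range(100):
        ai, at = augment_window((wi, wt), seed=seed)
        assert ai.shape == wi.shape and at.shape == wt.shape
        assert at.max() <= 1.0 + 1e-6  # renormalized after rescaling


def test_augmentation_seeded_determinism():
    rng = np.random.default_rng(2)
    pair = (rng.normal(size=(12, 12, 1)).astype(np.float32),
            rng.normal(size=(12, 12, 1)).astype(np.float32))
    a1, t1 = augment_window(pair, seed=9)
    a2, t2 = augment_window(pair, seed=9)
    np.testing.assert_array_equal(a1, a2)
    np.testing.assert_array_equal(t1, t2)


# --------------------------------------------------------------------- losses

def test_loss_identity_is_zero():
    p = np.random.default_rng(0).normal(size=(2, 1, 8, 8, 1))
    cfg = TrainConfig(loss="rmse", weight_decay=0.0)
    assert compute_loss(p, p.copy(), cfg) == 0.0


def test_rmse_of_unit_residual_is_one():
    t = np.zeros((3, 1, 5, 5, 1))
    cfg = TrainConfig(loss="rmse", weight_decay=0.0)
    assert compute_loss(t + 1.0, t, cfg) == pytest.approx(1.0)


def test_huber_piecewise_closed_form():
    cfg = TrainConfig(loss="huber", huber_delta=1.0, weight_decay=0.0)
    t = np.zeros((1, 1, 2, 2, 1))
    assert compute_loss(t + 0.5, t, cfg) == pytest.approx(0.125)  # quadratic zone
    assert compute_loss(t + 2.0, t, cfg) == pytest.approx(1.5)  # linear zone


def test_regularizer_terms_match_brute_force():
    m = build_network(NetConfig(base_channels=2, n_blocks_per_stage=1), seed=0)
    p = np.zeros((1, 1, 4, 4, 1))
    from acpcnet.training import _weight_arrays

    l1 = sum(np.abs(w).sum() for w in _weight_arrays(m.params))
    l2 = sum((w.astype(np.float64) ** 2).sum() for w in _weight_arrays(m.params))
    cfg1 = TrainConfig(loss="rmse", regularizer="L1", reg_weight=0.01)
    cfg2 = TrainConfig(loss="rmse", regularizer="L2", reg_weight=0.01)
    assert compute_loss(p, p, cfg1, m) == pytest.approx(0.01 * l1, rel=1e-6)
    assert compute_loss(p, p, cfg2, m) == pytest.approx(0.01 * l2, rel=1e-6)


def test_train_config_validation():
    with pytest.raises(ValueError):
        TrainConfig(loss="mae")
    with pytest.raises(ValueError):
        TrainConfig(split_ratios=(70, 10, 10))
    with pytest.raises(ValueError):
        TrainConfig(optimizer="sgd")


# ------------------------------------------------------------- training loop

def test_training_loop_curve_length_and_determinism():
    cohort = generate_cohort(
        6, PhantomParams(shape=(40, 40, 28), acpc_distance_mm=18, seed=21)
    )
    net = NetConfig(base_channels=2, n_blocks_per_stage=1, dilations=(1, 2))
    cfg = TrainConfig.desk(iterations=8, batch_windows=4, window=(24, 24, 1), seed=3)
    tmpl = default_template(18)
    m1, c1 = train_model(cohort, cfg, net, template=tmpl)
    assert len(c1) == cfg.iterations
    assert all(np.isfinite(c1.train_loss))
    assert c1.val_iterations[-1] == cfg.iterations
    m2, c2 = train_model(cohort, cfg, net, template=tmpl)
    np.testing.assert_allclose(c1.train_loss, c2.train_loss, rtol=0, atol=0)


def test_training_requires_at_least_two_volumes():
    cohort = generate_cohort(
        1, PhantomParams(shape=(40, 40, 28), acpc_distance_mm=18, seed=2)
    )
    with pytest.raises(ValueError, match="2"):
        train_model(cohort, TrainConfig.desk(iterations=1))
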