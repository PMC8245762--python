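"""Error metrics, scaled-MAD outlier filtering, model-comparison statistics."""

import math
import statistics

import numpy as np
import pytest
from scipy.optimize import brentq
from scipy.special import erfc

from acpcnet.evaluation import (
    StatConfig,
    annotation_consensus,
    compare_models,
    localization_errors,
    make_error_table,
    scaled_mad_constant,
    scaled_mad_filter,
    summarize_errors,
)
from acpcnet.volumes_io import FiducialSet


def _fids(ac, pc):
    return FiducialSet(points=[("AC", np.asarray(ac, float)), ("PC", np.asarray(pc, float))])


# ------------------------------------------------------------ distance errors

def test_localization_error_3_4_5():
    errs = localization_errors(_fids((1, 2, 2), (0, 0, 0)), _fids((0, 0, 0), (0, 0, 0)))
    assert errs["AC"] == pytest.approx(3.0)
    assert errs["PC"] == 0.0


def test_localization_error_rigid_rotation_invariance(rng):
    for _ in range(20):
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        if np.linalg.det(q) < 0:
            q[:, 0] = -q[:, 0]
        a, b = rng.normal(size=3), rng.normal(size=3)
        c, d = rng.normal(size=3), rng.normal(size=3)
        base = localization_errors(_fids(a, b), _fids(c, d))
        rot = localization_errors(_fids(q @ a, q @ b), _fids(q @ c, q @ d))
        assert rot["AC"] == pytest.approx(base["AC"], abs=1e-9)
        assert rot["PC"] == pytest.approx(base["PC"], abs=1e-9)


def test_localization_error_label_mismatch():
    with pytest.raises(ValueError, match="label"):
        localization_errors(
            _fids((0, 0, 0), (1, 1, 1)),
            FiducialSet(points=[("AC", np.zeros(3)), ("MID", np.ones(3))]),
        )


# ---------------------------------------------------------------- scaled MAD

def test_scaled_mad_constant_against_root_finding():
    # c = -1/(sqrt(2)*x) where erfc(x) = 3/2
    x = brentq(lambda t: erfc(t) - 1.5, -10, 0, xtol=1e-15)
    assert scaled_mad_constant() == pytest.approx(-1.0 / (math.sqrt(2) * x), abs=1e-9)
    assert scaled_mad_constant() == pytest.approx(1.4826022185, abs=1e-9)


def test_scaled_mad_hand_worked_example():
    kept, flags, smad = scaled_mad_filter([1, 2, 3, 4, 100])
    assert smad == pytest.approx(1.482602, abs=1e-6)
    # threshold 3*smad ~= 4.4478 around median 3: only 100 is flagged
    np.testing.assert_array_equal(flags, [False, False, False, False, True])
    np.testing.assert_array_equal(kept, [1, 2, 3, 4])


def test_scaled_mad_constant_sample_no_outliers():
    kept, flags, smad = scaled_mad_filter([5, 5, 5, 5])
    assert smad == 0.0 and not flags.any() and len(kept) == 4


def test_scaled_mad_zero_with_nonidentical_flags_and_warns():
    with pytest.warns(RuntimeWarning, match="scaled MAD is zero"):
        kept, flags, smad = scaled_mad_filter([1, 1, 1, 1, 9])
    assert smad == 0.0
    np.testing.assert_array_equal(flags, [False] * 4 + [True])


def test_scaled_mad_small_sample_rejected():
    with pytest.raises(ValueError):
        scaled_mad_filter([1, 2])


def _brute_force_mad_filter(values, k=3.0):
    """Independent oracle: pure-python evaluation of the printed formula."""
    c = 1.4826022185056018
    med = statistics.median(values)
    dev = [abs(v - med) for v in values]
    smad = c * statistics.median(dev)
    flags = [d > k * smad if smad > 0 else d > 0 for d in dev]
    return flags, smad


def test_scaled_mad_equals_brute_force_on_random_samples(rng):
    for _ in range(1000):
        n = int(rng.integers(3, 40))
        sample = rng.normal(rng.uniform(-5, 5), rng.uniform(0.1, 3), size=n)
        if rng.random() < 0.3:  # heavy outliers
            sample[: max(1, n // 8)] += rng.uniform(10, 100)
        _, flags, smad = scaled_mad_filter(sample)
        bf_flags, bf_smad = _brute_force_mad_filter(list(sample))
        assert smad == pytest.approx(bf_smad, rel=1e-9)
        assert list(flags) == bf_flags


def test_scaled_mad_estimates_sigma_for_normal_data(rng):
    sample = rng.normal(3.0, 1.7, size=10_000)
    _, _, smad = scaled_mad_filter(sample)
    assert smad == pytest.approx(1.7, rel=0.05)


# ------------------------------------------------------------------ summaries

def test_summarize_simple_sample():
    assert summarize_errors([1, 2, 3]) == (2.0, 1.0, 3.0, 3)


def test_summarize_single_value_rejected():
    with pytest.raises(ValueError):
        summarize_errors([1.5])


def test_summarize_mean_fixed_point(rng):
    sample = list(rng.normal(size=10))
    mean = summarize_errors(sample)[0]
    assert summarize_errors(sample + [mean])[0] == pytest.approx(mean)


# ------------------------------------------------------------- model compare

def _table(samples: dict[str, np.ndarray], landmark="AC"):
    records = []
    for model, vals in samples.items():
        for i, v in enumerate(vals):
            records.append((f"vol{i}", model, landmark, float(v)))
    return make_error_table(records)


def test_identical_samples_t_zero_p_one():
    t = _table({"a": np.array([1.0, 2, 3]), "b": np.array([1.0, 2, 3])})
    rep = compare_models(t, StatConfig(n_comparisons=1))
    pw = rep["landmarks"]["AC"]["pairwise"][0]
    assert pw["t"] == pytest.approx(0.0)
    assert pw["p"] == pytest.approx(1.0)


def test_bonferroni_divisor_six_models_is_720():
    samples = {f"m{i}": np.random.default_rng(i).normal(1, 0.1, 20) + i * 0.01 for i in range(6)}
    rep = compare_models(_table(samples))
    assert rep["n_comparisons"] == 720
    assert rep["adjusted_alpha"] == pytest.approx(0.05 / 720)
    assert rep["adjusted_alpha"] == pytest.approx(6.944e-5, rel=1e-3)


def test_one_tailed_direction_against_baseline(rng):
    better = np.abs(rng.normal(0.8, 0.3, 200))
    worse = np.abs(rng.normal(1.2, 0.3, 200))
    rep = compare_models(
        _table({"baseline": worse, "model": better}),
        StatConfig(n_comparisons=1),
        baseline="baseline",
    )
    pw = rep["landmarks"]["AC"]["pairwise"][0]
    assert pw["tail"] == "one-tailed"
    assert pw["p"] < 1e-6 and pw["p_display"] == "<0.001"
    # reversed direction: model worse than baseline -> p near 1
    rep2 = compare_models(
        _table({"baseline": better, "model": worse}),
        StatConfig(n_comparisons=1),
        baseline="baseline",
    )
    assert rep2["landmarks"]["AC"]["pairwise"][0]["p"] > 0.999


def test_false_positive_rate_controlled_under_null(rng):
    sig = 0
    total = 0
    for rep_i in range(200):
        samples = {m: np.abs(rng.normal(1.0, 0.3, 50)) for m in ("a", "b", "c")}
        rep = compare_models(_table(samples))  # divisor 3! = 6
        for pw in rep["landmarks"]["AC"]["pairwise"]:
            sig += pw["significant"]
            total += 1
    assert sig / total <= 0.05


def test_compare_models_requires_enough_data():
    with pytest.raises(ValueError):
        compare_models(_table({"a": np.array([1.0, 2, 3])}))
    with pytest.raises(ValueError):
        compare_models(_table({"a": np.array([1.0, 2]), "b": np.array([1.0, 2, 3])}))


# ------------------------------------------------------------------ consensus

def test_consensus_boundary_two_mm_not_flagged():
    sets = [_fids((0, 0, 0), (0, -26, 0)), _fids((2, 0, 0), (0, -26, 0))]
    cons, dists, flags = annotation_consensus(sets)
    np.testing.assert_allclose(cons["AC"], (1, 0, 0))
    assert dists["AC"] == [pytest.approx(2.0)]
    assert not flags["AC"]  # strict > 2.0 rule


def test_consensus_flags_above_threshold():
    sets = [_fids((0, 0, 0), (0, -26, 0)), _fids((0, 0, 2.5), (0, -26, 0))]
    _, _, flags = annotation_consensus(sets)
    assert flags["AC"] and not flags["PC"]


def test_consensus_single_annotator_identity():
    s = _fids((1, 2, 3), (4, 5, 6))
    cons, dists, flags = annotation_consensus([s])
    np.testing.assert_array_equal(cons.positions(), s.positions())
    assert dists["AC"] == [] and not any(flags.values())


def test_stat_config_validation():
    with pytest.raises(ValueError):
        StatConfig(mad_k=0)
    with pytest.raises(ValueError):
        StatConfig(alpha=1.5)
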