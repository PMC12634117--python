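"""Model heads, losses, risk composition, training mechanics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ecgsurv.cohort import DEFAULT_EDGES
from ecgsurv.model import (BackboneConfig, EcgRiskModel, SurvivalDataset,
                           TrainConfig, classification_loss, cumulative_risk,
                           load_model, save_model, survival_loss,
                           survival_loss_grad, train_model)

TINY = BackboneConfig(n_leads=2, input_len=128, stem_channels=4, stem_kernel=5,
                      stem_stride=2, channels=(6,), kernel=5, strides=(2,),
                      dropout=0.1)


# --------------------------------------------------------------------------
# losses


def test_survival_loss_worked_values():
    assert survival_loss([0.5, 0.2], [1, 0], [1, 0]) == pytest.approx(
        -np.log(0.5), abs=1e-12)
    assert survival_loss([0.1, 0.1], [0, 0], [1, 1]) == pytest.approx(
        -2 * np.log(0.9), abs=1e-12)
    assert survival_loss([0.3, 0.7], [0, 1], [0, 0]) == 0.0


def test_classification_loss_worked_values():
    assert classification_loss([0.5], [1]) == pytest.approx(np.log(2), abs=1e-12)
    assert classification_loss([0.9], [0]) == pytest.approx(-np.log(0.1), abs=1e-12)
    assert classification_loss([1 - 1e-9], [1]) < 1e-6  # perfect-fit limit


def test_loss_clamps_out_of_range_probs():
    with pytest.warns(UserWarning, match="clamped"):
        val = survival_loss([1.0], [1], [1])
    assert np.isfinite(val)


def test_survival_loss_gradient_matches_finite_differences():
    rng = np.random.default_rng(0)
    h = rng.uniform(0.05, 0.95, (5, 7))
    y = (rng.random((5, 7)) < 0.3).astype(float)
    m = (rng.random((5, 7)) < 0.7).astype(float)
    analytic = survival_loss_grad(h, y, m)
    eps = 1e-6
    for _ in range(20):
        i, k = rng.integers(5), rng.integers(7)
        hp, hm = h.copy(), h.copy()
        hp[i, k] += eps
        hm[i, k] -= eps
        fd = (survival_loss(hp, y, m) - survival_loss(hm, y, m)) / (2 * eps)
        assert analytic[i, k] == pytest.approx(fd, rel=1e-5, abs=1e-9)


@settings(max_examples=40, deadline=None)
@given(st.integers(0, 10_000))
def test_masked_intervals_never_change_loss(seed):
    rng = np.random.default_rng(seed)
    h = rng.uniform(0.01, 0.99, 7)
    y = (rng.random(7) < 0.3).astype(float)
    m = (rng.random(7) < 0.6).astype(float)
    h2 = h.copy()
    h2[m == 0] = rng.uniform(0.01, 0.99, int((m == 0).sum()))
    assert survival_loss(h, y, m) == survival_loss(h2, y, m)
    assert np.all(survival_loss_grad(h, y, m)[m == 0] == 0.0)


# --------------------------------------------------------------------------
# risk composition


def test_zero_logit_risk_over_two_intervals():
    """h_k = 0.5 everywhere; two post-baseline intervals: 1 - 0.25 = 0.75."""
    edges = np.array([0.0, 60 / 365.25, 1.0, 2.0])
    h = np.full((1, 3), 0.5)
    assert cumulative_risk(h, edges, horizon_years=5.0)[0] == pytest.approx(0.75)


def test_extreme_logits_risk_limits():
    model = EcgRiskModel(TINY, head="survival", seed=0)
    x = np.zeros((1, 2, 128), dtype=np.float32)
    # force the head to huge negative logits
    head = model.net.layers[-1]
    head.w.value[...] = 0.0
    head.b.value[...] = -30.0
    out = model.predict(x)
    assert out.risk_5y[0] == pytest.approx(0.0, abs=1e-10)
    head.b.value[...] = 0.0
    out = model.predict(x)
    np.testing.assert_allclose(out.hazards, 0.5, atol=1e-6)


def test_risk_5y_product_oracle_and_monotonicity():
    rng = np.random.default_rng(1)
    for _ in range(50):
        h = rng.uniform(0.01, 0.6, (1, 7))
        got = cumulative_risk(h, DEFAULT_EDGES)[0]
        expected = 1.0
        for k in (1, 2, 3, 4, 5):  # intervals ending at 1..5 years
            expected *= 1.0 - h[0, k]
        assert got == pytest.approx(1.0 - expected, abs=1e-12)
        # monotone non-decreasing in every hazard
        k = rng.integers(1, 6)
        h2 = h.copy()
        h2[0, k] = min(h2[0, k] + 0.1, 0.99)
        assert cumulative_risk(h2, DEFAULT_EDGES)[0] >= got


# --------------------------------------------------------------------------
# model mechanics


def test_forward_shape_validation():
    model = EcgRiskModel(TINY, seed=0)
    with pytest.raises(ValueError, match="expected input shape"):
        model.forward_logits(np.zeros((1, 2, 64), dtype=np.float32))


def test_inference_deterministic():
    model = EcgRiskModel(TINY, seed=3)
    x = np.random.default_rng(0).normal(0, 1, (4, 2, 128)).astype(np.float32)
    a = model.predict(x)
    b = model.predict(x)
    np.testing.assert_array_equal(a.hazards, b.hazards)


def test_classification_head_output():
    model = EcgRiskModel(TINY, head="classification", seed=0)
    out = model.predict(np.zeros((3, 2, 128), dtype=np.float32))
    assert out.classification_score.shape == (3,)
    assert out.hazards is None


def _toy_training_data(n=256, seed=0):
    """Planted signal: burst amplitude in channel 0 drives a 2-interval label."""
    rng = np.random.default_rng(seed)
    x = rng.normal(0, 0.3, (n, 2, 128)).astype(np.float32)
    amp = rng.uniform(0, 2, n).astype(np.float32)
    x[:, 0, 40:60] += amp[:, None]
    risk = amp > 1.0
    y = np.zeros((n, 7), dtype=np.float32)
    y[risk, 1] = 1.0
    mask = np.zeros((n, 7), dtype=np.float32)
    mask[:, :2] = 1.0
    return SurvivalDataset(x[: n - 64], y[: n - 64], mask[: n - 64]), \
        SurvivalDataset(x[n - 64:], y[n - 64:], mask[n - 64:])


def test_training_reduces_tuning_loss_and_is_reproducible():
    train_set, tune_set = _toy_training_data()
    cfg = TrainConfig(max_epochs=6, batch_size=32)
    m1 = EcgRiskModel(TINY, seed=1)
    log1 = train_model(m1, train_set, tune_set, cfg, seed=1)
    assert log1.attrs["best_tune_loss"] < log1.attrs["epoch0_tune_loss"]

    m2 = EcgRiskModel(TINY, seed=1)
    log2 = train_model(m2, train_set, tune_set, cfg, seed=1)
    np.testing.assert_array_equal(m1.predict(tune_set.x).hazards,
                                  m2.predict(tune_set.x).hazards)


def test_training_rejects_empty_dataset():
    train_set, tune_set = _toy_training_data(n=70)
    empty = SurvivalDataset(np.zeros((0, 2, 128), np.float32),
                            np.zeros((0, 7)), np.zeros((0, 7)))
    with pytest.raises(ValueError):
        train_model(EcgRiskModel(TINY, seed=0), empty, tune_set)


def test_checkpoint_roundtrip(tmp_path):
    train_set, tune_set = _toy_training_data(n=128)
    model = EcgRiskModel(TINY, seed=2)
    train_model(model, train_set, tune_set, TrainConfig(max_epochs=2), seed=2)
    save_model(model, tmp_path / "ckpt.npz")
    loaded = load_model(tmp_path / "ckpt.npz")
    np.testing.assert_array_equal(model.predict(tune_set.x).hazards,
                                  loaded.predict(tune_set.x).hazards)
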