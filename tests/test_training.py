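"""Curriculum mechanics (plateau scheduler, S advancement), the training
loop's invariants, validation, and checkpoint resume."""

import numpy as np
import pytest

from dynpot.exceptions import ParameterError, SizeError, TrainingFault
from dynpot.losses import BatchErrors, force_loss
from dynpot.model import EGNN, ModelConfig
from dynpot.training import (
    Adam,
    CurriculumState,
    TrainConfig,
    advance_curriculum,
    merge_samples,
    plateau_update,
    train,
    train_single_point,
    validate,
)


def _config(**kw):
    defaults = dict(s_max=2, s_val=3, plateau_patience=2, plateau_factor=0.5,
                    train_batch=8, val_batch=16, max_epochs=1000)
    defaults.update(kw)
    return TrainConfig(**defaults)


# ---------------------------------------------------------------------------
# plateau scheduler
# ---------------------------------------------------------------------------


def test_improving_sequence_never_decays():
    cfg = _config()
    state = CurriculumState(s=1, lr=cfg.initial_lr)
    for k in range(50):
        assert plateau_update(state, 1.0 / (k + 1), cfg) == "none"
    assert state.lr == cfg.initial_lr


def test_constant_error_follows_scripted_decay_schedule():
    """Hand simulation: with patience p, each decay takes p+1 non-improving
    epochs; the lr halves from 1e-3 until floored at 2e-6, then one more
    patience window emits convergence."""
    cfg = _config()
    state = CurriculumState(s=1, lr=cfg.initial_lr)

    # independent script of the expected lr sequence
    expected_lrs = [1e-3]
    while expected_lrs[-1] > cfg.min_lr:
        expected_lrs.append(max(expected_lrs[-1] * 0.5, cfg.min_lr))
    n_decays = len(expected_lrs) - 1  # 9 halvings from 1e-3 to the 2e-6 floor

    events = []
    epoch = 0
    assert plateau_update(state, 1.0, cfg) == "none"  # first epoch improves on inf
    epoch += 1
    while True:
        ev = plateau_update(state, 1.0, cfg)
        epoch += 1
        events.append((epoch, ev, state.lr))
        if ev == "converged":
            break
    decays = [e for e in events if e[1] == "lr_decayed"]
    assert len(decays) == n_decays
    assert [d[2] for d in decays] == expected_lrs[1:]
    # total epochs: 1 improving + (n_decays + 1) windows of (patience + 1)
    assert epoch == 1 + (n_decays + 1) * (cfg.plateau_patience + 1)


def test_improvement_at_window_boundary_resets_counter():
    cfg = _config()
    state = CurriculumState(s=1, lr=cfg.initial_lr)
    plateau_update(state, 1.0, cfg)
    assert plateau_update(state, 1.0, cfg) == "none"
    assert plateau_update(state, 1.0, cfg) == "none"  # counter == patience
    assert plateau_update(state, 0.5, cfg) == "none"  # improvement resets
    assert state.epochs_since_improve == 0
    assert state.lr == cfg.initial_lr


def test_nan_validation_error_is_a_training_fault():
    with pytest.raises(TrainingFault):
        plateau_update(CurriculumState(), float("nan"), _config())


def test_advance_resets_lr_to_reset_value():
    cfg = _config(s_max=3)
    state = CurriculumState(s=1, lr=cfg.min_lr, best_val_s=0.7)
    assert advance_curriculum(state, cfg)
    assert state.s == 2 and state.lr == pytest.approx(1e-4)
    assert state.best_val_s == float("inf") and state.epochs_since_improve == 0
    assert state.best_val_per_s[1] == 0.7


def test_advance_at_smax_is_terminal():
    cfg = _config(s_max=2)
    state = CurriculumState(s=2, lr=cfg.min_lr)
    s_before = state.s
    assert not advance_curriculum(state, cfg)
    assert state.s == s_before


def test_config_validation():
    with pytest.raises(ParameterError, match="min_lr"):
        TrainConfig(min_lr=1e-3, lr_reset=1e-4)
    with pytest.raises(ParameterError):
        TrainConfig(s_val=0)


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------


class _AnalyticStub:
    """Duck-typed 'model' whose forces are the exact reference forces."""

    def __init__(self, system):
        self.params = {}
        self._system = system

    def as_force_provider(self, create_graph=False):
        from dynpot.synthetic import analytic_force_provider

        return analytic_force_provider(self._system)


def test_perfect_model_validates_to_zero(toy_system, val_samples):
    # batch_size=1: the analytic stub is all-pairs, so samples must not be
    # merged into one block-diagonal graph
    got = validate(_AnalyticStub(toy_system), val_samples[:4], 3, batch_size=1)
    assert got == pytest.approx(0.0, abs=1e-12)


def test_sval_one_reduces_to_single_point_force_loss(tiny_model, val_samples):
    chunk = val_samples[:6]
    got = validate(tiny_model, chunk, 1, batch_size=3)
    resid, species = [], []
    for s in chunk:
        f, _ = tiny_model.forces(s.species, s.initial_positions,
                                 s.reference_edge_sets[0], s.cell, s.pbc)
        resid.append(f.numpy() - s.reference_forces[0])
        species.append(s.species)
    expected = force_loss(BatchErrors(np.zeros(len(chunk)), resid, species))
    assert got == pytest.approx(expected, rel=1e-10)


def test_validate_matches_independent_rollout_loop(tiny_model, toy_system, val_samples):
    """Two-path check: batched validate vs a per-sample loop composing
    rollout and the loss module directly."""
    from dynpot.dynamics import rollout
    from dynpot.losses import mepa, species_force_weights, weighted_l1

    chunk = val_samples[:5]
    s_val = 4
    got = validate(tiny_model, chunk, s_val, batch_size=2)
    provider = tiny_model.as_force_provider()
    per_sample = []
    for s in chunk:
        res = rollout(provider, s, s_val, mode="training").numpy()
        w = species_force_weights(s.species)
        per_sample.append(
            mepa([weighted_l1(res.forces[k] - s.reference_forces[k], w)
                  for k in range(s_val)])
        )
    assert got == pytest.approx(np.mean(per_sample), rel=1e-9)


def test_merge_samples_requires_supporting_length(train_samples):
    with pytest.raises(SizeError):
        merge_samples(train_samples[:2], train_samples[0].s_max + 1)
    with pytest.raises(SizeError):
        merge_samples([], 1)


# ---------------------------------------------------------------------------
# training loop
# ---------------------------------------------------------------------------


def _tiny_training_setup(train_samples, val_samples, **cfg_kw):
    model_cfg = ModelConfig(species=("H", "Pd"), node_dim=6, edge_dim=4,
                            num_layers=1, rff_seed=5, init_seed=6)
    cfg = _config(train_batch=16, max_epochs_per_s=2, max_epochs=10, seed=7, **cfg_kw)
    return EGNN.initialise(model_cfg), train_samples[::4], val_samples[:6], cfg


def test_history_s_nondecreasing_and_increments_at_converged(train_samples, val_samples):
    model, ts, vs, cfg = _tiny_training_setup(train_samples, val_samples)
    result = train(model, ts, vs, cfg)
    s_col = [row["s"] for row in result.history]
    assert s_col == sorted(s_col)
    for prev, cur in zip(result.history, result.history[1:]):
        if cur["s"] != prev["s"]:
            assert cur["s"] == prev["s"] + 1 and prev["event"] == "converged"
    assert set(result.best_checkpoints) == set(s_col)
    # lr is reset to the paper's reset value right after an advance
    for prev, cur in zip(result.history, result.history[1:]):
        if cur["s"] == prev["s"] + 1:
            assert cur["lr"] == pytest.approx(cfg.lr_reset)


def test_dt_at_s1_equals_conventional_training(train_samples, val_samples):
    """Locked at S=1, the curriculum is operationally identical to
    conventional single-point training: same per-epoch losses, same seed."""
    m1, ts, vs, cfg = _tiny_training_setup(train_samples, val_samples, s_max=1)
    r1 = train(m1, ts, vs, cfg)
    m2 = EGNN.initialise(m1.config)
    r2 = train_single_point(m2, ts, vs, cfg)
    assert [row["train_loss"] for row in r1.history] == [row["train_loss"] for row in r2.history]
    assert [row["val_mepa"] for row in r1.history] == [row["val_mepa"] for row in r2.history]
    for k in m1.params:
        np.testing.assert_array_equal(m1.params[k].data, m2.params[k].data)


def test_resume_reproduces_history(train_samples, val_samples):
    model_a, ts, vs, cfg_full = _tiny_training_setup(train_samples, val_samples)
    full = train(model_a, ts, vs, cfg_full)

    model_b = EGNN.initialise(model_a.config)
    cfg_half = TrainConfig(**{**cfg_full.__dict__, "max_epochs": 3})
    half = train(model_b, ts, vs, cfg_half)
    resumed = train(model_b, ts, vs, cfg_full, resume_state=half.resume_state)

    assert len(resumed.history) == len(full.history)
    for a, b in zip(full.history, resumed.history):
        assert a["train_loss"] == pytest.approx(b["train_loss"], rel=1e-12)
        assert a["s"] == b["s"] and a["event"] == b["event"]
    for k in model_a.params:
        np.testing.assert_allclose(model_a.params[k].data, model_b.params[k].data, rtol=1e-12)


def test_training_is_deterministic(train_samples, val_samples):
    m1, ts, vs, cfg = _tiny_training_setup(train_samples, val_samples)
    r1 = train(m1, ts, vs, cfg)
    m2 = EGNN.initialise(m1.config)
    r2 = train(m2, ts, vs, cfg)
    assert [row["train_loss"] for row in r1.history] == [row["train_loss"] for row in r2.history]


def test_samples_must_carry_enough_reference_frames(train_samples, val_samples):
    model, ts, vs, cfg = _tiny_training_setup(train_samples, val_samples)
    with pytest.raises(SizeError):
        train(model, ts, vs, TrainConfig(**{**cfg.__dict__, "s_max": 99}))
    with pytest.raises(SizeError):
        train(model, ts, vs, TrainConfig(**{**cfg.__dict__, "s_val": 99}))


def test_adam_reduces_quadratic_loss(rng):
    from dynpot import autodiff as ad

    target = rng.normal(size=(4,))
    p = ad.parameter(np.zeros(4))
    opt = Adam({"p": p}, lr=0.05)
    losses = []
    for _ in range(200):
        loss = ad.tsum(ad.power(p - target, 2.0))
        g = ad.grad(loss, p)
        opt.step({"p": g.data})
        losses.append(float(loss.data))
    assert losses[-1] < 1e-3 * losses[0]
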