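"""Velocity-Verlet integrator and rollout modes: convergence order, NVE
conservation, perfect-model identity, time reversibility, differentiability."""

import numpy as np
import pytest

from dynpot import autodiff as ad
from dynpot.dynamics import rollout, verlet_position_step, verlet_velocity_step
from dynpot.exceptions import ParameterError, SizeError
from dynpot.losses import species_force_weights, weighted_l1
from dynpot.synthetic import analytic_force_provider
from dynpot.trajectory import SubsequenceSample, radius_neighbors
from dynpot.units import ACC_CONV, kinetic_energy


def test_force_free_drift():
    r = verlet_position_step(np.zeros((1, 3)), np.array([[1.0, 0, 0]]),
                             np.zeros((1, 3)), np.array([1.0]), 0.5)
    np.testing.assert_allclose(r, [[0.5, 0, 0]])


def test_pure_acceleration_term():
    # choose F so that c_acc * F / m = 2 Å/fs²
    F = np.array([[2.0 / ACC_CONV, 0, 0]])
    r = verlet_position_step(np.zeros((1, 3)), np.zeros((1, 3)), F, np.array([1.0]), 1.0)
    np.testing.assert_allclose(r, [[1.0, 0, 0]])


def test_velocity_step_identity_and_cancellation(rng):
    v = rng.normal(size=(4, 3))
    m = rng.uniform(1, 10, size=4)
    z = np.zeros_like(v)
    np.testing.assert_array_equal(verlet_velocity_step(v, z, z, m, 0.5), v)
    F = rng.normal(size=(4, 3))
    np.testing.assert_allclose(verlet_velocity_step(v, F, -F, m, 0.5), v)


def test_velocity_step_matches_direct_formula(rng):
    v, Fo, Fn = rng.normal(size=(3, 5, 3))
    m = rng.uniform(0.5, 20, size=5)
    dt = 0.37
    out = verlet_velocity_step(v, Fo, Fn, m, dt)
    expected = v + 0.5 * dt * ACC_CONV * (Fo + Fn) / m[:, None]
    np.testing.assert_allclose(out, expected, rtol=1e-14)


def test_nonpositive_mass_or_dt_rejected():
    z = np.zeros((1, 3))
    with pytest.raises(ParameterError):
        verlet_position_step(z, z, z, np.array([-1.0]), 0.5)
    with pytest.raises(ParameterError):
        verlet_velocity_step(z, z, z, np.array([1.0]), 0.0)


def _harmonic_max_error(dt, n_steps=1000):
    """1D oscillator, k chosen so omega = 1 rad/fs; analytic x(t) = cos(t)."""
    k = 1.0 / ACC_CONV  # eV/Å² so that c_acc * k / m = 1 with m = 1 amu
    m = np.array([1.0])
    r = np.array([[1.0, 0.0, 0.0]])
    v = np.zeros((1, 3))
    F = -k * r
    err = 0.0
    for s in range(1, n_steps + 1):
        r = verlet_position_step(r, v, F, m, dt)
        F_new = -k * r
        v = verlet_velocity_step(v, F, F_new, m, dt)
        F = F_new
        err = max(err, abs(r[0, 0] - np.cos(s * dt)))
    return err


def test_harmonic_oscillator_second_order_convergence():
    # fixed total time: halving dt (doubling steps) → ~4x smaller max error
    e1 = _harmonic_max_error(0.05, n_steps=1000)
    e2 = _harmonic_max_error(0.025, n_steps=2000)
    assert 3.0 < e1 / e2 < 5.0


# ---------------------------------------------------------------------------
# rollout
# ---------------------------------------------------------------------------


def test_single_step_rollout_does_not_integrate(toy_system, train_samples):
    provider = analytic_force_provider(toy_system)
    res = rollout(provider, train_samples[0], 1, mode="inference")
    assert res.n_steps == 1
    np.testing.assert_array_equal(res.positions[0], train_samples[0].initial_positions)


def test_training_rollout_beyond_smax_rejected(toy_system, train_samples):
    provider = analytic_force_provider(toy_system)
    with pytest.raises(SizeError):
        rollout(provider, train_samples[0], train_samples[0].s_max + 1, mode="training")


def test_perfect_model_identity(toy_system, small_trajectories, train_samples):
    """With exact reference forces the rollout reproduces the reference
    trajectory: same integrator, same dt, same initial conditions."""
    provider = analytic_force_provider(toy_system)
    sample = train_samples[7]
    traj_id, start = sample.source
    res = rollout(provider, sample, sample.s_max, mode="training").numpy()
    for k in range(sample.s_max):
        ref = small_trajectories[traj_id].frames[start + k]
        assert np.abs(res.positions[k] - ref.positions).max() <= 1e-10
        assert np.abs(res.velocities[k] - ref.velocities).max() <= 1e-10


def test_inference_rollout_reproduces_generator_100_steps(toy_system, small_trajectories):
    from dynpot.trajectory import build_subsequence_dataset

    # rebuild with a 50-step reference window (longest these trajectories allow)
    sample = build_subsequence_dataset(small_trajectories[0], 50, 5.0)[0]
    provider = analytic_force_provider(toy_system)
    res = rollout(provider, sample, 50, mode="inference")
    for k in range(50):
        ref = small_trajectories[0].frames[k]
        assert np.abs(res.positions[k] - ref.positions).max() <= 1e-10


def test_nve_energy_conservation(toy_system, train_samples):
    provider = analytic_force_provider(toy_system)
    sample = train_samples[0]
    res = rollout(provider, sample, sample.s_max, mode="inference")
    # long free-running rollout from the same initial conditions
    from dynpot.dynamics import nve_integrate

    frames = nve_integrate(provider, sample.species, sample.initial_positions,
                           sample.initial_velocities, sample.masses, sample.dt, 1000)
    total = np.array([e + kinetic_energy(sample.masses, v) for _, v, _, e in frames])
    assert np.abs(total - total[0]).max() / len(sample.species) <= 1e-4


def test_time_reversibility(toy_system, train_samples):
    provider = analytic_force_provider(toy_system)
    sample = train_samples[0]
    res = rollout(provider, sample, 5, mode="inference")
    back = SubsequenceSample(
        species=sample.species, masses=sample.masses,
        initial_positions=res.positions[-1],
        initial_velocities=-res.velocities[-1],
        dt=sample.dt,
        reference_forces=sample.reference_forces,
        reference_energy_0=sample.reference_energy_0,
        reference_edge_sets=sample.reference_edge_sets,
        cell=sample.cell, pbc=sample.pbc,
    )
    rev = rollout(provider, back, 5, mode="inference")
    assert np.abs(rev.positions[-1] - sample.initial_positions).max() <= 1e-8


def test_gradients_flow_from_every_rollout_step(tiny_model, train_samples):
    """The computational graph stays connected: a scalar of step-k forces has
    a nonzero parameter gradient for k > 0."""
    sample = train_samples[0]
    provider = tiny_model.as_force_provider(create_graph=True)
    res = rollout(provider, sample, 3, mode="training")
    w = species_force_weights(sample.species)
    for k in (1, 2):
        scalar = weighted_l1(res.forces[k] - sample.reference_forces[k], w)
        grads = ad.grad(scalar, list(tiny_model.params.values()), allow_unused=True)
        norms = [np.abs(g.data).max() for g in grads]
        assert np.all(np.isfinite(norms)) and max(norms) > 0


def test_training_mode_uses_frozen_edges(tiny_model, train_samples):
    sample = train_samples[0]
    provider = tiny_model.as_force_provider()
    res = rollout(provider, sample, sample.s_max, mode="training").numpy()
    # re-evaluate step-3 forces with the frozen edge set vs a recomputed graph
    f_frozen, _ = tiny_model.forces(
        sample.species, res.positions[3], sample.reference_edge_sets[3],
        sample.cell, sample.pbc,
    )
    np.testing.assert_allclose(res.forces[3], f_frozen.numpy(), atol=1e-12)
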