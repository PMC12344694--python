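"""The graph-network potential: RFF embedding, forward oracle, symmetries,
force-energy consistency, parameter counting, checkpoints."""

import numpy as np
import pytest

from dynpot import autodiff as ad
from dynpot.exceptions import GeometryError, VocabularyError
from dynpot.model import EGNN, ModelConfig, count_parameters, one_hot, rff_embed
from dynpot.trajectory import radius_neighbors


def _random_config(rng, n=5, spread=3.0):
    species = [("H", "Pd")[int(b)] for b in rng.integers(0, 2, size=n)]
    positions = rng.normal(scale=spread, size=(n, 3))
    # keep atoms apart so all-pairs graphs have d > 0
    positions += np.arange(n)[:, None] * 0.7
    return species, positions


# ---------------------------------------------------------------------------
# RFF embedding
# ---------------------------------------------------------------------------


def test_rff_zero_distance_alternates():
    out = rff_embed(np.array([0.0]), np.array([0.3, 1.7, 2.2])).numpy()[0]
    np.testing.assert_allclose(out, [0, 1, 0, 1, 0, 1], atol=1e-15)


def test_rff_quarter_period():
    out = rff_embed(np.array([np.pi / 2]), np.array([1.0])).numpy()[0]
    np.testing.assert_allclose(out, [1.0, 0.0], atol=1e-15)


def test_rff_pairs_lie_on_unit_circle(rng):
    d = rng.uniform(0, 6, size=11)
    b = rng.normal(0, 4, size=7)
    out = rff_embed(d, b).numpy()
    s, c = out[:, 0::2], out[:, 1::2]
    np.testing.assert_allclose(s**2 + c**2, 1.0, atol=1e-12)


# ---------------------------------------------------------------------------
# forward oracle: straight-line numpy re-evaluation of the message passing
# ---------------------------------------------------------------------------


def _numpy_forward(model, species, positions):
    """Independent re-implementation: embeddings, K message-passing rounds,
    sum pooling, readout — plain numpy, no autodiff."""
    cfg = model.config
    P = {k: v.data for k, v in model.params.items()}
    silu = lambda x: x / (1 + np.exp(-x))

    def mlp(name, x, n_layers):
        for k in range(n_layers):
            x = x @ P[f"{name}.{k}.W"] + P[f"{name}.{k}.b"]
            if k < n_layers - 1:
                x = silu(x)
        return x

    edges = radius_neighbors(positions, cutoff=cfg.cutoff)
    d = np.linalg.norm(positions[edges.dst] - positions[edges.src], axis=1)
    b = model.rff_frequencies
    phi_e = np.empty((len(d), 2 * cfg.edge_dim))
    phi_e[:, 0::2] = np.sin(d[:, None] * b[None, :])
    phi_e[:, 1::2] = np.cos(d[:, None] * b[None, :])

    h = mlp("embed", one_hot(species, cfg.species), 1)
    for l in range(cfg.num_layers):
        e_in = np.concatenate([h[edges.src], h[edges.dst], phi_e], axis=1)
        m = mlp(f"message_{l}", e_in, 2)
        agg = np.zeros((len(species), cfg.node_dim))
        np.add.at(agg, edges.src, m)
        h = mlp(f"update_{l}", np.concatenate([h, agg], axis=1), 2)
    return float(mlp("readout", h.sum(axis=0, keepdims=True), 2)[0, 0])


def test_energy_matches_straight_line_oracle(tiny_model, rng):
    species, positions = _random_config(rng)
    e = tiny_model.energy(species, positions)
    assert np.isclose(e, _numpy_forward(tiny_model, species, positions), atol=1e-10)


def test_energy_deterministic_and_permutation_invariant(tiny_model, rng):
    species, positions = _random_config(rng, n=6)
    e1 = tiny_model.energy(species, positions)
    e2 = tiny_model.energy(species, positions)
    assert e1 == e2
    perm = rng.permutation(6)
    e3 = tiny_model.energy([species[i] for i in perm], positions[perm])
    assert np.isclose(e1, e3, atol=1e-10)


# ---------------------------------------------------------------------------
# symmetries of energy and forces
# ---------------------------------------------------------------------------


def _random_rotation(rng):
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q


def test_translation_invariance_and_zero_net_force(tiny_model, rng):
    species, positions = _random_config(rng)
    f, e = tiny_model.forces(species, positions)
    f2, e2 = tiny_model.forces(species, positions + np.array([3.0, -1.0, 2.5]))
    assert np.isclose(float(e.data[0]), float(e2.data[0]), atol=1e-9)
    np.testing.assert_allclose(f.numpy(), f2.numpy(), atol=1e-9)
    np.testing.assert_allclose(f.numpy().sum(axis=0), 0.0, atol=1e-6)


def test_rotation_covariance(tiny_model, rng):
    species, positions = _random_config(rng)
    f, e = tiny_model.forces(species, positions)
    q = _random_rotation(rng)
    fq, eq = tiny_model.forces(species, positions @ q.T)
    assert np.isclose(float(e.data[0]), float(eq.data[0]), atol=1e-9)
    scale = max(np.abs(f.numpy()).max(), 1e-12)
    assert np.abs(fq.numpy() - f.numpy() @ q.T).max() / scale < 1e-6


def test_forces_match_finite_differences(tiny_model, rng):
    species, positions = _random_config(rng, n=4)
    f, _ = tiny_model.forces(species, positions)
    h = 1e-4
    for i in range(len(species)):
        for a in range(3):
            dp = positions.copy(); dp[i, a] += h
            dm = positions.copy(); dm[i, a] -= h
            edges = radius_neighbors(positions, cutoff=tiny_model.config.cutoff)
            ep = tiny_model.energy(species, dp, edges)
            em = tiny_model.energy(species, dm, edges)
            assert abs(-(ep - em) / (2 * h) - f.numpy()[i, a]) < 1e-5


def test_energy_twice_differentiable(tiny_model, rng):
    """Gradients of forces (needed by the rollout loss) exist and are finite."""
    species, positions = _random_config(rng, n=4)
    edges = radius_neighbors(positions, cutoff=tiny_model.config.cutoff)
    f, _ = tiny_model.forces(species, positions, edges, create_graph=True)
    scalar = ad.tsum(ad.power(f, 2.0))
    grads = ad.grad(scalar, list(tiny_model.params.values()), allow_unused=True)
    assert all(np.all(np.isfinite(g.data)) for g in grads)
    assert any(np.abs(g.data).max() > 0 for g in grads)


# ---------------------------------------------------------------------------
# degenerate graphs and errors
# ---------------------------------------------------------------------------


def test_zero_edge_graph_has_exactly_zero_forces(tiny_model):
    species = ["H", "Pd", "H"]
    positions = np.array([[0.0, 0, 0], [20.0, 0, 0], [40.0, 0, 0]])  # beyond cutoff
    f, e = tiny_model.forces(species, positions)
    np.testing.assert_array_equal(f.numpy(), 0.0)
    # energy must not depend on where the isolated atoms sit
    e2 = tiny_model.energy(species, positions + np.array([1.7, 0.3, -2.0]))
    assert np.isclose(float(e.data[0]), e2, atol=1e-12)


def test_unknown_species_raises(tiny_model):
    with pytest.raises(VocabularyError):
        tiny_model.energy(["He"], np.zeros((1, 3)))


def test_coincident_atoms_on_edge_raise(tiny_model):
    with pytest.raises(GeometryError):
        tiny_model.forces(["H", "H"], np.zeros((2, 3)))


# ---------------------------------------------------------------------------
# parameter counting
# ---------------------------------------------------------------------------


def test_count_matches_instantiated_parameters(tiny_model):
    assert count_parameters(tiny_model.config) == tiny_model.n_parameters()


def test_count_tiny_config_hand_sum():
    cfg = ModelConfig(species=("A", "B"), node_dim=4, edge_dim=4, num_layers=1,
                      message_hidden=(8,), update_hidden=(8,), readout_hidden=(8,))
    # embed: 2*4+4; message: (2*4+2*4)->8->4; update: 8->8->4; readout: 4->8->1
    expected = (2 * 4 + 4) \
        + (16 * 8 + 8) + (8 * 4 + 4) \
        + (8 * 8 + 8) + (8 * 4 + 4) \
        + (4 * 8 + 8) + (8 * 1 + 1)
    assert count_parameters(cfg) == expected


def test_count_additive_in_layers():
    base = ModelConfig(species=("A", "B"), node_dim=4, edge_dim=4, num_layers=1)
    double = ModelConfig(species=("A", "B"), node_dim=4, edge_dim=4, num_layers=2)
    per_layer = count_parameters(double) - count_parameters(base)
    triple = ModelConfig(species=("A", "B"), node_dim=4, edge_dim=4, num_layers=3)
    assert count_parameters(triple) == count_parameters(double) + per_layer


# ---------------------------------------------------------------------------
# frozen RFF vector + checkpoints
# ---------------------------------------------------------------------------


def test_rff_vector_untouched_by_training_step(tiny_model, rng):
    from dynpot.training import Adam

    before = tiny_model.rff_frequencies.copy()
    species, positions = _random_config(rng)
    f, _ = tiny_model.forces(species, positions, create_graph=True)
    loss = ad.tsum(ad.absolute(f))
    grads = ad.grad(loss, list(tiny_model.params.values()), allow_unused=True)
    Adam(tiny_model.params, 1e-3).step(
        {k: g.data for k, g in zip(tiny_model.params, grads)}
    )
    np.testing.assert_array_equal(tiny_model.rff_frequencies, before)


def test_checkpoint_round_trip_bit_identical(tiny_model, tmp_path, rng):
    species, positions = _random_config(rng)
    e = tiny_model.energy(species, positions)
    path = tmp_path / "ckpt.json"
    tiny_model.save_checkpoint(path, extra={"note": 1})
    loaded, extra = EGNN.load_checkpoint(path)
    assert extra == {"note": 1}
    assert loaded.energy(species, positions) == e
    np.testing.assert_array_equal(loaded.rff_frequencies, tiny_model.rff_frequencies)
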