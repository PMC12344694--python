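"""Equivariant graph neural network potential.

Energy model: one-hot species vectors are embedded by an MLP; interatomic
distances are embedded by a random Fourier feature (RFF) map with frozen
Gaussian-sampled frequencies; K rounds of message passing (messages built
from both endpoint node states and the edge embedding, aggregated by
summation over the neighborhood) update the node states; the node states
are sum-pooled over atoms and a final readout MLP yields the scalar
potential energy.  Forces are the exact negative gradient of that energy
with respect to atomic positions (reverse-mode differentiation, not finite
differences), so the model is invariant under rigid translations, rotations
and atom permutations and the forces transform covariantly.

Because the model only ever sees pairwise *distances*, equivariance is
structural rather than learned.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .exceptions import GeometryError, ParameterError, VocabularyError
from .trajectory import EdgeList

__all__ = ["ModelConfig", "EGNN", "rff_embed", "count_parameters", "one_hot"]

_ACTIVATIONS = {"silu": ad.silu, "tanh": ad.tanh}


@dataclass(frozen=True)
class ModelConfig:
    """Hyperparameters of the potential.

    ``edge_dim`` is d_e: the RFF embedding has length 2*d_e (a sin/cos pair
    per frequency).  ``rff_sigma`` is the standard deviation of the normal
    distribution the frozen frequencies are drawn from.  ``cutoff`` (Å) is
    the radius-graph neighborhood radius.  Hidden-layer tuples configure the
    embedding, message, update and readout MLPs; empty tuple = single affine
    map.
    """

    species: tuple[str, ...]
    node_dim: int = 128
    edge_dim: int = 256
    num_layers: int = 3
    rff_sigma: float = 4.0
    cutoff: float = 5.0
    embed_hidden: tuple[int, ...] = ()
    message_hidden: tuple[int, ...] | None = None
    update_hidden: tuple[int, ...] | None = None
    readout_hidden: tuple[int, ...] | None = None
    activation: str = "silu"
    rff_seed: int = 0
    init_seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "species", tuple(sorted(self.species)))
        if len(self.species) == 0:
            raise ParameterError("species vocabulary must not be empty")
        if min(self.node_dim, self.edge_dim, self.num_layers) < 1:
            raise ParameterError("node_dim, edge_dim and num_layers must be >= 1")
        if self.rff_sigma <= 0:
            raise ParameterError("rff_sigma must be positive")
        if self.activation not in _ACTIVATIONS:
            raise ParameterError(f"unknown activation {self.activation!r}")
        for name in ("message_hidden", "update_hidden", "readout_hidden"):
            if getattr(self, name) is None:
                object.__setattr__(self, name, (self.node_dim,))

    @property
    def n_species(self) -> int:
        return len(self.species)


def _mlp_shapes(dims: list[int]) -> list[tuple[int, int]]:
    return list(zip(dims[:-1], dims[1:]))


def _network_shapes(config: ModelConfig) -> dict[str, list[tuple[int, int]]]:
    a, dn, de = config.n_species, config.node_dim, config.edge_dim
    nets = {"embed": _mlp_shapes([a, *config.embed_hidden, dn])}
    for l in range(config.num_layers):
        nets[f"message_{l}"] = _mlp_shapes([2 * dn + 2 * de, *config.message_hidden, dn])
        nets[f"update_{l}"] = _mlp_shapes([2 * dn, *config.update_hidden, dn])
    nets["readout"] = _mlp_shapes([dn, *config.readout_hidden, 1])
    return nets


def count_parameters(config: ModelConfig) -> int:
    """Number of optimizer-visible scalars (the frozen RFF vector excluded)."""
    return sum(
        fan_in * fan_out + fan_out
        for shapes in _network_shapes(config).values()
        for fan_in, fan_out in shapes
    )


def one_hot(species: list[str], vocabulary: tuple[str, ...]) -> np.ndarray:
    index = {s: k for k, s in enumerate(vocabulary)}
    out = np.zeros((len(species), len(vocabulary)))
    for row, s in enumerate(species):
        if s not in index:
            raise VocabularyError(f"species {s!r} not in vocabulary {vocabulary}")
        out[row, index[s]] = 1.0
    return out


def rff_embed(distances, frequencies) -> Tensor:
    """Random Fourier feature map of scalar distances.

    Returns ``[sin(b_1 d), cos(b_1 d), ..., sin(b_de d), cos(b_de d)]`` per
    distance (interleaved sin/cos pairs), shape (E, 2*d_e).
    """
    d = ad.tensor(distances)
    b = np.asarray(frequencies, dtype=float)
    de = b.shape[0]
    outer = ad.mul(ad.reshape(d, (-1, 1)), b[None, :])  # (E, d_e)
    s = ad.sin(outer)
    c = ad.cos(outer)
    stacked = ad.concat(
        [ad.reshape(s, (-1, de, 1)), ad.reshape(c, (-1, de, 1))], axis=2
    )
    return ad.reshape(stacked, (-1, 2 * de))


class EGNN:
    """The potential: frozen RFF frequencies + learnable MLP parameters."""

    def __init__(self, config: ModelConfig, params: dict[str, Tensor], rff_frequencies: np.ndarray):
        self.config = config
        self.params = params
        self.rff_frequencies = np.asarray(rff_frequencies, dtype=float)
        if self.rff_frequencies.shape != (config.edge_dim,):
            raise ParameterError("RFF frequency vector must have length edge_dim")

    # -- construction --------------------------------------------------
    @classmethod
    def initialise(cls, config: ModelConfig) -> "EGNN":
        rng = np.random.default_rng(config.init_seed)
        params: dict[str, Tensor] = {}
        for name, shapes in _network_shapes(config).items():
            for k, (fan_in, fan_out) in enumerate(shapes):
                params[f"{name}.{k}.W"] = ad.parameter(
                    rng.normal(0.0, 1.0 / np.sqrt(fan_in), size=(fan_in, fan_out))
                )
                params[f"{name}.{k}.b"] = ad.parameter(np.zeros(fan_out))
        rff_rng = np.random.default_rng(config.rff_seed)
        b = rff_rng.normal(0.0, config.rff_sigma, size=config.edge_dim)
        return cls(config, params, b)

    def n_parameters(self) -> int:
        return sum(int(np.prod(p.shape)) for p in self.params.values())

    def clone_params(self) -> dict[str, np.ndarray]:
        return {k: p.data.copy() for k, p in self.params.items()}

    def load_params(self, values: dict[str, np.ndarray]) -> None:
        for k, p in self.params.items():
            p.data = np.array(values[k], dtype=float)

    # -- forward -------------------------------------------------------
    def _mlp(self, name: str, x: Tensor) -> Tensor:
        act = _ACTIVATIONS[self.config.activation]
        n_layers = len(_network_shapes(self.config)[name])
        for k in range(n_layers):
            x = ad.affine(x, self.params[f"{name}.{k}.W"], self.params[f"{name}.{k}.b"])
            if k < n_layers - 1:
                x = act(x)
        return x

    def energy_from_graph(
        self,
        node_onehot: np.ndarray,
        edges: EdgeList,
        distances,
        graph_index: np.ndarray | None = None,
        n_graphs: int = 1,
    ) -> Tensor:
        """Per-graph potential energies (shape (n_graphs,)) from a prepared
        graph: one-hot node features, a directed edge list and the per-edge
        distances (Tensor for differentiable paths, ndarray otherwise)."""
        n_atoms = node_onehot.shape[0]
        h = self._mlp("embed", ad.constant(node_onehot))
        if len(edges):
            phi_e = rff_embed(distances, self.rff_frequencies)
        for l in range(self.config.num_layers):
            if len(edges):
                e_in = ad.concat(
                    [ad.gather(h, edges.src), ad.gather(h, edges.dst), phi_e], axis=1
                )
                m = self._mlp(f"message_{l}", e_in)
                agg = ad.scatter_add(m, edges.src, n_atoms)
            else:
                agg = ad.constant(np.zeros((n_atoms, self.config.node_dim)))
            h = self._mlp(f"update_{l}", ad.concat([h, agg], axis=1))
        if graph_index is None:
            pooled = ad.tsum(h, axis=0, keepdims=True)  # (1, d_n)
        else:
            pooled = ad.scatter_add(h, graph_index, n_graphs)
        return ad.reshape(self._mlp("readout", pooled), (-1,))

    def energy(self, species: list[str], positions, edges: EdgeList | None = None,
               cell=None, pbc=(False, False, False)) -> float:
        """Scalar potential energy (eV) of a single configuration."""
        from .trajectory import radius_neighbors, edge_distances

        positions = np.asarray(positions, dtype=float)
        if edges is None:
            edges = radius_neighbors(positions, cell, pbc, self.config.cutoff)
        onehot = one_hot(species, self.config.species)
        d = edge_distances(positions, edges, cell)
        with ad.no_grad():
            e = self.energy_from_graph(onehot, edges, ad.constant(d))
        return float(e.data[0])

    def forces(
        self,
        species: list[str],
        positions,
        edges: EdgeList | None = None,
        cell=None,
        pbc=(False, False, False),
        create_graph: bool = False,
    ):
        """Forces F_i = -dE/dr_i (eV/Å) and the per-graph energies.

        ``positions`` may be a Tensor already living in a larger graph
        (training-mode rollouts) or a plain array.  Distances are recomputed
        from the supplied positions while edge membership (and image shifts)
        are taken as given.
        """
        from .trajectory import radius_neighbors

        if isinstance(positions, Tensor):
            pos = positions
        else:
            pos = ad.parameter(np.asarray(positions, dtype=float))
        if edges is None:
            edges = radius_neighbors(pos.data, cell, pbc, self.config.cutoff)
        onehot = one_hot(species, self.config.species)
        d = _differentiable_distances(pos, edges, cell)
        graph_index = getattr(edges, "graph_index", None)
        n_graphs = getattr(edges, "n_graphs", 1)
        energies = self.energy_from_graph(onehot, edges, d, graph_index, n_graphs)
        total = ad.tsum(energies)
        # allow_unused covers zero-edge graphs, whose energy has no position
        # dependence: the forces are then exactly zero
        f = ad.mul(ad.grad(total, pos, create_graph=create_graph, allow_unused=True), -1.0)
        return f, energies

    # -- force-provider protocol for the MD engine ---------------------
    def as_force_provider(self, create_graph: bool = False):
        def provider(species, positions, cell, pbc, edges):
            return self.forces(species, positions, edges, cell, pbc, create_graph)

        provider.cutoff = self.config.cutoff  # lets inference rollouts rebuild graphs
        return provider

    # -- checkpointing -------------------------------------------------
    def save_checkpoint(self, path, extra: dict | None = None) -> None:
        """JSON checkpoint: config, parameters, frozen RFF vector, seeds.

        Plain-text floats round-trip bit-for-bit (shortest-repr encoding),
        so a reloaded model reproduces energies exactly."""
        payload = {
            "format_version": 1,
            "config": asdict(self.config),
            "rff_frequencies": self.rff_frequencies.tolist(),
            "params": {k: p.data.tolist() for k, p in self.params.items()},
        }
        if extra:
            payload["extra"] = extra
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def load_checkpoint(cls, path) -> tuple["EGNN", dict]:
        with open(path) as fh:
            payload = json.load(fh)
        cfgd = dict(payload["config"])
        for key in ("species", "embed_hidden", "message_hidden", "update_hidden", "readout_hidden"):
            if cfgd.get(key) is not None:
                cfgd[key] = tuple(cfgd[key])
        config = ModelConfig(**cfgd)
        model = cls.initialise(config)
        model.load_params({k: np.array(v) for k, v in payload["params"].items()})
        model.rff_frequencies = np.array(payload["rff_frequencies"], dtype=float)
        return model, payload.get("extra", {})


def _differentiable_distances(positions: Tensor, edges: EdgeList, cell=None) -> Tensor:
    """Per-edge distances as a differentiable function of positions.

    Image shifts are constants of the edge list, so the distance is a smooth
    function of the positions (no image switching inside a rollout)."""
    if len(edges) == 0:
        return ad.constant(np.zeros(0))
    rel = ad.add(
        ad.gather(positions, edges.dst), ad.mul(ad.gather(positions, edges.src), -1.0)
    )
    if cell is not None and edges.shifts.any():
        rel = ad.add(rel, ad.constant(edges.shifts @ np.asarray(cell, dtype=float)))
    d2 = ad.tsum(ad.mul(rel, rel), axis=1)
    if np.any(d2.data <= 1e-20):
        raise GeometryError("coincident atoms on an edge (d = 0)")
    return ad.sqrt(d2)
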