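"""Velocity-Verlet integration and trajectory rollout.

Two rollout modes exist:

* ``training``: the rollout is a differentiable computational graph.  Edge
  membership (and minimum-image shifts) for step k are *frozen* from the
  reference trajectory's frame k — the neighborhood is treated as a
  parameter of the sample — while distances are recomputed from the
  predicted positions, so gradients flow from every step's forces back to
  the model parameters.
* ``inference``: plain numpy integration; the radius graph is recomputed
  from the predicted positions at every step.

There is deliberately no thermostat: reference data and rollouts are
microcanonical.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .exceptions import ParameterError, SizeError
from .trajectory import SubsequenceSample, radius_neighbors
from .units import ACC_CONV

__all__ = [
    "RolloutResult",
    "verlet_position_step",
    "verlet_velocity_step",
    "rollout",
    "nve_integrate",
]

ForceProvider = Callable  # (species, positions, cell, pbc, edges) -> (forces, energy)


@dataclass
class RolloutResult:
    """Per-step predicted forces, energies, positions and velocities.

    Step 0 holds the initial conditions with the model's prediction for
    them; a length-S rollout holds exactly S entries per field.  In training
    mode the entries are autodiff tensors."""

    positions: list
    velocities: list
    forces: list
    energies: list

    @property
    def n_steps(self) -> int:
        return len(self.positions)

    def numpy(self) -> "RolloutResult":
        def conv(seq):
            return [x.numpy() if isinstance(x, Tensor) else np.asarray(x) for x in seq]

        return RolloutResult(
            conv(self.positions), conv(self.velocities), conv(self.forces), conv(self.energies)
        )


def _check_step_args(m, dt):
    m = np.asarray(m, dtype=float)
    if np.any(m <= 0):
        raise ParameterError("masses must be positive")
    if dt <= 0:
        raise ParameterError("dt must be positive")
    return m


def verlet_position_step(r, v, F, m, dt: float):
    """r' = r + v dt + (dt²/2) · c_acc · F / m  (per atom, per component)."""
    m = _check_step_args(m, dt)
    inv_m = (0.5 * dt * dt * ACC_CONV) / m[:, None]
    if isinstance(F, Tensor) or isinstance(r, Tensor) or isinstance(v, Tensor):
        return ad.tensor(r) + ad.tensor(v) * dt + ad.tensor(F) * inv_m
    return r + v * dt + F * inv_m


def verlet_velocity_step(v, F_old, F_new, m, dt: float):
    """v' = v + (dt/2) · c_acc · (F_old + F_new) / m."""
    m = _check_step_args(m, dt)
    inv_m = (0.5 * dt * ACC_CONV) / m[:, None]
    if any(isinstance(x, Tensor) for x in (v, F_old, F_new)):
        return ad.tensor(v) + (ad.tensor(F_old) + ad.tensor(F_new)) * inv_m
    return v + (F_old + F_new) * inv_m


def rollout(
    force_provider: ForceProvider,
    sample: SubsequenceSample,
    n_steps: int,
    mode: str = "inference",
    cutoff: float | None = None,
) -> RolloutResult:
    """Integrate ``n_steps`` velocity-Verlet steps from the sample's initial
    conditions, querying ``force_provider`` for forces at every step.

    ``n_steps == 1`` performs no integration: the result holds only the
    prediction for the initial frame.  Training mode requires
    ``n_steps <= sample.s_max`` (one frozen reference edge set per step) and
    returns a graph that is differentiable end-to-end.
    """
    if mode not in ("training", "inference"):
        raise ParameterError(f"unknown rollout mode {mode!r}")
    if n_steps < 1:
        raise SizeError("n_steps must be >= 1")
    training = mode == "training"
    if training and n_steps > sample.s_max:
        raise SizeError(
            f"training rollout of {n_steps} steps exceeds the sample's "
            f"s_max = {sample.s_max} reference edge sets"
        )
    if cutoff is None and not training:
        cutoff = getattr(force_provider, "cutoff", None)

    species, masses, dt = sample.species, sample.masses, sample.dt
    cell, pbc = sample.cell, sample.pbc

    if training:
        r = ad.parameter(sample.initial_positions)
        v: object = sample.initial_velocities
    else:
        r = sample.initial_positions.copy()
        v = sample.initial_velocities.copy()

    def edges_for(k, positions):
        if training:
            return sample.reference_edge_sets[k]
        if cutoff is None:
            return None  # provider does not need a neighbor list
        pos = positions.numpy() if isinstance(positions, Tensor) else positions
        return radius_neighbors(pos, cell, pbc, cutoff)

    F, E = force_provider(species, r, cell, pbc, edges_for(0, r))
    if not training:
        F, E = _as_numpy(F), _as_numpy(E)
    result = RolloutResult([r], [v], [F], [E])

    for k in range(1, n_steps):
        r = verlet_position_step(r, v, F, masses, dt)
        if not training and not np.all(np.isfinite(np.asarray(r))):
            raise ParameterError(f"integration blew up at step {k}")
        F_new, E = force_provider(species, r, cell, pbc, edges_for(k, r))
        if not training:
            F_new, E = _as_numpy(F_new), _as_numpy(E)
        v = verlet_velocity_step(v, F, F_new, masses, dt)
        F = F_new
        result.positions.append(r)
        result.velocities.append(v)
        result.forces.append(F)
        result.energies.append(E)
    return result


def nve_integrate(force_provider, species, positions, velocities, masses, dt,
                  n_steps: int, cell=None, pbc=(False, False, False)):
    """Plain microcanonical driver used by the synthetic generator; returns
    per-frame (positions, velocities, forces, potential energies) including
    the initial frame (n_steps + 1 entries)."""
    r = np.array(positions, dtype=float)
    v = np.array(velocities, dtype=float)
    F, E = force_provider(species, r, cell, pbc, None)
    F, E = _as_numpy(F), _as_numpy(E)
    frames = [(r.copy(), v.copy(), F.copy(), float(E))]
    for _ in range(n_steps):
        r = verlet_position_step(r, v, F, masses, dt)
        F_new, E = force_provider(species, r, cell, pbc, None)
        F_new, E = _as_numpy(F_new), _as_numpy(E)
        v = verlet_velocity_step(v, F, F_new, masses, dt)
        F = F_new
        frames.append((r.copy(), v.copy(), F.copy(), float(E)))
    return frames


def _as_numpy(x):
    if isinstance(x, Tensor):
        x = x.numpy()
    arr = np.asarray(x, dtype=float)
    if arr.ndim == 1 and arr.size == 1:
        return float(arr[0])
    if arr.ndim == 0:
        return float(arr)
    return arr
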