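"""Loss functions and the MEPA evaluation metric.

The force loss is a *per-species-balanced* mean absolute error: within each
configuration the absolute force residuals are averaged per atom species
(over that species' atoms and the 3 Cartesian components) and the species
means are summed, then averaged over the batch.  This balancing keeps a
rare species (e.g. a two-atom projectile on a large substrate) from being
drowned out — the property a plain weighted-MSE loss lacks.

MEPA (mean error of atomic forces per atom type and per simulation step) is
the mean of that force loss over the steps of a rollout.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .exceptions import PartitionError, SizeError

__all__ = [
    "BatchErrors",
    "LossWeights",
    "energy_loss",
    "force_loss",
    "dt_loss",
    "mepa",
    "weighted_mse_loss",
    "species_force_weights",
    "weighted_l1",
]


@dataclass
class BatchErrors:
    """Residuals of a batch of configurations.

    ``energy_residuals``: per configuration, E_pred - E_ref (eV).
    ``force_residuals``: per configuration, (N_b, 3) array of F_pred - F_ref.
    ``species``: per configuration, the per-atom species labels.
    """

    energy_residuals: np.ndarray
    force_residuals: list[np.ndarray]
    species: list[list[str]]

    def __post_init__(self):
        self.energy_residuals = np.atleast_1d(np.asarray(self.energy_residuals, dtype=float))
        self.force_residuals = [np.asarray(f, dtype=float) for f in self.force_residuals]
        b = len(self.energy_residuals)
        if b == 0:
            raise SizeError("empty batch")
        if len(self.force_residuals) != b or len(self.species) != b:
            raise SizeError("batch fields disagree in length")
        for f, s in zip(self.force_residuals, self.species):
            if len(s) == 0:
                raise PartitionError("configuration without atoms")
            if f.shape != (len(s), 3):
                raise PartitionError(
                    f"force residual shape {f.shape} does not match {len(s)} atoms"
                )

    @property
    def batch_size(self) -> int:
        return len(self.energy_residuals)

    @property
    def n_atoms(self) -> np.ndarray:
        return np.array([len(s) for s in self.species])


@dataclass
class LossWeights:
    """Per-step weights λ_k of the rollout loss (λ_1 = 50, λ_k>1 = 1 by
    default) and the λ_E / λ_F weights of the weighted-MSE baseline."""

    lambda_first: float = 50.0
    lambda_rest: float = 1.0
    lambda_energy: float = 1.0
    lambda_force: float = 1.0

    def __post_init__(self):
        if min(self.lambda_first, self.lambda_rest, self.lambda_energy, self.lambda_force) < 0:
            raise SizeError("loss weights must be nonnegative")

    def per_step(self, n_steps: int) -> np.ndarray:
        lam = np.full(n_steps, self.lambda_rest)
        lam[0] = self.lambda_first
        return lam


def energy_loss(batch: BatchErrors) -> float:
    """Per-atom-normalised mean absolute energy error:
    (1/B) Σ_b |ΔE_b| / N_b  (eV/atom)."""
    return float(np.mean(np.abs(batch.energy_residuals) / batch.n_atoms))


def force_loss(batch: BatchErrors) -> float:
    """Species-balanced force MAE:
    (1/B) Σ_b Σ_{a∈A_b} (1/(3 N_{a,b})) Σ_{i,α} |ΔF|  (eV/Å)."""
    total = 0.0
    for resid, species in zip(batch.force_residuals, batch.species):
        labels = np.asarray(species)
        for sp in sorted(set(species)):
            sel = labels == sp
            total += np.abs(resid[sel]).sum() / (3.0 * sel.sum())
    return total / batch.batch_size


def dt_loss(
    per_step_force_losses: Sequence,
    energy_loss_0=None,
    weights: LossWeights | None = None,
):
    """Rollout training loss.

    For a single step (S = 1) it is the sum of the energy loss and the force
    loss.  For S > 1 it is the λ-weighted sum of the per-step force losses,
    Σ_k λ_k L_force^k, with no energy term: only the first step's positions
    coincide with the reference, hence its dominant weight λ_1.
    Accepts floats or autodiff tensors (training path).
    """
    weights = weights or LossWeights()
    s = len(per_step_force_losses)
    if s < 1:
        raise SizeError("need at least one per-step force loss")
    if s == 1:
        if energy_loss_0 is None:
            raise SizeError("S = 1 loss requires the energy term")
        return energy_loss_0 + per_step_force_losses[0]
    lam = weights.per_step(s)
    total = per_step_force_losses[0] * float(lam[0])
    for k in range(1, s):
        total = total + per_step_force_losses[k] * float(lam[k])
    return total


def mepa(per_step_force_losses: Sequence[float]) -> float:
    """Mean error of atomic forces per atom type and per simulation step:
    the mean of the species-balanced force loss over rollout steps."""
    if len(per_step_force_losses) == 0:
        raise SizeError("empty per-step loss list")
    return float(np.mean([float(x) for x in per_step_force_losses]))


def weighted_mse_loss(batch: BatchErrors, weights: LossWeights | None = None) -> float:
    """Weighted mean-square baseline loss:
    λ_E (1/B) Σ_b (ΔE_b)²/N_b + λ_F (1/B) Σ_b (1/(3N_b)) Σ_{i,α} (ΔF)².

    Normalises forces per configuration rather than per species, so species
    with many atoms dominate (contrast with :func:`force_loss`)."""
    weights = weights or LossWeights()
    e_term = np.mean(batch.energy_residuals**2 / batch.n_atoms)
    f_term = np.mean(
        [ (resid**2).sum() / (3.0 * resid.shape[0]) for resid in batch.force_residuals ]
    )
    return float(weights.lambda_energy * e_term + weights.lambda_force * f_term)


# ---------------------------------------------------------------------------
# tensor-path helpers used inside training rollouts
# ---------------------------------------------------------------------------


def species_force_weights(
    species: Sequence[str], graph_index: np.ndarray | None = None, n_graphs: int = 1
) -> np.ndarray:
    """Per-atom weights w such that Σ_{i,α} w_i |ΔF_{i,α}| equals the
    species-balanced force loss of the (possibly batched) configuration."""
    labels = np.asarray(species)
    if graph_index is None:
        graph_index = np.zeros(len(labels), dtype=np.intp)
    w = np.empty(len(labels))
    for g in range(n_graphs):
        in_g = graph_index == g
        if not in_g.any():
            raise PartitionError(f"batched graph {g} has no atoms")
        for sp in set(labels[in_g]):
            sel = in_g & (labels == sp)
            w[sel] = 1.0 / (3.0 * sel.sum() * n_graphs)
    return w


def weighted_l1(delta, per_atom_weights: np.ndarray):
    """Σ_i w_i Σ_α |Δ_{i,α}| for a Tensor or ndarray residual of shape (N, 3)."""
    if isinstance(delta, Tensor):
        return ad.tsum(ad.mul(ad.absolute(delta), per_atom_weights[:, None]))
    return float(np.sum(np.abs(delta) * per_atom_weights[:, None]))
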