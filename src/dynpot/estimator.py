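"""Scikit-learn style estimator facade over the dynamic trainer.

``DTPotential`` is a regressor-shaped wrapper: ``fit`` consumes reference
trajectories, runs the subsequence-length curriculum, and exposes fitted
attributes; ``predict`` maps frames to forces.  It composes with sklearn
model-selection utilities through ``get_params``/``set_params``.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin

from .losses import BatchErrors, force_loss
from .model import EGNN, ModelConfig
from .trajectory import Trajectory, build_subsequence_dataset
from .training import TrainConfig, train, validate

__all__ = ["DTPotential"]


class DTPotential(RegressorMixin, BaseEstimator):
    """Neural-network interatomic potential trained on differentiable
    velocity-Verlet rollouts of increasing subsequence length.

    Parameters mirror :class:`~dynpot.model.ModelConfig` and
    :class:`~dynpot.training.TrainConfig`; see those for semantics.

    Attributes (after ``fit``)
    --------------------------
    model_ : the trained :class:`~dynpot.model.EGNN`
    history_ : per-epoch curriculum history (epoch, S, lr, losses, event)
    best_checkpoints_ : best parameter set recorded at each subsequence length
    state_ : final :class:`~dynpot.training.CurriculumState`
    """

    def __init__(
        self,
        node_dim: int = 16,
        edge_dim: int = 16,
        num_layers: int = 2,
        rff_sigma: float = 4.0,
        cutoff: float = 5.0,
        activation: str = "silu",
        s_max: int = 5,
        s_val: int = 20,
        initial_lr: float = 1e-3,
        lr_reset: float = 1e-4,
        min_lr: float = 2e-6,
        plateau_factor: float = 0.5,
        plateau_patience: int = 25,
        train_batch: int = 32,
        val_batch: int = 256,
        max_epochs: int = 100000,
        max_epochs_per_s: int | None = None,
        grad_clip: float = 10.0,
        validation_fraction: float = 0.1,
        sample_stride: int = 1,
        seed: int = 0,
    ):
        self.node_dim = node_dim
        self.edge_dim = edge_dim
        self.num_layers = num_layers
        self.rff_sigma = rff_sigma
        self.cutoff = cutoff
        self.activation = activation
        self.s_max = s_max
        self.s_val = s_val
        self.initial_lr = initial_lr
        self.lr_reset = lr_reset
        self.min_lr = min_lr
        self.plateau_factor = plateau_factor
        self.plateau_patience = plateau_patience
        self.train_batch = train_batch
        self.val_batch = val_batch
        self.max_epochs = max_epochs
        self.max_epochs_per_s = max_epochs_per_s
        self.grad_clip = grad_clip
        self.validation_fraction = validation_fraction
        self.sample_stride = sample_stride
        self.seed = seed

    # ------------------------------------------------------------------
    def _configs(self, species) -> tuple[ModelConfig, TrainConfig]:
        model_cfg = ModelConfig(
            species=tuple(sorted(set(species))),
            node_dim=self.node_dim,
            edge_dim=self.edge_dim,
            num_layers=self.num_layers,
            rff_sigma=self.rff_sigma,
            cutoff=self.cutoff,
            activation=self.activation,
            rff_seed=self.seed,
            init_seed=self.seed + 1,
        )
        train_cfg = TrainConfig(
            s_max=self.s_max,
            s_val=self.s_val,
            initial_lr=self.initial_lr,
            lr_reset=self.lr_reset,
            min_lr=self.min_lr,
            plateau_factor=self.plateau_factor,
            plateau_patience=self.plateau_patience,
            train_batch=self.train_batch,
            val_batch=self.val_batch,
            max_epochs=self.max_epochs,
            max_epochs_per_s=self.max_epochs_per_s,
            grad_clip=self.grad_clip,
            seed=self.seed + 2,
        )
        return model_cfg, train_cfg

    def fit(self, X: list[Trajectory], y=None):
        """Fit on a list of reference trajectories.

        A ``validation_fraction`` of the subsequence samples (taken from the
        end of each trajectory's sample list) is held out and rolled out for
        ``s_val`` steps as the validation benchmark."""
        if not X:
            raise ValueError("need at least one trajectory")
        species = X[0].species
        model_cfg, train_cfg = self._configs(species)
        train_samples, val_samples = [], []
        for t, traj in enumerate(X):
            ss = build_subsequence_dataset(
                traj, self.s_max, self.cutoff, traj_id=t, stride=self.sample_stride
            )
            vv = build_subsequence_dataset(
                traj, self.s_val, self.cutoff, traj_id=t, stride=self.sample_stride
            )
            n_val = max(1, int(len(vv) * self.validation_fraction))
            val_samples.extend(vv[-n_val:])
            train_samples.extend(ss[: len(ss) - n_val])
        self.model_ = EGNN.initialise(model_cfg)
        result = train(self.model_, train_samples, val_samples, train_cfg)
        self.history_ = result.history
        self.best_checkpoints_ = result.best_checkpoints
        self.state_ = result.state
        self.n_features_in_ = 3  # per-atom Cartesian coordinates
        return self

    def predict(self, X) -> list[np.ndarray]:
        """Predicted forces (eV/Å) for each frame in ``X`` (list of Frame)."""
        self._check_fitted()
        out = []
        for frame in X:
            f, _ = self.model_.forces(
                frame.species, frame.positions, None, frame.cell, frame.pbc
            )
            out.append(f.numpy())
        return out

    def predict_energy(self, X) -> np.ndarray:
        self._check_fitted()
        return np.array(
            [
                self.model_.energy(fr.species, fr.positions, None, fr.cell, fr.pbc)
                for fr in X
            ]
        )

    def score(self, X, y=None) -> float:
        """Negative species-balanced force MAE over frames (higher is better)."""
        self._check_fitted()
        preds = self.predict(X)
        batch = BatchErrors(
            energy_residuals=np.zeros(len(X)),
            force_residuals=[p - fr.forces for p, fr in zip(preds, X)],
            species=[fr.species for fr in X],
        )
        return -force_loss(batch)

    def validation_mepa(self, trajectories: list[Trajectory]) -> float:
        """Validation-style MEPA on fresh trajectories."""
        self._check_fitted()
        samples = []
        for t, traj in enumerate(trajectories):
            samples.extend(
                build_subsequence_dataset(traj, self.s_val, self.cutoff, traj_id=t)
            )
        return validate(self.model_, samples, self.s_val, self.val_batch)

    def _check_fitted(self):
        if not hasattr(self, "model_"):
            raise AttributeError("this DTPotential instance is not fitted yet")
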