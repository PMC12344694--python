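"""The dynamic-training curriculum.

Training starts at subsequence length S = 1 (conventional single-point
fitting of energies and forces).  After every epoch the model is validated
by running fixed-length (S_val) training-mode rollouts over the validation
samples and scoring them with MEPA.  A plateau scheduler decays the
learning rate when validation stops improving; when the patience period is
exceeded *at the minimum learning rate* the model is considered converged
for the current S, the subsequence length is incremented, and the learning
rate is reset.  The best parameters per S (lowest validation MEPA) are kept
throughout.

Batches of subsequences are merged into one block-diagonal graph and rolled
out in lockstep, so the per-step force losses are batch averages by
construction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .dynamics import rollout
from .exceptions import ParameterError, SizeError, TrainingFault
from .losses import LossWeights, dt_loss, species_force_weights, weighted_l1
from .model import EGNN
from .trajectory import EdgeList, SubsequenceSample

__all__ = [
    "TrainConfig",
    "CurriculumState",
    "TrainResult",
    "plateau_update",
    "advance_curriculum",
    "train",
    "train_single_point",
    "validate",
    "merge_samples",
    "Adam",
]


@dataclass
class TrainConfig:
    """Curriculum and optimization hyperparameters.

    Learning-rate schedule: start at ``initial_lr``; on plateau multiply by
    ``plateau_factor`` (floored at ``min_lr``); after each curriculum
    advance reset to ``lr_reset``.  ``max_epochs_per_s`` is an optional hard
    cap that forces the advance if the plateau rule has not fired."""

    s_max: int = 5
    s_val: int = 20
    initial_lr: float = 1e-3
    lr_reset: float = 1e-4
    min_lr: float = 2e-6
    plateau_factor: float = 0.5
    plateau_patience: int = 25
    min_delta: float = 0.0
    train_batch: int = 32
    val_batch: int = 256
    optimizer: str = "adam"
    max_epochs: int = 100000
    max_epochs_per_s: int | None = None
    grad_clip: float = 10.0
    seed: int = 0
    single_point_loss: str = "mae"  # "mae" (energy+force MAE) or "wmse" baseline
    lambda_first: float = 50.0
    include_energy_beyond_s1: bool = False

    def __post_init__(self):
        if not (self.min_lr < self.lr_reset <= self.initial_lr):
            raise ParameterError(
                "learning rates must satisfy min_lr < lr_reset <= initial_lr"
            )
        if self.s_max < 1 or self.s_val < 1:
            raise ParameterError("s_max and s_val must be >= 1")
        if self.single_point_loss not in ("mae", "wmse"):
            raise ParameterError("single_point_loss must be 'mae' or 'wmse'")

    @property
    def loss_weights(self) -> LossWeights:
        return LossWeights(lambda_first=self.lambda_first)


@dataclass
class CurriculumState:
    """Mutable curriculum bookkeeping carried across epochs."""

    s: int = 1
    lr: float = 1e-3
    epochs_since_improve: int = 0
    best_val: float = float("inf")  # overall
    best_val_s: float = float("inf")  # current S
    epoch: int = 0
    best_val_per_s: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        d = asdict(self)
        d["best_val_per_s"] = {str(k): v for k, v in self.best_val_per_s.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CurriculumState":
        d = dict(d)
        d["best_val_per_s"] = {int(k): v for k, v in d.get("best_val_per_s", {}).items()}
        return cls(**d)


@dataclass
class TrainResult:
    state: CurriculumState
    history: list[dict]
    best_checkpoints: dict[int, dict]  # S -> parameter arrays
    completed: bool
    resume_state: dict | None = None  # JSON-compatible snapshot for resumption


# ---------------------------------------------------------------------------
# plateau scheduler + curriculum
# ---------------------------------------------------------------------------


def plateau_update(state: CurriculumState, val_error: float, config: TrainConfig) -> str:
    """Advance the plateau bookkeeping by one validation result.

    Returns ``"none"``, ``"lr_decayed"`` or ``"converged"``.  Improvement
    (val_error < best - min_delta) resets the patience counter; exceeding
    the patience at lr > min_lr decays the learning rate; exceeding it at
    lr = min_lr signals convergence for the current subsequence length."""
    if not np.isfinite(val_error):
        raise TrainingFault(f"non-finite validation error {val_error!r}")
    if val_error < state.best_val_s - config.min_delta:
        state.best_val_s = val_error
        state.best_val = min(state.best_val, val_error)
        state.epochs_since_improve = 0
        return "none"
    state.epochs_since_improve += 1
    if state.epochs_since_improve <= config.plateau_patience:
        return "none"
    if state.lr > config.min_lr:
        state.lr = max(state.lr * config.plateau_factor, config.min_lr)
        state.epochs_since_improve = 0
        return "lr_decayed"
    return "converged"


def advance_curriculum(state: CurriculumState, config: TrainConfig) -> bool:
    """Increment S and reset the learning rate after a convergence event.

    Returns False (terminal: training complete) when S is already S_max;
    otherwise clears the per-S plateau bookkeeping and returns True."""
    state.best_val_per_s.setdefault(state.s, state.best_val_s)
    if state.s >= config.s_max:
        return False
    state.s += 1
    state.lr = config.lr_reset
    state.epochs_since_improve = 0
    state.best_val_s = float("inf")
    return True


# ---------------------------------------------------------------------------
# batching
# ---------------------------------------------------------------------------


class BatchedEdgeList(EdgeList):
    """Edge list of a block-diagonal batch graph, annotated with the
    node-to-graph index so pooling and losses stay per-configuration."""

    def __init__(self, src, dst, shifts, graph_index, n_graphs):
        super().__init__(src=src, dst=dst, shifts=shifts)
        self.graph_index = np.asarray(graph_index, dtype=np.intp)
        self.n_graphs = int(n_graphs)


def merge_samples(samples: list[SubsequenceSample], n_steps: int) -> SubsequenceSample:
    """Merge samples into one block-diagonal sample for lockstep rollouts.

    Requires a common dt/cell/pbc (batches always come from one dataset).
    ``reference_energy_0`` becomes the vector of per-sample energies."""
    if not samples:
        raise SizeError("empty batch")
    dt = samples[0].dt
    cell, pbc = samples[0].cell, samples[0].pbc
    for s in samples:
        if s.dt != dt or not np.allclose(s.cell, cell) or s.pbc != pbc:
            raise SizeError("cannot batch samples with differing dt/cell/pbc")
        if s.s_max < n_steps:
            raise SizeError("a sample does not support the requested rollout length")
    counts = [s.n_atoms for s in samples]
    offsets = np.concatenate([[0], np.cumsum(counts)])
    graph_index = np.concatenate(
        [np.full(c, k, dtype=np.intp) for k, c in enumerate(counts)]
    )
    edge_sets = []
    for step in range(n_steps):
        src = np.concatenate([s.reference_edge_sets[step].src + offsets[k]
                              for k, s in enumerate(samples)])
        dst = np.concatenate([s.reference_edge_sets[step].dst + offsets[k]
                              for k, s in enumerate(samples)])
        shifts = np.concatenate([s.reference_edge_sets[step].shifts for s in samples])
        edge_sets.append(BatchedEdgeList(src, dst, shifts, graph_index, len(samples)))
    merged = SubsequenceSample(
        species=[sp for s in samples for sp in s.species],
        masses=np.concatenate([s.masses for s in samples]),
        initial_positions=np.vstack([s.initial_positions for s in samples]),
        initial_velocities=np.vstack([s.initial_velocities for s in samples]),
        dt=dt,
        reference_forces=np.concatenate(
            [s.reference_forces[:n_steps] for s in samples], axis=1
        ),
        reference_energy_0=np.array([s.reference_energy_0 for s in samples]),
        reference_edge_sets=edge_sets,
        cell=cell,
        pbc=pbc,
        source=samples[0].source,
    )
    return merged


# ---------------------------------------------------------------------------
# optimizer
# ---------------------------------------------------------------------------


class Adam:
    """Adam with bias correction; operates in place on parameter tensors."""

    def __init__(self, params: dict[str, Tensor], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def step(self, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, p in self.params.items():
            g = grads[k]
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1**self.t)
            vhat = self.v[k] / (1 - b2**self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def state_dict(self) -> dict:
        return {
            "t": self.t, "lr": self.lr,
            "m": {k: v.tolist() for k, v in self.m.items()},
            "v": {k: v.tolist() for k, v in self.v.items()},
        }

    def load_state_dict(self, d: dict) -> None:
        self.t = int(d["t"])
        self.lr = float(d["lr"])
        self.m = {k: np.array(v) for k, v in d["m"].items()}
        self.v = {k: np.array(v) for k, v in d["v"].items()}


class _FrozenParams:
    """Temporarily exclude model parameters from graph construction
    (validation-path rollouts only need gradients w.r.t. positions)."""

    def __init__(self, model: EGNN):
        self.model = model

    def __enter__(self):
        for p in self.model.params.values():
            p.requires_grad = False
        return self

    def __exit__(self, *exc):
        for p in self.model.params.values():
            p.requires_grad = True
        return False


# ---------------------------------------------------------------------------
# loss of one batched rollout
# ---------------------------------------------------------------------------


def _rollout_losses(model: EGNN, batch: SubsequenceSample, n_steps: int,
                    create_graph: bool):
    """Training-mode rollout of a (merged) batch; returns the per-step
    species-balanced force losses and the S=1 energy loss term (tensors)."""
    provider = model.as_force_provider(create_graph=create_graph)
    result = rollout(provider, batch, n_steps, mode="training")
    edges0 = batch.reference_edge_sets[0]
    graph_index = getattr(edges0, "graph_index", None)
    n_graphs = getattr(edges0, "n_graphs", 1)
    w_force = species_force_weights(batch.species, graph_index, n_graphs)
    step_losses = []
    for k in range(n_steps):
        delta = result.forces[k] - batch.reference_forces[k]
        step_losses.append(weighted_l1(delta, w_force))
    # per-atom-normalised energy MAE of the initial frame
    e_ref = np.atleast_1d(np.asarray(batch.reference_energy_0, dtype=float))
    if graph_index is None:
        n_atoms = np.array([batch.n_atoms])
    else:
        n_atoms = np.bincount(graph_index, minlength=n_graphs)
    delta_e = result.energies[0] - e_ref
    if isinstance(delta_e, Tensor):
        e_loss = ad.tsum(ad.mul(ad.absolute(delta_e), 1.0 / (n_atoms * len(e_ref))))
    else:
        e_loss = float(np.sum(np.abs(delta_e) / (n_atoms * len(e_ref))))
    return step_losses, e_loss, result


def _single_point_wmse(model: EGNN, batch: SubsequenceSample):
    """Weighted-MSE baseline loss (energy + force square errors, per-atom
    normalised) on the initial frames of a batch; used by the
    conventionally trained reference model."""
    provider = model.as_force_provider(create_graph=True)
    result = rollout(provider, batch, 1, mode="training")
    edges0 = batch.reference_edge_sets[0]
    graph_index = getattr(edges0, "graph_index", None)
    n_graphs = getattr(edges0, "n_graphs", 1)
    if graph_index is None:
        graph_index = np.zeros(batch.n_atoms, dtype=np.intp)
    n_atoms = np.bincount(graph_index, minlength=n_graphs)
    e_ref = np.atleast_1d(np.asarray(batch.reference_energy_0, dtype=float))
    delta_e = result.energies[0] - e_ref
    e_term = ad.tsum(ad.mul(ad.power(delta_e, 2.0), 1.0 / (n_atoms * n_graphs)))
    delta_f = result.forces[0] - batch.reference_forces[0]
    w = (1.0 / (3.0 * n_atoms * n_graphs))[graph_index]
    f_term = ad.tsum(ad.mul(ad.power(delta_f, 2.0), w[:, None]))
    return e_term + f_term


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------


def validate(model: EGNN, val_samples: list[SubsequenceSample], s_val: int,
             batch_size: int = 256) -> float:
    """Validation MEPA: mean over samples of the per-step species-balanced
    force loss along S_val-step training-mode rollouts (frozen reference
    edge sets, no parameter gradients)."""
    if not val_samples:
        raise SizeError("empty validation set")
    total, count = 0.0, 0
    with _FrozenParams(model):
        for lo in range(0, len(val_samples), batch_size):
            chunk = val_samples[lo : lo + batch_size]
            batch = merge_samples(chunk, s_val) if len(chunk) > 1 else chunk[0]
            step_losses, _, _ = _rollout_losses(model, batch, s_val, create_graph=False)
            vals = [float(x.data) if isinstance(x, Tensor) else float(x) for x in step_losses]
            total += float(np.mean(vals)) * len(chunk)
            count += len(chunk)
    return total / count


# ---------------------------------------------------------------------------
# training loop
# ---------------------------------------------------------------------------


def _global_norm_clip(grads: dict[str, np.ndarray], max_norm: float) -> dict[str, np.ndarray]:
    total = np.sqrt(sum(float(np.sum(g * g)) for g in grads.values()))
    if max_norm and total > max_norm:
        scale = max_norm / (total + 1e-12)
        return {k: g * scale for k, g in grads.items()}
    return grads


def _train_epoch(model: EGNN, samples, order, config: TrainConfig, s: int, adam: Adam) -> float:
    weights = config.loss_weights
    losses = []
    for lo in range(0, len(order), config.train_batch):
        idx = order[lo : lo + config.train_batch]
        batch = merge_samples([samples[i] for i in idx], s)
        if s == 1 and config.single_point_loss == "wmse":
            loss = _single_point_wmse(model, batch)
        else:
            step_losses, e_loss, _ = _rollout_losses(model, batch, s, create_graph=True)
            energy_term = e_loss if (s == 1 or config.include_energy_beyond_s1) else None
            if s == 1:
                loss = dt_loss(step_losses, energy_term, weights)
            else:
                loss = dt_loss(step_losses, None, weights)
                if energy_term is not None:
                    loss = loss + energy_term
        if not np.isfinite(loss.data):
            raise TrainingFault("non-finite training loss")
        names = list(model.params)
        gs = ad.grad(loss, [model.params[n] for n in names], allow_unused=True)
        grads = _global_norm_clip(
            {n: g.data for n, g in zip(names, gs)}, config.grad_clip
        )
        adam.step(grads)
        losses.append(float(loss.data))
    return float(np.mean(losses))


def train(
    model: EGNN,
    train_samples: list[SubsequenceSample],
    val_samples: list[SubsequenceSample],
    config: TrainConfig,
    log=None,
    resume_state: dict | None = None,
) -> TrainResult:
    """Run the dynamic-training curriculum.

    Returns the final curriculum state, the per-epoch history and the best
    parameters recorded at each subsequence length.  Deterministic given
    the config seed (and a fixed BLAS thread count)."""
    for sample in train_samples:
        if sample.s_max < config.s_max:
            raise SizeError("every training sample must carry s_max reference frames")
    for sample in val_samples:
        if sample.s_max < config.s_val:
            raise SizeError("every validation sample must support s_val steps")

    state = CurriculumState(s=1, lr=config.initial_lr)
    adam = Adam(model.params, state.lr)
    rng = np.random.default_rng(config.seed)
    history: list[dict] = []
    best_checkpoints: dict[int, dict] = {}
    epochs_in_s = 0
    completed = False

    if resume_state is not None:
        state = CurriculumState.from_dict(resume_state["curriculum"])
        adam.load_state_dict(resume_state["adam"])
        model.load_params({k: np.array(v) for k, v in resume_state["params"].items()})
        rng.bit_generator.state = resume_state["rng"]
        history = list(resume_state.get("history", []))
        best_checkpoints = {
            int(k): {n: np.array(a) for n, a in v.items()}
            for k, v in resume_state.get("best_checkpoints", {}).items()
        }
        epochs_in_s = int(resume_state.get("epochs_in_s", 0))

    last_good = model.clone_params()
    while state.epoch < config.max_epochs:
        order = rng.permutation(len(train_samples))
        adam.lr = state.lr
        try:
            train_loss = _train_epoch(model, train_samples, order, config, state.s, adam)
            val_mepa = validate(model, val_samples, config.s_val, config.val_batch)
        except TrainingFault:
            model.load_params(last_good)
            raise
        last_good = model.clone_params()
        state.epoch += 1
        epochs_in_s += 1

        if val_mepa < state.best_val_s:
            best_checkpoints[state.s] = model.clone_params()
        event = plateau_update(state, val_mepa, config)
        forced = (
            config.max_epochs_per_s is not None
            and epochs_in_s >= config.max_epochs_per_s
            and event != "converged"
        )
        if forced:
            event = "converged"
        history.append(
            {
                "epoch": state.epoch,
                "s": state.s,
                "lr": state.lr,
                "train_loss": train_loss,
                "val_mepa": val_mepa,
                "event": event,
            }
        )
        if log is not None:
            log(history[-1])
        if event == "converged":
            best_checkpoints.setdefault(state.s, model.clone_params())
            if not advance_curriculum(state, config):
                completed = True
                break
            adam = Adam(model.params, state.lr)
            epochs_in_s = 0

    resume = {
        "curriculum": state.as_dict(),
        "params": {k: p.data.tolist() for k, p in model.params.items()},
        "adam": adam.state_dict(),
        "rng": rng.bit_generator.state,
        "history": history,
        "best_checkpoints": {
            str(k): {n: a.tolist() for n, a in v.items()}
            for k, v in best_checkpoints.items()
        },
        "epochs_in_s": epochs_in_s,
    }
    return TrainResult(
        state=state, history=history, best_checkpoints=best_checkpoints,
        completed=completed, resume_state=resume,
    )


def train_single_point(model, train_samples, val_samples, config: TrainConfig, log=None):
    """Conventional (non-curriculum) single-point training: identical to the
    dynamic trainer locked at S = 1, which is exactly how the two coincide
    operationally at the start of a curriculum."""
    cfg = TrainConfig(**{**asdict(config), "s_max": 1})
    return train(model, train_samples, val_samples, cfg, log=log)


# ---------------------------------------------------------------------------
# checkpoint/resume helpers
# ---------------------------------------------------------------------------


def save_training_state(path, model: EGNN, result_or_state, adam: Adam | None = None,
                        history=None, best_checkpoints=None, epochs_in_s: int = 0,
                        rng_state=None) -> None:
    state = result_or_state if isinstance(result_or_state, CurriculumState) else result_or_state.state
    payload = {
        "curriculum": state.as_dict(),
        "params": {k: p.data.tolist() for k, p in model.params.items()},
        "adam": adam.state_dict() if adam else None,
        "history": history or [],
        "best_checkpoints": {
            str(k): {n: a.tolist() for n, a in v.items()}
            for k, v in (best_checkpoints or {}).items()
        },
        "epochs_in_s": epochs_in_s,
        "rng": rng_state,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_training_state(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
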