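"""The scaled-down central experiment: does increasing the training
subsequence length improve long-horizon force accuracy?

Protocol (a desk-scale analog of the full study, sizes chosen so the whole
experiment runs on one CPU in minutes):

1. generate microcanonical reference trajectories of the toy
   projectile-on-cluster system;
2. split them into training and held-out test trajectories;
3. run the dynamic-training curriculum up to S_max over several repeats
   (independent model/optimizer seeds), keeping the best parameters per
   subsequence length (lowest validation MEPA at fixed S_val);
4. evaluate each per-S best model by inference-mode rollouts of a fixed
   horizon from test samples of the unseen trajectories, scoring MEPA;
5. additionally train an identical model conventionally (single-point,
   same loss and seed) and evaluate it the same way — operationally this
   coincides with the curriculum stopped at S = 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import EGNN, ModelConfig
from .synthetic import GeneratorSpec, default_system, generate_dataset
from .trajectory import build_subsequence_dataset
from .training import TrainConfig, train, train_single_point
from .workbench import evaluate_models_over_S

__all__ = ["EfficacyConfig", "run_dt_efficacy"]


@dataclass
class EfficacyConfig:
    """Study sizes of the desk-scale experiment."""

    n_train_trajectories: int = 6
    n_test_trajectories: int = 2
    n_steps: int = 100
    sample_stride: int = 3
    n_val_samples: int = 24
    n_test_samples: int = 16
    s_max: int = 5
    s_val: int = 20
    horizon: int = 50
    n_repeats: int = 3
    node_dim: int = 16
    edge_dim: int = 16
    num_layers: int = 2
    cutoff: float = 5.0
    train: TrainConfig = field(
        default_factory=lambda: TrainConfig(
            s_max=5,
            s_val=20,
            plateau_patience=2,
            plateau_factor=0.2,
            max_epochs_per_s=12,
            train_batch=32,
            val_batch=64,
        )
    )
    run_conventional: bool = True


def _subsample(samples, n, rng):
    if n >= len(samples):
        return list(samples)
    idx = np.sort(rng.choice(len(samples), size=n, replace=False))
    return [samples[i] for i in idx]


def run_dt_efficacy(seed: int, config: EfficacyConfig | None = None) -> dict:
    """Run the full experiment; deterministic given ``seed``.

    Returns per-repeat test MEPA per subsequence length, the medians of the
    best-at-S=1 and best-at-S_max models, and the conventionally trained
    reference's MEPA for the first repeat."""
    cfg = config or EfficacyConfig()
    system = default_system()
    gen = GeneratorSpec(
        n_steps=cfg.n_steps,
        n_trajectories=cfg.n_train_trajectories + cfg.n_test_trajectories,
        seed=seed,
    )
    trajectories = generate_dataset(system, gen)
    train_trajs = trajectories[: cfg.n_train_trajectories]
    test_trajs = trajectories[cfg.n_train_trajectories :]

    rng = np.random.default_rng(seed)
    train_samples, val_pool = [], []
    for t, traj in enumerate(train_trajs):
        train_samples.extend(
            build_subsequence_dataset(traj, cfg.s_max, cfg.cutoff, traj_id=t,
                                      stride=cfg.sample_stride)
        )
        val_pool.extend(
            build_subsequence_dataset(traj, cfg.s_val, cfg.cutoff, traj_id=t,
                                      stride=cfg.sample_stride)
        )
    val_samples = _subsample(val_pool, cfg.n_val_samples, rng)
    test_pool = []
    for t, traj in enumerate(test_trajs):
        test_pool.extend(
            build_subsequence_dataset(traj, cfg.horizon, cfg.cutoff,
                                      traj_id=cfg.n_train_trajectories + t)
        )
    test_samples = _subsample(test_pool, cfg.n_test_samples, rng)

    species = tuple(sorted(set(system.species)))
    per_repeat = []
    conventional = None
    for rep in range(cfg.n_repeats):
        rep_seed = (seed * 1000 + rep) % (2**31)
        model_cfg = ModelConfig(
            species=species,
            node_dim=cfg.node_dim,
            edge_dim=cfg.edge_dim,
            num_layers=cfg.num_layers,
            cutoff=cfg.cutoff,
            rff_seed=rep_seed,
            init_seed=rep_seed + 1,
        )
        train_cfg = TrainConfig(
            **{
                **cfg.train.__dict__,
                "s_max": cfg.s_max,
                "s_val": cfg.s_val,
                "seed": rep_seed + 2,
            }
        )
        model = EGNN.initialise(model_cfg)
        result = train(model, train_samples, val_samples, train_cfg)
        rows = evaluate_models_over_S(
            model_cfg, result.best_checkpoints, test_samples, cfg.horizon
        )
        per_repeat.append(
            {
                "seed": rep_seed,
                "mepa_by_s": {row["s"]: row["mepa"] for row in rows},
                "epochs": result.state.epoch,
                "history": result.history,
            }
        )
        if cfg.run_conventional and rep == 0:
            conv_model = EGNN.initialise(model_cfg)
            conv_result = train_single_point(
                conv_model, train_samples, val_samples, train_cfg
            )
            conv_rows = evaluate_models_over_S(
                model_cfg, conv_result.best_checkpoints, test_samples, cfg.horizon
            )
            conventional = {
                "mepa": conv_rows[0]["mepa"],
                "history": conv_result.history,
            }

    mepa_s1 = [r["mepa_by_s"][1] for r in per_repeat]
    mepa_smax = [r["mepa_by_s"][cfg.s_max] for r in per_repeat]
    out = {
        "per_repeat": per_repeat,
        "median_mepa_s1": float(np.median(mepa_s1)),
        "median_mepa_smax": float(np.median(mepa_smax)),
        "s_max": cfg.s_max,
        "horizon": cfg.horizon,
        "n_train_samples": len(train_samples),
        "n_val_samples": len(val_samples),
        "n_test_samples": len(test_samples),
    }
    if conventional is not None:
        out["conventional_mepa"] = conventional["mepa"]
        out["dt_s1_mepa_first_repeat"] = per_repeat[0]["mepa_by_s"][1]
        out["conventional_history"] = conventional["history"]
    return out
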