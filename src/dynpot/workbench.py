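"""Evaluation workbench: long-horizon rollout metrics and metric tables.

Mirrors the study protocol: from each test sample's initial conditions run
an inference-mode rollout (neighbor lists recomputed from predicted
positions every step) for a fixed horizon, compare predicted forces to the
reference forces frame by frame, and report the species-balanced per-step
force loss, its mean over steps (MEPA), and per-species force MAE.
"""

from __future__ import annotations

import csv
import json

import numpy as np

from .exceptions import SizeError
from .dynamics import rollout
from .losses import mepa, species_force_weights, weighted_l1
from .model import EGNN, ModelConfig
from .trajectory import SubsequenceSample

__all__ = ["evaluate_rollout", "evaluate_models_over_S", "write_metric_table"]


def evaluate_rollout(
    model: EGNN,
    samples: list[SubsequenceSample],
    horizon: int,
    mode: str = "inference",
) -> dict:
    """Rollout-error metrics of one model over test samples.

    Returns per-step force losses averaged over samples, their MEPA, and
    per-species MAE pooled over all steps and samples."""
    if not samples:
        raise SizeError("no test samples")
    for s in samples:
        if s.s_max < horizon:
            raise SizeError(
                f"horizon {horizon} exceeds the sample's {s.s_max} reference frames"
            )
    provider = model.as_force_provider(create_graph=False)
    per_step = np.zeros(horizon)
    species_abs: dict[str, list] = {}
    for sample in samples:
        result = rollout(provider, sample, horizon, mode=mode,
                         cutoff=model.config.cutoff).numpy()
        w = species_force_weights(sample.species)
        labels = np.asarray(sample.species)
        for k in range(horizon):
            delta = result.forces[k] - sample.reference_forces[k]
            per_step[k] += weighted_l1(delta, w)
            for sp in set(sample.species):
                species_abs.setdefault(sp, []).append(
                    np.abs(delta[labels == sp]).mean()
                )
    per_step /= len(samples)
    return {
        "per_step_force_loss": per_step.tolist(),
        "mepa": mepa(per_step),
        "per_species_mae": {sp: float(np.mean(v)) for sp, v in sorted(species_abs.items())},
        "horizon": horizon,
        "n_samples": len(samples),
    }


def evaluate_models_over_S(
    config: ModelConfig,
    checkpoints: dict[int, dict],
    test_samples: list[SubsequenceSample],
    horizon: int,
) -> list[dict]:
    """One metrics row per subsequence length, using the best parameters
    recorded at that length (all checkpoints share one architecture)."""
    rows = []
    model = EGNN.initialise(config)
    for s in sorted(checkpoints):
        model.load_params(checkpoints[s])
        metrics = evaluate_rollout(model, test_samples, horizon)
        row = {"s": s, "mepa": metrics["mepa"], "horizon": horizon}
        for sp, v in metrics["per_species_mae"].items():
            row[f"mae_{sp}"] = v
        rows.append(row)
    return rows


def write_metric_table(prefix, rows: list[dict]) -> None:
    """Serialize metric rows as a delimiter-separated table + JSON summary."""
    if not rows:
        raise SizeError("no rows to write")
    keys = list(rows[0].keys())
    with open(f"{prefix}.csv", "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=keys)
        writer.writeheader()
        writer.writerows(rows)
    with open(f"{prefix}.json", "w") as fh:
        json.dump(rows, fh, indent=2)
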