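"""Class-balanced SSAE ensemble.

Sleep recordings are heavily imbalanced (N2 dominates, N1 is rare), so a
single classifier trained on all epochs skews toward frequent stages.
Each ensemble member is instead trained on a class-balanced subsample:
within every recording the number of epochs drawn per stage equals that
recording's least-represented present stage count.  Members share
hyperparameters but see different samples; prediction averages the
members' class probabilities (optionally reweighted per stage) and takes
the argmax, with ties broken by canonical class order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import STAGES
from .ssae import SSAEHyper, SSAEModel, predict_proba, train_ssae

__all__ = [
    "EnsembleModel",
    "class_balanced_sample",
    "train_ensemble",
    "ensemble_predict",
    "save_ensemble",
    "load_ensemble",
]


@dataclass
class EnsembleModel:
    """Bag of independently sampled SSAE members."""

    members: list[SSAEModel]
    member_seeds: list[int]
    classes: tuple[str, ...] = STAGES
    seed: int | None = None

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("ensemble needs at least one member")


def class_balanced_sample(
    stages,
    recording_ids,
    seed: int,
) -> np.ndarray:
    """Epoch indices of one class-balanced subsample.

    Within each recording, let m be the minimum epoch count over the
    stages *present* there; m epochs per present stage are drawn
    uniformly without replacement.  Absent stages contribute nothing.
    Deterministic given ``seed``; returned indices are sorted.
    """
    stages = np.asarray(stages)
    rids = np.asarray(recording_ids)
    if len(stages) != len(rids):
        raise ValueError("stages and recording_ids lengths differ")
    rng = np.random.default_rng(seed)
    chosen: list[int] = []
    for rid in _unique_in_order(rids):
        mask = rids == rid
        idx = np.nonzero(mask)[0]
        present = [s for s in STAGES if np.any(stages[idx] == s)]
        if len(present) < 2:
            raise ValueError(
                f"recording {rid!r} has epochs of fewer than 2 stages"
            )
        m = min(int(np.sum(stages[idx] == s)) for s in present)
        for s in present:
            pool = idx[stages[idx] == s]
            pick = rng.choice(pool, size=m, replace=False)
            chosen.extend(int(i) for i in pick)
    return np.array(sorted(chosen), dtype=int)


def _member_seed(master_seed: int, k: int) -> int:
    ss = np.random.SeedSequence([master_seed, k])
    return int(ss.generate_state(1)[0] % 2**31)


def train_ensemble(
    X: np.ndarray,
    stages,
    recording_ids,
    hyper: SSAEHyper | None = None,
    n_members: int = 20,
    seed: int = 0,
) -> EnsembleModel:
    """Train ``n_members`` SSAEs, each on its own balanced subsample.

    Member k's sampling and weight-initialization seeds derive from
    ``(seed, k)``, so members are independent yet the whole ensemble is
    reproducible from the master seed.
    """
    if n_members < 1:
        raise ValueError("n_members must be >= 1")
    if hyper is None:
        hyper = SSAEHyper()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    stages = np.asarray(stages)
    members, member_seeds = [], []
    for k in range(n_members):
        mseed = _member_seed(seed, k)
        idx = class_balanced_sample(stages, recording_ids, mseed)
        model = train_ssae(X[idx], stages[idx], hyper=hyper, seed=mseed)
        members.append(model)
        member_seeds.append(mseed)
    return EnsembleModel(
        members=members, member_seeds=member_seeds, classes=STAGES, seed=seed
    )


def ensemble_predict(
    model: EnsembleModel,
    X: np.ndarray,
    stage_weights=None,
) -> tuple[list[str], np.ndarray]:
    """Predict stages by (optionally weighted) mean member probability.

    Returns ``(labels, mean_proba)`` where ``mean_proba`` is the plain
    mean of member probabilities (columns in canonical order).  Labels
    are the argmax of ``mean_proba * stage_weights``; ``np.argmax``
    takes the first maximum, so ties break by canonical class order.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if stage_weights is None:
        stage_weights = np.ones(len(model.classes))
    stage_weights = np.asarray(stage_weights, dtype=float)
    if stage_weights.shape != (len(model.classes),) or np.any(stage_weights <= 0):
        raise ValueError("stage_weights must be positive, one per class")
    mean_proba = np.mean(
        [predict_proba(m, X) for m in model.members], axis=0
    )
    scores = mean_proba * stage_weights
    labels = [model.classes[i] for i in np.argmax(scores, axis=1)]
    return labels, mean_proba


def save_ensemble(model: EnsembleModel, path) -> None:
    """Serialize the ensemble (all member weights) to one ``.npz`` file."""
    import json

    meta = {
        "classes": list(model.classes),
        "member_seeds": model.member_seeds,
        "seed": model.seed,
        "n_members": len(model.members),
        "layers_per_member": [len(m.layers) for m in model.members],
    }
    arrays = {}
    for k, m in enumerate(model.members):
        for i, (W, b) in enumerate(m.layers):
            arrays[f"m{k}_W{i}"] = W
            arrays[f"m{k}_b{i}"] = b
        arrays[f"m{k}_softmax_W"] = m.softmax_W
        arrays[f"m{k}_softmax_b"] = m.softmax_b
    np.savez(path, meta=json.dumps(meta), **arrays)


def load_ensemble(path) -> EnsembleModel:
    import json

    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["meta"]))
        members = []
        for k in range(meta["n_members"]):
            layers = [
                (data[f"m{k}_W{i}"], data[f"m{k}_b{i}"])
                for i in range(meta["layers_per_member"][k])
            ]
            members.append(
                SSAEModel(
                    layers=layers,
                    softmax_W=data[f"m{k}_softmax_W"],
                    softmax_b=data[f"m{k}_softmax_b"],
                    classes=tuple(meta["classes"]),
                )
            )
    return EnsembleModel(
        members=members,
        member_seeds=list(meta["member_seeds"]),
        classes=tuple(meta["classes"]),
        seed=meta["seed"],
    )


def _unique_in_order(values) -> list:
    out, seen = [], set()
    for v in values:
        if v not in seen:
            seen.add(v)
            out.append(v)
    return out
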