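"""Stacked sparse autoencoders with KL sparsity, trained by L-BFGS.

A sparse autoencoder reconstructs its input through a sigmoid hidden
layer while a KL-divergence penalty pushes the mean hidden activation
rho_hat toward a small target rho, and an L2 weight-decay term (lambda)
keeps weights small.  The full objective per layer is::

    J = (1/m) sum_i 0.5 * ||xhat_i - x_i||^2
        + (lambda/2) * sum(W^2)            (biases excluded)
        + beta * sum_j KL(rho || rho_hat_j)

Layers are pre-trained greedily on the previous layer's activations,
a softmax head is fitted on the top activations, and the whole network
is then fine-tuned on the supervised cross-entropy (plus weight decay).
Each optimization phase runs a quasi-Newton minimizer (L-BFGS) for a
fixed iteration budget ``r_iters`` and keeps the best iterate seen.

Default hyperparameters: lambda=1e-5, beta=2.0, rho=0.2, 20 hidden
units per layer, r=60 iterations per phase, 2 hidden layers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit as sigmoid

from . import STAGES

__all__ = [
    "SSAEHyper",
    "SSAEModel",
    "kl_sparsity",
    "sae_objective",
    "train_sae_layer",
    "train_ssae",
    "predict_proba",
    "save_model",
    "load_model",
]

_RHO_CLIP = 1e-8


@dataclass(frozen=True)
class SSAEHyper:
    """Hyperparameters shared by every layer of the stack.

    lam
        L2 weight-decay coefficient (applied to weight matrices only).
    beta
        Weight of the KL sparsity penalty.
    rho
        Target mean hidden activation in (0, 1).
    n_hidden
        Hidden units per layer.
    r_iters
        Optimizer iteration budget per training phase.
    n_layers
        Number of stacked hidden layers.
    """

    lam: float = 1e-5
    beta: float = 2.0
    rho: float = 0.2
    n_hidden: int = 20
    r_iters: int = 60
    n_layers: int = 2

    def __post_init__(self) -> None:
        if not 0 < self.rho < 1:
            raise ValueError("rho must be in (0, 1)")
        if self.lam < 0 or self.beta < 0:
            raise ValueError("lam and beta must be >= 0")
        if self.n_hidden < 1 or self.r_iters < 1 or self.n_layers < 1:
            raise ValueError("n_hidden, r_iters and n_layers must be >= 1")


@dataclass
class SSAEModel:
    """Trained stack: encoder layers plus a softmax head."""

    layers: list[tuple[np.ndarray, np.ndarray]]  # (W (h, d_in), b (h,))
    softmax_W: np.ndarray  # (C, h)
    softmax_b: np.ndarray  # (C,)
    classes: tuple[str, ...] = STAGES
    hyper: SSAEHyper | None = None
    seed: int | None = None

    @property
    def input_width(self) -> int:
        return self.layers[0][0].shape[1] if self.layers else self.softmax_W.shape[1]

    def hidden_activations(self, X: np.ndarray) -> np.ndarray:
        A = np.atleast_2d(np.asarray(X, dtype=float))
        for W, b in self.layers:
            A = sigmoid(A @ W.T + b)
        return A


def kl_sparsity(rho: float, rho_hat: np.ndarray) -> float:
    """Sum over hidden units of KL(rho || rho_hat).

    ``KL(p||q) = p log(p/q) + (1-p) log((1-p)/(1-q))``; ``rho_hat`` is
    clipped to [1e-8, 1 - 1e-8].  Zero iff every unit's mean activation
    equals ``rho``; nonnegative always.
    """
    rh = np.clip(np.asarray(rho_hat, dtype=float), _RHO_CLIP, 1 - _RHO_CLIP)
    return float(
        np.sum(rho * np.log(rho / rh) + (1 - rho) * np.log((1 - rho) / (1 - rh)))
    )


# ---------------------------------------------------------------------------
# Single-layer autoencoder objective


def _pack(*arrays: np.ndarray) -> np.ndarray:
    return np.concatenate([a.ravel() for a in arrays])


def _init_weights(shape: tuple[int, int], rng: np.random.Generator) -> np.ndarray:
    fan_out, fan_in = shape
    eps = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-eps, eps, size=shape)


def _unpack_ae(theta: np.ndarray, d: int, h: int):
    if theta.size != 2 * h * d + h + d:
        raise ValueError(
            f"parameter vector of size {theta.size} does not match "
            f"architecture d={d}, h={h}"
        )
    i = 0
    W1 = theta[i : i + h * d].reshape(h, d); i += h * d
    b1 = theta[i : i + h]; i += h
    W2 = theta[i : i + d * h].reshape(d, h); i += d * h
    b2 = theta[i : i + d]; i += d
    if i != theta.size:
        raise ValueError("parameter vector does not match architecture")
    return W1, b1, W2, b2


def sae_objective(
    theta: np.ndarray, X: np.ndarray, hyper: SSAEHyper
) -> tuple[float, np.ndarray]:
    """Sparse-autoencoder loss and its exact gradient.

    ``theta`` packs (W1, b1, W2, b2) for a d→h→d sigmoid autoencoder.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    m, d = X.shape
    h = hyper.n_hidden
    W1, b1, W2, b2 = _unpack_ae(theta, d, h)

    A1 = sigmoid(X @ W1.T + b1)
    A2 = sigmoid(A1 @ W2.T + b2)
    diff = A2 - X
    recon = 0.5 * float(np.sum(diff**2)) / m
    rho_hat = A1.mean(axis=0)
    loss = (
        recon
        + 0.5 * hyper.lam * (float(np.sum(W1**2)) + float(np.sum(W2**2)))
        + hyper.beta * kl_sparsity(hyper.rho, rho_hat)
    )
    if not np.isfinite(loss):
        raise FloatingPointError(
            f"non-finite autoencoder loss (recon={recon}, "
            f"|W1|max={np.abs(W1).max()}, |W2|max={np.abs(W2).max()})"
        )

    D2 = diff * A2 * (1 - A2) / m
    gW2 = D2.T @ A1 + hyper.lam * W2
    gb2 = D2.sum(axis=0)
    rh = np.clip(rho_hat, _RHO_CLIP, 1 - _RHO_CLIP)
    sparse_grad = hyper.beta * (-hyper.rho / rh + (1 - hyper.rho) / (1 - rh))
    D1 = (D2 @ W2 + sparse_grad / m) * A1 * (1 - A1)
    gW1 = D1.T @ X + hyper.lam * W1
    gb1 = D1.sum(axis=0)
    return loss, _pack(gW1, gb1, gW2, gb2)


def _minimize_best(fun, x0: np.ndarray, maxiter: int) -> tuple[np.ndarray, float]:
    """L-BFGS with an iteration cap, returning the best iterate seen."""
    best = {"f": np.inf, "x": np.array(x0, copy=True)}

    def wrapped(t):
        f, g = fun(t)
        if f < best["f"]:
            best["f"] = f
            best["x"] = np.array(t, copy=True)
        return f, g

    minimize(
        wrapped,
        x0,
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": maxiter},
    )
    return best["x"], best["f"]


@dataclass
class SparseAutoencoderLayer:
    """One pre-trained layer: encoder (W, b) plus its decoder."""

    W_enc: np.ndarray
    b_enc: np.ndarray
    W_dec: np.ndarray
    b_dec: np.ndarray

    def encode(self, X: np.ndarray) -> np.ndarray:
        return sigmoid(np.atleast_2d(X) @ self.W_enc.T + self.b_enc)

    def reconstruct(self, X: np.ndarray) -> np.ndarray:
        return sigmoid(self.encode(X) @ self.W_dec.T + self.b_dec)


def train_sae_layer(
    X: np.ndarray, hyper: SSAEHyper, seed: int
) -> SparseAutoencoderLayer:
    """Train one sparse autoencoder layer on ``X`` (unsupervised).

    Initial weights are uniform(-eps, eps) with
    ``eps = sqrt(6 / (fan_in + fan_out))``, biases zero; the optimizer
    runs for ``hyper.r_iters`` iterations and the best iterate is kept.
    Deterministic given ``seed``.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] < 2:
        raise ValueError("need at least 2 training examples")
    m, d = X.shape
    h = hyper.n_hidden
    rng = np.random.default_rng(seed)
    theta0 = _pack(
        _init_weights((h, d), rng),
        np.zeros(h),
        _init_weights((d, h), rng),
        np.zeros(d),
    )
    theta, _ = _minimize_best(
        lambda t: sae_objective(t, X, hyper), theta0, hyper.r_iters
    )
    W1, b1, W2, b2 = _unpack_ae(theta, d, h)
    return SparseAutoencoderLayer(W1, b1, W2, b2)


# ---------------------------------------------------------------------------
# Softmax head and fine-tuning


def _softmax(Z: np.ndarray) -> np.ndarray:
    Z = Z - Z.max(axis=1, keepdims=True)
    e = np.exp(Z)
    return e / e.sum(axis=1, keepdims=True)


def _cross_entropy_terms(Z: np.ndarray, Y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy and dJ/dZ for one-hot ``Y``."""
    m = Z.shape[0]
    Zs = Z - Z.max(axis=1, keepdims=True)
    logsum = np.log(np.exp(Zs).sum(axis=1, keepdims=True))
    logp = Zs - logsum
    loss = -float(np.sum(Y * logp)) / m
    return loss, (_softmax(Z) - Y) / m


def _softmax_objective(theta, A, Y, lam):
    m, h = A.shape
    c = Y.shape[1]
    Ws = theta[: c * h].reshape(c, h)
    bs = theta[c * h :]
    loss, dZ = _cross_entropy_terms(A @ Ws.T + bs, Y)
    loss += 0.5 * lam * float(np.sum(Ws**2))
    return loss, _pack(dZ.T @ A + lam * Ws, dZ.sum(axis=0))


def _finetune_objective(theta, X, Y, dims, lam):
    """Cross-entropy + weight decay over the whole stack; exact gradient.

    ``dims`` = [d_in, h1, ..., hL, C].
    """
    Ws_list, bs_list = [], []
    i = 0
    for a, b in zip(dims[:-1], dims[1:]):
        Ws_list.append(theta[i : i + b * a].reshape(b, a)); i += b * a
        bs_list.append(theta[i : i + b]); i += b
    if i != theta.size:
        raise ValueError("parameter vector does not match architecture")

    acts = [np.atleast_2d(X)]
    for W, b in zip(Ws_list[:-1], bs_list[:-1]):
        acts.append(sigmoid(acts[-1] @ W.T + b))
    Z = acts[-1] @ Ws_list[-1].T + bs_list[-1]
    loss, dZ = _cross_entropy_terms(Z, Y)
    loss += 0.5 * lam * sum(float(np.sum(W**2)) for W in Ws_list)

    grads: list[np.ndarray] = []
    delta = dZ
    for k in range(len(Ws_list) - 1, -1, -1):
        grads.append(delta.sum(axis=0))
        grads.append(delta.T @ acts[k] + lam * Ws_list[k])
        if k > 0:
            delta = (delta @ Ws_list[k]) * acts[k] * (1 - acts[k])
    grads.reverse()
    return loss, _pack(*grads)


def train_ssae(
    X: np.ndarray,
    y,
    hyper: SSAEHyper | None = None,
    seed: int = 0,
    classes: tuple[str, ...] = STAGES,
    return_pretrain: bool = False,
):
    """Train a stacked sparse autoencoder classifier.

    Greedy layer-wise pre-training on the (unlabelled) inputs, softmax
    head fitted on the top-layer activations, then supervised
    fine-tuning of the whole network.  Every class in ``classes`` must
    be present in ``y`` (the ensemble's balanced sampler guarantees
    this).  Deterministic given ``(X, y, hyper, seed)``.

    With ``return_pretrain=True`` returns ``(model, pretrained_model)``
    where the second model is the stack + head before fine-tuning.
    """
    if hyper is None:
        hyper = SSAEHyper()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y)
    if len(y) != X.shape[0]:
        raise ValueError("X and y lengths differ")
    class_to_idx = {c: i for i, c in enumerate(classes)}
    missing = [c for c in classes if c not in set(y.tolist())]
    if missing:
        raise ValueError(f"classes missing from training labels: {missing}")
    yi = np.array([class_to_idx[v] for v in y.tolist()])
    Y = np.eye(len(classes))[yi]

    ss = np.random.SeedSequence(seed)
    phase_seeds = [int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(hyper.n_layers + 1)]

    layers: list[tuple[np.ndarray, np.ndarray]] = []
    A = X
    for k in range(hyper.n_layers):
        layer = train_sae_layer(A, hyper, phase_seeds[k])
        layers.append((layer.W_enc, layer.b_enc))
        A = layer.encode(A)

    c, h = len(classes), hyper.n_hidden
    rng = np.random.default_rng(phase_seeds[-1])
    theta0 = _pack(_init_weights((c, h), rng), np.zeros(c))
    theta, _ = _minimize_best(
        lambda t: _softmax_objective(t, A, Y, hyper.lam), theta0, hyper.r_iters
    )
    Ws = theta[: c * h].reshape(c, h)
    bs = theta[c * h :]
    pretrained = SSAEModel(
        layers=[(W.copy(), b.copy()) for W, b in layers],
        softmax_W=Ws.copy(),
        softmax_b=bs.copy(),
        classes=tuple(classes),
        hyper=hyper,
        seed=seed,
    )

    dims = [X.shape[1]] + [hyper.n_hidden] * hyper.n_layers + [c]
    full0 = _pack(*[arr for W, b in layers for arr in (W, b)], Ws, bs)
    full, _ = _minimize_best(
        lambda t: _finetune_objective(t, X, Y, dims, hyper.lam),
        full0,
        hyper.r_iters,
    )
    i = 0
    tuned_layers = []
    for a, b in zip(dims[:-2], dims[1:-1]):
        W = full[i : i + b * a].reshape(b, a); i += b * a
        bb = full[i : i + b]; i += b
        tuned_layers.append((W, bb))
    Ws = full[i : i + c * h].reshape(c, h); i += c * h
    bs = full[i : i + c]

    model = SSAEModel(
        layers=tuned_layers,
        softmax_W=Ws,
        softmax_b=bs,
        classes=tuple(classes),
        hyper=hyper,
        seed=seed,
    )
    return (model, pretrained) if return_pretrain else model


def predict_proba(model: SSAEModel, X: np.ndarray) -> np.ndarray:
    """Row-stochastic class probabilities, columns in ``model.classes`` order."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.input_width:
        raise ValueError(
            f"input width {X.shape[1]} does not match model width "
            f"{model.input_width}"
        )
    A = model.hidden_activations(X)
    return _softmax(A @ model.softmax_W.T + model.softmax_b)


# ---------------------------------------------------------------------------
# Serialization

_FORMAT_VERSION = 1


def save_model(model: SSAEModel, path) -> None:
    """Serialize a model to a single self-describing ``.npz`` file."""
    meta = {
        "format_version": _FORMAT_VERSION,
        "classes": list(model.classes),
        "n_layers": len(model.layers),
        "seed": model.seed,
        "hyper": None
        if model.hyper is None
        else {k: getattr(model.hyper, k) for k in SSAEHyper.__dataclass_fields__},
    }
    arrays = {"softmax_W": model.softmax_W, "softmax_b": model.softmax_b}
    for i, (W, b) in enumerate(model.layers):
        arrays[f"W{i}"] = W
        arrays[f"b{i}"] = b
    np.savez(path, meta=json.dumps(meta), **arrays)


def load_model(path) -> SSAEModel:
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["meta"]))
        if meta["format_version"] != _FORMAT_VERSION:
            raise ValueError(f"unsupported model format {meta['format_version']}")
        layers = [
            (data[f"W{i}"], data[f"b{i}"]) for i in range(meta["n_layers"])
        ]
        hyper = SSAEHyper(**meta["hyper"]) if meta["hyper"] else None
        return SSAEModel(
            layers=layers,
            softmax_W=data["softmax_W"],
            softmax_b=data["softmax_b"],
            classes=tuple(meta["classes"]),
            hyper=hyper,
            seed=meta["seed"],
        )
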