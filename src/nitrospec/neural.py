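"""Feed-forward ANN and radial-basis-function network.

The feed-forward network has the fixed architecture used throughout the
pipeline: two hidden layers of 18 and 16 rectifier ("poslin") units and a
softmax output layer with one unit per class.  Its weights may be set by a
gradient trainer (cross-entropy with an L2 penalty, a stand-in for
Bayesian-regularised backpropagation) or by a metaheuristic searching the
flattened weight vector directly.

The RBF network uses Gaussian hidden units
``ω_i(x) = exp(−‖x−C_i‖² / (2∂_i²))`` and a linear readout
``Out_j = Σ_i β_ij ω_i(x)``; it is fitted by k-means centres, a shared
width heuristic and a least-squares solve onto one-hot targets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.distance import cdist
from scipy.special import softmax
from sklearn.cluster import KMeans

__all__ = ["AnnSpec", "init_ann", "ann_forward", "ann_train_gradient",
           "RbfNet", "rbf_forward", "rbf_fit", "DEFAULT_HIDDEN"]

DEFAULT_HIDDEN = (18, 16)


# ---------------------------------------------------------------------------
# feed-forward ANN
# ---------------------------------------------------------------------------

@dataclass
class AnnSpec:
    """Weights and biases of the rectifier/softmax feed-forward network.

    ``weights[l]`` has shape (fan_in, fan_out); ``biases[l]`` has shape
    (fan_out,).  Hidden layers use max(0, ·); the final layer is softmax.
    """

    weights: list[np.ndarray]
    biases: list[np.ndarray]

    @property
    def layer_sizes(self) -> tuple[int, ...]:
        return (self.weights[0].shape[0],) + tuple(
            w.shape[1] for w in self.weights)

    @property
    def n_parameters(self) -> int:
        return sum(w.size for w in self.weights) + sum(
            b.size for b in self.biases)

    def flatten(self) -> np.ndarray:
        return np.concatenate([w.ravel() for w in self.weights]
                              + [b.ravel() for b in self.biases])

    def with_flat(self, flat: np.ndarray) -> "AnnSpec":
        """Return a copy whose parameters are taken from a flat vector."""
        flat = np.asarray(flat, dtype=float)
        if flat.size != self.n_parameters:
            raise ValueError(
                f"expected {self.n_parameters} parameters, got {flat.size}")
        ws, bs, k = [], [], 0
        for w in self.weights:
            ws.append(flat[k:k + w.size].reshape(w.shape).copy())
            k += w.size
        for b in self.biases:
            bs.append(flat[k:k + b.size].copy())
            k += b.size
        return AnnSpec(weights=ws, biases=bs)

    def copy(self) -> "AnnSpec":
        return AnnSpec(weights=[w.copy() for w in self.weights],
                       biases=[b.copy() for b in self.biases])

    # -- checkpointing ------------------------------------------------
    def to_json(self) -> str:
        import json
        return json.dumps({"layer_sizes": list(self.layer_sizes),
                           "parameters": self.flatten().tolist()})

    @classmethod
    def from_json(cls, text: str) -> "AnnSpec":
        import json
        data = json.loads(text)
        sizes = data["layer_sizes"]
        template = init_ann(sizes[0], sizes[-1], hidden=tuple(sizes[1:-1]),
                            scale=0.0)
        return template.with_flat(np.asarray(data["parameters"]))


def init_ann(n_inputs: int, n_classes: int,
             hidden: tuple[int, ...] = DEFAULT_HIDDEN,
             rng: np.random.Generator | int | None = 0,
             scale: float | None = None) -> AnnSpec:
    """Random network of the standard architecture (Glorot-uniform init)."""
    if n_inputs < 1 or n_classes < 1:
        raise ValueError("n_inputs and n_classes must be >= 1")
    rng = np.random.default_rng(rng) if not isinstance(
        rng, np.random.Generator) else rng
    sizes = (n_inputs,) + tuple(hidden) + (n_classes,)
    weights, biases = [], []
    for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
        s = scale if scale is not None else np.sqrt(6.0 / (fan_in + fan_out))
        weights.append(rng.uniform(-s, s, size=(fan_in, fan_out)))
        biases.append(np.zeros(fan_out))
    return AnnSpec(weights=weights, biases=biases)


def _forward_cached(spec: AnnSpec, X: np.ndarray):
    activations = [X]
    h = X
    for W, b in zip(spec.weights[:-1], spec.biases[:-1]):
        h = np.maximum(h @ W + b, 0.0)
        activations.append(h)
    logits = h @ spec.weights[-1] + spec.biases[-1]
    return activations, logits


def ann_forward(spec: AnnSpec, inputs: np.ndarray) -> np.ndarray:
    """Per-class score matrix: softmax over the final layer; rows sum to 1."""
    X = np.atleast_2d(np.asarray(inputs, dtype=float))
    if X.shape[1] != spec.weights[0].shape[0]:
        raise ValueError(
            f"input dimension {X.shape[1]} != network input "
            f"{spec.weights[0].shape[0]}")
    _, logits = _forward_cached(spec, X)
    return softmax(logits, axis=1)


def _loss_and_grad(spec: AnnSpec, X, Y, l2):
    n = X.shape[0]
    acts, logits = _forward_cached(spec, X)
    P = softmax(logits, axis=1)
    eps = 1e-12
    loss = -np.sum(Y * np.log(P + eps)) / n
    loss += 0.5 * l2 * sum(float(np.sum(w * w)) for w in spec.weights)
    gw = [None] * len(spec.weights)
    gb = [None] * len(spec.biases)
    delta = (P - Y) / n
    for l in range(len(spec.weights) - 1, -1, -1):
        gw[l] = acts[l].T @ delta + l2 * spec.weights[l]
        gb[l] = delta.sum(axis=0)
        if l > 0:
            delta = (delta @ spec.weights[l].T) * (acts[l] > 0)
    return loss, gw, gb


def ann_train_gradient(spec: AnnSpec, X: np.ndarray, Y: np.ndarray,
                       l2_penalty: float = 1e-4,
                       max_epochs: int = 200) -> AnnSpec:
    """Full-batch gradient training of cross-entropy + L2 loss.

    Runs limited-memory BFGS with a line search on the flattened weight
    vector, so the loss over accepted iterates is non-increasing; the
    returned network is the better of the final iterate and the start.
    ``max_epochs = 0`` returns the initial network unchanged.
    Deterministic: no randomness is used.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if X.shape[0] == 0:
        raise ValueError("empty training set")
    if X.shape[0] != Y.shape[0]:
        raise ValueError("inputs and targets disagree on sample count")
    net = spec.copy()
    if max_epochs == 0:
        return net

    def fun(flat: np.ndarray):
        trial = net.with_flat(flat)
        loss, gw, gb = _loss_and_grad(trial, X, Y, l2_penalty)
        grad = np.concatenate([g.ravel() for g in gw]
                              + [g.ravel() for g in gb])
        return loss, grad

    x0 = net.flatten()
    result = minimize(fun, x0, jac=True, method="L-BFGS-B",
                      options={"maxiter": max_epochs, "ftol": 1e-12,
                               "gtol": 1e-10})
    if result.fun <= fun(x0)[0]:
        return net.with_flat(result.x)
    return net


# ---------------------------------------------------------------------------
# RBF network
# ---------------------------------------------------------------------------

@dataclass
class RbfNet:
    """Gaussian RBF network: centres, per-centre widths, linear readout."""

    centers: np.ndarray
    widths: np.ndarray
    beta: np.ndarray

    def __post_init__(self) -> None:
        self.centers = np.atleast_2d(np.asarray(self.centers, dtype=float))
        self.widths = np.asarray(self.widths, dtype=float)
        self.beta = np.atleast_2d(np.asarray(self.beta, dtype=float))
        if self.widths.size != self.centers.shape[0]:
            raise ValueError("one width per centre required")
        if np.any(self.widths <= 0):
            raise ValueError("widths must be strictly positive")
        if self.beta.shape[0] != self.centers.shape[0]:
            raise ValueError("beta rows must match number of centres")

    def to_json(self) -> str:
        import json
        return json.dumps({"centers": self.centers.tolist(),
                           "widths": self.widths.tolist(),
                           "beta": self.beta.tolist()})

    @classmethod
    def from_json(cls, text: str) -> "RbfNet":
        import json
        data = json.loads(text)
        return cls(centers=data["centers"], widths=data["widths"],
                   beta=data["beta"])


def _design_matrix(net: RbfNet, X: np.ndarray) -> np.ndarray:
    d2 = cdist(X, net.centers, metric="sqeuclidean")
    return np.exp(-d2 / (2.0 * net.widths[None, :] ** 2))


def rbf_forward(net: RbfNet, inputs: np.ndarray) -> np.ndarray:
    """Outputs Out_j = Σ_i β_ij ω_i(x) for each input row."""
    X = np.atleast_2d(np.asarray(inputs, dtype=float))
    if X.shape[1] != net.centers.shape[1]:
        raise ValueError("input dimension does not match centres")
    return _design_matrix(net, X) @ net.beta


def rbf_fit(X: np.ndarray, Y: np.ndarray, n_centers: int,
            seed: int = 0) -> RbfNet:
    """Fit an RBF network by k-means centres + least-squares readout.

    Widths are shared: ∂ = d_max / √(2·n_centers) with d_max the maximum
    inter-centre distance, floored at 1e−6.  ``Y`` is the (n, q) target
    matrix (one-hot class indicators for classification).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    n = X.shape[0]
    if n_centers < 1 or n_centers > n:
        raise ValueError("need 1 <= n_centers <= n training samples")
    if n_centers == n:
        centers = X.copy()
    else:
        km = KMeans(n_clusters=n_centers, random_state=seed, n_init=4)
        km.fit(X)
        centers = km.cluster_centers_
    if n_centers > 1:
        d_max = float(cdist(centers, centers).max())
    else:
        d_max = 0.0
    width = max(d_max / np.sqrt(2.0 * n_centers), 1e-6)
    widths = np.full(n_centers, width)
    net = RbfNet(centers=centers, widths=widths,
                 beta=np.zeros((n_centers, Y.shape[1])))
    G = _design_matrix(net, X)
    beta, *_ = np.linalg.lstsq(G, Y, rcond=None)
    net.beta = beta
    return net
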