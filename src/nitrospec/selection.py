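"""Effective-wavelength selection by an ANN-wrapped BBO search.

BBO proposes fixed-size subsets of band indices; the fitness of a subset is
the validation mean squared error of the standard feed-forward network
trained on those bands only (a single seeded 60/10 train/validation split
per run).  The subset with the lowest MSE wins; its indices map back to nm.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .dataset import SpectralDataset
from .metaheuristics import BBOParams, bbo_optimize, subset_objective
from .neural import DEFAULT_HIDDEN, ann_forward, ann_train_gradient, init_ann

__all__ = ["SelectionResult", "evaluate_subset", "select_wavelengths"]


@dataclass
class SelectionResult:
    """Outcome of a wavelength-selection run."""

    wavelengths: list[float]
    indices: list[int]
    fitness_history: np.ndarray
    mse_cache: dict[tuple[int, ...], float] = field(default_factory=dict)

    def to_json(self, path=None) -> str:
        payload = json.dumps({
            "wavelengths": list(map(float, self.wavelengths)),
            "indices": list(map(int, self.indices)),
            "fitness_history": [float(v) for v in self.fitness_history],
        }, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload + "\n")
        return payload

    @classmethod
    def from_json(cls, path) -> "SelectionResult":
        with open(path) as fh:
            data = json.load(fh)
        return cls(wavelengths=data["wavelengths"], indices=data["indices"],
                   fitness_history=np.asarray(data["fitness_history"]))


def _canonical_order(dataset: SpectralDataset) -> np.ndarray:
    """Sample order independent of input row permutation (content sort).

    Cached on the dataset instance: the sort is over every wavelength
    column and would otherwise dominate the cost of a subset evaluation.
    """
    cached = getattr(dataset, "_canonical_order_cache", None)
    if cached is not None and cached.size == dataset.n_samples:
        return cached
    keys = [dataset.values[:, j] for j in range(dataset.n_wavelengths - 1, -1, -1)]
    keys.append(np.asarray([str(l) for l in dataset.labels]))
    order = np.lexsort(keys)
    object.__setattr__(dataset, "_canonical_order_cache", order)
    return order


def _one_hot(labels, classes) -> np.ndarray:
    index = {c: i for i, c in enumerate(classes)}
    Y = np.zeros((len(labels), len(classes)))
    for r, lab in enumerate(labels):
        Y[r, index[str(lab)]] = 1.0
    return Y


def evaluate_subset(dataset: SpectralDataset, indices, split_seed: int = 0,
                    ann_epochs: int = 18, hidden=DEFAULT_HIDDEN,
                    train_frac: float = 0.6, val_frac: float = 0.1,
                    l2_penalty: float = 1e-2) -> float:
    """Validation MSE of the standard ANN restricted to the given bands.

    Samples are put in a content-canonical order, shuffled by
    ``split_seed`` and split 60/10 into train/validation (the remaining
    30% is untouched, mirroring the evaluation protocol's test share).
    Deterministic for a fixed dataset, subset and seed.
    """
    idx = np.asarray(indices, dtype=int)
    if idx.size == 0:
        raise ValueError("empty band subset")
    if np.unique(idx).size != idx.size:
        raise ValueError("duplicate band indices")
    if idx.min() < 0 or idx.max() >= dataset.n_wavelengths:
        raise ValueError("band index out of range")

    order = _canonical_order(dataset)
    rng = np.random.default_rng(split_seed)
    perm = order[rng.permutation(dataset.n_samples)]
    n = dataset.n_samples
    n_train = int(round(train_frac * n))
    n_val = max(int(round(val_frac * n)), 1)
    train, val = perm[:n_train], perm[n_train:n_train + n_val]
    if train.size == 0 or val.size == 0:
        raise ValueError("dataset too small for a 60/10 split")

    classes = dataset.classes
    X = dataset.values[:, idx]
    mu = X[train].mean(axis=0)
    sd = X[train].std(axis=0)
    sd[sd < 1e-12] = 1.0
    Xs = (X - mu) / sd
    Y = getattr(dataset, "_one_hot_cache", None)
    if Y is None or Y.shape[0] != dataset.n_samples:
        Y = _one_hot(dataset.labels, classes)
        object.__setattr__(dataset, "_one_hot_cache", Y)

    spec = init_ann(idx.size, len(classes), hidden=hidden, rng=split_seed)
    net = ann_train_gradient(spec, Xs[train], Y[train],
                             l2_penalty=l2_penalty, max_epochs=ann_epochs)
    P = ann_forward(net, Xs[val])
    return float(np.mean((P - Y[val]) ** 2))


def select_wavelengths(dataset: SpectralDataset, k: int = 3,
                       params: BBOParams | None = None,
                       split_seed: int = 0,
                       ann_epochs: int = 18) -> SelectionResult:
    """BBO search over band subsets of size ``k`` with ANN-MSE fitness."""
    if not 1 <= k <= dataset.n_wavelengths:
        raise ValueError("need 1 <= k <= number of wavelengths")
    if params is None:
        params = BBOParams(population=24, generations=70, mutation_prob=0.22,
                           seed=split_seed)
    cache: dict[tuple[int, ...], float] = {}

    def fitness(idx: np.ndarray) -> float:
        key = tuple(int(i) for i in idx)
        if key not in cache:
            cache[key] = evaluate_subset(dataset, idx, split_seed=split_seed,
                                         ann_epochs=ann_epochs)
        return cache[key]

    if k == dataset.n_wavelengths:
        idx = np.arange(k)
        mse = fitness(idx)
        return SelectionResult(
            wavelengths=[float(w) for w in dataset.wavelengths],
            indices=[int(i) for i in idx],
            fitness_history=np.array([mse]), mse_cache=cache)

    objective = subset_objective(fitness, n_choices=dataset.n_wavelengths,
                                 subset_size=k)
    best, history = bbo_optimize(objective, params)
    idx = np.sort(best.siv.astype(int))
    return SelectionResult(
        wavelengths=[float(dataset.wavelengths[i]) for i in idx],
        indices=[int(i) for i in idx],
        fitness_history=history, mse_cache=cache)
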