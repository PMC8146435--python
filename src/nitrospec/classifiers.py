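"""The five base classifiers behind one fit/predict/score contract.

ANN-ICA and ANN-HS train the standard feed-forward network by metaheuristic
search over its flattened weight vector (cost: training MSE of the softmax
outputs against one-hot targets), followed by a backpropagation polish —
the architecture's stated training function is a backprop rule, so the
metaheuristic supplies the starting weights and gradient descent finishes
the job.  KNN, stepwise LDA and the RBF network complete the ensemble.

Every fitted classifier exposes ``predict`` (one label per row) and
``predict_scores`` (rows sum to 1), so the majority-voting ensemble can
compare confidences across kinds.
"""

from __future__ import annotations

import warnings
from dataclasses import replace

import numpy as np
from scipy.spatial.distance import cdist
from scipy.special import softmax

from .metaheuristics import (HSParams, ICAParams, continuous_objective,
                             hs_optimize, ica_optimize)
from .neural import (DEFAULT_HIDDEN, AnnSpec, ann_forward, ann_train_gradient,
                     init_ann, rbf_fit, rbf_forward)

__all__ = [
    "TrainedClassifier", "AnnMetaheuristicClassifier", "KnnClassifier",
    "LdaClassifier", "RbfClassifier", "default_classifiers",
    "train_ann_metaheuristic", "knn_fit_predict", "lda_fit", "rbf_classifier",
    "CLASSIFIER_ORDER",
]

CLASSIFIER_ORDER = ("ANN-ICA", "ANN-HS", "KNN", "LDA", "RBF")


def _as_labels(y) -> np.ndarray:
    return np.asarray([str(v) for v in np.asarray(y).ravel()], dtype=object)


def _one_hot(y: np.ndarray, classes: tuple[str, ...]) -> np.ndarray:
    index = {c: i for i, c in enumerate(classes)}
    Y = np.zeros((y.size, len(classes)))
    for r, lab in enumerate(y):
        Y[r, index[lab]] = 1.0
    return Y


class TrainedClassifier:
    """Common contract: fit on labelled features, emit labels and scores."""

    kind: str = "?"

    def __init__(self) -> None:
        self.classes_: tuple[str, ...] | None = None

    def fit(self, X, y, X_val=None, y_val=None) -> "TrainedClassifier":
        raise NotImplementedError

    def predict_scores(self, X) -> np.ndarray:
        raise NotImplementedError

    def predict(self, X) -> np.ndarray:
        scores = self.predict_scores(X)
        idx = np.argmax(scores, axis=1)
        return np.asarray([self.classes_[i] for i in idx], dtype=object)

    # -- shared helpers -----------------------------------------------
    def _start_fit(self, X, y):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        y = _as_labels(y)
        if X.shape[0] != y.size:
            raise ValueError("X and y disagree on sample count")
        if X.shape[0] == 0:
            raise ValueError("empty training set")
        self.classes_ = tuple(sorted(set(y)))
        return X, y


class AnnMetaheuristicClassifier(TrainedClassifier):
    """Feed-forward ANN whose weights are found by ICA or harmony search.

    The search minimises the training MSE of the softmax outputs over the
    flattened weight vector within ``weight_bound``; the best vector is
    then polished by ``refine_epochs`` of L2-regularised gradient descent
    (set ``refine_epochs=0`` for the pure metaheuristic solution).
    """

    def __init__(self, algorithm: str = "ICA", params=None,
                 hidden=DEFAULT_HIDDEN, weight_bound: float = 2.0,
                 refine_epochs: int = 200, l2_penalty: float = 1e-4,
                 seed: int = 0):
        super().__init__()
        algorithm = algorithm.upper()
        if algorithm not in ("ICA", "HS"):
            raise ValueError("algorithm must be 'ICA' or 'HS'")
        self.kind = f"ANN-{algorithm}"
        self.algorithm = algorithm
        self.params = params
        self.hidden = tuple(hidden)
        self.weight_bound = weight_bound
        self.refine_epochs = refine_epochs
        self.l2_penalty = l2_penalty
        self.seed = seed
        self.spec_: AnnSpec | None = None
        self.history_: np.ndarray | None = None

    def fit(self, X, y, X_val=None, y_val=None):
        X, y = self._start_fit(X, y)
        if len(self.classes_) < 2:
            raise ValueError("need at least two classes")
        self._mu = X.mean(axis=0)
        self._sd = X.std(axis=0)
        self._sd[self._sd < 1e-12] = 1.0
        Xs = (X - self._mu) / self._sd
        Y = _one_hot(y, self.classes_)

        template = init_ann(X.shape[1], len(self.classes_), hidden=self.hidden,
                            rng=self.seed)

        def cost(flat: np.ndarray) -> float:
            P = ann_forward(template.with_flat(flat), Xs)
            return float(np.mean((P - Y) ** 2))

        objective = continuous_objective(cost, -self.weight_bound,
                                         self.weight_bound,
                                         template.n_parameters)
        if self.algorithm == "ICA":
            params = self.params or ICAParams(seed=self.seed)
            if params.seed != self.seed:
                params = replace(params, seed=self.seed)
            best, history = ica_optimize(objective, params)
        else:
            params = self.params or HSParams(seed=self.seed)
            if params.seed != self.seed:
                params = replace(params, seed=self.seed)
            best, history = hs_optimize(objective, params)
        self.history_ = history
        spec = template.with_flat(best.siv)
        if self.refine_epochs:
            spec = ann_train_gradient(spec, Xs, Y, l2_penalty=self.l2_penalty,
                                      max_epochs=self.refine_epochs)
        self.spec_ = spec
        return self

    def predict_scores(self, X):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return ann_forward(self.spec_, (X - self._mu) / self._sd)


class KnnClassifier(TrainedClassifier):
    """K-nearest neighbours by Euclidean distance.

    Label = modal class among the k nearest training rows; ties are broken
    by the smallest summed distance among tied classes, then class order.
    Scores are the neighbour class fractions.  When ``k`` is None it is
    chosen on the validation split from ``candidate_ks``.
    """

    kind = "KNN"

    def __init__(self, k: int | None = None, candidate_ks=(1, 3, 5, 7, 9)):
        super().__init__()
        self.k = k
        self.candidate_ks = tuple(candidate_ks)

    def fit(self, X, y, X_val=None, y_val=None):
        X, y = self._start_fit(X, y)
        self._X, self._y = X, y
        if self.k is not None:
            k = self.k
        elif X_val is not None and y_val is not None and len(y_val):
            y_val = _as_labels(y_val)
            best_k, best_acc = None, -1.0
            for cand in self.candidate_ks:
                if cand > X.shape[0]:
                    continue
                pred = self._predict_with_k(np.atleast_2d(
                    np.asarray(X_val, dtype=float)), cand)[0]
                acc = float(np.mean(pred == y_val))
                if acc > best_acc:
                    best_k, best_acc = cand, acc
            k = best_k if best_k is not None else min(5, X.shape[0])
        else:
            k = min(5, X.shape[0])
        if not 1 <= k <= X.shape[0]:
            raise ValueError("k out of range")
        self.k_ = k
        return self

    def _predict_with_k(self, X, k):
        d = cdist(X, self._X)
        nn = np.argpartition(d, kth=k - 1, axis=1)[:, :k]
        classes = self.classes_
        index = {c: i for i, c in enumerate(classes)}
        labels = np.empty(X.shape[0], dtype=object)
        scores = np.zeros((X.shape[0], len(classes)))
        for r in range(X.shape[0]):
            neigh = nn[r]
            counts = np.zeros(len(classes))
            sums = np.zeros(len(classes))
            for j in neigh:
                c = index[self._y[j]]
                counts[c] += 1
                sums[c] += d[r, j]
            scores[r] = counts / k
            top = counts.max()
            tied = np.nonzero(counts == top)[0]
            if tied.size > 1:
                tied = tied[sums[tied] == sums[tied].min()]
            labels[r] = classes[tied[0]]
        return labels, scores

    def predict_scores(self, X):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return self._predict_with_k(X, self.k_)[1]

    def predict(self, X):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return self._predict_with_k(X, self.k_)[0]


def _wilks_lambda(W: np.ndarray, T: np.ndarray, subset: list[int]) -> float:
    if not subset:
        return 1.0
    sub = np.ix_(subset, subset)
    sign_w, logdet_w = np.linalg.slogdet(W[sub])
    sign_t, logdet_t = np.linalg.slogdet(T[sub])
    if sign_w <= 0 or sign_t <= 0:
        return 1.0
    return float(np.exp(logdet_w - logdet_t))


class LdaClassifier(TrainedClassifier):
    """Linear discriminant analysis with optional stepwise selection.

    Stepwise selection enters/removes variables by the Wilks'-lambda
    partial-F statistic (enter when F >= f_enter, remove when F <
    f_remove).  Classification uses linear discriminant scores with the
    pooled within-class covariance (diagonal ridge 1e−8); scores are the
    softmax class posteriors with empirical priors.
    """

    kind = "LDA"

    def __init__(self, stepwise: bool = True, f_enter: float = 3.84,
                 f_remove: float = 2.71, ridge: float = 1e-8,
                 max_selected: int | None = 30):
        super().__init__()
        self.stepwise = stepwise
        self.f_enter = f_enter
        self.f_remove = f_remove
        self.ridge = ridge
        self.max_selected = max_selected

    def fit(self, X, y, X_val=None, y_val=None):
        X, y = self._start_fit(X, y)
        classes = self.classes_
        if len(classes) < 2:
            raise ValueError("need at least two classes")
        counts = {c: int(np.sum(y == c)) for c in classes}
        if min(counts.values()) < 2:
            bad = min(counts, key=counts.get)
            raise ValueError(f"class {bad!r} has fewer than 2 samples")
        n, p = X.shape
        g = len(classes)

        grand = X.mean(axis=0)
        T = (X - grand).T @ (X - grand)
        W = np.zeros_like(T)
        means = np.vstack([X[y == c].mean(axis=0) for c in classes])
        for i, c in enumerate(classes):
            Xi = X[y == c] - means[i]
            W += Xi.T @ Xi

        if self.stepwise and p > 1:
            selected = self._stepwise(W, T, n, g, p)
        else:
            selected = list(range(p))
        self.selected_ = selected

        S = W[np.ix_(selected, selected)] / (n - g)
        S = S + self.ridge * np.eye(len(selected))
        Sinv = np.linalg.inv(S)
        M = means[:, selected]
        self._coef = Sinv @ M.T                             # (p_sel, g)
        self._intercept = (-0.5 * np.einsum("ij,ji->i", M, self._coef)
                           + np.log(np.array([counts[c] for c in classes]) / n))
        return self

    def _stepwise(self, W, T, n, g, p):
        selected: list[int] = []
        limit = self.max_selected or p
        limit = min(limit, max(n - g - 1, 1))
        while True:
            changed = False
            if len(selected) < limit:
                lam0 = _wilks_lambda(W, T, selected)
                best_f, best_v = -np.inf, None
                df2 = n - g - len(selected)
                if df2 > 0:
                    for v in range(p):
                        if v in selected:
                            continue
                        lam1 = _wilks_lambda(W, T, selected + [v])
                        if lam1 <= 0:
                            continue
                        f = (df2 / (g - 1)) * (lam0 / lam1 - 1.0)
                        if f > best_f:
                            best_f, best_v = f, v
                if best_v is not None and best_f >= self.f_enter:
                    selected.append(best_v)
                    changed = True
            if len(selected) > 1:
                lam_full = _wilks_lambda(W, T, selected)
                worst_f, worst_v = np.inf, None
                df2 = n - g - len(selected) + 1
                for v in selected:
                    rest = [u for u in selected if u != v]
                    lam_rest = _wilks_lambda(W, T, rest)
                    f = (df2 / (g - 1)) * (lam_rest / lam_full - 1.0)
                    if f < worst_f:
                        worst_f, worst_v = f, v
                if worst_v is not None and worst_f < self.f_remove:
                    selected.remove(worst_v)
                    changed = True
                    if len(selected) >= limit:
                        break
            if not changed:
                break
        if not selected:
            warnings.warn("stepwise LDA: no variable passed the entry "
                          "threshold; falling back to all variables")
            selected = list(range(p))
        return sorted(selected)

    def predict_scores(self, X):
        X = np.atleast_2d(np.asarray(X, dtype=float))[:, self.selected_]
        return softmax(X @ self._coef + self._intercept, axis=1)


class RbfClassifier(TrainedClassifier):
    """RBF network classifier; scores are the softmax of the linear outputs."""

    kind = "RBF"

    def __init__(self, n_centers: int = 4, seed: int = 0):
        super().__init__()
        self.n_centers = n_centers
        self.seed = seed

    def fit(self, X, y, X_val=None, y_val=None):
        X, y = self._start_fit(X, y)
        Y = _one_hot(y, self.classes_)
        n_centers = min(self.n_centers, X.shape[0])
        self.net_ = rbf_fit(X, Y, n_centers=n_centers, seed=self.seed)
        return self

    def predict_scores(self, X):
        out = rbf_forward(self.net_, np.atleast_2d(np.asarray(X, dtype=float)))
        return softmax(out, axis=1)


# ---------------------------------------------------------------------------
# functional wrappers and the default ensemble
# ---------------------------------------------------------------------------

def train_ann_metaheuristic(X, y, algorithm: str, params=None,
                            seed: int = 0, **kwargs) -> AnnMetaheuristicClassifier:
    clf = AnnMetaheuristicClassifier(algorithm=algorithm, params=params,
                                     seed=seed, **kwargs)
    return clf.fit(X, y)


def knn_fit_predict(X_train, y_train, X_test, k: int):
    clf = KnnClassifier(k=k).fit(X_train, y_train)
    return clf.predict(X_test), clf.predict_scores(X_test)


def lda_fit(X, y, stepwise: bool = True, f_enter: float = 3.84,
            f_remove: float = 2.71) -> LdaClassifier:
    return LdaClassifier(stepwise=stepwise, f_enter=f_enter,
                         f_remove=f_remove).fit(X, y)


def rbf_classifier(X, y, n_centers: int = 4, seed: int = 0) -> RbfClassifier:
    return RbfClassifier(n_centers=n_centers, seed=seed).fit(X, y)


def default_classifiers(seed: int = 0, ica_params: ICAParams | None = None,
                        hs_params: HSParams | None = None,
                        knn_k: int | None = None, n_rbf_centers: int = 4,
                        refine_epochs: int = 200):
    """Fresh unfitted instances of the five-member ensemble."""
    return {
        "ANN-ICA": AnnMetaheuristicClassifier(
            "ICA", params=ica_params, seed=seed, refine_epochs=refine_epochs),
        "ANN-HS": AnnMetaheuristicClassifier(
            "HS", params=hs_params, seed=seed, refine_epochs=refine_epochs),
        "KNN": KnnClassifier(k=knn_k),
        "LDA": LdaClassifier(),
        "RBF": RbfClassifier(n_centers=n_rbf_centers, seed=seed),
    }
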