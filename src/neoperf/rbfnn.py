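"""Radial-basis-function network classifier for perfusion-state assessment.

A single Gaussian hidden layer with a linear output,

    y(x) = sum_k w_k * exp(-||x - c_k||^2 / (2 sigma^2)),

trained in two stages: hidden-unit centers by seeded Lloyd k-means, output
weights by the normalized least-mean-squares (NLMS) rule against binary
desired outputs (0 = good perfusion, 1 = poor perfusion). The fuzzy output
is thresholded (default 0.5) to a hard label; a tie at the threshold is
classified poor, failing safe toward flagging poor perfusion.

The estimator follows the scikit-learn protocol (``fit`` / ``predict`` /
``decision_function`` / ``get_params``) so it composes with sklearn
pipelines and model selection.
"""

from __future__ import annotations

import json
import warnings

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_array, check_is_fitted

__all__ = [
    "kmeans_centers",
    "rbf_activations",
    "nlms_train",
    "RBFNetClassifier",
    "split_trials",
]


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def kmeans_centers(
    X: np.ndarray,
    k: int,
    rng=None,
    n_init: int = 8,
    max_iter: int = 300,
) -> np.ndarray:
    """Hidden-unit centers by seeded multi-restart Lloyd k-means.

    Each restart initializes centers at ``k`` distinct data points, iterates
    assignment/update to stability (or ``max_iter``), and re-seeds any empty
    cluster at the point currently farthest from its own center. The restart
    with the lowest within-cluster sum of squares wins. With ``k`` larger
    than the number of points, centers are padded by sampling points with
    replacement (warning logged) before Lloyd iteration.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 1:
        raise ValueError("X must be a non-empty 2-d array")
    if k < 1:
        raise ValueError("k must be >= 1")
    rng = _as_rng(rng)
    n = X.shape[0]

    best_centers, best_obj = None, np.inf
    for _ in range(n_init):
        if k > n:
            warnings.warn(
                f"k={k} exceeds the {n} available points; padding centers by "
                "sampling with replacement",
                stacklevel=2,
            )
            idx = np.concatenate([rng.permutation(n), rng.choice(n, k - n)])
        else:
            idx = rng.choice(n, size=k, replace=False)
        centers = X[idx].copy()
        labels = None
        for _ in range(max_iter):
            d2 = cdist(X, centers, "sqeuclidean")
            new_labels = np.argmin(d2, axis=1)
            own = d2[np.arange(n), new_labels]
            for j in range(k):
                if not np.any(new_labels == j):
                    far = int(np.argmax(own))
                    centers[j] = X[far]
                    new_labels[far] = j
                    own[far] = 0.0
            for j in np.unique(new_labels):
                centers[j] = X[new_labels == j].mean(axis=0)
            if labels is not None and np.array_equal(labels, new_labels):
                break
            labels = new_labels
        d2 = cdist(X, centers, "sqeuclidean")
        obj = float(np.min(d2, axis=1).sum())
        if obj < best_obj - 1e-12:
            best_obj, best_centers = obj, centers
    return best_centers


def rbf_activations(X: np.ndarray, centers: np.ndarray, sigma2: float) -> np.ndarray:
    """Gaussian hidden-layer outputs ``exp(-||x - c_k||^2 / (2 sigma^2))``.

    Accepts a single vector or a (n, d) matrix; outputs lie in (0, 1].
    """
    if sigma2 <= 0:
        raise ValueError("sigma2 must be positive")
    X = np.asarray(X, dtype=float)
    single = X.ndim == 1
    X = np.atleast_2d(X)
    centers = np.asarray(centers, dtype=float)
    if X.shape[1] != centers.shape[1]:
        raise ValueError(
            f"input dimension {X.shape[1]} does not match center dimension "
            f"{centers.shape[1]}"
        )
    phi = np.exp(-cdist(X, centers, "sqeuclidean") / (2.0 * sigma2))
    return phi[0] if single else phi


def nlms_train(
    X: np.ndarray,
    targets: np.ndarray,
    centers: np.ndarray,
    sigma2: float,
    step: float = 0.05,
    epochs: int = 200,
    eps: float = 1e-8,
    rng=None,
    weights: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Normalized-LMS training of the output weights.

    Per presentation: ``y = phi . w``, ``e = d - y``,
    ``w <- w + step / (||phi||^2 + eps) * e * phi``; the data order is
    reshuffled every epoch with the provided generator. Targets must be binary
    {0, 1}. Returns the final weights and the per-epoch mean-squared-error
    trace.
    """
    targets = np.asarray(targets, dtype=float)
    if not np.all(np.isin(targets, (0.0, 1.0))):
        raise ValueError("desired outputs must be binary {0, 1}")
    rng = _as_rng(rng)
    phi = rbf_activations(X, centers, sigma2)
    n, n_hidden = phi.shape
    w = np.zeros(n_hidden) if weights is None else np.asarray(weights, dtype=float).copy()
    energies = np.einsum("ij,ij->i", phi, phi) + eps
    errors = np.empty(epochs)
    for epoch in range(epochs):
        for i in rng.permutation(n):
            e = targets[i] - phi[i] @ w
            w += (step / energies[i]) * e * phi[i]
        errors[epoch] = float(np.mean((targets - phi @ w) ** 2))
    return w, errors


def _resolve_width(width, X: np.ndarray, centers: np.ndarray) -> float:
    """Shared Gaussian width sigma^2 from the configured rule."""
    if isinstance(width, (int, float)):
        if width <= 0:
            raise ValueError("width must be positive")
        return float(width)
    if width == "data":
        # total variation of the training set: mean squared distance to centroid
        s2 = float(np.mean(np.sum((X - X.mean(axis=0)) ** 2, axis=1)))
        return s2 if s2 > 0 else 1.0
    if width == "cluster":
        d2 = cdist(X, centers, "sqeuclidean")
        s2 = float(np.min(d2, axis=1).mean())
        if s2 > 0:
            return s2
        dmax2 = float(cdist(centers, centers, "sqeuclidean").max())
        s2 = dmax2 / (2.0 * centers.shape[0])
        return s2 if s2 > 0 else 1.0
    raise ValueError(f"unknown width rule {width!r}")


class RBFNetClassifier(ClassifierMixin, BaseEstimator):
    """Gaussian RBF network with k-means centers and NLMS output weights.

    Parameters
    ----------
    n_hidden : int, default 64
        Number of Gaussian hidden units (the published operating point).
    threshold : float, default 0.5
        Fuzzy-output decision threshold; output >= threshold is classified
        as the poor-perfusion class.
    width : {"data", "cluster"} or float, default "data"
        Rule for the shared width sigma^2. "data" uses the total variation
        of the training inputs (mean squared distance to their centroid);
        "cluster" uses the mean squared distance of training points to their
        assigned k-means center with a d_max^2/(2 N1) fallback; a float is
        used verbatim.
    lms_step, lms_epochs, lms_eps :
        NLMS step size, number of shuffled epochs, and normalization guard.
    n_init, max_iter :
        k-means restarts and Lloyd iteration cap.
    random_state : int or numpy Generator, optional
        Seeds both the k-means initialization and the NLMS shuffling.

    Attributes
    ----------
    centers_ : (n_hidden, n_features) array of hidden-unit centers.
    sigma2_ : shared Gaussian width.
    weights_ : (n_hidden,) output weights.
    training_error_ : per-epoch NLMS mean-squared-error trace.
    classes_ : the two class labels; ``classes_[1]`` is the poor class
        (desired output 1).
    """

    def __init__(
        self,
        n_hidden: int = 64,
        threshold: float = 0.5,
        width="data",
        lms_step: float = 0.05,
        lms_epochs: int = 200,
        lms_eps: float = 1e-8,
        n_init: int = 8,
        max_iter: int = 300,
        random_state=None,
    ):
        self.n_hidden = n_hidden
        self.threshold = threshold
        self.width = width
        self.lms_step = lms_step
        self.lms_epochs = lms_epochs
        self.lms_eps = lms_eps
        self.n_init = n_init
        self.max_iter = max_iter
        self.random_state = random_state

    def fit(self, X, y):
        X = check_array(X)
        y = np.asarray(y)
        if y.shape[0] != X.shape[0]:
            raise ValueError("X and y length mismatch")
        self.classes_ = np.unique(y)
        if self.classes_.size != 2:
            raise ValueError(
                f"binary targets required, got classes {self.classes_.tolist()}"
            )
        if not 0.0 <= self.threshold <= 1.0:
            raise ValueError("threshold must lie in [0, 1]")
        targets = (y == self.classes_[1]).astype(float)
        rng = _as_rng(self.random_state)
        self.centers_ = kmeans_centers(
            X, self.n_hidden, rng, n_init=self.n_init, max_iter=self.max_iter
        )
        self.sigma2_ = _resolve_width(self.width, X, self.centers_)
        self.weights_, self.training_error_ = nlms_train(
            X,
            targets,
            self.centers_,
            self.sigma2_,
            step=self.lms_step,
            epochs=self.lms_epochs,
            eps=self.lms_eps,
            rng=rng,
        )
        self.n_features_in_ = X.shape[1]
        return self

    def decision_function(self, X) -> np.ndarray:
        """Fuzzy network output (unclamped; may fall slightly outside [0, 1])."""
        check_is_fitted(self, "weights_")
        X = check_array(X)
        return rbf_activations(X, self.centers_, self.sigma2_) @ self.weights_

    def predict(self, X) -> np.ndarray:
        """Hard labels; output >= threshold maps to the poor class."""
        out = self.decision_function(X)
        return np.where(out >= self.threshold, self.classes_[1], self.classes_[0])

    def to_json(self, extra: dict | None = None) -> str:
        """Serialize the fitted model (centers, width, weights, threshold)."""
        check_is_fitted(self, "weights_")
        payload = {
            "n_hidden": int(self.n_hidden),
            "threshold": float(self.threshold),
            "sigma2": float(self.sigma2_),
            "centers": self.centers_.tolist(),
            "weights": self.weights_.tolist(),
            "classes": np.asarray(self.classes_).tolist(),
        }
        if extra:
            payload.update(extra)
        return json.dumps(payload, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "RBFNetClassifier":
        payload = json.loads(text)
        model = cls(n_hidden=payload["n_hidden"], threshold=payload["threshold"])
        model.centers_ = np.asarray(payload["centers"], dtype=float)
        model.sigma2_ = float(payload["sigma2"])
        model.weights_ = np.asarray(payload["weights"], dtype=float)
        model.classes_ = np.asarray(payload["classes"])
        model.n_features_in_ = model.centers_.shape[1]
        return model


def split_trials(
    subject_ids,
    labels,
    train_per_class: int,
    test_per_class: int,
    level: str = "subject",
    rng=None,
) -> tuple[np.ndarray, np.ndarray]:
    """Seeded train/test split of trials, stratified by class.

    ``level="subject"`` keeps all trials of one infant on the same side of
    the split (the default, avoiding within-subject leakage);
    ``level="trial"`` splits individual trials irrespective of subject.
    Returns integer index arrays (train, test).
    """
    subject_ids = np.asarray(subject_ids)
    labels = np.asarray(labels)
    if level not in ("subject", "trial"):
        raise ValueError("level must be 'subject' or 'trial'")
    rng = _as_rng(rng)
    train_idx: list[int] = []
    test_idx: list[int] = []
    for cls in np.unique(labels):
        cls_idx = np.flatnonzero(labels == cls)
        if level == "trial":
            perm = rng.permutation(cls_idx)
            if perm.size < train_per_class + test_per_class:
                raise ValueError(
                    f"class {cls!r} has {perm.size} trials, need "
                    f"{train_per_class + test_per_class}"
                )
            train_idx.extend(perm[:train_per_class])
            test_idx.extend(perm[train_per_class:train_per_class + test_per_class])
        else:
            subjects = rng.permutation(np.unique(subject_ids[cls_idx]))
            pools = [("train", train_per_class, train_idx),
                     ("test", test_per_class, test_idx)]
            s = 0
            for name, need, sink in pools:
                got = 0
                while got < need:
                    if s >= subjects.size:
                        raise ValueError(
                            f"class {cls!r}: not enough subjects to fill the "
                            f"{name} split ({got}/{need} trials)"
                        )
                    trials = cls_idx[subject_ids[cls_idx] == subjects[s]]
                    trials = rng.permutation(trials)[: need - got]
                    sink.extend(trials)
                    got += trials.size
                    s += 1
    return np.array(sorted(train_idx)), np.array(sorted(test_idx))
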