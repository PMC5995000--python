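"""Relevance vector machine (sparse Bayesian) classification.

The binary model is a kernel logistic classifier

    p(c=1 | x) = sigma( sum_i w_i phi_i(x) )

with an independent zero-mean Gaussian prior N(w_i | 0, 1/alpha_i) on each
weight.  Training alternates a Newton (IRLS) maximization of the posterior
over w with MacKay evidence updates of the hyperparameters,

    alpha_i <- gamma_i / w_i**2,     gamma_i = 1 - alpha_i * Sigma_ii,

where Sigma is the posterior covariance at the mode.  Most alpha_i diverge,
their weights are pruned, and only a sparse set of relevance vectors is
retained.  Multiclass decisions use one-vs-rest submodels and the class of
highest probability.

Estimators follow the scikit-learn API (``fit`` / ``predict`` /
``predict_proba`` / ``get_params``) and compose with sklearn model
selection; thin module-level functions mirror the underlying operations.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y


def kernel_matrix(X: np.ndarray, Y: np.ndarray, kernel: str = "rbf", width: float | None = None,
                  include_bias: bool = True) -> np.ndarray:
    """Design matrix Phi[n, i] = k(x_n, y_i), with an appended bias column.

    ``rbf``: exp(-||x - y||^2 / (2 width^2)); ``linear``: x . y.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if kernel == "rbf":
        if width is None or width <= 0:
            raise ValueError("rbf kernel width must be positive")
        phi = np.exp(-cdist(X, Y, "sqeuclidean") / (2.0 * width**2))
    elif kernel == "linear":
        phi = X @ Y.T
    else:
        raise ValueError(f"unknown kernel {kernel!r}")
    if include_bias:
        phi = np.column_stack([phi, np.ones(len(X))])
    return phi


def _sigmoid(a: np.ndarray) -> np.ndarray:
    out = np.empty_like(a, dtype=float)
    pos = a >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-a[pos]))
    e = np.exp(a[~pos])
    out[~pos] = e / (1.0 + e)
    return out


def _penalized_nll(w: np.ndarray, alpha: np.ndarray, phi: np.ndarray, c: np.ndarray) -> float:
    a = phi @ w
    # -log sigma(a) = logaddexp(0, -a);  -log(1 - sigma(a)) = logaddexp(0, a)
    nll = np.sum(np.logaddexp(0.0, -a[c == 1])) + np.sum(np.logaddexp(0.0, a[c == 0]))
    return float(nll + 0.5 * np.sum(alpha * w * w))


def newton_weight_update(
    w: np.ndarray,
    alpha: np.ndarray,
    phi: np.ndarray,
    c: np.ndarray,
    max_iter: int = 100,
    grad_tol: float = 1e-6,
) -> tuple[np.ndarray, np.ndarray]:
    """Find the posterior mode of the weights by damped Newton iteration.

    Minimizes E(w) = -log p(c|w) + 0.5 w^T A w with A = diag(alpha);
    grad E = A w - Phi^T (c - sigma(Phi w)), H = Phi^T B Phi + A with
    B = diag(sigma_n (1 - sigma_n)).  Returns (w at the mode, Hessian there).
    """
    w = np.asarray(w, dtype=float).copy()
    alpha = np.asarray(alpha, dtype=float)
    c = np.asarray(c, dtype=float)
    A = np.diag(alpha)
    for _ in range(max_iter):
        y = _sigmoid(phi @ w)
        grad = alpha * w - phi.T @ (c - y)
        if not np.all(np.isfinite(grad)):
            raise FloatingPointError("non-finite gradient in Newton update")
        if np.linalg.norm(grad) < grad_tol:
            break
        b = np.clip(y * (1.0 - y), 1e-12, None)
        H = (phi.T * b) @ phi + A
        step = np.linalg.solve(H, grad)
        e0 = _penalized_nll(w, alpha, phi, c)
        t = 1.0
        while t > 1e-8:
            w_try = w - t * step
            if _penalized_nll(w_try, alpha, phi, c) <= e0:
                break
            t /= 2.0
        w = w - t * step
    y = _sigmoid(phi @ w)
    b = np.clip(y * (1.0 - y), 1e-12, None)
    H = (phi.T * b) @ phi + np.diag(alpha)
    return w, H


def update_hyperparameters(
    w: np.ndarray,
    alpha: np.ndarray,
    sigma: np.ndarray,
    prune_threshold: float = 1e12,
) -> np.ndarray:
    """MacKay evidence update: alpha_i <- gamma_i / w_i^2.

    gamma_i = 1 - alpha_i Sigma_ii is the effective number of parameters
    determined by the data for weight i; weights the prior fully constrains
    (gamma ~ 0) or that are exactly zero get alpha >= prune_threshold and
    are marked for pruning.
    """
    w = np.asarray(w, dtype=float)
    alpha = np.asarray(alpha, dtype=float)
    gamma = np.clip(1.0 - alpha * np.diag(sigma), 0.0, 1.0)
    out = np.empty_like(alpha)
    # gamma -> 0 means the prior fully determines the weight: alpha -> inf
    dead = (w == 0.0) | (gamma <= 1e-12)
    out[dead] = prune_threshold
    with np.errstate(divide="ignore"):
        out[~dead] = gamma[~dead] / (w[~dead] ** 2)
    out[~np.isfinite(out)] = prune_threshold
    return np.minimum(out, 10.0 * prune_threshold)


class RVMBinaryClassifier(ClassifierMixin, BaseEstimator):
    """Two-class relevance vector machine.

    Parameters
    ----------
    kernel : {"rbf", "linear"}
    width : float or None
        RBF width; ``None`` uses the median pairwise distance of the
        (standardized) training points.
    alpha_init, prune_threshold, tol, max_outer, newton_tol
        Hyperparameter initialization, pruning level, outer-loop
        convergence tolerance on ||delta w||, outer iteration cap, and the
        inner Newton gradient tolerance.
    standardize : bool
        Center/scale features from the training fold before the kernel.

    Attributes
    ----------
    relevance_vectors_ : retained training points, shape (n_rv, n_features)
    weights_, alphas_ : weights and hyperparameters of the retained basis
    relevance_indices_ : indices of retained training points
    bias_retained_ : whether the bias basis survived pruning
    converged_, n_iter_ : outer-loop convergence status
    """

    def __init__(self, kernel: str = "rbf", width: float | None = None, alpha_init: float = 1.0,
                 prune_threshold: float = 1e12, tol: float = 1e-4, max_outer: int = 500,
                 newton_tol: float = 1e-6, standardize: bool = True):
        self.kernel = kernel
        self.width = width
        self.alpha_init = alpha_init
        self.prune_threshold = prune_threshold
        self.tol = tol
        self.max_outer = max_outer
        self.newton_tol = newton_tol
        self.standardize = standardize

    def fit(self, X, y):
        X, y = check_X_y(X, y)
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise ValueError("RVMBinaryClassifier requires exactly two classes in y")
        c = (y == self.classes_[1]).astype(float)

        if self.standardize:
            self.center_ = X.mean(axis=0)
            scale = X.std(axis=0)
            self.scale_ = np.where(scale > 0, scale, 1.0)
        else:
            self.center_ = np.zeros(X.shape[1])
            self.scale_ = np.ones(X.shape[1])
        Xs = (X - self.center_) / self.scale_

        if self.kernel == "rbf" and self.width is None:
            d = cdist(Xs, Xs)
            med = np.median(d[np.triu_indices_from(d, k=1)]) if len(Xs) > 1 else 1.0
            self.width_ = float(med) if med > 0 else 1.0
        else:
            self.width_ = self.width

        phi_full = kernel_matrix(Xs, Xs, kernel=self.kernel, width=self.width_)
        n, m = phi_full.shape                      # m = n + 1 (bias last)
        active = np.arange(m)
        alpha = np.full(m, float(self.alpha_init))
        w = np.zeros(m)

        converged = False
        it = 0
        w_prev: dict[int, float] = {}
        for it in range(1, self.max_outer + 1):
            phi = phi_full[:, active]
            w, H = newton_weight_update(w, alpha, phi, c, grad_tol=self.newton_tol)
            sigma = np.linalg.inv(H)
            alpha_new = update_hyperparameters(w, alpha, sigma, self.prune_threshold)
            keep = alpha_new < self.prune_threshold
            if not np.any(keep):                   # never drop every basis
                keep[np.argmax(np.abs(w))] = True
            # ||delta w|| over the surviving basis (pruned weights count as
            # a change equal to their magnitude)
            delta = np.linalg.norm(
                [w[j] - w_prev.get(int(active[j]), 0.0) for j in range(len(w)) if keep[j]]
                + [w[j] for j in range(len(w)) if not keep[j]]
            )
            # hyperparameter movement on the surviving basis: weights can
            # stabilize numerically while alphas are still diverging, so
            # convergence also requires the log-alphas to settle
            dlog_alpha = float(np.max(np.abs(np.log(alpha_new[keep]) - np.log(alpha[keep]))))
            pruned_now = not np.all(keep)
            active = active[keep]
            alpha = alpha_new[keep]
            w = w[keep]
            w_prev = {int(a): float(v) for a, v in zip(active, w)}
            if delta < self.tol and dlog_alpha < 1e-2 and not pruned_now:
                converged = True
                break
        self.converged_ = converged
        self.n_iter_ = it

        # final Newton polish so the stored weights are the posterior mode
        # under the *final* hyperparameters
        phi = phi_full[:, active]
        w, H = newton_weight_update(w, alpha, phi, c, grad_tol=self.newton_tol)
        y_hat = _sigmoid(phi @ w)
        self.grad_norm_ = float(np.linalg.norm(alpha * w - phi.T @ (c - y_hat)))

        self.active_ = active
        self.bias_retained_ = bool(active[-1] == m - 1) if len(active) else False
        rv_idx = active[active < n]
        self.relevance_indices_ = rv_idx
        self.relevance_vectors_ = X[rv_idx]
        self._rv_std = Xs[rv_idx]
        self.weights_ = w
        self.alphas_ = alpha
        return self

    def decision_function(self, X):
        check_is_fitted(self, "weights_")
        X = check_array(X)
        Xs = (X - self.center_) / self.scale_
        phi = kernel_matrix(Xs, self._rv_std, kernel=self.kernel, width=self.width_,
                            include_bias=False)
        if self.bias_retained_:
            phi = np.column_stack([phi, np.ones(len(Xs))])
        return phi @ self.weights_

    def predict_proba(self, X):
        p1 = _sigmoid(self.decision_function(X))
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X):
        return self.classes_[(self.decision_function(X) > 0).astype(int)]


class RVMClassifier(ClassifierMixin, BaseEstimator):
    """One-vs-rest multiclass RVM; prediction is the class of highest
    probability (ties resolve to the first class in sorted order)."""

    def __init__(self, kernel: str = "rbf", width: float | None = None, alpha_init: float = 1.0,
                 prune_threshold: float = 1e12, tol: float = 1e-4, max_outer: int = 500,
                 newton_tol: float = 1e-6, standardize: bool = True):
        self.kernel = kernel
        self.width = width
        self.alpha_init = alpha_init
        self.prune_threshold = prune_threshold
        self.tol = tol
        self.max_outer = max_outer
        self.newton_tol = newton_tol
        self.standardize = standardize

    def fit(self, X, y):
        X, y = check_X_y(X, y, dtype=None)
        self.classes_ = np.unique(y)
        if len(self.classes_) < 2:
            raise ValueError("need at least two classes")
        self.estimators_ = []
        for cls in self.classes_:
            sub = RVMBinaryClassifier(**self.get_params())
            sub.fit(X, (y == cls).astype(int))
            self.estimators_.append(sub)
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "estimators_")
        return np.column_stack([est.predict_proba(X)[:, 1] for est in self.estimators_])

    def predict(self, X):
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]

    def n_relevance_vectors(self) -> int:
        check_is_fitted(self, "estimators_")
        return int(sum(len(e.relevance_indices_) for e in self.estimators_))


# ---------------------------------------------------------------------------
# thin functional wrappers and serialization


def predict_proba(model: RVMBinaryClassifier, x: np.ndarray) -> float:
    """Probability that a single vector belongs to the positive class."""
    return float(model.predict_proba(np.atleast_2d(x))[0, 1])


def train_binary(X, y, kernel: str = "rbf", width: float | None = None, max_outer: int = 500,
                 tol: float = 1e-4) -> RVMBinaryClassifier:
    return RVMBinaryClassifier(kernel=kernel, width=width, max_outer=max_outer, tol=tol).fit(X, y)


def train_multiclass(X, y, kernel: str = "rbf", width: float | None = None,
                     max_outer: int = 500, tol: float = 1e-4) -> RVMClassifier:
    return RVMClassifier(kernel=kernel, width=width, max_outer=max_outer, tol=tol).fit(X, y)


def classify(model: RVMClassifier, x: np.ndarray) -> tuple:
    """(predicted class, per-class probabilities) for one vector."""
    p = model.predict_proba(np.atleast_2d(x))[0]
    return model.classes_[int(np.argmax(p))], dict(zip(model.classes_, p.tolist()))


def save_model(model: RVMClassifier, path) -> None:
    state = {"classes": [str(c) for c in model.classes_], "params": model.get_params(), "submodels": []}
    for est in model.estimators_:
        state["submodels"].append({
            "relevance_vectors": est.relevance_vectors_.tolist(),
            "relevance_indices": est.relevance_indices_.tolist(),
            "weights": est.weights_.tolist(),
            "alphas": est.alphas_.tolist(),
            "center": est.center_.tolist(),
            "scale": est.scale_.tolist(),
            "width": est.width_,
            "bias_retained": est.bias_retained_,
            "converged": bool(est.converged_),
            "n_iter": int(est.n_iter_),
        })
    Path(path).write_text(json.dumps(state))


def load_model(path) -> RVMClassifier:
    state = json.loads(Path(path).read_text())
    model = RVMClassifier(**state["params"])
    model.classes_ = np.array(state["classes"])
    model.estimators_ = []
    for sub in state["submodels"]:
        est = RVMBinaryClassifier(**state["params"])
        est.classes_ = np.array([0, 1])
        est.relevance_vectors_ = np.array(sub["relevance_vectors"])
        est.relevance_indices_ = np.array(sub["relevance_indices"], dtype=int)
        est.weights_ = np.array(sub["weights"])
        est.alphas_ = np.array(sub["alphas"])
        est.center_ = np.array(sub["center"])
        est.scale_ = np.array(sub["scale"])
        est.width_ = sub["width"]
        est.bias_retained_ = sub["bias_retained"]
        est.converged_ = sub["converged"]
        est.n_iter_ = sub["n_iter"]
        est._rv_std = (est.relevance_vectors_ - est.center_) / est.scale_
        model.estimators_.append(est)
    return model
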