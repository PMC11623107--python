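"""Attentive tabular network with sparsemax feature masks.

A compact NumPy implementation of the sequential-attention architecture for
tabular data: at each decision step ``t`` an attentive transformer produces a
feature-selection mask ``M_t = sparsemax(P_t * A_t)``, where the prior scale
``P_t = prod_{s<t} (gamma - M_s)`` discourages re-using features already
attended to.  The masked features ``M_t * X`` feed a per-step feature
transformer whose output both contributes to the decision and conditions the
next step's attention.  Because sparsemax projects onto the simplex, each
sample's per-step mask is a (sparse) probability distribution over features.

Interpretability is the point: the cumulative mask ``sum_t M_{t,j}``,
averaged over samples and normalized, is the per-feature importance used for
marker ranking.

Architectural choices kept deliberately small for desk-scale genotype
matrices: one linear+ReLU feature transformer per step, attention width
``n_a``, and a semi-gradient treatment of the prior scale (the prior is a
constant during backpropagation).  Training is full manual backprop with
Adam, seeded and single-threaded, hence bit-reproducible.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

__all__ = ["sparsemax", "TabNetClassifier"]

_EPS = 1e-10


def sparsemax(z: np.ndarray) -> np.ndarray:
    """Row-wise sparsemax: Euclidean projection of each row onto the simplex.

    Returns a sparse probability distribution per row (nonnegative, sums
    to 1).  Equal inputs map to the uniform distribution.
    """
    z = np.atleast_2d(np.asarray(z, dtype=float))
    z_sorted = -np.sort(-z, axis=1)
    cumsum = np.cumsum(z_sorted, axis=1)
    k = np.arange(1, z.shape[1] + 1)
    support = 1.0 + k * z_sorted > cumsum
    k_z = support.sum(axis=1)
    tau = (cumsum[np.arange(z.shape[0]), k_z - 1] - 1.0) / k_z
    return np.maximum(z - tau[:, None], 0.0)


def _sparsemax_jvp(out: np.ndarray, grad: np.ndarray) -> np.ndarray:
    """Jacobian-vector product of sparsemax at a point with output ``out``."""
    support = out > 0
    v = np.where(support, grad, 0.0)
    mean = v.sum(axis=1) / np.maximum(support.sum(axis=1), 1)
    return np.where(support, grad - mean[:, None], 0.0)


class _DivergenceError(RuntimeError):
    """Training loss became non-finite; carries the loss trace."""

    def __init__(self, trace):
        self.trace = list(trace)
        super().__init__(f"training diverged; loss trace: {self.trace}")


class TabNetClassifier(ClassifierMixin, BaseEstimator):
    """Sparse-attention tabular classifier with retrievable feature masks.

    Parameters
    ----------
    n_steps : int, default=3
        Number of sequential decision steps ``T``.
    n_d, n_a : int, default=8
        Width of the decision output and of the attention representation.
    gamma : float, default=1.5
        Prior-scale relaxation; values > 1 allow a feature to be re-selected
        at later steps.
    lambda_sparse : float, default=1e-4
        Weight of the mask-entropy sparsity regularizer.
    learning_rate, batch_size, max_epochs : optimizer settings (Adam).
    patience : int, default=5
        Early-stopping patience on the validation logloss.
    val_fraction : float, default=0.1
        Held-out fraction (stratified) used for early stopping.
    class_weight : None or "balanced"
        Per-class loss weights; "balanced" reweights inversely to class
        frequency, useful under heavy case/control imbalance.
    random_state : int, default=0

    Attributes
    ----------
    classes_ : ndarray of shape (2,)
    feature_importances_ : ndarray of shape (n_features,)
        Mean cumulative mask over the training samples, normalized to sum 1.
    loss_trace_ : list of (train_loss, val_loss) per epoch.
    """

    def __init__(
        self,
        n_steps: int = 3,
        n_d: int = 8,
        n_a: int = 8,
        gamma: float = 1.5,
        lambda_sparse: float = 1e-4,
        learning_rate: float = 0.02,
        batch_size: int = 256,
        max_epochs: int = 20,
        patience: int = 5,
        val_fraction: float = 0.1,
        class_weight=None,
        random_state: int = 0,
    ):
        self.n_steps = n_steps
        self.n_d = n_d
        self.n_a = n_a
        self.gamma = gamma
        self.lambda_sparse = lambda_sparse
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.patience = patience
        self.val_fraction = val_fraction
        self.class_weight = class_weight
        self.random_state = random_state

    # -- internals ---------------------------------------------------------

    def _init_params(self, rng, p):
        params = {
            "W0": rng.standard_normal((self.n_a, p)) * np.sqrt(2.0 / p),
            "b0": np.zeros(self.n_a),
            "wo": rng.standard_normal(self.n_d) * np.sqrt(1.0 / self.n_d),
            "bo": np.zeros(1),
        }
        for t in range(self.n_steps):
            # small attention weights: masks start near-uniform and sharpen
            params[f"Wa{t}"] = rng.standard_normal((p, self.n_a)) * (0.1 / np.sqrt(self.n_a))
            params[f"ba{t}"] = np.zeros(p)
            params[f"Wf{t}"] = rng.standard_normal((self.n_d + self.n_a, p)) * np.sqrt(2.0 / p)
            params[f"bf{t}"] = np.zeros(self.n_d + self.n_a)
        return params

    def _forward(self, X, params, need_cache=False):
        B, p = X.shape
        h_pre = X @ params["W0"].T + params["b0"]
        h = np.maximum(h_pre, 0.0)
        prior = np.ones((B, p))
        D = np.zeros((B, self.n_d))
        masks = []
        caches = []
        for t in range(self.n_steps):
            A = h @ params[f"Wa{t}"].T + params[f"ba{t}"]
            M = sparsemax(prior * A)
            U = M * X
            F_pre = U @ params[f"Wf{t}"].T + params[f"bf{t}"]
            F = np.maximum(F_pre, 0.0)
            if need_cache:
                caches.append({"h_prev": h, "prior": prior.copy(), "M": M, "U": U, "F_pre": F_pre})
            masks.append(M)
            prior = prior * (self.gamma - M)
            D = D + F[:, : self.n_d]
            h = F[:, self.n_d :]
        logit = D @ params["wo"] + params["bo"][0]
        extras = {"h_pre": h_pre, "D": D, "caches": caches} if need_cache else None
        return logit, masks, extras

    def _loss_and_grads(self, X, y, w, params):
        B = X.shape[0]
        logit, masks, ex = self._forward(X, params, need_cache=True)
        prob = 1.0 / (1.0 + np.exp(-logit))
        wsum = w.sum()
        bce = -(w * (y * np.log(prob + _EPS) + (1 - y) * np.log(1 - prob + _EPS))).sum() / wsum
        sparse_pen = 0.0
        for M in masks:
            sparse_pen += (-(M * np.log(M + _EPS))).sum()
        sparse_pen *= self.lambda_sparse / (self.n_steps * B)
        loss = bce + sparse_pen

        grads = {k: np.zeros_like(v) for k, v in params.items()}
        gl = w * (prob - y) / wsum
        grads["wo"] = ex["D"].T @ gl
        grads["bo"] = np.array([gl.sum()])
        g_D = np.outer(gl, params["wo"])
        g_h = np.zeros((B, self.n_a))
        sp_scale = self.lambda_sparse / (self.n_steps * B)
        for t in reversed(range(self.n_steps)):
            c = ex["caches"][t]
            g_F = np.concatenate([g_D, g_h], axis=1) * (c["F_pre"] > 0)
            grads[f"Wf{t}"] = g_F.T @ c["U"]
            grads[f"bf{t}"] = g_F.sum(axis=0)
            g_U = g_F @ params[f"Wf{t}"]
            M = c["M"]
            g_M = g_U * X - sp_scale * (np.log(M + _EPS) + M / (M + _EPS))
            g_Z = _sparsemax_jvp(M, g_M)
            g_A = g_Z * c["prior"]  # prior treated as constant (semi-gradient)
            grads[f"Wa{t}"] = g_A.T @ c["h_prev"]
            grads[f"ba{t}"] = g_A.sum(axis=0)
            g_h = g_A @ params[f"Wa{t}"]
        g_h0 = g_h * (ex["h_pre"] > 0)
        grads["W0"] = g_h0.T @ X
        grads["b0"] = g_h0.sum(axis=0)
        return loss, grads

    def _weights(self, y):
        if self.class_weight == "balanced":
            n = len(y)
            w1 = n / (2.0 * max(y.sum(), 1))
            w0 = n / (2.0 * max((1 - y).sum(), 1))
            return np.where(y == 1, w1, w0)
        return np.ones_like(y, dtype=float)

    # -- sklearn API -------------------------------------------------------

    def fit(self, X, y):
        X, y = check_X_y(X, y, dtype=np.float64)
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise ValueError("TabNetClassifier is binary; got %d classes" % len(self.classes_))
        y01 = (y == self.classes_[1]).astype(float)
        rng = np.random.default_rng(self.random_state)

        self.mean_ = X.mean(axis=0)
        self.scale_ = X.std(axis=0)
        self.scale_[self.scale_ == 0] = 1.0
        Xs = (X - self.mean_) / self.scale_

        # stratified validation split for early stopping
        n = len(y01)
        val_idx = []
        for cls in (0.0, 1.0):
            idx = np.flatnonzero(y01 == cls)
            rng.shuffle(idx)
            n_val = max(1, int(round(self.val_fraction * len(idx)))) if len(idx) > 1 else 0
            val_idx.append(idx[:n_val])
        val_idx = np.concatenate(val_idx)
        train_idx = np.setdiff1d(np.arange(n), val_idx)
        Xtr, ytr = Xs[train_idx], y01[train_idx]
        Xva, yva = Xs[val_idx], y01[val_idx]
        wtr, wva = self._weights(ytr), self._weights(yva)

        params = self._init_params(rng, X.shape[1])
        m_adam = {k: np.zeros_like(v) for k, v in params.items()}
        v_adam = {k: np.zeros_like(v) for k, v in params.items()}
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        step = 0
        best_val = np.inf
        best_params = {k: v.copy() for k, v in params.items()}
        bad_epochs = 0
        self.loss_trace_ = []
        for epoch in range(self.max_epochs):
            order = rng.permutation(len(ytr))
            epoch_loss = 0.0
            n_batches = 0
            for start in range(0, len(ytr), self.batch_size):
                sel = order[start : start + self.batch_size]
                if len(sel) < 2:
                    continue
                loss, grads = self._loss_and_grads(Xtr[sel], ytr[sel], wtr[sel], params)
                if not np.isfinite(loss):
                    raise _DivergenceError([l for l, _ in self.loss_trace_] + [loss])
                epoch_loss += loss
                n_batches += 1
                step += 1
                for k in params:
                    m_adam[k] = beta1 * m_adam[k] + (1 - beta1) * grads[k]
                    v_adam[k] = beta2 * v_adam[k] + (1 - beta2) * grads[k] ** 2
                    mh = m_adam[k] / (1 - beta1**step)
                    vh = v_adam[k] / (1 - beta2**step)
                    params[k] -= self.learning_rate * mh / (np.sqrt(vh) + eps)
            if len(yva):
                logit_va, _, _ = self._forward(Xva, params)
                pva = 1.0 / (1.0 + np.exp(-logit_va))
                val_loss = -(
                    wva * (yva * np.log(pva + _EPS) + (1 - yva) * np.log(1 - pva + _EPS))
                ).sum() / wva.sum()
            else:
                val_loss = epoch_loss / max(n_batches, 1)
            self.loss_trace_.append((epoch_loss / max(n_batches, 1), float(val_loss)))
            if val_loss < best_val - 1e-5:
                best_val = val_loss
                best_params = {k: v.copy() for k, v in params.items()}
                bad_epochs = 0
            else:
                bad_epochs += 1
                if bad_epochs > self.patience:
                    break
        self.params_ = best_params
        self.n_features_in_ = X.shape[1]

        masks = self.feature_masks(X)
        cum = masks.sum(axis=0).mean(axis=0)  # sum over steps, mean over samples
        total = cum.sum()
        self.feature_importances_ = cum / total if total > 0 else cum
        return self

    def _transform_input(self, X):
        X = check_array(X, dtype=np.float64)
        if X.shape[1] != self.n_features_in_:
            raise ValueError("feature count mismatch")
        return (X - self.mean_) / self.scale_

    def decision_function(self, X):
        check_is_fitted(self, "params_")
        logit, _, _ = self._forward(self._transform_input(X), self.params_)
        return logit

    def predict_proba(self, X):
        p1 = 1.0 / (1.0 + np.exp(-self.decision_function(X)))
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X):
        return self.classes_[(self.decision_function(X) > 0).astype(int)]

    def feature_masks(self, X) -> np.ndarray:
        """Per-step, per-sample sparsemax masks, shape (n_steps, n_samples, p).

        Each ``masks[t, i]`` is a probability distribution over features.
        """
        check_is_fitted(self, "params_")
        Xs = self._transform_input(X)
        out = None
        for start in range(0, Xs.shape[0], 4096):
            _, masks, _ = self._forward(Xs[start : start + 4096], self.params_)
            chunk = np.stack(masks)
            out = chunk if out is None else np.concatenate([out, chunk], axis=1)
        return out
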