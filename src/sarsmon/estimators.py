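"""From-equation classifier implementations.

Five binary classifiers implemented directly from their defining equations:
Gaussian naive Bayes, a binned multinomial naive Bayes, a decision table
with greedy cross-validated feature selection, ridge-penalized logistic
regression fitted by damped Newton/IRLS, and a linear/RBF support vector
machine trained with the simplified sequential minimal optimization (SMO)
pair-update loop. All estimators follow the fit/predict(_proba) protocol of
:mod:`sarsmon._base`; every fit is a deterministic function of the data and
hyperparameters (SMO uses a fixed sweep order; its optional training
subsample is drawn from ``random_state``).

Model parameters serialize to plain JSON via ``to_dict`` / ``from_dict``
(no pickled code).
"""

from __future__ import annotations

import numpy as np

from ._base import BaseEstimator, ClassifierMixin

__all__ = [
    "GaussianNB",
    "BinnedMultinomialNB",
    "DecisionTableClassifier",
    "RidgeLogisticRegression",
    "SMOClassifier",
    "model_to_dict",
    "model_from_dict",
]


# ---------------------------------------------------------------------------
# Gaussian naive Bayes
# ---------------------------------------------------------------------------

class GaussianNB(BaseEstimator, ClassifierMixin):
    """Naive Bayes with per-class Gaussian feature densities.

    The posterior is the product of class prior and per-feature Gaussian
    likelihoods under the conditional-independence assumption; prediction is
    the argmax class. Plain Gaussian densities only (no kernel density
    estimation). ``var_floor`` guards zero-variance features.
    """

    def __init__(self, var_floor: float = 1e-9):
        self.var_floor = var_floor

    def fit(self, X, y):
        X, y, classes = self._validate_Xy(X, y)
        self.classes_ = classes
        self.n_features_in_ = X.shape[1]
        k = classes.size
        self.class_prior_ = np.empty(k)
        self.theta_ = np.empty((k, X.shape[1]))
        self.var_ = np.empty((k, X.shape[1]))
        for i, c in enumerate(classes):
            Xc = X[y == c]
            self.class_prior_[i] = Xc.shape[0] / X.shape[0]
            self.theta_[i] = Xc.mean(axis=0)
            self.var_[i] = np.maximum(Xc.var(axis=0), self.var_floor)
        return self

    def _joint_log_likelihood(self, X):
        jll = np.empty((X.shape[0], self.classes_.size))
        for i in range(self.classes_.size):
            diff = X - self.theta_[i]
            jll[:, i] = (
                np.log(self.class_prior_[i])
                - 0.5 * np.sum(np.log(2.0 * np.pi * self.var_[i]))
                - 0.5 * np.sum(diff**2 / self.var_[i], axis=1)
            )
        return jll

    def predict_proba(self, X):
        X = self._validate_X(X)
        jll = self._joint_log_likelihood(X)
        jll -= jll.max(axis=1, keepdims=True)
        p = np.exp(jll)
        return p / p.sum(axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# shared equal-width binning
# ---------------------------------------------------------------------------

def _fit_bins(X: np.ndarray, n_bins: int) -> np.ndarray:
    """Equal-width interior bin edges per feature, shape (d, n_bins-1)."""
    lo, hi = X.min(axis=0), X.max(axis=0)
    edges = np.empty((X.shape[1], n_bins - 1))
    for j in range(X.shape[1]):
        if hi[j] > lo[j]:
            edges[j] = np.linspace(lo[j], hi[j], n_bins + 1)[1:-1]
        else:  # constant feature: single occupied bin
            edges[j] = np.full(n_bins - 1, np.inf)
    return edges


def _digitize(X: np.ndarray, edges: np.ndarray) -> np.ndarray:
    out = np.empty(X.shape, dtype=np.int64)
    for j in range(X.shape[1]):
        out[:, j] = np.searchsorted(edges[j], X[:, j], side="right")
    return out


class BinnedMultinomialNB(BaseEstimator, ClassifierMixin):
    """Multinomial naive Bayes over equal-width-binned vitals.

    Continuous channels are discretized into ``n_bins`` equal-width bins
    fitted on the training data; per-class bin frequencies are Laplace
    smoothed with ``alpha``. A bin unseen in training keeps finite
    probability through the smoothing. A constant feature collapses to one
    bin and contributes an identical factor to every class.
    """

    def __init__(self, n_bins: int = 10, alpha: float = 1.0):
        self.n_bins = n_bins
        self.alpha = alpha

    def fit(self, X, y):
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0 (Laplace smoothing)")
        X, y, classes = self._validate_Xy(X, y)
        self.classes_ = classes
        self.n_features_in_ = X.shape[1]
        self.bin_edges_ = _fit_bins(X, self.n_bins)
        B = _digitize(X, self.bin_edges_)
        k, d = classes.size, X.shape[1]
        self.class_log_prior_ = np.empty(k)
        self.feature_log_prob_ = np.empty((k, d, self.n_bins))
        for i, c in enumerate(classes):
            Bc = B[y == c]
            self.class_log_prior_[i] = np.log(Bc.shape[0] / X.shape[0])
            for j in range(d):
                counts = np.bincount(Bc[:, j], minlength=self.n_bins).astype(float)
                counts += self.alpha
                self.feature_log_prob_[i, j] = np.log(counts / counts.sum())
        return self

    def predict_proba(self, X):
        X = self._validate_X(X)
        B = _digitize(X, self.bin_edges_)
        n, d = B.shape
        jll = np.tile(self.class_log_prior_, (n, 1))
        for i in range(self.classes_.size):
            for j in range(d):
                jll[:, i] += self.feature_log_prob_[i, j][B[:, j]]
        jll -= jll.max(axis=1, keepdims=True)
        p = np.exp(jll)
        return p / p.sum(axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# Decision table
# ---------------------------------------------------------------------------

class DecisionTableClassifier(BaseEstimator, ClassifierMixin):
    """IF condition-conjunction THEN action lookup table.

    Features are binned as for :class:`BinnedMultinomialNB`; a greedy forward
    search selects the condition features maximizing ``cv``-fold
    cross-validated accuracy (deterministic contiguous folds). Prediction
    looks up the exact selected-feature bin key and returns that key's
    training majority class; an unseen key falls back to the global majority.
    ``predict_proba`` returns the smoothed per-key class frequencies.
    """

    def __init__(self, n_bins: int = 10, cv: int = 5):
        self.n_bins = n_bins
        self.cv = cv

    @staticmethod
    def _keys(B: np.ndarray, feats: list[int], n_bins: int) -> np.ndarray:
        key = np.zeros(B.shape[0], dtype=np.int64)
        for f in feats:
            key = key * n_bins + B[:, f]
        return key

    def _cv_accuracy(self, B, yi, feats) -> float:
        n = B.shape[0]
        folds = np.arange(n) % self.cv  # deterministic striping
        correct = 0
        key = self._keys(B, feats, self.n_bins)
        for f in range(self.cv):
            tr, te = folds != f, folds == f
            pred = self._lookup_majority(key[tr], yi[tr], key[te])
            correct += int(np.sum(pred == yi[te]))
        return correct / n

    @staticmethod
    def _lookup_majority(train_key, train_y, test_key):
        uk, inv = np.unique(train_key, return_inverse=True)
        pos = np.bincount(inv, weights=train_y.astype(float))
        tot = np.bincount(inv).astype(float)
        global_major = int(train_y.mean() >= 0.5)
        maj = np.where(pos * 2 == tot, global_major, (pos * 2 > tot).astype(int))
        idx = np.searchsorted(uk, test_key)
        idx = np.clip(idx, 0, uk.size - 1)
        hit = uk[idx] == test_key
        return np.where(hit, maj[idx], global_major)

    def fit(self, X, y):
        X, y, classes = self._validate_Xy(X, y)
        self.classes_ = classes
        self.n_features_in_ = X.shape[1]
        yi = (y == classes[1]).astype(np.int64)
        self.bin_edges_ = _fit_bins(X, self.n_bins)
        B = _digitize(X, self.bin_edges_)

        selected: list[int] = []
        best_acc = max(yi.mean(), 1 - yi.mean())  # empty table = majority classifier
        improved = True
        while improved and len(selected) < X.shape[1]:
            improved = False
            best_f, best_f_acc = None, best_acc
            for f in range(X.shape[1]):
                if f in selected:
                    continue
                acc = self._cv_accuracy(B, yi, selected + [f])
                if acc > best_f_acc + 1e-12:
                    best_f, best_f_acc = f, acc
            if best_f is not None:
                selected.append(best_f)
                best_acc = best_f_acc
                improved = True
        self.selected_features_ = selected
        self.cv_accuracy_ = best_acc

        key = self._keys(B, selected, self.n_bins)
        uk, inv = np.unique(key, return_inverse=True)
        pos = np.bincount(inv, weights=yi.astype(float))
        tot = np.bincount(inv).astype(float)
        self._table_keys_ = uk
        # Laplace-smoothed positive-class frequency per condition key
        self._table_pos_frac_ = (pos + 1.0) / (tot + 2.0)
        self._global_pos_frac_ = float((yi.sum() + 1.0) / (yi.size + 2.0))
        self.global_majority_ = classes[int(yi.mean() >= 0.5)]
        return self

    def _pos_fraction(self, X):
        B = _digitize(X, self.bin_edges_)
        key = self._keys(B, self.selected_features_, self.n_bins)
        idx = np.searchsorted(self._table_keys_, key)
        idx = np.clip(idx, 0, max(self._table_keys_.size - 1, 0))
        if self._table_keys_.size == 0:
            return np.full(X.shape[0], self._global_pos_frac_)
        hit = self._table_keys_[idx] == key
        return np.where(hit, self._table_pos_frac_[idx], self._global_pos_frac_)

    def predict_proba(self, X):
        X = self._validate_X(X)
        pos = self._pos_fraction(X)
        return np.column_stack([1.0 - pos, pos])

    def predict(self, X):
        X = self._validate_X(X)
        pos = self._pos_fraction(X)
        return self.classes_[(pos >= 0.5).astype(int)]


# ---------------------------------------------------------------------------
# Ridge logistic regression (damped Newton / IRLS)
# ---------------------------------------------------------------------------

class RidgeLogisticRegression(BaseEstimator, ClassifierMixin):
    """L2-penalized binary logistic regression.

    Models ``P(Y=1 | x) = 1 / (1 + exp(-(b0 + b.x)))`` and maximizes the
    ridge-penalized log-likelihood with a damped Newton (IRLS) iteration;
    the intercept is unpenalized. The default ridge of 1e-8 matches the
    conventional weak default of rule-induction toolkits. Non-convergence at
    ``max_iter`` sets ``converged_ = False`` rather than raising.
    """

    def __init__(self, ridge: float = 1e-8, max_iter: int = 100, tol: float = 1e-8):
        self.ridge = ridge
        self.max_iter = max_iter
        self.tol = tol

    def fit(self, X, y):
        if self.ridge < 0:
            raise ValueError("ridge must be >= 0")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        X, y, classes = self._validate_Xy(X, y)
        self.classes_ = classes
        self.n_features_in_ = X.shape[1]
        t = (y == classes[1]).astype(float)

        n, d = X.shape
        Xa = np.hstack([np.ones((n, 1)), X])
        beta = np.zeros(d + 1)
        penalty = np.full(d + 1, self.ridge)
        penalty[0] = 0.0  # intercept unpenalized
        self.converged_ = False
        for it in range(self.max_iter):
            z = Xa @ beta
            p = 1.0 / (1.0 + np.exp(-z))
            grad = Xa.T @ (t - p) - penalty * beta
            w = np.maximum(p * (1.0 - p), 1e-10)
            H = (Xa * w[:, None]).T @ Xa + np.diag(penalty)
            try:
                step = np.linalg.solve(H, grad)
            except np.linalg.LinAlgError:
                step = np.linalg.lstsq(H, grad, rcond=None)[0]
            # damped step: halve until the penalized log-likelihood improves
            ll_old = self._penalized_ll(t, z, beta, penalty)
            scale = 1.0
            for _ in range(30):
                beta_new = beta + scale * step
                if (
                    self._penalized_ll(t, Xa @ beta_new, beta_new, penalty)
                    >= ll_old - 1e-12
                ):
                    break
                scale *= 0.5
            beta = beta + scale * step
            if np.max(np.abs(scale * step)) < self.tol:
                self.converged_ = True
                break
        self.intercept_ = float(beta[0])
        self.coef_ = beta[1:]
        self.n_iter_ = it + 1
        return self

    @staticmethod
    def _penalized_ll(t, z, beta, penalty):
        # log-likelihood via the numerically stable log1p(exp(.)) form
        ll = np.sum(t * z - np.logaddexp(0.0, z))
        return ll - 0.5 * np.sum(penalty * beta**2)

    def decision_function(self, X):
        X = self._validate_X(X)
        return self.intercept_ + X @ self.coef_

    def predict_proba(self, X):
        z = self.decision_function(X)
        p = 1.0 / (1.0 + np.exp(-z))
        return np.column_stack([1.0 - p, p])


# ---------------------------------------------------------------------------
# SMO-trained support vector machine
# ---------------------------------------------------------------------------

class SMOClassifier(BaseEstimator, ClassifierMixin):
    """Support vector machine trained by simplified SMO.

    The dual problem is optimized one multiplier pair at a time: for a pair
    (i, j) the errors ``E = f(x) - y`` are computed, alpha_j moves by
    ``y_j (E_i - E_j) / eta`` with curvature
    ``eta = K(xi,xi) + K(xj,xj) - 2 K(xi,xj)``, is clipped to the [L, H] box
    implied by ``0 <= alpha <= C`` and the pair constraint, alpha_i absorbs
    the complementary change, and the threshold ``b`` is re-estimated.
    Pairs with ``eta <= 0`` are skipped. Sweeps are deterministic (index
    order); training stops after ``max_passes`` sweeps without an update.

    ``max_samples`` optionally subsamples the training set (stratified,
    seeded by ``random_state``) to keep the quadratic loop at desk scale on
    large record tables. Decision values are min-max mapped into [0, 1] for
    the alerting layer; this mapping is monotone but not a calibrated
    probability.
    """

    def __init__(
        self,
        C: float = 1.0,
        tol: float = 1e-3,
        max_passes: int = 10,
        kernel: str = "linear",
        gamma: float = 1.0,
        max_samples: int | None = 2000,
        random_state: int = 0,
    ):
        self.C = C
        self.tol = tol
        self.max_passes = max_passes
        self.kernel = kernel
        self.gamma = gamma
        self.max_samples = max_samples
        self.random_state = random_state

    def _kernel_matrix(self, A, B):
        if self.kernel == "linear":
            return A @ B.T
        if self.kernel == "rbf":
            sq = (
                np.sum(A**2, axis=1)[:, None]
                + np.sum(B**2, axis=1)[None, :]
                - 2.0 * (A @ B.T)
            )
            return np.exp(-self.gamma * np.maximum(sq, 0.0))
        raise ValueError(f"unknown kernel {self.kernel!r}")

    def _subsample(self, X, yi):
        if self.max_samples is None or X.shape[0] <= self.max_samples:
            return X, yi
        rng = np.random.default_rng(self.random_state)
        idx_parts = []
        for v in (-1.0, 1.0):
            cls_idx = np.flatnonzero(yi == v)
            take = max(1, int(round(self.max_samples * cls_idx.size / yi.size)))
            idx_parts.append(rng.choice(cls_idx, size=min(take, cls_idx.size), replace=False))
        idx = np.sort(np.concatenate(idx_parts))
        return X[idx], yi[idx]

    def fit(self, X, y):
        if self.C <= 0:
            raise ValueError("C must be > 0")
        X, y, classes = self._validate_Xy(X, y)
        self.classes_ = classes
        self.n_features_in_ = X.shape[1]
        yi = np.where(y == classes[1], 1.0, -1.0)
        X, yi = self._subsample(X, yi)

        n = X.shape[0]
        K = self._kernel_matrix(X, X)
        self._alpha = np.zeros(n)
        self._b = 0.0
        # cached decision values f(x_k) = sum_i alpha_i y_i K(i,k) + b
        self._f = np.zeros(n)
        self._K, self._yi = K, yi
        offset_rng = np.random.default_rng(self.random_state + 1)
        passes = 0
        while passes < self.max_passes:
            changed = 0
            for i in range(n):
                Ei = self._f[i] - yi[i]
                if (yi[i] * Ei < -self.tol and self._alpha[i] < self.C) or (
                    yi[i] * Ei > self.tol and self._alpha[i] > 0
                ):
                    # second-choice hierarchy: maximal |Ei - Ej| step first,
                    # then a cyclic scan from a seeded random offset
                    j = int(np.argmax(np.abs(self._f - yi - Ei)))
                    if j != i and self._take_step(i, j, Ei):
                        changed += 1
                        continue
                    start = int(offset_rng.integers(n))
                    for off in range(n):
                        j = (start + off) % n
                        if j == i:
                            continue
                        if self._take_step(i, j, Ei):
                            changed += 1
                            break
            passes = passes + 1 if changed == 0 else 0
        alpha, b = self._alpha, self._b
        del self._K, self._f, self._alpha, self._yi
        sv = alpha > 1e-12
        self.alpha_ = alpha
        self.b_ = float(b)
        self.support_vectors_ = X[sv]
        self.support_alpha_y_ = alpha[sv] * yi[sv]
        self._train_X_ = X
        self._train_y_ = yi
        dv = self._raw_decision(X)
        self.decision_min_ = float(dv.min())
        self.decision_max_ = float(dv.max())
        return self

    def _take_step(self, i: int, j: int, Ei: float) -> bool:
        """Jointly optimize the multiplier pair (i, j); True if it moved."""
        K, yi, alpha, C = self._K, self._yi, self._alpha, self.C
        Ej = self._f[j] - yi[j]
        ai_old, aj_old = alpha[i], alpha[j]
        if yi[i] != yi[j]:
            L, H = max(0.0, aj_old - ai_old), min(C, C + aj_old - ai_old)
        else:
            L, H = max(0.0, ai_old + aj_old - C), min(C, ai_old + aj_old)
        if L >= H:
            return False
        eta = K[i, i] + K[j, j] - 2.0 * K[i, j]
        if eta <= 0:
            return False
        aj = aj_old + yi[j] * (Ei - Ej) / eta
        aj = min(H, max(L, aj))
        if abs(aj - aj_old) < 1e-7:
            return False
        ai = ai_old + yi[i] * yi[j] * (aj_old - aj)
        alpha[i], alpha[j] = ai, aj
        b = self._b
        # threshold update (standard simplified-SMO rules)
        b1 = b - Ei - yi[i] * (ai - ai_old) * K[i, i] - yi[j] * (aj - aj_old) * K[i, j]
        b2 = b - Ej - yi[i] * (ai - ai_old) * K[i, j] - yi[j] * (aj - aj_old) * K[j, j]
        if 0 < ai < C:
            b_new = b1
        elif 0 < aj < C:
            b_new = b2
        else:
            b_new = 0.5 * (b1 + b2)
        self._f += (
            yi[i] * (ai - ai_old) * K[i]
            + yi[j] * (aj - aj_old) * K[j]
            + (b_new - b)
        )
        self._b = b_new
        return True

    def _raw_decision(self, X):
        if self.support_vectors_.shape[0] == 0:
            return np.full(X.shape[0], self.b_)
        K = self._kernel_matrix(X, self.support_vectors_)
        return K @ self.support_alpha_y_ + self.b_

    def decision_function(self, X):
        X = self._validate_X(X)
        return self._raw_decision(X)

    def predict(self, X):
        return self.classes_[(self.decision_function(X) >= 0).astype(int)]

    def predict_proba(self, X):
        """Min-max mapped decision values (monotone score, not calibrated)."""
        dv = self.decision_function(X)
        span = self.decision_max_ - self.decision_min_
        if span <= 0:
            pos = np.full(dv.shape, 0.5)
        else:
            pos = np.clip((dv - self.decision_min_) / span, 0.0, 1.0)
        return np.column_stack([1.0 - pos, pos])


# ---------------------------------------------------------------------------
# JSON round-trip of fitted models
# ---------------------------------------------------------------------------

_MODEL_REGISTRY = {
    cls.__name__: cls
    for cls in (
        GaussianNB,
        BinnedMultinomialNB,
        DecisionTableClassifier,
        RidgeLogisticRegression,
        SMOClassifier,
    )
}


def model_to_dict(model) -> dict:
    """Serialize a fitted estimator to a JSON-compatible dict (no code)."""
    state = {}
    for k, v in vars(model).items():
        if isinstance(v, np.ndarray):
            state[k] = {"__ndarray__": v.tolist(), "dtype": str(v.dtype)}
        elif isinstance(v, (np.floating, np.integer)):
            state[k] = v.item()
        else:
            state[k] = v
    return {"model": type(model).__name__, "params": model.get_params(), "state": state}


def model_from_dict(d: dict):
    cls = _MODEL_REGISTRY[d["model"]]
    model = cls(**d["params"])
    for k, v in d["state"].items():
        if isinstance(v, dict) and "__ndarray__" in v:
            v = np.asarray(v["__ndarray__"], dtype=v["dtype"])
        setattr(model, k, v)
    return model
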