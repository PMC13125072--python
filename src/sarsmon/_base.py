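"""Minimal estimator base class.

Provides the ``get_params`` / ``set_params`` protocol so the classifiers
compose with pipeline and model-selection tooling that relies on it. The
implementation mirrors the constructor-introspection convention: every
keyword argument of ``__init__`` is a hyperparameter, and fitted state is
stored on attributes with a trailing underscore.
"""

from __future__ import annotations

import inspect

import numpy as np


class BaseEstimator:
    """Parameter-introspection base for all estimators in this package."""

    @classmethod
    def _get_param_names(cls):
        sig = inspect.signature(cls.__init__)
        return sorted(
            p.name
            for p in sig.parameters.values()
            if p.name != "self" and p.kind != p.VAR_KEYWORD
        )

    def get_params(self, deep: bool = True) -> dict:
        return {name: getattr(self, name) for name in self._get_param_names()}

    def set_params(self, **params):
        valid = self._get_param_names()
        for key, value in params.items():
            if key not in valid:
                raise ValueError(
                    f"Invalid parameter {key!r} for {type(self).__name__}; "
                    f"valid parameters are {valid}"
                )
            setattr(self, key, value)
        return self

    def __repr__(self) -> str:
        params = ", ".join(f"{k}={v!r}" for k, v in self.get_params().items())
        return f"{type(self).__name__}({params})"

    # -- shared plumbing -------------------------------------------------

    def _check_is_fitted(self):
        if not any(k.endswith("_") and not k.startswith("_") for k in vars(self)):
            raise RuntimeError(
                f"This {type(self).__name__} instance is not fitted yet; "
                "call 'fit' before using this method."
            )


class ClassifierMixin:
    """Binary-classifier conveniences shared by the estimators."""

    def _validate_Xy(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2:
            raise ValueError(f"X must be 2-D, got shape {X.shape}")
        if X.shape[0] != y.shape[0]:
            raise ValueError(
                f"X and y have inconsistent lengths: {X.shape[0]} vs {y.shape[0]}"
            )
        if not np.isfinite(X).all():
            raise ValueError("X contains NaN or infinite values")
        classes = np.unique(y)
        if classes.size < 2:
            raise ValueError("training data contains a single class")
        return X, y, classes

    def _validate_X(self, X):
        self._check_is_fitted()
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError(f"X must be 2-D, got shape {X.shape}")
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} features, expected {self.n_features_in_}"
            )
        return X

    def predict(self, X):
        proba = self.predict_proba(X)
        return self.classes_[np.argmax(proba, axis=1)]

    def score(self, X, y):
        return float(np.mean(self.predict(X) == np.asarray(y)))
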