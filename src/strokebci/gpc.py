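"""Binary Gaussian-process classification of the selected CSP features.

A latent function f with a GP prior (isotropic squared-exponential kernel
with a signal-variance factor) is squashed through the logistic sigmoid,
π(f) = p(y = 1 | f); inference uses the Laplace (deterministic Gaussian)
approximation to the posterior, and kernel hyperparameters maximize the
approximate marginal likelihood from a fixed initialization (log
length-scale 0, log signal amplitude 0; no random restarts), so fitting is
fully deterministic.  Each trial receives a class-1 probability in (0, 1)
and labels are assigned by a decision threshold, default 0.5, with the tie
p = threshold going to class +1.

Features are standardized per column using training-split statistics only,
so a single kernel length-scale is comparable across features.
"""

from __future__ import annotations

import numpy as np
from sklearn.gaussian_process import GaussianProcessClassifier
from sklearn.gaussian_process.kernels import RBF, ConstantKernel

__all__ = ["LaplaceGPClassifier", "fit_gpc", "predict_proba", "classify"]


class LaplaceGPClassifier:
    """Laplace-approximation GP classifier with logistic likelihood.

    Labels are +1 (move) / −1 (rest).  ``predict_proba`` returns p(y = +1).

    Parameters
    ----------
    length_scale, signal_amplitude : float
        Kernel hyperparameter initial values (the optimizer starts here).
    optimize : bool
        Maximize the Laplace approximate marginal likelihood (default).
    threshold : float
        Decision cut in (0, 1); p >= threshold is classified +1.
    """

    def __init__(self, length_scale: float = 1.0, signal_amplitude: float = 1.0,
                 optimize: bool = True, threshold: float = 0.5):
        self.length_scale = length_scale
        self.signal_amplitude = signal_amplitude
        self.optimize = optimize
        self.threshold = threshold

    def get_params(self, deep: bool = True) -> dict:
        return {"length_scale": self.length_scale,
                "signal_amplitude": self.signal_amplitude,
                "optimize": self.optimize, "threshold": self.threshold}

    def set_params(self, **params) -> "LaplaceGPClassifier":
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"invalid parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X: np.ndarray, y: np.ndarray) -> "LaplaceGPClassifier":
        X = np.asarray(X, float)
        if X.ndim != 2 or X.shape[1] < 1:
            raise ValueError("X must be 2-D with at least one feature")
        y = np.asarray(y).astype(int)
        if not set(np.unique(y)) == {-1, 1}:
            raise ValueError("both classes (+1/-1) must be present")
        if min((y == 1).sum(), (y == -1).sum()) < 2:
            raise ValueError("need >= 2 trials per class")
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must be in (0, 1)")
        self.mean_ = X.mean(axis=0)
        std = X.std(axis=0)
        self.scale_ = np.where(std > 0, std, 1.0)
        Xs = (X - self.mean_) / self.scale_
        kernel = ConstantKernel(self.signal_amplitude ** 2,
                                constant_value_bounds=(1e-6, 1e6)) * \
            RBF(self.length_scale, length_scale_bounds=(1e-3, 1e4))
        self._gpc = GaussianProcessClassifier(
            kernel=kernel,
            optimizer="fmin_l_bfgs_b" if self.optimize else None,
            n_restarts_optimizer=0)
        self._gpc.fit(Xs, y)
        self.kernel_ = self._gpc.kernel_
        self.log_marginal_likelihood_ = self._gpc.log_marginal_likelihood_value_
        self.n_features_in_ = X.shape[1]
        return self

    def _check_x(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, float))
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} features, model was fitted with "
                f"{self.n_features_in_}")
        return (X - self.mean_) / self.scale_

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Probability of class +1 for each row, strictly inside (0, 1)."""
        proba = self._gpc.predict_proba(self._check_x(X))
        p1 = proba[:, list(self._gpc.classes_).index(1)]
        return np.clip(p1, np.nextafter(0.0, 1.0), np.nextafter(1.0, 0.0))

    def predict(self, X: np.ndarray) -> np.ndarray:
        p = self.predict_proba(X)
        return np.where(p >= self.threshold, 1, -1)

    def score(self, X: np.ndarray, y: np.ndarray) -> float:
        """Accuracy in percent against supplied truth."""
        return classify(self.predict_proba(X), self.threshold, y)[1]


def fit_gpc(X: np.ndarray, y: np.ndarray, **params) -> LaplaceGPClassifier:
    return LaplaceGPClassifier(**params).fit(X, y)


def predict_proba(model: LaplaceGPClassifier, X: np.ndarray) -> np.ndarray:
    return model.predict_proba(X)


def classify(probabilities: np.ndarray, threshold: float = 0.5,
             truth: np.ndarray | None = None):
    """Threshold probabilities into ±1 labels; p = threshold goes to +1.

    Returns ``(labels, accuracy_percent)``; accuracy is None without truth.
    """
    p = np.atleast_1d(np.asarray(probabilities, float))
    if p.size == 0:
        raise ValueError("empty prediction set")
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0, 1)")
    labels = np.where(p >= threshold, 1, -1)
    accuracy = None
    if truth is not None:
        truth = np.asarray(truth).astype(int)
        accuracy = 100.0 * (labels == truth).mean()
    return labels, accuracy
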