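"""Filter-bank common spatial patterns and log proportional-variance features.

For each frequency band b, CSP solves the two-class simultaneous
diagonalization of the class covariance matrices: with Σ_move and Σ_rest the
(trace-normalized, trial-averaged) spatial covariances, the projection W_b
satisfies

    W_bᵀ (Σ_move + Σ_rest) W_b = I,      W_bᵀ Σ_move W_b = diag(λ),

i.e. the generalized eigenproblem Σ_move w = λ (Σ_move + Σ_rest) w.  Columns
of W_b are spatial filters, ordered by descending move-class whitened
eigenvalue λ; the move- and rest-class eigenvalues of a component sum to 1,
so the first and last components are the most discriminative pair.  Trials
are projected as Z_{b,i} = W_bᵀ E_{b,i}, and the feature of component c is
the log *proportional* variance across the trials of the batch:

    v_{b,i}[c] = log( var(Z_{b,i}[c]) / Σ_{i'} var(Z_{b,i'}[c]) )

with the sum running over all trials of the batch being transformed.  Note
this normalizes each component across trials (so per column the
exponentials sum to 1 over the batch) — it makes features batch-dependent:
transforming the same trial inside a different batch shifts its features by
the log of the batch variance sum.  The conventional across-component
normalization is available via ``feature_norm="components"``.

Per-band feature blocks are concatenated band-major into the trials ×
(bands·channels) matrix, with labels encoded move → +1, rest → −1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .preprocess import EpochedBandTensor

__all__ = [
    "FeatureMatrix",
    "FilterBankCSP",
    "fit_csp",
    "apply_csp",
    "extract_features",
    "batch_size_invariant",
    "spatial_patterns",
    "encode_labels",
]


def encode_labels(labels) -> np.ndarray:
    """move → +1, rest → −1 (numeric labels pass through)."""
    labels = np.asarray(labels)
    if labels.dtype.kind in "iuf":
        y = labels.astype(int)
        if not set(np.unique(y)) <= {-1, 1}:
            raise ValueError("numeric labels must be in {1, -1}")
        return y
    mapping = {"move": 1, "rest": -1}
    try:
        return np.array([mapping[str(l)] for l in labels])
    except KeyError as e:
        raise ValueError(f"unknown label {e.args[0]!r}; expected move/rest") from e


@dataclass
class FeatureMatrix:
    """Trials × (bands·channels) log proportional-variance features.

    ``column_index[j]`` is the ``(band, component)`` pair of column j;
    columns are ordered band-major.
    """

    V: np.ndarray
    y: np.ndarray | None
    column_index: list[tuple[int, int]]

    @property
    def n_trials(self) -> int:
        return self.V.shape[0]


def _trial_covariances(tensor: EpochedBandTensor) -> np.ndarray:
    """Centered per-trial spatial covariances, (trials, bands, ch, ch).

    Cached on the tensor: cross-validation folds subset the same recording
    and reuse the computation.
    """
    covs = getattr(tensor, "_covs", None)
    if covs is None:
        segs = tensor.segments
        centered = segs - segs.mean(axis=-1, keepdims=True)
        covs = np.einsum("nbcs,nbds->nbcd", centered, centered)
        covs /= segs.shape[-1]
        tensor._covs = covs
    return covs


def _class_covariances(tensor: EpochedBandTensor,
                       y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-class, per-band mean of trace-normalized trial covariances.

    Returns two (bands, channels, channels) arrays (move, rest).
    """
    covs = _trial_covariances(tensor)
    traces = np.trace(covs, axis1=2, axis2=3)[..., None, None]
    normed = covs / traces
    return normed[y == 1].mean(axis=0), normed[y == -1].mean(axis=0)


class FilterBankCSP:
    """Per-band CSP projections with log proportional-variance features.

    Parameters
    ----------
    ridge : float
        Optional diagonal loading ε added to the composite covariance before
        the generalized eigendecomposition (useful for near-singular grouped
        fits).  Default 0 (no shrinkage).
    feature_norm : {"trials", "components"}
        Across-trials proportional variance (the default) or the
        conventional across-components normalization.

    Attributes
    ----------
    filters_ : ndarray, (bands, channels, channels)
        W_b with spatial filters in columns, sorted by descending move-class
        whitened eigenvalue; column signs fixed so each column's
        largest-magnitude entry is positive.
    eigenvalues_ : ndarray, (bands, channels)
        Move-class whitened eigenvalues per component.
    """

    def __init__(self, ridge: float = 0.0, feature_norm: str = "trials"):
        self.ridge = ridge
        self.feature_norm = feature_norm

    def get_params(self, deep: bool = True) -> dict:
        return {"ridge": self.ridge, "feature_norm": self.feature_norm}

    def set_params(self, **params) -> "FilterBankCSP":
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"invalid parameter {k!r}")
            setattr(self, k, v)
        return self

    # -- fitting ---------------------------------------------------------

    def fit(self, tensor: EpochedBandTensor, y=None) -> "FilterBankCSP":
        if self.feature_norm not in ("trials", "components"):
            raise ValueError(f"unknown feature_norm {self.feature_norm!r}")
        y = encode_labels(tensor.labels if y is None else y)
        for cls, name in ((1, "move"), (-1, "rest")):
            if (y == cls).sum() < 2:
                raise ValueError(f"need >= 2 trials of class {name!r} to fit CSP")
        n_bands, n_ch = tensor.n_bands, tensor.n_channels
        self.filters_ = np.empty((n_bands, n_ch, n_ch))
        self.eigenvalues_ = np.empty((n_bands, n_ch))
        cov_moves, cov_rests = _class_covariances(tensor, y)
        for b in range(n_bands):
            cov_move, cov_rest = cov_moves[b], cov_rests[b]
            composite = cov_move + cov_rest + self.ridge * np.eye(n_ch)
            try:
                vals, vecs = scipy.linalg.eigh(cov_move, composite)
            except scipy.linalg.LinAlgError as e:
                raise ValueError(
                    f"singular composite covariance in band {tensor.bands[b]}; "
                    "consider setting ridge > 0") from e
            order = np.argsort(vals)[::-1]
            vals, vecs = vals[order], vecs[:, order]
            # reproducible signs: largest-|entry| of each filter positive
            flip = np.sign(vecs[np.abs(vecs).argmax(axis=0), np.arange(n_ch)])
            vecs = vecs * flip
            self.filters_[b] = vecs
            self.eigenvalues_[b] = vals
        self.bands_ = tuple(tensor.bands)
        self.channel_names_ = (tuple(tensor.channels.names)
                               if tensor.channels is not None else None)
        self.column_index_ = [(b, c) for b in range(n_bands) for c in range(n_ch)]
        return self

    def _check_layout(self, tensor: EpochedBandTensor) -> None:
        if tuple(tensor.bands) != self.bands_:
            raise ValueError("band list does not match the fitted model")
        if (self.channel_names_ is not None and tensor.channels is not None
                and tuple(tensor.channels.names) != self.channel_names_):
            raise ValueError("channel order does not match the fitted model "
                             "(no silent reordering)")
        if tensor.n_channels != self.filters_.shape[1]:
            raise ValueError("channel count does not match the fitted model")

    # -- application -----------------------------------------------------

    def transform_trials(self, tensor: EpochedBandTensor) -> np.ndarray:
        """Spatially filter every trial: Z_{b,i} = W_bᵀ E_{b,i}."""
        self._check_layout(tensor)
        # (trials, bands, comps, samples) via per-band projection
        return np.einsum("bcj,tbcs->tbjs", self.filters_, tensor.segments)

    def transform(self, tensor: EpochedBandTensor) -> FeatureMatrix:
        """Project and extract features for the whole batch of trials.

        Component variances are evaluated as wᵀ C_trial w from the centered
        per-trial covariances, which equals the time-domain variance of the
        projected signal without materializing it.
        """
        self._check_layout(tensor)
        covs = _trial_covariances(tensor)
        variances = np.einsum("tbcd,bcj,bdj->tbj", covs,
                              self.filters_, self.filters_, optimize=True)
        y = encode_labels(tensor.labels) if tensor.labels is not None else None
        return self._features_from_variances(variances, y)

    def _features_from_projected(self, z: np.ndarray,
                                 y: np.ndarray | None) -> FeatureMatrix:
        return self._features_from_variances(z.var(axis=-1), y)

    def _features_from_variances(self, variances: np.ndarray,
                                 y: np.ndarray | None) -> FeatureMatrix:
        if (variances <= 0).any():
            t, b, c = np.argwhere(variances <= 0)[0]
            raise ValueError(
                f"zero variance in trial {t}, band {self.bands_[b]}, component {c}")
        if self.feature_norm == "trials":
            denom = variances.sum(axis=0, keepdims=True)
        else:
            denom = variances.sum(axis=2, keepdims=True)
        V = np.log(variances / denom)
        return FeatureMatrix(V.reshape(variances.shape[0], -1), y,
                             list(self.column_index_))


def fit_csp(tensor: EpochedBandTensor, ridge: float = 0.0) -> FilterBankCSP:
    return FilterBankCSP(ridge=ridge).fit(tensor)


def apply_csp(model: FilterBankCSP, tensor: EpochedBandTensor) -> np.ndarray:
    return model.transform_trials(tensor)


def extract_features(model: FilterBankCSP, z: np.ndarray,
                     labels=None) -> FeatureMatrix:
    y = encode_labels(labels) if labels is not None else None
    return model._features_from_projected(z, y)


def batch_size_invariant(features: FeatureMatrix) -> FeatureMatrix:
    """Shift proportional-variance features onto a batch-size-free scale.

    Adding log(batch size) to every entry turns the across-trials sum
    normalization into a mean normalization: log(var_i / mean_i' var_i').
    The two conventions differ by a single per-column constant, to which
    both the MRelv ranking and a classifier standardized on training
    statistics are invariant — but when training and test batches have
    different trial counts (k-fold folds vs. the 9-fold training block),
    the sum convention injects a log(n_train/n_test) offset into every
    test feature.  The classification pipeline therefore compares features
    on this invariant scale.
    """
    V = features.V + np.log(features.n_trials)
    return FeatureMatrix(V, features.y, list(features.column_index))


def spatial_patterns(model: FilterBankCSP) -> np.ndarray:
    """Scalp patterns: column j of band b is the field map of component j.

    With filters in the columns of W_b, patterns are the columns of W_b⁻ᵀ,
    so patternsᵀ · filters = I (biorthogonality).
    """
    out = np.empty_like(model.filters_)
    for b, w in enumerate(model.filters_):
        if abs(np.linalg.det(w)) < 1e-300 or np.linalg.cond(w) > 1e12:
            raise ValueError(f"numerically singular projection in band {b}")
        out[b] = np.linalg.inv(w).T
    return out
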