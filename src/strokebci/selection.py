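"""Marginal-relevance ranking of CSP features and paired-filter selection.

The marginal relevance (MRelv) of a feature column is the ratio of its
between-group to within-group sum of squares,

    BSS = Σ_k n_k (μ_k − μ)²,   WSS = Σ_k Σ_i (x_{ik} − μ_k)²,

the quantity behind one-way ANOVA: for k groups and n samples,
MRelv = F · (k−1)/(n−k).  Ranking is by descending score, ties broken by
ascending (band, component) for reproducibility.

CSP filters come in complementary pairs: component j and component
c_t+1−j of the same band carry the two extremes of the variance ratio and
are most useful together.  Selection therefore takes the ``n_top``
highest-ranked columns (default 4) and adds each one's same-band partner,
deduplicating when a partner is itself a primary pick.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .csp import FeatureMatrix

__all__ = [
    "MRelvRanking",
    "MarginalRelevanceSelector",
    "mrelv_scores",
    "select_features",
    "apply_selection",
]


@dataclass
class MRelvRanking:
    """Per-column MRelv scores and the descending-score column order."""

    scores: np.ndarray
    order: np.ndarray
    tie_rule: str = "ties broken by ascending (band, component)"


def mrelv_scores(V: np.ndarray, y: np.ndarray) -> MRelvRanking:
    """Score every feature column; infinite score when WSS = 0."""
    V = np.asarray(V, float)
    y = np.asarray(y)
    classes = np.unique(y)
    for cls in classes:
        if (y == cls).sum() < 2:
            raise ValueError(f"class {cls!r} has fewer than 2 trials")
    mu = V.mean(axis=0)
    bss = np.zeros(V.shape[1])
    wss = np.zeros(V.shape[1])
    for cls in classes:
        block = V[y == cls]
        mu_k = block.mean(axis=0)
        bss += block.shape[0] * (mu_k - mu) ** 2
        wss += ((block - mu_k) ** 2).sum(axis=0)
    with np.errstate(divide="ignore"):
        scores = np.where(wss > 0, bss / np.where(wss > 0, wss, 1.0), np.inf)
    # stable sort on (-score, column) => descending score, ascending column
    order = np.lexsort((np.arange(len(scores)), -scores))
    return MRelvRanking(scores=scores, order=order)


@dataclass
class MarginalRelevanceSelector:
    """Select the top-MRelv CSP columns together with their partner filters.

    Fitted attributes: ``scores_``, ``order_``, ``selected_`` (ordered
    (band, component) pairs), ``primary_`` (the n_top top-ranked pairs) and
    ``columns_`` (column indices into the feature matrix, original order).
    """

    n_top: int = 4
    scores_: np.ndarray = field(init=False, repr=False, default=None)

    def get_params(self, deep: bool = True) -> dict:
        return {"n_top": self.n_top}

    def set_params(self, **params) -> "MarginalRelevanceSelector":
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"invalid parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, features: FeatureMatrix, y=None) -> "MarginalRelevanceSelector":
        if self.n_top < 1:
            raise ValueError("n_top must be >= 1")
        y = features.y if y is None else np.asarray(y)
        layout = features.column_index
        if self.n_top > len(layout):
            raise ValueError(f"n_top={self.n_top} exceeds {len(layout)} columns")
        ranking = mrelv_scores(features.V, y)
        n_comp = max(c for _, c in layout) + 1
        col_of = {bc: j for j, bc in enumerate(layout)}
        primary = [layout[j] for j in ranking.order[:self.n_top]]
        selected: list[tuple[int, int]] = []
        for band, comp in primary:
            partner = (band, n_comp - 1 - comp)
            for pick in ((band, comp), partner):
                if pick not in selected:
                    selected.append(pick)
        self.scores_ = ranking.scores
        self.order_ = ranking.order
        self.primary_ = primary
        self.selected_ = selected
        self.layout_ = list(layout)
        self.columns_ = sorted(col_of[bc] for bc in selected)
        return self

    def transform(self, features: FeatureMatrix) -> FeatureMatrix:
        """Restrict a feature matrix to the selected columns (original order)."""
        if features.column_index != self.layout_:
            missing = [bc for bc in self.selected_
                       if bc not in features.column_index]
            if missing:
                raise ValueError(f"selected columns absent from input: {missing}")
            cols = [features.column_index.index(self.layout_[j])
                    for j in self.columns_]
        else:
            cols = self.columns_
        return FeatureMatrix(features.V[:, cols], features.y,
                             [features.column_index[j] for j in cols])

    def primary_bands(self) -> list[int]:
        """Band index of each primary pick (histogram bookkeeping: the
        n_top ranked picks only; partners are excluded)."""
        return [band for band, _ in self.primary_]


def select_features(ranking_or_features, layout=None,
                    n_top: int = 4) -> MarginalRelevanceSelector:
    """Thin wrapper: fit a selector on a FeatureMatrix."""
    sel = MarginalRelevanceSelector(n_top=n_top)
    return sel.fit(ranking_or_features)


def apply_selection(model: MarginalRelevanceSelector,
                    features: FeatureMatrix) -> FeatureMatrix:
    return model.transform(features)
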