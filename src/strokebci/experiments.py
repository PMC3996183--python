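"""Evaluation schemes for the FBCSP + MRelv + GPC pipeline.

Four schemes mirror the study design: within-session 10-fold
cross-validation with temporally contiguous folds; one-on-one transfer
(individual BCIs trained on single sessions, tested on every other
session); grouped training (trials of several sessions pooled into one
general model) with leave-one-out over a healthy cohort; and longitudinal
training (a subject's early session trains the BCI tested on their late
session).  In every scheme the CSP projections, the MRelv ranking and the
classifier are fitted on training trials only; test trials are pushed
through the frozen bundle, with the proportional-variance features
computed over the test batch being transformed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .csp import FilterBankCSP, batch_size_invariant
from .gpc import LaplaceGPClassifier
from .preprocess import (EpochedBandTensor, FilterBankSpec,
                         default_filter_bank, preprocess_session)
from .selection import MarginalRelevanceSelector
from .simulate import Session

__all__ = [
    "BCIConfig",
    "TrainedBCI",
    "train_bci",
    "test_bci",
    "kfold_cv",
    "cross_matrix",
    "append_row_summary",
    "loocv_group",
    "longitudinal",
    "band_histogram",
]


@dataclass(frozen=True)
class BCIConfig:
    """All pipeline knobs in one place (band edges, window, selection, GPC)."""

    filter_bank: FilterBankSpec = field(default_factory=default_filter_bank)
    epoch_offset_s: float = 2.0
    epoch_duration_s: float = 6.0
    n_top: int = 4
    ridge: float = 0.0
    gpc_optimize: bool = True
    threshold: float = 0.5


@dataclass
class TrainedBCI:
    """The transferable bundle: CSP projections + selection + classifier."""

    csp: FilterBankCSP
    selection: MarginalRelevanceSelector
    classifier: LaplaceGPClassifier
    config: BCIConfig
    provenance: dict = field(default_factory=dict)

    def score_tensor(self, tensor: EpochedBandTensor) -> float:
        """Accuracy (%) of the frozen bundle on a batch of epoched trials."""
        feats = batch_size_invariant(self.csp.transform(tensor))
        feats = self.selection.transform(feats)
        return self.classifier.score(feats.V, feats.y)


def _epoch(session: Session, cfg: BCIConfig) -> EpochedBandTensor:
    return preprocess_session(session, cfg.filter_bank,
                              cfg.epoch_offset_s, cfg.epoch_duration_s)


def _concat(tensors: list[EpochedBandTensor]) -> EpochedBandTensor:
    first = tensors[0]
    for t in tensors[1:]:
        if t.bands != first.bands or t.segments.shape[1:] != first.segments.shape[1:]:
            raise ValueError("sessions have incompatible band/channel layouts")
    return EpochedBandTensor(
        np.concatenate([t.segments for t in tensors]),
        np.concatenate([t.labels for t in tensors]),
        first.bands, first.window, first.fs, first.channels)


def _fit_on_tensor(tensor: EpochedBandTensor, cfg: BCIConfig,
                   provenance: dict | None = None) -> TrainedBCI:
    csp = FilterBankCSP(ridge=cfg.ridge).fit(tensor)
    feats = batch_size_invariant(csp.transform(tensor))
    sel = MarginalRelevanceSelector(n_top=cfg.n_top).fit(feats)
    reduced = sel.transform(feats)
    clf = LaplaceGPClassifier(optimize=cfg.gpc_optimize,
                              threshold=cfg.threshold).fit(reduced.V, reduced.y)
    return TrainedBCI(csp, sel, clf, cfg, provenance or {})


def train_bci(sessions: Session | list[Session], grouped: bool = False,
              config: BCIConfig | None = None) -> TrainedBCI:
    """Train an individual (one session) or grouped (pooled trials) BCI."""
    cfg = config or BCIConfig()
    if isinstance(sessions, Session):
        sessions = [sessions]
    if not sessions:
        raise ValueError("need at least one training session")
    if grouped and len(sessions) < 2:
        raise ValueError("grouped training requires >= 2 sessions")
    if not grouped and len(sessions) > 1:
        raise ValueError("individual training takes exactly one session; "
                         "pass grouped=True to pool")
    tensor = _concat([_epoch(s, cfg) for s in sessions])
    prov = {"train_ids": [s.dataset_id for s in sessions], "grouped": grouped}
    return _fit_on_tensor(tensor, cfg, prov)


def test_bci(bci: TrainedBCI, session: Session) -> float:
    """Apply a frozen BCI to a whole session; accuracy % over its trials."""
    return bci.score_tensor(_epoch(session, bci.config))


def _contiguous_folds(n_trials: int, k: int) -> list[np.ndarray]:
    """k temporally contiguous blocks, sizes differing by at most 1,
    earlier blocks larger."""
    if k > n_trials:
        raise ValueError(f"k={k} exceeds trial count {n_trials}")
    return [idx for idx in np.array_split(np.arange(n_trials), k)]


def kfold_cv(session: Session | EpochedBandTensor, k: int = 10,
             config: BCIConfig | None = None,
             return_folds: bool = False):
    """Temporally blocked k-fold CV of one session; folds are never shuffled."""
    cfg = config or BCIConfig()
    tensor = session if isinstance(session, EpochedBandTensor) else _epoch(session, cfg)
    folds = _contiguous_folds(tensor.n_trials, k)
    accs = []
    all_idx = np.arange(tensor.n_trials)
    for test_idx in folds:
        train_idx = np.setdiff1d(all_idx, test_idx)
        bci = _fit_on_tensor(tensor.subset(train_idx), cfg)
        accs.append(bci.score_tensor(tensor.subset(test_idx)))
    mean = float(np.mean(accs))
    return (mean, accs) if return_folds else mean


def cross_matrix(train_sessions: list[Session], test_sessions: list[Session],
                 config: BCIConfig | None = None) -> pd.DataFrame:
    """One individual BCI per training session, applied to every test session.

    Returns a test-id × train-id accuracy table; self-pairs (same dataset
    id) are left missing, as in a cross-dataset accuracy table.
    """
    cfg = config or BCIConfig()
    if not train_sessions:
        raise ValueError("empty training session list")
    ids = [s.dataset_id for s in train_sessions + test_sessions]
    train_ids = [s.dataset_id for s in train_sessions]
    test_ids = [s.dataset_id for s in test_sessions]
    if len(set(train_ids)) != len(train_ids) or len(set(test_ids)) != len(test_ids):
        raise ValueError(f"dataset ids must be unique, got {ids}")
    test_tensors = {s.dataset_id: _epoch(s, cfg) for s in test_sessions}
    table = pd.DataFrame(index=test_ids, columns=train_ids, dtype=float)
    for tr in train_sessions:
        bci = train_bci(tr, config=cfg)
        for te in test_sessions:
            if te.dataset_id == tr.dataset_id:
                continue
            table.loc[te.dataset_id, tr.dataset_id] = bci.score_tensor(
                test_tensors[te.dataset_id])
    return table


def append_row_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Append per-test-dataset Avg and StDev columns (missing cells skipped)."""
    out = table.copy()
    out["Avg."] = table.mean(axis=1, skipna=True)
    out["StDev"] = table.std(axis=1, ddof=1, skipna=True)
    return out


def loocv_group(sessions: list[Session],
                config: BCIConfig | None = None) -> pd.Series:
    """Leave-one-out over a cohort: grouped BCI on all-but-one, test the rest."""
    cfg = config or BCIConfig()
    if len(sessions) < 3:
        raise ValueError("leave-one-out needs at least 3 sessions")
    tensors = [_epoch(s, cfg) for s in sessions]
    accs = {}
    for i, holdout in enumerate(sessions):
        rest = [t for j, t in enumerate(tensors) if j != i]
        bci = _fit_on_tensor(
            _concat(rest), cfg,
            {"train_ids": [s.dataset_id for j, s in enumerate(sessions) if j != i],
             "grouped": True})
        accs[holdout.dataset_id] = bci.score_tensor(tensors[i])
    return pd.Series(accs, name="accuracy")


def longitudinal(early: Session, late: Session,
                 config: BCIConfig | None = None) -> float:
    """Train on a subject's early session, test on the same subject's late one."""
    if early.subject_id != late.subject_id:
        raise ValueError(
            f"early/late sessions belong to different subjects: "
            f"{early.subject_id!r} vs {late.subject_id!r}")
    bci = train_bci(early, config=config)
    return test_bci(bci, late)


def band_histogram(selections: list[MarginalRelevanceSelector],
                   groups: list[str],
                   bands: tuple[tuple[float, float], ...] | None = None
                   ) -> pd.DataFrame:
    """Counts of the primary-pick frequency ranges per group.

    Only the n_top primary picks contribute (partners excluded), so each
    dataset adds exactly n_top counts; rows are groups, columns band labels.
    """
    if len(selections) != len(groups):
        raise ValueError("one group label per selection required")
    bands = bands or (selections[0].layout_ and None) or None
    n_bands = (max(b for sel in selections for b, _ in sel.layout_) + 1
               if selections else 0)
    if bands is None:
        from .preprocess import DEFAULT_BANDS
        bands = DEFAULT_BANDS[:n_bands] if n_bands else DEFAULT_BANDS
    labels = [f"{int(lo)}-{int(hi)}" for lo, hi in bands]
    group_order = list(dict.fromkeys(groups))
    counts = pd.DataFrame(0, index=group_order, columns=labels)
    for sel, grp in zip(selections, groups):
        for band in sel.primary_bands():
            counts.loc[grp, labels[band]] += 1
    return counts
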