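"""Sagittal mirroring, 9-band zero-phase filter bank, and trial epoching.

The filter bank covers 4-40 Hz in nine contiguous 4 Hz bands.  Each band is
a 4th-order Butterworth band-pass applied forward and backward
(``filtfilt``), so the net phase response is zero and waveform features are
not shifted in time; the magnitude response is consequently the square of
the single-pass design.  Recording edges are handled by ``filtfilt``'s
odd-reflection padding.  Filtering is applied to the continuous recording
before epoching, keeping filter transients outside the analysis windows.

Trials are windowed 2 s after each trial onset for 6 s, half-open in
samples: ``[onset + offset*fs, onset + (offset+duration)*fs)``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as _dc_replace

import numpy as np
from scipy import signal

from .montage import ChannelSet
from .simulate import Session

__all__ = [
    "FilterBankSpec",
    "EpochedBandTensor",
    "default_filter_bank",
    "mirror_channels",
    "apply_filter_bank",
    "epoch_trials",
    "preprocess_session",
]

DEFAULT_BANDS: tuple[tuple[float, float], ...] = tuple(
    (float(lo), float(lo + 4)) for lo in range(4, 40, 4)
)


@dataclass(frozen=True)
class FilterBankSpec:
    """Band edges (Hz), per-pass filter order, and the filter family."""

    bands: tuple[tuple[float, float], ...] = DEFAULT_BANDS
    order: int = 4
    design: str = "butter"

    def __post_init__(self) -> None:
        if self.order < 1:
            raise ValueError("filter order must be >= 1")
        if self.design != "butter":
            raise ValueError(f"unsupported filter design {self.design!r}")
        for lo, hi in self.bands:
            if not lo < hi:
                raise ValueError(f"band ({lo}, {hi}) has low >= high")


def default_filter_bank() -> FilterBankSpec:
    return FilterBankSpec()


@dataclass
class EpochedBandTensor:
    """Per-trial, per-band windowed EEG segments.

    ``segments`` has shape (trials, bands, channels, window samples);
    ``labels`` holds the per-trial class strings ``move``/``rest``.
    """

    segments: np.ndarray
    labels: np.ndarray
    bands: tuple[tuple[float, float], ...]
    window: tuple[float, float]
    fs: float
    channels: ChannelSet

    @property
    def n_trials(self) -> int:
        return self.segments.shape[0]

    @property
    def n_bands(self) -> int:
        return self.segments.shape[1]

    @property
    def n_channels(self) -> int:
        return self.segments.shape[2]

    def subset(self, idx) -> "EpochedBandTensor":
        """Trial subset (used by cross-validation fold construction)."""
        idx = np.asarray(idx)
        out = EpochedBandTensor(self.segments[idx], self.labels[idx],
                                self.bands, self.window, self.fs, self.channels)
        covs = getattr(self, "_covs", None)  # computed lazily downstream
        if covs is not None:
            out._covs = covs[idx]
        return out


def mirror_channels(session: Session) -> Session:
    """Fold a left-hand performer onto the right-hand convention.

    Left/right homologue channel rows are swapped and the hand relabelled
    ``right``; right-hand sessions pass through unchanged.
    """
    for name, mid in zip(session.channels.names, session.channels.midline_flags):
        if not mid and session.channels.mirror_label(name) == name:
            raise ValueError(f"channel {name!r} has no mirror pair and is not midline")
    if session.hand == "right":
        return session
    perm = session.channels.mirror_permutation()
    return _dc_replace(session, data=session.data[perm], hand="right")


def apply_filter_bank(data: np.ndarray, fs: float,
                      spec: FilterBankSpec | None = None) -> np.ndarray:
    """Filter a channels × samples recording into each band of the bank.

    Returns an array of shape (bands, channels, samples).  Zero-phase:
    forward-backward application of the band-pass design.
    """
    spec = spec or default_filter_bank()
    data = np.atleast_2d(np.asarray(data, float))
    out = np.empty((len(spec.bands),) + data.shape)
    for bi, (lo, hi) in enumerate(spec.bands):
        if fs <= 2.0 * hi:
            raise ValueError(
                f"sample rate {fs} Hz violates Nyquist for band {lo}-{hi} Hz")
        b, a = signal.butter(spec.order, [lo, hi], btype="bandpass", fs=fs)
        out[bi] = signal.filtfilt(b, a, data, axis=-1)
    return out


def epoch_trials(banded: np.ndarray, events: list[tuple[int, str]], fs: float,
                 offset_s: float = 2.0, duration_s: float = 6.0,
                 bands: tuple[tuple[float, float], ...] = DEFAULT_BANDS,
                 channels: ChannelSet | None = None) -> EpochedBandTensor:
    """Cut per-trial windows out of the band-filtered continuous signals."""
    banded = np.asarray(banded)
    if banded.ndim != 3:
        raise ValueError("banded must be (bands, channels, samples)")
    n_samples = banded.shape[-1]
    start_off = int(round(offset_s * fs))
    n_win = int(round(duration_s * fs))
    segs, labels = [], []
    for ti, (onset, label) in enumerate(events):
        lo = onset + start_off
        hi = lo + n_win
        if lo < 0 or hi > n_samples:
            raise ValueError(
                f"trial {ti} window [{lo}, {hi}) overruns the recording "
                f"of {n_samples} samples")
        segs.append(banded[:, :, lo:hi])
        labels.append(label)
    return EpochedBandTensor(
        segments=np.stack(segs), labels=np.array(labels),
        bands=tuple(bands), window=(offset_s, duration_s), fs=fs,
        channels=channels,
    )


def preprocess_session(session: Session, spec: FilterBankSpec | None = None,
                       offset_s: float = 2.0,
                       duration_s: float = 6.0) -> EpochedBandTensor:
    """Mirror (if left-handed) → filter bank → epoch, in that order."""
    spec = spec or default_filter_bank()
    session = mirror_channels(session)
    banded = apply_filter_bank(session.data, session.fs, spec)
    return epoch_trials(banded, session.events, session.fs, offset_s,
                        duration_s, spec.bands, session.channels)
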