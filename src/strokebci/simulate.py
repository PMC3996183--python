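"""Synthetic motor-task EEG cohorts with class-dependent band-power structure.

The generator emulates the statistical structure that a filter-bank CSP
analysis of a finger-tapping experiment relies on: a spatially mixed 1/f
background plus a narrow-band sensorimotor rhythm, lateralized over the
hand area contralateral to the performing hand, whose amplitude drops
during movement trials (event-related desynchronization, ERD).  Sessions
follow the alternating move/rest protocol: 20 + 20 trials of 10 s each,
move first, no inter-trial gap.

Three cohort profiles are provided.  ``healthy`` places the discriminative
rhythm in the beta range (16-24 Hz) over a C3-centred focus.  ``stroke_early``
moves the discriminative power down to 8-16 Hz with a shallower ERD, and
``stroke_late`` shifts it further toward low frequencies — mirroring the
observation that stroke-affected recordings favour CSP features in lower
frequency ranges, with the late session drifting relative to the early one.

Everything is driven by a single integer seed: identical profiles produce
bit-identical sessions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import signal

from .montage import ChannelSet, biosemi32

__all__ = [
    "CohortProfile",
    "Session",
    "make_profile",
    "drifted_profile",
    "generate_session",
    "generate_cohort",
    "save_session",
    "load_session",
]

GROUPS = ("healthy", "stroke_early", "stroke_late")

#: Spatial gain of the rhythm source over the right-hand motor area.
DEFAULT_FOCUS_WEIGHTS: dict[str, float] = {
    "C3": 1.0, "FC5": 0.4, "FC1": 0.4, "CP5": 0.4, "CP1": 0.4, "C4": 0.15,
}

#: Background model: 1/f^alpha source spectra, channel-space std in µV, and
#: rhythm-to-background amplitude ratio (within the ERD band, focus channel).
DEFAULT_NOISE_MODEL: dict[str, float] = {
    "alpha": 1.0, "background_std": 10.0, "rhythm_snr": 7.0,
}

_GROUP_DEFAULTS: dict[str, dict] = {
    # Beta-band ERD, deep modulation: the healthy sensorimotor stereotype.
    "healthy": {"erd_band": (16.0, 24.0), "erd_depth": 0.25},
    # Discriminative power shifted down to mu/low-beta, shallower ERD.
    "stroke_early": {"erd_band": (8.0, 16.0), "erd_depth": 0.35},
}


@dataclass(frozen=True)
class CohortProfile:
    """Generation parameters for one synthetic subject/session.

    ``erd_depth`` is the move/rest band-power ratio of the rhythm at the
    focus channels (1 means no class information).  ``session_drift`` is the
    fractional change applied to the ERD band centre (downward) and depth
    (upward, toward 1) when deriving a "late" session from this profile.
    """

    group: str = "healthy"
    n_trials_per_class: int = 20
    trial_length: float = 10.0
    fs: float = 256.0
    erd_band: tuple[float, float] = (16.0, 24.0)
    erd_depth: float = 0.25
    focus_weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_FOCUS_WEIGHTS))
    noise_model: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_NOISE_MODEL))
    session_drift: float = 0.25
    hand: str = "right"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.erd_depth <= 1.0:
            raise ValueError(f"erd_depth must be in (0, 1], got {self.erd_depth}")
        lo, hi = self.erd_band
        if not (4.0 <= lo < hi <= 40.0):
            raise ValueError(f"erd_band must lie within [4, 40] Hz, got {self.erd_band}")
        if self.n_trials_per_class < 1:
            raise ValueError("n_trials_per_class must be >= 1")
        if self.hand not in ("left", "right"):
            raise ValueError(f"hand must be 'left' or 'right', got {self.hand!r}")
        w = np.array(list(self.focus_weights.values()), float)
        if w.size == 0 or (w < 0).any() or not (w > 0).any():
            raise ValueError("focus_weights must be non-negative with a positive entry")


@dataclass
class Session:
    """One continuous multichannel recording with its trial events.

    ``data`` is channels × samples in µV, ``events`` a list of
    ``(onset_sample, label)`` with labels strictly alternating move/rest
    starting with move.
    """

    data: np.ndarray
    fs: float
    channels: ChannelSet
    events: list[tuple[int, str]]
    subject_id: str = "S0"
    dataset_id: str = "S0"
    group: str = "healthy"
    hand: str = "right"

    @property
    def labels(self) -> list[str]:
        return [lab for _, lab in self.events]

    def validate(self) -> None:
        if self.data.ndim != 2 or self.data.shape[0] != len(self.channels):
            raise ValueError("data must be channels x samples matching the channel set")
        onsets = [o for o, _ in self.events]
        if onsets != sorted(onsets):
            raise ValueError("events must be sorted by onset")
        for i, (_, lab) in enumerate(self.events):
            expect = "move" if i % 2 == 0 else "rest"
            if lab != expect:
                raise ValueError("labels must alternate move/rest starting with move")


def make_profile(group: str, overrides: dict | None = None, **kw) -> CohortProfile:
    """Build the default profile for a cohort group, with overrides.

    ``stroke_late`` is derived from ``stroke_early`` by applying the session
    drift, so the early → late relation of the generator is internally
    consistent.
    """
    overrides = {**(overrides or {}), **kw}
    unknown = set(overrides) - set(CohortProfile.__dataclass_fields__)
    if unknown:
        raise ValueError(f"unknown profile fields: {sorted(unknown)}")
    if group == "stroke_late":
        base = make_profile("stroke_early")
        prof = drifted_profile(replace(base, group="stroke_late"))
        return replace(prof, **overrides) if overrides else prof
    if group not in _GROUP_DEFAULTS:
        raise ValueError(f"unknown group {group!r}; valid groups: {GROUPS}")
    return CohortProfile(group=group, **{**_GROUP_DEFAULTS[group], **overrides})


def drifted_profile(profile: CohortProfile) -> CohortProfile:
    """Apply the between-session drift: band centre down, ERD shallower."""
    d = profile.session_drift
    lo, hi = profile.erd_band
    centre, half = (lo + hi) / 2.0, (hi - lo) / 2.0
    centre *= 1.0 - d
    lo_new = max(4.0, centre - half)
    hi_new = min(40.0, centre + half)
    depth = min(1.0, profile.erd_depth * (1.0 + d))
    return replace(profile, erd_band=(lo_new, hi_new), erd_depth=depth)


def _one_over_f_noise(rng: np.random.Generator, n_sources: int, n_samples: int,
                      fs: float, alpha: float) -> np.ndarray:
    """Unit-variance 1/f^alpha sources, spectrally shaped white noise."""
    white = rng.standard_normal((n_sources, n_samples))
    spec = np.fft.rfft(white, axis=1)
    f = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    shape = np.zeros_like(f)
    shape[1:] = f[1:] ** (-alpha / 2.0)
    out = np.fft.irfft(spec * shape, n=n_samples, axis=1)
    out /= out.std(axis=1, keepdims=True)
    return out


def generate_session(profile: CohortProfile, subject_id: str = "S0",
                     dataset_id: str | None = None) -> Session:
    """Generate one session from a profile; identical seeds are bit-identical."""
    lo, hi = profile.erd_band
    if profile.fs <= 2.0 * hi:
        raise ValueError(
            f"fs={profile.fs} too low for erd_band {profile.erd_band} (Nyquist)")
    channels = biosemi32()
    n_ch = len(channels)
    n_trials = 2 * profile.n_trials_per_class
    spt = int(round(profile.trial_length * profile.fs))  # samples per trial
    n_samples = n_trials * spt

    rng = np.random.default_rng(profile.seed)
    sources = _one_over_f_noise(rng, n_ch, n_samples, profile.fs,
                                profile.noise_model["alpha"])
    mix, _ = np.linalg.qr(rng.standard_normal((n_ch, n_ch)))
    background = profile.noise_model["background_std"] * (mix @ sources)

    # Narrow-band rhythm: band-limited Gaussian noise, unit variance.
    b, a = signal.butter(4, [lo, hi], btype="bandpass", fs=profile.fs)
    rhythm = signal.filtfilt(b, a, rng.standard_normal(n_samples))
    rhythm /= rhythm.std()

    # Spatial gain vector; left-hand performers get the mirrored focus.
    weights = np.zeros(n_ch)
    for name, w in profile.focus_weights.items():
        label = channels.mirror_label(name) if profile.hand == "left" else name
        weights[channels.index(label)] = w
    focus = int(np.argmax(weights))

    # Rhythm amplitude relative to the background's own power inside the band
    # at the focus channel, so erd_depth dominates the measured power ratio.
    bg_band = signal.filtfilt(b, a, background[focus])
    amplitude = profile.noise_model["rhythm_snr"] * bg_band.std()

    envelope = np.ones(n_samples)
    events: list[tuple[int, str]] = []
    for i in range(n_trials):
        label = "move" if i % 2 == 0 else "rest"
        onset = i * spt
        events.append((onset, label))
        if label == "move":
            envelope[onset:onset + spt] = np.sqrt(profile.erd_depth)

    data = background + np.outer(weights, amplitude * rhythm * envelope)
    session = Session(
        data=data, fs=profile.fs, channels=channels, events=events,
        subject_id=subject_id, dataset_id=dataset_id or subject_id,
        group=profile.group, hand=profile.hand,
    )
    session.validate()
    return session


def _derive_seed(*keys: int) -> int:
    return int(np.random.SeedSequence(list(keys)).generate_state(1)[0] % (2 ** 31))


def generate_cohort(
    groups: list[tuple[str, int, int]],
    overrides: dict | None = None,
) -> list[Session]:
    """Generate a cohort of sessions.

    ``groups`` is a list of ``(group, count, base_seed)`` with group either
    ``"healthy"`` (one session per subject, ids H1..) or ``"stroke"`` (an
    early and a late session per subject, ids S1E/S1L.., sharing a subject
    id, with the profile drift applied to the late session).
    """
    sessions: list[Session] = []
    for group, count, base_seed in groups:
        if count < 1:
            raise ValueError(f"count must be >= 1, got {count}")
        if group == "healthy":
            for k in range(count):
                prof = make_profile("healthy", overrides,
                                    seed=_derive_seed(base_seed, k))
                sid = f"H{k + 1}"
                sessions.append(generate_session(prof, sid, sid))
        elif group == "stroke":
            for k in range(count):
                early = make_profile("stroke_early", overrides,
                                     seed=_derive_seed(base_seed, k, 0))
                late = replace(
                    drifted_profile(replace(early, group="stroke_late")),
                    seed=_derive_seed(base_seed, k, 1))
                sid = f"S{k + 1}"
                sessions.append(generate_session(early, sid, f"{sid}E"))
                sessions.append(generate_session(late, sid, f"{sid}L"))
        else:
            raise ValueError(
                f"unknown cohort group {group!r}; valid: 'healthy', 'stroke'")
    return sessions


def save_session(session: Session, out_dir: str | Path) -> None:
    """Write ``<dataset_id>_data.csv`` (row per channel) + ``<id>_meta.json``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    np.savetxt(out_dir / f"{session.dataset_id}_data.csv", session.data,
               delimiter=",")
    meta = {
        "fs": session.fs,
        "channels": list(session.channels.names),
        "events": [[int(o), lab] for o, lab in session.events],
        "subject_id": session.subject_id,
        "dataset_id": session.dataset_id,
        "group": session.group,
        "hand": session.hand,
    }
    (out_dir / f"{session.dataset_id}_meta.json").write_text(
        json.dumps(meta, indent=1))


def load_session(out_dir: str | Path, dataset_id: str) -> Session:
    out_dir = Path(out_dir)
    meta = json.loads((out_dir / f"{dataset_id}_meta.json").read_text())
    data = np.loadtxt(out_dir / f"{dataset_id}_data.csv", delimiter=",")
    data = np.atleast_2d(data)
    channels = biosemi32()
    if list(channels.names) != meta["channels"]:
        raise ValueError("channel list in metadata does not match the montage")
    session = Session(
        data=data, fs=float(meta["fs"]), channels=channels,
        events=[(int(o), lab) for o, lab in meta["events"]],
        subject_id=meta["subject_id"], dataset_id=meta["dataset_id"],
        group=meta["group"], hand=meta["hand"],
    )
    session.validate()
    return session
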