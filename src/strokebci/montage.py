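"""10/20-system channel sets and left/right homologue bookkeeping.

The sagittal mirroring used to fold left-hand task performers onto the
right-hand convention needs, for every non-midline electrode, its homologue
in the opposite hemisphere (odd labels left, even labels right, ``z`` suffix
midline).  :class:`ChannelSet` carries that pair table and validates it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ChannelSet", "biosemi32"]

# Left/right homologues of the BioSemi 32-electrode 10/20 layout.
_BIOSEMI32_PAIRS: tuple[tuple[str, str], ...] = (
    ("Fp1", "Fp2"), ("AF3", "AF4"), ("F7", "F8"), ("F3", "F4"),
    ("FC1", "FC2"), ("FC5", "FC6"), ("T7", "T8"), ("C3", "C4"),
    ("CP1", "CP2"), ("CP5", "CP6"), ("P7", "P8"), ("P3", "P4"),
    ("PO3", "PO4"), ("O1", "O2"),
)

# Electrode order of the BioSemi ActiveTwo 32-channel cap (A1..A32).
_BIOSEMI32_NAMES: tuple[str, ...] = (
    "Fp1", "AF3", "F7", "F3", "FC1", "FC5", "T7", "C3",
    "CP1", "CP5", "P7", "P3", "Pz", "PO3", "O1", "Oz",
    "O2", "PO4", "P4", "P8", "CP6", "CP2", "C4", "T8",
    "FC6", "FC2", "F4", "F8", "AF4", "Fp2", "Fz", "Cz",
)


@dataclass(frozen=True)
class ChannelSet:
    """Ordered electrode labels plus the midline/mirror-pair structure.

    Parameters
    ----------
    names : tuple of str
        Channel labels in recording order.
    midline_flags : tuple of bool
        True for channels on the sagittal midline (``z`` suffix).
    mirror_pairs : tuple of (str, str)
        Left/right homologue label pairs.  Every non-midline channel must
        appear in exactly one pair.
    """

    names: tuple[str, ...]
    midline_flags: tuple[bool, ...]
    mirror_pairs: tuple[tuple[str, str], ...]
    _index: dict = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "_index", {n: i for i, n in enumerate(self.names)})
        if len(self.names) != len(set(self.names)):
            raise ValueError("duplicate channel labels")
        if len(self.midline_flags) != len(self.names):
            raise ValueError("midline_flags length mismatch")
        paired: list[str] = []
        for left, right in self.mirror_pairs:
            if left == right:
                raise ValueError(f"degenerate mirror pair ({left}, {right})")
            paired.extend((left, right))
        if len(paired) != len(set(paired)):
            raise ValueError("a channel appears in more than one mirror pair")
        for name, mid in zip(self.names, self.midline_flags):
            if not mid and name not in paired:
                raise ValueError(
                    f"channel {name!r} is neither midline nor in a mirror pair"
                )

    def __len__(self) -> int:
        return len(self.names)

    def index(self, name: str) -> int:
        return self._index[name]

    def mirror_permutation(self) -> np.ndarray:
        """Row permutation that swaps each channel with its homologue.

        Midline channels map to themselves; applying the permutation twice
        is the identity.
        """
        perm = np.arange(len(self.names))
        for left, right in self.mirror_pairs:
            li, ri = self._index[left], self._index[right]
            perm[li], perm[ri] = ri, li
        return perm

    def mirror_label(self, name: str) -> str:
        for left, right in self.mirror_pairs:
            if name == left:
                return right
            if name == right:
                return left
        return name


def biosemi32() -> ChannelSet:
    """The 32-channel BioSemi 10/20 cap with its standard homologue pairs."""
    midline = tuple(n.endswith("z") for n in _BIOSEMI32_NAMES)
    return ChannelSet(_BIOSEMI32_NAMES, midline, _BIOSEMI32_PAIRS)
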