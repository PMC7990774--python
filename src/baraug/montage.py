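"""10-20 montage parsing and hemisphere splitting.

The 10-20 naming convention encodes laterality in the label suffix: an odd
terminal digit marks a left-hemisphere electrode (C3, FC5, Fp1), an even one
a right-hemisphere electrode (C4, CP6, O2), and a terminal ``z`` the sagittal
midline (Fz, Cz, POz).  Brain-area recombination needs every channel on one
of exactly two sides, so midline electrodes are distributed alternately —
taken in montage order, the 1st, 3rd, 5th ... midline channel goes LEFT and
the 2nd, 4th ... goes RIGHT.  An explicit override table can replace the
automatic midline assignment.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from .epochs import EpochSet

__all__ = [
    "Side",
    "Montage",
    "HemisphereSplit",
    "HemiEpoch",
    "MontageError",
    "classify_label",
    "build_split",
    "halve",
    "recombine",
]


class MontageError(ValueError):
    """Raised for unparseable channel labels or inconsistent montages."""


class Side(Enum):
    LEFT = "left"
    RIGHT = "right"
    MIDLINE = "midline"


def classify_label(label: str) -> Side:
    """Classify a 10-20 channel label as LEFT, RIGHT, or MIDLINE.

    The terminal character decides: odd digit -> LEFT, even digit -> RIGHT,
    'z'/'Z' -> MIDLINE.  Labels with embedded digits (``AF7``, ``T10``)
    classify by the terminal digit.
    """
    label = label.strip()
    if not label:
        raise MontageError("empty channel label")
    last = label[-1]
    if last in ("z", "Z"):
        return Side.MIDLINE
    if last.isdigit():
        return Side.LEFT if int(last) % 2 == 1 else Side.RIGHT
    raise MontageError(f"cannot classify channel label {label!r}: no terminal digit or 'z'")


@dataclass(frozen=True)
class Montage:
    """Ordered, unique channel labels defining the canonical channel order."""

    channel_names: tuple[str, ...]

    def __init__(self, channel_names) -> None:
        names = tuple(str(c) for c in channel_names)
        if not names:
            raise MontageError("montage must contain at least one channel")
        if len(set(names)) != len(names):
            raise MontageError("channel labels must be unique")
        object.__setattr__(self, "channel_names", names)

    @property
    def n_channels(self) -> int:
        return len(self.channel_names)

    def sides(self) -> list[Side]:
        return [classify_label(c) for c in self.channel_names]


@dataclass(frozen=True)
class HemisphereSplit:
    """Disjoint index sets assigning every channel to LEFT or RIGHT.

    Both index tuples preserve the montage's internal order; together they
    are a permutation of ``0..C-1``.
    """

    left_indices: tuple[int, ...]
    right_indices: tuple[int, ...]

    def __post_init__(self) -> None:
        left, right = set(self.left_indices), set(self.right_indices)
        if left & right:
            raise MontageError("left and right index sets overlap")
        n = len(self.left_indices) + len(self.right_indices)
        if left | right != set(range(n)):
            raise MontageError("left and right indices must partition 0..C-1")

    @property
    def n_channels(self) -> int:
        return len(self.left_indices) + len(self.right_indices)


@dataclass
class HemiEpoch:
    """One hemisphere's channels of a single trial."""

    values: np.ndarray  # (side channels, samples)
    side: Side
    source_trial: int
    label: int

    def __post_init__(self) -> None:
        if self.values.ndim != 2:
            raise MontageError("HemiEpoch values must be 2-D (channels, samples)")
        if self.side is Side.MIDLINE:
            raise MontageError("a HemiEpoch is LEFT or RIGHT, never MIDLINE")


def build_split(
    montage: Montage,
    midline_override: dict[str, Side] | None = None,
) -> HemisphereSplit:
    """Partition a montage's channels into left and right index sets.

    Lateral channels are assigned by terminal-digit parity.  Midline
    channels, taken in montage order, alternate LEFT, RIGHT, LEFT, ... unless
    ``midline_override`` maps specific labels to a side explicitly.
    """
    override = {k: v for k, v in (midline_override or {}).items()}
    left: list[int] = []
    right: list[int] = []
    midline_count = 0
    for i, name in enumerate(montage.channel_names):
        side = classify_label(name)
        if side is Side.MIDLINE:
            if name in override:
                side = override[name]
                if side is Side.MIDLINE:
                    raise MontageError(f"override for {name!r} must be LEFT or RIGHT")
            else:
                side = Side.LEFT if midline_count % 2 == 0 else Side.RIGHT
            midline_count += 1
        (left if side is Side.LEFT else right).append(i)
    return HemisphereSplit(tuple(left), tuple(right))


def halve(epochs: EpochSet, split: HemisphereSplit) -> tuple[list[HemiEpoch], list[HemiEpoch]]:
    """Split every trial into its left and right hemisphere channel blocks."""
    if split.n_channels != epochs.n_channels:
        raise MontageError(
            f"split covers {split.n_channels} channels but epochs have {epochs.n_channels}"
        )
    li = np.asarray(split.left_indices)
    ri = np.asarray(split.right_indices)
    lefts = [
        HemiEpoch(epochs.data[t, li, :], Side.LEFT, int(epochs.trial_ids[t]), int(epochs.labels[t]))
        for t in range(epochs.n_trials)
    ]
    rights = [
        HemiEpoch(epochs.data[t, ri, :], Side.RIGHT, int(epochs.trial_ids[t]), int(epochs.labels[t]))
        for t in range(epochs.n_trials)
    ]
    return lefts, rights


def recombine(
    right: HemiEpoch,
    left: HemiEpoch,
    split: HemisphereSplit,
    check_labels: bool = True,
) -> np.ndarray:
    """Scatter a right and a left half back into original montage order.

    The output is a ``channels x samples`` trial whose rows at
    ``split.right_indices`` come from ``right`` and rows at
    ``split.left_indices`` from ``left`` — not a stacked [R; L] block, so
    spatially-aware consumers see a consistent channel layout.
    """
    if right.side is not Side.RIGHT or left.side is not Side.LEFT:
        raise MontageError("recombine expects (right=RIGHT half, left=LEFT half)")
    if right.values.shape[1] != left.values.shape[1]:
        raise MontageError("sample counts of the two halves differ")
    if right.values.shape[0] != len(split.right_indices):
        raise MontageError("right half channel count does not match the split")
    if left.values.shape[0] != len(split.left_indices):
        raise MontageError("left half channel count does not match the split")
    if check_labels and right.label != left.label:
        raise MontageError(
            f"label mismatch: right half has class {right.label}, left half {left.label}"
        )
    n_samples = right.values.shape[1]
    out = np.empty((split.n_channels, n_samples), dtype=np.result_type(right.values, left.values))
    out[np.asarray(split.right_indices), :] = right.values
    out[np.asarray(split.left_indices), :] = left.values
    return out
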