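"""Synthetic two-class motor-imagery EEG with lateralized ERD.

Each trial is white Gaussian background noise on every channel plus two
band-limited oscillatory sources — one per hemisphere — projected onto that
hemisphere's lateral channels through a fixed topography peaking over the
motor strip (C3/C4).  Imagining one hand attenuates the *contralateral*
hemisphere's oscillation amplitude by ``1 - erd_depth``, emulating
event-related desynchronization of the mu rhythm.  The oscillation is
band-passed Gaussian noise rather than a sinusoid, so trial-to-trial phase
varies while per-trial source variance is held at one.

The two hemisphere sources are conditionally independent given the class,
and the per-subject channel-mixing perturbation is block-diagonal within
each hemisphere (midline channels untouched), so left and right channel
blocks remain independent given the class.  That is the idealization under
which hemispheric recombination produces exact draws from the original
class-conditional distribution — a deliberate gap between this generator
and real EEG, where inter-hemispheric coupling exists.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .epochs import EpochSet
from .montage import Montage, Side, classify_label

__all__ = ["DEFAULT_CHANNELS", "GeneratorParams", "GroundTruth", "make_subject", "make_cohort"]

# 14-channel 10-20 subset: 12 lateral (6 per hemisphere) + 2 midline.
DEFAULT_CHANNELS = (
    "F3", "F4", "FC3", "FC4", "C3", "C4",
    "CP3", "CP4", "P3", "P4", "O1", "O2",
    "Fz", "Pz",
)

_FILTER_PAD = 300  # samples discarded to let the band-pass transient die out


@dataclass(frozen=True)
class GeneratorParams:
    """Study conditions for the synthetic generator.

    erd_depth is the fractional amplitude attenuation of the contralateral
    oscillatory source (0 = no class signal); background_noise_sd sets the
    white-noise floor per channel relative to the unit-variance sources;
    subject_mixing_sd scales the per-subject within-hemisphere channel
    mixing perturbation (identity + N(0, sd)).
    """

    montage: Montage = field(default_factory=lambda: Montage(DEFAULT_CHANNELS))
    fs: float = 100.0
    duration_s: float = 2.5
    n_trials_per_class: int = 100
    erd_depth: float = 0.6
    oscillation_band: tuple[float, float] = (8.0, 12.0)
    background_noise_sd: float = 0.5
    subject_mixing_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.erd_depth < 1.0:
            raise ValueError("erd_depth must lie in [0, 1)")
        lo, hi = self.oscillation_band
        if not 0 < lo < hi < self.fs / 2:
            raise ValueError(f"oscillation band {self.oscillation_band} invalid for fs={self.fs}")
        if self.n_trials_per_class < 1:
            raise ValueError("n_trials_per_class must be >= 1")

    @property
    def n_samples(self) -> int:
        return round(self.fs * self.duration_s)


@dataclass
class GroundTruth:
    """What was planted: topographies, attenuation targets, mixing matrix.

    ``topographies[side]`` is the effective (post-mixing) full-montage
    projection vector of that hemisphere's source; ``attenuated_channels``
    maps each class label to the channel indices whose oscillation it
    attenuates (contralateral to the imagined hand).
    """

    topographies: dict[Side, np.ndarray]
    attenuated_channels: dict[int, tuple[int, ...]]
    mixing_matrix: np.ndarray
    class_names: tuple[str, str] = ("left_hand", "right_hand")


def _hemisphere_indices(montage: Montage) -> tuple[list[int], list[int], list[int]]:
    left, right, mid = [], [], []
    for i, name in enumerate(montage.channel_names):
        side = classify_label(name)
        (left if side is Side.LEFT else right if side is Side.RIGHT else mid).append(i)
    return left, right, mid


def _topography_weight(label: str) -> float:
    """Source loading by electrode site: peaks over the motor strip."""
    stem = label.rstrip("0123456789").rstrip("zZ")
    return {"C": 1.0, "CP": 0.7, "FC": 0.7}.get(stem, 0.25)


def _base_topographies(montage: Montage) -> dict[Side, np.ndarray]:
    left, right, _ = _hemisphere_indices(montage)
    topo = {}
    for side, idx in ((Side.LEFT, left), (Side.RIGHT, right)):
        v = np.zeros(montage.n_channels)
        for i in idx:
            v[i] = _topography_weight(montage.channel_names[i])
        topo[side] = v
    return topo


def _mixing_matrix(montage: Montage, sd: float, rng: np.random.Generator) -> np.ndarray:
    """Identity + per-hemisphere perturbation; midline rows stay identity."""
    left, right, _ = _hemisphere_indices(montage)
    a = np.eye(montage.n_channels)
    for idx in (left, right):
        if sd > 0 and len(idx) > 0:
            block = np.ix_(idx, idx)
            a[block] = a[block] + rng.normal(0.0, sd, size=(len(idx), len(idx)))
    return a


def _band_noise(
    shape: tuple[int, ...], band: tuple[float, float], fs: float, rng: np.random.Generator
) -> np.ndarray:
    """Unit-variance band-limited Gaussian noise along the last axis."""
    n = shape[-1]
    raw = rng.standard_normal(shape[:-1] + (n + _FILTER_PAD,))
    sos = signal.butter(4, band, btype="bandpass", fs=fs, output="sos")
    filt = signal.sosfilt(sos, raw, axis=-1)[..., _FILTER_PAD:]
    sd = filt.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return filt / sd


def make_subject(
    params: GeneratorParams,
    subject: int = 0,
    seed: int | None = None,
) -> tuple[EpochSet, GroundTruth]:
    """Generate one subject's balanced two-class epoch set plus ground truth.

    Class 0 ("left hand" imagery) attenuates the RIGHT hemisphere source by
    ``1 - erd_depth``; class 1 attenuates the LEFT.  Same seed, same output,
    bit for bit.
    """
    rng = np.random.default_rng(params.seed if seed is None else seed)
    montage = params.montage
    left, right, _ = _hemisphere_indices(montage)
    if not left or not right:
        raise ValueError("montage must have lateral channels on both hemispheres")
    c, t = montage.n_channels, params.n_samples
    n_per = params.n_trials_per_class
    n = 2 * n_per

    mixing = _mixing_matrix(montage, params.subject_mixing_sd, rng)
    base = _base_topographies(montage)
    topo_mixed = {s: mixing @ v for s, v in base.items()}

    labels = rng.permutation(np.repeat([0, 1], n_per))
    # gain per (trial, hemisphere): class 0 attenuates RIGHT, class 1 LEFT
    att = 1.0 - params.erd_depth
    gain_l = np.where(labels == 1, att, 1.0)
    gain_r = np.where(labels == 0, att, 1.0)

    src = _band_noise((n, 2, t), params.oscillation_band, params.fs, rng)
    background = rng.normal(0.0, params.background_noise_sd, size=(n, c, t))

    clean = (
        base[Side.LEFT][None, :, None] * (gain_l[:, None, None] * src[:, 0:1, :])
        + base[Side.RIGHT][None, :, None] * (gain_r[:, None, None] * src[:, 1:2, :])
        + background
    )
    data = np.einsum("cd,nds->ncs", mixing, clean)

    epochs = EpochSet(
        data=data,
        labels=labels,
        channel_names=montage.channel_names,
        fs=params.fs,
        subject=subject,
    )
    truth = GroundTruth(
        topographies=topo_mixed,
        attenuated_channels={0: tuple(right), 1: tuple(left)},
        mixing_matrix=mixing,
    )
    return epochs, truth


def make_cohort(
    n_subjects: int,
    params: GeneratorParams,
) -> list[tuple[EpochSet, GroundTruth]]:
    """Generate a cohort sharing topographies but with per-subject mixing.

    Per-subject seeds are spawned deterministically from ``params.seed``;
    subjects differ in their mixing matrices and trial noise only.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    children = np.random.SeedSequence(params.seed).spawn(n_subjects)
    out = []
    for s, child in enumerate(children):
        sub_seed = int(child.generate_state(1)[0] % (2**31))
        out.append(make_subject(params, subject=s, seed=sub_seed))
    return out
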