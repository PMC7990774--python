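"""Data augmentation for motor-imagery EEG.

Three augmenters:

* **Brain-area recombination (BAR)** — split every trial into its left- and
  right-hemisphere channel blocks and take, per class, the cartesian product
  of right halves with left halves.  A class with ``n`` trials yields ``n**2``
  recombined trials, ``n`` of which are identity pairs reproducing the
  originals.  :func:`bar_intra` recombines within one subject;
  :func:`bar_multi` recombines across all source subjects while excluding
  every half that originates from the target subject, producing a
  cross-subject pre-training set.
* **Time flipping** — append a time-reversed copy of every trial (exact
  doubling; preserves the power spectrum magnitude).
* **SNR-controlled Gaussian noise** — append noisy copies whose per-trial
  linear power ratio signal/noise is enforced exactly (default 5).  Version 1
  matches flipping's expansion ratio (2n); version 2 resamples sources with
  replacement until a caller-chosen target size (typically the matching BAR
  size) is reached.

Every generated trial carries a provenance record naming its source subject
and trial for both hemisphere blocks, which the evaluation layer uses for
train/test leakage audits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .epochs import EpochSet
from .montage import HemisphereSplit, MontageError

__all__ = [
    "Provenance",
    "AugmentedSet",
    "NoiseConfig",
    "bar_intra",
    "bar_multi",
    "flip_time",
    "add_noise",
]


@dataclass(frozen=True)
class Provenance:
    """Where one augmented trial came from.

    ``right_source`` / ``left_source`` are ``(subject, trial_id)`` pairs for
    the hemisphere blocks; for whole-trial augmenters (flip, noise) both
    point at the same source trial.
    """

    method: str
    right_source: tuple[int, int]
    left_source: tuple[int, int]
    label: int
    is_original: bool


@dataclass
class AugmentedSet:
    """An augmented :class:`~baraug.epochs.EpochSet` plus per-trial provenance."""

    epochs: EpochSet
    provenance: list[Provenance] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.provenance) != self.epochs.n_trials:
            raise ValueError("one provenance record per trial required")

    @property
    def n_trials(self) -> int:
        return self.epochs.n_trials

    def source_trial_ids(self) -> set[tuple[int, int]]:
        """All (subject, trial_id) pairs any generated trial draws on."""
        out: set[tuple[int, int]] = set()
        for p in self.provenance:
            out.add(p.right_source)
            out.add(p.left_source)
        return out

    def provenance_table(self):
        """Provenance as a tidy :class:`pandas.DataFrame`."""
        import pandas as pd

        return pd.DataFrame(
            {
                "trial": np.arange(self.n_trials),
                "method": [p.method for p in self.provenance],
                "right_subject": [p.right_source[0] for p in self.provenance],
                "right_trial": [p.right_source[1] for p in self.provenance],
                "left_subject": [p.left_source[0] for p in self.provenance],
                "left_trial": [p.left_source[1] for p in self.provenance],
                "label": [p.label for p in self.provenance],
                "is_original": [p.is_original for p in self.provenance],
            }
        )


@dataclass(frozen=True)
class NoiseConfig:
    """Configuration for the noise-added augmenter.

    ``snr`` is a linear power ratio var(signal)/var(noise) by default
    (``db=True`` reinterprets it in decibels).  ``mode`` 'v1' doubles the
    set; 'v2' draws sources with replacement until ``target_size`` trials.
    """

    snr: float = 5.0
    mode: str = "v1"
    target_size: int | None = None
    seed: int = 0
    db: bool = False

    def __post_init__(self) -> None:
        if self.snr <= 0:
            raise ValueError("snr must be positive")
        if self.mode not in ("v1", "v2"):
            raise ValueError(f"mode must be 'v1' or 'v2', got {self.mode!r}")
        if self.mode == "v2" and self.target_size is None:
            raise ValueError("mode 'v2' requires target_size")

    @property
    def linear_snr(self) -> float:
        return 10.0 ** (self.snr / 10.0) if self.db else self.snr


def _check_split(epochs: EpochSet, split: HemisphereSplit) -> None:
    if split.n_channels != epochs.n_channels:
        raise MontageError(
            f"split covers {split.n_channels} channels but epochs have {epochs.n_channels}"
        )


def _subject_of(epochs: EpochSet) -> int:
    return epochs.subject if epochs.subject is not None else 0


def _recombine_pairs(
    pooled_data: np.ndarray,
    pairs: list[tuple[int, int]],
    split: HemisphereSplit,
) -> np.ndarray:
    """Materialize recombined trials for (right_pos, left_pos) index pairs."""
    ri = np.asarray(split.right_indices)
    i_idx = np.fromiter((p[0] for p in pairs), dtype=int, count=len(pairs))
    j_idx = np.fromiter((p[1] for p in pairs), dtype=int, count=len(pairs))
    out = pooled_data[j_idx].copy()  # left rows from j ...
    out[:, ri, :] = pooled_data[i_idx][:, ri, :]  # ... right rows from i
    return out


def _select_pairs(
    n: int,
    max_pairs: int | None,
    rng: np.random.Generator,
) -> list[tuple[int, int]]:
    """Ordered (right, left) position pairs for one class's n x n product.

    Pairs are enumerated in (right index, left index) order for determinism.
    Subsampling keeps every identity pair (i, i) and draws the remainder
    uniformly without replacement from the off-diagonal pairs.
    """
    if max_pairs is None or max_pairs >= n * n:
        return [(i, j) for i in range(n) for j in range(n)]
    if max_pairs < n:
        raise ValueError(f"max_pairs_per_class={max_pairs} cannot retain all {n} identity pairs")
    off_diag = [(i, j) for i in range(n) for j in range(n) if i != j]
    take = max_pairs - n
    chosen = rng.choice(len(off_diag), size=take, replace=False)
    pairs = [(i, i) for i in range(n)] + [off_diag[c] for c in sorted(chosen)]
    pairs.sort()
    return pairs


def bar_intra(
    epochs: EpochSet,
    split: HemisphereSplit,
    max_pairs_per_class: int | None = None,
    seed: int = 0,
) -> AugmentedSet:
    """Within-subject brain-area recombination.

    Per class, every right hemisphere half is paired with every left half of
    the same class (identity pairs included, so the originals are a subset
    of the output).  Output order is (class, right index, left index).
    """
    _check_split(epochs, split)
    rng = np.random.default_rng(seed)
    subj = _subject_of(epochs)
    classes = epochs.classes
    if classes.size == 0:
        raise ValueError("empty epoch set")

    blocks: list[np.ndarray] = []
    labels: list[np.ndarray] = []
    prov: list[Provenance] = []
    for c in classes:
        pos = epochs.class_indices(int(c))
        if pos.size == 0:
            raise ValueError(f"class {c} has no trials")
        pairs = _select_pairs(pos.size, max_pairs_per_class, rng)
        cls_data = epochs.data[pos]
        blocks.append(_recombine_pairs(cls_data, pairs, split))
        labels.append(np.full(len(pairs), c))
        ids = epochs.trial_ids[pos]
        for i, j in pairs:
            prov.append(
                Provenance(
                    method="bar",
                    right_source=(subj, int(ids[i])),
                    left_source=(subj, int(ids[j])),
                    label=int(c),
                    is_original=(i == j),
                )
            )
    out = EpochSet(
        data=np.concatenate(blocks, axis=0),
        labels=np.concatenate(labels),
        channel_names=epochs.channel_names,
        fs=epochs.fs,
        subject=epochs.subject,
    )
    return AugmentedSet(out, prov)


def bar_multi(
    subject_sets: list[EpochSet],
    excluded_subject: int,
    split: HemisphereSplit,
    max_pairs_per_class: int | None = None,
    seed: int = 0,
    allow_same_source: bool = True,
) -> AugmentedSet:
    """Cross-subject brain-area recombination for a pre-training set.

    Pools every source subject's halves (all subjects except
    ``excluded_subject``) and takes the per-class right x left product over
    the pooled halves — the union over all ordered source-subject pairs
    (i, j), i != target, j != target, with i = j allowed unless
    ``allow_same_source=False``.  No hemisphere block of any output trial
    originates from the excluded (target) subject.
    """
    if len(subject_sets) < 2:
        raise ValueError("bar_multi needs at least 2 subjects")
    if not 0 <= excluded_subject < len(subject_sets):
        raise ValueError(f"excluded_subject {excluded_subject} out of range")
    sources = [s for k, s in enumerate(subject_sets) if k != excluded_subject]
    ref = sources[0]
    for s in sources[1:]:
        if s.channel_names != ref.channel_names or s.fs != ref.fs:
            raise ValueError("all subjects must share montage and sampling rate")
    _check_split(ref, split)
    rng = np.random.default_rng(seed)

    pooled = np.concatenate([s.data for s in sources], axis=0)
    pooled_labels = np.concatenate([s.labels for s in sources])
    pooled_subj = np.concatenate(
        [np.full(s.n_trials, _subject_of(s)) for s in sources]
    )
    pooled_ids = np.concatenate([s.trial_ids for s in sources])

    classes = np.unique(pooled_labels)
    blocks: list[np.ndarray] = []
    labels: list[np.ndarray] = []
    prov: list[Provenance] = []
    for c in classes:
        pos = np.flatnonzero(pooled_labels == c)
        if pos.size == 0:
            raise ValueError(f"class {c} has no trials among the source subjects")
        pairs = _select_pairs(pos.size, max_pairs_per_class, rng)
        if not allow_same_source:
            pairs = [(i, j) for i, j in pairs if pooled_subj[pos[i]] != pooled_subj[pos[j]]]
            if not pairs:
                raise ValueError("no cross-subject pairs remain with allow_same_source=False")
        cls_data = pooled[pos]
        blocks.append(_recombine_pairs(cls_data, pairs, split))
        labels.append(np.full(len(pairs), c))
        for i, j in pairs:
            gi, gj = pos[i], pos[j]
            prov.append(
                Provenance(
                    method="bar-multi",
                    right_source=(int(pooled_subj[gi]), int(pooled_ids[gi])),
                    left_source=(int(pooled_subj[gj]), int(pooled_ids[gj])),
                    label=int(c),
                    is_original=(gi == gj),
                )
            )
    out = EpochSet(
        data=np.concatenate(blocks, axis=0),
        labels=np.concatenate(labels),
        channel_names=ref.channel_names,
        fs=ref.fs,
    )
    return AugmentedSet(out, prov)


def flip_time(epochs: EpochSet) -> AugmentedSet:
    """Append a time-reversed copy of every trial (exact doubling)."""
    if epochs.n_trials == 0:
        raise ValueError("empty epoch set")
    subj = _subject_of(epochs)
    flipped = epochs.data[:, :, ::-1].copy()
    out = EpochSet(
        data=np.concatenate([epochs.data, flipped], axis=0),
        labels=np.concatenate([epochs.labels, epochs.labels]),
        channel_names=epochs.channel_names,
        fs=epochs.fs,
        subject=epochs.subject,
    )
    prov = [
        Provenance("flip", (subj, int(t)), (subj, int(t)), int(l), True)
        for t, l in zip(epochs.trial_ids, epochs.labels)
    ] + [
        Provenance("flip", (subj, int(t)), (subj, int(t)), int(l), False)
        for t, l in zip(epochs.trial_ids, epochs.labels)
    ]
    return AugmentedSet(out, prov)


def _noisy_copy(trial: np.ndarray, snr: float, rng: np.random.Generator) -> np.ndarray:
    """Trial + Gaussian noise rescaled so var(trial)/var(noise) == snr exactly."""
    noise = rng.standard_normal(trial.shape)
    p_sig = float(np.var(trial))
    p_noise = float(np.var(noise))
    if p_sig == 0.0 or p_noise == 0.0:
        raise ValueError("cannot set an SNR on a zero-variance trial")
    noise *= np.sqrt(p_sig / (snr * p_noise))
    noise -= noise.mean()  # keep var == power after scaling
    return trial + noise


def add_noise(epochs: EpochSet, cfg: NoiseConfig) -> AugmentedSet:
    """Append Gaussian-noise copies at an exactly enforced per-trial SNR.

    Version 1 adds one noisy copy per original (size 2n, flipping's
    expansion ratio).  Version 2 draws source trials uniformly with
    replacement until ``cfg.target_size`` total trials — callers set this to
    the matching BAR output size for like-for-like comparisons.
    """
    if epochs.n_trials == 0:
        raise ValueError("empty epoch set")
    rng = np.random.default_rng(cfg.seed)
    subj = _subject_of(epochs)
    snr = cfg.linear_snr
    n = epochs.n_trials
    if cfg.mode == "v1":
        sources = np.arange(n)
    else:
        assert cfg.target_size is not None
        if cfg.target_size < n:
            raise ValueError(f"target_size {cfg.target_size} is smaller than the original set ({n})")
        sources = rng.integers(0, n, size=cfg.target_size - n)
    gen = np.stack([_noisy_copy(epochs.data[s], snr, rng) for s in sources]) if sources.size else np.empty((0,) + epochs.data.shape[1:])
    out = EpochSet(
        data=np.concatenate([epochs.data, gen], axis=0),
        labels=np.concatenate([epochs.labels, epochs.labels[sources]]),
        channel_names=epochs.channel_names,
        fs=epochs.fs,
        subject=epochs.subject,
    )
    prov = [
        Provenance("noise", (subj, int(t)), (subj, int(t)), int(l), True)
        for t, l in zip(epochs.trial_ids, epochs.labels)
    ] + [
        Provenance(
            "noise",
            (subj, int(epochs.trial_ids[s])),
            (subj, int(epochs.trial_ids[s])),
            int(epochs.labels[s]),
            False,
        )
        for s in sources
    ]
    return AugmentedSet(out, prov)
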