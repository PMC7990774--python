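"""Experiment schemas: intra-subject (IS) and adaptive-subject (AS).

The IS schema trains a fresh classifier per (subject, training-set size,
repeat) on a class-balanced, seeded subsample of the subject's training
pool, optionally augmented, and scores it on the subject's untouched test
set.  The AS schema adds a pre-training stage: the classifier is first
trained on a cross-subject set built from the *other* subjects (for
recombination, the multi-subject variant, which by construction contains no
half-trial from the target), then warm-started on the target subject's own
(augmented) subset before testing.

Augmentation only ever sees the sampled training subset; provenance records
make that auditable, and :meth:`ExperimentResult.assert_no_leakage` checks
it structurally for every record.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Protocol, runtime_checkable

import numpy as np
import pandas as pd
from scipy import stats

from .augment import AugmentedSet, NoiseConfig, Provenance, add_noise, bar_intra, bar_multi, flip_time
from .epochs import EpochSet
from .montage import HemisphereSplit

__all__ = [
    "ClassifierContract",
    "DeepTrainingConfig",
    "MajorityClassifier",
    "AugmenterSpec",
    "ExperimentConfig",
    "SubjectData",
    "ExperimentResult",
    "ZeroVarianceError",
    "split_pool",
    "run_is",
    "run_as",
    "paired_t_test",
]


@runtime_checkable
class ClassifierContract(Protocol):
    """What the schemas require of a classifier.

    ``fit(trials, labels)`` trains from scratch; ``fit(..., warm_start=True)``
    continues from the existing state (required by the AS schema's
    fine-tuning stage).  ``supports_warm_start`` advertises the capability.
    """

    supports_warm_start: bool

    def fit(self, trials: np.ndarray, labels: np.ndarray, warm_start: bool = False): ...

    def predict(self, trials: np.ndarray) -> np.ndarray: ...


@dataclass(frozen=True)
class DeepTrainingConfig:
    """Default training hyperparameters for a user-supplied deep plug-in."""

    epochs: int = 60
    batch_size: int = 16
    optimizer: str = "adam"
    learning_rate: float = 0.001
    beta1: float = 0.9
    beta2: float = 0.999


@dataclass
class MajorityClassifier:
    """Degenerate baseline predicting the most frequent training label."""

    supports_warm_start: bool = True
    _label: int | None = None

    def fit(self, trials, labels, warm_start: bool = False):
        vals, counts = np.unique(np.asarray(labels), return_counts=True)
        self._label = int(vals[np.argmax(counts)])
        return self

    def predict(self, trials):
        if self._label is None:
            raise ValueError("not fitted")
        return np.full(np.asarray(trials).shape[0], self._label)


@dataclass(frozen=True)
class AugmenterSpec:
    """Which augmenter a run uses, with its parameters.

    method: 'none' | 'bar' | 'flip' | 'noise'.  For 'noise',
    ``noise_mode`` 'v1' doubles the set and 'v2' matches the recombination
    output size.  ``max_pairs_per_class`` caps the recombination product.
    """

    method: str = "none"
    snr: float = 5.0
    noise_mode: str = "v1"
    max_pairs_per_class: int | None = None
    allow_same_source: bool = True

    def __post_init__(self) -> None:
        if self.method not in ("none", "bar", "flip", "noise"):
            raise ValueError(f"unknown augmenter {self.method!r}")


@dataclass(frozen=True)
class ExperimentConfig:
    schema: str  # 'IS' | 'AS'
    augmenter: AugmenterSpec = field(default_factory=AugmenterSpec)
    classifier: Callable[[], ClassifierContract] = MajorityClassifier
    sizes: tuple[int, ...] = tuple(range(10, 101, 10))
    n_repeats: int = 10
    seed: int = 0
    skip_pretrain: bool = False  # AS only: degenerate to stage 2

    def __post_init__(self) -> None:
        if self.schema not in ("IS", "AS"):
            raise ValueError("schema must be 'IS' or 'AS'")
        if any(s <= 0 for s in self.sizes):
            raise ValueError("training-set sizes must be positive")


@dataclass
class SubjectData:
    """One subject's disjoint training pool and held-out test set."""

    subject: int
    pool: EpochSet
    test: EpochSet


def split_pool(epochs: EpochSet, n_pool: int = 100, seed: int = 0) -> SubjectData:
    """Randomly reserve a class-balanced training pool; the rest is the test set."""
    rng = np.random.default_rng(seed)
    classes = epochs.classes
    per = n_pool // classes.size
    if per * classes.size != n_pool:
        raise ValueError(f"n_pool={n_pool} not divisible by {classes.size} classes")
    pool_idx = []
    for c in classes:
        pos = epochs.class_indices(int(c))
        if pos.size < per:
            raise ValueError(f"class {c} has only {pos.size} trials, need {per} for the pool")
        pool_idx.append(rng.choice(pos, size=per, replace=False))
    pool_idx = np.sort(np.concatenate(pool_idx))
    test_idx = np.setdiff1d(np.arange(epochs.n_trials), pool_idx)
    subj = epochs.subject if epochs.subject is not None else 0
    return SubjectData(subject=subj, pool=epochs.subset(pool_idx), test=epochs.subset(test_idx))


@dataclass
class AuditEntry:
    subject: int
    size: int
    repeat: int
    source_ids: frozenset  # (subject, trial_id) pairs feeding augmentation
    test_ids: frozenset  # (subject, trial_id) pairs of the scored test set


@dataclass
class ExperimentResult:
    """Tidy accuracy records plus the provenance audit trail."""

    records: pd.DataFrame
    config: ExperimentConfig
    audit: list[AuditEntry] = field(default_factory=list)

    def per_subject_mean(self) -> pd.Series:
        """Final per-subject accuracy: mean over all sizes and repeats."""
        return self.records.groupby("subject")["accuracy"].mean()

    def per_size_mean(self) -> pd.Series:
        return self.records.groupby("size")["accuracy"].mean()

    def assert_no_leakage(self) -> None:
        """Check structurally that no augmentation source was a test trial."""
        for e in self.audit:
            overlap = e.source_ids & e.test_ids
            if overlap:
                raise AssertionError(
                    f"leakage: subject {e.subject}, size {e.size}, repeat {e.repeat} "
                    f"used test trials {sorted(overlap)[:5]} as augmentation sources"
                )


class ZeroVarianceError(ValueError):
    """Paired differences have zero variance; the t statistic is undefined."""


def paired_t_test(acc_a: np.ndarray, acc_b: np.ndarray) -> tuple[float, float]:
    """Classical paired-sample t-test on per-subject accuracy means.

    Returns (t, two-sided p) with n-1 degrees of freedom.  Zero-variance
    differences raise :class:`ZeroVarianceError` rather than returning a
    silent p-value.
    """
    a = np.asarray(acc_a, dtype=float)
    b = np.asarray(acc_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ValueError("need two equal-length 1-D samples with at least 2 pairs")
    d = a - b
    if np.allclose(d, d[0]):
        raise ZeroVarianceError("paired differences are constant; t statistic undefined")
    res = stats.ttest_rel(a, b)
    return float(res.statistic), float(res.pvalue)


def _rng_for(cfg: ExperimentConfig, *key: int) -> np.random.Generator:
    """Fresh generator for one experimental cell, derived from the master seed."""
    return np.random.default_rng(np.random.SeedSequence(cfg.seed, spawn_key=tuple(key)))


def _balanced_subset(pool: EpochSet, size: int, rng: np.random.Generator) -> EpochSet:
    classes = pool.classes
    per = size // classes.size
    if per * classes.size != size or per < 1:
        raise ValueError(f"size {size} cannot be balanced over {classes.size} classes")
    idx = []
    for c in classes:
        pos = pool.class_indices(int(c))
        if pos.size < per:
            raise ValueError(f"class {c}: pool has {pos.size} trials, subset needs {per}")
        idx.append(rng.choice(pos, size=per, replace=False))
    return pool.subset(np.sort(np.concatenate(idx)))


def _originals_provenance(epochs: EpochSet, method: str = "none") -> list[Provenance]:
    subj = epochs.subject if epochs.subject is not None else 0
    return [
        Provenance(method, (subj, int(t)), (subj, int(t)), int(l), True)
        for t, l in zip(epochs.trial_ids, epochs.labels)
    ]


def _bar_target_size(labels: np.ndarray) -> int:
    _, counts = np.unique(labels, return_counts=True)
    return int(np.sum(counts**2))


def _augment_intra(
    subset: EpochSet, spec: AugmenterSpec, split: HemisphereSplit | None, seed: int
) -> AugmentedSet:
    if spec.method == "none":
        return AugmentedSet(subset.copy(), _originals_provenance(subset))
    if spec.method == "flip":
        return flip_time(subset)
    if spec.method == "noise":
        target = _bar_target_size(subset.labels) if spec.noise_mode == "v2" else None
        cfg = NoiseConfig(snr=spec.snr, mode=spec.noise_mode, target_size=target, seed=seed)
        return add_noise(subset, cfg)
    if split is None:
        raise ValueError("recombination requires a hemisphere split")
    return bar_intra(subset, split, max_pairs_per_class=spec.max_pairs_per_class, seed=seed)


_ID_STRIDE = 1_000_000  # disambiguates (subject, trial) pairs inside a pooled set


def _augment_multi(
    subsets: list[EpochSet], target: int, spec: AugmenterSpec, split: HemisphereSplit | None, seed: int
) -> AugmentedSet:
    """Stage-1 cross-subject set: BAR-multi, or the mixed-pool variants."""
    if spec.method == "bar":
        if split is None:
            raise ValueError("recombination requires a hemisphere split")
        return bar_multi(
            subsets,
            excluded_subject=_position_of(subsets, target),
            split=split,
            max_pairs_per_class=spec.max_pairs_per_class,
            seed=seed,
            allow_same_source=spec.allow_same_source,
        )

    sources = [s for s in subsets if s.subject != target]
    mixed = EpochSet(
        data=np.concatenate([s.data for s in sources], axis=0),
        labels=np.concatenate([s.labels for s in sources]),
        channel_names=sources[0].channel_names,
        fs=sources[0].fs,
        # encode (subject, trial) into a single id so pooled ids stay unique
        trial_ids=np.concatenate(
            [(s.subject or 0) * _ID_STRIDE + s.trial_ids for s in sources]
        ),
    )
    mixed_prov = []
    for s in sources:
        mixed_prov.extend(_originals_provenance(s))
    if spec.method == "none":
        return AugmentedSet(mixed, mixed_prov)
    if spec.method == "flip":
        flipped = EpochSet(
            data=np.concatenate([mixed.data, mixed.data[:, :, ::-1]], axis=0),
            labels=np.concatenate([mixed.labels, mixed.labels]),
            channel_names=mixed.channel_names,
            fs=mixed.fs,
        )
        mixed_prov = [replace(p, method="flip") for p in mixed_prov]
        gen = [replace(p, is_original=False) for p in mixed_prov]
        return AugmentedSet(flipped, mixed_prov + gen)
    # noise on the mixed pool
    if spec.noise_mode == "v2":
        cfg = NoiseConfig(
            snr=spec.snr, mode="v2", target_size=_bar_target_size(mixed.labels), seed=seed
        )
    else:
        cfg = NoiseConfig(snr=spec.snr, mode="v1", seed=seed)
    aug = add_noise(mixed, cfg)
    fixed = [
        replace(
            p,
            right_source=_decode_id(p.right_source[1]),
            left_source=_decode_id(p.left_source[1]),
        )
        for p in aug.provenance
    ]
    return AugmentedSet(aug.epochs, fixed)


def _decode_id(encoded: int) -> tuple[int, int]:
    return encoded // _ID_STRIDE, encoded % _ID_STRIDE


def _position_of(subsets: list[EpochSet], subject: int) -> int:
    for k, s in enumerate(subsets):
        if s.subject == subject:
            return k
    raise ValueError(f"subject {subject} not among the provided sets")


def _ids(epochs: EpochSet) -> frozenset:
    subj = epochs.subject if epochs.subject is not None else 0
    return frozenset((subj, int(t)) for t in epochs.trial_ids)


def run_is(
    subjects: list[SubjectData],
    cfg: ExperimentConfig,
    split: HemisphereSplit | None = None,
) -> ExperimentResult:
    """Intra-subject schema: train on own (augmented) subsets, test held out.

    Emits one accuracy record per (subject, size, repeat).  Augmentation is
    re-applied per repeat on the fresh subset; test trials never enter it.
    """
    rows = []
    audit: list[AuditEntry] = []
    for si, sd in enumerate(subjects):
        for zi, size in enumerate(cfg.sizes):
            for rep in range(cfg.n_repeats):
                rng = _rng_for(cfg, si, zi, rep)
                sub_seed = int(rng.integers(0, 2**31))
                subset = _balanced_subset(sd.pool, size, rng)
                aug = _augment_intra(subset, cfg.augmenter, split, sub_seed)
                clf = cfg.classifier()
                clf.fit(aug.epochs.data, aug.epochs.labels)
                acc = float(np.mean(clf.predict(sd.test.data) == sd.test.labels))
                rows.append(
                    dict(
                        subject=sd.subject,
                        schema="IS",
                        augmenter=cfg.augmenter.method,
                        size=size,
                        repeat=rep,
                        accuracy=acc,
                    )
                )
                audit.append(
                    AuditEntry(sd.subject, size, rep, frozenset(aug.source_trial_ids()), _ids(sd.test))
                )
    return ExperimentResult(pd.DataFrame(rows), cfg, audit)


def run_as(
    subjects: list[SubjectData],
    cfg: ExperimentConfig,
    split: HemisphereSplit | None = None,
) -> ExperimentResult:
    """Adaptive-subject schema: cross-subject pre-training, then fine-tuning.

    Stage 1 builds the multi-subject augmented set from equal-size subsets
    of every *other* subject and trains from scratch; stage 2 warm-starts on
    the target's own augmented subset; scoring is on the target's held-out
    test set.  ``cfg.skip_pretrain`` degenerates to the IS schema.
    """
    if len(subjects) < 2 and not cfg.skip_pretrain:
        raise ValueError("AS schema needs at least 2 subjects")
    rows = []
    audit: list[AuditEntry] = []
    for si, sd in enumerate(subjects):
        for zi, size in enumerate(cfg.sizes):
            for rep in range(cfg.n_repeats):
                rng = _rng_for(cfg, si, zi, rep)
                sub_seed = int(rng.integers(0, 2**31))
                subset = _balanced_subset(sd.pool, size, rng)
                sources: set[tuple[int, int]] = set()
                clf = cfg.classifier()
                warm = False
                if not cfg.skip_pretrain:
                    if not getattr(clf, "supports_warm_start", False):
                        raise ValueError(
                            f"{type(clf).__name__} does not support warm_start; "
                            "the AS schema's fine-tuning stage requires it"
                        )
                    src_subsets = []
                    for oj, other in enumerate(subjects):
                        if other.subject == sd.subject:
                            continue
                        o_rng = _rng_for(cfg, si, zi, rep, oj)
                        src_subsets.append(_balanced_subset(other.pool, size, o_rng))
                    # target's own (possibly empty-slot) set must be present for bar_multi indexing
                    all_sets = src_subsets + [subset]
                    pre = _augment_multi(all_sets, sd.subject, cfg.augmenter, split, sub_seed)
                    assert all(
                        p.right_source[0] != sd.subject and p.left_source[0] != sd.subject
                        for p in pre.provenance
                    ), "pre-training set contains target-subject material"
                    clf.fit(pre.epochs.data, pre.epochs.labels)
                    sources |= pre.source_trial_ids()
                    warm = True
                aug = _augment_intra(subset, cfg.augmenter, split, sub_seed + 1)
                clf.fit(aug.epochs.data, aug.epochs.labels, warm_start=warm)
                sources |= aug.source_trial_ids()
                acc = float(np.mean(clf.predict(sd.test.data) == sd.test.labels))
                rows.append(
                    dict(
                        subject=sd.subject,
                        schema="AS",
                        augmenter=cfg.augmenter.method,
                        size=size,
                        repeat=rep,
                        accuracy=acc,
                    )
                )
                audit.append(AuditEntry(sd.subject, size, rep, frozenset(sources), _ids(sd.test)))
    return ExperimentResult(pd.DataFrame(rows), cfg, audit)
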