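"""Recombination, flipping, and noise augmenters: cardinality, fidelity, SNR."""

import numpy as np
import pytest

from baraug import (
    EpochSet,
    NoiseConfig,
    add_noise,
    bar_intra,
    bar_multi,
    build_split,
    flip_time,
    Montage,
)

from conftest import random_epochs


def test_bar_intra_cardinality_and_identity_pairs(epochs10, split4):
    aug = bar_intra(epochs10, split4)
    assert aug.n_trials == 2 * 10**2
    assert sum(p.is_original for p in aug.provenance) == 2 * 10


def test_bar_intra_single_trial_per_class_is_identity(split4, rng):
    es = random_epochs(rng, n_per_class=1)
    aug = bar_intra(es, split4)
    assert aug.n_trials == 2
    # output ordered by (class, right, left); with one trial per class that is the input order
    np.testing.assert_array_equal(aug.epochs.data, es.data)


def test_bar_intra_blocks_match_sources_bruteforce(epochs10, split4):
    """Every generated trial's hemispheric rows equal its recorded sources exactly."""
    aug = bar_intra(epochs10, split4)
    li = np.asarray(split4.left_indices)
    ri = np.asarray(split4.right_indices)
    by_id = {int(t): k for k, t in enumerate(epochs10.trial_ids)}
    for t, p in enumerate(aug.provenance):
        i = by_id[p.right_source[1]]
        j = by_id[p.left_source[1]]
        np.testing.assert_array_equal(aug.epochs.data[t][ri], epochs10.data[i][ri])
        np.testing.assert_array_equal(aug.epochs.data[t][li], epochs10.data[j][li])
        assert p.label == epochs10.labels[i] == epochs10.labels[j]
        assert aug.epochs.labels[t] == p.label


def test_bar_intra_marginal_conservation(epochs10, split4):
    """Each right half appears exactly n_c times among one class's outputs."""
    aug = bar_intra(epochs10, split4)
    ri = np.asarray(split4.right_indices)
    for c in (0, 1):
        orig_hashes = [
            epochs10.data[t][ri].tobytes() for t in epochs10.class_indices(c)
        ]
        gen_hashes = [
            aug.epochs.data[t][ri].tobytes()
            for t in range(aug.n_trials)
            if aug.epochs.labels[t] == c
        ]
        for h in orig_hashes:
            assert gen_hashes.count(h) == 10


def test_bar_intra_subsample_keeps_identities(epochs10, split4):
    aug = bar_intra(epochs10, split4, max_pairs_per_class=30, seed=7)
    assert aug.n_trials == 60
    assert sum(p.is_original for p in aug.provenance) == 20
    again = bar_intra(epochs10, split4, max_pairs_per_class=30, seed=7)
    np.testing.assert_array_equal(aug.epochs.data, again.epochs.data)
    with pytest.raises(ValueError):
        bar_intra(epochs10, split4, max_pairs_per_class=5)


def test_bar_intra_missing_class_rejected(split4, rng):
    es = random_epochs(rng, n_per_class=3)
    with pytest.raises(ValueError):
        bar_intra(es.subset(np.arange(0, 0)), split4)


def test_bar_intra_split_mismatch_rejected(rng):
    es = random_epochs(rng, n_per_class=2, n_channels=4)
    wrong = build_split(Montage(("C3", "C4")))
    with pytest.raises(Exception):
        bar_intra(es, wrong)


def _cohort(rng, n_subjects=4, n_per_class=10):
    return [random_epochs(rng, n_per_class=n_per_class, subject=s) for s in range(n_subjects)]


def test_bar_multi_cardinality(split4, rng):
    sets = _cohort(rng)
    aug = bar_multi(sets, excluded_subject=0, split=split4)
    assert aug.n_trials == 2 * (3 * 10) ** 2


def test_bar_multi_excludes_target_provenance(split4, rng):
    sets = _cohort(rng)
    aug = bar_multi(sets, excluded_subject=2, split=split4)
    for p in aug.provenance:
        assert p.right_source[0] != 2
        assert p.left_source[0] != 2


def test_bar_multi_two_subjects_degenerates_to_intra(split4, rng):
    sets = _cohort(rng, n_subjects=2, n_per_class=4)
    multi = bar_multi(sets, excluded_subject=0, split=split4)
    intra = bar_intra(sets[1], split4)
    np.testing.assert_array_equal(multi.epochs.data, intra.epochs.data)
    np.testing.assert_array_equal(multi.epochs.labels, intra.epochs.labels)


def test_bar_multi_duplicate_free_triples(split4, rng):
    sets = _cohort(rng, n_subjects=3, n_per_class=4)
    aug = bar_multi(sets, excluded_subject=0, split=split4)
    triples = {(p.right_source, p.left_source, p.label) for p in aug.provenance}
    assert len(triples) == aug.n_trials


def test_bar_multi_cross_only_flag(split4, rng):
    sets = _cohort(rng, n_subjects=3, n_per_class=4)
    aug = bar_multi(sets, excluded_subject=0, split=split4, allow_same_source=False)
    for p in aug.provenance:
        assert p.right_source[0] != p.left_source[0]
    # (2*4)^2 minus 2 * 4^2 same-subject pairs, per class
    assert aug.n_trials == 2 * (64 - 32)


def test_bar_multi_single_subject_rejected(split4, rng):
    with pytest.raises(ValueError):
        bar_multi([random_epochs(rng, subject=0)], excluded_subject=0, split=split4)


def test_flip_doubles_and_reverses(epochs10):
    aug = flip_time(epochs10)
    assert aug.n_trials == 2 * epochs10.n_trials
    np.testing.assert_array_equal(aug.epochs.data[: epochs10.n_trials], epochs10.data)
    np.testing.assert_array_equal(
        aug.epochs.data[epochs10.n_trials :], epochs10.data[:, :, ::-1]
    )
    np.testing.assert_array_equal(aug.epochs.labels, np.tile(epochs10.labels, 2))


def test_flip_row_example():
    es = EpochSet(np.array([[[1.0, 2.0, 3.0]]]), np.array([0]), ("C3",), 100.0)
    aug = flip_time(es)
    np.testing.assert_array_equal(aug.epochs.data[1, 0], [3.0, 2.0, 1.0])


def test_flip_is_involution(epochs10):
    once = flip_time(epochs10)
    generated = once.epochs.subset(np.arange(epochs10.n_trials, once.n_trials))
    twice = flip_time(generated)
    np.testing.assert_array_equal(
        twice.epochs.data[generated.n_trials :], epochs10.data
    )


def test_flip_preserves_power_spectrum(epochs10):
    """Time reversal conjugates the spectrum; magnitudes are identical."""
    aug = flip_time(epochs10)
    orig = np.abs(np.fft.rfft(epochs10.data, axis=-1))
    flip = np.abs(np.fft.rfft(aug.epochs.data[epochs10.n_trials :], axis=-1))
    np.testing.assert_allclose(flip, orig, rtol=1e-9, atol=1e-12)


def test_noise_snr_enforced_exactly(epochs10):
    aug = add_noise(epochs10, NoiseConfig(snr=5.0, seed=3))
    n = epochs10.n_trials
    for t in range(n):
        noise = aug.epochs.data[n + t] - epochs10.data[t]
        ratio = np.var(epochs10.data[t]) / np.var(noise)
        assert ratio == pytest.approx(5.0, abs=1e-9)


def test_noise_v1_doubles(rng):
    es = random_epochs(rng, n_per_class=20)
    assert add_noise(es, NoiseConfig(seed=0)).n_trials == 80


def test_noise_v2_matches_target(epochs10):
    target = 2 * 10**2
    aug = add_noise(epochs10, NoiseConfig(mode="v2", target_size=target, seed=1))
    assert aug.n_trials == target
    with pytest.raises(ValueError):
        add_noise(epochs10, NoiseConfig(mode="v2", target_size=5, seed=1))


def test_noise_seed_reproducibility(epochs10):
    a = add_noise(epochs10, NoiseConfig(seed=11))
    b = add_noise(epochs10, NoiseConfig(seed=11))
    c = add_noise(epochs10, NoiseConfig(seed=12))
    np.testing.assert_array_equal(a.epochs.data, b.epochs.data)
    assert not np.array_equal(a.epochs.data, c.epochs.data)


def test_noise_db_interpretation(epochs10):
    aug = add_noise(epochs10, NoiseConfig(snr=10.0, db=True, seed=0))
    n = epochs10.n_trials
    noise = aug.epochs.data[n] - epochs10.data[0]
    assert np.var(epochs10.data[0]) / np.var(noise) == pytest.approx(10.0, abs=1e-9)


@pytest.mark.parametrize("method", ["bar", "flip", "noise"])
def test_label_conservation_and_ratios(method, epochs10, split4):
    if method == "bar":
        aug = bar_intra(epochs10, split4)
        expected = {0: 100, 1: 100}
    elif method == "flip":
        aug = flip_time(epochs10)
        expected = {0: 20, 1: 20}
    else:
        aug = add_noise(epochs10, NoiseConfig(seed=0))
        expected = {0: 20, 1: 20}
    vals, counts = np.unique(aug.epochs.labels, return_counts=True)
    assert dict(zip(vals.tolist(), counts.tolist())) == expected
    for p in aug.provenance:
        assert p.label in (0, 1)
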