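"""Common Spatial Patterns and the CSP-SVM baseline classifier.

CSP seeks spatial filters ``w`` extremizing the Rayleigh quotient
``J(w) = w' C1 w / w' C2 w`` of the two class covariance matrices.  With the
normalization ``w' C2 w = 1`` the stationary points satisfy the generalized
eigenproblem ``C1 w = lambda C2 w``; the filters most expressive for class 1
are the eigenvectors of the k largest eigenvalues, and swapping numerator
and denominator gives the class-2 filters.  Features are the log of the
normalized variance of each spatially filtered signal; the reference
classifier is an SVM on those 2k features.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg
from sklearn.svm import SVC

__all__ = [
    "CovarianceMode",
    "ClassCovariance",
    "SpatialFilterBank",
    "class_covariance",
    "fit_csp",
    "csp_features",
    "CSPSVMBaseline",
]

POOLED = "pooled"
AVERAGED_TRACE_NORM = "avg_trace_norm"
CovarianceMode = str


@dataclass(frozen=True)
class ClassCovariance:
    """Channel covariance of one class's trials.

    POOLED sums ``X X'`` over trials (the textbook pooled form);
    AVERAGED_TRACE_NORM averages per-trial trace-normalized covariances,
    which is robust to inter-trial amplitude drift.
    """

    matrix: np.ndarray
    class_id: int
    pooling_mode: CovarianceMode
    n_trials: int


@dataclass
class SpatialFilterBank:
    """2k spatial filters with eigenvalues and class attribution.

    Columns ``0..k-1`` solve the class-1 problem (``w' C2 w = 1``), columns
    ``k..2k-1`` the swapped class-2 problem (``w' C1 w = 1``); each block's
    eigenvalues are sorted descending.  The largest-magnitude entry of every
    filter is made positive to fix the sign indeterminacy.
    """

    filters: np.ndarray  # (C, 2k)
    eigenvalues: np.ndarray  # (2k,)
    class_of_filter: list[int]
    k: int

    @property
    def n_channels(self) -> int:
        return self.filters.shape[0]


def class_covariance(
    trials: np.ndarray,
    class_id: int = 0,
    mode: CovarianceMode = AVERAGED_TRACE_NORM,
) -> ClassCovariance:
    """Estimate a class covariance from a stack of (channels x samples) trials."""
    trials = np.asarray(trials, dtype=float)
    if trials.ndim != 3 or trials.shape[0] < 1:
        raise ValueError("need a non-empty (trials, channels, samples) stack")
    covs = np.einsum("tcs,tds->tcd", trials, trials)
    if mode == POOLED:
        mat = covs.sum(axis=0)
        if np.trace(mat) <= 0:
            raise ValueError("degenerate (zero-variance) covariance")
    elif mode == AVERAGED_TRACE_NORM:
        traces = np.trace(covs, axis1=1, axis2=2)
        if np.any(traces <= 0):
            raise ValueError("degenerate trial with zero variance")
        mat = (covs / traces[:, None, None]).mean(axis=0)
    else:
        raise ValueError(f"unknown covariance mode {mode!r}")
    mat = (mat + mat.T) / 2.0
    return ClassCovariance(matrix=mat, class_id=class_id, pooling_mode=mode, n_trials=trials.shape[0])


def _as_matrix(c) -> np.ndarray:
    return c.matrix if isinstance(c, ClassCovariance) else np.asarray(c, dtype=float)


def _check_psd(mat: np.ndarray, name: str) -> None:
    if not np.allclose(mat, mat.T, atol=1e-10 * max(1.0, float(np.abs(mat).max()))):
        raise ValueError(f"{name} is not symmetric")
    w = linalg.eigvalsh(mat)
    if w[0] < -1e-10 * max(1.0, w[-1]):
        raise ValueError(f"{name} is not positive semidefinite (min eigenvalue {w[0]:.3e})")


def _regularize(mat: np.ndarray, reg: float) -> np.ndarray:
    c = mat.shape[0]
    return mat + reg * (np.trace(mat) / c) * np.eye(c)


def _solve_block(num: np.ndarray, den: np.ndarray, k: int, reg: float) -> tuple[np.ndarray, np.ndarray]:
    """Top-k generalized eigenpairs of (num, den + ridge), descending.

    ``scipy.linalg.eigh`` returns B-orthonormal eigenvectors, so every
    column already satisfies w' den_reg w = 1.
    """
    vals, vecs = linalg.eigh(num, _regularize(den, reg))
    order = np.argsort(-vals, kind="stable")[:k]
    return vals[order], vecs[:, order]


def fit_csp(
    c1: ClassCovariance | np.ndarray,
    c2: ClassCovariance | np.ndarray,
    k: int = 3,
    reg: float = 1e-6,
) -> SpatialFilterBank:
    """Solve the two-class CSP generalized eigenproblem.

    Class-1 filters are the eigenvectors of the ``k`` largest eigenvalues of
    ``(C1, C2)``; class-2 filters solve the swapped problem ``(C2, C1)``.
    ``reg`` is a ridge fraction of the mean eigenvalue added to the
    denominator matrix before inversion, guarding rank deficiency at small
    trial counts.
    """
    m1, m2 = _as_matrix(c1), _as_matrix(c2)
    if m1.shape != m2.shape or m1.shape[0] != m1.shape[1]:
        raise ValueError("covariance matrices must be square and of equal size")
    c = m1.shape[0]
    if k < 1 or k > c // 2:
        raise ValueError(f"k={k} must satisfy 1 <= k <= C/2 = {c // 2}")
    _check_psd(m1, "C1")
    _check_psd(m2, "C2")

    ev1, w1 = _solve_block(m1, m2, k, reg)
    ev2, w2 = _solve_block(m2, m1, k, reg)
    filters = np.concatenate([w1, w2], axis=1)
    # sign convention: largest-magnitude entry positive
    peaks = np.argmax(np.abs(filters), axis=0)
    signs = np.sign(filters[peaks, np.arange(filters.shape[1])])
    signs[signs == 0] = 1.0
    filters = filters * signs
    return SpatialFilterBank(
        filters=filters,
        eigenvalues=np.concatenate([ev1, ev2]),
        class_of_filter=[1] * k + [2] * k,
        k=k,
    )


def csp_features(epochs: np.ndarray, bank: SpatialFilterBank) -> np.ndarray:
    """Log normalized variance of each spatially filtered signal.

    Accepts a single (channels x samples) epoch or a (trials x channels x
    samples) stack; returns a length-2k vector or an (n, 2k) matrix.
    Features are invariant to a global rescaling of the epoch.
    """
    x = np.asarray(epochs, dtype=float)
    single = x.ndim == 2
    if single:
        x = x[None]
    if x.shape[1] != bank.n_channels:
        raise ValueError(f"epoch has {x.shape[1]} channels, filter bank expects {bank.n_channels}")
    filtered = np.einsum("cf,tcs->tfs", bank.filters, x)
    v = filtered.var(axis=2)
    tot = v.sum(axis=1, keepdims=True)
    if np.any(tot <= 0):
        raise ValueError("zero total variance; cannot form CSP features")
    feats = np.log(v / tot)
    return feats[0] if single else feats


@dataclass
class CSPSVMBaseline:
    """CSP feature extraction followed by an SVM — the classical MI-EEG decoder.

    ``fit`` estimates the per-class covariances, solves the CSP problem, and
    trains the SVM on log-variance features.  A warm-started ``fit`` pools
    the previously fitted class covariances with the new data's (weighted by
    trial counts) before re-solving, so a pre-training stage carries over
    into fine-tuning; the SVM is refit on the fine-tuning features.
    """

    k: int = 3
    kernel: str = "rbf"
    C: float = 1.0
    cov_mode: CovarianceMode = AVERAGED_TRACE_NORM
    reg: float = 1e-6
    bank: SpatialFilterBank | None = field(default=None, repr=False)
    _svm: SVC | None = field(default=None, repr=False)
    _covs: dict[int, ClassCovariance] | None = field(default=None, repr=False)
    _classes: tuple[int, int] | None = field(default=None, repr=False)

    supports_warm_start: bool = True

    def fit(self, trials: np.ndarray, labels: np.ndarray, warm_start: bool = False) -> "CSPSVMBaseline":
        trials = np.asarray(trials, dtype=float)
        labels = np.asarray(labels)
        classes = np.unique(labels)
        if classes.size != 2:
            raise ValueError(f"CSP baseline is two-class; got classes {classes.tolist()}")
        covs = {
            int(c): class_covariance(trials[labels == c], int(c), self.cov_mode)
            for c in classes
        }
        if warm_start:
            if self._covs is None:
                raise ValueError("warm_start requested but the model has never been fitted")
            covs = {c: self._pool(self._covs[c], covs[c]) for c in covs}
        self._covs = covs
        self._classes = (int(classes[0]), int(classes[1]))
        self.bank = fit_csp(covs[self._classes[0]], covs[self._classes[1]], k=self.k, reg=self.reg)
        feats = csp_features(trials, self.bank)
        self._svm = SVC(kernel=self.kernel, C=self.C)
        self._svm.fit(feats, labels)
        return self

    @staticmethod
    def _pool(a: ClassCovariance, b: ClassCovariance) -> ClassCovariance:
        if a.pooling_mode != b.pooling_mode:
            raise ValueError("cannot pool covariances of different modes")
        if a.pooling_mode == POOLED:
            mat = a.matrix + b.matrix
        else:
            wa, wb = a.n_trials, b.n_trials
            mat = (wa * a.matrix + wb * b.matrix) / (wa + wb)
        return ClassCovariance(mat, a.class_id, a.pooling_mode, a.n_trials + b.n_trials)

    def predict(self, trials: np.ndarray) -> np.ndarray:
        if self._svm is None or self.bank is None:
            raise ValueError("model not fitted")
        return self._svm.predict(csp_features(np.asarray(trials, dtype=float), self.bank))

    def score(self, trials: np.ndarray, labels: np.ndarray) -> float:
        return float(np.mean(self.predict(trials) == np.asarray(labels)))
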