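"""Band-pass filtering and marker-based epoching.

Motor-imagery pipelines conventionally keep the 8–30 Hz band (mu and beta
rhythms, where event-related desynchronization lives) and cut fixed windows
relative to the cue markers.  The defaults here are a 5th-order Butterworth
band-pass at [8, 30] Hz and a [0, 2.5] s epoch window.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal

from .epochs import EpochSet
from .montage import Montage

__all__ = [
    "FilterSpec",
    "ContinuousRecording",
    "design_bandpass",
    "apply_filter",
    "extract_epochs",
]


@dataclass(frozen=True)
class FilterSpec:
    """A designed digital band-pass filter.

    ``sos`` (second-order sections) is the numerically stable realization
    used for application; ``b``/``a`` expose the equivalent rational
    transfer function.  The contract is on the magnitude response: -3 dB
    (1/sqrt(2)) at both cut-offs, maximally flat passband.
    """

    order: int
    low_hz: float
    high_hz: float
    fs: float
    sos: np.ndarray
    b: np.ndarray
    a: np.ndarray

    def response(self, freqs_hz: np.ndarray) -> np.ndarray:
        """Complex frequency response sampled at the given frequencies."""
        _, h = signal.sosfreqz(self.sos, worN=np.asarray(freqs_hz, dtype=float), fs=self.fs)
        return h


@dataclass
class ContinuousRecording:
    """Continuous multichannel EEG with cue markers.

    ``markers`` is a list of ``(sample_index, class_label)`` pairs; every
    marker index must lie within the recording.
    """

    values: np.ndarray  # (channels, samples)
    fs: float
    montage: Montage
    markers: list[tuple[int, int]]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("continuous values must be 2-D (channels, samples)")
        if self.values.shape[0] != self.montage.n_channels:
            raise ValueError("channel count does not match montage")
        n = self.values.shape[1]
        for k, (idx, _) in enumerate(self.markers):
            if not 0 <= idx < n:
                raise ValueError(f"marker {k} at sample {idx} lies outside the recording (length {n})")


def design_bandpass(low_hz: float, high_hz: float, order: int = 5, fs: float = 100.0) -> FilterSpec:
    """Design a Butterworth band-pass filter.

    The digital design (bilinear transform with prewarping) places the
    -3 dB points exactly at ``low_hz`` and ``high_hz``.
    """
    if not 0 < low_hz < high_hz:
        raise ValueError("need 0 < low_hz < high_hz")
    if high_hz >= fs / 2:
        raise ValueError(f"high cut-off {high_hz} Hz must be below Nyquist ({fs / 2} Hz)")
    if order < 1:
        raise ValueError("order must be positive")
    sos = signal.butter(order, [low_hz, high_hz], btype="bandpass", fs=fs, output="sos")
    b, a = signal.butter(order, [low_hz, high_hz], btype="bandpass", fs=fs, output="ba")
    return FilterSpec(order=order, low_hz=low_hz, high_hz=high_hz, fs=fs, sos=sos, b=b, a=a)


def apply_filter(
    data: ContinuousRecording | EpochSet,
    spec: FilterSpec,
    zero_phase: bool = False,
):
    """Filter every channel independently along the time axis.

    Default is causal single-pass application, so the effective order equals
    the designed order; ``zero_phase=True`` switches to forward-backward
    filtering (zero phase, squared magnitude response).
    """
    if data.fs != spec.fs:
        raise ValueError(f"data at {data.fs} Hz but filter designed for {spec.fs} Hz")
    filt = signal.sosfiltfilt if zero_phase else signal.sosfilt
    if isinstance(data, ContinuousRecording):
        return ContinuousRecording(
            values=np.ascontiguousarray(filt(spec.sos, data.values, axis=-1)),
            fs=data.fs,
            montage=data.montage,
            markers=list(data.markers),
        )
    if isinstance(data, EpochSet):
        return replace(data, data=np.ascontiguousarray(filt(spec.sos, data.data, axis=-1)))
    raise TypeError(f"cannot filter object of type {type(data).__name__}")


def extract_epochs(rec: ContinuousRecording, window_s: tuple[float, float]) -> EpochSet:
    """Cut one epoch per marker from a continuous recording.

    The window is half-open in samples: ``[round(start*fs), round(end*fs))``
    relative to each marker, so epoch length is ``round((end-start)*fs)``
    regardless of the marker position.
    """
    start_s, end_s = window_s
    off0 = round(start_s * rec.fs)
    off1 = round(end_s * rec.fs)
    n_samp = off1 - off0
    if n_samp <= 0:
        raise ValueError(f"window {window_s} yields an empty epoch")
    n_total = rec.values.shape[1]
    trials = np.empty((len(rec.markers), rec.montage.n_channels, n_samp), dtype=rec.values.dtype)
    labels = np.empty(len(rec.markers), dtype=int)
    for k, (idx, lab) in enumerate(rec.markers):
        lo, hi = idx + off0, idx + off1
        if lo < 0 or hi > n_total:
            raise ValueError(
                f"marker {k} at sample {idx}: window [{lo}, {hi}) exceeds recording bounds [0, {n_total})"
            )
        trials[k] = rec.values[:, lo:hi]
        labels[k] = lab
    return EpochSet(
        data=trials,
        labels=labels,
        channel_names=rec.montage.channel_names,
        fs=rec.fs,
    )
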