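"""Signal conditioning and band-feature sample construction.

Pipeline for one trial: common-average reference + zero-phase band
filtering, sliding-window segmentation into M x omega data units,
five-band differential entropy (DE) per unit, and packing of N adjacent
units into one (F, M, N) feature sample labelled by the median split of
the trial ratings.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal

__all__ = [
    "Recording",
    "WindowSpec",
    "BandSet",
    "DEFAULT_BANDS",
    "FeatureSample",
    "condition_signal",
    "segment_trial",
    "compute_de",
    "build_samples",
    "binarize_labels",
]

#: variance floor applied before the log in the DE formula
VARIANCE_FLOOR = 1e-10

#: fraction of Nyquist that a cutoff touching fs/2 is clipped to
_NYQUIST_CLIP = 0.98


@dataclass
class Recording:
    """One subject-trial's raw EEG: channels x samples at ``fs`` Hz."""

    subject_id: str
    trial_id: int
    signal: np.ndarray  # (M, L)
    fs: float

    def __post_init__(self):
        self.signal = np.asarray(self.signal, dtype=np.float64)
        if self.signal.ndim != 2 or min(self.signal.shape) < 1:
            raise ValueError("signal must be a non-empty (channels, samples) matrix")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if not np.all(np.isfinite(self.signal)):
            raise ValueError("non-finite values in recording signal")

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]


@dataclass(frozen=True)
class WindowSpec:
    """Sliding window: width and step in samples; height = all channels."""

    width: int
    step: int

    def __post_init__(self):
        if self.width < 1 or self.step < 1:
            raise ValueError("window width and step must be >= 1")

    def n_units(self, n_samples: int) -> int:
        if self.width > n_samples:
            raise ValueError(
                f"window width {self.width} exceeds trial length {n_samples} "
                "(requires width <= L)")
        return (n_samples - self.width) // self.step + 1


@dataclass(frozen=True)
class Band:
    name: str
    low_hz: float
    high_hz: float

    def __post_init__(self):
        if not (0 < self.low_hz < self.high_hz):
            raise ValueError(f"band {self.name}: need 0 < low < high")


class BandSet(tuple):
    """Ordered tuple of frequency bands; length F."""

    def __new__(cls, bands):
        bands = tuple(b if isinstance(b, Band) else Band(*b) for b in bands)
        return super().__new__(cls, bands)

    def validate_against(self, fs: float) -> None:
        for b in self:
            if b.high_hz > fs / 2:
                raise ValueError(
                    f"band {b.name} top edge {b.high_hz} Hz exceeds Nyquist {fs / 2} Hz")

    @property
    def names(self):
        return [b.name for b in self]


DEFAULT_BANDS = BandSet([
    ("delta", 1.0, 4.0),
    ("theta", 4.0, 8.0),
    ("low_alpha", 8.0, 11.0),
    ("high_alpha", 11.0, 14.0),
    ("beta", 14.0, 16.0),
])


@dataclass
class FeatureSample:
    """(F, M, N) DE tensor with trial metadata and binary labels."""

    X: np.ndarray
    subject_id: str
    trial_id: int
    segment_range: tuple[int, int]  # half-open unit-index range
    valence: float = np.nan         # raw trial ratings, for split-time labelling
    arousal: float = np.nan
    label_valence: int = -1
    label_arousal: int = -1

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=np.float64)
        if self.X.ndim != 3:
            raise ValueError("X must be (F, M, N)")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("non-finite feature entries")


# ------------------------------------------------------------------ filtering

def _sos_filter(low_hz, high_hz, fs, order=4):
    """4th-order Butterworth, cutoffs clipped off exact Nyquist."""
    nyq = fs / 2.0
    high_hz = min(high_hz, _NYQUIST_CLIP * nyq) if high_hz is not None else None
    if low_hz is not None and high_hz is not None:
        return signal.butter(order, [low_hz, high_hz], btype="bandpass", fs=fs, output="sos")
    if low_hz is not None:
        return signal.butter(order, low_hz, btype="highpass", fs=fs, output="sos")
    return signal.butter(order, high_hz, btype="lowpass", fs=fs, output="sos")


def condition_signal(rec: Recording, hp_hz: float = 1.0, lp_hz: float = 16.0) -> Recording:
    """Common-average reference, then zero-phase high- and low-pass filters.

    The CAR subtracts the across-channel mean at every sample, so it
    needs M >= 2.  A low-pass cutoff equal to fs/2 is clipped just below
    Nyquist; cutoffs beyond Nyquist are rejected.
    """
    nyq = rec.fs / 2.0
    if not (0 < hp_hz < lp_hz):
        raise ValueError("need 0 < hp_hz < lp_hz")
    if lp_hz > nyq:
        raise ValueError(f"low-pass cutoff {lp_hz} Hz exceeds Nyquist {nyq} Hz")
    if rec.n_channels < 2:
        raise ValueError("common average reference needs at least 2 channels")
    x = rec.signal - rec.signal.mean(axis=0, keepdims=True)
    x = signal.sosfiltfilt(_sos_filter(hp_hz, None, rec.fs), x, axis=1)
    x = signal.sosfiltfilt(_sos_filter(None, lp_hz, rec.fs), x, axis=1)
    return Recording(rec.subject_id, rec.trial_id, np.ascontiguousarray(x), rec.fs)


# ---------------------------------------------------------------- segmenting

def segment_trial(rec: Recording, spec: WindowSpec) -> list[np.ndarray]:
    """Cut the (M, L) matrix into U = (L - width)//step + 1 units.

    Unit k covers samples [k*step, k*step + width); trailing samples not
    covered by a full window are dropped.
    """
    U = spec.n_units(rec.n_samples)
    return [rec.signal[:, k * spec.step:k * spec.step + spec.width].copy()
            for k in range(U)]


# ------------------------------------------------------------------- features

def compute_de(unit: np.ndarray, bands: BandSet = DEFAULT_BANDS,
               fs: float = 32.0, *, bypass_filter: bool = False) -> np.ndarray:
    """Five-band differential entropy per channel: (F, M) matrix.

    For each band the channel signal is band-pass filtered (zero-phase
    Butterworth), its variance estimated, and
    ``DE = 0.5 * ln(2 pi e sigma^2)`` returned in nats.  Variance is
    floored at 1e-10 so degenerate (constant) channels stay finite.

    ``bypass_filter`` skips the band-pass (identity band) — used by
    closed-form tests against the Gaussian entropy formula.
    """
    unit = np.asarray(unit, dtype=np.float64)
    if unit.ndim != 2:
        raise ValueError("unit must be (M, width)")
    bands.validate_against(fs)
    lowest = min(b.low_hz for b in bands)
    if not bypass_filter and unit.shape[1] < fs / lowest:
        raise ValueError(
            f"window of {unit.shape[1]} samples is too short for the "
            f"{lowest} Hz band edge (need >= 1 cycle)")
    rows = []
    for band in bands:
        if bypass_filter:
            filtered = unit
        else:
            filtered = signal.sosfiltfilt(
                _sos_filter(band.low_hz, band.high_hz, fs), unit, axis=1)
        var = filtered.var(axis=1)
        if np.any(var <= VARIANCE_FLOOR):
            warnings.warn("channel variance at floor; DE clamped", RuntimeWarning)
            var = np.maximum(var, VARIANCE_FLOOR)
        rows.append(0.5 * np.log(2.0 * np.pi * np.e * var))
    return np.stack(rows, axis=0)


def trial_de_units(rec: Recording, spec: WindowSpec,
                   bands: BandSet = DEFAULT_BANDS) -> list[np.ndarray]:
    """Per-unit DE matrices for a whole (conditioned) trial.

    Equivalent to ``compute_de`` over ``segment_trial`` output except
    that each band filter runs once over the full trial before
    windowing, which avoids re-filtering short windows (and their edge
    transients) once per unit.  Returns U matrices of shape (F, M).
    """
    bands.validate_against(rec.fs)
    U = spec.n_units(rec.n_samples)
    starts = np.arange(U) * spec.step
    per_band_var = []
    for band in bands:
        filtered = signal.sosfiltfilt(
            _sos_filter(band.low_hz, band.high_hz, rec.fs), rec.signal, axis=1)
        # windowed variance per channel: (U, M)
        windows = np.stack([filtered[:, s:s + spec.width] for s in starts])
        per_band_var.append(windows.var(axis=2))
    var = np.maximum(np.stack(per_band_var, axis=1), VARIANCE_FLOOR)  # (U, F, M)
    de = 0.5 * np.log(2.0 * np.pi * np.e * var)
    return [de[k] for k in range(U)]


# -------------------------------------------------------------------- samples

def build_samples(de_units: list[np.ndarray], n_segments: int, *,
                  subject_id: str = "", trial_id: int = 0,
                  valence: float = np.nan, arousal: float = np.nan) -> list[FeatureSample]:
    """Pack consecutive non-overlapping blocks of N units into samples.

    Leftover (< N) trailing units are dropped; fewer than N units total
    yields an empty list with a warning.
    """
    if n_segments < 1:
        raise ValueError("n_segments must be >= 1")
    if len(de_units) < n_segments:
        warnings.warn(
            f"only {len(de_units)} units for N={n_segments}; no samples built",
            RuntimeWarning)
        return []
    samples = []
    for start in range(0, len(de_units) - n_segments + 1, n_segments):
        block = de_units[start:start + n_segments]
        X = np.stack(block, axis=-1)  # (F, M, N)
        samples.append(FeatureSample(
            X=X, subject_id=subject_id, trial_id=trial_id,
            segment_range=(start, start + n_segments),
            valence=valence, arousal=arousal))
    return samples


def binarize_labels(ratings: np.ndarray, threshold: float | None = None):
    """Median split: label 1 iff rating > median; ties go to 0.

    Returns ``(labels, threshold)``.  The caller controls the rating
    population the median is taken over (pass ``threshold`` to reuse a
    training-set median on held-out ratings).
    """
    ratings = np.asarray(ratings, dtype=np.float64)
    if threshold is None:
        if ratings.size < 2:
            raise ValueError("need at least 2 ratings to form a median split")
        if np.ptp(ratings) == 0:
            raise ValueError("all ratings identical: no two-part split exists")
        threshold = float(np.median(ratings))
    return (ratings > threshold).astype(int), threshold
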