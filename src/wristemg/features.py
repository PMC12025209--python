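"""Time-domain feature extraction for multichannel sEMG.

Five classical time-domain features are computed per channel over
sliding analysis windows:

* MAV — mean absolute value, (1/N) * sum |x_i|
* RMS — root mean square, sqrt((1/N) * sum x_i^2)
* VAR — population variance, (1/N) * sum (x_i - mean)^2
* ZC  — thresholded zero-crossing rate: (1/N) * count of adjacent pairs
  with a sign change AND |x_i - x_{i+1}| > x_th
* WL  — waveform length, (1/N) * sum |x_{i+1} - x_i|

ZC and WL carry a 1/N normalisation (rather than the more common raw
count/sum); VAR divides by N, not N-1.  Both conventions are kept
deliberately and are part of this package's feature contract.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic import EMGRecording, validate_movement

#: Fixed feature order; also the tie-break order in feature selection.
FEATURE_ORDER: tuple[str, ...] = ("MAV", "RMS", "VAR", "ZC", "WL")


def _as_vector(signal) -> np.ndarray:
    x = np.asarray(signal, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("signal must be nonempty")
    return x


def mav(signal) -> float:
    """Mean absolute value of a signal window."""
    return float(np.mean(np.abs(_as_vector(signal))))


def rms(signal) -> float:
    """Root mean square of a signal window."""
    return float(np.sqrt(np.mean(np.square(_as_vector(signal)))))


def var(signal) -> float:
    """Population variance (1/N normalisation) of a signal window."""
    x = _as_vector(signal)
    return float(np.mean(np.square(x - x.mean())))


def zc(signal, x_th: float = 0.0) -> float:
    """Thresholded zero-crossing rate.

    Counts adjacent pairs whose product is negative and whose absolute
    difference exceeds ``x_th`` (the noise-rejection threshold), divided
    by the window length N.
    """
    x = _as_vector(signal)
    if x.size < 2:
        raise ValueError("zc needs at least 2 samples")
    if x_th < 0:
        raise ValueError("x_th must be nonnegative")
    crossings = (x[:-1] * x[1:] < 0) & (np.abs(x[:-1] - x[1:]) > x_th)
    return float(np.count_nonzero(crossings)) / x.size


def wl(signal) -> float:
    """Waveform length divided by the window length N."""
    x = _as_vector(signal)
    if x.size < 2:
        raise ValueError("wl needs at least 2 samples")
    return float(np.sum(np.abs(np.diff(x)))) / x.size


@dataclass(frozen=True)
class FeatureConfig:
    """Windowing parameters for feature extraction.

    ``zc_threshold`` is an absolute threshold in signal units; when
    ``None`` (default) the threshold is 0.01 x the RMS of each window,
    a per-window adaptive noise floor.
    """

    window_length: float = 0.2
    window_step: float = 0.05
    zc_threshold: float | None = None

    def __post_init__(self) -> None:
        if self.window_length <= 0:
            raise ValueError("window_length must be positive")
        if not 0 < self.window_step <= self.window_length:
            raise ValueError("need 0 < window_step <= window_length")
        if self.zc_threshold is not None and self.zc_threshold < 0:
            raise ValueError("zc_threshold must be nonnegative")


@dataclass
class FeatureMatrix:
    """Windowed feature values: rows are analysis windows, columns are
    channel-feature pairs named ``ch{c}_{MAV|RMS|VAR|ZC|WL}`` in
    channel-major order.  ``labels`` is one movement label per window,
    or None for unlabeled data."""

    values: np.ndarray
    feature_names: list[str]
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.shape[1] != len(self.feature_names):
            raise ValueError("values width must match feature_names length")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature values must be finite")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=object)
            if len(self.labels) != self.values.shape[0]:
                raise ValueError("one label per window required")
            for lab in set(self.labels):
                validate_movement(lab)

    @property
    def n_windows(self) -> int:
        return self.values.shape[0]

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.values, columns=self.feature_names)
        if self.labels is not None:
            frame.insert(0, "label", self.labels)
        return frame

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "FeatureMatrix":
        frame = pd.read_csv(path)
        labels = None
        if "label" in frame.columns:
            labels = frame.pop("label").to_numpy(dtype=object)
        return cls(
            values=frame.to_numpy(dtype=float),
            feature_names=list(frame.columns),
            labels=labels,
        )

    @classmethod
    def concat(cls, matrices: list["FeatureMatrix"]) -> "FeatureMatrix":
        if not matrices:
            raise ValueError("nothing to concatenate")
        names = matrices[0].feature_names
        for m in matrices[1:]:
            if m.feature_names != names:
                raise ValueError("feature name mismatch across matrices")
        have_labels = [m.labels is not None for m in matrices]
        if any(have_labels) and not all(have_labels):
            raise ValueError("cannot mix labeled and unlabeled matrices")
        labels = (
            np.concatenate([m.labels for m in matrices])
            if all(have_labels)
            else None
        )
        return cls(
            values=np.vstack([m.values for m in matrices]),
            feature_names=list(names),
            labels=labels,
        )


def feature_names(n_channels: int) -> list[str]:
    """Channel-major feature column names for an n-channel recording."""
    return [
        f"ch{c + 1}_{feat}"
        for c in range(n_channels)
        for feat in FEATURE_ORDER
    ]


def _window_features(window: np.ndarray, x_th: float | None) -> list[float]:
    th = 0.01 * rms(window) if x_th is None else x_th
    return [mav(window), rms(window), var(window), zc(window, th), wl(window)]


def extract_features(
    recording: EMGRecording, config: FeatureConfig | None = None
) -> FeatureMatrix:
    """Slide analysis windows over a recording and compute all five
    features on every channel, yielding 5 x n_channels columns per
    window (40 for the standard 8-channel armband)."""
    if config is None:
        config = FeatureConfig()
    win = int(round(config.window_length * recording.sampling_rate))
    step = int(round(config.window_step * recording.sampling_rate))
    if win < 2:
        raise ValueError("window_length too short for the sampling rate")
    if step < 1:
        raise ValueError("window_step too short for the sampling rate")
    n = recording.n_samples
    if n < win:
        raise ValueError(
            f"recording ({n} samples) shorter than one window ({win} samples)"
        )
    n_windows = (n - win) // step + 1
    values = np.empty((n_windows, 5 * recording.n_channels))
    for w in range(n_windows):
        start = w * step
        seg = recording.samples[:, start : start + win]
        row = []
        for c in range(recording.n_channels):
            row.extend(_window_features(seg[c], config.zc_threshold))
        values[w] = row
    labels = None
    if recording.label is not None:
        labels = np.full(n_windows, recording.label, dtype=object)
    return FeatureMatrix(
        values=values,
        feature_names=feature_names(recording.n_channels),
        labels=labels,
    )


def extract_dataset(
    recordings: list[EMGRecording], config: FeatureConfig | None = None
) -> FeatureMatrix:
    """Extract and stack features from a list of labeled recordings."""
    return FeatureMatrix.concat(
        [extract_features(r, config) for r in recordings]
    )
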