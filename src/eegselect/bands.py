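"""Frequency-band decomposition and per-second band-electrode features.

Each channel of a segmented recording is band-pass filtered into the
four analysis bands (theta 4-7 Hz, alpha 8-12, beta 13-30, gamma 31-47;
delta is excluded for valence/arousal work) and summarized by one
statistic per non-overlapping one-second window.  The result is a
:class:`FeatureMatrix` whose rows are trial-seconds and whose columns
are band-electrode combinations named ``"<channel>_<band>"`` — 128
columns for a 32-channel recording.

The default per-second statistic is mean band power (mean of squared
band-filtered samples).  The arithmetic mean of a zero-mean band-passed
signal is ~0 and carries no information, so mean power is the
informative reading of a per-second "mean" summary; ``mean_abs`` and
``mean_raw`` are available as alternatives.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "Band",
    "DEFAULT_BANDS",
    "bandpass",
    "window_statistic",
    "build_feature_matrix",
    "FeatureMatrix",
    "BandFeatureExtractor",
    "STATS",
]


@dataclass(frozen=True)
class Band:
    """One analysis band: half-open in neither direction, ``low < high`` in Hz."""

    name: str
    low: float
    high: float

    def __post_init__(self):
        if not 0 < self.low < self.high:
            raise ValueError(f"invalid band {self.name}: [{self.low}, {self.high}]")


#: The four analysis bands; delta (0.5-3.5 Hz) is deliberately excluded.
DEFAULT_BANDS = (
    Band("theta", 4.0, 7.0),
    Band("alpha", 8.0, 12.0),
    Band("beta", 13.0, 30.0),
    Band("gamma", 31.0, 47.0),
)

_FILTER_ORDER = 4  # Butterworth band-pass, applied forward-backward


def bandpass(x, band: Band, fs: float) -> np.ndarray:
    """Zero-phase 4th-order Butterworth band-pass along the last axis."""
    if band.high >= fs / 2:
        raise ValueError(
            f"band {band.name} upper edge {band.high} Hz >= Nyquist ({fs / 2} Hz)"
        )
    sos = signal.butter(
        _FILTER_ORDER, (band.low, band.high), btype="band", fs=fs, output="sos"
    )
    return signal.sosfiltfilt(sos, np.asarray(x, dtype=np.float64), axis=-1)


def _stat_band_power(w):
    return np.mean(np.square(w), axis=-1)


def _stat_mean_abs(w):
    return np.mean(np.abs(w), axis=-1)


def _stat_mean_raw(w):
    return np.mean(w, axis=-1)


STATS = {
    "band_power": _stat_band_power,
    "mean_abs": _stat_mean_abs,
    "mean_raw": _stat_mean_raw,
}


def window_statistic(x, fs: float, stat: str = "band_power") -> np.ndarray:
    """One summary value per non-overlapping 1 s window along the last axis.

    A trailing partial second is dropped; the signal must cover at
    least one full window.
    """
    if stat not in STATS:
        raise ValueError(f"unknown statistic {stat!r}; choose from {sorted(STATS)}")
    x = np.asarray(x, dtype=np.float64)
    win = int(round(fs))
    n_win = x.shape[-1] // win
    if n_win < 1:
        raise ValueError(f"signal shorter than one {win}-sample window")
    windows = x[..., : n_win * win].reshape(*x.shape[:-1], n_win, win)
    return STATS[stat](windows)


class FeatureMatrix:
    """Instances (trial-seconds) by band-electrode features.

    Attributes
    ----------
    values : ndarray, shape (n_instances, n_features)
    feature_names : list of str, ``"<channel>_<band>"``
    meta : DataFrame with columns ``subject, trial, second``
        Row provenance; ``trial`` is a global trial index across
        subjects so instances can be traced back to their trial.
    """

    META_COLUMNS = ("subject", "trial", "second")

    def __init__(self, values, feature_names, meta):
        self.values = np.asarray(values, dtype=np.float64)
        self.feature_names = list(feature_names)
        self.meta = meta.reset_index(drop=True)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D")
        if self.values.shape[1] != len(self.feature_names):
            raise ValueError("feature_names length does not match values")
        if len(self.meta) != self.values.shape[0]:
            raise ValueError("meta length does not match values")
        if len(set(self.feature_names)) != len(self.feature_names):
            raise ValueError("duplicate feature names")
        if not np.isfinite(self.values).all():
            raise ValueError("non-finite feature values")

    @property
    def n_instances(self):
        return self.values.shape[0]

    @property
    def n_features(self):
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.concat(
            [self.meta, pd.DataFrame(self.values, columns=self.feature_names)],
            axis=1,
        )

    def select(self, names) -> "FeatureMatrix":
        """Restrict to a subset of named features (order as given)."""
        idx = [self.feature_names.index(n) for n in names]
        return FeatureMatrix(self.values[:, idx], list(names), self.meta)

    def instance_labels(self, trial_labels: pd.Series) -> np.ndarray:
        """Broadcast per-(subject, trial) labels to instances."""
        key = pd.MultiIndex.from_frame(self.meta[["subject", "trial"]])
        return trial_labels.reindex(key).to_numpy()

    def to_csv(self, path):
        self.to_frame().to_csv(path, index=False, float_format="%.17g")

    @classmethod
    def from_csv(cls, path) -> "FeatureMatrix":
        frame = pd.read_csv(path)
        meta = frame[list(cls.META_COLUMNS)]
        feats = [c for c in frame.columns if c not in cls.META_COLUMNS]
        return cls(frame[feats].to_numpy(float), feats, meta)

    def __repr__(self):
        return f"FeatureMatrix({self.n_instances} instances, {self.n_features} features)"


class BandFeatureExtractor(TransformerMixin, BaseEstimator):
    """Stateless transformer: (trial, channel, sample) tensor -> per-second features.

    Parameters
    ----------
    bands : sequence of Band
    fs : float
        Sampling rate in Hz of the input tensor.
    stat : {"band_power", "mean_abs", "mean_raw"}
    channel_names : sequence of str, optional
        Used for output feature names; defaults to ``ch0, ch1, ...``.

    ``transform`` returns an array of shape
    ``(n_trials * floor(trial_seconds), n_channels * n_bands)`` with
    columns ordered band-major within channel-major order.
    """

    def __init__(self, bands=DEFAULT_BANDS, fs=128.0, stat="band_power",
                 channel_names=None):
        self.bands = bands
        self.fs = fs
        self.stat = stat
        self.channel_names = channel_names

    def fit(self, X, y=None):
        self._validate(X)
        return self

    def _validate(self, X):
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 3:
            raise ValueError("X must be (trial, channel, sample)")
        names = [b.name for b in self.bands]
        if len(set(names)) != len(names):
            raise ValueError("duplicate band names")
        return X

    def transform(self, X):
        X = self._validate(X)
        n_trials, n_channels, _ = X.shape
        per_band = []
        for band in self.bands:
            filtered = bandpass(X, band, self.fs)
            per_band.append(window_statistic(filtered, self.fs, self.stat))
        # per_band[b]: (trial, channel, second)
        stacked = np.stack(per_band, axis=2)  # (trial, channel, band, second)
        n_seconds = stacked.shape[-1]
        # rows: trial-major then second; columns: channel-major then band
        out = stacked.transpose(0, 3, 1, 2).reshape(
            n_trials * n_seconds, n_channels * len(self.bands)
        )
        self._n_seconds = n_seconds
        return out

    def get_feature_names_out(self, input_features=None):
        names = self.channel_names
        if names is None:
            names = input_features
        if names is None:
            raise ValueError("channel_names not set")
        return np.array(
            [f"{ch}_{b.name}" for ch in names for b in self.bands], dtype=object
        )


def build_feature_matrix(rec, bands=DEFAULT_BANDS, stat="band_power") -> FeatureMatrix:
    """Band-decompose a baseline-trimmed recording into per-second features.

    Row provenance keys instances by ``(subject, trial, second)``;
    trial indices are per-subject, so matrices from several subjects
    concatenate without collision.

    Parameters
    ----------
    rec : EEGRecording
        Must have ``baseline_seconds == 0``.
    bands, stat : see :class:`BandFeatureExtractor`.
    """
    if rec.baseline_seconds != 0:
        raise ValueError("trim the baseline before feature extraction")
    ext = BandFeatureExtractor(
        bands=bands, fs=rec.sampling_rate, stat=stat,
        channel_names=rec.channel_names,
    )
    values = ext.transform(rec.data)
    n_seconds = ext._n_seconds
    meta = pd.DataFrame(
        {
            "subject": np.repeat(rec.subject_id, rec.n_trials * n_seconds),
            "trial": np.repeat(np.arange(rec.n_trials), n_seconds),
            "second": np.tile(np.arange(n_seconds), rec.n_trials),
        }
    )
    return FeatureMatrix(values, list(ext.get_feature_names_out()), meta)


def concat_feature_matrices(matrices) -> FeatureMatrix:
    """Pool instances from several subjects' feature matrices."""
    matrices = list(matrices)
    names = matrices[0].feature_names
    for m in matrices[1:]:
        if m.feature_names != names:
            raise ValueError("feature matrices have different columns")
    return FeatureMatrix(
        np.vstack([m.values for m in matrices]),
        names,
        pd.concat([m.meta for m in matrices], ignore_index=True),
    )
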