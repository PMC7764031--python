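"""EEG trial data containers, I/O and preprocessing.

The canonical in-memory model is :class:`EEGRecording`: a
``(trial, channel, sample)`` tensor in microvolts together with channel
names, sampling rate and the length of the pre-trial baseline still
attached at the start of every trial.  Recordings are interchanged on
disk through a small HDF5 container layout (``/data``, ``/channel_names``,
``/fs``, ``/baseline_seconds`` plus a ``subject_id`` attribute) or read
from EDF with a sidecar trial table.

Emotion self-assessment ratings live in a plain :class:`pandas.DataFrame`
with columns ``subject, trial, valence, arousal`` on the conventional
1-9 scale, and are binarized at a threshold of 4.5 into low/high labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from fractions import Fraction
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal

__all__ = [
    "DEAP_CHANNEL_ORDER",
    "EEGRecording",
    "read_recording",
    "write_recording",
    "read_ratings",
    "write_ratings",
    "trim_baseline",
    "resample_to",
    "binarize_ratings",
    "RecordingFormatError",
]

#: Canonical 10-20-system ordering for 32-channel recordings (DEAP layout).
DEAP_CHANNEL_ORDER = (
    "Fp1", "AF3", "F3", "F7", "FC5", "FC1", "C3", "T7",
    "CP5", "CP1", "P3", "P7", "PO3", "O1", "Oz", "Pz",
    "Fp2", "AF4", "Fz", "F4", "F8", "FC6", "FC2", "Cz",
    "C4", "T8", "CP6", "CP2", "P4", "P8", "PO4", "O2",
)

RATING_MIN, RATING_MAX = 1.0, 9.0
#: Ratings at or above this value are labeled "high" (label 1).
RATING_THRESHOLD = 4.5


class RecordingFormatError(ValueError):
    """A file does not conform to a supported recording layout."""


@dataclass(frozen=True)
class EEGRecording:
    """Segmented multi-trial EEG for one subject.

    Parameters
    ----------
    subject_id : str
        Identifier of the recorded subject.
    channel_names : tuple of str
        Unique 10-20-system electrode labels, in recording order.
    sampling_rate : float
        Sampling rate in Hz.
    data : ndarray, shape (n_trials, n_channels, n_samples)
        Signal in microvolts.  All trials share one sample count.
    baseline_seconds : float
        Seconds of pre-trial baseline still attached at the start of
        each trial (0 after :func:`trim_baseline`).
    """

    subject_id: str
    channel_names: tuple
    sampling_rate: float
    data: np.ndarray
    baseline_seconds: float = 0.0

    def __post_init__(self):
        data = np.asarray(self.data)
        if data.ndim != 3:
            raise ValueError(
                f"data must be (trial, channel, sample), got shape {data.shape}"
            )
        names = tuple(str(c) for c in self.channel_names)
        object.__setattr__(self, "channel_names", names)
        object.__setattr__(self, "data", data)
        if len(set(names)) != len(names):
            raise ValueError("channel names must be unique")
        if data.shape[1] != len(names):
            raise ValueError(
                f"{len(names)} channel names for {data.shape[1]} data channels"
            )
        if not self.sampling_rate > 0:
            raise ValueError("sampling_rate must be positive")
        if self.baseline_seconds < 0:
            raise ValueError("baseline_seconds must be non-negative")
        bad = ~np.isfinite(data)
        if bad.any():
            t, c, _ = np.argwhere(bad)[0]
            raise ValueError(
                "non-finite sample in trial "
                f"{t}, channel {names[c]!r}"
            )

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def trial_seconds(self) -> float:
        """Trial duration in seconds, baseline included."""
        return self.n_samples / self.sampling_rate


# ---------------------------------------------------------------------------
# HDF5 container
# ---------------------------------------------------------------------------

def write_recording(rec: EEGRecording, path):
    """Write a recording to the HDF5 container layout.

    ``/data`` is stored as float32; round-trips are bit-exact for
    float32 inputs.
    """
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=rec.data.astype(np.float32, copy=False))
        f.create_dataset(
            "channel_names",
            data=np.array(rec.channel_names, dtype=h5py.string_dtype("utf-8")),
        )
        f.create_dataset("fs", data=float(rec.sampling_rate))
        f.create_dataset("baseline_seconds", data=float(rec.baseline_seconds))
        f.attrs["subject_id"] = rec.subject_id


def _read_hdf5(path) -> EEGRecording:
    import h5py

    with h5py.File(path, "r") as f:
        for name in ("data", "channel_names", "fs", "baseline_seconds"):
            if name not in f:
                raise RecordingFormatError(
                    f"HDF5 container {path} is missing dataset /{name}"
                )
        data = np.asarray(f["data"])
        names = [
            c.decode("utf-8") if isinstance(c, bytes) else str(c)
            for c in f["channel_names"][()]
        ]
        fs = float(f["fs"][()])
        baseline = float(f["baseline_seconds"][()])
        subject = str(f.attrs.get("subject_id", Path(path).stem))
    return EEGRecording(subject, tuple(names), fs, data, baseline)


def _read_edf(path, trial_table, baseline_seconds=0.0) -> EEGRecording:
    """Read a continuous EDF recording and segment it into trials.

    ``trial_table`` is a CSV path or DataFrame with columns
    ``trial_id, onset_s, duration_s``; trials are cut from the
    continuous record at those onsets.  All EDF channels must share
    one sampling rate.
    """
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="ERROR")
    fs = float(raw.info["sfreq"])
    # mne resamples mixed-rate EDF channels silently; detect the original rates
    with open(path, "rb") as f:
        header = f.read(256)
        n_sig = int(header[252:256].decode().strip())
        f.seek(256 + 216 * n_sig)
        spr = [int(f.read(8).decode().strip()) for _ in range(n_sig)]
    phys = [i for i, ch in enumerate(raw.ch_names) if not ch.startswith("EDF Ann")]
    if len({spr[i] for i in phys}) > 1:
        raise RecordingFormatError(
            "EDF channels have mixed sampling rates; not supported"
        )
    if trial_table is None:
        raise RecordingFormatError(
            "EDF input requires a sidecar trial table (trial_id, onset_s, duration_s)"
        )
    table = (
        pd.read_csv(trial_table)
        if not isinstance(trial_table, pd.DataFrame)
        else trial_table
    )
    for col in ("trial_id", "onset_s", "duration_s"):
        if col not in table.columns:
            raise RecordingFormatError(f"trial table is missing column {col!r}")
    sig = raw.get_data(picks=phys) * 1e6  # volts -> microvolts
    names = [raw.ch_names[i] for i in phys]
    durations = table["duration_s"].to_numpy(float)
    if len(set(durations.tolist())) > 1:
        raise RecordingFormatError("all trials must share one duration")
    n_samp = int(round(durations[0] * fs))
    trials = []
    for onset in table["onset_s"].to_numpy(float):
        start = int(round(onset * fs))
        if start + n_samp > sig.shape[1]:
            raise RecordingFormatError(
                f"trial at onset {onset}s extends past end of recording"
            )
        trials.append(sig[:, start : start + n_samp])
    data = np.stack(trials).astype(np.float32)
    return EEGRecording(Path(path).stem, tuple(names), fs, data, baseline_seconds)


def read_recording(path, format="hdf5", trial_table=None, baseline_seconds=0.0):
    """Read and validate an :class:`EEGRecording` from disk.

    Parameters
    ----------
    path : path-like
    format : {"hdf5", "edf"}
    trial_table : path or DataFrame, optional
        Required for EDF: trial onsets/durations in seconds.
    baseline_seconds : float
        Baseline length to record for EDF input (HDF5 carries its own).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format in ("hdf5", "hdf5_container"):
        return _read_hdf5(path)
    if format == "edf":
        return _read_edf(path, trial_table, baseline_seconds)
    raise ValueError(f"unknown format {format!r}")


def read_ratings(path) -> pd.DataFrame:
    """Read a ratings CSV (``subject,trial,valence,arousal``) and validate it."""
    ratings = pd.read_csv(path)
    return validate_ratings(ratings)


def write_ratings(ratings: pd.DataFrame, path):
    validate_ratings(ratings).to_csv(path, index=False)


def validate_ratings(ratings: pd.DataFrame) -> pd.DataFrame:
    for col in ("subject", "trial", "valence", "arousal"):
        if col not in ratings.columns:
            raise ValueError(f"ratings table is missing column {col!r}")
    for col in ("valence", "arousal"):
        vals = ratings[col].to_numpy(float)
        if not np.isfinite(vals).all():
            raise ValueError(f"non-finite {col} rating")
        if ((vals < RATING_MIN) | (vals > RATING_MAX)).any():
            raise ValueError(f"{col} ratings must lie in [1, 9]")
    if ratings.duplicated(["subject", "trial"]).any():
        raise ValueError("duplicate (subject, trial) rows in ratings")
    return ratings


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------

def trim_baseline(rec: EEGRecording) -> EEGRecording:
    """Remove the attached pre-trial baseline from every trial.

    Idempotent: a recording with ``baseline_seconds == 0`` is returned
    unchanged.
    """
    if rec.baseline_seconds == 0:
        return rec
    n_cut = int(round(rec.baseline_seconds * rec.sampling_rate))
    if n_cut >= rec.n_samples:
        raise ValueError(
            f"baseline ({rec.baseline_seconds}s) is not shorter than the trial "
            f"({rec.trial_seconds}s)"
        )
    return replace(rec, data=rec.data[:, :, n_cut:], baseline_seconds=0.0)


def resample_to(rec: EEGRecording, target_hz: float) -> EEGRecording:
    """Downsample every trial/channel with anti-aliasing.

    A zero-phase Butterworth low-pass at ``0.4 * target_hz`` is applied
    before polyphase resampling.  Upsampling is not supported.
    """
    if not target_hz > 0:
        raise ValueError("target_hz must be positive")
    if target_hz > rec.sampling_rate:
        raise ValueError(
            f"upsampling ({rec.sampling_rate} -> {target_hz} Hz) is not supported"
        )
    if target_hz == rec.sampling_rate:
        return rec
    sos = signal.butter(
        8, 0.4 * target_hz, btype="low", fs=rec.sampling_rate, output="sos"
    )
    filtered = signal.sosfiltfilt(sos, rec.data, axis=-1)
    ratio = Fraction(target_hz / rec.sampling_rate).limit_denominator(1000)
    out = signal.resample_poly(filtered, ratio.numerator, ratio.denominator, axis=-1)
    return replace(
        rec,
        data=out.astype(rec.data.dtype, copy=False),
        sampling_rate=float(target_hz),
    )


def binarize_ratings(
    ratings: pd.DataFrame, emotion: str, threshold: float = RATING_THRESHOLD
) -> pd.Series:
    """Binarize 1-9 ratings into low (0) / high (1) labels for one emotion.

    Ratings below ``threshold`` map to 0 and ratings above it to 1; a
    rating exactly at the threshold maps to 1 (>= convention, declared
    since the midpoint is not otherwise defined).

    Returns a Series of {0, 1} indexed by ``(subject, trial)``.
    """
    if emotion not in ("valence", "arousal"):
        raise ValueError(f"unknown emotion {emotion!r}")
    validate_ratings(ratings)
    labels = (ratings[emotion].to_numpy(float) >= threshold).astype(np.int64)
    index = pd.MultiIndex.from_frame(ratings[["subject", "trial"]])
    return pd.Series(labels, index=index, name=emotion)
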