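"""Seeded synthetic EEG with known band-power effects and redundancy.

The generator emulates the data regime of segmented emotion-rating
EEG studies: 32 scalp channels at 128 Hz, 60 s trials with a 3 s
pre-trial baseline, and one continuous 1-9 rating per trial and
emotion.  Each channel is a sum of band-limited Gaussian oscillations
(white noise band-passed to the canonical theta/alpha/beta/gamma
ranges), a 1/f background, and white sensor noise.

Three structures make every pipeline stage testable:

* **redundancy groups** — sets of channels that share one latent
  band-limited waveform per band (mixed with a per-channel weight
  plus independent noise), producing the correlated electrode blocks
  that a redundancy-reducing selector should avoid;
* **per-second amplitude envelopes** — every band component's
  amplitude is modulated by a log-normal per-second gain, giving
  band-power features realistic within-trial variability.  Envelope
  log-gains of non-planted components share a common factor, and that
  common factor is driven by the planted components' envelopes
  (``envelope_leak``).  This makes every non-planted feature
  positively correlated with every planted feature while planted
  features stay mutually uncorrelated — the structure under which a
  least-correlated-first greedy selector identifies the planted
  band-electrodes;
* **planted effects** — chosen (channel, band) combinations whose
  band amplitude is multiplied by a known ratio on trials of the
  high class, giving the classifier a recoverable signal at a known
  location.  Planted combinations are excluded from group waveform
  sharing by default (``decorrelate_effects``).

Ratings are drawn uniformly from [1, 4.3] for the low class and
[4.7, 9] for the high class, keeping a margin around the 4.5
binarization threshold so label recovery is exact.

Everything is deterministic given the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bands import DEFAULT_BANDS, Band, FeatureMatrix, bandpass
from .recording import DEAP_CHANNEL_ORDER, EEGRecording

__all__ = [
    "SynthConfig",
    "Effect",
    "RedundancyGroup",
    "default_config",
    "generate",
    "make_clone_matrix",
]


@dataclass(frozen=True)
class Effect:
    """Class-dependent band-power effect planted at one band-electrode.

    ``amplitude_ratio`` multiplies the band's amplitude on high-class
    trials, so the planted band-power ratio is ``amplitude_ratio**2``.
    """

    channel: str
    band: str
    amplitude_ratio: float = 2.0
    emotion: str = "valence"

    @property
    def feature_name(self) -> str:
        return f"{self.channel}_{self.band}"


@dataclass(frozen=True)
class RedundancyGroup:
    """Channels sharing one latent band-limited waveform per band.

    Each member channel's band waveform is
    ``weight * latent + sqrt(1 - weight**2) * own`` so its marginal
    variance is independent of the weight; ``bands=None`` means all
    bands share.
    """

    channels: tuple
    weight: float = 0.9
    bands: tuple | None = None

    def __post_init__(self):
        if not 0 <= self.weight <= 1:
            raise ValueError("mixing weight must lie in [0, 1]")
        object.__setattr__(self, "channels", tuple(self.channels))
        if self.bands is not None:
            object.__setattr__(self, "bands", tuple(self.bands))


@dataclass(frozen=True)
class SynthConfig:
    """Full parameterization of the synthetic EEG generator.

    ``envelope_scale`` is the sd of the per-second log-amplitude gain
    (0 disables envelopes); ``envelope_leak`` is the fraction
    (in log-variance share, 0..1) of every non-planted component's
    envelope carried by the common factor driven by the planted
    components' envelopes.
    """

    n_subjects: int = 2
    n_trials_per_subject: int = 10
    channel_names: tuple = DEAP_CHANNEL_ORDER
    fs: float = 128.0
    trial_seconds: float = 60.0
    baseline_seconds: float = 3.0
    bands: tuple = DEFAULT_BANDS
    band_amplitudes: tuple = (("theta", 4.0), ("alpha", 5.0), ("beta", 3.0),
                              ("gamma", 1.5))  # microvolt scale
    background_noise_sd: float = 1.0  # white sensor noise, microvolts
    one_over_f_amplitude: float = 3.0
    one_over_f_exponent: float = 1.0
    redundancy_groups: tuple = ()
    effects: tuple = ()
    decorrelate_effects: bool = True
    envelope_scale: float = 0.5
    envelope_leak: float = 1.0
    rating_low: tuple = (1.0, 4.3)
    rating_high: tuple = (4.7, 9.0)
    class_balance: float = 0.5
    seed: int = 0

    def __post_init__(self):
        names = tuple(self.channel_names)
        object.__setattr__(self, "channel_names", names)
        if self.n_subjects < 1 or self.n_trials_per_subject < 1:
            raise ValueError("n_subjects and n_trials_per_subject must be >= 1")
        if self.fs <= 0 or self.trial_seconds <= 0 or self.baseline_seconds < 0:
            raise ValueError("fs and durations must be positive")
        if not 0 <= self.envelope_leak <= 1:
            raise ValueError("envelope_leak must lie in [0, 1]")
        if self.envelope_scale < 0:
            raise ValueError("envelope_scale must be non-negative")
        band_names = {b.name for b in self.bands}
        for bname, amp in self.band_amplitudes:
            if bname not in band_names:
                raise ValueError(f"band_amplitudes names unknown band {bname!r}")
            if amp < 0:
                raise ValueError("band amplitudes must be non-negative")
        for eff in self.effects:
            if eff.channel not in names:
                raise ValueError(f"effect channel {eff.channel!r} not in channel_names")
            if eff.band not in band_names:
                raise ValueError(f"effect band {eff.band!r} unknown")
            if not eff.amplitude_ratio > 0:
                raise ValueError("effect amplitude_ratio must be positive")
        for grp in self.redundancy_groups:
            for ch in grp.channels:
                if ch not in names:
                    raise ValueError(f"redundancy channel {ch!r} not in channel_names")

    @property
    def amplitude_map(self):
        return dict(self.band_amplitudes)


def default_config(seed: int = 0, **overrides) -> SynthConfig:
    """The reference study conditions for desk-scale experiments.

    Two subjects of ten 60 s trials each (1200 one-second instances),
    32 channels in the canonical order, three planted effects of
    amplitude ratio 2 at mutually decorrelated band-electrodes, and
    four regional redundancy groups covering the scalp.
    """
    effects = (
        Effect("P8", "alpha", 1.5),
        Effect("AF4", "gamma", 1.5),
        Effect("Cz", "theta", 1.5),
    )
    names = DEAP_CHANNEL_ORDER
    quarter = len(names) // 4
    groups = tuple(
        RedundancyGroup(names[i * quarter : (i + 1) * quarter], weight=0.9)
        for i in range(4)
    )
    cfg = dict(
        effects=effects,
        redundancy_groups=groups,
        seed=seed,
    )
    cfg.update(overrides)
    return SynthConfig(**cfg)


def _one_over_f(n, fs, exponent, rng):
    """Gaussian noise with a 1/f^exponent amplitude spectrum, unit sd."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    shaping = np.ones_like(freqs)
    nz = freqs > 0
    shaping[nz] = freqs[nz] ** (-exponent / 2.0)
    shaping[0] = 0.0  # no DC drift
    x = np.fft.irfft(spec * shaping, n=n)
    sd = x.std()
    return x / sd if sd > 0 else x


def _band_noise(n, band: Band, fs, rng):
    """Unit-sd band-limited Gaussian noise."""
    x = bandpass(rng.standard_normal(n), band, fs)
    sd = x.std()
    return x / sd if sd > 0 else x


def _expand_gains(gains, fs, n_samp):
    """Per-second gains -> per-sample multiplier of length n_samp."""
    per = int(round(fs))
    out = np.repeat(gains, per)
    if out.size < n_samp:  # trailing partial second reuses the last gain
        out = np.concatenate([out, np.full(n_samp - out.size, gains[-1])])
    return out[:n_samp]


def generate(config: SynthConfig):
    """Generate per-subject recordings and the ratings table.

    Returns ``(recordings, ratings)`` where ``recordings`` is a list
    of :class:`EEGRecording` (one per subject, baseline attached) and
    ``ratings`` a DataFrame ``subject, trial, valence, arousal``.
    """
    rng = np.random.default_rng(config.seed)
    n_samp = int(round((config.trial_seconds + config.baseline_seconds) * config.fs))
    n_sec = int(np.ceil(n_samp / config.fs))
    names = config.channel_names
    n_ch = len(names)
    amp = config.amplitude_map
    tau = config.envelope_scale
    leak = np.sqrt(config.envelope_leak)
    own_frac = np.sqrt(1.0 - config.envelope_leak)

    planted = [(e.channel, e.band) for e in config.effects]
    decorr = set(planted) if config.decorrelate_effects else set()
    group_of = {}
    for gi, grp in enumerate(config.redundancy_groups):
        for ch in grp.channels:
            for band in config.bands:
                if grp.bands is not None and band.name not in grp.bands:
                    continue
                if (ch, band.name) in decorr:
                    continue
                group_of[(ch, band.name)] = gi
    effect_at = {(e.channel, e.band): e for e in config.effects}

    recordings = []
    rating_rows = []
    for s in range(config.n_subjects):
        subject = f"S{s + 1:02d}"
        trials = np.empty((config.n_trials_per_subject, n_ch, n_samp), np.float64)
        for t in range(config.n_trials_per_subject):
            latent_class = {
                emo: int(rng.random() < config.class_balance)
                for emo in ("valence", "arousal")
            }
            # shared waveform latents: one per redundancy group and band
            latents = {
                (gi, band.name): _band_noise(n_samp, band, config.fs, rng)
                for gi in range(len(config.redundancy_groups))
                for band in config.bands
            }
            # per-second envelope log-gains of the planted components,
            # and the common factor they drive
            z_planted = {
                key: rng.standard_normal(n_sec) for key in planted
            }
            if z_planted:
                common = np.sum(list(z_planted.values()), axis=0)
                common /= np.sqrt(len(z_planted))
            else:
                common = rng.standard_normal(n_sec)
            for c, ch in enumerate(names):
                sig = np.zeros(n_samp)
                for band in config.bands:
                    key = (ch, band.name)
                    a = amp.get(band.name, 0.0)
                    eff = effect_at.get(key)
                    if eff is not None and latent_class[eff.emotion] == 1:
                        a *= eff.amplitude_ratio
                    gi = group_of.get(key)
                    if gi is not None:
                        w = config.redundancy_groups[gi].weight
                        comp = w * latents[(gi, band.name)] + np.sqrt(
                            1.0 - w * w
                        ) * _band_noise(n_samp, band, config.fs, rng)
                    else:
                        comp = _band_noise(n_samp, band, config.fs, rng)
                    if tau > 0:
                        if key in z_planted:
                            logg = z_planted[key]
                        else:
                            logg = leak * common + own_frac * rng.standard_normal(n_sec)
                        comp = comp * _expand_gains(
                            np.exp(tau * logg), config.fs, n_samp
                        )
                    sig += a * comp
                sig += config.one_over_f_amplitude * _one_over_f(
                    n_samp, config.fs, config.one_over_f_exponent, rng
                )
                sig += config.background_noise_sd * rng.standard_normal(n_samp)
                trials[t, c] = sig
            row = {"subject": subject, "trial": t}
            for emo in ("valence", "arousal"):
                lo, hi = (
                    config.rating_high
                    if latent_class[emo] == 1
                    else config.rating_low
                )
                row[emo] = float(rng.uniform(lo, hi))
            rating_rows.append(row)
        recordings.append(
            EEGRecording(
                subject,
                names,
                config.fs,
                trials.astype(np.float32),
                config.baseline_seconds,
            )
        )
    ratings = pd.DataFrame(
        rating_rows, columns=["subject", "trial", "valence", "arousal"]
    )
    return recordings, ratings


def make_clone_matrix(n_rows, groups, noise_sd=0.1, n_independent=0, seed=0):
    """Feature matrix of correlated clone groups plus independent columns.

    Columns within one group equal a shared latent plus independent
    N(0, noise_sd) clone noise; latents of different groups and the
    ``n_independent`` trailing columns are *exactly* sample-decorrelated
    (the latent/independent basis is orthogonalized after centering),
    so independent columns have pairwise Pearson correlation 0 while
    clones retain a small nonzero correlation to everything through
    their clone noise.  A direct fixture for redundancy-selection
    tests: greedy least-correlated selection of k features recovers
    the k independent columns whenever ``noise_sd > 0``.

    A group of size 1 behaves like one more independent column (plus
    its clone noise).

    Parameters
    ----------
    n_rows : int
        Must exceed the number of latent directions by at least 1.
    groups : sequence of int
        Clone-group sizes (each >= 1).
    noise_sd : float
        Within-group clone noise; smaller means tighter correlation.
    n_independent : int
        Mutually decorrelated columns appended after the groups.
    seed : int
    """
    groups = list(groups)
    if not groups and n_independent == 0:
        raise ValueError("need at least one group or independent column")
    if any(g < 1 for g in groups):
        raise ValueError("group sizes must be >= 1")
    n_latent = len(groups) + n_independent
    if n_rows < n_latent + 2:
        raise ValueError("n_rows too small to decorrelate the latent basis")
    rng = np.random.default_rng(seed)
    raw = rng.standard_normal((n_rows, n_latent))
    raw -= raw.mean(axis=0)
    q, _ = np.linalg.qr(raw)
    basis = q * np.sqrt(n_rows)  # zero-mean, exactly orthogonal, unit-ish sd
    cols, names = [], []
    for gi, size in enumerate(groups):
        latent = basis[:, gi]
        for j in range(size):
            cols.append(latent + noise_sd * rng.standard_normal(n_rows))
            names.append(f"g{gi}c{j}")
    for j in range(n_independent):
        cols.append(basis[:, len(groups) + j])
        names.append(f"ind{j}")
    values = np.column_stack(cols)
    meta = pd.DataFrame(
        {"subject": "synthetic", "trial": np.arange(n_rows), "second": 0}
    )
    return FeatureMatrix(values, names, meta)
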