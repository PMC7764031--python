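"""Shared fixtures: small synthetic recordings and test-time file writers."""

import numpy as np
import pandas as pd
import pytest

import eegselect as es


@pytest.fixture(scope="session")
def small_config():
    """Desk-scale generator config: 1 subject, 4 trials of 6 s, 8 channels."""
    names = ("Fp1", "AF3", "Cz", "Pz", "AF4", "P8", "Fz", "O2")
    return es.default_config(
        seed=11,
        n_subjects=1,
        n_trials_per_subject=4,
        trial_seconds=6.0,
        baseline_seconds=1.0,
        channel_names=names,
        redundancy_groups=(es.RedundancyGroup(("Fp1", "AF3", "Fz", "O2")),),
        effects=(es.Effect("P8", "alpha", 1.5),),
    )


@pytest.fixture(scope="session")
def small_data(small_config):
    recordings, ratings = es.generate(small_config)
    return recordings, ratings


@pytest.fixture(scope="session")
def small_features(small_data):
    recordings, ratings = small_data
    X = es.concat_feature_matrices(
        es.build_feature_matrix(es.trim_baseline(r)) for r in recordings
    )
    return X, ratings


@pytest.fixture(scope="session")
def default_dataset():
    """One draw of the full default study conditions (1200 instances)."""
    cfg = es.default_config(seed=202)
    recordings, ratings = es.generate(cfg)
    X = es.concat_feature_matrices(
        es.build_feature_matrix(es.trim_baseline(r)) for r in recordings
    )
    return cfg, X, ratings


def write_minimal_edf(path, data, fs, channel_names):
    """Write a continuous multi-channel int16 EDF file (test plumbing only).

    ``data``: (n_channels, n_samples) in microvolts; one data record per
    second.  Not part of the package API — packages read EDF via mne.
    """
    data = np.asarray(data, float)
    n_ch, n_samp = data.shape
    spr = int(round(fs))
    n_rec = n_samp // spr
    assert n_rec * spr == n_samp, "whole seconds required"

    def pad(text, width):
        s = str(text)[:width]
        return s.ljust(width).encode("ascii")

    pmin, pmax = -3276.8, 3276.7
    with open(path, "wb") as f:
        f.write(pad("0", 8))
        f.write(pad("X X X X", 80))
        f.write(pad("Startdate 01-JAN-2020", 80))
        f.write(pad("01.01.20", 8))
        f.write(pad("00.00.00", 8))
        f.write(pad(256 * (1 + n_ch), 8))
        f.write(pad("", 44))
        f.write(pad(n_rec, 8))
        f.write(pad("1", 8))  # record duration, seconds
        f.write(pad(n_ch, 4))
        for name in channel_names:
            f.write(pad(name, 16))
        for _ in range(n_ch):
            f.write(pad("AgAgCl electrode", 80))
        for _ in range(n_ch):
            f.write(pad("uV", 8))
        for _ in range(n_ch):
            f.write(pad(pmin, 8))
        for _ in range(n_ch):
            f.write(pad(pmax, 8))
        for _ in range(n_ch):
            f.write(pad(-32768, 8))
        for _ in range(n_ch):
            f.write(pad(32767, 8))
        for _ in range(n_ch):
            f.write(pad("", 80))
        for _ in range(n_ch):
            f.write(pad(spr, 8))
        for _ in range(n_ch):
            f.write(pad("", 32))
        scale = (32767 - (-32768)) / (pmax - pmin)
        dig = np.clip(np.round((data - pmin) * scale) + (-32768), -32768, 32767)
        dig = dig.astype("<i2")
        for r in range(n_rec):
            for c in range(n_ch):
                f.write(dig[c, r * spr : (r + 1) * spr].tobytes())
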