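"""Synthetic stage-labelled EEG epochs for testing without real recordings.

Each sleep stage is described by a :class:`StageProfile`: relative powers
over the classical EEG rhythm bands (delta 0.5-4 Hz, theta 4-8 Hz, alpha
8-13 Hz, sigma 12-16 Hz, beta 16-30 Hz — all inside the 0-35 Hz regime the
preprocessing keeps) and an overall amplitude.  An epoch is a sum of
band-limited Gaussian noise components, one per band, realized with the same
zero-phase Butterworth family the preprocessing uses, plus a small broadband
noise floor; optionally a state-space model colours the floor instead.

The defaults mimic, coarsely, the rhythm structure of wake (alpha/beta
dominant, low amplitude), REM (mixed theta), N1 (theta), N2 (sigma-rich) and
N3 (high-amplitude delta).  This is a test instrument, not a claim of
physiological realism: real EEG has transients (spindles, K-complexes),
artifacts and non-stationarity that these stationary mixtures do not have.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import signal

from .preprocess import EpochMatrix
from .signal_io import AASM, Hypnogram, save_hypnogram
from .sysid import SSModel, simulate_ssm

DEFAULT_FS = 128.0  # Hz; keeps te=30 s epochs divisible by 2**7 for the WPD
DEFAULT_TE = 30.0  # s

#: band name -> (low, high) Hz
BANDS = {
    "delta": (0.5, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "sigma": (12.0, 16.0),
    "beta": (16.0, 30.0),
}


@dataclass(frozen=True)
class StageProfile:
    """Spectral description of one synthetic sleep stage."""

    name: str
    band_powers: dict  # (low_hz, high_hz) -> relative power, sums to 1
    amplitude_sd: float = 20.0  # µV
    dynamics: SSModel | None = None  # optional colouring model for the floor
    noise_fraction: float = 0.05  # relative power of the broadband floor

    def __post_init__(self):
        powers = np.array(list(self.band_powers.values()), dtype=float)
        if np.any(powers < 0) or abs(powers.sum() - 1.0) > 1e-9:
            raise ValueError("band powers must be non-negative and sum to 1")
        for lo, hi in self.band_powers:
            if not (0.0 <= lo < hi <= 35.0):
                raise ValueError(f"band ({lo}, {hi}) outside the 0-35 Hz regime")
        if self.amplitude_sd <= 0:
            raise ValueError("amplitude_sd must be positive")
        if not 0.0 <= self.noise_fraction < 1.0:
            raise ValueError("noise_fraction must be in [0, 1)")


def _named(powers: dict) -> dict:
    return {BANDS[name]: p for name, p in powers.items()}


def default_profiles() -> list:
    """Five profiles loosely mimicking Awa / REM / N1 / N2 / N3."""
    return [
        StageProfile("Awa", _named({"alpha": 0.40, "beta": 0.30,
                                    "theta": 0.15, "delta": 0.15}), 15.0),
        StageProfile("REM", _named({"theta": 0.45, "beta": 0.20,
                                    "alpha": 0.20, "delta": 0.15}), 20.0),
        StageProfile("N1", _named({"theta": 0.50, "alpha": 0.25,
                                   "delta": 0.15, "beta": 0.10}), 25.0),
        StageProfile("N2", _named({"sigma": 0.35, "delta": 0.30,
                                   "theta": 0.25, "beta": 0.10}), 40.0),
        StageProfile("N3", _named({"delta": 0.70, "theta": 0.20,
                                   "alpha": 0.05, "beta": 0.05}), 60.0),
    ]


def _band_sos(lo: float, hi: float, fs: float):
    return signal.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")


def _one_epoch(profile: StageProfile, j: int, fs: float,
               rng: np.random.Generator, seed_for_dynamics: int) -> np.ndarray:
    x = np.zeros(j)
    pad = j  # generate double length, keep the centre: avoids filter edges
    for (lo, hi), power in profile.band_powers.items():
        if power == 0:
            continue
        white = rng.standard_normal(j + pad)
        comp = signal.sosfiltfilt(_band_sos(lo, hi, fs), white)[pad // 2:
                                                               pad // 2 + j]
        sd = comp.std()
        if sd > 0:
            x += np.sqrt(power) * comp / sd
    nf = profile.noise_fraction
    if profile.dynamics is not None:
        floor = simulate_ssm(profile.dynamics, j, 1.0, seed_for_dynamics)
        floor = floor - floor.mean()
    else:
        floor = rng.standard_normal(j)
    sd = floor.std()
    if sd > 0:
        x = np.sqrt(1.0 - nf) * x + np.sqrt(nf) * floor / sd
    return profile.amplitude_sd * x


def generate_stage_epochs(profiles, n_per_stage: int, te: float = DEFAULT_TE,
                          fs: float = DEFAULT_FS, seed: int = 0) -> EpochMatrix:
    """Labelled synthetic epochs, ``n_per_stage`` rows per profile in order."""
    if n_per_stage < 1:
        raise ValueError("n_per_stage must be >= 1")
    j = te * fs
    if abs(j - round(j)) > 1e-9:
        raise ValueError(f"te*fs = {j} is not an integer")
    j = int(round(j))
    profiles = list(profiles)
    rng = np.random.default_rng(seed)
    epochs = np.empty((len(profiles) * n_per_stage, j))
    labels = np.empty(len(profiles) * n_per_stage, dtype=int)
    names = []
    row = 0
    for cls, prof in enumerate(profiles):
        for _ in range(n_per_stage):
            epochs[row] = _one_epoch(prof, j, fs, rng,
                                     seed_for_dynamics=(seed + row) % 2 ** 31)
            labels[row] = cls
            names.append(prof.name)
            row += 1
    return EpochMatrix(epochs, te, fs, labels=labels,
                       stage_names=tuple(names), source_id=f"synth(seed={seed})")


def write_fixture_edf(em: EpochMatrix, path) -> tuple:
    """Write an epoch matrix as an EDF file plus a dreams-style hypnogram.

    Returns ``(edf_path, hypnogram_path)``.  The signal is the row-wise
    concatenation of the epochs; the sidecar text hypnogram holds one stage
    token per epoch so the pair round-trips through the readers (within
    16-bit amplitude quantization).
    """
    from . import _edf

    path = Path(path)
    if em.stage_names is None:
        raise ValueError("epoch matrix carries no stage names to write")
    flat = em.epochs.reshape(-1)
    _edf.write_edf(path, flat, fs=em.fs, channel="EEG synth")
    standard = AASM if set(em.stage_names) <= {"Awa", "REM", "N1", "N2", "N3"} \
        else "R&K"
    hyp = Hypnogram(tuple(em.stage_names), em.te, standard)
    hyp_path = path.with_suffix(".hyp.txt")
    save_hypnogram(hyp, hyp_path, "dreams_txt")
    return path, hyp_path
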