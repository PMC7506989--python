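"""Low-pass filtering and segmentation into fixed-length epochs.

The raw channel is filtered once over the whole record with a zero-phase
forward-backward Butterworth low-pass (default 0-35 Hz, order 8 per pass),
then cut into non-overlapping epochs of ``te`` seconds.  Trailing samples
that do not fill an epoch are dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy import signal

from .signal_io import EEGRecord

logger = logging.getLogger(__name__)

DEFAULT_CUTOFF_HZ = 35.0
DEFAULT_FILTER_ORDER = 8


@dataclass(frozen=True)
class EpochMatrix:
    """L x j matrix of non-overlapping epochs with optional per-row labels."""

    epochs: np.ndarray  # (L, j), µV
    te: float  # epoch length, s
    fs: float  # Hz
    labels: np.ndarray | None = None  # class index per row
    stage_names: tuple | None = None  # canonical stage label per row
    source_id: str = ""

    def __post_init__(self):
        epochs = np.asarray(self.epochs, dtype=float)
        object.__setattr__(self, "epochs", epochs)
        if epochs.ndim != 2 or epochs.shape[0] < 1:
            raise ValueError("epochs must be a non-empty L x j matrix")
        j = self.te * self.fs
        if abs(j - round(j)) > 1e-9 or int(round(j)) != epochs.shape[1]:
            raise ValueError(
                f"epoch length mismatch: te*fs = {j} but matrix has "
                f"{epochs.shape[1]} columns"
            )
        if self.labels is not None:
            labels = np.asarray(self.labels, dtype=int)
            object.__setattr__(self, "labels", labels)
            if labels.shape != (epochs.shape[0],):
                raise ValueError("labels must have one entry per epoch row")

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]

    @property
    def samples_per_epoch(self) -> int:
        return self.epochs.shape[1]


def design_lowpass(fs: float, cutoff: float = DEFAULT_CUTOFF_HZ,
                   order: int = DEFAULT_FILTER_ORDER) -> np.ndarray:
    """Second-order sections of the Butterworth low-pass used throughout."""
    if cutoff >= fs / 2:
        raise ValueError(f"cutoff {cutoff} Hz must be below Nyquist {fs / 2} Hz")
    return signal.butter(order, cutoff, btype="low", fs=fs, output="sos")


def lowpass_filter(rec: EEGRecord, cutoff: float = DEFAULT_CUTOFF_HZ,
                   order: int = DEFAULT_FILTER_ORDER) -> EEGRecord:
    """Zero-phase low-pass; same length and sampling rate as the input."""
    sos = design_lowpass(rec.fs, cutoff, order)
    filtered = signal.sosfiltfilt(sos, rec.samples)
    return EEGRecord(filtered, rec.fs, rec.channel, rec.source_id)


def epoch_signal(rec: EEGRecord, te: float) -> EpochMatrix:
    """Cut the record into floor(M / (te*fs)) non-overlapping epochs."""
    j = te * rec.fs
    if abs(j - round(j)) > 1e-9:
        raise ValueError(f"te*fs = {j} is not an integer number of samples")
    j = int(round(j))
    m = rec.n_samples
    if m < j:
        raise ValueError(f"record has {m} samples, fewer than one epoch ({j})")
    n = m // j
    dropped = m - n * j
    if dropped:
        logger.info("dropping %d trailing samples that do not fill an epoch",
                    dropped)
    epochs = rec.samples[: n * j].reshape(n, j).copy()
    return EpochMatrix(epochs, te, rec.fs, source_id=rec.source_id)


def align_epochs_labels(em: EpochMatrix, classes: np.ndarray,
                        keep: np.ndarray) -> EpochMatrix:
    """Attach class labels row-wise, removing epochs masked out by ``keep``."""
    keep = np.asarray(keep, dtype=bool)
    classes = np.asarray(classes, dtype=int)
    if em.n_epochs != keep.size:
        raise ValueError(
            f"{em.n_epochs} epochs but keep-mask covers {keep.size} scoring "
            "epochs"
        )
    if classes.size != int(keep.sum()):
        raise ValueError(
            f"{classes.size} class labels but mask keeps {int(keep.sum())} epochs"
        )
    return EpochMatrix(
        em.epochs[keep], em.te, em.fs, labels=classes, source_id=em.source_id
    )
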