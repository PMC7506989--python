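"""EDF reading, hypnogram parsing and sleep-stage label schemes.

Recordings are read with MNE; hypnograms come either from EDF+ annotation
tracks or from one-label-per-line text files as distributed with the public
polysomnography collections (DREAMS-style and ISRUC-style dialects).

Stage labels are normalized to a canonical alphabet: ``Awa``, ``REM``,
``S1``..``S4`` under the six-stage R&K scoring manual, ``Awa``, ``REM``,
``N1``..``N3`` under the AASM manual, plus the sentinel ``excluded`` for
movement/unknown epochs, which are masked out rather than merged into wake.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

RK = "R&K"
AASM = "AASM"
EXCLUDED = "excluded"

RK_STAGES = ("Awa", "REM", "S1", "S2", "S3", "S4")
AASM_STAGES = ("Awa", "REM", "N1", "N2", "N3")

# class merging under each scoring manual, from 2-class up to the full set
_RK_GROUPS = {
    6: [["Awa"], ["REM"], ["S1"], ["S2"], ["S3"], ["S4"]],
    5: [["Awa"], ["REM"], ["S1"], ["S2"], ["S3", "S4"]],
    4: [["Awa"], ["REM"], ["S1", "S2"], ["S3", "S4"]],
    3: [["Awa"], ["REM"], ["S1", "S2", "S3", "S4"]],
    2: [["Awa"], ["REM", "S1", "S2", "S3", "S4"]],
}
_AASM_GROUPS = {
    5: [["Awa"], ["REM"], ["N1"], ["N2"], ["N3"]],
    4: [["Awa"], ["REM"], ["N1", "N2"], ["N3"]],
    3: [["Awa"], ["REM"], ["N1", "N2", "N3"]],
    2: [["Awa"], ["REM", "N1", "N2", "N3"]],
}


@dataclass(frozen=True)
class EEGRecord:
    """One channel of a recording, in the physical units of the file header."""

    samples: np.ndarray  # µV
    fs: float  # Hz
    channel: str
    source_id: str = ""

    def __post_init__(self):
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if self.fs <= 0:
            raise ValueError(f"sampling frequency must be positive, got {self.fs}")
        if samples.ndim != 1 or samples.size == 0:
            raise ValueError("samples must be a non-empty 1-D vector")
        if not np.all(np.isfinite(samples)):
            raise ValueError("samples contain non-finite values")

    @property
    def n_samples(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs


@dataclass(frozen=True)
class Hypnogram:
    """Expert stage labels, one per scoring epoch."""

    labels: tuple
    epoch_seconds: float
    standard: str  # RK or AASM

    def __post_init__(self):
        object.__setattr__(self, "labels", tuple(self.labels))
        if self.standard not in (RK, AASM):
            raise ValueError(f"unknown scoring standard {self.standard!r}")
        alphabet = set(RK_STAGES if self.standard == RK else AASM_STAGES)
        alphabet.add(EXCLUDED)
        bad = [lab for lab in self.labels if lab not in alphabet]
        if bad:
            raise ValueError(f"labels outside the {self.standard} alphabet: {bad[:5]}")
        if not self.labels:
            raise ValueError("hypnogram has zero labels")

    def __len__(self) -> int:
        return len(self.labels)


@dataclass(frozen=True)
class LabelScheme:
    """Mapping from canonical stage labels to contiguous class indices."""

    standard: str
    n_classes: int
    mapping: dict = field(default_factory=dict)
    class_names: tuple = ()

    @staticmethod
    def rk(n_classes: int) -> "LabelScheme":
        return _scheme(RK, n_classes, _RK_GROUPS)

    @staticmethod
    def aasm(n_classes: int) -> "LabelScheme":
        return _scheme(AASM, n_classes, _AASM_GROUPS)


def _scheme(standard, n_classes, groups_table) -> LabelScheme:
    if n_classes not in groups_table:
        raise ValueError(
            f"{standard} supports {sorted(groups_table)} classes, got {n_classes}"
        )
    groups = groups_table[n_classes]
    mapping = {stage: idx for idx, group in enumerate(groups) for stage in group}
    if n_classes == 2:
        names = ("Awa", "Asleep")
    elif n_classes == 3:
        names = ("Awa", "REM", "NREM")
    else:
        names = tuple("+".join(g) for g in groups)
    return LabelScheme(standard, n_classes, mapping, names)


def load_recording(path, channel: str) -> EEGRecord:
    """Read one EEG channel from an EDF/EDF+ file, in µV.

    Channel matching is exact after whitespace/case normalization; a missing
    channel raises with the list of available channels.
    """
    import mne

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such EDF file: {path}")
    raw = mne.io.read_raw_edf(path, preload=False, verbose="error")
    wanted = channel.strip().casefold()
    matches = [ch for ch in raw.ch_names if ch.strip().casefold() == wanted]
    if not matches:
        raise ValueError(
            f"channel {channel!r} not found in {path.name}; "
            f"available channels: {raw.ch_names}"
        )
    data = raw.get_data(picks=[matches[0]], units="uV")[0]
    return EEGRecord(
        samples=data,
        fs=float(raw.info["sfreq"]),
        channel=matches[0],
        source_id=path.name,
    )


# --- hypnogram dialects ----------------------------------------------------

# text token -> canonical stage; covers letter codes, stage digits and the
# AASM N-codes.  Codes conventionally meaning movement/unknown map to the
# exclusion sentinel and are preserved, never dropped.
_TEXT_TOKENS = {
    "W": "Awa", "A": "Awa", "AWA": "Awa", "WAKE": "Awa",
    "R": "REM", "REM": "REM",
    "1": "S1", "2": "S2", "3": "S3", "4": "S4",
    "S1": "S1", "S2": "S2", "S3": "S3", "S4": "S4",
    "N1": "N1", "N2": "N2", "N3": "N3",
}
_TEXT_EXCLUDED = {"9", "-1", "M", "MT", "?", "X", "U"}

# ISRUC-style numeric codes (AASM scoring)
_ISRUC_TOKENS = {"0": "Awa", "1": "N1", "2": "N2", "3": "N3", "5": "REM"}
_ISRUC_EXCLUDED = {"7", "9", "-1", "?"}

# EDF+ annotation descriptions
_EDFPLUS_DESC = {
    "Sleep stage W": "Awa", "Sleep stage R": "REM",
    "Sleep stage 1": "S1", "Sleep stage 2": "S2",
    "Sleep stage 3": "S3", "Sleep stage 4": "S4",
    "Sleep stage N1": "N1", "Sleep stage N2": "N2", "Sleep stage N3": "N3",
    "Sleep stage ?": EXCLUDED, "Movement time": EXCLUDED,
}
_STAGE_TO_DESC = {
    "Awa": "Sleep stage W", "REM": "Sleep stage R",
    "S1": "Sleep stage 1", "S2": "Sleep stage 2",
    "S3": "Sleep stage 3", "S4": "Sleep stage 4",
    "N1": "Sleep stage N1", "N2": "Sleep stage N2", "N3": "Sleep stage N3",
    EXCLUDED: "Sleep stage ?",
}

DIALECTS = ("edfplus", "dreams_txt", "isruc_txt")


def _infer_standard(labels, fallback=RK) -> str:
    stages = set(labels) - {EXCLUDED}
    if stages & {"N1", "N2", "N3"}:
        return AASM
    if stages & {"S1", "S2", "S3", "S4"}:
        return RK
    return fallback


def load_hypnogram(
    path, dialect: str, epoch_seconds: float, standard: str | None = None
) -> Hypnogram:
    """Parse a hypnogram file into one canonical label per scoring epoch."""
    path = Path(path)
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")
    if not path.exists():
        raise FileNotFoundError(f"no such hypnogram file: {path}")

    if dialect == "edfplus":
        labels = _parse_edfplus(path, epoch_seconds)
    else:
        tokens = _ISRUC_TOKENS if dialect == "isruc_txt" else _TEXT_TOKENS
        excluded = _ISRUC_EXCLUDED if dialect == "isruc_txt" else _TEXT_EXCLUDED
        labels = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                tok = line.strip()
                if not tok or tok.startswith("["):
                    continue
                key = tok.upper() if dialect == "dreams_txt" else tok
                if key in tokens:
                    labels.append(tokens[key])
                elif key in excluded:
                    labels.append(EXCLUDED)
                else:
                    raise ValueError(
                        f"unknown stage code {tok!r} at {path.name}:{lineno}"
                    )
    if not labels:
        raise ValueError(f"hypnogram {path.name} contains zero labels")
    if standard is None:
        standard = AASM if dialect == "isruc_txt" else _infer_standard(labels)
    return Hypnogram(tuple(labels), float(epoch_seconds), standard)


def _parse_edfplus(path, epoch_seconds: float) -> list:
    import mne

    ann = mne.read_annotations(str(path))
    events = sorted(
        (
            (float(a["onset"]), float(a["duration"]), a["description"])
            for a in ann
            if a["description"] in _EDFPLUS_DESC
        ),
        key=lambda t: t[0],
    )
    labels: list = []
    for onset, duration, desc in events:
        n = max(1, int(round(duration / epoch_seconds)))
        labels.extend([_EDFPLUS_DESC[desc]] * n)
    return labels


def save_hypnogram(hyp: Hypnogram, path, dialect: str) -> None:
    """Write a hypnogram in one of the supported dialects (round-trip safe)."""
    path = Path(path)
    if dialect == "dreams_txt":
        inverse = {"Awa": "W", "REM": "R", "S1": "1", "S2": "2", "S3": "3",
                   "S4": "4", "N1": "N1", "N2": "N2", "N3": "N3", EXCLUDED: "9"}
        path.write_text("".join(inverse[lab] + "\n" for lab in hyp.labels))
    elif dialect == "isruc_txt":
        if hyp.standard != AASM:
            raise ValueError("the isruc_txt dialect encodes AASM labels only")
        inverse = {"Awa": "0", "N1": "1", "N2": "2", "N3": "3", "REM": "5",
                   EXCLUDED: "7"}
        path.write_text("".join(inverse[lab] + "\n" for lab in hyp.labels))
    elif dialect == "edfplus":
        from . import _edf

        anns = [
            (i * hyp.epoch_seconds, hyp.epoch_seconds, _STAGE_TO_DESC[lab])
            for i, lab in enumerate(hyp.labels)
        ]
        # carrier channel: one sample per record keeps the file tiny
        dummy = np.zeros(len(hyp.labels))
        _edf.write_edf(
            path, dummy, fs=1.0 / hyp.epoch_seconds, channel="carrier",
            annotations=anns, record_duration=hyp.epoch_seconds,
        )
    else:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")


def map_labels(hyp: Hypnogram, scheme: LabelScheme):
    """Map stage labels to class indices under ``scheme``.

    Returns ``(classes, keep)`` where ``keep`` is a boolean mask over the
    hypnogram (False for excluded epochs) and ``classes`` holds the class
    index of each *kept* epoch, in order.
    """
    if hyp.standard != scheme.standard:
        raise ValueError(
            f"hypnogram follows {hyp.standard} but scheme is {scheme.standard}"
        )
    keep = np.array([lab != EXCLUDED for lab in hyp.labels], dtype=bool)
    classes = np.array(
        [scheme.mapping[lab] for lab in hyp.labels if lab != EXCLUDED], dtype=int
    )
    return classes, keep
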