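"""Record I/O and preprocessing for two-channel EEG records.

Records follow the Bern-Barcelona layout: plain ASCII text, one sample pair
per line, two columns ``X`` and ``Y`` recorded from adjacent intracranial
channels at 512 Hz.  Preprocessing forms the noise-reduced difference channel
``X - Y`` and applies a first-difference (differential) operator before
wavelet decomposition.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np

DEFAULT_FS = 512.0

LABELS = ("focal", "nonfocal", "unknown")


class RecordFormatError(ValueError):
    """Raised when a record file does not parse as two numeric columns."""


@dataclass
class EEGRecordPair:
    """One record: two adjacent-channel time series (microvolts).

    Parameters
    ----------
    x, y : ndarray
        Equal-length sample sequences for the two channels.
    fs : float
        Sampling rate in Hz (default 512).
    label : str
        One of ``focal``, ``nonfocal``, ``unknown``.
    """

    x: np.ndarray
    y: np.ndarray
    fs: float = DEFAULT_FS
    label: str = "unknown"

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.ndim != 1 or self.y.ndim != 1:
            raise ValueError("channels must be one-dimensional")
        if len(self.x) != len(self.y):
            raise ValueError(
                f"channel length mismatch: len(x)={len(self.x)} != len(y)={len(self.y)}"
            )
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if self.label not in LABELS:
            raise ValueError(f"label must be one of {LABELS}, got {self.label!r}")

    def __len__(self) -> int:
        return len(self.x)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, EEGRecordPair):
            return NotImplemented
        return (
            np.array_equal(self.x, other.x)
            and np.array_equal(self.y, other.y)
            and self.fs == other.fs
            and self.label == other.label
        )


@dataclass
class Signal:
    """A single real-valued time series with its sampling rate."""

    samples: np.ndarray
    fs: float = DEFAULT_FS

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")

    def __len__(self) -> int:
        return len(self.samples)


_LABEL_PATTERNS = {
    "focal": re.compile(r"(?i)\bf(ocal)?[_\-]?\d|focal"),
    "nonfocal": re.compile(r"(?i)\bn(onfocal)?[_\-]?\d|nonfocal"),
}


def infer_label(path: str | Path) -> str:
    """Infer the class label from a filename, Bern-Barcelona style.

    Filenames containing ``nonfocal``/``N_…`` map to nonfocal, ``focal``/
    ``F_…`` to focal; anything else is ``unknown``.  The dataset encodes
    class membership in filenames, not in file content.
    """
    name = Path(path).name
    if _LABEL_PATTERNS["nonfocal"].search(name):
        return "nonfocal"
    if _LABEL_PATTERNS["focal"].search(name):
        return "focal"
    return "unknown"


def read_record(
    path: str | Path,
    fs: float = DEFAULT_FS,
    label: str | None = None,
) -> EEGRecordPair:
    """Read a two-column ASCII record (comma- or whitespace-separated).

    Each non-empty line must hold exactly two real numbers ``x, y``.
    ``label`` defaults to the filename convention (see :func:`infer_label`).
    """
    path = Path(path)
    xs: list[float] = []
    ys: list[float] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            parts = stripped.replace(",", " ").split()
            if len(parts) != 2:
                raise RecordFormatError(
                    f"{path}:{lineno}: expected two columns, got {len(parts)}"
                )
            try:
                xs.append(float(parts[0]))
                ys.append(float(parts[1]))
            except ValueError as exc:
                raise RecordFormatError(
                    f"{path}:{lineno}: could not parse {stripped!r}"
                ) from exc
    if not xs:
        raise RecordFormatError(f"{path}: empty record file")
    return EEGRecordPair(
        x=np.asarray(xs),
        y=np.asarray(ys),
        fs=fs,
        label=label if label is not None else infer_label(path),
    )


def write_record(pair: EEGRecordPair, path: str | Path, fmt: str = "%.17g") -> Path:
    """Write a record in the two-column comma-separated dialect.

    The default float format round-trips IEEE doubles bit-exactly through
    :func:`read_record`.
    """
    path = Path(path)
    with open(path, "w") as fh:
        for xv, yv in zip(pair.x, pair.y):
            fh.write(f"{fmt % xv}, {fmt % yv}\n")
    return path


def channel_difference(pair: EEGRecordPair) -> Signal:
    """Noise-reduced difference channel ``X - Y``.

    Subtracting the adjacent channel cancels interference common to both
    electrodes (mains pickup, reference drift) while preserving local
    activity that differs between them.
    """
    return Signal(samples=pair.x - pair.y, fs=pair.fs)


def differencing(signal: Signal) -> Signal:
    """First-difference operator: ``out[i] = in[i+1] - in[i]``.

    A length-n input yields n-1 samples; this whitens the 1/f trend of EEG
    before decomposition.
    """
    if len(signal) < 2:
        raise ValueError(f"differencing needs >= 2 samples, got {len(signal)}")
    return Signal(samples=np.diff(signal.samples), fs=signal.fs)


def preprocess_record(pair: EEGRecordPair) -> Signal:
    """Full preprocessing chain: channel difference then first differencing."""
    return differencing(channel_difference(pair))


def read_dataset(
    paths: Iterable[str | Path], fs: float = DEFAULT_FS
) -> list[EEGRecordPair]:
    """Read a collection of record files, labels inferred from filenames."""
    return [read_record(p, fs=fs) for p in paths]
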