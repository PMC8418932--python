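"""Seeded generator of focal-like and nonfocal-like EEG record pairs.

The generator emulates the statistical contrast the discrimination method
exploits, not the physiology of epileptic tissue: focal-like records are
more rhythmic and less random (a few theta/alpha-band sinusoids plus a
narrowband AR(2) process and low-variance white noise), nonfocal-like
records are broadband and noisier (a wide-pole AR(2) process plus
higher-variance white noise).  Each record's two channels X and Y carry
independent realizations of the class process plus a SHARED interference
term (mains hum and slow drift) plus small per-channel sensor noise, so
the preprocessing difference X - Y cancels the common interference while
keeping the class signature.

Records are deterministic functions of (seed, class, index) and are
written in the same two-column ASCII dialect the preprocessing module
reads.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .preprocess import EEGRecordPair

__all__ = ["SynthConfig", "generate_record", "generate_dataset", "write_dataset"]


@dataclass(frozen=True)
class SynthConfig:
    """Generator settings.

    Amplitudes are in microvolts.  ``focal_rhythm_freqs`` bounds the band
    the focal rhythm is drawn from (theta/alpha, 4-12 Hz).  The AR(2)
    processes are parameterized by pole radius and center frequency:
    focal poles sit close to the unit circle at the rhythm frequency
    (narrowband), nonfocal poles are well inside it (broadband).
    """

    n_per_class: int = 50
    fs: float = 512.0
    duration: float = 20.0
    focal_rhythm_freqs: tuple[float, float] = (4.0, 12.0)
    focal_noise_sd: float = 5.0
    nonfocal_noise_sd: float = 25.0
    focal_ar: tuple[float, float] = (0.97, 8.0)      # (pole radius, pole freq Hz)
    nonfocal_ar: tuple[float, float] = (0.6, 40.0)
    focal_ar_sd: float = 8.0
    nonfocal_ar_sd: float = 25.0
    focal_sin_amp: tuple[float, float] = (10.0, 18.0)
    mains_amp: float = 15.0
    drift_amp: float = 30.0
    channel_noise_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_class < 1:
            raise ValueError("n_per_class must be >= 1")
        if self.fs * self.duration < 64:
            raise ValueError("fs * duration must be >= 64 samples")
        if self.nonfocal_noise_sd <= self.focal_noise_sd:
            raise ValueError(
                "nonfocal_noise_sd must exceed focal_noise_sd "
                "(the nonfocal class is the more random one)"
            )

    @property
    def n_samples(self) -> int:
        return int(round(self.fs * self.duration))


def _ar2(
    radius: float,
    freq_hz: float,
    fs: float,
    n: int,
    target_sd: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Seeded AR(2) realization with poles radius*exp(+-2i*pi*f/fs),
    rescaled to the target standard deviation; 1 s burn-in discarded."""
    theta_p = 2.0 * np.pi * freq_hz / fs
    a1 = 2.0 * radius * np.cos(theta_p)
    a2 = -radius * radius
    burn = int(fs)
    e = rng.standard_normal(n + burn)
    x = lfilter([1.0], [1.0, -a1, -a2], e)[burn:]
    sd = x.std()
    if sd > 0:
        x = x * (target_sd / sd)
    return x


def _class_signal(
    label: str, cfg: SynthConfig, rng: np.random.Generator, n: int
) -> np.ndarray:
    t = np.arange(n) / cfg.fs
    if label == "focal":
        n_sin = int(rng.integers(2, 4))
        lo, hi = cfg.focal_rhythm_freqs
        sig = np.zeros(n)
        for _ in range(n_sin):
            f = rng.uniform(lo, hi)
            amp = rng.uniform(*cfg.focal_sin_amp)
            sig += amp * np.sin(2.0 * np.pi * f * t + rng.uniform(0, 2 * np.pi))
        sig += _ar2(*cfg.focal_ar, cfg.fs, n, cfg.focal_ar_sd, rng)
        sig += rng.normal(0.0, cfg.focal_noise_sd, n)
    elif label == "nonfocal":
        sig = _ar2(*cfg.nonfocal_ar, cfg.fs, n, cfg.nonfocal_ar_sd, rng)
        sig += rng.normal(0.0, cfg.nonfocal_noise_sd, n)
    else:
        raise ValueError(f"class must be 'focal' or 'nonfocal', got {label!r}")
    return sig


def generate_record(label: str, cfg: SynthConfig, index: int) -> EEGRecordPair:
    """One seeded two-channel record of the requested class.

    The record is a pure function of (cfg.seed, class, index).
    """
    class_id = {"focal": 0, "nonfocal": 1}.get(label)
    if class_id is None:
        raise ValueError(f"class must be 'focal' or 'nonfocal', got {label!r}")
    rng = np.random.default_rng([cfg.seed, class_id, index])
    n = cfg.n_samples
    t = np.arange(n) / cfg.fs

    # interference common to both channels: mains hum + slow drift
    common = cfg.mains_amp * np.sin(
        2.0 * np.pi * 50.0 * t + rng.uniform(0, 2 * np.pi)
    ) + cfg.drift_amp * np.sin(2.0 * np.pi * 0.3 * t + rng.uniform(0, 2 * np.pi))

    x = (
        _class_signal(label, cfg, rng, n)
        + common
        + rng.normal(0.0, cfg.channel_noise_sd, n)
    )
    y = (
        _class_signal(label, cfg, rng, n)
        + common
        + rng.normal(0.0, cfg.channel_noise_sd, n)
    )
    return EEGRecordPair(x=x, y=y, fs=cfg.fs, label=label)


def generate_dataset(cfg: SynthConfig) -> list[EEGRecordPair]:
    """n_per_class records per class, focal first, labels attached."""
    records = []
    for label in ("focal", "nonfocal"):
        for i in range(cfg.n_per_class):
            records.append(generate_record(label, cfg, i))
    return records


def write_dataset(
    records: list[EEGRecordPair], out_dir: str | Path, cfg: SynthConfig | None = None
) -> pd.DataFrame:
    """Write records as two-column ASCII files plus a manifest CSV.

    Filenames follow the class-in-filename convention
    (``focal_0001.txt`` / ``nonfocal_0001.txt``).
    """
    from .preprocess import write_record

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    counters: dict[str, int] = {}
    for rec in records:
        idx = counters.get(rec.label, 0)
        counters[rec.label] = idx + 1
        name = f"{rec.label}_{idx + 1:04d}.txt"
        write_record(rec, out_dir / name)
        row = {"filename": name, "label": rec.label, "index": idx}
        if cfg is not None:
            row.update(seed=cfg.seed, fs=cfg.fs, duration=cfg.duration)
        rows.append(row)
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest
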