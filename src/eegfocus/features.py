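"""Subband entropy features and Kruskal-Wallis screening.

Four entropies are computed per TQWT subband and concatenated into one
feature vector per record (4*(J+1) values; 108 at J=26):

* LE   — log-energy: sum_i log(s_i**2), with the log(0) term taken as 0.
* LL2  — log of the total energy: log(sum_i s_i**2).
* SURE — Stein's unbiased risk estimate at threshold eps:
         n - #{i : |s_i| <= eps} + sum_i min(s_i**2, eps**2).
* TH   — threshold entropy: #{i : |s_i| > eps}.

The threshold eps defaults to 0.2.  Logs are natural by default with a
base-2 option.  Thresholds compare |s_i| (wavelet coefficients are signed);
ties at exactly eps count as below threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .tqwt import SubbandSet

__all__ = [
    "EntropyConfig",
    "FeatureMatrix",
    "le_entropy",
    "ll2_entropy",
    "sure_entropy",
    "th_entropy",
    "extract_features",
    "feature_names",
    "kws_pvalues",
    "kws_mask",
]

ENTROPY_NAMES = ("LE", "LL2", "SURE", "TH")


@dataclass(frozen=True)
class EntropyConfig:
    """Entropy settings: threshold ``epsilon`` (> 0) and log base.

    ``log_base=None`` means natural log; ``2`` selects base-2 logs in LE
    and LL2.
    """

    epsilon: float = 0.2
    log_base: float | None = None

    def __post_init__(self) -> None:
        if self.epsilon <= 0:
            raise ValueError(f"epsilon must be positive, got {self.epsilon}")

    def _log(self, x):
        if self.log_base is None:
            return np.log(x)
        return np.log(x) / np.log(self.log_base)


DEFAULT_ENTROPY_CONFIG = EntropyConfig()


def _as_seq(s) -> np.ndarray:
    s = np.asarray(s, dtype=float)
    if s.size == 0:
        raise ValueError("entropy of an empty sequence is undefined")
    return s.ravel()


def le_entropy(s, cfg: EntropyConfig = DEFAULT_ENTROPY_CONFIG) -> float:
    """Log-energy entropy: sum of log(s_i**2), zero terms contributing 0."""
    s = _as_seq(s)
    sq = s * s
    nz = sq > 0.0
    if not nz.any():
        return 0.0
    return float(np.sum(cfg._log(sq[nz])))


def ll2_entropy(s, cfg: EntropyConfig = DEFAULT_ENTROPY_CONFIG) -> float:
    """Log of the summed squared coefficients; 0 for an all-zero sequence."""
    s = _as_seq(s)
    total = float(np.sum(s * s))
    if total == 0.0:
        warnings.warn(
            "ll2_entropy of an all-zero sequence: returning 0 by convention",
            RuntimeWarning,
            stacklevel=2,
        )
        return 0.0
    return float(cfg._log(total))


def sure_entropy(s, cfg: EntropyConfig = DEFAULT_ENTROPY_CONFIG) -> float:
    """Stein risk entropy: n - #{|s_i| <= eps} + sum min(s_i**2, eps**2)."""
    s = _as_seq(s)
    eps = cfg.epsilon
    n = s.size
    below = int(np.count_nonzero(np.abs(s) <= eps))
    return float(n - below + np.sum(np.minimum(s * s, eps * eps)))


def th_entropy(s, cfg: EntropyConfig = DEFAULT_ENTROPY_CONFIG) -> float:
    """Threshold entropy: number of coefficients with |s_i| > eps."""
    s = _as_seq(s)
    return float(np.count_nonzero(np.abs(s) > cfg.epsilon))


_ENTROPY_FUNCS = {
    "LE": le_entropy,
    "LL2": ll2_entropy,
    "SURE": sure_entropy,
    "TH": th_entropy,
}


def feature_names(J: int) -> list[str]:
    """Ordered labels ``{entropy}_{subband}``; subband J+1 is the approximation."""
    names = []
    for ent in ENTROPY_NAMES:
        names += [f"{ent}_d{j}" for j in range(1, J + 1)]
        names.append(f"{ent}_a{J}")
    return names


def extract_features(
    subbands: SubbandSet, cfg: EntropyConfig = DEFAULT_ENTROPY_CONFIG
) -> np.ndarray:
    """4*(J+1) feature vector: LE block, then LL2, SURE, TH, each over
    subbands 1..J+1 in order (details high-to-low frequency, approximation
    last)."""
    seqs = subbands.subbands
    values = []
    for ent in ENTROPY_NAMES:
        func = _ENTROPY_FUNCS[ent]
        for j, s in enumerate(seqs, start=1):
            v = func(s, cfg)
            if not np.isfinite(v):
                raise ArithmeticError(
                    f"{ent} entropy of subband {j} is non-finite ({v})"
                )
            values.append(v)
    return np.asarray(values)


@dataclass
class FeatureMatrix:
    """Records-by-features table with per-record class labels."""

    values: np.ndarray
    labels: np.ndarray
    feature_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.values.ndim != 2:
            raise ValueError("feature matrix must be two-dimensional")
        if len(self.labels) != self.values.shape[0]:
            raise ValueError("one label per row required")
        if not np.isfinite(self.values).all():
            raise ValueError("feature matrix contains non-finite entries")
        if not self.feature_names:
            self.feature_names = [f"f{i}" for i in range(self.values.shape[1])]
        if len(self.feature_names) != self.values.shape[1]:
            raise ValueError("one name per feature column required")

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def select(self, mask) -> "FeatureMatrix":
        """Restrict to the feature columns where ``mask`` is nonzero."""
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != (self.n_features,):
            raise ValueError("mask length must equal the feature count")
        names = [n for n, m in zip(self.feature_names, mask) if m]
        return FeatureMatrix(self.values[:, mask], self.labels, names)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.feature_names)
        df["label"] = self.labels
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "FeatureMatrix":
        df = pd.read_csv(path)
        labels = df.pop("label").to_numpy()
        return cls(df.to_numpy(dtype=float), labels, list(df.columns))


def kws_pvalues(matrix: FeatureMatrix) -> np.ndarray:
    """Two-sample Kruskal-Wallis p-value per feature column.

    The Kruskal-Wallis rank test (equivalent to the Mann-Whitney test for
    two groups) screens each entropy feature for a class effect; features
    with p < 0.05 are conventionally kept.
    """
    classes = np.unique(matrix.labels)
    if len(classes) != 2:
        raise ValueError(f"exactly two classes required, got {list(classes)}")
    a = matrix.values[matrix.labels == classes[0]]
    b = matrix.values[matrix.labels == classes[1]]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each class needs at least two rows")
    pvals = np.empty(matrix.n_features)
    for i in range(matrix.n_features):
        col_a, col_b = a[:, i], b[:, i]
        if np.ptp(np.concatenate([col_a, col_b])) == 0.0:
            pvals[i] = 1.0  # constant column: no group effect
        else:
            pvals[i] = stats.kruskal(col_a, col_b).pvalue
    return pvals


def kws_mask(matrix: FeatureMatrix, alpha: float = 0.05) -> np.ndarray:
    """Screening mask: True for features with Kruskal-Wallis p < alpha."""
    return kws_pvalues(matrix) < alpha


def pvalues_to_csv(matrix: FeatureMatrix, path) -> None:
    """Write a (feature, p) two-column CSV."""
    pd.DataFrame(
        {"feature": matrix.feature_names, "p": kws_pvalues(matrix)}
    ).to_csv(path, index=False)
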