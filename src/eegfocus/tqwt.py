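"""Tunable Q-factor wavelet transform (TQWT).

An oversampled, perfect-reconstruction wavelet transform for oscillatory
signals whose Q-factor (oscillation count) and redundancy r are user-set.
Each analysis stage splits the current low-pass branch with a two-channel
filter bank realized directly in the DFT domain:

    F0(w) = 1                                for |w| <  (1-b)*pi
            theta((w + (b-1)*pi)/(a+b-1))    for (1-b)*pi <= |w| < a*pi
            0                                for a*pi <= |w| <= pi

    F1(w) = 0                                for |w| <  (1-b)*pi
            theta((a*pi - w)/(a+b-1))        for (1-b)*pi <= |w| < a*pi
            1                                for a*pi <= |w| <= pi

with theta the 2*pi-periodic power-complementary Daubechies response
``theta(w) = 0.5*(1+cos w)*sqrt(2-cos w)``, low-pass scaling a = 1 - b/r and
high-pass scaling b = 2/(Q+1).  Scaling is frequency-domain resampling: the
low-pass output keeps the band |w| <= a*pi on 2*round(a*N/2) DFT bins, the
high-pass output keeps (1-b)*pi <= |w| <= pi on 2*round(b*N/2) bins (the
radix-2 realization: inputs are zero-padded to the next power of two, and
subband lengths are rounded to even integers at every stage, so arbitrary —
including odd — input lengths are handled).  J stages yield J detail
subbands (detail 1 = highest frequency) plus one final approximation.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .preprocess import Signal

__all__ = [
    "TQWTParams",
    "SubbandSet",
    "design_params",
    "theta",
    "max_levels",
    "decompose",
    "reconstruct",
    "subband_freq",
    "save_subbands",
    "load_subbands",
]

# Smallest admissible low-pass branch length, in units of 1/beta samples:
# the level rule keeps beta * (final low-pass length) >= _MIN_BETA_N.
_MIN_BETA_N = 8.0


class TQWTDesignError(ValueError):
    """Raised for (Q, r, J) combinations that do not yield a valid filter bank."""


@dataclass(frozen=True)
class TQWTParams:
    """Transform parameters: Q-factor, redundancy, derived scalings, levels.

    ``beta = 2/(Q+1)`` and ``alpha = 1 - beta/r``; the redundancy and
    Q-factor are recovered as ``r = beta/(1-alpha)`` and ``Q = (2-beta)/beta``.
    """

    Q: float
    r: float
    alpha: float
    beta: float
    J: int


@dataclass
class SubbandSet:
    """J+1 variable-length coefficient sequences from one decomposition.

    ``details[0]`` is the highest-frequency subband (detail 1); the
    approximation is the final low-pass output and is conventionally listed
    last (subband J+1).
    """

    details: list[np.ndarray]
    approximation: np.ndarray
    params: TQWTParams
    n_original: int
    fs: float = 512.0

    @property
    def subbands(self) -> list[np.ndarray]:
        """All J+1 sequences, details 1..J then the approximation."""
        return list(self.details) + [self.approximation]

    def __len__(self) -> int:
        return len(self.details) + 1


def design_params(Q: float, r: float, J: int) -> TQWTParams:
    """Derive the filter-bank scalings (alpha, beta) from (Q, r) and check J.

    Raises
    ------
    TQWTDesignError
        If Q < 1, r <= 1, J < 1, or the implied scalings leave no
        transition band (alpha + beta <= 1) or a non-positive alpha.
    """
    if Q < 1:
        raise TQWTDesignError(f"Q must be >= 1, got {Q}")
    if r <= 1:
        raise TQWTDesignError(f"r must be > 1, got {r}")
    if J < 1 or int(J) != J:
        raise TQWTDesignError(f"J must be a positive integer, got {J}")
    beta = 2.0 / (Q + 1.0)
    alpha = 1.0 - beta / r
    if alpha <= 0:
        raise TQWTDesignError(f"alpha = {alpha} <= 0 for Q={Q}, r={r}")
    if alpha + beta <= 1:
        raise TQWTDesignError(
            f"alpha + beta = {alpha + beta} <= 1 for Q={Q}, r={r}: "
            "degenerate transition band"
        )
    return TQWTParams(Q=float(Q), r=float(r), alpha=alpha, beta=beta, J=int(J))


def theta(omega):
    """Power-complementary transition response theta(w) on [0, pi].

    ``theta(w) = 0.5*(1 + cos w) * sqrt(2 - cos w)``; satisfies
    ``theta(w)**2 + theta(pi - w)**2 == 1``.
    """
    w = np.asarray(omega, dtype=float)
    if np.any(w < -1e-12) or np.any(w > np.pi + 1e-12):
        raise ValueError("theta is defined on [0, pi]")
    w = np.clip(w, 0.0, np.pi)
    val = 0.5 * (1.0 + np.cos(w)) * np.sqrt(2.0 - np.cos(w))
    return val if val.ndim else float(val)


def max_levels(n: int, Q: float, r: float) -> int:
    """Largest admissible decomposition level for a length-n signal.

    ``Jmax = floor( log(beta*n/8) / log(1/alpha) )`` — the deepest level at
    which every subband still retains enough samples for the transition-band
    filters.  For a 20 s, 512 Hz record after first differencing
    (n = 10239) at Q = r = 3 this gives 35.
    """
    if n < 4:
        raise ValueError(f"signal too short for decomposition: n={n}")
    p = design_params(Q, r, 1)
    arg = p.beta * n / _MIN_BETA_N
    if arg * p.alpha < 1.0:
        # not even one level fits
        raise ValueError(f"signal too short for even one level: n={n}, Q={Q}, r={r}")
    return int(np.floor(np.log(arg) / np.log(1.0 / p.alpha)))


def _even_round(x: float) -> int:
    return 2 * int(round(x / 2.0))


def _stage_lengths(N: int, alpha: float, beta: float) -> tuple[int, int]:
    N0 = _even_round(alpha * N)
    N1 = _even_round(beta * N)
    if N0 < 4 or N1 < 2 or N0 >= N or N0 + N1 <= N:
        raise TQWTDesignError(
            f"stage of length {N} admits no valid split (N0={N0}, N1={N1})"
        )
    return N0, N1


def _stage_windows(N: int, N0: int, N1: int) -> tuple[np.ndarray, np.ndarray, int]:
    """Real gain windows for one analysis/synthesis stage.

    Returns ``(g0, g1, P)`` where the low-pass subband DFT is
    ``concat(X[:N0//2+1], X[N-N0//2+1:]) * g0`` and the high-pass subband DFT
    is ``X[P:P+N1] * g1`` (P the pass-band edge).  ``g0**2 + g1**2 == 1`` on
    the shared transition band, which is what makes the bank self-inverting.
    """
    P = (N - N1) // 2          # low-pass pass-band edge bin, gain 1 up to here
    T = (N0 + N1 - N) // 2     # transition bins; P + T == N0 // 2
    k = np.arange(1, T)
    t0 = theta(k * np.pi / T) if T > 0 else np.empty(0)
    t1 = theta((T - k) * np.pi / T) if T > 0 else np.empty(0)

    g0 = np.zeros(N0)
    g0[: P + 1] = 1.0
    g0[P + 1 : P + T] = t0
    g0[N0 // 2] = 0.0
    g0[N0 // 2 + 1 :] = g0[1 : N0 // 2][::-1]  # conjugate-symmetric mirror

    g1 = np.zeros(N1)
    g1[1:T] = t1
    g1[T : N1 - T + 1] = 1.0
    if T > 1:
        g1[N1 - T + 1 :] = t1[::-1]
    return g0, g1, P


def _analysis_stage(X: np.ndarray, N0: int, N1: int) -> tuple[np.ndarray, np.ndarray]:
    N = len(X)
    g0, g1, P = _stage_windows(N, N0, N1)
    V0 = np.concatenate([X[: N0 // 2 + 1], X[N - N0 // 2 + 1 :]]) * g0
    V1 = X[P : P + N1] * g1
    return V0, V1


def _synthesis_stage(V0: np.ndarray, V1: np.ndarray, N: int) -> np.ndarray:
    N0, N1 = len(V0), len(V1)
    g0, g1, P = _stage_windows(N, N0, N1)
    Y = np.zeros(N, dtype=complex)
    Y[P : P + N1] += V1 * g1
    Y[: N0 // 2 + 1] += V0[: N0 // 2 + 1] * g0[: N0 // 2 + 1]
    Y[N - N0 // 2 + 1 :] += V0[N0 // 2 + 1 :] * g0[N0 // 2 + 1 :]
    return Y


def _padded_length(n: int) -> int:
    return 1 << int(np.ceil(np.log2(n)))


def decompose(signal, params: TQWTParams, fs: float | None = None) -> SubbandSet:
    """Analyze a signal into J detail subbands plus one approximation.

    Accepts a :class:`~eegfocus.preprocess.Signal` or a plain 1-D array.
    The transform is energy-normalized (a tight frame): the sum of subband
    energies equals the signal energy.
    """
    if isinstance(signal, Signal):
        x = signal.samples
        fs = signal.fs if fs is None else fs
    else:
        x = np.asarray(signal, dtype=float)
        fs = 512.0 if fs is None else fs
    if x.ndim != 1:
        raise ValueError("decompose expects a one-dimensional signal")
    n = len(x)
    jmax = max_levels(n, params.Q, params.r)
    if params.J > jmax:
        raise TQWTDesignError(
            f"J={params.J} exceeds max_levels={jmax} for n={n}, "
            f"Q={params.Q}, r={params.r}"
        )
    N = _padded_length(n)
    xp = np.zeros(N)
    xp[:n] = x
    X = np.fft.fft(xp) / np.sqrt(N)

    details: list[np.ndarray] = []
    for _ in range(params.J):
        N0, N1 = _stage_lengths(len(X), params.alpha, params.beta)
        X, V1 = _analysis_stage(X, N0, N1)
        details.append(np.fft.ifft(V1).real * np.sqrt(N1))
    approximation = np.fft.ifft(X).real * np.sqrt(len(X))
    return SubbandSet(
        details=details,
        approximation=approximation,
        params=params,
        n_original=n,
        fs=fs,
    )


def reconstruct(subbands: SubbandSet) -> Signal:
    """Invert :func:`decompose`; returns a signal of the original length.

    Subbands may be modified (e.g. details zeroed) before reconstruction;
    the inverse bank then returns the corresponding band-limited signal.
    """
    params = subbands.params
    if len(subbands.details) != params.J:
        raise ValueError(
            f"expected {params.J} detail subbands, got {len(subbands.details)}"
        )
    N = _padded_length(subbands.n_original)
    # Recompute the per-stage lengths of the analysis cascade.
    lengths = [N]
    for _ in range(params.J):
        N0, N1 = _stage_lengths(lengths[-1], params.alpha, params.beta)
        lengths.append(N0)
    expect = len(subbands.approximation)
    if lengths[-1] != expect:
        raise ValueError(
            f"approximation length {expect} inconsistent with params "
            f"(expected {lengths[-1]})"
        )
    X = np.fft.fft(subbands.approximation) / np.sqrt(lengths[-1])
    for j in range(params.J - 1, -1, -1):
        d = subbands.details[j]
        _, N1_expected = _stage_lengths(lengths[j], params.alpha, params.beta)
        if len(d) != N1_expected:
            raise ValueError(
                f"detail {j + 1} has length {len(d)}, expected {N1_expected}"
            )
        V1 = np.fft.fft(d) / np.sqrt(len(d))
        X = _synthesis_stage(X, V1, lengths[j])
    x = np.fft.ifft(X).real * np.sqrt(N)
    return Signal(samples=x[: subbands.n_original], fs=subbands.fs)


def subband_freq(j: int, params: TQWTParams, fs: float) -> tuple[float, float]:
    """Center frequency and bandwidth (Hz) of subband j (1-based).

    Details (j = 1..J) scale geometrically: ``fc = alpha**(j-1)*(2-beta)*fs/4``
    and ``BW = beta*alpha**(j-1)*fs/4``, so ``fc/BW == Q`` for every detail.
    Subband J+1 is the approximation, occupying [0, alpha**J * fs/2].
    """
    if not 1 <= j <= params.J + 1:
        raise IndexError(f"subband index {j} out of range 1..{params.J + 1}")
    a, b = params.alpha, params.beta
    if j <= params.J:
        fc = a ** (j - 1) * (2.0 - b) * fs / 4.0
        bw = b * a ** (j - 1) * fs / 4.0
    else:
        fc = a ** params.J * fs / 4.0
        bw = a ** params.J * fs / 2.0
    return fc, bw


def save_subbands(subbands: SubbandSet, path: str | Path) -> Path:
    """Write one record's subbands plus a small parameter header (.npz)."""
    path = Path(path)
    arrays = {f"detail_{j + 1}": d for j, d in enumerate(subbands.details)}
    arrays["approximation"] = subbands.approximation
    header = np.array(
        [
            subbands.params.Q,
            subbands.params.r,
            subbands.params.J,
            subbands.n_original,
            subbands.fs,
        ]
    )
    np.savez_compressed(path, header=header, **arrays)
    return path


def load_subbands(path: str | Path) -> SubbandSet:
    """Inverse of :func:`save_subbands`."""
    with np.load(path) as data:
        Q, r, J, n_original, fs = data["header"]
        params = design_params(float(Q), float(r), int(J))
        details = [data[f"detail_{j + 1}"] for j in range(int(J))]
        approximation = data["approximation"]
    return SubbandSet(
        details=details,
        approximation=approximation,
        params=params,
        n_original=int(n_original),
        fs=float(fs),
    )
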