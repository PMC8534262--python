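"""Dyadic discrete wavelet decomposition into eight subbands.

Seven cascaded low/high-pass splits (each followed by decimation by two)
turn a signal sampled at fs into seven detail coefficient sets CD_1..CD_7
and one final approximation CA_7.  Each coefficient set is nominally
assigned a dyadic frequency range: detail k covers [fs/2^(k+1), fs/2^k)
and the approximation covers [0, fs/2^8).  At fs = 500 Hz, subbands 1 and
2 (125-250 and 62.5-125 Hz) carry nothing after the 40 Hz low-pass of
preprocessing and are excluded from the feature table.

Default wavelet is Daubechies-4 with periodized boundaries, which makes
the transform exactly orthogonal: coefficient energy equals signal energy
and reconstruction is perfect to rounding error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pywt

from .containers import EpochSet

N_LEVELS = 7
N_SUBBANDS = 8
DISCARDED_SUBBANDS = (1, 2)


@dataclass
class WaveletDecomposition:
    """Coefficients of a 7-level dyadic decomposition.

    details[k-1] holds CD_k, the detail of subband k (k = 1 is the first,
    highest-frequency split); approx holds CA_7 (subband 8).
    """

    details: list[np.ndarray]
    approx: np.ndarray
    wavelet: str
    mode: str
    fs: float
    n_samples: int

    def subband_coeffs(self, index: int) -> np.ndarray:
        """Coefficient array of subband ``index`` (1..8)."""
        if not 1 <= index <= N_SUBBANDS:
            raise ValueError("subband index must be in 1..8")
        return self.approx if index == N_SUBBANDS else self.details[index - 1]

    def _pywt_coeffs(self) -> list[np.ndarray]:
        # pywt order: [cA_L, cD_L, ..., cD_1]
        return [self.approx] + self.details[::-1]

    def reconstruct(self) -> np.ndarray:
        return pywt.waverec(self._pywt_coeffs(), self.wavelet, mode=self.mode)[
            : self.n_samples
        ]


def dwt_decompose(
    signal: np.ndarray,
    fs: float,
    levels: int = N_LEVELS,
    wavelet: str = "db4",
    mode: str = "periodization",
) -> WaveletDecomposition:
    """Multilevel DWT; requires signal length >= 2**levels."""
    x = np.asarray(signal, dtype=float)
    if x.ndim != 1:
        raise ValueError("signal must be 1-D")
    if x.size < 2**levels:
        raise ValueError(
            f"signal of length {x.size} too short for {levels} levels "
            f"(needs >= {2**levels})"
        )
    import warnings

    with warnings.catch_warnings():
        # pywt warns when levels exceed its conservative heuristic; depth 7
        # on 1 s epochs is the intended decomposition
        warnings.simplefilter("ignore", UserWarning)
        coeffs = pywt.wavedec(x, wavelet, mode=mode, level=levels)
    return WaveletDecomposition(
        details=coeffs[1:][::-1],
        approx=coeffs[0],
        wavelet=wavelet,
        mode=mode,
        fs=fs,
        n_samples=x.size,
    )


def nominal_band_edges(fs: float, subband_index: int) -> tuple[float, float]:
    """Nominal frequency range of a subband, truncated to one decimal.

    Details k = 1..7 cover [fs/2^(k+1), fs/2^k); subband 8 (approximation)
    covers [0, fs/2^8).  Edges are truncated (not rounded) to one decimal,
    matching how dyadic edges are conventionally printed (e.g. 500/64 =
    7.8125 -> 7.8).
    """
    if not 1 <= subband_index <= N_SUBBANDS:
        raise ValueError("subband index must be in 1..8")
    if subband_index == N_SUBBANDS:
        lo, hi = 0.0, fs / 2**8
    else:
        lo, hi = fs / 2 ** (subband_index + 1), fs / 2**subband_index
    trunc = lambda v: math.floor(v * 10) / 10  # noqa: E731
    return trunc(lo), trunc(hi)


@dataclass
class SubbandSet:
    """Eight time-domain subband signals reconstructed one at a time."""

    signals: np.ndarray  # [8 x n_samples]
    fs: float
    retained: list[bool] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.retained:
            self.retained = [
                k not in DISCARDED_SUBBANDS for k in range(1, N_SUBBANDS + 1)
            ]


def subband_signals(
    signal: np.ndarray,
    fs: float,
    wavelet: str = "db4",
    mode: str = "periodization",
) -> SubbandSet:
    """Reconstruct each subband separately; the eight signals sum to the input."""
    dec = dwt_decompose(signal, fs, wavelet=wavelet, mode=mode)
    out = np.empty((N_SUBBANDS, dec.n_samples))
    for k in range(1, N_SUBBANDS + 1):
        coeffs = [np.zeros_like(c) for c in dec._pywt_coeffs()]
        # position in pywt list: approx at 0, CD_k at index levels - k + 1
        pos = 0 if k == N_SUBBANDS else N_LEVELS - k + 1
        coeffs[pos] = dec._pywt_coeffs()[pos]
        out[k - 1] = pywt.waverec(coeffs, wavelet, mode=mode)[: dec.n_samples]
    return SubbandSet(signals=out, fs=fs)


def subband_features(
    epochs: EpochSet,
    wavelet: str = "db4",
    mode: str = "periodization",
) -> dict[str, float]:
    """Log-energy of retained subbands (3..8) per channel.

    Per epoch and channel, the coefficient energy of subband k is
    sum(c^2)/n_coeff; energies are averaged over epochs and reported as
    log10(1 + E) (zero signal maps to feature value 0).  Feature names are
    ``wt|<channel>|sb<k>|logE``; subbands 1-2 are excluded.
    """
    if epochs.n_times < 2**N_LEVELS:
        raise ValueError("epochs too short for a 7-level decomposition")
    retained = [k for k in range(1, N_SUBBANDS + 1) if k not in DISCARDED_SUBBANDS]
    energy = np.zeros((epochs.n_channels, len(retained)))
    for ep in epochs.epochs:
        for ci in range(epochs.n_channels):
            dec = dwt_decompose(ep[ci], epochs.fs, wavelet=wavelet, mode=mode)
            for ki, k in enumerate(retained):
                c = dec.subband_coeffs(k)
                energy[ci, ki] += float(c @ c) / c.size
    energy /= max(epochs.n_epochs, 1)
    row: dict[str, float] = {}
    for ki, k in enumerate(retained):
        for ci, ch in enumerate(epochs.channel_names):
            row[f"wt|{ch}|sb{k}|logE"] = float(np.log10(1.0 + energy[ci, ki]))
    return row
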