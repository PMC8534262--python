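"""Quantitative EEG: DFT-based band power per channel.

The total frequency range is divided into six non-overlapping, half-open
bands: delta [1, 4), theta [4, 8) (also called "ipsilon" in some clinical
reports), alpha [8, 14), beta [14, 30), gamma [30, 45), and an out-of-band
remainder OoB [45, fs/2) kept only as a diagnostic.  Band power is the
integral of a per-epoch Hann periodogram over the band's bins, averaged
over epochs (a Welch-style estimate where the 1 s epochs play the role of
the segments).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .containers import EpochSet

#: Name aliases accepted on input (the 4-8 Hz band is sometimes labeled
#: "ipsilon" in clinical qEEG reports).
BAND_ALIASES = {"ipsilon": "theta"}


@dataclass(frozen=True)
class BandDefinition:
    """A half-open frequency band [lo, hi) in Hz."""

    name: str
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not (0 <= self.lo < self.hi):
            raise ValueError(f"invalid band edges [{self.lo}, {self.hi})")

    def contains(self, freqs: np.ndarray) -> np.ndarray:
        return (freqs >= self.lo) & (freqs < self.hi)


def default_bands(fs: float = 500.0, include_oob: bool = True) -> list[BandDefinition]:
    """The six standard bands; OoB's upper edge is the Nyquist frequency."""
    bands = [
        BandDefinition("delta", 1.0, 4.0),
        BandDefinition("theta", 4.0, 8.0),
        BandDefinition("alpha", 8.0, 14.0),
        BandDefinition("beta", 14.0, 30.0),
        BandDefinition("gamma", 30.0, 45.0),
    ]
    if include_oob:
        bands.append(BandDefinition("oob", 45.0, fs / 2.0))
    return bands


#: The five bands that enter the classifier feature table (OoB excluded:
#: the 40 Hz low-pass in preprocessing empties it).
def classifier_bands() -> list[BandDefinition]:
    return default_bands(include_oob=False)


@dataclass
class Spectrum:
    """Complex DFT of a real signal: X_k = sum_n x_n e^{-2*pi*i*k*n/N}."""

    freqs: np.ndarray
    coeffs: np.ndarray
    N: int
    fs: float


def dft(x: np.ndarray, fs: float) -> Spectrum:
    """Discrete Fourier transform of a real vector.

    Returns all N complex coefficients on the grid f_k = k*fs/N.  The
    inverse transform (numpy ``ifft``) recovers the input to machine
    precision.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size == 0:
        raise ValueError("signal must be a non-empty 1-D vector")
    N = x.size
    coeffs = np.fft.fft(x)
    freqs = np.arange(N) * fs / N
    return Spectrum(freqs=freqs, coeffs=coeffs, N=N, fs=fs)


@dataclass
class SpectralFeatures:
    """Per channel x band power, averaged over epochs.

    absolute is in uV^2 (integral of the PSD over the band); relative is
    the fraction of total power over the delta..gamma range [1, 45) Hz.
    """

    channel_names: list[str]
    band_names: list[str]
    absolute: np.ndarray  # [channels x bands]
    relative: np.ndarray  # [channels x bands]

    def feature_row(
        self,
        include: tuple[str, ...] = ("rel", "logabs"),
        exclude_oob: bool = True,
    ) -> dict[str, float]:
        """Flatten into named features ``qeeg|<channel>|<band>|<abs|rel>``.

        ``logabs`` emits log10 absolute power under the ``abs`` tag.
        """
        row: dict[str, float] = {}
        for bi, band in enumerate(self.band_names):
            if exclude_oob and band == "oob":
                continue
            for ci, ch in enumerate(self.channel_names):
                if "rel" in include:
                    row[f"qeeg|{ch}|{band}|rel"] = float(self.relative[ci, bi])
                if "logabs" in include:
                    row[f"qeeg|{ch}|{band}|abs"] = float(
                        np.log10(self.absolute[ci, bi] + 1e-12)
                    )
                elif "abs" in include:
                    row[f"qeeg|{ch}|{band}|abs"] = float(self.absolute[ci, bi])
        return row


def band_power(
    epochs: EpochSet,
    bands: list[BandDefinition] | None = None,
    window: str = "hann",
) -> SpectralFeatures:
    """Band power per channel, averaged over epochs.

    Per epoch and channel a periodogram with the given window is computed
    (density scaling, so that the integral over a band estimates the signal
    variance contributed by that band, in uV^2); band power is the PSD
    summed over the bins whose frequency falls in the half-open band and
    multiplied by the bin width.  Epoch length must be at least one second
    so the 1 Hz band edges are resolved.
    """
    if epochs.n_epochs == 0:
        raise ValueError("empty epoch set")
    if bands is None:
        bands = default_bands(epochs.fs)
    nyq = epochs.fs / 2.0
    for b in bands:
        if b.lo >= nyq:
            raise ValueError(f"band {b.name} starts at/above Nyquist")
    if epochs.n_times < epochs.fs:
        raise ValueError("epoch shorter than 1 s: band edges unresolvable")

    freqs, psd = sps.periodogram(
        epochs.epochs, fs=epochs.fs, window=window, scaling="density", axis=-1
    )
    psd = psd.mean(axis=0)  # [channels x freqs]
    df = freqs[1] - freqs[0]

    absolute = np.empty((epochs.n_channels, len(bands)))
    for bi, b in enumerate(bands):
        mask = b.contains(freqs)
        absolute[:, bi] = psd[:, mask].sum(axis=1) * df

    core = [i for i, b in enumerate(bands) if b.name != "oob"]
    total = absolute[:, core].sum(axis=1, keepdims=True)
    total = np.where(total > 0, total, 1.0)
    relative = absolute / total
    return SpectralFeatures(
        channel_names=list(epochs.channel_names),
        band_names=[b.name for b in bands],
        absolute=absolute,
        relative=relative,
    )
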