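"""Synthetic resting-state EEG cohorts with known ground truth.

Emulates the statistical structure the downstream analysis assumes for a
four-group cohort (controls CG plus the nfvPPA / svPPA / lvPPA variants of
primary progressive aphasia):

* a 1/f (pink) background plus band-limited oscillatory power, with
  group-specific mean log-power per band (patients: theta up, alpha down
  relative to controls, the slowing pattern reported clinically);
* group-specific cross-channel dependence, planted as a latent precision
  matrix: channels are unit-variance sources mixed through the Cholesky
  factor of the implied covariance, so the empirical partial-correlation
  matrix of a long recording converges to a configured truth;
* nuisance components removed by preprocessing: 50 Hz line noise,
  low-frequency drift, and stereotyped frontal blink transients.

Band oscillators are realized as narrowband Gaussian processes (spectral
shaping of white noise), i.e. randomly amplitude- and phase-modulated
sinusoids; this keeps every per-band power exactly calibrated, so planted
group effects can be recovered without bias.  The mixing matrix rows are
unit-normalized: partial correlation is invariant under per-channel
scaling, hence both the connectivity truth and the per-channel band
powers hold simultaneously.  All signals are in microvolts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .channels import FRONTAL, default_channel_names
from .containers import Recording
from .spectral import classifier_bands

GROUPS = ("CG", "nfvPPA", "svPPA", "lvPPA")

#: Study-sized cohort: 20 controls and 40 patients (18/10/12 by variant).
DEFAULT_GROUP_SIZES = {"CG": 20, "nfvPPA": 18, "svPPA": 10, "lvPPA": 12}

BAND_NAMES = ("delta", "theta", "alpha", "beta", "gamma")

#: Mean log10 band power (uV^2) for controls; a plausible resting-state
#: profile with prominent alpha and delta.
CG_BAND_PROFILE = {"delta": 1.4, "theta": 1.0, "alpha": 1.4, "beta": 0.9, "gamma": 0.4}

#: Patient deviations from the control profile: theta increase and alpha
#: decrease, with mild variant-specific differences so the four-class
#: problem is not degenerate.
PATIENT_SHIFTS = {
    "nfvPPA": {"theta": +0.5, "alpha": -0.4},
    "svPPA": {"theta": +0.3, "alpha": -0.5},
    "lvPPA": {"theta": +0.4, "alpha": -0.3},
}


def default_band_power_profile() -> dict[str, dict[str, float]]:
    prof = {"CG": dict(CG_BAND_PROFILE)}
    for g, shifts in PATIENT_SHIFTS.items():
        p = dict(CG_BAND_PROFILE)
        for band, d in shifts.items():
            p[band] += d
        prof[g] = p
    return prof


def ring_precision(n_channels: int, rho: float = 0.25) -> np.ndarray:
    """Precision of a ring lattice (each channel tied to its 2 neighbours).

    The implied latent graph has no triangles (low clustering)."""
    P = np.eye(n_channels)
    for i in range(n_channels):
        P[i, (i + 1) % n_channels] = P[(i + 1) % n_channels, i] = rho
    _check_spd(P)
    return P


def block_precision(
    n_channels: int, block_size: int = 4, rho: float = 0.25
) -> np.ndarray:
    """Precision of disjoint fully-connected blocks (clique graph).

    The latent graph is a union of cliques (maximal clustering)."""
    P = np.eye(n_channels)
    for start in range(0, n_channels - block_size + 1, block_size):
        idx = np.arange(start, start + block_size)
        for i in idx:
            for j in idx:
                if i != j:
                    P[i, j] = rho
    _check_spd(P)
    return P


def default_connectivity_profile(n_channels: int) -> dict[str, np.ndarray]:
    """Controls: sparse triangle-free ring; patients: clique blocks."""
    prof = {"CG": ring_precision(n_channels)}
    for g in ("nfvPPA", "svPPA", "lvPPA"):
        prof[g] = block_precision(n_channels)
    return prof


def _check_spd(P: np.ndarray) -> None:
    P = np.asarray(P, dtype=float)
    if P.ndim != 2 or P.shape[0] != P.shape[1]:
        raise ValueError("precision matrix must be square")
    if not np.allclose(P, P.T, atol=1e-10):
        raise ValueError("precision matrix must be symmetric")
    try:
        np.linalg.cholesky(P)
    except np.linalg.LinAlgError as err:
        raise ValueError("precision matrix is not positive definite") from err


@dataclass
class ArtifactRates:
    """Nuisance-component intensities (all can be zeroed)."""

    blink_per_min: float = 10.0
    drift_uV: float = 20.0
    line_uV: float = 10.0


@dataclass
class CohortSpec:
    """Full description of a synthetic cohort."""

    group_sizes: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_SIZES)
    )
    n_channels: int = 32
    fs: float = 500.0
    duration: float = 1200.0
    band_power_profile: dict[str, dict[str, float]] | None = None
    connectivity_profile: dict[str, np.ndarray] | None = None
    artifact_rates: ArtifactRates = field(default_factory=ArtifactRates)
    background_power: float = 5.0  # total pink-noise power, uV^2
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n < 0 for n in self.group_sizes.values()):
            raise ValueError("group sizes must be non-negative")
        if self.band_power_profile is None:
            self.band_power_profile = default_band_power_profile()
        if self.connectivity_profile is None:
            self.connectivity_profile = default_connectivity_profile(self.n_channels)
        top = max(b.hi for b in classifier_bands())
        if self.fs <= 2 * top:
            raise ValueError(
                f"fs = {self.fs} must exceed twice the highest band edge ({top} Hz)"
            )
        for g in self.group_sizes:
            if g not in self.band_power_profile:
                raise ValueError(f"no band-power profile for group {g!r}")
            if g not in self.connectivity_profile:
                raise ValueError(f"no connectivity profile for group {g!r}")
        for g, P in self.connectivity_profile.items():
            P = np.asarray(P, dtype=float)
            if P.shape != (self.n_channels, self.n_channels):
                raise ValueError(f"precision matrix for {g} has wrong shape")
            _check_spd(P)
            self.connectivity_profile[g] = P

    @property
    def groups(self) -> list[str]:
        return list(self.group_sizes)

    @property
    def channel_names(self) -> list[str]:
        return default_channel_names(self.n_channels)


@dataclass
class GroundTruth:
    """What the generator planted, for recovery tests."""

    subjects: list[tuple[str, str]]  # (subject_id, group)
    band_power: dict[str, dict[str, float]]  # group -> band -> log10 power
    partial_corr: dict[str, np.ndarray]  # group -> [channels x channels]
    channel_names: list[str]

    def labels(self) -> dict[str, str]:
        return dict(self.subjects)

    def to_json(self) -> str:
        return json.dumps(
            {
                "subjects": self.subjects,
                "band_power": self.band_power,
                "partial_corr": {g: m.tolist() for g, m in self.partial_corr.items()},
                "channel_names": self.channel_names,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        d = json.loads(text)
        return cls(
            subjects=[tuple(s) for s in d["subjects"]],
            band_power=d["band_power"],
            partial_corr={g: np.array(m) for g, m in d["partial_corr"].items()},
            channel_names=d["channel_names"],
        )


def truth_partial_corr(P: np.ndarray) -> np.ndarray:
    """Partial correlation implied by a precision matrix, diagonal zeroed."""
    d = np.sqrt(np.diag(P))
    pc = -P / np.outer(d, d)
    np.fill_diagonal(pc, 0.0)
    return pc


def _source_psd(spec: CohortSpec, group: str, freqs: np.ndarray) -> np.ndarray:
    """One-sided PSD (uV^2/Hz) shared by every latent source of a group."""
    df = freqs[1] - freqs[0]
    raw = np.zeros_like(freqs)
    pos = freqs > 0
    raw[pos] = 1.0 / np.maximum(freqs[pos], 1.0)
    psd = raw * (spec.background_power / (raw.sum() * df))
    profile = spec.band_power_profile[group]
    for band in classifier_bands():
        if band.name not in profile:
            continue
        mask = band.contains(freqs)
        if not mask.any():
            continue
        target = 10.0 ** profile[band.name]
        pink_here = psd[mask].sum() * df
        extra = target - pink_here
        if extra > 0:
            psd[mask] += extra / (mask.sum() * df)
    return psd


def generate_recording(
    spec: CohortSpec, group: str, subject_seed: int
) -> Recording:
    """One synthetic recording; deterministic given (spec.seed, subject_seed)."""
    if group not in spec.group_sizes:
        raise ValueError(f"unknown group label {group!r}")
    n = int(round(spec.duration * spec.fs))
    if n < 1:
        raise ValueError("duration * fs must be >= 1")
    rng = np.random.default_rng([spec.seed, subject_seed])

    freqs = np.fft.rfftfreq(n, 1.0 / spec.fs)
    psd = _source_psd(spec, group, freqs) if n > 1 else np.zeros_like(freqs)
    amp = np.sqrt(psd * spec.fs * n / 2.0)
    z = rng.standard_normal((spec.n_channels, freqs.size)) * (1 / np.sqrt(2))
    z = z + 1j * rng.standard_normal((spec.n_channels, freqs.size)) * (1 / np.sqrt(2))
    sources = np.fft.irfft(amp * z, n=n, axis=1)

    P = spec.connectivity_profile[group]
    L = np.linalg.cholesky(np.linalg.inv(P))
    L = L / np.linalg.norm(L, axis=1, keepdims=True)
    data = L @ sources

    t = np.arange(n) / spec.fs
    ar = spec.artifact_rates
    if ar.line_uV > 0 and 50.0 < spec.fs / 2:
        phase = rng.uniform(0, 2 * np.pi)
        amps = ar.line_uV * rng.uniform(0.8, 1.2, spec.n_channels)
        data += amps[:, None] * np.sin(2 * np.pi * 50.0 * t + phase)
    if ar.drift_uV > 0:
        for ci in range(spec.n_channels):
            a = ar.drift_uV * rng.uniform(0.5, 1.5)
            fd = rng.uniform(0.05, 0.3)
            data[ci] += a * np.sin(2 * np.pi * fd * t + rng.uniform(0, 2 * np.pi))
    names = spec.channel_names
    if ar.blink_per_min > 0:
        weights = np.array(
            [
                1.0 if ch in ("Fp1", "Fp2") else (0.6 if ch in FRONTAL else 0.05)
                for ch in names
            ]
        )
        n_blinks = rng.poisson(ar.blink_per_min * spec.duration / 60.0)
        wlen = int(round(0.3 * spec.fs))
        if wlen >= 2:
            tw = np.arange(wlen) / spec.fs
            shape = np.sin(2 * np.pi * tw / 0.3) * np.hanning(wlen)
            for _ in range(n_blinks):
                start = rng.integers(0, max(n - wlen, 1))
                a = 120.0 * rng.uniform(0.8, 1.2)
                data[:, start : start + wlen] += a * np.outer(weights, shape)

    return Recording(
        channel_names=names,
        fs=spec.fs,
        data=data,
        reference="A1",
        subject_id=f"sub{subject_seed:03d}",
        group=group,
    )


def generate_cohort(spec: CohortSpec) -> tuple[list[Recording], GroundTruth]:
    """One recording per subject plus the planted ground truth."""
    recordings: list[Recording] = []
    subjects: list[tuple[str, str]] = []
    idx = 0
    for group, size in spec.group_sizes.items():
        for _ in range(size):
            rec = generate_recording(spec, group, subject_seed=idx)
            recordings.append(rec)
            subjects.append((rec.subject_id, group))
            idx += 1
    truth = GroundTruth(
        subjects=subjects,
        band_power={g: dict(spec.band_power_profile[g]) for g in spec.group_sizes},
        partial_corr={
            g: truth_partial_corr(spec.connectivity_profile[g])
            for g in spec.group_sizes
        },
        channel_names=spec.channel_names,
    )
    return recordings, truth
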