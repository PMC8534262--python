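import numpy as np
import pytest

from ppaeeg import synthdata as sd
from ppaeeg.containers import EpochSet, Recording


@pytest.fixture(scope="session")
def small_spec():
    """A short four-group cohort spec used across tests."""
    return sd.CohortSpec(
        group_sizes={"CG": 2, "nfvPPA": 2, "svPPA": 2, "lvPPA": 2},
        duration=20.0,
        seed=7,
    )


@pytest.fixture(scope="session")
def clean_recording():
    """One artifact-free 60 s control recording."""
    spec = sd.CohortSpec(
        group_sizes={"CG": 1},
        duration=60.0,
        band_power_profile={"CG": dict(sd.CG_BAND_PROFILE)},
        connectivity_profile={"CG": sd.ring_precision(32)},
        artifact_rates=sd.ArtifactRates(0, 0, 0),
        seed=3,
    )
    return sd.generate_recording(spec, "CG", 0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_epochs(data: np.ndarray, fs: float = 500.0, subject="s0", group="CG"):
    """Wrap a [n_epochs x channels x times] array as an EpochSet."""
    n_ch = data.shape[1]
    from ppaeeg.channels import default_channel_names

    return EpochSet(
        epochs=data,
        fs=fs,
        channel_names=default_channel_names(n_ch),
        subject_id=subject,
        group=group,
    )


def make_recording(data: np.ndarray, fs: float = 500.0, **kw) -> Recording:
    from ppaeeg.channels import default_channel_names

    return Recording(
        channel_names=default_channel_names(data.shape[0]), fs=fs, data=data, **kw
    )
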