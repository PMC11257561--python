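import numpy as np
import pytest

from ifkit import charge, synth


@pytest.fixture(scope="session")
def vimentin_seq() -> str:
    return charge.ProteinSpecies.from_fasta(charge.bundled_fasta("P08670")).sequence


@pytest.fixture(scope="session")
def gfap_seq() -> str:
    return charge.ProteinSpecies.from_fasta(charge.bundled_fasta("P14136")).sequence


@pytest.fixture
def settings() -> synth.AcquisitionSettings:
    return synth.AcquisitionSettings(dt=1e-3, sigma_loc=0.02, capture_radius=0.8, seed=1)


@pytest.fixture
def noiseless_settings() -> synth.AcquisitionSettings:
    return synth.AcquisitionSettings(dt=1e-3, sigma_loc=0.0, capture_radius=0.8, seed=1)


@pytest.fixture
def uniform_field() -> synth.DiffusivityField:
    shape = (32, 32)
    return synth.DiffusivityField(
        D=np.full(shape, 7.0),
        filament_mask=np.zeros(shape, dtype=bool),
        bound_fraction=0.0,
        bin_size=0.4,
    )


@pytest.fixture
def two_region_field() -> synth.DiffusivityField:
    """Left half slow (1.5), right half fast (7.0); mask = slow region."""
    shape = (32, 32)
    mask = np.zeros(shape, dtype=bool)
    mask[:, :16] = True
    return synth.DiffusivityField(
        D=np.where(mask, 1.5, 7.0).astype(float),
        filament_mask=mask,
        bound_fraction=0.5,
        bin_size=0.4,
    )
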