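import pytest

from tetherdrive.dynamics import FitnessModel
from tetherdrive.genetics import DriveParams, HomingLocusRule


@pytest.fixture(scope="session")
def measured_params() -> DriveParams:
    """TARE-only configuration at the measured cleavage rates."""
    return DriveParams.tare_only(0.888, 0.632)


@pytest.fixture(scope="session")
def measured_fitness() -> FitnessModel:
    """Estimated codominant multiplicative homozygote fitness, both sexes."""
    return FitnessModel(f_hom=0.867)


@pytest.fixture(scope="session")
def tethered_params() -> DriveParams:
    """Two-locus configuration with a haplolethal-rescue homing element."""
    return DriveParams(
        c_germ_tare=0.888,
        c_embryo_tare=0.632,
        homing_germ_cut=0.9,
        homing_conversion_frac=0.7,
        c_embryo_homing=0.3,
        homing_locus_rule=HomingLocusRule.HAPLOLETHAL_RESCUE,
    )
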