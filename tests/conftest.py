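import numpy as np
import pytest

from cellshift import SimConfig, simulate_plate
from cellshift.simulate import HazardParams


@pytest.fixture(scope="session")
def small_config():
    """Reduced plate for structural tests: 2 doses x 2 wells + 4 controls."""
    return SimConfig(
        doses=(4.0, 32.0),
        wells_per_dose=2,
        control_wells=4,
        cells_per_well_range=(30, 50),
        n_timepoints=24,
        master_seed=7,
    )


@pytest.fixture(scope="session")
def small_plate(small_config):
    return simulate_plate(small_config)


@pytest.fixture(scope="session")
def default_plate():
    """Full study-design plate (6 doses x 6 wells + 36 controls, 48 h)."""
    return simulate_plate(SimConfig(master_seed=1))


@pytest.fixture()
def noiseless_config():
    """Deterministic intensities, no control shifting: latent truth is exact."""
    return SimConfig(
        doses=(8.0,),
        wells_per_dose=2,
        control_wells=2,
        cells_per_well_range=(40, 40),
        n_timepoints=24,
        intensity_sd_log2=0.0,
        control_hazard=0.0,
        master_seed=3,
    )


def constant_hazard_config(p_per_hour: float, **kw):
    """Config whose drug wells shift with a constant per-hour probability."""
    rate = -np.log1p(-min(p_per_hour, 1 - 1e-15))  # p=1 maps to a huge rate
    hp = HazardParams(
        gamma_plateau=rate,
        ec50_uM=1e-9,  # saturate the dose response
        hill=1.0,
        onset_h=-1e3,  # saturate the onset logistic
        onset_width_h=1.0,
    )
    defaults = dict(
        doses=(10.0,),
        wells_per_dose=1,
        control_wells=1,
        cells_per_well_range=(200, 200),
        n_timepoints=24,
        hazard_params=hp,
        control_hazard=0.0,
        intensity_sd_log2=0.0,
    )
    defaults.update(kw)
    return SimConfig(**defaults)
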