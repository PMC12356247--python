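import numpy as np
import pytest

from srnmr import AcqParams, build_schedule, generate_shift_table

HNCA = dict(j_hz=35.0, delta_a_s=10e-6, delta_b_s=2e-3, t1_max_s=38e-3,
            n_increments=200, base_scans=4)
HSQC = dict(j_hz=38.0, delta_a_s=1e-3, delta_b_s=3e-3, t1_max_s=33e-3,
            n_increments=960, base_scans=4)


@pytest.fixture(scope="session")
def hnca_params():
    return AcqParams(**HNCA)


@pytest.fixture(scope="session")
def hsqc_params():
    return AcqParams(**HSQC)


@pytest.fixture(scope="session")
def hnca_sr_schedule(hnca_params):
    return build_schedule(hnca_params, "SR")


@pytest.fixture(scope="session")
def hsqc_sr_schedule(hsqc_params):
    return build_schedule(hsqc_params, "SR")


@pytest.fixture(scope="session")
def small_sr_schedule():
    """Coarse SR schedule for Monte-Carlo noise tests."""
    return build_schedule(
        AcqParams(j_hz=35.0, delta_a_s=10e-6, delta_b_s=2e-3, t1_max_s=38e-3,
                  n_increments=24, base_scans=4),
        "SR",
    )


@pytest.fixture(scope="session")
def six_residue_table():
    """Clean 6-residue table, no proline, distinct types."""
    return generate_shift_table("MQIFVK", dispersion_scale=1.0, seed=7)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
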