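import numpy as np
import pytest

import stafkit as sk


@pytest.fixture(scope="session")
def geometry():
    return sk.DisplayGeometry()


@pytest.fixture(scope="session")
def m7_pair():
    """Two distinct order-7 m-sequences from the built-in table."""
    return (sk.generate_msequence(7, sk.builtin_taps(7, 0)),
            sk.generate_msequence(7, sk.builtin_taps(7, 1)))


@pytest.fixture(scope="session")
def uniform_plant(geometry):
    """Noiseless plant with azimuth-constant ground truth (exactness tests)."""
    em, fm = sk.make_ground_truth_stafs(geometry, uniform_azimuth=True)
    return sk.PlantModel(staf_em_true=em, staf_fm_true=fm, noise_sigma=0.0)


@pytest.fixture(scope="session")
def shaped_plant(geometry):
    """Noiseless plant with the realistic frontal/center-surround shapes."""
    em, fm = sk.make_ground_truth_stafs(geometry)
    return sk.PlantModel(staf_em_true=em, staf_fm_true=fm, noise_sigma=0.0)


@pytest.fixture(scope="session")
def paired_uniform_run(geometry, m7_pair, uniform_plant):
    """One noiseless (+m_EM, -m_EM) protocol pair at front center."""
    m_fm, m_em = m7_pair
    real_p = sk.build_compound_protocol(m_fm, m_em, 1, 0.0, geometry,
                                        n_periods=4)
    real_m = sk.build_compound_protocol(m_fm, m_em, -1, 0.0, geometry,
                                        n_periods=4)
    y1 = sk.simulate_response(uniform_plant, real_p, geometry, noiseless=True)
    y2 = sk.simulate_response(uniform_plant, real_m, geometry, noiseless=True)
    return {"real_p": real_p, "real_m": real_m, "y1": y1, "y2": y2}
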